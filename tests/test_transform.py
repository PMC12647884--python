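"""Law responses, two-stage pooling, feature assembly and persistence."""

import numpy as np
import pytest

from lawtime import (ALTModel, LawDictionary, LTSplitConfig, PoolingSpec,
                     PoolingError, Schedule, SinusoidClass, SyntheticSpec,
                     TransformError, build_row_embeddings,
                     generate_recurrence_dataset, law_responses,
                     pool_across_laws, pool_across_windows, validate_triplet)
from lawtime.transform import ResponseMatrix, feature_names
from tests.conftest import random_dataset, random_valid_triplet


def make_dictionary(P, pi, trip=None, channel=0):
    trip = trip or validate_triplet(5, 3, 1)
    return LawDictionary(P=np.asarray(P, dtype=float),
                         pi=np.asarray(pi, dtype=np.intp),
                         channel=channel, triplet=trip)


class TestLawResponses:
    def test_identity_projection(self):
        trip = validate_triplet(5, 3, 1)
        A = build_row_embeddings(np.arange(10.0), trip)
        D = make_dictionary([[1.0], [0.0], [0.0]], [1], trip)
        M = law_responses(A, D)
        assert np.array_equal(M.M[:, 0], A.values[:, 0])

    def test_shape(self, rng):
        trip = validate_triplet(5, 3, 1)
        A = rng.normal(size=(3, 3))
        D = make_dictionary(rng.normal(size=(3, 6)), [1, 1, 2, 2, 1, 2], trip)
        assert law_responses(A, D).M.shape == (3, 6)

    def test_own_frequency_annihilation(self):
        """Laws from a sinusoid annihilate same-frequency rows anywhere."""
        from lawtime import build_embedding_matrix, extract_law

        amp, omega = 4.0, 0.7
        x = amp * np.sin(omega * np.arange(300) + 1.234)
        trip = validate_triplet(5, 3, 1)
        law = extract_law(build_embedding_matrix(x, 42, trip))
        D = make_dictionary(law.v[:, None], [1], trip)
        z = amp * np.sin(omega * np.arange(200) + 2.5)  # other phase
        M = law_responses(build_row_embeddings(z, trip), D)
        assert np.max(np.abs(M.M)) <= 1e-6 * amp

    def test_dimension_mismatch(self, rng):
        D = make_dictionary(rng.normal(size=(3, 2)), [1, 2])
        with pytest.raises(TransformError):
            law_responses(rng.normal(size=(4, 4)), D)

    def test_matches_naive_double_loop(self, rng):
        A = rng.normal(size=(7, 4))
        trip = validate_triplet(7, 4, 1)
        P = rng.normal(size=(4, 9))
        D = make_dictionary(P, rng.integers(1, 3, size=9), trip)
        M = law_responses(A, D).M
        naive = np.array([[sum(A[u, q] * P[q, a] for q in range(4))
                           for a in range(9)] for u in range(7)])
        assert np.allclose(M, naive, atol=1e-12)


class TestPoolAcrossLaws:
    def resp(self, M, pi):
        return ResponseMatrix(M=np.asarray(M, dtype=float),
                              channel=0, triplet=validate_triplet(5, 3, 1),
                              pi=np.asarray(pi, dtype=np.intp))

    def test_mean_of_squares(self):
        M = self.resp([[1.0, -2.0, 3.0]], [1, 1, 1])
        seq = pool_across_laws(M, 1, PoolingSpec("mean", None, "mean"))
        assert np.isclose(seq[0], 14.0 / 3.0)

    def test_quantile_linear_interpolation(self):
        M = self.resp([[1.0, 2.0, 3.0]], [1, 1, 1])  # squares 1, 4, 9
        seq = pool_across_laws(M, 1, PoolingSpec("quantile", 0.05, "mean"))
        assert np.isclose(seq[0], 1.3)  # position 0.05*(3-1) between 1 and 4

    def test_single_matching_column(self):
        M = self.resp([[2.0, 5.0], [3.0, 7.0]], [1, 2])
        seq = pool_across_laws(M, 2, PoolingSpec("mean", None, "mean"))
        assert np.allclose(seq, [25.0, 49.0])

    def test_no_matching_columns(self):
        M = self.resp([[1.0]], [1])
        with pytest.raises(PoolingError):
            pool_across_laws(M, 3, PoolingSpec())


class TestPoolAcrossWindows:
    def test_variance_of_constant(self):
        assert pool_across_windows([1.0, 1.0, 1.0],
                                   PoolingSpec("mean", None, "variance")) == 0.0

    def test_fourth_central_moment(self):
        assert pool_across_windows([0.0, 2.0],
                                   PoolingSpec("mean", None, "m4")) == 1.0

    def test_excess_kurtosis_degenerate_rule(self):
        assert pool_across_windows([3.0] * 5,
                                   PoolingSpec("mean", None,
                                               "excess_kurtosis")) == 0.0

    def test_population_moments(self, rng):
        seq = rng.normal(size=50) ** 2
        mu = seq.mean()
        assert np.isclose(
            pool_across_windows(seq, PoolingSpec("mean", None, "variance")),
            np.mean((seq - mu) ** 2))
        assert np.isclose(
            pool_across_windows(seq, PoolingSpec("mean", None, "m3")),
            np.mean((seq - mu) ** 3))

    def test_empty_sequence(self):
        with pytest.raises(PoolingError):
            pool_across_windows([], PoolingSpec())


class TestPoolingSpec:
    @pytest.mark.parametrize("text,laws,q,windows", [
        ("mean-mean", "mean", None, "mean"),
        ("p05-variance", "quantile", 0.05, "variance"),
        ("p05-m4", "quantile", 0.05, "m4"),
        ("p50-excess_kurtosis", "quantile", 0.50, "excess_kurtosis"),
    ])
    def test_round_trip_names(self, text, laws, q, windows):
        spec = PoolingSpec.from_string(text)
        assert (spec.across_laws, spec.q, spec.across_windows) == (laws, q, windows)
        assert spec.name == text

    def test_invalid(self):
        with pytest.raises(PoolingError):
            PoolingSpec("quantile", 1.5, "mean")
        with pytest.raises(PoolingError):
            PoolingSpec("mean", None, "median")


class TestTransform:
    def fit_model(self, ds, schedule=None, specs=None, rho=0.5, seed=0):
        return ALTModel.fit(ds, schedule or Schedule([(5, 3, 1)]),
                            specs or [PoolingSpec()],
                            LTSplitConfig(rho=rho, seed=seed))

    def test_feature_length_formula(self, rng):
        for _ in range(100):
            n_trip = int(rng.integers(1, 4))
            triplets = []
            while len(triplets) < n_trip:
                t = random_valid_triplet(rng, l_max=5, s_max=2)
                if all((t.r, t.l, t.k) != (u.r, u.l, u.k) for u in triplets):
                    triplets.append(t)
            sched = Schedule(triplets)
            m = int(rng.integers(1, 4))
            c = int(rng.integers(2, 5))
            n = int(rng.integers(1, 4))
            specs = [PoolingSpec("quantile", round(0.05 * (i + 1), 2), "mean")
                     for i in range(n)]
            names = feature_names(sched, m, c, specs)
            assert len(names) == len(sched) * m * c * n
            assert len(set(names)) == len(names)

    def test_worked_feature_count(self, rng):
        # one triplet, 4 classes, 6 channels, 2 pooling pairs -> 48
        ds = random_dataset(rng, n_classes=4, per_class=4, m=6, h=60)
        model = self.fit_model(
            ds, specs=[PoolingSpec("mean", None, "mean"),
                       PoolingSpec("quantile", 0.05, "m4")])
        assert model.n_features == 48
        feats = model.transform(ds)
        assert feats.values.shape == (ds.n_instances, 48)
        assert np.all(np.isfinite(feats.values))

    def test_determinism(self, rng):
        ds = random_dataset(rng)
        model = self.fit_model(ds)
        a = model.transform(ds).values
        b = model.transform(ds).values
        assert np.array_equal(a, b)

    def test_lt_instance_transforms_cleanly(self, rng):
        ds = random_dataset(rng)
        model = self.fit_model(ds)
        v = model.transform_instance(ds.instances[int(model.lt_ids[0])])
        assert np.all(np.isfinite(v))

    def test_too_short_instance_names_triplet(self, rng):
        ds = random_dataset(rng, h=40)
        model = self.fit_model(ds, schedule=Schedule([(33, 17, 1)]))
        with pytest.raises(TransformError, match="r=33"):
            model.transform_instance(np.zeros((1, 20)))

    def test_positive_scaling_covariance(self, rng):
        """Scaling inputs by a>0: laws unchanged, mean-of-squares x a^2,
        their variance x a^4, excess kurtosis invariant."""
        alpha = 3.0
        ds = random_dataset(rng, n_classes=2, per_class=4, h=50)
        scaled = ds.copy()
        scaled.instances = [alpha * x for x in scaled.instances]
        specs = [PoolingSpec("mean", None, "mean"),
                 PoolingSpec("mean", None, "variance"),
                 PoolingSpec("mean", None, "excess_kurtosis")]
        m1 = self.fit_model(ds, specs=specs)
        m2 = self.fit_model(scaled, specs=specs)
        for key in m1.dictionaries:
            assert np.allclose(m1.dictionaries[key].P,
                               m2.dictionaries[key].P, atol=1e-9)
        f1 = m1.transform(ds).values
        f2 = m2.transform(scaled).values
        mean_cols = [i for i, n in enumerate(m1.feature_names)
                     if n.endswith("mean-mean")]
        var_cols = [i for i, n in enumerate(m1.feature_names)
                    if n.endswith("mean-variance")]
        kurt_cols = [i for i, n in enumerate(m1.feature_names)
                     if n.endswith("excess_kurtosis")]
        assert np.allclose(f2[:, mean_cols], alpha**2 * f1[:, mean_cols],
                           rtol=1e-8)
        assert np.allclose(f2[:, var_cols], alpha**4 * f1[:, var_cols],
                           rtol=1e-8)
        assert np.allclose(f2[:, kurt_cols], f1[:, kurt_cols],
                           rtol=1e-6, atol=1e-9)

    def test_end_to_end_annihilation_separates_classes(self):
        """Own-class mean-mean features vanish for noiseless recurrence
        classes; cross-class features are strictly larger."""
        amp = 10.0
        spec = SyntheticSpec(
            classes=(SinusoidClass(0.3, amp), SinusoidClass(0.9, amp)),
            n_channels=1, length=100, instances_per_class=6, seed=3)
        ds = generate_recurrence_dataset(spec)
        model = self.fit_model(ds, rho=0.5)
        feats = model.transform(ds)
        own = [feats.names.index("t0_r5_l3_k1|ch0|class1|mean-mean"),
               feats.names.index("t0_r5_l3_k1|ch0|class2|mean-mean")]
        for i in range(ds.n_instances):
            cls = int(ds.labels[i])
            own_val = feats.values[i, own[cls - 1]]
            other_val = feats.values[i, own[2 - cls]]
            assert own_val <= 1e-10 * amp**2
            assert other_val > own_val

    def test_save_load_round_trip(self, rng, tmp_path):
        ds = random_dataset(rng, n_classes=2, per_class=4, m=2, h=50)
        model = self.fit_model(
            ds, schedule=Schedule([(5, 3, 1), (9, 5, 1)]),
            specs=[PoolingSpec(), PoolingSpec("quantile", 0.05, "variance")])
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = ALTModel.load(path)
        assert loaded.feature_names == model.feature_names
        for key in model.dictionaries:
            assert np.array_equal(loaded.dictionaries[key].P,
                                  model.dictionaries[key].P)
            assert np.array_equal(loaded.dictionaries[key].pi,
                                  model.dictionaries[key].pi)
        assert np.array_equal(loaded.transform(ds).values,
                              model.transform(ds).values)
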