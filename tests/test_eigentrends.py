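import numpy as np
import pytest

from circaphase import (
    ExpressionMatrix, anchor_phase_axes, cosine_r2, empirical_component_test,
    projection_kurtosis, randomize_matrix, reconstruction_error, run_ica,
    run_pca, select_circadian_components,
)

T12 = np.arange(12) * 4.0


def _normalized(V, times=None):
    V = np.asarray(V, float)
    V = V - V.mean(axis=1, keepdims=True)
    V = V / V.std(axis=1, keepdims=True)
    times = list(T12[: V.shape[1]]) if times is None else times
    return ExpressionMatrix([f"G{i}" for i in range(V.shape[0])], times, V,
                            normalized=True)


@pytest.fixture(scope="module")
def two_trend_noiseless():
    """400 genes on the two planted orthogonal 24 h profiles at 12 points,
    4 h apart, with only a trace of noise.

    Row standardization maps every gene onto the unit circle of the trend
    plane, so the in-plane rotation is identifiable only through the phase
    distribution; strongly unequal phase-class masses (the midday-dominant
    pattern of real data) make the planted axes the skew-contrast optimum.
    """
    rng = np.random.default_rng(42)
    cos = np.cos(2 * np.pi * T12 / 24)
    sin = np.sin(2 * np.pi * T12 / 24)
    counts = {(0.0, 1.0): 200, (1.0, 0.0): 100, (-1.0, 0.0): 60, (0.0, -1.0): 40}
    rows = []
    for (a, b), n in counts.items():
        amp = rng.uniform(1, 2, size=n)
        rows.append(np.outer(amp * a, cos) + np.outer(amp * b, sin))
    V = np.vstack(rows) + 0.02 * rng.normal(size=(400, 12))
    return _normalized(V)


class TestProjectionKurtosis:
    def test_dense_sinusoid_sample(self):
        # projections distributed like sin(U) have excess kurtosis -1.5
        u = np.linspace(0, 2 * np.pi, 100000, endpoint=False)
        comp = np.zeros(12)
        comp[0] = 1.0
        V = np.zeros((u.size, 12))
        V[:, 0] = np.sin(u)
        X = ExpressionMatrix([f"G{i}" for i in range(u.size)], list(T12), V)
        assert projection_kurtosis(X, comp) == pytest.approx(-1.5, abs=0.01)

    def test_gaussian_projections(self, rng):
        comp = np.zeros(12)
        comp[3] = 1.0
        V = np.zeros((100000, 12))
        V[:, 3] = rng.normal(size=100000)
        X = ExpressionMatrix([f"G{i}" for i in range(100000)], list(T12), V)
        assert projection_kurtosis(X, comp) == pytest.approx(0.0, abs=0.05)

    def test_balanced_two_point(self):
        comp = np.zeros(12)
        comp[0] = 1.0
        V = np.zeros((100, 12))
        V[:50, 0] = 1.0
        V[50:, 0] = -1.0
        X = ExpressionMatrix([f"G{i}" for i in range(100)], list(T12), V)
        assert projection_kurtosis(X, comp) == pytest.approx(-2.0, abs=1e-9)

    def test_rejects_non_unit_component(self, two_trend_noiseless):
        with pytest.raises(ValueError, match="unit norm"):
            projection_kurtosis(two_trend_noiseless, np.ones(12))


class TestRunICA:
    def test_recovers_planted_trends(self, two_trend_noiseless):
        # run_ica pins down the circadian plane; the in-plane rotation of an
        # equal-period pair is resolved by the four-fold anchor
        dec = run_ica(two_trend_noiseless, n_components=2, n_runs=20, seed=0)
        v1, v2 = anchor_phase_axes(two_trend_noiseless, *dec.components)
        cos = np.cos(2 * np.pi * T12 / 24)
        sin = np.sin(2 * np.pi * T12 / 24)
        for comp in (v1, v2):
            r = max(abs(np.corrcoef(comp, cos)[0, 1]),
                    abs(np.corrcoef(comp, sin)[0, 1]))
            assert r >= 0.99

    def test_deterministic_under_seed(self, two_trend_noiseless):
        a = run_ica(two_trend_noiseless, n_components=2, n_runs=1, seed=5)
        b = run_ica(two_trend_noiseless, n_components=2, n_runs=1, seed=5)
        np.testing.assert_array_equal(a.components, b.components)

    def test_too_many_components_rejected(self, two_trend_noiseless):
        with pytest.raises(ValueError):
            run_ica(two_trend_noiseless, n_components=13)

    def test_requires_normalized(self, rng):
        X = ExpressionMatrix(["G1", "G2"], [0, 4, 8], rng.normal(size=(2, 3)))
        with pytest.raises(ValueError, match="normalized"):
            run_ica(X, n_components=2)

    def test_component_rows_unit_norm(self, two_trend_noiseless):
        dec = run_ica(two_trend_noiseless, n_components=3, n_runs=5, seed=1)
        np.testing.assert_allclose(np.linalg.norm(dec.components, axis=1), 1,
                                   atol=1e-9)


class TestRunPCA:
    def test_agrees_with_ica_on_planted_trends(self, two_trend_noiseless):
        ica = run_ica(two_trend_noiseless, n_components=2, n_runs=20, seed=0)
        v1, v2 = anchor_phase_axes(two_trend_noiseless, *ica.components)
        pca = run_pca(two_trend_noiseless, n_components=2)
        for comp in (v1, v2):
            r = max(abs(np.corrcoef(comp, pc)[0, 1]) for pc in pca.components)
            assert r >= 0.99

    def test_explained_variance_fractions(self, two_trend_noiseless):
        pca = run_pca(two_trend_noiseless)
        assert pca.explained_variance.sum() <= 1 + 1e-9
        assert (np.diff(pca.explained_variance) <= 1e-12).all()

    def test_rank_one_matrix(self):
        v = np.sin(2 * np.pi * T12 / 24)
        V = np.outer(np.linspace(1, 3, 20), v)
        X = _normalized(V + 1e-12)
        pca = run_pca(X, n_components=2)
        assert pca.explained_variance[0] >= 1 - 1e-9


class TestReconstructionError:
    def test_exact_for_full_rank_subspace(self, two_trend_noiseless):
        # noiseless 2-trend data is (nearly) rank 2
        err = reconstruction_error(two_trend_noiseless, d=4, seed=0)
        assert err <= 0.15 * np.linalg.norm(two_trend_noiseless.values)

    def test_d_zero_is_total_norm(self, two_trend_noiseless):
        err = reconstruction_error(two_trend_noiseless, d=0)
        assert err == pytest.approx(np.linalg.norm(two_trend_noiseless.values))

    def test_exactly_rank_two(self):
        cos = np.cos(2 * np.pi * T12 / 24)
        sin = np.sin(2 * np.pi * T12 / 24)
        rng = np.random.default_rng(0)
        V = np.array([a * cos + b * sin
                      for a, b in rng.normal(size=(50, 2))])
        V = V - V.mean(axis=1, keepdims=True)
        V = V / V.std(axis=1, keepdims=True)
        X = ExpressionMatrix([f"G{i}" for i in range(50)], list(T12), V,
                             normalized=True)
        err = reconstruction_error(X, d=2, seed=1)
        assert err <= 1e-6 * np.linalg.norm(V)

    def test_monotone_in_d(self, reference_study):
        Xn, _ = reference_study
        errs = [reconstruction_error(Xn, d, seed=3) for d in (1, 2, 3, 5, 8)]
        for lo, hi in zip(errs[1:], errs[:-1]):
            assert lo <= hi * 1.01  # allow 1% ICA stochasticity


class TestRandomizeMatrix:
    def test_row_permute_preserves_row_multisets(self, reference_study):
        Xn, _ = reference_study
        R = randomize_matrix(Xn, "row_permute", seed=2)
        np.testing.assert_allclose(np.sort(R.values, axis=1),
                                   np.sort(Xn.values, axis=1))

    def test_swap_discretized_preserves_bin_histograms(self, reference_study):
        Xn, _ = reference_study
        n_bins = 10
        R = randomize_matrix(Xn, "swap_discretized", seed=2, n_bins=n_bins)
        quantiles = np.quantile(Xn.values.ravel(),
                                np.linspace(0, 1, n_bins + 1)[1:-1])
        bins_orig = np.searchsorted(quantiles, Xn.values, side="right")
        bins_rand = np.searchsorted(quantiles, R.values, side="right")
        for axis in (0, 1):
            for b in range(n_bins):
                np.testing.assert_array_equal((bins_orig == b).sum(axis=axis),
                                              (bins_rand == b).sum(axis=axis))

    def test_deterministic(self, reference_study):
        Xn, _ = reference_study
        a = randomize_matrix(Xn, "row_permute", seed=9)
        b = randomize_matrix(Xn, "row_permute", seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_method(self, reference_study):
        Xn, _ = reference_study
        with pytest.raises(ValueError, match="unknown"):
            randomize_matrix(Xn, "bootstrap", seed=0)


class TestEmpiricalComponentTest:
    def test_p_zero_when_observed_gain_beats_all(self, two_trend_noiseless):
        ct = empirical_component_test(two_trend_noiseless, d=1,
                                      n_randomizations=20, seed=0)
        assert ct.p_value == 0.0

    def test_absolute_statistic_boundary(self, two_trend_noiseless):
        ct = empirical_component_test(two_trend_noiseless, d=2,
                                      n_randomizations=20, seed=0,
                                      statistic="absolute")
        assert ct.p_value == 0.0  # real error far below any randomized error

    def test_reproducible_under_seed(self, reference_study):
        Xn, _ = reference_study
        a = empirical_component_test(Xn, d=2, n_randomizations=10, seed=4)
        b = empirical_component_test(Xn, d=2, n_randomizations=10, seed=4)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.randomized_errors, b.randomized_errors)

    def test_validates_arguments(self, two_trend_noiseless):
        with pytest.raises(ValueError):
            empirical_component_test(two_trend_noiseless, d=1, n_randomizations=0)
        with pytest.raises(ValueError):
            empirical_component_test(two_trend_noiseless, d=1,
                                     n_randomizations=5, statistic="banana")


class TestSelectCircadianComponents:
    def test_planted_pair_selected(self, two_trend_noiseless):
        dec = run_ica(two_trend_noiseless, n_components=2, n_runs=10, seed=0)
        i, j = select_circadian_components(dec, T12)
        assert {i, j} == {0, 1}

    def test_noise_only_raises(self, rng):
        X = _normalized(rng.normal(size=(300, 12)))
        dec = run_pca(X, n_components=6)
        with pytest.raises(ValueError, match="manual"):
            select_circadian_components(dec, T12)

    def test_override_wins(self, two_trend_noiseless):
        dec = run_ica(two_trend_noiseless, n_components=2, n_runs=5, seed=0)
        assert select_circadian_components(dec, T12, override=(1, 0)) == (1, 0)


class TestAnchorPhaseAxes:
    def test_rotation_recovers_axes(self, reference_study):
        Xn, truth = reference_study
        cos = np.cos(2 * np.pi * T12 / 24)
        sin = np.sin(2 * np.pi * T12 / 24)
        # start from a deliberately rotated basis of the true plane
        c = cos / np.linalg.norm(cos)
        s = sin - sin @ c * c
        s /= np.linalg.norm(s)
        th = np.radians(37)
        v1 = np.cos(th) * c + np.sin(th) * s
        v2 = -np.sin(th) * c + np.cos(th) * s
        a1, a2 = anchor_phase_axes(Xn, v1, v2)
        # +v1 is the noon axis: profile peaking at 6 h, i.e. the sin trend
        assert abs(np.corrcoef(a1, sin)[0, 1]) >= 0.99
        assert np.corrcoef(a1, sin)[0, 1] > 0
        assert abs(np.corrcoef(a2, cos)[0, 1]) >= 0.99
        assert np.corrcoef(a2, cos)[0, 1] > 0


class TestCosineR2:
    def test_exact_cosine(self):
        y = np.cos(2 * np.pi * (T12 - 3) / 24)
        assert cosine_r2(y, T12) == pytest.approx(1.0)

    def test_linear_trend_fits_poorly(self):
        assert cosine_r2(np.linspace(0, 1, 12), T12) < 0.5
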