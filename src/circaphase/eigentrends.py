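"""Latent circadian trend ("eigentrend") extraction.

The normalized expression matrix is modelled as ``X = A S``: rows of ``S``
are statistically independent time profiles (eigentrends) and ``A`` carries
per-gene loadings.  Because FastICA is initialized randomly and its component
order and sign are arbitrary, each decomposition averages many runs after
aligning components across runs by maximal absolute correlation.  Components
are then ordered by the excess kurtosis of the distribution of gene
projections along them — strongly platykurtic (negative-kurtosis) projections
indicate that an unusually large share of genes follow that trend, which is
the signature of a dominant circadian pattern.

How many components genuinely represent the data is decided by an empirical
randomization test: the reconstruction error of a rank-``d`` decomposition of
the real matrix is compared with the errors obtained from randomized
matrices, and the p-value is the frequency with which randomized errors fall
below the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA

from .expr_io import ExpressionMatrix

__all__ = [
    "EigentrendDecomposition", "ComponentCountTest",
    "run_ica", "run_pca", "projection_kurtosis", "reconstruction_error",
    "randomize_matrix", "empirical_component_test", "select_circadian_components",
    "anchor_phase_axes", "extract_circadian_pair", "cosine_r2",
]


@dataclass
class EigentrendDecomposition:
    """A set of latent time profiles with loadings and kurtosis ordering.

    ``components`` is ``d x m`` with unit-Euclidean-norm rows;
    ``loadings`` is ``n x d`` (``X @ components.T``); ``kurtosis[k]`` is the
    excess kurtosis of the gene-projection distribution along component ``k``;
    ``order`` permutes components ascending in kurtosis (most negative first).
    """

    components: np.ndarray
    loadings: np.ndarray
    kurtosis: np.ndarray
    order: np.ndarray
    method: str
    n_runs: int
    seed: int
    explained_variance: np.ndarray | None = None  # PCA only

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.components, axis=1)
        if np.abs(norms - 1).max() > 1e-9:
            raise ValueError("component rows must have unit Euclidean norm")
        if self.components.shape[0] > self.components.shape[1]:
            raise ValueError("cannot extract more components than timepoints")

    @property
    def d(self) -> int:
        return self.components.shape[0]

    def ordered_components(self) -> np.ndarray:
        return self.components[self.order]


@dataclass
class ComponentCountTest:
    """Empirical significance of a ``d``-component representation.

    With the default ``increment`` statistic the question is whether the
    ``d``-th component decreases the reconstruction error more than adding a
    ``d``-th component to a randomized matrix does; ``observed_gain`` /
    ``randomized_gains`` hold those decreases.  With the ``absolute``
    statistic the raw errors are compared and the p-value is the frequency
    of randomized errors below the observed one.
    """

    d: int
    observed_error: float
    randomized_errors: np.ndarray
    p_value: float
    n_randomizations: int
    randomizer: str
    statistic: str = "increment"
    observed_gain: float | None = None
    randomized_gains: np.ndarray | None = None


def _skew_contrast(x, fun_args=None):
    """Odd FastICA nonlinearity g(x) = x^2 (third-moment / skewness contrast).

    Even contrasts (logcosh, cube) cannot distinguish a direction from its
    reflection and, for four-fold phase-module structure, prefer the
    inter-module diagonal; the skew contrast keys on the asymmetric phase
    distribution instead.  Same convention as the 'skew' option of the
    reference FastICA distribution.
    """
    return x**2, np.mean(2 * x, axis=-1)


_CONTRASTS = {"logcosh": "logcosh", "exp": "exp", "cube": "cube",
              "skew": _skew_contrast}


def _fit_ica_once(V: np.ndarray, n_components: int, seed: int,
                  fun: str = "logcosh",
                  max_retries: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """One FastICA fit; returns (profiles d x m, gene sources n x d).

    Non-convergent fits are retried with fresh sub-seeds; if none of the
    retries converges the last fit is used with a warning (near-degenerate
    rotations oscillate within tolerance of the optimum, and the run
    averaging absorbs the residual jitter).
    """
    contrast = _CONTRASTS.get(fun, fun)
    result = None
    for attempt in range(max_retries + 1):
        ica = FastICA(n_components=n_components, random_state=seed + 7919 * attempt,
                      max_iter=1000, tol=1e-4, fun=contrast, whiten="unit-variance")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            sources = ica.fit_transform(V)
        result = (ica.mixing_.T, sources)
        converged = not any("did not converge" in str(w.message) for w in caught)
        if converged:
            return result
    warnings.warn(f"FastICA did not converge in {max_retries + 1} attempts; "
                  "using the last fit", RuntimeWarning, stacklevel=2)
    return result


def _align_to_reference(ref: np.ndarray, comp: np.ndarray) -> np.ndarray:
    """Match rows of ``comp`` to rows of ``ref`` by greedy max |correlation|,
    flipping signs so matched correlations are positive."""
    d = ref.shape[0]
    C = np.corrcoef(ref, comp)[:d, d:]
    aligned = np.empty_like(ref)
    free_ref, free_comp = set(range(d)), set(range(d))
    absC = np.abs(C)
    for _ in range(d):
        best = max(((absC[i, j], i, j) for i in free_ref for j in free_comp))
        _, i, j = best
        aligned[i] = comp[j] * np.sign(C[i, j] if C[i, j] != 0 else 1.0)
        free_ref.remove(i)
        free_comp.remove(j)
    return aligned


def run_ica(X: ExpressionMatrix, n_components: int | None = None,
            n_runs: int = 100, seed: int = 0,
            fun: str = "logcosh") -> EigentrendDecomposition:
    """Averaged-FastICA eigentrend decomposition.

    ``n_runs`` independent FastICA fits are aligned to the first run
    (greedy matching on absolute component correlation, sign-flipped
    positive) and averaged; the averaged profiles are renormalized to unit
    norm, loadings recomputed as ``X @ components.T``, and components
    annotated with projection kurtosis.  ``n_components`` defaults to all
    extractable components, i.e. the numerical rank of ``X`` (row
    standardization makes every row sum to zero, so this is at most m - 1).
    """
    if not X.normalized:
        raise ValueError("run_ica requires a normalized matrix (see preprocess)")
    d = int(np.linalg.matrix_rank(X.values)) if n_components is None else int(n_components)
    if not 1 <= d <= X.m:
        raise ValueError(f"n_components must lie in [1, {X.m}], got {d}")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")

    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    ref, _ = _fit_ica_once(X.values, d, int(sub_seeds[0]), fun=fun)
    acc = ref.copy()
    for k in range(1, n_runs):
        comp, _ = _fit_ica_once(X.values, d, int(sub_seeds[k]), fun=fun)
        acc += _align_to_reference(ref, comp)
    mean_comp = acc / n_runs
    norms = np.linalg.norm(mean_comp, axis=1, keepdims=True)
    if (norms == 0).any():
        raise RuntimeError("averaged component collapsed to zero")
    components = mean_comp / norms
    loadings = X.values @ components.T
    kurt = np.array([projection_kurtosis(X, components[k]) for k in range(d)])
    return EigentrendDecomposition(components, loadings, kurt, np.argsort(kurt),
                                   method="ICA", n_runs=n_runs, seed=seed)


def run_pca(X: ExpressionMatrix, n_components: int | None = None,
            seed: int = 0) -> EigentrendDecomposition:
    """PCA counterpart: right singular vectors ordered by explained variance."""
    if not X.normalized:
        raise ValueError("run_pca requires a normalized matrix")
    d = int(np.linalg.matrix_rank(X.values)) if n_components is None else int(n_components)
    if not 1 <= d <= X.m:
        raise ValueError(f"n_components must lie in [1, {X.m}], got {d}")
    _, s, Vt = np.linalg.svd(X.values, full_matrices=False)
    components = Vt[:d]
    loadings = X.values @ components.T
    kurt = np.array([projection_kurtosis(X, components[k]) for k in range(d)])
    frac = (s**2 / (s**2).sum())[:d]
    return EigentrendDecomposition(components, loadings, kurt, np.argsort(kurt),
                                   method="PCA", n_runs=1, seed=seed,
                                   explained_variance=frac)


def projection_kurtosis(X: ExpressionMatrix, component: np.ndarray) -> float:
    """Excess kurtosis of the gene projections along a unit-norm component.

    Population moments: fourth central moment / variance^2 - 3.
    """
    component = np.asarray(component, dtype=float)
    if abs(np.linalg.norm(component) - 1) > 1e-6:
        raise ValueError("component must have unit norm")
    proj = X.values @ component
    if proj.std() == 0:
        raise ValueError("projections have zero variance")
    return float(stats.kurtosis(proj, fisher=True, bias=True))


def reconstruction_error(X: ExpressionMatrix, d: int, seed: int = 0,
                         n_runs: int = 1) -> float:
    """Frobenius distance between ``X`` and its rank-``d`` ICA reconstruction.

    ``d = 0`` returns ``||X||_F`` (the empty model).
    """
    if not 0 <= d <= X.m:
        raise ValueError(f"d must lie in [0, {X.m}]")
    if d == 0:
        return float(np.linalg.norm(X.values))
    dec = run_ica(X, n_components=d, n_runs=n_runs, seed=seed)
    # least-squares loadings: averaged ICA profiles need not be orthonormal
    A, *_ = np.linalg.lstsq(dec.components.T, X.values.T, rcond=None)
    recon = A.T @ dec.components
    return float(np.linalg.norm(X.values - recon))


def randomize_matrix(X: ExpressionMatrix, method: str = "row_permute",
                     seed: int = 0, n_bins: int = 10,
                     swap_multiplier: int = 10) -> ExpressionMatrix:
    """Destroy temporal structure while preserving marginal distributions.

    ``row_permute`` independently permutes each gene's values (exactly
    preserving every row's multiset).  ``swap_discretized`` bins all values
    into ``n_bins`` equal-frequency bins and performs ``swap_multiplier*n*m``
    random swap moves between same-bin cells, which preserves each row's and
    column's bin-count histogram while the continuous values travel with
    their bins.
    """
    rng = np.random.default_rng(seed)
    V = X.values.copy()
    if method == "row_permute":
        V = rng.permuted(V, axis=1)
        return ExpressionMatrix(list(X.gene_ids), list(X.time_hours), V,
                                normalized=X.normalized)
    if method == "swap_discretized":
        flat = V.ravel()
        quantiles = np.quantile(flat, np.linspace(0, 1, n_bins + 1)[1:-1])
        bins = np.searchsorted(quantiles, flat, side="right")
        n_swaps = swap_multiplier * V.size
        idx1 = rng.integers(0, flat.size, size=n_swaps)
        idx2 = rng.integers(0, flat.size, size=n_swaps)
        for a, b in zip(idx1, idx2):
            if bins[a] == bins[b]:
                flat[a], flat[b] = flat[b], flat[a]
        return ExpressionMatrix(list(X.gene_ids), list(X.time_hours),
                                flat.reshape(V.shape), normalized=False)
    raise ValueError(f"unknown randomization method {method!r}")


def empirical_component_test(X: ExpressionMatrix, d: int,
                             n_randomizations: int = 1000,
                             method: str = "row_permute", seed: int = 0,
                             n_runs: int = 1, statistic: str = "increment",
                             plus_one_correction: bool = False) -> ComponentCountTest:
    """Empirical p-value for the significance of ``d`` components.

    ``statistic="increment"`` (default) asks whether the ``d``-th component
    earns its keep: the observed decrease in reconstruction error from
    ``d - 1`` to ``d`` components is compared with the same decrease on
    randomized matrices, and p is the fraction of randomized decreases at
    least as large.  A structureless direction gains no more than chance, so
    p jumps once ``d`` exceeds the number of real trends — the behaviour of
    the reconstruction-error elbow.  ``statistic="absolute"`` compares the
    raw rank-``d`` errors instead (p = frequency of randomized errors below
    the observed); because the leading real trends depress the rank-``d``
    error for every ``d`` at or beyond them, this variant discriminates
    poorly above the true dimension and is kept for completeness.

    With ``plus_one_correction`` the conservative (k+1)/(N+1) estimate is
    used; the plain frequency (which can be exactly 0) is the default.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    if statistic not in ("increment", "absolute"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    obs = reconstruction_error(X, d, seed=int(rng.integers(2**31 - 1)), n_runs=n_runs)
    if statistic == "increment":
        obs_prev = reconstruction_error(X, d - 1, seed=int(rng.integers(2**31 - 1)),
                                        n_runs=n_runs)
        obs_gain = obs_prev - obs
    rre = np.empty(n_randomizations)
    gains = np.empty(n_randomizations)
    for r in range(n_randomizations):
        RX = randomize_matrix(X, method=method, seed=int(rng.integers(2**31 - 1)))
        rre[r] = reconstruction_error(RX, d, seed=int(rng.integers(2**31 - 1)),
                                      n_runs=n_runs)
        if statistic == "increment":
            prev = reconstruction_error(RX, d - 1, seed=int(rng.integers(2**31 - 1)),
                                        n_runs=n_runs)
            gains[r] = prev - rre[r]
    if statistic == "absolute":
        k = int((rre < obs).sum())
        p = (k + 1) / (n_randomizations + 1) if plus_one_correction else k / n_randomizations
        return ComponentCountTest(d=d, observed_error=obs, randomized_errors=rre,
                                  p_value=float(p), n_randomizations=n_randomizations,
                                  randomizer=method, statistic=statistic)
    k = int((gains >= obs_gain).sum())
    p = (k + 1) / (n_randomizations + 1) if plus_one_correction else k / n_randomizations
    return ComponentCountTest(d=d, observed_error=obs, randomized_errors=rre,
                              p_value=float(p), n_randomizations=n_randomizations,
                              randomizer=method, statistic=statistic,
                              observed_gain=float(obs_gain), randomized_gains=gains)


def anchor_phase_axes(X: ExpressionMatrix, v1: np.ndarray, v2: np.ndarray,
                      radius_floor: float = 0.7, period_h: float = 24.0,
                      noon_hour: float = 6.0,
                      dawn_hour: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the in-plane rotation of a circadian component pair.

    Two orthogonal trends of the same period span a plane, but independence
    criteria leave the rotation *within* that plane poorly determined: for a
    four-module phase distribution the non-Gaussianity extremum sits on the
    inter-module diagonal, 45 degrees off the module axes.  The module axes
    themselves are identifiable from the gene cloud: phase modules impose a
    four-fold angular symmetry whose orientation is the circular mean of
    ``4*theta`` over high-radius genes, and the dominant (midday) lobe fixes
    which of the four candidate directions is the positive first axis.

    Parameters
    ----------
    X
        Normalized expression matrix.
    v1, v2
        A (near-)orthogonal spanning pair for the circadian plane, e.g. the
        two circadian components of :func:`run_ica`.
    radius_floor
        Only genes whose unit-normalized vectors project at least this far
        into the plane vote for the orientation; the default keeps the vote
        to clearly rhythmic genes, whose angles are robust to the small
        angular bias column centring leaves on weak genes.
    noon_hour, dawn_hour
        Zeitgeber anchors used only to label the four candidate axes: the
        quarter whose fitted cosine peaks nearest ``noon_hour`` becomes +v1
        (the noon-midnight axis) and the orthogonal direction peaking nearest
        ``dawn_hour`` becomes +v2.  Times are hours since subjective dawn, so
        these defaults are the experiment's own clock.

    Returns
    -------
    (v1', v2') : unit vectors spanning the same plane, rotated onto the
    four-fold symmetry axes of the gene cloud and oriented by Zeitgeber time.
    """
    B = np.linalg.qr(np.column_stack([v1, v2]))[0].T  # orthonormal 2 x m
    U = X.values / np.linalg.norm(X.values, axis=1, keepdims=True)
    q = U @ B.T
    rad = np.hypot(q[:, 0], q[:, 1])
    theta = np.arctan2(q[:, 1], q[:, 0])
    sel = rad >= radius_floor
    if not sel.any():
        raise ValueError(f"no gene reaches in-plane radius {radius_floor}")
    psi = np.angle((rad[sel] * np.exp(4j * theta[sel])).sum()) / 4

    t = np.asarray(X.time_hours, dtype=float)
    w = 2 * np.pi / period_h

    def peak_hour(v: np.ndarray) -> float:
        design = np.column_stack([np.cos(w * t), np.sin(w * t), np.ones_like(t)])
        a, b, _ = np.linalg.lstsq(design, v, rcond=None)[0]
        return (np.arctan2(b, a) / w) % period_h

    def circ_dist(a: float, b: float) -> float:
        d = abs(a - b) % period_h
        return min(d, period_h - d)

    candidates = []
    for k in range(4):
        c = psi + k * np.pi / 2
        vc = np.cos(c) * B[0] + np.sin(c) * B[1]
        candidates.append((c, vc, peak_hour(vc)))
    c, v1n, _ = min(candidates, key=lambda kv: circ_dist(kv[2], noon_hour))
    v2_options = [(s, s * (-np.sin(c) * B[0] + np.cos(c) * B[1])) for s in (+1, -1)]
    _, v2n = min(v2_options, key=lambda sv: circ_dist(peak_hour(sv[1]), dawn_hour))
    return v1n, v2n


def extract_circadian_pair(X: ExpressionMatrix, n_runs: int = 100, seed: int = 0,
                           period_h: float = 24.0, r2_floor: float = 0.5,
                           anchor: bool = True,
                           ) -> tuple[np.ndarray, np.ndarray, EigentrendDecomposition]:
    """Averaged two-component ICA plus phase-axis anchoring.

    Convenience wrapper for the headline workflow: extract the two dominant
    eigentrends, check both follow a ~``period_h`` cosine, and anchor the
    in-plane rotation to the module axes.  Returns (v1, v2, decomposition).
    """
    dec = run_ica(X, n_components=2, n_runs=n_runs, seed=seed)
    i, j = select_circadian_components(dec, X.time_hours, period_h=period_h,
                                       r2_floor=r2_floor)
    v1, v2 = dec.components[i], dec.components[j]
    if anchor:
        v1, v2 = anchor_phase_axes(X, v1, v2)
    return v1, v2, dec


def cosine_r2(profile: np.ndarray, time_hours, period_h: float = 24.0) -> float:
    """R^2 of a free-phase, free-amplitude cosine fit to a time profile."""
    t = np.asarray(time_hours, dtype=float)
    y = np.asarray(profile, dtype=float)
    w = 2 * np.pi / period_h
    design = np.column_stack([np.cos(w * t), np.sin(w * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    return float(1 - (resid**2).sum() / ss_tot)


def select_circadian_components(dec: EigentrendDecomposition, time_hours,
                                period_h: float = 24.0, r2_floor: float = 0.5,
                                override: tuple[int, int] | None = None,
                                ) -> tuple[int, int]:
    """Pick the two components that best follow a ~24 h cosine.

    Returns component indices (into ``dec.components``) of the two profiles
    with the highest free-phase cosine R^2, ordered by kurtosis rank.  An
    ``override`` pair is returned unconditionally (manual selection).
    """
    if override is not None:
        return tuple(override)  # type: ignore[return-value]
    if dec.d < 2:
        raise ValueError("need at least two components")
    r2 = np.array([cosine_r2(dec.components[k], time_hours, period_h)
                   for k in range(dec.d)])
    qualifying = np.flatnonzero(r2 >= r2_floor)
    if qualifying.size < 2:
        raise ValueError(
            f"fewer than two components reach cosine R^2 >= {r2_floor} "
            f"(best: {np.sort(r2)[::-1][:3]}); select components manually via override"
        )
    top = qualifying[np.argsort(r2[qualifying])[::-1][:2]]
    rank = {comp: pos for pos, comp in enumerate(dec.order)}
    a, b = sorted(top, key=lambda c: rank[int(c)])
    return int(a), int(b)
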