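"""Cross-study conservation statistics.

Two studies measured on different platforms cannot be compared value-for-
value, but the *correlation structure* among shared (orthologous) genes can:
for each ortholog pair, the integrative correlation (corCor) is the Pearson
correlation between the gene's correlation profile — its correlations with
the other mapped genes — in study A and the orthologous profile in study B.
A within-gene permutation null calibrates it.

Module preservation is scored on co-expression graphs: edges are gene pairs
with Pearson r >= 0.8 (one-sided — anti-correlated pairs are not edges), the
observed Jaccard overlap of the two modules' edge sets is compared with a
null of same-size random gene sets, and reported as a z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix

__all__ = ["OrthologMap", "CorCorResult", "ModulePreservation",
           "read_ortholog_map", "integrative_correlation", "corcor_null",
           "coexpression_edges", "jaccard_similarity", "module_preservation"]


@dataclass
class OrthologMap:
    """One-to-one gene pairs linking two studies."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("ortholog map must be one-to-one; duplicates found")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes_a(self) -> list[str]:
        return [a for a, _ in self.pairs]

    @property
    def genes_b(self) -> list[str]:
        return [b for _, b in self.pairs]

    def reversed(self) -> "OrthologMap":
        return OrthologMap([(b, a) for a, b in self.pairs])


def read_ortholog_map(path) -> OrthologMap:
    """Two-column TSV with header; one ortholog pair per line."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns")
    return OrthologMap(list(df.itertuples(index=False, name=None)))


@dataclass
class CorCorResult:
    """Per-pair integrative correlations (NaN for excluded pairs)."""

    pairs: list[tuple[str, str]]
    corcor: np.ndarray
    excluded: list[tuple[str, str]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_a": [a for a, _ in self.pairs],
                             "gene_b": [b for _, b in self.pairs],
                             "corCor": self.corcor})


def _row_standardize(V: np.ndarray) -> np.ndarray:
    mu = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (V - mu) / sd


def _corr_matrix(V: np.ndarray) -> np.ndarray:
    Z = _row_standardize(V)
    return (Z @ Z.T) / V.shape[1]


def integrative_correlation(Xa: ExpressionMatrix, Xb: ExpressionMatrix,
                            omap: OrthologMap) -> CorCorResult:
    """corCor for every ortholog pair over the mapped gene universe.

    For pair i: correlate gene i with the other mapped genes within each
    study, then Pearson-correlate the two length-(m-1) profiles.  Pairs whose
    expression vector is constant in either study are excluded (NaN) and
    reported.
    """
    if len(omap) < 3:
        raise ValueError("need at least 3 ortholog pairs")
    A = Xa.subset(omap.genes_a).values
    B = Xb.subset(omap.genes_b).values
    m = len(omap)
    const = (A.std(axis=1) == 0) | (B.std(axis=1) == 0)
    excluded = [omap.pairs[i] for i in np.flatnonzero(const)]
    if excluded:
        warnings.warn(f"excluding {len(excluded)} pair(s) with constant expression",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        Ca = _corr_matrix(A)
        Cb = _corr_matrix(B)
    out = np.full(m, np.nan)
    mask = ~np.eye(m, dtype=bool)
    for i in range(m):
        if const[i]:
            continue
        keep = mask[i] & ~const
        x = Ca[i, keep]
        y = Cb[i, keep]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0 or x.size < 3:
            out[i] = np.nan
            continue
        out[i] = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return CorCorResult(list(omap.pairs), out, excluded)


def corcor_null(Xa: ExpressionMatrix, Xb: ExpressionMatrix, omap: OrthologMap,
                n_permutations: int = 20, seed: int = 0) -> np.ndarray:
    """Pooled null corCor values from within-gene shuffling of study B."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    Xb_sub = Xb.subset(omap.genes_b)
    pooled = []
    for _ in range(n_permutations):
        Vp = rng.permuted(Xb_sub.values, axis=1)
        Xp = ExpressionMatrix(list(Xb_sub.gene_ids), list(Xb_sub.time_hours), Vp,
                              normalized=False)
        res = integrative_correlation(Xa, Xp, omap)
        pooled.append(res.corcor[~np.isnan(res.corcor)])
    return np.concatenate(pooled)


def coexpression_edges(X: ExpressionMatrix, genes, threshold: float = 0.8) -> set:
    """Undirected edges between genes with Pearson r >= threshold.

    One-sided on purpose: strong anti-correlation does not make an edge.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    V = X.subset(genes).values
    C = _corr_matrix(V)
    edges = set()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if C[i, j] >= threshold:
                edges.add(frozenset((genes[i], genes[j])))
    return edges


def jaccard_similarity(E1: set, E2: set) -> float:
    """|E1 ∩ E2| / |E1 ∪ E2| (shared true edges over all predicted edges);
    1.0 when both sets are empty."""
    union = E1 | E2
    if not union:
        return 1.0
    return len(E1 & E2) / len(union)


@dataclass
class ModulePreservation:
    jaccard: float
    null_mean: float
    null_sd: float
    z_score: float
    n_permutations: int
    edge_threshold: float


def module_preservation(Xa: ExpressionMatrix, Xb: ExpressionMatrix,
                        omap: OrthologMap, module_a, module_b,
                        n_permutations: int = 100, threshold: float = 0.8,
                        seed: int = 0) -> ModulePreservation:
    """Jaccard z-score for preservation of a module across studies.

    Edges are computed per study on the ortholog-aligned node universe (study
    B genes relabelled by their study A orthologs so edge sets are
    comparable).  The null redraws both modules as random gene sets of the
    same sizes from the mapped universe.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    a2b = dict(omap.pairs)
    module_a = [g for g in module_a if g in a2b]
    module_b = [g for g in module_b if g in a2b]
    if not module_a or not module_b:
        raise ValueError("modules empty after ortholog alignment")

    universe = omap.genes_a
    Xb_aligned = Xb.subset(omap.genes_b)
    Xb_aligned = ExpressionMatrix(universe, list(Xb_aligned.time_hours),
                                  Xb_aligned.values, normalized=Xb_aligned.normalized)

    def score(mod_a, mod_b) -> float:
        Ea = coexpression_edges(Xa, mod_a, threshold)
        Eb = coexpression_edges(Xb_aligned, mod_b, threshold)
        return jaccard_similarity(Ea, Eb)

    observed = score(module_a, module_b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for r in range(n_permutations):
        ra = list(rng.choice(universe, size=len(module_a), replace=False))
        rb = list(rng.choice(universe, size=len(module_b), replace=False))
        null[r] = score(ra, rb)
    mu, sd = float(null.mean()), float(null.std())
    if sd == 0:
        warnings.warn("degenerate null (sd = 0); reporting infinite z", stacklevel=2)
        z = float("inf") if observed > mu else (float("-inf") if observed < mu else 0.0)
    else:
        z = (observed - mu) / sd
    return ModulePreservation(observed, mu, sd, z, n_permutations, threshold)
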