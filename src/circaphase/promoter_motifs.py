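"""Promoter k-mer enumeration, enrichment and feature-matrix construction.

Promoters arrive as 1 kb upstream FASTA sequences.  All 5-8-mers over ACGT
are candidate cis elements; over-representation in a target promoter set
(e.g. circadian genes) against a background set is scored with a one-sided
hypergeometric test on presence/absence, the top-ranked elements become the
feature set, and genes x motifs matrices (binary presence by default) feed
the downstream Random-Forest phase classifier.

Counting is single-strand 5'->3' exact matching with overlaps; windows
containing N never match.  A reverse-complement-inclusive mode is available.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats

__all__ = ["PromoterSet", "MotifFeatureMatrix", "read_fasta", "write_fasta",
           "count_motif", "enrichment_rank", "build_feature_matrix",
           "enumerate_kmers"]

_ALPHABET = set("ACGTN")
K_MIN, K_MAX = 5, 8


@dataclass
class PromoterSet:
    """gene id -> uppercase promoter sequence (ACGTN), nominally 1000 bp."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(f"record {gene!r}: illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene: str) -> str:
        return self.sequences[gene]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)


@dataclass
class MotifFeatureMatrix:
    """Genes x motifs features; binary presence or overlapping counts."""

    gene_ids: list[str]
    motifs: list[str]
    values: np.ndarray
    mode: str  # "binary" | "count"
    enrichment: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.motifs)
        df.insert(0, "gene_id", self.gene_ids)
        return df


def read_fasta(path, expected_length: int = 1000) -> PromoterSet:
    """Read promoters; ids are the first whitespace token, sequences are
    uppercased; deviations from the expected length warn, never fail."""
    sequences: dict[str, str] = {}
    off_length = 0
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate record id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"{path}: record {record.id!r} contains illegal "
                             f"characters {sorted(bad)}")
        if expected_length and len(seq) != expected_length:
            off_length += 1
        sequences[record.id] = seq
    if off_length:
        warnings.warn(f"{off_length} promoter(s) deviate from the expected "
                      f"{expected_length} bp", stacklevel=2)
    return PromoterSet(sequences)


def write_fasta(promoters: PromoterSet, path) -> None:
    with open(path, "w") as fh:
        for gene, seq in promoters.sequences.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def _validate_motif(motif: str) -> None:
    if not K_MIN <= len(motif) <= K_MAX:
        raise ValueError(f"motif length must be {K_MIN}-{K_MAX}, got "
                         f"{len(motif)} ({motif!r})")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be ACGT only: {motif!r}")


def count_motif(sequence: str, motif: str, include_revcomp: bool = False) -> int:
    """Overlapping exact occurrences of ``motif`` in ``sequence``.

    Single strand by default; ``include_revcomp`` also counts the reverse
    complement.  Windows containing N never match.
    """
    _validate_motif(motif)
    targets = {motif}
    if include_revcomp:
        targets.add(str(Seq(motif).reverse_complement()))
    k = len(motif)
    count = 0
    for t in targets:
        start = 0
        while True:
            pos = sequence.find(t, start)
            if pos == -1:
                break
            count += 1
            start = pos + 1
    return count


def enumerate_kmers(k_min: int = K_MIN, k_max: int = K_MAX):
    """All ACGT k-mers for k in [k_min, k_max], lexicographic within each k."""
    for k in range(k_min, k_max + 1):
        for kmer in itertools.product("ACGT", repeat=k):
            yield "".join(kmer)


def _present_kmers(seq: str, k_min: int, k_max: int) -> set[str]:
    out: set[str] = set()
    for k in range(k_min, k_max + 1):
        for i in range(len(seq) - k + 1):
            window = seq[i:i + k]
            if "N" not in window:
                out.add(window)
    return out


def _presence_counts(promoters: PromoterSet, k_min: int, k_max: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in promoters.sequences.values():
        for kmer in _present_kmers(seq, k_min, k_max):
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def enrichment_rank(target: PromoterSet, background: PromoterSet,
                    k_min: int = K_MIN, k_max: int = K_MAX,
                    top_n: int = 21) -> pd.DataFrame:
    """Rank k-mers by over-representation in target vs background promoters.

    Presence/absence per promoter; the score is the one-sided hypergeometric
    survival probability of seeing at least the observed number of target
    promoters containing the motif, drawing |target| promoters from the
    combined pool.  Smaller is more enriched; ties break lexicographically.
    Returns the ``top_n`` motifs as a DataFrame (motif, target_hits, bg_hits,
    p_value, rank).
    """
    if not len(target) or not len(background):
        raise ValueError("target and background promoter sets must be nonempty")
    overlap = set(target.gene_ids) & set(background.gene_ids)
    if overlap:
        warnings.warn(f"{len(overlap)} gene(s) appear in both target and "
                      "background", stacklevel=2)
    tc = _presence_counts(target, k_min, k_max)
    bc = _presence_counts(background, k_min, k_max)
    motifs = sorted(set(tc) | set(bc))
    if top_n > len(motifs):
        raise ValueError(f"top_n={top_n} exceeds the {len(motifs)} distinct "
                         "motifs observed")
    if top_n == 0:
        return pd.DataFrame(columns=["motif", "target_hits", "bg_hits",
                                     "p_value", "rank"])
    nt, nb = len(target), len(background)
    t_hits = np.array([tc.get(m, 0) for m in motifs])
    b_hits = np.array([bc.get(m, 0) for m in motifs])
    # P(X >= t_hits) with X ~ Hypergeom(M=nt+nb, n=t_hits+b_hits, N=nt)
    pvals = stats.hypergeom.sf(t_hits - 1, nt + nb, t_hits + b_hits, nt)
    df = pd.DataFrame({"motif": motifs, "target_hits": t_hits,
                       "bg_hits": b_hits, "p_value": pvals})
    df = df.sort_values(["p_value", "motif"], kind="stable").head(top_n)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def build_feature_matrix(promoters: PromoterSet, motifs, mode: str = "binary",
                         gene_ids=None, include_revcomp: bool = False,
                         ) -> MotifFeatureMatrix:
    """Genes x motifs matrix; binary presence (count >= 1) or raw counts.

    ``gene_ids`` restricts/orders the rows; genes without a promoter are an
    error (listed).
    """
    motifs = list(motifs)
    for m in motifs:
        _validate_motif(m)
    if mode not in ("binary", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    genes = list(gene_ids) if gene_ids is not None else promoters.gene_ids
    missing = [g for g in genes if g not in promoters.sequences]
    if missing:
        raise ValueError(f"genes without promoters: {missing[:10]}")
    values = np.zeros((len(genes), len(motifs)),
                      dtype=int if mode == "count" else np.int8)
    for i, g in enumerate(genes):
        seq = promoters[g]
        for j, motif in enumerate(motifs):
            c = count_motif(seq, motif, include_revcomp=include_revcomp)
            values[i, j] = c if mode == "count" else int(c >= 1)
    return MotifFeatureMatrix(genes, motifs, values, mode)
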