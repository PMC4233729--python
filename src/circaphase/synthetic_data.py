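"""Synthetic expression and promoter generators with full ground truth.

The expression generator emulates a free-running circadian microarray time
course: 12 timepoints at 4 h intervals whose variance is dominated by two
orthogonal ~24 h trends (sine/cosine), optionally plus a damping trend, with
i.i.d. Gaussian noise on top.  Circadian genes are planted in four phase
classes peaking at subjective dawn (0 h), noon (6 h), dusk (12 h) and
midnight (18 h).  The promoter generator plants progressively overlapping
motif sets into i.i.d. background sequence, one motif set per phase class.
All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix

__all__ = [
    "SimulationSpec", "PromoterSimSpec",
    "simulate_expression", "simulate_promoters", "simulate_study_pair",
    "reference_spec", "three_trend_spec",
    "DEFAULT_PHASE_ASSIGNMENT", "DEFAULT_CLASS_MOTIFS",
]


def reference_spec(seed: int = 1) -> "SimulationSpec":
    """The reference study conditions: 2000 genes, 200 strong cyclers in four
    phase classes, 12 timepoints at 4 h — the defaults, pinned to a seed."""
    return SimulationSpec(seed=seed)


def three_trend_spec(seed: int = 1) -> "SimulationSpec":
    """Conditions with a third latent trend for the component-count test:
    two circadian trends plus a shared damped rhythm (360 transient genes,
    decay rate 0.10/h), against a quieter weak background so the question
    "how many trends?" is non-trivial."""
    return SimulationSpec(seed=seed, n_genes=2000, n_circadian=300,
                          amplitude_range=(2.2, 2.8), noise_sd=0.8,
                          subthreshold_scales=(0.02, 0.02),
                          subthreshold_clip=(0.05, 0.05),
                          damping_fraction=1.2, damping_rate=0.10)

#: module label -> peak hour; classes 1..4 are dawn/dusk on the second
#: component axis and noon/midnight on the first.
DEFAULT_PHASE_ASSIGNMENT: dict[int, float] = {1: 0.0, 2: 12.0, 3: 6.0, 4: 18.0}

#: progressively overlapping motif sets (class -> planted 5-8-mers), built so
#: consecutive phases share elements the way combinatorial promoter grammars do:
#: {M1..M3} / {M2..M4} / {M3..M5} / {M4,M5,M1}.  The elements extend cores of
#: known circadian/light promoter elements (evening element AATATC, I-box
#: GATAA, CDA-1 CAAAA, W-box TTGACC, CCAAT box) to 8-mers of mixed base
#: composition so their chance rate in 1 kb of AT-rich background stays low
#: (~1-2% of promoters) and planted presence carries the signal.
_MOTIF_POOL = ["AATATCCG", "GATAAGCG", "CAAAATGC", "TTGACCGA", "GGCCAATC"]
DEFAULT_CLASS_MOTIFS: dict[int, tuple[str, ...]] = {
    1: tuple(_MOTIF_POOL[0:3]),
    3: tuple(_MOTIF_POOL[1:4]),
    2: tuple(_MOTIF_POOL[2:5]),
    4: (_MOTIF_POOL[3], _MOTIF_POOL[4], _MOTIF_POOL[0]),
}


@dataclass
class SimulationSpec:
    """Conditions for a synthetic circadian time course.

    Defaults give the reference dataset used throughout the test suite:
    2000 genes of which 200 cycle, split over four phase classes, sampled at
    12 points 4 h apart (two full 24 h periods), amplitude ~ U(1, 2) against
    noise_sd 0.5 (signal-to-noise >= 2).
    """

    n_genes: int = 2000
    n_circadian: int = 200
    timepoints: tuple[float, ...] = tuple(float(4 * i) for i in range(12))
    period_h: float = 24.0
    phase_assignment: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_ASSIGNMENT))
    #: share of circadian genes per class; midday-dominant, mirroring the
    #: strong noon clustering real free-running plant time courses show.
    #: Unequal shares anchor the two latent axes (equal shares would make the
    #: circadian plane rotationally symmetric and the axes unidentifiable).
    class_proportions: dict[int, float] = field(
        default_factory=lambda: {3: 0.40, 1: 0.25, 2: 0.20, 4: 0.15})
    amplitude_range: tuple[float, float] = (1.0, 2.0)
    #: sub-threshold rhythmicity of the remaining genes: free-running plant
    #: transcriptomes are pervasively but weakly clock-influenced, so the two
    #: latent trends dominate total variance while only strong cyclers pass
    #: the radial cutoff.  Each weak gene follows both trends with
    #: independent coefficients c1 ~ Laplace(0, b1), c2 ~ Laplace(0, b2)
    #: (clipped) — a sparse, heavy-tailed strength distribution, which is
    #: exactly the source model ICA assumes for expression data.  The
    #: resulting weak peak phases cover the full circle, and b1 > b2 mirrors
    #: the stronger midday trend real data show, anchoring the first latent
    #: axis for the variance ordering.  b1 scales the noon-midnight axis
    #: (the trend peaking at the noon class's hour), b2 the dawn-dusk axis.
    subthreshold_scales: tuple[float, float] = (0.15, 0.10)
    subthreshold_clip: tuple[float, float] = (0.35, 0.28)
    noise_sd: float = 0.5
    baseline_range: tuple[float, float] = (6.0, 10.0)
    #: optional third latent trend — a rhythm gradually lost after transfer
    #: to constant conditions.  ``damping_fraction * n_circadian`` additional
    #: genes (drawn from the non-circadian pool) share the single profile
    #: cos(w*(t - damped_peak_h)) * exp(-damping_rate * t); a shared profile
    #: is what makes this one extra latent dimension rather than a smear.
    damping_fraction: float = 0.0
    damping_rate: float = 0.06
    damped_peak_h: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_circadian > self.n_genes:
            raise ValueError("n_circadian exceeds n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if len(self.timepoints) < 3:
            raise ValueError("need at least 3 timepoints")
        if self.damping_fraction < 0:
            raise ValueError("damping_fraction must be >= 0")
        if set(self.class_proportions) != set(self.phase_assignment):
            raise ValueError("class_proportions keys must match phase_assignment")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")


@dataclass
class PromoterSimSpec:
    """Conditions for synthetic 1 kb promoters with planted motif sets."""

    gene_modules: dict[str, int] = field(default_factory=dict)  # gene -> class 1..4
    class_motifs: dict[int, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MOTIFS))
    p_in_class: float = 0.9
    p_out_class: float = 0.1
    promoter_length: int = 1000
    base_composition: tuple[float, float, float, float] = (0.31, 0.19, 0.19, 0.31)
    seed: int = 0

    def validate(self) -> None:
        if not self.gene_modules:
            raise ValueError("gene_modules is empty")
        for p in (self.p_in_class, self.p_out_class):
            if not 0 <= p <= 1:
                raise ValueError("planting probabilities must lie in [0, 1]")
        for cls, motifs in self.class_motifs.items():
            for m in motifs:
                if not (5 <= len(m) <= 8) or set(m) - set("ACGT"):
                    raise ValueError(f"class {cls}: invalid motif {m!r}")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")


def simulate_expression(spec: SimulationSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate an expression matrix plus its ground-truth table.

    Circadian rows are ``baseline + amplitude * cos(2*pi*(t - peak)/period)``
    (times an exponential envelope for the damping fraction) + Gaussian noise;
    the rest are baseline + a weak sub-threshold wave at a uniform-random
    phase + noise.  Returns the raw (un-normalized) matrix and a truth
    DataFrame with columns gene_id, is_circadian, peak_phase, amplitude,
    module (peak_phase/amplitude are filled for weak genes too; their module
    is 0).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.timepoints, dtype=float)
    n, m = spec.n_genes, t.size
    gene_ids = [f"G{i:05d}" for i in range(n)]

    classes = sorted(spec.phase_assignment)
    module = np.zeros(n, dtype=int)
    peak = np.full(n, np.nan)
    is_circ = np.zeros(n, dtype=bool)
    is_circ[: spec.n_circadian] = True
    # deterministic class counts from the proportions (largest remainder)
    exact = {c: spec.class_proportions[c] * spec.n_circadian for c in classes}
    counts = {c: int(np.floor(exact[c])) for c in classes}
    leftover = spec.n_circadian - sum(counts.values())
    for c in sorted(classes, key=lambda c: exact[c] - np.floor(exact[c]), reverse=True)[:leftover]:
        counts[c] += 1
    class_seq = [c for c in classes for _ in range(counts[c])]
    module[: spec.n_circadian] = class_seq
    peak[: spec.n_circadian] = [spec.phase_assignment[c] for c in class_seq]

    baseline = rng.uniform(*spec.baseline_range, size=n)
    V = np.tile(baseline[:, None], (1, m)) + rng.normal(0.0, spec.noise_sd, size=(n, m))
    # every gene is baseline + c1*cos(wt) + c2*sin(wt) (+ damping) + noise;
    # strong cyclers have (c1, c2) on the circle of their class peak, weak
    # genes draw c1, c2 independently.
    w = 2 * np.pi / spec.period_h
    amp = np.empty(n)
    amp[: spec.n_circadian] = rng.uniform(*spec.amplitude_range, size=spec.n_circadian)
    c1 = amp[: spec.n_circadian] * np.cos(w * peak[: spec.n_circadian])
    c2 = amp[: spec.n_circadian] * np.sin(w * peak[: spec.n_circadian])
    (b1, b2), (l1, l2) = spec.subthreshold_scales, spec.subthreshold_clip
    n_weak = n - spec.n_circadian
    # heavy scale b1 on the noon-midnight axis: noon peaks at 6 h, i.e. the
    # sin(wt) trend, so b1 multiplies the sin coefficient
    noon_hour = spec.phase_assignment.get(3, spec.period_h / 4)
    ax1 = np.array([np.cos(w * noon_hour), np.sin(w * noon_hour)])
    ax2 = np.array([-ax1[1], ax1[0]])
    ca = np.clip(rng.laplace(0.0, b1, size=n_weak), -l1, l1)
    cb = np.clip(rng.laplace(0.0, b2, size=n_weak), -l2, l2)
    c1 = np.concatenate([c1, ca * ax1[0] + cb * ax2[0]])
    c2 = np.concatenate([c2, ca * ax1[1] + cb * ax2[1]])
    amp[spec.n_circadian:] = np.hypot(c1[spec.n_circadian:], c2[spec.n_circadian:])
    peak[spec.n_circadian:] = (np.arctan2(c2[spec.n_circadian:],
                                          c1[spec.n_circadian:]) / w) % spec.period_h
    cos_t, sin_t = np.cos(w * t), np.sin(w * t)
    V += c1[:, None] * cos_t + c2[:, None] * sin_t

    # damping trend: a shared damped-cosine profile on extra genes
    n_damped = int(round(spec.damping_fraction * spec.n_circadian))
    is_damped = np.zeros(n, dtype=bool)
    if n_damped:
        if spec.n_circadian + n_damped > n:
            raise ValueError("damping_fraction leaves no room for damped genes")
        lo, hi = spec.n_circadian, spec.n_circadian + n_damped
        is_damped[lo:hi] = True
        damped_profile = (np.cos(w * (t - spec.damped_peak_h))
                          * np.exp(-spec.damping_rate * t))
        amp_d = rng.uniform(*spec.amplitude_range, size=n_damped)
        # replace the weak wave on these genes with the damped trend
        V[lo:hi] -= c1[lo:hi, None] * cos_t + c2[lo:hi, None] * sin_t
        V[lo:hi] += amp_d[:, None] * damped_profile
        amp[lo:hi] = amp_d
        peak[lo:hi] = np.nan

    order = rng.permutation(n)  # shuffle so cyclers are not a contiguous block
    truth = pd.DataFrame({
        "gene_id": [gene_ids[i] for i in order],
        "is_circadian": is_circ[order],
        "is_damped": is_damped[order],
        "peak_phase": peak[order],
        "amplitude": amp[order],
        "module": np.where(is_circ[order], module[order], 0),
    })
    X = ExpressionMatrix([gene_ids[i] for i in order], list(t), V[order], normalized=False)
    return X, truth


_BASES = np.array(list("ACGT"))


def simulate_promoters(spec: PromoterSimSpec) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate promoters with class motif sets planted at random positions.

    Each gene's promoter is i.i.d. background sequence; every motif of every
    class is planted independently with probability ``p_in_class`` if the gene
    belongs to that class, else ``p_out_class``, at uniform-random
    non-overlapping positions.  Returns (gene -> sequence, truth table of
    planted motifs per gene).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.promoter_length
    probs = np.asarray(spec.base_composition)
    promoters: dict[str, str] = {}
    rows = []
    for gene, cls in spec.gene_modules.items():
        seq = rng.choice(4, size=L, p=probs)
        planted = []
        own = set(spec.class_motifs.get(cls, ()))
        all_motifs = sorted({m for ms in spec.class_motifs.values() for m in ms})
        for motif in all_motifs:
            p = spec.p_in_class if motif in own else spec.p_out_class
            if rng.random() < p:
                planted.append(motif)
        occupied: list[tuple[int, int]] = []
        total = sum(len(mo) for mo in planted)
        if total > L:
            raise ValueError(f"{gene}: motifs total {total} bp exceed promoter length {L}")
        for motif in planted:
            pos = _place(rng, L, len(motif), occupied)
            occupied.append((pos, pos + len(motif)))
            seq[pos:pos + len(motif)] = [("ACGT").index(b) for b in motif]
        promoters[gene] = "".join(_BASES[seq])
        rows.append({"gene_id": gene, "module": cls,
                     "planted_motifs": ",".join(planted)})
    return promoters, pd.DataFrame(rows)


def _place(rng, L: int, k: int, occupied, max_tries: int = 1000) -> int:
    for _ in range(max_tries):
        pos = int(rng.integers(0, L - k + 1))
        if all(pos + k <= a or pos >= b for a, b in occupied):
            return pos
    raise ValueError("could not place motif without overlap; too many/long motifs")


def simulate_study_pair(spec: SimulationSpec, study_noise_sd: float = 0.5,
                        conserved_fraction: float = 1.0, seed: int = 0,
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate two studies sharing latent circadian structure.

    Study A is ``simulate_expression(spec)``.  Study B regenerates a
    ``conserved_fraction`` of genes from the same latent trends (same class,
    peak and amplitude statistics) with independent noise of
    ``study_noise_sd``; the remaining genes are re-randomized (noise only).
    The ortholog map is the identity over gene ids.

    Returns (Xa, Xb, ortholog_map, truth) where truth adds a ``conserved``
    column to study A's truth table.
    """
    spec.validate()
    Xa, truth = simulate_expression(spec)
    rng = np.random.default_rng(seed + 1)
    t = np.asarray(spec.timepoints)
    n, m = Xa.n, Xa.m
    conserved = rng.random(n) < conserved_fraction
    baseline = rng.uniform(*spec.baseline_range, size=n)
    Vb = np.tile(baseline[:, None], (1, m)) + rng.normal(0.0, study_noise_sd, size=(n, m))
    circ = truth["is_circadian"].to_numpy()
    peaks = truth["peak_phase"].to_numpy()
    amp = truth["amplitude"].to_numpy()
    new_peaks = rng.uniform(0.0, spec.period_h, size=n)
    for i in range(n):
        if np.isnan(peaks[i]):
            continue  # transient (damped) genes are not regenerated in B
        if conserved[i]:
            # same latent phase and amplitude, independent noise
            Vb[i] += amp[i] * np.cos(2 * np.pi * (t - peaks[i]) / spec.period_h)
        else:
            # re-randomized: same amplitude class but an unrelated phase
            Vb[i] += amp[i] * np.cos(2 * np.pi * (t - new_peaks[i]) / spec.period_h)
    Xb = ExpressionMatrix(list(Xa.gene_ids), list(Xa.time_hours), Vb, normalized=False)
    omap = pd.DataFrame({"gene_a": Xa.gene_ids, "gene_b": Xa.gene_ids})
    truth = truth.assign(conserved=conserved)
    return Xa, Xb, omap, truth
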