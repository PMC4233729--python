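# Methods

`circaphase` implements an unbiased pipeline for finding circadian genes in
short free-running expression time courses, grouping them into four phase
modules, scoring how well those modules are conserved between studies, and
classifying phase from combinations of promoter elements with a Random
Forest. This note records the model, the choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Pre-processing

The input is an `n x m` matrix `X` of `n` genes at `m` timepoints (typically
12 points at 4 h intervals — two full circadian cycles under constant
conditions). Pre-processing applies, in order: log2 transform (optional, for
intensity-scale data), column centring, column scaling to unit SD, row
centring, row scaling to unit SD. After this every gene's transcriptional
response has mean 0 and unit standard deviation, so genes contribute equally
regardless of expression level. All moments are population moments
(`ddof=0`); with the population convention the closed-form kurtosis of a
sampled sinusoid (−1.5) is exact, which the tests exploit.

Two consequences matter downstream. First, row standardization makes every
row sum to zero, so the matrix has rank at most `m − 1`; decompositions
default to the numerical rank rather than `m` (FastICA degenerates on
rank-deficient input). Second, the chain is only approximately idempotent:
after one pass the columns are near-standardized (they average over all
genes), so a second pass moves values at the `1/sqrt(n)` scale, not zero.

Constant rows are a hard error naming the offending genes — silent dropping
would make reported circadian-gene counts irreproducible. `log2` of
non-positive values is an error unless a pseudocount is supplied explicitly.

## Eigentrends

The normalized matrix is modelled as `X = A S`: rows of `S` are latent time
profiles ("eigentrends"), `A` holds per-gene loadings. FastICA (scikit-learn)
estimates the decomposition; because it is randomly initialized and its
component order/sign are arbitrary, `run_ica` averages `n_runs` (default
100) fits after aligning each run to the first by greedy maximal absolute
correlation with sign flipping, then renormalizes the averaged profiles and
recomputes loadings as `X @ S.T`.

Components are annotated with the excess kurtosis of the gene-projection
distribution along them and ordered ascending (most negative first). The
kurtosis signature is regime-dependent: a broad phase continuum gives
platykurtic (negative-kurtosis) projections along circadian trends, whereas
a few discrete phase classes against a Gaussian background give leptokurtic
ones. In both regimes the circadian components are the kurtosis *extreme*
of the decomposition — the property the pipeline and tests rely on.

### In-plane rotation and anchoring

Two orthogonal trends of the same period span a plane, and independence
criteria under-determine the rotation *within* that plane. This is not an
implementation artifact: after row standardization, genes drawn from a
four-class phase structure place the most non-Gaussian in-plane direction on
the inter-class diagonal, 45° off the class axes, for every even FastICA
contrast (logcosh, exp, cube) — and for discrete classes the axis fixed
points are unstable, so single runs and averages alike settle on the
diagonal. An odd (skewness) contrast, available as `fun="skew"` (the same
convention as the reference FastICA distribution), keys on phase-class
asymmetry instead and is offered for exploration.

The pipeline resolves the rotation explicitly with `anchor_phase_axes`:

1. Genes are unit-normalized and projected into the plane; genes with
   in-plane radius ≥ 0.7 vote (restricting to clearly rhythmic genes avoids
   the small anti-modal bias that column centring leaves on weak genes).
2. The four-fold orientation is the circular mean of `4θ`,
   `ψ = arg(Σ r·e^{4iθ})/4` — phase modules impose a four-fold angular
   symmetry whose orientation this estimates with sub-degree precision.
3. Of the four candidate axes `ψ + k·90°`, the quarter is labelled by
   Zeitgeber time, which the experiment provides for free: the candidate
   whose fitted cosine peaks nearest 6 h becomes `+v1` (noon–midnight axis)
   and the orthogonal direction peaking nearest 0 h becomes `+v2`
   (dawn–dusk axis).

`extract_circadian_pair` chains `run_ica` at `d = 2`, a free-phase cosine
check (`cosine_r2`, floor 0.5, with a manual override escape hatch), and the
anchor. Extraction at `d = 2` is deliberate: on 12-point data, full-rank ICA
components are unstable mixtures, consistent with truncating to the
significant components before interpretation.

## How many components? The empirical significance test

For dimension `d`, the reconstruction error `r.e. = ||X − Â Ŝ||_F` of a
`d`-component fit (least-squares loadings against the averaged profiles) is
compared with the errors of randomized matrices. Two randomizers are
provided: `row_permute` (each gene's values independently permuted — exactly
preserving row marginals) and `swap_discretized` (equal-frequency decile
binning, `10·n·m` swap moves between same-bin cells, preserving every row
and column bin histogram).

The default statistic is the **increment**: the decrease in error from
`d − 1` to `d` components, with p the fraction of randomized matrices whose
`d`-th component gains at least as much. A structureless direction gains no
more than chance, so p jumps once `d` exceeds the number of real trends —
the elbow of the reconstruction-error curve. The literal comparison of raw
rank-`d` errors is retained as `statistic="absolute"`, but it discriminates
poorly above the true dimension: the leading real trends sit inside every
rank-`d` fit, holding the real error below essentially all randomized errors
for every `d` at or beyond them. p-values are plain frequencies (0 is
possible); a `(k+1)/(N+1)` flag exists for downstream use.

## Projection, circadian calling, modules

Gene vectors are rescaled to unit Euclidean norm before projection, so with
orthonormal components the radius `sqrt(q1² + q2²)` lies in [0, 1] and
behaves like a correlation-type similarity — this is what makes the radial
cutoff of 0.8 meaningful (raw dot products would scale with `sqrt(m)`).
The cutoff is inclusive (radius ≥ 0.8). Modules are assigned to the signed
axis with the largest projection — `+q1` noon (3), `−q1` midnight (4),
`+q2` dawn (1), `−q2` dusk (2) — with exact ties resolved by that fixed
precedence order. `phase_h` maps the angular position to an estimated peak
hour: `(6 − angle/2π · 24) mod 24`, so a gene on the noon axis reads 6 h and
one on the dawn axis reads 0 h; phase advances clockwise because peak hour
decreases counter-clockwise under this axis convention. `circular_order`
sorts circadian genes by angle for the circular expression heat-map export.

## Cross-study conservation

The integrative correlation (corCor) of an ortholog pair is the Pearson
correlation between the pair's correlation profiles: gene `x`'s correlations
with the other `m − 1` mapped genes in study A versus ortholog `y`'s
correlations over the same ortholog-aligned list in study B. Profiles are
computed over the mapped gene universe only; pairs with constant expression
are excluded with a warning. The null shuffles values within every gene row
of study B. The implementation is a standardized matrix product, checked in
the tests against a literal double-loop oracle to 1e-10.

Module preservation builds co-expression graphs per study (edges: Pearson
r ≥ 0.8, one-sided — anti-correlated pairs are not edges; an |r| flag
exists), scores the Jaccard overlap `|E1 ∩ E2| / |E1 ∪ E2|` of the two
modules' edge sets (1 when both are empty), and normalizes against a null of
random gene sets of the same sizes drawn from the mapped universe
(z-score; a degenerate zero-variance null reports an infinite sentinel with
a warning). The same-size random-set null is this package's explicit choice
where the randomization scheme was open.

## Promoter elements and the phase classifier

Candidate cis elements are all 5–8-mers over ACGT. Counting is exact,
overlapping, single-strand (promoters arrive oriented 5'→3'; a
reverse-complement flag exists); windows containing N never match.
Over-representation uses a one-sided hypergeometric test on promoter-level
presence/absence (target vs background), ranked by p-value with
lexicographic tie-breaks; the top 21 become the feature set, and features
are binary presence by default.

One one-vs-rest forest of 2000 trees is trained per phase class, with
`mtry = floor(sqrt(#features))` (4 for 21 features). Training uses a
stratified random two-thirds with an equal number of genes per class
(downsampled to the smallest class); the held-out third supplies
vote-fraction scores for ROC curves (threshold sweep; trapezoid AUC, equal
to the Mann–Whitney U statistic normalized by `n₊·n₋`), the confusion table,
and permutation importance (VIMP: mean decrease in held-out accuracy over 10
shuffles of a feature column, ties lexicographic). One-vs-rest forests
rather than a single multiclass forest because class-conditional importance
is what the progressive analysis consumes. A repeated-split mode
(`n_splits > 1`) reports mean ± sd AUC.

Two properties of permutation VIMP shape the downstream tables. It is
**sign-blind** — the absence of a neighbouring phase's element discriminates
a class as well as the presence of its own — so the progressive
presence/absence table gates motifs on positive in-class association (mean
presence higher in-class than out) when the trained model is supplied.  And
importance **splits across correlated features**: the top-21 enrichment
inevitably admits substring variants of a strong element (every
planted-correlated k-mer outranks noise k-mers), so rankings are best read
at the level of element families (substring-related groups), the way
presence tables in this literature list AATATC and ATATC as related columns.
The progressive table emits classes in circadian day order (dawn, noon,
dusk, midnight) and repeats the block once ("double plotting") to make the
cyclic progression visible.

`mean_phase_of_combination` averages the (q1, q2) projections of circadian
genes carrying every element of a combination; an `exclude` list restricts
the group to the *distinct* combination of one class — progressive overlap
means a neighbouring class's genes already carry most of a combination, and
without the exclusion they drag the mean vector measurably toward their own
axis.

## The synthetic benchmark

`synthetic_data` generates studies with full ground truth. Every gene is
`baseline + c1·cos(ωt) + c2·sin(ωt) (+ damped trend) + N(0, noise_sd)`:

- **Strong cyclers** (default 200 of 2000): `(c1, c2)` on the circle of
  their class peak (dawn 0 h, noon 6 h, dusk 12 h, midnight 18 h), amplitude
  U(1, 2) against noise SD 0.5 — signal-to-noise 2–4. Class shares are
  unequal (noon 0.40, dawn 0.25, dusk 0.20, midnight 0.15), mirroring the
  midday-dominant clustering of real free-running plant data; equal shares
  would make the circadian plane rotationally symmetric and the axes
  unidentifiable for any method.
- **Sub-threshold genes** (the rest): independent `c1 ~ Laplace(0, 0.15)`,
  `c2 ~ Laplace(0, 0.10)` (clipped at 0.35/0.28) — pervasive weak clock
  influence with a sparse, heavy-tailed strength distribution, which is the
  source model ICA itself assumes. This makes the two trends dominate total
  variance while keeping every weak gene safely below the 0.8 radius, and
  it gives the full continuum of weak peak phases.
- **Damping trend** (optional): extra genes share the single profile
  `cos(ω(t − 8)) · e^{−λt}` — a rhythm fading after transfer to constant
  conditions. A shared profile is what makes this one additional latent
  dimension rather than a smear across several.

The component-count benchmark (`three_trend_spec`) strengthens this third
trend (360 genes, decay 0.10/h, amplitudes 2.2–2.8 against noise 0.8) and
quiets the weak background so that "how many trends?" is a question with a
non-trivial answer.

Promoters are 1 kb of i.i.d. sequence at A/C/G/T = 0.31/0.19/0.19/0.31
(AT-rich, as plant promoters are), with per-class element sets planted at
uniform random non-overlapping positions: probability 0.9 for a gene's own
class elements, 0.1 otherwise, one draw per distinct element. The five
default elements extend cores of known circadian/light elements (evening
element AATATC, I-box GATAA, CDA-1 CAAAA, W-box TTGACC, CCAAT box) to
8-mers of mixed composition so that their chance rate in AT-rich background
stays near 1–2% and planted presence carries the signal. The class sets
overlap progressively — {M1,M2,M3}, {M2,M3,M4}, {M3,M4,M5}, {M4,M5,M1}
around the day — so neighbouring phases share elements, which is the
combinatorial-grammar structure the classifier is supposed to resolve.

What passing on this benchmark does *not* show: microarray platform noise
(probe effects, saturation), probe-set-to-gene collapsing, non-sinusoidal
waveforms, period drift, sequence evolution of promoters, or degenerate
(PWM-style) motifs. Real cross-platform comparisons also add homology
ambiguity and laboratory effects that the identity ortholog map of the
simulator sidesteps.

## Problem sizes and numerical choices

The shipped analyses use 2000 genes × 12 timepoints, 100 ICA runs, 200
randomizations for the component test, 100 permutations for module
preservation, 10 corCor null permutations, and a 4 × 250-gene promoter
design with 2000-tree forests; these sizes make the full pipeline and its
tests complete in a few minutes on one core while leaving all recovery
margins wide. Tolerances: component unit norms and normalization contracts
at 1e-9; corCor against its brute-force oracle at 1e-10; ICA stochasticity
allowance of 1% on the monotone reconstruction-error property. Ties are
always broken deterministically (lexicographic for motifs, fixed precedence
for module axes); every stochastic routine takes an explicit seed and is
bitwise reproducible under it.

## Known limitations

- The in-plane rotation of the circadian pair is fundamentally
  unidentifiable from independence alone; the anchor resolves it using the
  four-fold symmetry and Zeitgeber labels, which presumes a phase-module
  structure and a known dawn.
- The empirical component test's increment statistic judges one added
  component at a time; strongly correlated latent trends (e.g. a damped
  copy of an existing trend) can split across dimensions and be
  under-counted.
- Permutation VIMP on correlated binary features dilutes importance within
  element families; rankings are reliable at family level, not for choosing
  among near-identical variants.
- The 0.8 radial cutoff and 0.8 co-expression threshold are conventions
  carried from the underlying method, not optimized values.
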