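# circaphase

Unbiased discovery of circadian genes in short free-running expression time
courses, and classification of their phase of expression from combinatorial
promoter elements.

Plant transcriptomes sampled every 4 h for two days under constant
conditions carry two dominant, orthogonal ~24 h latent trends. `circaphase`
extracts these "eigentrends" by averaged independent component analysis,
projects every gene onto them, calls genes circadian by a radial cutoff on
the projection, sorts them into four phase modules (dawn, noon, dusk,
midnight) by their strongest signed axis, quantifies how well modules are
conserved between studies or species, and asks — with a Random Forest over
k-mer promoter features — whether progressive combinations of cis elements
predict a gene's phase module. It is written for computational biologists
working with bulk circadian time courses (microarray or RNA-seq counts
summarized to a genes × timepoints table) and promoter sequence sets.

## The model

The normalized expression matrix is decomposed as

    X = A S,        X ∈ R^(n×m),  A ∈ R^(n×d),  S ∈ R^(d×m)

where rows of `S` are latent time profiles and `A` carries gene loadings.
FastICA is run many times and the aligned runs averaged; components are
ordered by the excess kurtosis of the gene projections along them, and an
empirical randomization test on the reconstruction error `‖X − Â Ŝ‖_F`
decides how many components significantly represent the data. Each gene's
unit-normalized response `n_i` is projected on the two circadian components
`v_k` as `q_{i,k} = n_i · v_k`; genes with radius `√(q₁² + q₂²) ≥ 0.8` are
circadian, and the signed axis with the largest projection fixes the phase
module. Cross-study reproducibility uses the integrative correlation
(corCor) between ortholog correlation profiles and a Jaccard score
`TP/(TP+FP+FN)` on co-expression graph edges (r ≥ 0.8), normalized to a
z-score against same-size random modules. Phase classification trains one
2000-tree Random Forest per module (mtry = ⌊√p⌋) on binary motif-presence
features chosen by hypergeometric over-representation, and reports held-out
ROC/AUC, permutation variable importance (VIMP), a progressive
presence/absence table of elements across the circadian day, and the mean
projection of genes carrying each module's distinct element combination.

See `docs/methods.md` for the full account, including how the in-plane
rotation of the circadian pair is anchored and what the synthetic benchmark
does and does not emulate.

## Worked example

```python
import numpy as np
from circaphase import (
    reference_spec, simulate_expression, preprocess, extract_circadian_pair,
    project_genes, classify_circadian, assign_modules,
)

X, truth = simulate_expression(reference_spec(seed=1))   # 2000 genes x 12 timepoints
Xn = preprocess(X, apply_log2=False)
v1, v2, dec = extract_circadian_pair(Xn, n_runs=100, seed=12)
proj = assign_modules(classify_circadian(project_genes(Xn, v1, v2), cutoff=0.8))

t = np.asarray(Xn.time_hours)
sin = np.sin(2 * np.pi * t / 24)
print("kurtosis of the two components:", np.round(dec.kurtosis, 2))
print("|r| of v1 vs the planted noon trend:",
      round(abs(np.corrcoef(v1, sin)[0, 1]), 4))
print("circadian genes at cutoff 0.8:", proj.n_circadian)
counts = {m: int((proj.module == m).sum()) for m in (1, 2, 3, 4)}
print("module sizes (dawn, dusk, noon, midnight):", counts)
```

prints

```
kurtosis of the two components: [-0.82 -0.79]
|r| of v1 vs the planted noon trend: 0.9953
circadian genes at cutoff 0.8: 263
module sizes (dawn, dusk, noon, midnight): {1: 58, 2: 51, 3: 93, 4: 61}
```

The negative kurtosis marks the two components as the trends that an
unusually broad share of genes follow; v1 recovers the planted noon
(sin) trend to r ≈ 0.995; 263 of 2000 genes pass the radial cutoff —
the 200 planted cyclers (96% recall here) plus a small tail of
weakly rhythmic background genes — and the module sizes reflect the
midday-dominant phase distribution the generator plants.

The same stages are available from the shell for file-based work
(`circaphase --help`): `simulate`, `preprocess`, `ica`, `significance`,
`project`, `corcor`, `preserve`, `motifs`, `classify`, and `full`, each
writing TSV/JSON artifacts plus a run manifest, with one master seed and a
YAML config whose defaults are the pipeline's fixed constants (cutoff 0.8,
100 ICA runs, top-21 motifs, 2000 trees, ...).

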