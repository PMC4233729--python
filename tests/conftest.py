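"""Shared fixtures: the reference synthetic study and the trained classifier.

Everything expensive (averaged ICA, Random-Forest training) is computed once
per session; individual tests read from these artifacts.
"""

from __future__ import annotations

import numpy as np
import pytest

from circaphase import (
    DEFAULT_CLASS_MOTIFS, ForestConfig, PromoterSet, PromoterSimSpec,
    build_feature_matrix, assign_modules, classify_circadian, enrichment_rank,
    extract_circadian_pair, preprocess, project_genes, reference_spec,
    simulate_expression, simulate_promoters, train_phase_forests,
)

#: motifs planted by the default promoter design, in pool order
PLANTED_POOL = sorted({m for ms in DEFAULT_CLASS_MOTIFS.values() for m in ms})


def motif_family(feature: str) -> list[str]:
    """Planted elements a feature belongs to (substring in either direction)."""
    return [p for p in PLANTED_POOL if p in feature or feature in p]


@pytest.fixture(scope="session")
def reference_study():
    """Reference expression dataset, normalized, with truth."""
    X, truth = simulate_expression(reference_spec(seed=1))
    Xn = preprocess(X, apply_log2=False)
    return Xn, truth.set_index("gene_id")


@pytest.fixture(scope="session")
def circadian_pair(reference_study):
    """Anchored circadian component pair for the reference dataset."""
    Xn, _ = reference_study
    v1, v2, dec = extract_circadian_pair(Xn, n_runs=100, seed=501)
    return v1, v2, dec


@pytest.fixture(scope="session")
def reference_projection(reference_study, circadian_pair):
    Xn, _ = reference_study
    v1, v2, _ = circadian_pair
    proj = classify_circadian(project_genes(Xn, v1, v2), cutoff=0.8)
    return assign_modules(proj)


@pytest.fixture(scope="session")
def classifier_design():
    """The four-class, 250-genes-per-class promoter design with enrichment,
    features and the trained one-vs-rest forests."""
    genes = {f"G{i:04d}": (i % 4) + 1 for i in range(1000)}
    promoters, _ = simulate_promoters(PromoterSimSpec(gene_modules=genes, seed=5))
    background, _ = simulate_promoters(PromoterSimSpec(
        gene_modules={f"B{i:04d}": 1 for i in range(400)},
        p_in_class=0.0, p_out_class=0.0, seed=99))
    target = PromoterSet(promoters)
    enrichment = enrichment_rank(target, PromoterSet(background), top_n=21)
    features = build_feature_matrix(target, enrichment["motif"].tolist())
    model, report = train_phase_forests(features, genes, ForestConfig(seed=11))
    return {"genes": genes, "promoters": target, "enrichment": enrichment,
            "features": features, "model": model, "report": report}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
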