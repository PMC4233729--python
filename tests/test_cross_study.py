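import numpy as np
import pytest

from circaphase import (
    ExpressionMatrix, OrthologMap, coexpression_edges, corcor_null,
    integrative_correlation, jaccard_similarity, module_preservation,
    preprocess, simulate_study_pair, SimulationSpec,
)
from circaphase.cross_study import read_ortholog_map


def _matrix(V, prefix="G"):
    V = np.asarray(V, float)
    return ExpressionMatrix([f"{prefix}{i}" for i in range(V.shape[0])],
                            list(range(V.shape[1])), V)


def _identity_map(X):
    return OrthologMap([(g, g) for g in X.gene_ids])


def corcor_bruteforce(Xa, Xb, omap):
    """Independent double-loop oracle for the integrative correlation."""
    def pearson(x, y):
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        return float((x * y).mean())

    A = Xa.subset(omap.genes_a).values
    B = Xb.subset(omap.genes_b).values
    m = len(omap)
    out = np.empty(m)
    for i in range(m):
        prof_a = [pearson(A[i], A[j]) for j in range(m) if j != i]
        prof_b = [pearson(B[i], B[j]) for j in range(m) if j != i]
        out[i] = pearson(np.array(prof_a), np.array(prof_b))
    return out


class TestIntegrativeCorrelation:
    def test_identical_studies_give_one(self, rng):
        X = _matrix(rng.normal(size=(8, 6)))
        res = integrative_correlation(X, X, _identity_map(X))
        np.testing.assert_allclose(res.corcor, 1.0, atol=1e-9)

    def test_negated_study_gives_one(self, rng):
        X = _matrix(rng.normal(size=(8, 6)))
        Y = _matrix(-X.values)
        res = integrative_correlation(X, Y, _identity_map(X))
        np.testing.assert_allclose(res.corcor, 1.0, atol=1e-9)

    def test_matches_bruteforce_oracle(self, rng):
        Xa = _matrix(rng.normal(size=(10, 6)))
        Xb = _matrix(rng.normal(size=(10, 6)))
        omap = _identity_map(Xa)
        res = integrative_correlation(Xa, Xb, omap)
        np.testing.assert_allclose(res.corcor, corcor_bruteforce(Xa, Xb, omap),
                                   atol=1e-10)

    def test_symmetric_in_studies(self, rng):
        Xa = _matrix(rng.normal(size=(9, 5)))
        Xb = _matrix(rng.normal(size=(9, 5)))
        omap = _identity_map(Xa)
        fwd = integrative_correlation(Xa, Xb, omap)
        rev = integrative_correlation(Xb, Xa, omap.reversed())
        np.testing.assert_allclose(fwd.corcor, rev.corcor, atol=1e-12)

    def test_constant_gene_excluded(self, rng):
        V = rng.normal(size=(6, 5))
        V[2] = 3.0
        Xa = _matrix(V)
        Xb = _matrix(rng.normal(size=(6, 5)))
        with pytest.warns(UserWarning, match="constant"):
            res = integrative_correlation(Xa, Xb, _identity_map(Xa))
        assert np.isnan(res.corcor[2])
        assert ("G2", "G2") in res.excluded

    def test_requires_three_pairs(self, rng):
        Xa = _matrix(rng.normal(size=(3, 5)))
        with pytest.raises(ValueError, match="3"):
            integrative_correlation(Xa, Xa, OrthologMap([("G0", "G0"), ("G1", "G1")]))

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="one-to-one"):
            OrthologMap([("A", "X"), ("A", "Y")])


class TestCorcorNull:
    def test_null_centred_near_zero(self):
        spec = SimulationSpec(n_genes=500, n_circadian=100, seed=21)
        Xa, Xb, omap_df, _ = simulate_study_pair(spec, seed=21)
        Xan = preprocess(Xa, apply_log2=False)
        Xbn = preprocess(Xb, apply_log2=False)
        omap = OrthologMap(list(zip(omap_df.gene_a, omap_df.gene_b)))
        null = corcor_null(Xan, Xbn, omap, n_permutations=20, seed=1)
        assert abs(null.mean()) <= 0.02

    def test_deterministic(self, rng):
        Xa = _matrix(rng.normal(size=(12, 8)))
        Xb = _matrix(rng.normal(size=(12, 8)))
        omap = _identity_map(Xa)
        a = corcor_null(Xa, Xb, omap, n_permutations=3, seed=5)
        b = corcor_null(Xa, Xb, omap, n_permutations=3, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_rejects_zero_permutations(self, rng):
        Xa = _matrix(rng.normal(size=(5, 5)))
        with pytest.raises(ValueError):
            corcor_null(Xa, Xa, _identity_map(Xa), n_permutations=0)


class TestCoexpressionEdges:
    def test_identical_rows_make_an_edge(self):
        V = np.vstack([np.arange(5.0), np.arange(5.0) * 2 + 1,
                       np.array([5, 1, 4, 2, 3.0])])
        X = _matrix(V)
        edges = coexpression_edges(X, X.gene_ids)
        assert frozenset(("G0", "G1")) in edges

    def test_anticorrelated_rows_make_no_edge(self):
        V = np.vstack([np.arange(5.0), -np.arange(5.0), np.ones(5) + np.arange(5) * 0.1])
        X = _matrix(V)
        edges = coexpression_edges(X, X.gene_ids, threshold=0.8)
        assert frozenset(("G0", "G1")) not in edges

    def test_matches_bruteforce(self, rng):
        X = _matrix(rng.normal(size=(20, 8)))
        edges = coexpression_edges(X, X.gene_ids, threshold=0.3)
        expected = set()
        for i in range(20):
            for j in range(i + 1, 20):
                if np.corrcoef(X.values[i], X.values[j])[0, 1] >= 0.3:
                    expected.add(frozenset((f"G{i}", f"G{j}")))
        assert edges == expected


class TestJaccard:
    def test_identity(self):
        e = {frozenset(("a", "b")), frozenset(("b", "c"))}
        assert jaccard_similarity(e, set(e)) == 1.0

    def test_closed_form_third(self):
        e1 = {frozenset(("a", "b")), frozenset(("b", "c"))}
        e2 = {frozenset(("b", "c")), frozenset(("c", "d"))}
        assert jaccard_similarity(e1, e2) == pytest.approx(1 / 3)

    def test_disjoint(self):
        assert jaccard_similarity({frozenset(("a", "b"))},
                                  {frozenset(("c", "d"))}) == 0.0

    def test_both_empty(self):
        assert jaccard_similarity(set(), set()) == 1.0

    def test_monotone_in_intersection(self):
        universe = [frozenset((f"n{i}", f"n{i+1}")) for i in range(10)]
        base = set(universe[:6])
        prev = -1.0
        for k in range(7):
            other = set(universe[:k]) | set(universe[6:6 + (6 - k)])
            j = jaccard_similarity(base, other)
            assert j >= prev
            prev = j


@pytest.fixture(scope="module")
def pair():
    spec = SimulationSpec(n_genes=400, n_circadian=120, seed=31)
    Xa, Xb, omap_df, truth = simulate_study_pair(spec, study_noise_sd=0.5,
                                                 conserved_fraction=1.0, seed=31)
    Xan = preprocess(Xa, apply_log2=False)
    Xbn = preprocess(Xb, apply_log2=False)
    omap = OrthologMap(list(zip(omap_df.gene_a, omap_df.gene_b)))
    mods = truth[truth.is_circadian].groupby("module").gene_id.apply(list)
    return Xan, Xbn, omap, mods


class TestModulePreservation:

    def test_preserved_module_strong_z(self, pair):
        Xan, Xbn, omap, mods = pair
        mp = module_preservation(Xan, Xbn, omap, mods[3], mods[3],
                                 n_permutations=100, seed=7)
        assert mp.z_score >= 5
        assert mp.z_score == pytest.approx((mp.jaccard - mp.null_mean) / mp.null_sd)

    def test_random_module_weak_z(self, pair, rng):
        Xan, Xbn, omap, mods = pair
        random_set = list(rng.choice(Xbn.gene_ids, size=len(mods[3]), replace=False))
        mp = module_preservation(Xan, Xbn, omap, mods[3], random_set,
                                 n_permutations=50, seed=8)
        assert mp.z_score < 5

    def test_deterministic(self, pair):
        Xan, Xbn, omap, mods = pair
        a = module_preservation(Xan, Xbn, omap, mods[1], mods[1],
                                n_permutations=20, seed=9)
        b = module_preservation(Xan, Xbn, omap, mods[1], mods[1],
                                n_permutations=20, seed=9)
        assert a.z_score == b.z_score


def test_read_ortholog_map(tmp_path):
    p = tmp_path / "orth.tsv"
    p.write_text("gene_a\tgene_b\nAT1\tOS1\nAT2\tOS2\n")
    omap = read_ortholog_map(p)
    assert omap.pairs == [("AT1", "OS1"), ("AT2", "OS2")]
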