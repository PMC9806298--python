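"""Co-expression network: TOM oracle, module detection, eigengenes, MM/GS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import immunoscore as im
from immunoscore import coexpression as co


def triple_loop_tom(a: np.ndarray) -> np.ndarray:
    """Independent brute-force TOM from the definition (O(n^3) loops)."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (L + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def random_adjacency(n, rng) -> pd.DataFrame:
    r = rng.uniform(0, 1, size=(n, n))
    a = (r + r.T) / 2
    np.fill_diagonal(a, 1.0)
    idx = [f"g{i}" for i in range(n)]
    return pd.DataFrame(a, index=idx, columns=idx)


class TestFilterGenes:
    def test_zero_keeps_all(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(10, 5)))
        assert co.filter_genes(expr, 0) is expr

    def test_mad_ordering(self):
        expr = pd.DataFrame(
            {"s1": [0, 0, 0], "s2": [1, 10, 0.1], "s3": [-1, -10, -0.1]},
            index=["mid", "wide", "narrow"],
        )
        out = co.filter_genes(expr, 2)
        assert set(out.index) == {"wide", "mid"}

    def test_constant_gene_never_kept(self):
        expr = pd.DataFrame(
            {"s1": [5, 1], "s2": [5, 2], "s3": [5, 3]}, index=["flat", "var"])
        assert list(co.filter_genes(expr, 1).index) == ["var"]


class TestAdjacency:
    def test_perfect_pair_is_one(self):
        expr = pd.DataFrame({"s1": [1, 2], "s2": [2, 4], "s3": [3, 6]},
                            index=["a", "b"], dtype=float)
        for beta in (1, 6, 9):
            assert co.adjacency(expr, beta).loc["a", "b"] == pytest.approx(1.0)

    def test_beta_one_is_abs_correlation(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(6, 30)))
        adj = co.adjacency(expr, 1)
        want = np.abs(np.corrcoef(expr.to_numpy()))
        np.testing.assert_allclose(adj.to_numpy(), want, atol=1e-12)

    def test_independent_pair_shrinks(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(2, 500)), index=["a", "b"])
        assert co.adjacency(expr, 6).loc["a", "b"] < 1e-4

    def test_constant_gene_error(self):
        expr = pd.DataFrame({"s1": [1, 1], "s2": [1, 2], "s3": [1, 3]},
                            index=["flat", "ok"], dtype=float)
        with pytest.raises(ValueError, match="flat"):
            co.adjacency(expr, 6)


class TestSoftThreshold:
    def test_singleton_grid(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(60, 30)))
        beta, table = co.pick_soft_threshold(expr, beta_grid=(6,))
        assert beta == 6
        assert table.shape[0] == 1

    def test_heterogeneous_connectivity_reaches_target(self):
        """A hub continuum (one factor, spread loadings) is scale-free-like."""
        rng = np.random.default_rng(7)
        n_genes, n = 600, 150
        factor = rng.normal(size=n)
        load = rng.uniform(0.05, 1.2, size=n_genes) ** 2
        x = load[:, None] * factor[None, :] + rng.normal(0, 0.8, size=(n_genes, n))
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)])
        beta, table = co.pick_soft_threshold(expr, target_r2=0.85)
        assert table["fit"].max() >= 0.85
        assert float(table.loc[table.beta == beta, "fit"].iloc[0]) >= 0.85

    def test_block_structure_takes_fallback(self, caplog):
        """Equal-size planted blocks have homogeneous connectivity, nothing
        like a scale-free decay, so selection falls back to the conventional
        unsigned power for the sample size."""
        expr, _ = _planted_expression(n_modules=5, genes_per=20, n=80, seed=8)
        with caplog.at_level("WARNING", logger="immunoscore"):
            beta, table = co.pick_soft_threshold(expr)
        assert "falling back" in caplog.text
        assert beta == 6  # conventional unsigned power at n >= 40 samples
        assert table["fit"].max() < 0.85


class TestTOM:
    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            adj = random_adjacency(20, rng)
            got = co.tom_similarity(adj).to_numpy()
            want = triple_loop_tom(adj.to_numpy())
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_identical_neighbourhoods_full_overlap(self):
        # binary network: a-b connected, both fully connected to c and d
        a = np.array([
            [1.0, 1.0, 1.0, 1.0],
            [1.0, 1.0, 1.0, 1.0],
            [1.0, 1.0, 1.0, 0.0],
            [1.0, 1.0, 0.0, 1.0],
        ])
        adj = pd.DataFrame(a, index=list("abcd"), columns=list("abcd"))
        assert co.tom_similarity(adj).loc["a", "b"] == pytest.approx(1.0)

    def test_empty_network_zero_off_diagonal(self):
        adj = pd.DataFrame(np.eye(5))
        tom = co.tom_similarity(adj).to_numpy()
        assert np.allclose(tom, np.eye(5))

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(13)
        tom = co.tom_similarity(random_adjacency(30, rng)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1


def _planted_expression(n_modules=5, genes_per=12, n=80, seed=0):
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(n_modules, n))
    rows, names, truth = [], [], []
    for m in range(n_modules):
        for g in range(genes_per):
            rows.append(2.0 * factors[m] + rng.normal(0, 0.5, size=n))
            names.append(f"m{m}g{g}")
            truth.append(m)
    expr = pd.DataFrame(rows, index=names)
    return expr, pd.Series(truth, index=names)


class TestDetectModules:
    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        expr, truth = _planted_expression()
        tom = co.tom_similarity(co.adjacency(expr, 6))
        labels = co.detect_modules(1 - tom, min_size=5, cut_height=0.9)
        assert adjusted_rand_score(truth, labels) >= 0.8

    def test_min_size_above_gene_count_all_grey(self):
        expr, _ = _planted_expression(n_modules=2, genes_per=5, n=40)
        tom = co.tom_similarity(co.adjacency(expr, 6))
        labels = co.detect_modules(1 - tom, min_size=50, cut_height=0.9)
        assert (labels == "grey").all()

    def test_gene_order_equivariance(self):
        expr, _ = _planted_expression(seed=2)
        tom = co.tom_similarity(co.adjacency(expr, 6))
        diss = 1 - tom
        perm = np.random.default_rng(1).permutation(len(diss))
        diss_p = diss.iloc[perm, perm]
        l1 = co.detect_modules(diss, min_size=5, cut_height=0.9)
        l2 = co.detect_modules(diss_p, min_size=5, cut_height=0.9).loc[l1.index]
        # identical partitions (names may differ only on exact size ties)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(l1, l2) == 1.0

    def test_names_by_decreasing_size(self):
        expr, truth = _planted_expression(n_modules=2, genes_per=10, n=60, seed=3)
        extra, _ = _planted_expression(n_modules=1, genes_per=20, n=60, seed=4)
        extra.index = [f"x{i}" for i in range(len(extra))]
        both = pd.concat([expr, extra])
        tom = co.tom_similarity(co.adjacency(both, 6))
        labels = co.detect_modules(1 - tom, min_size=5, cut_height=0.9)
        sizes = labels[labels != "grey"].value_counts()
        assert sizes.index[0] == "turquoise" and sizes.iloc[0] == 20


class TestEigengenes:
    def test_identical_genes_give_common_profile(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=30)
        expr = pd.DataFrame([profile, profile, profile], index=["a", "b", "c"])
        labels = pd.Series("blue", index=expr.index)
        eig = co.module_eigengenes(expr, labels)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(eig.loc["blue"].to_numpy(), z, atol=1e-8)

    def test_negation_invariance(self):
        expr, _ = _planted_expression(n_modules=1, genes_per=8, n=40)
        labels = pd.Series("brown", index=expr.index)
        e1 = co.module_eigengenes(expr, labels)
        e2 = co.module_eigengenes(-expr, labels)
        np.testing.assert_allclose(e1.to_numpy(), -e2.to_numpy(), atol=1e-10)
        # orientation rule: each correlates positively with its mean profile
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=1), axis=0)
        assert np.corrcoef(e1.loc["brown"], z.mean(axis=0))[0, 1] > 0

    def test_unit_variance(self):
        expr, truth = _planted_expression(n_modules=3, genes_per=6, n=50, seed=5)
        labels = truth.map({0: "blue", 1: "brown", 2: "red"})
        eig = co.module_eigengenes(expr, labels)
        np.testing.assert_allclose(eig.std(axis=1, ddof=1).to_numpy(), 1.0, atol=1e-10)

    def test_explains_more_variance_than_random_directions(self):
        expr, _ = _planted_expression(n_modules=1, genes_per=10, n=60, seed=6)
        labels = pd.Series("blue", index=expr.index)
        eig = co.module_eigengenes(expr, labels).loc["blue"].to_numpy()
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=1), axis=0)
        z = z.to_numpy()

        def explained(direction):
            direction = direction / np.linalg.norm(direction)
            return float(((z @ direction) ** 2).sum())

        best = explained(eig)
        rng = np.random.default_rng(9)
        for _ in range(50):
            assert explained(rng.normal(size=z.shape[1])) <= best + 1e-9


class TestModuleTrait:
    def test_self_correlation(self):
        trait = pd.Series([0, 0, 0, 1, 1, 1], index=list("abcdef"))
        z = (trait - trait.mean()) / trait.std(ddof=1)
        eig = pd.DataFrame([z.to_numpy()], index=["blue"], columns=trait.index)
        out = co.module_trait_correlation(eig, trait)
        assert out.loc["blue", "r"] == pytest.approx(1.0)

    def test_complement_flips_sign(self):
        rng = np.random.default_rng(1)
        trait = pd.Series(rng.integers(0, 2, 20), index=[f"s{i}" for i in range(20)])
        eig = pd.DataFrame(rng.normal(size=(2, 20)), index=["a", "b"],
                           columns=trait.index)
        r1 = co.module_trait_correlation(eig, trait)["r"]
        r2 = co.module_trait_correlation(eig, 1 - trait)["r"]
        np.testing.assert_allclose(r1.to_numpy(), -r2.to_numpy(), atol=1e-12)

    def test_constant_trait_rejected(self):
        eig = pd.DataFrame([[0.1, 0.2, 0.3]], index=["m"], columns=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            co.module_trait_correlation(eig, pd.Series([1, 1, 1], index=list("abc")))


class TestMMGS:
    def test_gene_equal_to_eigengene_has_mm_one(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=40)
        expr = pd.DataFrame([profile, profile * 2 + 1], index=["a", "b"])
        labels = pd.Series("blue", index=expr.index)
        eig = co.module_eigengenes(expr, labels)
        trait = pd.Series(rng.integers(0, 2, 40), index=expr.columns)
        out = co.compute_mm_gs(expr, eig, labels, trait)
        np.testing.assert_allclose(out["MM"].to_numpy(), 1.0, atol=1e-10)

    def test_gs_near_one_for_trait_tracking_gene(self):
        rng = np.random.default_rng(4)
        trait = pd.Series(rng.integers(0, 2, 200))
        expr = pd.DataFrame(
            [trait.to_numpy() + rng.normal(0, 0.01, 200),
             rng.normal(size=200)],
            index=["tracker", "noise"], columns=trait.index,
        )
        labels = pd.Series("grey", index=expr.index)
        out = co.compute_mm_gs(expr, pd.DataFrame(columns=expr.columns), labels, trait)
        assert out.loc["tracker", "GS"] > 0.99
        assert out.loc["noise", "GS"] < 0.2
        assert np.isnan(out.loc["tracker", "MM"])  # grey genes carry no MM

    def test_planted_cohort_signature_modules_track_cluster(self, benchmark_result):
        mt = benchmark_result.modules.module_trait
        assert (mt["r"] < -0.5).all()  # every signature module anti-tracks clusterB
        assert (mt["p"] < 1e-6).all()
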