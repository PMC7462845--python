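"""Correlation-stage tests: Brownian covariance oracles, PGLS against OLS
and statsmodels GLS, Pearson/Bonferroni behaviour and the focal-taxon
pipeline on constructed matrices."""
import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastorate.phylocorr import (
    bonferroni,
    brownian_covariance,
    clade_summary,
    feature_rate_table,
    focal_taxon_correlations,
    pearson_test,
    pgls_fit,
    prune_tree,
)


# ---------------------------------------------------------------------------
# Brownian covariance
# ---------------------------------------------------------------------------

def test_brownian_covariance_two_leaves():
    tree = dendropy.Tree.get(data="(A:1.5,B:1.5);", schema="newick")
    V = brownian_covariance(tree, ["A", "B"])
    assert np.allclose(V, [[1.5, 0.0], [0.0, 1.5]])


def test_brownian_covariance_three_taxon_hand_computed(three_taxon_tree):
    V = brownian_covariance(three_taxon_tree, ["A", "B", "C"])
    assert np.allclose(V, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])


def test_brownian_covariance_star_is_diagonal():
    tree = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1);", schema="newick")
    V = brownian_covariance(tree, ["A", "B", "C", "D"])
    assert np.allclose(V, np.eye(4))


def test_brownian_covariance_unknown_taxon(three_taxon_tree):
    with pytest.raises(ValueError):
        brownian_covariance(three_taxon_tree, ["A", "Z"])


def test_prune_tree_removes_outgroup(three_taxon_tree):
    pruned = prune_tree(three_taxon_tree, ["C"])
    assert sorted(lf.taxon.label for lf in pruned.leaf_node_iter()) == ["A", "B"]
    # original untouched
    assert len(three_taxon_tree.leaf_nodes()) == 3


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

def test_pgls_identity_covariance_equals_ols(rng):
    import statsmodels.api as sm

    n = 30
    x = rng.normal(size=n)
    y = 1.0 + 2.0 * x + rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    fit = pgls_fit(y, X, V=np.eye(n))
    ols = sm.OLS(y, X).fit()
    assert np.allclose(fit.beta, ols.params, atol=1e-8)
    assert np.allclose(fit.se, ols.bse, atol=1e-8)
    assert np.allclose(fit.p, ols.pvalues, atol=1e-8)


def test_pgls_matches_statsmodels_gls(rng):
    import statsmodels.api as sm

    n = 25
    A = rng.normal(size=(n, n))
    V = A @ A.T + n * np.eye(n)
    x = rng.normal(size=n)
    y = 0.5 - 1.2 * x + rng.multivariate_normal(np.zeros(n), V)
    X = np.column_stack([np.ones(n), x])
    fit = pgls_fit(y, X, V=V)
    gls = sm.GLS(y, X, sigma=V).fit()
    assert np.allclose(fit.beta, gls.params, atol=1e-8)
    assert np.allclose(fit.se, gls.bse, atol=1e-8)


def test_pgls_exact_linear_data(three_taxon_tree):
    V = brownian_covariance(three_taxon_tree, ["A", "B", "C"])
    x = np.array([0.0, 1.0, 2.0])
    y = 3.0 + 2.0 * x
    fit = pgls_fit(y, np.column_stack([np.ones(3), x]), V=V)
    assert fit.beta == pytest.approx([3.0, 2.0])
    assert fit.sigma2 == pytest.approx(0.0, abs=1e-16)


def test_pgls_rank_deficiency_names_columns():
    y = np.arange(5.0)
    X = np.column_stack([np.ones(5), np.arange(5.0), 2 * np.arange(5.0)])
    with pytest.raises(ValueError, match="collinear"):
        pgls_fit(y, X, V=np.eye(5), columns=["intercept", "x", "x2"])


def test_pgls_brownian_slope_coverage():
    """Planted slope 2.0 under Brownian residuals: 95% CI covers it in >=90%
    of seeded replicates on a 40-tip tree."""
    from scipy import stats as sps

    from plastorate.synthetic_data import SimulationConfig, simulate_tree

    tree = simulate_tree(SimulationConfig(n_taxa=40, depth=1.0), 99)
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    V = brownian_covariance(tree, taxa)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(40))
    rng = np.random.default_rng(7)
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        x = rng.normal(size=40)
        y = 1.0 + 2.0 * x + L @ rng.normal(size=40)
        fit = pgls_fit(y, np.column_stack([np.ones(40), x]), V=V)
        tcrit = sps.t.ppf(0.975, fit.n - fit.k)
        lo, hi = fit.beta[1] - tcrit * fit.se[1], fit.beta[1] + tcrit * fit.se[1]
        hits += lo <= 2.0 <= hi
    assert hits / n_rep >= 0.90


# ---------------------------------------------------------------------------
# Pearson / Bonferroni
# ---------------------------------------------------------------------------

def test_pearson_exact_three_points():
    assert pearson_test([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
    assert pearson_test([1, 2, 3], [6, 4, 2]).r == pytest.approx(-1.0)


def test_pearson_degenerate_inputs():
    assert "zero_variance" in pearson_test([1, 1, 1], [1, 2, 3]).flags
    assert "too_few_points" in pearson_test([1, 2], [3, 4]).flags


def test_pearson_null_rejection_rate():
    """rho = 0, n = 39: rejection at alpha = .05 within the binomial band."""
    rng = np.random.default_rng(11)
    rejections = sum(
        pearson_test(rng.normal(size=39), rng.normal(size=39)).p < 0.05 for _ in range(1000)
    )
    assert 36 <= rejections <= 64


def test_bonferroni_examples():
    assert bonferroni([0.01], m=40) == [0.4]
    assert bonferroni([0.9], m=2) == [1.0]
    with pytest.raises(ValueError):
        bonferroni([0.1, 0.2], m=1)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
def test_bonferroni_properties(ps):
    adj = bonferroni(ps)
    assert all(a >= p for a, p in zip(adj, ps))  # never decreases
    assert all(a <= 1.0 for a in adj)  # capped
    order = np.argsort(ps)
    assert all(adj[order[i]] <= adj[order[i + 1]] for i in range(len(ps) - 1))  # monotone


# ---------------------------------------------------------------------------
# focal-taxon pipeline on constructed matrices
# ---------------------------------------------------------------------------

def test_focal_correlations_perfect_when_rate_equals_iv(rng):
    k = 10
    iv = rng.integers(1, 20, size=(k, k)).astype(float)
    iv = np.triu(iv, 1) + np.triu(iv, 1).T
    taxa = [f"t{i}" for i in range(k)]
    res = focal_taxon_correlations(taxa, iv, iv)
    assert len(res) == k
    assert all(r.r == pytest.approx(1.0) for r in res)
    assert all(r.significant for r in res)
    assert all(r.p_adj >= r.p for r in res)


def test_focal_correlations_drops_undefined_pairs(rng):
    k = 6
    rate = rng.normal(size=(k, k))
    rate = np.triu(rate, 1) + np.triu(rate, 1).T
    rate[0, 1] = rate[1, 0] = np.nan
    iv = np.abs(rate) + 1
    res = focal_taxon_correlations([f"t{i}" for i in range(k)], rate, iv)
    assert res[0].n == k - 2
    assert any("dropped_undefined_pairs:1" in f for f in res[0].flags)


def test_clade_summary():
    res = focal_taxon_correlations(["a", "b", "c", "d"],
                                   np.array([[0, 1, 2, 3.0]] * 4),
                                   np.array([[0, 1, 2, 3.0]] * 4))
    df = clade_summary(res, {"a": "x", "b": "x", "c": "y", "d": "y"})
    assert set(df["clade"]) == {"x", "y"}


# ---------------------------------------------------------------------------
# feature-rate table
# ---------------------------------------------------------------------------

def test_feature_rate_table_identical_feature(three_taxon_tree, rng):
    taxa = ["A", "B", "C"]
    vals = {t: v for t, v in zip(taxa, (1.0, 2.0, 4.0))}
    df = feature_rate_table({"dN": vals}, {"same": dict(vals)}, tree=three_taxon_tree)
    pearson = df[df.method == "pearson"].iloc[0]
    assert pearson.r_or_beta == pytest.approx(1.0)
    pgls = df[df.method == "pgls"].iloc[0]
    assert pgls.r_or_beta == pytest.approx(1.0)


def test_feature_rate_table_constant_feature_flagged():
    vals = {"A": 1.0, "B": 2.0, "C": 3.0}
    df = feature_rate_table({"dN": vals}, {"const": {"A": 5.0, "B": 5.0, "C": 5.0}})
    assert np.isnan(df.iloc[0].r_or_beta)


def test_feature_rate_table_permuted_feature_mostly_null(rng):
    """A feature decoupled by permutation should rarely reach significance."""
    n = 30
    taxa = [f"t{i}" for i in range(n)]
    base = rng.normal(size=n)
    rates = {"dN": dict(zip(taxa, base))}
    hits = 0
    n_perm = 100
    for _ in range(n_perm):
        permuted = dict(zip(taxa, rng.permutation(base)))
        df = feature_rate_table(rates, {"f": permuted})
        hits += bool(df.iloc[0].p < 0.05)
    assert hits / n_perm <= 0.10
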