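"""Correlation stage: Pearson tests with Bonferroni correction and
phylogenetic generalized least squares (PGLS).

Two result surfaces are produced:

* focal-taxon correlations — for each focal taxon i, the Pearson
  correlation between its pairwise substitution rates rate(i, j) and its
  pairwise inversion distances iv(i, j) over all other taxa j, with a
  Bonferroni family per rate type (one test per focal taxon);
* rate-vs-feature regressions — each substitution-rate summary (dN, dS,
  omega vs the outgroup) against plastome features (size, indel count,
  IR/LSC/SSC lengths), both by ordinary Pearson test and by PGLS under a
  Brownian-motion covariance V_ij = shared root-to-MRCA path length on the
  pruned tree.

PGLS uses the closed form beta = (X'V^-1X)^-1 X'V^-1 y with
sigma^2 = r'V^-1 r/(n-k) and t-based p-values; with V = I it reduces
exactly to ordinary least squares. No Pagel's lambda is estimated by
default (a lambda multiplier on off-diagonals is available as a knob).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    label: str
    n: int
    r: float
    p: float
    p_adj: float = None
    significant: bool = None
    mode: str = "raw"  # which p the significance call used
    flags: list = field(default_factory=list)


@dataclass
class PGLSFit:
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma2: float
    lnL: float
    n: int
    k: int
    columns: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Brownian covariance from a tree
# ---------------------------------------------------------------------------

def brownian_covariance(tree, taxa) -> np.ndarray:
    """V_ij = root-to-MRCA(i,j) path length; V_ii = root-to-leaf depth.

    ``tree`` is a dendropy Tree with branch lengths; ``taxa`` an ordered
    list of leaf labels selecting and ordering the matrix.
    """
    taxa = list(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = set(taxa) - leaf_names
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)}")
    k = len(taxa)
    V = np.zeros((k, k))

    depth = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth.get(node.parent_node, 0.0)
        depth[node] = parent_depth + (node.edge.length or 0.0)

    # leaves below each node, combined bottom-up; pairs first meeting at a
    # node get that node's depth as their covariance
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            below[node] = [index[label]] if label in index else []
            if label in index:
                V[index[label], index[label]] = depth[node]
            continue
        child_sets = [below.pop(ch) for ch in node.child_nodes()]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        V[i, j] = V[j, i] = depth[node]
        below[node] = [i for s in child_sets for i in s]
    return V


def prune_tree(tree, drop_labels):
    """Copy of the tree with the given leaves removed (outgroup pruning)."""
    import dendropy

    pruned = tree.clone(depth=1)
    taxa = [t for t in pruned.taxon_namespace if t.label in set(drop_labels)]
    if taxa:
        pruned.prune_taxa(taxa)
    return pruned


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

def pgls_fit(y, X, tree=None, taxa=None, V=None, columns=None, lam: float = 1.0) -> PGLSFit:
    """Generalized least squares with phylogenetic covariance.

    Either pass ``V`` directly, or a tree plus the taxon order of the rows.
    ``lam`` multiplies the off-diagonal of V (Pagel's lambda as a fixed
    knob, default 1 = plain Brownian). A singular V gets a 1e-10 diagonal
    jitter, logged.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if np.any(np.isnan(y)) or np.any(np.isnan(X)):
        raise ValueError("missing values in y or X; drop them (with a log line) first")
    if V is None:
        if tree is None or taxa is None:
            raise ValueError("pass V, or tree plus taxa")
        V = brownian_covariance(tree, taxa)
    V = np.asarray(V, dtype=float)
    if lam != 1.0:
        V = lam * V + (1.0 - lam) * np.diag(np.diag(V))
    if np.linalg.matrix_rank(X) < k:
        # identify offending columns by leave-one-out rank
        bad = [i for i in range(k) if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == np.linalg.matrix_rank(X)]
        names = [columns[i] if columns else i for i in bad]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {names}")
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        logger.warning("singular phylogenetic covariance; adding 1e-10 jitter to the diagonal")
        V = V + 1e-10 * np.eye(n)
        L = np.linalg.cholesky(V)
    # whiten: solve L z = y etc., then OLS on whitened data
    from scipy.linalg import solve_triangular

    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    dof = n - k
    sigma2 = float(resid @ resid / dof) if dof > 0 else float("nan")
    cov_beta = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    _, logdet = np.linalg.slogdet(V)
    lnL = -0.5 * (n * np.log(2 * np.pi * sigma2 * dof / n) + logdet + n) if sigma2 > 0 else float("nan")
    return PGLSFit(beta=beta, se=se, t=tvals, p=pvals, sigma2=sigma2, lnL=float(lnL), n=n, k=k, columns=columns or [])


# ---------------------------------------------------------------------------
# Pearson / Bonferroni
# ---------------------------------------------------------------------------

def pearson_test(x, y, label: str = "") -> CorrelationResult:
    """Pearson r with two-sided p from t = r*sqrt((n-2)/(1-r^2)), df = n-2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        return CorrelationResult(label=label, n=n, r=float("nan"), p=float("nan"), flags=["too_few_points"])
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(label=label, n=n, r=float("nan"), p=float("nan"), flags=["zero_variance"])
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(label=label, n=n, r=float(r), p=float(p))


def bonferroni(ps, m: int | None = None):
    """p_adj = min(1, m*p); m defaults to len(ps), larger m is allowed."""
    ps = list(ps)
    m = len(ps) if m is None else m
    if m < len(ps):
        raise ValueError("family size m smaller than the number of p-values")
    return [min(1.0, m * p) if not np.isnan(p) else p for p in ps]


def focal_taxon_correlations(taxa, rate_matrix, iv_matrix, alpha: float = 0.05, family_size: int | None = None):
    """Per-focal-taxon Pearson tests of pairwise rate vs inversion distance.

    For each focal taxon i the test uses the points
    {(rate(i,j), iv(i,j)) : j != i} with NaN rates dropped (undefined
    omega pairs). Significance is called on the raw p at ``alpha`` (the
    convention of per-focal significance counts), with Bonferroni-adjusted
    p-values (family = one test per focal taxon) reported alongside.
    """
    rate_matrix = np.asarray(rate_matrix, dtype=float)
    iv_matrix = np.asarray(iv_matrix, dtype=float)
    k = len(taxa)
    if rate_matrix.shape != (k, k) or iv_matrix.shape != (k, k):
        raise ValueError("matrices must be square over the same taxa")
    results = []
    for i, taxon in enumerate(taxa):
        idx = [j for j in range(k) if j != i and not np.isnan(rate_matrix[i, j])]
        dropped = (k - 1) - len(idx)
        if len(idx) < 3:
            logger.warning("focal taxon %s skipped: only %d defined pairs", taxon, len(idx))
            continue
        res = pearson_test(rate_matrix[i, idx], iv_matrix[i, idx], label=taxon)
        if dropped:
            res.flags.append(f"dropped_undefined_pairs:{dropped}")
        results.append(res)
    m = family_size if family_size is not None else len(results)
    adj = bonferroni([r.p for r in results], m)
    for r, pa in zip(results, adj):
        r.p_adj = pa
        r.significant = bool(r.p < alpha) if not np.isnan(r.p) else None
        r.mode = "raw"
    return results


def clade_summary(results, clade_of: dict):
    """Fraction of significant focal taxa per clade (clade labels are input)."""
    import pandas as pd

    rows = []
    for clade in sorted(set(clade_of.values())):
        members = [r for r in results if clade_of.get(r.label) == clade]
        if not members:
            continue
        rows.append(
            {
                "clade": clade,
                "n_taxa": len(members),
                "n_significant": sum(1 for r in members if r.significant),
            }
        )
    return pd.DataFrame(rows)


def feature_rate_table(rates: dict, features: dict, tree=None, alpha: float = 0.05):
    """Rate-vs-feature report: Pearson and (when a tree is given) PGLS rows.

    ``rates``: {rate_name: {taxon: value}}; ``features``:
    {feature_name: {taxon: value}}. Taxa are intersected per pair; missing
    or undefined values are dropped pairwise with a log line. Returns a
    DataFrame with one row per (rate, feature, method).
    """
    import pandas as pd

    rows = []
    for rname, rvals in rates.items():
        for fname, fvals in features.items():
            taxa = sorted(set(rvals) & set(fvals))
            y = np.array([rvals[t] for t in taxa], dtype=float)
            x = np.array([fvals[t] for t in taxa], dtype=float)
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < len(taxa):
                logger.info("%s vs %s: dropped %d taxa with missing values", rname, fname, int(len(taxa) - mask.sum()))
            kept = [t for t, ok in zip(taxa, mask) if ok]
            y, x = y[mask], x[mask]
            res = pearson_test(x, y, label=f"{rname}~{fname}")
            rows.append(
                {
                    "method": "pearson",
                    "rate": rname,
                    "feature": fname,
                    "n": res.n,
                    "r_or_beta": res.r,
                    "p": res.p,
                }
            )
            if tree is not None and len(kept) >= 3 and not np.isnan(res.r):
                X = np.column_stack([np.ones(len(kept)), x])
                fit = pgls_fit(y, X, tree=tree, taxa=kept, columns=["intercept", fname])
                rows.append(
                    {
                        "method": "pgls",
                        "rate": rname,
                        "feature": fname,
                        "n": fit.n,
                        "r_or_beta": float(fit.beta[1]),
                        "p": float(fit.p[1]),
                    }
                )
    df = pd.DataFrame(rows)
    # Bonferroni within each method family
    df["p_adj"] = np.nan
    for method in df["method"].unique():
        sel = df["method"] == method
        df.loc[sel, "p_adj"] = bonferroni(df.loc[sel, "p"].tolist())
    df["significant"] = df["p_adj"] < alpha
    return df
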