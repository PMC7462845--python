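"""Codon substitution-rate estimation.

Two estimators are provided, mirroring the two ways plastome rates are
usually reported:

* :func:`ng86_pairwise` — the Nei–Gojobori (1986) counting method for a pair
  of gap-free coding sequences, with Jukes–Cantor correction, giving dN, dS
  and omega = dN/dS per pair (typically each taxon against an outgroup, or
  all-vs-all for focal-taxon correlation analyses).
* :func:`fit_m0` — maximum likelihood under the Goldman–Yang (1994) codon
  model with a single omega shared across sites and branches (the "model 0"
  of codon-model practice), on a fixed tree topology whose branch-length
  proportions are kept and jointly rescaled.

Likelihood-ratio tests between nested site models are reduced to their
arithmetic: the chi-square tail probability of 2*(lnL1 - lnL0), so published
log-likelihood pairs can be checked directly.

Stop-codon handling in the counting method: single-base changes that would
create a stop codon are excluded from both the site and the difference
counts (each excluded change removes 1/3 of a site, so a codon's s + n may
fall short of 3; the shortfall is reported). Mutational pathways through
stop codons are likewise skipped when averaging over the k! orderings for
codons differing at k sites.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .codons import (
    encode_codon_sequence,
    f3x4_frequencies,
    genetic_code,
    sense_codons,
    single_step_neighbors,
)


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

@dataclass
class RateEstimate:
    """Pairwise dN/dS estimate with the counts behind it.

    S, N are synonymous / nonsynonymous site counts (averaged over the two
    sequences); Sd, Nd the fractional difference counts after pathway
    averaging. dS, dN are Jukes-Cantor corrected; omega is None when dS is 0
    or saturated (reported as undefined, never coerced to 0).
    """

    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int
    stop_shortfall: float = 0.0
    flags: list = field(default_factory=list)

    @property
    def pS(self):
        return self.Sd / self.S if self.S > 0 else float("nan")

    @property
    def pN(self):
        return self.Nd / self.N if self.N > 0 else float("nan")

    @property
    def dS(self):
        return jukes_cantor(self.pS)

    @property
    def dN(self):
        return jukes_cantor(self.pN)

    @property
    def omega(self):
        dn, ds = self.dN, self.dS
        if ds is None or dn is None or ds == 0.0:
            return None
        return dn / ds


def jukes_cantor(p: float):
    """d = -(3/4) ln(1 - 4p/3); None when saturated (p >= 3/4)."""
    if np.isnan(p):
        return float("nan")
    if p >= 0.75:
        return None
    return -0.75 * np.log1p(-4.0 * p / 3.0)


@lru_cache(maxsize=None)
def _site_count_arrays(table_id: int = 11):
    """Per sense codon: (s, n) site fractions under stop exclusion."""
    nbrs = single_step_neighbors(table_id)
    codons = sense_codons(table_id)
    s = np.zeros(len(codons))
    n = np.zeros(len(codons))
    for i, codon in enumerate(codons):
        for _, _, syn, _ in nbrs[codon]:
            if syn:
                s[i] += 1.0 / 3.0
            else:
                n[i] += 1.0 / 3.0
    return s, n


def ng86_site_counts(codon: str, table_id: int = 11):
    """(s, n) synonymous/nonsynonymous site fractions for one sense codon.

    Each of the nine single-base changes contributes 1/3 of a site to s or
    n; changes creating stops contribute to neither, so s + n < 3 exactly
    when the codon has stop-adjacent changes.
    """
    codon = codon.upper()
    code = genetic_code(table_id)
    if "-" in codon or "N" in codon:
        raise ValueError(f"codon {codon!r} contains gap or ambiguity")
    if codon in code["stops"]:
        raise ValueError(f"{codon!r} is a stop codon")
    s_arr, n_arr = _site_count_arrays(table_id)
    i = sense_codons(table_id).index(codon)
    return float(s_arr[i]), float(n_arr[i])


def _pathway_counts(c1: str, c2: str, table_id: int):
    """Average (syn, nonsyn) steps over stop-free orderings of the changes.

    Falls back to all orderings (stop intermediates counted nonsynonymous)
    when every pathway is blocked; the caller flags that case.
    """
    code = genetic_code(table_id)
    fwd, stops = code["forward"], code["stops"]
    diff = [i for i in range(3) if c1[i] != c2[i]]

    def walk(order, allow_stops):
        cur = c1
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stops and not allow_stops:
                return None
            aa_cur = fwd.get(cur, "*")
            aa_nxt = fwd.get(nxt, "*")
            if cur not in stops and nxt not in stops and aa_cur == aa_nxt:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [r for order in itertools.permutations(diff) if (r := walk(order, False)) is not None]
    blocked = not results
    if blocked:
        results = [walk(order, True) for order in itertools.permutations(diff)]
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd, blocked


@lru_cache(maxsize=None)
def _pair_tables(table_id: int = 11):
    """61x61 lookup tables of pathway-averaged (Sd, Nd) and blocked flags."""
    codons = sense_codons(table_id)
    k = len(codons)
    sd = np.zeros((k, k))
    nd = np.zeros((k, k))
    blocked = np.zeros((k, k), dtype=bool)
    for i, c1 in enumerate(codons):
        for j in range(i + 1, k):
            s, n, b = _pathway_counts(c1, codons[j], table_id)
            sd[i, j] = sd[j, i] = s
            nd[i, j] = nd[j, i] = n
            blocked[i, j] = blocked[j, i] = b
    return sd, nd, blocked


def ng86_pairwise(a: str, b: str, table_id: int = 11) -> RateEstimate:
    """Nei–Gojobori pairwise estimate for two equal-length gap-free sequences.

    Sites are averaged over the two sequences; differences at codons that
    differ in 2 or 3 positions are averaged over all stop-free mutational
    orderings. Symmetric in its arguments.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if len(a) == 0:
        raise ValueError("need at least one codon")
    ia = encode_codon_sequence(a, table_id)
    ib = encode_codon_sequence(b, table_id)
    s_arr, n_arr = _site_count_arrays(table_id)
    sd_t, nd_t, blocked_t = _pair_tables(table_id)
    S = 0.5 * (s_arr[ia].sum() + s_arr[ib].sum())
    N = 0.5 * (n_arr[ia].sum() + n_arr[ib].sum())
    Sd = float(sd_t[ia, ib].sum())
    Nd = float(nd_t[ia, ib].sum())
    shortfall = 3.0 * len(ia) - (S + N)
    flags = []
    n_blocked = int(blocked_t[ia, ib].sum())
    if n_blocked:
        flags.append(f"stop_blocked_pathways:{n_blocked}")
    est = RateEstimate(S=float(S), N=float(N), Sd=Sd, Nd=Nd, n_codons=len(ia), stop_shortfall=float(shortfall), flags=flags)
    if est.dS is None:
        flags.append("dS_saturated")
    if est.dN is None:
        flags.append("dN_saturated")
    if est.dS == 0.0:
        flags.append("omega_undefined_dS_zero")
    return est


def pairwise_rate_matrices(sequences: dict, table_id: int = 11):
    """All-vs-all NG86 dN, dS and omega matrices for {taxon: gapfree seq}.

    Returns (taxa, dN, dS, omega) with NaN where a quantity is undefined
    (saturated distance or dS = 0); undefined entries are meant to be
    dropped, with a logged count, by downstream correlation code.
    """
    taxa = list(sequences)
    k = len(taxa)
    dN = np.zeros((k, k))
    dS = np.zeros((k, k))
    om = np.full((k, k), np.nan)
    np.fill_diagonal(om, np.nan)
    enc = {t: encode_codon_sequence(sequences[t], table_id) for t in taxa}
    s_arr, n_arr = _site_count_arrays(table_id)
    sd_t, nd_t, _ = _pair_tables(table_id)
    for i in range(k):
        for j in range(i + 1, k):
            ia, ib = enc[taxa[i]], enc[taxa[j]]
            S = 0.5 * (s_arr[ia].sum() + s_arr[ib].sum())
            N = 0.5 * (n_arr[ia].sum() + n_arr[ib].sum())
            ds = jukes_cantor(sd_t[ia, ib].sum() / S)
            dn = jukes_cantor(nd_t[ia, ib].sum() / N)
            dS[i, j] = dS[j, i] = np.nan if ds is None else ds
            dN[i, j] = dN[j, i] = np.nan if dn is None else dn
            if ds not in (None, 0.0) and dn is not None:
                om[i, j] = om[j, i] = dn / ds
    return taxa, dN, dS, om


# ---------------------------------------------------------------------------
# GY94 / model 0
# ---------------------------------------------------------------------------

@dataclass
class CodonModel:
    """Goldman–Yang codon model: Q scaled to one expected event per unit time."""

    kappa: float
    omega: float
    pi: np.ndarray
    Q: np.ndarray
    table_id: int = 11

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) via eigendecomposition of the symmetrised generator."""
        evals, left, right = self._eig()
        P = (right * np.exp(evals * t)) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def _eig(self):
        if not hasattr(self, "_eig_cache"):
            d = np.sqrt(self.pi)
            B = (self.Q * d[:, None]) / d[None, :]
            B = 0.5 * (B + B.T)  # symmetric up to round-off for reversible Q
            evals, U = np.linalg.eigh(B)
            right = U / d[:, None]
            left = U.T * d[None, :]
            self._eig_cache = (evals, left, right)
        return self._eig_cache


def gy94_rate_matrix(kappa: float, omega: float, pi: np.ndarray, table_id: int = 11) -> CodonModel:
    """Build the single-omega GY94 rate matrix over sense codons.

    q_ij is nonzero only for single-nucleotide changes and proportional to
    pi_j, multiplied by kappa for transitions and omega for nonsynonymous
    changes; Q is scaled so the expected substitution rate at stationarity
    is 1 (branch lengths are then substitutions per codon).
    """
    if kappa < 0 or omega < 0:
        raise ValueError("kappa and omega must be nonnegative")
    codons = sense_codons(table_id)
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (len(codons),) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("pi must be a probability distribution over sense codons")
    idx = {c: i for i, c in enumerate(codons)}
    Q = np.zeros((len(codons), len(codons)))
    for codon, nbrs in single_step_neighbors(table_id).items():
        i = idx[codon]
        for other, _, syn, transition in nbrs:
            j = idx[other]
            rate = pi[j]
            if transition:
                rate *= kappa
            if not syn:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    if scale > 0:
        Q /= scale
    return CodonModel(kappa=kappa, omega=omega, pi=pi, Q=Q, table_id=table_id)


def _alignment_patterns(aln, taxa_order, table_id: int = 11):
    """Compress codon columns into unique site patterns with multiplicities."""
    mat = np.stack([encode_codon_sequence(aln.sequences[t], table_id) for t in taxa_order])
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return patterns, counts


def _postorder_edges(tree):
    """(node, children) in postorder over a dendropy tree."""
    return [nd for nd in tree.postorder_node_iter()]


def m0_loglik(aln, tree, model: CodonModel, tree_scale: float = 1.0, _patterns=None) -> float:
    """Log-likelihood of a codon alignment on a fixed tree by pruning.

    Site patterns are compressed with multiplicities; each branch uses
    P = exp(Q * length * tree_scale). Alignment taxa must all be tree leaves
    and the alignment must be gap-free.
    """
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(aln.taxa) - leaf_names
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    if _patterns is None:
        patterns, counts = _alignment_patterns(aln, aln.taxa, model.table_id)
    else:
        patterns, counts = _patterns
    row_of = {t: i for i, t in enumerate(aln.taxa)}
    npat = patterns.shape[1]
    nstates = len(model.pi)
    partial = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        L = np.ones((npat, nstates))
        for child in node.child_nodes():
            t = (child.edge.length or 0.0) * tree_scale
            P = model.transition_matrix(t)
            if child.is_leaf():
                obs = patterns[row_of[child.taxon.label]]
                msg = P[:, obs].T  # (npat, parent_state)
            else:
                msg = partial.pop(child) @ P.T
            L *= msg
        partial[node] = L
    root_partial = partial[tree.seed_node]
    site_lik = root_partial @ model.pi
    return float(np.dot(counts, np.log(site_lik)))


@dataclass
class M0Fit:
    kappa: float
    omega: float
    tree_scale: float
    lnL: float
    converged: bool
    flags: list = field(default_factory=list)
    n_starts: int = 3


#: optimiser box constraints and multi-start points (kappa, omega)
_M0_BOUNDS = {"kappa": (0.01, 100.0), "omega": (1e-4, 20.0), "scale": (1e-6, 1e3)}
_M0_STARTS = [(1.0, 0.1), (2.0, 0.5), (5.0, 1.0)]


def fit_m0(aln, tree, pi=None, table_id: int = 11, starts=None):
    """ML fit of (kappa, omega, tree_scale) under the single-omega model.

    Branch-length proportions are fixed to the input tree; one global scale
    is optimised — a deliberate simplification of per-branch optimisation,
    recorded in the fit flags. Codon frequencies default to F3x4 computed
    from the alignment. Bounded quasi-Newton (L-BFGS-B in log-parameter
    space) from three documented starts.
    """
    if pi is None:
        pi = f3x4_frequencies([aln.sequences[t] for t in aln.taxa], table_id)
    patterns = _alignment_patterns(aln, aln.taxa, table_id)
    lo = np.log([_M0_BOUNDS["kappa"][0], _M0_BOUNDS["omega"][0], _M0_BOUNDS["scale"][0]])
    hi = np.log([_M0_BOUNDS["kappa"][1], _M0_BOUNDS["omega"][1], _M0_BOUNDS["scale"][1]])

    def negloglik(theta):
        kappa, omega, scale = np.exp(theta)
        model = gy94_rate_matrix(kappa, omega, pi, table_id)
        return -m0_loglik(aln, tree, model, scale, _patterns=patterns)

    best = None
    any_converged = False
    start_points = starts or _M0_STARTS
    for kappa0, omega0 in start_points:
        x0 = np.log([kappa0, omega0, 1.0])
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)),
            options={"maxiter": 200, "ftol": 1e-10},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    kappa, omega, scale = np.exp(best.x)
    flags = ["branch_proportions_fixed_single_scale"]
    if scale <= _M0_BOUNDS["scale"][0] * 1.01:
        flags.append("tree_scale_at_lower_bound")
    if not any_converged:
        flags.append("non_convergence")
    return M0Fit(
        kappa=float(kappa), omega=float(omega), tree_scale=float(scale),
        lnL=float(-best.fun), converged=any_converged, flags=flags,
        n_starts=len(start_points),
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio test arithmetic
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    lnL0: float
    lnL1: float
    stat: float
    df: int
    p: float
    flags: list = field(default_factory=list)


def lrt(lnL0: float, lnL1: float, df: int) -> LRTResult:
    """2*(lnL1 - lnL0) against the chi-square upper tail with df degrees.

    A negative statistic (alternative fitting worse than the null, which can
    happen with converged-to-boundary published fits) is reported as-is with
    p = 1 and a warning flag.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnL1 - lnL0)
    flags = []
    if stat < 0:
        warnings.warn("negative LRT statistic; p set to 1", stacklevel=2)
        flags.append("negative_statistic")
        p = 1.0
    else:
        p = float(stats.chi2.sf(stat, df))
    return LRTResult(lnL0=lnL0, lnL1=lnL1, stat=float(stat), df=df, p=p, flags=flags)
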