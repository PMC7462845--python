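"""Rate-estimation tests: hand-enumerated NG86 oracles, a brute-force
ancestral-summation oracle for the pruning likelihood, and published
likelihood-ratio arithmetic."""
import itertools

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from plastorate.codons import genetic_code, sense_codons
from plastorate.rates import (
    CodonModel,
    LRTResult,
    RateEstimate,
    fit_m0,
    gy94_rate_matrix,
    jukes_cantor,
    lrt,
    m0_loglik,
    ng86_pairwise,
    ng86_site_counts,
)
from plastorate.seqio_align import CodonAlignment, GeneBlock
from plastorate.synthetic_data import simulate_codon_alignment, simulate_tree, SimulationConfig


# ---------------------------------------------------------------------------
# NG86 site counting (hand enumeration oracles)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "codon,s,n",
    [
        # TTT(F): only TTT->TTC (pos 3) is synonymous; no stop-adjacent change
        ("TTT", 1 / 3, 8 / 3),
        # ATG(M): single-codon family, no synonymous change, no stop-adjacent
        ("ATG", 0.0, 3.0),
        # TGG(W): no synonymous change; TAG and TGA are stops -> 2/3 shortfall
        ("TGG", 0.0, 7 / 3),
    ],
)
def test_ng86_site_counts_hand_enumerated(codon, s, n):
    got_s, got_n = ng86_site_counts(codon)
    assert got_s == pytest.approx(s)
    assert got_n == pytest.approx(n)


def test_ng86_site_counts_rejects_stop_and_ambiguous():
    with pytest.raises(ValueError):
        ng86_site_counts("TAA")
    with pytest.raises(ValueError):
        ng86_site_counts("ATN")


def test_site_counts_sum_to_three_minus_stop_shortfall():
    code = genetic_code(11)
    for codon in sense_codons(11):
        s, n = ng86_site_counts(codon)
        n_stop_adjacent = sum(
            1
            for pos in range(3)
            for b in "TCAG"
            if b != codon[pos] and codon[:pos] + b + codon[pos + 1 :] in code["stops"]
        )
        assert s + n == pytest.approx(3 - n_stop_adjacent / 3)


# ---------------------------------------------------------------------------
# NG86 pairwise
# ---------------------------------------------------------------------------

def _brute_pathway_counts(c1, c2):
    """Independent pathway-averaging oracle (no shared code with rates)."""
    code = genetic_code(11)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in code["stops"]:
                ok = False
                break
            if code["forward"][cur] == code["forward"][nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    return results


def test_pairwise_pathway_averaging_matches_bruteforce(rng):
    codons = sense_codons(11)
    for _ in range(200):
        c1, c2 = rng.choice(codons, size=2)
        paths = _brute_pathway_counts(c1, c2)
        if not paths:
            continue  # fully blocked pairs use the flagged fallback
        est = ng86_pairwise(c1, c2)
        assert est.Sd == pytest.approx(np.mean([p[0] for p in paths]))
        assert est.Nd == pytest.approx(np.mean([p[1] for p in paths]))


def test_pairwise_identical_and_symmetry():
    a = "ATGAAATTTCCC"
    est = ng86_pairwise(a, a)
    assert est.Sd == 0 and est.Nd == 0
    assert est.dS == 0 and est.dN == 0
    assert est.omega is None  # dS = 0 -> undefined, not 0
    b = "ATGAAGTTTCCC"
    e1, e2 = ng86_pairwise(a, b), ng86_pairwise(b, a)
    assert (e1.S, e1.N, e1.Sd, e1.Nd) == (e2.S, e2.N, e2.Sd, e2.Nd)


def test_pairwise_twenty_codon_toy():
    """2 synonymous + 1 nonsynonymous single-base differences; JC by formula."""
    base = ["GCT", "CGT", "AAA"] + ["ATG", "TTT", "CCC", "GGG", "GAA"] * 3 + ["ATC", "ACC"]
    other = list(base)
    other[0] = "GCC"  # Ala->Ala synonymous
    other[1] = "CGC"  # Arg->Arg synonymous
    other[2] = "GAA"  # Lys->Glu nonsynonymous
    a, b = "".join(base), "".join(other)
    assert len(a) == 60
    est = ng86_pairwise(a, b)
    assert est.Sd == pytest.approx(2.0)
    assert est.Nd == pytest.approx(1.0)
    assert est.dS == pytest.approx(-0.75 * np.log(1 - 4 / 3 * (2.0 / est.S)))
    assert est.dN == pytest.approx(-0.75 * np.log(1 - 4 / 3 * (1.0 / est.N)))


def test_sd_nd_additive_over_concatenation():
    a1, b1 = "GCTAAA", "GCCAAA"
    a2, b2 = "TTTCGT", "TTACGC"
    e1, e2 = ng86_pairwise(a1, b1), ng86_pairwise(a2, b2)
    cat = ng86_pairwise(a1 + a2, b1 + b2)
    assert cat.Sd == pytest.approx(e1.Sd + e2.Sd)
    assert cat.Nd == pytest.approx(e1.Nd + e2.Nd)
    assert cat.S == pytest.approx(e1.S + e2.S)


def test_saturation_flagged():
    assert jukes_cantor(0.8) is None


def test_pairwise_omega_one_simulation():
    """NG86 recovers omega ~= 1 on data simulated without selection (kappa=1)."""
    tree = dendropy.Tree.get(data="(A:0.15,B:0.15);", schema="newick")
    mult = {n: 1.0 for n in tree.preorder_node_iter()}
    oms = []
    for seed in range(5):
        aln = simulate_codon_alignment(
            tree, mult, genes=(("g", "all", 1000),), group_omega={"all": 1.0}, kappa=1.0, seed=seed
        )
        oms.append(ng86_pairwise(aln.sequences["A"], aln.sequences["B"]).omega)
    assert 0.9 <= np.mean(oms) <= 1.1


# ---------------------------------------------------------------------------
# GY94 / M0
# ---------------------------------------------------------------------------

def test_gy94_generator_properties():
    nstates = len(sense_codons(11))
    pi = np.full(nstates, 1 / nstates)
    model = gy94_rate_matrix(kappa=2.0, omega=0.3, pi=pi)
    assert np.allclose(model.Q.sum(axis=1), 0.0, atol=1e-12)
    # detailed balance
    flux = pi[:, None] * model.Q
    assert np.allclose(flux, flux.T, atol=1e-12)
    # mean rate 1
    assert -np.dot(pi, np.diag(model.Q)) == pytest.approx(1.0)


def test_gy94_omega_zero_kills_nonsynonymous():
    from plastorate.codons import single_step_neighbors, codon_index

    nstates = len(sense_codons(11))
    pi = np.full(nstates, 1 / nstates)
    model = gy94_rate_matrix(kappa=2.0, omega=0.0, pi=pi)
    idx = codon_index(11)
    for codon, nbrs in single_step_neighbors(11).items():
        for other, _, syn, _ in nbrs:
            if not syn:
                assert model.Q[idx[codon], idx[other]] == 0.0


def test_transition_matrix_matches_expm():
    nstates = len(sense_codons(11))
    rng = np.random.default_rng(0)
    pi = rng.dirichlet(np.ones(nstates))
    model = gy94_rate_matrix(kappa=3.0, omega=0.5, pi=pi)
    for t in (0.01, 0.3, 2.0):
        assert np.allclose(model.transition_matrix(t), expm(model.Q * t), atol=1e-8)


def _brute_force_loglik(aln, tree, model, scale):
    """Ancestral-state enumeration oracle; transition matrices via expm."""
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    internal = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
    nstates = len(model.pi)
    P = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            P[nd] = expm(model.Q * (nd.edge.length or 0.0) * scale)
    from plastorate.codons import encode_codon_sequence

    enc = {t: encode_codon_sequence(aln.sequences[t]) for t in aln.taxa}
    nsites = len(next(iter(enc.values())))
    lnL = 0.0
    for site in range(nsites):
        total = 0.0
        for assign in itertools.product(range(nstates), repeat=len(internal)):
            state = dict(zip(internal, assign))
            prob = model.pi[state[tree.seed_node]]
            for nd in tree.preorder_node_iter():
                if nd.parent_node is None:
                    continue
                parent_state = state[nd.parent_node]
                child_state = state[nd] if not nd.is_leaf() else enc[nd.taxon.label][site]
                prob *= P[nd][parent_state, child_state]
            total += prob
        lnL += np.log(total)
    return lnL


@pytest.mark.parametrize("newick,seqs", [
    ("(A:0.2,B:0.4);", {"A": "ATG", "B": "ATA"}),
    ("(A:0.2,B:0.4);", {"A": "ATGAAA", "B": "ACGAAG"}),
    ("((A:0.3,B:0.2):0.1,C:0.5);", {"A": "TTT", "B": "TTC", "C": "CTT"}),
])
def test_m0_loglik_matches_bruteforce(newick, seqs):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa = sorted(seqs)
    aln = CodonAlignment(taxa=taxa, sequences=seqs, gene_blocks=[GeneBlock("g", 0, len(seqs[taxa[0]]))])
    nstates = len(sense_codons(11))
    pi = np.full(nstates, 1 / nstates)
    model = gy94_rate_matrix(kappa=2.5, omega=0.4, pi=pi)
    got = m0_loglik(aln, tree, model, tree_scale=1.3)
    want = _brute_force_loglik(aln, tree, model, 1.3)
    assert got == pytest.approx(want, abs=1e-8)


def test_m0_loglik_pattern_multiplicity():
    tree = dendropy.Tree.get(data="(A:0.2,B:0.4);", schema="newick")
    nstates = len(sense_codons(11))
    pi = np.full(nstates, 1 / nstates)
    model = gy94_rate_matrix(2.0, 0.3, pi)
    one = CodonAlignment(taxa=["A", "B"], sequences={"A": "ATG", "B": "ATA"}, gene_blocks=[])
    two = CodonAlignment(taxa=["A", "B"], sequences={"A": "ATGATG", "B": "ATAATA"}, gene_blocks=[])
    assert m0_loglik(two, tree, model) == pytest.approx(2 * m0_loglik(one, tree, model))


def test_m0_loglik_decreases_as_scale_vanishes():
    tree = dendropy.Tree.get(data="(A:0.2,B:0.4);", schema="newick")
    nstates = len(sense_codons(11))
    pi = np.full(nstates, 1 / nstates)
    model = gy94_rate_matrix(2.0, 0.3, pi)
    aln = CodonAlignment(taxa=["A", "B"], sequences={"A": "ATG", "B": "ATA"}, gene_blocks=[])
    lls = [m0_loglik(aln, tree, model, s) for s in (1.0, 0.1, 0.01, 0.001)]
    assert lls[0] > lls[1] > lls[2] > lls[3]


def test_fit_m0_recovers_omega():
    cfg = SimulationConfig(n_taxa=8, depth=0.3, tau=0.0)
    tree = simulate_tree(cfg, 5)
    mult = {n: 1.0 for n in tree.preorder_node_iter()}
    aln = simulate_codon_alignment(tree, mult, genes=(("g", "all", 500),), group_omega={"all": 0.2}, kappa=2.0, seed=5)
    fit = fit_m0(aln, tree)
    assert fit.converged
    assert abs(fit.omega - 0.2) / 0.2 < 0.2
    assert abs(fit.kappa - 2.0) / 2.0 < 0.3


def test_fit_m0_synonymous_only_alignment():
    """Only synonymous variation -> omega pinned near its lower bound."""
    seqs = {"A": "GCTCGTAAACCT" * 10, "B": "GCCCGCAAACCC" * 10, "C": "GCACGAAAACCA" * 10}
    tree = dendropy.Tree.get(data="((A:0.1,B:0.1):0.05,C:0.15);", schema="newick")
    aln = CodonAlignment(taxa=["A", "B", "C"], sequences=seqs, gene_blocks=[])
    fit = fit_m0(aln, tree)
    assert fit.omega <= 0.01


def test_fit_m0_identical_sequences_flagged():
    seqs = {"A": "ATGAAA" * 20, "B": "ATGAAA" * 20}
    tree = dendropy.Tree.get(data="(A:0.15,B:0.15);", schema="newick")
    aln = CodonAlignment(taxa=["A", "B"], sequences=seqs, gene_blocks=[])
    fit = fit_m0(aln, tree)
    assert "tree_scale_at_lower_bound" in fit.flags


# ---------------------------------------------------------------------------
# LRT arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "lnl0,lnl1,stat,p",
    [
        (-6492.11, -6275.91, 432.40, 1.28e-94),
        (-9013.33, -8757.67, 511.32, 9.30e-112),
    ],
)
def test_lrt_published_site_model_values(lnl0, lnl1, stat, p):
    res = lrt(lnl0, lnl1, df=2)
    assert res.stat == pytest.approx(stat, abs=1e-9)
    assert res.p == pytest.approx(p, rel=0.02)


def test_lrt_equal_likelihoods_and_negative_stat():
    assert lrt(-10.0, -10.0, 2).p == 1.0
    with pytest.warns(UserWarning):
        res = lrt(-10.0, -11.0, 2)
    assert res.p == 1.0 and "negative_statistic" in res.flags
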