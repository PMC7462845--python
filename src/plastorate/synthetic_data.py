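"""Synthetic plastome-evolution scenarios.

Generates complete datasets with the statistical structure the analysis
assumes: a rooted tree, lineage-specific rate multipliers, codon alignments
evolved under group-specific omega, signed LCB permutations produced by
random reversals accumulating along branches, and in-frame indel events —
with a tunable planted coupling between a branch's substitution-rate
multiplier and its rearrangement/indel intensity.

Every stochastic operation is a pure function of its arguments and a seed.

The coupling mechanism: along a branch of length b with rate multiplier m,
the number of reversals (and of indel events) is Poisson with intensity
rate * b * (coupling * m + (1 - coupling)), so coupling = 1 makes
rearrangement intensity fully proportional to the branch's substitution
rate and coupling = 0 makes it depend on branch length only.

For size/power calibration of the correlation stage the canonical scenario
uses a star tree with equal depths: on a structured tree both pairwise
rates and pairwise inversion counts grow with the shared path length, so a
coupling of 0 would not be a true null of the focal-taxon Pearson test.
On a star tree with coupling 0 the two quantities are exactly independent
across partners of a focal taxon.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .codons import sense_codons
from .rates import gy94_rate_matrix
from .rearrangement import SignedPermutation, apply_reversal
from .seqio_align import CodonAlignment, GeneBlock

#: default gene set: a reduced emulation of a plastome coding complement,
#: with group-specific omega reflecting strong purifying selection on
#: photosynthesis genes and weaker constraint on ribosomal-protein and
#: RNA-polymerase genes
DEFAULT_GENES = (
    ("psaA", "photosynthesis", 150),
    ("psaB", "photosynthesis", 150),
    ("psbA", "photosynthesis", 120),
    ("psbC", "photosynthesis", 120),
    ("petB", "photosynthesis", 100),
    ("atpB", "photosynthesis", 150),
    ("rps4", "ribosomal", 100),
    ("rps7", "ribosomal", 100),
    ("rpl2", "ribosomal", 100),
    ("rpl16", "ribosomal", 80),
    ("rpoB", "ribosomal", 150),
    ("rpoC1", "ribosomal", 150),
)

DEFAULT_GROUP_OMEGA = {"photosynthesis": 0.05, "ribosomal": 0.3}


@dataclass
class SimulationConfig:
    """Study-condition knobs for scenario generation.

    depth is the root-to-tip tree depth in expected substitutions per codon;
    tau the standard deviation of log branch-rate multipliers; lambda_inv
    and mu_indel are event intensities per unit rate-weighted branch length;
    coupling in [0, 1] links those intensities to the branch multiplier.
    """

    n_taxa: int = 40
    tree_shape: str = "yule"  # "yule" | "star" | a newick string
    depth: float = 0.05
    tau: float = 0.6
    kappa: float = 2.0
    group_omega: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_OMEGA))
    genes: tuple = DEFAULT_GENES
    n_blocks: int = 42
    lambda_inv: float = 60.0
    mu_indel: float = 200.0
    coupling: float = 0.0
    outgroup_label: str = "Outgroup"

    def __post_init__(self):
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must be in [0, 1]")
        for name in ("depth", "tau", "kappa", "lambda_inv", "mu_indel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.n_blocks < 2:
            raise ValueError("need at least 2 LCBs")


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is mandatory for every stochastic call")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# tree and branch rates
# ---------------------------------------------------------------------------

def simulate_tree(config: SimulationConfig, seed) -> dendropy.Tree:
    """Rooted ultrametric tree with root-to-tip depth = config.depth.

    "yule" grows a pure-birth tree (random lineage splits at exponential
    waiting times) rescaled to the requested depth; "star" attaches all
    leaves directly to the root; a newick string is parsed as given.
    """
    rng = _rng(seed)
    labels = [f"T{i + 1:02d}" for i in range(config.n_taxa)]
    if config.tree_shape == "star":
        newick = "(" + ",".join(f"{t}:{config.depth}" for t in labels) + ");"
        return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    if config.tree_shape != "yule":
        return dendropy.Tree.get(data=config.tree_shape, schema="newick", preserve_underscores=True)
    return _yule_tree(labels, config.depth, rng)


def _yule_tree(labels, depth, rng) -> dendropy.Tree:
    """Pure-birth tree grown forward in time, rescaled to the given depth."""
    n = len(labels)
    tree = dendropy.Tree()
    root = tree.seed_node
    born = {}
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        born[child] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        v = active.pop(int(rng.integers(len(active))))
        v.edge.length = t - born[v]
        for _ in range(2):
            child = dendropy.Node()
            v.add_child(child)
            born[child] = t
            active.append(child)
    end = t + rng.exponential(1.0 / n)
    order = rng.permutation(n)
    namespace = tree.taxon_namespace
    for i, v in enumerate(active):
        v.edge.length = end - born[v]
        v.taxon = namespace.new_taxon(label=labels[int(order[i])])
    root.edge.length = None
    # rescale to the requested root-to-tip depth
    if end > 0 and depth > 0:
        scale = depth / end
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    return tree


def simulate_branch_rates(tree: dendropy.Tree, tau: float, seed) -> dict:
    """Per-branch lognormal rate multipliers, keyed by child node.

    log-multipliers are i.i.d. Normal(0, tau); tau = 0 gives all ones.
    The root (no branch above it) gets multiplier 1.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    rng = _rng(seed)
    rates = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            rates[node] = 1.0
        else:
            rates[node] = float(np.exp(rng.normal(0.0, tau))) if tau > 0 else 1.0
    return rates


def _branch_intensity(length, multiplier, coupling) -> float:
    return length * (coupling * multiplier + (1.0 - coupling))


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    tree, multipliers, genes=DEFAULT_GENES, group_omega=None, kappa: float = 2.0,
    seed=None, pi=None, table_id: int = 11,
) -> CodonAlignment:
    """Evolve codon sequences along the tree under group-specific omega.

    Root codons are drawn from pi (uniform over sense codons by default);
    each branch applies exp(Q_g * length * multiplier) for its gene's group
    model. The state space is sense codons, so no stop codons are emitted.
    """
    rng = _rng(seed)
    group_omega = dict(DEFAULT_GROUP_OMEGA) if group_omega is None else group_omega
    nstates = len(sense_codons(table_id))
    if pi is None:
        pi = np.full(nstates, 1.0 / nstates)
    models = {g: gy94_rate_matrix(kappa, om, pi, table_id) for g, om in group_omega.items()}
    site_group = []
    blocks = []
    offset = 0
    for name, group, ncod in genes:
        if group not in models:
            raise ValueError(f"gene {name!r} has unknown functional group {group!r}")
        site_group.extend([group] * ncod)
        blocks.append(GeneBlock(name, offset * 3, (offset + ncod) * 3))
        offset += ncod
    nsites = len(site_group)
    group_sites = {g: np.array([i for i, gg in enumerate(site_group) if gg == g]) for g in models}

    root_state = rng.choice(nstates, size=nsites, p=pi)
    states = {tree.seed_node: root_state}
    leaf_states = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = states[node.parent_node]
        t = (node.edge.length or 0.0) * multipliers.get(node, 1.0)
        child = parent.copy()
        for g, sites in group_sites.items():
            if len(sites) == 0 or t == 0:
                continue
            P = models[g].transition_matrix(t)
            sub = parent[sites]
            new = np.empty_like(sub)
            for s in np.unique(sub):
                sel = sub == s
                new[sel] = rng.choice(nstates, size=int(sel.sum()), p=P[s])
            child[sites] = new
        states[node] = child
        if node.is_leaf():
            leaf_states[node.taxon.label] = child
    codons = sense_codons(table_id)
    sequences = {t: "".join(codons[s] for s in st) for t, st in leaf_states.items()}
    taxa = sorted(sequences)
    return CodonAlignment(taxa=taxa, sequences=sequences, gene_blocks=blocks)


# ---------------------------------------------------------------------------
# rearrangements
# ---------------------------------------------------------------------------

def simulate_rearrangements(tree, multipliers, n_blocks: int = 42, lambda_inv: float = 60.0,
                            coupling: float = 0.0, seed=None):
    """Random-reversal histories along the tree.

    The root carries the identity order; each branch applies
    K ~ Poisson(lambda_inv * b * (coupling*m + 1-coupling)) reversals with
    uniformly chosen interval endpoints. Returns (permutations keyed by
    leaf label, total applied reversal count per leaf).
    """
    rng = _rng(seed)
    state = {tree.seed_node: (tuple(range(1, n_blocks + 1)), 0)}
    leaves = {}
    counts = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        blocks, k_total = state[node.parent_node]
        intensity = lambda_inv * _branch_intensity(node.edge.length or 0.0, multipliers.get(node, 1.0), coupling)
        k = int(rng.poisson(intensity))
        for _ in range(k):
            i = int(rng.integers(n_blocks))
            j = int(rng.integers(n_blocks))
            i, j = min(i, j), max(i, j)
            blocks = apply_reversal(blocks, i, j)
        state[node] = (blocks, k_total + k)
        if node.is_leaf():
            leaves[node.taxon.label] = SignedPermutation(node.taxon.label, blocks)
            counts[node.taxon.label] = k_total + k
    return leaves, counts


# ---------------------------------------------------------------------------
# indels
# ---------------------------------------------------------------------------

#: in-frame event length distribution (nucleotides): 3, 6, 9 at 70/20/10%
INDEL_LENGTHS = (3, 6, 9)
INDEL_LENGTH_PROBS = (0.7, 0.2, 0.1)


def simulate_indels(tree, multipliers, genes=DEFAULT_GENES, mu_indel: float = 200.0,
                    coupling: float = 0.0, seed=None, frameshift_prob: float = 0.0):
    """Poisson in-frame insertion/deletion events accumulating along branches.

    Each event is (gene, codon position, length in nt, kind). Lengths are
    multiples of 3 so genes stay intact by construction; ``frameshift_prob``
    optionally injects 1-nt deletions for testing exclusion logic. Returns
    (events per leaf label, event count per leaf).
    """
    rng = _rng(seed)
    gene_names = [g[0] for g in genes]
    gene_codons = {g[0]: g[2] for g in genes}
    state = {tree.seed_node: ()}
    leaves, counts = {}, {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        events = state[node.parent_node]
        intensity = mu_indel * _branch_intensity(node.edge.length or 0.0, multipliers.get(node, 1.0), coupling)
        k = int(rng.poisson(intensity))
        new = list(events)
        for _ in range(k):
            gene = gene_names[int(rng.integers(len(gene_names)))]
            pos = int(rng.integers(gene_codons[gene]))
            if frameshift_prob > 0 and rng.random() < frameshift_prob:
                # frameshifts are emitted as 1-nt deletions so the joint
                # alignment keeps its codon framing
                length = 1
                kind = "del"
            else:
                length = int(rng.choice(INDEL_LENGTHS, p=INDEL_LENGTH_PROBS))
                kind = "ins" if rng.random() < 0.5 else "del"
            new.append((gene, pos, length, kind))
        state[node] = tuple(new)
        if node.is_leaf():
            leaves[node.taxon.label] = tuple(new)
            counts[node.taxon.label] = len(new)
    return leaves, counts


def apply_indels(aln: CodonAlignment, events_per_taxon: dict, seed=None, table_id: int = 11) -> CodonAlignment:
    """Materialise indel events as gap runs in a joint alignment.

    Deletions blank the event's codon range in the carrying taxon; each
    insertion event adds a new codon-column block carried (with random sense
    codons) only by its taxa — every other row, including the reference,
    shows gaps there. Taxa without an events entry carry none.
    """
    rng = _rng(seed)
    codons = sense_codons(table_id)
    pieces = {t: [] for t in aln.taxa}
    new_blocks = []
    offset = 0
    for b in aln.gene_blocks:
        gene_len = b.length
        # columns of this gene, per taxon, as mutable lists
        rows = {t: list(aln.sequences[t][b.start : b.end]) for t in aln.taxa}
        # deletions first (positions refer to the gene's own codon grid)
        for taxon in aln.taxa:
            for gene, pos, length, kind in events_per_taxon.get(taxon, ()):
                if gene != b.name or kind != "del":
                    continue
                start = min(pos * 3, gene_len - length) if gene_len >= length else 0
                for i in range(start, min(start + length, gene_len)):
                    rows[taxon][i] = "-"
        # insertions: group identical inherited events so shared history
        # yields a single shared column block
        ins_events = {}
        for taxon in aln.taxa:
            for ev in events_per_taxon.get(taxon, ()):
                gene, pos, length, kind = ev
                if gene == b.name and kind == "ins":
                    ins_events.setdefault(ev, []).append(taxon)
        out_cols = {t: [] for t in aln.taxa}
        ncod = gene_len // 3
        ins_by_pos = {}
        for (gene, pos, length, kind), carriers in sorted(ins_events.items()):
            ins_by_pos.setdefault(pos, []).append((length, tuple(sorted(carriers))))
        for c in range(ncod + 1):
            for length, carriers in ins_by_pos.get(c, ()):
                content = "".join(codons[int(rng.integers(len(codons)))] for _ in range(length // 3))
                for t in aln.taxa:
                    out_cols[t].append(content if t in carriers else "-" * length)
            if c < ncod:
                for t in aln.taxa:
                    out_cols[t].append("".join(rows[t][3 * c : 3 * c + 3]))
        gene_cols = len("".join(out_cols[aln.taxa[0]]))
        for t in aln.taxa:
            pieces[t].append("".join(out_cols[t]))
        new_blocks.append(GeneBlock(b.name, offset, offset + gene_cols))
        offset += gene_cols
    sequences = {t: "".join(pieces[t]) for t in aln.taxa}
    return CodonAlignment(taxa=list(aln.taxa), sequences=sequences, gene_blocks=new_blocks)


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

def attach_outgroup(tree: dendropy.Tree, label: str, branch_length: float) -> dendropy.Tree:
    """New tree with an outgroup leaf joined at the old root."""
    newick = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True).strip().rstrip(";")
    combined = f"({newick}:{branch_length},{label}:{branch_length * 2});"
    return dendropy.Tree.get(data=combined, schema="newick", preserve_underscores=True)


def make_scenario(config: SimulationConfig, seed, out_dir=None):
    """Generate a complete dataset bundle under one configuration.

    Returns a dict with the ingroup tree, the tree including the outgroup,
    branch multipliers, the gapped codon alignment (outgroup included),
    signed permutations, per-taxon features and a truth record (branch
    multipliers, applied reversal and indel counts, the planted coupling).
    Deterministic per (config, seed); with ``out_dir`` the bundle is written
    as FASTA + gene TSV + newick + LCB TSV + feature TSV + truth TSV.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(7)]
    tree = simulate_tree(config, seeds[0])
    full = attach_outgroup(tree, config.outgroup_label, config.depth)
    rates_by_node = simulate_branch_rates(full, config.tau, seeds[1])
    aln = simulate_codon_alignment(
        full, rates_by_node, config.genes, config.group_omega, config.kappa, seeds[2]
    )
    perms, rev_counts = simulate_rearrangements(
        full, rates_by_node, config.n_blocks, config.lambda_inv, config.coupling, seeds[3]
    )
    indel_events, indel_counts = simulate_indels(
        full, rates_by_node, config.genes, config.mu_indel, config.coupling, seeds[4]
    )
    gapped = apply_indels(aln, indel_events, seeds[5])
    rng = _rng(seeds[6])
    features = {}
    for taxon in sorted(perms):
        size = float(rng.normal(120_000, 5_000))
        ir = float(0.06 * size + rng.normal(0, 500))
        ssc = float(0.3 * size + rng.normal(0, 2_000))
        features[taxon] = {
            "plastome_size": round(size, 1),
            "ir_length": round(ir, 1),
            "lsc_length": round(size - ir - ssc, 1),  # size counts one IR copy only
            "ssc_length": round(ssc, 1),
        }
    multiplier_by_leaf = {
        lf.taxon.label: rates_by_node[lf] for lf in full.leaf_node_iter()
    }
    bundle = {
        "config": config,
        "seed": seed,
        "tree": tree,
        "tree_with_outgroup": full,
        "alignment": gapped,
        "alignment_gapfree": aln,
        "permutations": perms,
        "features": features,
        "truth": {
            "coupling": config.coupling,
            "leaf_multiplier": multiplier_by_leaf,
            "reversals_applied": rev_counts,
            "indel_events": indel_counts,
        },
    }
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle, out_dir):
    import pandas as pd
    from pathlib import Path

    from .seqio_align import write_alignment, write_gene_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_alignment(bundle["alignment"], out / "alignment.fasta")
    write_gene_table(bundle["alignment"], out / "genes.tsv")
    bundle["tree"].write(path=str(out / "tree.nwk"), schema="newick", unquoted_underscores=True)
    bundle["tree_with_outgroup"].write(path=str(out / "tree_with_outgroup.nwk"), schema="newick", unquoted_underscores=True)
    with open(out / "lcb_orders.tsv", "w") as fh:
        fh.write("taxon\tblocks\n")
        for taxon in sorted(bundle["permutations"]):
            p = bundle["permutations"][taxon]
            fh.write(taxon + "\t" + " ".join(str(x) for x in p.blocks) + "\n")
    pd.DataFrame.from_dict(bundle["features"], orient="index").rename_axis("taxon").to_csv(
        out / "features.tsv", sep="\t"
    )
    truth = bundle["truth"]
    rows = []
    for taxon in sorted(truth["leaf_multiplier"]):
        rows.append(
            {
                "taxon": taxon,
                "branch_multiplier": truth["leaf_multiplier"][taxon],
                "reversals_applied": truth["reversals_applied"].get(taxon, 0),
                "indel_events": truth["indel_events"].get(taxon, 0),
                "coupling": truth["coupling"],
            }
        )
    pd.DataFrame(rows).to_csv(out / "truth.tsv", sep="\t", index=False)


def calibration_config(coupling: float, n_taxa: int = 40) -> SimulationConfig:
    """The canonical size/power scenario: star tree, single omega class.

    Used to check that the focal-taxon correlation stage detects a planted
    coupling and stays at its nominal false-positive rate when there is
    none (see module docstring for why the star topology is the right
    null here).
    """
    return SimulationConfig(
        n_taxa=n_taxa,
        tree_shape="star",
        depth=0.05,
        tau=0.6,
        kappa=2.0,
        group_omega={"all": 0.3},
        genes=(("g1", "all", 300),),
        coupling=coupling,
    )
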