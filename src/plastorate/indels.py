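"""In-frame indel counting against a designated reference taxon.

Indels in aligned protein-coding genes are summarised as one integer per
taxon: the number of indel events (maximal gap runs) accumulated over all
genes that remain intact for that taxon. A gene is intact for a taxon when
every gap run in either the taxon row or the reference row has a length
divisible by three — a frameshifting run disqualifies the gene for that
taxon only, not for the others.

An "event" is a maximal run of '-' characters: a run in the taxon row is a
deletion relative to the reference, a run in the reference row an
insertion. Columns gapped in both rows (typically another taxon's
insertion) carry no information about this pair and are stripped before
counting, with the number of stripped columns reported. A per-column mode
(counting gapped columns rather than runs) is available behind a flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .seqio_align import CodonAlignment


@dataclass
class GeneIndelResult:
    gene: str
    count: int
    intact: bool
    shared_gap_columns: int = 0


@dataclass
class IndelSummary:
    """Per-taxon indel totals over intact genes."""

    taxon: str
    per_gene: list  # GeneIndelResult per gene
    total: int
    n_genes_included: int
    n_genes_excluded: int
    excluded_genes: list = field(default_factory=list)


def _gap_runs(seq: str):
    runs = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(seq) - start))
    return runs


def gene_indel_events(ref_row: str, taxon_row: str, per_column: bool = False):
    """(count, intact, shared_gap_columns) for one gene's aligned pair.

    count is the number of maximal gap runs in either row after columns
    gapped in both rows are removed; intact is True iff every run length is
    a multiple of 3 in both rows. With ``per_column`` the count is gapped
    columns instead of runs (intactness unchanged).
    """
    if len(ref_row) != len(taxon_row):
        raise ValueError("rows must have equal length")
    shared = sum(1 for a, b in zip(ref_row, taxon_row) if a == "-" and b == "-")
    if shared:
        keep = [i for i, (a, b) in enumerate(zip(ref_row, taxon_row)) if not (a == "-" and b == "-")]
        ref_row = "".join(ref_row[i] for i in keep)
        taxon_row = "".join(taxon_row[i] for i in keep)
    ref_runs = _gap_runs(ref_row)
    tax_runs = _gap_runs(taxon_row)
    intact = all(length % 3 == 0 for _, length in ref_runs + tax_runs)
    if per_column:
        count = sum(length for _, length in ref_runs + tax_runs)
    else:
        count = len(ref_runs) + len(tax_runs)
    return count, intact, shared


def indel_totals(aln: CodonAlignment, reference_taxon: str, per_column: bool = False):
    """Per-taxon indel totals relative to the reference, intact genes only.

    Totals are invariant to gene order. The reference taxon itself gets a
    total of 0 by construction (identical rows have no gap runs after
    shared-gap stripping).
    """
    if reference_taxon not in aln.sequences:
        raise ValueError(f"reference taxon {reference_taxon!r} not in alignment")
    ref = aln.sequences[reference_taxon]
    out = []
    for taxon in aln.taxa:
        row = aln.sequences[taxon]
        per_gene = []
        total = 0
        excluded = []
        for b in aln.gene_blocks:
            count, intact, shared = gene_indel_events(ref[b.start : b.end], row[b.start : b.end], per_column=per_column)
            per_gene.append(GeneIndelResult(gene=b.name, count=count, intact=intact, shared_gap_columns=shared))
            if intact:
                total += count
            else:
                excluded.append(b.name)
        out.append(
            IndelSummary(
                taxon=taxon,
                per_gene=per_gene,
                total=total,
                n_genes_included=len(aln.gene_blocks) - len(excluded),
                n_genes_excluded=len(excluded),
                excluded_genes=excluded,
            )
        )
    return out


def indel_report(summaries) -> "pandas.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "taxon": s.taxon,
                "total_indels": s.total,
                "n_genes_included": s.n_genes_included,
                "n_genes_excluded": s.n_genes_excluded,
            }
            for s in summaries
        ]
    )
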