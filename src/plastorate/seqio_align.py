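"""Codon-alignment container and I/O.

A :class:`CodonAlignment` holds per-taxon aligned coding sequences together
with gene boundaries, with codon framing enforced throughout: the alignment
length and every gene block span are multiples of three, so codon columns are
well defined. Gene coordinates are 0-based half-open internally; the gene
table on disk uses 1-based inclusive coordinates, as do user-facing reports.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import translate_codon

VALID_CHARS = frozenset("ACGTN-")


class FramingError(ValueError):
    """Alignment or gene block breaks codon framing."""


class AlignmentInputError(ValueError):
    """Malformed alignment input (ragged rows, duplicate taxa, bad symbols)."""


@dataclass
class GeneBlock:
    name: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CodonAlignment:
    """In-frame multiple alignment of protein-coding sequence.

    sequences are uppercase strings over {A,C,G,T,N,-}; all the same length,
    which is a multiple of 3. gene_blocks tile (a subset of) the columns in
    codon-sized, non-overlapping spans.
    """

    taxa: list
    sequences: dict  # taxon -> str
    gene_blocks: list = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    @property
    def length(self) -> int:
        return len(self.sequences[self.taxa[0]]) if self.taxa else 0

    @property
    def gene_names(self) -> list:
        return [b.name for b in self.gene_blocks]

    def validate(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentInputError("duplicate taxon labels")
        if set(self.taxa) != set(self.sequences):
            raise AlignmentInputError("taxa and sequence keys disagree")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise FramingError(f"ragged alignment: row lengths {sorted(lengths)}")
        if self.taxa:
            n = self.length
            if n % 3:
                raise FramingError(f"alignment length {n} is not a multiple of 3")
            for s in self.sequences.values():
                bad = set(s) - VALID_CHARS
                if bad:
                    raise AlignmentInputError(f"unsupported symbols {sorted(bad)}; only A,C,G,T,N,- are accepted")
        prev_end = 0
        seen = set()
        for b in self.gene_blocks:
            if b.name in seen:
                raise AlignmentInputError(f"duplicate gene block {b.name!r}")
            seen.add(b.name)
            if b.start % 3 or b.end % 3 or b.end <= b.start:
                raise FramingError(f"gene block {b.name!r} [{b.start},{b.end}) breaks codon framing")
            if b.start < prev_end:
                raise AlignmentInputError(f"gene block {b.name!r} overlaps the previous block")
            if b.end > self.length:
                raise AlignmentInputError(f"gene block {b.name!r} extends past the alignment")
            prev_end = b.end

    def sequence(self, taxon: str) -> str:
        return self.sequences[taxon]

    def gene_slice(self, gene: str) -> GeneBlock:
        for b in self.gene_blocks:
            if b.name == gene:
                return b
        raise KeyError(f"unknown gene {gene!r}")


def _blocks_from_table(gene_table) -> list:
    """Gene table with 1-based inclusive start/end -> internal blocks."""
    blocks = []
    for row in gene_table.itertuples(index=False):
        blocks.append(GeneBlock(name=str(row.gene), start=int(row.start) - 1, end=int(row.end)))
    blocks.sort(key=lambda b: b.start)
    return blocks


def read_gene_table(path) -> pd.DataFrame:
    """Read the gene table TSV (columns gene, group, start, end; 1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "group": str})
    required = {"gene", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise AlignmentInputError(f"gene table missing columns: {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = "ungrouped"
    return df


def functional_group_map(gene_table: pd.DataFrame) -> dict:
    """gene -> functional group label (e.g. PSA, PSB, ATP, RPS...)."""
    return dict(zip(gene_table["gene"], gene_table["group"].fillna("ungrouped")))


def _parse_fasta(path) -> list:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _parse_relaxed_phylip(path) -> list:
    """Relaxed PHYLIP: header 'ntaxa ncols', then 'name  sequence' rows
    (sequence possibly whitespace-split; interleaved continuation supported)."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 2:
            raise AlignmentInputError("PHYLIP header must give taxon and column counts")
        ntax, ncols = int(header[0]), int(header[1])
        names, seqs = [], []
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            if len(names) < ntax:
                names.append(parts[0])
                seqs.append("".join(parts[1:]))
            else:  # interleaved continuation block
                i = min(range(len(seqs)), key=lambda j: len(seqs[j]))
                seqs[i] += "".join(parts)
    if len(names) != ntax:
        raise AlignmentInputError(f"PHYLIP header promised {ntax} taxa, found {len(names)}")
    for name, seq in zip(names, seqs):
        if len(seq) != ncols:
            raise AlignmentInputError(f"PHYLIP row {name!r} has {len(seq)} columns, header says {ncols}")
    return list(zip(names, (s.upper() for s in seqs)))


def read_alignment(path, gene_table=None, fmt: str | None = None) -> CodonAlignment:
    """Read a codon alignment from FASTA or relaxed PHYLIP.

    Parameters
    ----------
    path : str or Path
    gene_table : path, DataFrame or None
        Gene table (TSV columns gene, group, start, end; coordinates 1-based
        inclusive). If None, the whole alignment is one block named "all".
    fmt : "fasta" | "phylip" | None
        None sniffs from the first byte ('>' means FASTA).
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.read(1)
        fmt = "fasta" if first == ">" else "phylip"
    records = _parse_fasta(path) if fmt == "fasta" else _parse_relaxed_phylip(path)
    if not records:
        raise AlignmentInputError(f"no sequences found in {path}")
    taxa = [name for name, _ in records]
    if len(set(taxa)) != len(taxa):
        raise AlignmentInputError("duplicate taxon labels in alignment")
    sequences = dict(records)
    if gene_table is None:
        ncols = len(records[0][1])
        blocks = [GeneBlock("all", 0, ncols)] if ncols else []
    else:
        if not isinstance(gene_table, pd.DataFrame):
            gene_table = read_gene_table(gene_table)
        blocks = _blocks_from_table(gene_table)
    return CodonAlignment(taxa=taxa, sequences=sequences, gene_blocks=blocks)


def write_alignment(aln: CodonAlignment, path, fmt: str = "fasta") -> None:
    path = Path(path)
    if fmt == "fasta":
        records = [SeqRecord(Seq(aln.sequences[t]), id=t, description="") for t in aln.taxa]
        SeqIO.write(records, str(path), "fasta")
    elif fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(aln.taxa)} {aln.length}\n")
            for t in aln.taxa:
                fh.write(f"{t}  {aln.sequences[t]}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_gene_table(aln: CodonAlignment, path) -> None:
    """Write the gene table with 1-based inclusive coordinates."""
    rows = [{"gene": b.name, "group": "", "start": b.start + 1, "end": b.end} for b in aln.gene_blocks]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def strip_gapped_codon_columns(aln: CodonAlignment, taxa: list | None = None) -> CodonAlignment:
    """Remove every codon column containing a gap or N in any (selected) taxon.

    Mirrors PAL2NAL's -nogap behaviour: removal is codon-granular (triplets)
    and applies across all taxa so the result stays a single alignment.
    Restricting ``taxa`` gives the per-pair variant used before pairwise rate
    estimation. Gene-block coordinates are remapped; blocks that lose all
    their columns are dropped. The operation is idempotent.
    """
    focus = aln.taxa if taxa is None else list(taxa)
    seqs = [aln.sequences[t] for t in focus]
    keep = [
        i
        for i in range(0, aln.length, 3)
        if not any("-" in s[i : i + 3] or "N" in s[i : i + 3] for s in seqs)
    ]
    keep_set = set(keep)
    new_seqs = {t: "".join(aln.sequences[t][i : i + 3] for i in keep) for t in aln.taxa}
    new_blocks = []
    offset = 0
    for b in aln.gene_blocks:
        kept_here = sum(1 for i in range(b.start, b.end, 3) if i in keep_set)
        if kept_here:
            new_blocks.append(GeneBlock(b.name, offset, offset + 3 * kept_here))
            offset += 3 * kept_here
    if not keep:
        warnings.warn("all codon columns contained gaps; stripped alignment is empty", stacklevel=2)
    return CodonAlignment(taxa=list(aln.taxa), sequences=new_seqs, gene_blocks=new_blocks)


def concatenate(aln: CodonAlignment, genes: list) -> CodonAlignment:
    """New alignment whose columns are the requested gene blocks, in order.

    Passing every gene of one functional group yields that group's
    concatenated alignment; passing all genes in their original order is the
    identity.
    """
    blocks = [aln.gene_slice(g) for g in genes]
    new_seqs = {t: "".join(aln.sequences[t][b.start : b.end] for b in blocks) for t in aln.taxa}
    new_blocks = []
    offset = 0
    for b in blocks:
        new_blocks.append(GeneBlock(b.name, offset, offset + b.length))
        offset += b.length
    return CodonAlignment(taxa=list(aln.taxa), sequences=new_seqs, gene_blocks=new_blocks)


def genes_in_group(gene_table: pd.DataFrame, group: str) -> list:
    genes = list(gene_table.loc[gene_table["group"] == group, "gene"])
    if not genes:
        raise KeyError(f"no genes in functional group {group!r}")
    return genes


def translate(seq: str, table_id: int = 11) -> tuple:
    """Translate an ungapped coding sequence.

    Returns (protein string, internal stop positions). Stops translate to
    '*'; codons containing N translate to 'X'.
    """
    if "-" in seq:
        raise ValueError("translate expects an ungapped sequence; strip gaps first")
    if len(seq) % 3:
        raise FramingError(f"sequence length {len(seq)} is not a multiple of 3")
    aas = [translate_codon(seq[i : i + 3], table_id) for i in range(0, len(seq), 3)]
    protein = "".join(aas)
    internal_stops = [i + 1 for i, aa in enumerate(aas[:-1]) if aa == "*"]
    return protein, internal_stops
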