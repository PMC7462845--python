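"""Genetic-code tables and codon indexing shared by the rate estimators and
the sequence simulator.

The default code is NCBI translation table 11 (bacterial/archaeal/plant
plastid), the code used for plastid protein-coding genes. Its amino-acid
assignments coincide with the standard code; the tables are kept behind a
``table_id`` parameter so another code can be swapped in.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
NUC_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}

#: transition partners (purine<->purine, pyrimidine<->pyrimidine)
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

ALL_CODONS = tuple(a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES)


def is_transition(x: str, y: str) -> bool:
    return (x, y) in TRANSITIONS


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 11) -> dict:
    """Return the forward table {codon: aa} plus the stop-codon set."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fwd = dict(table.forward_table)
    stops = frozenset(table.stop_codons)
    return {"forward": fwd, "stops": stops}


@lru_cache(maxsize=None)
def sense_codons(table_id: int = 11) -> tuple:
    """Sense (non-stop) codons in fixed TCAG order; 61 for table 11."""
    stops = genetic_code(table_id)["stops"]
    return tuple(c for c in ALL_CODONS if c not in stops)


@lru_cache(maxsize=None)
def codon_index(table_id: int = 11) -> dict:
    return {c: i for i, c in enumerate(sense_codons(table_id))}


def translate_codon(codon: str, table_id: int = 11) -> str:
    """Translate one codon; 'X' for codons containing N, '*' for stops."""
    codon = codon.upper()
    if "N" in codon:
        return "X"
    code = genetic_code(table_id)
    if codon in code["stops"]:
        return "*"
    try:
        return code["forward"][codon]
    except KeyError as exc:
        raise ValueError(f"unrecognised codon {codon!r}") from exc


@lru_cache(maxsize=None)
def single_step_neighbors(table_id: int = 11):
    """For each sense codon, the sense codons one nucleotide change away.

    Returns a dict codon -> list of (neighbor, position, synonymous: bool,
    transition: bool). Changes to stop codons are not listed.
    """
    code = genetic_code(table_id)
    out = {}
    for codon in sense_codons(table_id):
        aa = code["forward"][codon]
        nbrs = []
        for pos in range(3):
            for base in NUCLEOTIDES:
                if base == codon[pos]:
                    continue
                other = codon[:pos] + base + codon[pos + 1 :]
                if other in code["stops"]:
                    continue
                nbrs.append(
                    (
                        other,
                        pos,
                        code["forward"][other] == aa,
                        is_transition(codon[pos], base),
                    )
                )
        out[codon] = nbrs
    return out


@lru_cache(maxsize=None)
def stop_adjacent_changes(table_id: int = 11) -> dict:
    """codon -> number of single-base changes that would create a stop."""
    code = genetic_code(table_id)
    out = {}
    for codon in sense_codons(table_id):
        k = 0
        for pos in range(3):
            for base in NUCLEOTIDES:
                if base != codon[pos]:
                    other = codon[:pos] + base + codon[pos + 1 :]
                    if other in code["stops"]:
                        k += 1
        out[codon] = k
    return out


def codons_of(seq: str):
    """Split a nucleotide string into codons; length must be 0 mod 3."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def encode_codon_sequence(seq: str, table_id: int = 11) -> np.ndarray:
    """Encode a gap-free coding sequence as sense-codon indices.

    Raises on stops, gaps and ambiguity codes: the codon-model machinery is
    defined on unambiguous sense codons only.
    """
    idx = codon_index(table_id)
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for i, codon in enumerate(codons_of(seq.upper())):
        try:
            out[i] = idx[codon]
        except KeyError as exc:
            raise ValueError(f"codon {codon!r} at codon position {i + 1} is not a sense codon") from exc
    return out


def f3x4_frequencies(sequences, table_id: int = 11) -> np.ndarray:
    """F3x4 equilibrium codon frequencies from observed sequences.

    Position-specific nucleotide frequencies are multiplied per codon,
    stops removed and the result renormalised over sense codons. Gaps and
    N are ignored in the counts. A pseudo-count avoids zero frequencies.
    """
    counts = np.ones((3, 4))  # pseudo-count 1 per (position, base)
    for seq in sequences:
        s = seq.upper()
        for i in range(0, len(s) - 2, 3):
            for pos in range(3):
                b = s[i + pos]
                if b in NUC_INDEX:
                    counts[pos, NUC_INDEX[b]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [freqs[0, NUC_INDEX[c[0]]] * freqs[1, NUC_INDEX[c[1]]] * freqs[2, NUC_INDEX[c[2]]] for c in sense_codons(table_id)]
    )
    return pi / pi.sum()
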