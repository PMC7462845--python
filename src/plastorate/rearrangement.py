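"""Signed gene-order permutations and exact inversion (reversal) distances.

A plastome's architecture, after removal of one inverted-repeat copy, is
summarised as a signed permutation of locally collinear blocks (LCBs):
block identity gives the order, the sign gives strand orientation. The
minimum number of segment reversals transforming one order into another is
computed exactly with the Hannenhalli–Pevzner breakpoint-graph formula

    d = (n + 1) - c + h + f

where c counts alternating cycles of the breakpoint graph of the permutation
framed by 0 and n+1, h counts hurdles (minimal unoriented components plus
the greatest unoriented component when it contains all others), and f is 1
exactly when the hurdles are odd in number and all of them are superhurdles
(the fortress case).

Chromosomes are treated as linear with fixed framing by default; a circular
mode (minimising over rotations and whole-molecule flips) is available
behind a flag. A breadth-first-search oracle over the reversal graph is
included for validation at small n.
"""
from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

_MINUS_CHARS = "−‑‐–"  # unicode minus / hyphen variants


class PermutationError(ValueError):
    pass


@dataclass(frozen=True)
class SignedPermutation:
    """An LCB order as signed integers; |values| are exactly 1..n."""

    taxon: str
    blocks: tuple

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(int(x) for x in self.blocks))
        if 0 in self.blocks:
            raise PermutationError(f"{self.taxon}: block id 0 is not allowed")
        absvals = sorted(abs(x) for x in self.blocks)
        n = len(self.blocks)
        if absvals != list(range(1, n + 1)):
            seen = set()
            for x in self.blocks:
                if abs(x) in seen:
                    raise PermutationError(f"{self.taxon}: duplicate block id {abs(x)}")
                seen.add(abs(x))
            missing = sorted(set(range(1, n + 1)) - seen)
            raise PermutationError(f"{self.taxon}: missing block ids {missing}")

    @property
    def n(self) -> int:
        return len(self.blocks)

    def is_identity(self) -> bool:
        return self.blocks == tuple(range(1, self.n + 1))

    def reversed_negated(self) -> "SignedPermutation":
        """Whole-molecule reversal (reverse order, flip all signs)."""
        return SignedPermutation(self.taxon, tuple(-x for x in reversed(self.blocks)))


@dataclass
class BreakpointStats:
    """Internals of the Hannenhalli–Pevzner computation; d = (n+1) - c + h + f."""

    n: int
    c: int
    h: int
    f: int

    @property
    def d(self) -> int:
        return (self.n + 1) - self.c + self.h + self.f


def parse_lcb_table(path) -> list:
    """Parse a signed-LCB-order TSV: one row per taxon.

    Accepted layouts: ``taxon<TAB>1 2 -3 ...`` or ``taxon 1 2 -3 ...``
    (label must not contain spaces in the latter). A header row starting
    with 'taxon' is skipped. Unicode minus signs are normalised.
    """
    perms = []
    text = Path(path).read_text()
    for ch in _MINUS_CHARS:
        text = text.replace(ch, "-")
    text = text.replace(" ", " ")
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if lineno == 1 and line.lower().startswith("taxon"):
            continue
        if "\t" in line:
            label, rest = line.split("\t", 1)
        else:
            label, rest = line.split(None, 1)
        # "- 28" (sign separated from digits) is normalised to "-28"
        rest = re.sub(r"-\s+(\d)", r"-\1", rest)
        try:
            blocks = tuple(int(tok) for tok in rest.split())
        except ValueError as exc:
            raise PermutationError(f"row {lineno} ({label}): non-integer block id") from exc
        try:
            perms.append(SignedPermutation(label.strip(), blocks))
        except PermutationError as exc:
            raise PermutationError(f"row {lineno}: {exc}") from exc
    if not perms:
        raise PermutationError("no permutations found")
    sizes = {p.n for p in perms}
    if len(sizes) > 1:
        raise PermutationError(f"mixed block counts across rows: {sorted(sizes)}")
    labels = [p.taxon for p in perms]
    if len(set(labels)) != len(labels):
        raise PermutationError("duplicate taxon labels in LCB table")
    return perms


def identical_order_groups(perms, up_to_reversal: bool = False):
    """Partition permutations by identical signed order.

    Returns (groups, shared_count) where groups is a list of taxon-label
    lists and shared_count is the number of taxa in groups of size >= 2.
    With ``up_to_reversal`` two orders also match when one is the
    whole-molecule reversal of the other (off by default; the exact-equality
    convention is what gene-order identity counts use).
    """
    buckets = {}
    for p in perms:
        key = p.blocks
        if up_to_reversal:
            key = min(p.blocks, p.reversed_negated().blocks)
        buckets.setdefault(key, []).append(p.taxon)
    groups = list(buckets.values())
    shared = sum(len(g) for g in groups if len(g) >= 2)
    return groups, shared


# ---------------------------------------------------------------------------
# Hannenhalli–Pevzner machinery
# ---------------------------------------------------------------------------

def _breakpoint_graph(blocks):
    """Unsigned doubling with frame: returns (sequence a, positions, n)."""
    n = len(blocks)
    a = [0]
    for x in blocks:
        if x > 0:
            a.extend((2 * x - 1, 2 * x))
        else:
            a.extend((-2 * x, -2 * x - 1))
    a.append(2 * n + 1)
    pos = [0] * (2 * n + 2)
    for i, v in enumerate(a):
        pos[v] = i
    return a, pos, n


def _cycles(a, pos, n):
    """Alternating black/gray cycles; returns list of cycles, each a list of
    gray edges (i, meaning gray edge {2i, 2i+1})."""
    # adjacency: black edge partner and gray edge partner per vertex
    black = {}
    for k in range(n + 1):
        u, v = a[2 * k], a[2 * k + 1]
        black[u] = v
        black[v] = u
    gray = {}
    for i in range(n + 1):
        gray[2 * i] = 2 * i + 1
        gray[2 * i + 1] = 2 * i
    seen = [False] * (2 * n + 2)
    cycles = []
    for start in range(2 * n + 2):
        if seen[start]:
            continue
        edges = []
        v = start
        use_black = True
        while not seen[v]:
            seen[v] = True
            if use_black:
                w = black[v]
            else:
                w = gray[v]
                edges.append(min(v, w) // 2)
            seen[w] = True if w == start else seen[w]
            v = w
            use_black = not use_black
            if v == start and use_black:
                break
        cycles.append(sorted(set(edges)))
    return cycles


def _hurdle_count(spans):
    """Hurdles among unoriented components given their position spans.

    Minimal components (containing no other) are hurdles; the greatest
    component is additionally a hurdle when its span contains every other
    unoriented component.
    """
    hurdles = []
    for i, (lo, hi) in enumerate(spans):
        contains_other = any(j != i and lo <= spans[j][0] and spans[j][1] <= hi for j in range(len(spans)))
        if not contains_other:
            hurdles.append(i)
        else:
            contains_all = all(j == i or (lo <= spans[j][0] and spans[j][1] <= hi) for j in range(len(spans)))
            if contains_all:
                hurdles.append(i)
    return hurdles


def breakpoint_stats(p: SignedPermutation) -> BreakpointStats:
    """Cycles, hurdles and fortress indicator for distance-to-identity."""
    a, pos, n = _breakpoint_graph(p.blocks)
    cycles = _cycles(a, pos, n)
    c = len(cycles)

    # nontrivial cycles and their gray-edge intervals
    nontrivial = [cyc for cyc in cycles if len(cyc) > 1]
    intervals = []  # per cycle: list of (lo, hi) position intervals of gray edges
    oriented_cycle = []
    for cyc in nontrivial:
        ivs = []
        oriented = False
        for i in cyc:
            pu, pv = pos[2 * i], pos[2 * i + 1]
            lo, hi = (pu, pv) if pu < pv else (pv, pu)
            ivs.append((lo, hi))
            if (pu + pv) % 2 == 0:  # same-parity endpoints: oriented gray edge
                oriented = True
        intervals.append(ivs)
        oriented_cycle.append(oriented)

    # interleaving graph over nontrivial cycles -> components
    m = len(nontrivial)
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for i, j in combinations(range(m), 2):
        done = False
        for lo1, hi1 in intervals[i]:
            for lo2, hi2 in intervals[j]:
                if (lo1 < lo2 < hi1 < hi2) or (lo2 < lo1 < hi2 < hi1):
                    union(i, j)
                    done = True
                    break
            if done:
                break

    comp_members = {}
    for i in range(m):
        comp_members.setdefault(find(i), []).append(i)

    unoriented_spans = []
    for members in comp_members.values():
        if any(oriented_cycle[i] for i in members):
            continue
        lo = min(iv[0] for i in members for iv in intervals[i])
        hi = max(iv[1] for i in members for iv in intervals[i])
        unoriented_spans.append((lo, hi))

    hurdles = _hurdle_count(unoriented_spans)
    h = len(hurdles)
    f = 0
    if h and h % 2 == 1:
        # fortress iff every hurdle is a superhurdle: removing it does not
        # reduce the hurdle count (a protected component becomes a hurdle)
        all_super = True
        for idx in hurdles:
            reduced = [s for k, s in enumerate(unoriented_spans) if k != idx]
            if len(_hurdle_count(reduced)) < h:
                all_super = False
                break
        f = 1 if all_super else 0
    return BreakpointStats(n=n, c=c, h=h, f=f)


def reversal_distance_to_identity(p: SignedPermutation) -> BreakpointStats:
    """Exact minimum number of reversals sorting p to +1..+n (linear frame)."""
    return breakpoint_stats(p)


def _relabel(a: SignedPermutation, b: SignedPermutation) -> SignedPermutation:
    """Express a in the coordinate system where b is the identity."""
    if a.n != b.n:
        raise PermutationError(f"block counts differ: {a.n} vs {b.n}")
    mapping = {}
    for k, x in enumerate(b.blocks, start=1):
        mapping[abs(x)] = k if x > 0 else -k
    return SignedPermutation(a.taxon, tuple((mapping[abs(x)] if x > 0 else -mapping[abs(x)]) for x in a.blocks))


def reversal_distance(a: SignedPermutation, b: SignedPermutation, circular: bool = False) -> int:
    """Reversal distance between two signed permutations; symmetric.

    ``circular`` minimises over all rotations and the whole-molecule flip of
    one genome, for circular molecules without a fixed linearisation point.
    """
    rel = _relabel(a, b)
    if not circular:
        return breakpoint_stats(rel).d
    best = None
    for variant in (rel, rel.reversed_negated()):
        blocks = variant.blocks
        for r in range(len(blocks)):
            rotated = SignedPermutation(a.taxon, blocks[r:] + blocks[:r])
            d = breakpoint_stats(rotated).d
            best = d if best is None else min(best, d)
    return best


def apply_reversal(blocks: tuple, i: int, j: int) -> tuple:
    """Reverse the segment [i, j] (0-based inclusive), negating signs."""
    return blocks[:i] + tuple(-x for x in reversed(blocks[i : j + 1])) + blocks[j + 1 :]


def bfs_oracle_distance(a: SignedPermutation, b: SignedPermutation, max_n: int = 8) -> int:
    """Exact distance by breadth-first search over the reversal graph.

    Independent of the breakpoint-graph formula; guarded to n <= max_n
    because the state space is n! * 2^n.
    """
    if a.n != b.n:
        raise PermutationError("block counts differ")
    if a.n > max_n:
        raise PermutationError(f"n = {a.n} too large for the BFS oracle (max {max_n})")
    start, goal = a.blocks, b.blocks
    if start == goal:
        return 0
    dist = {start: 0}
    queue = deque([start])
    n = a.n
    while queue:
        cur = queue.popleft()
        d = dist[cur]
        for i in range(n):
            for j in range(i, n):
                nxt = apply_reversal(cur, i, j)
                if nxt == goal:
                    return d + 1
                if nxt not in dist:
                    dist[nxt] = d + 1
                    queue.append(nxt)
    raise RuntimeError("unreachable: reversal graph is connected")


def bfs_distances_from_identity(n: int, max_n: int = 6) -> dict:
    """All reversal distances from the identity at size n, by one BFS sweep."""
    if n > max_n:
        raise PermutationError(f"n = {n} too large for exhaustive BFS (max {max_n})")
    start = tuple(range(1, n + 1))
    dist = {start: 0}
    queue = deque([start])
    while queue:
        cur = queue.popleft()
        d = dist[cur]
        for i in range(n):
            for j in range(i, n):
                nxt = apply_reversal(cur, i, j)
                if nxt not in dist:
                    dist[nxt] = d + 1
                    queue.append(nxt)
    return dist


def pairwise_iv_matrix(perms, circular: bool = False):
    """Symmetric matrix of pairwise inversion distances.

    Returns (taxa, matrix) with a zero diagonal. Distances use the
    consistency identity d = (n+1) - c + h + f internally; an assertion
    failure there would indicate a breakpoint-graph bug.
    """
    taxa = [p.taxon for p in perms]
    k = len(perms)
    mat = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            d = reversal_distance(perms[i], perms[j], circular=circular)
            mat[i, j] = mat[j, i] = d
    return taxa, mat


def write_iv_matrix(taxa, mat, path) -> None:
    import pandas as pd

    pd.DataFrame(mat, index=taxa, columns=taxa).to_csv(path, sep="\t")


def random_permutation(n: int, rng: np.random.Generator, taxon: str = "random") -> SignedPermutation:
    order = rng.permutation(n) + 1
    signs = rng.choice([-1, 1], size=n)
    return SignedPermutation(taxon, tuple(int(o * s) for o, s in zip(order, signs)))
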