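"""Independent brute-force oracles used by the test suite.

Everything here is written from the problem definitions alone — plain
loops, recursion and enumeration — and never calls into phenoscreen, so
agreement with the package is evidence, not tautology.
"""

from __future__ import annotations

import math
from itertools import combinations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = 11
GAP_EXTEND = 1


def blosum62(a: str, b: str) -> float:
    return float(_B62[a, b])


# ---------------------------------------------------------------- consensus

def consensus_oracle(rows: list[str], tau: float):
    """Per-column (callable, residue) by direct counting; gap rows count in
    the denominator, modal ties break alphabetically."""
    n = len(rows)
    out = []
    for j in range(len(rows[0])):
        col = [r[j] for r in rows]
        residues = sorted({c for c in col if c != "-"})
        best = None
        for r in residues:
            k = col.count(r)
            if best is None or k > best[1]:
                best = (r, k)
        if best is not None and best[1] >= tau * n - 1e-12:
            out.append((True, best[0]))
        else:
            out.append((False, None))
    return out


def maximal_runs_oracle(flags: list[bool], min_len: int):
    """(start, end) spans of maximal True runs of length >= min_len."""
    spans = []
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j < len(flags) and flags[j]:
                j += 1
            if j - i >= min_len:
                spans.append((i, j))
            i = j
        else:
            i += 1
    return spans


# ------------------------------------------------------- pairwise alignment

def _enumerate_alignments(a: str, b: str):
    """Yield every gapped alignment (ga, gb) of the full strings."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ga, gb in _enumerate_alignments(a[1:], b):
            yield a[0] + ga, "-" + gb
    if b:
        for ga, gb in _enumerate_alignments(a, b[1:]):
            yield "-" + ga, b[0] + gb
    if a and b:
        for ga, gb in _enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ga, b[0] + gb


def _score_gapped(ga: str, gb: str) -> float:
    """Affine-gap score of one gapped alignment: a gap of length k costs
    GAP_OPEN + k * GAP_EXTEND."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(ga, gb):
        if x == "-" and y == "-":
            return -math.inf  # not a valid alignment column
        if x == "-":
            score -= (GAP_OPEN + GAP_EXTEND) if not in_gap_a else GAP_EXTEND
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= (GAP_OPEN + GAP_EXTEND) if not in_gap_b else GAP_EXTEND
            in_gap_a, in_gap_b = False, True
        else:
            score += blosum62(x, y)
            in_gap_a = in_gap_b = False
    return score


def global_enumeration_score(a: str, b: str):
    """Best global alignment by full enumeration (tiny inputs only)."""
    best, best_aln = -math.inf, None
    for ga, gb in _enumerate_alignments(a, b):
        s = _score_gapped(ga, gb)
        if s > best:
            best, best_aln = s, (ga, gb)
    return best, best_aln


def local_enumeration_score(a: str, b: str) -> float:
    """Best local alignment by enumerating every substring pair and every
    alignment of each pair (use only for len <= ~5)."""
    best = 0.0
    for i, j in combinations(range(len(a) + 1), 2):
        for k, l in combinations(range(len(b) + 1), 2):
            s, _ = global_enumeration_score(a[i:j], b[k:l])
            best = max(best, s)
    return best


def local_dp_score(a: str, b: str) -> float:
    """Smith-Waterman affine-gap score by an explicit three-state recurrence
    written independently (checked against local_enumeration_score)."""
    n, m = len(a), len(b)
    NEG = -math.inf
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0.0)
            M[i][j] = blosum62(a[i - 1], b[j - 1]) + prev
            Ix[i][j] = max(
                M[i - 1][j] - GAP_OPEN - GAP_EXTEND, Ix[i - 1][j] - GAP_EXTEND
            )
            Iy[i][j] = max(
                M[i][j - 1] - GAP_OPEN - GAP_EXTEND, Iy[i][j - 1] - GAP_EXTEND
            )
            best = max(best, M[i][j])
    return best


# ------------------------------------------------------------------- ORFs

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _rc(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def orf_oracle(seq: str, min_aa: int):
    """Set of (frame, nt_start, nt_end, protein) by direct codon scanning."""
    L = len(seq)
    found = set()
    for strand, s in ((1, seq), (-1, _rc(seq))):
        for off in range(3):
            aa = ""
            for p in range(off, L - 2, 3):
                aa += _CODON_TABLE.get(s[p : p + 3], "X")
            start = 0
            for i, c in enumerate(aa + "*"):
                if c == "*":
                    if i - start >= min_aa:
                        s0, e0 = off + 3 * start, off + 3 * i
                        if strand == 1:
                            span = (s0, e0)
                        else:
                            span = (L - e0, L - s0)
                        found.add(
                            (strand * (off + 1), span[0], span[1], aa[start:i])
                        )
                    start = i + 1
    return found


# -------------------------------------------------------------------- trees

def _four_point_fit(labels, dist, topology):
    """Least-squares branch lengths of one unrooted topology; returns
    (residual, lengths).  `topology` is a frozenset of non-trivial
    bipartitions (each a frozenset of labels)."""
    import numpy as np

    pairs = list(combinations(labels, 2))
    # edges: one terminal edge per leaf + one internal edge per bipartition
    edges = [frozenset([x]) for x in labels] + list(topology)
    X = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (p, q) in enumerate(pairs):
        y[r] = dist[p][q]
        for c, side in enumerate(edges):
            # edge lies on the p-q path iff it separates p from q
            if (p in side) != (q in side):
                X[r, c] = 1.0
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    return float(((fitted - y) ** 2).sum()), dict(zip(map(tuple, edges), coef))


def all_unrooted_topologies(labels):
    """All non-trivial-bipartition sets of unrooted binary trees on the
    labels (4 taxa: 3 trees; 5 taxa: 15 trees)."""
    labels = list(labels)
    n = len(labels)
    if n == 4:
        a, b, c, d = labels
        return [
            frozenset([frozenset([a, b])]),
            frozenset([frozenset([a, c])]),
            frozenset([frozenset([a, d])]),
        ]
    if n == 5:
        tops = set()
        for pair in combinations(labels, 2):
            rest = [x for x in labels if x not in pair]
            for pair2 in combinations(rest, 2):
                # caterpillar: cherry `pair`, cherry `pair2`
                tops.add(
                    frozenset(
                        [frozenset(pair), frozenset(pair2)]
                    )
                )
        return sorted(tops, key=lambda t: sorted(map(sorted, t)))
    raise ValueError("oracle supports 4 or 5 taxa")


def best_additive_topology(labels, dist):
    """Topology whose least-squares fit to the distances is (near) exact."""
    best = None
    for top in all_unrooted_topologies(labels):
        res, lengths = _four_point_fit(labels, dist, top)
        if best is None or res < best[0]:
            best = (res, top, lengths)
    return best
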