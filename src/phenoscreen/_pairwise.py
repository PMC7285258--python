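"""Shared pairwise protein alignment machinery (BLOSUM62, affine gaps 11/1).

Gap cost follows the BLAST convention: a gap of length k costs
open + k * extend = 11 + k, so the aligner's first-gap-residue score is
-(open + extend) = -12 and each further gapped residue scores -1.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

GAP_OPEN = 11
GAP_EXTEND = 1

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
AA_VALID = AA20 | {"X"}


def validate_protein(seq: str, *, where: str = "sequence") -> None:
    bad = set(seq.upper()) - AA_VALID
    if not seq:
        raise ValueError(f"empty {where}")
    if bad:
        raise ValueError(
            f"non-amino-acid characters {sorted(bad)} in {where}"
        )


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    a.extend_gap_score = -GAP_EXTEND
    a.mode = mode
    return a


def global_align(a: str, b: str) -> tuple[str, str, float]:
    """Optimal global alignment; returns (gapped_a, gapped_b, score)."""
    aln = _aligner("global").align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1]), aln.score


def local_align_raw(a: str, b: str):
    """Best local alignment or None when no positive-scoring one exists.

    Returns (gapped_a, gapped_b, score, a_span, b_span) with spans as
    0-based half-open coordinates on the ungapped inputs.
    """
    alns = _aligner("local").align(a.upper(), b.upper())
    if len(alns) == 0:
        return None
    best = alns[0]
    if best.score <= 0:
        return None
    a_blocks, b_blocks = best.aligned
    a_span = (int(a_blocks[0][0]), int(a_blocks[-1][1]))
    b_span = (int(b_blocks[0][0]), int(b_blocks[-1][1]))
    return str(best[0]), str(best[1]), float(best.score), a_span, b_span


def column_identity(ga: str, gb: str) -> float:
    """Identical residue pairs over all alignment columns (gaps count)."""
    if len(ga) != len(gb) or not ga:
        raise ValueError("gapped sequences must be non-empty and equal length")
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return matches / len(ga)


def global_identity(a: str, b: str) -> float:
    """Identity of the optimal global alignment of two ungapped sequences."""
    ga, gb, _ = global_align(a, b)
    return column_identity(ga, gb)
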