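"""Homology screening of predicted proteins against consensus probes.

Candidate proteins are predicted from contigs as stop-to-stop open reading
frames in all six frames, aligned locally against each probe
(Smith-Waterman, BLOSUM62, affine gaps 11/1) and filtered with the screen's
pass thresholds: E-value < 0.1, identity > 40%, query coverage > 50% (all
strict).  E-values use the Karlin-Altschul form E = K*m*n*exp(-lambda*S)
with the published gapped BLOSUM62-11/1 constants as defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq

from phenoscreen._pairwise import (
    column_identity,
    local_align_raw,
    validate_protein,
)

_NT = set("ACGTN")


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    sample_label: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r} is empty")
        bad = set(self.sequence.upper()) - _NT
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r} has non-nucleotide characters "
                f"{sorted(bad)}"
            )


@dataclass(frozen=True)
class PredictedProtein:
    """An ORF translation with forward-strand 0-based half-open coordinates."""

    protein_id: str
    contig_id: str
    frame: int  # one of +1..+3, -1..-3
    nt_start: int
    nt_end: int
    sequence: str
    sample_label: str = ""

    def __post_init__(self):
        if (self.nt_end - self.nt_start) % 3:
            raise ValueError("ORF span not divisible by 3")
        if "*" in self.sequence:
            raise ValueError("internal stop codon in predicted protein")


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Gapped BLOSUM62 11/1 constants: lambda in nats per score unit."""

    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self):
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    identity: float          # identical pairs / alignment columns (gaps incl.)
    query_coverage: float    # aligned query residues / probe length
    evalue: float = math.nan


@dataclass(frozen=True)
class FilterThresholds:
    """Pass thresholds; all comparisons are strict (E < E_max, id > id_min,
    cov > cov_min), so boundary values fail."""

    E_max: float = 0.1
    id_min: float = 0.40
    cov_min: float = 0.50

    def __post_init__(self):
        for name in ("id_min", "cov_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if self.E_max <= 0:
            raise ValueError("E_max must be positive")

    def passes(self, r: AlignmentResult) -> bool:
        return (
            r.evalue < self.E_max
            and r.identity > self.id_min
            and r.query_coverage > self.cov_min
        )


@dataclass(frozen=True)
class HomologyHit:
    probe_id: str
    family_id: str
    protein_id: str
    sample_label: str
    result: AlignmentResult
    passed: bool


def read_contigs(path, sample_label: str = "") -> list[Contig]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no contigs in {path}")
    return [
        Contig(r.id, str(r.seq).upper(), sample_label=sample_label)
        for r in records
    ]


def _frame_orfs(aa: str, min_aa: int):
    """(aa_start, aa_end) spans of stop-to-stop segments of length >= min_aa."""
    spans = []
    start = 0
    for i, c in enumerate(aa + "*"):
        if c == "*":
            if i - start >= min_aa:
                spans.append((start, i))
            start = i + 1
    return spans


def six_frame_orfs(contig: Contig, min_aa: int = 60) -> list[PredictedProtein]:
    """All maximal stop-to-stop ORFs of >= min_aa residues in all six frames.

    Translation uses the standard genetic code; negative-frame coordinates
    are mirrored back onto the forward strand.  Output order is frame
    (+1, +2, +3, -1, -2, -3), then position.
    """
    seq = contig.sequence.upper()
    L = len(seq)
    if L < 3 * min_aa:
        return []
    out: list[PredictedProtein] = []
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    for strand, template in ((+1, fwd), (-1, rev)):
        for off in range(3):
            sub = template[off : off + 3 * ((L - off) // 3)]
            aa = str(sub.translate())
            for a0, a1 in _frame_orfs(aa, min_aa):
                s, e = off + 3 * a0, off + 3 * a1
                if strand == 1:
                    nt_start, nt_end = s, e
                else:
                    nt_start, nt_end = L - e, L - s
                frame = strand * (off + 1)
                out.append(
                    PredictedProtein(
                        protein_id=(
                            f"{contig.contig_id}|{'+' if frame > 0 else ''}"
                            f"{frame}|{nt_start}-{nt_end}"
                        ),
                        contig_id=contig.contig_id,
                        frame=frame,
                        nt_start=nt_start,
                        nt_end=nt_end,
                        sequence=aa[a0:a1],
                        sample_label=contig.sample_label,
                    )
                )
    return out


def local_align(probe: str, target: str) -> AlignmentResult | None:
    """Optimal Smith-Waterman local alignment (BLOSUM62, gaps 11/1).

    Returns None when no positive-scoring local alignment exists.  The
    E-value field is left NaN; `evalue` fills it in against a search-set
    size.
    """
    validate_protein(probe, where="probe")
    validate_protein(target, where="target")
    raw = local_align_raw(probe, target)
    if raw is None:
        return None
    ga, gb, score, a_span, b_span = raw
    return AlignmentResult(
        score=score,
        query_span=a_span,
        target_span=b_span,
        identity=column_identity(ga, gb),
        query_coverage=(a_span[1] - a_span[0]) / len(probe),
    )


def evalue(S: float, m: int, n: int, params: KarlinAltschulParams = KarlinAltschulParams()) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    return params.K * m * n * math.exp(-params.lam * S)


def screen(
    probes,
    proteins,
    thresholds: FilterThresholds = FilterThresholds(),
    params: KarlinAltschulParams = KarlinAltschulParams(),
    decoys: dict[str, str] | None = None,
) -> list[HomologyHit]:
    """Screen every probe against every protein; one best hit per pair.

    `decoys` maps decoy IDs to reference protein sequences known to attract
    spurious hits (e.g. copper-transporting P-type ATPases in a PH screen);
    a hit whose protein aligns better to any decoy than to the probe is
    dropped.  Hits are sorted by ascending E-value.
    """
    probes = list(probes)
    proteins = list(proteins)
    if not probes:
        raise ValueError("empty probe set: screen misconfigured")
    n_total = sum(len(p.sequence) for p in proteins)
    hits: list[HomologyHit] = []
    decoy_best: dict[str, float] = {}
    if decoys:
        for prot in proteins:
            best = 0.0
            for dseq in decoys.values():
                raw = local_align_raw(dseq, prot.sequence)
                if raw is not None:
                    best = max(best, raw[2])
            decoy_best[prot.protein_id] = best
    for probe in probes:
        for prot in proteins:
            res = local_align(probe.sequence, prot.sequence)
            if res is None:
                continue
            if decoys and decoy_best.get(prot.protein_id, 0.0) > res.score:
                continue
            E = evalue(res.score, len(probe.sequence), max(n_total, 1), params)
            res = AlignmentResult(
                score=res.score,
                query_span=res.query_span,
                target_span=res.target_span,
                identity=res.identity,
                query_coverage=res.query_coverage,
                evalue=E,
            )
            hits.append(
                HomologyHit(
                    probe_id=probe.probe_id,
                    family_id=probe.family_id,
                    protein_id=prot.protein_id,
                    sample_label=prot.sample_label,
                    result=res,
                    passed=thresholds.passes(res),
                )
            )
    hits.sort(key=lambda h: (h.result.evalue, h.probe_id, h.protein_id))
    return hits


def hits_table(hits) -> list[dict]:
    """Rows for the hits TSV."""
    return [
        {
            "probe_id": h.probe_id,
            "protein_id": h.protein_id,
            "sample": h.sample_label,
            "score": h.result.score,
            "evalue": h.result.evalue,
            "identity": round(h.result.identity, 6),
            "coverage": round(h.result.query_coverage, 6),
            "passed": h.passed,
        }
        for h in hits
    ]
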