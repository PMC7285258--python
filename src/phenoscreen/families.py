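"""Reference protein families and consensus-probe construction.

A consensus probe is the amino-acid sequence of a conserved region of a
family alignment: a maximal run of columns whose modal residue is shared by
at least a fraction ``consensus_threshold`` (default 50%) of the family
members.  The probes are the queries of the downstream homology screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import SeqIO

from phenoscreen._pairwise import global_align, validate_protein

log = logging.getLogger(__name__)

GAP = "-"


@dataclass(frozen=True)
class ReferenceFamily:
    """A curated set of homologous proteins (e.g. the PH, C12O or C23O set)."""

    family_id: str
    members: tuple[tuple[str, str], ...]  # (seq_id, ungapped aa sequence)
    source_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError(
                f"family {self.family_id!r} needs >=2 members, "
                f"got {len(self.members)}"
            )
        seen = set()
        for seq_id, seq in self.members:
            if seq_id in seen:
                raise ValueError(f"duplicate sequence ID {seq_id!r}")
            seen.add(seq_id)
            validate_protein(seq, where=f"member {seq_id!r}")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MultipleAlignment:
    """Gapped rows of equal length; degapping recovers the input members."""

    rows: tuple[tuple[str, str], ...]  # (seq_id, gapped sequence)
    family_id: str = ""

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment has no rows")
        lens = {len(s) for _, s in self.rows}
        if len(lens) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lens)}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> list[str]:
        return [s[j] for _, s in self.rows]

    def degapped(self) -> list[tuple[str, str]]:
        return [(sid, s.replace(GAP, "")) for sid, s in self.rows]


@dataclass(frozen=True)
class ProbeConfig:
    """Probe-extraction settings.

    consensus_threshold: fraction of all rows (gaps included in the
        denominator) the modal residue must reach for a column to be
        callable; 0.5 is the standard at-least-half rule.
    min_region_len: shortest conserved run emitted as a probe, in residues.
    """

    consensus_threshold: float = 0.5
    min_region_len: int = 8

    def __post_init__(self):
        if not (0.0 < self.consensus_threshold <= 1.0):
            raise ValueError("consensus_threshold must be in (0, 1]")
        if self.min_region_len < 1:
            raise ValueError("min_region_len must be >= 1")


@dataclass(frozen=True)
class ConsensusProbe:
    probe_id: str
    family_id: str
    sequence: str
    column_span: tuple[int, int]  # 0-based half-open alignment columns

    def __post_init__(self):
        start, end = self.column_span
        if len(self.sequence) != end - start:
            raise ValueError("probe length does not match its column span")
        if GAP in self.sequence:
            raise ValueError("probe sequence contains gap characters")


def read_family(path, family_id: str) -> ReferenceFamily:
    """Read an ungapped protein FASTA into a ReferenceFamily.

    Record order is preserved; duplicate IDs and non-amino-acid characters
    are rejected with the offending identifier in the message.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    members = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence ID {rec.id!r} in {path}")
        seen.add(rec.id)
        members.append((rec.id, str(rec.seq).upper()))
    return ReferenceFamily(family_id=family_id, members=tuple(members))


def read_alignment(path, family_id: str = "") -> MultipleAlignment:
    """Read a pre-aligned FASTA (gap character '-')."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    rows = tuple((r.id, str(r.seq).upper()) for r in records)
    for sid, s in rows:
        validate_protein(s.replace(GAP, ""), where=f"row {sid!r}")
    return MultipleAlignment(rows=rows, family_id=family_id)


def _merge_into_master(master: str, pairwise_master: str):
    """Column insertion maps merging a new pairwise view of the centre.

    Returns (merged_master, ins_old, ins_new): positions (in the merged
    coordinate system) at which gap columns must be inserted into rows
    aligned against the old master / the new pairwise row respectively.
    """
    i = j = 0
    merged = []
    ins_old, ins_new = [], []
    while i < len(master) or j < len(pairwise_master):
        a = master[i] if i < len(master) else None
        b = pairwise_master[j] if j < len(pairwise_master) else None
        if a is not None and b is not None and (a == b or (a != GAP and b != GAP)):
            merged.append(a)
            i += 1
            j += 1
        elif a == GAP:
            merged.append(GAP)
            ins_new.append(len(merged) - 1)
            i += 1
        else:  # b == GAP or one string exhausted
            merged.append(b if b is not None else a)
            if b is not None:
                ins_old.append(len(merged) - 1)
                j += 1
            else:
                ins_new.append(len(merged) - 1)
                i += 1
    return "".join(merged), ins_old, ins_new


def _insert_gaps(row: str, positions: list[int]) -> str:
    chars = list(row)
    for p in positions:  # positions are in final coordinates, ascending
        chars.insert(p, GAP)
    return "".join(chars)


def align_family(family) -> MultipleAlignment:
    """Align a family with the built-in centre-star progressive aligner.

    Global pairwise alignments (BLOSUM62, gap open 11 / extend 1) of every
    member against the longest member are merged under the
    once-a-gap-always-a-gap rule.  A MultipleAlignment passed in is
    returned unchanged, so pre-aligned input flows through untouched.
    """
    if isinstance(family, MultipleAlignment):
        return family
    if len(family) < 2:
        raise ValueError(
            "cannot align a single-member family; pass a pre-aligned file"
        )
    # centre = longest member, first wins ties: deterministic
    centre_idx = max(
        range(len(family.members)), key=lambda i: (len(family.members[i][1]), -i)
    )
    centre_id, centre_seq = family.members[centre_idx]
    master = centre_seq
    aligned: list[tuple[str, str]] = [(centre_id, centre_seq)]
    for idx, (sid, seq) in enumerate(family.members):
        if idx == centre_idx:
            continue
        g_centre, g_new, _ = global_align(centre_seq, seq)
        master, ins_old, ins_new = _merge_into_master(master, g_centre)
        aligned = [(rid, _insert_gaps(row, ins_old)) for rid, row in aligned]
        aligned.append((sid, _insert_gaps(g_new, ins_new)))
    # restore input member order
    order = {sid: k for k, (sid, _) in enumerate(family.members)}
    aligned.sort(key=lambda r: order[r[0]])
    aln = MultipleAlignment(rows=tuple(aligned), family_id=family.family_id)
    for (sid, gapped), (_, original) in zip(aln.rows, family.members):
        if gapped.replace(GAP, "") != original:
            raise AssertionError(f"alignment corrupted member {sid!r}")
    return aln


def call_consensus_columns(
    aln: MultipleAlignment, cfg: ProbeConfig = ProbeConfig()
) -> list[tuple[bool, str | None]]:
    """Per-column consensus calls.

    A column is callable iff its most frequent non-gap residue occurs in at
    least ``consensus_threshold`` of ALL rows (gap rows count against it).
    Modal ties break alphabetically.
    """
    n = aln.n_rows
    out: list[tuple[bool, str | None]] = []
    for j in range(aln.n_cols):
        counts: dict[str, int] = {}
        for c in aln.column(j):
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append((False, None))
            continue
        residue = min(counts, key=lambda r: (-counts[r], r))
        callable_ = counts[residue] >= cfg.consensus_threshold * n - 1e-12
        out.append((callable_, residue) if callable_ else (False, None))
    return out


def extract_probes(
    aln: MultipleAlignment,
    consensus_calls: list[tuple[bool, str | None]],
    cfg: ProbeConfig = ProbeConfig(),
) -> list[ConsensusProbe]:
    """Emit each maximal run of callable columns of length >= min_region_len
    as one probe, the concatenated modal residues."""
    if len(consensus_calls) != aln.n_cols:
        raise ValueError("consensus_calls length does not match alignment")
    probes: list[ConsensusProbe] = []
    run_start = None
    calls = list(consensus_calls) + [(False, None)]  # sentinel closes last run
    for j, (ok, _) in enumerate(calls):
        if ok and run_start is None:
            run_start = j
        elif not ok and run_start is not None:
            if j - run_start >= cfg.min_region_len:
                seq = "".join(calls[k][1] for k in range(run_start, j))
                probes.append(
                    ConsensusProbe(
                        probe_id=f"{aln.family_id or 'family'}|probe_{len(probes) + 1}",
                        family_id=aln.family_id,
                        sequence=seq,
                        column_span=(run_start, j),
                    )
                )
            run_start = None
    if not probes:
        log.warning(
            "no conserved run of >=%d columns in family %r",
            cfg.min_region_len, aln.family_id,
        )
    return probes


def write_probes_fasta(probes, path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            s, e = p.column_span
            fh.write(f">{p.family_id}|{p.probe_id.split('|')[-1]}|span={s}-{e}\n")
            fh.write(p.sequence + "\n")


def probe_manifest(probes):
    """Rows for the TSV probe manifest."""
    return [
        {
            "probe_id": p.probe_id,
            "family_id": p.family_id,
            "start": p.column_span[0],
            "end": p.column_span[1],
            "length": len(p.sequence),
        }
        for p in probes
    ]
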