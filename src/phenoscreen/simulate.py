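"""Seeded generators for every pipeline input, with ground truth attached.

The generators emulate the study's inputs at desk scale: curated reference
protein families, assembled contigs with implanted oxygenase-homolog CDS at
controlled amino-acid identities plus composition-matched shuffled decoys,
OD580 growth curves from known Gompertz parameters, binomial FACS draws and
dose-response plates.  Identity — not mutational realism — is the
controlled variable, because identity is what the screen's thresholds act
on: substitutions are i.i.d. uniform over the 19 alternative residues.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from phenoscreen.families import ReferenceFamily
from phenoscreen.kinetics import FACSSample, GompertzFit, GrowthCurve, gompertz
from phenoscreen.screen import Contig

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# standard genetic code, inverted: aa -> codons (no stop codons appear,
# so reverse-translated CDS can never contain an internal stop)
_CODONS: dict[str, list[str]] = {}
_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
for codon, aa in _TABLE.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()

_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class FamilySimSpec:
    """Reference-family simulation: members diverge from a common ancestor
    to identities drawn from [identity_lo, identity_hi]."""

    family_id: str
    ancestor_len: int = 300
    n_members: int = 10
    identity_lo: float = 0.7
    identity_hi: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.identity_lo <= self.identity_hi <= 1.0):
            raise ValueError("identity range must satisfy 0 < lo <= hi <= 1")
        if self.ancestor_len < 1 or self.n_members < 2:
            raise ValueError("need ancestor_len >= 1 and n_members >= 2")


@dataclass(frozen=True)
class ImplantPlan:
    """Per-family implant plan for a synthetic metagenome."""

    family_id: str
    n_implants: int
    identity: float  # target aa identity of each implant to the ancestor


@dataclass(frozen=True)
class MetagenomeSimSpec:
    implants: tuple[ImplantPlan, ...]
    n_decoys: int = 5
    n_background_contigs: int = 5
    contig_len_mean: int = 6000
    contig_len_sd: int = 1000
    sample_labels: tuple[str, ...] = ("S", "C", "G")
    seed: int = 0

    def __post_init__(self):
        if self.n_decoys < 0 or self.n_background_contigs < 0:
            raise ValueError("counts must be >= 0")
        if not self.sample_labels:
            raise ValueError("need at least one sample label")


@dataclass(frozen=True)
class TruthRow:
    contig_id: str
    nt_start: int
    nt_end: int
    strand: str  # '+' or '-'
    label: str   # family_id or 'decoy'
    identity: float  # realized aa identity to the family ancestor (decoys: to source)


def _mutate_to_identity(seq: str, n_sub: int, rng) -> str:
    """Substitute n_sub distinct positions, uniform over 19 alternatives."""
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for p in pos:
        alternatives = [a for a in AA20 if a != chars[p]]
        chars[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def evolve_family(spec: FamilySimSpec) -> tuple[ReferenceFamily, str, list[float]]:
    """Simulate a reference family; returns (family, ancestor, identities).

    Substitution counts are chosen so every member's realized identity to
    the ancestor falls exactly inside the target range; an empty attainable
    count range (identity window narrower than 1/length) is an error.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.ancestor_len
    ancestor = "".join(AA20[i] for i in rng.integers(0, 20, size=L))
    k_min = math.ceil((1.0 - spec.identity_hi) * L - 1e-9)
    k_max = math.floor((1.0 - spec.identity_lo) * L + 1e-9)
    if k_min > k_max:
        raise ValueError(
            f"identity range [{spec.identity_lo}, {spec.identity_hi}] is "
            f"unattainable at length {L}"
        )
    members, identities = [], []
    for i in range(spec.n_members):
        k = int(rng.integers(k_min, k_max + 1))
        seq = _mutate_to_identity(ancestor, k, rng)
        members.append((f"{spec.family_id}_ref{i + 1:02d}", seq))
        identities.append(1.0 - k / L)
    fam = ReferenceFamily(family_id=spec.family_id, members=tuple(members))
    return fam, ancestor, identities


def reverse_translate(protein: str, rng) -> str:
    """Uniform synonymous codon choice; never contains an internal stop."""
    return "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    )


def _random_contig(length: int, rng) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _revcomp(s: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return s.translate(comp)[::-1]


def build_metagenome(
    spec: MetagenomeSimSpec,
    ancestors: dict[str, str],
    max_retries: int = 50,
) -> tuple[list[Contig], list[TruthRow]]:
    """Implant homolog CDS and shuffled decoys into random contigs.

    Each insert is a homolog of a family ancestor mutated to the plan's
    target identity, reverse-translated and framed by in-frame stop codons
    so the encoded protein is a clean stop-to-stop ORF.  Decoys are
    shuffled homologs: same residue composition, destroyed order.  Inserts
    land at random positions and strands on contigs round-robin across the
    sample labels; the truth table records forward-strand 0-based half-open
    CDS coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    inserts: list[tuple[str, str, float]] = []  # (label, protein, identity)
    for plan in spec.implants:
        if plan.family_id not in ancestors:
            raise KeyError(f"no ancestor for family {plan.family_id!r}")
        anc = ancestors[plan.family_id]
        k = round((1.0 - plan.identity) * len(anc))
        for _ in range(plan.n_implants):
            prot = _mutate_to_identity(anc, k, rng)
            inserts.append((plan.family_id, prot, 1.0 - k / len(anc)))
    homolog_pool = [p for _, p, _ in inserts]
    for _ in range(spec.n_decoys):
        if homolog_pool:
            src = homolog_pool[rng.integers(len(homolog_pool))]
        else:  # decoys without implants: shuffle a random protein
            src = "".join(AA20[i] for i in rng.integers(0, 20, size=300))
        shuffled = "".join(
            src[i] for i in rng.permutation(len(src))
        )
        ident = sum(a == b for a, b in zip(src, shuffled)) / len(src)
        inserts.append(("decoy", shuffled, ident))

    contigs: list[Contig] = []
    truth: list[TruthRow] = []
    n_carrier = len(inserts)
    for idx, (label, prot, ident) in enumerate(inserts):
        cds = reverse_translate(prot, rng)
        stop = _STOPS[rng.integers(3)]
        cassette = stop + cds + _STOPS[rng.integers(3)]
        for _ in range(max_retries):
            length = int(rng.normal(spec.contig_len_mean, spec.contig_len_sd))
            if length >= len(cassette) + 100:
                break
        else:
            raise RuntimeError("could not draw a contig long enough")
        backbone = _random_contig(length, rng)
        pos = int(rng.integers(0, length - len(cassette) + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        piece = cassette if strand == "+" else _revcomp(cassette)
        seq = backbone[:pos] + piece + backbone[pos + len(cassette):]
        # revcomp maps the cassette onto itself end-for-end, so the CDS sits
        # at [pos+3, pos+3+len(cds)) on the forward strand either way
        cds_fwd_start = pos + 3
        cds_fwd_end = cds_fwd_start + len(cds)
        cid = f"contig_{idx + 1:03d}"
        sample = spec.sample_labels[idx % len(spec.sample_labels)]
        contigs.append(Contig(cid, seq, sample_label=sample))
        truth.append(
            TruthRow(cid, cds_fwd_start, cds_fwd_end, strand, label, ident)
        )
    for b in range(spec.n_background_contigs):
        length = max(200, int(rng.normal(spec.contig_len_mean, spec.contig_len_sd)))
        cid = f"contig_{n_carrier + b + 1:03d}"
        sample = spec.sample_labels[(n_carrier + b) % len(spec.sample_labels)]
        contigs.append(Contig(cid, _random_contig(length, rng), sample_label=sample))
    return contigs, truth


def truth_protein(contig: Contig, row: TruthRow) -> str:
    """Translate a truth interval back to its implanted protein."""
    from Bio.Seq import Seq

    sub = contig.sequence[row.nt_start : row.nt_end]
    if row.strand == "-":
        sub = _revcomp(sub)
    return str(Seq(sub).translate())


def score_screen(passing_hits, proteins, truth) -> dict:
    """Recall/precision of a screen against a synthetic truth table.

    A truth implant is recovered when a passing hit of its family comes
    from a protein overlapping the implant's interval on the same contig.
    A passing (protein, family) pair is a true positive under the same
    overlap test; decoy intervals and background contigs can only produce
    false positives.
    """
    spans = {p.protein_id: (p.contig_id, p.nt_start, p.nt_end) for p in proteins}
    pairs = {
        (h.protein_id, h.family_id) for h in passing_hits if h.passed
    }
    implants = [r for r in truth if r.label != "decoy"]

    def overlaps(pid, row):
        contig, s, e = spans[pid]
        return contig == row.contig_id and s < row.nt_end and row.nt_start < e

    tp_rows = sum(
        1
        for row in implants
        if any(
            fam == row.label and overlaps(pid, row) for pid, fam in pairs
        )
    )
    tp_pairs = sum(
        1
        for pid, fam in pairs
        if any(fam == row.label and overlaps(pid, row) for row in implants)
    )
    recall = tp_rows / len(implants) if implants else float("nan")
    precision = tp_pairs / len(pairs) if pairs else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "n_implants": len(implants),
        "n_passing_pairs": len(pairs),
        "true_positive_pairs": tp_pairs,
    }


def simulate_growth(
    truth: GompertzFit, times, noise_sd: float = 0.01, seed: int = 0, **labels
) -> GrowthCurve:
    """Gompertz model values plus i.i.d. Gaussian noise, floored at 0."""
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    y = gompertz(t, truth.y0, truth.A, truth.mu_m, truth.lam)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    return GrowthCurve(times=t, od580=np.maximum(y, 0.0), **labels)


def simulate_facs(
    p_gfp: float, f: float = 1.0, N: int = 30000, seed: int = 0
) -> FACSSample:
    """Binomial FACS draw: F ~ Binomial(N, p_gfp * f)."""
    if not (0.0 <= p_gfp <= 1.0):
        raise ValueError("p_gfp must be in [0, 1]")
    rng = np.random.default_rng(seed)
    F = int(rng.binomial(N, p_gfp * f))
    return FACSSample(N=N, F=F, f=f)


def simulate_plate(
    concentrations_mM,
    max_growth_conc: float,
    timepoints_h=(24.0, 48.0),
    n_replicates: int = 3,
    blank_od: float = 0.05,
    growth_od: float = 0.5,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Dose-response plate: growth up to max_growth_conc, blank beyond."""
    rng = np.random.default_rng(seed)
    rows = []
    for tp in timepoints_h:
        for c in concentrations_mM:
            grows = 0 < c <= max_growth_conc
            base = blank_od + (growth_od if grows else 0.0)
            for r in range(n_replicates):
                od = max(0.0, base + rng.normal(0.0, noise_sd))
                rows.append(
                    {"conc_mM": float(c), "timepoint_h": float(tp),
                     "replicate": r + 1, "od580": od}
                )
    return pd.DataFrame(rows)


def write_fasta(records, path) -> None:
    """records: iterable of (id, sequence)."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_truth_tsv(truth, path) -> None:
    """Minimal GFF3-like TSV: contig, start, end, strand, label, identity."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tlabel\tidentity\n")
        for r in truth:
            fh.write(
                f"{r.contig_id}\t{r.nt_start}\t{r.nt_end}\t{r.strand}\t"
                f"{r.label}\t{r.identity:.6f}\n"
            )


def read_truth_tsv(path) -> list[TruthRow]:
    df = pd.read_csv(path, sep="\t")
    return [
        TruthRow(r.contig, int(r.start), int(r.end), r.strand, r.label,
                 float(r.identity))
        for r in df.itertuples()
    ]
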