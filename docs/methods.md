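# Methods

This note documents the models and procedures implemented in `phenoscreen`,
the parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Consensus probes

A reference family (curated PH, C12O or C23O homologs; ≥ 2 members) is
aligned and reduced to consensus probes. A column is *callable* when its
most frequent non-gap residue occurs in at least τ of **all** rows — gap
rows count in the denominator, which is the strictest reading of an
"at least half of the aligned proteins" rule: a column that is 50 % gaps
can only be callable if one residue still reaches τ of all members. Modal
ties break alphabetically so output is deterministic. Maximal runs of
callable columns with length ≥ `min_region_len` are emitted, one probe per
run, as the concatenated modal residues.

Parameters: `consensus_threshold` τ ∈ (0, 1], default 0.5 (the standard
rule); `min_region_len`, default 8 aa — short enough to keep genuine
conserved motifs, long enough that a probe is not a single lucky column.
Nothing in the rule forces one probe per family; families with several
conserved regions yield several probes, and each is screened independently.

Alignment: pre-aligned FASTA is the primary input path. The built-in
aligner is centre-star progressive: every member is globally aligned
(BLOSUM62, gap open 11 / extend 1, BLAST convention — a gap of length k
costs 11 + k) against the longest member and merged under
once-a-gap-always-a-gap. Centre-star is not profile-quality alignment; for
production reference sets an external MSA tool's output should be passed
in pre-aligned. Degapping any output row always reproduces the input
member exactly (enforced, and property-tested).

## Homology screen

Candidate proteins are all maximal stop-to-stop ORFs ≥ 60 aa in all six
frames (standard genetic code; coordinates 0-based half-open on the
forward strand). Stop-to-stop calling needs no start-codon model and is
the conservative choice when the assembly's gene-calling provenance is
unknown; true CDS predictions (e.g. Prodigal output) can be supplied as a
protein FASTA instead, bypassing ORF calling.

Each probe × protein pair is aligned with exact Smith–Waterman (BLOSUM62,
affine 11/1 — BLASTP's default scoring, without BLASTP's heuristic
seeding, so scores are exactly reproducible and testable against
enumeration). Identity is identical pairs over all alignment columns
including gap columns; query coverage is aligned probe residues over probe
length. The expectation E = K·m·n·exp(−λS) uses m = probe length and
n = total residues in the searched protein set, with the published gapped
BLOSUM62-11/1 constants λ = 0.267, K = 0.041 (configurable). This is a
desk-checkable surrogate for BLAST's internal calibration; E-values agree
with BLASTP to the order of magnitude, which is sufficient for a 0.1 cut.

Pass thresholds: E < 0.1, identity > 0.40, coverage > 0.50 — all strict,
so boundary values fail. An optional decoy list generalises the removal of
spurious hits that actually belong to an unrelated family (the classic
case: probes for multicomponent phenol hydroxylases attracting
copper-transporting P-type ATPases): any protein scoring higher against a
decoy than against the probe is dropped.

## OPFs

Passing hits are collapsed into operational protein families by greedy
centroid clustering: proteins sorted longest-first (ties by ID), each
joining the first representative it matches at ≥ `cluster_identity`
(default 0.95) global identity, else founding a new OPF. The threshold is
deliberately configurable and surfaced in reports: "protein species" has
no canonical definition, and 1.0 reproduces a unique-sequence collapse
while 0.95 mirrors common dereplication practice. An OPF inherits the
family of its members' best hit. The count table scores an OPF once per
sample in which it has a member, which is the per-sample bar-chart
statistic. Shannon (natural log, as in vegan's `diversity`) and Simpson
(1 − Σp²) indices summarise count vectors.

## Trees

Trees of OPF representatives plus reference members are distance-based
stand-ins for full ML inference: pairwise p-distances over mutually
ungapped columns with Kimura's protein correction
d = −ln(1 − D − 0.2 D²), neighbor joining, midpoint rooting, and
column-bootstrap supports (% of replicates containing each original
bipartition; default 100 replicates at desk scale, 1000 by config). The
correction diverges for D ≳ 0.854; such pairs are set to a ceiling
(default 5.0 substitutions/site) rather than infinity so NJ stays finite.
Negative NJ branch-length estimates are clamped to zero (additive inputs
are unaffected). Rows are put in canonical (sorted-ID) order before
bootstrapping so tie-breaks — hence supports — do not depend on input row
order. Gamma-distributed rate variation has no analogue in this distance
scheme and is not emulated; the downstream use of the trees (structural
clade attribution) does not depend on it.

## Growth kinetics

The modified Gompertz model in the Zwietering (A, μₘ, λ) form:
y(t) = y₀ + A·exp(−exp(μₘ·e/A·(λ−t) + 1)), with y₀ the baseline OD, A the
asymptotic rise, μₘ the slope at the inflection (h⁻¹) and λ the lag time
(h) where the inflection tangent crosses the baseline. Fitting is bounded
trust-region least squares with deterministic multi-start: λ started at
0/25/50 % of the time span, μₘ at the maximum finite-difference slope, A
at the observed OD rise; the lowest-RSS solution wins, and
non-convergence raises an error rather than returning defaults. Because
the literature uses both conventions, a switch fits the same model to
ln(OD/OD₀) instead of OD (default: OD).

## FACS mixture proportions

For a two-strain mixture in which only one strain carries GFP, and only a
fraction f of that strain's cells fluoresce in pure culture (the
calibration ratio), the GFP strain's event count is estimated as F/f from
F fluorescent events among N (default 30 000) — so p̂ = (F/f)/N, clipped
to [0, 1] with a warning when F/f exceeds N by more than 2 % (a
calibration inconsistency). The estimator is unbiased before clipping:
E[F] = N·p·f.

## Photometry

Beer–Lambert conversion c = A/(ε·l) and specific activity
(slope/(ε·l))·V·10⁶/m_protein in µmol·min⁻¹·mg⁻¹. Molar absorptivities
for cis,cis-muconate (260 nm, C12O product) and 2-hydroxymuconic
semialdehyde (375 nm, C23O product) are **always config inputs**, never
package constants: published values vary with pH and buffer, and the
package cannot know the assay conditions. The demo config carries
16 800 and 36 000 M⁻¹cm⁻¹ as illustrative values.

Dose–response plates reduce to growth/no-growth: a (concentration,
timepoint) cell grows iff its mean OD exceeds the same timepoint's 0 mM
blank by more than `growth_delta` (0.05 OD, strict). The summary reports
the highest concentration with growth per timepoint; non-monotone patterns
are reported as-is rather than smoothed, since a gap in the series is
information about the assay, not noise to clean.

## Synthetic data

The generators are first-class, tested code, and every one is a pure
function of (spec, seed). Reference families evolve from a random ancestor
by i.i.d. substitution, uniform over the 19 alternative residues; the
substitution count is drawn so the realized identity lands exactly in the
target range. Uniform substitution is deliberate: identity — the variable
the screen's thresholds act on — is controlled exactly, at the cost of
mutational realism (no BLOSUM-weighted exchanges, no indels, no rate
heterogeneity). Homolog CDS are reverse-translated with uniform synonymous
codon choice (hence no internal stops by construction), framed by in-frame
stop codons so each implant is a clean stop-to-stop ORF, and implanted at
random positions and strands into uniform-composition contigs
(length ~ N(6000, 1000²) nt). Decoys are residue-shuffles of implanted
homologs — same composition, destroyed order — to probe composition-driven
false positives. The truth table (GFF-like TSV: contig, start, end,
strand, label, identity) round-trips: translating each interval reproduces
the implanted protein exactly.

What passing benchmarks show — and what they do not: recovery of implants
at 80 % identity with shuffled decoys demonstrates the screen's threshold
logic and the aligner's correctness, not performance on real metagenomes,
where fragmented ORFs, compositional bias, paralogs and genuinely
borderline homologs make both recall and precision worse than on this
benchmark. The demo's problem sizes (2 families × 10 members, 3 implants
each, 5 decoys, ~14 contigs of ~6 kb; Gompertz study: 50 curves × 30
points; FACS: 1000 draws of 30 000 events) were chosen as the smallest
sizes at which every failure mode the tests probe can actually occur.

## Pipeline

Configuration is a single YAML file mirroring the dataclass fields;
defaults reproduce the standard settings (τ = 0.5, E < 0.1, id > 40 %,
cov > 50 %, 95 % OPF clustering, N = 30 000). Unknown keys and
out-of-range values fail at parse time. Runs write a manifest (config
hash, seed, package version, stage list) and no timestamps, so identical
config + seed gives byte-identical outputs; the CLI exits 0 on success, 2
on validation errors and 1 on runtime failures.

## Known limitations

- Centre-star alignment degrades for deeply diverged families; pass
  pre-aligned input there.
- Exact Smith–Waterman over all probe × ORF pairs is O(m·n) per pair and
  meant for contig-scale screens, not raw-read searches.
- The Karlin–Altschul constants are treated as scale-free; no
  composition-based statistics or length-dependent edge corrections.
- NJ + Kimura distances approximate, but are not, ML trees; bootstrap
  supports are supports of the distance method.
- The FACS model ignores doublets, autofluorescence and gating error; f
  absorbs them only to the extent they are strain-stable.
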