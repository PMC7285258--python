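"""End-to-end orchestration: config, mining stage chain, kinetics stage
chain, demo-dataset generation and run manifests.

Outputs are deterministic for a fixed config and seed: no timestamps are
written, stage order is fixed, and every TSV begins with a one-line schema
header (its column row).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from phenoscreen import __version__
from phenoscreen.families import (
    MultipleAlignment,
    ProbeConfig,
    align_family,
    call_consensus_columns,
    extract_probes,
    probe_manifest,
    read_alignment,
    read_family,
    write_probes_fasta,
)
from phenoscreen.kinetics import (
    EnzymeAssay,
    FACSSample,
    GompertzFitError,
    GrowthCurve,
    dose_response_summary,
    fit_gompertz,
    mixture_proportions,
    specific_activity,
)
from phenoscreen.opf import count_opfs, dereplicate, diversity_index, opf_table
from phenoscreen.phylo import bootstrap_support, write_newick
from phenoscreen.screen import (
    FilterThresholds,
    KarlinAltschulParams,
    hits_table,
    read_contigs,
    screen,
    six_frame_orfs,
)
from phenoscreen.simulate import write_fasta

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults reproduce the screen's standard
    settings (consensus threshold 0.5, E<0.1, identity>40%, coverage>50%,
    FACS N=30000; bootstrap 1000 reachable by config)."""

    families: dict[str, str] = field(default_factory=dict)  # family -> FASTA
    contigs: dict[str, str] = field(default_factory=dict)   # sample -> FASTA
    proteins: dict[str, str] = field(default_factory=dict)  # sample -> FASTA
    outdir: str = "phenoscreen_out"
    families_prealigned: bool = False
    consensus_threshold: float = 0.5
    min_region_len: int = 8
    E_max: float = 0.1
    id_min: float = 0.40
    cov_min: float = 0.50
    ka_lambda: float = 0.267
    ka_K: float = 0.041
    cluster_identity: float = 0.95
    bootstrap_reps: int = 100
    min_orf_aa: int = 60
    seed: int = 0
    epsilon: dict[str, float] = field(default_factory=dict)  # enzyme -> M-1 cm-1
    gompertz_on_log: bool = False
    growth_delta: float = 0.05
    growth_csv: str = ""
    facs_csv: str = ""
    activity_csv: str = ""
    plate_csv: str = ""

    def __post_init__(self):
        # construct the typed sub-configs eagerly so bad values fail at parse
        self.probe_config = ProbeConfig(self.consensus_threshold, self.min_region_len)
        self.thresholds = FilterThresholds(self.E_max, self.id_min, self.cov_min)
        self.ka_params = KarlinAltschulParams(self.ka_lambda, self.ka_K)
        if not (0.0 < self.cluster_identity <= 1.0):
            raise ValueError("cluster_identity must be in (0, 1]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _write_manifest(outdir: Path, config: PipelineConfig, stages: list[str]) -> None:
    manifest = {
        "phenoscreen_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
        "config": asdict(config),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def run_mining(config: PipelineConfig, stop_after: str = "tree") -> dict[str, Path]:
    """Probe building -> ORF calling -> screen -> OPFs -> counts -> trees.

    `stop_after` truncates the chain ('probes', 'screen', 'opf' or 'tree').
    """
    if stop_after not in ("probes", "screen", "opf", "tree"):
        raise ValueError(f"unknown stage {stop_after!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.families:
        raise PipelineError("probe stage: no reference families configured")
    if not config.contigs and not config.proteins:
        raise PipelineError("screen stage: neither contigs nor proteins configured")

    # --- probes
    probes = []
    alignments: dict[str, MultipleAlignment] = {}
    for fam_id, path in sorted(config.families.items()):
        try:
            if config.families_prealigned:
                aln = read_alignment(path, family_id=fam_id)
            else:
                aln = align_family(read_family(path, family_id=fam_id))
        except ValueError as e:
            raise PipelineError(f"probe stage: family {fam_id!r}: {e}") from e
        alignments[fam_id] = aln
        calls = call_consensus_columns(aln, config.probe_config)
        probes.extend(extract_probes(aln, calls, config.probe_config))
    if not probes:
        raise PipelineError("probe stage: no probes extracted from any family")
    write_probes_fasta(probes, outdir / "probes.fasta")
    _write_tsv(pd.DataFrame(probe_manifest(probes)), outdir / "probes.tsv")
    if stop_after == "probes":
        _write_manifest(outdir, config, ["probes"])
        return {"probes": outdir / "probes.fasta"}

    # --- proteins
    proteins = []
    if config.proteins:
        from Bio import SeqIO

        for sample, path in sorted(config.proteins.items()):
            from phenoscreen.screen import PredictedProtein

            for rec in SeqIO.parse(str(path), "fasta"):
                proteins.append(
                    PredictedProtein(
                        protein_id=rec.id, contig_id=rec.id, frame=1,
                        nt_start=0, nt_end=3 * len(rec.seq),
                        sequence=str(rec.seq).upper(), sample_label=sample,
                    )
                )
    else:
        for sample, path in sorted(config.contigs.items()):
            try:
                contigs = read_contigs(path, sample_label=sample)
            except ValueError as e:
                raise PipelineError(f"screen stage: sample {sample!r}: {e}") from e
            for contig in contigs:
                proteins.extend(six_frame_orfs(contig, min_aa=config.min_orf_aa))
    if not proteins:
        raise PipelineError("screen stage: no candidate proteins predicted")
    write_fasta(
        ((p.protein_id, p.sequence) for p in proteins),
        outdir / "proteins.fasta",
    )

    # --- screen
    hits = screen(probes, proteins, config.thresholds, config.ka_params)
    _write_tsv(pd.DataFrame(hits_table(hits)), outdir / "hits.tsv")
    if stop_after == "screen":
        _write_manifest(outdir, config, ["probes", "screen"])
        return {"probes": outdir / "probes.fasta", "hits": outdir / "hits.tsv"}

    # --- OPFs
    seqs = {p.protein_id: p.sequence for p in proteins}
    opfs = dereplicate(
        [h for h in hits if h.passed], seqs, config.cluster_identity
    )
    _write_tsv(pd.DataFrame(opf_table(opfs)), outdir / "opfs.tsv")
    write_fasta(
        ((o.opf_id, seqs[o.representative_protein_id]) for o in opfs),
        outdir / "opf_representatives.fasta",
    )
    counts = count_opfs(
        opfs,
        families=config.families.keys(),
        samples=config.contigs.keys() or config.proteins.keys(),
    )
    counts.reset_index().to_csv(outdir / "opf_counts.tsv", sep="\t", index=False)
    div_rows = []
    for sample in counts.columns:
        vec = counts[sample].to_numpy()
        if vec.sum() > 0:
            div_rows.append(
                {"sample": sample,
                 "shannon": diversity_index(vec, "shannon"),
                 "simpson": diversity_index(vec, "simpson")}
            )
    _write_tsv(
        pd.DataFrame(div_rows, columns=["sample", "shannon", "simpson"]),
        outdir / "opf_diversity.tsv",
    )
    if stop_after == "opf":
        _write_manifest(outdir, config, ["probes", "screen", "opf"])
        return {
            "probes": outdir / "probes.fasta",
            "hits": outdir / "hits.tsv",
            "opfs": outdir / "opfs.tsv",
            "opf_counts": outdir / "opf_counts.tsv",
        }

    # --- trees: per family, OPF representatives + reference members
    treedir = outdir / "trees"
    treedir.mkdir(exist_ok=True)
    support_rows = []
    for fam_id, aln in sorted(alignments.items()):
        fam_reps = [
            (o.opf_id, seqs[o.representative_protein_id])
            for o in opfs
            if o.family_id == fam_id
        ]
        leaves = list(aln.degapped()) + fam_reps
        if len(leaves) < 3:
            continue
        from phenoscreen.families import ReferenceFamily

        fam = ReferenceFamily(family_id=fam_id, members=tuple(leaves))
        joint = align_family(fam)
        tree, support = bootstrap_support(
            joint, n_reps=config.bootstrap_reps, seed=config.seed
        )
        write_newick(tree, treedir / f"{fam_id}.nwk")
        for bp, s in sorted(support.items(), key=lambda kv: sorted(kv[0])):
            support_rows.append(
                {"family": fam_id, "bipartition": ",".join(sorted(bp)),
                 "support_pct": s}
            )
    _write_tsv(
        pd.DataFrame(support_rows, columns=["family", "bipartition", "support_pct"]),
        outdir / "tree_supports.tsv",
    )

    _write_manifest(outdir, config, ["probes", "screen", "opf", "tree"])
    return {
        "probes": outdir / "probes.fasta",
        "hits": outdir / "hits.tsv",
        "opfs": outdir / "opfs.tsv",
        "opf_counts": outdir / "opf_counts.tsv",
        "trees": treedir,
        "manifest": outdir / "manifest.json",
    }


def run_kinetics(config: PipelineConfig) -> dict[str, Path]:
    """Growth fits, FACS proportions, enzyme activities, dose-response."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if config.growth_csv:
        df = pd.read_csv(config.growth_csv)
        rows = []
        for (strain, temp, phenol), grp in df.groupby(
            ["strain", "temp_C", "phenol_mM"], dropna=False
        ):
            grp = grp.sort_values("time_h")
            curve = GrowthCurve(
                times=grp["time_h"].to_numpy(),
                od580=grp["od580"].to_numpy(),
                strain=str(strain), temperature_C=temp, phenol_mM=phenol,
            )
            try:
                fit = fit_gompertz(curve, on_log=config.gompertz_on_log)
            except (ValueError, GompertzFitError) as e:
                raise PipelineError(
                    f"kinetics stage: curve ({strain}, {temp} C, "
                    f"{phenol} mM): {e}"
                ) from e
            rows.append(
                {"strain": strain, "temp_C": temp, "phenol_mM": phenol,
                 "y0": fit.y0, "A": fit.A, "mu_m": fit.mu_m,
                 "lambda_h": fit.lam, "rss": fit.rss}
            )
        path = outdir / "gompertz_fits.tsv"
        _write_tsv(pd.DataFrame(rows), path)
        written["fits"] = path

    if config.facs_csv:
        df = pd.read_csv(config.facs_csv)
        rows = []
        for i, r in df.iterrows():
            try:
                sample = FACSSample(N=int(r["N"]), F=int(r["F"]), f=float(r["f"]))
            except ValueError as e:
                raise PipelineError(
                    f"kinetics stage: FACS row {i} rejected: {e}"
                ) from e
            p_gfp, p_other = mixture_proportions(sample)
            rows.append(
                {"row": i, "N": sample.N, "F": sample.F, "f": sample.f,
                 "p_gfp_strain": p_gfp, "p_other": p_other}
            )
        path = outdir / "facs_proportions.tsv"
        _write_tsv(pd.DataFrame(rows), path)
        written["proportions"] = path

    if config.activity_csv:
        df = pd.read_csv(config.activity_csv)
        rows = []
        for i, r in df.iterrows():
            enzyme = str(r.get("enzyme", ""))
            eps = float(r["epsilon"]) if "epsilon" in df.columns else \
                config.epsilon.get(enzyme, 0.0)
            if eps <= 0:
                raise PipelineError(
                    f"kinetics stage: no molar absorptivity for enzyme "
                    f"{enzyme!r} (row {i}); add it to the config epsilon table"
                )
            assay = EnzymeAssay(
                slope=float(r["slope"]), epsilon=eps,
                path_cm=float(r.get("path_cm", 1.0)),
                volume_L=float(r.get("volume_L", 0.001)),
                protein_mg=float(r["protein_mg"]),
            )
            rows.append(
                {"enzyme": enzyme, "slope": assay.slope, "epsilon": eps,
                 "specific_activity_umol_min_mg": specific_activity(assay)}
            )
        path = outdir / "enzyme_activities.tsv"
        _write_tsv(pd.DataFrame(rows), path)
        written["activities"] = path

    if config.plate_csv:
        df = pd.read_csv(config.plate_csv)
        try:
            cells, summary = dose_response_summary(df, config.growth_delta)
        except ValueError as e:
            raise PipelineError(
                f"kinetics stage: plate {config.plate_csv!r}: {e}"
            ) from e
        path = outdir / "dose_response.tsv"
        _write_tsv(cells, path)
        srows = [
            {"timepoint_h": tp,
             "max_conc_with_growth_mM": "" if c is None else c}
            for tp, c in sorted(summary.items())
        ]
        _write_tsv(pd.DataFrame(srows), outdir / "dose_response_summary.tsv")
        written["dose_response"] = path

    _write_manifest(outdir, config, ["kinetics"])
    return written
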