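"""Seeded end-to-end demo fixture: a complete miniature input set.

Writes reference families, a synthetic metagenome with implanted homolog
CDS and shuffled decoys plus its truth table, and the culture-side CSVs
(growth curves, FACS draws, enzyme assays, a dose-response plate), together
with a ready-to-run pipeline config.  Everything is a pure function of the
seed.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from phenoscreen.kinetics import GompertzFit, gompertz
from phenoscreen.pipeline import PipelineConfig
from phenoscreen.simulate import (
    FamilySimSpec,
    ImplantPlan,
    MetagenomeSimSpec,
    build_metagenome,
    evolve_family,
    simulate_facs,
    simulate_growth,
    simulate_plate,
    write_fasta,
    write_truth_tsv,
)

#: ground-truth growth parameters of the two demo strains
DEMO_GROWTH_TRUTH = {
    "ICP1": GompertzFit(y0=0.05, A=0.6, mu_m=0.3, lam=2.0, rss=0.0),
    "ICTN13": GompertzFit(y0=0.05, A=0.5, mu_m=0.25, lam=3.0, rss=0.0),
}

#: demo molar absorptivities (M^-1 cm^-1) for the ring-cleavage products;
#: user-supplied config values, not package constants
DEMO_EPSILON = {"C12O": 16800.0, "C23O": 36000.0}


def make_demo_dataset(
    outdir,
    seed: int = 0,
    n_families: int = 2,
    implants_per_family: int = 3,
    implant_identity: float = 0.8,
    n_decoys: int = 5,
    family_members: int = 10,
) -> tuple[PipelineConfig, dict]:
    """Generate the demo fixture under `outdir`; returns (config, truth).

    truth holds the implant table, the per-family ancestors, the growth
    parameters, the FACS ground truth and the plate's growth ceiling.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    family_ids = ["PH", "C23O", "C12O"][:n_families]

    families = {}
    ancestors = {}
    for i, fam_id in enumerate(family_ids):
        fam, anc, _ = evolve_family(
            FamilySimSpec(
                family_id=fam_id,
                ancestor_len=300,
                n_members=family_members,
                identity_lo=0.75,
                identity_hi=0.95,
                seed=seed * 1009 + i,
            )
        )
        path = outdir / f"family_{fam_id}.fasta"
        write_fasta(fam.members, path)
        families[fam_id] = str(path)
        ancestors[fam_id] = anc

    spec = MetagenomeSimSpec(
        implants=tuple(
            ImplantPlan(fam_id, implants_per_family, implant_identity)
            for fam_id in family_ids
        ),
        n_decoys=n_decoys,
        n_background_contigs=3,
        seed=seed * 1013 + 7,
    )
    contigs, truth_rows = build_metagenome(spec, ancestors)
    by_sample: dict[str, list] = {}
    for c in contigs:
        by_sample.setdefault(c.sample_label, []).append(c)
    contig_paths = {}
    for sample, cs in sorted(by_sample.items()):
        path = outdir / f"contigs_{sample}.fasta"
        write_fasta(((c.contig_id, c.sequence) for c in cs), path)
        contig_paths[sample] = str(path)
    write_truth_tsv(truth_rows, outdir / "truth.tsv")

    # growth curves: 30 points over 24 h, Gaussian OD noise sd 0.01
    times = np.linspace(0.0, 24.0, 30)
    growth_rows = []
    for i, (strain, p) in enumerate(sorted(DEMO_GROWTH_TRUTH.items())):
        curve = simulate_growth(p, times, noise_sd=0.01, seed=seed * 1019 + i)
        for t, od in zip(curve.times, curve.od580):
            growth_rows.append(
                {"time_h": t, "od580": od, "strain": strain,
                 "temp_C": 30.0, "phenol_mM": 1.3}
            )
    pd.DataFrame(growth_rows).to_csv(outdir / "growth.csv", index=False)

    # FACS: mixed culture at a known GFP-strain share, calibration f=0.8
    facs_truth = {"p_gfp": 0.3, "f": 0.8, "N": 30000}
    facs_rows = []
    for i in range(9):
        s = simulate_facs(
            facs_truth["p_gfp"], facs_truth["f"], facs_truth["N"],
            seed=seed * 1021 + i,
        )
        facs_rows.append({"N": s.N, "F": s.F, "f": s.f})
    pd.DataFrame(facs_rows).to_csv(outdir / "facs.csv", index=False)

    # enzyme assays: rates chosen to give activities of order 0.1 U/mg
    pd.DataFrame(
        [
            {"enzyme": "C12O", "slope": 0.168, "protein_mg": 0.1},
            {"enzyme": "C23O", "slope": 0.360, "protein_mg": 0.1},
        ]
    ).to_csv(outdir / "activity.csv", index=False)

    # dose-response plate: growth up to 5 mM phenol, none above
    plate = simulate_plate(
        concentrations_mM=(0.0, 0.5, 1.0, 2.0, 5.0, 7.5, 10.0),
        max_growth_conc=5.0,
        seed=seed * 1031 + 3,
    )
    plate.to_csv(outdir / "plate.csv", index=False)

    config = PipelineConfig(
        families=families,
        contigs=contig_paths,
        outdir=str(outdir / "out"),
        seed=seed,
        epsilon=dict(DEMO_EPSILON),
        growth_csv=str(outdir / "growth.csv"),
        facs_csv=str(outdir / "facs.csv"),
        activity_csv=str(outdir / "activity.csv"),
        plate_csv=str(outdir / "plate.csv"),
    )
    cfg_dict = asdict(config)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    truth = {
        "implants": truth_rows,
        "ancestors": ancestors,
        "growth": DEMO_GROWTH_TRUTH,
        "facs": facs_truth,
        "max_growth_conc": 5.0,
    }
    return config, truth
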