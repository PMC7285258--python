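"""Operational protein families: dereplication, per-sample counting,
alpha diversity.

Passing hits are collapsed into OPFs ("protein species") by greedy centroid
clustering: sequences sorted longest-first each join the first existing
representative they match at >= the clustering identity (global alignment,
matches over all columns), otherwise they found a new OPF.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy

from phenoscreen._pairwise import global_identity


@dataclass
class OPF:
    opf_id: str
    family_id: str
    representative_protein_id: str
    member_protein_ids: list[str]
    sample_counts: Counter  # sample label -> number of member proteins

    @property
    def samples(self) -> list[str]:
        return sorted(self.sample_counts)


def dereplicate(
    passing_hits,
    protein_sequences: dict[str, str],
    cluster_identity: float = 0.95,
) -> list[OPF]:
    """Collapse passing hits into OPFs by greedy centroid clustering.

    Each protein inherits the family of its best (lowest-E) passing hit.
    Ties in the longest-first ordering break on protein ID so the result is
    deterministic.
    """
    if not (0.0 < cluster_identity <= 1.0):
        raise ValueError("cluster_identity must be in (0, 1]")
    best_hit: dict[str, object] = {}
    sample_of: dict[str, str] = {}
    for h in passing_hits:
        if not h.passed:
            continue
        if h.protein_id not in protein_sequences:
            raise KeyError(
                f"hit references unknown protein {h.protein_id!r}"
            )
        prev = best_hit.get(h.protein_id)
        if prev is None or h.result.evalue < prev.result.evalue:
            best_hit[h.protein_id] = h
        sample_of[h.protein_id] = h.sample_label
    order = sorted(
        best_hit, key=lambda pid: (-len(protein_sequences[pid]), pid)
    )
    opfs: list[OPF] = []
    for pid in order:
        seq = protein_sequences[pid]
        placed = False
        for opf in opfs:
            rep_seq = protein_sequences[opf.representative_protein_id]
            if global_identity(seq, rep_seq) >= cluster_identity:
                opf.member_protein_ids.append(pid)
                opf.sample_counts[sample_of[pid]] += 1
                placed = True
                break
        if not placed:
            fam = best_hit[pid].family_id
            opfs.append(
                OPF(
                    opf_id=f"OPF_{len(opfs) + 1:04d}",
                    family_id=fam,
                    representative_protein_id=pid,
                    member_protein_ids=[pid],
                    sample_counts=Counter({sample_of[pid]: 1}),
                )
            )
    return opfs


def count_opfs(opfs, families=None, samples=None) -> pd.DataFrame:
    """Families x samples table of distinct-OPF counts.

    A cell counts OPFs with at least one member from that sample, so an OPF
    spanning several samples contributes once per sample.  Row and column
    order are the sorted union of observed (or supplied) labels.
    """
    fams = sorted(set(families or []) | {o.family_id for o in opfs})
    samps = sorted(set(samples or []) | {s for o in opfs for s in o.samples})
    table = pd.DataFrame(0, index=fams, columns=samps, dtype=int)
    for o in opfs:
        for s in o.samples:
            table.loc[o.family_id, s] += 1
    table.index.name = "family_id"
    return table


def diversity_index(counts, index: str = "shannon") -> float:
    """Shannon H' = -sum p_i ln p_i or Simpson 1 - sum p_i^2 of a count
    vector (the alpha-diversity indices of vegan's `diversity`)."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector has no diversity")
    p = c / total
    if index == "shannon":
        return float(entropy(p))
    if index == "simpson":
        return float(1.0 - np.sum(p ** 2))
    raise ValueError(f"unknown index {index!r}; use 'shannon' or 'simpson'")


def opf_table(opfs) -> list[dict]:
    """Rows for the OPF TSV."""
    return [
        {
            "opf_id": o.opf_id,
            "family": o.family_id,
            "representative": o.representative_protein_id,
            "n_members": len(o.member_protein_ids),
            "samples": ",".join(o.samples),
        }
        for o in opfs
    ]
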