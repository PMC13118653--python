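"""Occupancy-specificity (SPEC-OCCU) analysis, core OTU sets, and Venn arithmetic.

Specificity of an OTU for a group is its share of group-mean relative
abundances across groups (so specificities sum to 1 over groups);
occupancy is the fraction of the group's samples in which the OTU is
detected. Taxa with both at or above 0.7 are specialists. Core sets are
defined by within-group occupancy alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rivasm.tables import CommunityTable, tss_normalize, RANKS

__all__ = [
    "spec_occ",
    "classify_specialists",
    "core_sets",
    "detected_sets",
    "overlap_report",
    "phylum_composition",
    "CoreSet",
]


def _group_map(sample_ids, groups) -> pd.Series:
    g = pd.Series(list(groups), index=[str(s) for s in sample_ids]).astype(str)
    if g.nunique() < 2:
        raise ValueError("need at least two groups")
    return g


def spec_occ(table: CommunityTable, groups, spec_stat: str = "mean") -> pd.DataFrame:
    """Per OTU x group specificity, occupancy and mean relative abundance.

    ``spec_stat`` selects whether specificity shares are built from
    group-mean ("mean") or group-summed ("sum") relative abundances.
    """
    g = _group_map(table.sample_ids, groups)
    rel = tss_normalize(table)
    rows = []
    agg = rel.T.groupby(g).mean().T if spec_stat == "mean" else rel.T.groupby(g).sum().T
    totals = agg.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"OTU(s) absent everywhere: {bad[:5]}")
    spec = agg.div(totals, axis=0)
    presence = pd.DataFrame(
        table.counts > 0, index=table.otu_ids, columns=table.sample_ids
    )
    occ = presence.T.groupby(g).mean().T
    for grp in agg.columns:
        for otu in agg.index:
            rows.append(
                {
                    "otu_id": otu,
                    "group": grp,
                    "spec": float(spec.loc[otu, grp]),
                    "occ": float(occ.loc[otu, grp]),
                    "mean_rel_abund": float(agg.loc[otu, grp]),
                }
            )
    return pd.DataFrame(rows)


def classify_specialists(
    records: pd.DataFrame, spec_min: float = 0.7, occ_min: float = 0.7
) -> pd.DataFrame:
    """Flag specialists: spec >= spec_min and occ >= occ_min (inclusive)."""
    out = records.copy()
    out["is_specialist"] = (out["spec"] >= spec_min) & (out["occ"] >= occ_min)
    return out


@dataclass
class CoreSet:
    group: str
    occ_min: float
    members: set


def core_sets(table: CommunityTable, groups, occ_min: float = 0.7) -> dict:
    """Within-group core OTUs by occupancy threshold (inclusive)."""
    g = _group_map(table.sample_ids, groups)
    presence = pd.DataFrame(
        table.counts > 0, index=table.otu_ids, columns=table.sample_ids
    )
    occ = presence.T.groupby(g).mean().T
    out = {}
    for grp in occ.columns:
        n_samples = int((g == grp).sum())
        if n_samples < 2:
            raise ValueError(f"group {grp!r} has fewer than two samples")
        members = set(occ.index[occ[grp] >= occ_min])
        out[str(grp)] = CoreSet(group=str(grp), occ_min=occ_min, members=members)
    return out


def detected_sets(table: CommunityTable, groups) -> dict:
    """OTUs detected (count > 0 in >= 1 sample) per group."""
    g = _group_map(table.sample_ids, groups)
    presence = pd.DataFrame(
        table.counts > 0, index=table.otu_ids, columns=table.sample_ids
    )
    det = presence.T.groupby(g).any().T
    return {str(grp): set(det.index[det[grp]]) for grp in det.columns}


def overlap_report(set_a: set, set_b: set, name_a: str = "A", name_b: str = "B") -> dict:
    """Two-set Venn summary with the union identity asserted."""
    shared = set_a & set_b
    only_a = set_a - set_b
    only_b = set_b - set_a
    union = set_a | set_b
    assert len(union) == len(set_a) + len(set_b) - len(shared)
    return {
        f"n_{name_a}": len(set_a),
        f"n_{name_b}": len(set_b),
        "n_shared": len(shared),
        f"n_{name_a}_specific": len(only_a),
        f"n_{name_b}_specific": len(only_b),
        "n_union": len(union),
        f"shared_frac_of_{name_a}": len(shared) / len(set_a) if set_a else np.nan,
        f"shared_frac_of_{name_b}": len(shared) / len(set_b) if set_b else np.nan,
    }


def phylum_composition(otu_set, taxonomy: pd.DataFrame, rank: str = "phylum") -> pd.DataFrame:
    """Share of a rank's taxa within an OTU set; missing lineages count as
    'unclassified'. Shares sum to 1."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    otus = sorted(str(o) for o in otu_set)
    if not otus:
        raise ValueError("empty OTU set")
    labels = [
        str(taxonomy.loc[o, rank]) if o in taxonomy.index else "unclassified"
        for o in otus
    ]
    counts = pd.Series(labels).value_counts()
    return pd.DataFrame(
        {"count": counts, "share": counts / counts.sum()}
    ).rename_axis(rank)
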