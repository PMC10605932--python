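"""Hub identification from group-mean nodal betweenness AUC values.

A region is a hub for a group when its group-mean betweenness-centrality AUC
is at least one standard deviation above the mean across the 90 regions
(sample SD, n-1 denominator). The criterion is scale- and shift-invariant; a
degenerate all-equal vector (SD = 0) yields an empty hub set, since no region
is then exceptional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HubSet", "identify_hubs", "compare_hub_sets", "hub_report"]


@dataclass(frozen=True)
class HubSet:
    group: str
    hubs: frozenset  # region abbreviations
    values: np.ndarray  # group-mean BC AUC per region
    mean: float
    sd: float

    @property
    def threshold(self) -> float:
        return self.mean + self.sd


def identify_hubs(group_mean_bc_auc, region_labels=None,
                  group: str = "") -> HubSet:
    """Regions whose group-mean BC AUC >= mean + 1 SD across regions."""
    values = np.asarray(group_mean_bc_auc, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("BC AUC values must be finite")
    if region_labels is None:
        from .regions import aal90_table

        if values.size == 90:
            region_labels = list(aal90_table()["abbreviation"])
        else:
            region_labels = [f"R{i}" for i in range(1, values.size + 1)]
    if len(region_labels) != values.size:
        raise ValueError("one label per region required")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if sd == 0.0:
        hubs = frozenset()
    else:
        hubs = frozenset(np.asarray(region_labels)[values >= mean + sd])
    return HubSet(group=group, hubs=hubs, values=values, mean=mean, sd=sd)


def compare_hub_sets(hubsets: dict) -> dict:
    """Common hubs (intersection) and per-group unique hubs across groups."""
    if len(hubsets) < 2:
        raise ValueError("need at least two groups to compare hub sets")
    sets = {g: set(h.hubs if isinstance(h, HubSet) else h)
            for g, h in hubsets.items()}
    common = set.intersection(*sets.values())
    unique = {}
    for g, s in sets.items():
        others = set.union(*(o for og, o in sets.items() if og != g))
        unique[g] = s - others
    return {"common": common, "unique": unique}


def hub_report(bc_auc_by_group: dict, region_labels=None) -> pd.DataFrame:
    """Per-group hub table: region, mean +/- SD of BC AUC across subjects.

    ``bc_auc_by_group`` maps group -> (n_subjects, n_regions) array. The hub
    criterion is applied to the group-mean vector; the across-subject SD is
    reported alongside for context.
    """
    frames = []
    for group, mat in bc_auc_by_group.items():
        mat = np.asarray(mat, dtype=float)
        hs = identify_hubs(mat.mean(axis=0), region_labels, group=group)
        labels = (region_labels if region_labels is not None
                  else ([f"R{i}" for i in range(1, mat.shape[1] + 1)]
                        if mat.shape[1] != 90 else None))
        if labels is None:
            from .regions import aal90_table

            labels = list(aal90_table()["abbreviation"])
        df = pd.DataFrame({
            "group": group,
            "region": labels,
            "bc_auc_mean": mat.mean(axis=0),
            "bc_auc_sd": mat.std(axis=0, ddof=1),
            "is_hub": [lab in hs.hubs for lab in labels],
        })
        frames.append(df[df["is_hub"]].sort_values("bc_auc_mean",
                                                   ascending=False))
    return pd.concat(frames, ignore_index=True)
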