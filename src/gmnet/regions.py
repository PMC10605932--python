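"""The 90-region cortical/subcortical parcellation used as network nodes.

Nodes follow the automated anatomical labeling (AAL) scheme restricted to the
90 cerebral regions (cerebellum excluded). Odd indices are left-hemisphere,
even indices the right homologue, so homologues sit at consecutive indices.
Each region carries a functional-module label used to annotate nodal results
(default mode network, attention, sensory/motor, subcortical, vision, other).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["aal90_table", "region_index", "MODULES"]

MODULES = ("DMN", "attention", "sensory/motor", "subcortical", "vision", "other")

# (abbreviation stem, full name, functional module) — one entry per homologue
# pair, in AAL index order. Abbreviations get ".L"/".R" suffixes.
_PAIRS = [
    ("PreCG", "Precentral gyrus", "sensory/motor"),
    ("SFGdor", "Superior frontal gyrus, dorsolateral", "DMN"),
    ("ORBsup", "Superior frontal gyrus, orbital part", "other"),
    ("MFG", "Middle frontal gyrus", "attention"),
    ("ORBmid", "Middle frontal gyrus, orbital part", "other"),
    ("IFGoperc", "Inferior frontal gyrus, opercular part", "attention"),
    ("IFGtriang", "Inferior frontal gyrus, triangular part", "attention"),
    ("ORBinf", "Inferior frontal gyrus, orbital part", "other"),
    ("ROL", "Rolandic operculum", "sensory/motor"),
    ("SMA", "Supplementary motor area", "sensory/motor"),
    ("OLF", "Olfactory cortex", "other"),
    ("SFGmed", "Superior frontal gyrus, medial", "DMN"),
    ("ORBsupmed", "Superior frontal gyrus, medial orbital", "DMN"),
    ("REC", "Gyrus rectus", "other"),
    ("INS", "Insula", "sensory/motor"),
    ("ACG", "Anterior cingulate and paracingulate gyri", "DMN"),
    ("DCG", "Median cingulate and paracingulate gyri", "other"),
    ("PCG", "Posterior cingulate gyrus", "DMN"),
    ("HIP", "Hippocampus", "other"),
    ("PHG", "Parahippocampal gyrus", "other"),
    ("AMYG", "Amygdala", "subcortical"),
    ("CAL", "Calcarine fissure and surrounding cortex", "vision"),
    ("CUN", "Cuneus", "vision"),
    ("LING", "Lingual gyrus", "vision"),
    ("SOG", "Superior occipital gyrus", "vision"),
    ("MOG", "Middle occipital gyrus", "vision"),
    ("IOG", "Inferior occipital gyrus", "vision"),
    ("FFG", "Fusiform gyrus", "vision"),
    ("PoCG", "Postcentral gyrus", "sensory/motor"),
    ("SPG", "Superior parietal gyrus", "sensory/motor"),
    ("IPL", "Inferior parietal lobule", "attention"),
    ("SMG", "Supramarginal gyrus", "attention"),
    ("ANG", "Angular gyrus", "DMN"),
    ("PCUN", "Precuneus", "DMN"),
    ("PCL", "Paracentral lobule", "sensory/motor"),
    ("CAU", "Caudate nucleus", "subcortical"),
    ("PUT", "Lenticular nucleus, putamen", "subcortical"),
    ("PAL", "Lenticular nucleus, pallidum", "subcortical"),
    ("THA", "Thalamus", "subcortical"),
    ("HES", "Heschl gyrus", "sensory/motor"),
    ("STG", "Superior temporal gyrus", "sensory/motor"),
    ("TPOsup", "Temporal pole: superior temporal gyrus", "other"),
    ("MTG", "Middle temporal gyrus", "DMN"),
    ("TPOmid", "Temporal pole: middle temporal gyrus", "other"),
    ("ITG", "Inferior temporal gyrus", "attention"),
]

N_REGIONS = 90


def aal90_table() -> pd.DataFrame:
    """Return the region table, indexed 1..90.

    Columns: ``abbreviation`` (e.g. ``"ACG.L"``), ``full_name``,
    ``functional_module``, ``hemisphere`` (``"L"``/``"R"``).
    """
    rows = []
    for p, (abbr, name, module) in enumerate(_PAIRS):
        for side in ("L", "R"):
            rows.append(
                {
                    "abbreviation": f"{abbr}.{side}",
                    "full_name": f"{name} ({side.lower()}eft)" if side == "L"
                    else f"{name} (right)",
                    "functional_module": module,
                    "hemisphere": side,
                }
            )
    table = pd.DataFrame(rows, index=pd.RangeIndex(1, N_REGIONS + 1, name="index"))
    return table


def region_index(abbreviation: str, table: pd.DataFrame | None = None) -> int:
    """Map a region abbreviation like ``"SPG.L"`` to its 1-based index."""
    if table is None:
        table = aal90_table()
    hit = table.index[table["abbreviation"] == abbreviation]
    if len(hit) != 1:
        raise KeyError(f"unknown region abbreviation: {abbreviation!r}")
    return int(hit[0])
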