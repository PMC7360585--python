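"""Built-in panel configurations.

Two dried-antibody panels are modelled. Panel 1 covers the major leukocyte
lineages (T/B/NK cells, monocyte subsets, granulocytes); panel 2 covers
dendritic-cell and basophil populations, with the lineage-exclusion cocktail
("Lin") treated as a single dump channel. Each panel bundles:

* a :class:`~cytoharm.fcs_io.ChannelMap` translating Beckman ("FL1 INT") and
  BD ("FITC-A") detector dialects to canonical marker names,
* per-marker gating thresholds expressed on the normalized reference scale
  (normalization is what makes one threshold set valid across instruments),
* the population hierarchy as :class:`~cytoharm.gating.PopulationDef` rules,
* log-normal population templates used by the synthetic generator, and
* a default spillover matrix.

All intensities are linear; template locations below are log10 means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fcs_io import ChannelMap
from .gating import Condition, PopulationDef


@dataclass(frozen=True)
class Panel:
    panel_id: str
    channel_map: ChannelMap
    thresholds: dict
    populations: tuple
    templates: dict
    spillover: np.ndarray
    scatter_classes: tuple = ("debris", "beads", "lymphocytes",
                              "monocytes", "granulocytes")

    @property
    def markers(self) -> tuple:
        return tuple(c for c in self.channel_map.canonical_order
                     if c not in ("FSC", "SSC"))


# ---------------------------------------------------------------------------
# shared scatter geometry (log10 linear-scale units)
# ---------------------------------------------------------------------------

# boxes used by the threshold hierarchy; generator templates sit well inside
_FSC_DEBRIS_MAX = 10 ** 3.55
_FSC_BEADS_MIN = 10 ** 4.9
_FSC_LYMPH_MAX = 10 ** 4.2
_SSC_LYMPH_MAX = 10 ** 3.8
_SSC_GRAN_MIN = 10 ** 4.3

#: (FSC log10 mean, FSC sigma, SSC log10 mean, SSC sigma)
SCATTER_TEMPLATES = {
    "debris": (3.0, 0.15, 3.0, 0.15),
    "lymphocytes": (4.0, 0.06, 3.5, 0.08),
    "monocytes": (4.35, 0.05, 4.0, 0.07),
    "granulocytes": (4.45, 0.06, 4.6, 0.06),
    "beads": (5.3, 0.02, 5.3, 0.02),
}


def _scatter_defs() -> list[PopulationDef]:
    between = lambda m, lo, hi: Condition(m, "between", (lo, hi))
    return [
        PopulationDef("all", None, ()),
        PopulationDef("debris", "all",
                      (between("FSC", None, _FSC_DEBRIS_MAX),)),
        PopulationDef("beads", "all",
                      (between("FSC", _FSC_BEADS_MIN, None),)),
        PopulationDef("leukocytes", "all",
                      (between("FSC", _FSC_DEBRIS_MAX, _FSC_BEADS_MIN),)),
        PopulationDef("lymphocytes", "leukocytes",
                      (between("FSC", None, _FSC_LYMPH_MAX),
                       between("SSC", None, _SSC_LYMPH_MAX))),
        PopulationDef("monocytes", "leukocytes",
                      (between("FSC", _FSC_LYMPH_MAX, None),
                       between("SSC", None, _SSC_GRAN_MIN))),
        PopulationDef("granulocytes", "leukocytes",
                      (between("FSC", _FSC_LYMPH_MAX, None),
                       between("SSC", _SSC_GRAN_MIN, None))),
    ]


# ---------------------------------------------------------------------------
# panel 1 — leukocyte populations
# ---------------------------------------------------------------------------

_P1_MARKERS = ("CD3", "CD4", "CD8", "CD19", "CD56", "CD16", "CD14", "CD15")

_P1_BC = {rf"FL{i + 1}(\s+INT.*|\s+LOG.*)?": m
          for i, m in enumerate(_P1_MARKERS)}
_P1_BD_DYES = ("FITC-A", "PE-A", "PerCP-Cy5-5-A", "PE-Cy7-A",
               "APC-A", "APC-H7-A", "V450-A", "V500-A")
_P1_BD = {dye.replace("-", r"\-"): m for dye, m in zip(_P1_BD_DYES, _P1_MARKERS)}

PANEL1_CHANNEL_MAP = ChannelMap(
    panel_id="panel1",
    entries={r"FS(C)?([ \-].*)?": "FSC", r"SS(C)?([ \-].*)?": "SSC",
             **_P1_BC, **_P1_BD},
    canonical_order=("FSC", "SSC") + _P1_MARKERS,
)

# single positivity cutoff per marker plus a "high" cutoff for CD16
PANEL1_THRESHOLDS = {m: 1.0e3 for m in _P1_MARKERS}
PANEL1_THRESHOLDS["CD16:high"] = 10 ** 3.85


def _p1_population_defs() -> tuple:
    c = Condition
    defs = _scatter_defs() + [
        PopulationDef("T cells", "lymphocytes",
                      (c("CD3", "+"), c("CD19", "-")),
                      record_markers=("CD3",)),
        PopulationDef("CD4 T cells", "T cells",
                      (c("CD4", "+"), c("CD8", "-"), c("CD56", "-")),
                      record_markers=("CD3", "CD4")),
        PopulationDef("CD8 T cells", "T cells",
                      (c("CD8", "+"), c("CD4", "-"), c("CD56", "-")),
                      record_markers=("CD3", "CD8")),
        PopulationDef("NK-like T cells", "T cells",
                      (c("CD56", "+"),),
                      record_markers=("CD3", "CD56")),
        PopulationDef("B cells", "lymphocytes",
                      (c("CD19", "+"), c("CD3", "-")),
                      record_markers=("CD19",)),
        PopulationDef("NK cells", "lymphocytes",
                      (c("CD56", "+"), c("CD3", "-"), c("CD19", "-")),
                      record_markers=("CD56",)),
        PopulationDef("CD56high CD16low NK cells", "NK cells",
                      (c("CD16", "low"),),
                      record_markers=("CD56", "CD16")),
        PopulationDef("CD56low CD16high NK cells", "NK cells",
                      (c("CD16", "high"),),
                      record_markers=("CD56", "CD16")),
        PopulationDef("classical monocytes", "monocytes",
                      (c("CD14", "+"), c("CD16", "-")),
                      record_markers=("CD14",)),
        PopulationDef("intermediate monocytes", "monocytes",
                      (c("CD14", "+"), c("CD16", "+")),
                      record_markers=("CD14", "CD16")),
        PopulationDef("non-classical monocytes", "monocytes",
                      (c("CD14", "-"), c("CD16", "+")),
                      record_markers=("CD16",)),
        PopulationDef("neutrophils", "granulocytes",
                      (c("CD15", "+"), c("CD16", "high")),
                      record_markers=("CD15", "CD16")),
        PopulationDef("eosinophils", "granulocytes",
                      (c("CD15", "+"), c("CD16", "low")),
                      record_markers=("CD15",)),
    ]
    return tuple(defs)


# population templates: mixture weight and log10 marker locations; markers
# not listed sit at the negative baseline (2.0). sigma is per-marker log10 SD.
_NEG = 2.0
PANEL1_TEMPLATES = {
    "baseline_log10": _NEG,
    "sigma_log10": 0.12,
    "populations": {
        "CD4 T cells": {"weight": 0.28, "scatter": "lymphocytes",
                        "markers": {"CD3": 4.0, "CD4": 4.0}},
        "CD8 T cells": {"weight": 0.14, "scatter": "lymphocytes",
                        "markers": {"CD3": 4.0, "CD8": 4.0}},
        "NK-like T cells": {"weight": 0.02, "scatter": "lymphocytes",
                            "markers": {"CD3": 4.0, "CD56": 3.9}},
        "B cells": {"weight": 0.10, "scatter": "lymphocytes",
                    "markers": {"CD19": 4.0}},
        "CD56high CD16low NK cells": {"weight": 0.02,
                                      "scatter": "lymphocytes",
                                      "markers": {"CD56": 4.4}},
        "CD56low CD16high NK cells": {"weight": 0.06,
                                      "scatter": "lymphocytes",
                                      "markers": {"CD56": 3.6, "CD16": 4.3}},
        "classical monocytes": {"weight": 0.08, "scatter": "monocytes",
                                "markers": {"CD14": 4.2, "CD4": 3.2}},
        "intermediate monocytes": {"weight": 0.02, "scatter": "monocytes",
                                   "markers": {"CD14": 4.1, "CD16": 3.5,
                                               "CD4": 3.2}},
        "non-classical monocytes": {"weight": 0.02, "scatter": "monocytes",
                                    "markers": {"CD16": 4.1, "CD4": 3.2}},
        "neutrophils": {"weight": 0.23, "scatter": "granulocytes",
                        "markers": {"CD15": 4.3, "CD16": 4.4}},
        "eosinophils": {"weight": 0.03, "scatter": "granulocytes",
                        "markers": {"CD15": 4.0, "CD16": 2.5}},
    },
}


def _default_spillover(n: int) -> np.ndarray:
    """Adjacent-channel spillover: 8% into the next, 3% into the previous."""
    s = np.eye(n)
    for i in range(n - 1):
        s[i, i + 1] = 0.08
        s[i + 1, i] = 0.03
    return s


PANEL1 = Panel(
    panel_id="panel1",
    channel_map=PANEL1_CHANNEL_MAP,
    thresholds=PANEL1_THRESHOLDS,
    populations=_p1_population_defs(),
    templates=PANEL1_TEMPLATES,
    spillover=_default_spillover(len(_P1_MARKERS)),
)


# ---------------------------------------------------------------------------
# panel 2 — dendritic cells and basophils
# ---------------------------------------------------------------------------

_P2_MARKERS = ("HLA-DR", "Lin", "CD123", "CD11c", "CD1c", "CD141")
_P2_BC = {rf"FL{i + 1}(\s+INT.*|\s+LOG.*)?": m
          for i, m in enumerate(_P2_MARKERS)}
_P2_BD_DYES = ("FITC-A", "PE-A", "PerCP-Cy5-5-A", "PE-Cy7-A", "APC-A",
               "APC-H7-A")
_P2_BD = {dye.replace("-", r"\-"): m for dye, m in zip(_P2_BD_DYES, _P2_MARKERS)}

PANEL2_CHANNEL_MAP = ChannelMap(
    panel_id="panel2",
    entries={r"FS(C)?([ \-].*)?": "FSC", r"SS(C)?([ \-].*)?": "SSC",
             **_P2_BC, **_P2_BD},
    canonical_order=("FSC", "SSC") + _P2_MARKERS,
)

PANEL2_THRESHOLDS = {m: 1.0e3 for m in _P2_MARKERS}


def _p2_population_defs() -> tuple:
    c = Condition
    defs = _scatter_defs() + [
        PopulationDef("basophils", "lymphocytes",
                      (c("HLA-DR", "-"), c("CD123", "+"), c("Lin", "-")),
                      record_markers=("CD123",)),
        PopulationDef("pDC", "lymphocytes",
                      (c("HLA-DR", "+"), c("Lin", "-"),
                       c("CD123", "+"), c("CD11c", "-")),
                      record_markers=("CD123",)),
        PopulationDef("mDC", "monocytes",
                      (c("HLA-DR", "+"), c("Lin", "-"),
                       c("CD123", "-"), c("CD11c", "+")),
                      record_markers=("CD11c",)),
        PopulationDef("mDC1", "mDC",
                      (c("CD1c", "+"), c("CD141", "-")),
                      record_markers=("CD1c",)),
        PopulationDef("mDC2", "mDC",
                      (c("CD1c", "-"), c("CD141", "+")),
                      record_markers=("CD141",)),
    ]
    return tuple(defs)


PANEL2_TEMPLATES = {
    "baseline_log10": _NEG,
    "sigma_log10": 0.12,
    "populations": {
        "Lin+ leukocytes": {"weight": 0.952, "scatter": "lymphocytes",
                            "markers": {"Lin": 4.0}},
        "basophils": {"weight": 0.012, "scatter": "lymphocytes",
                      "markers": {"CD123": 4.0}},
        "pDC": {"weight": 0.008, "scatter": "lymphocytes",
                "markers": {"HLA-DR": 4.0, "CD123": 4.0}},
        "mDC1": {"weight": 0.02, "scatter": "monocytes",
                 "markers": {"HLA-DR": 4.0, "CD11c": 4.0, "CD1c": 4.0}},
        "mDC2": {"weight": 0.008, "scatter": "monocytes",
                 "markers": {"HLA-DR": 4.0, "CD11c": 4.0, "CD141": 4.0}},
    },
}

PANEL2 = Panel(
    panel_id="panel2",
    channel_map=PANEL2_CHANNEL_MAP,
    thresholds=PANEL2_THRESHOLDS,
    populations=_p2_population_defs(),
    templates=PANEL2_TEMPLATES,
    spillover=_default_spillover(len(_P2_MARKERS)),
)

PANELS = {"panel1": PANEL1, "panel2": PANEL2}


def get_panel(panel_id: str) -> Panel:
    try:
        return PANELS[panel_id]
    except KeyError:
        raise KeyError(f"unknown panel {panel_id!r}; "
                       f"have {sorted(PANELS)}") from None
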