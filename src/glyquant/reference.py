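"""The packaged 17-glycan secretome reference panel.

Seventeen N-glycans observed by MALDI QIT-TOF in the mixed secretome of the
SKOV3 ovarian cancer line (amide-15N-Gln labeled, heavy channel) and its
metastatic derivative SKOV3-ip (amide-14N-Gln labeled, light channel):
compositions, observed/theoretical sodiated m/z, published SKOV3-ip/SKOV3
ratios with replicate CVs (n = 9), change calls at the 0.83/1.20 thresholds,
and curated structural classes (composition alone cannot separate a
bisecting-GlcNAc isomer from an antennary one; the curated classes encode
the MS/MS- and database-supported assignments).

This panel drives the default synthetic scenario and the curated class map.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .chem import GlycanComposition

__all__ = ["PanelRow", "reference_panel", "curated_class_map"]


@dataclass(frozen=True)
class PanelRow:
    observed_mz: float
    theoretical_mz: float
    ratio: float
    cv_percent: float
    change: str
    composition: GlycanComposition
    glycan_class: str


def _data_text(name: str) -> str:
    return resources.files("glyquant.data").joinpath(name).read_text()


def reference_panel() -> list[PanelRow]:
    """The 17-row reference panel, ascending in theoretical m/z."""
    rows = []
    for rec in csv.DictReader(_data_text("reference_panel.csv").splitlines()):
        rows.append(
            PanelRow(
                observed_mz=float(rec["observed_mz"]),
                theoretical_mz=float(rec["theoretical_mz"]),
                ratio=float(rec["ratio"]),
                cv_percent=float(rec["cv_percent"]),
                change=rec["change"],
                composition=GlycanComposition.parse(rec["composition"]),
                glycan_class=rec["glycan_class"],
            )
        )
    rows.sort(key=lambda r: r.theoretical_mz)
    return rows


def curated_class_map() -> dict[GlycanComposition, str]:
    """Curated composition -> glycan class map (overrides the heuristic)."""
    out: dict[GlycanComposition, str] = {}
    for rec in csv.DictReader(_data_text("curated_classes.csv").splitlines()):
        out[GlycanComposition.parse(rec["composition"])] = rec["glycan_class"]
    return out
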