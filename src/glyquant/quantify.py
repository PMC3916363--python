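"""Light/heavy ratio estimation with isotopic-envelope overlap correction.

The measured signal around each glycan is a superposition of two isotopic
envelopes: the light (amide-14N) species and the heavy (amide-15N) species
shifted by ``n_aminosugar_N x 0.99703`` Da. For glycans with only two
aminosugar nitrogens the shift is ~2 Da, so the heavy monoisotopic peak
lands on the light M+2 isotopologue and a naive height ratio is biased.
The estimator here models the observed intensities at the expected
isotopologue positions as a non-negative linear combination of the two
normalized theoretical envelopes and solves for the two amounts by NNLS;
the ratio is their quotient. Replicate ratios aggregate to a mean and CV%,
and the mean is thresholded into an up / no / down change call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .annotate import StructureAnnotation, classify
from .chem import (
    SODIATED,
    GlycanComposition,
    IonSpec,
    N15_SHIFT,
    composition_formula,
    composition_mass,
    labeled_nitrogens,
)
from .isotopes import IsotopicEnvelope, labeled_envelope, natural_envelope
from .spectra import PeakList

__all__ = [
    "LabeledPair",
    "FitResult",
    "QuantRecord",
    "build_pair",
    "fit_pair",
    "naive_height_ratio",
    "aggregate",
    "change_call",
    "quantify_experiment",
    "quant_table",
    "replicate_table",
    "DOWN_THRESHOLD",
    "UP_THRESHOLD",
    "CV_GATE_PERCENT",
]

#: SKOV3-ip/SKOV3 ratio thresholds separating down / no-change / up calls.
DOWN_THRESHOLD = 0.83
UP_THRESHOLD = 1.20
#: replicate-CV quality gate (%).
CV_GATE_PERCENT = 20.0

_WINDOW_MARGIN = 1.5  # Da either side of the light/heavy envelope span
_POSITION_TOL = 0.3  # Da; matching observed peaks to template positions
_HIGH_RESIDUAL = 0.25  # fraction of window signal left unexplained


@dataclass(frozen=True)
class LabeledPair:
    """Theoretical light/heavy envelope pair for one glycan composition."""

    composition: GlycanComposition
    light: IsotopicEnvelope
    heavy: IsotopicEnvelope
    shift: float  # Da, = labeled_nitrogens * (m(15N) - m(14N))
    window: tuple[float, float]


@lru_cache(maxsize=512)
def _cached_pair(comp: GlycanComposition, ion: IonSpec, n_peaks: int) -> LabeledPair:
    formula = composition_formula(comp, ion.derivatization)
    n_lab = labeled_nitrogens(comp)
    extra = ion.adduct_mass / ion.charge
    light = natural_envelope(formula, n_peaks=n_peaks, extra_mass=extra)
    heavy = labeled_envelope(
        formula, n_lab, ion.enrichment, n_peaks=n_peaks, extra_mass=extra
    )
    shift = n_lab * N15_SHIFT
    lo = light.monoisotopic_mz - _WINDOW_MARGIN
    hi = max(light.mz[-1], heavy.mz[-1]) + _WINDOW_MARGIN
    return LabeledPair(comp, light, heavy, shift, (lo, hi))


def build_pair(
    comp: GlycanComposition, ion: IonSpec = SODIATED, n_peaks: int = 10
) -> LabeledPair:
    """Theoretical envelopes of the light and heavy species of *comp*.

    The heavy envelope is computed at the ion's configured 15N enrichment
    (1.0 = complete incorporation). The analysis window spans both envelopes
    plus a 1.5 Da margin on each side.
    """
    if comp.is_empty():
        raise ValueError("empty composition")
    return _cached_pair(comp, ion, n_peaks)


@dataclass(frozen=True)
class FitResult:
    light_amount: float
    heavy_amount: float
    ratio: float  # nan when undefined
    residual: float  # fraction of window signal unexplained
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return math.isfinite(self.ratio)


def _template_positions(pair: LabeledPair, merge_tol: float = 0.2):
    """Union of light/heavy peak positions, merged within *merge_tol* Da.

    Returns (positions, light column, heavy column): the design matrix of
    the two-template model on the merged position grid.
    """
    pts = [(m, a, 0) for m, a in zip(pair.light.mz, pair.light.abundance)]
    pts += [(m, a, 1) for m, a in zip(pair.heavy.mz, pair.heavy.abundance)]
    pts.sort()
    positions: list[float] = []
    cols = [[], []]
    for m, a, ch in pts:
        if positions and m - positions[-1] <= merge_tol:
            w = cols[0][-1] + cols[1][-1] + a
            positions[-1] = (positions[-1] * (w - a) + m * a) / w if w > 0 else m
            cols[ch][-1] += a
            cols[1 - ch][-1] += 0.0
        else:
            positions.append(m)
            cols[ch].append(a)
            cols[1 - ch].append(0.0)
    return np.asarray(positions), np.asarray(cols[0]), np.asarray(cols[1])


def fit_pair(
    peaks: PeakList,
    pair: LabeledPair,
    tolerance: float = _POSITION_TOL,
    use_area: bool = True,
    signal_floor: float = 1e-9,
) -> FitResult:
    """Estimate light and heavy amounts by two-template NNLS.

    Observed centroid areas (or apex heights with ``use_area=False``) at the
    expected isotopologue positions are modeled as
    ``light_amount * L + heavy_amount * H`` with L, H the normalized
    theoretical envelopes; the non-negative least-squares solution gives the
    two amounts and ``ratio = light/heavy``. A vanishing heavy amount yields
    a flagged NaN ratio, never an infinity; total window signal below
    ``signal_floor`` yields a low-signal flag and no ratio.
    """
    positions, light_col, heavy_col = _template_positions(pair)
    values = peaks.area if use_area else peaks.intensity
    lo, hi = pair.window
    in_window = (peaks.mz >= lo) & (peaks.mz <= hi)
    total_signal = float(values[in_window].sum())
    if total_signal <= signal_floor:
        return FitResult(0.0, 0.0, float("nan"), 1.0, ("low_signal",))
    b = np.zeros(len(positions))
    matched = np.zeros(len(peaks), dtype=bool)
    for j, p in enumerate(positions):
        sel = np.abs(peaks.mz - p) <= tolerance
        b[j] = float(values[sel].sum())
        matched |= sel
    A = np.column_stack([light_col, heavy_col])
    x, _ = nnls(A, b)
    light_amt, heavy_amt = float(x[0]), float(x[1])
    model = A @ x
    unmatched = float(values[in_window & ~matched].sum())
    residual = (float(np.abs(b - model).sum()) + unmatched) / total_signal
    flags: list[str] = []
    if residual > _HIGH_RESIDUAL:
        flags.append("high_residual")
    if heavy_amt <= 0:
        flags.append("undefined_ratio")
        return FitResult(light_amt, heavy_amt, float("nan"), residual, tuple(flags))
    return FitResult(light_amt, heavy_amt, light_amt / heavy_amt, residual, tuple(flags))


def naive_height_ratio(
    peaks: PeakList, pair: LabeledPair, tolerance: float = _POSITION_TOL
) -> float:
    """Uncorrected monoisotopic height ratio (light apex / heavy apex).

    Biased upward-in-denominator whenever the label shift is small enough
    that the heavy monoisotopic peak overlaps the light envelope; kept as
    the comparison estimator, not the default.
    """
    def height_at(p: float) -> float:
        sel = np.abs(peaks.mz - p) <= tolerance
        return float(peaks.intensity[sel].sum())

    light_h = height_at(pair.light.monoisotopic_mz)
    heavy_h = height_at(pair.light.monoisotopic_mz + pair.shift)
    if heavy_h <= 0:
        return float("nan")
    return light_h / heavy_h


def aggregate(ratios: Sequence[float]) -> tuple[float, float | None]:
    """Mean and CV% (sample sd, n-1) of finite replicate ratios.

    With fewer than two finite ratios the CV is unavailable (None).
    """
    vals = np.asarray([r for r in ratios if math.isfinite(r)], dtype=float)
    if len(vals) == 0:
        raise ValueError("no finite ratios to aggregate")
    mean = float(vals.mean())
    if len(vals) < 2:
        return mean, None
    cv = 100.0 * float(vals.std(ddof=1)) / mean
    return mean, cv


def change_call(
    mean_ratio: float,
    lower: float = DOWN_THRESHOLD,
    upper: float = UP_THRESHOLD,
) -> str:
    """Threshold rule: < lower -> 'down', > upper -> 'up', else 'no'.

    The boundaries themselves are 'no' (a ratio must clear the threshold to
    be called changed).
    """
    if not math.isfinite(mean_ratio) or mean_ratio <= 0:
        raise ValueError(f"mean ratio must be positive and finite, got {mean_ratio}")
    if mean_ratio < lower:
        return "down"
    if mean_ratio > upper:
        return "up"
    return "no"


@dataclass(frozen=True)
class QuantRecord:
    """One glycan's quantification summary — one row of the report table."""

    composition: GlycanComposition
    annotation: StructureAnnotation
    theoretical_mz: float
    observed_mz: float | None
    replicate_ratios: tuple[float, ...]
    mean_ratio: float | None
    cv_percent: float | None
    change: str | None
    flags: tuple[str, ...] = ()


def quantify_experiment(
    replicates: Sequence[PeakList],
    compositions: Iterable[GlycanComposition],
    ion: IonSpec = SODIATED,
    curated: dict[GlycanComposition, str] | None = None,
    tolerance: float = _POSITION_TOL,
    use_area: bool = True,
    estimator: str = "nnls",
    lower: float = DOWN_THRESHOLD,
    upper: float = UP_THRESHOLD,
    cv_gate: float = CV_GATE_PERCENT,
    observed_mzs: dict[GlycanComposition, float] | None = None,
) -> list[QuantRecord]:
    """Per-composition ratio estimation across replicates -> report records.

    Deterministic given inputs; records sorted by theoretical m/z. A
    composition with no usable signal in any replicate yields a QC-flagged
    record without a call.
    """
    if len(replicates) == 0:
        raise ValueError("at least one replicate is required")
    if estimator not in ("nnls", "height"):
        raise ValueError(f"unknown estimator: {estimator!r}")
    comps = sorted(set(compositions), key=lambda c: composition_mass(c, ion))
    records: list[QuantRecord] = []
    for comp in comps:
        pair = build_pair(comp, ion)
        ratios: list[float] = []
        flags: set[str] = set()
        for rep in replicates:
            if estimator == "height":
                r = naive_height_ratio(rep, pair, tolerance)
                ratios.append(r)
                if not math.isfinite(r):
                    flags.add("undefined_ratio")
            else:
                fit = fit_pair(rep, pair, tolerance, use_area)
                ratios.append(fit.ratio)
                flags.update(fit.flags)
        finite = [r for r in ratios if math.isfinite(r)]
        if finite:
            mean, cv = aggregate(ratios)
            call = change_call(mean, lower, upper)
            if cv is not None and cv > cv_gate:
                flags.add("cv_above_gate")
            if cv is None:
                flags.add("cv_unavailable")
        else:
            mean = cv = call = None
            flags.add("no_signal")
        records.append(
            QuantRecord(
                composition=comp,
                annotation=classify(comp, curated),
                theoretical_mz=composition_mass(comp, ion),
                observed_mz=(observed_mzs or {}).get(comp),
                replicate_ratios=tuple(ratios),
                mean_ratio=mean,
                cv_percent=cv,
                change=call,
                flags=tuple(sorted(flags)),
            )
        )
    return records


def quant_table(records: Sequence[QuantRecord]) -> pd.DataFrame:
    """Report table: one row per glycan, ascending theoretical m/z."""
    return pd.DataFrame(
        {
            "observed_mz": [r.observed_mz for r in records],
            "theoretical_mz": [round(r.theoretical_mz, 1) for r in records],
            "ratio": [None if r.mean_ratio is None else round(r.mean_ratio, 3) for r in records],
            "cv_percent": [None if r.cv_percent is None else round(r.cv_percent, 2) for r in records],
            "change": [r.change for r in records],
            "composition": [str(r.composition) for r in records],
            "glycan_class": [r.annotation.glycan_class.value for r in records],
            "bisecting": [r.annotation.bisecting for r in records],
            "flags": [";".join(r.flags) for r in records],
        }
    )


def replicate_table(records: Sequence[QuantRecord]) -> pd.DataFrame:
    """Long-format companion: one row per (glycan, replicate) ratio."""
    rows = []
    for r in records:
        for i, ratio in enumerate(r.replicate_ratios):
            rows.append(
                {
                    "composition": str(r.composition),
                    "replicate": i,
                    "ratio": ratio if math.isfinite(ratio) else None,
                }
            )
    return pd.DataFrame(rows)
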