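"""End-to-end orchestration: spectra -> annotation -> quantification -> report.

A run is driven by a :class:`PipelineConfig` (loadable from YAML) that names
the two channels explicitly — which biological sample carries the light
(amide-14N) label and which the heavy (amide-15N) label — and which sample
is the ratio numerator. The orientation is never defaulted silently: a
config without a channel declaration is rejected before any stage runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import annotate as _annotate
from . import chem, quantify, spectra
from .chem import GlycanComposition, IonSpec
from .quantify import QuantRecord, quant_table, replicate_table
from .reference import curated_class_map

__all__ = ["PipelineConfig", "RunResult", "run", "summarize"]

log = logging.getLogger("glyquant")


@dataclass
class PipelineConfig:
    """Resolved run configuration; every run writes it back verbatim."""

    # labeling orientation — mandatory, no default channel assignment
    channels: dict[str, str]  # {"light": <sample>, "heavy": <sample>}
    numerator: str  # sample name whose amount goes on top of the ratio
    enrichment: float = 1.0
    library_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "hexnac": (2, 8), "hex": (3, 10), "fuc": (0, 2), "neuac": (0, 4)
        }
    )
    library_path: str | None = None
    match_tolerance: float = 0.3
    smoothing_sigma: float = 0.08  # Da; Gaussian profile smoothing
    centroid_threshold_fraction: float = 0.25
    centroid_threshold_offset: float = 0.5
    estimator: str = "nnls"  # nnls | height
    use_area: bool = True
    lower_threshold: float = quantify.DOWN_THRESHOLD
    upper_threshold: float = quantify.UP_THRESHOLD
    cv_gate_percent: float = quantify.CV_GATE_PERCENT
    adduct: str = "Na"
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.channels) != {"light", "heavy"}:
            raise ValueError(
                "config must state the labeling orientation explicitly: "
                "channels: {light: <sample>, heavy: <sample>}"
            )
        if self.numerator not in self.channels.values():
            raise ValueError(
                f"numerator {self.numerator!r} is not one of the declared "
                f"channel samples {sorted(self.channels.values())}"
            )
        if self.estimator not in ("nnls", "height"):
            raise ValueError(f"unknown estimator: {self.estimator!r}")
        self.library_ranges = {
            k: tuple(v) for k, v in self.library_ranges.items()
        }

    @property
    def ion(self) -> IonSpec:
        return IonSpec(adduct=self.adduct, enrichment=self.enrichment)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"unparsable config: {path}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class RunResult:
    records: list[QuantRecord]
    table: pd.DataFrame
    replicates: pd.DataFrame
    config: PipelineConfig
    log_lines: list[str]


def _load_input(path_or_obj) -> spectra.PeakList:
    if isinstance(path_or_obj, spectra.PeakList):
        return path_or_obj
    if isinstance(path_or_obj, spectra.ProfileSpectrum):
        return spectra.centroid(path_or_obj)
    return spectra.read_peaklist(path_or_obj)


def run(
    config: PipelineConfig,
    inputs: Sequence[Any],
    outdir: str | Path | None = None,
    centroid_profiles: bool = True,
) -> RunResult:
    """Execute the pipeline on replicate inputs.

    *inputs* may be paths to peak-list files, :class:`PeakList` objects, or
    :class:`ProfileSpectrum` objects (smoothed and centroided with the
    configured parameters). Deterministic given (inputs, config). QC issues
    surface as record flags and warnings, never as errors.
    """
    if len(inputs) == 0:
        raise ValueError("at least one replicate input is required")
    lines: list[str] = []

    def note(msg: str) -> None:
        log.info(msg)
        lines.append(msg)

    peaklists: list[spectra.PeakList] = []
    for i, item in enumerate(inputs):
        if isinstance(item, spectra.ProfileSpectrum) and centroid_profiles:
            sm = spectra.smooth(item, config.smoothing_sigma)
            pl = spectra.centroid(
                sm,
                config.centroid_threshold_fraction,
                config.centroid_threshold_offset,
            )
        else:
            pl = _load_input(item)
        pl = spectra.normalize_base_peak(pl)
        peaklists.append(pl)
        note(f"replicate {i}: {len(pl)} peaks after centroiding/normalization")

    if config.library_path:
        library = chem.read_library_csv(config.library_path)
    else:
        r = config.library_ranges
        library = chem.build_library(
            hexnac=r["hexnac"], hex=r["hex"], fuc=r["fuc"], neuac=r["neuac"],
            ion=config.ion,
        )
    note(f"library: {len(library)} compositions")

    assignments = [
        _deisotope(
            _annotate.match_peaks(pl, library, config.match_tolerance),
            config.ion,
            config.match_tolerance,
        )
        for pl in peaklists
    ]
    observed: dict[GlycanComposition, float] = {}
    comps: set[GlycanComposition] = set()
    for rep_assign in assignments:
        for a in rep_assign:
            if a.assigned:
                comps.add(a.composition)
                observed.setdefault(a.composition, a.observed_mz)
    n_unassigned = sum(
        1 for rep in assignments for a in rep if not a.assigned
    )
    note(f"assigned compositions: {len(comps)}; unassigned peaks: {n_unassigned}")

    records = quantify.quantify_experiment(
        peaklists,
        comps,
        ion=config.ion,
        curated=curated_class_map(),
        tolerance=config.match_tolerance,
        use_area=config.use_area,
        estimator=config.estimator,
        lower=config.lower_threshold,
        upper=config.upper_threshold,
        cv_gate=config.cv_gate_percent,
        observed_mzs=observed,
    )

    # ratio orientation: fits report light/heavy; invert if the declared
    # numerator sample carries the heavy label
    if config.numerator == config.channels["heavy"]:
        records = [_invert_record(r, config) for r in records]
        note("orientation: numerator is the heavy channel; ratios inverted")
    denom = next(s for s in config.channels.values() if s != config.numerator)
    note(f"ratio orientation: {config.numerator} / {denom}")

    table = quant_table(records)
    reps = replicate_table(records)
    result = RunResult(records, table, reps, config, lines)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "quant_table.csv", index=False)
        reps.to_csv(outdir / "replicate_ratios.csv", index=False)
        config.to_yaml(outdir / "config.resolved.yaml")
        (outdir / "run.log").write_text("\n".join(lines) + "\n")
    return result


def _deisotope(assignments, ion: IonSpec, tolerance: float):
    """Drop assignments that are isotopologues of an accepted lighter species.

    Peaks are visited in ascending m/z; a matched peak only seeds a new
    composition if it does not sit (within the match tolerance) on an
    expected isotopologue position — light or heavy envelope — of a
    composition already accepted at lower m/z. Satellite peaks revert to
    unassigned so they are reported, not silently dropped.
    """
    import numpy as np

    from .quantify import _template_positions, build_pair

    accepted: list[float] = []
    out = []
    for a in sorted(assignments, key=lambda x: x.observed_mz):
        if not a.assigned:
            out.append(a)
            continue
        pos = np.asarray(accepted)
        if len(pos) and np.any(np.abs(pos - a.observed_mz) <= tolerance):
            out.append(
                _annotate.Assignment(a.observed_mz, None, None, None)
            )
            continue
        pair = build_pair(a.composition, ion)
        accepted.extend(float(p) for p in _template_positions(pair)[0])
        out.append(a)
    return out


def _invert_record(r: QuantRecord, config: PipelineConfig) -> QuantRecord:
    inv = tuple(1.0 / x if x and x == x else float("nan") for x in r.replicate_ratios)
    if r.mean_ratio is None:
        return r
    mean, cv = quantify.aggregate(inv)
    return QuantRecord(
        composition=r.composition,
        annotation=r.annotation,
        theoretical_mz=r.theoretical_mz,
        observed_mz=r.observed_mz,
        replicate_ratios=inv,
        mean_ratio=mean,
        cv_percent=cv,
        change=quantify.change_call(
            mean, config.lower_threshold, config.upper_threshold
        ),
        flags=r.flags,
    )


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-class summary: counts, ratio range/median, and call tallies.

    Classes with no rows are omitted; call tallies sum to the table's row
    count. The bisecting class row surfaces the headline range directly.
    """
    if len(table) == 0:
        raise ValueError("empty quantification table")
    rows = []
    for cls, grp in table.groupby("glycan_class", sort=True):
        ratios = grp["ratio"].dropna()
        rows.append(
            {
                "glycan_class": cls,
                "n": len(grp),
                "min_ratio": ratios.min() if len(ratios) else None,
                "median_ratio": ratios.median() if len(ratios) else None,
                "max_ratio": ratios.max() if len(ratios) else None,
                "n_up": int((grp["change"] == "up").sum()),
                "n_down": int((grp["change"] == "down").sum()),
                "n_no": int((grp["change"] == "no").sum()),
            }
        )
    return pd.DataFrame(rows)
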