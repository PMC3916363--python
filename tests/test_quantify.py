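"""Ratio estimation: NNLS overlap correction, aggregation, change calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glyquant.chem import GlycanComposition, IonSpec
from glyquant.quantify import (
    _template_positions,
    aggregate,
    build_pair,
    change_call,
    fit_pair,
    naive_height_ratio,
    quantify_experiment,
)
from glyquant.reference import reference_panel
from glyquant.simulate import ScenarioEntry, ScenarioSpec, simulate_experiment
from glyquant.spectra import PeakList

from conftest import noise_free_pair_peaklist


def test_pair_shift_and_window():
    p2 = build_pair(GlycanComposition(2, 6))
    assert p2.shift == pytest.approx(2 * 0.99703, abs=1e-5)
    p7 = build_pair(GlycanComposition(7, 7, 1))
    assert p7.shift == pytest.approx(6.979, abs=0.001)
    for p in (p2, p7):
        lo, hi = p.window
        assert lo < p.light.mz[0] and hi > p.heavy.mz[-1]


@pytest.mark.parametrize("true_ratio", [0.12, 0.5, 1.0, 2.0, 10.0])
def test_noise_free_recovery_any_ratio(true_ratio):
    peaks = noise_free_pair_peaklist(GlycanComposition(2, 6), true_ratio, 1.0)
    fit = fit_pair(peaks, build_pair(GlycanComposition(2, 6)))
    assert fit.ratio == pytest.approx(true_ratio, abs=1e-6)
    assert fit.residual < 1e-9


def test_noise_free_one_to_one_mixture_of_every_panel_pair(panel):
    for row in panel:
        peaks = noise_free_pair_peaklist(row.composition, 1.0, 1.0)
        fit = fit_pair(peaks, build_pair(row.composition))
        assert fit.ratio == pytest.approx(1.0, abs=1e-6)


def test_overlap_correction_beats_naive_height_ratio():
    """2 Da shift, true ratio 0.5: NNLS is exact, the height ratio is biased."""
    comp = GlycanComposition(2, 6)
    peaks = noise_free_pair_peaklist(comp, 0.5, 1.0)
    pair = build_pair(comp)
    assert fit_pair(peaks, pair).ratio == pytest.approx(0.500, abs=0.005)
    naive = naive_height_ratio(peaks, pair)
    assert abs(naive / 0.5 - 1) > 0.02


def test_pure_light_signal_is_flagged_not_infinite():
    comp = GlycanComposition(4, 5)
    pair = build_pair(comp)
    peaks = PeakList(pair.light.mz, pair.light.abundance, pair.light.abundance)
    fit = fit_pair(peaks, pair)
    assert math.isnan(fit.ratio)
    assert "undefined_ratio" in fit.flags


def test_empty_window_low_signal_flag():
    pair = build_pair(GlycanComposition(2, 6))
    peaks = PeakList(np.array([3000.0]), np.array([5.0]), np.array([5.0]))
    fit = fit_pair(peaks, pair)
    assert "low_signal" in fit.flags and math.isnan(fit.ratio)


def test_fit_agrees_with_grid_search_oracle():
    """NNLS matches a brute-force 2-parameter search of the same objective."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        comp = GlycanComposition(
            int(rng.integers(2, 8)), int(rng.integers(3, 9)), int(rng.integers(0, 2))
        )
        pair = build_pair(comp)
        light, heavy = rng.uniform(0.2, 3.0, size=2)
        peaks = noise_free_pair_peaklist(comp, light, heavy)
        noisy = peaks.scaled(1.0)
        noisy.area = noisy.area * np.exp(rng.normal(0, 0.03, len(noisy)))
        fit = fit_pair(noisy, pair)
        pos, L, H = _template_positions(pair)
        b = np.array([noisy.area[np.abs(noisy.mz - p) <= 0.3].sum() for p in pos])
        # coarse grid then local refinement around the minimum
        center = np.array([max(light, 1e-3), max(heavy, 1e-3)])
        for span in (1.0, 0.1, 0.01, 0.001):
            lg = np.linspace(center[0] * (1 - span), center[0] * (1 + span), 81)
            hg = np.linspace(center[1] * (1 - span), center[1] * (1 + span), 81)
            LG, HG = np.meshgrid(np.clip(lg, 0, None), np.clip(hg, 1e-12, None), indexing="ij")
            resid = ((LG[..., None] * L + HG[..., None] * H - b) ** 2).sum(-1)
            i, j = np.unravel_index(resid.argmin(), resid.shape)
            center = np.array([LG[i, j], HG[i, j]])
        grid_ratio = center[0] / center[1]
        assert fit.ratio == pytest.approx(grid_ratio, rel=0.005)


def test_scale_invariance_of_ratio():
    comp = GlycanComposition(5, 5, 1)
    pair = build_pair(comp)
    peaks = noise_free_pair_peaklist(comp, 0.12, 1.0)
    r1 = fit_pair(peaks, pair).ratio
    r2 = fit_pair(peaks.scaled(137.5), pair).ratio
    assert r1 == pytest.approx(r2, rel=1e-12)


def test_separated_pair_limit_equals_summed_intensity_ratio():
    """When the label shift clears the light envelope, NNLS equals the
    plain summed-envelope intensity ratio."""
    comp = GlycanComposition(7, 7, 1)  # 7 Da shift
    pair = build_pair(comp, n_peaks=6)  # envelope support < shift
    light_amt, heavy_amt = 1.7, 0.9
    mz = np.concatenate([pair.light.mz, pair.heavy.mz])
    amp = np.concatenate(
        [light_amt * pair.light.abundance, heavy_amt * pair.heavy.abundance]
    )
    order = np.argsort(mz)
    peaks = PeakList(mz[order], amp[order], amp[order])
    fit = fit_pair(peaks, pair)
    light_sum = amp[: len(pair.light.mz)].sum()
    heavy_sum = amp[len(pair.light.mz) :].sum()
    assert fit.ratio == pytest.approx(light_sum / heavy_sum, abs=1e-6)


def test_monotonicity_in_true_light_fraction():
    comp = GlycanComposition(2, 6)
    pair = build_pair(comp)
    ratios = []
    for frac in np.linspace(0.1, 0.9, 9):
        peaks = noise_free_pair_peaklist(comp, frac, 1 - frac)
        ratios.append(fit_pair(peaks, pair).ratio)
    assert all(b > a for a, b in zip(ratios, ratios[1:]))


def test_aggregate_examples_and_permutation_invariance():
    mean, cv = aggregate([0.28] * 9)
    assert mean == pytest.approx(0.28) and cv == pytest.approx(0.0, abs=1e-9)
    mean, cv = aggregate([1.0, 1.0, 4.0])
    assert mean == pytest.approx(2.0)
    assert cv == pytest.approx(100 * math.sqrt(3) / 2, abs=0.01)
    mean2, cv2 = aggregate([4.0, 1.0, 1.0])
    assert (mean2, cv2) == (mean, cv)
    mean, cv = aggregate([1.5])
    assert mean == 1.5 and cv is None
    with pytest.raises(ValueError):
        aggregate([float("nan")])


@pytest.mark.parametrize(
    "ratio,call",
    [(1.46, "up"), (0.95, "no"), (0.28, "down"), (0.83, "no"), (1.20, "no"),
     (0.8299, "down"), (1.2001, "up")],
)
def test_change_call_thresholds(ratio, call):
    assert change_call(ratio) == call


def test_change_call_rejects_nonpositive():
    with pytest.raises(ValueError):
        change_call(0.0)
    with pytest.raises(ValueError):
        change_call(float("nan"))


def test_quantify_experiment_orders_rows_and_flags_missing(panel):
    comp_present = GlycanComposition(2, 6)
    comp_absent = GlycanComposition(7, 7, 1)
    peaks = noise_free_pair_peaklist(comp_present, 1.46, 1.0)
    records = quantify_experiment([peaks, peaks], [comp_absent, comp_present])
    assert [r.composition for r in records] == [comp_present, comp_absent]
    present, absent = records
    assert present.change == "up" and present.cv_percent is not None
    assert absent.change is None and "no_signal" in absent.flags


def test_parameter_recovery_across_ratios_and_panel(panel):
    """Median relative ratio error < 5%, 95th percentile < 15% (n = 9)."""
    errors = []
    for k, true_ratio in enumerate([0.1, 0.33, 1.0, 3.0, 10.0]):
        entries = tuple(
            ScenarioEntry(row.composition, true_ratio, ab)
            for row, ab in zip(panel, np.linspace(100, 20, len(panel)))
        )
        spec = ScenarioSpec(entries=entries, seed=1000 + k)
        reps, _ = simulate_experiment(spec)
        records = quantify_experiment(reps, [e.composition for e in entries])
        for r in records:
            errors.append(abs(r.mean_ratio / true_ratio - 1))
    errors = np.asarray(errors)
    assert len(errors) == 5 * len(panel)
    assert np.median(errors) < 0.05
    assert np.quantile(errors, 0.95) < 0.15
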