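"""Aggregated isotopic envelopes, including partial 15N enrichment.

An aggregated (unit-mass-binned) envelope collapses the fine isotopic
structure of an ion into one peak per nominal mass (per "extra neutron"
count), which is what a quadrupole-ion-trap TOF resolves for glycans in the
m/z 1400-2800 range. Each element contributes a distribution over extra
neutrons; the molecular envelope is the convolution of per-element
distributions, with each aggregated peak's m/z reported as the
abundance-weighted centroid of the isotopologues it collects.

Metabolic amide-15N labeling is modeled by splitting the molecule's nitrogen
pool: the ``n_labeled`` glutamine-amide nitrogens follow a
binomial(enrichment) 15N distribution; every other atom follows natural
abundance.

Isotope masses and natural abundances come from the NIST table shipped with
:mod:`pyteomics` (``pyteomics.mass.nist_mass``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Any

import numpy as np
from pyteomics import mass as _pmass

from .chem import ElementalFormula

__all__ = ["IsotopicEnvelope", "natural_envelope", "labeled_envelope", "convolve"]

#: drop isotopologue bins below this relative abundance during convolution
_PRUNE = 1e-12
#: default number of aggregated peaks returned
DEFAULT_N_PEAKS = 10
#: average extra-neutron mass for nominal spacing checks (13C - 12C)
NEUTRON_SPACING = 1.0033548378


@dataclass(frozen=True)
class IsotopicEnvelope:
    """Aggregated envelope: ascending m/z, abundances normalized to sum 1."""

    mz: np.ndarray
    abundance: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "abundance", np.asarray(self.abundance, dtype=float))
        if self.mz.shape != self.abundance.shape:
            raise ValueError("mz and abundance must have equal length")
        if len(self.mz) and np.any(np.diff(self.mz) <= 0):
            raise ValueError("envelope m/z must be strictly increasing")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def monoisotopic_mz(self) -> float:
        return float(self.mz[0])

    def shifted(self, delta: float) -> "IsotopicEnvelope":
        return IsotopicEnvelope(self.mz + delta, self.abundance.copy(), dict(self.metadata))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["mz", "abundance"])
            for m, a in zip(self.mz, self.abundance):
                w.writerow([f"{m:.6f}", f"{a:.10f}"])


class _Dist:
    """Distribution over extra-neutron counts with per-bin mass moments.

    ``ab[k]`` is the probability of k extra neutrons; ``mm[k]`` is the
    abundance-weighted mass sum of that bin (so mm[k]/ab[k] is its centroid).
    """

    __slots__ = ("ab", "mm")

    def __init__(self, ab: np.ndarray, mm: np.ndarray):
        self.ab = ab
        self.mm = mm

    @staticmethod
    def delta(mass: float) -> "_Dist":
        return _Dist(np.array([1.0]), np.array([mass]))

    def convolve(self, other: "_Dist") -> "_Dist":
        ab = np.convolve(self.ab, other.ab)
        # mass moment of a sum of independent parts:
        # mm_z[k] = sum_j mm_x[j] ab_y[k-j] + ab_x[j] mm_y[k-j]
        mm = np.convolve(self.mm, other.ab) + np.convolve(self.ab, other.mm)
        return _Dist(ab, mm)._pruned()

    def _pruned(self) -> "_Dist":
        keep = len(self.ab)
        while keep > 1 and self.ab[keep - 1] < _PRUNE:
            keep -= 1
        return _Dist(self.ab[:keep], self.mm[:keep])

    def power(self, n: int) -> "_Dist":
        result = _Dist.delta(0.0)
        base = self
        while n:
            if n & 1:
                result = result.convolve(base)
            base = base.convolve(base)
            n >>= 1
        return result


@lru_cache(maxsize=None)
def _single_atom_dist(element: str) -> _Dist:
    try:
        table = _pmass.nist_mass[element]
    except KeyError:
        raise KeyError(f"unknown element: {element!r}") from None
    isotopes = sorted(
        (num, m, a) for num, (m, a) in table.items() if num != 0 and a > 0.0
    )
    if not isotopes:
        raise KeyError(f"no natural-abundance data for element: {element!r}")
    base = isotopes[0][0]
    size = isotopes[-1][0] - base + 1
    ab = np.zeros(size)
    mm = np.zeros(size)
    for num, m, a in isotopes:
        ab[num - base] = a
        mm[num - base] = a * m
    return _Dist(ab, mm)


@lru_cache(maxsize=None)
def _atom_power(element: str, n: int) -> _Dist:
    return _single_atom_dist(element).power(n)


def _labeled_n_dist(enrichment: float) -> _Dist:
    """One amide nitrogen: 14N with prob (1 - enrichment), 15N with prob e."""
    m14 = _pmass.nist_mass["N"][14][0]
    m15 = _pmass.nist_mass["N"][15][0]
    ab = np.array([1.0 - enrichment, enrichment])
    mm = np.array([(1.0 - enrichment) * m14, enrichment * m15])
    return _Dist(ab, mm)._pruned() if enrichment < 1.0 else _Dist(
        np.array([0.0, 1.0]), np.array([0.0, m15])
    )


def _finalize(
    dist: _Dist, n_peaks: int, extra_mass: float, metadata: dict[str, Any]
) -> IsotopicEnvelope:
    ab = dist.ab
    mm = dist.mm
    # leading all-zero bins can appear (e.g. pure-15N label at enrichment 1)
    nz = np.flatnonzero(ab > 0)
    ab = ab[nz[0] : nz[-1] + 1]
    mm = mm[nz[0] : nz[-1] + 1]
    n = min(n_peaks, len(ab))
    ab, mm = ab[:n], mm[:n]
    with np.errstate(invalid="ignore", divide="ignore"):
        mz = np.where(ab > 0, mm / np.where(ab > 0, ab, 1.0), 0.0) + extra_mass
    # interior zero-abundance bins keep a nominal position to stay monotone
    for i in range(len(mz)):
        if ab[i] == 0:
            mz[i] = mz[i - 1] + NEUTRON_SPACING if i else extra_mass
    total = ab.sum()
    if total <= 0:
        raise ValueError("envelope has no abundance")
    return IsotopicEnvelope(mz, ab / total, metadata)


def natural_envelope(
    formula: ElementalFormula,
    n_peaks: int = DEFAULT_N_PEAKS,
    extra_mass: float = 0.0,
) -> IsotopicEnvelope:
    """Natural-abundance aggregated envelope of *formula*.

    ``extra_mass`` is added to every peak position (e.g. an adduct cation
    whose isotopes are not modeled, or a charge-carrier offset).

    Raises on an empty formula or an unknown element.
    """
    if not formula or formula.total_atoms() == 0:
        raise ValueError("cannot compute an envelope for an empty formula")
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    dist = _Dist.delta(0.0)
    for el, n in sorted(formula.items()):
        dist = dist.convolve(_atom_power(el, n))
    return _finalize(dist, n_peaks, extra_mass, {"formula": str(formula), "labeling_state": "natural"})


def labeled_envelope(
    formula: ElementalFormula,
    n_labeled_n: int,
    enrichment: float,
    n_peaks: int = DEFAULT_N_PEAKS,
    extra_mass: float = 0.0,
) -> IsotopicEnvelope:
    """Envelope with *n_labeled_n* nitrogens 15N-enriched to *enrichment*.

    The labeled nitrogens follow an independent binomial(enrichment) 15N
    distribution convolved with the natural envelope of all remaining atoms.
    ``enrichment=0`` reduces exactly to :func:`natural_envelope`.
    """
    if not 0.0 <= enrichment <= 1.0:
        raise ValueError("enrichment must be in [0, 1]")
    if n_labeled_n < 0 or n_labeled_n > formula.get("N", 0):
        raise ValueError(
            f"n_labeled_n={n_labeled_n} exceeds formula nitrogen count "
            f"{formula.get('N', 0)}"
        )
    remainder = ElementalFormula(
        {el: (n - n_labeled_n if el == "N" else n) for el, n in formula.items()}
    )
    dist = _Dist.delta(0.0)
    for el, n in sorted(remainder.items()):
        dist = dist.convolve(_atom_power(el, n))
    if n_labeled_n and enrichment > 0.0:
        dist = dist.convolve(_labeled_n_dist(enrichment).power(n_labeled_n))
    elif n_labeled_n:
        dist = dist.convolve(_atom_power("N", n_labeled_n))
    return _finalize(
        dist,
        n_peaks,
        extra_mass,
        {
            "formula": str(formula),
            "labeling_state": "labeled",
            "n_labeled_n": n_labeled_n,
            "enrichment": enrichment,
        },
    )


def convolve(e1: IsotopicEnvelope, e2: IsotopicEnvelope, n_peaks: int = DEFAULT_N_PEAKS) -> IsotopicEnvelope:
    """Convolve two aggregated envelopes (envelope of the combined formula).

    Bins are aligned by extra-neutron index relative to each envelope's
    monoisotopic peak.
    """
    d1 = _Dist(e1.abundance, e1.abundance * e1.mz)
    d2 = _Dist(e2.abundance, e2.abundance * e2.mz)
    return _finalize(d1.convolve(d2), n_peaks, 0.0, {"labeling_state": "convolved"})
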