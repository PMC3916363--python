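"""Isotope engine vs an exhaustive enumeration oracle."""

import itertools
import math
from collections import defaultdict

import numpy as np
import pytest
from pyteomics import mass as pmass

from glyquant.chem import ElementalFormula, GlycanComposition, composition_formula
from glyquant.isotopes import convolve, labeled_envelope, natural_envelope


def _exhaustive_envelope(formula, n_labeled_n=0, enrichment=0.0, n_peaks=10):
    """Brute-force oracle: enumerate every isotopologue combination.

    Independent of the engine: per-element multinomial expansion by direct
    enumeration of isotope assignments, aggregated by extra-neutron count.
    Only feasible for small formulas.
    """
    per_element = []
    for el, n in sorted(formula.items()):
        n_natural = n - n_labeled_n if el == "N" else n
        isos = sorted(
            (num, m, a)
            for num, (m, a) in pmass.nist_mass[el].items()
            if num != 0 and a > 0
        )
        base = isos[0][0]
        states = [(num - base, m, a) for num, m, a in isos]
        # distribute n_natural atoms over the isotope states
        dist = defaultdict(lambda: [0.0, 0.0])  # shift -> [abundance, mass moment]
        for combo in itertools.combinations_with_replacement(states, n_natural):
            counts = defaultdict(int)
            for s in combo:
                counts[s] += 1
            multiplicity = math.factorial(n_natural)
            prob = 1.0
            shift = 0
            m_tot = 0.0
            for (k, m, a), c in counts.items():
                multiplicity //= math.factorial(c)
                prob *= a**c
                shift += k * c
                m_tot += m * c
            p = multiplicity * prob
            dist[shift][0] += p
            dist[shift][1] += p * m_tot
        per_element.append(dict(dist))
        if el == "N" and n_labeled_n:
            m14 = pmass.nist_mass["N"][14][0]
            m15 = pmass.nist_mass["N"][15][0]
            lab = defaultdict(lambda: [0.0, 0.0])
            for k in range(n_labeled_n + 1):
                p = math.comb(n_labeled_n, k) * enrichment**k * (1 - enrichment) ** (n_labeled_n - k)
                m_tot = k * m15 + (n_labeled_n - k) * m14
                lab[k][0] += p
                lab[k][1] += p * m_tot
            per_element.append(dict(lab))
    total = {0: [1.0, 0.0]}
    for dist in per_element:
        new = defaultdict(lambda: [0.0, 0.0])
        for k1, (a1, m1) in total.items():
            for k2, (a2, m2) in dist.items():
                new[k1 + k2][0] += a1 * a2
                new[k1 + k2][1] += a1 * m2 + a2 * m1
        total = new
    ks = sorted(k for k in total if total[k][0] > 0)
    ab = np.array([total[k][0] for k in ks])[:n_peaks]
    mm = np.array([total[k][1] for k in ks])[:n_peaks]
    return mm / ab, ab / ab.sum()


SMALL_FORMULAS = [
    ElementalFormula(C=10, H=15, N=2, O=5),
    ElementalFormula(C=6, H=10, O=5),
    ElementalFormula(C=8, H=13, N=1, O=5),
    ElementalFormula(C=20, H=10, N=4, O=6),
]


@pytest.mark.parametrize("formula", SMALL_FORMULAS, ids=str)
def test_natural_envelope_matches_exhaustive_enumeration(formula):
    env = natural_envelope(formula, n_peaks=8)
    mz, ab = _exhaustive_envelope(formula, n_peaks=8)
    n = min(len(ab), len(env))
    assert np.max(np.abs(ab[:n] - env.abundance[:n])) < 1e-10
    # centroid positions are well conditioned only where abundance is non-tiny
    sig = ab[:n] > 1e-6
    assert np.max(np.abs(mz[:n][sig] - env.mz[:n][sig])) < 1e-8


@pytest.mark.parametrize("enrichment", [0.5, 0.98, 1.0])
def test_labeled_envelope_matches_exhaustive_enumeration(enrichment):
    formula = ElementalFormula(C=10, H=15, N=3, O=5)
    env = labeled_envelope(formula, 2, enrichment, n_peaks=8)
    mz, ab = _exhaustive_envelope(formula, n_labeled_n=2, enrichment=enrichment, n_peaks=8)
    n = min(len(ab), len(env))
    assert np.max(np.abs(ab[:n] - env.abundance[:n])) < 1e-10
    sig = ab[:n] > 1e-6
    assert np.max(np.abs(mz[:n][sig] - env.mz[:n][sig])) < 1e-8


def test_envelope_normalization_for_reference_panel(panel):
    for row in panel:
        f = composition_formula(row.composition)
        for env in (natural_envelope(f), labeled_envelope(f, row.composition.n_hexnac, 0.98)):
            assert abs(env.abundance.sum() - 1.0) < 1e-9
            assert np.all(env.abundance >= 0)
            assert np.all(np.diff(env.mz) > 0)
            # aggregated spacing is ~1.003 Da between successive peaks
            assert np.all(np.abs(np.diff(env.mz) - 1.0034) < 0.01)


def test_single_hydrogen_deuterium_ratio():
    env = natural_envelope(ElementalFormula(H=1), n_peaks=2)
    assert env.abundance[1] / env.abundance[0] == pytest.approx(0.000115, rel=0.02)


def test_c100_m1_ratio_matches_binomial_closed_form():
    env = natural_envelope(ElementalFormula(C=100), n_peaks=5)
    p13 = pmass.nist_mass["C"][13][1]
    p12 = pmass.nist_mass["C"][12][1]
    assert env.abundance[1] / env.abundance[0] == pytest.approx(100 * p13 / p12, rel=1e-9)
    assert env.abundance[1] / env.abundance[0] == pytest.approx(1.08, abs=0.01)


def test_enrichment_zero_reduces_to_natural():
    f = ElementalFormula(C=14, H=23, N=3, O=10)
    nat = natural_envelope(f)
    lab = labeled_envelope(f, 2, 0.0)
    assert np.allclose(nat.abundance, lab.abundance, atol=1e-12)
    assert np.allclose(nat.mz, lab.mz, atol=1e-9)


def test_full_enrichment_shifts_monoisotopic_by_label_count():
    f = ElementalFormula(C=14, H=23, N=3, O=10)
    nat = natural_envelope(f)
    lab = labeled_envelope(f, 3, 1.0)
    assert lab.monoisotopic_mz - nat.monoisotopic_mz == pytest.approx(3 * 0.99703, abs=1e-4)


def test_partial_enrichment_has_minus_one_satellite():
    """At 98% 15N, the single-14N species sits 1 Da below the main peak."""
    f = composition_formula(GlycanComposition(2, 6))
    e98 = labeled_envelope(f, 2, 0.98)
    e100 = labeled_envelope(f, 2, 1.0)
    # leading peak of the 98% envelope is the all-14N species (prob 0.02^2)
    assert e98.monoisotopic_mz == pytest.approx(e100.monoisotopic_mz - 2 * 0.99703, abs=1e-3)
    i_main = int(np.argmin(np.abs(e98.mz - e100.monoisotopic_mz)))
    satellite = e98.abundance[i_main - 1] / e98.abundance[i_main]
    # dominated by the one-14N species: ~ 2 * 0.02/0.98 on top of natural M-1=0
    assert satellite == pytest.approx(2 * 0.02 / 0.98, rel=0.05)


def test_convolution_consistency():
    f1 = ElementalFormula(C=6, H=10, O=5)
    f2 = ElementalFormula(C=8, H=13, N=1, O=5)
    direct = natural_envelope(f1 + f2, n_peaks=8)
    combined = convolve(natural_envelope(f1), natural_envelope(f2), n_peaks=8)
    assert np.max(np.abs(direct.abundance - combined.abundance)) < 1e-9


def test_empty_formula_and_unknown_element_rejected():
    with pytest.raises(ValueError):
        natural_envelope(ElementalFormula())
    with pytest.raises(KeyError):
        natural_envelope(ElementalFormula(Xx=2))
    with pytest.raises(ValueError):
        labeled_envelope(ElementalFormula(C=2, N=1), 2, 0.98)
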