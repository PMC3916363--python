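"""Monosaccharide residue chemistry and theoretical m/z libraries.

Glycan compositions are multisets of four residue classes — HexNAc
(N-acetylhexosamine), Hex (hexose: mannose or galactose), Fuc (deoxyhexose)
and NeuAc (sialic acid). A *residue* is the glycosidically linked unit, i.e.
the free monosaccharide minus one water; a free glycan is therefore the sum
of its residues plus one water. Under amide-nitrogen metabolic labeling
(IDAWG), each aminosugar residue (HexNAc, NeuAc) carries exactly one
glutamine-derived amide nitrogen, so the heavy/light mass split of a glycan
is ``(n_HexNAc + n_NeuAc) * (m(15N) - m(14N))``.

Monoisotopic masses throughout; atomic masses come from the NIST table
shipped with :mod:`pyteomics`.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

from pyteomics import mass as _pmass

__all__ = [
    "ElementalFormula",
    "MonosaccharideResidue",
    "GlycanComposition",
    "IonSpec",
    "LibraryEntry",
    "RESIDUES",
    "WATER",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "N15_SHIFT",
    "PERMETHYL_END_GROUP",
    "atomic_mass",
    "composition_mass",
    "composition_formula",
    "labeled_nitrogens",
    "build_library",
    "write_library_csv",
    "read_library_csv",
]

ELECTRON_MASS = 0.000548579909
PROTON_MASS = 1.007276466


def atomic_mass(element: str) -> float:
    """Monoisotopic mass of *element* (most abundant isotope)."""
    try:
        return _pmass.nist_mass[element][0][0]
    except KeyError:
        raise KeyError(f"unknown element: {element!r}") from None


#: 15N - 14N monoisotopic mass difference (Da); the per-aminosugar label shift.
N15_SHIFT = _pmass.nist_mass["N"][15][0] - _pmass.nist_mass["N"][14][0]


class ElementalFormula(dict):
    """Element symbol -> non-negative integer count, with element-wise algebra."""

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        super().__init__()
        for k, v in {**(counts or {}), **kw}.items():
            if v < 0:
                raise ValueError(f"negative count for {k}: {v}")
            if v:
                self[k] = int(v)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = dict(self)
        for k, v in other.items():
            out[k] = out.get(k, 0) + v
        return ElementalFormula(out)

    def __mul__(self, n: int) -> "ElementalFormula":
        return ElementalFormula({k: v * n for k, v in self.items()})

    __rmul__ = __mul__

    def mass(self) -> float:
        """Monoisotopic mass (Da) via the NIST atomic-mass table."""
        return sum(atomic_mass(el) * n for el, n in self.items())

    def total_atoms(self) -> int:
        return sum(self.values())

    def __str__(self) -> str:
        return "".join(f"{el}{n}" for el, n in sorted(self.items()))


WATER = ElementalFormula(H=2, O=1)

#: CH2 increment added per methylation site during permethylation.
_CH2 = ElementalFormula(C=1, H=2)

#: End-group increment for a permethylated free glycan: the reducing-end
#: O-methyl and the non-reducing-end methyl on top of the residue sum
#: (equivalent to water + 2 CH2, i.e. C2H6O, 46.0419 Da).
PERMETHYL_END_GROUP = (WATER + 2 * _CH2).mass()


@dataclass(frozen=True)
class MonosaccharideResidue:
    """One residue class: glycosidically linked unit (monosaccharide - water).

    ``nitrogen_count`` is the number of glutamine-amide-derived nitrogens the
    hexosamine pathway installs (1 for HexNAc and NeuAc, 0 otherwise);
    ``methylation_sites`` is the number of CH2 increments permethylation adds
    to the internal residue.
    """

    name: str
    elemental_formula: ElementalFormula
    nitrogen_count: int
    methylation_sites: int

    @property
    def monoisotopic_residue_mass(self) -> float:
        return self.elemental_formula.mass()

    @property
    def permethylated_residue_mass(self) -> float:
        return self.monoisotopic_residue_mass + self.methylation_sites * _CH2.mass()


RESIDUES: dict[str, MonosaccharideResidue] = {
    "HexNAc": MonosaccharideResidue("HexNAc", ElementalFormula(C=8, H=13, N=1, O=5), 1, 3),
    "Hex": MonosaccharideResidue("Hex", ElementalFormula(C=6, H=10, O=5), 0, 3),
    "Fuc": MonosaccharideResidue("Fuc", ElementalFormula(C=6, H=10, O=4), 0, 2),
    "NeuAc": MonosaccharideResidue("NeuAc", ElementalFormula(C=11, H=17, N=1, O=8), 1, 5),
}


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of the four residue classes; the unit of identification."""

    n_hexnac: int = 0
    n_hex: int = 0
    n_fuc: int = 0
    n_neuac: int = 0

    def __post_init__(self) -> None:
        for f in ("n_hexnac", "n_hex", "n_fuc", "n_neuac"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "HexNAc": self.n_hexnac,
            "Hex": self.n_hex,
            "Fuc": self.n_fuc,
            "NeuAc": self.n_neuac,
        }

    def is_empty(self) -> bool:
        return self.total_residues() == 0

    def total_residues(self) -> int:
        return self.n_hexnac + self.n_hex + self.n_fuc + self.n_neuac

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.n_hexnac + other.n_hexnac,
            self.n_hex + other.n_hex,
            self.n_fuc + other.n_fuc,
            self.n_neuac + other.n_neuac,
        )

    def __str__(self) -> str:
        return (
            f"HexNAc{self.n_hexnac}Hex{self.n_hex}"
            f"Fuc{self.n_fuc}NeuAc{self.n_neuac}"
        )

    def compact(self) -> str:
        """Short alias: H<hex>N<hexnac>[F<fuc>][S<neuac>], e.g. ``H6N2``."""
        s = f"H{self.n_hex}N{self.n_hexnac}"
        if self.n_fuc:
            s += f"F{self.n_fuc}"
        if self.n_neuac:
            s += f"S{self.n_neuac}"
        return s

    _PARSE_RE = re.compile(
        r"^(?:HexNAc(?P<hexnac>\d+))?(?:Hex(?P<hex>\d+))?"
        r"(?:Fuc(?P<fuc>\d+))?(?:NeuAc(?P<neuac>\d+))?$"
    )
    _COMPACT_RE = re.compile(
        r"^H(?P<hex>\d+)N(?P<hexnac>\d+)(?:F(?P<fuc>\d+))?(?:S(?P<neuac>\d+))?$"
    )

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        """Parse either the long form (``HexNAc2Hex6Fuc0NeuAc0``, counts may
        be omitted) or the compact alias (``H6N2F1``)."""
        text = text.strip()
        m = cls._COMPACT_RE.match(text) or cls._PARSE_RE.match(text)
        if not m or not text:
            raise ValueError(f"cannot parse glycan composition: {text!r}")
        g = {k: int(v) if v else 0 for k, v in m.groupdict().items()}
        return cls(g["hexnac"], g["hex"], g["fuc"], g["neuac"])


_ADDUCT_MASSES = {
    # cation mass = atom - electron
    "Na": atomic_mass("Na") - ELECTRON_MASS,
    "H": atomic_mass("H") - ELECTRON_MASS,
    "K": atomic_mass("K") - ELECTRON_MASS,
    # neutral mass (no adduct): for formula/mass cross-checks
    "neutral": 0.0,
}


@dataclass(frozen=True)
class IonSpec:
    """How a glycan is observed: adduct, charge, derivatization and label state.

    ``enrichment`` is the fraction of labeled amide nitrogens that are 15N
    (1.0 = complete incorporation; 0.98 mirrors the isotopic purity of
    commercial amide-15N-glutamine). It affects envelope shapes, not the
    nominal heavy m/z, which is always the fully labeled isotopologue.
    """

    adduct: str = "Na"
    charge: int = 1
    derivatization: str = "native"  # native | permethylated
    labeling_state: str = "light"  # light | heavy
    enrichment: float = 1.0

    def __post_init__(self) -> None:
        if self.adduct not in _ADDUCT_MASSES:
            raise ValueError(f"unsupported adduct: {self.adduct!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.derivatization not in ("native", "permethylated"):
            raise ValueError(f"unknown derivatization: {self.derivatization!r}")
        if self.labeling_state not in ("light", "heavy"):
            raise ValueError(f"unknown labeling_state: {self.labeling_state!r}")
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment must be in [0, 1]")

    @property
    def adduct_mass(self) -> float:
        return _ADDUCT_MASSES[self.adduct]

    def as_state(self, labeling_state: str) -> "IonSpec":
        return replace(self, labeling_state=labeling_state)


SODIATED = IonSpec()
NEUTRAL = IonSpec(adduct="neutral", charge=1)


def labeled_nitrogens(comp: GlycanComposition) -> int:
    """Number of Gln-amide-derived nitrogens: one per HexNAc and per NeuAc."""
    return comp.n_hexnac + comp.n_neuac


def composition_formula(
    comp: GlycanComposition, derivatization: str = "native"
) -> ElementalFormula:
    """Elemental formula of the free glycan (residue sum plus one water).

    The permethylated variant adds one CH2 per residue methylation site plus
    two end-group CH2 (reducing- and non-reducing-end methyls).
    """
    formula = ElementalFormula(WATER)
    n_me = 0
    for name, n in comp.counts.items():
        res = RESIDUES[name]
        formula = formula + n * res.elemental_formula
        n_me += n * res.methylation_sites
    if derivatization == "permethylated":
        formula = formula + (n_me + 2) * _CH2
    elif derivatization != "native":
        raise ValueError(f"unknown derivatization: {derivatization!r}")
    return formula


def composition_mass(comp: GlycanComposition, ion: IonSpec = SODIATED) -> float:
    """Monoisotopic m/z of *comp* under *ion*.

    Native: (sum of residue masses + water + adduct) / charge. The heavy
    labeling state adds ``labeled_nitrogens * (m(15N) - m(14N))`` — the
    position of the fully 15N-labeled isotopologue.
    """
    if comp.is_empty():
        raise ValueError("empty glycan composition has no ion mass")
    neutral = composition_formula(comp, ion.derivatization).mass()
    if ion.labeling_state == "heavy":
        neutral += labeled_nitrogens(comp) * N15_SHIFT
    return (neutral + ion.adduct_mass * ion.charge) / ion.charge


@dataclass(frozen=True)
class LibraryEntry:
    composition: GlycanComposition
    mz: float


def build_library(
    hexnac: tuple[int, int] = (2, 8),
    hex: tuple[int, int] = (3, 10),
    fuc: tuple[int, int] = (0, 2),
    neuac: tuple[int, int] = (0, 4),
    ion: IonSpec = SODIATED,
) -> list[LibraryEntry]:
    """Enumerate compositions over inclusive count ranges, sorted by m/z.

    Deterministic: sorted ascending by m/z with composition order as the
    tie-break; deduplicated (compositions are unique by construction).
    """
    entries: list[LibraryEntry] = []
    for nn in range(hexnac[0], hexnac[1] + 1):
        for nh in range(hex[0], hex[1] + 1):
            for nf in range(fuc[0], fuc[1] + 1):
                for ns in range(neuac[0], neuac[1] + 1):
                    comp = GlycanComposition(nn, nh, nf, ns)
                    if comp.is_empty():
                        continue
                    entries.append(LibraryEntry(comp, composition_mass(comp, ion)))
    entries.sort(key=lambda e: (e.mz, e.composition))
    return entries


_LIB_COLUMNS = ["composition", "compact", "neutral_mass", "light_mz", "heavy_mz", "n_labeled"]


def write_library_csv(entries: Iterable[LibraryEntry], path, ion: IonSpec = SODIATED) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_LIB_COLUMNS)
        for e in entries:
            c = e.composition
            w.writerow([
                str(c),
                c.compact(),
                f"{composition_formula(c).mass():.5f}",
                f"{composition_mass(c, ion.as_state('light')):.5f}",
                f"{composition_mass(c, ion.as_state('heavy')):.5f}",
                labeled_nitrogens(c),
            ])


def read_library_csv(path) -> list[LibraryEntry]:
    entries = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                comp = GlycanComposition.parse(row["composition"])
                mz = float(row["light_mz"])
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
            entries.append(LibraryEntry(comp, mz))
    entries.sort(key=lambda e: (e.mz, e.composition))
    return entries
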