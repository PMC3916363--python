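"""Peak-to-composition assignment, glycan classing, and fragment masses.

Matching is nearest-neighbour within a mass tolerance against a theoretical
library. Classing distinguishes high-mannose, hybrid, complex biantennary,
tri-/tetra-antennary and bisecting-GlcNAc N-glycans; because a composition
such as HexNAc5Hex5 is consistent with both a bisected biantennary and an
agalacto-triantennary structure, a curated map (MS/MS- and database-backed)
takes precedence over the composition heuristic, which is flagged as
ambiguous for HexNAc counts >= 5.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

from .chem import (
    RESIDUES,
    SODIATED,
    GlycanComposition,
    IonSpec,
    LibraryEntry,
    WATER,
    composition_mass,
)
from .reference import curated_class_map

__all__ = [
    "GlycanClass",
    "Assignment",
    "StructureAnnotation",
    "FragmentIon",
    "match_peaks",
    "classify",
    "fragment_masses",
    "DEFAULT_TOLERANCE",
]

DEFAULT_TOLERANCE = 0.3  # Da; observed-vs-theoretical deviations run <= 0.2
WATER_MASS = WATER.mass()


class GlycanClass(str, Enum):
    HIGH_MANNOSE = "HighMannose"
    HYBRID = "Hybrid"
    COMPLEX_BIANTENNARY = "ComplexBiantennary"
    TRIANTENNARY = "Triantennary"
    TETRAANTENNARY = "TetraAntennary"
    BISECTING = "Bisecting"


@dataclass(frozen=True)
class Assignment:
    """One observed peak matched (or not) to a library composition."""

    observed_mz: float
    composition: GlycanComposition | None
    theoretical_mz: float | None
    error: float | None  # observed - theoretical, Da
    ambiguous: tuple[LibraryEntry, ...] = ()  # other entries within tolerance

    @property
    def assigned(self) -> bool:
        return self.composition is not None


def match_peaks(
    peak_mzs,
    library: list[LibraryEntry],
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[Assignment]:
    """Assign each observed m/z its nearest library entry within *tolerance*.

    Accepts a :class:`~glyquant.spectra.PeakList` or any iterable of m/z
    values. Unassigned peaks are reported with ``composition=None``, never
    dropped. Ties break on smaller |error|, then composition order.
    """
    if not library:
        raise ValueError("library must be non-empty")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    mzs = getattr(peak_mzs, "mz", peak_mzs)
    out: list[Assignment] = []
    for mz in mzs:
        mz = float(mz)
        within = [e for e in library if abs(mz - e.mz) <= tolerance]
        if not within:
            out.append(Assignment(mz, None, None, None))
            continue
        within.sort(key=lambda e: (abs(mz - e.mz), e.composition))
        best = within[0]
        out.append(
            Assignment(mz, best.composition, best.mz, mz - best.mz, tuple(within[1:]))
        )
    return out


@dataclass(frozen=True)
class StructureAnnotation:
    composition: GlycanComposition
    glycan_class: GlycanClass
    provenance: str  # curated | heuristic
    ambiguous: bool = False

    @property
    def bisecting(self) -> bool:
        return self.glycan_class is GlycanClass.BISECTING


def classify(
    comp: GlycanComposition,
    curated: dict[GlycanComposition, str] | None = None,
) -> StructureAnnotation:
    """Class assignment: curated map first, composition heuristic otherwise.

    Heuristic (for compositions absent from the curated map): HexNAc 2
    without fucose -> high mannose; HexNAc 3 -> hybrid; HexNAc 4 -> complex
    biantennary; HexNAc >= 5 is ambiguous without MS/MS (bisecting vs extra
    antenna) and is labeled by antenna count with ``ambiguous=True``.
    """
    if comp.is_empty():
        raise ValueError("cannot classify an empty composition")
    if curated is None:
        curated = curated_class_map()
    if comp in curated:
        return StructureAnnotation(comp, GlycanClass(curated[comp]), "curated")
    if comp.n_hexnac <= 2 and comp.n_fuc == 0:
        cls, amb = GlycanClass.HIGH_MANNOSE, False
    elif comp.n_hexnac == 3:
        cls, amb = GlycanClass.HYBRID, False
    elif comp.n_hexnac == 4:
        cls, amb = GlycanClass.COMPLEX_BIANTENNARY, False
    elif comp.n_hexnac == 5:
        cls, amb = GlycanClass.TRIANTENNARY, True
    else:
        cls, amb = GlycanClass.TETRAANTENNARY, True
    return StructureAnnotation(comp, cls, "heuristic", amb)


@dataclass(frozen=True)
class FragmentIon:
    """Sodiated glycosidic-cleavage fragment (B or Y), composition level."""

    kind: str  # "B" | "Y"
    lost: GlycanComposition  # residues on the other side of the cleavage
    retained: GlycanComposition
    mz: float
    water_loss: bool = False


def fragment_masses(
    comp: GlycanComposition,
    max_losses: int = 2,
    ion: IonSpec = SODIATED,
    include_water_loss: bool = True,
) -> list[FragmentIon]:
    """Enumerate sodiated B/Y fragments from glycosidic cleavages.

    Y ions retain the reducing end (precursor minus a residue sub-multiset
    of size 1..max_losses); B ions are the complementary sodiated
    oxocarbenium-type fragments (lost residues + adduct), so that
    ``m(B) + m(Y) = m(precursor) + m(adduct)``. Optional -H2O variants
    mirror the water-loss satellites typical of sodiated glycan CID spectra.
    Deduplicated by (kind, m/z); ascending m/z.
    """
    if comp.is_empty():
        raise ValueError("empty precursor composition")
    precursor_mz = composition_mass(comp, ion)
    res_names = ["HexNAc", "Hex", "Fuc", "NeuAc"]
    counts = [comp.n_hexnac, comp.n_hex, comp.n_fuc, comp.n_neuac]
    seen: set[tuple[str, float]] = set()
    out: list[FragmentIon] = []

    def emit(kind: str, lost: GlycanComposition, retained: GlycanComposition, mz: float, wl: bool):
        key = (kind, round(mz, 4))
        if key in seen:
            return
        seen.add(key)
        out.append(FragmentIon(kind, lost, retained, mz, wl))

    loss_ranges = [range(0, min(c, max_losses) + 1) for c in counts]
    for combo in itertools.product(*loss_ranges):
        n_lost = sum(combo)
        if n_lost == 0 or n_lost > max_losses:
            continue
        lost = GlycanComposition(*combo)
        retained = GlycanComposition(*(c - l for c, l in zip(counts, combo)))
        if retained.is_empty():
            continue
        lost_mass = sum(
            RESIDUES[n].monoisotopic_residue_mass * k for n, k in zip(res_names, combo)
        )
        y_mz = precursor_mz - lost_mass
        b_mz = lost_mass + ion.adduct_mass
        emit("Y", lost, retained, y_mz, False)
        emit("B", retained, lost, b_mz, False)
        if include_water_loss:
            emit("Y", lost, retained, y_mz - WATER_MASS, True)
            emit("B", retained, lost, b_mz - WATER_MASS, True)
    out.sort(key=lambda f: f.mz)
    return out
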