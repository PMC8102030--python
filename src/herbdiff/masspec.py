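"""Formula-mass arithmetic and neutral-loss annotation for negative-mode ESI.

Marker peaks in the two chrysanthemum herbs are caffeoylquinic acids and
flavone glycosides, which in negative-mode electrospray give deprotonated
molecular ions [M-H]- and fragment by losing whole neutral residues
(caffeoyl, sugar residues, malonyl, CH3, CO2).  This module computes
monoisotopic masses from molecular formulas, the [M-H]- m/z, ppm mass
errors, and greedy neutral-loss assignments of fragment ions.

Formula parsing and monoisotopic element masses are delegated to
:mod:`pyteomics.mass`; the ionisation convention, ppm arithmetic and loss
assignment logic live here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from pyteomics import mass as _pmass

from .errors import ValidationError

__all__ = [
    "FormulaComposition",
    "LossLibraryEntry",
    "AnnotationResult",
    "DEFAULT_LOSS_LIBRARY",
    "parse_formula",
    "monoisotopic_mass",
    "deprotonated_mz",
    "ppm_error",
    "annotate_losses",
    "H_ATOM_MASS",
    "PROTON_MASS",
]

#: Hydrogen-atom mass used by the default [M-H]- convention.  The electron
#: mass is deliberately neglected: subtracting the H atom reproduces the
#: conventional 4-decimal values used in phytochemical tables (e.g.
#: C16H18O9 -> 353.0873), whereas the physically exact proton subtraction
#: gives 353.0878.
H_ATOM_MASS = 1.00783

#: Proton mass (H atom minus electron), for the rigorous convention.
PROTON_MASS = 1.00727646

_SUPPORTED_ELEMENTS = frozenset({"C", "H", "N", "O", "S"})


class FormulaComposition(dict):
    """Element -> count map for a molecular formula (C, H, N, O, S).

    A thin dict subclass; construct via :func:`parse_formula` or from a
    mapping.  Counts must be positive integers.
    """

    def __init__(self, counts):
        counts = dict(counts)
        for elem, n in counts.items():
            if elem not in _SUPPORTED_ELEMENTS:
                raise ValidationError(f"unsupported element {elem!r} (supported: C, H, N, O, S)")
            if not isinstance(n, int) or n <= 0:
                raise ValidationError(f"element count for {elem} must be a positive integer, got {n!r}")
        super().__init__(counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        order = [e for e in ("C", "H", "N", "O", "S") if e in self]
        return "".join(f"{e}{self[e]}" if self[e] > 1 else e for e in order)


def parse_formula(formula: str) -> FormulaComposition:
    """Parse a molecular-formula string such as ``"C16H18O9"``.

    Raises
    ------
    ValidationError
        If the formula does not parse or contains unsupported elements.
    """
    try:
        comp = _pmass.Composition(formula=formula)
    except Exception as exc:  # pyteomics raises PyteomicsError
        raise ValidationError(f"cannot parse formula {formula!r}: {exc}") from exc
    return FormulaComposition({e: int(n) for e, n in comp.items() if n})


def monoisotopic_mass(f: FormulaComposition | str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a formula, in Da."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(n * _pmass.nist_mass[e][0][0] for e, n in f.items())


def deprotonated_mz(f: FormulaComposition | str, electron_correct: bool = False) -> float:
    """m/z of the [M-H]- ion of a neutral molecule with formula ``f``.

    By default subtracts the hydrogen-atom mass (``H_ATOM_MASS``), the
    convention used throughout phytochemical identification tables; with
    ``electron_correct=True`` subtracts the proton mass instead, which is
    physically exact for a singly charged anion.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    if f.get("H", 0) < 1:
        raise ValidationError("cannot deprotonate a molecule with no hydrogen")
    delta = PROTON_MASS if electron_correct else H_ATOM_MASS
    return monoisotopic_mass(f) - delta


def ppm_error(observed: float, calculated: float) -> float:
    """Relative mass error in parts per million, 1e6*(obs - calc)/calc."""
    if calculated <= 0:
        raise ValidationError("calculated m/z must be positive")
    return 1e6 * (observed - calculated) / calculated


@dataclass(frozen=True)
class LossLibraryEntry:
    """A named neutral loss with its formula and monoisotopic mass."""

    name: str
    formula: FormulaComposition
    delta_mass: float

    def __post_init__(self):
        recomputed = monoisotopic_mass(self.formula)
        if abs(recomputed - self.delta_mass) > 1e-4:
            raise ValidationError(
                f"loss {self.name!r}: delta_mass {self.delta_mass} does not match "
                f"its formula mass {recomputed:.4f}"
            )


def _loss(name: str, formula: str) -> LossLibraryEntry:
    comp = parse_formula(formula)
    return LossLibraryEntry(name, comp, round(monoisotopic_mass(comp), 4))


#: Neutral losses observed in the fragmentation of caffeoylquinic acids and
#: flavone glycosides.  Every delta_mass is recomputed from its formula at
#: import time (and self-checked by the dataclass).
DEFAULT_LOSS_LIBRARY: tuple[LossLibraryEntry, ...] = (
    _loss("caffeoyl", "C9H6O3"),            # 162.0317
    _loss("glucose-residue", "C6H10O5"),    # 162.0528
    _loss("rhamnose-residue", "C6H10O4"),   # 146.0579
    _loss("glucuronide-residue", "C6H8O6"),  # 176.0321
    _loss("rutinose-residue", "C12H20O9"),  # 308.1107
    _loss("malonyl", "C3H2O3"),             # 86.0004
    _loss("CH3", "CH3"),                    # 15.0235
    _loss("CO2", "CO2"),                    # 43.9898
)


@dataclass
class AnnotationResult:
    """Outcome of annotating one precursor and its fragment ions."""

    observed_mz: float
    formula: FormulaComposition | None
    calc_mz: float | None
    ppm_error: float | None
    assigned_losses: list[tuple[float, str, float]] = field(default_factory=list)
    unassigned: list[float] = field(default_factory=list)


def annotate_losses(
    precursor_mz: float,
    fragments: list[float],
    library: tuple[LossLibraryEntry, ...] = DEFAULT_LOSS_LIBRARY,
    tol_ppm: float = 10.0,
    formula: FormulaComposition | str | None = None,
) -> AnnotationResult:
    """Assign neutral losses to fragment ions of a deprotonated precursor.

    For each fragment the mass difference to the precursor is matched
    greedily against every single loss and every unordered two-loss
    combination in the library; the candidate with the smallest residual
    (in ppm of the expected fragment m/z) within ``tol_ppm`` wins.
    Fragments with no match within tolerance are reported as unassigned.
    A fragment equal to the precursor is assigned "no loss" with residual 0.

    When ``formula`` is given, the precursor's calculated [M-H]- m/z and
    ppm error are included in the result.
    """
    for frag in fragments:
        if frag > precursor_mz + 1e-9:
            raise ValidationError(f"fragment m/z {frag} exceeds precursor {precursor_mz}")

    # single losses + unordered pairs (with repetition: e.g. 2x caffeoyl)
    candidates: list[tuple[str, float]] = [(e.name, e.delta_mass) for e in library]
    for a, b in itertools.combinations_with_replacement(library, 2):
        candidates.append((f"{a.name}+{b.name}", a.delta_mass + b.delta_mass))

    calc = ppm = None
    if formula is not None:
        calc = deprotonated_mz(formula)
        ppm = ppm_error(precursor_mz, calc)

    result = AnnotationResult(precursor_mz, parse_formula(formula) if isinstance(formula, str) else formula, calc, ppm)
    for frag in sorted(fragments, reverse=True):
        if abs(frag - precursor_mz) <= 1e-9:
            result.assigned_losses.append((frag, "no loss", 0.0))
            continue
        best: tuple[float, str] | None = None
        for name, delta in candidates:
            expected = precursor_mz - delta
            if expected <= 0:
                continue
            residual = ppm_error(frag, expected)
            if abs(residual) <= tol_ppm and (best is None or abs(residual) < abs(best[0])):
                best = (residual, name)
        if best is None:
            result.unassigned.append(frag)
        else:
            result.assigned_losses.append((frag, best[1], best[0]))
    return result
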