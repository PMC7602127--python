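"""Molecular-formula arithmetic and exact-mass dereplication.

Dereplication — recognizing already-known compounds among detected features
— is done by comparing observed feature m/z against theoretical adduct m/z
computed from a user-supplied reference table of compound names with
molecular formulas (or neutral monoisotopic masses) and expected adducts.

Ion m/z is computed as (M + Δ_adduct − z·mₑ)/|z| for z positive charges
(electrons removed), with the electron-mass correction exposed as a flag:
at four-decimal precision the correction (≈0.0005 Da per charge) is visible,
and published values mix both conventions.

Fragment matching additionally allows integer hydrogen-rearrangement
shifts: a candidate substructure of mass m matches an observed fragment at
m + k·1.007825 for small |k|, reflecting H transfers during fragmentation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .bucket import BucketTable, parse_key
from .errors import ParseError, ValidationError
from .masses import ELECTRON_MASS, HALOGENS, HYDROGEN_MASS, MONOISOTOPIC

__all__ = [
    "Formula",
    "ReferenceCompound",
    "Annotation",
    "DereplicationResult",
    "Adduct",
    "BUILTIN_ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "rdbe",
    "match_reference",
    "match_fragments",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental composition, e.g. {C: 27, H: 40, N: 2, O: 4}."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValidationError("formula must contain at least one element")
        for element, count in self.counts:
            if element not in MONOISOTOPIC:
                raise ParseError(f"unknown element symbol {element!r}")
            if count < 1:
                raise ValidationError(f"element count for {element} must be >= 1")

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return self.as_dict().get(element, 0)

    def __add__(self, other: "Formula") -> "Formula":
        merged = self.as_dict()
        for element, count in other.counts:
            merged[element] = merged.get(element, 0) + count
        return Formula(tuple(sorted(merged.items())))

    def __str__(self) -> str:
        return "".join(
            f"{el}{c if c > 1 else ''}" for el, c in self.counts
        )


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string like ``"C27H40N2O4"``."""
    text = text.strip()
    if not text:
        raise ParseError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ParseError(f"malformed formula {text!r} at position {pos}")
        element = match.group(1)
        if element not in MONOISOTOPIC:
            raise ParseError(f"unknown element symbol {element!r} in {text!r}")
        count = int(match.group(2)) if match.group(2) else 1
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
    if pos != len(text):
        raise ParseError(f"malformed formula {text!r} at position {pos}")
    return Formula(tuple(counts.items()))


def monoisotopic_mass(formula: Formula | str) -> float:
    """Sum of most-abundant-isotope atomic masses, in Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(MONOISOTOPIC[el] * count for el, count in formula.counts)


@dataclass(frozen=True)
class Adduct:
    """An ionization mode: name, neutral mass delta (Da) and signed charge."""

    name: str
    delta: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValidationError(f"adduct {self.name!r} must have nonzero charge")


BUILTIN_ADDUCTS: dict[str, Adduct] = {
    a.name: a
    for a in (
        Adduct("[M+H]+", MONOISOTOPIC["H"], +1),
        Adduct("[M+Na]+", MONOISOTOPIC["Na"], +1),
        Adduct("[M+K]+", MONOISOTOPIC["K"], +1),
        Adduct("[M+NH4]+", MONOISOTOPIC["N"] + 4 * MONOISOTOPIC["H"], +1),
        Adduct("[M+2H]2+", 2 * MONOISOTOPIC["H"], +2),
        Adduct("[M-H]-", -MONOISOTOPIC["H"], -1),
    )
}


def _resolve_adduct(adduct: str | Adduct) -> Adduct:
    if isinstance(adduct, Adduct):
        return adduct
    try:
        return BUILTIN_ADDUCTS[adduct]
    except KeyError:
        raise ValidationError(
            f"unknown adduct {adduct!r}; known: {sorted(BUILTIN_ADDUCTS)}"
        ) from None


def adduct_mz(
    compound: Formula | str | float,
    adduct: str | Adduct,
    electron_correction: bool = True,
) -> float:
    """Theoretical m/z of a neutral compound under a given adduct.

    ``compound`` may be a Formula, a formula string, or a neutral
    monoisotopic mass in Da. With ``electron_correction`` the mass of the
    electrons gained/lost on ionization is accounted for (z·mₑ removed for
    positive ions, added for negative ones).
    """
    spec = _resolve_adduct(adduct)
    if isinstance(compound, (int, float)):
        neutral = float(compound)
    else:
        neutral = monoisotopic_mass(compound)
    total = neutral + spec.delta
    if electron_correction:
        sign = 1 if spec.charge > 0 else -1
        total -= sign * abs(spec.charge) * ELECTRON_MASS
    return total / abs(spec.charge)


def rdbe(formula: Formula | str) -> float:
    """Ring-and-double-bond equivalents (degrees of unsaturation).

    RDBE = C + 1 + (N − H − halogens)/2; divalent elements (O, S) do not
    contribute. Computed for the standalone neutral formula.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    d = formula.as_dict()
    h_like = d.get("H", 0) + sum(d.get(x, 0) for x in HALOGENS)
    return d.get("C", 0) + 1 + (d.get("N", 0) - h_like) / 2.0


@dataclass
class ReferenceCompound:
    """One row of the user's reference spreadsheet."""

    name: str
    formula: Formula | None = None
    neutral_mass: float | None = None
    adducts: list[str] = field(default_factory=lambda: ["[M+H]+"])

    def __post_init__(self) -> None:
        if (self.formula is None) == (self.neutral_mass is None):
            raise ValidationError(
                f"reference {self.name!r}: exactly one of formula/neutral_mass required"
            )
        if self.neutral_mass is not None and self.neutral_mass <= 0:
            raise ValidationError(f"reference {self.name!r}: neutral_mass must be > 0")

    @property
    def mass(self) -> float:
        if self.neutral_mass is not None:
            return self.neutral_mass
        return monoisotopic_mass(self.formula)


@dataclass
class Annotation:
    """A putative identification of one feature as one compound adduct."""

    feature_key: str
    compound: str
    adduct: str
    observed_mz: float
    theoretical_mz: float

    @property
    def delta(self) -> float:
        return self.observed_mz - self.theoretical_mz


@dataclass
class DereplicationResult:
    """Annotations plus the features no reference compound explained."""

    annotations: list[Annotation]
    not_dereplicated: list[str]


def read_reference_csv(path) -> list[ReferenceCompound]:
    """Load a reference table CSV: name,formula,neutral_mass,adducts.

    ``adducts`` is a semicolon-separated list of adduct names; exactly one
    of ``formula``/``neutral_mass`` must be filled per row.
    """
    import csv as _csv

    refs = []
    with open(path, newline="") as fh:
        reader = _csv.DictReader(fh)
        required = {"name", "formula", "neutral_mass", "adducts"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(
                f"{path}: reference CSV must have columns {sorted(required)}"
            )
        for row in reader:
            formula_s = (row["formula"] or "").strip()
            mass_s = (row["neutral_mass"] or "").strip()
            adducts = [a.strip() for a in (row["adducts"] or "").split(";") if a.strip()]
            refs.append(
                ReferenceCompound(
                    name=row["name"].strip(),
                    formula=parse_formula(formula_s) if formula_s else None,
                    neutral_mass=float(mass_s) if mass_s else None,
                    adducts=adducts or ["[M+H]+"],
                )
            )
    names = [r.name for r in refs]
    if len(set(names)) != len(names):
        raise ValidationError(f"{path}: duplicate reference compound names")
    return refs


def match_reference(
    table: BucketTable,
    refs: list[ReferenceCompound],
    mz_tol: float,
    rt_window: tuple[float, float] | None = None,
    electron_correction: bool = True,
) -> DereplicationResult:
    """Dereplicate bucket-table features against a reference set.

    For every feature and every (compound, adduct) pair, an annotation is
    emitted when |observed − theoretical| ≤ ``mz_tol``. A feature may carry
    several annotations; features matching nothing are reported as not
    dereplicated. ``rt_window``, when given, restricts matching to features
    whose rt centroid falls inside it.
    """
    if mz_tol < 0:
        raise ValidationError("mz_tol must be >= 0")
    theoretical = [
        (ref.name, adduct, adduct_mz(ref.mass, adduct, electron_correction))
        for ref in refs
        for adduct in ref.adducts
    ]
    annotations: list[Annotation] = []
    not_derep: list[str] = []
    for key in table.feature_keys:
        mz, rt = parse_key(key)
        if rt_window is not None and rt is not None:
            if not rt_window[0] <= rt <= rt_window[1]:
                not_derep.append(key)
                continue
        hits = [
            Annotation(key, name, adduct, mz, theo)
            for name, adduct, theo in theoretical
            if abs(mz - theo) <= mz_tol
        ]
        if hits:
            annotations.extend(hits)
        else:
            not_derep.append(key)
    return DereplicationResult(annotations=annotations, not_dereplicated=not_derep)


def match_fragments(
    observed: list[tuple[float, float]],
    candidates: list[tuple[str, float]],
    mz_tol: float,
    max_h_shifts: int = 0,
) -> list[tuple[str, float, int, float]]:
    """Match observed fragment peaks to candidate substructure masses.

    A candidate of mass m matches an observed peak at m + k·1.007825 for
    any integer |k| ≤ ``max_h_shifts`` (hydrogen rearrangements). For each
    candidate the match with the smallest |k| (ties: smallest |delta|) is
    reported as (label, matched m/z, h_shift k, delta).
    """
    if max_h_shifts < 0:
        raise ValidationError("max_h_shifts must be >= 0")
    results = []
    for label, mass in candidates:
        best = None
        for mz, _intensity in observed:
            for k in range(-max_h_shifts, max_h_shifts + 1):
                delta = mz - (mass + k * HYDROGEN_MASS)
                if abs(delta) <= mz_tol:
                    cand = (abs(k), abs(delta), label, mz, k, delta)
                    if best is None or cand[:2] < best[:2]:
                        best = cand
        if best is not None:
            results.append((best[2], best[3], best[4], best[5]))
    return results
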