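"""Monoisotopic mass arithmetic for residues, substitutions, and modifications.

This module is the search-design layer of the pipeline: it defines the mass
deltas used to detect amino-acid substitutions (e.g. serine misincorporated
at valine codons shifts the peptide mass by about -12.0364 Da) and the fixed
and variable chemical modifications carried by a typical database search
(cysteine carbamidomethylation, methionine oxidation, N-terminal
acetylation).  All masses are neutral monoisotopic masses in daltons,
computed from hard-coded elemental isotope masses so results are
reproducible without any external resource.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ELEMENT_MASS",
    "RESIDUE_FORMULA",
    "RESIDUE_MASS",
    "WATER_MASS",
    "SubstitutionSpec",
    "ModificationSpec",
    "MODIFICATIONS",
    "substitution_delta",
    "substitution",
    "modification_mass",
    "peptide_mass",
    "within_ppm",
    "all_substitutions",
    "collision_scan",
    "write_substitution_table",
]

# Monoisotopic masses of the light isotopes (Da), IUPAC/AME values.
ELEMENT_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

# Residue (i.e. dehydrated) elemental compositions of the 20 canonical
# amino acids.
RESIDUE_FORMULA: Mapping[str, Mapping[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}


def formula_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental composition, in Da."""
    return sum(ELEMENT_MASS[el] * n for el, n in formula.items())


#: Monoisotopic residue masses (Da) of the 20 canonical amino acids.
RESIDUE_MASS: Mapping[str, float] = {
    aa: formula_mass(f) for aa, f in RESIDUE_FORMULA.items()
}

#: Mass of a water molecule (Da); a peptide's neutral mass is the sum of
#: its residue masses plus one water.
WATER_MASS: float = formula_mass({"H": 2, "O": 1})

CANONICAL_RESIDUES = frozenset(RESIDUE_MASS)


@dataclass(frozen=True)
class SubstitutionSpec:
    """An origin -> destination amino-acid substitution and its mass delta.

    ``delta`` is mass(to_aa) - mass(from_aa) and may be negative: serine is
    lighter than both valine and threonine, so V->S and T->S searches look
    for peptides about 12 and 14 Da lighter than their wild-type forms.
    """

    from_aa: str
    to_aa: str
    delta: float
    label: str

    def __post_init__(self) -> None:
        _check_residue(self.from_aa)
        _check_residue(self.to_aa)
        if self.from_aa == self.to_aa:
            raise ValueError(
                f"identity substitution {self.from_aa}->{self.to_aa} is not allowed"
            )
        expected = RESIDUE_MASS[self.to_aa] - RESIDUE_MASS[self.from_aa]
        if abs(self.delta - expected) > 1e-6:
            raise ValueError(
                f"delta {self.delta!r} inconsistent with residue masses "
                f"for {self.from_aa}->{self.to_aa} (expected {expected!r})"
            )


@dataclass(frozen=True)
class ModificationSpec:
    """A chemical modification: a named mass delta on a residue or terminus.

    ``fixed`` modifications (e.g. carbamidomethyl-C) apply to every
    occurrence of the target; variable ones may or may not be present.
    """

    name: str
    target: str  # residue one-letter code, "N-term" or "C-term"
    delta: float
    fixed: bool = False


def _check_residue(aa: str) -> None:
    if aa not in CANONICAL_RESIDUES:
        raise ValueError(f"unknown residue code {aa!r}")


# Registry of common modifications: name -> (elemental delta, default
# target, fixed-by-default).  Deltas are computed from composition, never
# typed in as decimals.
_MOD_FORMULAS: Mapping[str, tuple[Mapping[str, int], str, bool]] = {
    "carbamidomethyl": ({"C": 2, "H": 3, "N": 1, "O": 1}, "C", True),
    "oxidation": ({"O": 1}, "M", False),
    "acetyl": ({"C": 2, "H": 2, "O": 1}, "N-term", False),
    "methyl": ({"C": 1, "H": 2}, "K", False),
    "dimethyl": ({"C": 2, "H": 4}, "K", False),
    "trimethyl": ({"C": 3, "H": 6}, "K", False),
    "phospho": ({"H": 1, "P": 1, "O": 3}, "S", False),
    "deamidation": ({"H": -1, "N": -1, "O": 1}, "N", False),
}

#: Built-in modification registry keyed by name.
MODIFICATIONS: Mapping[str, ModificationSpec] = {
    name: ModificationSpec(name, target, formula_mass(f), fixed)
    for name, (f, target, fixed) in _MOD_FORMULAS.items()
}


def substitution_delta(from_aa: str, to_aa: str) -> float:
    """Mass shift (Da) caused by replacing ``from_aa`` with ``to_aa``.

    >>> round(substitution_delta("V", "S"), 4)
    -12.0364
    """
    _check_residue(from_aa)
    _check_residue(to_aa)
    if from_aa == to_aa:
        raise ValueError("identity substitution has no mass delta")
    return RESIDUE_MASS[to_aa] - RESIDUE_MASS[from_aa]


def substitution(from_aa: str, to_aa: str, label: str | None = None) -> SubstitutionSpec:
    """Build a :class:`SubstitutionSpec` from the built-in mass table."""
    delta = substitution_delta(from_aa, to_aa)
    return SubstitutionSpec(
        from_aa, to_aa, delta, label if label is not None else f"{from_aa}->{to_aa}"
    )


def modification_mass(name: str) -> float:
    """Monoisotopic delta (Da) of a named modification from the registry."""
    try:
        return MODIFICATIONS[name].delta
    except KeyError:
        raise ValueError(
            f"unknown modification {name!r}; known: {sorted(MODIFICATIONS)}"
        ) from None


def peptide_mass(
    sequence: str, mods: Iterable[tuple[int, float]] | None = None
) -> float:
    """Neutral monoisotopic mass of a peptide with optional position deltas.

    ``mods`` is an iterable of (0-based position, delta Da) pairs; positions
    must fall inside the sequence.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    mass = WATER_MASS
    for aa in sequence:
        _check_residue(aa)
        mass += RESIDUE_MASS[aa]
    if mods is not None:
        n = len(sequence)
        for pos, delta in mods:
            if not 0 <= pos < n:
                raise ValueError(f"modification position {pos} outside peptide of length {n}")
            mass += delta
    return mass


def within_ppm(observed: float, theoretical: float, tol_ppm: float) -> bool:
    """True iff |observed - theoretical| is within ``tol_ppm`` parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return abs(observed - theoretical) / theoretical * 1e6 <= tol_ppm


def all_substitutions() -> list[SubstitutionSpec]:
    """All 380 ordered single-residue substitutions with their deltas."""
    residues = sorted(CANONICAL_RESIDUES)
    return [
        substitution(a, b) for a in residues for b in residues if a != b
    ]


def collision_scan(
    spec: SubstitutionSpec,
    tol: float,
    registry: Sequence[SubstitutionSpec | ModificationSpec] | None = None,
) -> list[SubstitutionSpec | ModificationSpec]:
    """Find registry entries nearly isobaric with ``spec``'s delta.

    A substitution search is blind to any other substitution or
    modification whose mass delta falls within the instrument tolerance of
    the one searched for (e.g. T->A is within a millidalton of V->S), so
    candidate identifications overlapping this list warrant manual spectrum
    inspection.  ``registry`` defaults to all 380 substitutions plus the
    built-in modifications; ``spec`` itself is excluded.
    """
    if tol < 0:
        raise ValueError("tolerance must be nonnegative")
    if registry is None:
        registry = list(all_substitutions()) + list(MODIFICATIONS.values())
    hits = [
        entry
        for entry in registry
        if entry != spec and abs(entry.delta - spec.delta) <= tol
    ]
    hits.sort(key=lambda e: (abs(e.delta - spec.delta), _entry_key(e)))
    return hits


def _entry_key(entry: SubstitutionSpec | ModificationSpec) -> str:
    if isinstance(entry, SubstitutionSpec):
        return f"sub:{entry.from_aa}{entry.to_aa}"
    return f"mod:{entry.name}"


def write_substitution_table(path: str) -> None:
    """Export the 380-pair substitution delta registry as a TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("from\tto\tdelta_da\n")
        for spec in all_substitutions():
            fh.write(f"{spec.from_aa}\t{spec.to_aa}\t{spec.delta:.6f}\n")
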