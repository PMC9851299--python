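"""Monoisotopic mass arithmetic for residues, modifications and fragment ions.

Every downstream comparison in this package — amino-acid matching, fragment
annotation, spectrum simulation — reduces to arithmetic over monoisotopic
residue masses and cumulative prefix masses.  This module owns that
arithmetic: the residue/modification mass table, the modified-peptide
container with its canonical string syntax, and the m/z formulas for the
eight HCD fragment ion types (b, b2+, b-NH3, b-H2O, y, y2+, y-NH3, y-H2O).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from pyteomics import mass as _ptmass

__all__ = [
    "PROTON",
    "WATER",
    "AMMONIA",
    "MassTable",
    "Residue",
    "ModifiedPeptide",
    "ToleranceConfig",
    "ION_TYPES",
    "residue_mass",
    "prefix_masses",
    "neutral_mass",
    "precursor_mz",
    "fragment_mz",
]

#: Monoisotopic mass of a proton (Da).
PROTON: float = _ptmass.nist_mass["H+"][0][0]
#: Monoisotopic mass of water (Da), the terminal groups of a peptide.
WATER: float = _ptmass.calculate_mass(formula="H2O")
#: Monoisotopic mass of ammonia (Da), lost by b-NH3/y-NH3 ions.
AMMONIA: float = _ptmass.calculate_mass(formula="NH3")

#: The eight fragment ion types considered throughout the package.
ION_TYPES: tuple[str, ...] = (
    "b", "b2+", "b-NH3", "b-H2O", "y", "y2+", "y-NH3", "y-H2O",
)

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class UnknownTokenError(ValueError):
    """A residue code or modification name not present in the mass table."""


@dataclass(frozen=True)
class MassTable:
    """Residue and modification monoisotopic masses.

    The default table takes the 20 standard residue masses from pyteomics
    and carries the three modifications used for antibody digests:
    carbamidomethylation of cysteine (fixed, +57.021464 Da), oxidation of
    methionine (+15.994915 Da) and deamidation of asparagine/glutamine
    (+0.984016 Da).  Full-precision deltas are stored; rounding to two
    decimals yields the conventional +57.02 / +15.99 / +0.98 labels.
    """

    residue_masses: dict[str, float] = field(
        default_factory=lambda: {
            aa: _ptmass.std_aa_mass[aa] for aa in _STANDARD_RESIDUES
        }
    )
    modification_deltas: dict[str, float] = field(
        default_factory=lambda: {
            "carbamidomethyl": 57.021464,
            "oxidation": 15.994915,
            "deamidation": 0.984016,
        }
    )
    proton_mass: float = PROTON
    water_mass: float = WATER

    def __post_init__(self) -> None:
        missing = set(_STANDARD_RESIDUES) - set(self.residue_masses)
        if missing:
            raise ValueError(f"mass table lacks standard residues: {sorted(missing)}")
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("residue masses must be positive")

    def residue_mass(self, code: str, modification: str | None = None) -> float:
        if code not in self.residue_masses:
            raise UnknownTokenError(f"unknown residue code {code!r}")
        mass = self.residue_masses[code]
        if modification is not None:
            if modification not in self.modification_deltas:
                raise UnknownTokenError(f"unknown modification {modification!r}")
            mass += self.modification_deltas[modification]
        return mass


#: A single peptide position: one-letter residue code plus optional
#: modification name (a key of ``MassTable.modification_deltas``).
Residue = tuple[str, str | None]

_RESIDUE_RE = re.compile(r"([A-Z])(?:\[([+-]\d+(?:\.\d+)?)\])?")


@dataclass(frozen=True)
class ModifiedPeptide:
    """An ordered sequence of (residue, modification) positions.

    The canonical string syntax writes each modification as a bracketed
    signed delta rounded to two decimals after the residue letter, e.g.
    ``C[+57.02]``, ``M[+15.99]``, ``N[+0.98]``.  ``parse`` and ``format``
    round-trip exactly.
    """

    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("peptide must contain at least one residue")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def plain_sequence(self) -> str:
        """Residue letters with modifications stripped."""
        return "".join(code for code, _ in self.residues)

    @classmethod
    def from_plain(cls, sequence: str) -> "ModifiedPeptide":
        return cls(tuple((aa, None) for aa in sequence))

    @classmethod
    def parse(cls, text: str, table: MassTable | None = None) -> "ModifiedPeptide":
        table = table or DEFAULT_MASS_TABLE
        residues: list[Residue] = []
        pos = 0
        while pos < len(text):
            m = _RESIDUE_RE.match(text, pos)
            if m is None:
                raise ValueError(
                    f"malformed peptide string {text!r} at offset {pos}"
                )
            code, delta = m.group(1), m.group(2)
            mod: str | None = None
            if delta is not None:
                mod = _delta_to_name(float(delta), table)
                if mod is None:
                    raise UnknownTokenError(
                        f"no modification with delta {delta} Da in mass table"
                    )
            residues.append((code, mod))
            pos = m.end()
        return cls(tuple(residues))

    def format(self, table: MassTable | None = None) -> str:
        table = table or DEFAULT_MASS_TABLE
        parts = []
        for code, mod in self.residues:
            if mod is None:
                parts.append(code)
            else:
                delta = table.modification_deltas[mod]
                parts.append(f"{code}[{delta:+.2f}]")
        return "".join(parts)

    def __str__(self) -> str:
        return self.format()


def _delta_to_name(delta: float, table: MassTable) -> str | None:
    for name, value in table.modification_deltas.items():
        if abs(round(value, 2) - delta) < 5e-3:
            return name
    return None


DEFAULT_MASS_TABLE = MassTable()


@dataclass(frozen=True)
class ToleranceConfig:
    """The mass tolerances used across the evaluation.

    aa_mass_tol: residue-mass agreement for an amino-acid match (Da).
    prefix_mass_tol: prefix-mass agreement for positional alignment (Da).
    fragment_tol: peak-to-theoretical-ion matching in annotation (Da).
    precursor_tol_ppm: precursor m/z agreement (ppm).
    fragment_sim_tol: maximum m/z deviation of simulated fragment peaks (Da).
    """

    aa_mass_tol: float = 0.1
    prefix_mass_tol: float = 0.5
    fragment_tol: float = 0.5
    precursor_tol_ppm: float = 10.0
    fragment_sim_tol: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "aa_mass_tol", "prefix_mass_tol", "fragment_tol",
            "precursor_tol_ppm", "fragment_sim_tol",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def residue_mass(
    residue: Residue, table: MassTable = DEFAULT_MASS_TABLE
) -> float:
    """Monoisotopic mass of one (residue, modification) position in Da."""
    code, modification = residue
    return table.residue_mass(code, modification)


def residue_masses(
    peptide: ModifiedPeptide, table: MassTable = DEFAULT_MASS_TABLE
) -> np.ndarray:
    """Per-position residue masses as a float array."""
    return np.array([table.residue_mass(c, m) for c, m in peptide], dtype=float)


def prefix_masses(
    peptide: ModifiedPeptide, table: MassTable = DEFAULT_MASS_TABLE
) -> np.ndarray:
    """Cumulative residue masses: element i is the mass of positions 1..i+1.

    The last element equals the neutral peptide mass minus water.
    """
    return np.cumsum(residue_masses(peptide, table))


def neutral_mass(
    peptide: ModifiedPeptide, table: MassTable = DEFAULT_MASS_TABLE
) -> float:
    """Neutral monoisotopic peptide mass: sum of residues plus water."""
    return float(residue_masses(peptide, table).sum() + table.water_mass)


def precursor_mz(
    peptide: ModifiedPeptide, charge: int, table: MassTable = DEFAULT_MASS_TABLE
) -> float:
    """m/z of the [M + zH]z+ precursor ion."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass(peptide, table) + charge * table.proton_mass) / charge


def fragment_mz(
    peptide: ModifiedPeptide,
    site: int,
    ion_type: str,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> float:
    """m/z of one fragment ion at a backbone cleavage site.

    ``site`` counts cleavage positions 1..len-1: site i separates the
    N-terminal prefix of i residues (b ions) from the C-terminal suffix
    (y ions).  Doubly charged variants divide the protonated mass by two;
    neutral-loss variants subtract NH3 or H2O from the singly charged ion.
    """
    n = len(peptide)
    if not 1 <= site <= n - 1:
        raise ValueError(f"site must be in 1..{n - 1}, got {site}")
    if ion_type not in ION_TYPES:
        raise ValueError(f"unknown ion type {ion_type!r}; expected one of {ION_TYPES}")

    prefix = float(prefix_masses(peptide, table)[site - 1])
    total = neutral_mass(peptide, table)
    b1 = prefix + table.proton_mass
    y1 = (total - prefix) + table.proton_mass

    series, _, loss = ion_type.partition("-")
    base = b1 if series.startswith("b") else y1
    if series in ("b2+", "y2+"):
        # neutral fragment mass + 2 protons, divided by charge 2
        return (base - table.proton_mass + 2 * table.proton_mass) / 2
    if loss == "NH3":
        return base - AMMONIA
    if loss == "H2O":
        return base - table.water_mass
    return base


def theoretical_fragments(
    peptide: ModifiedPeptide,
    table: MassTable = DEFAULT_MASS_TABLE,
    ion_types: Sequence[str] = ION_TYPES,
) -> dict[int, dict[str, float]]:
    """All theoretical fragment m/z values, keyed by site then ion type."""
    return {
        site: {ion: fragment_mz(peptide, site, ion, table) for ion in ion_types}
        for site in range(1, len(peptide))
    }
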