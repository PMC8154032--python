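"""Peptide mass arithmetic: monoisotopic masses, m/z, modifications, b/y ions.

All masses are monoisotopic (the substrates were measured on high-resolution
Orbitrap instruments).  A peptide's neutral mass is the sum of its residue
masses plus one water; an ion of charge z appears at (M + z*m_proton)/z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

from .core import validate_sequence
from .errors import InvalidChargeError, ModificationCountError, ParameterError

#: Monoisotopic residue masses in Da (residue = amino acid minus water).
RESIDUE_MASSES = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_MASS = 18.010565  # H2O, Da
PROTON_MASS = 1.007276  # H+, Da


def monoisotopic_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of ``sequence`` (empty string -> one water)."""
    validate_sequence(sequence)
    return sum(RESIDUE_MASSES[aa] for aa in sequence) + WATER_MASS


def mz_values(mass: float, charges: Sequence[int]) -> List[float]:
    """m/z of the [M + zH]^z+ ions for each charge in ``charges``."""
    if mass <= 0:
        raise ParameterError(f"mass must be > 0, got {mass}")
    out = []
    for z in charges:
        if z <= 0:
            raise InvalidChargeError(f"charge must be positive, got {z}")
        out.append((mass + z * PROTON_MASS) / z)
    return out


@dataclass(frozen=True)
class Modification:
    """A chemical modification applied post-cleavage (e.g. oxidation)."""

    name: str
    delta_mass: float
    max_count: int = 1

    def __post_init__(self) -> None:
        if self.max_count < 1:
            raise ParameterError(f"max_count must be >= 1, got {self.max_count}")


#: Default modification set: oxidation (+O) only.
OXIDATION = Modification("oxidation", 15.99491, max_count=1)
DEFAULT_MODIFICATIONS: Tuple[Modification, ...] = (OXIDATION,)


def modified_mass(sequence: str, mods: Iterable[Tuple[Modification, int]]) -> float:
    """Neutral mass of ``sequence`` carrying ``count`` copies of each modifier."""
    mass = monoisotopic_mass(sequence)
    for mod, count in mods:
        if count > mod.max_count:
            raise ModificationCountError(
                f"{count} copies of {mod.name} exceeds max_count {mod.max_count}"
            )
        mass += count * mod.delta_mass
    return mass


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical backbone fragment ion (b or y series)."""

    series: str  # "b" or "y"
    index: int
    charge: int
    mz: float


def theoretical_fragment_ions(sequence: str,
                              charges: Sequence[int] = (1,)) -> List[FragmentIon]:
    """All b_n / y_n ions for n = 1..len-1 at the requested charges, sorted by m/z.

    b_n carries the first n residues (no water); y_n carries the last n
    residues plus water.  Only singly and doubly charged fragments are
    meaningful for the CID/HCD spectra modeled here.
    """
    validate_sequence(sequence)
    n = len(sequence)
    if n < 2:
        raise ParameterError(f"need length >= 2 to fragment, got {n}")
    for z in charges:
        if z not in (1, 2):
            raise InvalidChargeError(f"fragment charge must be 1 or 2, got {z}")
    prefix = [0.0]
    for aa in sequence:
        prefix.append(prefix[-1] + RESIDUE_MASSES[aa])
    total = prefix[-1]
    ions: List[FragmentIon] = []
    for idx in range(1, n):
        b_neutral = prefix[idx]
        y_neutral = total - prefix[n - idx] + WATER_MASS
        for z in charges:
            ions.append(FragmentIon("b", idx, z, (b_neutral + z * PROTON_MASS) / z))
            ions.append(FragmentIon("y", idx, z, (y_neutral + z * PROTON_MASS) / z))
    ions.sort(key=lambda ion: ion.mz)
    return ions


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz
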