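"""Coordinate algebra for substrates, cleavage products, and splice products.

The proteasome degrades a polypeptide substrate into contiguous cleavage
products (PCPs) and can additionally ligate two excised fragments into a
splice product (PSP) whose sequence is absent from the parent protein.
Everything downstream (database generation, MS assignment) is built on the
coordinate conventions defined here:

* Coordinates are 1-based, inclusive, and expressed in FULL-PROTEIN
  numbering.  A :class:`Substrate` carries an ``offset`` — the protein
  coordinate of its first residue — so that, e.g., the KRAS 2-14 substrate
  has residue 5 at local position 4.
* A cleavage product ``P(i, j)`` is the contiguous fragment from residue
  ``i`` through ``j`` (length ``j - i + 1``).
* A splice product ``SP(i, j, k, l)`` is the concatenation of an acceptor
  fragment ``P(i, j)`` followed by a donor fragment ``P(k, l)``; its length
  is ``j + l - i - k + 2``.  The product sequence is always acceptor-first;
  "inverse order" refers to the fragments' positions in the substrate, not
  to the order of ligation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import InvalidCoordinateError, ParameterError, UnknownResidueError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

ORDER_NORMAL = "normal"
ORDER_INVERSE = "inverse"
ORDER_OVERLAPPING = "overlapping"
ORDER_TRANS = "trans"

ORDER_MODE_NORMAL = "normal"
ORDER_MODE_NORMAL_INVERSE = "normal+inverse"
ORDER_MODE_ALL = "all"
ORDER_MODES = (ORDER_MODE_NORMAL, ORDER_MODE_NORMAL_INVERSE, ORDER_MODE_ALL)


def validate_sequence(sequence: str) -> None:
    """Raise :class:`UnknownResidueError` unless ``sequence`` uses the 20-letter alphabet."""
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise UnknownResidueError(
            f"non-standard residue(s) {sorted(bad)} in sequence {sequence!r}"
        )


@dataclass(frozen=True)
class Substrate:
    """A synthetic polypeptide substrate in full-protein numbering.

    Parameters
    ----------
    id : str
        Short label, e.g. ``"KRAS_G12V_2-14"``.
    sequence : str
        Amino-acid sequence, uppercase, 20-letter alphabet.
    offset : int
        Protein coordinate of the first residue (>= 1).
    """

    id: str
    sequence: str
    offset: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise UnknownResidueError("substrate sequence must be nonempty")
        validate_sequence(self.sequence)
        if self.offset < 1:
            raise ParameterError(f"offset must be >= 1, got {self.offset}")

    @property
    def L(self) -> int:
        return len(self.sequence)

    @property
    def start(self) -> int:
        return self.offset

    @property
    def end(self) -> int:
        """Protein coordinate of the last residue."""
        return self.offset + self.L - 1

    def to_local(self, coord: int) -> int:
        """Protein coordinate -> 1-based local position."""
        if not (self.start <= coord <= self.end):
            raise InvalidCoordinateError(
                f"coordinate {coord} outside substrate {self.id} "
                f"[{self.start}, {self.end}]"
            )
        return coord - self.offset + 1

    def to_protein(self, local: int) -> int:
        """1-based local position -> protein coordinate."""
        if not (1 <= local <= self.L):
            raise InvalidCoordinateError(
                f"local position {local} outside [1, {self.L}] for {self.id}"
            )
        return self.offset + local - 1

    def residue(self, coord: int) -> str:
        return self.sequence[self.to_local(coord) - 1]

    def subsequence(self, i: int, j: int) -> str:
        """Residues ``i..j`` inclusive, protein coordinates."""
        if i > j:
            raise InvalidCoordinateError(f"require i <= j, got ({i}, {j})")
        return self.sequence[self.to_local(i) - 1 : self.to_local(j)]


@dataclass(frozen=True)
class CleavageProduct:
    """A contiguous proteasomal cleavage product P(i, j)."""

    substrate_id: str
    i: int
    j: int
    sequence: str

    @property
    def length(self) -> int:
        return self.j - self.i + 1

    @classmethod
    def from_substrate(cls, substrate: Substrate, i: int, j: int) -> "CleavageProduct":
        return cls(substrate.id, i, j, substrate.subsequence(i, j))


@dataclass(frozen=True)
class SpliceProduct:
    """A proteasomal splice product SP(i, j, k, l): P(i, j) ligated to P(k, l).

    ``donor_substrate_id`` is set only for trans products, where the donor
    fragment comes from a second substrate molecule.
    """

    substrate_id: str
    i: int
    j: int
    k: int
    l: int
    order: str
    sequence: str
    donor_substrate_id: Optional[str] = None

    @property
    def length(self) -> int:
        return self.j + self.l - self.i - self.k + 2

    @property
    def acceptor_length(self) -> int:
        return self.j - self.i + 1

    @property
    def donor_length(self) -> int:
        return self.l - self.k + 1

    @property
    def gap(self) -> Optional[int]:
        """Residues skipped between the fragments in substrate space.

        ``k - j - 1`` for normal order, ``i - l - 1`` for inverse order,
        undefined (None) for overlapping and trans products.
        """
        if self.order == ORDER_NORMAL:
            return self.k - self.j - 1
        if self.order == ORDER_INVERSE:
            return self.i - self.l - 1
        return None


def classify_order(i: int, j: int, k: int, l: int,
                   substrate: Optional[Substrate] = None) -> str:
    """Classify the relative arrangement of the fragments P(i,j) and P(k,l).

    normal       acceptor strictly upstream of donor (j < k)
    inverse      acceptor strictly downstream of donor (l < i)
    overlapping  the fragments share >= 1 position (max(i,k) <= min(j,l))

    The three classes partition all coordinate pairs from one substrate.
    """
    if i > j or k > l:
        raise InvalidCoordinateError(
            f"require i <= j and k <= l, got ({i},{j},{k},{l})"
        )
    if substrate is not None:
        for c in (i, j, k, l):
            substrate.to_local(c)  # bounds check
    if j < k:
        return ORDER_NORMAL
    if l < i:
        return ORDER_INVERSE
    # not disjoint in either direction => intervals intersect
    assert max(i, k) <= min(j, l)
    return ORDER_OVERLAPPING


def spliced_length(i: int, j: int, k: int, l: int) -> int:
    """Length of SP(i, j, k, l): ``j + l - i - k + 2``."""
    if i > j or k > l:
        raise InvalidCoordinateError(
            f"require i <= j and k <= l, got ({i},{j},{k},{l})"
        )
    return j + l - i - k + 2


def assemble_spliced_sequence(substrate: Substrate, i: int, j: int,
                              k: int, l: int,
                              donor_substrate: Optional[Substrate] = None) -> str:
    """Sequence of SP(i, j, k, l): acceptor P(i, j) then donor P(k, l).

    For trans products pass the donor's substrate separately.
    """
    donor_sub = donor_substrate if donor_substrate is not None else substrate
    return substrate.subsequence(i, j) + donor_sub.subsequence(k, l)


def make_splice_product(substrate: Substrate, i: int, j: int, k: int, l: int,
                        donor_substrate: Optional[Substrate] = None) -> SpliceProduct:
    """Build a fully classified :class:`SpliceProduct` from coordinates."""
    if donor_substrate is not None and donor_substrate.id != substrate.id:
        order = ORDER_TRANS
        seq = assemble_spliced_sequence(substrate, i, j, k, l, donor_substrate)
        return SpliceProduct(substrate.id, i, j, k, l, order, seq,
                             donor_substrate_id=donor_substrate.id)
    order = classify_order(i, j, k, l, substrate)
    seq = assemble_spliced_sequence(substrate, i, j, k, l)
    return SpliceProduct(substrate.id, i, j, k, l, order, seq)


@dataclass(frozen=True)
class EnumerationParams:
    """Search-space limits for splice-product enumeration.

    Attributes
    ----------
    min_part, max_part : int
        Length bounds for each of the two fragments (MinP/MaxP).
    min_gap, max_gap : int / int or None
        Bounds on the number of substrate residues skipped between the
        fragments (MinG/MaxG); ``max_gap=None`` means unbounded.  Gaps apply
        to normal- and inverse-order products only.  Contiguous normal-order
        products (j + 1 = k) are always excluded — they are identical to the
        plain cleavage product P(i, l) — so the effective minimum gap for
        normal order is max(min_gap, 1).
    min_len, max_len : int
        Length bounds on the whole splice product (MinS/MaxS).
    include_pcps : bool
        Whether database construction should also emit plain cleavage
        products (recommended).
    exclude_substrate_substrings : bool
        Suppress splice products whose sequence occurs contiguously in the
        substrate (they are indistinguishable from cleavage products).
    order_mode : str
        ``"normal"``, ``"normal+inverse"``, or ``"all"`` (adds overlapping
        products; trans products across two substrates are enumerated by a
        dedicated function since they need a partner substrate).
    """

    min_part: int
    max_part: int
    min_len: int
    max_len: int
    min_gap: int = 0
    max_gap: Optional[int] = None
    include_pcps: bool = True
    exclude_substrate_substrings: bool = True
    order_mode: str = ORDER_MODE_NORMAL_INVERSE

    def __post_init__(self) -> None:
        if not (1 <= self.min_part <= self.max_part):
            raise ParameterError(
                f"require 1 <= min_part <= max_part, got ({self.min_part}, {self.max_part})"
            )
        if self.min_gap < 0:
            raise ParameterError(f"min_gap must be >= 0, got {self.min_gap}")
        if self.max_gap is not None and self.max_gap < self.min_gap:
            raise ParameterError(
                f"require min_gap <= max_gap, got ({self.min_gap}, {self.max_gap})"
            )
        if not (2 * self.min_part <= self.min_len <= self.max_len):
            raise ParameterError(
                f"require 2*min_part <= min_len <= max_len, got "
                f"min_part={self.min_part}, min_len={self.min_len}, max_len={self.max_len}"
            )
        if self.order_mode not in ORDER_MODES:
            raise ParameterError(
                f"order_mode must be one of {ORDER_MODES}, got {self.order_mode!r}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "EnumerationParams":
        return cls(**d)
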