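"""Splice-product database generation: enumeration, size prediction, FASTA I/O.

Given a substrate of length L there are L(L+1)/2 contiguous fragments and
hence (L(L+1)/2)^2 ordered fragment pairs — about 25.5 million for L = 100 —
so databases are streamed record by record, and an analytic size predictor
is provided to decide whether enumeration is worthwhile at all.

Enumeration rules (cis products):

* both fragment lengths in [min_part, max_part], total length in
  [min_len, max_len];
* normal order (acceptor upstream of donor): gap ``k - j - 1`` in
  [max(min_gap, 1), max_gap] — contiguous products (j + 1 = k) are never
  emitted because they are identical to the plain cleavage product P(i, l);
* inverse order (acceptor downstream): gap ``i - l - 1`` in
  [min_gap, max_gap] — an adjacency in inverse order is a genuine sequence
  rearrangement, so gap 0 is allowed;
* overlapping products (fragments sharing positions) only in order_mode
  ``"all"``; no gap constraint applies to them;
* optionally, products whose sequence occurs contiguously in the substrate
  are suppressed (they cannot be distinguished from cleavage products by
  mass spectrometry), while equal-sequence products at *different*
  coordinates are all retained — fragment-level evidence can later favor
  one coordinate version over another.

Output order is deterministic: by total length, then acceptor length, then
acceptor start, then donor start.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, TextIO, Tuple, Union

import pandas as pd

from .chemistry import monoisotopic_mass, mz_values
from .core import (
    ORDER_INVERSE,
    ORDER_MODE_ALL,
    ORDER_NORMAL,
    ORDER_OVERLAPPING,
    ORDER_TRANS,
    CleavageProduct,
    EnumerationParams,
    SpliceProduct,
    Substrate,
)
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeptideRecord:
    """A database entry: a PCP or PSP annotated with mass and m/z (z = 1, 2, 3)."""

    kind: str  # "PCP" or "PSP"
    product: Union[CleavageProduct, SpliceProduct]
    sequence: str
    mass: float
    mz1: float
    mz2: float
    mz3: float
    annotations: Dict[str, object] = field(default_factory=dict, compare=False)

    def mz(self, charge: int) -> float:
        return {1: self.mz1, 2: self.mz2, 3: self.mz3}[charge]


def _annotate(kind: str, product, sequence: str, **annotations) -> PeptideRecord:
    mass = monoisotopic_mass(sequence)
    z1, z2, z3 = mz_values(mass, (1, 2, 3))
    return PeptideRecord(kind, product, sequence, mass, z1, z2, z3,
                         dict(annotations))


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_pcps(substrate: Substrate, min_len: int, max_len: int) -> Iterator[PeptideRecord]:
    """All cleavage products P(i, j) with min_len <= j-i+1 <= max_len, by (i, j)."""
    if not (1 <= min_len <= max_len <= substrate.L):
        raise ParameterError(
            f"require 1 <= min_len <= max_len <= L, got "
            f"({min_len}, {max_len}) for L={substrate.L}"
        )
    for li in range(1, substrate.L + 1):
        i = substrate.to_protein(li)
        for lj in range(li + min_len - 1, min(li + max_len - 1, substrate.L) + 1):
            j = substrate.to_protein(lj)
            product = CleavageProduct.from_substrate(substrate, i, j)
            yield _annotate("PCP", product, product.sequence)


def substrate_substring_filter(sequence: str, substrate: Substrate) -> bool:
    """True (= suppress) iff ``sequence`` occurs contiguously in the substrate."""
    return sequence in substrate.sequence


def _cis_pairs(L: int, params: EnumerationParams) -> Iterator[Tuple[int, int, int, int, str]]:
    """Yield local-coordinate (i, j, k, l, order) tuples in canonical order."""
    want_inverse = params.order_mode in (ORDER_MODE_ALL, "normal+inverse")
    want_overlap = params.order_mode == ORDER_MODE_ALL
    gmax = params.max_gap if params.max_gap is not None else L
    for total in range(params.min_len, params.max_len + 1):
        for p1 in range(params.min_part, min(params.max_part, total - params.min_part) + 1):
            p2 = total - p1
            if not (params.min_part <= p2 <= params.max_part):
                continue
            block: List[Tuple[int, int, str]] = []
            # normal order: gap >= 1 always (j+1 = k duplicates the PCP P(i, l))
            gmin_n = max(params.min_gap, 1)
            for i in range(1, L - p1 + 2):
                j = i + p1 - 1
                k_lo = j + 1 + gmin_n
                k_hi = min(j + 1 + gmax, L - p2 + 1)
                for k in range(k_lo, k_hi + 1):
                    block.append((i, k, ORDER_NORMAL))
            if want_inverse:
                # acceptor downstream of donor: gap = i - l - 1 in [min_gap, gmax]
                for i in range(1, L - p1 + 2):
                    l_hi = i - 1 - params.min_gap
                    l_lo = max(p2, i - 1 - gmax)
                    for l in range(l_lo, l_hi + 1):
                        k = l - p2 + 1
                        block.append((i, k, ORDER_INVERSE))
            if want_overlap:
                # fragments share >= 1 position: k <= j and i <= l
                for i in range(1, L - p1 + 2):
                    j = i + p1 - 1
                    k_lo = max(1, i - p2 + 1)
                    k_hi = min(L - p2 + 1, j)
                    for k in range(k_lo, k_hi + 1):
                        block.append((i, k, ORDER_OVERLAPPING))
            block.sort(key=lambda t: (t[0], t[1]))
            for i, k, order in block:
                yield i, i + p1 - 1, k, k + p2 - 1, order


def enumerate_psps(substrate: Substrate, params: EnumerationParams) -> Iterator[PeptideRecord]:
    """Stream all splice products of one substrate satisfying ``params``.

    Coordinates in the emitted records are protein coordinates (mapped
    through the substrate offset).  Unachievable constraints simply yield an
    empty stream.
    """
    for li, lj, lk, ll, order in _cis_pairs(substrate.L, params):
        seq = substrate.sequence[li - 1:lj] + substrate.sequence[lk - 1:ll]
        if params.exclude_substrate_substrings and seq in substrate.sequence:
            continue
        product = SpliceProduct(
            substrate.id,
            substrate.to_protein(li), substrate.to_protein(lj),
            substrate.to_protein(lk), substrate.to_protein(ll),
            order, seq,
        )
        yield _annotate("PSP", product, seq)


def enumerate_trans_psps(acceptor: Substrate, donor: Substrate,
                         params: EnumerationParams) -> Iterator[PeptideRecord]:
    """Trans splice products: acceptor fragment from one substrate molecule,
    donor fragment from another.  No gap constraint applies (a gap is
    undefined across molecules).  The substring filter compares against the
    two source substrates only.
    """
    for total in range(params.min_len, params.max_len + 1):
        for p1 in range(params.min_part, min(params.max_part, total - params.min_part) + 1):
            p2 = total - p1
            if not (params.min_part <= p2 <= params.max_part):
                continue
            for li in range(1, acceptor.L - p1 + 2):
                for lk in range(1, donor.L - p2 + 2):
                    seq = (acceptor.sequence[li - 1:li + p1 - 1]
                           + donor.sequence[lk - 1:lk + p2 - 1])
                    if params.exclude_substrate_substrings and (
                            seq in acceptor.sequence or seq in donor.sequence):
                        continue
                    product = SpliceProduct(
                        acceptor.id,
                        acceptor.to_protein(li), acceptor.to_protein(li + p1 - 1),
                        donor.to_protein(lk), donor.to_protein(lk + p2 - 1),
                        ORDER_TRANS, seq, donor_substrate_id=donor.id,
                    )
                    yield _annotate("PSP", product, seq)


# ---------------------------------------------------------------------------
# analytic size prediction
# ---------------------------------------------------------------------------

def count_fragments(L: int) -> int:
    """Number of contiguous fragments of a length-L substrate: L(L+1)/2."""
    if L < 1:
        raise ParameterError(f"L must be >= 1, got {L}")
    return L * (L + 1) // 2


@dataclass(frozen=True)
class DatabaseSizeReport:
    """Predicted candidate counts and (informational) on-disk FASTA size."""

    n_pcps: int
    n_psps: int
    n_total: int
    estimated_bytes: int


# rough FASTA overhead: header punctuation, coordinates, five-decimal mass
# and three m/z fields, plus two newlines
_HEADER_OVERHEAD = 75


def predict_database_size(L: int, params: Optional[EnumerationParams] = None,
                          unrestricted: bool = False) -> DatabaseSizeReport:
    """Exact candidate counts without enumerating the database.

    ``unrestricted=True`` counts *every* ordered fragment pair —
    (L(L+1)/2)^2, the size of the full splice-product space with no length,
    gap, or exclusion limits (25,502,500 for L = 100).  Otherwise the count
    replicates the enumeration rules for ``params`` exactly, except the
    substrate-substring exclusion, which depends on the actual sequence and
    cannot be predicted analytically.
    """
    if unrestricted:
        n_frag = count_fragments(L)
        n_psps = n_frag * n_frag
        n_pcps = n_frag if params is None or params.include_pcps else 0
        mean_len = (2 * (L + 2)) / 3  # mean fragment length (L+2)/3, two parts
        n_total = n_pcps + n_psps
        est = int(n_total * (_HEADER_OVERHEAD + mean_len))
        return DatabaseSizeReport(n_pcps, n_psps, n_total, est)
    if params is None:
        raise ParameterError("params required unless unrestricted=True")
    want_inverse = params.order_mode in (ORDER_MODE_ALL, "normal+inverse")
    want_overlap = params.order_mode == ORDER_MODE_ALL
    gmax = params.max_gap if params.max_gap is not None else L
    n_psps = 0
    len_weighted = 0
    for total in range(params.min_len, params.max_len + 1):
        for p1 in range(params.min_part, min(params.max_part, total - params.min_part) + 1):
            p2 = total - p1
            if not (params.min_part <= p2 <= params.max_part):
                continue
            n_here = 0
            # normal and inverse: placements with gap g = L - total - g + 1
            for gmin in ((max(params.min_gap, 1),) if not want_inverse
                         else (max(params.min_gap, 1), params.min_gap)):
                for g in range(gmin, min(gmax, L - total) + 1):
                    n_here += L - total - g + 1
                if not want_inverse:
                    break
            if want_overlap:
                for i in range(1, L - p1 + 2):
                    j = i + p1 - 1
                    k_lo = max(1, i - p2 + 1)
                    k_hi = min(L - p2 + 1, j)
                    if k_hi >= k_lo:
                        n_here += k_hi - k_lo + 1
            n_psps += n_here
            len_weighted += n_here * total
    n_pcps = 0
    pcp_len_weighted = 0
    if params.include_pcps:
        for n in range(params.min_part, min(params.max_part, L) + 1):
            n_pcps += L - n + 1
            pcp_len_weighted += (L - n + 1) * n
    n_total = n_pcps + n_psps
    est = int(n_total * _HEADER_OVERHEAD + len_weighted + pcp_len_weighted)
    return DatabaseSizeReport(n_pcps, n_psps, n_total, est)


def predict_trans_count(L_acceptor: int, L_donor: int,
                        params: EnumerationParams) -> int:
    """Number of trans products for one ordered substrate pair."""
    n = 0
    for total in range(params.min_len, params.max_len + 1):
        for p1 in range(params.min_part, min(params.max_part, total - params.min_part) + 1):
            p2 = total - p1
            if not (params.min_part <= p2 <= params.max_part):
                continue
            a = L_acceptor - p1 + 1
            d = L_donor - p2 + 1
            if a > 0 and d > 0:
                n += a * d
    return n


# ---------------------------------------------------------------------------
# affinity filtering
# ---------------------------------------------------------------------------

def load_affinity_table(path) -> Dict[str, float]:
    """Read a peptide -> IC50 (nM) table from TSV with columns peptide, ic50_nM."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - surface as domain error
        raise DataError(f"cannot parse affinity table {path}: {exc}") from exc
    if not {"peptide", "ic50_nM"} <= set(df.columns):
        raise DataError(
            f"affinity table must have columns peptide, ic50_nM; got {list(df.columns)}"
        )
    return dict(zip(df["peptide"].astype(str), df["ic50_nM"].astype(float)))


def filter_by_affinity(records: Iterable[PeptideRecord],
                       affinity_table: Mapping[str, float],
                       threshold: float) -> Iterator[PeptideRecord]:
    """Keep records with predicted IC50 < threshold (nM).

    Records absent from the table are dropped with a logged warning; the
    binding prediction itself comes from an external predictor and is
    consumed only as a table.
    """
    if threshold <= 0:
        raise ParameterError(f"threshold must be > 0, got {threshold}")
    for rec in records:
        ic50 = affinity_table.get(rec.sequence)
        if ic50 is None:
            logger.warning("no affinity prediction for %s; dropped", rec.sequence)
            continue
        if ic50 < threshold:
            annotations = dict(rec.annotations, ic50_nM=ic50)
            yield PeptideRecord(rec.kind, rec.product, rec.sequence, rec.mass,
                                rec.mz1, rec.mz2, rec.mz3, annotations)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def _header(rec: PeptideRecord) -> str:
    p = rec.product
    if rec.kind == "PSP":
        sid = p.substrate_id
        if p.donor_substrate_id is not None:
            sid = f"{p.substrate_id}+{p.donor_substrate_id}"
        coords = f"{p.i}-{p.j}/{p.k}-{p.l}|order={p.order}"
    else:
        sid = p.substrate_id
        coords = f"{p.i}-{p.j}"
    return (f">{rec.kind}|{sid}|{coords}|len={len(rec.sequence)}"
            f"|M={rec.mass:.5f}|z1={rec.mz1:.5f}|z2={rec.mz2:.5f}|z3={rec.mz3:.5f}")


def write_fasta(records: Iterable[PeptideRecord], destination) -> int:
    """Write records as two-line FASTA entries; returns the number written."""
    close = False
    if isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__"):
        handle: TextIO = open(destination, "w")
        close = True
    else:
        handle = destination
    n = 0
    try:
        for rec in records:
            handle.write(_header(rec) + "\n" + rec.sequence + "\n")
            n += 1
    finally:
        if close:
            handle.close()
    return n


_PSP_RE = re.compile(
    r">PSP\|(?P<sid>[^|]+)\|(?P<i>\d+)-(?P<j>\d+)/(?P<k>\d+)-(?P<l>\d+)"
    r"\|order=(?P<order>\w+)\|len=(?P<n>\d+)\|M=(?P<M>[\d.]+)"
    r"\|z1=(?P<z1>[\d.]+)\|z2=(?P<z2>[\d.]+)\|z3=(?P<z3>[\d.]+)$"
)
_PCP_RE = re.compile(
    r">PCP\|(?P<sid>[^|]+)\|(?P<i>\d+)-(?P<j>\d+)\|len=(?P<n>\d+)\|M=(?P<M>[\d.]+)"
    r"\|z1=(?P<z1>[\d.]+)\|z2=(?P<z2>[\d.]+)\|z3=(?P<z3>[\d.]+)$"
)


def read_fasta_db(source) -> List[PeptideRecord]:
    """Parse a database written by :func:`write_fasta` back into records."""
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        handle: TextIO = open(source)
        close = True
    else:
        handle = source
    records: List[PeptideRecord] = []
    try:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    finally:
        if close:
            handle.close()
    for hdr, seq in zip(lines[::2], lines[1::2]):
        m = _PSP_RE.match(hdr)
        if m:
            sid = m["sid"]
            donor = None
            if "+" in sid:
                sid, donor = sid.split("+", 1)
            product = SpliceProduct(sid, int(m["i"]), int(m["j"]), int(m["k"]),
                                    int(m["l"]), m["order"], seq,
                                    donor_substrate_id=donor)
        else:
            m = _PCP_RE.match(hdr)
            if m is None:
                raise DataError(f"unparseable database header: {hdr!r}")
            product = CleavageProduct(m["sid"], int(m["i"]), int(m["j"]), seq)
        records.append(PeptideRecord(
            "PSP" if isinstance(product, SpliceProduct) else "PCP",
            product, seq, float(m["M"]),
            float(m["z1"]), float(m["z2"]), float(m["z3"]),
        ))
    return records


def read_substrates(path, default_offset: int = 1) -> List[Substrate]:
    """Read substrates from standard FASTA.

    A header suffix of the form ``|start=<n>`` sets the protein coordinate of
    the first residue; otherwise ``default_offset`` applies.
    """
    from Bio import SeqIO

    substrates = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        name = seqrec.id
        offset = default_offset
        m = re.search(r"\|start=(\d+)$", name)
        if m:
            offset = int(m.group(1))
            name = name[: m.start()]
        substrates.append(Substrate(name, str(seqrec.seq).upper(), offset))
    return substrates
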