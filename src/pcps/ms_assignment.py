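"""Assigning database candidates to MS1 peak lists.

The in-vitro digest of a substrate is measured by LC-MS; candidate peptides
from the splice database are matched to centroid peaks within a ppm
precursor tolerance and scored on four criteria: mass accuracy, occurrence
of the expected charge states, retention-time similarity to a synthetic
reference, and MS/MS fragment coverage.  Acceptance is tiered:

1. conventional — plain cleavage products;
2. modified — chemically modified (e.g. oxidized) cleavage products,
   accepted only if the unmodified peptide was itself identified;
3. spliced — splice products explain the remaining peaks, accepted only if
   BOTH constituent fragments were identified as conventional peptides.

A separate t = 0 screen flags any splice-product mass already present in
the undigested substrate — a hallmark of faulty synthesis byproducts that
mimic splicing — and a deletion-variant audit decides whether a candidate
sequence could equally arise from the substrate with a few residues
deleted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .chemistry import (
    DEFAULT_MODIFICATIONS,
    PROTON_MASS,
    Modification,
    ppm_error,
    theoretical_fragment_ions,
)
from .core import SpliceProduct, Substrate
from .errors import DataError, ParameterError
from .splice_db import PeptideRecord

TIER_CONVENTIONAL = "conventional"
TIER_MODIFIED = "modified"
TIER_SPLICED = "spliced"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToleranceConfig:
    """Instrument tolerances and scoring knobs.

    ``weights`` are (mass, charge, rt, msms) and must sum to 1; the noise
    threshold, when None, defaults to 3x the median intensity of the input.
    """

    precursor_ppm: float = 6.0
    fragment_tol: float = 0.02
    charge_set: Tuple[int, ...] = (1, 2, 3)
    rt_window: float = 1.0
    noise_threshold: Optional[float] = None
    score_threshold: float = 0.6
    weights: Tuple[float, float, float, float] = (0.35, 0.15, 0.15, 0.35)
    goodness_floor: float = 0.8

    def __post_init__(self) -> None:
        if self.precursor_ppm <= 0 or self.fragment_tol <= 0 or self.rt_window <= 0:
            raise ParameterError("tolerances must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ParameterError(f"weights must sum to 1, got {self.weights}")
        if not set(self.charge_set) <= {1, 2, 3}:
            raise ParameterError(f"charge_set must be within {{1,2,3}}, got {self.charge_set}")


#: Instrument presets from the original acquisition settings.
PRESETS: Dict[str, ToleranceConfig] = {
    # LTQ Orbitrap XL: 10 ppm precursor; 0.06 Da Orbitrap fragments
    "orbitrap-xl": ToleranceConfig(precursor_ppm=10.0, fragment_tol=0.06),
    # Q Exactive Plus: 6 ppm precursor, 0.02 Da fragments
    "q-exactive": ToleranceConfig(precursor_ppm=6.0, fragment_tol=0.02),
}
DEFAULT_CONFIG = PRESETS["q-exactive"]


# ---------------------------------------------------------------------------
# peaks and Gaussian fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianFit:
    mean: float
    sigma: float
    amplitude: float
    goodness: float  # R^2 on the fitted window

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    rt: float = 0.0
    fit: Optional[GaussianFit] = None
    reliable: bool = True


def _gauss(x, amplitude, mean, sigma):
    return amplitude * np.exp(-0.5 * ((x - mean) / sigma) ** 2)


def detect_peaks(profile: Sequence[Tuple[float, float]],
                 config: ToleranceConfig = DEFAULT_CONFIG,
                 max_peaks: int = 50) -> List[Peak]:
    """Greedy Gaussian decomposition of an intensity profile.

    The most intense remaining point seeds a single-Gaussian least-squares
    fit on a local window; the fit is subtracted and the residual searched
    again.  Peaks with fit R^2 below ``config.goodness_floor`` are retained
    but flagged unreliable.  Output is sorted by position.
    """
    arr = np.asarray(profile, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 5:
        raise DataError("profile must be an (n >= 5, 2) array of (x, intensity)")
    if np.any(~np.isfinite(arr)):
        raise DataError("profile contains non-finite values")
    x, y = arr[:, 0], arr[:, 1].copy()
    if np.any(np.diff(x) <= 0):
        raise DataError("profile x values must be strictly increasing")
    threshold = config.noise_threshold
    if threshold is None:
        threshold = 3.0 * float(np.median(y))
    peaks: List[Peak] = []
    residual = y.copy()
    for _ in range(max_peaks):
        idx = int(np.argmax(residual))
        apex = residual[idx]
        if apex < threshold or apex <= 0:
            break
        # window: walk out until the residual falls below 10% of the apex
        lo = idx
        while lo > 0 and residual[lo - 1] > 0.1 * apex:
            lo -= 1
        hi = idx
        while hi < len(x) - 1 and residual[hi + 1] > 0.1 * apex:
            hi += 1
        lo, hi = max(0, lo - 2), min(len(x) - 1, hi + 2)
        xs, ys = x[lo:hi + 1], residual[lo:hi + 1]
        sigma0 = max((xs[-1] - xs[0]) / 6.0, np.finfo(float).eps)
        try:
            popt, _ = curve_fit(_gauss, xs, ys, p0=(apex, x[idx], sigma0),
                                maxfev=5000)
            amplitude, mean, sigma = popt[0], popt[1], abs(popt[2])
        except RuntimeError:
            amplitude, mean, sigma = apex, x[idx], sigma0
        model = _gauss(xs, amplitude, mean, sigma)
        ss_res = float(np.sum((ys - model) ** 2))
        ss_tot = float(np.sum((ys - ys.mean()) ** 2))
        goodness = max(0.0, min(1.0, 1.0 - ss_res / ss_tot)) if ss_tot > 0 else 0.0
        fit = GaussianFit(mean, max(sigma, np.finfo(float).eps), amplitude, goodness)
        peaks.append(Peak(mz=mean, intensity=amplitude, rt=0.0, fit=fit,
                          reliable=goodness >= config.goodness_floor))
        residual -= _gauss(x, amplitude, mean, sigma)
        residual = np.clip(residual, 0.0, None)
    peaks.sort(key=lambda p: p.mz)
    return peaks


def read_peaks_tsv(path) -> List[Peak]:
    """Read a centroid peak list from TSV with header columns mz, intensity, rt."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise DataError(f"cannot parse peak list {path}: {exc}") from exc
    required = {"mz", "intensity", "rt"}
    if not required <= set(df.columns):
        raise DataError(f"peak list needs columns {sorted(required)}, got {list(df.columns)}")
    return [Peak(float(r.mz), float(r.intensity), float(r.rt))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# candidate matching and scoring
# ---------------------------------------------------------------------------

class PeptideIndex:
    """m/z-sorted index over (record, charge) pairs for fast ppm lookups."""

    def __init__(self, records: Sequence[PeptideRecord],
                 charge_set: Sequence[int] = (1, 2, 3)):
        entries = []
        for rec in records:
            for z in charge_set:
                entries.append((rec.mz(z), rec, z))
        entries.sort(key=lambda e: e[0])
        self._mz = np.array([e[0] for e in entries])
        self._entries = entries

    def query(self, mz: float, tol_ppm: float) -> List[Tuple[PeptideRecord, int, float]]:
        """All (record, charge, signed ppm error) within ``tol_ppm`` of ``mz``,
        nearest first."""
        if len(self._entries) == 0:
            return []
        delta = mz * tol_ppm * 1e-6
        lo = int(np.searchsorted(self._mz, mz - delta, side="left"))
        hi = int(np.searchsorted(self._mz, mz + delta, side="right"))
        out = []
        for theo, rec, z in self._entries[lo:hi]:
            err = ppm_error(mz, theo)
            if abs(err) <= tol_ppm:
                out.append((rec, z, err))
        out.sort(key=lambda t: (abs(t[2]), t[0].sequence))
        return out


def match_candidates(peak: Peak, index: PeptideIndex,
                     config: ToleranceConfig = DEFAULT_CONFIG
                     ) -> List[Tuple[PeptideRecord, int, float]]:
    """Database records whose m/z (any configured charge) matches ``peak``."""
    return index.query(peak.mz, config.precursor_ppm)


@dataclass(frozen=True)
class AssignmentScore:
    mass_score: float
    charge_score: float
    rt_score: float
    msms_score: float
    total: float
    ppm_error: float


@dataclass(frozen=True)
class Assignment:
    record: PeptideRecord
    peak: Peak
    charge: int
    tier: str
    score: AssignmentScore
    accepted: bool
    rejection_reason: Optional[str] = None


def _charge_score(record: PeptideRecord, peak: Peak,
                  all_peaks: Optional[Sequence[Peak]],
                  matched_charge: int, config: ToleranceConfig) -> float:
    if all_peaks is None:
        return 1.0 / len(config.charge_set)
    seen = 0
    for z in config.charge_set:
        if z == matched_charge:
            seen += 1
            continue
        theo = record.mz(z)
        tol = theo * config.precursor_ppm * 1e-6
        for other in all_peaks:
            if (abs(other.mz - theo) <= tol
                    and abs(other.rt - peak.rt) <= config.rt_window):
                seen += 1
                break
    return seen / len(config.charge_set)


def _msms_score(record: PeptideRecord, observed_msms, config: ToleranceConfig) -> float:
    if observed_msms is None:
        return 0.5  # neutral prior: no MS/MS evidence either way
    frag_mzs = observed_msms.get("fragments") if isinstance(observed_msms, dict) \
        else observed_msms
    observed = np.array([f[0] if isinstance(f, (list, tuple)) else f
                         for f in frag_mzs], dtype=float)
    ions = theoretical_fragment_ions(record.sequence, charges=(1,))
    if len(observed) == 0:
        return 0.0
    matched = sum(
        1 for ion in ions if np.any(np.abs(observed - ion.mz) <= config.fragment_tol)
    )
    return matched / len(ions)


def score_candidate(record: PeptideRecord, peak: Peak, charge: int,
                    config: ToleranceConfig = DEFAULT_CONFIG,
                    all_peaks: Optional[Sequence[Peak]] = None,
                    observed_msms=None,
                    reference_rt: Optional[float] = None) -> AssignmentScore:
    """Four-criterion likelihood that ``record`` explains ``peak``.

    mass    1 - |ppm error| / tolerance (floored at 0)
    charge  fraction of configured charge states seen as co-eluting peaks
    rt      1 inside the reference window, exponential decay outside
            (1 when no reference retention time is available)
    msms    fraction of theoretical b/y ions matched (0.5 without MS/MS)
    """
    err = ppm_error(peak.mz, record.mz(charge))
    mass_score = max(0.0, 1.0 - abs(err) / config.precursor_ppm)
    charge_score = _charge_score(record, peak, all_peaks, charge, config)
    if reference_rt is None:
        rt_score = 1.0
    else:
        excess = abs(peak.rt - reference_rt) - config.rt_window
        rt_score = 1.0 if excess <= 0 else float(np.exp(-excess / config.rt_window))
    msms_score = _msms_score(record, observed_msms, config)
    w = config.weights
    total = (w[0] * mass_score + w[1] * charge_score
             + w[2] * rt_score + w[3] * msms_score)
    return AssignmentScore(mass_score, charge_score, rt_score, msms_score,
                           total, err)


# ---------------------------------------------------------------------------
# tiered assignment
# ---------------------------------------------------------------------------

def modified_records(records: Sequence[PeptideRecord],
                     modifications: Sequence[Modification]) -> List[PeptideRecord]:
    """Expand PCP records with modified-mass counterparts (1..max_count copies)."""
    out: List[PeptideRecord] = []
    for rec in records:
        for mod in modifications:
            for count in range(1, mod.max_count + 1):
                mass = rec.mass + count * mod.delta_mass
                z1, z2, z3 = [(mass + z * PROTON_MASS) / z for z in (1, 2, 3)]
                annotations = dict(rec.annotations, modification=mod.name,
                                   mod_count=count, base_sequence=rec.sequence)
                out.append(PeptideRecord(rec.kind, rec.product, rec.sequence,
                                         mass, z1, z2, z3, annotations))
    return out


def _apply_noise_threshold(peaks: Sequence[Peak],
                           config: ToleranceConfig) -> List[Peak]:
    if not peaks:
        return []
    threshold = config.noise_threshold
    if threshold is None:
        threshold = 3.0 * float(np.median([p.intensity for p in peaks]))
    return [p for p in peaks if p.intensity >= threshold]


def _best_candidate(peak: Peak, index: PeptideIndex, config: ToleranceConfig,
                    all_peaks, msms_for, rt_for):
    """Score every match for one peak; return (best, score) or None.

    Ties resolve by total score, then |ppm error|, then sequence.
    """
    matches = match_candidates(peak, index, config)
    scored = []
    for rec, z, _err in matches:
        s = score_candidate(rec, peak, z, config, all_peaks=all_peaks,
                            observed_msms=msms_for(rec, peak),
                            reference_rt=rt_for(rec))
        scored.append((rec, z, s))
    if not scored:
        return None
    scored.sort(key=lambda t: (-t[2].total, abs(t[2].ppm_error), t[0].sequence))
    return scored[0]


def assign(peaks: Sequence[Peak],
           pcp_records: Sequence[PeptideRecord],
           psp_records: Sequence[PeptideRecord],
           modifications: Sequence[Modification] = DEFAULT_MODIFICATIONS,
           config: ToleranceConfig = DEFAULT_CONFIG,
           msms_by_peak: Optional[Mapping[float, object]] = None,
           reference_rts: Optional[Mapping[str, float]] = None) -> List[Assignment]:
    """Three-phase tiered assignment of peaks to database candidates.

    Parameters
    ----------
    msms_by_peak : optional mapping of peak m/z -> MS/MS spectrum
        ``{"precursor_mz": ..., "charge": ..., "fragments": [[mz, i], ...]}``.
    reference_rts : optional mapping of peptide sequence -> synthetic-standard
        retention time (minutes).

    Returns every considered best-per-peak assignment, accepted or not;
    rejected entries carry a ``rejection_reason``.
    """
    peaks = _apply_noise_threshold(peaks, config)
    msms_by_peak = msms_by_peak or {}
    reference_rts = reference_rts or {}

    def msms_for(_rec, peak):
        return msms_by_peak.get(peak.mz)

    def rt_for(rec):
        return reference_rts.get(rec.sequence)

    assignments: List[Assignment] = []
    explained: set = set()
    accepted_sequences: set = set()

    # phase 1: conventional cleavage products
    pcp_index = PeptideIndex(pcp_records, config.charge_set)
    for pi, peak in enumerate(peaks):
        best = _best_candidate(peak, pcp_index, config, peaks, msms_for, rt_for)
        if best is None:
            continue
        rec, z, s = best
        ok = s.total >= config.score_threshold
        assignments.append(Assignment(rec, peak, z, TIER_CONVENTIONAL, s, ok,
                                      None if ok else "below score threshold"))
        if ok:
            explained.add(pi)
            accepted_sequences.add(rec.sequence)

    # phase 2: chemically modified cleavage products on unexplained peaks
    mod_index = PeptideIndex(modified_records(pcp_records, modifications),
                             config.charge_set)
    for pi, peak in enumerate(peaks):
        if pi in explained:
            continue
        best = _best_candidate(peak, mod_index, config, peaks, msms_for, rt_for)
        if best is None:
            continue
        rec, z, s = best
        if s.total < config.score_threshold:
            assignments.append(Assignment(rec, peak, z, TIER_MODIFIED, s, False,
                                          "below score threshold"))
            continue
        if rec.annotations.get("base_sequence") not in accepted_sequences:
            assignments.append(Assignment(
                rec, peak, z, TIER_MODIFIED, s, False,
                "unmodified counterpart not identified"))
            continue
        assignments.append(Assignment(rec, peak, z, TIER_MODIFIED, s, True))
        explained.add(pi)

    # phase 3: splice products on the remaining unexplained peaks, requiring
    # both constituent fragments among the accepted conventional peptides
    psp_index = PeptideIndex(psp_records, config.charge_set)
    for pi, peak in enumerate(peaks):
        if pi in explained:
            continue
        best = _best_candidate(peak, psp_index, config, peaks, msms_for, rt_for)
        if best is None:
            continue
        rec, z, s = best
        if s.total < config.score_threshold:
            assignments.append(Assignment(rec, peak, z, TIER_SPLICED, s, False,
                                          "below score threshold"))
            continue
        product = rec.product
        acceptor = rec.sequence[: product.acceptor_length]
        donor = rec.sequence[product.acceptor_length:]
        if acceptor not in accepted_sequences or donor not in accepted_sequences:
            assignments.append(Assignment(rec, peak, z, TIER_SPLICED, s, False,
                                          "missing fragment evidence"))
            continue
        assignments.append(Assignment(rec, peak, z, TIER_SPLICED, s, True))
        explained.add(pi)

    return assignments


def write_assignments_tsv(assignments: Sequence[Assignment], path) -> None:
    rows = []
    for a in assignments:
        p = a.record.product
        coords = (f"{p.i}-{p.j}/{p.k}-{p.l}" if isinstance(p, SpliceProduct)
                  else f"{p.i}-{p.j}")
        rows.append({
            "peptide": a.record.sequence,
            "coordinates": coords,
            "tier": a.tier,
            "charge": a.charge,
            "mz": a.peak.mz,
            "rt": a.peak.rt,
            "peak_intensity": a.peak.intensity,
            "ppm_error": a.score.ppm_error,
            "mass_score": a.score.mass_score,
            "charge_score": a.score.charge_score,
            "rt_score": a.score.rt_score,
            "msms_score": a.score.msms_score,
            "total_score": a.score.total,
            "accepted": a.accepted,
            "rejection_reason": a.rejection_reason or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# t = 0 contamination screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContaminantFlag:
    record: PeptideRecord
    peak: Peak
    charge: int
    ppm_error: float


def baseline_contamination_screen(peaks_t0: Sequence[Peak],
                                  psp_records: Sequence[PeptideRecord],
                                  config: ToleranceConfig = DEFAULT_CONFIG
                                  ) -> List[ContaminantFlag]:
    """Flag splice-product masses already present before digestion (t = 0).

    Any match of the undigested substrate's spectrum against the splice
    database indicates a pre-existing synthesis artifact, not true splicing;
    a clean substrate yields an empty list.
    """
    peaks = _apply_noise_threshold(peaks_t0, config)
    index = PeptideIndex(psp_records, config.charge_set)
    flags: List[ContaminantFlag] = []
    for peak in peaks:
        for rec, z, err in match_candidates(peak, index, config):
            flags.append(ContaminantFlag(rec, peak, z, err))
    return flags


# ---------------------------------------------------------------------------
# deletion-artifact audit
# ---------------------------------------------------------------------------

def deletion_artifact_check(candidate: Union[str, SpliceProduct],
                            substrate: Substrate,
                            d_max: int = 2) -> Tuple[bool, Optional[Tuple[int, ...]]]:
    """Can ``candidate`` arise from the substrate with <= d_max residues deleted?

    Solid-phase synthesis of hydrophobic substrates produces deletion
    variants; a candidate whose sequence occurs contiguously in such a
    variant is ambiguous — it may be a proteolysis product of the faulty
    substrate rather than a true splice product.  Returns (ambiguous,
    witness), where the witness lists deleted positions in protein
    coordinates.  The search anchors the candidate at each substrate
    position and greedily matches left to right; the earliest-match
    alignment minimizes the span and hence the number of deletions for that
    anchor.
    """
    if d_max < 0:
        raise ParameterError(f"d_max must be >= 0, got {d_max}")
    seq = candidate.sequence if isinstance(candidate, SpliceProduct) else candidate
    if not seq:
        return False, None
    s = substrate.sequence
    best: Optional[Tuple[int, Tuple[int, ...]]] = None
    for start in range(len(s) - len(seq) + 1):
        if s[start] != seq[0]:
            continue
        deleted: List[int] = []
        pos = start
        ok = True
        for ch in seq:
            while pos < len(s) and s[pos] != ch:
                deleted.append(pos)
                pos += 1
                if len(deleted) > d_max:
                    ok = False
                    break
            if not ok or pos >= len(s):
                ok = False
                break
            pos += 1
        if not ok:
            continue
        witness = tuple(substrate.to_protein(p + 1) for p in deleted)
        if best is None or len(witness) < len(best[1]):
            best = (start, witness)
            if len(witness) == 0:
                break
    if best is None:
        return False, None
    return True, best[1]


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def kinetics_table(assignments_by_timepoint: Union[Mapping[str, Sequence[Assignment]],
                                                   Sequence[Tuple[str, Sequence[Assignment]]]],
                   accepted_only: bool = True,
                   normalize: bool = False) -> pd.DataFrame:
    """Peptide x timepoint table of summed signal intensities.

    Intensity per assignment is the Gaussian peak area when a fit is
    available, else the raw centroid intensity; missing peptide/timepoint
    combinations are 0.  With ``normalize=True`` each peptide's trace is
    scaled to its maximum.
    """
    if isinstance(assignments_by_timepoint, Mapping):
        items = list(assignments_by_timepoint.items())
    else:
        items = list(assignments_by_timepoint)
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        raise DataError(f"duplicate timepoint labels in {labels}")
    data: Dict[str, Dict[str, float]] = {}
    for label, assignments in items:
        col: Dict[str, float] = {}
        for a in assignments:
            if accepted_only and not a.accepted:
                continue
            value = a.peak.fit.area if a.peak.fit is not None else a.peak.intensity
            col[a.record.sequence] = col.get(a.record.sequence, 0.0) + value
        data[label] = col
    peptides = sorted({pep for col in data.values() for pep in col})
    table = pd.DataFrame(
        [[data[label].get(pep, 0.0) for label in labels] for pep in peptides],
        index=peptides, columns=labels,
    )
    table.index.name = "peptide"
    if normalize and not table.empty:
        maxima = table.max(axis=1).replace(0.0, 1.0)
        table = table.div(maxima, axis=0)
    return table
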