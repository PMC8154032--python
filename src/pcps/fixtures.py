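"""Packaged substrates and a seeded synthetic-spectrum generator.

The substrates are the synthetic polypeptides used for in-vitro proteasome
digestion: N-terminal stretches of KRAS carrying the G12V driver mutation,
and a RAC2 segment carrying P29L.  The generator emulates an LC-MS1 run of
a digest: each planted peptide appears at its theoretical m/z per charge
state with Gaussian ppm jitter and an intensity proportional to its
abundance, riding on uniform-random noise peaks.  A companion truth table
makes recovery scoring exact.  Everything is determined by the seed.

Defaults reflect a Q-Exactive-style acquisition: 200-2000 m/z scan range,
3-85 min gradient, 3 ppm m/z jitter (half the 6 ppm precursor tolerance),
planted signals ten-fold above the noise ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .chemistry import PROTON_MASS, monoisotopic_mass, theoretical_fragment_ions
from .core import Substrate
from .errors import ParameterError

# Substrate sequences, verified against hard-coded strings at import time.
_SUBSTRATE_TABLE = (
    ("KRAS_G12V_2-14", 2, "TEYKLVVVGAVGV"),
    ("KRAS_G12V_2-21", 2, "TEYKLVVVGAVGVGKSALTI"),
    ("KRAS_G12V_2-32", 2, "TEYKLVVVGAVGVGKSALTIQLIQNHFVDEY"),
    ("KRAS_G12V_2-35", 2, "TEYKLVVVGAVGVGKSALTIQLIQNHFVDEYDPT"),
    ("KRAS_G12V_1-21", 1, "MTEYKLVVVGAVGVGKSALTI"),
    ("RAC2_P29L_20-44", 20, "LISYTTNAFLGEYIPTVFDNYSANV"),
)


def paper_substrates() -> List[Substrate]:
    """The packaged digestion substrates, each with its protein-coordinate offset."""
    subs = [Substrate(name, seq, offset) for name, offset, seq in _SUBSTRATE_TABLE]
    # sanity anchors: the driver mutations must sit at their protein positions
    assert subs[3].residue(12) == "V"   # KRAS G12V
    assert subs[5].residue(29) == "L"   # RAC2 P29L
    return subs


def get_substrate(name: str) -> Substrate:
    for sub in paper_substrates():
        if sub.id == name:
            return sub
    raise KeyError(f"unknown substrate {name!r}; see paper_substrates()")


# ---------------------------------------------------------------------------
# synthetic spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPeptide:
    """A peptide signal to plant into a synthetic spectrum."""

    sequence: str
    abundance: float = 3e6
    charge_dist: Dict[int, float] = field(
        default_factory=lambda: {1: 1 / 3, 2: 1 / 3, 3: 1 / 3})
    rt: float = 40.0

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ParameterError("abundance must be > 0")
        if abs(sum(self.charge_dist.values()) - 1.0) > 1e-9:
            raise ParameterError(f"charge distribution must sum to 1: {self.charge_dist}")
        if not set(self.charge_dist) <= {1, 2, 3}:
            raise ParameterError(f"charges must be in {{1,2,3}}: {self.charge_dist}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full specification of one synthetic LC-MS1 run."""

    substrate: Substrate
    planted: Tuple[PlantedPeptide, ...]
    ppm_jitter_sd: float = 3.0
    noise_peaks: int = 200
    noise_intensity_range: Tuple[float, float] = (1e4, 1e5)
    mz_range: Tuple[float, float] = (200.0, 2000.0)
    rt_range: Tuple[float, float] = (3.0, 85.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm_jitter_sd < 0 or self.noise_peaks < 0:
            raise ParameterError("jitter sd and noise count must be >= 0")
        lo, hi = self.noise_intensity_range
        if not (0 < lo <= hi):
            raise ParameterError(f"bad noise intensity range {self.noise_intensity_range}")


def generate_spectrum(spec: SyntheticSpec
                      ) -> Tuple[pd.DataFrame, Dict[float, dict], pd.DataFrame]:
    """Render a synthetic peak list from ``spec``.

    Returns ``(peaks, msms, truth)``:

    * peaks — DataFrame with columns mz, intensity, rt (sorted by mz);
    * msms  — mapping of planted-peak m/z -> MS/MS spectrum dict with all
      singly charged b/y fragment ions present;
    * truth — DataFrame (peptide, charge, mz, rt, intensity); every emitted
      non-noise peak is attributable to exactly one planted peptide/charge.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth_rows = []
    msms: Dict[float, dict] = {}
    for pep in spec.planted:
        mass = monoisotopic_mass(pep.sequence)
        for z in sorted(pep.charge_dist):
            prob = pep.charge_dist[z]
            if prob <= 0:
                continue
            theo = (mass + z * PROTON_MASS) / z
            mz = theo * (1.0 + rng.normal(0.0, spec.ppm_jitter_sd) * 1e-6)
            intensity = pep.abundance * prob
            rows.append((mz, intensity, pep.rt))
            truth_rows.append((pep.sequence, z, mz, pep.rt, intensity))
            if len(pep.sequence) >= 2 and mz not in msms:
                frags = [[ion.mz, 1e4] for ion in
                         theoretical_fragment_ions(pep.sequence, charges=(1,))]
                msms[mz] = {"precursor_mz": mz, "charge": z, "fragments": frags}
    for _ in range(spec.noise_peaks):
        mz = rng.uniform(*spec.mz_range)
        intensity = rng.uniform(*spec.noise_intensity_range)
        rt = rng.uniform(*spec.rt_range)
        rows.append((mz, intensity, rt))
    peaks = pd.DataFrame(rows, columns=["mz", "intensity", "rt"])
    peaks = peaks.sort_values("mz", kind="mergesort").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows,
                         columns=["peptide", "charge", "mz", "rt", "intensity"])
    return peaks, msms, truth


def default_digest_spec(substrate: Substrate, n_planted: int = 20,
                        seed: int = 0,
                        length_range: Tuple[int, int] = (5, 12),
                        include: Sequence[str] = ()) -> SyntheticSpec:
    """A digest-like spectrum: ``n_planted`` cleavage products of the substrate
    planted at default abundance, plus any explicitly requested sequences."""
    from .splice_db import enumerate_pcps

    lo = min(length_range[0], substrate.L)
    hi = min(length_range[1], substrate.L)
    pool = sorted({rec.sequence for rec in enumerate_pcps(substrate, lo, hi)})
    rng = np.random.default_rng(seed)
    chosen = list(include)
    remaining = [s for s in pool if s not in chosen]
    extra = max(0, n_planted - len(chosen))
    if extra > len(remaining):
        raise ParameterError(
            f"substrate yields only {len(pool)} distinct fragments; "
            f"cannot plant {n_planted}")
    idx = rng.choice(len(remaining), size=extra, replace=False)
    chosen += [remaining[i] for i in sorted(idx)]
    rts = rng.uniform(5.0, 80.0, size=len(chosen))
    planted = tuple(PlantedPeptide(seq, rt=float(rt))
                    for seq, rt in zip(chosen, rts))
    return SyntheticSpec(substrate=substrate, planted=planted, seed=seed)


# ---------------------------------------------------------------------------
# faulty synthesis
# ---------------------------------------------------------------------------

def apply_deletions(substrate: Substrate, positions: Sequence[int]) -> str:
    """Substrate sequence with the given protein-coordinate positions removed."""
    local = {substrate.to_local(p) - 1 for p in positions}
    return "".join(ch for idx, ch in enumerate(substrate.sequence)
                   if idx not in local)


def generate_faulty_substrate_batch(substrate: Substrate, deletion_rate: float,
                                    seed: int = 0, n_molecules: int = 10000
                                    ) -> List[Tuple[str, float]]:
    """Monte-Carlo sample of deletion variants from imperfect solid-phase synthesis.

    Each residue is independently skipped with probability ``deletion_rate``,
    so the full-length product has expected frequency (1 - rate)^L.  Returns
    (variant sequence, frequency) sorted by decreasing frequency, sequence.
    """
    if not (0 <= deletion_rate < 1):
        raise ParameterError(f"deletion_rate must be in [0, 1), got {deletion_rate}")
    if deletion_rate == 0:
        return [(substrate.sequence, 1.0)]
    rng = np.random.default_rng(seed)
    L = substrate.L
    keep = rng.random((n_molecules, L)) >= deletion_rate
    counts: Dict[str, int] = {}
    seq_arr = np.frombuffer(substrate.sequence.encode(), dtype="S1")
    for row in keep:
        variant = seq_arr[row].tobytes().decode()
        counts[variant] = counts.get(variant, 0) + 1
    out = [(seq, n / n_molecules) for seq, n in counts.items()]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out
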