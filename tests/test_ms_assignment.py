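"""Peak detection, candidate scoring, tiered assignment, artifact audits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcps import (
    EnumerationParams,
    Peak,
    PeptideIndex,
    Substrate,
    ToleranceConfig,
    assign,
    baseline_contamination_screen,
    deletion_artifact_check,
    detect_peaks,
    enumerate_pcps,
    enumerate_psps,
    kinetics_table,
    match_candidates,
    monoisotopic_mass,
    mz_values,
    score_candidate,
    theoretical_fragment_ions,
)
from pcps.fixtures import PlantedPeptide, SyntheticSpec, generate_spectrum
from pcps.ms_assignment import DEFAULT_CONFIG, GaussianFit
from pcps.errors import DataError, ParameterError
from pcps.splice_db import PeptideRecord
from pcps.core import CleavageProduct, make_splice_product


def record_for(seq, sub=None, i=1, j=None):
    j = i + len(seq) - 1 if j is None else j
    product = CleavageProduct(sub.id if sub else "t", i, j, seq)
    mass = monoisotopic_mass(seq)
    z1, z2, z3 = mz_values(mass, (1, 2, 3))
    return PeptideRecord("PCP", product, seq, mass, z1, z2, z3, {})


# ---------------------------------------------------------------------------
# Gaussian peak detection
# ---------------------------------------------------------------------------

def gaussian_profile(x, components, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.zeros_like(x)
    for amp, mean, sigma in components:
        y += amp * np.exp(-0.5 * ((x - mean) / sigma) ** 2)
    if noise_sd:
        y = np.clip(y + rng.normal(0, noise_sd, x.shape), 0, None)
    return np.column_stack([x, y])


def test_single_gaussian_recovered():
    x = np.linspace(499.9, 500.1, 401)
    profile = gaussian_profile(x, [(1e6, 500.0, 0.01)], noise_sd=1e4, seed=3)
    peaks = detect_peaks(profile, ToleranceConfig(noise_threshold=1e5))
    assert len(peaks) == 1
    assert abs(peaks[0].fit.mean - 500.0) < 0.001  # sigma / 10
    assert peaks[0].reliable


def test_flat_profile_below_threshold_is_empty():
    x = np.linspace(100.0, 101.0, 50)
    profile = np.column_stack([x, np.full_like(x, 5.0)])
    assert detect_peaks(profile, ToleranceConfig(noise_threshold=100.0)) == []


def test_two_separated_gaussians_in_order():
    x = np.linspace(10.0, 30.0, 600)
    profile = gaussian_profile(x, [(5e5, 15.0, 0.3), (8e5, 25.0, 0.4)])
    peaks = detect_peaks(profile, ToleranceConfig(noise_threshold=1e4))
    assert len(peaks) == 2
    assert peaks[0].fit.mean == pytest.approx(15.0, abs=0.05)
    assert peaks[1].fit.mean == pytest.approx(25.0, abs=0.05)


def test_detect_peaks_rejects_bad_profile():
    with pytest.raises(DataError):
        detect_peaks(np.array([[1.0, 2.0], [0.5, 1.0], [2.0, 1.0],
                               [3.0, 1.0], [4.0, 1.0]]))


# ---------------------------------------------------------------------------
# matching and scoring
# ---------------------------------------------------------------------------

def test_match_exact_and_out_of_tolerance():
    rec = record_for("FLGEYIP")
    index = PeptideIndex([rec], (1, 2, 3))
    cfg = DEFAULT_CONFIG
    hit = match_candidates(Peak(rec.mz1, 1e6, 10.0), index, cfg)
    assert len(hit) == 1 and hit[0][2] == pytest.approx(0.0, abs=1e-9)
    off = rec.mz1 * (1 + 2 * cfg.precursor_ppm * 1e-6)
    assert match_candidates(Peak(off, 1e6, 10.0), index, cfg) == []


def test_match_doublet_nearest_first():
    # AK and AQ differ by 0.0364 Da (~170 ppm at this m/z); a wide-open
    # tolerance admits both and the nearer candidate must come first
    a, q = record_for("AK"), record_for("AQ")
    mz = a.mz1 * (1 + 1e-6)  # 1 ppm above AK
    index = PeptideIndex([a, q], (1,))
    hits = match_candidates(Peak(mz, 1e6, 10.0), index,
                            ToleranceConfig(precursor_ppm=400.0))
    assert [h[0].sequence for h in hits] == ["AK", "AQ"]
    assert abs(hits[0][2]) < abs(hits[1][2])


def test_perfect_candidate_scores_one():
    rec = record_for("FLGEYIP")
    peaks = [Peak(rec.mz(z), 1e6, 12.0) for z in (1, 2, 3)]
    msms = {"fragments": [[ion.mz, 1.0] for ion in
                          theoretical_fragment_ions("FLGEYIP", charges=(1,))]}
    s = score_candidate(rec, peaks[0], 1, DEFAULT_CONFIG, all_peaks=peaks,
                        observed_msms=msms, reference_rt=12.0)
    assert s.total == pytest.approx(1.0, abs=1e-9)
    assert (s.mass_score, s.charge_score, s.rt_score, s.msms_score) == (1, 1, 1, 1)


def test_mass_score_zero_at_tolerance_boundary():
    rec = record_for("FLGEYIP")
    cfg = DEFAULT_CONFIG
    peak = Peak(rec.mz1 * (1 + cfg.precursor_ppm * 1e-6), 1e6, 10.0)
    s = score_candidate(rec, peak, 1, cfg)
    assert s.mass_score == pytest.approx(0.0, abs=1e-6)


def test_msms_score_half_when_half_ions_present():
    rec = record_for("FLGEYIPTV")
    ions = theoretical_fragment_ions("FLGEYIPTV", charges=(1,))
    msms = {"fragments": [[ion.mz, 1.0] for ion in ions[::2]]}  # every other ion
    s = score_candidate(rec, Peak(rec.mz1, 1e6, 5.0), 1, DEFAULT_CONFIG,
                        observed_msms=msms)
    assert s.msms_score == pytest.approx(0.5)


def test_neutral_scores_without_optional_evidence():
    rec = record_for("FLGEYIP")
    s = score_candidate(rec, Peak(rec.mz1, 1e6, 5.0), 1, DEFAULT_CONFIG)
    assert s.rt_score == 1.0
    assert s.msms_score == 0.5


# ---------------------------------------------------------------------------
# tiered assignment
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def rac2_dbs(rac2):
    pcp = list(enumerate_pcps(rac2, 2, 14))
    params = EnumerationParams(min_part=2, max_part=12, min_len=9, max_len=12)
    psp = list(enumerate_psps(rac2, params))
    return pcp, psp


def peaks_for(sequences, rt=20.0):
    out = []
    for seq in sequences:
        mass = monoisotopic_mass(seq)
        for z in (1, 2, 3):
            out.append(Peak(mz_values(mass, [z])[0], 1e6, rt))
    return out


def test_spliced_accepted_with_both_fragment_evidences(rac2, rac2_dbs):
    pcp, psp = rac2_dbs
    peaks = peaks_for(["FLGEYIP", "VFDNY", "FLGEYIPVFDNY"])
    asg = assign(peaks, pcp, psp, config=ToleranceConfig(noise_threshold=1.0))
    spliced = [a for a in asg if a.tier == "spliced" and a.accepted]
    assert {a.record.sequence for a in spliced} == {"FLGEYIPVFDNY"}
    assert all(a.record.product.order == "normal" for a in spliced)


def test_spliced_rejected_without_donor_fragment(rac2, rac2_dbs):
    pcp, psp = rac2_dbs
    peaks = peaks_for(["FLGEYIP", "FLGEYIPVFDNY"])  # VFDNY signal absent
    asg = assign(peaks, pcp, psp, config=ToleranceConfig(noise_threshold=1.0))
    psp_assignments = [a for a in asg if a.record.sequence == "FLGEYIPVFDNY"
                       and a.tier == "spliced"]
    assert psp_assignments and not any(a.accepted for a in psp_assignments)
    assert all(a.rejection_reason == "missing fragment evidence"
               for a in psp_assignments)


def test_modified_requires_unmodified_counterpart(rac2, rac2_dbs):
    from pcps import OXIDATION

    pcp, psp = rac2_dbs
    # LISYT's oxidized mass is not isobaric with any plain cleavage product,
    # so the peak cannot be explained at the conventional tier
    seq = "LISYT"
    ox_mass = monoisotopic_mass(seq) + OXIDATION.delta_mass
    cfg = ToleranceConfig(noise_threshold=1.0)
    ox_peaks = [Peak(mz_values(ox_mass, [z])[0], 1e6, 20.0) for z in (1, 2, 3)]
    # unmodified absent -> rejected
    asg = assign(ox_peaks, pcp, psp, config=cfg)
    mod = [a for a in asg if a.tier == "modified"
           and a.record.annotations.get("base_sequence") == seq]
    assert mod and not any(a.accepted for a in mod)
    assert all(a.rejection_reason == "unmodified counterpart not identified"
               for a in mod)
    # unmodified present -> accepted
    asg2 = assign(ox_peaks + peaks_for([seq]), pcp, psp, config=cfg)
    mod2 = [a for a in asg2 if a.tier == "modified" and a.accepted]
    assert {a.record.annotations["base_sequence"] for a in mod2} == {seq}


def test_tier_soundness_on_synthetic_digest(rac2, rac2_dbs):
    """No accepted modified assignment without its accepted unmodified
    counterpart; no accepted spliced assignment without both fragments."""
    from pcps.fixtures import default_digest_spec

    pcp, psp = rac2_dbs
    spec = default_digest_spec(rac2, n_planted=15, seed=11,
                               include=["FLGEYIP", "VFDNY", "FLGEYIPVFDNY"])
    peaks_df, msms, _ = generate_spectrum(spec)
    peaks = [Peak(r.mz, r.intensity, r.rt) for r in peaks_df.itertuples(index=False)]
    asg = assign(peaks, pcp, psp, msms_by_peak=msms)
    accepted_conventional = {a.record.sequence for a in asg
                             if a.tier == "conventional" and a.accepted}
    for a in asg:
        if not a.accepted:
            continue
        if a.tier == "modified":
            assert a.record.annotations["base_sequence"] in accepted_conventional
        elif a.tier == "spliced":
            n1 = a.record.product.acceptor_length
            assert a.record.sequence[:n1] in accepted_conventional
            assert a.record.sequence[n1:] in accepted_conventional


def test_assignment_deterministic(rac2, rac2_dbs):
    from pcps.fixtures import default_digest_spec

    pcp, psp = rac2_dbs
    spec = default_digest_spec(rac2, n_planted=10, seed=5)
    peaks_df, msms, _ = generate_spectrum(spec)
    peaks = [Peak(r.mz, r.intensity, r.rt) for r in peaks_df.itertuples(index=False)]
    a1 = assign(peaks, pcp, psp, msms_by_peak=msms)
    a2 = assign(peaks, pcp, psp, msms_by_peak=msms)
    assert a1 == a2


# ---------------------------------------------------------------------------
# t = 0 contamination screen
# ---------------------------------------------------------------------------

def test_clean_substrate_yields_no_flags(rac2, rac2_dbs):
    _, psp = rac2_dbs
    spec = SyntheticSpec(substrate=rac2,
                         planted=(PlantedPeptide(rac2.sequence, rt=50.0),), seed=1)
    peaks_df, _, _ = generate_spectrum(spec)
    peaks = [Peak(r.mz, r.intensity, r.rt) for r in peaks_df.itertuples(index=False)]
    assert baseline_contamination_screen(peaks, psp) == []


def test_planted_splice_mass_at_t0_is_flagged(kras_2_14):
    params = EnumerationParams(min_part=2, max_part=8, min_len=9, max_len=9)
    psp = list(enumerate_psps(kras_2_14, params))
    spec = SyntheticSpec(substrate=kras_2_14,
                         planted=(PlantedPeptide(kras_2_14.sequence, rt=50.0),
                                  PlantedPeptide("KLVVGAVGV", rt=30.0)),
                         seed=2)
    peaks_df, _, _ = generate_spectrum(spec)
    peaks = [Peak(r.mz, r.intensity, r.rt) for r in peaks_df.itertuples(index=False)]
    flags = baseline_contamination_screen(peaks, psp)
    assert flags
    assert "KLVVGAVGV" in {f.record.sequence for f in flags}
    assert {f.charge for f in flags} <= {1, 2, 3}


def test_t0_flag_carries_charge_annotation(kras_2_14):
    params = EnumerationParams(min_part=2, max_part=8, min_len=9, max_len=9)
    psp = list(enumerate_psps(kras_2_14, params))
    rec = next(r for r in psp if r.sequence == "KLVVGAVGV")
    peaks = [Peak(rec.mz2, 1e6, 10.0)]  # z=2 only
    flags = baseline_contamination_screen(
        peaks, psp, ToleranceConfig(noise_threshold=1.0))
    assert flags and all(f.charge == 2 for f in flags)


# ---------------------------------------------------------------------------
# deletion-artifact audit
# ---------------------------------------------------------------------------

def brute_force_deletion_oracle(candidate, substrate, d_max):
    """Exhaustive check over all deletion sets of size <= d_max."""
    from itertools import combinations

    s = substrate.sequence
    for d in range(d_max + 1):
        for positions in combinations(range(len(s)), d):
            variant = "".join(ch for idx, ch in enumerate(s) if idx not in positions)
            if candidate in variant:
                return True
    return False


@pytest.mark.parametrize(
    "candidate, sub_fixture, d_max, expected, witness",
    [
        ("KLVVGAVGV", "kras_1_21", 1, True, (9,)),     # delete V9
        ("FLGEYIPVF", "rac2", 1, True, (35,)),         # delete T35
        ("VFFLGEYIP", "rac2", 2, False, None),         # inverse-order product
    ],
)
def test_deletion_artifact_worked_examples(candidate, sub_fixture, d_max,
                                           expected, witness, request):
    substrate = request.getfixturevalue(sub_fixture)
    assert brute_force_deletion_oracle(candidate, substrate, d_max) is expected
    ambiguous, got_witness = deletion_artifact_check(candidate, substrate, d_max)
    assert ambiguous is expected
    assert got_witness == witness


def test_deletion_witness_reproduces_candidate(kras_1_21):
    from pcps import apply_deletions

    ambiguous, witness = deletion_artifact_check("KLVVGAVGV", kras_1_21, 1)
    assert ambiguous
    assert "KLVVGAVGV" in apply_deletions(kras_1_21, witness)


@given(st.integers(0, 4), st.integers(1, 4), st.integers(1, 4), st.data())
@settings(max_examples=100, derandomize=True)
def test_normal_psp_ambiguous_at_gap_deletions(gap, p1, p2, data):
    """Any normal-order cis splice product with gap g is a deletion artifact
    at d_max >= g: deleting exactly the gap residues reproduces it."""
    L = p1 + gap + p2 + data.draw(st.integers(0, 3))
    seq = "".join(data.draw(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"))
                  for _ in range(L))
    sub = Substrate("rnd", seq)
    i = 1
    j, k = p1, p1 + gap + 1
    l = k + p2 - 1
    product = make_splice_product(sub, i, j, k, l)
    if product.order != "normal":
        return
    ambiguous, witness = deletion_artifact_check(product, sub, d_max=gap)
    assert ambiguous
    assert witness is not None and len(witness) <= gap


def test_deletion_check_rejects_negative_budget(rac2):
    with pytest.raises(ParameterError):
        deletion_artifact_check("FLGEYIP", rac2, d_max=-1)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def make_assignment(seq, intensity, fit=None, accepted=True):
    from pcps.ms_assignment import Assignment, AssignmentScore

    rec = record_for(seq)
    peak = Peak(rec.mz1, intensity, 10.0, fit=fit)
    score = AssignmentScore(1, 1, 1, 1, 1.0, 0.0)
    return Assignment(rec, peak, 1, "conventional", score, accepted)


def test_kinetics_monotone_trace_and_zero_fill():
    table = kinetics_table([
        ("t0", []),
        ("t4", [make_assignment("FLGEYIP", 1e5)]),
        ("t24", [make_assignment("FLGEYIP", 5e5), make_assignment("VFDNY", 2e5)]),
    ])
    assert list(table.columns) == ["t0", "t4", "t24"]
    assert table.loc["FLGEYIP"].tolist() == [0.0, 1e5, 5e5]
    assert table.loc["VFDNY", "t0"] == 0.0


def test_kinetics_single_timepoint():
    table = kinetics_table({"t24": [make_assignment("FLGEYIP", 1e5)]})
    assert table.shape == (1, 1)


def test_kinetics_uses_gaussian_area_and_amplitude_ratio():
    fit1 = GaussianFit(mean=10.0, sigma=0.2, amplitude=1e5, goodness=0.99)
    fit2 = GaussianFit(mean=30.0, sigma=0.2, amplitude=2e5, goodness=0.99)
    table = kinetics_table([
        ("t4", [make_assignment("FLGEYIP", 0.0, fit=fit1)]),
        ("t24", [make_assignment("FLGEYIP", 0.0, fit=fit2)]),
    ])
    ratio = table.loc["FLGEYIP", "t24"] / table.loc["FLGEYIP", "t4"]
    assert ratio == pytest.approx(2.0, rel=1e-6)


def test_kinetics_rejects_duplicate_labels():
    with pytest.raises(DataError):
        kinetics_table([("t0", []), ("t0", [])])


def test_kinetics_normalization():
    table = kinetics_table([
        ("t4", [make_assignment("FLGEYIP", 2e5)]),
        ("t24", [make_assignment("FLGEYIP", 8e5)]),
    ], normalize=True)
    assert table.loc["FLGEYIP"].max() == 1.0
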