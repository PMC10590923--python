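"""Phantom generation: offset schedules, forward model, calibration, labels,
and cohort simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from noemri.phantom import (GROUND_TRUTH, NOE_OFFSET, PhantomConfig, ROI_NAMES,
                            ZSPEC_SEGMENTS, build_offset_schedule, calibrate_noe_mtr,
                            default_wassr_schedule, default_zspec_schedule,
                            make_label_phantom, noiseless_noe_mtr, roi_pool_set,
                            simulate_cohort, simulate_subject)
from noemri.pools import Pool, PoolSet, zspec_forward


def _pool_set(**amps):
    base = {"DS": (0.0, 4.0), "MT": (-2.5, 25.0), "NOE": (-3.5, 3.0),
            "amide": (3.5, 2.0), "amine": (2.0, 2.0)}
    return PoolSet(pools={n: Pool(n, c, amps.get(n, 0.0), f) for n, (c, f) in base.items()})


# --------------------------------------------------------------------------
# offset schedule
# --------------------------------------------------------------------------

def test_single_segment_enumeration():
    s = build_offset_schedule([(0, 6, 0.1)], sides="one-sided")
    assert len(s) == 61
    assert s.offsets[0] == 0.0 and s.offsets[-1] == 6.0
    assert np.allclose(np.diff(s.offsets), 0.1)


def test_symmetric_schedule_mirrors_offsets():
    s = build_offset_schedule(ZSPEC_SEGMENTS, sides="symmetric")
    for w in s.offsets:
        assert -w in s.offsets


def test_full_schedule_count_matches_set_oracle():
    # independent enumeration: integer arithmetic over scaled segments
    oracle = set()
    for start, end, step in ZSPEC_SEGMENTS:
        k = int(round(step * 1000))
        for v in range(int(round(start * 1000)), int(round(end * 1000)) + 1, k):
            oracle.add(v)
            oracle.add(-v)
    s = default_zspec_schedule()
    assert len(s) == len(oracle)
    assert set(np.round(s.offsets * 1000).astype(int)) == oracle


def test_wassr_schedule_within_window():
    s = default_wassr_schedule()
    assert np.abs(s.offsets).max() <= 1.0
    assert len(s) == 21


@pytest.mark.parametrize("segments,err", [
    ([], "at least one segment"),
    ([(0, 6, 0.0)], "step"),
    ([(6, 0, 0.1)], "end"),
])
def test_schedule_rejects_bad_segments(segments, err):
    with pytest.raises(ValueError, match=err):
        build_offset_schedule(segments)


def test_schedule_monotonic_no_duplicates():
    s = default_zspec_schedule()
    assert np.all(np.diff(s.offsets) > 0)


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------

def test_forward_all_zero_amplitudes_is_unity():
    ps = _pool_set()
    w = np.linspace(-100, 100, 201)
    assert np.allclose(zspec_forward(w, ps), 1.0)


def test_forward_single_pool_peak():
    ps = _pool_set(NOE=0.15)
    assert zspec_forward(np.array([-3.5]), ps)[0] == pytest.approx(1 - 0.15)


def test_forward_five_pool_hand_arithmetic():
    # per-term scalar arithmetic, written out independently of the library
    amps = {"DS": 0.7, "MT": 0.06, "NOE": 0.154, "amide": 0.102, "amine": 0.08}
    ps = _pool_set(**amps)
    w = -3.5
    expected = 1.0
    for a, c, f in [(0.7, 0.0, 4.0), (0.06, -2.5, 25.0), (0.154, -3.5, 3.0),
                    (0.102, 3.5, 2.0), (0.08, 2.0, 2.0)]:
        expected -= a * f ** 2 / (f ** 2 + 4.0 * (w - c) ** 2)
    assert zspec_forward(np.array([w]), ps)[0] == pytest.approx(expected, abs=1e-12)


def test_forward_rejects_negative_signal():
    ps = PoolSet(pools={n: Pool(n, c, a, f) for n, c, a, f in [
        ("DS", 0.0, 0.9, 4.0), ("MT", -2.5, 0.5, 25.0), ("NOE", -3.5, 0.1, 3.0),
        ("amide", 3.5, 0.05, 2.0), ("amine", 2.0, 0.05, 2.0)]})
    with pytest.raises(ValueError, match="negative"):
        zspec_forward(np.array([0.0]), ps)


def test_forward_bounded_on_valid_poolsets():
    z = zspec_forward(default_zspec_schedule().offsets, roi_pool_set("WT", "hippocampus"))
    assert np.all((z >= 0) & (z <= 1))


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def test_calibration_closure():
    ps = calibrate_noe_mtr(_pool_set(MT=0.06, NOE=0.15, amide=0.1, amine=0.08), 40.1)
    assert noiseless_noe_mtr(ps) == pytest.approx(40.1, abs=1e-6)


def test_calibration_zero_target_limit():
    # a nearly-zero target with only tail pools leaves almost no DS amplitude
    ps = calibrate_noe_mtr(_pool_set(amide=0.001), 0.01)
    assert ps.pools["DS"].amplitude < 0.01


def test_calibration_matches_bisection_oracle():
    base = _pool_set(MT=0.06, NOE=0.154, amide=0.102, amine=0.08)
    target = 40.1
    lo, hi = 0.0, 1.0  # plain bisection, independent of the brentq path
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if noiseless_noe_mtr(base.with_pool("DS", amplitude=mid)) < target:
            lo = mid
        else:
            hi = mid
    ps = calibrate_noe_mtr(base, target)
    assert ps.pools["DS"].amplitude == pytest.approx(0.5 * (lo + hi), abs=1e-9)


def test_calibration_unreachable_target_reports():
    with pytest.raises(ValueError, match="unreachable"):
        calibrate_noe_mtr(_pool_set(), 90.0)


# --------------------------------------------------------------------------
# label phantom
# --------------------------------------------------------------------------

@pytest.mark.parametrize("size", [64, 128])
def test_label_phantom_contains_all_rois(size):
    lab = make_label_phantom(size)
    for label in ROI_NAMES:
        assert (lab.labels == label).sum() >= 50


def test_label_phantom_deterministic():
    assert np.array_equal(make_label_phantom(96).labels, make_label_phantom(96).labels)


def test_label_phantom_rejects_small_size():
    with pytest.raises(ValueError):
        make_label_phantom(32)


def test_label_phantom_counts_match_counting_oracle(labels96):
    counts = np.bincount(labels96.labels.ravel())
    for label in ROI_NAMES:
        assert counts[label] == sum(1 for v in labels96.labels.ravel() if v == label)


# --------------------------------------------------------------------------
# subject / cohort simulation
# --------------------------------------------------------------------------

def test_noiseless_subject_matches_forward_model(noiseless_subject):
    subj, _, labels = noiseless_subject
    for label, name in ROI_NAMES.items():
        ps = roi_pool_set("WT", name)
        expected = zspec_forward(subj.zspec.schedule.offsets, ps)
        got = subj.zspec.data[labels.pixels(label)]
        assert np.allclose(got, expected[None, :], atol=1e-12)


def test_noiseless_noe_mtr_closure(noiseless_subject):
    from noemri.contrasts import compute_noe_mtr
    subj, _, labels = noiseless_subject
    mtr = compute_noe_mtr(subj.zspec)
    for label, name in ROI_NAMES.items():
        vals = mtr.values[labels.pixels(label)]
        assert np.allclose(vals, GROUND_TRUTH["WT"][name]["noe_mtr"], atol=1e-9)


def test_background_noise_sd_matches_config(noisy_subject):
    subj, _, labels = noisy_subject
    bg = ~labels.mask
    sample = subj.zspec.data[bg][:1000].ravel()
    assert np.std(sample) == pytest.approx(0.01, rel=0.05)


def test_subject_determinism(labels96, coarse_schedule):
    cfg = PhantomConfig(size=96, n_subjects=1)
    a, _ = simulate_subject(cfg, labels96, coarse_schedule, "AD", seed=3)
    b, _ = simulate_subject(cfg, labels96, coarse_schedule, "AD", seed=3)
    assert np.array_equal(a.zspec.data, b.zspec.data)
    assert np.array_equal(a.wassr.data, b.wassr.data)
    assert np.array_equal(a.zspec.reference, b.zspec.reference)


def test_cohort_size_and_determinism(coarse_schedule):
    cfg = PhantomConfig(size=64, n_subjects=1, seed=42)
    s1, _, t1 = simulate_cohort(cfg, schedule=coarse_schedule)
    s2, _, t2 = simulate_cohort(cfg, schedule=coarse_schedule)
    assert len(s1) == 2  # one per group
    assert np.array_equal(s1[0].zspec.data, s2[0].zspec.data)
    pd.testing.assert_frame_equal(t1, t2)


def test_cohort_truth_means_equal_config_exactly(coarse_schedule):
    cfg = PhantomConfig(size=64, n_subjects=2, seed=9)
    _, _, truth = simulate_cohort(cfg, schedule=coarse_schedule)
    agg = truth.groupby(["group", "roi", "metric"])["truth"].mean()
    for (group, roi, metric), val in agg.items():
        assert val == GROUND_TRUTH[group][roi][metric]


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.floats(min_value=25.0, max_value=45.0))
def test_calibrated_targets_roundtrip(target):
    ps = calibrate_noe_mtr(_pool_set(MT=0.06, NOE=0.15, amide=0.1, amine=0.08), target)
    assert noiseless_noe_mtr(ps) == pytest.approx(target, abs=1e-6)
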