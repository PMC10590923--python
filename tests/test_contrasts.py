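"""NOE_MTR, MTR asymmetry, five-pool fitting and decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from noemri.contrasts import (ContrastMap, compute_mtr_asym, compute_noe_mtr,
                              decompose_at_offset, fit_multipool, fit_spectrum,
                              gaussian_smooth)
from noemri.phantom import (GROUND_TRUTH, PhantomConfig, ROI_NAMES, roi_pool_set,
                            simulate_subject)
from noemri.pools import Pool, PoolSet, default_fit_config, lorentzian_eval, zspec_forward
from noemri.preproc import ZSpectrumImage


def _pool_set(**amps):
    base = {"DS": (0.0, 4.0), "MT": (-2.5, 25.0), "NOE": (-3.5, 3.0),
            "amide": (3.5, 2.0), "amine": (2.0, 2.0)}
    return PoolSet(pools={n: Pool(n, c, amps.get(n, 0.0), f) for n, (c, f) in base.items()})


def _single_voxel_zspec(ps, schedule):
    data = zspec_forward(schedule.offsets, ps)[None, None]
    return ZSpectrumImage(data=data, schedule=schedule, reference=np.ones((1, 1)),
                          mask=np.ones((1, 1), bool))


# --------------------------------------------------------------------------
# Lorentzian identities
# --------------------------------------------------------------------------

def test_lorentzian_peak_equals_amplitude():
    p = Pool("NOE", -3.5, 0.12, 3.0)
    assert lorentzian_eval(-3.5, p) == pytest.approx(0.12)


def test_lorentzian_half_maximum_at_half_width():
    p = Pool("amide", 3.5, 0.2, 2.0)
    assert lorentzian_eval(3.5 + 1.0, p) == pytest.approx(0.1)
    assert lorentzian_eval(3.5 - 1.0, p) == pytest.approx(0.1)


def test_lorentzian_hand_arithmetic():
    # a=0.1, fwhm=3, one ppm off-center: 0.1 * 9 / (9 + 4) = 9/130
    p = Pool("NOE", -3.5, 0.1, 3.0)
    assert lorentzian_eval(-2.5, p) == pytest.approx(9.0 / 130.0)


def test_lorentzian_rejects_nonpositive_width():
    with pytest.raises(ValueError):
        Pool("DS", 0.0, 0.5, 0.0)


# --------------------------------------------------------------------------
# NOE_MTR
# --------------------------------------------------------------------------

def test_noe_mtr_zero_when_signal_equals_reference(coarse_schedule):
    k = len(coarse_schedule)
    zs = ZSpectrumImage(data=np.ones((1, 1, k)), schedule=coarse_schedule,
                        reference=np.ones((1, 1)), mask=np.ones((1, 1), bool))
    assert compute_noe_mtr(zs).values[0, 0] == pytest.approx(0.0)


def test_noe_mtr_full_when_signal_is_zero(coarse_schedule):
    k = len(coarse_schedule)
    zs = ZSpectrumImage(data=np.zeros((1, 1, k)), schedule=coarse_schedule,
                        reference=np.ones((1, 1)), mask=np.ones((1, 1), bool))
    assert compute_noe_mtr(zs).values[0, 0] == pytest.approx(100.0)


def test_noe_mtr_nan_for_nonpositive_reference(coarse_schedule):
    k = len(coarse_schedule)
    zs = ZSpectrumImage(data=np.ones((1, 2, k)), schedule=coarse_schedule,
                        reference=np.array([[0.0, -1.0]]), mask=np.ones((1, 2), bool))
    assert np.isnan(compute_noe_mtr(zs).values).all()


# --------------------------------------------------------------------------
# MTR asymmetry
# --------------------------------------------------------------------------

def test_mtr_asym_zero_for_symmetric_spectrum(coarse_schedule):
    zs = _single_voxel_zspec(_pool_set(DS=0.7), coarse_schedule)
    out = compute_mtr_asym(zs)
    assert np.allclose(out["asym"][0, 0], 0.0, atol=1e-12)


def test_mtr_asym_single_noe_pool_forward_oracle(coarse_schedule):
    ps = _pool_set(NOE=0.15)
    zs = _single_voxel_zspec(ps, coarse_schedule)
    out = compute_mtr_asym(zs)
    k = np.argmin(np.abs(out["offsets_ppm"] + 3.5))
    # S(+3.5) - S(-3.5) = L_NOE(-3.5) - L_NOE(+3.5), evaluated directly
    expected = 100.0 * (lorentzian_eval(-3.5, ps.pools["NOE"]) -
                        lorentzian_eval(3.5, ps.pools["NOE"]))
    assert out["asym"][0, 0, k] == pytest.approx(expected, abs=1e-9)
    assert out["asym"][0, 0, k] > 0  # NOE-dominated asymmetry plots positive


def test_mtr_asym_wt_exceeds_ad_in_hippocampus(coarse_schedule):
    curves = {}
    for group in ("WT", "AD"):
        zs = _single_voxel_zspec(roi_pool_set(group, "hippocampus"), coarse_schedule)
        out = compute_mtr_asym(zs)
        k = np.argmin(np.abs(out["offsets_ppm"] + 3.5))
        curves[group] = out["asym"][0, 0, k]
    assert curves["WT"] > curves["AD"]


# --------------------------------------------------------------------------
# five-pool fitting
# --------------------------------------------------------------------------

def test_single_ds_spectrum_recovered_exactly(coarse_schedule):
    truth = Pool("DS", 0.1, 0.75, 3.2)
    y = 1.0 - lorentzian_eval(coarse_schedule.offsets, truth)
    ps, info = fit_spectrum(coarse_schedule.offsets, y)
    assert info["converged"]
    assert ps.pools["DS"].amplitude == pytest.approx(0.75, abs=1e-4)
    assert ps.pools["DS"].center == pytest.approx(0.1, abs=1e-4)
    assert ps.pools["DS"].fwhm == pytest.approx(3.2, abs=1e-4)
    for name in ("NOE", "amide", "amine", "MT"):
        assert ps.pools[name].amplitude < 1e-4


def test_five_pool_noiseless_recovery_with_grid_oracle(coarse_schedule):
    truth = roi_pool_set("WT", "hippocampus")
    y = zspec_forward(coarse_schedule.offsets, truth)
    rng = np.random.default_rng(0)
    for _ in range(10):  # ten voxels, identical model but fresh fits
        ps, info = fit_spectrum(coarse_schedule.offsets, y)
        for name, p in truth.pools.items():
            rel = abs(ps.pools[name].amplitude - p.amplitude) / p.amplitude
            assert rel < 0.01
            assert abs(ps.pools[name].center - p.center) < 0.05
            assert abs(ps.pools[name].fwhm - p.fwhm) / p.fwhm < 0.01
        # grid-search oracle: no nearby parameter grid point fits better
        x_hat = ps.initial_vector()

        def rss(x):
            total = np.zeros_like(coarse_schedule.offsets)
            for i, n in enumerate(ps.pools):
                a, c, s = x[3 * i], x[3 * i + 1], x[3 * i + 2]
                d = coarse_schedule.offsets - c
                total = total + a * s * s / (s * s + 4 * d * d)
            return float(np.sum((1.0 - total - y) ** 2))

        base = rss(x_hat)
        for j in rng.choice(x_hat.size, size=4, replace=False):
            for delta in (-0.02, 0.02):
                x_try = x_hat.copy()
                x_try[j] = x_hat[j] * (1 + delta) if x_hat[j] != 0 else delta
                assert rss(x_try) >= base - 1e-12


def test_parallel_serial_fit_identity(coarse_schedule, labels96):
    cfg = PhantomConfig(size=96, n_subjects=1)
    subj, _ = simulate_subject(cfg, labels96, coarse_schedule, "WT", seed=2)
    mask = labels96.pixels(5)  # hypothalamus: small ROI, fast
    serial = fit_multipool(subj.zspec, mask=mask, n_jobs=1)
    parallel = fit_multipool(subj.zspec, mask=mask, n_jobs=2)
    for name in serial.amplitude:
        assert np.array_equal(serial.amplitude[name][mask], parallel.amplitude[name][mask])


def test_fit_residual_not_above_initial(coarse_schedule):
    truth = roi_pool_set("AD", "thalamus")
    rng = np.random.default_rng(3)
    y = zspec_forward(coarse_schedule.offsets, truth) + rng.normal(0, 0.01, len(coarse_schedule))
    ps, info = fit_spectrum(coarse_schedule.offsets, y)
    assert info["rms"] <= info["rms0"] + 1e-12


# --------------------------------------------------------------------------
# decomposition
# --------------------------------------------------------------------------

def test_single_pool_decomposition_is_total():
    d = decompose_at_offset(_pool_set(NOE=0.2))
    assert d["NOE"] == pytest.approx(100.0)


def test_equal_pools_split_evenly():
    ps = PoolSet(pools={
        "DS": Pool("DS", -3.5, 0.1, 3.0), "NOE": Pool("NOE", -3.5, 0.1, 3.0),
        "MT": Pool("MT", -2.5, 0.0, 25.0), "amide": Pool("amide", 3.5, 0.0, 2.0),
        "amine": Pool("amine", 2.0, 0.0, 2.0)})
    d = decompose_at_offset(ps)
    assert d["DS"] == pytest.approx(50.0)
    assert d["NOE"] == pytest.approx(50.0)


def test_zero_attenuation_undefined():
    with pytest.warns(UserWarning, match="undefined"):
        d = decompose_at_offset(_pool_set())
    assert all(np.isnan(v) for v in d.values())


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.tuples(*[st.floats(min_value=0.01, max_value=0.15) for _ in range(5)]))
def test_decomposition_sums_to_100(amps):
    ps = _pool_set(DS=amps[0], MT=amps[1], NOE=amps[2], amide=amps[3], amine=amps[4])
    d = decompose_at_offset(ps)
    assert sum(d.values()) == pytest.approx(100.0, abs=1e-9)


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------

def test_smooth_sigma_zero_is_identity():
    v = np.random.default_rng(0).random((20, 20)) * 50
    cm = ContrastMap(values=v, name="x")
    assert np.array_equal(gaussian_smooth(cm, 0.0).values, v)


def test_smooth_preserves_constant():
    cm = ContrastMap(values=np.full((30, 30), 40.0), name="x")
    assert np.allclose(gaussian_smooth(cm, 2.0).values, 40.0)


def test_smooth_impulse_mass_conserved():
    v = np.zeros((41, 41))
    v[20, 20] = 1.0
    out = gaussian_smooth(ContrastMap(values=v, name="x"), 0.75)
    assert out.values.sum() == pytest.approx(1.0, abs=1e-6)


def test_smooth_keeps_nan_outside_mask():
    v = np.full((10, 10), np.nan)
    v[4:7, 4:7] = 30.0
    out = gaussian_smooth(ContrastMap(values=v, name="x"), 1.0)
    assert np.isnan(out.values[0, 0])
    assert np.allclose(out.values[4:7, 4:7], 30.0)
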