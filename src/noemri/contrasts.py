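"""NOE contrasts: magnetization-transfer-ratio maps, Z-spectrum asymmetry,
and per-voxel five-pool Lorentzian decomposition.

The simple contrast is

    NOE_MTR (%) = 100 * (S_ref - S_-3.5ppm) / S_ref

with the unsaturated +/-300 ppm acquisition as S_ref; it lumps direct
saturation, semi-solid MT and relayed NOE.  The model-based contrast fits
S/S0 = 1 - sum of five Lorentzians per voxel (bounded trust-region least
squares) and maps each pool's amplitude, which separates the relayed-NOE
line at -3.5 ppm from its DS/MT background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from joblib import Parallel, delayed
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares

from .phantom import NOE_OFFSET, OffsetSchedule
from .pools import POOL_NAMES, Pool, PoolSet, default_fit_config, lorentzian_eval
from .preproc import ZSpectrumImage

__all__ = [
    "ContrastMap", "FitMaps", "lorentzian_eval", "compute_noe_mtr",
    "compute_mtr_asym", "fit_multipool", "fit_spectrum", "decompose_at_offset",
    "gaussian_smooth",
]


@dataclass
class ContrastMap:
    """A per-voxel contrast in percent, NaN outside the mask, with provenance."""

    values: np.ndarray
    name: str
    b0_corrected: bool = False
    denoised: bool = False
    smoothing_sigma: float = 0.0

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -100.0 - 1e-9 or finite.max() > 100.0 + 1e-9):
            raise ValueError(f"contrast {self.name}: values outside [-100, 100]%")


@dataclass
class FitMaps:
    """Per-pool parameter maps from the voxelwise fit (amplitudes in percent)."""

    amplitude: Dict[str, np.ndarray]
    center: Dict[str, np.ndarray]
    width: Dict[str, np.ndarray]
    residual_rms: np.ndarray
    converged: np.ndarray
    n_iterations: np.ndarray

    def pool_set_at(self, r: int, c: int) -> PoolSet:
        pools = {n: Pool(n, float(self.center[n][r, c]), float(self.amplitude[n][r, c]) / 100.0,
                         float(self.width[n][r, c])) for n in POOL_NAMES}
        return PoolSet(pools=pools)


def compute_noe_mtr(zspec: ZSpectrumImage, offset: float = NOE_OFFSET) -> ContrastMap:
    """Per-voxel NOE_MTR (%) referenced to the unsaturated image.

    Voxels with non-positive reference, and voxels outside the mask, are NaN.
    """
    s = zspec.at_offset(offset).astype(float)
    ref = zspec.reference.astype(float)
    values = np.full(ref.shape, np.nan)
    ok = zspec.mask & (ref > 0)
    values[ok] = 100.0 * (ref[ok] - s[ok]) / ref[ok]
    values = np.clip(values, -100.0, 100.0)
    return ContrastMap(values=values, name="NOE_MTR", b0_corrected=zspec.b0_corrected,
                       denoised=zspec.denoised)


def compute_mtr_asym(zspec: ZSpectrumImage, offsets_range: Tuple[float, float] = (2.0, 5.0),
                     labels=None) -> Dict[str, np.ndarray]:
    """Z-spectrum asymmetry  asym(dw) = 100 (S(+dw) - S(-dw)) / S_ref.

    Returned against the negative (upfield) offsets, with the sign chosen so
    NOE-dominated asymmetry is positive.  ``offsets_range`` selects the
    magnitudes dw to evaluate; magnitudes whose mirror is missing from the
    schedule are interpolated with a warning.  If ``labels`` (a LabelImage)
    is given, per-ROI mean curves are included under ``"roi_curves"``.
    """
    lo, hi = offsets_range
    x = zspec.schedule.offsets
    mags = x[(x >= lo - 1e-9) & (x <= hi + 1e-9)]
    ref = np.where(zspec.reference > 0, zspec.reference, np.nan)
    asym = np.full(zspec.reference.shape + (mags.size,), np.nan)
    for k, m in enumerate(mags):
        try:
            s_pos = zspec.at_offset(m)
        except KeyError:
            warnings.warn(f"offset +{m} missing; interpolating", stacklevel=2)
            s_pos = np.apply_along_axis(lambda v: np.interp(m, x, v), -1, zspec.data)
        try:
            s_neg = zspec.at_offset(-m)
        except KeyError:
            warnings.warn(f"offset -{m} missing; interpolating", stacklevel=2)
            s_neg = np.apply_along_axis(lambda v: np.interp(-m, x, v), -1, zspec.data)
        asym[..., k] = 100.0 * (s_pos - s_neg) / ref
    asym[~zspec.mask] = np.nan
    out = {"offsets_ppm": -mags, "asym": asym}
    if labels is not None:
        curves = {}
        for label, name in labels.roi_names.items():
            sel = labels.pixels(label)
            curves[name] = np.nanmean(asym[sel], axis=0)
        out["roi_curves"] = curves
    return out


def flat_profile_range(curve: np.ndarray, offsets_ppm: np.ndarray,
                       window: Tuple[float, float] = (-3.5, -2.0)) -> float:
    """Peak-to-peak spread of an asymmetry curve over the macromolecular window."""
    sel = (offsets_ppm >= window[0] - 1e-9) & (offsets_ppm <= window[1] + 1e-9)
    return float(np.ptp(curve[sel]))


# --------------------------------------------------------------------------
# five-pool fitting
# --------------------------------------------------------------------------

def _model_and_jac(x: np.ndarray, w: np.ndarray):
    """S/S0 model value and its Jacobian for the flat 15-parameter vector."""
    total = np.zeros_like(w)
    J = np.empty((w.size, x.size))
    for i in range(len(POOL_NAMES)):
        a, c, s = x[3 * i], x[3 * i + 1], x[3 * i + 2]
        d = w - c
        s2 = s * s
        den = s2 + 4.0 * d * d
        shape = s2 / den
        total += a * shape
        J[:, 3 * i] = shape
        J[:, 3 * i + 1] = a * s2 * 8.0 * d / (den * den)
        J[:, 3 * i + 2] = 8.0 * a * s * d * d / (den * den)
    return 1.0 - total, J


def fit_spectrum(offsets: np.ndarray, y: np.ndarray, config: PoolSet | None = None,
                 max_iter: int = 200, tol: float = 1e-8):
    """Bounded nonlinear least squares of one spectrum; returns (PoolSet, info).

    ``info`` carries rms residual, convergence flag, iteration count and the
    rms residual at the initial values.
    """
    config = config or default_fit_config()
    x0 = config.initial_vector()
    lo, hi = config.bounds_vectors()

    def resid(x):
        return _model_and_jac(x, offsets)[0] - y

    def jac(x):
        return -_model_and_jac(x, offsets)[1]

    r0 = float(np.sqrt(np.mean(resid(x0) ** 2)))
    try:
        res = least_squares(resid, x0, jac=jac, bounds=(lo, hi), method="trf",
                            xtol=tol, ftol=tol, gtol=tol, max_nfev=max_iter)
        x, ok, nit = res.x, bool(res.success), int(res.nfev)
        rms = float(np.sqrt(np.mean(res.fun ** 2)))
    except Exception:  # pathological spectrum: report the initial values
        x, ok, nit, rms = x0, False, 0, r0
    if not ok:
        x = x0 if rms > r0 else x
    info = {"rms": min(rms, r0) if not ok else rms, "converged": ok, "n_iter": nit, "rms0": r0}
    return PoolSet.from_vector(x), info


def fit_multipool(zspec: ZSpectrumImage, pool_config: PoolSet | None = None,
                  mask: np.ndarray | None = None, n_jobs: int = 1,
                  max_iter: int = 200, tol: float = 1e-8) -> FitMaps:
    """Voxelwise five-pool Lorentzian fit over the masked region.

    Every voxel is fitted independently from the same initial values, so the
    result is identical for any worker count or processing order.
    Non-convergent voxels are flagged and carry their initial parameters
    (maps stay NaN-free inside the mask).
    """
    pool_config = pool_config or default_fit_config()
    mask = zspec.mask if mask is None else (mask & zspec.mask)
    offsets = zspec.schedule.offsets
    idx = np.argwhere(mask)
    norm = zspec.normalized()
    spectra = norm[mask]

    def one(y):
        return fit_spectrum(offsets, y, pool_config, max_iter=max_iter, tol=tol)

    if n_jobs == 1:
        results = [one(y) for y in spectra]
    else:
        results = Parallel(n_jobs=n_jobs, batch_size=64)(delayed(one)(y) for y in spectra)

    shape = zspec.reference.shape
    amp = {n: np.full(shape, np.nan) for n in POOL_NAMES}
    cen = {n: np.full(shape, np.nan) for n in POOL_NAMES}
    wid = {n: np.full(shape, np.nan) for n in POOL_NAMES}
    rms = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    nit = np.zeros(shape, dtype=np.int32)
    for (r, c), (ps, info) in zip(idx, results):
        for n in POOL_NAMES:
            amp[n][r, c] = 100.0 * ps.pools[n].amplitude
            cen[n][r, c] = ps.pools[n].center
            wid[n][r, c] = ps.pools[n].fwhm
        rms[r, c] = info["rms"]
        conv[r, c] = info["converged"]
        nit[r, c] = info["n_iter"]
    return FitMaps(amplitude=amp, center=cen, width=wid, residual_rms=rms,
                   converged=conv, n_iterations=nit)


def decompose_at_offset(pool_set: PoolSet, offset: float = NOE_OFFSET) -> Dict[str, float]:
    """Percent contribution of each pool to the total attenuation at ``offset``.

    contribution_n = 100 * L_n(offset) / sum_m L_m(offset); the values sum to
    100 wherever the total attenuation is non-zero (else NaN with a warning).
    """
    terms = {p.name: float(lorentzian_eval(offset, p)) for p in pool_set.ordered()}
    total = sum(terms.values())
    if total <= 0:
        warnings.warn(f"total attenuation at {offset} ppm is zero; decomposition undefined",
                      stacklevel=2)
        return {n: float("nan") for n in terms}
    return {n: 100.0 * v / total for n, v in terms.items()}


def gaussian_smooth(contrast: ContrastMap, sigma: float) -> ContrastMap:
    """2D Gaussian smoothing (reflect boundary), NaN-aware.

    NaN voxels (outside the mask) are excluded by normalized convolution and
    remain NaN; ``sigma = 0`` is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return ContrastMap(values=contrast.values.copy(), name=contrast.name,
                           b0_corrected=contrast.b0_corrected, denoised=contrast.denoised,
                           smoothing_sigma=0.0)
    v = contrast.values
    finite = np.isfinite(v)
    filled = np.where(finite, v, 0.0)
    num = gaussian_filter(filled, sigma, mode="reflect")
    den = gaussian_filter(finite.astype(float), sigma, mode="reflect")
    out = np.full_like(v, np.nan)
    ok = finite & (den > 0)
    out[ok] = num[ok] / den[ok]
    return ContrastMap(values=np.clip(out, -100, 100), name=contrast.name,
                       b0_corrected=contrast.b0_corrected, denoised=contrast.denoised,
                       smoothing_sigma=float(sigma))
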