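"""Lorentzian pool model of the Z-spectrum.

A Z-spectrum is the normalized water signal S/S0 as a function of the
saturation frequency offset from water (ppm, water = 0).  Each saturable
pool (direct water saturation, semi-solid magnetization transfer, relayed
NOE, amide, amine) attenuates the spectrum with a Lorentzian line

    L_n(w) = a_n * s_n^2 / (s_n^2 + 4 (w - w_n)^2)

parameterized by its amplitude ``a_n`` (fraction of the reference signal),
center ``w_n`` (ppm) and full width at half maximum ``s_n`` (ppm), so that

    S/S0 = 1 - sum_n L_n(w).

The amplitude/FWHM parameterization has the two defining identities
L_n(w_n) = a_n and L_n(w_n +/- s_n/2) = a_n / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import yaml

#: canonical pool order used throughout the package
POOL_NAMES: Tuple[str, ...] = ("DS", "MT", "NOE", "amide", "amine")


@dataclass(frozen=True)
class Pool:
    """One Lorentzian pool: center (ppm), amplitude (fraction of S0), FWHM (ppm)."""

    name: str
    center: float
    amplitude: float
    fwhm: float

    def __post_init__(self) -> None:
        if self.name not in POOL_NAMES:
            raise ValueError(f"unknown pool name {self.name!r}; expected one of {POOL_NAMES}")
        if not (0.0 <= self.amplitude <= 1.0):
            raise ValueError(f"pool {self.name}: amplitude {self.amplitude} outside [0, 1]")
        if not self.fwhm > 0:
            raise ValueError(f"pool {self.name}: fwhm must be > 0, got {self.fwhm}")


def lorentzian_eval(offset_ppm, pool: Pool):
    """Evaluate the Lorentzian attenuation of ``pool`` at ``offset_ppm``.

    Vectorized over ``offset_ppm``; returns values in [0, amplitude].
    """
    w = np.asarray(offset_ppm, dtype=float)
    d = w - pool.center
    s2 = pool.fwhm * pool.fwhm
    return pool.amplitude * s2 / (s2 + 4.0 * d * d)


# per-parameter (low, high) bounds and initial values, keyed
# "<pool>.<amplitude|center|fwhm>"
ParamTable = Dict[str, float]
BoundsTable = Dict[str, Tuple[float, float]]


@dataclass
class PoolSet:
    """Five named pools plus fitting metadata (per-parameter bounds/initials).

    ``pools`` maps each of the five canonical names to a :class:`Pool`.  When
    used as ground truth the pools carry the true parameters; when used as a
    fit configuration the pools carry the initial values and ``bounds`` the
    box constraints.
    """

    pools: Dict[str, Pool]
    bounds: BoundsTable = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.pools) != set(POOL_NAMES):
            raise ValueError(f"PoolSet requires exactly the pools {POOL_NAMES}, got {sorted(self.pools)}")
        for key, (lo, hi) in self.bounds.items():
            init = self._param(key)
            if not (lo <= init <= hi):
                raise ValueError(f"initial value {init} of {key!r} outside bounds ({lo}, {hi})")

    def _param(self, key: str) -> float:
        name, attr = key.split(".")
        return getattr(self.pools[name], attr)

    def ordered(self) -> Tuple[Pool, ...]:
        return tuple(self.pools[n] for n in POOL_NAMES)

    def with_pool(self, name: str, **changes) -> "PoolSet":
        pools = dict(self.pools)
        pools[name] = replace(pools[name], **changes)
        return PoolSet(pools=pools, bounds=dict(self.bounds))

    # -- flat parameter vector interface used by the fitter -----------------
    @staticmethod
    def param_keys() -> Tuple[str, ...]:
        return tuple(f"{n}.{a}" for n in POOL_NAMES for a in ("amplitude", "center", "fwhm"))

    def initial_vector(self) -> np.ndarray:
        return np.array([self._param(k) for k in self.param_keys()])

    def bounds_vectors(self) -> Tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for k in self.param_keys():
            b = self.bounds.get(k)
            if b is None:
                name, attr = k.split(".")
                b = (0.0, 1.0) if attr == "amplitude" else ((-100.0, 100.0) if attr == "center" else (1e-3, 200.0))
            lo.append(b[0])
            hi.append(b[1])
        return np.array(lo), np.array(hi)

    @staticmethod
    def from_vector(x: Sequence[float]) -> "PoolSet":
        pools = {}
        for i, name in enumerate(POOL_NAMES):
            a, c, s = x[3 * i], x[3 * i + 1], x[3 * i + 2]
            pools[name] = Pool(name=name, center=float(c), amplitude=float(np.clip(a, 0, 1)), fwhm=float(s))
        return PoolSet(pools=pools)

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pools": {n: {"center": p.center, "amplitude": p.amplitude, "fwhm": p.fwhm}
                      for n, p in self.pools.items()},
            "bounds": {k: list(v) for k, v in self.bounds.items()},
        }

    @staticmethod
    def from_dict(d: Mapping) -> "PoolSet":
        pools = {n: Pool(name=n, **spec) for n, spec in d["pools"].items()}
        bounds = {k: tuple(v) for k, v in d.get("bounds", {}).items()}
        return PoolSet(pools=pools, bounds=bounds)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @staticmethod
    def from_yaml(path) -> "PoolSet":
        with open(path) as fh:
            return PoolSet.from_dict(yaml.safe_load(fh))


def zspec_forward(offset_ppm, pool_set: PoolSet):
    """Noiseless Z-spectrum S/S0 = 1 - sum of pool Lorentzians.

    Raises ``ValueError`` if the configuration drives the signal negative at
    any evaluated offset (un-physical pool amplitudes).
    """
    w = np.asarray(offset_ppm, dtype=float)
    total = np.zeros_like(w)
    for pool in pool_set.ordered():
        total = total + lorentzian_eval(w, pool)
    z = 1.0 - total
    if np.any(z < 0):
        raise ValueError("pool amplitudes sum above 1 at some offsets: negative Z-spectrum")
    return z


def default_fit_config(amine_center: float = 2.0) -> PoolSet:
    """Initial values and box bounds for the five-pool fit.

    Centers: DS at water (0 ppm, free within +/-0.3), MT broad and slightly
    upfield (-2.5 +/- 2 ppm), relayed NOE at -3.5 +/- 0.5, amide at +3.5 +/-
    0.5 and amine at +2.0 +/- 0.5 (the amine center is configurable; some
    protocols place it at 2.75 ppm).  Widths in ppm (FWHM); the MT pool is
    constrained to stay broad (>= 10 ppm) so it cannot collapse onto the
    NOE/DS lines.
    """
    pools = {
        "DS": Pool("DS", center=0.0, amplitude=0.8, fwhm=2.0),
        "MT": Pool("MT", center=-2.5, amplitude=0.1, fwhm=25.0),
        "NOE": Pool("NOE", center=-3.5, amplitude=0.1, fwhm=3.0),
        "amide": Pool("amide", center=3.5, amplitude=0.05, fwhm=2.0),
        "amine": Pool("amine", center=amine_center, amplitude=0.05, fwhm=2.0),
    }
    bounds = {
        "DS.amplitude": (0.0, 1.0), "DS.center": (-0.3, 0.3), "DS.fwhm": (0.3, 12.0),
        "MT.amplitude": (0.0, 1.0), "MT.center": (-4.5, -0.5), "MT.fwhm": (10.0, 100.0),
        "NOE.amplitude": (0.0, 1.0), "NOE.center": (-4.0, -3.0), "NOE.fwhm": (0.5, 10.0),
        "amide.amplitude": (0.0, 1.0), "amide.center": (3.0, 4.0), "amide.fwhm": (0.5, 10.0),
        "amine.amplitude": (0.0, 1.0), "amine.center": (amine_center - 0.5, amine_center + 0.5),
        "amine.fwhm": (0.5, 10.0),
    }
    return PoolSet(pools=pools, bounds=bounds)
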