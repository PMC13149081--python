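"""Conventional per-pixel Z-spectrum quantification.

Implements the two classical feature extractors used as comparison inputs:
MTRasym-based APT-weighted contrast and bounded multi-pool Lorentzian
least-squares fitting.  These produce the features that the off-the-shelf
logistic-regression baselines consume; the classifiers themselves are out of
scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .phantom import PoolParams


@dataclass
class LorentzianFitResult:
    """Result of a bounded multi-pool Lorentzian fit on one Z-spectrum."""

    pools: tuple[PoolParams, ...]
    residual: float
    converged: bool
    n_iter: int

    def amplitude(self, name: str) -> float:
        for p in self.pools:
            if p.name == name:
                return p.amplitude
        raise KeyError(name)


def _interp_z(zspec: np.ndarray, offsets: np.ndarray, target: float) -> np.ndarray:
    """Linear interpolation of Z at ``target`` ppm along the last axis."""
    offsets = np.asarray(offsets, float)
    if target < offsets.min() or target > offsets.max():
        raise ValueError(
            f"target {target} ppm outside offset span "
            f"[{offsets.min()}, {offsets.max()}]"
        )
    idx = np.searchsorted(offsets, target, side="right") - 1
    idx = min(max(idx, 0), offsets.size - 2)
    left = offsets[idx]
    frac = (target - left) / (offsets[idx + 1] - left)
    z = np.asarray(zspec, float)
    return z[..., idx] * (1.0 - frac) + z[..., idx + 1] * frac


def mtr_asym(
    zspec: np.ndarray, offsets: Sequence[float] | np.ndarray, target: float = 3.5
) -> np.ndarray | float:
    """Magnetization-transfer-ratio asymmetry ``Z(-target) - Z(+target)``.

    At 3.5 ppm this is the APT-weighted (APTw) contrast.  ``zspec`` may be a
    single spectrum (C,) or a map (..., C); offsets not on the grid are
    linearly interpolated (the default grid is dense, 0.25 ppm).
    """
    out = _interp_z(zspec, offsets, -target) - _interp_z(zspec, offsets, target)
    return float(out) if np.ndim(out) == 0 else out


def default_pool_template() -> list[PoolParams]:
    """Initial values for the 6-pool fit (centers are nominal positions)."""
    return [
        PoolParams("water", 0.8, 0.0, 1.6),
        PoolParams("mt", 0.05, -1.0, 25.0),
        PoolParams("apt", 0.02, 3.5, 1.2),
        PoolParams("noe", 0.02, -3.5, 2.5),
        PoolParams("cr", 0.01, 2.0, 0.8),
        PoolParams("glc", 0.01, 1.2, 1.0),
    ]


def lorentzian_fit(
    zspec: np.ndarray,
    offsets: Sequence[float] | np.ndarray,
    pool_template: Sequence[PoolParams] | None = None,
    free_water_center: float = 0.3,
    max_iter: int = 2000,
) -> LorentzianFitResult:
    """Bounded nonlinear least-squares fit of ``1 - Z`` by a pool sum.

    Free parameters per pool: amplitude in [0, 1) and FWHM in [0.1, 60] ppm;
    centers are fixed at their nominal positions except water, which may move
    within ``+-free_water_center`` ppm.  The fit minimizes the sum of squared
    differences between ``sum of pools`` and the observed ``1 - Z``.
    Deterministic given identical inputs and template.
    """
    offsets = np.asarray(offsets, float)
    z = np.asarray(zspec, float)
    pools = list(pool_template) if pool_template is not None else default_pool_template()
    if offsets.size < 2 * 3 * len(pools):
        raise ValueError(
            f"need >= {2 * 3 * len(pools)} offsets for {len(pools)} pools, "
            f"got {offsets.size}"
        )

    sat = 1.0 - z
    water_free = [p.name == "water" for p in pools]

    # parameter vector: per pool (A, G) plus one water-center slot if present
    x0, lo, hi = [], [], []
    for p in pools:
        x0 += [p.amplitude, p.width]
        lo += [0.0, 0.1]
        hi += [1.0 - 1e-9, 60.0]
    has_water = any(water_free)
    if has_water:
        wi = water_free.index(True)
        x0.append(pools[wi].center)
        lo.append(pools[wi].center - free_water_center)
        hi.append(pools[wi].center + free_water_center)

    centers = np.array([p.center for p in pools])
    hw_factor = 0.25  # (G/2)^2 = G^2/4

    def model(x: np.ndarray) -> np.ndarray:
        cs = centers.copy()
        if has_water:
            cs[wi] = x[-1]
        amps = x[0 : 2 * len(pools) : 2]
        wids = x[1 : 2 * len(pools) : 2]
        hw2 = hw_factor * wids**2
        return np.sum(
            amps[:, None] * hw2[:, None] / (hw2[:, None] + (offsets[None, :] - cs[:, None]) ** 2),
            axis=0,
        )

    res = least_squares(
        lambda x: model(x) - sat,
        np.asarray(x0, float),
        bounds=(np.asarray(lo), np.asarray(hi)),
        max_nfev=max_iter,
        method="trf",
        ftol=1e-14,
        xtol=1e-14,
        gtol=1e-14,
    )
    x = res.x
    fitted = []
    for j, p in enumerate(pools):
        center = x[-1] if (has_water and j == wi) else p.center
        fitted.append(
            PoolParams(p.name, float(x[2 * j]), float(center), float(x[2 * j + 1]))
        )
    return LorentzianFitResult(
        pools=tuple(fitted),
        residual=float(2.0 * res.cost),
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
    )


def mtr_asym_map(
    data: np.ndarray, offsets: np.ndarray, target: float = 3.5
) -> np.ndarray:
    """Per-pixel APTw map for an (H, W, C) Z-stack."""
    return np.asarray(mtr_asym(data, offsets, target))


def lorentzian_fit_map(
    data: np.ndarray,
    offsets: np.ndarray,
    mask: np.ndarray | None = None,
    pool_template: Sequence[PoolParams] | None = None,
) -> dict[str, np.ndarray]:
    """Per-pixel fitted amplitude maps (slow; restrict via ``mask``)."""
    H, W, _ = data.shape
    template = list(pool_template) if pool_template else default_pool_template()
    maps = {p.name: np.full((H, W), np.nan) for p in template}
    sel = np.ones((H, W), bool) if mask is None else np.asarray(mask, bool)
    for r, c in zip(*np.nonzero(sel)):
        fit = lorentzian_fit(data[r, c], offsets, pool_template=template)
        for p in fit.pools:
            maps[p.name][r, c] = p.amplitude
    return maps
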