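"""Synthetic multi-offset CEST phantom.

Generates 2-D multi-offset CEST "patients" with known tumor masks and
genotype-dependent Z-spectral structure, plus the two acquisition-degradation
operators used in robustness experiments (Rician noise, B0 field shift).

The forward model is a sum of Lorentzian saturation pools on top of a flat
baseline::

    Z(dw) = 1 - sum_p  A_p * (G_p/2)^2 / ((G_p/2)^2 + (dw - d_p)^2)

with amplitudes ``A`` as fractions of M0, centers ``d`` and full widths at
half maximum ``G`` in ppm.  Saturation-pulse physics (power/duration) is not
modeled — only its Lorentzian-shaped end effect on the Z-spectrum.

Conventions (fixed package-wide):

* Z-spectra are stored as S/M0; the reference image (M0, nominally acquired
  far off-resonance at +100 ppm) is saturation-free, Z = 1.
* The default offset grid is 41 evenly spaced values from -5.0 to +5.0 ppm
  (0.25 ppm spacing).
* A B0 field value ``f`` (ppm) means the voxel's resonance is displaced by
  ``f``: the observed spectrum is the stored spectrum sampled at
  ``offset - f``, so a water-only minimum relocates from 0 to ``+f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class PoolParams:
    """One Lorentzian saturation pool.

    Parameters
    ----------
    name : str
        Pool label (e.g. ``"apt"``, ``"noe"``).
    amplitude : float
        Peak saturation as a fraction of M0, ``>= 0`` and ``< 1``.
    center : float
        Resonance offset in ppm (water at 0).
    width : float
        Full width at half maximum in ppm, ``> 0``.
    """

    name: str
    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.amplitude >= 1:
            raise ValueError(f"pool {self.name!r}: amplitude must be in [0, 1), got {self.amplitude}")
        if self.width <= 0:
            raise ValueError(f"pool {self.name!r}: width must be > 0, got {self.width}")


@dataclass(frozen=True)
class TissueSpectralParams:
    """The pool collection defining one tissue class's Z-spectrum."""

    label: str
    pools: tuple[PoolParams, ...]

    def validate(self, offsets: np.ndarray) -> None:
        """Check that total saturation stays below 1 everywhere on the grid."""
        total = sum_lorentzians(np.asarray(offsets, float), self.pools)
        if np.any(total >= 1.0):
            raise ValueError(
                f"tissue {self.label!r}: summed pool saturation reaches "
                f"{total.max():.3f} >= 1 on the offset grid"
            )


@dataclass
class CESTVolume:
    """One patient-slice stack: Z-values, M0 image and the ppm offset list.

    ``data`` has shape (H, W, C) with C == len(offsets); values are S/M0.
    ``clamp_mask`` (optional) flags pixels whose spectrum was clamped at a
    grid end during a B0 resampling.
    """

    data: np.ndarray
    m0: np.ndarray
    offsets: np.ndarray
    clamp_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.m0 = np.asarray(self.m0, dtype=np.float64)
        self.offsets = np.asarray(self.offsets, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be H x W x C, got shape {self.data.shape}")
        if self.data.shape[2] != self.offsets.size:
            raise ValueError(
                f"channel count {self.data.shape[2]} != offset count {self.offsets.size}"
            )
        if self.m0.shape != self.data.shape[:2]:
            raise ValueError("M0 image shape must match spatial shape of data")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Z-values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class PatientRecord:
    """A phantom patient: volume, tumor mask, genotype labels, split slot."""

    patient_id: str
    volume: CESTVolume
    tumor_mask: np.ndarray
    idh: int
    mgmt: int
    split: str | int | None = None  # "holdout" or a dev fold index

    def __post_init__(self) -> None:
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        if self.tumor_mask.shape != self.volume.shape:
            raise ValueError("mask shape must match volume spatial shape")
        if self.idh not in (0, 1) or self.mgmt not in (0, 1):
            raise ValueError("genotype labels must be binary")


def default_offsets() -> np.ndarray:
    """41 evenly spaced saturation offsets from -5.0 to +5.0 ppm."""
    return np.linspace(-5.0, 5.0, 41)


# Pool presets.  Amplitudes/widths are package constants chosen to give
# plausible-looking Z-spectra (water-dominated dip at 0, broad MT background,
# myelin-rich white matter with stronger NOE); they are configuration, not
# measurements.
_WATER = dict(name="water", center=0.0, width=1.6)
_MT = dict(name="mt", center=-1.0, width=25.0)
_APT = dict(name="apt", center=3.5, width=1.2)
_NOE = dict(name="noe", center=-3.5, width=2.5)
_CR = dict(name="cr", center=2.0, width=0.8)
_GLC = dict(name="glc", center=1.2, width=1.0)


def _tissue(label: str, amps: dict[str, float]) -> TissueSpectralParams:
    base = {"water": _WATER, "mt": _MT, "apt": _APT, "noe": _NOE, "cr": _CR, "glc": _GLC}
    pools = tuple(
        PoolParams(amplitude=amps[k], **base[k]) for k in base if k in amps
    )
    return TissueSpectralParams(label=label, pools=pools)


def gray_matter_params() -> TissueSpectralParams:
    return _tissue(
        "gray_matter",
        {"water": 0.80, "mt": 0.055, "apt": 0.030, "noe": 0.040, "cr": 0.008, "glc": 0.006},
    )


def white_matter_params() -> TissueSpectralParams:
    # abundant myelin -> strong NOE, larger semi-solid MT background
    return _tissue(
        "white_matter",
        {"water": 0.78, "mt": 0.090, "apt": 0.034, "noe": 0.070, "cr": 0.007, "glc": 0.005},
    )


def tumor_params(
    apt_shift: float = 0.0, noe_shift: float = 0.0
) -> TissueSpectralParams:
    """Tumor preset; genotype effects enter as additive amplitude shifts.

    The deeper water pool reflects elevated free-water content (edema),
    which gives tumors a clear direct-saturation contrast against both
    normal-tissue classes for every genotype combination.
    """
    return _tissue(
        "tumor",
        {
            "water": 0.85,
            "mt": 0.070,
            "apt": 0.060 + apt_shift,
            "noe": 0.035 + noe_shift,
            "cr": 0.012,
            "glc": 0.012,
        },
    )


@dataclass
class PhantomConfig:
    """Generator settings; the seed fully determines the output cohort.

    Genotype effects are additive shifts on the tumor APT/NOE amplitudes for
    label-1 patients (IDH-mutant: higher APT, lower NOE; MGMT-methylated:
    lower APT, slightly higher NOE).  ``idh_direction=-1`` reverses the IDH
    APT direction.
    """

    n_patients: int = 20
    image_size: int = 240
    offsets: np.ndarray = field(default_factory=default_offsets)
    tumor_radius_range: tuple[float, float] = (9.0, 16.0)
    tumor_irregularity: float = 0.35
    idh_apt_effect: float = 0.030
    idh_noe_effect: float = -0.010
    mgmt_apt_effect: float = -0.015
    mgmt_noe_effect: float = 0.005
    idh_direction: int = 1
    class_balance: float = 0.5
    noise_sigma: float = 0.01
    b0_amplitude: float = 0.0
    b0_smoothness: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.float64)
        lo, hi = self.tumor_radius_range
        if not (0 < lo <= hi):
            raise ValueError("tumor radius range must satisfy 0 < lo <= hi")
        if 2 * hi >= self.image_size:
            raise ValueError(
                f"tumor radius {hi} incompatible with image size {self.image_size}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if not 0 < self.class_balance < 1:
            raise ValueError("class balance must be in (0, 1)")


# --------------------------------------------------------------------------- #
# spectral forward model
# --------------------------------------------------------------------------- #


def lorentzian(offsets: Sequence[float] | np.ndarray, pool: PoolParams) -> np.ndarray:
    """Evaluate one Lorentzian line, peak ``A`` at the center, FWHM ``G``.

    ``L(dw) = A (G/2)^2 / ((G/2)^2 + (dw - d)^2)``
    """
    if pool.width <= 0:
        raise ValueError("width must be > 0")
    dw = np.asarray(offsets, dtype=np.float64)
    hw2 = (pool.width / 2.0) ** 2
    return pool.amplitude * hw2 / (hw2 + (dw - pool.center) ** 2)


def sum_lorentzians(offsets: np.ndarray, pools: Sequence[PoolParams]) -> np.ndarray:
    out = np.zeros(np.asarray(offsets, float).shape, dtype=np.float64)
    for p in pools:
        out += lorentzian(offsets, p)
    return out


def simulate_zspectrum(
    params: TissueSpectralParams, offsets: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Noiseless Z-spectrum of a tissue class: ``Z = 1 - sum of pools``."""
    dw = np.asarray(offsets, dtype=np.float64)
    params.validate(dw)
    return 1.0 - sum_lorentzians(dw, params.pools)


# --------------------------------------------------------------------------- #
# degradation operators
# --------------------------------------------------------------------------- #


def add_rician_noise(volume: CESTVolume, sigma: float, seed: int) -> CESTVolume:
    """Per-channel Rician noise: ``v -> sqrt((v + n1)^2 + n2^2)``.

    ``sigma`` is the Gaussian sd of each quadrature component as a fraction
    of M0.  Channels are corrupted independently (magnitude-image physics;
    no inter-offset noise correlation).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return volume
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=volume.data.shape)
    n2 = rng.normal(0.0, sigma, size=volume.data.shape)
    noisy = np.sqrt((volume.data + n1) ** 2 + n2**2)
    return CESTVolume(noisy, volume.m0.copy(), volume.offsets.copy())


def apply_b0_shift(volume: CESTVolume, fieldmap: np.ndarray) -> CESTVolume:
    """Resample each pixel's Z-spectrum at ``offsets - field`` (linear interp).

    Shifts beyond the grid ends are clamped to the edge value; affected
    pixels are flagged in the returned volume's ``clamp_mask``.
    """
    fieldmap = np.asarray(fieldmap, dtype=np.float64)
    if fieldmap.shape != volume.shape:
        raise ValueError("field map shape must match volume spatial shape")
    if not np.all(np.isfinite(fieldmap)):
        raise ValueError("field map must be finite")
    offs = volume.offsets
    span = offs.max() - offs.min()
    if np.any(np.abs(fieldmap) >= span / 2):
        raise ValueError("field magnitude must be below half the offset span")

    H, W = volume.shape
    C = offs.size
    # sample positions per pixel: offsets - f
    pos = offs[None, :] - fieldmap.reshape(-1)[:, None]  # (H*W, C)
    clamped = (pos < offs[0]) | (pos > offs[-1])
    pos_c = np.clip(pos, offs[0], offs[-1])
    idx = np.searchsorted(offs, pos_c, side="right") - 1
    idx = np.clip(idx, 0, C - 2)
    left = offs[idx]
    step = offs[idx + 1] - left
    frac = (pos_c - left) / step
    flat = volume.data.reshape(-1, C)
    rows = np.arange(flat.shape[0])[:, None]
    out = flat[rows, idx] * (1.0 - frac) + flat[rows, idx + 1] * frac
    return CESTVolume(
        out.reshape(H, W, C),
        volume.m0.copy(),
        offs.copy(),
        clamp_mask=clamped.any(axis=1).reshape(H, W),
    )


# --------------------------------------------------------------------------- #
# cohort generation
# --------------------------------------------------------------------------- #


def _smooth_field(rng: np.random.Generator, size: int, smoothness: float) -> np.ndarray:
    """Unit-amplitude smooth random field in [-1, 1]."""
    raw = rng.normal(size=(size, size))
    sm = ndimage.gaussian_filter(raw, smoothness)
    peak = np.abs(sm).max()
    return sm / peak if peak > 0 else sm


def _brain_and_tissue_masks(size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brain ellipse with an inner white-matter ellipse and gray-matter ring."""
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    ry, rx = size * 0.46, size * 0.40
    brain = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    wm = ((yy - cy) / (0.65 * ry)) ** 2 + ((xx - cx) / (0.65 * rx)) ** 2 <= 1.0
    gm = brain & ~wm
    return brain, gm, wm


def _tumor_mask(
    rng: np.random.Generator, brain: np.ndarray, radius: float, irregularity: float
) -> np.ndarray:
    """Smoothed-noise blob around a random in-brain center; largest component."""
    size = brain.shape[0]
    ys, xs = np.nonzero(ndimage.binary_erosion(brain, iterations=int(radius) + 2))
    k = rng.integers(len(ys))
    cy, cx = ys[k], xs[k]
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    bump = ndimage.gaussian_filter(rng.normal(size=(size, size)), radius / 3.0)
    peak = np.abs(bump).max()
    if peak > 0:
        bump = bump / peak
    field = (1.0 - dist / radius) + irregularity * bump
    mask = (field > 0) & brain
    if not mask.any():
        mask = dist <= max(radius / 2.0, 1.5)
        mask &= brain
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def generate_phantom(config: PhantomConfig) -> list[PatientRecord]:
    """Generate a cohort of phantom patients from ``config`` (seeded).

    Each patient gets a connected tumor blob inside a gray/white-matter brain
    ellipse; tumor pixels carry the genotype-conditioned spectrum.  Class
    labels follow ``class_balance`` exactly (floor for class 1 of IDH;
    MGMT labels are an independent balanced assignment).
    """
    rng = np.random.default_rng(config.seed)
    offs = config.offsets
    size = config.image_size

    # deterministic balanced labels, shuffled per cohort
    n = config.n_patients
    n1 = int(round(n * config.class_balance))
    idh_labels = np.array([1] * n1 + [0] * (n - n1))
    mgmt_labels = np.array([1] * n1 + [0] * (n - n1))
    rng.shuffle(idh_labels)
    rng.shuffle(mgmt_labels)

    gm = gray_matter_params()
    wm = white_matter_params()
    z_gm = simulate_zspectrum(gm, offs)
    z_wm = simulate_zspectrum(wm, offs)
    brain, gm_mask, wm_mask = _brain_and_tissue_masks(size)

    records: list[PatientRecord] = []
    for i in range(n):
        idh = int(idh_labels[i])
        mgmt = int(mgmt_labels[i])
        apt_shift = (
            config.idh_direction * config.idh_apt_effect * idh
            + config.mgmt_apt_effect * mgmt
        )
        noe_shift = (
            config.idh_direction * config.idh_noe_effect * idh
            + config.mgmt_noe_effect * mgmt
        )
        tum = tumor_params(apt_shift=apt_shift, noe_shift=noe_shift)
        z_tum = simulate_zspectrum(tum, offs)

        radius = rng.uniform(*config.tumor_radius_range)
        mask = _tumor_mask(rng, brain, radius, config.tumor_irregularity)

        data = np.ones((size, size, offs.size), dtype=np.float64)
        data[gm_mask] = z_gm
        data[wm_mask] = z_wm
        data[mask] = z_tum

        m0 = np.full((size, size), 0.02)
        m0[gm_mask] = 1.0
        m0[wm_mask] = 0.95
        m0[mask] = 1.05

        vol = CESTVolume(data, m0, offs.copy())
        if config.b0_amplitude > 0:
            fieldmap = config.b0_amplitude * _smooth_field(
                rng, size, config.b0_smoothness
            )
            vol = apply_b0_shift(vol, fieldmap)
        if config.noise_sigma > 0:
            vol = add_rician_noise(
                vol, config.noise_sigma, seed=int(rng.integers(2**31 - 1))
            )
        records.append(
            PatientRecord(
                patient_id=f"P{i:03d}",
                volume=vol,
                tumor_mask=mask,
                idh=idh,
                mgmt=mgmt,
            )
        )
    return records


def degrade_cohort(
    records: Sequence[PatientRecord],
    noise_sigma: float = 0.0,
    b0_amplitude: float = 0.0,
    b0_smoothness: float = 8.0,
    seed: int = 0,
) -> list[PatientRecord]:
    """Apply test-time degradations to an existing cohort (robustness runs)."""
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        vol = rec.volume
        if b0_amplitude > 0:
            fieldmap = b0_amplitude * _smooth_field(
                rng, vol.shape[0], b0_smoothness
            )
            vol = apply_b0_shift(vol, fieldmap)
        if noise_sigma > 0:
            vol = add_rician_noise(vol, noise_sigma, seed=int(rng.integers(2**31 - 1)))
        out.append(replace(rec, volume=vol))
    return out
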