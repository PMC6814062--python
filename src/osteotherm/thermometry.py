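"""Synthetic PRFS MR thermometry and the intracortical fluoroptic sensor.

Emulation operates on temperature maps directly (no k-space or phase
reconstruction): the truth field is slab-averaged over the slice
thickness, resampled in-plane, and corrupted with Gaussian noise plus a
slow spatially-uniform drift.  Voxels whose tissue class carries no
PRFS signal (cortical bone, fatty medulla) are NaN throughout.

Default slice orientation is perpendicular to the bone axis (x), so a
frame is indexed by (y, z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import pearsonr

from .geometry import Tissue, TissueMap

__all__ = [
    "ThermoConfig",
    "DriftModel",
    "ThermoFrame",
    "SensorTrace",
    "sample_frame",
    "drift_correct",
    "disc_offsets",
    "roi_mean",
    "virtual_sensor_sample",
    "cross_correlate",
]


@dataclass(frozen=True)
class DriftModel:
    """Slow background drift, linear plus sinusoid (degC-equivalent)."""

    linear_c_per_min: float = 0.025
    sine_amplitude_c: float = 0.3
    sine_period_s: float = 720.0

    def __call__(self, t_s: float) -> float:
        return (self.linear_c_per_min * t_s / 60.0
                + self.sine_amplitude_c * np.sin(2 * np.pi * t_s / self.sine_period_s))


ZERO_DRIFT = DriftModel(0.0, 0.0)


@dataclass(frozen=True)
class ThermoConfig:
    in_plane_mm: float = 1.0
    slice_thickness_mm: float = 4.0
    frame_interval_s: float = 1.6
    noise_std_c: float = 0.2
    drift: DriftModel = field(default_factory=DriftModel)
    masked_classes: tuple[int, ...] = (int(Tissue.CORTICAL), int(Tissue.MEDULLA))

    def __post_init__(self) -> None:
        if self.noise_std_c < 0 or self.frame_interval_s <= 0:
            raise ValueError("noise_std_c >= 0 and frame_interval_s > 0 required")


@dataclass
class ThermoFrame:
    """Single-slice temperature-elevation map (NaN where no MR signal)."""

    data: np.ndarray            # (ny, nz)
    truth: np.ndarray           # noiseless, drift-free resampled elevation
    y_mm: np.ndarray
    z_mm: np.ndarray
    t_s: float
    pixel_mm: float

    def index_of(self, y: float, z: float) -> tuple[int, int]:
        iy = int(np.clip(round((y - self.y_mm[0]) / self.pixel_mm), 0,
                         self.y_mm.size - 1))
        iz = int(np.clip(round((z - self.z_mm[0]) / self.pixel_mm), 0,
                         self.z_mm.size - 1))
        return iy, iz


@dataclass
class SensorTrace:
    """Fluoroptic point-sensor readings (0.1 degC quantization)."""

    times_s: np.ndarray
    values_c: np.ndarray


def _pixel_axis(lo: float, hi: float, pitch: float) -> np.ndarray:
    half = int(np.floor(min(-lo, hi) / pitch))
    return np.arange(-half, half + 1) * pitch


def sample_frame(T: np.ndarray, tmap: TissueMap, cfg: ThermoConfig, t_s: float,
                 rng: np.random.Generator | None = None,
                 slice_x_mm: float = 0.0) -> ThermoFrame:
    """Acquire one thermometry frame from the truth field.

    Slab-averages over the slice thickness along x, linearly resamples
    to the in-plane pixel pitch, then applies drift and i.i.d. Gaussian
    noise; masked tissue classes become NaN.
    """
    x, y, z = tmap.axes_mm
    half = cfg.slice_thickness_mm / 2.0
    in_slab = np.abs(x - slice_x_mm) <= half + 1e-9
    if not np.any(in_slab):
        in_slab = np.abs(x - slice_x_mm) == np.min(np.abs(x - slice_x_mm))
    slab = T[in_slab].mean(axis=0)          # (ny, nz)

    yq = _pixel_axis(y[0], y[-1], cfg.in_plane_mm)
    zq = _pixel_axis(z[0], z[-1], cfg.in_plane_mm)
    if yq.size == y.size and zq.size == z.size and \
            np.allclose(yq, y) and np.allclose(zq, z):
        truth = slab.copy()
    else:
        interp = RegularGridInterpolator((y, z), slab, bounds_error=False,
                                         fill_value=0.0)
        YY, ZZ = np.meshgrid(yq, zq, indexing="ij")
        truth = interp(np.column_stack([YY.ravel(), ZZ.ravel()])).reshape(YY.shape)

    # mask from the labels on the central slice plane
    ix = int(np.argmin(np.abs(x - slice_x_mm)))
    lab_interp = RegularGridInterpolator((y, z), tmap.labels[ix].astype(float),
                                         method="nearest", bounds_error=False,
                                         fill_value=float(Tissue.WATER))
    YY, ZZ = np.meshgrid(yq, zq, indexing="ij")
    labs = lab_interp(np.column_stack([YY.ravel(), ZZ.ravel()])).reshape(YY.shape)
    masked = np.isin(labs.astype(int), cfg.masked_classes)

    data = truth + cfg.drift(t_s)
    if cfg.noise_std_c > 0:
        if rng is None:
            rng = np.random.default_rng()
        data = data + rng.normal(0.0, cfg.noise_std_c, size=data.shape)
    data = np.where(masked, np.nan, data)
    return ThermoFrame(data=data, truth=np.where(masked, np.nan, truth),
                       y_mm=yq, z_mm=zq, t_s=float(t_s),
                       pixel_mm=cfg.in_plane_mm)


def drift_correct(frame: ThermoFrame, roi: np.ndarray) -> ThermoFrame:
    """Subtract the mean of an unheated ROI from the whole frame.

    ``roi`` is a boolean mask over the frame.  Needs >= 5 unmasked
    pixels; warns when the ROI is actually heated (truth > 0.5 degC).
    """
    sel = roi & ~np.isnan(frame.data)
    if np.count_nonzero(sel) < 5:
        raise ValueError("drift-correction ROI must contain >= 5 unmasked pixels")
    truth_roi = frame.truth[sel]
    if np.nanmean(truth_roi) > 0.5:
        warnings.warn("drift-correction ROI overlaps the heated region "
                      f"(mean truth elevation {np.nanmean(truth_roi):.2f} degC)",
                      stacklevel=2)
    offset = float(np.mean(frame.data[sel]))
    return ThermoFrame(data=frame.data - offset, truth=frame.truth,
                       y_mm=frame.y_mm, z_mm=frame.z_mm, t_s=frame.t_s,
                       pixel_mm=frame.pixel_mm)


def disc_offsets(radius_px: int = 2) -> np.ndarray:
    """In-plane disc of pixel offsets; radius 2 gives the 13-pixel ROI."""
    offs = [(dy, dz) for dy in range(-radius_px, radius_px + 1)
            for dz in range(-radius_px, radius_px + 1)
            if dy * dy + dz * dz <= radius_px * radius_px]
    return np.array(offs, dtype=int)


def roi_mean(frame: ThermoFrame, center_yz_mm: tuple[float, float],
             radius_px: int = 2) -> float:
    """NaN-excluding mean over the 13-pixel disc ROI at ``center``.

    Raises when more than half of the ROI carries no signal.
    """
    cy, cz = frame.index_of(*center_yz_mm)
    offs = disc_offsets(radius_px)
    iy = np.clip(cy + offs[:, 0], 0, frame.y_mm.size - 1)
    iz = np.clip(cz + offs[:, 1], 0, frame.z_mm.size - 1)
    vals = frame.data[iy, iz]
    n_nan = int(np.count_nonzero(np.isnan(vals)))
    if n_nan > vals.size // 2:
        raise ValueError(f"ROI mean undefined: {n_nan}/{vals.size} pixels "
                         "have no MR signal")
    return float(np.nanmean(vals))


def virtual_sensor_sample(T: np.ndarray, tmap: TissueMap,
                          locus_mm: tuple[float, float, float],
                          precision_c: float = 0.1) -> float:
    """Fluoroptic reading: trilinear truth at the locus, quantized."""
    from scipy.ndimage import map_coordinates

    idx = (np.asarray(locus_mm) - tmap.origin_mm) / tmap.spacing_mm
    val = float(map_coordinates(T, idx.reshape(3, 1), order=1)[0])
    return round(val / precision_c) * precision_c


def cross_correlate(times_a, values_a, times_b, values_b) -> dict:
    """Pearson r and offset statistics of (a - b) on the overlap grid.

    Series b is linearly interpolated onto the samples of a that fall
    inside its support.  Needs >= 10 common samples.
    """
    ta = np.asarray(times_a, dtype=float)
    va = np.asarray(values_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    sel = (ta >= tb.min()) & (ta <= tb.max())
    if np.count_nonzero(sel) < 10:
        raise ValueError("fewer than 10 overlapping samples")
    a = va[sel]
    b = np.interp(ta[sel], tb, vb)
    diff = a - b
    if np.std(a) == 0 or np.std(b) == 0:
        r = 1.0 if np.allclose(a - a.mean(), b - b.mean()) else 0.0
    else:
        r = float(pearsonr(a, b)[0])
    return {"r": r, "mean_offset_c": float(diff.mean()),
            "min_offset_c": float(diff.min()), "max_offset_c": float(diff.max())}
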