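"""Heat diffusion by iterative Gaussian-kernel convolution.

Each time step convolves the temperature-elevation field with an
isotropic Gaussian of width ``sigma = sqrt(2 * D * dt)`` (the exact
propagator of the homogeneous heat equation) and then adds the source
term ``q * dt / C``.  Thermal properties are spatially uniform, which is
what makes the convolution kernel shift-invariant; cortical bone's
lower conductivity is deliberately neglected.

The module also provides the impulse-response / time-lag analysis: the
delay ``eps`` between the end of a short sonication and the focal-point
temperature maximum, its table over (bone radius R, focal offset H) and
the six-term quadratic surface fitted to it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import acoustics, sources
from .geometry import GeometryParams, Tissue, TissueMap, build_tissue_map

__all__ = [
    "ThermalParams",
    "TemperatureSeries",
    "LagSurfaceFit",
    "step",
    "simulate",
    "impulse_response",
    "time_lag",
    "lag_table",
    "fit_quadratic",
    "ring_uniformity",
    "cortical_hotspot",
]


@dataclass(frozen=True)
class ThermalParams:
    """Homogeneous thermal properties (ex vivo: no perfusion)."""

    diffusivity_m2_s: float = 1.4e-7
    volumetric_heat_capacity_j_m3_k: float = 3.8e6
    time_step_s: float = 2.0

    def __post_init__(self) -> None:
        if self.diffusivity_m2_s <= 0 or self.time_step_s <= 0:
            raise ValueError("diffusivity and time_step must be positive")

    def kernel_sigma_mm(self) -> float:
        return float(np.sqrt(2.0 * self.diffusivity_m2_s * self.time_step_s) * 1e3)


@dataclass
class TemperatureSeries:
    """Scalar temperature-elevation probe sampled over time."""

    times_s: np.ndarray
    values_c: np.ndarray
    sonication_end_s: float | None = None

    def __len__(self) -> int:
        return int(self.times_s.size)


def step(T: np.ndarray, q: np.ndarray | None, params: ThermalParams,
         spacing_mm: float) -> np.ndarray:
    """One diffusion step: ``T <- G_sigma * T + q dt / C``.

    Raises when the kernel is under-resolved (sigma < 0.5 voxel).
    """
    sigma_vox = params.kernel_sigma_mm() / spacing_mm
    if sigma_vox < 0.5:
        raise ValueError(
            f"under-resolved diffusion kernel: sigma = {sigma_vox:.2f} voxels "
            "(< 0.5); increase the time step or refine the grid")
    out = ndimage.gaussian_filter(T, sigma_vox, mode="constant", truncate=4.0)
    if q is not None:
        out = out + q * (params.time_step_s / params.volumetric_heat_capacity_j_m3_k)
    return out


def simulate(q_w_m3: np.ndarray, duty: np.ndarray, params: ThermalParams,
             spacing_mm: float, *, probe_index: tuple[int, int, int] | None = None,
             snapshot_steps: tuple[int, ...] = (),
             T0: np.ndarray | None = None):
    """Run ``len(duty)`` diffusion steps with a per-step source scaling.

    ``duty[i]`` multiplies the source during step ``i`` (0 = source off,
    as in post-sonication cooling where both the cortical and the
    tumoral absorption coefficients are nulled).

    Returns ``(series, snapshots, T_final)`` where ``series`` is the
    probe trace (None when no probe was requested) and ``snapshots``
    maps step index -> field copy.
    """
    T = np.zeros_like(q_w_m3) if T0 is None else T0.copy()
    n = len(duty)
    times = np.empty(n)
    probe = np.empty(n) if probe_index is not None else None
    snapshots: dict[int, np.ndarray] = {}
    for i, d in enumerate(duty):
        T = step(T, q_w_m3 * float(d) if d else None, params, spacing_mm)
        times[i] = (i + 1) * params.time_step_s
        if probe is not None:
            probe[i] = T[probe_index]
        if i in snapshot_steps:
            snapshots[i] = T.copy()
    on_steps = np.nonzero(np.asarray(duty) > 0)[0]
    end_s = float((on_steps[-1] + 1) * params.time_step_s) if on_steps.size else 0.0
    series = None
    if probe is not None:
        series = TemperatureSeries(times, probe, sonication_end_s=end_s)
    return series, snapshots, T


def build_sources(geom: GeometryParams, transducer: acoustics.TransducerSpec,
                  medium: acoustics.MediumSpec, src_params: sources.SourceParams,
                  *, element_size_mm: float = 0.8,
                  tmap: TissueMap | None = None):
    """Plumbing shared by the lag study and the closed-loop harness.

    Builds (tissue map, intensity field, facet, cortical source,
    tumoral source) for the configured focal offset.
    """
    from .geometry import inner_cortical_facet

    if tmap is None:
        tmap = build_tissue_map(geom)
    p = acoustics.rayleigh_pressure(transducer, medium, tmap,
                                    element_size_mm=element_size_mm)
    intensity = acoustics.intensity_from_pressure(p, medium)
    focus = tmap.breakthrough_center_mm + np.array([0, 0, transducer.focal_offset_mm])
    facet = inner_cortical_facet(tmap, transducer.beam_spec(focus))
    q_oven = sources.oven_effect_source(intensity, facet, src_params, tmap=tmap)
    q_direct = sources.direct_absorption_source(intensity, tmap, src_params,
                                                medium, transducer.frequency_hz)
    return tmap, intensity, facet, q_oven, q_direct


def impulse_response(geom: GeometryParams, transducer: acoustics.TransducerSpec,
                     medium: acoustics.MediumSpec,
                     src_params: sources.SourceParams, thermal: ThermalParams,
                     *, on_time_s: float = 10.0, max_time_s: float = 2400.0,
                     source: str = "cortical", element_size_mm: float = 0.8,
                     tmap: TissueMap | None = None) -> TemperatureSeries:
    """Focal-point elevation following a short sonication.

    With the cortical-only source the curve keeps rising after the
    sonication ends (delayed centripetal heating from the inner facet);
    with the tumoral source alone it decays monotonically.  The run
    stops once the post-sonication maximum is clearly passed.

    The oven deposit is restricted to the exposed facet here (the lag
    measures the transit of the post-focal energy across the cavity
    from the far wall; spreading the deposit around the perimeter would
    place sources arbitrarily close to the focal point and erase it).
    """
    if source not in ("cortical", "tumoral", "cumulated"):
        raise ValueError("source must be 'cortical', 'tumoral' or 'cumulated'")
    src_params = replace(src_params, redistribution="facet")
    tmap, _, _, q_oven, q_direct = build_sources(
        geom, transducer, medium, src_params,
        element_size_mm=element_size_mm, tmap=tmap)
    q = {"cortical": q_oven, "tumoral": q_direct,
         "cumulated": sources.combine_sources(q_oven, q_direct)}[source]

    focus = tmap.breakthrough_center_mm + np.array([0, 0, transducer.focal_offset_mm])
    probe = tmap.index_of(focus)

    dt = thermal.time_step_s
    n_on = max(1, int(round(on_time_s / dt)))
    T = np.zeros_like(q.q_w_m3)
    times, vals = [], []
    t_max, v_max = 0.0, -np.inf
    i = 0
    while (i + 1) * dt <= max_time_s:
        d = 1.0 if i < n_on else 0.0
        T = step(T, q.q_w_m3 if d else None, thermal, tmap.spacing_mm)
        t = (i + 1) * dt
        v = T[probe]
        times.append(t)
        vals.append(v)
        if v > v_max:
            v_max, t_max = v, t
        # stop once well past the (post-sonication) peak
        if t > n_on * dt + 30.0 and v < 0.85 * v_max and t > t_max + 30.0:
            break
        i += 1
    return TemperatureSeries(np.array(times), np.array(vals),
                             sonication_end_s=n_on * dt)


def time_lag(series: TemperatureSeries) -> float:
    """``eps = t(max) - t(end of sonication)``, clipped at 0.

    Raises when the maximum sits on the final sample (simulation too
    short to bracket the peak).
    """
    if series.sonication_end_s is None:
        raise ValueError("series has no recorded sonication end")
    i = int(np.argmax(series.values_c))
    if i == len(series) - 1:
        raise RuntimeError("temperature maximum at final sample: "
                           "simulation too short to measure the time lag")
    t_peak = series.times_s[i]
    if 0 < i < len(series) - 1:
        # parabolic refinement removes the time-step quantization
        y0, y1, y2 = series.values_c[i - 1:i + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            t_peak = t_peak + 0.5 * (y0 - y2) / denom * \
                (series.times_s[i + 1] - series.times_s[i])
    return float(max(0.0, t_peak - series.sonication_end_s))


def lag_table(r_values_mm, h_values_mm, *, transducer=None, medium=None,
              src_params=None, thermal=None, geom_template=None,
              element_size_mm: float = 0.8,
              on_time_s: float = 10.0) -> pd.DataFrame:
    """Cortical-source-only time lags over a (R, H) grid.

    Offsets with ``|H| >= R`` are skipped (outside the prescribed
    range).  Returns columns ``R_mm, H_mm, eps_s``.
    """
    transducer = transducer or acoustics.TransducerSpec()
    medium = medium or acoustics.MediumSpec()
    src_params = src_params or sources.SourceParams()
    thermal = thermal or ThermalParams()
    geom_template = geom_template or GeometryParams(grid_spacing_mm=1.0)

    rows = []
    for r in r_values_mm:
        geom = replace(geom_template, cortical_radius_mm=float(r))
        tmap = build_tissue_map(geom)
        for h in h_values_mm:
            if abs(h) >= r:
                continue
            tr = replace(transducer, focal_offset_mm=float(h))
            series = impulse_response(
                geom, tr, medium, src_params, thermal, on_time_s=on_time_s,
                source="cortical", element_size_mm=element_size_mm, tmap=tmap)
            rows.append({"R_mm": float(r), "H_mm": float(h),
                         "eps_s": time_lag(series)})
    return pd.DataFrame(rows)


_TERMS = ("c00", "c10", "c01", "c20", "c11", "c02")  # 1, H, R, H^2, HR, R^2


def _design(h: np.ndarray, r: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(h), h, r, h**2, h * r, r**2])


@dataclass
class LagSurfaceFit:
    """Six-term quadratic ``eps = sum c_mn H^m R^n`` (m + n <= 2)."""

    coefficients: dict[str, float]
    mean_abs_residual_s: float
    h_range_mm: tuple[float, float]
    r_range_mm: tuple[float, float]

    def predict(self, h_mm, r_mm) -> np.ndarray:
        h = np.asarray(h_mm, dtype=float)
        r = np.asarray(r_mm, dtype=float)
        c = self.coefficients
        return (c["c00"] + c["c10"] * h + c["c01"] * r + c["c20"] * h**2
                + c["c11"] * h * r + c["c02"] * r**2)


def fit_quadratic(table: pd.DataFrame) -> LagSurfaceFit:
    """Least-squares fit of the six-term quadratic lag surface."""
    h = table["H_mm"].to_numpy(dtype=float)
    r = table["R_mm"].to_numpy(dtype=float)
    eps = table["eps_s"].to_numpy(dtype=float)
    A = _design(h, r)
    coef, _, rank, _ = np.linalg.lstsq(A, eps, rcond=None)
    if rank < A.shape[1]:
        raise ValueError("rank-deficient design: need >= 6 independent (H, R) "
                         "combinations spanning both axes")
    resid = eps - A @ coef
    return LagSurfaceFit(
        coefficients=dict(zip(_TERMS, (float(c) for c in coef))),
        mean_abs_residual_s=float(np.mean(np.abs(resid))),
        h_range_mm=(float(h.min()), float(h.max())),
        r_range_mm=(float(r.min()), float(r.max())),
    )


def ring_uniformity(T: np.ndarray, tmap: TissueMap,
                    radius_mm: float | None = None, n_samples: int = 72) -> float:
    """Coefficient of variation of the elevation on an intra-cavity ring.

    The ring lies in the mid-plane x = 0, centred on the bone axis, with
    default radius ``(Rc - thickness) / 2``.  A uniform field gives 0.
    """
    if radius_mm is None:
        radius_mm = tmap.params.cavity_radius_mm / 2.0
    theta = np.linspace(0.0, 2 * np.pi, n_samples, endpoint=False)
    y = radius_mm * np.cos(theta)
    z = radius_mm * np.sin(theta)
    ix = tmap.index_of((0.0, 0.0, 0.0))[0]
    plane = T[ix]
    iy = (y - tmap.origin_mm[1]) / tmap.spacing_mm
    iz = (z - tmap.origin_mm[2]) / tmap.spacing_mm
    vals = ndimage.map_coordinates(plane, np.vstack([iy, iz]), order=1)
    mean = float(np.mean(vals))
    if mean == 0.0:
        return 0.0
    return float(np.std(vals) / mean)


def cortical_hotspot(T: np.ndarray, tmap: TissueMap) -> dict:
    """Location and value of the maximum cortical elevation."""
    cort = tmap.labels == int(Tissue.CORTICAL)
    if not np.any(cort):
        raise ValueError("tissue map contains no cortical voxels")
    vals = np.where(cort, T, -np.inf)
    idx = np.unravel_index(int(np.argmax(vals)), T.shape)
    pos = tmap.origin_mm + tmap.spacing_mm * np.array(idx, dtype=float)
    return {"value_c": float(T[idx]), "position_mm": pos,
            "distal": bool(pos[2] > 0.0)}
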