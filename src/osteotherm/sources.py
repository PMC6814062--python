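"""Volumetric heat sources: direct focal absorption + acoustic-oven term.

Two mechanisms deposit acoustic power as heat:

* direct absorption in soft tissue, ``q = 2 * beta * I`` (plane-wave
  absorption of the local time-averaged intensity);
* the "acoustic oven" term: the post-focal beam power crossing the
  inner cortical facet is averaged over that surface and re-deposited
  uniformly in the cortical shell (by default around the full inner
  perimeter of the sonicated segment).  The uniformization is the
  point -- it stands in for the reflection/refraction/evanescent-wave
  physics that redistributes energy around the cortical perimeter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .acoustics import IntensityField, MediumSpec, attenuation_np_per_m
from .geometry import FacetSet, Tissue, TissueMap

__all__ = [
    "SourceParams",
    "HeatSourceMap",
    "direct_absorption_source",
    "oven_effect_source",
    "combine_sources",
]


@dataclass(frozen=True)
class SourceParams:
    """Absorption parameters for the two heating mechanisms.

    ``cortical_absorption_fraction`` (alpha) is the fraction of the beam
    power incident on the inner cortical facet that is deposited there.
    ``tissue_absorption_np_m`` (beta) is the soft-tissue amplitude
    absorption coefficient in Np/m at the operating frequency; when
    ``None`` it is derived from a :class:`MediumSpec` as
    ``absorption_fraction_of_attenuation`` times the attenuation
    coefficient (the silica-loaded tissue-mimicking gel attenuates
    largely by scattering, which does not heat).
    ``deposition_depth_mm`` is the thickness of the cortical shell
    receiving the oven term, measured inward from the exposed facet
    (the default matches the cortical thickness: at 1 MHz the shell is
    comparable to both the wavelength and the penetration depth).
    ``redistribution`` selects where the averaged power is re-deposited:
    ``"perimeter"`` spreads it around the full inner circumference of
    the sonicated axial bone segment (the wave-guide picture behind the
    circumferential isotherms), ``"facet"`` restricts it to the exposed
    facet itself.
    """

    cortical_absorption_fraction: float = 0.9
    tissue_absorption_np_m: float | None = None
    absorption_fraction_of_attenuation: float = 0.35
    deposition_depth_mm: float = 3.0
    redistribution: str = "perimeter"
    axial_spread_mm: float = 0.0      # extra wave-guide spread along the bone axis

    def __post_init__(self) -> None:
        if not 0.0 <= self.cortical_absorption_fraction <= 1.0:
            raise ValueError("cortical_absorption_fraction must be in [0, 1]")
        if self.tissue_absorption_np_m is not None and self.tissue_absorption_np_m < 0:
            raise ValueError("tissue_absorption_np_m must be >= 0")
        if not 0.0 <= self.absorption_fraction_of_attenuation <= 1.0:
            raise ValueError("absorption_fraction_of_attenuation must be in [0, 1]")
        if self.deposition_depth_mm <= 0:
            raise ValueError("deposition_depth_mm must be positive")
        if self.axial_spread_mm < 0:
            raise ValueError("axial_spread_mm must be >= 0")
        if self.redistribution not in ("perimeter", "facet"):
            raise ValueError("redistribution must be 'perimeter' or 'facet'")

    def beta_np_m(self, medium: MediumSpec, frequency_hz: float) -> float:
        if self.tissue_absorption_np_m is not None:
            return self.tissue_absorption_np_m
        return (self.absorption_fraction_of_attenuation
                * attenuation_np_per_m(medium, frequency_hz))


@dataclass
class HeatSourceMap:
    """Volumetric power density (W/m^3) with provenance flags."""

    q_w_m3: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray
    provenance: frozenset = frozenset()

    def total_power_w(self) -> float:
        voxel_m3 = (self.spacing_mm * 1e-3) ** 3
        return float(self.q_w_m3.sum() * voxel_m3)

    def scaled(self, factor: float) -> "HeatSourceMap":
        return HeatSourceMap(self.q_w_m3 * factor, self.spacing_mm,
                             self.origin_mm, self.provenance)


_SOFT = (int(Tissue.MUSCLE), int(Tissue.GEL), int(Tissue.MEDULLA))


def direct_absorption_source(intensity: IntensityField, tmap: TissueMap,
                             params: SourceParams, medium: MediumSpec,
                             frequency_hz: float) -> HeatSourceMap:
    """``q = 2 beta I`` in soft tissue; zero in cortical bone and water."""
    beta = params.beta_np_m(medium, frequency_hz)
    soft = np.isin(tmap.labels, _SOFT)
    q = np.where(soft, 2.0 * beta * intensity.data, 0.0)
    return HeatSourceMap(q, tmap.spacing_mm, tmap.origin_mm.copy(),
                         provenance=frozenset({"tumoral"}))


def incident_facet_power_w(intensity: IntensityField, facet: FacetSet) -> float:
    """Beam power crossing the facet, by direct quadrature sum(I_i * a_i)."""
    if len(facet) == 0:
        return 0.0
    vals = intensity.data[tuple(facet.indices.T)]
    return float(np.sum(vals * facet.areas_mm2 * 1e-6))


def _perimeter_ring(facet: FacetSet, tmap: TissueMap,
                    axial_spread_mm: float = 0.0) -> FacetSet:
    """Full-circumference inner-cortical ring of the sonicated segment.

    Wave-guide propagation inside the cortical shell carries the
    incident energy around the bone axis (and a little way along it),
    so the deposition region is the whole cavity-adjacent perimeter
    within the axial (bone-axis) extent crossed by the beam, extended
    by ``axial_spread_mm`` on each side.
    """
    from .geometry import _cavity_adjacency

    pad = int(round(axial_spread_mm / tmap.spacing_mm))
    ix_lo = max(0, int(facet.indices[:, 0].min()) - pad)
    ix_hi = min(tmap.labels.shape[0] - 1, int(facet.indices[:, 0].max()) + pad)
    n_faces = _cavity_adjacency(tmap.labels)
    ring = (tmap.labels == int(Tissue.CORTICAL)) & (n_faces > 0)
    ring[:ix_lo] = False
    ring[ix_hi + 1:] = False
    idx = np.argwhere(ring)
    areas = n_faces[ring].astype(float) * tmap.spacing_mm**2
    return FacetSet(indices=idx, areas_mm2=areas, spacing_mm=tmap.spacing_mm)


def _deposition_mask(facet: FacetSet, tmap: TissueMap,
                     depth_mm: float) -> np.ndarray:
    """Facet voxels dilated into the cortical shell down to ``depth_mm``."""
    from scipy import ndimage

    mask = facet.mask(tmap.labels.shape)
    n_extra = int(round(depth_mm / facet.spacing_mm)) - 1
    if n_extra > 0:
        cortical = tmap.labels == int(Tissue.CORTICAL)
        struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        for _ in range(n_extra):
            mask = (ndimage.binary_dilation(mask, struct) & cortical) | mask
    return mask


def oven_effect_source(intensity: IntensityField, facet: FacetSet,
                       params: SourceParams,
                       tmap: TissueMap | None = None) -> HeatSourceMap:
    """Uniform cortical deposition of the averaged incident intensity.

    The beam power incident on the facet is computed by area-weighted
    quadrature, averaged (each receiving voxel gets an identical power
    density -- this uniformization IS the oven effect) and deposited
    such that the total equals ``alpha * incident power``.  When a
    tissue map is supplied the deposition extends from the facet into
    the cortical shell down to ``deposition_depth_mm``; otherwise only
    the innermost voxel layer receives power.  An empty facet yields a
    zero map with a warning.
    """
    shape_src = intensity.data.shape
    q = np.zeros(shape_src, dtype=float)
    if len(facet) == 0:
        warnings.warn("empty cortical facet: oven-effect source is zero",
                      stacklevel=2)
        return HeatSourceMap(q, intensity.spacing_mm, intensity.origin_mm.copy(),
                             provenance=frozenset({"cortical"}))

    p_inc = incident_facet_power_w(intensity, facet)
    voxel_m3 = (facet.spacing_mm * 1e-3) ** 3
    if tmap is None:
        deposit = facet.mask(shape_src)
    else:
        if params.redistribution == "perimeter":
            seed = _perimeter_ring(facet, tmap, params.axial_spread_mm)
        else:
            seed = facet
        deposit = _deposition_mask(seed, tmap, params.deposition_depth_mm)
    n_dep = int(np.count_nonzero(deposit))
    q_uniform = params.cortical_absorption_fraction * p_inc / (n_dep * voxel_m3)
    q[deposit] = q_uniform
    return HeatSourceMap(q, intensity.spacing_mm, intensity.origin_mm.copy(),
                         provenance=frozenset({"cortical"}))


def combine_sources(a: HeatSourceMap, b: HeatSourceMap) -> HeatSourceMap:
    """Voxel-wise sum; provenance union.  Grids must match."""
    if a.q_w_m3.shape != b.q_w_m3.shape or a.spacing_mm != b.spacing_mm \
            or not np.allclose(a.origin_mm, b.origin_mm):
        raise ValueError("cannot combine heat sources on mismatched grids")
    return HeatSourceMap(a.q_w_m3 + b.q_w_m3, a.spacing_mm, a.origin_mm,
                         provenance=a.provenance | b.provenance)
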