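"""Linear focused-ultrasound field of a spherical-cap transducer.

The complex pressure is evaluated with a Rayleigh--Sommerfeld surface
integral over the discretized cap.  Since the bowl is axisymmetric, the
field is first computed on a cylindrical (rho, z) half-plane in the
transducer frame (apex at z = 0, geometric focus at z = F) and then
interpolated onto the voxel grid.  The per-unit-velocity 2-D field is
cached per (transducer, medium, discretization), so sweeps over focal
offset H and acoustic power reuse a single surface integration: moving
the rigid transducer only translates the sampling, and the field scales
as sqrt(power).

Soft-tissue attenuation enters through a complex wavenumber
``k = omega/c + i * alpha`` with ``alpha`` in Np/m.  Propagation through
cortical bone is deliberately not modelled; the "acoustic oven" source
operator (see :mod:`osteotherm.sources`) replaces detailed bone
acoustics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geometry import BeamSpec, TissueMap

__all__ = [
    "TransducerSpec",
    "MediumSpec",
    "PressureField",
    "IntensityField",
    "attenuation_np_per_m",
    "cap_elements",
    "pressure_at_points",
    "rayleigh_pressure",
    "intensity_from_pressure",
    "focal_metrics",
]

NEPER_PER_DB = np.log(10.0) / 20.0


@dataclass(frozen=True)
class TransducerSpec:
    """Single-element spherical-cap emitter.

    ``efficiency`` is the fraction of the nominal electric/free-field
    acoustic power that is effectively radiated into the tissue path; it
    folds the electro-acoustic conversion of the physical phased array
    and in-situ insertion losses into a single calibration constant (see
    the README for the calibration procedure).
    """

    focal_radius_mm: float = 130.0
    aperture_diameter_mm: float = 120.0
    frequency_hz: float = 1.0e6
    acoustic_power_w: float = 60.0
    focal_offset_mm: float = 0.0      # H, signed along +z; 0 = breakthrough plane
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.acoustic_power_w < 0:
            raise ValueError("acoustic_power_w must be >= 0")
        if self.aperture_diameter_mm >= 2 * self.focal_radius_mm:
            raise ValueError("aperture cannot exceed the full sphere")

    @property
    def f_number(self) -> float:
        return self.focal_radius_mm / self.aperture_diameter_mm

    @property
    def half_aperture_angle_rad(self) -> float:
        return float(np.arcsin(0.5 * self.aperture_diameter_mm / self.focal_radius_mm))

    def beam_spec(self, focus_mm) -> BeamSpec:
        return BeamSpec(focus_mm=tuple(float(c) for c in focus_mm),
                        half_angle_deg=float(np.rad2deg(self.half_aperture_angle_rad)))

    def wavelength_mm(self, medium: "MediumSpec") -> float:
        return medium.sound_speed_m_s / self.frequency_hz * 1e3


@dataclass(frozen=True)
class MediumSpec:
    """Homogeneous soft-tissue propagation medium."""

    sound_speed_m_s: float = 1541.0
    density_kg_m3: float = 1054.0
    attenuation_db_cm_mhz: float = 0.5

    def __post_init__(self) -> None:
        if self.sound_speed_m_s <= 0 or self.density_kg_m3 <= 0:
            raise ValueError("sound speed and density must be positive")
        if self.attenuation_db_cm_mhz < 0:
            raise ValueError("attenuation must be >= 0")

    @property
    def impedance_rayl(self) -> float:
        return self.sound_speed_m_s * self.density_kg_m3


#: water-like characteristic impedance used for the paper's free-field
#: plane-wave conversions (1.5 MRayl)
WATER_RHO_C = 1.5e6


def attenuation_np_per_m(medium: MediumSpec, frequency_hz: float) -> float:
    """Amplitude attenuation coefficient in Np/m at the given frequency."""
    db_per_m = medium.attenuation_db_cm_mhz * (frequency_hz / 1e6) * 100.0
    return db_per_m * NEPER_PER_DB


@dataclass
class _Field:
    data: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray

    @property
    def shape(self):
        return self.data.shape

    def index_of(self, point_mm) -> tuple[int, int, int]:
        idx = np.rint((np.asarray(point_mm) - self.origin_mm) / self.spacing_mm)
        idx = np.clip(idx, 0, np.array(self.data.shape) - 1)
        return tuple(int(i) for i in idx)

    def point_of(self, index) -> np.ndarray:
        return self.origin_mm + self.spacing_mm * np.asarray(index, dtype=float)

    def to_nifti(self, path: str) -> None:
        import nibabel as nib

        affine = np.diag([self.spacing_mm] * 3 + [1.0])
        affine[:3, 3] = self.origin_mm
        data = self.data
        if np.iscomplexobj(data):
            data = np.abs(data)
        nib.save(nib.Nifti1Image(data.astype(np.float32), affine), path)


class PressureField(_Field):
    """Complex focal pressure amplitude (Pa) on the voxel grid."""


class IntensityField(_Field):
    """Time-averaged acoustic intensity (W/m^2) on the voxel grid."""


def cap_elements(spec: TransducerSpec, element_size_mm: float):
    """Discretize the cap into surface elements.

    Returns ``(points_mm, areas_mm2)`` in the transducer frame (apex at
    the origin, focus on +z at ``focal_radius_mm``).  Elements are laid
    out on rings of constant polar angle with approximately square
    cells of side ``element_size_mm``.
    """
    a = spec.focal_radius_mm
    theta_max = spec.half_aperture_angle_rad
    n_rings = max(2, int(np.ceil(a * theta_max / element_size_mm)))
    dtheta = theta_max / n_rings
    pts, areas = [], []
    for j in range(n_rings):
        theta = (j + 0.5) * dtheta
        ring_r = a * np.sin(theta)
        n_phi = max(1, int(np.ceil(2 * np.pi * ring_r / element_size_mm)))
        phi = (np.arange(n_phi) + 0.5) * (2 * np.pi / n_phi)
        x = ring_r * np.cos(phi)
        y = ring_r * np.sin(phi)
        z = np.full(n_phi, a * (1.0 - np.cos(theta)))
        pts.append(np.column_stack([x, y, z]))
        areas.append(np.full(n_phi, a**2 * np.sin(theta) * dtheta * (2 * np.pi / n_phi)))
    return np.concatenate(pts), np.concatenate(areas)


def _surface_velocity(spec: TransducerSpec, medium: MediumSpec,
                      total_area_mm2: float) -> float:
    """Uniform normal velocity (m/s) radiating the spec'd acoustic power."""
    s_m2 = total_area_mm2 * 1e-6
    p_eff = spec.efficiency * spec.acoustic_power_w
    return float(np.sqrt(2.0 * p_eff / (medium.impedance_rayl * s_m2)))


def pressure_at_points(spec: TransducerSpec, medium: MediumSpec,
                       points_mm: np.ndarray, *, element_size_mm: float,
                       u0: float | None = None,
                       chunk_elems: int = 4096) -> np.ndarray:
    """Rayleigh integral at arbitrary points (transducer frame, mm)."""
    pts_src, areas = cap_elements(spec, element_size_mm)
    if u0 is None:
        u0 = _surface_velocity(spec, medium, areas.sum())
    if u0 == 0.0:
        return np.zeros(points_mm.shape[0], dtype=complex)

    k = (2 * np.pi * spec.frequency_hz / medium.sound_speed_m_s
         + 1j * attenuation_np_per_m(medium, spec.frequency_hz))
    field_pts = np.asarray(points_mm, dtype=float) * 1e-3
    src = pts_src * 1e-3
    areas_m2 = areas * 1e-6
    pref = -1j * medium.density_kg_m3 * medium.sound_speed_m_s * \
        (2 * np.pi * spec.frequency_hz / medium.sound_speed_m_s) * u0 / (2 * np.pi)

    out = np.zeros(field_pts.shape[0], dtype=complex)
    for i0 in range(0, src.shape[0], chunk_elems):
        s = src[i0:i0 + chunk_elems]
        a_el = areas_m2[i0:i0 + chunk_elems]
        d = field_pts[:, None, :] - s[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        r = np.maximum(r, 1e-6)
        out += np.einsum("ij,j->i", np.exp(1j * k * r) / r, a_el)
    return pref * out


# per-process cache of unit-velocity axisymmetric fields
_RZ_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _axisymmetric_unit_field(spec: TransducerSpec, medium: MediumSpec,
                             rho_max_mm: float, z_range_mm: tuple[float, float],
                             resolution_mm: float, element_size_mm: float):
    """(rho, z, p) for u0 = 1 m/s in the transducer frame, cached."""
    key = (round(spec.focal_radius_mm, 6), round(spec.aperture_diameter_mm, 6),
           round(spec.frequency_hz, 3), round(medium.sound_speed_m_s, 6),
           round(medium.density_kg_m3, 6), round(medium.attenuation_db_cm_mhz, 6),
           round(element_size_mm, 6), round(resolution_mm, 6),
           round(rho_max_mm, 3), round(z_range_mm[0], 3), round(z_range_mm[1], 3))
    if key in _RZ_CACHE:
        return _RZ_CACHE[key]

    rho = np.arange(0.0, rho_max_mm + resolution_mm, resolution_mm)
    z = np.arange(z_range_mm[0], z_range_mm[1] + resolution_mm, resolution_mm)
    RR, ZZ = np.meshgrid(rho, z, indexing="ij")
    pts = np.column_stack([RR.ravel(), np.zeros(RR.size), ZZ.ravel()])
    p = pressure_at_points(spec, medium, pts, element_size_mm=element_size_mm,
                           u0=1.0)
    p2d = p.reshape(RR.shape)
    _RZ_CACHE[key] = (rho, z, p2d)
    return rho, z, p2d


def rayleigh_pressure(spec: TransducerSpec, medium: MediumSpec, tmap: TissueMap,
                      *, element_size_mm: float | None = None,
                      rz_resolution_mm: float = 0.5) -> PressureField:
    """Complex pressure on the voxel grid of ``tmap``.

    The focus is placed on the beam axis at ``breakthrough_center + H``
    (rigid translation of the transducer along +z).
    """
    lam = spec.wavelength_mm(medium)
    if tmap.spacing_mm > lam / 2.0:
        warnings.warn(
            f"grid spacing {tmap.spacing_mm} mm exceeds lambda/2 = {lam / 2:.3f} mm; "
            "the sampled field may be aliased in the focal region", stacklevel=2)
    if element_size_mm is None:
        element_size_mm = lam / 3.0

    x, y, z = tmap.axes_mm
    focus_z = tmap.breakthrough_center_mm[2] + spec.focal_offset_mm
    apex_z = focus_z - spec.focal_radius_mm     # transducer apex in grid coords

    if spec.acoustic_power_w == 0.0:
        return PressureField(
            np.zeros((x.size, y.size, z.size), dtype=complex),
            tmap.spacing_mm, tmap.origin_mm.copy())

    # snap the cached (rho, z) window outward to a coarse lattice so that
    # focal-offset / radius sweeps reuse one surface integration
    rho_max = float(np.sqrt(np.max(np.abs(x))**2 + np.max(np.abs(y))**2))
    rho_max = np.ceil(rho_max / 10.0) * 10.0
    z_lo = np.floor(float(z[0] - apex_z) / 20.0) * 20.0
    z_hi = np.ceil(float(z[-1] - apex_z) / 20.0) * 20.0
    rho_ax, z_ax, p2d = _axisymmetric_unit_field(
        spec, medium, rho_max, (z_lo, z_hi), rz_resolution_mm, element_size_mm)

    _, areas = cap_elements(spec, element_size_mm)
    u0 = _surface_velocity(spec, medium, areas.sum())

    interp_re = RegularGridInterpolator((rho_ax, z_ax), p2d.real,
                                        bounds_error=False, fill_value=0.0)
    interp_im = RegularGridInterpolator((rho_ax, z_ax), p2d.imag,
                                        bounds_error=False, fill_value=0.0)
    X, Y = np.meshgrid(x, y, indexing="ij")
    rho3 = np.sqrt(X**2 + Y**2)
    out = np.empty((x.size, y.size, z.size), dtype=complex)
    for kz, zv in enumerate(z):
        q = np.column_stack([rho3.ravel(), np.full(rho3.size, zv - apex_z)])
        out[:, :, kz] = (interp_re(q) + 1j * interp_im(q)).reshape(rho3.shape)
    return PressureField(u0 * out, tmap.spacing_mm, tmap.origin_mm.copy())


def intensity_from_pressure(p: PressureField, medium: MediumSpec) -> IntensityField:
    """Plane-wave relation ``I = |p|^2 / (2 rho c)`` voxel-wise."""
    i = np.abs(p.data) ** 2 / (2.0 * medium.impedance_rayl)
    return IntensityField(i, p.spacing_mm, p.origin_mm.copy())


def _width_6db(profile: np.ndarray, coords: np.ndarray, peak_idx: int) -> float:
    """Full width of ``profile`` at a quarter of its peak (-6 dB in pressure)."""
    thr = profile[peak_idx] / 4.0
    lo = peak_idx
    while lo > 0 and profile[lo - 1] >= thr:
        lo -= 1
    hi = peak_idx
    while hi < profile.size - 1 and profile[hi + 1] >= thr:
        hi += 1

    def _edge(i_in: int, i_out: int) -> float:
        if i_in == i_out:
            return coords[i_in]
        f = (profile[i_in] - thr) / (profile[i_in] - profile[i_out])
        return coords[i_in] + f * (coords[i_out] - coords[i_in])

    left = _edge(lo, lo - 1) if lo > 0 else coords[0]
    right = _edge(hi, hi + 1) if hi < profile.size - 1 else coords[-1]
    return float(right - left)


def focal_metrics(intensity: IntensityField) -> dict:
    """Peak intensity, focus position and -6 dB focal extents.

    Raises on an all-zero field.
    """
    data = intensity.data
    if not np.any(data > 0):
        raise ValueError("focal_metrics: intensity field is identically zero")
    idx = np.unravel_index(int(np.argmax(data)), data.shape)
    pos = intensity.point_of(idx)
    sp = intensity.spacing_mm
    ax_prof = data[idx[0], idx[1], :]
    lat_prof = data[:, idx[1], idx[2]]
    zc = intensity.origin_mm[2] + sp * np.arange(data.shape[2])
    xc = intensity.origin_mm[0] + sp * np.arange(data.shape[0])
    return {
        "peak_w_m2": float(data[idx]),
        "position_mm": pos,
        "width_axial_mm": _width_6db(ax_prof, zc, idx[2]),
        "width_lateral_mm": _width_6db(lat_prof, xc, idx[0]),
    }
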