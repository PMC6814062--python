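"""Voxelized phantom of an osteolytic bone lesion.

The bone is a cortical cylinder (axis = +x) pierced by a conical
breakthrough (axis = -z, i.e. the cone opens toward the transducer,
apex on the bone axis).  The breakthrough and the beam-facing sector of
the medullar cavity are filled with tumour-mimicking gel; the remaining
interior is medulla (fat); the exterior defaults to muscle.

Conventions
-----------
* Beam propagates along +z, bone axis is +x.
* Voxel-centred, isotropic grid; physical coordinates refer to voxel
  centres; the grid is centred on the bone axis so that (0, 0, 0) is an
  exact voxel centre.
* The breakthrough centre (where the cone axis meets the cortical
  surface) lies at (0, 0, -Rc).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Tissue",
    "GeometryParams",
    "TissueMap",
    "BeamSpec",
    "FacetSet",
    "build_tissue_map",
    "inner_cortical_facet",
]


class Tissue(IntEnum):
    """Voxel labels."""

    WATER = 0
    MUSCLE = 1
    GEL = 2        # tumour-mimicking gel filling the osteolytic cavity
    CORTICAL = 3
    MEDULLA = 4    # fatty medulla (no MR signal, no direct heating focus)


#: labels that behave acoustically/thermally as soft tissue
SOFT_TISSUES = (Tissue.MUSCLE, Tissue.GEL, Tissue.MEDULLA)


@dataclass(frozen=True)
class GeometryParams:
    """Geometric description of the phantom.

    Parameters
    ----------
    cortical_radius_mm:
        Outer radius ``Rc`` of the cortical cylinder.
    cortical_thickness_mm:
        Thickness of the cortical shell; the medullar cavity has radius
        ``Rc - thickness``.
    cone_aperture_deg:
        Full aperture of the breakthrough cone (72 degrees by default).
    grid_spacing_mm:
        Isotropic voxel pitch.
    domain_extent_mm:
        Physical size of the computational box along (x, y, z).
    exterior:
        Tissue class filling the space outside the bone, ``"muscle"``
        or ``"water"``.
    """

    cortical_radius_mm: float = 6.0
    cortical_thickness_mm: float = 3.0
    cone_aperture_deg: float = 72.0
    grid_spacing_mm: float = 0.5
    domain_extent_mm: tuple[float, float, float] = (40.0, 40.0, 56.0)
    exterior: str = "muscle"

    def __post_init__(self) -> None:
        if self.grid_spacing_mm <= 0:
            raise ValueError("grid_spacing_mm must be positive")
        if not 0 < self.cone_aperture_deg < 180:
            raise ValueError("cone_aperture_deg must be in (0, 180)")
        if self.cortical_thickness_mm >= self.cortical_radius_mm:
            raise ValueError("cortical_thickness_mm must be < cortical_radius_mm")
        if self.exterior not in ("muscle", "water"):
            raise ValueError("exterior must be 'muscle' or 'water'")

    @property
    def cavity_radius_mm(self) -> float:
        return self.cortical_radius_mm - self.cortical_thickness_mm


def _axis(extent: float, spacing: float) -> np.ndarray:
    """Symmetric voxel-centre coordinates including 0."""
    half = int(np.floor(extent / (2.0 * spacing)))
    return np.arange(-half, half + 1) * spacing


@dataclass
class TissueMap:
    """Labelled voxel volume plus grid metadata."""

    labels: np.ndarray            # (nx, ny, nz) uint8 of Tissue values
    spacing_mm: float
    origin_mm: np.ndarray         # physical coordinate of voxel (0, 0, 0)
    params: GeometryParams

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin_mm[i] + self.spacing_mm * np.arange(self.labels.shape[i])
            for i in range(3)
        )

    @property
    def breakthrough_center_mm(self) -> np.ndarray:
        """Point where the cone axis meets the cortical surface."""
        return np.array([0.0, 0.0, -self.params.cortical_radius_mm])

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x, y, z = self.axes_mm
        return np.meshgrid(x, y, z, indexing="ij", sparse=True)

    def voxel_volume_mm3(self) -> float:
        return float(self.spacing_mm**3)

    def label_counts(self) -> dict[Tissue, int]:
        return {t: int(np.count_nonzero(self.labels == t)) for t in Tissue}

    def volume_mm3(self, *tissues: Tissue) -> float:
        mask = np.isin(self.labels, [int(t) for t in tissues])
        return float(np.count_nonzero(mask)) * self.voxel_volume_mm3()

    def index_of(self, point_mm: np.ndarray) -> tuple[int, int, int]:
        """Nearest voxel index of a physical point."""
        idx = np.rint((np.asarray(point_mm) - self.origin_mm) / self.spacing_mm)
        idx = np.clip(idx, 0, np.array(self.shape) - 1)
        return tuple(int(i) for i in idx)

    def to_nifti(self, path: str) -> None:
        import nibabel as nib

        affine = np.diag([self.spacing_mm] * 3 + [1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.labels.astype(np.uint8), affine), path)


def build_tissue_map(params: GeometryParams) -> TissueMap:
    """Assign tissue labels by geometric membership.

    Raises
    ------
    ValueError
        If the grid cannot resolve the cortical shell with at least two
        voxels across its thickness.
    """
    if params.cortical_thickness_mm / params.grid_spacing_mm < 2.0:
        raise ValueError(
            "grid too coarse: fewer than 2 voxels across the cortical shell "
            f"(thickness {params.cortical_thickness_mm} mm at "
            f"{params.grid_spacing_mm} mm spacing)"
        )

    x = _axis(params.domain_extent_mm[0], params.grid_spacing_mm)
    y = _axis(params.domain_extent_mm[1], params.grid_spacing_mm)
    z = _axis(params.domain_extent_mm[2], params.grid_spacing_mm)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij", sparse=True)

    rc = params.cortical_radius_mm
    ri = params.cavity_radius_mm
    half_angle = np.deg2rad(params.cone_aperture_deg / 2.0)

    rho = np.sqrt(Y**2 + Z**2)           # distance from the bone axis
    r = np.sqrt(X**2 + Y**2 + Z**2)      # distance from the cone apex
    in_cyl = rho <= rc
    in_cavity = rho <= ri
    # cone opens toward -z (toward the transducer); apex at the origin
    with np.errstate(invalid="ignore", divide="ignore"):
        in_cone = np.where(r > 0, (-Z) / np.maximum(r, 1e-300), 1.0) >= np.cos(half_angle)

    shape = (x.size, y.size, z.size)
    in_cyl = np.broadcast_to(in_cyl, shape)
    in_cavity = np.broadcast_to(in_cavity, shape)
    in_cone = np.broadcast_to(in_cone, shape)

    exterior = Tissue.MUSCLE if params.exterior == "muscle" else Tissue.WATER
    labels = np.full(shape, int(exterior), dtype=np.uint8)
    labels[in_cyl & ~in_cavity] = int(Tissue.CORTICAL)
    labels[in_cavity] = int(Tissue.MEDULLA)
    labels[in_cyl & in_cone] = int(Tissue.GEL)

    origin = np.array([x[0], y[0], z[0]])
    return TissueMap(labels=labels, spacing_mm=params.grid_spacing_mm,
                     origin_mm=origin, params=params)


@dataclass(frozen=True)
class BeamSpec:
    """Geometric cone of the focused beam, used to select the exposed facet.

    ``focus_mm`` is the focal position; ``half_angle_deg`` the aperture
    half-angle (``asin(a/F)`` for a bowl of half-aperture ``a`` and focal
    radius ``F``).  The beam propagates along +z.
    """

    focus_mm: tuple[float, float, float]
    half_angle_deg: float


@dataclass
class FacetSet:
    """Inner-cortical voxels exposed to the post-focal beam."""

    indices: np.ndarray     # (n, 3) voxel indices
    areas_mm2: np.ndarray   # (n,) exposed-face area per voxel
    spacing_mm: float

    def __len__(self) -> int:
        return int(self.indices.shape[0])

    @property
    def total_area_mm2(self) -> float:
        return float(self.areas_mm2.sum())

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        if len(self):
            m[tuple(self.indices.T)] = True
        return m


def _cavity_adjacency(labels: np.ndarray) -> np.ndarray:
    """Per-voxel count of 6-neighbour faces touching cavity tissue."""
    cavity = (labels == int(Tissue.GEL)) | (labels == int(Tissue.MEDULLA))
    count = np.zeros(labels.shape, dtype=np.int8)
    for ax in range(3):
        for shift in (1, -1):
            count += np.roll(cavity, shift, axis=ax)
    return count


def inner_cortical_facet(tmap: TissueMap, beam: BeamSpec) -> FacetSet:
    """Cortical voxels adjacent to the medullar cavity inside the post-focal cone.

    Returns an empty set (with a warning) when the beam misses the bone.
    """
    labels = tmap.labels
    n_faces = _cavity_adjacency(labels)
    cortical = labels == int(Tissue.CORTICAL)
    adjacent = cortical & (n_faces > 0)

    X, Y, Z = tmap.coordinate_grids()
    fx, fy, fz = beam.focus_mm
    vx, vy, vz = X - fx, Y - fy, Z - fz
    dist = np.sqrt(vx**2 + vy**2 + vz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(dist > 0, vz / np.maximum(dist, 1e-300), 1.0)
    in_beam = cosang >= np.cos(np.deg2rad(beam.half_angle_deg))

    sel = adjacent & in_beam
    idx = np.argwhere(sel)
    if idx.shape[0] == 0:
        warnings.warn("HIFU beam cone does not intersect the inner cortical "
                      "facet; returning an empty facet", stacklevel=2)
    areas = n_faces[sel].astype(float) * tmap.spacing_mm**2
    return FacetSet(indices=idx, areas_mm2=areas, spacing_mm=tmap.spacing_mm)
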