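"""Synthetic granule-lattice and tomogram generator.

Emulates the structures seen in fat-body protein aggregates: ~20 nm spherical
granules packed on body-centered tetragonal (BCT) or triclinic lattices,
assembled into a five-sector cyclic twin about a common axis, with thin linker
filaments between in-plane nearest neighbours, positional jitter, vacancies,
smooth bending, additive noise and an optional dual-axis missing-wedge filter.

Coordinates are right-handed, in nm, with z the optical/beam axis.  Voxel
grids are 0-based and indexed (z, y, x); the physical position of voxel
centre (k, j, i) is ``origin + (i + 0.5, j + 0.5, k + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial import cKDTree
from scipy.special import erfc

from .cells import UnitCell, CENTERING_OFFSETS

__all__ = [
    "TwinSpec",
    "DisorderSpec",
    "RenderSpec",
    "Volume3D",
    "build_unit_cell_points",
    "make_cyclic_twin",
    "build_twinned_assembly",
    "apply_disorder",
    "render_volume",
    "apply_missing_wedge",
    "missing_wedge_mask",
    "extract_slab_projection",
]


def _as_box(box) -> np.ndarray:
    """Normalize a box spec to a (3, 2) array of (lo, hi) per axis (x, y, z).

    A sequence of three scalars means extents [0, L) per axis.
    """
    box = np.asarray(box, dtype=float)
    if box.shape == (3,):
        box = np.stack([np.zeros(3), box], axis=1)
    if box.shape != (3, 2) or np.any(box[:, 1] - box[:, 0] <= 0):
        raise ValueError("box must be three positive extents or three (lo, hi) pairs")
    return box


def build_unit_cell_points(
    cell: UnitCell,
    orientation: Optional[Rotation] = None,
    box=(100.0, 100.0, 100.0),
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """All lattice points of ``cell`` (rotated by ``orientation``) inside ``box``.

    Corner sites plus centering sites are generated; a point is kept when
    lo <= coord < hi on every axis (half-open convention).  ``origin`` shifts
    the lattice origin in the lab frame.  Deterministic.
    """
    box = _as_box(box)
    R = np.eye(3) if orientation is None else orientation.as_matrix()
    B = cell.basis() @ R.T  # rows are lab-frame cell vectors
    origin = np.asarray(origin, dtype=float)

    # Integer ranges: map box corners to fractional coordinates.
    corners = np.array(
        [[box[0, i], box[1, j], box[2, k]] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    )
    frac = (corners - origin) @ np.linalg.inv(B)
    lo = np.floor(frac.min(axis=0)).astype(int) - 1
    hi = np.ceil(frac.max(axis=0)).astype(int) + 1

    hh, kk, ll = np.meshgrid(
        *[np.arange(lo[i], hi[i] + 1) for i in range(3)], indexing="ij"
    )
    hkl = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1).astype(float)
    offsets = CENTERING_OFFSETS[cell.centering]
    pts = (hkl[:, None, :] + offsets[None, :, :]).reshape(-1, 3) @ B + origin
    keep = np.all((pts >= box[:, 0]) & (pts < box[:, 1]), axis=1)
    return pts[keep]


@dataclass(frozen=True)
class TwinSpec:
    """A cyclic multiply-twinned assembly about a common axis.

    ``wedge_angles`` are the azimuthal sector widths in degrees, in order;
    ``sectors`` pairs each wedge with the (cell, orientation) filling it.
    When the wedges sum to less than 360 deg the deficit is handled per
    ``closure``: ``"stretch_last"`` widens the last sector to close the ring
    (angular strain interpretation), ``"gap"`` leaves an empty wedge
    (measurement-gap interpretation).
    """

    wedge_angles: tuple
    sectors: tuple  # tuple of (UnitCell, Rotation-or-None)
    common_axis: tuple = (0.0, 0.0, 1.0)
    closure: str = "stretch_last"

    def __post_init__(self) -> None:
        w = np.asarray(self.wedge_angles, dtype=float)
        if len(w) != len(self.sectors):
            raise ValueError("one sector per wedge angle required")
        if np.any(w <= 0):
            raise ValueError("wedge angles must be positive")
        if w.sum() > 360.0 + 1e-9:
            raise ValueError("wedge angles must sum to at most 360 degrees")
        if self.closure not in ("stretch_last", "gap"):
            raise ValueError("closure must be 'stretch_last' or 'gap'")

    def sector_bounds(self) -> np.ndarray:
        """(n, 2) azimuthal bounds in degrees after applying the closure policy."""
        w = np.asarray(self.wedge_angles, dtype=float).copy()
        deficit = 360.0 - w.sum()
        if self.closure == "stretch_last" and deficit > 0:
            w[-1] += deficit
        edges = np.concatenate([[0.0], np.cumsum(w)])
        return np.stack([edges[:-1], edges[1:]], axis=1)


def make_cyclic_twin(
    cell: UnitCell,
    wedge_angles: Sequence[float],
    common_axis: Sequence[float] = (0.0, 0.0, 1.0),
    closure: str = "stretch_last",
    sector_cells: Optional[Sequence[UnitCell]] = None,
) -> TwinSpec:
    """Convenience constructor: each sector holds ``cell`` rotated about the
    common axis so that its lattice rows follow the sector's start azimuth.
    """
    axis = np.asarray(common_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    w = np.asarray(wedge_angles, dtype=float)
    starts = np.concatenate([[0.0], np.cumsum(w)[:-1]])
    cells = list(sector_cells) if sector_cells is not None else [cell] * len(w)
    sectors = tuple(
        (cells[i], Rotation.from_rotvec(np.radians(starts[i]) * axis))
        for i in range(len(w))
    )
    return TwinSpec(
        wedge_angles=tuple(w), sectors=sectors, common_axis=tuple(axis), closure=closure
    )


def _azimuth_frame(axis: np.ndarray) -> tuple:
    """Orthonormal in-plane vectors (u, v) completing ``axis`` to a RH frame."""
    axis = axis / np.linalg.norm(axis)
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, axis)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    u = trial - np.dot(trial, axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def build_twinned_assembly(spec: TwinSpec, box=(600.0, 600.0, 85.0), center=None):
    """Points and sector labels for a cyclic twinned assembly.

    Each sector's lattice fills the box (anchored at the twin axis so sector
    lattices share the common origin), and only points whose azimuth about the
    common axis falls inside the sector's wedge are kept.

    Returns ``(points, labels)`` with labels in ``range(n_sectors)``.
    """
    if len(spec.sectors) < 2:
        raise ValueError("a twin needs at least 2 sectors")
    box = _as_box(box)
    axis = np.asarray(spec.common_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if center is None:
        center = box.mean(axis=1)
    center = np.asarray(center, dtype=float)
    u, v = _azimuth_frame(axis)
    bounds = spec.sector_bounds()

    all_pts, all_lab = [], []
    for i, (cell, orientation) in enumerate(spec.sectors):
        pts = build_unit_cell_points(cell, orientation, box, origin=center)
        rel = pts - center
        az = np.degrees(np.arctan2(rel @ v, rel @ u)) % 360.0
        lo, hi = bounds[i]
        on_axis = np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1) < 1e-9
        keep = ((az >= lo) & (az < hi)) | (on_axis & (i == 0))
        all_pts.append(pts[keep])
        all_lab.append(np.full(keep.sum(), i, dtype=int))
    return np.concatenate(all_pts), np.concatenate(all_lab)


@dataclass(frozen=True)
class DisorderSpec:
    """Positional disorder: Gaussian jitter, vacancies, smooth bending.

    Bending displaces granules along +x by ``bend_amplitude *
    sin(2*pi*z/bend_wavelength)``, mimicking the smooth column bending seen
    along the beam axis.
    """

    jitter_sigma: float = 0.0  # nm, isotropic
    vacancy_prob: float = 0.0
    bend_amplitude: float = 0.0  # nm
    bend_wavelength: float = 200.0  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if not 0.0 <= self.vacancy_prob < 1.0:
            raise ValueError("vacancy_prob must be in [0, 1)")


def apply_disorder(points: np.ndarray, spec: DisorderSpec, return_kept: bool = False):
    """Apply vacancies, jitter and bending; reproducible under ``spec.seed``.

    With ``return_kept=True`` also returns the boolean survival mask over the
    input points (for carrying per-granule labels through vacancies).
    """
    rng = np.random.default_rng(spec.seed)
    pts = np.asarray(points, dtype=float).copy()
    kept = np.ones(len(pts), dtype=bool)
    if spec.vacancy_prob > 0:
        kept = rng.random(len(pts)) >= spec.vacancy_prob
        pts = pts[kept]
    if spec.jitter_sigma > 0:
        pts = pts + rng.normal(0.0, spec.jitter_sigma, pts.shape)
    if spec.bend_amplitude != 0.0:
        pts[:, 0] += spec.bend_amplitude * np.sin(
            2.0 * np.pi * pts[:, 2] / spec.bend_wavelength
        )
    return (pts, kept) if return_kept else pts


@dataclass(frozen=True)
class RenderSpec:
    """Rendering parameters for turning granule centres into a density volume.

    Contrast convention: protein bright (inverted with respect to raw
    bright-field slices).  ``edge_softness`` is the error-function falloff
    scale of the sphere edge; the profile is built so the full width at half
    maximum equals ``granule_diameter``.  ``linker_planes`` lists lab-frame
    plane normals; linker rods are drawn between nearest-neighbour pairs whose
    connecting vector lies within 10 degrees of one of those planes.
    """

    voxel_size: float = 1.1  # nm
    granule_diameter: float = 20.1  # nm (hIAPP)
    edge_softness: float = 1.5  # nm
    linker_radius: float = 2.0  # nm
    linker_planes: tuple = ()  # e.g. ((0, 0, 1),) for the (001) plane
    linker_amplitude: float = 0.6  # relative to granule peak 1.0
    noise_sigma: float = 0.0
    missing_wedge: Optional[tuple] = None  # (tilt_range_deg, dual_axis)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0 or self.granule_diameter <= 0:
            raise ValueError("voxel_size and granule_diameter must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class Volume3D:
    """Density grid indexed (z, y, x) with physical voxel size and origin (nm)."""

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be a 3D grid")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self):
        return self.data.shape

    def physical_extent(self) -> np.ndarray:
        """(3, 2) physical (lo, hi) per axis in (x, y, z) order."""
        nz, ny, nx = self.data.shape
        size = np.array([nx, ny, nz]) * self.voxel_size
        return np.stack([self.origin, self.origin + size], axis=1)

    def to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map physical (x, y, z) nm to fractional (z, y, x) voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        idx = (xyz - self.origin) / self.voxel_size - 0.5
        return idx[:, ::-1]

    def to_physical(self, zyx_index: np.ndarray) -> np.ndarray:
        """Map (z, y, x) voxel indices to physical (x, y, z) nm (voxel centres)."""
        idx = np.atleast_2d(np.asarray(zyx_index, dtype=float))[:, ::-1]
        return (idx + 0.5) * self.voxel_size + self.origin


def _sphere_profile(r: np.ndarray, radius: float, softness: float) -> np.ndarray:
    # erfc falloff centred on the nominal radius: value 0.5 at r = radius,
    # so the FWHM of the rendered sphere equals its nominal diameter.
    return 0.5 * erfc((r - radius) / (np.sqrt(2.0) * softness))


def nearest_neighbor_pairs(points: np.ndarray, factor: float = 1.15) -> np.ndarray:
    """Index pairs (i, j), i<j, closer than ``factor`` x modal NN distance."""
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    modal = np.median(d[:, 1])
    pairs = tree.query_pairs(r=factor * modal, output_type="ndarray")
    return pairs


def render_volume(
    points: np.ndarray,
    render: RenderSpec,
    box=None,
    margin: Optional[float] = None,
) -> Volume3D:
    """Render granule centres (and linkers) into a :class:`Volume3D`.

    Spheres use a soft error-function edge; density is accumulated with a
    voxelwise maximum so overlapping spheres and linkers keep a flat-top
    profile with the intensity maximum at granule centres.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) == 0:
        raise ValueError("no points to render")
    radius = render.granule_diameter / 2.0
    if render.voxel_size > radius:
        raise ValueError("voxel_size exceeds the granule radius: unresolvable")
    if margin is None:
        margin = render.granule_diameter
    if box is None:
        lo = points.min(axis=0) - margin
        hi = points.max(axis=0) + margin
    else:
        b = _as_box(box)
        lo, hi = b[:, 0], b[:, 1]
    shape_xyz = np.ceil((hi - lo) / render.voxel_size).astype(int)
    nz, ny, nx = shape_xyz[::-1]
    vol = np.zeros((nz, ny, nx), dtype=np.float32)
    out = Volume3D(vol, render.voxel_size, origin=lo)

    support = radius + 4.0 * render.edge_softness

    def _paint_ball(center_xyz, radius_nm, amplitude, axis_pair=None):
        # axis_pair: (p0, p1) -> paint a soft rod instead of a sphere
        cx = (np.asarray(center_xyz) - lo) / render.voxel_size - 0.5
        if axis_pair is None:
            half = support / render.voxel_size
            lo_i = np.maximum(np.floor(cx - half).astype(int), 0)
            hi_i = np.minimum(np.ceil(cx + half).astype(int) + 1, shape_xyz)
        else:
            p0, p1 = axis_pair
            seg_lo = np.minimum(p0, p1) - (radius_nm + 4 * render.edge_softness)
            seg_hi = np.maximum(p0, p1) + (radius_nm + 4 * render.edge_softness)
            lo_i = np.maximum(((seg_lo - lo) / render.voxel_size - 0.5).astype(int), 0)
            hi_i = np.minimum(
                np.ceil((seg_hi - lo) / render.voxel_size - 0.5).astype(int) + 1,
                shape_xyz,
            )
        if np.any(hi_i <= lo_i):
            return
        ix = np.arange(lo_i[0], hi_i[0])
        iy = np.arange(lo_i[1], hi_i[1])
        iz = np.arange(lo_i[2], hi_i[2])
        X = (ix + 0.5) * render.voxel_size + lo[0]
        Y = (iy + 0.5) * render.voxel_size + lo[1]
        Z = (iz + 0.5) * render.voxel_size + lo[2]
        gz, gy, gx = np.meshgrid(Z, Y, X, indexing="ij")
        if axis_pair is None:
            c = np.asarray(center_xyz)
            r = np.sqrt((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2)
        else:
            p0, p1 = axis_pair
            d = p1 - p0
            L = np.linalg.norm(d)
            d = d / L
            px, py, pz = gx - p0[0], gy - p0[1], gz - p0[2]
            t = np.clip(px * d[0] + py * d[1] + pz * d[2], 0.0, L)
            r = np.sqrt(
                (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
            )
        prof = amplitude * _sphere_profile(r, radius_nm, render.edge_softness)
        sub = vol[lo_i[2] : hi_i[2], lo_i[1] : hi_i[1], lo_i[0] : hi_i[0]]
        np.maximum(sub, prof.astype(np.float32), out=sub)

    for p in points:
        _paint_ball(p, radius, 1.0)

    if render.linker_planes and len(points) > 1:
        pairs = nearest_neighbor_pairs(points)
        normals = np.asarray(render.linker_planes, dtype=float)
        normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
        sin_tol = np.sin(np.radians(10.0))
        for i, j in pairs:
            vec = points[j] - points[i]
            vhat = vec / np.linalg.norm(vec)
            if np.any(np.abs(normals @ vhat) < sin_tol):
                _paint_ball(
                    0.5 * (points[i] + points[j]),
                    render.linker_radius,
                    render.linker_amplitude,
                    axis_pair=(points[i], points[j]),
                )

    if render.noise_sigma > 0:
        rng = np.random.default_rng(render.seed)
        vol += rng.normal(0.0, render.noise_sigma, vol.shape).astype(np.float32)

    if render.missing_wedge is not None:
        tilt_range, dual_axis = render.missing_wedge
        out = apply_missing_wedge(out, tilt_range=tilt_range, dual_axis=dual_axis)
    return out


def missing_wedge_mask(shape, tilt_range: float = 60.0, dual_axis: bool = True) -> np.ndarray:
    """Binary Fourier mask: 1 where data is sampled, 0 in the missing region.

    Single-axis tomography with tilt axis y and tilt range +-t leaves the
    region |kz| > |kx| * tan(t) unsampled.  A dual-axis acquisition adds a
    second series with tilt axis x; its missing wedge is |kz| > |ky| * tan(t).
    The combined missing region is the intersection (a pyramid), so the
    sampled mask is the union of the two single-axis masks.
    """
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    ky = np.fft.fftfreq(ny)[None, :, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    t = np.tan(np.radians(tilt_range))
    mask_y_axis = np.abs(kz) <= np.abs(kx) * t  # tilt about y samples x-z fan
    if not dual_axis:
        return np.broadcast_to(mask_y_axis, shape).copy()
    mask_x_axis = np.abs(kz) <= np.abs(ky) * t
    return np.broadcast_to(mask_y_axis | mask_x_axis, shape).copy()


def apply_missing_wedge(
    vol: Volume3D, tilt_range: float = 60.0, dual_axis: bool = True
) -> Volume3D:
    """Zero the Fourier components in the missing wedge (dual-axis by default)."""
    mask = missing_wedge_mask(vol.data.shape, tilt_range, dual_axis)
    ft = np.fft.fftn(vol.data)
    filtered = np.fft.ifftn(ft * mask).real.astype(np.float32)
    return Volume3D(filtered, vol.voxel_size, origin=vol.origin.copy())


def extract_slab_projection(
    vol: Volume3D,
    normal: Sequence[float] = (0.0, 0.0, 1.0),
    anchor: Optional[Sequence[float]] = None,
    thickness: float = 20.0,
):
    """Sum the density over a slab of given thickness and return a 2D image.

    ``normal`` (lab frame, xyz) defines the slab orientation, ``anchor`` a
    physical point (nm) on the slab's mid-plane (defaults to the volume
    centre).  The returned image has the volume's voxel size as pixel size;
    rows map to the in-plane v axis and columns to the u axis of a
    right-handed (u, v, normal) frame.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    ext = vol.physical_extent()
    center = ext.mean(axis=1)
    if anchor is None:
        anchor = center
    anchor = np.asarray(anchor, dtype=float)
    span = ext[:, 1] - ext[:, 0]
    if thickness <= 0 or thickness > float(np.abs(span @ np.abs(n)) + 1e-9):
        raise ValueError("slab thickness must be positive and fit in the volume")
    if not np.all((anchor >= ext[:, 0]) & (anchor <= ext[:, 1])):
        raise ValueError("slab anchor lies outside the volume")

    # Fast path: axis-aligned z-normal slab.
    if abs(n[2]) > 1 - 1e-12:
        z0 = anchor[2] - thickness / 2.0
        z1 = anchor[2] + thickness / 2.0
        k0 = max(int(np.floor((z0 - vol.origin[2]) / vol.voxel_size)), 0)
        k1 = min(int(np.ceil((z1 - vol.origin[2]) / vol.voxel_size)), vol.data.shape[0])
        if k1 <= k0:
            raise ValueError("slab does not intersect the volume")
        return vol.data[k0:k1].sum(axis=0)

    from scipy.ndimage import map_coordinates

    u, v = _azimuth_frame(n)
    half_diag = 0.5 * np.linalg.norm(span)
    npix = int(np.ceil(2 * half_diag / vol.voxel_size))
    coords_u = (np.arange(npix) - npix / 2 + 0.5) * vol.voxel_size
    steps = np.arange(
        -thickness / 2 + vol.voxel_size / 2, thickness / 2, vol.voxel_size
    )
    image = np.zeros((npix, npix), dtype=np.float64)
    gu, gv = np.meshgrid(coords_u, coords_u, indexing="xy")
    for s in steps:
        pts = anchor + gu[..., None] * u + gv[..., None] * v + s * n
        idx = (pts - vol.origin) / vol.voxel_size - 0.5  # (x, y, z) fractional
        sample = map_coordinates(
            vol.data, [idx[..., 2], idx[..., 1], idx[..., 0]], order=1, cval=0.0
        )
        image += sample
    return image.astype(np.float32)
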