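"""Crystalline-domain segmentation and cyclic twin-boundary analysis.

Partitions a granule assembly into domains of consistent local lattice
orientation, fits the planar boundaries between adjacent domains, estimates
the common (wedge) axis shared by the boundary planes, and measures the
azimuthal wedge angles between consecutive boundaries — the quantities that
characterize a five-fold cyclic twin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .lattice import NeighborVectorField, modal_nn_distance, neighbor_vectors

__all__ = [
    "TwinBoundary",
    "TwinPartition",
    "estimate_common_axis",
    "local_orientation_field",
    "segment_domains",
    "boundary_planes_and_axis",
    "wedge_angles",
    "analyze_twins",
]

#: Neighbour pairs farther than this multiple of the modal spacing are
#: treated as non-contact and excluded from adjacency and boundary fitting.
CONTACT_FACTOR = 1.3


def estimate_common_axis(points: np.ndarray) -> np.ndarray:
    """Initial guess of the twin axis: the thinnest principal direction.

    The analysed assemblies are slab-like (hundreds of nm wide, tens of nm
    thick along the beam axis), so the smallest-variance principal component
    of the centred point cloud points along the common axis.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    axis = vt[-1]
    return axis if axis[np.argmax(np.abs(axis))] >= 0 else -axis


def _inplane_frame(axis: np.ndarray):
    axis = axis / np.linalg.norm(axis)
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, axis)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    u = trial - np.dot(trial, axis) * axis
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def local_orientation_field(
    points: np.ndarray,
    field: Optional[NeighborVectorField] = None,
    axis: Optional[Sequence[float]] = None,
    symmetry_deg: float = 90.0,
    min_neighbors: int = 3,
) -> np.ndarray:
    """Per-granule in-plane row direction, in degrees modulo ``symmetry_deg``.

    For each granule, the azimuths (about ``axis``) of its in-plane contact
    vectors are folded modulo the local lattice's in-plane rotational
    symmetry (90 deg for the square net of a BCT (001) plane, 180 deg for a
    triclinic net) and averaged circularly.  Granules with fewer than
    ``min_neighbors`` contacts are returned as NaN (undetermined).
    """
    points = np.asarray(points, dtype=float)
    if field is None:
        field = neighbor_vectors(points, cutoff_factor=CONTACT_FACTOR)
    if axis is None:
        axis = estimate_common_axis(points)
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    u, v = _inplane_frame(axis)

    vecs = field.vectors
    owner = field.owner
    lens = np.linalg.norm(vecs, axis=1)
    contact = lens <= CONTACT_FACTOR * field.modal_nn
    out_comp = np.abs(vecs @ axis)
    inplane = contact & (out_comp <= np.sin(np.radians(25.0)) * lens)

    orientations = np.full(len(points), np.nan)
    az = np.degrees(np.arctan2(vecs @ v, vecs @ u)) % symmetry_deg
    for i in range(len(points)):
        sel = inplane & (owner == i)
        if sel.sum() < min_neighbors:
            continue
        # Strongest azimuth cluster = the granule's row direction.  Using the
        # dominant cluster (not the mean over all vectors) keeps boundary
        # granules with mixed-domain neighbours from acquiring intermediate
        # orientations that would bridge distinct domains.
        orientations[i] = _dominant_direction(az[sel], symmetry_deg, lengths=lens[sel])
    return orientations


def _dominant_direction(
    az: np.ndarray, period: float, tol: float = 7.0, lengths=None
) -> float:
    """Circular mean of the largest azimuth cluster (greedy, ``tol`` degrees).

    Ties between equally-populated clusters go to the one with the shortest
    mean neighbour distance (the closest-packed row), so every granule of a
    multi-row net reports the same canonical row family.
    """
    az = np.asarray(az, dtype=float)
    if lengths is None:
        lengths = np.ones_like(az)
    lengths = np.asarray(lengths, dtype=float)
    remaining = np.ones(len(az), dtype=bool)
    best_idx: np.ndarray = np.empty(0, dtype=int)
    best_key = None
    while remaining.any():
        seed = az[remaining][0]
        members = np.where(
            remaining & (_circ_diff(az, seed, period) <= tol)
        )[0]
        key = (-len(members), float(lengths[members].mean()))
        if best_key is None or key < best_key:
            best_key, best_idx = key, members
        remaining[members] = False
    m = az[best_idx]
    fold = np.radians(m * (360.0 / period))
    mean_angle = np.degrees(np.angle(np.exp(1j * fold).mean()))
    return float((mean_angle / (360.0 / period)) % period)


def _circ_diff(a: np.ndarray, b: np.ndarray, period: float) -> np.ndarray:
    d = np.abs(a - b) % period
    return np.minimum(d, period - d)


def segment_domains(
    points: np.ndarray,
    orientations: np.ndarray,
    tolerance_deg: float = 5.0,
    symmetry_deg: float = 90.0,
    min_domain: int = 10,
) -> np.ndarray:
    """Cluster granules into domains of consistent row orientation.

    Orientation modes are found globally on a smoothed circular histogram
    (peaks closer than ``tolerance_deg`` merge); each granule joins its
    nearest mode, and mode groups are split into spatially connected
    components on the contact graph.  The global-mode step (rather than
    merging contact pairs that agree locally) prevents the gradual
    orientation gradient across a twin boundary from chaining two domains
    together.  Domains smaller than ``min_domain`` are absorbed into their
    most-connected neighbour; undetermined granules join their nearest
    determined granule's domain.
    """
    points = np.asarray(points, dtype=float)
    orientations = np.asarray(orientations, dtype=float)
    det = np.isfinite(orientations)
    if not det.any():
        raise ValueError("all granule orientations undetermined")

    modes = _orientation_modes(orientations[det], symmetry_deg, tolerance_deg)
    vals = orientations[det]
    dd = _circ_diff(vals[:, None], modes[None, :], symmetry_deg)
    mode_of = np.argmin(dd, axis=1)
    labels = np.full(len(points), -1)
    labels[det] = mode_of

    # Undetermined granules adopt their nearest determined granule's mode.
    det_idx = np.where(det)[0]
    for i in np.where(~det)[0]:
        d = np.linalg.norm(points[det] - points[i], axis=1)
        labels[i] = labels[det_idx[np.argmin(d)]]

    # Same orientation can occur in disjoint regions: split each mode group
    # into spatially connected components.
    modal = modal_nn_distance(points)
    pairs = cKDTree(points).query_pairs(r=CONTACT_FACTOR * modal, output_type="ndarray")
    same = labels[pairs[:, 0]] == labels[pairs[:, 1]]
    good = pairs[same]
    n = len(points)
    adj = coo_matrix((np.ones(len(good)), (good[:, 0], good[:, 1])), shape=(n, n))
    _, comp = connected_components(adj + adj.T, directed=False)

    comp = _absorb_small_domains(comp, pairs, min_domain)
    # Relabel by decreasing size for determinism.
    uniq, counts = np.unique(comp, return_counts=True)
    remap = {u: r for r, u in enumerate(uniq[np.argsort(-counts)])}
    return np.array([remap[c] for c in comp])


def _orientation_modes(
    vals: np.ndarray, period: float, tolerance_deg: float, step: float = 0.5
) -> np.ndarray:
    """Peaks of a Gaussian-smoothed circular histogram of orientations."""
    from scipy.signal import find_peaks

    grid = np.arange(0.0, period, step)
    d = _circ_diff(vals[None, :], grid[:, None], period)
    dens = np.exp(-0.5 * (d / 2.0) ** 2).sum(axis=1)
    ext = np.concatenate([dens, dens, dens])
    min_sep = max(1, min(int(tolerance_deg / step), len(grid) - 1))
    peaks, _ = find_peaks(ext, height=0.1 * dens.max(), distance=min_sep)
    peaks = peaks[(peaks >= len(grid)) & (peaks < 2 * len(grid))] - len(grid)
    if len(peaks) == 0:
        return np.array([float(grid[np.argmax(dens)])])
    return np.sort(grid[peaks])


def _absorb_small_domains(labels: np.ndarray, pairs: np.ndarray, min_domain: int):
    labels = labels.copy()
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        small = uniq[counts < min_domain]
        if len(small) == 0 or len(uniq) == 1:
            return labels
        changed = False
        for s in small:
            mask0 = labels[pairs[:, 0]] == s
            mask1 = labels[pairs[:, 1]] == s
            targets = np.concatenate(
                [labels[pairs[mask0, 1]], labels[pairs[mask1, 0]]]
            )
            targets = targets[targets != s]
            if len(targets):
                vals, cnt = np.unique(targets, return_counts=True)
                labels[labels == s] = vals[np.argmax(cnt)]
                changed = True
        if not changed:
            return labels


def refine_labels_by_lattice(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Reassign boundary granules to the adjacent domain whose fitted lattice
    best predicts their position.

    Orientation alone localizes the boundary to about one granule row; the
    per-domain lattice residual (distance to the nearest site of the domain's
    own inferred lattice) is far sharper, because a granule belongs exactly to
    one sector's lattice while the neighbouring sector's sites are generically
    a large fraction of a cell away.
    """
    from .lattice import NoLatticeError, infer_primitive_basis
    from .lattice import neighbor_vectors as _nv

    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels).copy()
    models: dict = {}
    for lab in np.unique(labels):
        sub = points[labels == lab]
        if len(sub) < 20:
            continue
        try:
            basis = infer_primitive_basis(_nv(sub))
        except (NoLatticeError, ValueError):
            continue
        inv = np.linalg.inv(basis)
        frac = (sub - sub[0]) @ inv
        shift = np.angle(np.exp(2j * np.pi * frac).mean(axis=0)) / (2 * np.pi)
        models[lab] = (basis, inv, sub[0], shift)

    modal = modal_nn_distance(points)
    pairs = cKDTree(points).query_pairs(r=CONTACT_FACTOR * modal, output_type="ndarray")
    cross = pairs[labels[pairs[:, 0]] != labels[pairs[:, 1]]]
    adjacent: dict = {}
    for i, j in cross:
        adjacent.setdefault(i, set()).add(labels[j])
        adjacent.setdefault(j, set()).add(labels[i])

    def residual(p: np.ndarray, lab) -> float:
        if lab not in models:
            return np.inf
        basis, inv, p0, shift = models[lab]
        dev = (p - p0) @ inv - shift
        dev -= np.round(dev)
        return float(np.linalg.norm(dev @ basis))

    new = labels.copy()
    for i, others in adjacent.items():
        options = sorted({labels[i]} | others)
        res = [residual(points[i], lab) for lab in options]
        if np.isfinite(min(res)):
            new[i] = options[int(np.argmin(res))]
    return new


@dataclass
class TwinBoundary:
    """Planar boundary between two adjacent domains."""

    domains: tuple  # (label_a, label_b)
    point: Optional[np.ndarray]  # a point on the fitted plane (nm)
    normal: Optional[np.ndarray]  # unit normal (None if < 3 midpoints)
    midpoints: np.ndarray  # cross-boundary contact midpoints used for the fit
    rms_residual: float = np.nan


def boundary_planes_and_axis(
    points: np.ndarray, labels: np.ndarray, apex: Optional[np.ndarray] = None
):
    """Fit a plane to every adjacent-domain interface; estimate the twin axis.

    Each boundary plane is a total-least-squares fit (SVD) to the midpoints
    of cross-label contact pairs.  When ``apex`` (the meeting point of the
    wedges) is given, midpoints within two lattice spacings of it are held
    out of the fit: in that region contact pairs straddle wide azimuth ranges
    and systematically tilt the plane.  The common axis is the direction most
    nearly contained in all boundary planes: the smallest right singular
    vector of the stacked plane normals.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 domains to fit boundaries")
    modal = modal_nn_distance(points)
    pairs = cKDTree(points).query_pairs(r=CONTACT_FACTOR * modal, output_type="ndarray")
    cross = labels[pairs[:, 0]] != labels[pairs[:, 1]]
    pairs = pairs[cross]

    boundaries = []
    keys = set()
    for i, j in pairs:
        keys.add(tuple(sorted((labels[i], labels[j]))))
    for a, b in sorted(keys):
        sel = (
            ((labels[pairs[:, 0]] == a) & (labels[pairs[:, 1]] == b))
            | ((labels[pairs[:, 0]] == b) & (labels[pairs[:, 1]] == a))
        )
        mid = 0.5 * (points[pairs[sel, 0]] + points[pairs[sel, 1]])
        fit_mid = mid
        if apex is not None and len(mid) > 10:
            far = np.linalg.norm(mid - np.asarray(apex), axis=1) > 2.0 * modal
            if far.sum() >= 3:
                fit_mid = mid[far]
        if len(fit_mid) < 3:
            boundaries.append(TwinBoundary((a, b), None, None, mid))
            continue
        center = fit_mid.mean(axis=0)
        _, svals, vt = np.linalg.svd(fit_mid - center, full_matrices=False)
        normal = vt[-1]
        rms = svals[-1] / np.sqrt(len(fit_mid))
        boundaries.append(TwinBoundary((a, b), center, normal, mid, float(rms)))

    normals = np.array([b.normal for b in boundaries if b.normal is not None])
    if len(normals) == 0:
        raise ValueError("no boundary could be fitted")
    if len(normals) == 1:
        # Single planar boundary: any in-plane direction serves as the axis.
        axis = _inplane_frame(normals[0])[0]
    else:
        _, _, vt = np.linalg.svd(normals, full_matrices=False)
        axis = vt[-1]
    axis = axis / np.linalg.norm(axis)
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return boundaries, axis


@dataclass
class TwinPartition:
    """Full twin analysis result."""

    labels: np.ndarray
    boundaries: list
    common_axis: np.ndarray
    wedge_angles: np.ndarray  # degrees, azimuthal order
    wedge_domains: list  # domain label occupying each wedge (by azimuth)
    closure_deficit: float
    cyclic: bool

    def to_dict(self) -> dict:
        return {
            "n_domains": int(len(np.unique(self.labels))),
            "common_axis": self.common_axis.tolist(),
            "wedge_angles_deg": np.round(self.wedge_angles, 3).tolist(),
            "closure_deficit_deg": float(self.closure_deficit),
            "cyclic": bool(self.cyclic),
            "boundary_rms_nm": [
                float(b.rms_residual) for b in self.boundaries if b.normal is not None
            ],
        }


def wedge_angles(
    boundaries: Sequence[TwinBoundary],
    common_axis: np.ndarray,
    center: np.ndarray,
    min_support: float = 0.25,
    points: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
):
    """Azimuthal wedge angles between consecutive boundary traces.

    Each boundary's trace direction comes from the fitted plane (axis x
    normal); when ``points`` and ``labels`` are supplied the trace azimuth is
    refined to the optimal 1D separator between the two domains' granule
    azimuths (margin midpoint), which removes the half-row localization bias
    of the contact-midpoint cloud.  A boundary whose midpoints straddle both
    sides of the centre (a full plane, as between two half-space domains)
    contributes two antipodal traces.  Returns the consecutive azimuthal gaps
    in order plus the closure deficit (360 deg minus their sum; 0 for a
    closed cyclic arrangement).
    """
    axis = np.asarray(common_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    u, v = _inplane_frame(axis)
    center = np.asarray(center, dtype=float)

    fitted = [b for b in boundaries if b.normal is not None and len(b.midpoints)]
    if not fitted:
        return np.array([360.0]), 0.0, [0]
    # Domains that only touch near the twin apex produce spurious low-support
    # "boundaries"; keep interfaces with a substantial midpoint population.
    max_n = max(len(b.midpoints) for b in fitted)
    fitted = [b for b in fitted if len(b.midpoints) >= max(3, min_support * max_n)]

    az_pts = None
    if points is not None and labels is not None:
        rel_pts = np.asarray(points, dtype=float) - center
        inplane_r = np.linalg.norm(rel_pts - np.outer(rel_pts @ axis, axis), axis=1)
        az_pts = np.degrees(np.arctan2(rel_pts @ v, rel_pts @ u)) % 360.0
        r_min = 2.0 * modal_nn_distance(np.asarray(points, dtype=float))

    rays = []
    for b in fitted:
        # The ray direction lies in the boundary plane and perpendicular to
        # the axis: d = axis x normal.  Using the fitted plane (rather than
        # averaging midpoint azimuths) avoids the angular bias of midpoints
        # close to the apex.
        d = np.cross(axis, b.normal)
        norm_d = np.linalg.norm(d)
        rel = b.midpoints - center
        az_mid = np.degrees(np.arctan2(rel @ v, rel @ u)) % 360.0
        if norm_d < 1e-6:
            # Boundary plane perpendicular to the axis: no azimuthal trace.
            continue
        d = d / norm_d
        phi = float(np.degrees(np.arctan2(np.dot(d, v), np.dot(d, u))) % 360.0)
        # One ray (wedge boundary) or two antipodal rays (full plane)?
        mean1 = _circular_mean(az_mid)
        spread1 = _circular_spread(az_mid, mean1)
        if spread1 > 45.0:
            g1 = az_mid[_circ_diff(az_mid, phi, 360.0) <= 90.0]
            g2 = az_mid[_circ_diff(az_mid, phi, 360.0) > 90.0]
            if len(g1) and len(g2):
                rays.extend([phi, (phi + 180.0) % 360.0])
                continue
        # Orient the ray toward the midpoint cloud.
        if _circ_diff(np.array([phi]), mean1, 360.0)[0] > 90.0:
            phi = (phi + 180.0) % 360.0
        if az_pts is not None:
            # Exclude the apex region, where azimuths are ill-conditioned.
            a_lab, b_lab = b.domains
            sel_a = (np.asarray(labels) == a_lab) & (inplane_r > r_min)
            sel_b = (np.asarray(labels) == b_lab) & (inplane_r > r_min)
            phi = _margin_azimuth(phi, az_pts[sel_a], az_pts[sel_b])
        rays.append(phi)
    if len(rays) < 2:
        return np.array([360.0]), 0.0, np.asarray(rays)
    sorted_rays = np.sort(np.asarray(rays))
    gaps = np.diff(np.concatenate([sorted_rays, [sorted_rays[0] + 360.0]]))
    deficit = 360.0 - gaps.sum()
    return gaps, float(deficit), sorted_rays


def _margin_azimuth(phi: float, az_a: np.ndarray, az_b: np.ndarray) -> float:
    """Optimal 1D azimuthal separator between two domains, near ``phi``.

    Folds both domains' azimuths around ``phi``, finds the threshold
    minimizing misclassifications and returns the midpoint of the widest gap
    among optimal thresholds.  Falls back to ``phi`` with sparse data.
    """
    ra = (az_a - phi + 180.0) % 360.0 - 180.0
    rb = (az_b - phi + 180.0) % 360.0 - 180.0
    ra = ra[np.abs(ra) < 30.0]
    rb = rb[np.abs(rb) < 30.0]
    if len(ra) < 5 or len(rb) < 5:
        return phi
    if np.mean(ra) > np.mean(rb):
        ra, rb = rb, ra
    merged = np.sort(np.concatenate([ra, rb]))
    thresholds = 0.5 * (merged[:-1] + merged[1:])
    errs = np.array([(ra > t).sum() + (rb < t).sum() for t in thresholds])
    best = thresholds[errs == errs.min()]
    margins = [np.min(np.abs(merged - t)) for t in best]
    return float((phi + best[int(np.argmax(margins))]) % 360.0)


def _circular_mean(deg: np.ndarray) -> float:
    return float(np.degrees(np.angle(np.exp(1j * np.radians(deg)).mean())) % 360.0)


def _circular_spread(deg: np.ndarray, mean: float) -> float:
    return float(np.sqrt(np.mean(_circ_diff(deg, mean, 360.0) ** 2)))


def analyze_twins(
    points: np.ndarray,
    labels: Optional[np.ndarray] = None,
    symmetry_deg: float = 90.0,
    tolerance_deg: float = 5.0,
    refine: bool = True,
) -> TwinPartition:
    """End-to-end twin analysis: orientation field -> segmentation ->
    lattice-residual label refinement -> boundary/axis fitting -> wedge
    angles (with margin-separator ray refinement)."""
    points = np.asarray(points, dtype=float)
    if labels is None:
        axis0 = estimate_common_axis(points)
        orient = local_orientation_field(points, axis=axis0, symmetry_deg=symmetry_deg)
        labels = segment_domains(
            points, orient, tolerance_deg=tolerance_deg, symmetry_deg=symmetry_deg
        )
        if refine:
            labels = refine_labels_by_lattice(points, labels)
    center = points.mean(axis=0)
    boundaries, axis = boundary_planes_and_axis(points, labels, apex=center)
    gaps, deficit, sorted_rays = wedge_angles(
        boundaries, axis, center, points=points, labels=labels
    )

    # Which domain occupies each wedge: use the domain centroids' azimuths.
    u, v = _inplane_frame(axis)
    wedge_domains: list = []
    if len(gaps) > 1:
        for k in range(len(sorted_rays)):
            mid_az = sorted_rays[k] + gaps[k] / 2.0
            best, best_d = None, np.inf
            for lab in np.unique(labels):
                cen = points[labels == lab].mean(axis=0) - center
                az_c = np.degrees(np.arctan2(cen @ v, cen @ u)) % 360.0
                d = _circ_diff(np.array([az_c]), mid_az % 360.0, 360.0)[0]
                if d < best_d:
                    best, best_d = lab, d
            wedge_domains.append(int(best))

    n_dom = len(np.unique(labels))
    cyclic = len(gaps) == n_dom and n_dom >= 3
    return TwinPartition(
        labels=np.asarray(labels),
        boundaries=boundaries,
        common_axis=axis,
        wedge_angles=np.asarray(gaps),
        wedge_domains=wedge_domains,
        closure_deficit=deficit,
        cyclic=cyclic,
    )
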