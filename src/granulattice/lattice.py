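"""Unit-cell inference from a 3D granule point cloud.

The pipeline automates the marker-based cell determination performed on the
tomograms: collect displacement vectors to near neighbours, cluster them into
the discrete lattice translations, extract a primitive basis, reduce it to
the canonical (Buerger/Niggli) cell, then search small supercells for a
higher-symmetry conventional cell and classify the Bravais type.

Only the classes needed to reproduce and challenge the reported packing are
implemented: BCT, triclinic_P, cubic_P, FCC, plus an HCP layering-motif
detector (HCP is a lattice-with-basis, not a Bravais lattice, and is flagged
separately via the non-centrosymmetry of its neighbour shell).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .cells import UnitCell

__all__ = [
    "NoLatticeError",
    "NeighborVectorField",
    "LatticeFit",
    "neighbor_vectors",
    "infer_primitive_basis",
    "niggli_reduce",
    "conventionalize_and_classify",
    "infer_lattice",
    "hcp_layering_score",
    "modal_nn_distance",
]


class NoLatticeError(ValueError):
    """Raised when the point cloud does not support a 3D lattice fit."""


def modal_nn_distance(points: np.ndarray) -> float:
    """Mode of the nearest-neighbour distance distribution (histogram peak)."""
    points = np.asarray(points, dtype=float)
    d, _ = cKDTree(points).query(points, k=2)
    d = d[:, 1]
    if np.ptp(d) < 1e-9 * d.mean():
        return float(d.mean())
    hist, edges = np.histogram(d, bins=max(10, int(np.sqrt(len(d)))))
    i = int(np.argmax(hist))
    sel = d[(d >= edges[i]) & (d <= edges[i + 1])]
    return float(sel.mean()) if len(sel) else float(np.median(d))


@dataclass
class VectorCluster:
    centroid: np.ndarray
    count: int
    lengths: np.ndarray  # realized member lengths
    members: np.ndarray  # realized member vectors (sign-aligned to centroid)


@dataclass
class NeighborVectorField:
    """Per-granule neighbour displacement vectors and their symmetrized
    cluster representatives (v and -v identified)."""

    vectors: np.ndarray  # (m, 3) all displacement vectors within cutoff
    owner: np.ndarray  # (m,) granule index of each vector
    clusters: list  # list[VectorCluster], sorted by descending count
    cutoff: float
    modal_nn: float
    n_points: int


def neighbor_vectors(
    points: np.ndarray,
    cutoff_factor: float = 1.6,
    angle_tol: float = 15.0,
    length_tol: float = 0.2,
) -> NeighborVectorField:
    """Collect and cluster displacement vectors to neighbours within cutoff.

    The cutoff is ``cutoff_factor`` x the modal nearest-neighbour distance.
    Clustering is greedy: a vector joins an existing cluster when it matches
    the centroid (either sign) within ``angle_tol`` degrees and ``length_tol``
    relative length; otherwise it seeds a new cluster.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 2:
        raise NoLatticeError("need at least 2 points")
    modal = modal_nn_distance(points)
    cutoff = cutoff_factor * modal
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs) == 0:
        raise NoLatticeError("no neighbour pairs within cutoff")
    vecs = points[pairs[:, 1]] - points[pairs[:, 0]]
    vectors = np.concatenate([vecs, -vecs])
    owner = np.concatenate([pairs[:, 0], pairs[:, 1]])

    clusters = _cluster_vectors(vecs, angle_tol, length_tol)
    clusters.sort(key=lambda c: (-c.count, np.linalg.norm(c.centroid)))
    return NeighborVectorField(
        vectors=vectors,
        owner=owner,
        clusters=clusters,
        cutoff=cutoff,
        modal_nn=modal,
        n_points=len(points),
    )


def _cluster_vectors(vecs: np.ndarray, angle_tol: float, length_tol: float) -> list:
    cos_tol = np.cos(np.radians(angle_tol))
    sums: list[np.ndarray] = []
    members: list[list[np.ndarray]] = []
    order = np.argsort(np.linalg.norm(vecs, axis=1))
    for v in vecs[order]:
        lv = np.linalg.norm(v)
        if lv == 0:
            continue
        placed = False
        for i, s in enumerate(sums):
            c = s / len(members[i])
            lc = np.linalg.norm(c)
            cosang = np.dot(v, c) / (lv * lc)
            if abs(cosang) >= cos_tol and abs(lv - lc) <= length_tol * lc:
                vv = v if cosang >= 0 else -v
                sums[i] = s + vv
                members[i].append(vv)
                placed = True
                break
        if not placed:
            sums.append(v.copy())
            members.append([v.copy()])
    out = []
    for s, mem in zip(sums, members):
        mem = np.asarray(mem)
        out.append(
            VectorCluster(
                centroid=s / len(mem),
                count=len(mem),
                lengths=np.linalg.norm(mem, axis=1),
                members=mem,
            )
        )
    return out


def _major_clusters(field: NeighborVectorField) -> list:
    floor = max(2, int(0.05 * field.n_points))
    major = [c for c in field.clusters if c.count >= floor]
    return major if major else field.clusters[:14]


def _shortest_independent_triple(vectors: np.ndarray, volume: Optional[float] = None):
    """Greedy pick of the three shortest linearly independent vectors.

    In 3D the successive minima of a lattice always form a basis, so when
    ``vectors`` enumerates lattice vectors this returns a Buerger-reduced
    basis.  Deterministic: ties broken lexicographically.
    """
    lens = np.linalg.norm(vectors, axis=1)
    order = np.lexsort((vectors[:, 2], vectors[:, 1], vectors[:, 0], np.round(lens, 9)))
    sel: list[np.ndarray] = []
    for v in vectors[order]:
        if np.linalg.norm(v) < 1e-9:
            continue
        if len(sel) == 1 and np.linalg.norm(np.cross(sel[0], v)) < 1e-6 * np.linalg.norm(v):
            continue
        if len(sel) == 2:
            det = abs(np.linalg.det(np.vstack(sel + [v])))
            if det < 1e-6:
                continue
            if volume is not None and det < 0.5 * volume:
                continue  # would generate a sublattice
        sel.append(v)
        if len(sel) == 3:
            return np.vstack(sel)
    return None


def infer_primitive_basis(
    field: NeighborVectorField, volume_floor_factor: float = 0.05
) -> np.ndarray:
    """Select a primitive basis from the clustered neighbour vectors.

    Picks the three shortest pairwise non-coplanar cluster centroids with
    |det| above ``volume_floor_factor`` x the product of their lengths, then
    augments the basis until every major cluster centroid is an integer
    combination (this absorbs centering vectors such as the BCT half body
    diagonal).  Raises :class:`NoLatticeError` for coplanar (2D) fields or
    when the candidate basis fails to index the neighbour vectors.
    """
    major = _major_clusters(field)
    cents = np.array([c.centroid for c in major])
    if len(cents) < 3:
        raise NoLatticeError("fewer than 3 vector clusters: no 3D lattice")

    order = np.argsort(np.linalg.norm(cents, axis=1))
    basis = None
    for i, j, k in itertools.combinations(order, 3):
        tri = cents[[i, j, k]]
        det = abs(np.linalg.det(tri))
        if det > volume_floor_factor * np.prod(np.linalg.norm(tri, axis=1)):
            basis = tri
            break
    if basis is None:
        raise NoLatticeError("all vector clusters coplanar: no 3D lattice")

    # Absorb clusters not yet generated by the basis (sublattice repair).
    for _ in range(4):
        frac = cents @ np.linalg.inv(basis)
        off = np.abs(frac - np.round(frac)).max(axis=1)
        bad = np.where(off > 0.15)[0]
        if len(bad) == 0:
            break
        gens = np.vstack([basis, cents[bad[0]]])
        combos = np.array(list(itertools.product(range(-2, 3), repeat=4)), dtype=float)
        cand = combos @ gens
        new_basis = _shortest_independent_triple(cand)
        if new_basis is None:
            raise NoLatticeError("degenerate generator set")
        basis = new_basis
    else:
        raise NoLatticeError("neighbour vectors not indexable by a single lattice")

    # Validate: the weighted majority of clusters must index as integers.
    frac = cents @ np.linalg.inv(basis)
    off = np.abs(frac - np.round(frac)).max(axis=1)
    weights = np.array([c.count for c in major], dtype=float)
    explained = weights[off < 0.15].sum() / weights.sum()
    if explained < 0.6:
        raise NoLatticeError("no 3D lattice: neighbour vectors are not crystalline")
    return basis


def niggli_reduce(basis: np.ndarray) -> np.ndarray:
    """Canonical reduced basis: the three shortest lattice translations.

    Enumerates small integer combinations of the input basis, takes the
    successive minima (a Buerger cell), then normalizes signs so the pairwise
    scalar products are all non-negative (all-acute, Niggli type I) or all
    non-positive (type II), preferring type I, with rows ordered by length
    and a right-handed overall orientation.  The generated lattice is
    unchanged (the transformation is unimodular).
    """
    basis = np.asarray(basis, dtype=float)
    vol = abs(np.linalg.det(basis))
    if vol < 1e-9:
        raise ValueError("singular basis")
    combos = np.array(
        [m for m in itertools.product(range(-3, 4), repeat=3) if m != (0, 0, 0)],
        dtype=float,
    )
    cand = combos @ basis
    red = _shortest_independent_triple(cand, volume=vol)
    if red is None or not np.isclose(abs(np.linalg.det(red)), vol, rtol=1e-6):
        raise ValueError("reduction failed to preserve the lattice volume")
    red = red[np.argsort(np.linalg.norm(red, axis=1))]

    best = None
    for signs in itertools.product((1.0, -1.0), repeat=3):
        M = red * np.array(signs)[:, None]
        d = np.array(
            [np.dot(M[1], M[2]), np.dot(M[0], M[2]), np.dot(M[0], M[1])]
        )
        if np.all(d >= -1e-9):
            rank = 0  # type I preferred
        elif np.all(d <= 1e-9):
            rank = 1
        else:
            continue
        key = (rank, tuple(np.round(-d, 9)))
        if best is None or key < best[0]:
            best = (key, M)
    M = red if best is None else best[1]
    if np.linalg.det(M) < 0:
        M = -M
    return M


@dataclass
class LatticeFit:
    """Result of unit-cell inference on a granule point cloud."""

    label: str  # BCT | triclinic_P | cubic_P | FCC | HCP_layering | unclassified
    cell: Optional[UnitCell]
    conventional_basis: Optional[np.ndarray]
    primitive_basis: Optional[np.ndarray]
    reduced_basis: Optional[np.ndarray]
    parameter_sd: dict = field(default_factory=dict)
    residuals: Optional[np.ndarray] = None
    explained_fraction: float = np.nan
    hcp_score: float = np.nan
    candidates: list = field(default_factory=list)

    @property
    def primitive_volume(self) -> float:
        return abs(float(np.linalg.det(self.primitive_basis)))

    def to_dict(self) -> dict:
        out = {
            "label": self.label,
            "explained_fraction": float(self.explained_fraction),
            "hcp_score": None if np.isnan(self.hcp_score) else float(self.hcp_score),
            "parameter_sd": {k: float(v) for k, v in self.parameter_sd.items()},
        }
        if self.cell is not None:
            out["cell"] = {
                "a": self.cell.a, "b": self.cell.b, "c": self.cell.c,
                "alpha": self.cell.alpha, "beta": self.cell.beta,
                "gamma": self.cell.gamma, "centering": self.cell.centering,
            }
        if self.reduced_basis is not None:
            out["reduced_basis_nm"] = np.asarray(self.reduced_basis).tolist()
        if self.residuals is not None and len(self.residuals):
            out["residual_rms_nm"] = float(np.sqrt(np.mean(self.residuals**2)))
        return out


def _cell_angles(tri: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(tri, axis=1)
    cosv = np.array(
        [
            np.dot(tri[1], tri[2]) / (n[1] * n[2]),
            np.dot(tri[0], tri[2]) / (n[0] * n[2]),
            np.dot(tri[0], tri[1]) / (n[0] * n[1]),
        ]
    )
    return np.degrees(np.arccos(np.clip(cosv, -1, 1)))


def _is_lattice_vector(v: np.ndarray, basis: np.ndarray, tol: float = 0.05) -> bool:
    x = v @ np.linalg.inv(basis)
    return bool(np.all(np.abs(x - np.round(x)) < tol))


def _canonical_triclinic(red: np.ndarray) -> np.ndarray:
    """Order rows a >= b >= c and fold angles to their acute representatives
    (report convention; the all-acute triple may not form a consistent basis,
    so folding is applied to the reported parameters only)."""
    order = np.argsort(-np.linalg.norm(red, axis=1))
    return red[order]


def conventionalize_and_classify(
    reduced: np.ndarray,
    field: Optional[NeighborVectorField] = None,
    tol_angle: float = 1.0,
    tol_length: float = 0.02,
) -> LatticeFit:
    """Search small supercells of the reduced basis for a symmetric
    conventional cell and classify the Bravais type.

    Candidate conventional bases are integer combinations (coefficients in
    [-2, 2]) of the reduced basis with 1 or 2 lattice points per cell.  A
    tetragonal candidate (a = b != c, right angles) containing the half
    body-diagonal lattice point is labelled BCT; an all-equal right-angle
    primitive candidate is cubic_P; a reduced cell with equal edges and 60
    degree angles is FCC (reported with its conventional cubic cell); and
    when no symmetric supercell exists the reduced (canonically ordered)
    triclinic cell is reported.  Two distinct labels with indistinguishable
    deviation scores yield "unclassified" with both candidates listed.
    """
    reduced = np.asarray(reduced, dtype=float)
    vp = abs(np.linalg.det(reduced))
    red_len = np.linalg.norm(reduced, axis=1)
    red_ang = _cell_angles(reduced)
    acute = np.minimum(red_ang, 180.0 - red_ang)

    candidates = []  # (label, score, conv_basis, cell)

    combos = np.array(
        [m for m in itertools.product(range(-2, 3), repeat=3) if m != (0, 0, 0)],
        dtype=float,
    )
    vecs = combos @ reduced
    lens = np.linalg.norm(vecs, axis=1)
    keep = lens <= 2.2 * red_len.max()
    vecs, lens = vecs[keep], lens[keep]

    # FCC has the unique 12-vector minimal shell among the implemented
    # classes (cubic_P: 6, BCC/BCT: 8, triclinic: 2).  It must be recognized
    # before the supercell search, because the FCC lattice also admits a
    # valid 2-point body-centered tetragonal supercell (a/sqrt2, a/sqrt2, a)
    # that would otherwise win the classification.
    lmin = lens.min()
    shell = vecs[lens <= lmin * (1.0 + tol_length)]
    if len(shell) == 12:
        a_conv = float(lmin * np.sqrt(2.0))
        conv = _orthogonal_axes(vecs, lens, a_conv, tol_length)
        cell = UnitCell(a_conv, a_conv, a_conv, centering="face_centered")
        fit = LatticeFit(
            label="FCC",
            cell=cell,
            conventional_basis=conv,
            primitive_basis=reduced,
            reduced_basis=reduced,
        )
        if field is not None:
            fit.parameter_sd = _parameter_uncertainties(fit, field)
        return fit

    order = np.argsort(lens)[:48]
    vecs = vecs[order]

    for i, j, k in itertools.combinations(range(len(vecs)), 3):
        tri = vecs[[i, j, k]]
        det = abs(np.linalg.det(tri))
        if det < 1e-9:
            continue
        ratio = det / vp
        n_points = int(round(ratio))
        if n_points not in (1, 2) or abs(ratio - n_points) > 0.05:
            continue
        l = np.linalg.norm(tri, axis=1)
        ang = _cell_angles(tri)
        if np.any(np.abs(ang - 90.0) > tol_angle * 3):
            continue
        ang_dev = np.abs(ang - 90.0)
        if np.all(ang_dev <= tol_angle):
            pairs_eq = [
                (p, q) for p, q in ((0, 1), (0, 2), (1, 2))
                if abs(l[p] - l[q]) <= tol_length * max(l[p], l[q])
            ]
            score = float(ang_dev.sum() / tol_angle)
            if n_points == 1 and len(pairs_eq) == 3:
                score += float(np.ptp(l) / l.mean() / tol_length)
                cell = UnitCell(float(l.mean()), float(l.mean()), float(l.mean()))
                candidates.append(("cubic_P", score, tri, cell))
            elif n_points == 2 and len(pairs_eq) >= 1:
                if not _is_lattice_vector(tri.sum(axis=0) / 2.0, reduced):
                    continue
                # unique axis = the edge not in the (first) equal pair
                p, q = pairs_eq[0]
                r = ({0, 1, 2} - {p, q}).pop()
                a_len = float((l[p] + l[q]) / 2.0)
                score += float(abs(l[p] - l[q]) / a_len / tol_length)
                cell = UnitCell(a_len, a_len, float(l[r]), centering="body_centered")
                conv = tri[[p, q, r]]
                candidates.append(("BCT", score, conv, cell))

    if not candidates:
        conv = _canonical_triclinic(reduced)
        l = np.linalg.norm(conv, axis=1)
        ang = _cell_angles(conv)
        ang = np.minimum(ang, 180.0 - ang)  # report acute representatives
        cell = UnitCell(l[0], l[1], l[2], ang[0], ang[1], ang[2])
        fit = LatticeFit(
            label="triclinic_P",
            cell=cell,
            conventional_basis=conv,
            primitive_basis=reduced,
            reduced_basis=reduced,
        )
    else:
        best_per_label: dict = {}
        for lab, score, conv, cell in candidates:
            if lab not in best_per_label or score < best_per_label[lab][0]:
                best_per_label[lab] = (score, conv, cell)
        ranked = sorted(best_per_label.items(), key=lambda kv: kv[1][0])
        label, (score, conv, cell) = ranked[0]
        if len(ranked) > 1 and ranked[1][1][0] - score < 0.5:
            fit = LatticeFit(
                label="unclassified",
                cell=cell,
                conventional_basis=conv,
                primitive_basis=reduced,
                reduced_basis=reduced,
                candidates=[(lab, s) for lab, (s, _, _) in ranked[:2]],
            )
        else:
            fit = LatticeFit(
                label=label,
                cell=cell,
                conventional_basis=conv,
                primitive_basis=reduced,
                reduced_basis=reduced,
            )

    if field is not None and fit.conventional_basis is not None:
        fit.parameter_sd = _parameter_uncertainties(fit, field)
    return fit


def _orthogonal_axes(
    vecs: np.ndarray, lens: np.ndarray, target_len: float, tol_length: float
):
    """Three mutually orthogonal lattice vectors of ~target_len (FCC cube axes)."""
    sel = vecs[np.abs(lens - target_len) <= 2 * tol_length * target_len]
    for i, j, k in itertools.combinations(range(len(sel)), 3):
        tri = sel[[i, j, k]]
        ang = _cell_angles(tri)
        if np.all(np.abs(ang - 90.0) < 2.0) and np.linalg.det(tri) > 0:
            return tri
    return None


def _parameter_uncertainties(fit: LatticeFit, field: NeighborVectorField) -> dict:
    """sd of realized edge lengths per conventional axis, from the neighbour
    vector clusters matching each conventional basis vector."""
    out: dict = {}
    names = ("a", "b", "c")
    for name, v in zip(names, fit.conventional_basis):
        lv = np.linalg.norm(v)
        best = None
        for c in field.clusters:
            lc = np.linalg.norm(c.centroid)
            if abs(lc - lv) > 0.2 * lv:
                continue
            cosang = abs(np.dot(c.centroid, v) / (lc * lv))
            if cosang < np.cos(np.radians(15.0)):
                continue
            if best is None or c.count > best.count:
                best = c
        if best is not None and best.count > 1:
            out[name] = float(np.std(best.lengths, ddof=1))
    return out


def lattice_residuals(points: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Distance (nm) from each point to the nearest site of the fitted lattice
    anchored at the point cloud's best-matching origin."""
    points = np.asarray(points, dtype=float)
    inv = np.linalg.inv(basis)
    frac = (points - points[0]) @ inv
    # Anchor: circular mean of the fractional offsets, mapped back.
    shift = np.angle(np.exp(2j * np.pi * frac).mean(axis=0)) / (2 * np.pi)
    dev = frac - shift
    dev -= np.round(dev)
    return np.linalg.norm(dev @ basis, axis=1)


def hcp_layering_score(points: np.ndarray, length_tol: float = 0.15) -> float:
    """Fraction of first-shell neighbour vectors lacking an antipodal partner,
    averaged over fully-coordinated granules.

    A Bravais-lattice neighbour shell is centrosymmetric (score ~0); the
    12-neighbour shell of an HCP stacking has 6 unpaired out-of-plane vectors
    (score ~0.5).  Scores above ~0.3 indicate an HCP-type layering motif.
    """
    points = np.asarray(points, dtype=float)
    modal = modal_nn_distance(points)
    tree = cKDTree(points)
    neigh = tree.query_ball_point(points, r=(1.0 + length_tol) * modal)
    counts = np.array([len(n) - 1 for n in neigh])
    if counts.max() < 3:
        return 0.0
    full = counts >= np.percentile(counts, 75)
    scores = []
    cos_tol = np.cos(np.radians(20.0))
    for i in np.where(full)[0]:
        vs = points[[j for j in neigh[i] if j != i]] - points[i]
        norms = np.linalg.norm(vs, axis=1)
        unit = vs / norms[:, None]
        cosm = unit @ unit.T
        unpaired = 0
        for a in range(len(vs)):
            has = np.any(
                (cosm[a] < -cos_tol)
                & (np.abs(norms - norms[a]) < length_tol * norms[a])
            )
            unpaired += not has
        scores.append(unpaired / len(vs))
    return float(np.mean(scores)) if scores else 0.0


def infer_lattice(
    points: np.ndarray,
    cutoff_factor: float = 1.6,
    tol_angle: float = 1.0,
    tol_length: float = 0.02,
) -> LatticeFit:
    """Full inference chain: neighbour vectors -> primitive basis -> reduction
    -> conventionalization/classification, with residuals and an HCP check."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    field = neighbor_vectors(points, cutoff_factor=cutoff_factor)
    try:
        basis = infer_primitive_basis(field)
        if _site_occupancy(points, basis) < 0.6:
            # The candidate lattice over-generates: most of its sites hold no
            # granule.  A lattice-with-basis (e.g. HCP stacking) produces
            # exactly this, because the inter-layer offset gets absorbed as if
            # it were a translation of a finer lattice.
            raise NoLatticeError("candidate lattice sites are mostly unoccupied")
    except NoLatticeError:
        # HCP is still highly ordered: sharp NN distance distribution and a
        # non-centrosymmetric first neighbour shell.  Random points are neither.
        d, _ = cKDTree(points).query(points, k=2)
        ordered = np.std(d[:, 1]) / np.mean(d[:, 1]) < 0.15
        hcp = hcp_layering_score(points) if ordered else 0.0
        if ordered and hcp > 0.3:
            return LatticeFit(
                label="HCP_layering",
                cell=None,
                conventional_basis=None,
                primitive_basis=None,
                reduced_basis=None,
                hcp_score=hcp,
            )
        raise
    reduced = niggli_reduce(basis)
    fit = conventionalize_and_classify(
        reduced, field=field, tol_angle=tol_angle, tol_length=tol_length
    )
    fit.hcp_score = hcp_layering_score(points)
    fit.residuals = lattice_residuals(points, fit.primitive_basis)
    frac_ok = float(np.mean(fit.residuals < 0.25 * field.modal_nn))
    fit.explained_fraction = frac_ok
    return fit


def _site_occupancy(points: np.ndarray, basis: np.ndarray) -> float:
    """Observed point density times the primitive cell volume: ~1 when the
    lattice matches the cloud, << 1 when the lattice over-generates."""
    from scipy.spatial import ConvexHull

    try:
        hull_volume = ConvexHull(points).volume
    except Exception:
        return 1.0  # degenerate hull: leave the decision to other checks
    vp = abs(np.linalg.det(basis))
    return float(len(points) * vp / hull_volume)
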