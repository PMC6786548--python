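"""Unit-cell parameterization and basic lattice geometry.

Conventions used throughout the package: right-handed lab frame, lengths in
nanometres, angles in degrees.  A cell is parameterized by edge lengths
(a, b, c), inter-edge angles (alpha, beta, gamma) with alpha = angle(b, c),
beta = angle(a, c), gamma = angle(a, b), and a centering flag.  The basis
matrix follows the standard crystallographic orientation: **a** along x,
**b** in the xy-plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

Centering = Literal["primitive", "body_centered", "face_centered"]

#: Number of lattice points per conventional cell for each centering.
CENTERING_MULTIPLICITY = {"primitive": 1, "body_centered": 2, "face_centered": 4}

#: Fractional coordinates of the lattice points inside one conventional cell.
CENTERING_OFFSETS = {
    "primitive": np.zeros((1, 3)),
    "body_centered": np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.5]]),
    "face_centered": np.array(
        [[0.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]
    ),
}


class DegenerateCellError(ValueError):
    """Raised when cell parameters do not define a positive cell volume."""


@dataclass(frozen=True)
class UnitCell:
    """A Bravais cell: edge lengths (nm), angles (degrees) and centering.

    Raises :class:`DegenerateCellError` if the metric tensor is not
    positive-definite (collapsed cell).
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    centering: Centering = "primitive"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise DegenerateCellError("cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise DegenerateCellError("cell angles must lie in (0, 180) degrees")
        if self.centering not in CENTERING_MULTIPLICITY:
            raise ValueError(f"unknown centering {self.centering!r}")
        if self.volume_factor() <= 1e-12:
            raise DegenerateCellError("cell volume is (numerically) zero")

    def volume_factor(self) -> float:
        """sqrt(1 - cos^2 terms) appearing in the triclinic volume formula."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca**2 - cb**2 - cg**2 + 2.0 * ca * cb * cg
        return float(np.sqrt(max(arg, 0.0)))

    @property
    def volume(self) -> float:
        """Conventional cell volume in nm^3."""
        return self.a * self.b * self.c * self.volume_factor()

    @property
    def primitive_volume(self) -> float:
        """Volume per lattice point (conventional volume / multiplicity)."""
        return self.volume / CENTERING_MULTIPLICITY[self.centering]

    def basis(self) -> np.ndarray:
        """Conventional basis as a 3x3 matrix with basis vectors as rows (nm)."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        va = np.array([self.a, 0.0, 0.0])
        vb = np.array([self.b * cg, self.b * sg, 0.0])
        cx = self.c * cb
        cy = self.c * (ca - cb * cg) / sg
        cz2 = self.c**2 - cx**2 - cy**2
        if cz2 <= 0:
            raise DegenerateCellError("cell angles incompatible with a 3D cell")
        vc = np.array([cx, cy, np.sqrt(cz2)])
        return np.vstack([va, vb, vc])

    def metric_tensor(self) -> np.ndarray:
        """Gram matrix G = B B^T of the conventional basis."""
        B = self.basis()
        return B @ B.T


def cell_from_basis(basis: np.ndarray, centering: Centering = "primitive") -> UnitCell:
    """Cell parameters (a, b, c, alpha, beta, gamma) of a 3x3 row-vector basis."""
    basis = np.asarray(basis, dtype=float)
    lengths = np.linalg.norm(basis, axis=1)
    if np.any(lengths <= 0) or abs(np.linalg.det(basis)) < 1e-12:
        raise DegenerateCellError("singular basis")

    def ang(i: int, j: int) -> float:
        cosv = np.dot(basis[i], basis[j]) / (lengths[i] * lengths[j])
        return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))

    return UnitCell(
        a=float(lengths[0]),
        b=float(lengths[1]),
        c=float(lengths[2]),
        alpha=ang(1, 2),
        beta=ang(0, 2),
        gamma=ang(0, 1),
        centering=centering,
    )


def primitive_basis(cell: UnitCell) -> np.ndarray:
    """A primitive basis (rows, nm) of the lattice generated by ``cell``.

    For a body-centered cell the primitive vectors are the usual
    half-body-diagonal set; for a face-centered cell the half-face-diagonal
    set; for a primitive cell the conventional basis itself.
    """
    B = cell.basis()
    if cell.centering == "primitive":
        return B
    if cell.centering == "body_centered":
        M = 0.5 * np.array([[-1, 1, 1], [1, -1, 1], [1, 1, -1]], dtype=float)
    else:  # face_centered
        M = 0.5 * np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    return M @ B


# Cells reported for the two crystalline areas of the hIAPP aggregate; used as
# package-wide defaults for the synthetic generator.
HIAPP_BCT_CELL = UnitCell(a=27.9, b=27.9, c=33.0, centering="body_centered")
HIAPP_TRICLINIC_CELL = UnitCell(
    a=28.4, b=26.5, c=24.2, alpha=78.0, beta=66.0, gamma=61.0, centering="primitive"
)

#: Wedge angles (degrees) of the five-fold cyclic twin, in azimuthal order.
FIVEFOLD_WEDGE_ANGLES = (76.0, 70.0, 71.0, 73.0, 69.0)
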