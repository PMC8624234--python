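"""Rigid-body geometry: RMSD, Kabsch superposition, pulling-axis alignment.

Before mode analysis the molecule is rotated so that the vector between the
two tether-attachment residues lies along a chosen coordinate axis (the
z-axis by convention).  Modes that drive the domains apart along the applied
force then show up directly in the z-components of the eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from pullnma.errors import DegenerateGeometryError
from pullnma.structure_io import CoarseModel, ResidueId

Z_AXIS = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class PullingGeometry:
    """Where the tethers attach and which axis the force should lie along.

    Attachments are named by residue (the Cα bead stands in for the real
    tether chemistry); the default target axis is z.
    """

    attach_a: ResidueId | tuple | str
    attach_b: ResidueId | tuple | str
    target_axis: np.ndarray = field(default_factory=lambda: Z_AXIS.copy())

    def __post_init__(self) -> None:
        axis = np.asarray(self.target_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("target_axis must be non-zero")
        object.__setattr__(self, "target_axis", axis / norm)
        if self.attach_a == self.attach_b:
            raise ValueError("attachment residues must differ")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-10):
            raise ValueError("rotation matrix is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_flat(self) -> list[float]:
        """12 numbers (9 rotation entries row-major + 3 translation) for run reports."""
        return [*self.rotation.ravel().tolist(), *self.translation.tolist()]


def rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Raw coordinate RMSD between two equally-sized point sets (no superposition)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ or are not (N, 3): {X.shape} vs {Y.shape}")
    return float(np.sqrt(np.mean(np.sum((X - Y) ** 2, axis=1))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the optimal proper :class:`RigidTransform` (reflections are
    corrected) and the RMSD after applying it.  Uses the SVD-based Kabsch
    solution as implemented by scipy's ``Rotation.align_vectors``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be equal-shape (N, 3) arrays")
    if mobile.shape[0] < 3:
        raise DegenerateGeometryError("superposition needs at least 3 sites")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    # collinear point sets leave a free rotation about the common axis
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise DegenerateGeometryError("collinear coordinates: superposition is not unique")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = reference.mean(axis=0) - R @ mobile.mean(axis=0)
    transform = RigidTransform(R, t)
    return transform, rmsd(transform.apply(mobile), reference)


def _rotation_taking(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix R with R v̂ = ŵ."""
    v = v / np.linalg.norm(v)
    w = w / np.linalg.norm(w)
    c = float(np.dot(v, w))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 degrees: rotate about any axis perpendicular to v
        helper = np.array([1.0, 0.0, 0.0])
        if abs(v[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(v, helper)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = np.cross(v, w)
    axis /= np.linalg.norm(axis)
    angle = np.arccos(np.clip(c, -1.0, 1.0))
    return Rotation.from_rotvec(angle * axis).as_matrix()


def align_pulling_axis(model: CoarseModel, pull: PullingGeometry):
    """Rotate the model so the attach_a -> attach_b vector lies along the target axis.

    The centroid is moved to the origin.  Spin about the pulling axis is left
    free (only one direction is physically fixed by the experiment); the
    minimal rotation is used, so an already-aligned model is returned with an
    identity rotation.  Returns the aligned model and the transform applied.
    """
    ia = model.index_of(pull.attach_a)
    ib = model.index_of(pull.attach_b)
    v = model.coords[ib] - model.coords[ia]
    norm = np.linalg.norm(v)
    if norm < 1e-6:
        raise DegenerateGeometryError(
            f"attachment residues {pull.attach_a} and {pull.attach_b} are coincident in space"
        )
    R = _rotation_taking(v, pull.target_axis)
    centroid = model.coords.mean(axis=0)
    transform = RigidTransform(R, -R @ centroid)
    aligned = model.with_coords(transform.apply(model.coords))
    return aligned, transform
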