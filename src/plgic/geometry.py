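"""Superposition, pore-axis estimation and swing–twist rotation decomposition.

The swing–twist split is the workhorse for reporting subunit-domain motion:
any rotation R is written uniquely (for tilt < 180°) as R = S · T where T
("twist") is a rotation about the channel pore axis and S ("swing") tips
that axis without twisting about it. The twist angle is the subunit
*rotation* (signed, counterclockwise positive when viewed from the
extracellular side, i.e. right-handed about the axis pointing ECD-ward) and
the swing angle is the subunit *tilt*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, AnnotationError
from .structures import StructureModel, CorrespondenceMap, select_atoms


@dataclass
class RigidTransform:
    """Proper rigid transform x → R x + t with the post-fit RMSD attached."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_after_fit: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
                "rmsd_after_fit": float(self.rmsd_after_fit)}


@dataclass
class Axis:
    """Oriented line in space; direction is unit length, points ECD-ward."""

    point: np.ndarray
    direction: np.ndarray
    orientation_tag: str = "ECD_positive"

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0 or not np.isfinite(n):
            raise DegenerateGeometryError("axis direction has zero length")
        self.direction = d / n

    def coordinate(self, coords: np.ndarray) -> np.ndarray:
        """Signed axial coordinate (Å) of points, 0 at ``point``."""
        return (np.atleast_2d(coords) - self.point) @ self.direction

    def to_dict(self) -> dict:
        return {"point": self.point.tolist(),
                "direction": self.direction.tolist(),
                "orientation_tag": self.orientation_tag}


@dataclass
class SwingTwist:
    """Tilt (swing, deg, in [0,180]) and rotation (twist, deg, in (−180,180])."""

    tilt_deg: float
    rotation_deg: float
    residual_rmsd: float = 0.0
    swing: Rotation = field(default=None, repr=False)
    twist: Rotation = field(default=None, repr=False)


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray,
                     weights: np.ndarray | None = None) -> RigidTransform:
    """Least-squares proper rigid superposition of ``mobile`` onto ``reference``.

    Returns the transform minimising the (weighted) RMSD; reflections are
    never returned. Degenerate inputs (n < 3, or points of rank < 2 in either
    set) raise :class:`DegenerateGeometryError`.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise DegenerateGeometryError(
            f"paired coordinate sets required, got {ref.shape} vs {mob.shape}")
    n = len(ref)
    if n < 3:
        raise DegenerateGeometryError(f"need ≥ 3 paired points, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    ref_com = w @ ref
    mob_com = w @ mob
    ref_c = ref - ref_com
    mob_c = mob - mob_com
    for arr, which in ((ref_c, "reference"), (mob_c, "mobile")):
        if np.linalg.matrix_rank(arr * w[:, None], tol=1e-9) < 2:
            raise DegenerateGeometryError(f"{which} set is collinear/degenerate")
    rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=w)
    R = rot.as_matrix()
    t = ref_com - R @ mob_com
    resid = ref - (mob @ R.T + t)
    rmsd = float(np.sqrt((w * np.sum(resid ** 2, axis=1)).sum()))
    return RigidTransform(rotation=R, translation=t, rmsd_after_fit=rmsd)


def pore_axis(model: StructureModel, user_axis: Axis | None = None) -> Axis:
    """Channel long axis: leading principal direction of receptor C-α.

    The channel is prolate, so the largest-variance eigenvector of the C-α
    covariance runs along the pore; by 5-fold pseudosymmetry the lateral
    directions are (near-)degenerate and orthogonal to it. The axis passes
    through the all-C-α centroid and is oriented so the ECD centroid sits on
    the positive side.
    """
    if user_axis is not None:
        return user_axis
    chains = model.receptor_chains()
    if len(chains) < 2:
        raise AnnotationError(
            f"{model.label!r}: pore axis needs an annotated multi-subunit "
            f"receptor ({len(chains)} receptor chains)")
    ca = select_atoms(model, atoms="CA", warn_empty=False)
    coords = model.coords[ca]
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, np.argmax(evals)]
    if model.domains is not None and "ECD" in model.domains.domains:
        ecd = select_atoms(model, domain="ECD", atoms="CA", warn_empty=False)
        if len(ecd) and (model.coords[ecd].mean(axis=0) - centroid) @ direction < 0:
            direction = -direction
    elif direction[2] < 0:  # fall back: assume build frame has ECD up
        direction = -direction
    return Axis(point=centroid, direction=direction)


def swing_twist_decompose(rotation: np.ndarray | Rotation, axis: Axis,
                          residual_rmsd: float = 0.0) -> SwingTwist:
    """Split a rotation into twist about ``axis`` and a residual swing.

    The twist quaternion is the projection of the rotation quaternion onto
    the axis; the swing is what remains, so that swing ∘ twist reproduces the
    input exactly. Twist is signed right-handed about the (ECD-ward) axis,
    i.e. counterclockwise positive viewed from the extracellular side.
    """
    if isinstance(rotation, Rotation):
        rot = rotation
        R = rotation.as_matrix()
    else:
        R = np.asarray(rotation, dtype=float)
        if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > 1e-6 \
                or np.linalg.det(R) < 0:
            raise DegenerateGeometryError("input is not a proper rotation matrix")
        rot = Rotation.from_matrix(R)
    a = axis.direction
    qx, qy, qz, qw = rot.as_quat()
    if qw < 0:
        qx, qy, qz, qw = -qx, -qy, -qz, -qw
    proj = np.array([qx, qy, qz]) @ a
    tw = np.array([*(proj * a), qw])
    norm = np.linalg.norm(tw)
    if norm < 1e-12:  # 180° swing exactly orthogonal to the axis: twist = 0
        twist = Rotation.identity()
    else:
        twist = Rotation.from_quat(tw / norm)
    swing = rot * twist.inv()
    rotation_deg = float(np.degrees(2.0 * np.arctan2(proj, qw)))
    if rotation_deg <= -180.0:
        rotation_deg += 360.0
    elif rotation_deg > 180.0:
        rotation_deg -= 360.0
    tilt_deg = float(np.degrees(swing.magnitude()))
    return SwingTwist(tilt_deg=tilt_deg, rotation_deg=rotation_deg,
                      residual_rmsd=float(residual_rmsd),
                      swing=swing, twist=twist)


def superpose_model(mobile: StructureModel, reference: StructureModel,
                    corr: CorrespondenceMap) -> tuple[StructureModel, RigidTransform]:
    """Superpose ``mobile`` onto ``reference`` over all paired C-α (unweighted).

    ``corr`` must have been built with ``reference`` as model A and ``mobile``
    as model B.
    """
    tr = kabsch_superpose(reference.coords[corr.idx_A],
                          mobile.coords[corr.idx_B])
    return mobile.transformed(tr.rotation, tr.translation), tr
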