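"""Femoral and tibial anatomical reference frames from bony landmarks.

The femoral frame is built from the mechanical axis (femoral head centre to
knee centre) and the transepicondylar line; the tibial frame treats the knee
as a simple hinge, sharing the femoral mediolateral axis and using the talus
centre as the distal landmark. Frames are orthonormal and right-handed, with
axes (rows) ordered ML (medial->lateral), AP, PROX (distal->proximal), and
origin at the knee centre. Constructing frames from landmarks rather than
scanner coordinates makes every downstream measurement independent of how
the patient lay in the scanner.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

_MIN_SEPARATION_MM = 1.0  # degeneracy guard: far below anatomy, far above noise
_MIN_ANGLE_DEG = 1.0
_ORTHO_TOL = 1e-9


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a zero vector")
    return v / n


@dataclass
class LandmarkSet:
    """Named anatomical points in world mm (LPS) plus limb side.

    Either ``femoral_head_centre`` or ``head_surface_points`` (>= 4
    non-coplanar points on the head, from which the centre is sphere-fitted)
    must be provided. ``talus_centre`` is required only for the tibial frame.
    """

    medial_epicondyle: np.ndarray
    lateral_epicondyle: np.ndarray
    side: Literal["left", "right"]
    femoral_head_centre: np.ndarray | None = None
    head_surface_points: np.ndarray | None = None
    talus_centre: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.medial_epicondyle = np.asarray(self.medial_epicondyle, dtype=float)
        self.lateral_epicondyle = np.asarray(self.lateral_epicondyle, dtype=float)
        if self.femoral_head_centre is not None:
            self.femoral_head_centre = np.asarray(self.femoral_head_centre, dtype=float)
        if self.head_surface_points is not None:
            self.head_surface_points = np.asarray(self.head_surface_points, dtype=float)
        if self.talus_centre is not None:
            self.talus_centre = np.asarray(self.talus_centre, dtype=float)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if np.linalg.norm(self.lateral_epicondyle - self.medial_epicondyle) <= _MIN_SEPARATION_MM:
            raise ValueError("epicondyles must be more than 1 mm apart")
        if self.femoral_head_centre is None and self.head_surface_points is None:
            raise ValueError("provide femoral_head_centre or head_surface_points")

    def head_centre(self) -> np.ndarray:
        """Head centre: directly given, or least-squares fitted from surface points."""
        if self.femoral_head_centre is not None:
            return self.femoral_head_centre
        centre, _radius = fit_head_centre(self.head_surface_points)
        return centre

    @classmethod
    def from_json(cls, path: os.PathLike | str) -> "LandmarkSet":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            medial_epicondyle=data["medial_epicondyle"],
            lateral_epicondyle=data["lateral_epicondyle"],
            side=data["side"],
            femoral_head_centre=data.get("femoral_head_centre"),
            head_surface_points=data.get("head_surface_points"),
            talus_centre=data.get("talus_centre"),
        )

    def to_json(self, path: os.PathLike | str) -> None:
        data = {
            "medial_epicondyle": self.medial_epicondyle.tolist(),
            "lateral_epicondyle": self.lateral_epicondyle.tolist(),
            "side": self.side,
        }
        if self.femoral_head_centre is not None:
            data["femoral_head_centre"] = self.femoral_head_centre.tolist()
        if self.head_surface_points is not None:
            data["head_surface_points"] = self.head_surface_points.tolist()
        if self.talus_centre is not None:
            data["talus_centre"] = self.talus_centre.tolist()
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)


@dataclass
class AnatomicFrame:
    """Origin (knee centre, mm) plus an orthonormal right-handed axis triad.

    ``axes`` rows are the ML, AP and PROX unit vectors expressed in world
    coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray
    bone: Literal["femur", "tibia"] = "femur"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.shape != (3, 3):
            raise ValueError("axes must be 3x3 (rows ML, AP, PROX)")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame must be right-handed (det = +1)")

    @property
    def ml(self) -> np.ndarray:
        return self.axes[0]

    @property
    def ap(self) -> np.ndarray:
        return self.axes[1]

    @property
    def prox(self) -> np.ndarray:
        return self.axes[2]

    @classmethod
    def identity(cls, bone: str = "femur") -> "AnatomicFrame":
        """The scanner frame itself (origin 0, axes = world axes)."""
        return cls(np.zeros(3), np.eye(3), bone=bone)

    def to_json(self, path: os.PathLike | str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"origin": self.origin.tolist(), "axes": self.axes.tolist(), "bone": self.bone},
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: os.PathLike | str) -> "AnatomicFrame":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["origin"], d["axes"], bone=d.get("bone", "femur"))


def knee_centre(medial_epi: Sequence[float], lateral_epi: Sequence[float]) -> np.ndarray:
    """Midpoint of the transepicondylar line — the centre of the knee."""
    a = np.asarray(medial_epi, dtype=float)
    b = np.asarray(lateral_epi, dtype=float)
    if np.linalg.norm(b - a) <= _MIN_SEPARATION_MM:
        raise ValueError("epicondyles must be more than 1 mm apart")
    return (a + b) / 2.0


def fit_head_centre(points: Sequence[Sequence[float]]) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit of the femoral head from surface points.

    Algebraic (Pratt-style) linear fit followed by one Gauss-Newton step on
    the geometric distances. Returns ``(centre, radius)``.

    The fit is the reproducible stand-in for the manual construction of the
    head centre as the intersection of head diameters in three planes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise ValueError("need at least 4 points of dimension 3")
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[-1] < 1e-6 * max(sv[0], 1.0):
        raise ValueError("points are coplanar or otherwise degenerate for a sphere fit")

    # |x|^2 = 2 c.x + (r^2 - |c|^2): linear in (c, d)
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.sum(pts**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:3]
    radius = float(np.sqrt(sol[3] + centre @ centre))

    # one Gauss-Newton refinement on residuals r_i = |p_i - c| - R
    diff = pts - centre
    dist = np.linalg.norm(diff, axis=1)
    resid = dist - radius
    J = np.hstack([-diff / dist[:, None], -np.ones((len(pts), 1))])
    try:
        step, *_ = np.linalg.lstsq(J, resid, rcond=None)
        centre = centre - step[:3]
        radius = radius - float(step[3])
    except np.linalg.LinAlgError:
        pass
    return centre, radius


def femoral_frame(landmarks: LandmarkSet) -> AnatomicFrame:
    """Femoral anatomic frame from head centre and epicondyles.

    PROX is the mechanical axis (knee centre -> head centre), AP the cross
    product of the transepicondylar line and PROX, ML the cross product of AP
    and PROX. AP and ML are flipped jointly (preserving handedness) if needed
    so that ML points medial -> lateral.
    """
    head = landmarks.head_centre()
    kc = knee_centre(landmarks.medial_epicondyle, landmarks.lateral_epicondyle)
    if np.linalg.norm(head - kc) <= _MIN_SEPARATION_MM:
        raise ValueError("femoral head centre coincides with knee centre")
    prox = _unit(head - kc)
    t = _unit(landmarks.lateral_epicondyle - landmarks.medial_epicondyle)
    sin_angle = np.linalg.norm(np.cross(t, prox))
    if sin_angle < np.sin(np.deg2rad(_MIN_ANGLE_DEG)):
        raise ValueError("mechanical axis is (nearly) parallel to the transepicondylar line")
    ap = _unit(np.cross(t, prox))
    ml = _unit(np.cross(ap, prox))
    if np.dot(ml, t) < 0:  # joint flip keeps det = +1
        ap = -ap
        ml = -ml
    return AnatomicFrame(origin=kc, axes=np.vstack([ml, ap, prox]), bone="femur")


def tibial_frame(
    femoral: AnatomicFrame,
    knee_centre_pt: Sequence[float],
    talus_centre: Sequence[float],
) -> AnatomicFrame:
    """Tibial frame: the knee as a simple hinge sharing the femoral ML axis.

    The tibial long axis runs talus centre -> knee centre; AP is its cross
    product with ML, PROX completes the right-handed triad (pointing
    proximally).
    """
    kc = np.asarray(knee_centre_pt, dtype=float)
    talus = np.asarray(talus_centre, dtype=float)
    if np.linalg.norm(kc - talus) <= _MIN_SEPARATION_MM:
        raise ValueError("talus centre coincides with knee centre")
    long_axis = _unit(kc - talus)
    ml = femoral.ml
    sin_angle = np.linalg.norm(np.cross(long_axis, ml))
    if sin_angle < np.sin(np.deg2rad(_MIN_ANGLE_DEG)):
        raise ValueError("tibial long axis is (nearly) parallel to the femoral ML axis")
    ap = _unit(np.cross(long_axis, ml))
    prox = _unit(np.cross(ml, ap))
    if np.dot(prox, long_axis) < 0:  # joint flip keeps det = +1
        prox = -prox
        ap = -ap
    return AnatomicFrame(origin=kc, axes=np.vstack([ml, ap, prox]), bone="tibia")


def frame_rotation(a: AnatomicFrame, b: AnatomicFrame) -> dict[str, float]:
    """Rotation taking frame ``a``'s axes to frame ``b``'s axes, in degrees.

    Returns ``total_deg`` (rotation angle of R = axes_b @ axes_a.T) and
    ``about_PROX_deg``, the signed axial component: the angle by which the
    image of ``a``'s ML axis has turned about ``a``'s PROX axis. Passing
    ``AnatomicFrame.identity()`` as ``a`` measures realignment relative to
    the scanner.
    """
    R = np.asarray(b.axes).T @ np.asarray(a.axes)  # world rotation: R a_i = b_i
    # atan2(2 sin, 2 cos) stays accurate near 0 and 180 deg, unlike acos
    vee = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    total = float(np.degrees(np.arctan2(np.linalg.norm(vee), np.trace(R) - 1.0)))

    p = a.prox
    u = a.ml
    w = _rotated(a, b, u)
    u_perp = u - np.dot(u, p) * p
    w_perp = w - np.dot(w, p) * p
    about = float(
        np.degrees(np.arctan2(np.dot(p, np.cross(u_perp, w_perp)), np.dot(u_perp, w_perp)))
    )
    return {"total_deg": total, "about_PROX_deg": about}


def _rotated(a: AnatomicFrame, b: AnatomicFrame, v: np.ndarray) -> np.ndarray:
    R = np.asarray(b.axes).T @ np.asarray(a.axes)
    return R @ v


def world_to_anatomic(p: np.ndarray, frame: AnatomicFrame) -> np.ndarray:
    """World mm -> (ML, AP, PROX) coordinates relative to the frame origin."""
    p = np.asarray(p, dtype=float)
    return (p - frame.origin) @ np.asarray(frame.axes).T


def anatomic_to_world(p: np.ndarray, frame: AnatomicFrame) -> np.ndarray:
    """Inverse of :func:`world_to_anatomic` (exact for orthonormal frames)."""
    p = np.asarray(p, dtype=float)
    return p @ np.asarray(frame.axes) + frame.origin
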