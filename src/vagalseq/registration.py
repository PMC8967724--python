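"""Landmark-based registration of in vivo 3-D imaging to serial 2-D sections.

tdTomato-labelled cells serve as geographic landmarks: they are matched
between the in vivo stack and the sectioned tissue, a least-squares rigid
(optionally similarity) transform is estimated from the matched pairs, a
virtual plane with minimal total projection distance replaces each physical
section plane, and unlabelled cells are then registered by nearest-neighbour
assignment under the fitted transform with an ambiguity gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

DEFAULT_GATE_RADIUS = 15.0  # one cell diameter, micrometres
DEFAULT_AMBIGUITY_RATIO = 1.5

__all__ = [
    "RigidTransform",
    "match_landmarks",
    "estimate_transform",
    "fit_virtual_plane",
    "register_nonlandmark",
    "registration_rate",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid (or similarity) transform x -> scale * R @ x + t."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    scale: float = 1.0

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det +1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler(
        cls, angles_deg: tuple[float, float, float], translation, scale: float = 1.0
    ) -> "RigidTransform":
        """Build from intrinsic z-y-x Euler angles in degrees."""
        az, ay, ax = np.deg2rad(angles_deg)
        cz, sz = np.cos(az), np.sin(az)
        cy, sy = np.cos(ay), np.sin(ay)
        cx, sx = np.cos(ax), np.sin(ax)
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        return cls(rz @ ry @ rx, np.asarray(translation, dtype=float), scale)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * (p @ self.rotation.T) + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation / self.scale, 1.0 / self.scale)


def match_landmarks(
    invivo: np.ndarray,
    section: np.ndarray,
    transform: RigidTransform | None = None,
    gate_radius: float = np.inf,
) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour landmark pairs under the current transform.

    Returns (invivo index, section index) pairs whose distance after
    transforming the in vivo points is within ``gate_radius`` and which are
    each other's nearest neighbours.  Raises when fewer than 3 mutual pairs
    survive (too few to estimate a transform).
    """
    invivo = np.atleast_2d(np.asarray(invivo, dtype=float))
    section = np.atleast_2d(np.asarray(section, dtype=float))
    if len(invivo) < 3 or len(section) < 3:
        raise ValueError("need at least 3 landmarks on each side")
    moved = transform.apply(invivo) if transform is not None else invivo
    fwd = cKDTree(section)
    rev = cKDTree(moved)
    d_fwd, j_fwd = fwd.query(moved)
    _, i_rev = rev.query(section)
    pairs = [
        (i, int(j))
        for i, (d, j) in enumerate(zip(d_fwd, j_fwd))
        if d <= gate_radius and i_rev[j] == i
    ]
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} mutual landmark pairs found; need >= 3")
    return pairs


def estimate_transform(
    source: np.ndarray, target: np.ndarray, allow_scale: bool = False
) -> tuple[RigidTransform, float]:
    """Least-squares rigid (Kabsch) or similarity (Umeyama) transform.

    Finds the proper rotation R (det +1 enforced, so reflections are never
    returned), translation t and optional isotropic scale s minimising
    sum ||s R x_i + t - y_i||^2 over the paired points.  Returns the
    transform and its residual (that minimised sum of squares).
    """
    x = np.atleast_2d(np.asarray(source, dtype=float))
    y = np.atleast_2d(np.asarray(target, dtype=float))
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need >= 3 paired points of equal shape")
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    cov = yc.T @ xc / len(x)
    u, s, vt = np.linalg.svd(cov)
    # collinear sets leave rotation about the line axis unconstrained
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(u @ vt))
    sign = np.diag([1.0, 1.0, d])
    rot = u @ sign @ vt
    if allow_scale:
        var_x = (xc**2).sum() / len(x)
        scale = float((s * np.diag(sign)).sum() / var_x)
    else:
        scale = 1.0
    t = my - scale * rot @ mx
    tf = RigidTransform(rot, t, scale)
    residual = float(((tf.apply(x) - y) ** 2).sum())
    return tf, residual


def fit_virtual_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through a 3-D point set.

    Returns (point on plane, unit normal, residual) where the plane
    minimises the total squared point-to-plane projection distance; the
    normal is the smallest-spread direction of the centred set and the
    residual is the minimised sum of squares.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if len(p) < 3:
        raise ValueError("need >= 3 points")
    centroid = p.mean(axis=0)
    centred = p - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("collinear points do not define a plane")
    normal = vt[-1]
    residual = float(s[-1] ** 2)
    return centroid, normal, residual


@dataclass(frozen=True)
class RegistrationOutcome:
    """Per-cell registration status and matched candidate indices."""

    status: tuple[str, ...]  # registered | ambiguous | unmatched
    matches: tuple[int, ...] = field(default=())  # candidate index or -1


def register_nonlandmark(
    cells: np.ndarray,
    candidates: np.ndarray,
    transform: RigidTransform,
    gate_radius: float = DEFAULT_GATE_RADIUS,
    ambiguity_ratio: float = DEFAULT_AMBIGUITY_RATIO,
) -> RegistrationOutcome:
    """Register unlabelled cells to section candidates under the transform.

    A cell registers to its nearest transformed candidate iff that candidate
    lies within ``gate_radius`` AND the second-nearest candidate is more
    than ``ambiguity_ratio`` times farther (equal distances are ambiguous).
    Cells with no candidate in the gate are unmatched; registration failures
    are meant to be dropped from downstream analysis.
    """
    cells = np.atleast_2d(np.asarray(cells, dtype=float))
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    if len(candidates) == 0:
        raise ValueError("no candidate cells")
    moved = transform.apply(cells)
    tree = cKDTree(candidates)
    k = min(2, len(candidates))
    dist, idx = tree.query(moved, k=k)
    dist = np.atleast_2d(dist.reshape(len(cells), k))
    idx = np.atleast_2d(idx.reshape(len(cells), k))
    status, matches = [], []
    for d, j in zip(dist, idx):
        if d[0] > gate_radius:
            status.append("unmatched")
            matches.append(-1)
        elif k == 2 and d[1] <= ambiguity_ratio * d[0]:
            status.append("ambiguous")
            matches.append(-1)
        else:
            status.append("registered")
            matches.append(int(j[0]))
    return RegistrationOutcome(tuple(status), tuple(matches))


def registration_rate(outcome: RegistrationOutcome | tuple[str, ...]) -> float:
    """Fraction of cells unambiguously registered."""
    status = outcome.status if isinstance(outcome, RegistrationOutcome) else tuple(outcome)
    if len(status) == 0:
        raise ValueError("no outcomes")
    return sum(s == "registered" for s in status) / len(status)
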