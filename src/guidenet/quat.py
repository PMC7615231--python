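"""Quaternion algebra for probe orientation and rotation guidance.

Probe orientation is carried as a unit quaternion ``q = (q_w, q_x, q_y, q_z)``
in the scalar-first Hamilton (right-handed) convention. Because ``q`` and
``-q`` encode the same rotation (double cover), every quaternion is
sign-canonicalized (``w >= 0``; on the ``w = 0`` great circle, first nonzero
component >= 0) before it is used as a regression target, so target signs
never flip mid-sequence.

The per-step relative rotation is ``r_t = conj(q_{t-1}) * q_t`` and the
rotation-to-plane variant is ``r_t = conj(q_{t-1}) * q_T`` with ``q_T`` the
target ("standard plane") orientation. Angles are reported in degrees
throughout, matching the coarse/fine staging of the evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UnitQuaternion",
    "RotationStep",
    "conjugate",
    "multiply",
    "relative_rotation",
    "angular_distance",
    "is_toward_target",
    "slerp",
    "canonicalize",
    "from_axis_angle",
    "random_unit",
]

_NORM_TOL = 1e-6


def _check_finite(arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError("quaternion has non-finite components")


@dataclass(frozen=True)
class UnitQuaternion:
    """Unit quaternion, scalar-first ``(w, x, y, z)``."""

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self):
        arr = np.array([self.w, self.x, self.y, self.z], dtype=float)
        _check_finite(arr)
        n = np.linalg.norm(arr)
        if n == 0:
            raise ValueError("zero quaternion cannot be normalized")
        if abs(n - 1.0) > _NORM_TOL:
            arr = arr / n
            object.__setattr__(self, "w", float(arr[0]))
            object.__setattr__(self, "x", float(arr[1]))
            object.__setattr__(self, "y", float(arr[2]))
            object.__setattr__(self, "z", float(arr[3]))

    @classmethod
    def identity(cls) -> "UnitQuaternion":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_array(cls, arr) -> "UnitQuaternion":
        arr = np.asarray(arr, dtype=float)
        return cls(arr[0], arr[1], arr[2], arr[3])

    def to_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z])

    def canonical(self) -> "UnitQuaternion":
        return UnitQuaternion.from_array(canonicalize(self.to_array()))


@dataclass(frozen=True)
class RotationStep:
    """A relative rotation together with its magnitude in degrees."""

    r: UnitQuaternion
    angle_deg: float

    def __post_init__(self):
        if not (-1e-9 <= self.angle_deg <= 180.0 + 1e-9):
            raise ValueError(f"rotation angle {self.angle_deg} outside [0, 180]")

    @classmethod
    def identity(cls) -> "RotationStep":
        return cls(UnitQuaternion.identity(), 0.0)


# -- array-level core (used in batch by the simulator and evaluation) ---------


def canonicalize(q: np.ndarray) -> np.ndarray:
    """Resolve the double cover: flip sign so w >= 0 (ties broken by the
    first nonzero component). Works on (..., 4) arrays."""
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    flat = q.reshape(-1, 4).copy()
    first_nonzero = (flat != 0).argmax(axis=1)
    sign = np.sign(flat[np.arange(len(flat)), first_nonzero])
    sign[sign == 0] = 1.0  # all-zero rows left untouched (invalid anyway)
    flat *= sign[:, None]
    return flat[0] if single else flat.reshape(q.shape)


def _mul_arr(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = np.moveaxis(np.asarray(q1, dtype=float), -1, 0)
    w2, x2, y2, z2 = np.moveaxis(np.asarray(q2, dtype=float), -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def _conj_arr(q: np.ndarray) -> np.ndarray:
    return np.asarray(q, dtype=float) * np.array([1.0, -1.0, -1.0, -1.0])


def _angle_arr(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    dot = np.abs(np.sum(np.asarray(q1, float) * np.asarray(q2, float), axis=-1))
    return np.degrees(2.0 * np.arccos(np.clip(dot, -1.0, 1.0)))


# -- public operations ---------------------------------------------------------


def conjugate(q: UnitQuaternion) -> UnitQuaternion:
    """Quaternion conjugate (inverse for unit quaternions)."""
    return UnitQuaternion(q.w, -q.x, -q.y, -q.z)


def multiply(q1: UnitQuaternion, q2: UnitQuaternion) -> UnitQuaternion:
    """Hamilton product ``q1 * q2`` (applies q2 after q1 in the convention
    ``r_t = conj(q_{t-1}) * q_t``), renormalized."""
    return UnitQuaternion.from_array(_mul_arr(q1.to_array(), q2.to_array()))


def angular_distance(q1: UnitQuaternion, q2: UnitQuaternion) -> float:
    """Geodesic rotation angle ``2 arccos(|<q1, q2>|)`` in degrees.

    Symmetric and invariant under the double cover (q vs -q).
    """
    return float(_angle_arr(q1.to_array(), q2.to_array()))


def relative_rotation(q_prev: UnitQuaternion, q_curr: UnitQuaternion) -> RotationStep:
    """Rotation step r with ``q_prev * r = q_curr`` (up to sign),
    i.e. ``r = conj(q_prev) * q_curr``, sign-canonicalized."""
    r = multiply(conjugate(q_prev), q_curr).canonical()
    return RotationStep(r, angular_distance(q_prev, q_curr))


def is_toward_target(q_prev: UnitQuaternion, r_hat: RotationStep | UnitQuaternion, q_target: UnitQuaternion) -> bool:
    """Guidance-direction criterion: does applying the predicted rotation
    leave the probe no farther (in angle) from the target orientation?

    Non-strict, so the identity rotation counts as toward.
    """
    r = r_hat.r if isinstance(r_hat, RotationStep) else r_hat
    moved = multiply(q_prev, r)
    return angular_distance(moved, q_target) <= angular_distance(q_prev, q_target)


def slerp(q1: UnitQuaternion, q2: UnitQuaternion, fraction: float) -> UnitQuaternion:
    """Spherical linear interpolation along the shorter arc.

    ``fraction`` 0 gives q1 and 1 gives q2;
    ``angular_distance(q1, slerp(q1, q2, f)) = f * angular_distance(q1, q2)``.
    Near-antipodal pairs (arc > 179.9 deg) have no unique shortest path; a
    fixed orthogonal intermediate axis is used so the result is deterministic.
    """
    a = q1.to_array()
    b = q2.to_array()
    dot = float(np.dot(a, b))
    if dot < 0.0:  # shorter arc
        b = -b
        dot = -dot
    dot = min(dot, 1.0)
    half_angle = np.arccos(dot)
    if np.degrees(2.0 * half_angle) > 179.9:
        # ambiguous geodesic: route through a fixed orthogonal waypoint
        ortho = np.array([-a[1], a[0], -a[3], a[2]])
        mid = UnitQuaternion.from_array(ortho)
        if fraction <= 0.5:
            return slerp(q1, mid, 2.0 * fraction)
        return slerp(mid, UnitQuaternion.from_array(b), 2.0 * fraction - 1.0)
    if half_angle < 1e-8:
        return UnitQuaternion.from_array((1 - fraction) * a + fraction * b)
    s = np.sin(half_angle)
    out = (np.sin((1 - fraction) * half_angle) / s) * a + (np.sin(fraction * half_angle) / s) * b
    return UnitQuaternion.from_array(out)


def from_axis_angle(axis, angle_deg: float) -> UnitQuaternion:
    """Unit quaternion rotating by ``angle_deg`` about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero rotation axis")
    axis = axis / n
    half = np.radians(angle_deg) / 2.0
    return UnitQuaternion.from_array(np.concatenate([[np.cos(half)], np.sin(half) * axis]))


def random_unit(rng: np.random.Generator) -> UnitQuaternion:
    """Uniform random rotation (normalized 4-D Gaussian)."""
    v = rng.normal(size=4)
    return UnitQuaternion.from_array(v).canonical()
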