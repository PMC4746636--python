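"""Quaternion helpers for rigid-body orientation (scalar-first convention)."""

from __future__ import annotations

import numpy as np


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    """Unit quaternion for a rotation vector (axis * angle, radians)."""
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]]) / np.sqrt(
            1.0 + 0.25 * angle**2
        )
    axis = v / angle
    s = np.sin(angle / 2.0)
    return np.array([np.cos(angle / 2.0), s * axis[0], s * axis[1], s * axis[2]])


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (Shoemake's method)."""
    u1, u2, u3 = rng.random(3)
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    return np.array(
        [
            a * np.sin(2 * np.pi * u2),
            a * np.cos(2 * np.pi * u2),
            b * np.sin(2 * np.pi * u3),
            b * np.cos(2 * np.pi * u3),
        ]
    )


def rotate_quaternions(quats: np.ndarray, rotvecs: np.ndarray) -> np.ndarray:
    """Apply small world-frame rotation vectors to an array of quaternions.

    Vectorized over bodies; result is renormalized each call so integration
    drift never accumulates.
    """
    angle = np.linalg.norm(rotvecs, axis=1)
    half = 0.5 * angle
    dw = np.cos(half)
    # sin(a/2)/a, series-safe at a -> 0 via numpy's sinc
    scale = 0.5 * np.sinc(half / np.pi)
    dx, dy, dz = (scale[:, None] * rotvecs).T
    aw, ax, ay, az = quats[:, 0], quats[:, 1], quats[:, 2], quats[:, 3]
    out = np.empty_like(quats)
    out[:, 0] = dw * aw - dx * ax - dy * ay - dz * az
    out[:, 1] = dw * ax + dx * aw + dy * az - dz * ay
    out[:, 2] = dw * ay - dx * az + dy * aw + dz * ax
    out[:, 3] = dw * az + dx * ay - dy * ax + dz * aw
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out
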