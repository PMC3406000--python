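"""Minimal quaternion helpers (scalar-last [x, y, z, w], scipy convention).

The BD inner loop cannot use scipy.spatial.transform directly (it runs under
numba), so rotation arithmetic is implemented once here and reused by both
the pure-python API and the compiled kernels.
"""

import numpy as np

IDENTITY = np.array([0.0, 0.0, 0.0, 1.0])


def normalize(q):
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q)


def to_matrix(q):
    """Rotation matrix of a unit quaternion (scalar-last)."""
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def multiply(q1, q2):
    """Hamilton product q1*q2 (apply q2 first, then q1), scalar-last."""
    x1, y1, z1, w1 = q1
    x2, y2, z2, w2 = q2
    return np.array([
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
    ])


def from_rotvec(v):
    """Quaternion of a rotation vector (axis * angle, radians)."""
    v = np.asarray(v, dtype=float)
    angle = np.linalg.norm(v)
    if angle < 1e-300:
        return IDENTITY.copy()
    axis = v / angle
    s = np.sin(angle / 2.0)
    return np.array([axis[0] * s, axis[1] * s, axis[2] * s, np.cos(angle / 2.0)])


def random_uniform(rng):
    """Uniform random rotation (Shoemake's subgroup algorithm)."""
    u1, u2, u3 = rng.uniform(size=3)
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    return np.array([
        a * np.sin(2 * np.pi * u2),
        a * np.cos(2 * np.pi * u2),
        b * np.sin(2 * np.pi * u3),
        b * np.cos(2 * np.pi * u3),
    ])


def rotate(q, vecs):
    """Rotate (n,3) or (3,) vectors by quaternion q."""
    return np.asarray(vecs, dtype=float) @ to_matrix(q).T
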