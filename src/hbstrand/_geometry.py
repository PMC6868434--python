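"""Small vector-geometry helpers shared by the hydrogen-placement and
secondary-structure code.

All positions are numpy float arrays of shape (3,) in Angstrom; angles are
returned in degrees.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "distance",
    "angle_deg",
    "rotate_about",
    "perpendicular",
]


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b."""
    u = unit(np.asarray(a) - np.asarray(b))
    v = unit(np.asarray(c) - np.asarray(b))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def rotate_about(v: np.ndarray, axis: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rodrigues rotation of v about axis by theta_deg."""
    k = unit(np.asarray(axis))
    v = np.asarray(v, dtype=float)
    t = np.radians(theta_deg)
    return (
        v * np.cos(t)
        + np.cross(k, v) * np.sin(t)
        + k * np.dot(k, v) * (1.0 - np.cos(t))
    )


def perpendicular(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to v."""
    v = unit(np.asarray(v))
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, ref))
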