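"""Rigid-body math shared by docking and trajectory analysis."""

from __future__ import annotations

import numpy as np


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniformly distributed unit vector (normalised 3D Gaussian)."""
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - astronomically unlikely
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal (least-RMSD) superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimises the RMSD to
    ``reference``.  ``R`` is a proper rotation (determinant +1); reflections
    are excluded by the usual sign correction on the smallest singular value.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return R, t


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Coordinates of ``mobile`` after optimal superposition onto ``reference``."""
    R, t = kabsch(mobile, reference)
    return mobile @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two equally shaped coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
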