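"""Minimum-image distance helpers for orthorhombic periodic boxes."""

from __future__ import annotations

import numpy as np


def minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the primary image.

    ``delta`` has shape (..., 3); ``box`` is three orthorhombic edge lengths
    or ``None`` for a non-periodic system.
    """
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Minimum-image Euclidean distance between points ``a`` and ``b``."""
    d = minimum_image(np.asarray(b, float) - np.asarray(a, float), box)
    return np.sqrt(np.sum(d * d, axis=-1))


def minimum_image_xy(delta_xy: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Minimum-image convention applied to in-plane (x, y) displacements."""
    if box is None:
        return delta_xy
    b = np.asarray(box, dtype=float)[:2]
    return delta_xy - b * np.round(delta_xy / b)


def angle_deg(a: np.ndarray, vertex: np.ndarray, c: np.ndarray,
              box: np.ndarray | None = None) -> float:
    """Angle a–vertex–c in degrees (minimum-image arms)."""
    v1 = minimum_image(np.asarray(a, float) - vertex, box)
    v2 = minimum_image(np.asarray(c, float) - vertex, box)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
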