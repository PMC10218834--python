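"""Minimum-image helpers for orthorhombic periodic boxes."""

from __future__ import annotations

import numpy as np

__all__ = ["min_image_displacement", "min_image_distance", "pair_distances"]


def min_image_displacement(disp: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    disp = np.asarray(disp, dtype=float)
    if box is None:
        return disp
    box = np.asarray(box, dtype=float)
    return disp - box * np.round(disp / box)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> float:
    """Minimum-image distance between two points."""
    return float(np.linalg.norm(min_image_displacement(np.asarray(a) - np.asarray(b), box)))


def pair_distances(coords_a: np.ndarray, coords_b: np.ndarray,
                   box: np.ndarray | None) -> np.ndarray:
    """(len(a), len(b)) matrix of minimum-image distances."""
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    diff = min_image_displacement(diff, box)
    return np.sqrt(np.sum(diff ** 2, axis=-1))
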