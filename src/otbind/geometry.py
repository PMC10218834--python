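"""Rigid-body superposition, RMSD statistics and aromatic-ring geometry.

The superposition is the classic Kabsch least-squares fit (computed through
``scipy.spatial.transform.Rotation.align_vectors``, which returns the proper
rotation minimising the fit-atom RMSD).  Ring plane normals come from a
principal-axis fit of the member atoms, which stays well defined for large,
slightly puckered rings such as a porphyrin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .md_model import Frame, RingSpec, Selection, Trajectory

__all__ = [
    "RingGeometry",
    "PiPiDescriptor",
    "kabsch_align",
    "rmsd",
    "rmsd_series",
    "series_rmse",
    "ring_geometry",
    "pi_pi_descriptor",
]


@dataclass(frozen=True)
class RingGeometry:
    """Centroid, unit plane normal and out-of-plane RMS of a ring."""

    centroid: np.ndarray
    unit_normal: np.ndarray
    planarity_rms: float


@dataclass(frozen=True)
class PiPiDescriptor:
    """Geometric descriptor of a ring pair.

    ``r_cen`` is the centroid–centroid distance, ``d`` the perpendicular
    distance from the centroid of ring A to the plane of ring B (asymmetric
    in the ring order), and ``theta`` the acute interplanar angle in degrees.
    """

    r_cen: float
    d: float
    theta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 90.0 + 1e-9):
            raise ValueError(f"theta must lie in [0, 90], got {self.theta}")
        if self.d > self.r_cen + 1e-9:
            raise ValueError("perpendicular distance cannot exceed r_cen")


def _indices(selection) -> np.ndarray:
    if isinstance(selection, Selection):
        return np.asarray(selection.indices, dtype=int)
    return np.asarray(list(selection), dtype=int)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unaligned) RMSD between two equally shaped coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _check_not_collinear(coords: np.ndarray, what: str) -> None:
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s.size < 2 or s[1] < 1e-8:
        raise ValueError(f"{what}: points are collinear or degenerate")


def kabsch_align(
    mobile: Frame,
    reference: Frame,
    fit_selection,
) -> tuple[Frame, np.ndarray, np.ndarray]:
    """Least-squares superpose ``mobile`` onto ``reference``.

    The rotation/translation minimising the RMSD over ``fit_selection`` is
    found and applied to *all* atoms of the mobile frame.  Returns the
    aligned frame, the proper rotation matrix and the translation, such that
    ``aligned = mobile @ R.T + t``.
    """
    idx = _indices(fit_selection)
    if idx.size < 3:
        raise ValueError("need >= 3 fit atoms for superposition")
    mob = mobile.coordinates[idx]
    ref = reference.coordinates[idx]
    _check_not_collinear(mob, "fit selection")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    R = rot.as_matrix()
    t = ref_c - mob_c @ R.T
    aligned = Frame(
        mobile.coordinates @ R.T + t,
        None if mobile.box is None else mobile.box.copy(),
        mobile.time,
    )
    return aligned, R, t


def rmsd_series(
    trajectory: Trajectory,
    reference_frame: Frame,
    fit_selection,
    measure_selection,
) -> np.ndarray:
    """Per-frame RMSD over ``measure_selection`` after fitting on ``fit_selection``.

    This is the standard protocol of superposing each frame's backbone (or
    other fit set) onto a reference before measuring, so that overall
    translation and rotation do not contribute.
    """
    midx = _indices(measure_selection)
    if midx.size == 0:
        raise ValueError("measure selection is empty")
    ref = reference_frame.coordinates[midx]
    out = np.empty(trajectory.n_frames)
    for k, frame in enumerate(trajectory):
        aligned, _, _ = kabsch_align(frame, reference_frame, fit_selection)
        out[k] = rmsd(aligned.coordinates[midx], ref)
    return out


def series_rmse(values: Sequence[float], about: str = "mean",
                reference: float = 0.0) -> float:
    """Fluctuation (RMSE) of a time series.

    ``about="mean"`` (default) returns the population standard deviation
    sqrt(mean((x - mean(x))^2)) — the fluctuation measure quoted alongside an
    average RMSD.  ``about="reference"`` instead measures the RMS deviation
    from a fixed reference value.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if about == "mean":
        return float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    if about == "reference":
        return float(np.sqrt(np.mean((x - reference) ** 2)))
    raise ValueError(f"unknown mode {about!r}")


def ring_geometry(frame: Frame, ring: RingSpec) -> RingGeometry:
    """Centroid and best-fit plane of a ring in one frame.

    The normal is the principal axis with the smallest variance
    (least-squares plane fit), sign-normalised into the +z hemisphere
    (ties broken toward +x, then +y).
    """
    coords = frame.coordinates[np.asarray(ring.member_atoms, dtype=int)]
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8:
        raise ValueError(f"ring {ring.label!r}: members are collinear")
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    # sign normalisation
    if normal[2] < 0 or (normal[2] == 0 and (normal[0] < 0 or
                                             (normal[0] == 0 and normal[1] < 0))):
        normal = -normal
    planarity = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return RingGeometry(centroid, normal / np.linalg.norm(normal), planarity)


def pi_pi_descriptor(frame: Frame, ring_a: RingSpec, ring_b: RingSpec) -> PiPiDescriptor:
    """Ring-pair descriptor (r_cen, d, theta).

    theta is folded into [0, 90] degrees (acute interplanar angle);
    d projects the A→B centroid vector onto ring B's plane normal, so
    ``d(a, b) != d(b, a)`` in general while r_cen and theta are symmetric.
    """
    ga = ring_geometry(frame, ring_a)
    gb = ring_geometry(frame, ring_b)
    dc = ga.centroid - gb.centroid
    r_cen = float(np.linalg.norm(dc))
    d = float(abs(dc @ gb.unit_normal))
    cos_t = abs(float(ga.unit_normal @ gb.unit_normal))
    theta = float(np.degrees(np.arccos(np.clip(cos_t, 0.0, 1.0))))
    return PiPiDescriptor(r_cen=r_cen, d=min(d, r_cen), theta=min(theta, 90.0))
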