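"""Radial distribution functions between site sets.

g(r) is normalised against the ideal-gas expectation
4*pi*r^2*dr * rho_target, with the target bulk density taken from the
instantaneous box volume of each frame (NPT-compatible).  Reference sites
may be atoms or named rings, in which case the ring centroid is recomputed
every frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .geometry import ring_geometry
from .md_model import Topology, Trajectory
from .pbc import pair_distances

__all__ = ["RDFResult", "compute_rdf", "first_peak"]


@dataclass
class RDFResult:
    bin_centers: np.ndarray
    g_of_r: np.ndarray
    reference_count: int
    target_density: float        # mean target number density, 1/A^3
    frames_used: int
    dr: float

    def coordination_number(self) -> np.ndarray:
        """Cumulative mean number of targets within r of a reference."""
        shell = 4.0 * np.pi * self.bin_centers ** 2 * self.dr
        return np.cumsum(self.g_of_r * shell * self.target_density)


def _site_coords(frame, topology: Topology, sites) -> np.ndarray:
    coords = []
    for s in sites:
        if isinstance(s, str):
            coords.append(ring_geometry(frame, topology.ring(s)).centroid)
        else:
            coords.append(frame.coordinates[s])
    return np.asarray(coords, dtype=float)


def compute_rdf(
    trajectory: Trajectory,
    reference_sites: Sequence,
    target_sites: Sequence,
    r_max: float = 12.0,
    dr: float = 0.05,
    use_pbc: bool = True,
) -> RDFResult:
    """Radial distribution function of targets around references.

    ``reference_sites`` and ``target_sites`` are atom indices and/or ring
    labels.  Under PBC, ``r_max`` must not exceed half the smallest box
    edge.  Self-pairs (identical atom index) are excluded.
    """
    ref_sites = list(reference_sites)
    tgt_sites = list(target_sites)
    if not tgt_sites:
        raise ValueError("no target sites")
    if not ref_sites:
        raise ValueError("no reference sites")
    top = trajectory.topology
    edges = np.arange(0.0, r_max + dr * 0.5, dr)
    hist = np.zeros(edges.size - 1)
    norm = 0.0  # accumulates N_ref * rho_frame over frames
    rho_sum = 0.0
    frames_used = 0
    for frame in trajectory:
        box = frame.box if use_pbc else None
        if use_pbc:
            if frame.box is None:
                raise ValueError("use_pbc requires frames with a box")
            if r_max > frame.box.min() / 2 + 1e-9:
                raise ValueError(
                    f"r_max {r_max} exceeds half the smallest box edge "
                    f"{frame.box.min() / 2:.3f}"
                )
        if frame.box is None:
            raise ValueError("RDF normalisation needs a box volume")
        ref = _site_coords(frame, top, ref_sites)
        tgt = _site_coords(frame, top, tgt_sites)
        dists = pair_distances(ref, tgt, box)
        # mask self-pairs (same atom index used as ref and target)
        for i, rs in enumerate(ref_sites):
            if isinstance(rs, str):
                continue
            for j, ts in enumerate(tgt_sites):
                if rs == ts:
                    dists[i, j] = np.inf
        hist += np.histogram(dists[np.isfinite(dists)], bins=edges)[0]
        volume = float(np.prod(frame.box))
        rho = len(tgt_sites) / volume
        norm += len(ref_sites) * rho
        rho_sum += rho
        frames_used += 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centers ** 2 * dr
    g = hist / (shell * norm)
    return RDFResult(
        bin_centers=centers,
        g_of_r=g,
        reference_count=len(ref_sites),
        target_density=rho_sum / frames_used,
        frames_used=frames_used,
        dr=dr,
    )


def first_peak(rdf_result: RDFResult, min_prominence: float = 0.5
               ) -> tuple[float, float] | None:
    """Smallest-r local maximum of g(r) with the requested prominence.

    Returns (r_peak, g_peak) or None when no qualifying peak exists
    (e.g. a monotone g(r)).
    """
    peaks, _ = find_peaks(rdf_result.g_of_r, prominence=min_prominence)
    if peaks.size == 0:
        return None
    k = int(peaks[0])
    return float(rdf_result.bin_centers[k]), float(rdf_result.g_of_r[k])
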