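"""Hydrogen bonds, X–H···π contacts, π–π classification and water bridges.

Detection criteria follow the geometric convention used throughout the
analysis: a hydrogen bond exists when the acceptor···H distance is below
2.5 Å and the donor–H···acceptor angle exceeds 120°, where the acceptor X
is an O or N heavy atom.  π systems (phenyl, indole, porphyrin rings) can
additionally accept an X–H via the ring centroid, with a distance cutoff
near the quantum-chemical H···π equilibrium (~2.7 Å; working cutoff 3.0 Å)
and an approach cone about the ring normal.

Water-mediated bridges are simple paths ligand-site → water(s) → protein-site
in the per-frame hydrogen-bond graph; water identity is tracked by residue
id so that exchanges of the bridging water can be counted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .geometry import PiPiDescriptor, ring_geometry
from .md_model import Frame, Selection, Topology, Trajectory
from .pbc import min_image_displacement

__all__ = [
    "HBondCriteria",
    "HBondEvent",
    "PiPiCategory",
    "PiPiContact",
    "WaterBridge",
    "BridgeStatistics",
    "BondProbability",
    "detect_hbonds",
    "detect_pi_hbonds",
    "bond_forming_probability",
    "classify_pipi",
    "find_water_bridges",
    "bridge_statistics",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric thresholds for conventional and π hydrogen bonds."""

    d_cut: float = 2.5            # acceptor...H distance, angstrom
    angle_cut: float = 120.0      # donor-H...acceptor angle, degrees
    d_cut_h_pi: float = 3.0       # H...ring-centroid distance, angstrom
    approach_angle_cut: float = 30.0  # H->centroid vs ring normal, degrees


@dataclass(frozen=True)
class HBondEvent:
    """One detected hydrogen bond in one frame.

    ``acceptor`` is an atom index for conventional bonds or a ring label
    (str) for π acceptors.  ``angle`` is donor–H···acceptor for conventional
    bonds and the approach angle off the ring normal for π bonds.
    """

    frame: int
    donor_heavy: int
    hydrogen: int
    acceptor: int | str
    distance: float
    angle: float

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if not (0.0 <= self.angle <= 180.0):
            raise ValueError("angle must lie in [0, 180]")


class PiPiCategory(enum.Enum):
    T_SHAPED = "T_SHAPED"
    STACKED = "STACKED"
    INTERMEDIATE = "INTERMEDIATE"
    NONE = "NONE"


@dataclass(frozen=True)
class PiPiContact:
    frame: int
    ring_a: str
    ring_b: str
    descriptor: PiPiDescriptor
    category: PiPiCategory


@dataclass
class WaterBridge:
    frame: int
    ligand_site: int | str
    protein_site: int | str
    water_chain: list[int]
    events: list[HBondEvent] = field(default_factory=list)


@dataclass
class BridgeStatistics:
    occupancy: float
    exchange_count: int
    frames_present: int
    n_frames: int


@dataclass
class BondProbability:
    """Fraction of frames with a qualifying bond plus distance/angle averages.

    ``mean_distance``/``mean_angle`` average over qualifying events only;
    ``mean_distance_all_frames`` averages the closest acceptor···H distance
    over *every* frame regardless of bond formation (both statistics are
    reported because either averaging convention appears in the literature).
    """

    probability: float
    mean_distance: float
    mean_angle: float
    mean_distance_all_frames: float
    n_frames: int


def _donor_atoms(topology: Topology, sel: Iterable[int]) -> list[int]:
    out = []
    for i in sel:
        a = topology.atom(i)
        if a.is_donor_heavy and a.bound_hydrogens:
            out.append(i)
    return out


def _acceptor_atoms(topology: Topology, sel: Iterable[int]) -> list[int]:
    return [i for i in sel if topology.atom(i).is_acceptor]


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    donor_selection,
    acceptor_selection,
    d_cut: float = 2.5,
    angle_cut: float = 120.0,
    frame_index: int = 0,
) -> list[HBondEvent]:
    """All donor→acceptor hydrogen bonds in one frame.

    An event fires iff distance(acceptor, H) < ``d_cut`` AND the angle
    donor–H···acceptor > ``angle_cut``; distances use the minimum-image
    convention when the frame has a box.  Donors without recorded bound
    hydrogens are skipped.
    """
    coords = frame.coordinates
    box = frame.box
    donors = _donor_atoms(topology, donor_selection)
    acceptors = _acceptor_atoms(topology, acceptor_selection)
    events: list[HBondEvent] = []
    for d in donors:
        for h in topology.atom(d).bound_hydrogens:
            for a in acceptors:
                if a == d or a == h:
                    continue
                ha = min_image_displacement(coords[a] - coords[h], box)
                dist = float(np.linalg.norm(ha))
                if dist >= d_cut:
                    continue
                hd = min_image_displacement(coords[d] - coords[h], box)
                cosang = float(hd @ ha) / (np.linalg.norm(hd) * dist)
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle > angle_cut:
                    events.append(HBondEvent(frame_index, d, h, a, dist, angle))
    return events


def detect_pi_hbonds(
    frame: Frame,
    topology: Topology,
    donor_selection,
    rings: Sequence = (),
    d_cut_h_pi: float = 3.0,
    approach_angle_cut: float = 30.0,
    frame_index: int = 0,
) -> list[HBondEvent]:
    """X–H···π hydrogen bonds against ring centroids.

    An event fires iff the H···centroid distance is below ``d_cut_h_pi`` and
    the angle between the H→centroid vector and the ring normal is below
    ``approach_angle_cut`` (the H approaches the π face, not the ring edge).
    """
    coords = frame.coordinates
    box = frame.box
    ring_specs = [topology.ring(r) if isinstance(r, str) else r for r in rings]
    events: list[HBondEvent] = []
    for d in _donor_atoms(topology, donor_selection):
        for h in topology.atom(d).bound_hydrogens:
            for ring in ring_specs:
                if h in ring.member_atoms or d in ring.member_atoms:
                    continue
                geo = ring_geometry(frame, ring)
                v = min_image_displacement(geo.centroid - coords[h], box)
                dist = float(np.linalg.norm(v))
                if dist >= d_cut_h_pi:
                    continue
                cosang = abs(float(v @ geo.unit_normal)) / dist
                approach = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
                if approach < approach_angle_cut:
                    events.append(
                        HBondEvent(frame_index, d, h, ring.label, dist, approach)
                    )
    return events


def bond_forming_probability(
    trajectory: Trajectory,
    donor_site,
    acceptor_site,
    criteria: HBondCriteria = HBondCriteria(),
) -> BondProbability:
    """Fraction of frames in which the site pair forms a hydrogen bond.

    ``donor_site``/``acceptor_site`` are selections (or index iterables); a
    frame counts when >= 1 qualifying event links the two sites.
    """
    if trajectory.n_frames == 0:
        raise ValueError("trajectory is empty")
    top = trajectory.topology
    donor_list = list(donor_site)
    acceptor_list = list(acceptor_site)
    n_formed = 0
    q_dists: list[float] = []
    q_angles: list[float] = []
    closest: list[float] = []
    for k, frame in enumerate(trajectory):
        events = detect_hbonds(
            frame, top, donor_list, acceptor_list,
            d_cut=criteria.d_cut, angle_cut=criteria.angle_cut, frame_index=k,
        )
        if events:
            n_formed += 1
            q_dists.extend(e.distance for e in events)
            q_angles.extend(e.angle for e in events)
        # closest acceptor...H distance in this frame, bond or not
        dmin = np.inf
        for d in _donor_atoms(top, donor_list):
            for h in top.atom(d).bound_hydrogens:
                for a in _acceptor_atoms(top, acceptor_list):
                    if a in (d, h):
                        continue
                    v = min_image_displacement(
                        frame.coordinates[a] - frame.coordinates[h], frame.box
                    )
                    dmin = min(dmin, float(np.linalg.norm(v)))
        if np.isfinite(dmin):
            closest.append(dmin)
    return BondProbability(
        probability=n_formed / trajectory.n_frames,
        mean_distance=float(np.mean(q_dists)) if q_dists else float("nan"),
        mean_angle=float(np.mean(q_angles)) if q_angles else float("nan"),
        mean_distance_all_frames=float(np.mean(closest)) if closest else float("nan"),
        n_frames=trajectory.n_frames,
    )


def classify_pipi(
    descriptor: PiPiDescriptor,
    t_theta_min: float = 60.0,
    s_theta_max: float = 30.0,
    r_cen_max: float = 6.0,
    d_max: float = 5.0,
) -> PiPiCategory:
    """Classify a ring-pair geometry.

    NONE beyond ``r_cen_max``; T_SHAPED for near-perpendicular planes
    (theta >= ``t_theta_min``); STACKED for near-parallel planes
    (theta <= ``s_theta_max``) with the centroid within ``d_max`` of the
    partner plane; anything else is INTERMEDIATE.  The categories partition
    descriptor space.
    """
    if descriptor.r_cen > r_cen_max:
        return PiPiCategory.NONE
    if descriptor.theta >= t_theta_min:
        return PiPiCategory.T_SHAPED
    if descriptor.theta <= s_theta_max and descriptor.d <= d_max:
        return PiPiCategory.STACKED
    return PiPiCategory.INTERMEDIATE


# ---------------------------------------------------------------------------
# water bridges
# ---------------------------------------------------------------------------

def _site_atoms(topology: Topology, site: int | str) -> list[int] | None:
    """Atom indices of a site; None when the site is a ring label."""
    if isinstance(site, str):
        return None
    return [site]


def _hbonded(frame, topology, atoms_x, atoms_y, criteria, frame_index):
    """Events linking two atom groups, donors tried in both directions."""
    ev = detect_hbonds(frame, topology, atoms_x, atoms_y,
                       criteria.d_cut, criteria.angle_cut, frame_index)
    ev += detect_hbonds(frame, topology, atoms_y, atoms_x,
                        criteria.d_cut, criteria.angle_cut, frame_index)
    return ev


def _pi_hbonded(frame, topology, donor_atoms, ring_label, criteria, frame_index):
    return detect_pi_hbonds(frame, topology, donor_atoms, [ring_label],
                            criteria.d_cut_h_pi, criteria.approach_angle_cut,
                            frame_index)


def find_water_bridges(
    frame: Frame,
    topology: Topology,
    ligand_sites: Sequence[int | str],
    protein_sites: Sequence[int | str],
    water_selection,
    criteria: HBondCriteria = HBondCriteria(),
    max_waters: int = 2,
    frame_index: int = 0,
) -> list[WaterBridge]:
    """All ligand→water(s)→protein bridges in one frame.

    Sites are atom indices or ring labels (π acceptors).  The per-frame
    hydrogen-bond graph over sites and water molecules is built and every
    simple path from a ligand site through 1..``max_waters`` waters to a
    protein site is returned with its constituent events.
    """
    water_atoms = list(water_selection)
    waters: dict[int, list[int]] = {}
    for i in water_atoms:
        waters.setdefault(topology.atom(i).residue_id, []).append(i)

    G = nx.Graph()
    edge_events: dict[tuple, list[HBondEvent]] = {}

    def add_edge(u, v, events):
        if events:
            G.add_edge(u, v)
            edge_events[frozenset((u, v))] = events

    def link_site_water(tag, site, wid, watoms):
        node = (tag, site)
        if isinstance(site, str):
            donors = _donor_atoms(topology, watoms)
            ev = _pi_hbonded(frame, topology, donors, site, criteria, frame_index)
        else:
            ev = _hbonded(frame, topology, [site], watoms, criteria, frame_index)
        add_edge(node, ("W", wid), ev)

    for wid, watoms in waters.items():
        G.add_node(("W", wid))
        for site in ligand_sites:
            link_site_water("L", site, wid, watoms)
        for site in protein_sites:
            link_site_water("P", site, wid, watoms)
    wids = sorted(waters)
    for a in range(len(wids)):
        for b in range(a + 1, len(wids)):
            ev = _hbonded(frame, topology, waters[wids[a]], waters[wids[b]],
                          criteria, frame_index)
            add_edge(("W", wids[a]), ("W", wids[b]), ev)

    bridges: list[WaterBridge] = []
    for lsite in ligand_sites:
        lnode = ("L", lsite)
        if lnode not in G:
            continue
        for psite in protein_sites:
            pnode = ("P", psite)
            if pnode not in G:
                continue
            for path in nx.all_simple_paths(G, lnode, pnode, cutoff=max_waters + 1):
                interior = path[1:-1]
                if not interior or any(n[0] != "W" for n in interior):
                    continue
                events = []
                for u, v in zip(path, path[1:]):
                    events.extend(edge_events[frozenset((u, v))])
                bridges.append(
                    WaterBridge(
                        frame=frame_index,
                        ligand_site=lsite,
                        protein_site=psite,
                        water_chain=[n[1] for n in interior],
                        events=events,
                    )
                )
    return bridges


def bridge_statistics(
    trajectory: Trajectory,
    ligand_site: int | str,
    protein_site: int | str,
    water_selection,
    criteria: HBondCriteria = HBondCriteria(),
    max_waters: int = 2,
) -> BridgeStatistics:
    """Occupancy and water-exchange count of one bridge pattern.

    The pattern fixes the ligand and protein endpoints; water identity is
    free.  Occupancy is the fraction of frames with >= 1 matching bridge.
    An exchange is a frame-to-frame transition in which the pattern persists
    but the set of bridging water residue ids changes.
    """
    per_frame_waters: list[frozenset[int] | None] = []
    for k, frame in enumerate(trajectory):
        bridges = find_water_bridges(
            frame, trajectory.topology, [ligand_site], [protein_site],
            water_selection, criteria, max_waters, frame_index=k,
        )
        if bridges:
            ids: set[int] = set()
            for b in bridges:
                ids.update(b.water_chain)
            per_frame_waters.append(frozenset(ids))
        else:
            per_frame_waters.append(None)
    present = [w is not None for w in per_frame_waters]
    exchanges = 0
    for prev, cur in zip(per_frame_waters, per_frame_waters[1:]):
        if prev is not None and cur is not None and prev != cur:
            exchanges += 1
    n = trajectory.n_frames
    return BridgeStatistics(
        occupancy=sum(present) / n if n else 0.0,
        exchange_count=exchanges,
        frames_present=sum(present),
        n_frames=n,
    )
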