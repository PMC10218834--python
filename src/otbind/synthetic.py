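"""Seeded synthetic fixtures with known ground truth for every pipeline stage.

Each generator plants a geometric or statistical feature (an H-bond of
prescribed distance/angle, a ring pair of prescribed tilt, a water bridge
with prescribed occupancy, an ideal gas, a first solvation shell, a
two-state conformational switch, Gaussian energy fluctuations) that the
corresponding analysis stage must recover.  Identical (parameters, seed)
always produce identical output arrays.

The toy complex emulates the substrate of the full analysis: a five-residue
pocket (an amide donor, a carbonyl acceptor, an indole-like ring, a
hydroxyl and a second amide), a tin-centred ligand carrying a hydroxyl, a
phenyl ring and a short alkyl tail, a heme-like ring below the ligand, and
a set of waters one of which mediates a planted ligand-water-protein
bridge.  It makes no attempt to mimic the true aromatase fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .energetics import EnergySeries
from .geometry import kabsch_align, rmsd
from .md_model import AtomRecord, Frame, RingSpec, Topology, Trajectory

__all__ = [
    "make_hbond_fixture",
    "make_ring_pair",
    "make_bridge_trajectory",
    "make_ideal_gas",
    "make_shell_fixture",
    "make_two_state_trajectory",
    "make_planted_rmsd_frames",
    "make_gaussian_energy_series",
    "make_toy_complex",
    "ToyComplex",
]


def _hexagon(center: np.ndarray, normal: np.ndarray, radius: float = 1.39
             ) -> np.ndarray:
    """Six points of a regular hexagon with the given centre and plane normal."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    # orthonormal in-plane basis
    trial = np.array([0.0, 0.0, 1.0])
    if abs(normal @ trial) > 0.9:
        trial = np.array([1.0, 0.0, 0.0])
    u = np.cross(normal, trial)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    angles = np.arange(6) * np.pi / 3.0
    return center + radius * (np.outer(np.cos(angles), u) +
                              np.outer(np.sin(angles), v))


def make_hbond_fixture(
    distance: float,
    angle: float,
    donor_element: str = "O",
    acceptor_element: str = "O",
) -> tuple[Topology, Frame]:
    """Three-atom D–H···A geometry with exact acceptor···H distance and angle.

    The donor sits in a ligand residue, the acceptor in a MET-374-like
    residue, so selections by residue work out of the box.
    """
    if distance <= 0.5:
        raise ValueError("acceptor...H distance must exceed 0.5 A")
    if not (0.0 < angle <= 180.0):
        raise ValueError("angle must lie in (0, 180]")
    d_dh = 0.97
    donor = np.zeros(3)
    hydrogen = np.array([d_dh, 0.0, 0.0])
    alpha = math.radians(angle)
    acceptor = hydrogen + distance * np.array([-math.cos(alpha),
                                               math.sin(alpha), 0.0])
    atoms = [
        AtomRecord(0, donor_element + "1", donor_element, "OTL", 1, "L",
                   is_donor_heavy=True, is_acceptor=donor_element in "NO",
                   bound_hydrogens=[1]),
        AtomRecord(1, "HO", "H", "OTL", 1, "L"),
        AtomRecord(2, acceptor_element, acceptor_element, "MET", 374, "A",
                   is_acceptor=True),
    ]
    top = Topology(atoms, bonds=[(0, 1)])
    return top, Frame(np.array([donor, hydrogen, acceptor]))


def make_ring_pair(
    theta: float,
    d: float,
    lateral_offset: float = 0.0,
    label_a: str = "alpha",
    label_b: str = "HEM",
) -> tuple[Topology, Frame]:
    """Two labelled hexagons with prescribed interplanar angle and separation.

    Ring B lies in the xy-plane at the origin (normal +z); ring A's centroid
    sits ``d`` above it with the given lateral offset, its plane tilted by
    ``theta`` degrees, so the descriptor of (A, B) returns exactly the
    requested theta and d.
    """
    if not (0.0 <= theta <= 90.0):
        raise ValueError("theta must lie in [0, 90]")
    th = math.radians(theta)
    center_b = np.zeros(3)
    center_a = np.array([lateral_offset, 0.0, d])
    normal_a = np.array([math.sin(th), 0.0, math.cos(th)])
    coords = np.vstack([
        _hexagon(center_a, normal_a),
        _hexagon(center_b, np.array([0.0, 0.0, 1.0])),
    ])
    atoms = [
        AtomRecord(i, f"CA{i + 1}", "C", "OTL", 1, "L") for i in range(6)
    ] + [
        AtomRecord(6 + i, f"CH{i + 1}", "C", "HEM", 600, "A") for i in range(6)
    ]
    top = Topology(
        atoms,
        rings=[RingSpec(label_a, list(range(6))),
               RingSpec(label_b, list(range(6, 12)))],
    )
    return top, Frame(coords)


# ---------------------------------------------------------------------------
# bridge trajectory
# ---------------------------------------------------------------------------

def _water(first_index: int, resid: int, o_pos: np.ndarray,
           h1: np.ndarray, h2: np.ndarray):
    atoms = [
        AtomRecord(first_index, "OW", "O", "HOH", resid, "W",
                   is_donor_heavy=True, is_acceptor=True,
                   bound_hydrogens=[first_index + 1, first_index + 2]),
        AtomRecord(first_index + 1, "HW1", "H", "HOH", resid, "W"),
        AtomRecord(first_index + 2, "HW2", "H", "HOH", resid, "W"),
    ]
    return atoms, np.vstack([o_pos, h1, h2])


def make_bridge_trajectory(
    n_frames: int,
    occupancy: float,
    exchange_frames: tuple[int, ...] = (),
    seed: int = 0,
) -> Trajectory:
    """Ligand-OH···water···HN-protein motif present in a Bernoulli subset.

    In occupied frames one of two waters (residues 100, 101) sits at the
    bridging position between the ligand hydroxyl oxygen (atom 1) and the
    MET-374 amide (N donor, atom 3); the other is parked far away.  At each
    frame listed in ``exchange_frames`` the identity of the bridging water
    swaps while the geometry persists.
    """
    if not (0.0 <= occupancy <= 1.0):
        raise ValueError("occupancy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    # ligand hydroxyl (acceptor O with its H) and protein amide donor
    lig = [
        AtomRecord(0, "SN", "Sn", "OTL", 1, "L"),
        AtomRecord(1, "O1", "O", "OTL", 1, "L", is_donor_heavy=True,
                   is_acceptor=True, bound_hydrogens=[2]),
        AtomRecord(2, "HO", "H", "OTL", 1, "L"),
    ]
    prot = [
        AtomRecord(3, "N", "N", "MET", 374, "A", is_donor_heavy=True,
                   is_acceptor=True, bound_hydrogens=[4]),
        AtomRecord(4, "H", "H", "MET", 374, "A"),
    ]
    wat_a, _ = _water(5, 100, np.zeros(3), np.zeros(3), np.zeros(3))
    wat_b, _ = _water(8, 101, np.zeros(3), np.zeros(3), np.zeros(3))
    top = Topology(lig + prot + wat_a + wat_b, bonds=[(1, 2), (3, 4)])

    lig_coords = np.array([[-2.0, 0.0, 0.0],   # Sn
                           [0.0, 0.0, 0.0],    # O1
                           [0.84, 0.49, 0.0]])  # HO, points away from bridge
    prot_coords = np.array([[1.6, -5.23, 0.0],  # N
                            [1.6, -4.23, 0.0]])  # H_N, points toward Ow
    # bridging water: O accepts from MET N-H, one H donates to ligand O1
    site_o = np.array([1.6, -2.3, 0.0])
    site_h1 = np.array([1.045, -1.504, 0.0])   # toward O1 at origin
    site_h2 = np.array([2.52, -2.0, 0.0])
    far_a = np.array([14.0, 14.0, 14.0])
    far_b = np.array([-14.0, 14.0, 14.0])

    present = rng.random(n_frames) < occupancy
    exchange_set = set(exchange_frames)
    active = 100
    frames = []
    for k in range(n_frames):
        if k in exchange_set:
            active = 101 if active == 100 else 100
        coords = np.zeros((11, 3))
        coords[0:3] = lig_coords
        coords[3:5] = prot_coords
        if present[k]:
            site = np.vstack([site_o, site_h1, site_h2])
        else:
            site = None
        if active == 100:
            coords[5:8] = site if site is not None else far_a + np.array([0, 2.0, 0])
            coords[8:11] = far_b
        else:
            coords[8:11] = site if site is not None else far_b + np.array([0, 2.0, 0])
            coords[5:8] = far_a
        frames.append(Frame(coords, time=10.0 * k))
    return Trajectory(top, frames, sampling_interval=10.0)


def make_ideal_gas(
    n_atoms: int,
    box: float,
    n_frames: int,
    seed: int = 0,
) -> Trajectory:
    """Uniform i.i.d. positions in a cubic box — the g(r) = 1 reference."""
    if n_atoms < 2:
        raise ValueError("need >= 2 atoms")
    rng = np.random.default_rng(seed)
    atoms = [AtomRecord(i, "AR", "Ar", "GAS", i + 1, "G") for i in range(n_atoms)]
    top = Topology(atoms)
    box_vec = np.full(3, float(box))
    frames = [
        Frame(rng.uniform(0.0, box, size=(n_atoms, 3)), box_vec, time=float(k))
        for k in range(n_frames)
    ]
    return Trajectory(top, frames, sampling_interval=1.0)


def make_shell_fixture(
    shell_radius: float,
    n_shell: int,
    background_density: float,
    box: float = 30.0,
    n_frames: int = 50,
    seed: int = 0,
) -> tuple[Trajectory, str, list[int]]:
    """A ring with a planted first solvation shell plus uniform background.

    ``n_shell`` hydrogen-like targets sit on the hemisphere above the ring
    plane at exactly ``shell_radius`` from the centroid; the rest fill the
    box uniformly at ``background_density`` (per cubic angstrom).  Returns
    (trajectory, ring label, target atom indices) — the first g(r) peak of
    targets around the ring centroid lies at the shell radius.
    """
    if shell_radius <= 0:
        raise ValueError("shell radius must be positive")
    rng = np.random.default_rng(seed)
    center = np.full(3, box / 2.0)
    ring_coords = _hexagon(center, np.array([0.0, 0.0, 1.0]))
    n_bg = int(round(background_density * box ** 3))
    atoms = [AtomRecord(i, f"CB{i + 1}", "C", "LIG", 1, "L") for i in range(6)]
    targets = []
    for k in range(n_shell + n_bg):
        idx = 6 + k
        atoms.append(AtomRecord(idx, "HW1", "H", "HOH", 100 + k, "W"))
        targets.append(idx)
    top = Topology(atoms, rings=[RingSpec("beta", list(range(6)))])
    box_vec = np.full(3, float(box))
    frames = []
    for k in range(n_frames):
        # hemisphere points at exactly shell_radius above the ring plane
        z = rng.uniform(0.05, 1.0, n_shell)
        phi = rng.uniform(0.0, 2.0 * np.pi, n_shell)
        s = np.sqrt(1.0 - z ** 2)
        shell = center + shell_radius * np.column_stack(
            (s * np.cos(phi), s * np.sin(phi), z)
        )
        bg = rng.uniform(0.0, box, size=(n_bg, 3))
        # keep background out of the planted shell region
        d = np.linalg.norm(bg - center, axis=1)
        clash = d < shell_radius + 1.0
        while np.any(clash):
            bg[clash] = rng.uniform(0.0, box, size=(clash.sum(), 3))
            d = np.linalg.norm(bg - center, axis=1)
            clash = d < shell_radius + 1.0
        frames.append(Frame(np.vstack([ring_coords, shell, bg]), box_vec,
                            time=float(k)))
    return Trajectory(top, frames, sampling_interval=1.0), "beta", targets


# ---------------------------------------------------------------------------
# planted-RMSD conformations
# ---------------------------------------------------------------------------

def _aligned_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    fa, fb = Frame(a), Frame(b)
    aligned, _, _ = kabsch_align(fb, fa, list(range(a.shape[0])))
    return rmsd(aligned.coordinates, a)


def _plant_displacement(base: np.ndarray, target: float,
                        rng: np.random.Generator) -> np.ndarray:
    """A perturbed copy of ``base`` at exactly ``target`` aligned RMSD."""
    direction = rng.standard_normal(base.shape)
    direction -= direction.mean(axis=0)
    direction /= np.sqrt(np.mean(np.sum(direction ** 2, axis=1)))

    def f(s: float) -> float:
        return _aligned_rmsd(base, base + s * direction) - target

    hi = 2.0 * target + 1.0
    while f(hi) < 0:
        hi *= 2.0
    s = brentq(f, 0.0, hi, xtol=1e-10)
    return base + s * direction


def make_planted_rmsd_frames(
    distances: tuple[float, ...],
    seed: int = 0,
    n_atoms: int = 10,
    spread: float = 4.0,
) -> Trajectory:
    """Frames whose Kabsch RMSD from frame 0 equals the given distances.

    Frame 0 is a random cloud; frame k (k >= 1) is planted at exactly
    ``distances[k-1]`` aligned RMSD from frame 0 along independent random
    perturbation directions.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(-spread, spread, size=(n_atoms, 3))
    coords = [base]
    for dist in distances:
        coords.append(_plant_displacement(base, float(dist), rng))
    atoms = [AtomRecord(i, f"C{i + 1}", "C", "CLD", 1, "A") for i in range(n_atoms)]
    top = Topology(atoms)
    frames = [Frame(c, time=float(k)) for k, c in enumerate(coords)]
    return Trajectory(top, frames, sampling_interval=1.0)


def make_two_state_trajectory(
    n_frames: int,
    intra_spread: float,
    inter_gap: float,
    switch_frame: int,
    seed: int = 0,
    n_atoms: int = 10,
) -> Trajectory:
    """Frames jittering around two conformations separated by ``inter_gap``.

    Frames before ``switch_frame`` jitter around state A, the rest around
    state B, with the aligned RMSD between the two states planted at
    ``inter_gap``.  ``intra_spread`` is the per-atom RMS jitter amplitude.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(-4.0, 4.0, size=(n_atoms, 3))
    other = _plant_displacement(base, inter_gap, rng)
    sigma = intra_spread / math.sqrt(3.0)
    atoms = [AtomRecord(i, f"C{i + 1}", "C", "CLD", 1, "A") for i in range(n_atoms)]
    top = Topology(atoms)
    frames = []
    for k in range(n_frames):
        ref = base if k < switch_frame else other
        frames.append(
            Frame(ref + rng.normal(0.0, sigma, size=ref.shape), time=10.0 * k)
        )
    return Trajectory(top, frames, sampling_interval=10.0)


def make_gaussian_energy_series(
    sigma: float,
    n: int,
    seed: int = 0,
    mean: float = 0.0,
    temperature: float = 298.15,
) -> EnergySeries:
    """i.i.d. normal interaction energies — the entropy estimator's oracle.

    For this series the interaction entropy has the closed form
    -T*dS = sigma^2 / (2 kB T).
    """
    rng = np.random.default_rng(seed)
    return EnergySeries(rng.normal(mean, sigma, n), temperature=temperature)


# ---------------------------------------------------------------------------
# toy complex
# ---------------------------------------------------------------------------

@dataclass
class ToyComplex:
    """A small pocket + tin ligand + waters with planted interactions.

    ``info`` records the planted ground truth: site indices, ring labels,
    occupancies and the cluster switch frame.
    """

    topology: Topology
    trajectory: Trajectory
    parameter_table: dict[tuple[str, str], dict[str, float]]
    info: dict = field(default_factory=dict)


def _toy_parameter_table() -> dict[tuple[str, str], dict[str, float]]:
    def p(q, s, e):
        return {"charge_e": q, "sigma_A": s, "epsilon_kJmol": e}

    table: dict[tuple[str, str], dict[str, float]] = {}
    table[("OTL", "SN")] = p(0.60, 4.20, 2.00)
    table[("OTL", "O1")] = p(-0.58, 3.00, 0.71)
    table[("OTL", "HO")] = p(0.40, 2.00, 0.065)
    for i in range(6):
        table[("OTL", f"CA{i + 1}")] = p(-0.06, 3.40, 0.36)
    for i in range(3):
        table[("OTL", f"CT{i + 1}")] = p(-0.02, 3.40, 0.36)
    table[("HEM", "FE")] = p(0.40, 3.80, 0.80)
    for i in range(6):
        table[("HEM", f"CH{i + 1}")] = p(-0.10, 3.40, 0.36)
    table[("LEU", "C")] = p(0.50, 3.75, 0.44)
    table[("LEU", "O")] = p(-0.50, 2.96, 0.88)
    table[("MET", "N")] = p(-0.42, 3.25, 0.71)
    table[("MET", "H")] = p(0.42, 1.07, 0.065)
    for i in range(6):
        table[("TRP", f"CW{i + 1}")] = p(-0.05, 3.40, 0.36)
    table[("TRP", "HW0")] = p(0.30, 1.07, 0.065)
    table[("THR", "OG1")] = p(-0.65, 3.07, 0.88)
    table[("THR", "HG1")] = p(0.65, 1.00, 0.065)
    table[("ALA", "N")] = p(-0.42, 3.25, 0.71)
    table[("ALA", "H")] = p(0.42, 1.07, 0.065)
    table[("HOH", "OW")] = p(-0.834, 3.1506, 0.6364)
    table[("HOH", "HW1")] = p(0.417, 1.00, 0.0)
    table[("HOH", "HW2")] = p(0.417, 1.00, 0.0)
    return table


def make_toy_complex(
    seed: int = 0,
    n_frames: int = 120,
    hbond_p: float = 0.5,
    bridge_p: float = 0.7,
    exchange_frames: tuple[int, ...] = (),
    switch_frame: int | None = None,
    jitter: float = 0.03,
    box: float = 40.0,
) -> ToyComplex:
    """End-to-end analysis substrate with planted interactions.

    Planted ground truth (recorded in ``info``):
      * a ligand-OH → LEU-372 carbonyl hydrogen bond present in a
        Bernoulli(``hbond_p``) subset of frames,
      * a T-shaped contact between the ligand phenyl ("alpha") and the
        heme-like ring ("HEM"), present in every frame (small angular
        jitter around 90 degrees),
      * a (Sn)-O···H2O···HN-(MET-374) water bridge present in a
        Bernoulli(``bridge_p``) subset, with identity swaps of the
        bridging water at ``exchange_frames``,
      * a two-state motion of the ligand alkyl tail switching at
        ``switch_frame`` (default: half the trajectory), separating the
        ligand conformations by well over 2 A RMSD.
    """
    rng = np.random.default_rng(seed)
    if switch_frame is None:
        switch_frame = n_frames // 2
    origin = np.full(3, box / 2.0)

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []

    def add(name, element, resname, resid, chain, pos, **kw):
        atoms.append(AtomRecord(len(atoms), name, element, resname, resid,
                                chain, **kw))
        coords.append(origin + np.asarray(pos, dtype=float))
        return len(atoms) - 1

    # --- ligand (OTL 1): Sn + hydroxyl + phenyl ring + alkyl tail
    i_sn = add("SN", "Sn", "OTL", 1, "L", (0.0, 0.0, 3.5))
    i_o1 = add("O1", "O", "OTL", 1, "L", (2.0, 0.0, 3.5),
               is_donor_heavy=True, is_acceptor=True)
    i_ho = add("HO", "H", "OTL", 1, "L", (2.82, 0.51, 3.5))
    atoms[i_o1].bound_hydrogens = [i_ho]
    alpha_center = np.array([1.0, 0.0, 4.6])
    alpha_ring = []
    for k, pos in enumerate(_hexagon(alpha_center, np.array([1.0, 0.0, 0.0]))):
        alpha_ring.append(add(f"CA{k + 1}", "C", "OTL", 1, "L", pos - 0.0))
    tail = [
        add("CT1", "C", "OTL", 1, "L", (-2.0, 0.0, 3.5)),
        add("CT2", "C", "OTL", 1, "L", (-3.5, 0.8, 3.7)),
        add("CT3", "C", "OTL", 1, "L", (-5.0, 1.6, 3.9)),
    ]

    # --- heme-like ring (HEM 600) in the xy-plane below the ligand
    i_fe = add("FE", "Fe", "HEM", 600, "A", (0.0, 0.0, 0.0))
    hem_ring = []
    for k, pos in enumerate(_hexagon(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                                     radius=2.0)):
        hem_ring.append(add(f"CH{k + 1}", "C", "HEM", 600, "A", pos))

    # --- pocket residues
    # LEU-372 carbonyl: planted H-bond acceptor
    u = np.array([0.8, 0.5, 0.0])
    u /= np.linalg.norm(u)
    o1_rel = np.array([2.0, 0.0, 3.5])
    ho_on = o1_rel + 0.97 * u
    o_leu_rel = ho_on + 2.0 * u
    ho_off = o1_rel + 0.97 * np.array([-u[0], -u[1], 0.0])
    i_leu_c = add("C", "C", "LEU", 372, "A", o_leu_rel + 1.23 * u)
    i_leu_o = add("O", "O", "LEU", 372, "A", o_leu_rel, is_acceptor=True)
    # MET-374 amide: bridge donor
    i_met_n = add("N", "N", "MET", 374, "A", (2.0, -5.73, 3.5),
                  is_donor_heavy=True, is_acceptor=True)
    i_met_h = add("H", "H", "MET", 374, "A", (2.0, -4.73, 3.5))
    atoms[i_met_n].bound_hydrogens = [i_met_h]
    # TRP-224 indole-like ring (kept clear of the mobile alkyl tail)
    trp_ring = []
    for k, pos in enumerate(_hexagon(np.array([-4.5, -2.5, 6.5]),
                                     np.array([0.0, 0.0, 1.0]))):
        trp_ring.append(add(f"CW{k + 1}", "C", "TRP", 224, "A", pos))
    # THR-310 hydroxyl and ALA-306 amide (no planted interaction)
    i_thr_o = add("OG1", "O", "THR", 310, "A", (6.0, -3.0, 6.0),
                  is_donor_heavy=True, is_acceptor=True)
    i_thr_h = add("HG1", "H", "THR", 310, "A", (6.8, -3.4, 6.2))
    atoms[i_thr_o].bound_hydrogens = [i_thr_h]
    i_ala_n = add("N", "N", "ALA", 306, "A", (-2.5, -6.0, 4.5),
                  is_donor_heavy=True, is_acceptor=True)
    i_ala_h = add("H", "H", "ALA", 306, "A", (-2.5, -5.0, 4.7))
    atoms[i_ala_n].bound_hydrogens = [i_ala_h]

    # --- waters: the two bridge candidates plus background
    site_o = np.array([2.0, -2.8, 3.5])
    site_h1 = np.array([2.0, -1.83, 3.5])   # donates to the ligand O1
    site_h2 = np.array([2.92, -3.1, 3.5])
    far_a = np.array([12.0, 12.0, 12.0])
    far_b = np.array([-12.0, 12.0, 12.0])
    water_atoms: list[int] = []

    def add_water(resid, o, h1, h2):
        io = add("OW", "O", "HOH", resid, "W", o, is_donor_heavy=True,
                 is_acceptor=True)
        ih1 = add("HW1", "H", "HOH", resid, "W", h1)
        ih2 = add("HW2", "H", "HOH", resid, "W", h2)
        atoms[io].bound_hydrogens = [ih1, ih2]
        water_atoms.extend([io, ih1, ih2])
        return io

    add_water(100, site_o, site_h1, site_h2)        # bridge candidate a
    add_water(101, far_b, far_b + (0.7, 0.7, 0.0), far_b + (-0.7, 0.7, 0.0))
    bg_centers = []
    keep_out = [far_a, far_b]
    for k in range(8):
        # background waters well clear of the pocket, the parked bridge
        # waters and each other, so no accidental H-bond paths form
        while True:
            c = rng.uniform(-14.0, 14.0, 3)
            if np.linalg.norm(c) > 12.0 and all(
                    np.linalg.norm(c - b) > 5.0 for b in bg_centers + keep_out):
                bg_centers.append(c)
                break
        add_water(110 + k, c, c + (0.76, 0.59, 0.0), c + (-0.76, 0.59, 0.0))

    base = np.asarray(coords)
    rings = [
        RingSpec("alpha", alpha_ring),
        RingSpec("HEM", hem_ring),
        RingSpec("TRP-224-indole", trp_ring),
    ]
    bonds = [(i_o1, i_ho), (i_met_n, i_met_h), (i_thr_o, i_thr_h),
             (i_ala_n, i_ala_h), (i_leu_c, i_leu_o)]
    top = Topology(atoms, bonds=bonds, rings=rings)

    # per-frame randomness
    hb_on = rng.random(n_frames) < hbond_p
    br_on = rng.random(n_frames) < bridge_p
    theta_jit = rng.normal(0.0, 2.0, n_frames)   # degrees about 90
    exchange_set = set(exchange_frames)
    w100 = slice(water_atoms[0], water_atoms[0] + 3)
    w101 = slice(water_atoms[3], water_atoms[3] + 3)
    site_block = origin + np.vstack([site_o, site_h1, site_h2])
    far_a_block = origin + np.vstack([far_a, far_a + (0.7, 0.7, 0.0),
                                      far_a + (-0.7, 0.7, 0.0)])
    far_b_block = origin + np.vstack([far_b, far_b + (0.7, 0.7, 0.0),
                                      far_b + (-0.7, 0.7, 0.0)])
    tail_shift = np.array([0.0, 5.4, -7.2])      # 9 A displacement

    active = 100
    frames = []
    box_vec = np.full(3, float(box))
    for k in range(n_frames):
        if k in exchange_set:
            active = 101 if active == 100 else 100
        c = base.copy()
        # planted H-bond: swing the hydroxyl hydrogen
        c[i_ho] = origin + (ho_on if hb_on[k] else ho_off)
        # planted T-shaped contact: tilt the alpha ring about the y-axis
        ang = math.radians(theta_jit[k])
        rot = np.array([[math.cos(ang), 0.0, math.sin(ang)],
                        [0.0, 1.0, 0.0],
                        [-math.sin(ang), 0.0, math.cos(ang)]])
        ctr = origin + alpha_center
        c[alpha_ring] = (c[alpha_ring] - ctr) @ rot.T + ctr
        # planted bridge: park the inactive water, place/remove the active one
        if active == 100:
            c[w100] = site_block if br_on[k] else far_a_block
            c[w101] = far_b_block
        else:
            c[w101] = site_block if br_on[k] else far_b_block
            c[w100] = far_a_block
        # two-state tail motion
        if k >= switch_frame:
            c[tail] = c[tail] + tail_shift
        c = c + rng.normal(0.0, jitter, size=c.shape)
        frames.append(Frame(c, box_vec, time=10.0 * k))

    traj = Trajectory(top, frames, sampling_interval=10.0)
    info = {
        "hbond_p": hbond_p,
        "hbond_on": hb_on,
        "hbond_donor": i_o1,
        "hbond_hydrogen": i_ho,
        "hbond_acceptor": i_leu_o,
        "bridge_p": bridge_p,
        "bridge_on": br_on,
        "bridge_ligand_site": i_o1,
        "bridge_protein_site": i_met_n,
        "exchange_frames": tuple(sorted(exchange_set)),
        "water_atoms": water_atoms,
        "ring_pair": ("alpha", "HEM"),
        "switch_frame": switch_frame,
        "ligand_atoms": [i_sn, i_o1, i_ho] + alpha_ring + tail,
        "tail_atoms": tail,
        "pocket_residues": [372, 374, 224, 310, 306, 600],
    }
    return ToyComplex(top, traj, _toy_parameter_table(), info)
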