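"""End-state binding free-energy bookkeeping and its ingredients.

The binding free energy is assembled as

    dG_bind = dE_gas - T*dS_gas + dG_sol
    dE_gas  = dE_vdW + dE_Coul
    dG_sol  = ddG_PB + ddG_SA

with the gas-phase terms from pairwise Lennard-Jones/Coulomb sums over
trajectory snapshots, the entropic term from the interaction-entropy
estimator

    -T*dS_gas = kB*T * ln< exp(beta * dE_int) >,   dE_int = E_int - <E_int>,

the nonpolar solvation term from a linear SASA model, and the polar term
from a pairwise generalized-Born surrogate (a grid Poisson-Boltzmann solver
is deliberately out of scope; the bookkeeping is solver-agnostic).

Units: kJ/mol, angstrom, elementary charges, kelvin throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .md_model import Frame, ParameterError, Topology, Trajectory
from .pbc import pair_distances

__all__ = [
    "KB_KJ_MOL_K",
    "COULOMB_KJ_A_E2",
    "EnergySeries",
    "EntropyEstimate",
    "FreeEnergyTable",
    "lj_coulomb_energy",
    "interaction_energy_series",
    "interaction_entropy",
    "sasa",
    "nonpolar_solvation",
    "gb_energy",
    "gb_polar_surrogate",
    "mmpbsa_totals",
    "per_residue_decomposition",
    "ki_to_delta_g",
]

#: Boltzmann constant, kJ/(mol K)
KB_KJ_MOL_K = 0.008314462618
#: Coulomb prefactor k_e = 138.935458 kJ nm / (mol e^2), converted to angstrom
COULOMB_KJ_A_E2 = 1389.35458

#: Bondi-style van der Waals radii (angstrom) used for SASA and as
#: generic Born radii in the polar surrogate.
ELEMENT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "FE": 2.00, "SN": 2.17, "AR": 1.88,
}


def element_radii_for(topology, default: float = 1.70) -> dict[int, float]:
    """Per-atom radius lookup by element for a whole topology."""
    return {
        a.index: ELEMENT_RADII.get(a.element.upper(), default)
        for a in topology.atoms
    }


@dataclass
class EnergySeries:
    """Per-frame protein-ligand interaction energies (kJ/mol)."""

    values: np.ndarray
    temperature: float = 298.15
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("energy series must not be empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("energy series contains non-finite values")


@dataclass
class EntropyEstimate:
    """Interaction-entropy result with a running (per-prefix) estimate."""

    minus_TdS: float
    running_estimate: np.ndarray
    running_n: np.ndarray
    converged: bool
    temperature: float


@dataclass
class FreeEnergyTable:
    """The component ledger of an end-state binding free energy.

    The identities dE_gas = dE_vdW + dE_Coul, dG_sol = ddG_PB + ddG_SA and
    dG_bind = dE_gas + minus_TdS + dG_sol hold by construction.
    """

    dE_vdW: float
    dE_Coul: float
    ddG_PB: float
    ddG_SA: float
    minus_TdS: float
    per_residue: dict[int, dict[str, float]] = field(default_factory=dict)

    @property
    def dE_gas(self) -> float:
        return self.dE_vdW + self.dE_Coul

    @property
    def dG_sol(self) -> float:
        return self.ddG_PB + self.ddG_SA

    @property
    def dG_bind(self) -> float:
        return self.dE_gas + self.minus_TdS + self.dG_sol

    def as_dict(self) -> dict[str, float]:
        return {
            "dG_bind": self.dG_bind,
            "dE_vdW": self.dE_vdW,
            "dE_Coul": self.dE_Coul,
            "dE_gas": self.dE_gas,
            "ddG_PB": self.ddG_PB,
            "ddG_SA": self.ddG_SA,
            "dG_sol": self.dG_sol,
            "minus_TdS": self.minus_TdS,
        }


def _gather(topology: Topology, selection) -> tuple[np.ndarray, np.ndarray,
                                                    np.ndarray, np.ndarray]:
    idx = np.asarray(list(selection), dtype=int)
    missing = [int(i) for i in idx if not topology.atom(i).parameterized]
    if missing:
        raise ParameterError(f"unparameterized atoms in selection: {missing}")
    q = np.array([topology.atom(i).charge for i in idx])
    sig = np.array([topology.atom(i).lj_sigma for i in idx])
    eps = np.array([topology.atom(i).lj_epsilon for i in idx])
    return idx, q, sig, eps


def lj_coulomb_energy(
    frame: Frame,
    selection_a,
    selection_b,
    topology: Topology,
    use_pbc: bool = True,
) -> tuple[float, float]:
    """Pairwise (E_vdW, E_Coul) between two disjoint selections, kJ/mol.

    Lorentz-Berthelot combination, minimum-image distances, and no cutoff
    (the end-state convention).  Overlapping atoms (r < 0.1 A) raise.
    """
    ia, qa, sa, ea = _gather(topology, selection_a)
    ib, qb, sb, eb = _gather(topology, selection_b)
    if set(ia) & set(ib):
        raise ValueError("selections must be disjoint")
    box = frame.box if use_pbc else None
    r = pair_distances(frame.coordinates[ia], frame.coordinates[ib], box)
    if np.any(r < 0.1):
        raise ValueError("overlapping atoms (r < 0.1 A) in energy evaluation")
    sig = 0.5 * (sa[:, None] + sb[None, :])
    eps = np.sqrt(ea[:, None] * eb[None, :])
    sr6 = (sig / r) ** 6
    e_vdw = float(np.sum(4.0 * eps * (sr6 ** 2 - sr6)))
    e_coul = float(COULOMB_KJ_A_E2 * np.sum(qa[:, None] * qb[None, :] / r))
    return e_vdw, e_coul


def interaction_energy_series(
    trajectory: Trajectory,
    selection_a,
    selection_b,
    topology: Topology | None = None,
    temperature: float = 298.15,
    use_pbc: bool = True,
) -> EnergySeries:
    """Per-frame vdW + Coulomb interaction energy between two selections."""
    top = topology if topology is not None else trajectory.topology
    values = np.empty(trajectory.n_frames)
    for k, frame in enumerate(trajectory):
        ev, ec = lj_coulomb_energy(frame, selection_a, selection_b, top, use_pbc)
        values[k] = ev + ec
    return EnergySeries(values, temperature=temperature, times=trajectory.times)


def interaction_entropy(
    series: EnergySeries,
    temperature: float | None = None,
    n_checkpoints: int = 50,
    convergence_tol: float = 0.05,
) -> EntropyEstimate:
    """Interaction-entropy estimator -T*dS = kB*T ln<exp(beta*dE)>.

    Evaluated with a log-sum-exp formulation, stable for beta*dE up to ~700.
    The running estimate is computed on ~``n_checkpoints`` prefixes of the
    series (each with its own prefix mean); the convergence flag requires
    the relative spread over the final 20% of checkpoints to stay below
    ``convergence_tol``.
    """
    T = temperature if temperature is not None else series.temperature
    x = series.values
    if x.size < 2:
        raise ValueError("need >= 2 energy values")
    kbt = KB_KJ_MOL_K * T
    beta = 1.0 / kbt

    def estimate(prefix: np.ndarray) -> float:
        de = prefix - prefix.mean()
        return kbt * (logsumexp(beta * de) - np.log(prefix.size))

    total = estimate(x)
    if not np.isfinite(total):
        raise FloatingPointError(
            "interaction entropy did not stabilise; consider block averaging"
        )
    ns = np.unique(np.linspace(2, x.size, min(n_checkpoints, x.size - 1),
                               dtype=int))
    running = np.array([estimate(x[:n]) for n in ns])
    tail = running[int(np.ceil(0.8 * running.size)):]
    if tail.size == 0:
        tail = running[-1:]
    scale = max(abs(total), 1e-12)
    converged = bool((tail.max() - tail.min()) / scale < convergence_tol)
    return EntropyEstimate(
        minus_TdS=float(total),
        running_estimate=running,
        running_n=ns,
        converged=converged,
        temperature=T,
    )


# ---------------------------------------------------------------------------
# solvation surrogates
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa(
    frame: Frame,
    selection,
    radii: Mapping[int, float] | Sequence[float],
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area, A^2.

    ``radii`` maps atom index -> vdW radius (or gives one radius per
    selection atom in order).  Returns (per-atom areas, total).  The sphere
    point set is deterministic for a fixed ``n_points``.
    """
    idx = np.asarray(list(selection), dtype=int)
    if isinstance(radii, Mapping):
        try:
            rad = np.array([radii[int(i)] for i in idx], dtype=float)
        except KeyError as exc:
            raise ParameterError(f"missing radius for atom {exc}") from exc
    else:
        rad = np.asarray(radii, dtype=float)
        if rad.size != idx.size:
            raise ParameterError("need one radius per selection atom")
    coords = frame.coordinates[idx]
    sphere = _sphere_points(n_points)
    areas = np.empty(idx.size)
    ext = rad + probe
    for i in range(idx.size):
        pts = coords[i] + ext[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(idx.size):
            if j == i:
                continue
            if np.linalg.norm(coords[i] - coords[j]) > ext[i] + ext[j]:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.mean()
    return areas, float(areas.sum())


def nonpolar_solvation(
    sasa_complex: float,
    sasa_receptor: float,
    sasa_ligand: float,
    gamma: float = 0.0227,
    beta_const: float = 3.849,
) -> float:
    """Linear SASA model ddG_SA = gamma * dSASA - b, kJ/mol.

    gamma in kJ/(mol A^2); the additive constant b enters once per species
    so the difference complex - receptor - ligand leaves -b.
    """
    if min(sasa_complex, sasa_receptor, sasa_ligand) < 0:
        raise ValueError("SASA values must be non-negative")
    return gamma * (sasa_complex - sasa_receptor - sasa_ligand) - beta_const


def gb_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    born_radii: np.ndarray,
    eps_in: float = 1.0,
    eps_out: float = 80.0,
) -> float:
    """Pairwise generalized-Born polar solvation energy, kJ/mol.

    G = -(k_e/2)(1/eps_in - 1/eps_out) * sum_ij q_i q_j / f_GB(r_ij),
    f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j))), the double sum
    running over all ordered pairs including i == j (the Born self terms).
    """
    coords = np.asarray(coords, dtype=float)
    q = np.asarray(charges, dtype=float)
    R = np.asarray(born_radii, dtype=float)
    if np.any(R <= 0):
        raise ValueError("Born radii must be positive")
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = np.sum(diff ** 2, axis=-1)
    RiRj = R[:, None] * R[None, :]
    f = np.sqrt(r2 + RiRj * np.exp(-r2 / (4.0 * RiRj)))
    pref = -0.5 * COULOMB_KJ_A_E2 * (1.0 / eps_in - 1.0 / eps_out)
    return float(pref * np.sum(q[:, None] * q[None, :] / f))


def gb_polar_surrogate(
    frame: Frame,
    complex_selection,
    receptor_selection,
    ligand_selection,
    topology: Topology,
    born_radii: Mapping[int, float],
    eps_in: float = 1.0,
    eps_out: float = 80.0,
) -> float:
    """ddG_polar = G_GB(complex) - G_GB(receptor) - G_GB(ligand), kJ/mol.

    Born radii are held fixed across the three states (single-trajectory
    end-state convention).
    """
    def g(selection) -> float:
        idx = np.asarray(list(selection), dtype=int)
        q = np.array([topology.atom(int(i)).charge for i in idx])
        try:
            R = np.array([born_radii[int(i)] for i in idx], dtype=float)
        except KeyError as exc:
            raise ParameterError(f"missing Born radius for atom {exc}") from exc
        return gb_energy(frame.coordinates[idx], q, R, eps_in, eps_out)

    return g(complex_selection) - g(receptor_selection) - g(ligand_selection)


def mmpbsa_totals(
    dE_vdW: float,
    dE_Coul: float,
    ddG_PB: float,
    ddG_SA: float,
    minus_TdS: float,
    per_residue: dict[int, dict[str, float]] | None = None,
) -> FreeEnergyTable:
    """Assemble the end-state free-energy ledger from its components."""
    return FreeEnergyTable(
        dE_vdW=float(dE_vdW),
        dE_Coul=float(dE_Coul),
        ddG_PB=float(ddG_PB),
        ddG_SA=float(ddG_SA),
        minus_TdS=float(minus_TdS),
        per_residue=per_residue or {},
    )


def per_residue_decomposition(
    trajectory: Trajectory,
    ligand_selection,
    topology: Topology | None = None,
    residue_ids: Sequence[int] | None = None,
    use_pbc: bool = True,
) -> dict[int, dict[str, float]]:
    """Mean per-residue (vdW, Coul) contributions against the ligand, kJ/mol.

    Residue contributions sum exactly to the total gas-phase interaction
    energy of the ligand with the union of the listed residues.
    """
    top = topology if topology is not None else trajectory.topology
    lig = list(ligand_selection)
    if residue_ids is None:
        lig_set = set(lig)
        residue_ids = sorted(
            rid for rid, atoms in top.residue_index.items()
            if not lig_set & set(atoms)
        )
    acc = {rid: np.zeros(2) for rid in residue_ids}
    for frame in trajectory:
        for rid in residue_ids:
            res_atoms = top.residue_index[rid]
            ev, ec = lj_coulomb_energy(frame, res_atoms, lig, top, use_pbc)
            acc[rid] += (ev, ec)
    n = trajectory.n_frames
    return {
        rid: {"vdW": float(v[0] / n), "Coul": float(v[1] / n)}
        for rid, v in acc.items()
    }


def ki_to_delta_g(ki_molar: float, temperature: float = 310.0,
                  gas_constant: float = 8.314) -> float:
    """Binding free energy from an inhibition constant: dG = R*T*ln(Ki/1M).

    ``gas_constant`` is in J/(mol K); the result is in kJ/mol.
    """
    if ki_molar <= 0:
        raise ValueError("Ki must be positive")
    return gas_constant * temperature * float(np.log(ki_molar)) / 1000.0
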