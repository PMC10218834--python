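import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from otbind.md_model import AtomRecord, Frame, Topology, Trajectory, assign_parameters
from otbind.synthetic import make_toy_complex

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """Toy pocket/ligand/water complex with planted interactions."""
    complex_ = make_toy_complex(seed=1, n_frames=120, hbond_p=0.5,
                                bridge_p=0.7, exchange_frames=(40, 80))
    assign_parameters(complex_.topology, complex_.parameter_table)
    return complex_


def random_hbond_system(rng: np.random.Generator, n_heavy: int = 12,
                        box: float | None = 12.0):
    """A random mix of donors (with hydrogens) and acceptors in a box.

    Returns (topology, frame).  Used to compare detection against the
    brute-force oracle.
    """
    atoms = []
    coords = []
    idx = 0
    span = box if box is not None else 12.0
    for _ in range(n_heavy):
        element = rng.choice(["O", "N", "C"])
        pos = rng.uniform(0, span, 3)
        is_no = element in ("O", "N")
        has_h = is_no and rng.random() < 0.7
        heavy = AtomRecord(idx, element + "X", element, "RES", idx + 1, "A",
                           is_donor_heavy=has_h, is_acceptor=is_no)
        atoms.append(heavy)
        coords.append(pos)
        idx += 1
        if has_h:
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            atoms.append(AtomRecord(idx, "HX", "H", "RES", heavy.residue_id, "A"))
            coords.append(pos + 1.0 * direction)
            heavy.bound_hydrogens = [idx]
            idx += 1
    top = Topology(atoms)
    box_vec = None if box is None else np.full(3, float(box))
    return top, Frame(np.asarray(coords), box_vec)


def random_cloud_trajectory(rng: np.random.Generator, n_frames: int = 6,
                            n_atoms: int = 8, spread: float = 3.0) -> Trajectory:
    atoms = [AtomRecord(i, f"C{i+1}", "C", "CLD", 1, "A") for i in range(n_atoms)]
    top = Topology(atoms)
    frames = [Frame(rng.uniform(-spread, spread, (n_atoms, 3)), time=float(k))
              for k in range(n_frames)]
    return Trajectory(top, frames)
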