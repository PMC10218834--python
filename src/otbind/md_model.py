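"""Data model and file I/O for topologies, frames, trajectories and selections.

Coordinates are always stored in angstrom (GRO files, which store nm, are
converted on read).  Residue ids follow the source file verbatim — analyses
refer to residues by their crystal numbering (e.g. TRP-224), so no
renumbering is ever performed.  Only orthorhombic periodic boxes are
supported; triclinic input raises :class:`StructureError`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "RingSpec",
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "StructureError",
    "SelectionError",
    "ParameterError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
    "assign_parameters",
    "load_parameter_table",
    "assign_bound_hydrogens",
]

# residue-name vocabularies used by the selection keywords
WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP3P", "SPC"}
PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH",
    # the heme prosthetic group belongs to the receptor, not the ligand
    "HEM",
}
ION_RESNAMES = {"NA", "CL", "K", "MG", "CA", "ZN", "NA+", "CL-"}


class StructureError(ValueError):
    """Raised on malformed or unsupported structure/trajectory input."""


class SelectionError(ValueError):
    """Raised on a syntactically invalid selection expression."""


class ParameterError(ValueError):
    """Raised when required force-field parameters are missing."""


@dataclass
class AtomRecord:
    """One atom with its identity and (optional) nonbonded parameters.

    ``charge`` is in elementary charge units, ``lj_sigma`` in angstrom and
    ``lj_epsilon`` in kJ/mol (Lorentz–Berthelot combination is applied at
    energy-evaluation time).  ``bound_hydrogens`` lists the indices of
    hydrogens covalently bound to this (heavy) atom and is what makes the
    atom usable as a hydrogen-bond donor.
    """

    index: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str = "A"
    charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0
    is_donor_heavy: bool = False
    is_acceptor: bool = False
    bound_hydrogens: list[int] = field(default_factory=list)
    parameterized: bool = False

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"atom index must be >= 0, got {self.index}")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError("Lennard-Jones parameters must be non-negative")


@dataclass
class RingSpec:
    """A named aromatic ring given by >= 3 member atoms ordered around it."""

    label: str
    member_atoms: list[int]

    def __post_init__(self) -> None:
        if len(self.member_atoms) < 3:
            raise ValueError(
                f"ring {self.label!r} needs >= 3 member atoms, "
                f"got {len(self.member_atoms)}"
            )


class Topology:
    """Ordered atom list plus bonds, named rings and a residue index."""

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        bonds: Iterable[tuple[int, int]] = (),
        rings: Sequence[RingSpec] = (),
    ):
        self.atoms: list[AtomRecord] = list(atoms)
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise StructureError("duplicate atom indices in topology")
        n = len(self.atoms)
        self._by_index = {a.index: a for a in self.atoms}
        self.bonds: set[tuple[int, int]] = set()
        for i, j in bonds:
            if i not in self._by_index or j not in self._by_index:
                raise StructureError(f"bond ({i},{j}) references missing atom")
            self.bonds.add((min(i, j), max(i, j)))
        self.rings: list[RingSpec] = list(rings)
        for ring in self.rings:
            for m in ring.member_atoms:
                if m not in self._by_index:
                    raise StructureError(
                        f"ring {ring.label!r} references missing atom {m}"
                    )
        for a in self.atoms:
            for h in a.bound_hydrogens:
                if h not in self._by_index:
                    raise StructureError(
                        f"atom {a.index} lists missing bound hydrogen {h}"
                    )
        # residue index: residue_id -> atom indices (file order)
        self.residue_index: dict[int, list[int]] = {}
        for a in self.atoms:
            self.residue_index.setdefault(a.residue_id, []).append(a.index)
        self._n_atoms = n

    @property
    def n_atoms(self) -> int:
        return self._n_atoms

    def atom(self, index: int) -> AtomRecord:
        return self._by_index[index]

    def ring(self, label: str) -> RingSpec:
        for r in self.rings:
            if r.label == label:
                return r
        raise KeyError(f"no ring labeled {label!r}")

    def positions_of(self, indices: Sequence[int]) -> list[int]:
        """Map atom indices to row positions in the coordinate array."""
        pos = {a.index: k for k, a in enumerate(self.atoms)}
        return [pos[i] for i in indices]

    def __len__(self) -> int:
        return self._n_atoms


@dataclass
class Frame:
    """One snapshot: N x 3 coordinates (angstrom), optional box, time in ps."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError("coordinates must be an (N, 3) array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise StructureError("box edge lengths must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Frame":
        box = None if self.box is None else self.box.copy()
        return Frame(self.coordinates.copy(), box, self.time)


class Trajectory:
    """An ordered list of frames sharing one topology."""

    def __init__(
        self,
        topology: Topology,
        frames: Sequence[Frame],
        sampling_interval: float | None = None,
    ):
        frames = list(frames)
        for k, f in enumerate(frames):
            if f.n_atoms != topology.n_atoms:
                raise StructureError(
                    f"frame {k} has {f.n_atoms} atoms, topology has "
                    f"{topology.n_atoms}"
                )
        times = [f.time for f in frames]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise StructureError("frame times must be non-decreasing")
        self.topology = topology
        self.frames = frames
        if sampling_interval is None and len(frames) >= 2:
            dts = np.diff(times)
            if dts.size and np.allclose(dts, dts[0]) and dts[0] > 0:
                sampling_interval = float(dts[0])
        self.sampling_interval = sampling_interval

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, k):
        if isinstance(k, slice):
            return Trajectory(self.topology, self.frames[k])
        return self.frames[k]


@dataclass(frozen=True)
class Selection:
    """An ordered, duplicate-free list of atom indices with provenance."""

    indices: tuple[int, ...]
    expression: str = ""

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise SelectionError("selection contains duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)


# ---------------------------------------------------------------------------
# structure / trajectory I/O (delegated to biotite)
# ---------------------------------------------------------------------------

_PDB_ELEMENTS = {"C", "N", "O", "H", "S", "P", "F", "CL", "BR", "I", "FE", "SN",
                 "NA", "K", "MG", "ZN", "CA", "AR"}


def _infer_element(name: str) -> str:
    """PDB v3 style element inference from the atom name."""
    stripped = name.strip()
    if stripped[:2].upper() in {"SN", "FE", "CL", "BR", "NA", "MG", "ZN"} and \
            len(stripped) >= 2 and not stripped[0].isdigit():
        return stripped[:2].capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _check_orthorhombic(box_vectors: np.ndarray | None) -> np.ndarray | None:
    if box_vectors is None:
        return None
    box_vectors = np.asarray(box_vectors, dtype=float)
    off = box_vectors - np.diag(np.diag(box_vectors))
    if not np.allclose(off, 0.0, atol=1e-6):
        raise StructureError("only orthorhombic boxes are supported")
    edges = np.diag(box_vectors)
    if np.all(edges == 0):
        return None
    return edges.copy()


def _atom_array_to_topology(arr) -> Topology:
    atoms = []
    for k in range(arr.array_length()):
        element = str(arr.element[k]).strip()
        name = str(arr.atom_name[k])
        if not element:
            element = _infer_element(name)
            warnings.warn(
                f"atom {k} ({name}): element missing, inferred {element!r}"
            )
        atoms.append(
            AtomRecord(
                index=k,
                name=name,
                element=element.capitalize() if len(element) > 1 else element,
                residue_name=str(arr.res_name[k]),
                residue_id=int(arr.res_id[k]),
                chain=str(arr.chain_id[k]) or "A",
            )
        )
    return Topology(atoms)


def read_structure(path: str | Path, fmt: str | None = None) -> tuple[Topology, Frame]:
    """Read a single-model PDB or GRO file into (Topology, Frame).

    GRO coordinates (nm) are converted to angstrom.  ``fmt`` defaults to the
    file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    try:
        if fmt == "PDB":
            from biotite.structure.io.pdb import PDBFile

            pdb = PDBFile.read(str(path))
            arr = pdb.get_structure(model=1)
        elif fmt == "GRO":
            from biotite.structure.io.gro import GROFile

            gro = GROFile.read(str(path))
            arr = gro.get_structure(model=1)
        else:
            raise StructureError(f"unsupported structure format {fmt!r}")
    except StructureError:
        raise
    except Exception as exc:  # biotite raises InvalidFileError etc.
        raise StructureError(f"failed to parse {path}: {exc}") from exc
    topology = _atom_array_to_topology(arr)
    box = _check_orthorhombic(arr.box)
    return topology, Frame(np.asarray(arr.coord, dtype=float), box)


def _topology_to_atom_array(topology: Topology, frame: Frame):
    import biotite.structure as struc

    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(frame.coordinates, dtype=np.float32)
    arr.atom_name = np.array([a.name for a in topology.atoms], dtype="U6")
    arr.res_name = np.array([a.residue_name for a in topology.atoms], dtype="U5")
    arr.res_id = np.array([a.residue_id for a in topology.atoms])
    arr.chain_id = np.array([a.chain for a in topology.atoms], dtype="U4")
    arr.element = np.array([a.element.upper() for a in topology.atoms], dtype="U2")
    arr.hetero = np.array(
        [a.residue_name not in PROTEIN_RESNAMES for a in topology.atoms]
    )
    if frame.box is not None:
        arr.box = np.diag(frame.box)
    return arr


def write_structure(path: str | Path, topology: Topology, frame: Frame,
                    fmt: str | None = None) -> None:
    """Write a single frame as PDB or GRO (format from suffix by default)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    arr = _topology_to_atom_array(topology, frame)
    if fmt == "PDB":
        from biotite.structure.io.pdb import PDBFile

        f = PDBFile()
        f.set_structure(arr)
        f.write(str(path))
    elif fmt == "GRO":
        from biotite.structure.io.gro import GROFile

        f = GROFile()
        f.set_structure(arr)
        f.write(str(path))
    else:
        raise StructureError(f"unsupported structure format {fmt!r}")


def read_trajectory(
    path: str | Path,
    topology: Topology | None = None,
    fmt: str | None = None,
    sampling_interval: float | None = None,
) -> Trajectory:
    """Read a multi-model PDB file as a Trajectory.

    Each MODEL block becomes one frame.  Frame times are assigned from
    ``sampling_interval`` (ps) when given, else spaced 1 ps apart; the
    interval is re-inferred from the times by the Trajectory constructor.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt != "PDB":
        raise StructureError(f"unsupported trajectory format {fmt!r}")
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()
    except Exception as exc:
        raise StructureError(f"failed to parse {path}: {exc}") from exc
    if topology is None:
        topology = _atom_array_to_topology(stack[0])
    dt = sampling_interval if sampling_interval is not None else 1.0
    frames = []
    for k in range(stack.stack_depth()):
        coords = np.asarray(stack.coord[k], dtype=float)
        if coords.shape[0] != topology.n_atoms:
            raise StructureError(
                f"frame {k}: atom count {coords.shape[0]} does not match "
                f"topology ({topology.n_atoms})"
            )
        box = _check_orthorhombic(stack.box[k] if stack.box is not None else None)
        frames.append(Frame(coords, box, time=k * dt))
    return Trajectory(topology, frames, sampling_interval=sampling_interval)


def write_trajectory(path: str | Path, trajectory: Trajectory) -> None:
    """Write a trajectory as a multi-model PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arrays = [
        _topology_to_atom_array(trajectory.topology, f) for f in trajectory.frames
    ]
    stack = struc.stack(arrays)
    if arrays[0].box is not None:
        stack.box = np.stack([a.box for a in arrays])
    f = PDBFile()
    f.set_structure(stack)
    f.write(str(Path(path)))


# ---------------------------------------------------------------------------
# selection language
# ---------------------------------------------------------------------------

_KEYWORDS = {"and", "or", "not", "(", ")"}
_FIELDS = {"residue_name", "residue_id", "name", "element",
           "ligand", "water", "protein", "all"}


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(expression):
        ch = expression[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append((ch, i))
            i += 1
            continue
        j = i
        while j < len(expression) and not expression[j].isspace() \
                and expression[j] not in "()":
            j += 1
        tokens.append((expression[i:j], i))
        i = j
    return tokens


class _Parser:
    """Recursive-descent parser for the small selection grammar.

    expr  := term ('or' term)*
    term  := factor ('and' factor)*
    factor:= 'not' factor | '(' expr ')' | predicate
    predicates: residue_name N+, residue_id N ['to' M] ..., name N+,
    element E+, and the keywords ligand / water / protein / all.
    """

    def __init__(self, tokens: list[tuple[str, int]], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        if self.pos >= len(self.tokens):
            raise SelectionError("unexpected end of expression")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> set[int]:
        result = self.expr()
        if self.pos != len(self.tokens):
            tok, at = self.tokens[self.pos]
            raise SelectionError(f"unexpected token {tok!r} at position {at}")
        return result

    def expr(self) -> set[int]:
        result = self.term()
        while self.peek() == "or":
            self.next()
            result = result | self.term()
        return result

    def term(self) -> set[int]:
        result = self.factor()
        while self.peek() == "and":
            self.next()
            result = result & self.factor()
        return result

    def factor(self) -> set[int]:
        tok = self.peek()
        if tok == "not":
            self.next()
            universe = {a.index for a in self.top.atoms}
            return universe - self.factor()
        if tok == "(":
            self.next()
            result = self.expr()
            closing, at = self.next()
            if closing != ")":
                raise SelectionError(f"expected ')' at position {at}")
            return result
        return self.predicate()

    def _values(self) -> list[str]:
        vals = []
        while True:
            tok = self.peek()
            if tok is None or tok in _KEYWORDS or tok in _FIELDS:
                break
            vals.append(self.next()[0])
        if not vals:
            tok, at = self.tokens[self.pos - 1]
            raise SelectionError(
                f"field {tok!r} at position {at} expects at least one value"
            )
        return vals

    def predicate(self) -> set[int]:
        tok, at = self.next()
        atoms = self.top.atoms
        if tok == "residue_name":
            vals = set(self._values())
            return {a.index for a in atoms if a.residue_name in vals}
        if tok == "name":
            vals = set(self._values())
            return {a.index for a in atoms if a.name in vals}
        if tok == "element":
            vals = {v.capitalize() for v in self._values()}
            return {a.index for a in atoms if a.element.capitalize() in vals}
        if tok == "residue_id":
            vals = self._values()
            ids: set[int] = set()
            k = 0
            while k < len(vals):
                if k + 2 < len(vals) and vals[k + 1] == "to":
                    lo, hi = int(vals[k]), int(vals[k + 2])
                    ids.update(range(lo, hi + 1))
                    k += 3
                else:
                    ids.add(int(vals[k]))
                    k += 1
            return {a.index for a in atoms if a.residue_id in ids}
        if tok == "water":
            return {a.index for a in atoms if a.residue_name in WATER_RESNAMES}
        if tok == "protein":
            return {a.index for a in atoms if a.residue_name in PROTEIN_RESNAMES}
        if tok == "ligand":
            return {
                a.index for a in atoms
                if a.residue_name not in WATER_RESNAMES
                and a.residue_name not in PROTEIN_RESNAMES
                and a.residue_name not in ION_RESNAMES
            }
        if tok == "all":
            return {a.index for a in atoms}
        raise SelectionError(f"unknown token {tok!r} at position {at}")


def select(topology: Topology, expression: str) -> Selection:
    """Evaluate a selection expression; returns indices in topology order."""
    tokens = _tokenize(expression)
    if not tokens:
        return Selection((), expression)
    matched = _Parser(tokens, topology).parse()
    ordered = tuple(a.index for a in topology.atoms if a.index in matched)
    return Selection(ordered, expression)


# ---------------------------------------------------------------------------
# parameter assignment
# ---------------------------------------------------------------------------

def load_parameter_table(path: str | Path) -> dict[tuple[str, str], dict[str, float]]:
    """Load a parameter table from CSV or YAML.

    Columns / keys: residue_name, atom_name, charge_e, sigma_A, epsilon_kJmol.
    """
    path = Path(path)
    rows: list[Mapping[str, object]]
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        with open(path) as fh:
            rows = yaml.safe_load(fh)
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    table = {}
    for row in rows:
        key = (str(row["residue_name"]), str(row["atom_name"]))
        table[key] = {
            "charge_e": float(row["charge_e"]),
            "sigma_A": float(row["sigma_A"]),
            "epsilon_kJmol": float(row["epsilon_kJmol"]),
        }
    return table


def assign_parameters(
    topology: Topology,
    parameter_table: Mapping[tuple[str, str], Mapping[str, float]],
) -> Topology:
    """Attach charges and LJ parameters from a (residue_name, atom_name) table.

    Atoms without a table entry keep ``parameterized=False``; energy
    evaluation over such atoms raises :class:`ParameterError` listing them.
    """
    for atom in topology.atoms:
        entry = parameter_table.get((atom.residue_name, atom.name))
        if entry is None:
            atom.parameterized = False
            continue
        atom.charge = float(entry["charge_e"])
        atom.lj_sigma = float(entry["sigma_A"])
        atom.lj_epsilon = float(entry["epsilon_kJmol"])
        atom.parameterized = True
    return topology


def assign_bound_hydrogens(
    topology: Topology, frame: Frame, cutoff: float = 1.25
) -> Topology:
    """Infer X–H bonds by distance and set donor/acceptor flags.

    Heavy N/O atoms within ``cutoff`` angstrom of a hydrogen in the same
    residue become donors; all N/O atoms are flagged as acceptors
    (the convention that X in an X...H contact is an O or N atom).
    """
    coords = frame.coordinates
    for atom in topology.atoms:
        if atom.element.upper() in {"N", "O"}:
            atom.is_acceptor = True
    hydrogens = [a for a in topology.atoms if a.element.upper() == "H"]
    for atom in topology.atoms:
        if atom.element.upper() not in {"N", "O"}:
            continue
        bound = []
        for h in hydrogens:
            if h.residue_id != atom.residue_id:
                continue
            d = np.linalg.norm(coords[atom.index] - coords[h.index])
            if d < cutoff:
                bound.append(h.index)
        if bound:
            atom.bound_hydrogens = bound
            atom.is_donor_heavy = True
    return topology
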