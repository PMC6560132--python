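"""Structure and trajectory I/O.

Trajectories are multi-model PDB files (one MODEL per snapshot, explicit
hydrogens, Å coordinates).  The heavy lifting of parsing/writing the PDB
format is delegated to :mod:`biotite`; this module wraps the result in the
light-weight containers the rest of the pipeline consumes, infers covalent
connectivity from first-frame geometry, and resolves named atom groups
(receptor / ligand / water) from residue-name selectors.

Coordinates are Å, residue numbering is 1-based PDB convention and no
periodic-boundary handling is performed: input molecules must be whole.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .errors import ConfigError, FormatError, SelectionError, TopologyError

Residue = tuple[str, int]  # (chain id, residue sequence number)

#: Covalent radii in Å (Cordero et al. consensus values) for the elements a
#: receptor/glycoside/water system can contain.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "NA": 1.66, "K": 2.03,
    "MG": 1.41, "CA": 1.76, "ZN": 1.22, "FE": 1.32,
}

#: Scale factor applied to the covalent-radius sum when deciding bonding.
BOND_TOLERANCE = 1.3

#: Residue names treated as water by default.
DEFAULT_WATER_NAMES = ("HOH", "WAT", "SOL", "TIP", "TIP3", "SPC")


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    coords: tuple[float, float, float]

    @property
    def residue(self) -> Residue:
        return (self.chain, self.res_seq)


@dataclass
class Topology:
    atoms: list[AtomRecord]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    groups: dict[str, frozenset[int]] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_of(self, index: int) -> Residue:
        return self.atoms[index].residue

    def residues(self, indices: Iterable[int] | None = None) -> list[Residue]:
        """Ordered unique residues among ``indices`` (default: all atoms)."""
        if indices is None:
            indices = range(self.n_atoms)
        seen: dict[Residue, None] = {}
        for i in indices:
            seen.setdefault(self.atoms[i].residue, None)
        return list(seen)

    def res_name_of(self, residue: Residue) -> str:
        for atom in self.atoms:
            if atom.residue == residue:
                return atom.res_name
        raise KeyError(residue)

    def bonded_to(self, index: int) -> list[int]:
        out = []
        for i, j in self.bonds:
            if i == index:
                out.append(j)
            elif j == index:
                out.append(i)
        return sorted(out)

    def bond_index(self) -> dict[int, list[int]]:
        """Adjacency map; cheaper than repeated :meth:`bonded_to` calls."""
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj


@dataclass
class Frame:
    index: int
    time: float  # ns
    coords: np.ndarray  # (n_atoms, 3) Å

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise FormatError(f"frame {self.index}: non-finite coordinates")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]

    def __post_init__(self):
        if not self.frames:
            raise FormatError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for fr in self.frames:
            if fr.coords.shape != (n, 3):
                raise FormatError(
                    f"frame {fr.index} has {fr.coords.shape[0]} atoms, "
                    f"topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def coords_stack(self) -> np.ndarray:
        return np.stack([fr.coords for fr in self.frames])


# ---------------------------------------------------------------------------
# element + bond inference


def infer_element(name: str, res_name: str, element: str = "") -> str:
    """Resolve the chemical element of an atom.

    The PDB element column wins when present; otherwise the first alphabetic
    character of the atom name is used.  Two-letter ambiguity (``CA`` calcium
    vs Cα) is resolved by residue context: inside amino-acid/ligand residues
    the atom is carbon.
    """
    element = element.strip().upper()
    if element:
        return element
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        raise FormatError(f"cannot infer element for atom name {name!r}")
    if stripped in ("CL", "BR", "NA", "MG", "ZN", "FE") and res_name.upper() == stripped:
        return stripped  # bare ion residues keep the two-letter symbol
    return stripped[0]


def infer_bonds(topology: Topology, frame0: Frame) -> set[tuple[int, int]]:
    """Infer covalent bonds from first-frame geometry.

    Two atoms are bonded iff their distance is at most ``BOND_TOLERANCE``
    times the sum of their covalent radii.  Hydrogens are then pruned to a
    single bond with their nearest heavy atom; a hydrogen with no heavy atom
    within 1.5 Å is a topology error.
    """
    from scipy.spatial import cKDTree

    coords = frame0.coords
    elements = [a.element.upper() for a in topology.atoms]
    radii = np.array([COVALENT_RADII.get(e, 0.77) for e in elements])
    tree = cKDTree(coords)
    max_cut = BOND_TOLERANCE * 2 * radii.max()
    pairs = tree.query_pairs(max_cut, output_type="ndarray")
    bonds: set[tuple[int, int]] = set()
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        cut = BOND_TOLERANCE * (radii[pairs[:, 0]] + radii[pairs[:, 1]])
        for (i, j), ok in zip(pairs, d <= cut):
            if ok:
                bonds.add((min(i, j), max(i, j)))

    is_h = np.array([e == "H" for e in elements])
    for h in np.flatnonzero(is_h):
        heavy = [
            (np.linalg.norm(coords[h] - coords[o]), o)
            for o in range(topology.n_atoms)
            if not is_h[o] and np.linalg.norm(coords[h] - coords[o]) <= 1.5
        ]
        if not heavy:
            a = topology.atoms[h]
            raise TopologyError(
                f"hydrogen {a.name} ({a.chain}{a.res_seq}) has no heavy atom "
                "within 1.5 Å"
            )
        nearest = min(heavy)[1]
        bonds = {
            (i, j) for (i, j) in bonds if h not in (i, j)
        }
        bonds.add((min(h, nearest), max(h, nearest)))
    return bonds


# ---------------------------------------------------------------------------
# group resolution


def resolve_groups(
    topology: Topology, group_config: Mapping[str, Sequence[str]] | None
) -> dict[str, frozenset[int]]:
    """Resolve receptor/ligand/water groups from residue-name selectors.

    ``group_config`` maps group names to lists of residue names, e.g.
    ``{"ligand": ["LIG"], "water": ["HOH"]}``.  The receptor group is the
    complement of ligand ∪ water unless configured explicitly.
    """
    cfg = {k: tuple(v) for k, v in (group_config or {}).items()}
    cfg.setdefault("water", DEFAULT_WATER_NAMES)
    groups: dict[str, frozenset[int]] = {}
    assigned: set[int] = set()
    for name, res_names in cfg.items():
        wanted = {r.upper() for r in res_names}
        members = frozenset(
            i for i, a in enumerate(topology.atoms) if a.res_name.upper() in wanted
        )
        groups[name] = members
        assigned |= members
    if "ligand" not in groups:
        raise ConfigError("group config must name the ligand residue(s)")
    if not groups["ligand"]:
        raise ConfigError(
            "ligand group selector matched no atoms; check residue names "
            f"{cfg.get('ligand')}"
        )
    if "receptor" not in groups:
        groups["receptor"] = frozenset(range(topology.n_atoms)) - assigned
    for a, b in (("receptor", "ligand"), ("receptor", "water"), ("ligand", "water")):
        if groups.get(a, frozenset()) & groups.get(b, frozenset()):
            raise ConfigError(f"groups {a!r} and {b!r} overlap")
    return groups


# ---------------------------------------------------------------------------
# PDB reading / writing


def _scan_model_atom_counts(text: str) -> list[int]:
    counts, current, in_model, seen_model = [], 0, False, False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            seen_model, in_model, current = True, True, 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
    if not seen_model:
        counts.append(current)
    elif in_model:
        counts.append(current)
    return counts


def read_multimodel_pdb(
    path: str | Path,
    group_config: Mapping[str, Sequence[str]] | None = None,
    dt: float | None = None,
    total_time: float = 800.0,
) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Frame times are not stored in PDB files; they are reconstructed as
    ``index * dt`` (ns).  When ``dt`` is not given it defaults to
    ``total_time / n_frames`` so that a full-length trajectory spans
    ``total_time`` ns (0.8 μs by default).

    Raises :class:`FormatError` naming the offending MODEL when atom counts
    are inconsistent across models.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    counts = _scan_model_atom_counts(text)
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise FormatError(
            f"{path.name}: MODEL {bad} has {counts[bad - 1]} atoms, "
            f"MODEL 1 has {counts[0]}"
        )
    pdb_file = pdbio.PDBFile.read(io.StringIO(text))
    stack = pdb_file.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # single implicit model
        stack = struc.stack([stack])

    atoms: list[AtomRecord] = []
    first = stack[0]
    for i in range(stack.array_length()):
        name = str(first.atom_name[i])
        res_name = str(first.res_name[i])
        element = infer_element(name, res_name, str(first.element[i]))
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=name,
                element=element,
                res_name=res_name,
                res_seq=int(first.res_id[i]),
                chain=str(first.chain_id[i]) or "A",
                coords=tuple(np.asarray(first.coord[i], dtype=float)),
            )
        )
    topology = Topology(atoms=atoms)
    n_frames = stack.stack_depth()
    if dt is None:
        dt = total_time / n_frames
    frames = [
        Frame(index=k, time=k * dt, coords=np.asarray(stack.coord[k], dtype=float))
        for k in range(n_frames)
    ]
    traj = Trajectory(topology=topology, frames=frames)
    topology.bonds = infer_bonds(topology, frames[0])
    topology.groups = resolve_groups(topology, group_config)
    return traj


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL per frame)."""
    top = traj.topology
    n = top.n_atoms
    template = struc.AtomArray(n)
    template.chain_id = np.array([a.chain for a in top.atoms])
    template.res_id = np.array([a.res_seq for a in top.atoms])
    template.res_name = np.array([a.res_name for a in top.atoms])
    template.atom_name = np.array([a.name for a in top.atoms])
    template.element = np.array([a.element for a in top.atoms])
    template.hetero = np.array(
        [i not in top.groups.get("receptor", frozenset()) for i in range(n)]
    )
    arrays = []
    for fr in traj.frames:
        arr = template.copy()
        arr.coord = np.asarray(fr.coords, dtype=np.float32)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# selection mini-language


def select(
    topology: Topology, expression: str, allow_empty: bool = False
) -> frozenset[int]:
    """Resolve a selector expression to an atom-index set.

    Grammar (whitespace separated)::

        expr    := term ("or" term)*
        term    := atom ("and" atom)*
        atom    := "(" expr ")" | "element" SYM | "resseq" N | "resseq" N-M
                   | GROUP_NAME

    Example: ``"resseq 85-93 and receptor"``.
    """
    tokens: list[tuple[str, int]] = []
    pos = 0
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        pos = expression.find(raw, pos)
        tokens.append((raw, pos))
        pos += len(raw)

    universe = frozenset(range(topology.n_atoms))
    cursor = 0

    def fail(msg: str, at: int) -> None:
        raise SelectionError(f"{msg} at position {at}: {expression!r}")

    def parse_expr() -> frozenset[int]:
        nonlocal cursor
        result = parse_term()
        while cursor < len(tokens) and tokens[cursor][0].lower() == "or":
            cursor += 1
            result = result | parse_term()
        return result

    def parse_term() -> frozenset[int]:
        nonlocal cursor
        result = parse_atom()
        while cursor < len(tokens) and tokens[cursor][0].lower() == "and":
            cursor += 1
            result = result & parse_atom()
        return result

    def parse_atom() -> frozenset[int]:
        nonlocal cursor
        if cursor >= len(tokens):
            fail("unexpected end of expression", len(expression))
        word, at = tokens[cursor]
        low = word.lower()
        cursor += 1
        if word == "(":
            inner = parse_expr()
            if cursor >= len(tokens) or tokens[cursor][0] != ")":
                fail("missing closing parenthesis", at)
            cursor += 1
            return inner
        if low == "element":
            if cursor >= len(tokens):
                fail("element filter needs a symbol", at)
            sym, _ = tokens[cursor]
            cursor += 1
            sym = sym.upper()
            return frozenset(
                i for i, a in enumerate(topology.atoms) if a.element.upper() == sym
            )
        if low == "resseq":
            if cursor >= len(tokens):
                fail("resseq needs a number or range", at)
            spec, spec_at = tokens[cursor]
            cursor += 1
            try:
                if "-" in spec:
                    lo, hi = (int(x) for x in spec.split("-", 1))
                else:
                    lo = hi = int(spec)
            except ValueError:
                fail(f"bad residue range {spec!r}", spec_at)
            return frozenset(
                i for i, a in enumerate(topology.atoms) if lo <= a.res_seq <= hi
            )
        if low == "all":
            return universe
        if low in topology.groups:
            return topology.groups[low]
        fail(f"unknown selector token {word!r}", at)

    result = parse_expr()
    if cursor != len(tokens):
        fail(f"unexpected token {tokens[cursor][0]!r}", tokens[cursor][1])
    if not result and not allow_empty:
        raise SelectionError(f"selection {expression!r} matched no atoms")
    return result
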