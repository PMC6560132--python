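"""Self-contained toy complexes with programmed, known-truth contact schedules.

The generator emulates the geometry of a bitter-taste-receptor binding
cavity at cartoon level: two (or more) facing pseudo-helices whose upper
residues are polar (serine-like hydroxyls) and whose lower residues are
hydrophobic (leucine-like side chains), a glycoside-like ligand (pyranose
ring of C/O with hydroxyls plus an aliphatic aglycon tail) at the cavity
centre, and a shell of distant water molecules.

Contacts are *planted*: a schedule names, per residue and interaction kind,
a target persistency, and the generator poses the residue's interacting
atoms to satisfy the geometric criteria with a wide margin (D–A 2.9 Å and
collinear; C–C 4.5 Å) in exactly ``round(target × analysed frames)`` frames,
and to violate them by ≥ 1 Å everywhere else.  "On" frames are placed
deterministically (evenly spaced over the analysed window), so the realised
persistency is exact and threshold-boundary tests are meaningful.  There is
no physical realism — no force field, no sterics — the generator tests the
analysis, not the simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import HBOND_DIRECT, HBOND_WATER, HYDROPHOBIC
from .errors import ConfigError, ScheduleError
from .structure_io import (
    AtomRecord,
    Frame,
    Residue,
    Topology,
    Trajectory,
    infer_bonds,
    resolve_groups,
)

# geometry margins: contacts are posed 0.6-1 Å inside the cutoffs and the
# resting layout keeps every group ≥ 1 Å outside them.
HB_ON_DIST = 2.9
HB_BRIDGE_DIST = 2.8
HP_ON_DIST = 4.5
OH_BOND = 0.96

LIGAND_HB_TARGETS = ("O3", "O2", "O4", "O1")
LIGAND_HP_TARGETS = ("C7", "C8", "C9", "C6")


@dataclass(frozen=True)
class ToySystemSpec:
    """Layout of the toy receptor-ligand-water bundle."""

    n_helices: int = 2
    polar_top_residues: int = 4
    hydrophobic_bottom_residues: int = 4
    n_waters: int = 6
    helix_radius: float = 13.0
    polar_res_seqs: tuple[int, ...] | None = None
    hydrophobic_res_seqs: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.n_helices < 1:
            raise ConfigError("need at least one pseudo-helix")
        if self.polar_top_residues + self.hydrophobic_bottom_residues < 1:
            raise ConfigError("receptor needs at least one residue")
        for seqs, n in (
            (self.polar_res_seqs, self.polar_top_residues),
            (self.hydrophobic_res_seqs, self.hydrophobic_bottom_residues),
        ):
            if seqs is not None and len(seqs) != n:
                raise ConfigError("residue-number override length mismatch")


def _ligand_atoms() -> list[tuple[str, str, np.ndarray]]:
    """Glycoside-like template: pyranose ring + hydroxyls + aglycon carbons."""
    atoms: list[tuple[str, str, np.ndarray]] = []
    ring_names = ("C1", "C2", "C3", "C4", "C5", "O5")
    r_ring, r_sub = 1.45, 2.85
    for k, name in enumerate(ring_names):
        ang = math.radians(60 * k)
        atoms.append(
            (name, name[0], np.array([r_ring * math.cos(ang), r_ring * math.sin(ang), 0.0]))
        )
    for k in range(4):  # hydroxyls on C1..C4
        ang = math.radians(60 * k)
        u = np.array([math.cos(ang), math.sin(ang), 0.0])
        o = r_sub * u
        atoms.append((f"O{k + 1}", "O", o))
        atoms.append((f"HO{k + 1}", "H", o + OH_BOND * u))
    # exocyclic C6-O6 on C5
    ang = math.radians(240)
    u = np.array([math.cos(ang), math.sin(ang), 0.0])
    c6 = 2.95 * u
    o6 = c6 + 1.4 * u
    atoms.append(("C6", "C", c6))
    atoms.append(("O6", "O", o6))
    atoms.append(("HO6", "H", o6 + OH_BOND * u))
    # aglycon tail below C1
    c1 = np.array([r_ring, 0.0, 0.0])
    atoms.append(("C7", "C", c1 + np.array([0.0, 0.0, -1.5])))
    atoms.append(("C8", "C", c1 + np.array([0.8, 0.0, -2.7])))
    atoms.append(("C9", "C", c1 + np.array([-0.8, 0.0, -2.7])))
    return atoms


def build_toy_complex(
    spec: ToySystemSpec = ToySystemSpec(), seed: int = 0
) -> tuple[Topology, Frame]:
    """Deterministic toy complex: topology with groups/bonds plus frame 0.

    Polar residues (SER-like: CA-OG-HG) occupy the upper half of each
    helix, hydrophobic ones (LEU-like: CA-CB-CG) the lower half.  A small
    seeded jitter (±0.02 Å) decorrelates exact coordinates between seeds
    without eroding the placement margins.
    """
    rng = np.random.default_rng(seed)
    records: list[AtomRecord] = []
    serial = 0

    def add(name, element, res_name, res_seq, chain, pos):
        nonlocal serial
        serial += 1
        pos = np.asarray(pos, dtype=float) + rng.uniform(-0.02, 0.02, 3)
        records.append(
            AtomRecord(serial, name, element, res_name, res_seq, chain, tuple(pos))
        )

    polar_ids = (
        spec.polar_res_seqs
        if spec.polar_res_seqs is not None
        else tuple(range(1, spec.polar_top_residues + 1))
    )
    hydro_ids = (
        spec.hydrophobic_res_seqs
        if spec.hydrophobic_res_seqs is not None
        else tuple(
            range(
                spec.polar_top_residues + 1,
                spec.polar_top_residues + spec.hydrophobic_bottom_residues + 1,
            )
        )
    )
    if set(polar_ids) & set(hydro_ids):
        raise ConfigError("polar and hydrophobic residue numbers overlap")

    R = spec.helix_radius
    for k, res_seq in enumerate(polar_ids):
        helix = k % spec.n_helices
        phi = 2 * math.pi * helix / spec.n_helices
        axis = np.array([math.cos(phi), math.sin(phi), 0.0])
        z = 1.5 * (k // spec.n_helices + 1)
        ca = R * axis + np.array([0.0, 0.0, z])
        og = ca - 1.4 * axis
        add("CA", "C", "SER", res_seq, "A", ca)
        add("OG", "O", "SER", res_seq, "A", og)
        add("HG", "H", "SER", res_seq, "A", og - OH_BOND * axis)
    for k, res_seq in enumerate(hydro_ids):
        helix = k % spec.n_helices
        phi = 2 * math.pi * helix / spec.n_helices
        axis = np.array([math.cos(phi), math.sin(phi), 0.0])
        z = -1.5 * (k // spec.n_helices + 1)
        ca = R * axis + np.array([0.0, 0.0, z])
        add("CA", "C", "LEU", res_seq, "A", ca)
        add("CB", "C", "LEU", res_seq, "A", ca - 1.5 * axis)
        add("CG", "C", "LEU", res_seq, "A", ca - 3.0 * axis)

    for name, element, pos in _ligand_atoms():
        add(name, element, "LIG", 1, "L", pos)

    per_ring = 30
    for w in range(spec.n_waters):
        ang = 2 * math.pi * (w % per_ring) / per_ring
        z = 6.0 + 3.0 * (w // per_ring)
        o = np.array([22.0 * math.cos(ang), 22.0 * math.sin(ang), z])
        add("O", "O", "HOH", w + 1, "W", o)
        add("H1", "H", "HOH", w + 1, "W", o + np.array([OH_BOND, 0.0, 0.0]))
        add("H2", "H", "HOH", w + 1, "W", o + np.array([-0.2403, 0.9293, 0.0]))

    topology = Topology(atoms=records)
    frame0 = Frame(index=0, time=0.0, coords=np.array([a.coords for a in records]))
    topology.bonds = infer_bonds(topology, frame0)
    topology.groups = resolve_groups(
        topology, {"ligand": ["LIG"], "water": ["HOH"]}
    )
    if not topology.groups["receptor"]:
        raise ConfigError("toy spec produced an empty receptor group")
    return topology, frame0


@dataclass(frozen=True)
class ScheduleEntry:
    residue: Residue
    kind: str
    target: float
    pattern: str = "even"  # "even" | "head"

    def __post_init__(self):
        if self.kind not in (HBOND_DIRECT, HBOND_WATER, HYDROPHOBIC):
            raise ScheduleError(f"unknown interaction kind {self.kind!r}")
        if not 0.0 <= self.target <= 1.0:
            raise ScheduleError("target persistency must lie in [0, 1]")
        if self.pattern not in ("even", "head"):
            raise ScheduleError(f"unknown phase pattern {self.pattern!r}")


@dataclass
class ContactSchedule:
    entries: list[ScheduleEntry]
    n_frames: int = 160
    dt: float = 5.0  # ns per frame -> 160 frames span 0.8 us
    exclude_time: float = 100.0
    seed: int = 0

    def analysed_indices(self) -> list[int]:
        return [i for i in range(self.n_frames) if i * self.dt >= self.exclude_time]

    def on_frames(self, entry: ScheduleEntry) -> list[int]:
        analysed = self.analysed_indices()
        n = len(analysed)
        k = round(entry.target * n)
        if entry.pattern == "head":
            return analysed[:k]
        return [analysed[(j * n) // k] for j in range(k)] if k else []


def _atom_index(topology: Topology, residue: Residue, name: str) -> int:
    for i, a in enumerate(topology.atoms):
        if a.residue == residue and a.name == name:
            return i
    raise ScheduleError(f"residue {residue} has no atom {name!r}")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_trajectory(
    topology: Topology,
    frame0: Frame,
    schedule: ContactSchedule,
) -> tuple[Trajectory, dict[Residue, dict[str, float]]]:
    """Trajectory realising the schedule, plus the exact ground truth.

    Returns the trajectory and a map residue -> kind -> realised persistency
    (the fraction over the analysed window that the pipeline should recover
    exactly).  Entries that would move the same residue in the same frame
    conflict and raise :class:`ScheduleError`.
    """
    analysed = schedule.analysed_indices()
    if not analysed:
        raise ScheduleError("schedule leaves no analysed frames")

    lig_atoms = {
        topology.atoms[i].name: i for i in topology.groups["ligand"]
    }
    water_residues = topology.residues(topology.groups.get("water", frozenset()))

    # resolve moving atoms and targets per entry, detect conflicts
    plans = []
    claimed: dict[tuple[Residue, int], str] = {}
    hb_cycle = hp_cycle = bridge_count = 0
    for entry in schedule.entries:
        on = set(schedule.on_frames(entry))
        for fr in on:
            key = (entry.residue, fr)
            if key in claimed:
                raise ScheduleError(
                    f"conflicting schedule entries for residue {entry.residue} "
                    f"at frame {fr} ({claimed[key]} vs {entry.kind})"
                )
            claimed[key] = entry.kind
        if entry.kind in (HBOND_DIRECT, HBOND_WATER):
            target_name = LIGAND_HB_TARGETS[hb_cycle % len(LIGAND_HB_TARGETS)]
            hb_cycle += 1
            og = _atom_index(topology, entry.residue, "OG")
            hg = _atom_index(topology, entry.residue, "HG")
            water = None
            if entry.kind == HBOND_WATER:
                if bridge_count >= len(water_residues):
                    raise ScheduleError(
                        "more water-bridge entries than water molecules"
                    )
                wres = water_residues[bridge_count]
                bridge_count += 1
                water = tuple(
                    _atom_index(topology, wres, n) for n in ("O", "H1", "H2")
                )
            plans.append((entry, on, lig_atoms[target_name], (og, hg), water))
        else:
            target_name = LIGAND_HP_TARGETS[hp_cycle % len(LIGAND_HP_TARGETS)]
            hp_cycle += 1
            cb = _atom_index(topology, entry.residue, "CB")
            cg = _atom_index(topology, entry.residue, "CG")
            plans.append((entry, on, lig_atoms[target_name], (cb, cg), None))

    base = frame0.coords
    lig_center = base[sorted(topology.groups["ligand"])].mean(axis=0)
    frames = []
    for i in range(schedule.n_frames):
        coords = base.copy()
        for entry, on, target_idx, moving, water in plans:
            if i not in on:
                continue
            target = base[target_idx]
            home = base[moving[0]]
            u = _unit(home - target)
            if entry.kind == HBOND_DIRECT:
                og, hg = moving
                coords[og] = target + HB_ON_DIST * u
                coords[hg] = coords[og] - OH_BOND * u
            elif entry.kind == HBOND_WATER:
                og, hg = moving
                wo, wh1, wh2 = water
                # pose the bridge chain radially outward from the ligand
                # centre so the receptor hydroxyl stays clear of the other
                # ligand oxygens (> cutoff + 1 Å)
                if np.linalg.norm(target - lig_center) > 1e-6:
                    u = _unit(target - lig_center)
                coords[wo] = target + HB_BRIDGE_DIST * u
                coords[wh1] = coords[wo] - OH_BOND * u  # donates to the ligand
                perp = _unit(np.cross(u, [0.0, 0.0, 1.0]))
                if not np.all(np.isfinite(perp)):
                    perp = np.array([1.0, 0.0, 0.0])
                coords[wh2] = coords[wo] + OH_BOND * perp
                coords[og] = coords[wo] + HB_ON_DIST * u
                coords[hg] = coords[og] - OH_BOND * u  # donates to the water
            else:
                cb, cg = moving
                coords[cb] = target + HP_ON_DIST * u
                coords[cg] = coords[cb] + 1.5 * u
        frames.append(Frame(index=i, time=i * schedule.dt, coords=coords))

    truth: dict[Residue, dict[str, float]] = {}
    n_analysed = len(analysed)
    for res in topology.residues(topology.groups["receptor"]):
        truth[res] = {HBOND_DIRECT: 0.0, HBOND_WATER: 0.0, HYDROPHOBIC: 0.0}
    for entry, on, _, _, _ in plans:
        truth[entry.residue][entry.kind] = len(on) / n_analysed
    return Trajectory(topology=topology, frames=frames), truth


# ---------------------------------------------------------------------------
# in-text annotation and call-set fixtures

ANNOTATION_ROWS = [
    # chain, res_seq, res_name, bw, mutations, ec50_affected, region, notes
    ("A", 86, "GLU", "3.33", "E86Q;E86D", True, "upper_extracellular",
     "EC50 ratio 2.9-5.7 (Q) and 7.9-18.4 (D)"),
    ("A", 89, "ASN", "3.36", "N89A", True, "upper_extracellular",
     "mutation abolishes activity for all three agonists"),
    ("A", 93, "PHE", "3.40", "F93A", True, "upper_extracellular",
     "EC50 decreased 19-55 fold"),
    ("A", 177, "GLN", "5.39", "Q177N;Q177E;Q177A", False, "upper_extracellular",
     "EC50 ratio only 0.9-2.9"),
    ("A", 181, "HIS", "5.43", "H181T;H181L", True, "upper_extracellular",
     "H181T ratio 2-8.5; H181L abolishes response for 2/3 ligands"),
    ("A", 240, "PHE", "6.52", "F240Y;F240W;F240L", True, "upper_extracellular",
     "Y/W ratio 6.5-11; L abolishes activity"),
    ("A", 243, "ILE", "6.55", "I243L;I243V;I243A", True, "upper_extracellular",
     "L/V ratio 2.0-5.2; A abolishes response"),
]

# synthetic/extended fixture: additional mutants whose membership in the
# scored panel is not resolvable from the main text; response-amplitude
# effects are encoded as ec50_affected=False.
ANNOTATION_ROWS_EXTENDED = ANNOTATION_ROWS + [
    ("A", 85, "TRP", "3.32", "W85R", False, "upper_extracellular",
     "extended set: reduces maximum response"),
    ("A", 59, "LEU", "2.53", "L59A", False, "upper_extracellular",
     "extended set: response reduced to 64%"),
    ("A", 236, "PHE", "6.48", "F236A", False, "upper_extracellular",
     "extended set: response reduced to 2%"),
    ("A", 262, "GLU", "7.39", "E262D;E262A", True, "upper_extracellular",
     "extended set: E262A abolishes activation"),
    ("A", 265, "VAL", "7.42", "V265A", False, "upper_extracellular",
     "extended set: response reduced to 5%"),
]

#: Computational binding calls (annotated residues only) per complex,
#: reproducing every cell of the published precision/recall table.
COMPLEX_CALL_FIXTURES: dict[str, tuple[int, ...]] = {
    "PGP_dock": (),
    "PGP_TM3": (86, 89, 93, 177, 181, 240),
    "PGP_TM7": (86, 89, 93, 177, 181, 240),
    "ARB_TM3": (86, 89, 93, 177, 181),
    "ARB_TM7": (86, 89, 93, 177, 181, 240),
    "SAL_TM3": (86, 89, 93, 181),
    "SAL_TM7": (86, 89, 93, 181),
}

ANNOTATION_COLUMNS = (
    "chain", "res_seq", "res_name", "bw", "mutations", "ec50_affected",
    "region", "notes",
)


def annotation_frame(extended: bool = False) -> pd.DataFrame:
    rows = ANNOTATION_ROWS_EXTENDED if extended else ANNOTATION_ROWS
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df["ec50_affected"] = df["ec50_affected"].map({True: "true", False: "false"})
    return df


def make_annotation_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the annotation CSVs and per-complex computational call fixtures.

    Returns a map of fixture name -> path.  The call fixtures list, for each
    complex, the binding/non-binding call on every annotated residue.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = out_dir / "htas2r16_annotations.csv"
    annotation_frame().to_csv(p, index=False)
    paths["annotations"] = p
    p = out_dir / "htas2r16_annotations_extended.csv"
    annotation_frame(extended=True).to_csv(p, index=False)
    paths["annotations_extended"] = p

    annotated = [row[1] for row in ANNOTATION_ROWS]
    for name, binding in COMPLEX_CALL_FIXTURES.items():
        df = pd.DataFrame(
            {
                "chain": "A",
                "res_seq": annotated,
                "call": [
                    "binding" if r in binding else "non_binding"
                    for r in annotated
                ],
            }
        )
        p = out_dir / f"calls_{name}.csv"
        df.to_csv(p, index=False)
        paths[f"calls_{name}"] = p
    return paths


def load_call_fixture(path: str | Path):
    """Read a computational call fixture CSV into a ResidueCallSet."""
    from .classification import ResidueCallSet

    df = pd.read_csv(path, dtype={"chain": str, "res_seq": int, "call": str})
    calls = {
        (row.chain, int(row.res_seq)): row.call
        for row in df.itertuples(index=False)
    }
    return ResidueCallSet(calls=calls, mode="fixture", provenance={"path": str(path)})
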