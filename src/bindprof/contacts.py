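"""Per-frame geometric contact detection between receptor and ligand.

Three interaction kinds are detected:

* **Direct hydrogen bonds** — donor–acceptor distance ≤ 3.5 Å and
  donor–hydrogen–acceptor angle within 30° of linearity (i.e. ≥ 150°,
  measured at the hydrogen).
* **Water-mediated hydrogen bonds** — the same geometric criteria, with one
  water molecule simultaneously hydrogen-bonded (in either donor or acceptor
  role) to a receptor residue and to the ligand within the same frame.
* **Hydrophobic contacts** — minimum carbon–carbon distance ≤ 5.5 Å (the sum
  of two carbon van der Waals radii plus the diameter of a water molecule).

All boundary comparisons are inclusive.  Donor/acceptor typing is restricted
to N and O atoms; donors require at least one bonded hydrogen.  Events are
always keyed by the receptor residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, TopologyError
from .structure_io import Frame, Residue, Topology

HBOND_DIRECT = "hbond_direct"
HBOND_WATER = "hbond_water"
HYDROPHOBIC = "hydrophobic"
KINDS = (HBOND_DIRECT, HBOND_WATER, HYDROPHOBIC)


@dataclass(frozen=True)
class HBondParams:
    """Geometric hydrogen-bond criteria.

    ``d_max`` is the donor–acceptor distance cutoff in Å; ``theta_dev_max``
    the allowed deviation (degrees) of the D–H–A angle from linearity.
    """

    d_max: float = 3.5
    theta_dev_max: float = 30.0

    def __post_init__(self):
        if self.d_max <= 0:
            raise ConfigError("H-bond distance cutoff must be positive")
        if not 0 < self.theta_dev_max < 90:
            raise ConfigError("H-bond angle deviation must be in (0, 90)")

    @property
    def theta_min(self) -> float:
        return 180.0 - self.theta_dev_max


@dataclass(frozen=True)
class HydrophobicParams:
    """Minimum-distance cutoff (Å) between carbon atoms."""

    d_max: float = 5.5

    def __post_init__(self):
        if self.d_max <= 0:
            raise ConfigError("hydrophobic distance cutoff must be positive")


@dataclass(frozen=True)
class ContactEvent:
    kind: str
    residue: Residue
    partner_atoms: tuple[int, ...]
    distance: float
    angle: float | None = None
    water_index: int | None = None  # bridging water res_seq for hbond_water


@dataclass
class FrameContacts:
    frame_index: int
    events: list[ContactEvent] = field(default_factory=list)

    def residues(self, kind: str) -> set[Residue]:
        return {e.residue for e in self.events if e.kind == kind}

    def collapsed(self) -> "FrameContacts":
        """Keep one event per (kind, residue) — the closest-distance one."""
        best: dict[tuple[str, Residue], ContactEvent] = {}
        for e in self.events:
            key = (e.kind, e.residue)
            if key not in best or e.distance < best[key].distance:
                best[key] = e
        return FrameContacts(self.frame_index, list(best.values()))


@dataclass
class PolarTyping:
    """Donor (heavy, hydrogen) pairs and acceptor indices for a topology."""

    donors: list[tuple[int, int]]
    acceptors: list[int]


def typed_polar_atoms(topology: Topology) -> PolarTyping:
    """Type hydrogen-bond donors and acceptors.

    Donors are N/O atoms with ≥ 1 bonded hydrogen (one entry per bonded
    hydrogen); acceptors are all N/O atoms.  The same rule applies to
    receptor, ligand and water atoms alike.
    """
    if not any(a.element.upper() == "H" for a in topology.atoms):
        raise TopologyError(
            "H-bond analysis requires explicit hydrogens; the structure "
            "contains none"
        )
    adj = topology.bond_index()
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    for i, atom in enumerate(topology.atoms):
        if atom.element.upper() not in ("N", "O"):
            continue
        acceptors.append(i)
        for j in adj[i]:
            if topology.atoms[j].element.upper() == "H":
                donors.append((i, j))
    return PolarTyping(donors, acceptors)


def _dha_angles(coords: np.ndarray, d: np.ndarray, h: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Angle (degrees) at the hydrogen for stacked (D, H, A) index arrays."""
    v1 = coords[d] - coords[h]
    v2 = coords[a] - coords[h]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    cosang = np.einsum("ij,ij->i", v1, v2) / np.maximum(n1 * n2, 1e-12)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _hbond_pairs(
    coords: np.ndarray,
    donors: Sequence[tuple[int, int]],
    acceptor_idx: Sequence[int],
    params: HBondParams,
) -> list[tuple[int, int, int, float, float]]:
    """All (D, H, A) triples satisfying the criteria.

    Returns tuples (donor, hydrogen, acceptor, distance, angle).  Uses a
    KD-tree on the acceptors; equivalent to the exhaustive all-pairs search.
    """
    if not donors or not len(acceptor_idx):
        return []
    acceptor_idx = np.asarray(acceptor_idx, dtype=int)
    d_idx = np.array([d for d, _ in donors], dtype=int)
    h_idx = np.array([h for _, h in donors], dtype=int)
    tree = cKDTree(coords[acceptor_idx])
    hits = tree.query_ball_point(coords[d_idx], params.d_max)
    out: list[tuple[int, int, int, float, float]] = []
    di, hi, ai = [], [], []
    for k, neighbours in enumerate(hits):
        for n in neighbours:
            a = int(acceptor_idx[n])
            if a == d_idx[k]:
                continue
            di.append(d_idx[k])
            hi.append(h_idx[k])
            ai.append(a)
    if not di:
        return []
    di, hi, ai = np.array(di), np.array(hi), np.array(ai)
    dist = np.linalg.norm(coords[di] - coords[ai], axis=1)
    ang = _dha_angles(coords, di, hi, ai)
    ok = (dist <= params.d_max) & (ang >= params.theta_min)
    for d, h, a, r, t in zip(di[ok], hi[ok], ai[ok], dist[ok], ang[ok]):
        out.append((int(d), int(h), int(a), float(r), float(t)))
    return out


def _split_typing(typing: PolarTyping, members: frozenset[int]):
    donors = [(d, h) for d, h in typing.donors if d in members]
    acceptors = [a for a in typing.acceptors if a in members]
    return donors, acceptors


def find_hbonds(
    frame: Frame,
    topology: Topology,
    typing: PolarTyping,
    params: HBondParams = HBondParams(),
    group_a: str = "receptor",
    group_b: str = "ligand",
) -> list[ContactEvent]:
    """Direct hydrogen bonds between ``group_a`` and ``group_b``.

    Both donor directions are considered (A-donor → B-acceptor and
    B-donor → A-acceptor); events are keyed by the ``group_a`` residue.
    """
    ga, gb = topology.groups[group_a], topology.groups[group_b]
    coords = frame.coords
    events: list[ContactEvent] = []
    don_a, acc_a = _split_typing(typing, ga)
    don_b, acc_b = _split_typing(typing, gb)
    for d, h, a, dist, ang in _hbond_pairs(coords, don_a, acc_b, params):
        events.append(
            ContactEvent(HBOND_DIRECT, topology.residue_of(d), (d, h, a), dist, ang)
        )
    for d, h, a, dist, ang in _hbond_pairs(coords, don_b, acc_a, params):
        events.append(
            ContactEvent(HBOND_DIRECT, topology.residue_of(a), (d, h, a), dist, ang)
        )
    return events


def find_water_bridges(
    frame: Frame,
    topology: Topology,
    typing: PolarTyping,
    params: HBondParams = HBondParams(),
    receptor_group: str = "receptor",
    ligand_group: str = "ligand",
    water_group: str = "water",
) -> list[ContactEvent]:
    """Water-mediated hydrogen bonds.

    A bridge is reported for receptor residue R when one water molecule W
    simultaneously satisfies the H-bond criteria (donor or acceptor role)
    with ≥ 1 atom of R and ≥ 1 ligand atom.  The bridging water's residue
    number is recorded.  An empty water group yields an empty list.
    """
    waters = topology.groups.get(water_group, frozenset())
    if not waters:
        return []
    coords = frame.coords
    rec, lig = topology.groups[receptor_group], topology.groups[ligand_group]
    don_w, acc_w = _split_typing(typing, waters)
    don_r, acc_r = _split_typing(typing, rec)
    don_l, acc_l = _split_typing(typing, lig)

    # receptor residue <-> water residue hbond pairs (either role)
    rw_pairs: dict[Residue, set[Residue]] = {}
    geom: dict[tuple[Residue, Residue], tuple[tuple[int, ...], float, float]] = {}
    for d, h, a, dist, ang in _hbond_pairs(coords, don_r, acc_w, params):
        rres, wres = topology.residue_of(d), topology.residue_of(a)
        rw_pairs.setdefault(rres, set()).add(wres)
        geom.setdefault((rres, wres), ((d, h, a), dist, ang))
    for d, h, a, dist, ang in _hbond_pairs(coords, don_w, acc_r, params):
        rres, wres = topology.residue_of(a), topology.residue_of(d)
        rw_pairs.setdefault(rres, set()).add(wres)
        geom.setdefault((rres, wres), ((d, h, a), dist, ang))

    # water residues hbonded to the ligand (either role)
    lw: set[Residue] = set()
    for d, h, a, _, _ in _hbond_pairs(coords, don_l, acc_w, params):
        lw.add(topology.residue_of(a))
    for d, h, a, _, _ in _hbond_pairs(coords, don_w, acc_l, params):
        lw.add(topology.residue_of(d))

    events: list[ContactEvent] = []
    for rres, bridging in rw_pairs.items():
        for wres in sorted(bridging & lw):
            atoms, dist, ang = geom[(rres, wres)]
            events.append(
                ContactEvent(
                    HBOND_WATER, rres, atoms, dist, ang, water_index=wres[1]
                )
            )
    return events


def find_hydrophobic_contacts(
    frame: Frame,
    topology: Topology,
    params: HydrophobicParams = HydrophobicParams(),
    receptor_group: str = "receptor",
    ligand_group: str = "ligand",
    carbons_only: bool = True,
) -> list[ContactEvent]:
    """Hydrophobic contacts: per-residue minimum C–C distance ≤ cutoff.

    With ``carbons_only=False`` all heavy atoms enter the minimum-distance
    computation instead of carbons alone.
    """

    def keep(i: int) -> bool:
        e = topology.atoms[i].element.upper()
        return e == "C" if carbons_only else e != "H"

    lig = [i for i in topology.groups[ligand_group] if keep(i)]
    if not lig:
        raise ConfigError("ligand has no carbon atoms for hydrophobic analysis")
    rec = [i for i in topology.groups[receptor_group] if keep(i)]
    if not rec:
        return []
    coords = frame.coords
    tree = cKDTree(coords[np.asarray(lig)])
    dmin, jmin = tree.query(coords[np.asarray(rec)], k=1)
    best: dict[Residue, tuple[float, int, int]] = {}
    for r, d, j in zip(rec, dmin, jmin):
        res = topology.residue_of(r)
        if res not in best or d < best[res][0]:
            best[res] = (float(d), r, lig[int(j)])
    return [
        ContactEvent(HYDROPHOBIC, res, (r, l), d)
        for res, (d, r, l) in best.items()
        if d <= params.d_max
    ]


def compute_frame_contacts(
    frame: Frame,
    topology: Topology,
    typing: PolarTyping,
    hb_params: HBondParams = HBondParams(),
    hp_params: HydrophobicParams = HydrophobicParams(),
    carbons_only: bool = True,
) -> FrameContacts:
    """All three contact kinds for one frame, collapsed per (kind, residue)."""
    events = (
        find_hbonds(frame, topology, typing, hb_params)
        + find_water_bridges(frame, topology, typing, hb_params)
        + find_hydrophobic_contacts(
            frame, topology, hp_params, carbons_only=carbons_only
        )
    )
    return FrameContacts(frame.index, events).collapsed()


def compute_trajectory_contacts(
    traj,
    typing: PolarTyping | None = None,
    hb_params: HBondParams = HBondParams(),
    hp_params: HydrophobicParams = HydrophobicParams(),
    carbons_only: bool = True,
) -> list[FrameContacts]:
    if typing is None:
        typing = typed_polar_atoms(traj.topology)
    return [
        compute_frame_contacts(
            fr, traj.topology, typing, hb_params, hp_params, carbons_only
        )
        for fr in traj.frames
    ]
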