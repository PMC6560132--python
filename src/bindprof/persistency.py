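"""Contact persistency over the analysed trajectory window.

Persistency of an interaction is the number of analysed frames showing it
divided by the number of analysed frames, where the analysed window excludes
an initial equilibration stretch (100 ns by default).  Excluded frames enter
neither numerator nor denominator.

Fractions are kept at full precision internally; display strings are
truncated (not rounded) to two decimals, so 4/6 renders as ``0.66``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .contacts import FrameContacts, HBOND_DIRECT, HBOND_WATER, HYDROPHOBIC
from .errors import ConfigError
from .structure_io import Residue, Trajectory

#: Extra channel: frame-level union of direct and water-mediated H-bonds.
HBOND_UNION = "hbond_union"


def truncate_display(x: float, decimals: int = 2) -> str:
    """Floor-truncate a fraction for display (4/6 -> '0.66', 0.8 -> '0.80')."""
    scale = 10**decimals
    return f"{math.floor(x * scale + 1e-9) / scale:.{decimals}f}"


@dataclass(frozen=True)
class EquilibrationPolicy:
    """Initial window (ns) excluded from the persistency statistics."""

    exclude_time: float = 100.0

    def __post_init__(self):
        if self.exclude_time < 0:
            raise ConfigError("exclusion window must be non-negative")


@dataclass
class PersistencyTable:
    """Per-residue, per-kind persistency with frame-level provenance.

    ``frame_sets[residue][kind]`` holds the analysed frame indices in which
    the residue shows the interaction; fractions are derived from these sets
    so that channel unions operate at frame level rather than on fractions.
    """

    frame_sets: dict[Residue, dict[str, frozenset[int]]]
    analysed_frames: tuple[int, ...]
    res_names: dict[Residue, str]
    bw: dict[Residue, str] = field(default_factory=dict)

    @property
    def n_frames_analysed(self) -> int:
        return len(self.analysed_frames)

    def residues(self) -> list[Residue]:
        return sorted(self.frame_sets, key=lambda r: (r[0], r[1]))

    def frames_with(self, residue: Residue, kind: str) -> frozenset[int]:
        if kind == HBOND_UNION:
            return self.frames_with(residue, HBOND_DIRECT) | self.frames_with(
                residue, HBOND_WATER
            )
        return self.frame_sets.get(residue, {}).get(kind, frozenset())

    def fraction(self, residue: Residue, kind: str) -> float:
        return len(self.frames_with(residue, kind)) / self.n_frames_analysed

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for res in self.residues():
            chain, res_seq = res
            rows.append(
                {
                    "chain": chain,
                    "res_seq": res_seq,
                    "res_name": self.res_names.get(res, ""),
                    "bw": self.bw.get(res, ""),
                    HBOND_DIRECT: self.fraction(res, HBOND_DIRECT),
                    HBOND_WATER: self.fraction(res, HBOND_WATER),
                    HBOND_UNION: self.fraction(res, HBOND_UNION),
                    HYDROPHOBIC: self.fraction(res, HYDROPHOBIC),
                    "n_frames": self.n_frames_analysed,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_persistency(
    traj: Trajectory,
    contacts_per_frame: list[FrameContacts],
    policy: EquilibrationPolicy = EquilibrationPolicy(),
) -> PersistencyTable:
    """Aggregate frame-wise contacts into a persistency table.

    Frames with time < ``policy.exclude_time`` are dropped from numerator
    and denominator.  Every receptor residue receives a row (zero fractions
    when it never contacts the ligand), so downstream classification can
    call every residue.
    """
    if len(contacts_per_frame) != traj.n_frames:
        raise ConfigError(
            f"{len(contacts_per_frame)} contact frames for {traj.n_frames} "
            "trajectory frames"
        )
    analysed = tuple(
        fr.index for fr in traj.frames if fr.time >= policy.exclude_time
    )
    if not analysed:
        raise ConfigError("empty analysis window: all frames excluded")
    analysed_set = set(analysed)

    top = traj.topology
    receptor_residues = top.residues(top.groups["receptor"])
    frame_sets: dict[Residue, dict[str, set[int]]] = {
        res: {} for res in receptor_residues
    }
    by_index = {fc.frame_index: fc for fc in contacts_per_frame}
    for idx in analysed:
        fc = by_index[idx]
        for ev in fc.events:
            if ev.residue not in frame_sets:
                continue  # contact keyed outside the receptor group
            frame_sets[ev.residue].setdefault(ev.kind, set()).add(idx)

    res_names = {res: top.res_name_of(res) for res in receptor_residues}
    frozen = {
        res: {kind: frozenset(v & analysed_set) for kind, v in kinds.items()}
        for res, kinds in frame_sets.items()
    }
    return PersistencyTable(
        frame_sets=frozen,
        analysed_frames=analysed,
        res_names=res_names,
    )


def merge_hbond_channels(
    table: PersistencyTable, include_water: bool = True
) -> PersistencyTable:
    """Fold water-mediated H-bonds into the direct channel at frame level.

    With ``include_water`` a frame counts toward a residue's H-bond
    numerator when it shows a direct OR a water-mediated event (set union,
    not a sum of fractions); otherwise the direct channel is kept as is.
    The merged channel replaces ``hbond_direct`` in the returned table and
    the water channel is zeroed to avoid double counting.
    """
    merged: dict[Residue, dict[str, frozenset[int]]] = {}
    for res in table.frame_sets:
        direct = table.frames_with(res, HBOND_DIRECT)
        if include_water:
            direct = direct | table.frames_with(res, HBOND_WATER)
        merged[res] = {
            HBOND_DIRECT: direct,
            HBOND_WATER: frozenset(),
            HYDROPHOBIC: table.frames_with(res, HYDROPHOBIC),
        }
    return PersistencyTable(
        frame_sets=merged,
        analysed_frames=table.analysed_frames,
        res_names=dict(table.res_names),
        bw=dict(table.bw),
    )
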