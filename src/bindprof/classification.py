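"""Computational binding-residue calls.

Trajectory mode: a residue is called *binding* when its hydrogen-bond
persistency exceeds 10% or its hydrophobic persistency exceeds 80%
(strict inequalities; OR semantics across interaction types).  The two
thresholds differ to absorb the larger frame-to-frame fluctuation of the
hydrogen-bond network relative to hydrophobic packing.

Static-pose mode (docked complexes, no dynamics): the persistency criterion
is replaced by simple presence/absence of any interaction in the single pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .contacts import FrameContacts, HYDROPHOBIC
from .errors import ConfigError, ModeError
from .persistency import HBOND_UNION, PersistencyTable
from .structure_io import Residue

BINDING = "binding"
NON_BINDING = "non_binding"


@dataclass(frozen=True)
class CallThresholds:
    """Strict lower bounds on persistency fractions."""

    hbond_min: float = 0.10
    hydrophobic_min: float = 0.80

    def __post_init__(self):
        for v in (self.hbond_min, self.hydrophobic_min):
            if not 0 < v < 1:
                raise ConfigError("call thresholds must lie in (0, 1)")


@dataclass
class ResidueCallSet:
    calls: dict[Residue, str]
    mode: str  # "trajectory" | "static_pose"
    provenance: dict = field(default_factory=dict)
    triggers: dict[Residue, tuple[str, float]] = field(default_factory=dict)

    def binding(self) -> set[Residue]:
        return {r for r, c in self.calls.items() if c == BINDING}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for res in sorted(self.calls, key=lambda r: (r[0], r[1])):
            channel, value = self.triggers.get(res, ("", float("nan")))
            rows.append(
                {
                    "chain": res[0],
                    "res_seq": res[1],
                    "call": self.calls[res],
                    "trigger_channel": channel,
                    "trigger_value": value,
                }
            )
        return pd.DataFrame(rows)


def call_from_persistency(
    table: PersistencyTable,
    thresholds: CallThresholds = CallThresholds(),
    hbond_channel: str = HBOND_UNION,
) -> ResidueCallSet:
    """Trajectory-mode calls from a persistency table.

    ``hbond_channel`` selects which H-bond statistic faces the 10% bound:
    the frame-level union of direct and water-mediated events (default) or
    ``"hbond_direct"`` alone.
    """
    calls: dict[Residue, str] = {}
    triggers: dict[Residue, tuple[str, float]] = {}
    for res in table.residues():
        hb = table.fraction(res, hbond_channel)
        hp = table.fraction(res, HYDROPHOBIC)
        if hb > thresholds.hbond_min:
            calls[res] = BINDING
            triggers[res] = (hbond_channel, hb)
        elif hp > thresholds.hydrophobic_min:
            calls[res] = BINDING
            triggers[res] = (HYDROPHOBIC, hp)
        else:
            calls[res] = NON_BINDING
            triggers[res] = (
                (hbond_channel, hb) if hb >= hp else (HYDROPHOBIC, hp)
            )
    return ResidueCallSet(
        calls=calls,
        mode="trajectory",
        provenance={
            "hbond_min": thresholds.hbond_min,
            "hydrophobic_min": thresholds.hydrophobic_min,
            "hbond_channel": hbond_channel,
        },
        triggers=triggers,
    )


def call_from_static_pose(
    contacts: FrameContacts | list[FrameContacts],
    receptor_residues: list[Residue],
    res_names: dict[Residue, str] | None = None,
) -> ResidueCallSet:
    """Static-pose calls: binding iff ≥ 1 event of any kind in the pose.

    ``contacts`` must describe exactly one frame; multi-frame input is a
    mode error (use trajectory mode with persistency thresholds instead).
    """
    if isinstance(contacts, list):
        if len(contacts) != 1:
            raise ModeError(
                f"static-pose mode requires exactly one frame, got "
                f"{len(contacts)}; run trajectory mode for multi-frame input"
            )
        contacts = contacts[0]
    touched = {e.residue for e in contacts.events}
    calls = {
        res: (BINDING if res in touched else NON_BINDING)
        for res in receptor_residues
    }
    triggers = {}
    for e in contacts.events:
        if e.residue in calls and e.residue not in triggers:
            triggers[e.residue] = (e.kind, e.distance)
    return ResidueCallSet(
        calls=calls,
        mode="static_pose",
        provenance={"pose": contacts.frame_index},
        triggers=triggers,
    )
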