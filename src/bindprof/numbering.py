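"""Ballesteros–Weinstein generic residue numbering.

Class-A GPCR residues are labelled ``tm.position`` where ``tm`` is the
transmembrane helix (1–7) and position 50 marks the helix's most conserved
residue (the X.50 anchor).  Other positions follow by sequence offset:
``position = 50 + (res_seq − anchor_res_seq)``.  Anchors are explicit inputs
taken from an alignment or the literature; no alignment is computed here.

For hTAS2R16 the anchoring used throughout this package places residue 89 at
3.36, hence residue 86 is 3.33, matching the receptor's published helix
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class BWAnchor:
    tm: int
    anchor_res_seq: int
    helix_range: tuple[int, int]
    chain: str = "A"

    def __post_init__(self):
        if not 1 <= self.tm <= 7:
            raise ConfigError("helix index must be in 1..7")
        lo, hi = self.helix_range
        if not lo <= self.anchor_res_seq <= hi:
            raise ConfigError(
                f"anchor {self.anchor_res_seq} outside helix range {lo}-{hi}"
            )

    def contains(self, res_seq: int) -> bool:
        return self.helix_range[0] <= res_seq <= self.helix_range[1]


@dataclass(frozen=True)
class GenericNumber:
    tm: int
    position: int

    @property
    def display(self) -> str:
        return f"{self.tm}.{self.position}"

    @property
    def value(self) -> float:
        return self.tm + self.position / 100.0


def validate_anchors(anchors: list[BWAnchor]) -> None:
    seen_tm = set()
    for a in anchors:
        if a.tm in seen_tm:
            raise ConfigError(f"duplicate anchor for TM{a.tm}")
        seen_tm.add(a.tm)
    spans = sorted((a.helix_range, a.tm) for a in anchors)
    for ((lo1, hi1), t1), ((lo2, hi2), t2) in zip(spans, spans[1:]):
        if lo2 <= hi1:
            raise ConfigError(
                f"helix ranges of TM{t1} and TM{t2} overlap"
            )


def assign_bw(res_seq: int, anchors: list[BWAnchor]) -> GenericNumber | None:
    """Generic number for a residue, or None when it lies in a loop.

    The residue must fall in at most one helix range; the position is the
    linear offset from that helix's X.50 anchor.
    """
    validate_anchors(anchors)
    hits = [a for a in anchors if a.contains(res_seq)]
    if not hits:
        return None
    anchor = hits[0]
    return GenericNumber(
        tm=anchor.tm, position=50 + (res_seq - anchor.anchor_res_seq)
    )


def load_anchors(path: str | Path) -> list[BWAnchor]:
    """Anchors from YAML: list of {tm, anchor, range: [start, end], chain}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    anchors = [
        BWAnchor(
            tm=int(item["tm"]),
            anchor_res_seq=int(item["anchor"]),
            helix_range=(int(item["range"][0]), int(item["range"][1])),
            chain=str(item.get("chain", "A")),
        )
        for item in raw
    ]
    validate_anchors(anchors)
    return anchors


def annotate(res_seqs, anchors: list[BWAnchor]) -> list[str]:
    """Display strings (empty for loop residues) for a residue-number list."""
    out = []
    for rs in res_seqs:
        gn = assign_bw(int(rs), anchors)
        out.append(gn.display if gn else "")
    return out
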