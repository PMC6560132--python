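"""Experimental binding labels from site-directed mutagenesis annotations.

The annotation table is curated from functional assays: for each mutated
residue it records whether mutation shifts the receptor's EC50 (dose–response
midpoint) and whether the residue sits in the upper extracellular part of the
receptor — the location of the canonical class-A GPCR orthosteric site — or
in the lower intracellular part.

A residue is an *experimental binding* residue iff its mutation affects the
EC50 AND it lies in the upper extracellular region; all other annotated
residues are *experimental non-binding*.  ``ec50_affected`` is a curated
boolean input: no fold-change threshold is canonical, so it is not derived
from raw ratios here (a convenience helper with an explicit fold cutoff is
provided for curation work).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigError
from .structure_io import Residue

UPPER = "upper_extracellular"
LOWER = "lower_intracellular"
REGIONS = (UPPER, LOWER)

REQUIRED_COLUMNS = ("res_seq", "res_name", "ec50_affected", "region")


@dataclass(frozen=True)
class MutagenesisRecord:
    residue: Residue
    res_name: str
    bw: str = ""
    mutations: tuple[str, ...] = ()
    ec50_affected: bool = False
    region: str = UPPER
    notes: str = ""


@dataclass
class ExperimentalCallSet:
    calls: dict[Residue, str]

    @property
    def annotated_residues(self) -> set[Residue]:
        return set(self.calls)

    def binding(self) -> set[Residue]:
        return {r for r, c in self.calls.items() if c == "binding"}

    def non_binding(self) -> set[Residue]:
        return {r for r, c in self.calls.items() if c == "non_binding"}


def _parse_bool(value, row: int) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "y"):
        return True
    if text in ("false", "0", "no", "n"):
        return False
    raise ConfigError(f"row {row}: cannot parse boolean {value!r}")


def load_annotation(path: str | Path) -> list[MutagenesisRecord]:
    """Load and validate a mutagenesis annotation CSV.

    Required columns: res_seq, res_name, ec50_affected, region; optional:
    chain (default A), bw, mutations (semicolon separated), notes.
    Duplicate residues and unknown region tokens are rejected with the row
    number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"annotation table lacks columns: {missing}")
    records: list[MutagenesisRecord] = []
    seen: set[Residue] = set()
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header=1
        try:
            res_seq = int(getattr(row, "res_seq"))
        except ValueError:
            raise ConfigError(f"row {pos}: res_seq must be an integer") from None
        chain = getattr(row, "chain", "A") or "A"
        region = getattr(row, "region").strip()
        if region not in REGIONS:
            raise ConfigError(
                f"row {pos}: unknown region {region!r} (expected one of "
                f"{REGIONS})"
            )
        residue = (chain, res_seq)
        if residue in seen:
            raise ConfigError(f"row {pos}: duplicate residue {residue}")
        seen.add(residue)
        mutations = tuple(
            m.strip()
            for m in str(getattr(row, "mutations", "")).split(";")
            if m.strip()
        )
        records.append(
            MutagenesisRecord(
                residue=residue,
                res_name=getattr(row, "res_name"),
                bw=str(getattr(row, "bw", "")),
                mutations=mutations,
                ec50_affected=_parse_bool(getattr(row, "ec50_affected"), pos),
                region=region,
                notes=str(getattr(row, "notes", "")),
            )
        )
    return records


def call_experimental(records: list[MutagenesisRecord]) -> ExperimentalCallSet:
    """Label annotated residues: binding iff EC50-affected AND upper region."""
    calls: dict[Residue, str] = {}
    for rec in records:
        binding = rec.ec50_affected and rec.region == UPPER
        calls[rec.residue] = "binding" if binding else "non_binding"
    return ExperimentalCallSet(calls=calls)


def flag_ec50_affected(ratio: float, fold: float = 2.0) -> bool:
    """Convenience curation helper: flag mutant/wild-type EC50 ratios ≥ fold.

    Non-canonical: the binding/non-binding rule consumes a curated boolean,
    not a ratio; this helper merely assists building annotation tables.
    """
    if fold <= 0:
        raise ConfigError("fold cutoff must be positive")
    return ratio >= fold or (ratio > 0 and 1.0 / ratio >= fold)
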