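"""Representative-snapshot selection.

The representative frame of a trajectory is chosen in two steps: (1) build
the average structure over all frames after least-squares superposition of
each frame onto frame 0 using the non-water atoms; (2) compute, per frame,
the RMSD of a subset — transmembrane helices plus ligand, heavy atoms by
default — to that average after superposing the subset, and return the
frame minimising it (ties break to the lowest frame index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigError
from .structure_io import Topology, Trajectory


@dataclass(frozen=True)
class SubsetSpec:
    """Atom subset for the per-frame RMSD.

    ``tm_ranges`` lists the transmembrane helices as (chain, start_res,
    end_res) inclusive residue ranges; the ligand group is appended unless
    ``include_ligand`` is off.  ``atom_filter`` is "heavy" (default) or
    "all"; hydrogen positions are force-field noise, so they are excluded
    by default.
    """

    tm_ranges: tuple[tuple[str, int, int], ...] = ()
    include_ligand: bool = True
    atom_filter: str = "heavy"

    def __post_init__(self):
        if self.atom_filter not in ("heavy", "all"):
            raise ConfigError("atom_filter must be 'heavy' or 'all'")
        spans = sorted(self.tm_ranges)
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            if c1 == c2 and s2 <= e1:
                raise ConfigError(
                    f"overlapping TM ranges {s1}-{e1} and {s2}-{e2}"
                )

    def atom_indices(self, topology: Topology) -> np.ndarray:
        receptor = topology.groups.get("receptor", frozenset())
        out = []
        for i, atom in enumerate(topology.atoms):
            if self.atom_filter == "heavy" and atom.element.upper() == "H":
                continue
            in_tm = i in receptor and any(
                atom.chain == c and s <= atom.res_seq <= e
                for c, s, e in self.tm_ranges
            )
            in_lig = self.include_ligand and i in topology.groups.get(
                "ligand", frozenset()
            )
            if in_tm or in_lig:
                out.append(i)
        if not out:
            raise ConfigError("representative subset selects no atoms")
        return np.array(out, dtype=int)


@dataclass
class RepresentativeResult:
    frame_index: int
    rmsd: float
    rmsd_series: np.ndarray = field(repr=False, default=None)


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares (Kabsch) fit of ``mobile`` onto ``reference``.

    Returns a callable applying the fitted rigid transform to arbitrary
    coordinates expressed in the mobile frame.
    """
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)

    def transform(coords: np.ndarray) -> np.ndarray:
        return rot.apply(coords - mc) + rc

    return transform


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def average_structure(
    traj: Trajectory, exclude: str = "water"
) -> np.ndarray:
    """Per-atom mean coordinates after fitting each frame onto frame 0.

    The least-squares fit uses the atoms outside the ``exclude`` group
    (water by default); the mean is then taken per atom over all frames.
    A single-frame trajectory is returned unchanged with a notice.
    """
    top = traj.topology
    excluded = top.groups.get(exclude, frozenset())
    fit_idx = np.array(
        [i for i in range(top.n_atoms) if i not in excluded], dtype=int
    )
    if fit_idx.size == 0:
        raise ConfigError(f"excluding group {exclude!r} leaves no atoms to fit")
    if traj.n_frames == 1:
        warnings.warn(
            "single-frame trajectory: average structure equals the frame",
            stacklevel=2,
        )
        return traj.frames[0].coords.copy()
    ref = traj.frames[0].coords
    acc = np.zeros_like(ref)
    for fr in traj.frames:
        t = superpose(fr.coords[fit_idx], ref[fit_idx])
        acc += t(fr.coords)
    return acc / traj.n_frames


def select_representative(
    traj: Trajectory,
    avg: np.ndarray,
    subset: SubsetSpec,
) -> RepresentativeResult:
    """Frame with the lowest subset RMSD to the average structure.

    Each frame's subset is superposed onto the average's subset before the
    RMSD is taken, so rigid-body drift does not bias the choice.  Ties go to
    the lowest frame index.
    """
    idx = subset.atom_indices(traj.topology)
    target = avg[idx]
    series = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        sub = fr.coords[idx]
        t = superpose(sub, target)
        series[k] = rmsd(t(sub), target)
    best = int(np.argmin(series))  # argmin returns the first minimum
    return RepresentativeResult(
        frame_index=best, rmsd=float(series[best]), rmsd_series=series
    )
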