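#!/usr/bin/env python
"""Build the synthetic study systems.

Generates the toy receptor-ligand-water bundle carrying the annotated
hTAS2R16 residue numbering, plants the per-complex contact schedules (three
ligands x two binding modes, plus the contact-free docked pose), and writes:

  scratch/synthetic/<complex>.pdb   multi-model trajectories (large, scratch)
  results/synthetic_truth.json      exact planted persistencies per complex
"""

import json
from pathlib import Path

from bindprof.structure_io import Trajectory, write_multimodel_pdb
from bindprof.study import STUDY_SCHEDULES, build_study_system
from bindprof.synthetic import generate_trajectory, make_annotation_fixtures

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    topology, frame0 = build_study_system(seed=SEED)
    print(
        f"toy system: {topology.n_atoms} atoms, "
        f"{len(topology.residues(topology.groups['receptor']))} receptor residues, "
        f"{len(topology.residues(topology.groups['water']))} waters"
    )

    truth_all = {}
    for name, schedule in STUDY_SCHEDULES.items():
        traj, truth = generate_trajectory(topology, frame0, schedule)
        write_multimodel_pdb(traj, SCRATCH / f"{name}.pdb")
        truth_all[name] = {
            f"{c}{r}": kinds for (c, r), kinds in truth.items()
            if any(kinds.values())
        }
        print(f"{name}: {traj.n_frames} frames -> scratch/synthetic/{name}.pdb")

    # contact-free single pose standing in for the initial docking result
    write_multimodel_pdb(
        Trajectory(topology=topology, frames=[frame0]), SCRATCH / "PGP_dock.pdb"
    )
    print("PGP_dock: 1 frame (no receptor-ligand contacts by construction)")

    with open(RESULTS / "synthetic_truth.json", "w") as fh:
        json.dump(truth_all, fh, indent=2)
    make_annotation_fixtures(RESULTS / "fixtures")
    print(f"planted persistencies -> {RESULTS / 'synthetic_truth.json'}")
    print(f"annotation + call-set fixtures -> {RESULTS / 'fixtures'}")


if __name__ == "__main__":
    main()
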