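#!/usr/bin/env python
"""Contact detection and persistency profiling for every simulated complex.

Re-generates each synthetic trajectory deterministically (same seed as
01_build_synthetic_complexes.py), detects direct H-bonds (3.5 Å, 30°
deviation), water-mediated H-bonds and hydrophobic contacts (5.5 Å), and
aggregates per-residue persistency over the analysed window (first 100 ns
excluded).  Verifies the recovered fractions against the planted ground
truth and writes one combined table:

  results/persistency.csv    per complex, per residue, per channel
"""

from pathlib import Path

import pandas as pd

from bindprof.contacts import KINDS, compute_trajectory_contacts
from bindprof.numbering import annotate
from bindprof.persistency import compute_persistency
from bindprof.study import HTAS2R16_ANCHORS, STUDY_SCHEDULES, build_study_system
from bindprof.synthetic import generate_trajectory

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    frames = []
    for name, schedule in STUDY_SCHEDULES.items():
        topology, frame0 = build_study_system(seed=SEED)
        traj, truth = generate_trajectory(topology, frame0, schedule)
        contacts = compute_trajectory_contacts(traj)
        table = compute_persistency(traj, contacts)
        table.bw = {
            res: gn
            for res, gn in zip(
                table.residues(),
                annotate([r[1] for r in table.residues()], HTAS2R16_ANCHORS),
            )
        }
        mismatches = [
            (res, kind)
            for res, kinds in truth.items()
            for kind in KINDS
            if abs(table.fraction(res, kind) - kinds[kind]) > 1e-12
        ]
        status = "exact" if not mismatches else f"MISMATCH {mismatches}"
        print(
            f"{name}: {table.n_frames_analysed} analysed frames, "
            f"ground-truth recovery {status}"
        )
        df = table.to_frame()
        df.insert(0, "complex", name)
        frames.append(df)

    combined = pd.concat(frames, ignore_index=True)
    combined.to_csv(RESULTS / "persistency.csv", index=False)
    print(f"persistency table ({len(combined)} rows) -> {RESULTS / 'persistency.csv'}")


if __name__ == "__main__":
    main()
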