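import numpy as np
import pandas as pd
import pytest

from bindprof.contacts import (
    HBOND_DIRECT,
    HBOND_WATER,
    HYDROPHOBIC,
    compute_trajectory_contacts,
)
from bindprof.errors import ScheduleError
from bindprof.persistency import compute_persistency
from bindprof.synthetic import (
    COMPLEX_CALL_FIXTURES,
    ContactSchedule,
    ScheduleEntry,
    ToySystemSpec,
    build_toy_complex,
    generate_trajectory,
    load_call_fixture,
    make_annotation_fixtures,
)


class TestBuildToyComplex:
    def test_default_groups_all_non_empty(self):
        top, _ = build_toy_complex()
        assert top.groups["receptor"]
        assert top.groups["ligand"]
        assert top.groups["water"]

    def test_same_seed_identical_coordinates(self):
        _, f1 = build_toy_complex(seed=42)
        _, f2 = build_toy_complex(seed=42)
        assert np.array_equal(f1.coords, f2.coords)

    def test_different_seed_differs(self):
        _, f1 = build_toy_complex(seed=1)
        _, f2 = build_toy_complex(seed=2)
        assert not np.array_equal(f1.coords, f2.coords)

    def test_residue_count_follows_spec(self):
        spec = ToySystemSpec(
            n_helices=2, polar_top_residues=8, hydrophobic_bottom_residues=8
        )
        top, _ = build_toy_complex(spec)
        assert len(top.residues(top.groups["receptor"])) == 16

    def test_ligand_has_donor_acceptor_and_carbon(self):
        from bindprof.contacts import typed_polar_atoms

        top, _ = build_toy_complex()
        typing = typed_polar_atoms(top)
        lig = top.groups["ligand"]
        assert any(d in lig for d, _ in typing.donors)
        assert any(a in lig for a in typing.acceptors)
        assert any(top.atoms[i].element == "C" for i in lig)

    def test_resting_layout_has_no_contacts(self):
        from bindprof.contacts import compute_frame_contacts, typed_polar_atoms

        top, frame0 = build_toy_complex()
        fc = compute_frame_contacts(frame0, top, typed_polar_atoms(top))
        assert not [e for e in fc.events if e.residue in
                    set(top.residues(top.groups["receptor"]))]


class TestGenerateTrajectory:
    def recover(self, schedule, seed=0, spec=ToySystemSpec()):
        top, frame0 = build_toy_complex(spec, seed=seed)
        traj, truth = generate_trajectory(top, frame0, schedule)
        table = compute_persistency(traj, compute_trajectory_contacts(traj))
        return table, truth

    @pytest.mark.parametrize("kind", [HBOND_DIRECT, HBOND_WATER, HYDROPHOBIC])
    def test_planted_truth_recovered_exactly_per_kind(self, kind):
        res = ("A", 1) if kind != HYDROPHOBIC else ("A", 5)
        schedule = ContactSchedule(
            entries=[ScheduleEntry(res, kind, 0.5)], n_frames=160, dt=5.0
        )
        table, truth = self.recover(schedule)
        assert truth[res][kind] == 0.5
        assert table.fraction(res, kind) == 0.5
        # nothing leaks into other residues or kinds
        for other in table.residues():
            for k in (HBOND_DIRECT, HBOND_WATER, HYDROPHOBIC):
                if (other, k) != (res, kind):
                    assert table.fraction(other, k) == 0.0

    def test_half_persistency_with_100ns_exclusion_of_800ns(self):
        schedule = ContactSchedule(
            entries=[ScheduleEntry(("A", 2), HBOND_DIRECT, 0.5)],
            n_frames=200, dt=4.0,  # 800 ns span, 25 frames excluded
        )
        table, truth = self.recover(schedule)
        assert table.n_frames_analysed == 175
        assert truth[("A", 2)][HBOND_DIRECT] == pytest.approx(
            round(0.5 * 175) / 175
        )
        assert table.fraction(("A", 2), HBOND_DIRECT) == truth[("A", 2)][HBOND_DIRECT]

    def test_conflicting_entries_rejected(self):
        top, frame0 = build_toy_complex()
        schedule = ContactSchedule(
            entries=[
                ScheduleEntry(("A", 1), HBOND_DIRECT, 1.0),
                ScheduleEntry(("A", 1), HBOND_WATER, 1.0),
            ],
            n_frames=40, dt=20.0,
        )
        with pytest.raises(ScheduleError, match="conflicting"):
            generate_trajectory(top, frame0, schedule)

    def test_bad_target_rejected(self):
        with pytest.raises(ScheduleError):
            ScheduleEntry(("A", 1), HBOND_DIRECT, 1.5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ScheduleError):
            ScheduleEntry(("A", 1), "stacking", 0.5)

    def test_more_bridges_than_waters_rejected(self):
        top, frame0 = build_toy_complex(ToySystemSpec(n_waters=1))
        schedule = ContactSchedule(
            entries=[
                ScheduleEntry(("A", 1), HBOND_WATER, 0.3),
                ScheduleEntry(("A", 2), HBOND_WATER, 0.3),
            ],
            n_frames=40, dt=20.0,
        )
        with pytest.raises(ScheduleError, match="water"):
            generate_trajectory(top, frame0, schedule)

    def test_output_roundtrips_through_structure_io(self, tmp_path):
        from bindprof.structure_io import read_multimodel_pdb, write_multimodel_pdb

        top, frame0 = build_toy_complex(seed=2)
        schedule = ContactSchedule(
            entries=[ScheduleEntry(("A", 1), HBOND_DIRECT, 0.4)],
            n_frames=30, dt=20.0,
        )
        traj, truth = generate_trajectory(top, frame0, schedule)
        p = tmp_path / "toy.pdb"
        write_multimodel_pdb(traj, p)
        back = read_multimodel_pdb(p, {"ligand": ["LIG"], "water": ["HOH"]}, dt=20.0)
        table = compute_persistency(back, compute_trajectory_contacts(back))
        assert table.fraction(("A", 1), HBOND_DIRECT) == truth[("A", 1)][HBOND_DIRECT]


class TestAnnotationFixtures:
    def test_files_written_and_loadable(self, tmp_path):
        paths = make_annotation_fixtures(tmp_path)
        assert len(paths) == 2 + len(COMPLEX_CALL_FIXTURES)
        df = pd.read_csv(paths["annotations"])
        assert len(df) == 7
        ext = pd.read_csv(paths["annotations_extended"])
        assert len(ext) == 12

    def test_generated_fixtures_match_packaged_data(self, tmp_path, data_dir):
        paths = make_annotation_fixtures(tmp_path)
        for name, p in paths.items():
            packaged = (data_dir / p.name).read_text()
            assert p.read_text() == packaged

    def test_sal_tm3_fixture_confusion(self, tmp_path, annotation_path):
        from bindprof.mutagenesis import call_experimental, load_annotation
        from bindprof.validation import confusion

        paths = make_annotation_fixtures(tmp_path)
        comp = load_call_fixture(paths["calls_SAL_TM3"])
        exp = call_experimental(load_annotation(annotation_path))
        cm = confusion(comp, exp)
        assert (cm.tp, cm.fp, cm.fn) == (4, 0, 2)

    def test_empty_call_set_gives_zero_tp(self, tmp_path, annotation_path):
        from bindprof.mutagenesis import call_experimental, load_annotation
        from bindprof.validation import confusion, precision_recall

        paths = make_annotation_fixtures(tmp_path)
        comp = load_call_fixture(paths["calls_PGP_dock"])
        exp = call_experimental(load_annotation(annotation_path))
        cm = confusion(comp, exp)
        assert cm.tp == 0
        scores = precision_recall(cm)
        assert scores.precision == 0.0 and scores.recall == 0.0
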