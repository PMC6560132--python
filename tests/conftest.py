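import numpy as np
import pytest
from importlib import resources

from bindprof.structure_io import (
    AtomRecord,
    Frame,
    Topology,
    infer_bonds,
    resolve_groups,
)


@pytest.fixture(scope="session")
def annotation_path():
    return str(resources.files("bindprof") / "data" / "htas2r16_annotations.csv")


@pytest.fixture(scope="session")
def data_dir():
    return resources.files("bindprof") / "data"


def make_topology(atom_specs, groups=True):
    """Tiny hand-built topology from (name, element, res_name, res_seq,
    chain, xyz) tuples; bonds inferred from the given coordinates."""
    atoms = [
        AtomRecord(i + 1, name, element, res_name, res_seq, chain, tuple(xyz))
        for i, (name, element, res_name, res_seq, chain, xyz) in enumerate(atom_specs)
    ]
    top = Topology(atoms=atoms)
    frame0 = Frame(0, 0.0, np.array([a.coords for a in atoms]))
    top.bonds = infer_bonds(top, frame0)
    if groups:
        top.groups = resolve_groups(top, {"ligand": ["LIG"], "water": ["HOH"]})
    return top, frame0


@pytest.fixture
def minimal_pair():
    """One serine-like receptor hydroxyl and one ligand oxygen acceptor."""

    def build(d_pos, h_pos, a_pos):
        return make_topology(
            [
                ("OG", "O", "SER", 1, "A", d_pos),
                ("HG", "H", "SER", 1, "A", h_pos),
                ("O1", "O", "LIG", 1, "L", a_pos),
                ("C1", "C", "LIG", 1, "L", np.asarray(a_pos) + [0.0, 1.4, 0.0]),
            ]
        )

    return build
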