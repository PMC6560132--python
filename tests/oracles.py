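"""Independent brute-force reference implementations used only by tests.

These enumerate every pair/triple explicitly with plain numpy, independent
of the KD-tree-accelerated code paths under test.
"""

import numpy as np


def angle_deg(p_d, p_h, p_a):
    v1 = p_d - p_h
    v2 = p_a - p_h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def brute_hbond_triples(coords, donors, acceptors, d_max=3.5, theta_min=150.0):
    """All (donor, hydrogen, acceptor) triples meeting the criteria."""
    out = set()
    for d, h in donors:
        for a in acceptors:
            if a == d:
                continue
            if np.linalg.norm(coords[d] - coords[a]) <= d_max and (
                angle_deg(coords[d], coords[h], coords[a]) >= theta_min
            ):
                out.add((d, h, a))
    return out


def brute_direct_hbond_residues(coords, topology, typing, d_max=3.5, theta_min=150.0):
    """Receptor residues with a direct receptor-ligand H-bond (either role)."""
    rec, lig = topology.groups["receptor"], topology.groups["ligand"]
    residues = set()
    don_r = [(d, h) for d, h in typing.donors if d in rec]
    don_l = [(d, h) for d, h in typing.donors if d in lig]
    acc_r = [a for a in typing.acceptors if a in rec]
    acc_l = [a for a in typing.acceptors if a in lig]
    for d, h, a in brute_hbond_triples(coords, don_r, acc_l, d_max, theta_min):
        residues.add(topology.residue_of(d))
    for d, h, a in brute_hbond_triples(coords, don_l, acc_r, d_max, theta_min):
        residues.add(topology.residue_of(a))
    return residues


def brute_water_bridge_residues(coords, topology, typing, d_max=3.5, theta_min=150.0):
    """(receptor residue, water residue) bridges by exhaustive enumeration."""
    rec = topology.groups["receptor"]
    lig = topology.groups["ligand"]
    wat = topology.groups.get("water", frozenset())
    don = {g: [(d, h) for d, h in typing.donors if d in g] for g in (rec, lig, wat)}
    acc = {g: [a for a in typing.acceptors if a in g] for g in (rec, lig, wat)}

    rw = set()
    for d, h, a in brute_hbond_triples(coords, don[rec], acc[wat], d_max, theta_min):
        rw.add((topology.residue_of(d), topology.residue_of(a)))
    for d, h, a in brute_hbond_triples(coords, don[wat], acc[rec], d_max, theta_min):
        rw.add((topology.residue_of(a), topology.residue_of(d)))
    lw = set()
    for d, h, a in brute_hbond_triples(coords, don[lig], acc[wat], d_max, theta_min):
        lw.add(topology.residue_of(a))
    for d, h, a in brute_hbond_triples(coords, don[wat], acc[lig], d_max, theta_min):
        lw.add(topology.residue_of(d))
    return {(r, w) for (r, w) in rw if w in lw}


def brute_min_cc_distances(coords, topology, carbons_only=True):
    """Per receptor residue, the minimum C-C distance to the ligand."""
    def keep(i):
        e = topology.atoms[i].element.upper()
        return e == "C" if carbons_only else e != "H"

    lig = [i for i in topology.groups["ligand"] if keep(i)]
    mins = {}
    for i in topology.groups["receptor"]:
        if not keep(i):
            continue
        res = topology.residue_of(i)
        for j in lig:
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if res not in mins or d < mins[res]:
                mins[res] = d
    return mins


def scramble_residues(topology, frame0, rng, amplitude=12.0):
    """Random rigid per-residue translation; molecules stay intact."""
    coords = frame0.coords.copy()
    for res in topology.residues():
        idx = [i for i in range(topology.n_atoms) if topology.atoms[i].residue == res]
        coords[idx] += rng.uniform(-amplitude, amplitude, 3)
    return coords
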