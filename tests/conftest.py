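"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive every quantity from first principles
(plain ``math`` loops, explicit formulas) so they stay independent of the
package implementation they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from mdpost.io_structures import Atom, Topology


# ---------------------------------------------------------------------------
# brute-force contact oracles
# ---------------------------------------------------------------------------


def oracle_hbonds(frame, topology, max_da=0.35, min_angle=150.0, exclude_intra_residue=True):
    """Exhaustive O(D*H*A) hydrogen-bond scan with its own distance/angle math."""
    frame = np.asarray(frame, dtype=float)
    hydrogens = {a.index for a in topology.atoms if a.element == "H"}
    residue = {a.index: (a.chain, a.residue_index) for a in topology.atoms}
    found = set()
    for d in topology.atoms:
        if not d.is_donor_heavy:
            continue
        for h in topology.bonded(d.index):
            if h not in hydrogens:
                continue
            for acc in topology.atoms:
                if not acc.is_acceptor or acc.index == d.index:
                    continue
                if exclude_intra_residue and residue[acc.index] == residue[d.index]:
                    continue
                da = math.dist(frame[d.index], frame[acc.index])
                if da >= max_da:
                    continue
                v1 = frame[d.index] - frame[h]
                v2 = frame[acc.index] - frame[h]
                cosang = float(np.dot(v1, v2)) / (math.dist(frame[d.index], frame[h]) * math.dist(frame[acc.index], frame[h]))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if ang > min_angle:
                    found.add((d.index, h, acc.index))
    return found


def oracle_salt_bridges(frame, topology, max_distance=0.7, anion_names=("P",), cation_specs=(("ARG", "CZ"), ("LYS", "NZ"))):
    """Exhaustive all-pairs salt-bridge scan (inclusive cut-off)."""
    frame = np.asarray(frame, dtype=float)
    found = set()
    for an in topology.atoms:
        if an.name not in anion_names:
            continue
        for cat in topology.atoms:
            if (cat.residue_name, cat.name) not in cation_specs:
                continue
            if math.dist(frame[an.index], frame[cat.index]) <= max_distance:
                found.add((an.index, cat.index))
    return found


def random_contact_system(seed: int, n_atoms: int | None = None):
    """Random dense atom cloud with donors/acceptors/cations for oracle tests."""
    rng = np.random.default_rng(seed)
    n_heavy = int(n_atoms) if n_atoms else int(rng.integers(15, 60))
    box = 1.1 * max(1.0, (n_heavy / 30.0) ** (1 / 3))
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []

    def add(name, element, resname, rid, xyz):
        i = len(atoms)
        atoms.append(Atom(index=i, name=name, element=element, residue_name=resname, residue_index=rid))
        coords.append(np.asarray(xyz, dtype=float))
        return i

    # guarantee at least one donor candidate, one acceptor, one anion/cation
    add("N0", "N", "GLN", 1, rng.uniform(0, box, 3))
    add("O0", "O", "SER", 2, rng.uniform(0, box, 3))
    add("P", "P", "LIG", 3, rng.uniform(0, box, 3))
    add("NZ", "N", "LYS", 4, rng.uniform(0, box, 3))
    kinds = ["N", "O", "C", "P"]
    for k in range(4, n_heavy):
        el = kinds[int(rng.integers(0, len(kinds)))]
        if el == "P":
            add("P", "P", "LIG", k + 1, rng.uniform(0, box, 3))
        elif el == "C" and rng.random() < 0.4:
            add("CZ", "C", "ARG", k + 1, rng.uniform(0, box, 3))
        elif el == "N" and rng.random() < 0.3:
            add("NZ", "N", "LYS", k + 1, rng.uniform(0, box, 3))
        else:
            add(f"{el}{k}", el, "UNK", k + 1, rng.uniform(0, box, 3))

    # attach hydrogens to a subset of N/O heavies (always to the first N)
    for a in list(atoms):
        if a.element in ("N", "O") and (a.index == 0 or rng.random() < 0.6):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            h = add(f"H{a.index}", "H", a.residue_name, a.residue_index, coords[a.index] + 0.1 * u)
            bonds.append((a.index, h))

    topo = Topology(atoms=atoms, bonds=bonds)
    topo.assign_donors_acceptors()
    return topo, np.array(coords)


# ---------------------------------------------------------------------------
# brute-force nonbonded energy oracle
# ---------------------------------------------------------------------------

K_COULOMB = 33.2063711  # kcal nm / (mol e^2)


def oracle_switch(r, s, c):
    if r <= s:
        return 1.0
    if r >= c:
        return 0.0
    r2, s2, c2 = r * r, s * s, c * c
    return (c2 - r2) ** 2 * (c2 + 2 * r2 - 3 * s2) / (c2 - s2) ** 3


def oracle_pair(qi, qj, ei, ej, rmi, rmj, r, s=1.0, c=1.2):
    sw = oracle_switch(r, s, c)
    eps = math.sqrt(ei * ej)
    rmin = rmi + rmj
    vdw = eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6) * sw if eps > 0 else 0.0
    el = K_COULOMB * qi * qj / r * sw
    return vdw, el


def oracle_ligand_energy(frame, topology, ligand, s=1.0, c=1.2):
    """O(N^2) double loop over (ligand, environment) pairs."""
    frame = np.asarray(frame, dtype=float)
    lig = set(ligand)
    env = [a for a in topology.atoms if a.index not in lig]
    vdw = el = 0.0
    for i in lig:
        ai = topology.atoms[i]
        for aj in env:
            r = math.dist(frame[i], frame[aj.index])
            v, e = oracle_pair(ai.charge, aj.charge, ai.lj_epsilon, aj.lj_epsilon,
                               ai.lj_rmin_half, aj.lj_rmin_half, r, s, c)
            vdw += v
            el += e
    return vdw, el


def random_energy_system(seed: int, n_atoms: int | None = None):
    """Non-overlapping random atoms (jittered grid) with random LJ/charges.

    Grid spacing 0.3 nm with +/-0.04 nm jitter keeps every pair separation
    above ~0.2 nm so pair energies stay in a physically sane range and the
    brute-force comparison is meaningful at 1e-9 kcal/mol.
    """
    rng = np.random.default_rng(seed)
    n = int(n_atoms) if n_atoms else int(rng.integers(10, 50))
    atoms = []
    for i in range(n):
        atoms.append(
            Atom(
                index=i,
                name=f"A{i}",
                element="C",
                residue_name="UNK",
                residue_index=i + 1,
                charge=float(rng.uniform(-1, 1)),
                lj_epsilon=float(rng.uniform(0, 0.4)),
                lj_rmin_half=float(rng.uniform(0.15, 0.25)),
            )
        )
    side = int(np.ceil(n ** (1 / 3)))
    cells = rng.permutation(side**3)[:n]
    grid = np.stack([cells // side**2, (cells // side) % side, cells % side], axis=1) * 0.3
    coords = grid + rng.uniform(-0.04, 0.04, size=(n, 3))
    n_lig = int(rng.integers(1, max(2, n // 3)))
    ligand = sorted(rng.choice(n, size=n_lig, replace=False).tolist())
    return Topology(atoms=atoms), coords, ligand


@pytest.fixture(scope="session")
def toy_complex_default():
    from mdpost.synthetic import ToySystemSpec, make_toy_complex

    return make_toy_complex(ToySystemSpec())


@pytest.fixture(scope="session")
def syn_ensemble_small():
    """300-conformer syn/syn ensemble shared by conformation and NOE tests."""
    from mdpost.conformation import GlycosidicTorsions, sample_ensemble

    return sample_ensemble(GlycosidicTorsions(60.0, -60.0), 15.0, 300, seed=11)
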