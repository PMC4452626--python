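"""Synthetic systems with known ground truth for every pipeline stage.

Generators are seed-deterministic and return explicit ledgers from which the
expected value of each downstream statistic follows in closed form or by
brute-force enumeration:

* toy receptor-ligand complexes with planted hydrogen bonds/salt bridges
  (placed with safety margins so frame jitter cannot flip any detection);
* bound/unbound interaction-energy series with prescribed means, noise and
  AR(1) autocorrelation, carrying their implied LIE ground truth;
* the small deterministic file fixtures used in docs and tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import HBondCriteria, SaltBridgeCriteria
from .energetics import InteractionEnergySeries, LIEParameters
from .io_structures import (
    Atom,
    NOERestraint,
    Topology,
    Trajectory,
    write_parameter_table,
    write_restraints,
    write_structure,
    write_trajectory_pdb,
    write_trajectory_xyz,
)

__all__ = [
    "ToySystemSpec",
    "EnergySeriesSpec",
    "make_toy_complex",
    "make_energy_series",
    "make_reference_fixtures",
]

# planted-contact placement margins (nm / deg): planted hydrogen bonds sit at
# d = 0.29 < 0.33 and ~178 deg > 160; decoys miss one criterion by >= 0.02 nm
# or >= 5 deg.  Jitter up to MAX_JITTER cannot bridge these gaps (a 6-sigma
# excursion on each of six coordinates moves a distance by < 0.015 nm).
MAX_JITTER = 0.002
_HB_DIST = 0.29
_HB_DECOY_DIST = 0.40
_SB_DISTANCES = (0.60, 0.62, 0.64, 0.66, 0.68)
_SB_DECOY_DIST = 0.80
_CLUSTER_SPACING = 3.0  # nm between planted clusters; >> every cutoff


@dataclass(frozen=True)
class ToySystemSpec:
    n_hbonds_planted: int = 7
    n_hbond_decoys: int = 5
    n_salt_bridges_planted: int = 4
    n_bridge_decoys: int = 2
    n_noise_atoms: int = 20
    jitter: float = 0.001  # nm, per-coordinate Gaussian sd
    n_frames: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.n_hbonds_planted, self.n_hbond_decoys, self.n_salt_bridges_planted,
               self.n_bridge_decoys, self.n_noise_atoms) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter < 0 or self.jitter > MAX_JITTER:
            raise ValueError(f"jitter must be in [0, {MAX_JITTER}] nm to keep planted contacts stable")


@dataclass
class ToyComplex:
    topology: Topology
    trajectory: Trajectory
    ledger: dict = field(default_factory=dict)


def _grid_origin(k: int) -> np.ndarray:
    # spread clusters on a coarse 3D grid so nothing interacts across clusters
    return np.array([k % 5, (k // 5) % 5, k // 25], dtype=float) * _CLUSTER_SPACING


def make_toy_complex(spec: ToySystemSpec) -> ToyComplex:
    """Build a receptor-ligand toy system with exactly known contact counts.

    The ligand residue (LIG, chain L) carries the hydrogen-bond donors and
    the phosphorus anions; the receptor side provides acceptors (SER OG) and
    Arg/Lys cations.  Each planted or decoy contact lives in its own cluster
    separated by 3 nm from every other.  Per-frame Gaussian jitter is applied
    everywhere; generation fails rather than emit a frame whose planted or
    decoy contacts would be misdetected.
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    ligand_idx: list[int] = []
    receptor_idx: list[int] = []
    expected_hbonds: list[tuple[int, int, int]] = []
    expected_bridges: list[tuple[int, int]] = []
    resid = 0
    cluster = 0

    def add(name, element, resname, rid, chain, xyz, side):
        i = len(atoms)
        atoms.append(Atom(index=i, name=name, element=element, residue_name=resname,
                          residue_index=rid, chain=chain))
        coords.append(np.asarray(xyz, dtype=float))
        (ligand_idx if side == "ligand" else receptor_idx).append(i)
        return i

    # planted hydrogen bonds: ligand N-H donor, receptor O acceptor, near-linear
    for k in range(spec.n_hbonds_planted):
        o = _grid_origin(cluster); cluster += 1
        resid += 1
        u = np.array([1.0, 0.0, 0.0])
        d = add(f"N{k+1}", "N", "LIG", 1, "L", o, "ligand")
        h = add(f"HN{k+1}", "H", "LIG", 1, "L", o + 0.10 * u, "ligand")
        a = add("OG", "O", "SER", 100 + resid, "R", o + _HB_DIST * u, "receptor")
        bonds.append((d, h))
        expected_hbonds.append((d, h, a))

    # decoys: alternate distance violation (0.40 nm) and angle violation (~100 deg)
    for k in range(spec.n_hbond_decoys):
        o = _grid_origin(cluster); cluster += 1
        resid += 1
        u = np.array([1.0, 0.0, 0.0])
        v = np.array([0.0, 1.0, 0.0])
        d = add(f"ND{k+1}", "N", "LIG", 1, "L", o, "ligand")
        if k % 2 == 0:
            h = add(f"HD{k+1}", "H", "LIG", 1, "L", o + 0.10 * u, "ligand")
            a = add("OG", "O", "SER", 100 + resid, "R", o + _HB_DECOY_DIST * u, "receptor")
        else:
            h = add(f"HD{k+1}", "H", "LIG", 1, "L", o + 0.10 * (0.5 * u + 0.8660254 * v), "ligand")
            a = add("OG", "O", "SER", 100 + resid, "R", o + _HB_DIST * u, "receptor")
        bonds.append((d, h))

    # planted salt bridges: ligand P vs alternating Arg CZ / Lys NZ
    for k in range(spec.n_salt_bridges_planted):
        o = _grid_origin(cluster); cluster += 1
        resid += 1
        dist = _SB_DISTANCES[k % len(_SB_DISTANCES)]
        p = add("P", "P", "LIG", 1, "L", o, "ligand")
        if k % 2 == 0:
            c = add("NZ", "N", "LYS", 100 + resid, "R", o + np.array([dist, 0, 0]), "receptor")
        else:
            c = add("CZ", "C", "ARG", 100 + resid, "R", o + np.array([dist, 0, 0]), "receptor")
        expected_bridges.append((p, c))

    for k in range(spec.n_bridge_decoys):
        o = _grid_origin(cluster); cluster += 1
        resid += 1
        add("P", "P", "LIG", 1, "L", o, "ligand")
        if k % 2 == 0:
            add("CZ", "C", "ARG", 100 + resid, "R", o + np.array([_SB_DECOY_DIST, 0, 0]), "receptor")
        else:
            add("NZ", "N", "LYS", 100 + resid, "R", o + np.array([_SB_DECOY_DIST, 0, 0]), "receptor")

    # inert noise atoms in their own clusters
    for k in range(spec.n_noise_atoms):
        o = _grid_origin(cluster + k // 4)
        xyz = o + np.array([1.5, 1.5, 1.5]) + rng.uniform(-0.4, 0.4, size=3)
        add(f"C{k+1}", "C", "NSE", 900, "N", xyz, "receptor")

    base = np.array(coords)
    topology = Topology(
        atoms=atoms,
        bonds=bonds,
        groups={"ligand": sorted(ligand_idx), "receptor": sorted(receptor_idx)},
    )
    topology.assign_donors_acceptors()

    frames = base[None, :, :] + rng.normal(0.0, spec.jitter, size=(spec.n_frames, len(atoms), 3))
    traj = Trajectory(coordinates=frames, frame_times=np.arange(spec.n_frames, dtype=float))

    _verify_planted(topology, traj, expected_hbonds, expected_bridges)

    ledger = {
        "n_hbonds_per_frame": spec.n_hbonds_planted,
        "n_salt_bridges_per_frame": spec.n_salt_bridges_planted,
        "expected_hbond_triples": [list(t) for t in expected_hbonds],
        "expected_bridge_pairs": [list(p) for p in expected_bridges],
        "seed": spec.seed,
    }
    return ToyComplex(topology=topology, trajectory=traj, ledger=ledger)


def _verify_planted(topology, traj, hbonds, bridges):
    """Check every frame preserves planted contacts with margin; else raise."""
    hb = HBondCriteria()
    sb = SaltBridgeCriteria()
    for f, frame in enumerate(traj.coordinates):
        for d, h, a in hbonds:
            dda = np.linalg.norm(frame[a] - frame[d])
            v1 = frame[d] - frame[h]
            v2 = frame[a] - frame[h]
            ang = np.degrees(np.arccos(np.clip(
                np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))
            if not (dda < hb.max_da_distance and ang > hb.min_dha_angle):
                raise RuntimeError(f"frame {f}: planted hydrogen bond {(d, h, a)} left the criteria")
        for p, c in bridges:
            if np.linalg.norm(frame[p] - frame[c]) > sb.max_distance:
                raise RuntimeError(f"frame {f}: planted salt bridge {(p, c)} left the cut-off")


@dataclass(frozen=True)
class EnergySeriesSpec:
    mean_vdw_bound: float = -40.0
    mean_el_bound: float = -20.0
    mean_vdw_unbound: float = -30.0
    mean_el_unbound: float = -15.0
    noise_sd: float = 2.0  # kcal/mol, stationary sd of each series
    autocorrelation: float = 0.3  # AR(1) coefficient in [0, 1)
    n_frames: int = 5000
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.autocorrelation < 1):
            raise ValueError("autocorrelation must be in [0, 1)")
        if self.noise_sd < 0 or self.n_frames < 1:
            raise ValueError("invalid noise_sd or n_frames")

    def ground_truth_dg(self, params: LIEParameters = LIEParameters()) -> float:
        """Closed-form LIE free energy implied by the four prescribed means."""
        return params.alpha * (self.mean_vdw_bound - self.mean_vdw_unbound) + params.beta * (
            self.mean_el_bound - self.mean_el_unbound
        )


def _ar1(rng, mean, sd, phi, n):
    """Stationary AR(1) series with the requested mean and marginal sd."""
    if sd == 0:
        return np.full(n, mean)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return mean + x


def make_energy_series(spec: EnergySeriesSpec) -> tuple[InteractionEnergySeries, InteractionEnergySeries]:
    """(bound, unbound) interaction-energy series with prescribed statistics."""
    rng = np.random.default_rng(spec.seed)
    phi, sd, n = spec.autocorrelation, spec.noise_sd, spec.n_frames
    bound = InteractionEnergySeries(
        v_vdw=_ar1(rng, spec.mean_vdw_bound, sd, phi, n),
        v_el=_ar1(rng, spec.mean_el_bound, sd, phi, n),
    )
    unbound = InteractionEnergySeries(
        v_vdw=_ar1(rng, spec.mean_vdw_unbound, sd, phi, n),
        v_el=_ar1(rng, spec.mean_el_unbound, sd, phi, n),
    )
    return bound, unbound


def _three_atom_fixture() -> tuple[Topology, np.ndarray]:
    atoms = [
        Atom(index=0, name="O", element="O", residue_name="HOH", residue_index=1),
        Atom(index=1, name="H1", element="H", residue_name="HOH", residue_index=1),
        Atom(index=2, name="N", element="N", residue_name="AMM", residue_index=2),
    ]
    coords = np.array([[0.0, 0.0, 0.0], [0.095, 0.0, 0.0], [0.30, 0.0, 0.0]])
    return Topology(atoms=atoms, bonds=[(0, 1)]), coords


def make_reference_fixtures(out_dir) -> dict[str, Path]:
    """Write the small deterministic fixture files used in docs and tests.

    Contents: a 3-atom PDB, the default toy complex (PDB topology, XYZ-table
    trajectory, parameter table, ledger JSON), the two-restraint NOE table
    (upper bounds 0.25 and 0.35 nm) and a 10-conformer disaccharide ensemble
    as a multi-MODEL PDB.  Regeneration is byte-identical.
    """
    from .conformation import GlycosidicTorsions, sample_ensemble

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    topo3, xyz3 = _three_atom_fixture()
    paths["three_atoms"] = out / "three_atoms.pdb"
    write_structure(paths["three_atoms"], topo3, xyz3)

    toy = make_toy_complex(ToySystemSpec())
    paths["toy_topology"] = out / "toy_complex.pdb"
    write_structure(paths["toy_topology"], toy.topology, toy.trajectory.coordinates[0])
    paths["toy_trajectory"] = out / "toy_trajectory.tsv"
    write_trajectory_xyz(paths["toy_trajectory"], toy.trajectory)
    paths["toy_ledger"] = out / "toy_ledger.json"
    with open(paths["toy_ledger"], "w") as fh:
        json.dump(toy.ledger, fh, indent=1, sort_keys=True)

    params = pd.DataFrame(
        [
            ("LIG", "P", -1.0, 0.585, 0.2150),
            ("LYS", "NZ", 1.0, 0.170, 0.1850),
            ("ARG", "CZ", 1.0, 0.110, 0.2000),
            ("SER", "OG", -0.5, 0.152, 0.1770),
        ],
        columns=["residue_name", "atom_name", "charge_e", "epsilon_kcal_mol", "rmin_half_nm"],
    )
    paths["parameters"] = out / "toy_parameters.tsv"
    write_parameter_table(paths["parameters"], params)

    restraints = [
        NOERestraint("H1A", "H1B", 0.25),
        NOERestraint("H5A", "H2B", 0.35),
    ]
    paths["restraints"] = out / "noe_restraints.tsv"
    write_restraints(paths["restraints"], restraints)

    ens = sample_ensemble(GlycosidicTorsions(60.0, -60.0), 15.0, 10, seed=0)
    paths["disaccharide_ensemble"] = out / "disaccharide_ensemble.pdb"
    write_trajectory_pdb(paths["disaccharide_ensemble"], ens.topology, ens.coordinates)

    return paths
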