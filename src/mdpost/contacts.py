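"""Per-frame hydrogen-bond and salt-bridge detection plus occupancy statistics.

Geometric criteria:

* hydrogen bond — donor-heavy→acceptor distance strictly below
  ``max_da_distance`` (default 0.35 nm) AND donor–hydrogen–acceptor angle
  strictly above ``min_dha_angle`` (default 150°);
* salt bridge — anion (central phosphorus by default) to cation
  (Arg CZ / Lys NZ by default) distance ≤ ``max_distance`` (default 0.7 nm;
  the cut-off is inclusive and boundary behavior is pinned by tests).

No periodic-boundary minimum-image handling is applied: frames are assumed
to contain whole, contiguously imaged complexes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import stats
from .geometry import angle
from .io_structures import Topology, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "HBondCriteria",
    "SaltBridgeCriteria",
    "ContactTimeSeries",
    "detect_hbonds",
    "detect_salt_bridges",
    "contact_timeseries",
]


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 0.35  # nm
    min_dha_angle: float = 150.0  # degrees

    def __post_init__(self):
        if not (0 < self.max_da_distance < 1):
            raise ValueError("max_da_distance must be in (0, 1) nm")
        if not (0 < self.min_dha_angle <= 180):
            raise ValueError("min_dha_angle must be in (0, 180] degrees")


@dataclass(frozen=True)
class SaltBridgeCriteria:
    max_distance: float = 0.7  # nm
    anion_atom_names: frozenset = frozenset({"P"})
    cation_atom_specs: frozenset = frozenset({("ARG", "CZ"), ("LYS", "NZ")})

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not self.anion_atom_names or not self.cation_atom_specs:
            raise ValueError("anion and cation atom sets must be non-empty")


@dataclass
class ContactTimeSeries:
    per_frame_counts: np.ndarray
    mean_count: float
    error: float
    n_blocks: int
    per_partner_occupancy: dict[str, float]

    def ranked_partners(self) -> list[tuple[str, float]]:
        return sorted(self.per_partner_occupancy.items(), key=lambda kv: (-kv[1], kv[0]))


def _scope_indices(topology: Topology, scope: str) -> tuple[set[int], set[int]]:
    """(side-1 atoms, side-2 atoms) for a contact scope.

    ``ligand-all`` needs a ``ligand`` group; ``ligand-protein`` additionally a
    ``receptor`` group; ``all`` imposes no partition (both sides = everything).
    """
    every = set(range(topology.n_atoms))
    if scope == "all":
        return every, every
    if "ligand" not in topology.groups:
        raise ValueError(f"scope {scope!r} requires a 'ligand' group in the topology")
    lig = set(topology.groups["ligand"])
    if scope == "ligand-all":
        return lig, every - lig
    if scope == "ligand-protein":
        if "receptor" not in topology.groups:
            raise ValueError("scope 'ligand-protein' requires a 'receptor' group")
        return lig, set(topology.groups["receptor"])
    raise ValueError(f"unknown scope {scope!r}")


def detect_hbonds(
    frame: np.ndarray,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
    scope: str = "all",
    exclude_intra_residue: bool = True,
) -> set[tuple[int, int, int]]:
    """Hydrogen bonds in one frame as (donor_heavy, hydrogen, acceptor) index triples.

    A triple is reported iff d(D, A) < max_da_distance and the D–H–A angle
    exceeds min_dha_angle (both strict), with D ≠ A.  Donor/acceptor roles
    come from the topology flags; under a two-sided scope the bond is kept
    when donor and acceptor fall on opposite sides (either direction).
    """
    frame = np.asarray(frame, dtype=float)
    side1, side2 = _scope_indices(topology, scope)
    in_scope = side1 | side2
    donors = [a for a in topology.atoms if a.is_donor_heavy and a.index in in_scope]
    acceptors = [a for a in topology.atoms if a.is_acceptor and a.index in in_scope]
    if not donors or not acceptors:
        raise ValueError(
            f"no flagged {'donors' if not donors else 'acceptors'} in scope {scope!r}: "
            "scope is empty rather than contact-free"
        )
    hydrogens = {a.index for a in topology.atoms if a.element == "H"}
    resid = {a.index: (a.chain, a.residue_index) for a in topology.atoms}

    acc_idx = np.array([a.index for a in acceptors], dtype=int)
    found: set[tuple[int, int, int]] = set()
    for d in donors:
        dist = np.linalg.norm(frame[acc_idx] - frame[d.index], axis=1)
        close = acc_idx[dist < criteria.max_da_distance]
        if close.size == 0:
            continue
        d_hydrogens = [j for j in topology.bonded(d.index) if j in hydrogens]
        for a_i in close:
            a_i = int(a_i)
            if a_i == d.index:
                continue
            if exclude_intra_residue and resid[a_i] == resid[d.index]:
                continue
            cross = (d.index in side1 and a_i in side2) or (d.index in side2 and a_i in side1)
            if not cross:
                continue
            for h in d_hydrogens:
                if angle(frame[d.index], frame[h], frame[a_i]) > criteria.min_dha_angle:
                    found.add((d.index, h, a_i))
    return found


def detect_salt_bridges(
    frame: np.ndarray,
    topology: Topology,
    criteria: SaltBridgeCriteria = SaltBridgeCriteria(),
) -> set[tuple[int, int]]:
    """Salt bridges in one frame as (anion_atom, cation_atom) index pairs.

    A pair is reported iff the distance is ≤ max_distance (inclusive).
    Anions are matched by atom name, cations by (residue_name, atom_name).
    """
    frame = np.asarray(frame, dtype=float)
    anions = [a for a in topology.atoms if a.name in criteria.anion_atom_names]
    cations = [a for a in topology.atoms if (a.residue_name, a.name) in criteria.cation_atom_specs]
    if not anions or not cations:
        raise ValueError(
            f"no {'anion' if not anions else 'cation'} atoms resolvable for salt-bridge detection: "
            "empty scope rather than zero contacts"
        )
    found: set[tuple[int, int]] = set()
    for an in anions:
        for cat in cations:
            if np.linalg.norm(frame[an.index] - frame[cat.index]) <= criteria.max_distance:
                found.add((an.index, cat.index))
    return found


def contact_timeseries(
    trajectory: Trajectory,
    topology: Topology,
    detector,
    detector_args: dict | None = None,
    n_blocks: int = stats.DEFAULT_N_BLOCKS,
) -> ContactTimeSeries:
    """Run a per-frame detector over a trajectory and aggregate statistics.

    Returns per-frame counts, the mean, the block-average error (0 with a
    warning when the series is too short to block) and per-partner occupancy
    fractions keyed by human-readable partner labels.
    """
    detector_args = detector_args or {}
    counts = []
    partner_frames: dict[str, int] = {}
    for frame in trajectory.coordinates:
        hits = detector(frame, topology, **detector_args)
        counts.append(len(hits))
        for hit in hits:
            # partner label: the two end atoms of the contact (D...A or anion-cation)
            i, j = hit[0], hit[-1]
            key = f"{topology.atoms[i].label}--{topology.atoms[j].label}"
            partner_frames[key] = partner_frames.get(key, 0) + 1
    counts = np.array(counts, dtype=float)
    n = len(counts)
    if n >= n_blocks:
        ba = stats.block_average(counts, n_blocks)
        mean, err, nb = ba.mean, ba.error, ba.n_blocks
    else:
        logger.warning("series of %d frames too short for %d blocks; error reported as 0", n, n_blocks)
        mean, err, nb = float(counts.mean()), 0.0, 1
    occ = {k: v / n for k, v in sorted(partner_frames.items())}
    return ContactTimeSeries(
        per_frame_counts=counts, mean_count=mean, error=err, n_blocks=nb, per_partner_occupancy=occ
    )


def hbond_loss_on_binding(unbound: ContactTimeSeries, bound: ContactTimeSeries) -> float:
    """Average number of hydrogen bonds lost upon binding.

    Difference of mean totals between the free-ligand reference series and
    the bound series (solvent partners included when present).
    """
    return unbound.mean_count - bound.mean_count
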