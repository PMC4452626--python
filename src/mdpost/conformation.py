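"""Idealized beta,alpha(1<->1)-linked diglucosamine builder and torsion analysis.

The two-bond (1<->1) glycosidic linkage between the alpha- and beta-configured
glucosamine rings is characterized by two torsions:

* ``phi_alpha`` = O5(alpha)-C1(alpha)-O1-C1(beta)
* ``phi_beta``  = C1(alpha)-O1-C1(beta)-O5(beta)

In the double exo-anomeric geometry each torsion sits in the gauche well of
its O5-C1-O1-C1' arrangement; with the atom ordering above and the builder's
D-sugar convention this is phi_alpha ~ +60 deg, phi_beta ~ -60 deg::

        O5a                       O5b
          \\                       /
           C1a --- O1 --- C1b----
          (alpha: O1 axial)   (beta: O1 equatorial)

Rings are ideal 4C1 chairs built from standard bond lengths (C-C 0.1526 nm,
C-O 0.143 nm, C-H 0.109 nm) and tetrahedral angles, closed exactly by
solving for the three free ring torsions.  Acyl chains and phosphates are
replaced by minimal caps (N2/O3/O4 heteroatoms and a C6 methyl carbon): the
inter-proton distance targets of the backbone do not depend on the chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import fsolve

from .geometry import angle, dihedral, kabsch_superpose, place_atom
from .io_structures import Atom, Topology, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "GlycosidicTorsions",
    "ConformerEnsemble",
    "build_disaccharide",
    "measure_glycosidic_torsions",
    "classify_conformation",
    "sample_ensemble",
    "ring_torsions",
]

# standard bond lengths (nm) and angles (deg)
BOND_CC = 0.1526
BOND_CO = 0.143
BOND_CH = 0.109
BOND_CN = 0.147
ANGLE_TET = 109.4712206
ANGLE_RING_O = 112.0  # C5-O5-C1 endocyclic ether angle
ANGLE_GLYC = 117.0  # C1-O1-C1' glycosidic valence angle
# O5-C1-O1 valence angle at the anomeric carbon.  Pyranosides open this
# O-C-O angle to ~112 deg (anomeric effect); a plain tetrahedral value here
# would leave the gauche-well H1-H1 distance above the 0.25 nm NMR bound.
ANGLE_ANOMERIC = 112.0

_SYN_HALF_WIDTH = 40.0  # syn-exo well: center +/- 40 deg, edges exclusive


def wrap_angle(x: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    y = (x + 180.0) % 360.0 - 180.0
    return 180.0 if y <= -180.0 + 1e-12 else float(y)


@dataclass(frozen=True)
class GlycosidicTorsions:
    phi_alpha: float  # deg, O5a-C1a-O1-C1b
    phi_beta: float  # deg, C1a-O1-C1b-O5b


def classify_conformation(t: GlycosidicTorsions) -> str:
    """"syn-exo/syn-exo" iff phi_alpha in (20, 100) and phi_beta in (-100, -20)."""
    lo_a, hi_a = 60.0 - _SYN_HALF_WIDTH, 60.0 + _SYN_HALF_WIDTH
    lo_b, hi_b = -60.0 - _SYN_HALF_WIDTH, -60.0 + _SYN_HALF_WIDTH
    if lo_a < t.phi_alpha < hi_a and lo_b < t.phi_beta < hi_b:
        return "syn-exo/syn-exo"
    return "other"


# ---------------------------------------------------------------------------
# ring template
# ---------------------------------------------------------------------------


def _ring_closure_residual(torsions, bonds, angles):
    o5, c1, c2, c3, c4, c5 = _ring_chain(torsions, bonds, angles)
    return [
        np.linalg.norm(c5 - o5) - bonds[5],
        angle(c4, c5, o5) - angles[4],
        angle(c5, o5, c1) - angles[5],
    ]


def _ring_chain(torsions, bonds, angles):
    """NeRF chain O5,C1..C5 from ring bonds/angles and three free torsions."""
    t1, t2, t3 = torsions
    o5 = np.zeros(3)
    c1 = np.array([bonds[0], 0.0, 0.0])
    c2 = place_atom(o5 + np.array([0.0, 1.0, 0.0]), o5, c1, bonds[1], angles[0], 0.0)
    # torsion t1 = O5-C1-C2-C3 etc.; angles[k] sits at the k-th placed atom
    c3 = place_atom(o5, c1, c2, bonds[2], angles[1], t1)
    c4 = place_atom(c1, c2, c3, bonds[3], angles[2], t2)
    c5 = place_atom(c2, c3, c4, bonds[4], angles[3], t3)
    return o5, c1, c2, c3, c4, c5


@lru_cache(maxsize=4)
def _chair_ring(handedness: int = 1) -> dict:
    """Exactly closed ideal 4C1 pyranose ring (6 atoms) plus helper frames.

    Bonds around the ring O5-C1-C2-C3-C4-C5-O5 use C-O 0.143 nm for the two
    ether bonds and C-C 0.1526 nm elsewhere; angles are tetrahedral at the
    carbons and 112 deg at the ring oxygen.  The three free torsions are
    solved so the ring closes exactly; ``handedness`` selects the chair
    enantiomer (+1 is the builder's D-sugar convention).
    """
    bonds = [BOND_CO, BOND_CC, BOND_CC, BOND_CC, BOND_CC, BOND_CO]
    angles = [ANGLE_TET] * 5 + [ANGLE_RING_O]
    guess = np.array([55.0, -55.0, 55.0]) * handedness
    sol = fsolve(_ring_closure_residual, guess, args=(bonds, angles), full_output=False, xtol=1e-13)
    res = _ring_closure_residual(sol, bonds, angles)
    if max(abs(v) for v in res) > 1e-8:
        raise RuntimeError(f"ring closure failed: residual {res}")
    o5, c1, c2, c3, c4, c5 = _ring_chain(sol, bonds, angles)
    ring = np.array([o5, c1, c2, c3, c4, c5])
    centroid = ring.mean(axis=0)
    normal = np.zeros(3)
    for i in range(6):
        normal += np.cross(ring[i] - centroid, ring[(i + 1) % 6] - centroid)
    normal /= np.linalg.norm(normal)
    return {"ring": ring, "normal": normal}


def _exocyclic_directions(center, nb1, nb2):
    """The two tetrahedral substituent unit vectors at ``center``.

    ``nb1``/``nb2`` are the ring neighbors; the returned directions make the
    tetrahedral angle with both ring bonds.
    """
    u1 = (nb1 - center) / np.linalg.norm(nb1 - center)
    u2 = (nb2 - center) / np.linalg.norm(nb2 - center)
    s = -(u1 + u2)
    s /= np.linalg.norm(s)
    n = np.cross(u1, u2)
    n /= np.linalg.norm(n)
    cos_t = np.cos(np.radians(ANGLE_TET)) / np.dot(s, u1)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return s * cos_t + n * sin_t, s * cos_t - n * sin_t


def _axial_equatorial(center, nb1, nb2, normal):
    """(axial, equatorial) unit substituent directions at a ring carbon."""
    wa, wb = _exocyclic_directions(center, nb1, nb2)
    if abs(np.dot(wa, normal)) >= abs(np.dot(wb, normal)):
        return wa, wb
    return wb, wa


def _direction_two_angles(center, nb1, nb2, ang1_deg, ang2_deg, like):
    """Unit vector from ``center`` at given angles to the two neighbor bonds.

    Of the two solutions the one closer to the reference direction ``like``
    is returned (used to keep the axial/equatorial identity of a substituent
    while refining one valence angle).
    """
    u1 = (nb1 - center) / np.linalg.norm(nb1 - center)
    u2 = (nb2 - center) / np.linalg.norm(nb2 - center)
    n = np.cross(u1, u2)
    n /= np.linalg.norm(n)
    g = float(np.dot(u1, u2))
    a, b = np.linalg.solve(
        np.array([[1.0, g], [g, 1.0]]),
        np.array([np.cos(np.radians(ang1_deg)), np.cos(np.radians(ang2_deg))]),
    )
    w_in = a * u1 + b * u2
    c = np.sqrt(max(1.0 - float(np.dot(w_in, w_in)), 0.0))
    cands = [w_in + c * n, w_in - c * n]
    best = max(cands, key=lambda w: float(np.dot(w, like)))
    return best / np.linalg.norm(best)


@lru_cache(maxsize=4)
def _glcn_template(anomeric: str) -> dict:
    """Full GlcN ring template with named atom positions.

    ``anomeric`` is "alpha" (O1 axial in the 4C1 chair) or "beta"
    (O1 equatorial); H1 takes the other slot.  Heavy substituents at
    C2..C5 (N2, O3, O4, C6) are equatorial, their protons axial.
    """
    if anomeric not in ("alpha", "beta"):
        raise ValueError("anomeric must be 'alpha' or 'beta'")
    chair = _chair_ring(1)
    o5, c1, c2, c3, c4, c5 = chair["ring"]
    normal = chair["normal"]
    pos = {"O5": o5, "C1": c1, "C2": c2, "C3": c3, "C4": c4, "C5": c5}
    neighbors = {"C1": (o5, c2), "C2": (c1, c3), "C3": (c2, c4), "C4": (c3, c5), "C5": (c4, o5)}

    ax1, eq1 = _axial_equatorial(c1, *neighbors["C1"], normal)
    if anomeric == "alpha":
        dir_o1, dir_h1 = ax1, eq1
    else:
        dir_o1, dir_h1 = eq1, ax1
    # refine O5-C1-O1 to the anomeric value, keeping the axial/equatorial slot
    dir_o1 = _direction_two_angles(c1, o5, c2, ANGLE_ANOMERIC, ANGLE_TET, like=dir_o1)
    pos["O1"] = c1 + BOND_CO * dir_o1
    pos["H1"] = c1 + BOND_CH * dir_h1

    heavies = {"C2": ("N2", BOND_CN), "C3": ("O3", BOND_CO), "C4": ("O4", BOND_CO), "C5": ("C6", BOND_CC)}
    for cname, (sub, blen) in heavies.items():
        ax, eq = _axial_equatorial(pos[cname], *neighbors[cname], normal)
        pos[sub] = pos[cname] + blen * eq
        pos["H" + cname[1]] = pos[cname] + BOND_CH * ax
    return {"pos": pos, "angle_o1_c1_o5": angle(pos["O1"], pos["C1"], pos["O5"])}


_RING_ATOM_ORDER = ["O5", "C1", "C2", "C3", "C4", "C5", "C6", "N2", "O3", "O4", "H1", "H2", "H3", "H4", "H5"]
_RING_BONDS = [
    ("O5", "C1"), ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"), ("C5", "O5"),
    ("C5", "C6"), ("C2", "N2"), ("C3", "O3"), ("C4", "O4"),
    ("C1", "H1"), ("C2", "H2"), ("C3", "H3"), ("C4", "H4"), ("C5", "H5"),
]


def build_disaccharide(phi_alpha: float, phi_beta: float) -> tuple[Topology, np.ndarray]:
    """Build the capped beta,alpha(1<->1) diglucosamine backbone at given torsions.

    Returns a Topology (alpha ring = residue GCA/1, suffix "A"; beta ring =
    residue GCB/2, suffix "B"; bridging oxygen "O1" on GCA) and coordinates
    in nm.  The measured torsions of the output reproduce the requested ones
    exactly (NeRF placement).  Non-bonded heavy-atom pairs closer than
    0.15 nm trigger a warning but the structure is still returned.
    """
    for phi in (phi_alpha, phi_beta):
        if not (-180.0 < phi <= 180.0):
            raise ValueError("torsions must lie in (-180, 180]")
    alpha = _glcn_template("alpha")
    beta = _glcn_template("beta")
    apos = alpha["pos"]

    o1 = apos["O1"]
    c1b = place_atom(apos["O5"], apos["C1"], o1, BOND_CO, ANGLE_GLYC, phi_alpha)
    o5b = place_atom(apos["C1"], o1, c1b, BOND_CO, beta["angle_o1_c1_o5"], phi_beta)

    bpos = beta["pos"]
    tmpl_pts = np.array([bpos["C1"], bpos["O1"], bpos["O5"]])
    target_pts = np.array([c1b, o1, o5b])
    fit = kabsch_superpose(tmpl_pts, target_pts, [0, 1, 2])
    if fit.fit_rmsd > 1e-9:
        raise RuntimeError(f"beta-ring attachment frame mismatch (rmsd {fit.fit_rmsd:.2e} nm)")

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    name_to_index: dict[str, int] = {}

    def add(name, element, resname, resid, xyz):
        name_to_index[name] = len(atoms)
        atoms.append(
            Atom(index=len(atoms), name=name, element=element, residue_name=resname, residue_index=resid)
        )
        coords.append(np.asarray(xyz, dtype=float))

    for base in _RING_ATOM_ORDER:
        add(base + "A", base[0] if base[0] != "H" else "H", "GCA", 1, apos[base])
    add("O1", "O", "GCA", 1, o1)
    for base in _RING_ATOM_ORDER:
        add(base + "B", base[0] if base[0] != "H" else "H", "GCB", 2, fit.apply(bpos[base][None, :])[0])

    bonds = []
    for suffix in ("A", "B"):
        for i, j in _RING_BONDS:
            bonds.append((name_to_index[i + suffix], name_to_index[j + suffix]))
    bonds.append((name_to_index["C1A"], name_to_index["O1"]))
    bonds.append((name_to_index["O1"], name_to_index["C1B"]))

    topology = Topology(atoms=atoms, bonds=bonds, groups={"alpha_ring": list(range(16)), "beta_ring": list(range(16, 31))})
    xyz = np.array(coords)

    bonded = {tuple(sorted(b)) for b in bonds}
    heavy = [a.index for a in atoms if a.element != "H"]
    for ii, i in enumerate(heavy):
        for j in heavy[ii + 1:]:
            if tuple(sorted((i, j))) in bonded:
                continue
            if np.linalg.norm(xyz[i] - xyz[j]) < 0.15:
                logger.warning(
                    "steric clash: %s-%s at %.3f nm (phi_alpha=%.1f, phi_beta=%.1f)",
                    atoms[i].name, atoms[j].name, float(np.linalg.norm(xyz[i] - xyz[j])), phi_alpha, phi_beta,
                )
    return topology, xyz


def measure_glycosidic_torsions(frame: np.ndarray, topology: Topology) -> GlycosidicTorsions:
    """Measure phi_alpha/phi_beta from a built (or compatible) structure.

    Requires atoms named O5A, C1A, O1, C1B, O5B to be resolvable.
    """
    frame = np.asarray(frame, dtype=float)
    try:
        idx = [topology.find(n) for n in ("O5A", "C1A", "O1", "C1B", "O5B")]
    except KeyError as exc:
        raise KeyError(f"cannot measure glycosidic torsions: {exc}") from exc
    o5a, c1a, o1, c1b, o5b = (frame[i] for i in idx)
    return GlycosidicTorsions(
        phi_alpha=dihedral(o5a, c1a, o1, c1b),
        phi_beta=dihedral(c1a, o1, c1b, o5b),
    )


def ring_torsions(frame: np.ndarray, topology: Topology, suffix: str) -> list[float]:
    """The six endocyclic torsions of one ring ("A" or "B"), in ring order."""
    names = ["O5", "C1", "C2", "C3", "C4", "C5"]
    idx = [topology.find(n + suffix) for n in names]
    pts = [np.asarray(frame, dtype=float)[i] for i in idx]
    return [dihedral(pts[k % 6], pts[(k + 1) % 6], pts[(k + 2) % 6], pts[(k + 3) % 6]) for k in range(6)]


def anomeric_chirality_sign(frame: np.ndarray, topology: Topology, suffix: str) -> int:
    """Sign of the O5-C1-O1/C2 improper at the anomeric center of one ring.

    Opposite signs for the two rings certify opposite (alpha vs beta)
    anomeric configurations.
    """
    frame = np.asarray(frame, dtype=float)
    c1 = frame[topology.find("C1" + suffix)]
    o5 = frame[topology.find("O5" + suffix)]
    o1 = frame[topology.find("O1")]
    c2 = frame[topology.find("C2" + suffix)]
    vol = np.dot(np.cross(o5 - c1, o1 - c1), c2 - c1)
    return int(np.sign(vol))


@dataclass
class ConformerEnsemble:
    """Seeded ensemble of built conformers with their generating torsions."""

    topology: Topology
    coordinates: np.ndarray  # (n_conformers, n_atoms, 3) nm
    torsions: np.ndarray  # (n_conformers, 2) deg: generating (phi_alpha, phi_beta)
    seed: int | None = None

    @property
    def n_conformers(self) -> int:
        return int(self.coordinates.shape[0])

    def trajectory(self) -> Trajectory:
        return Trajectory(coordinates=self.coordinates)

    def proton_distances(self, name_a: str, name_b: str) -> np.ndarray:
        ia, ib = self.topology.find(name_a), self.topology.find(name_b)
        return np.linalg.norm(self.coordinates[:, ia, :] - self.coordinates[:, ib, :], axis=1)


def sample_ensemble(
    center: GlycosidicTorsions,
    spread_deg: float,
    n: int,
    seed: int = 0,
) -> ConformerEnsemble:
    """Sample ``n`` conformers with torsions ~ Gaussian(center, spread), wrapped.

    The two torsions are drawn independently; conformers are built with
    :func:`build_disaccharide`.  Reproducible by ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spread_deg < 0:
        raise ValueError("spread must be >= 0")
    rng = np.random.default_rng(seed)
    pa = np.array([wrap_angle(v) for v in rng.normal(center.phi_alpha, spread_deg, size=n)])
    pb = np.array([wrap_angle(v) for v in rng.normal(center.phi_beta, spread_deg, size=n)])
    topology = None
    frames = []
    for a, b in zip(pa, pb):
        topo, xyz = build_disaccharide(float(a), float(b))
        topology = topology or topo
        frames.append(xyz)
    return ConformerEnsemble(
        topology=topology,
        coordinates=np.array(frames),
        torsions=np.column_stack([pa, pb]),
        seed=seed,
    )
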