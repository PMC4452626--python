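"""Ligand–environment nonbonded energies and LIE binding free energies.

The evaluator uses a Lennard-Jones 12-6 potential with Lorentz–Berthelot
combination and a Coulomb term, both damped by the cubic-in-r² switching
function acting between ``switch_on`` (1.0 nm) and ``cutoff`` (1.2 nm).
Energies are in kcal/mol, distances in nm, charges in elementary charges.

Binding free energies follow the linear interaction energy (LIE) model

    dG_bind = alpha * d<V_vdw> + beta * d<V_el>

with alpha = 0.18 and beta = 0.09, where the differences are taken between
the ligand-bound and unbound simulations.  Multiple binding poses are
combined by a Boltzmann-weighted (exponential) average with equal priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from . import stats
from .io_structures import Topology, Trajectory

__all__ = [
    "COULOMB_CONSTANT_KCAL",
    "NonbondedParams",
    "InteractionEnergySeries",
    "LIEParameters",
    "LIEResult",
    "pair_energy",
    "ligand_environment_energy",
    "interaction_energy_series",
    "lie_free_energy",
    "combine_poses",
    "dissociation_ratio",
    "pose_preference",
]

#: Coulomb constant in kcal·nm/(mol·e²) (138.935458 kJ·nm/(mol·e²) / 4.184)
COULOMB_CONSTANT_KCAL = 33.2063711


@dataclass(frozen=True)
class NonbondedParams:
    cutoff: float = 1.2  # nm
    switch_on: float = 1.0  # nm
    coulomb_constant: float = COULOMB_CONSTANT_KCAL
    relative_dielectric: float = 1.0

    def __post_init__(self):
        if not (0 < self.switch_on < self.cutoff):
            raise ValueError("require 0 < switch_on < cutoff")


def _switch_factor(r2: np.ndarray, s2: float, c2: float) -> np.ndarray:
    """Cubic-in-r² switch: 1 below switch_on, 0 beyond cutoff, C¹ in between."""
    sw = (c2 - r2) ** 2 * (c2 + 2.0 * r2 - 3.0 * s2) / (c2 - s2) ** 3
    return np.where(r2 <= s2, 1.0, np.where(r2 >= c2, 0.0, sw))


def pair_energy(atom_i, atom_j, r: float, params: NonbondedParams = NonbondedParams()) -> tuple[float, float]:
    """(v_vdw, v_el) in kcal/mol for one atom pair at separation ``r`` (nm).

    LJ uses eps_ij = sqrt(eps_i eps_j) and rmin_ij = rmin_half_i +
    rmin_half_j so that V = eps[(rmin/r)^12 - 2(rmin/r)^6]; the Coulomb term
    is k q_i q_j / (eps_r r).  Both are multiplied by the switching factor
    and are exactly zero at and beyond the cutoff.
    """
    if r <= 0:
        raise ValueError("pair separation must be positive")
    if r >= params.cutoff:
        return 0.0, 0.0
    sw = float(_switch_factor(np.array(r * r), params.switch_on**2, params.cutoff**2))
    eps = np.sqrt(atom_i.lj_epsilon * atom_j.lj_epsilon)
    v_vdw = 0.0
    if eps > 0:
        rmin = atom_i.lj_rmin_half + atom_j.lj_rmin_half
        x6 = (rmin / r) ** 6
        v_vdw = eps * (x6 * x6 - 2.0 * x6) * sw
    v_el = params.coulomb_constant * atom_i.charge * atom_j.charge / (params.relative_dielectric * r) * sw
    return float(v_vdw), float(v_el)


def ligand_environment_energy(
    frame: np.ndarray,
    topology: Topology,
    ligand_selection,
    params: NonbondedParams = NonbondedParams(),
) -> tuple[float, float]:
    """Total (v_vdw, v_el) between the ligand and everything else in one frame.

    Sums over all (ligand, non-ligand) pairs; intra-ligand and
    environment-internal pairs are excluded.
    """
    frame = np.asarray(frame, dtype=float)
    lig = sorted(set(int(i) for i in ligand_selection))
    if not lig:
        raise ValueError("ligand selection is empty")
    env = sorted(set(range(topology.n_atoms)) - set(lig))
    if not env:
        raise ValueError("environment is empty: ligand selection covers every atom")

    q = np.array([a.charge for a in topology.atoms])
    eps = np.array([a.lj_epsilon for a in topology.atoms])
    rmh = np.array([a.lj_rmin_half for a in topology.atoms])

    diff = frame[lig][:, None, :] - frame[env][None, :, :]
    r2 = np.sum(diff * diff, axis=-1)
    if (r2 <= 0).any():
        raise ValueError("coincident ligand/environment atoms (r = 0)")
    c2, s2 = params.cutoff**2, params.switch_on**2
    mask = r2 < c2
    sw = np.where(mask, _switch_factor(r2, s2, c2), 0.0)

    eps_ij = np.sqrt(np.outer(eps[lig], eps[env]))
    rmin_ij = rmh[lig][:, None] + rmh[env][None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        x6 = np.where(mask, (rmin_ij**2 / r2) ** 3, 0.0)
    v_vdw = float(np.sum(eps_ij * (x6 * x6 - 2.0 * x6) * sw))

    r = np.sqrt(r2)
    v_el = float(
        np.sum(np.where(mask, params.coulomb_constant * np.outer(q[lig], q[env]) / (params.relative_dielectric * r), 0.0) * sw)
    )
    return v_vdw, v_el


@dataclass
class InteractionEnergySeries:
    """Per-frame ligand–surrounding vdW and electrostatic energies (kcal/mol)."""

    v_vdw: np.ndarray
    v_el: np.ndarray
    n_blocks: int = stats.DEFAULT_N_BLOCKS
    mean_vdw: float = field(init=False)
    mean_el: float = field(init=False)
    error_vdw: float = field(init=False)
    error_el: float = field(init=False)

    def __post_init__(self):
        self.v_vdw = np.asarray(self.v_vdw, dtype=float)
        self.v_el = np.asarray(self.v_el, dtype=float)
        if self.v_vdw.size == 0 or self.v_vdw.shape != self.v_el.shape:
            raise ValueError("v_vdw and v_el must be non-empty series of equal length")
        if self.v_vdw.size >= self.n_blocks:
            bv = stats.block_average(self.v_vdw, self.n_blocks)
            be = stats.block_average(self.v_el, self.n_blocks)
            self.mean_vdw, self.error_vdw = bv.mean, bv.error
            self.mean_el, self.error_el = be.mean, be.error
        else:
            self.mean_vdw = float(self.v_vdw.mean())
            self.mean_el = float(self.v_el.mean())
            self.error_vdw = self.error_el = 0.0


def interaction_energy_series(
    trajectory: Trajectory,
    topology: Topology,
    ligand_selection,
    params: NonbondedParams = NonbondedParams(),
    n_blocks: int = stats.DEFAULT_N_BLOCKS,
) -> InteractionEnergySeries:
    """Evaluate :func:`ligand_environment_energy` over every frame."""
    vdw, el = [], []
    for frame in trajectory.coordinates:
        v, e = ligand_environment_energy(frame, topology, ligand_selection, params)
        vdw.append(v)
        el.append(e)
    return InteractionEnergySeries(v_vdw=np.array(vdw), v_el=np.array(el), n_blocks=n_blocks)


@dataclass(frozen=True)
class LIEParameters:
    alpha: float = 0.18
    beta: float = 0.09
    temperature: float = 298.0  # K
    gas_constant: float = 1.9872e-3  # kcal/(mol K)

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0 or self.temperature <= 0:
            raise ValueError("alpha, beta and temperature must be positive")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass
class LIEResult:
    dg_bind: float  # kcal/mol
    error: float  # kcal/mol
    kd: float  # exp(dG/RT): dimensionless ratio to standard state
    delta_vdw: float
    delta_el: float
    params: LIEParameters


def lie_free_energy(
    bound: InteractionEnergySeries,
    unbound: InteractionEnergySeries,
    params: LIEParameters = LIEParameters(),
) -> LIEResult:
    """LIE binding free energy from bound/unbound interaction-energy series.

    The error is the quadrature combination of the four block-average errors
    weighted by alpha/beta.
    """
    d_vdw = bound.mean_vdw - unbound.mean_vdw
    d_el = bound.mean_el - unbound.mean_el
    dg = params.alpha * d_vdw + params.beta * d_el
    err = float(
        np.sqrt(
            params.alpha**2 * (bound.error_vdw**2 + unbound.error_vdw**2)
            + params.beta**2 * (bound.error_el**2 + unbound.error_el**2)
        )
    )
    return LIEResult(
        dg_bind=float(dg),
        error=err,
        kd=float(np.exp(dg / params.rt)),
        delta_vdw=float(d_vdw),
        delta_el=float(d_el),
        params=params,
    )


def combine_poses(per_pose_dg: dict, params: LIEParameters = LIEParameters()) -> float:
    """Boltzmann-weighted (exponential-average) free energy over binding poses.

    dG_comb = -RT ln[(1/N) sum_i exp(-dG_i/RT)] with equal pose priors, so
    min_i dG_i <= dG_comb <= min_i dG_i + RT ln N: the left bound is reached
    when all poses are equal (equal poses return their common value), the
    right when a single pose dominates.
    """
    if not per_pose_dg:
        raise ValueError("need at least one pose")
    g = np.array(list(per_pose_dg.values()), dtype=float)
    rt = params.rt
    return float(-rt * (logsumexp(-g / rt) - np.log(g.size)))


def dissociation_ratio(dg_a: float, dg_b: float, params: LIEParameters = LIEParameters()) -> float:
    """Fold difference in Kd between two ligands: exp((dG_b - dG_a)/RT).

    Greater than 1 iff ligand A binds more strongly (more negative dG).
    """
    if not (np.isfinite(dg_a) and np.isfinite(dg_b)):
        raise ValueError("free energies must be finite")
    return float(np.exp((dg_b - dg_a) / params.rt))


def pose_preference(dg_pose_a: float, dg_pose_b: float) -> float:
    """Relative pose free energy ddG = dG_B - dG_A; positive means pose B disfavored."""
    if not (np.isfinite(dg_pose_a) and np.isfinite(dg_pose_b)):
        raise ValueError("free energies must be finite")
    return float(dg_pose_b - dg_pose_a)
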