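"""Configuration-driven end-to-end runs.

A single declarative YAML config describes inputs, selections and criteria;
``run_contacts``, ``run_lie`` and ``run_noe`` produce the three report
surfaces (contact/occupancy table, LIE free-energy report, NOE violation
table).  All numeric defaults equal the methodology constants (0.35 nm/150
deg hydrogen bonds, 0.7 nm salt bridges, alpha 0.18/beta 0.09, 298 K,
1.0/1.2 nm switching, block count 5), so an override-free run reproduces the
reference analysis choices.  Every report embeds the parameters used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats
from .contacts import (
    HBondCriteria,
    SaltBridgeCriteria,
    contact_timeseries,
    detect_hbonds,
    detect_salt_bridges,
)
from .energetics import (
    InteractionEnergySeries,
    LIEParameters,
    NonbondedParams,
    combine_poses,
    dissociation_ratio,
    interaction_energy_series,
    lie_free_energy,
    pose_preference,
)
from .geometry import rmsd_timeseries
from .io_structures import (
    Topology,
    apply_parameters,
    infer_bonds,
    read_parameter_table,
    read_restraints,
    read_structure,
    read_trajectory,
    select_atoms,
)
from .noe import violation_report

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "DataError", "RunConfig", "run_contacts", "run_lie", "run_noe", "run_all"]


class ConfigError(ValueError):
    """Invalid or incomplete configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Inputs that parse but cannot be analysed (CLI exit code 3)."""


@dataclass
class RunConfig:
    raw: dict
    base_dir: Path

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        return cls(raw=raw, base_dir=path.parent)

    def path(self, value: str) -> Path:
        p = Path(value)
        p = p if p.is_absolute() else self.base_dir / p
        if not p.exists():
            raise ConfigError(f"referenced file does not exist: {p}")
        return p

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def n_blocks(self) -> int:
        return int(self.raw.get("n_blocks", stats.DEFAULT_N_BLOCKS))

    @property
    def discard_initial_ps(self) -> float:
        return float(self.raw.get("discard_initial_ps", 0.0))

    def output_dir(self, override=None) -> Path:
        out = Path(override) if override else Path(self.raw.get("output_dir", "mdpost_out"))
        out = out if out.is_absolute() else self.base_dir / out
        out.mkdir(parents=True, exist_ok=True)
        return out

    def lie_parameters(self) -> LIEParameters:
        sec = self.raw.get("lie", {}) or {}
        return LIEParameters(
            alpha=float(sec.get("alpha", 0.18)),
            beta=float(sec.get("beta", 0.09)),
            temperature=float(sec.get("temperature", 298.0)),
        )


def _load_system(cfg: RunConfig) -> tuple[Topology, np.ndarray]:
    if "topology" not in cfg.raw:
        raise ConfigError("config needs a 'topology' entry")
    topo, coords = read_structure(cfg.path(cfg.raw["topology"]), dialect="pdb")
    if "parameters" in cfg.raw:
        apply_parameters(topo, read_parameter_table(cfg.path(cfg.raw["parameters"])))
    if cfg.raw.get("infer_bonds", False):
        infer_bonds(topo, coords)
    topo.assign_donors_acceptors()
    for gname, expr in (cfg.raw.get("selections") or {}).items():
        topo.groups[gname] = select_atoms(topo, expr)
    return topo, coords


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_contacts(cfg: RunConfig, out_dir=None) -> dict:
    """Contact occupancy report: mean H-bonds/salt bridges ± block errors,
    per-partner occupancies, and optional marker-residue RMSD."""
    sec = cfg.raw.get("contacts")
    if not sec:
        raise ConfigError("config has no 'contacts' section")
    topo, ref_coords = _load_system(cfg)
    if "trajectory" not in sec:
        raise ConfigError("'contacts' section needs a 'trajectory'")
    traj = read_trajectory(cfg.path(sec["trajectory"]), topo, discard_initial=cfg.discard_initial_ps)

    hb_over = sec.get("hbond", {}) or {}
    hb = HBondCriteria(
        max_da_distance=float(hb_over.get("max_da_distance", 0.35)),
        min_dha_angle=float(hb_over.get("min_dha_angle", 150.0)),
    )
    sb_over = sec.get("salt_bridge", {}) or {}
    sb = SaltBridgeCriteria(
        max_distance=float(sb_over.get("max_distance", 0.7)),
        anion_atom_names=frozenset(sb_over.get("anion_atom_names", ["P"])),
        cation_atom_specs=frozenset(
            tuple(x) for x in sb_over.get("cation_atom_specs", [("ARG", "CZ"), ("LYS", "NZ")])
        ),
    )
    scope = sec.get("scope", "ligand-all")
    try:
        hb_series = contact_timeseries(
            traj, topo, detect_hbonds, {"criteria": hb, "scope": scope}, n_blocks=cfg.n_blocks
        )
        sb_series = contact_timeseries(traj, topo, detect_salt_bridges, {"criteria": sb}, n_blocks=cfg.n_blocks)
    except ValueError as exc:
        raise DataError(str(exc)) from exc

    report = {
        "criteria": {
            "hbond_max_da_distance_nm": hb.max_da_distance,
            "hbond_min_dha_angle_deg": hb.min_dha_angle,
            "salt_bridge_max_distance_nm": sb.max_distance,
            "scope": scope,
            "n_blocks": cfg.n_blocks,
        },
        "n_frames": traj.n_frames,
        "hbonds": {"mean": hb_series.mean_count, "error": hb_series.error},
        "salt_bridges": {"mean": sb_series.mean_count, "error": sb_series.error},
    }

    marker = sec.get("marker")
    if marker:
        fit_idx = select_atoms(topo, marker["fit"])
        meas_idx = select_atoms(topo, marker["measure"])
        if marker.get("heavy_only", True):
            meas_idx = [i for i in meas_idx if topo.atoms[i].element != "H"]
        if len(fit_idx) < 3 or not meas_idx:
            raise DataError("marker RMSD needs >=3 fit atoms and a non-empty measure selection")
        series = rmsd_timeseries(traj, ref_coords, fit_idx, meas_idx)
        report["marker_rmsd"] = {"final_nm": series.final, "mean_nm": series.mean}

    out = cfg.output_dir(out_dir)
    _write_json(out / "contacts_summary.json", report)
    rows = [("hbond", key, occ) for key, occ in hb_series.ranked_partners()]
    rows += [("salt_bridge", key, occ) for key, occ in sb_series.ranked_partners()]
    pd.DataFrame(rows, columns=["contact_type", "partner", "occupancy"]).to_csv(
        out / "contacts_partners.tsv", sep="\t", index=False, float_format="%.6f"
    )
    pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames) + 1,
            "n_hbonds": hb_series.per_frame_counts.astype(int),
            "n_salt_bridges": sb_series.per_frame_counts.astype(int),
        }
    ).to_csv(out / "contacts_series.tsv", sep="\t", index=False)
    return report


def _load_energy_series(cfg: RunConfig, entry, state: str, topo_cache: dict) -> InteractionEnergySeries:
    key_series = f"{state}_series"
    key_traj = f"{state}_trajectory"
    if key_series in entry:
        df = pd.read_csv(cfg.path(entry[key_series]), sep=r"\s+")
        for c in ("v_vdw_kcal", "v_el_kcal"):
            if c not in df.columns:
                raise ConfigError(f"energy series {entry[key_series]} missing column {c!r}")
        return InteractionEnergySeries(
            v_vdw=df["v_vdw_kcal"].to_numpy(), v_el=df["v_el_kcal"].to_numpy(), n_blocks=cfg.n_blocks
        )
    if key_traj in entry:
        if "system" not in topo_cache:
            topo_cache["system"] = _load_system(cfg)
        topo, _ = topo_cache["system"]
        if "ligand" not in topo.groups:
            raise ConfigError("LIE from trajectories needs a 'ligand' selection")
        traj = read_trajectory(cfg.path(entry[key_traj]), topo, discard_initial=cfg.discard_initial_ps)
        nb = cfg.raw.get("nonbonded", {}) or {}
        params = NonbondedParams(
            cutoff=float(nb.get("cutoff", 1.2)), switch_on=float(nb.get("switch_on", 1.0))
        )
        return interaction_energy_series(traj, topo, topo.groups["ligand"], params, n_blocks=cfg.n_blocks)
    raise ConfigError(
        f"pose entry needs '{key_series}' or '{key_traj}': LIE requires both bound and unbound states"
    )


def run_lie(cfg: RunConfig, out_dir=None) -> dict:
    """LIE report: per-pose dG ± error, pose-combined dG, pose preference and
    Kd fold-ratios versus named reference ligands."""
    sec = cfg.raw.get("lie")
    if not sec:
        raise ConfigError("config has no 'lie' section")
    poses = sec.get("poses")
    if not poses:
        raise ConfigError("'lie' section needs a non-empty 'poses' mapping")
    params = cfg.lie_parameters()
    topo_cache: dict = {}
    per_pose = {}
    for pose_id, entry in sorted(poses.items()):
        bound = _load_energy_series(cfg, entry, "bound", topo_cache)
        unbound = _load_energy_series(cfg, entry, "unbound", topo_cache)
        res = lie_free_energy(bound, unbound, params)
        per_pose[pose_id] = {
            "dg_kcal": res.dg_bind,
            "error_kcal": res.error,
            "delta_vdw_kcal": res.delta_vdw,
            "delta_el_kcal": res.delta_el,
        }
    dgs = {p: v["dg_kcal"] for p, v in per_pose.items()}
    combined = combine_poses(dgs, params)
    report = {
        "parameters": {
            "alpha": params.alpha,
            "beta": params.beta,
            "temperature_K": params.temperature,
            "n_blocks": cfg.n_blocks,
        },
        "per_pose": per_pose,
        "combined_dg_kcal": combined,
    }
    if set(dgs) >= {"A", "B"}:
        report["ddg_pose_b_minus_a_kcal"] = pose_preference(dgs["A"], dgs["B"])
    for name, ref_dg in sorted((sec.get("reference_ligands") or {}).items()):
        report.setdefault("kd_fold_vs_reference", {})[name] = dissociation_ratio(
            combined, float(ref_dg), params
        )
    out = cfg.output_dir(out_dir)
    _write_json(out / "lie_report.json", report)
    return report


def run_noe(cfg: RunConfig, out_dir=None) -> dict:
    """NOE report: per-restraint effective distance ± error, bound, violation."""
    sec = cfg.raw.get("noe")
    if not sec:
        raise ConfigError("config has no 'noe' section")
    if "restraints" not in sec:
        raise ConfigError("'noe' section needs a 'restraints' table")
    restraints = read_restraints(cfg.path(sec["restraints"]))
    if "trajectory" not in sec:
        raise ConfigError("'noe' section needs a 'trajectory' (multi-MODEL PDB ensemble)")
    # NOE ensembles come as their own multi-model file carrying its own topology
    ens_path = cfg.path(sec["trajectory"])
    topo, _ = read_structure(ens_path, dialect="pdb")
    traj = read_trajectory(ens_path, topo, discard_initial=cfg.discard_initial_ps)
    out = cfg.output_dir(out_dir)
    if not restraints:
        logger.warning("restraint table is empty; writing empty report")
        pd.DataFrame(columns=["atom_a", "atom_b", "upper_bound_nm", "effective_nm", "mean_nm", "error_nm", "violation_nm"]).to_csv(
            out / "noe_report.tsv", sep="\t", index=False
        )
        report = {"max_violation_nm": 0.0, "n_violated": 0, "n_restraints": 0, "n_blocks": cfg.n_blocks}
        _write_json(out / "noe_summary.json", report)
        return report
    try:
        summary = violation_report(traj, topo, restraints, n_blocks=cfg.n_blocks)
    except KeyError as exc:
        raise DataError(str(exc)) from exc
    pd.DataFrame(
        [
            (
                r.restraint.atom_a_name,
                r.restraint.atom_b_name,
                r.restraint.upper_bound,
                r.effective_distance,
                r.mean_distance,
                r.error,
                r.violation,
            )
            for r in summary.results
        ],
        columns=["atom_a", "atom_b", "upper_bound_nm", "effective_nm", "mean_nm", "error_nm", "violation_nm"],
    ).to_csv(out / "noe_report.tsv", sep="\t", index=False, float_format="%.6f")
    report = {
        "max_violation_nm": summary.max_violation,
        "n_violated": summary.n_violated,
        "n_restraints": len(summary.results),
        "n_blocks": cfg.n_blocks,
    }
    _write_json(out / "noe_summary.json", report)
    return report


def run_all(cfg: RunConfig, out_dir=None) -> dict:
    results = {}
    for name, fn in (("contacts", run_contacts), ("lie", run_lie), ("noe", run_noe)):
        if cfg.raw.get(name):
            results[name] = fn(cfg, out_dir)
    if not results:
        raise ConfigError("config has no 'contacts', 'lie' or 'noe' section")
    return results
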