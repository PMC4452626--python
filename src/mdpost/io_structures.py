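"""Structure / trajectory / table I/O and atom selection.

Internal units are nm everywhere; PDB files are converted Å↔nm at the
boundary (factor 0.1).  Atom indices are 0-based in memory and 1-based in all
file output.

Charges and Lennard-Jones parameters are not part of the PDB format; they are
supplied in a whitespace-delimited parameter table keyed by
``(residue_name, atom_name)`` and applied with :func:`apply_parameters`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "NOERestraint",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory_xyz",
    "write_trajectory_pdb",
    "read_parameter_table",
    "apply_parameters",
    "read_restraints",
    "write_restraints",
    "select_atoms",
    "infer_bonds",
    "SelectionError",
]

ANGSTROM_PER_NM = 10.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    """One atom with identity, charge and LJ parameters (kcal/mol, nm)."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain: str = "A"
    charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 0.0
    is_donor_heavy: bool = False
    is_acceptor: bool = False

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.name}: lj_epsilon must be >= 0")

    @property
    def label(self) -> str:
        """Human-readable id, e.g. ``LYS122:NZ``."""
        return f"{self.residue_name}{self.residue_index}:{self.name}"


@dataclass
class Topology:
    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    groups: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            if a.index in seen:
                raise ValueError(f"duplicate atom index {a.index}")
            seen.add(a.index)
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) references invalid atom index")
        for gname, idx in self.groups.items():
            for i in idx:
                if not (0 <= i < n):
                    raise ValueError(f"group {gname!r} references invalid atom index {i}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def bonded(self, index: int) -> list[int]:
        out = [j for i, j in self.bonds if i == index]
        out += [i for i, j in self.bonds if j == index]
        return sorted(set(out))

    def assign_donors_acceptors(self) -> None:
        """Element-based donor/acceptor flags.

        Acceptor: any N or O.  Donor heavy atom: N or O covalently bonded to
        at least one hydrogen (requires bonds).
        """
        hydrogens = {a.index for a in self.atoms if a.element == "H"}
        for a in self.atoms:
            a.is_acceptor = a.element in ("N", "O")
            a.is_donor_heavy = a.element in ("N", "O") and any(
                j in hydrogens for j in self.bonded(a.index)
            )

    def validate_hydrogens(self) -> None:
        if not self.bonds:
            return
        for a in self.atoms:
            if a.element == "H" and not self.bonded(a.index):
                raise ValueError(f"hydrogen {a.label} has no bonded heavy atom")

    def find(self, name: str, residue_index: int | None = None) -> int:
        """Index of the unique atom with ``name`` (optionally within a residue)."""
        hits = [
            a.index
            for a in self.atoms
            if a.name == name and (residue_index is None or a.residue_index == residue_index)
        ]
        if not hits:
            raise KeyError(f"no atom named {name!r}" + (f" in residue {residue_index}" if residue_index else ""))
        if len(hits) > 1:
            raise KeyError(f"atom name {name!r} is ambiguous ({len(hits)} matches); qualify by residue")
        return hits[0]


@dataclass
class Trajectory:
    """Ordered coordinate frames in nm; shape (n_frames, n_atoms, 3)."""

    coordinates: np.ndarray
    frame_times: np.ndarray | None = None  # ps

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape[0] != self.n_frames:
                raise ValueError("frame_times length must match n_frames")

    @property
    def n_frames(self) -> int:
        return int(self.coordinates.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coordinates.shape[1])


@dataclass(frozen=True)
class NOERestraint:
    """An inter-proton NMR upper-bound restraint (nm)."""

    atom_a_name: str
    atom_b_name: str
    upper_bound: float

    def __post_init__(self):
        if self.upper_bound <= 0:
            raise ValueError("upper_bound must be positive")


# ---------------------------------------------------------------------------
# element inference
# ---------------------------------------------------------------------------

_TWO_LETTER = {"CL", "BR", "NA", "MG", "ZN", "FE", "CA", "MN", "SE"}


def _element_from_name(name: str) -> str:
    # Strip leading digits (PDB-style names like 1HB), then take the leading
    # letter; sugar/protein systems here only need one-letter elements plus P.
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "X"
    return stripped[0].upper()


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def _parse_pdb_atom_line(line: str, lineno: int) -> tuple[dict, np.ndarray]:
    try:
        name = line[12:16].strip()
        resname = line[17:21].strip()
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"unparseable ATOM record at line {lineno}: {line.rstrip()!r}") from exc
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = _element_from_name(name)
    fields = dict(name=name, element=element, residue_name=resname, residue_index=resid, chain=chain)
    return fields, np.array([x, y, z]) / ANGSTROM_PER_NM


def _read_pdb(path: Path) -> tuple[list[list[dict]], list[np.ndarray]]:
    """All models of a PDB file as (per-model atom fields, per-model coords in nm)."""
    models: list[list[dict]] = []
    coords: list[np.ndarray] = []
    cur_fields: list[dict] = []
    cur_xyz: list[np.ndarray] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                cur_fields, cur_xyz = [], []
            elif rec in ("ATOM", "HETATM"):
                f, xyz = _parse_pdb_atom_line(line, lineno)
                cur_fields.append(f)
                cur_xyz.append(xyz)
            elif rec == "ENDMDL":
                models.append(cur_fields)
                coords.append(np.array(cur_xyz))
                cur_fields, cur_xyz = [], []
                in_model = False
    if cur_fields:
        models.append(cur_fields)
        coords.append(np.array(cur_xyz))
    if not models:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    del in_model
    return models, coords


def _topology_from_fields(fields: list[dict]) -> Topology:
    atoms = [Atom(index=i, **f) for i, f in enumerate(fields)]
    return Topology(atoms=atoms)


def read_structure(path, dialect: str = "pdb") -> tuple[Topology, np.ndarray]:
    """Read a structure file; returns (Topology, first-frame coordinates in nm).

    ``dialect`` is ``"pdb"`` or ``"xyz-table"`` (the flat per-frame table also
    used for trajectories; the first frame is taken, and atom identities are
    synthesized as unnamed carbons — the PDB dialect is the one that carries
    identity).  Multi-MODEL PDB input yields the first model with a warning.
    """
    path = Path(path)
    if dialect == "pdb":
        models, coords = _read_pdb(path)
        if len(models) > 1:
            logger.warning("%s contains %d models; using the first", path, len(models))
        return _topology_from_fields(models[0]), coords[0]
    if dialect == "xyz-table":
        frames, _times = _read_xyz_table(path)
        fields = [
            dict(name=f"C{i+1}", element="C", residue_name="UNK", residue_index=1, chain="A")
            for i in range(frames.shape[1])
        ]
        return _topology_from_fields(fields), frames[0]
    raise ValueError(f"unknown dialect {dialect!r}")


def write_structure(path, topology: Topology, coordinates: np.ndarray) -> None:
    """Write a single-model PDB (coordinates nm→Å, 1-based serials)."""
    write_trajectory_pdb(path, topology, np.asarray(coordinates, dtype=float)[None, :, :], model_records=False)


def _pdb_atom_line(serial: int, a: Atom, xyz_nm: np.ndarray) -> str:
    x, y, z = xyz_nm * ANGSTROM_PER_NM
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {serial:>5d} {name:<4.4s} {a.residue_name:<4.4s}{a.chain[:1]}{a.residue_index:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2.2s}\n"
    )


def write_trajectory_pdb(path, topology: Topology, coordinates: np.ndarray, model_records: bool = True) -> None:
    coordinates = np.asarray(coordinates, dtype=float)
    with open(path, "w") as fh:
        for m, frame in enumerate(coordinates, start=1):
            if model_records:
                fh.write(f"MODEL     {m:>4d}\n")
            for a in topology.atoms:
                fh.write(_pdb_atom_line(a.index + 1, a, frame[a.index]))
            if model_records:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# flat XYZ-table trajectories (native dialect, nm)
# ---------------------------------------------------------------------------

_XYZ_COLUMNS = ["frame", "atom_index", "x", "y", "z"]


def _read_xyz_table(path: Path) -> tuple[np.ndarray, np.ndarray | None]:
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _XYZ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: xyz table header missing columns {missing}")
    n_frames = df["frame"].nunique()
    frames = []
    times = [] if "time_ps" in df.columns else None
    for fkey, sub in df.groupby("frame", sort=True):
        sub = sub.sort_values("atom_index")
        if (sub["atom_index"].to_numpy() != np.arange(1, len(sub) + 1)).any():
            raise ValueError(f"{path}: frame {fkey} has non-contiguous 1-based atom indices")
        frames.append(sub[["x", "y", "z"]].to_numpy(dtype=float))
        if times is not None:
            times.append(float(sub["time_ps"].iloc[0]))
    lengths = {f.shape[0] for f in frames}
    if len(lengths) > 1:
        raise ValueError(f"{path}: frames have inconsistent atom counts {sorted(lengths)}")
    del n_frames
    return np.array(frames), (np.array(times) if times is not None else None)


def write_trajectory_xyz(path, trajectory: Trajectory) -> None:
    """Write the flat per-frame table (1-based frame and atom indices, nm)."""
    with open(path, "w") as fh:
        cols = _XYZ_COLUMNS + (["time_ps"] if trajectory.frame_times is not None else [])
        fh.write("\t".join(cols) + "\n")
        for f in range(trajectory.n_frames):
            for i in range(trajectory.n_atoms):
                x, y, z = trajectory.coordinates[f, i]
                row = f"{f + 1}\t{i + 1}\t{x:.9f}\t{y:.9f}\t{z:.9f}"
                if trajectory.frame_times is not None:
                    row += f"\t{trajectory.frame_times[f]:.6f}"
                fh.write(row + "\n")


def read_trajectory(path, topology: Topology, discard_initial: float = 0.0, dialect: str | None = None) -> Trajectory:
    """Read a multi-frame trajectory and drop the initial equilibration part.

    Frames with time < ``discard_initial`` (ps) are removed; when the file
    carries no explicit times the frame index in ps is used.  The dialect is
    inferred from the suffix (``.pdb`` → multi-model PDB, else xyz table)
    unless given explicitly.
    """
    path = Path(path)
    if dialect is None:
        dialect = "pdb" if path.suffix.lower() == ".pdb" else "xyz-table"
    if dialect == "pdb":
        models, coords = _read_pdb(path)
        for k, frame in enumerate(coords):
            if frame.shape[0] != topology.n_atoms:
                raise ValueError(
                    f"{path}: frame {k + 1} has {frame.shape[0]} atoms, topology has {topology.n_atoms}"
                )
        frames = np.array(coords)
        times = None
    else:
        frames, times = _read_xyz_table(path)
        for k, frame in enumerate(frames):
            if frame.shape[0] != topology.n_atoms:
                raise ValueError(
                    f"{path}: frame {k + 1} has {frame.shape[0]} atoms, topology has {topology.n_atoms}"
                )
    if times is None:
        times = np.arange(frames.shape[0], dtype=float)  # frame index as ps
    keep = times >= discard_initial
    if not keep.any():
        raise ValueError(f"{path}: discard_initial={discard_initial} ps removes every frame")
    return Trajectory(coordinates=frames[keep], frame_times=times[keep])


# ---------------------------------------------------------------------------
# parameter and restraint tables
# ---------------------------------------------------------------------------

_PARAM_COLUMNS = ["residue_name", "atom_name", "charge_e", "epsilon_kcal_mol", "rmin_half_nm"]


def read_parameter_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: parameter table missing columns {missing}")
    return df


def apply_parameters(topology: Topology, table: pd.DataFrame) -> None:
    """Assign charges/LJ parameters by (residue_name, atom_name) lookup.

    Atoms without an entry keep zero parameters; a warning lists them.
    """
    lut = {
        (str(r.residue_name), str(r.atom_name)): (float(r.charge_e), float(r.epsilon_kcal_mol), float(r.rmin_half_nm))
        for r in table.itertuples()
    }
    unmatched = []
    for a in topology.atoms:
        key = (a.residue_name, a.name)
        if key in lut:
            a.charge, a.lj_epsilon, a.lj_rmin_half = lut[key]
        else:
            unmatched.append(a.label)
    if unmatched:
        logger.warning("no parameters for %d atoms (left at zero): %s", len(unmatched), ", ".join(unmatched[:8]))


def write_parameter_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_restraints(path) -> list[NOERestraint]:
    df = pd.read_csv(path, sep=r"\s+")
    for c in ("atom_a", "atom_b", "upper_bound_nm"):
        if c not in df.columns:
            raise ValueError(f"{path}: restraint table missing column {c!r}")
    return [
        NOERestraint(atom_a_name=str(r.atom_a), atom_b_name=str(r.atom_b), upper_bound=float(r.upper_bound_nm))
        for r in df.itertuples()
    ]


def write_restraints(path, restraints: list[NOERestraint]) -> None:
    with open(path, "w") as fh:
        fh.write("atom_a\tatom_b\tupper_bound_nm\n")
        for r in restraints:
            fh.write(f"{r.atom_a_name}\t{r.atom_b_name}\t{r.upper_bound:.4f}\n")


# ---------------------------------------------------------------------------
# selection language
# ---------------------------------------------------------------------------


class SelectionError(ValueError):
    pass


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<field>name|residue_name|residue_index|chain|group|element)\s*==\s*
        (?P<value>"[^"]*"|'[^']*'|\S+)
      | (?P<and>[Aa][Nn][Dd])
    )""",
    re.VERBOSE,
)


def _parse_selection(expression: str) -> list[tuple[str, str]]:
    tests: list[tuple[str, str]] = []
    pos = 0
    expect_test = True
    while pos < len(expression):
        if expression[pos:].strip() == "":
            break
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            raise SelectionError(f"malformed selection at position {pos}: {expression[pos:]!r}")
        if m.group("and"):
            if expect_test:
                raise SelectionError(f"unexpected 'and' at position {m.start()}")
            expect_test = True
        else:
            if not expect_test:
                raise SelectionError(f"missing 'and' before position {m.start()}")
            value = m.group("value").strip("\"'")
            tests.append((m.group("field"), value))
            expect_test = False
        pos = m.end()
    if expect_test:
        raise SelectionError(f"empty or dangling selection: {expression!r}")
    return tests


def select_atoms(topology: Topology, expression: str) -> list[int]:
    """Evaluate a selection expression; returns ascending 0-based indices.

    Grammar: conjunctions (``and``) of equality tests on ``name``,
    ``residue_name``, ``residue_index``, ``chain``, ``element`` or ``group``,
    e.g. ``residue_name == "ARG" and name == "CZ"``.  An empty result is
    allowed but logged.
    """
    tests = _parse_selection(expression)
    hits = set(range(topology.n_atoms))
    for fieldname, value in tests:
        if fieldname == "group":
            if value not in topology.groups:
                raise SelectionError(f"unknown group {value!r}")
            hits &= set(topology.groups[value])
        elif fieldname == "residue_index":
            try:
                target = int(value)
            except ValueError as exc:
                raise SelectionError(f"residue_index needs an integer, got {value!r}") from exc
            hits &= {a.index for a in topology.atoms if a.residue_index == target}
        else:
            hits &= {a.index for a in topology.atoms if getattr(a, fieldname) == value}
    if not hits:
        logger.warning("selection %r matched no atoms", expression)
    return sorted(hits)


def infer_bonds(topology: Topology, coordinates: np.ndarray, cutoff: float = 0.18) -> None:
    """Opt-in fallback: bond each hydrogen to heavy atoms within ``cutoff`` nm.

    Logged loudly; intended only for inputs lacking explicit connectivity.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    added = 0
    existing = {tuple(sorted(b)) for b in topology.bonds}
    h_idx = [a.index for a in topology.atoms if a.element == "H"]
    heavy_idx = [a.index for a in topology.atoms if a.element != "H"]
    for h in h_idx:
        d = np.linalg.norm(coordinates[heavy_idx] - coordinates[h], axis=1)
        for j, dist in zip(heavy_idx, d):
            if dist < cutoff:
                key = tuple(sorted((h, j)))
                if key not in existing:
                    topology.bonds.append(key)
                    existing.add(key)
                    added += 1
    logger.warning("infer_bonds: added %d H-heavy bonds by distance (cutoff %.3f nm)", added, cutoff)


def permute_topology(topology: Topology, order: list[int]) -> tuple[Topology, np.ndarray]:
    """Reindex atoms by ``order`` (new position k holds old atom order[k]).

    Returns the permuted topology and the old→new index map.  Used by tests
    to verify selections are order-independent.
    """
    old_to_new = np.empty(len(order), dtype=int)
    for new, old in enumerate(order):
        old_to_new[old] = new
    atoms = [replace(topology.atoms[old], index=new) for new, old in enumerate(order)]
    bonds = [(int(old_to_new[i]), int(old_to_new[j])) for i, j in topology.bonds]
    groups = {g: sorted(int(old_to_new[i]) for i in idx) for g, idx in topology.groups.items()}
    return Topology(atoms=atoms, bonds=bonds, groups=groups), old_to_new
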