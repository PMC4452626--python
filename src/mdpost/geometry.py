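"""Core vector geometry: distances, angles, dihedrals, Kabsch superposition, RMSD.

All coordinates are in nm; all angles in the public API are in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "angle",
    "dihedral",
    "kabsch_superpose",
    "place_atom",
    "rmsd_timeseries",
    "SuperpositionResult",
    "RMSDSeries",
]

_EPS = 1e-12


def _asvec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


def distance(p1, p2) -> float:
    """Euclidean distance between two points (nm)."""
    return float(np.linalg.norm(_asvec(p1) - _asvec(p2)))


def angle(p1, p2, p3) -> float:
    """Angle at ``p2`` formed by ``p1-p2-p3``, in degrees within [0, 180]."""
    v1 = _asvec(p1) - _asvec(p2)
    v2 = _asvec(p3) - _asvec(p2)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < _EPS or n2 < _EPS:
        raise ValueError("angle undefined: coincident points")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    Sign follows the IUPAC convention: looking from p2 toward p3, a
    clockwise rotation of p4 relative to p1 is positive.  A planar cis
    arrangement gives 0, trans gives 180.

    Raises ``ValueError`` for degenerate geometry (coincident consecutive
    points or three collinear consecutive points).
    """
    b1 = _asvec(p2) - _asvec(p1)
    b2 = _asvec(p3) - _asvec(p2)
    b3 = _asvec(p4) - _asvec(p3)
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < _EPS:
            raise ValueError("dihedral undefined: coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise ValueError("dihedral undefined: collinear consecutive points")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    ang = np.degrees(np.arctan2(y, x))
    # map to (-180, 180]
    if ang <= -180.0 + 1e-12:
        ang += 360.0
    return float(ang)


def place_atom(a, b, c, bond: float, ang_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a point ``d`` from internal coordinates (NeRF construction).

    ``d`` satisfies |c-d| = ``bond``, angle(b, c, d) = ``ang_deg`` and
    dihedral(a, b, c, d) = ``torsion_deg`` (same sign convention as
    :func:`dihedral`).
    """
    a, b, c = _asvec(a), _asvec(b), _asvec(c)
    theta = np.radians(ang_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        raise ValueError("cannot place atom: reference atoms are collinear")
    n /= nn
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


@dataclass(frozen=True)
class SuperpositionResult:
    """Result of a least-squares rigid-body fit.

    ``rotation`` and ``translation`` map mobile coordinates onto the
    reference frame as ``x @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float
    measure_rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_selection,
    measure_selection=None,
) -> SuperpositionResult:
    """Optimal proper-rotation superposition (Kabsch) of ``mobile`` onto ``reference``.

    The rotation/translation minimizing the RMSD over ``fit_selection`` is
    found by SVD with a reflection correction so the rotation is always
    proper (det = +1).  ``measure_rmsd`` is evaluated over
    ``measure_selection`` (default: all atoms) using the *fit* transform —
    the measure set is never refit.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    fit_idx = np.asarray(list(fit_selection), dtype=int)
    if fit_idx.size < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    mf = mobile[fit_idx]
    rf = reference[fit_idx]
    mc = mf.mean(axis=0)
    rc = rf.mean(axis=0)
    a = mf - mc
    b = rf - rc
    # collinearity check: rank of the centered fit cloud must be >= 2
    if np.linalg.matrix_rank(a, tol=1e-10) < 2:
        raise ValueError("fit selection is collinear; rotation underdetermined")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - mc @ rot.T
    fitted = mf @ rot.T + trans
    fit_rmsd = _rmsd(fitted, rf)
    if measure_selection is None:
        meas_idx = np.arange(len(mobile))
    else:
        meas_idx = np.asarray(list(measure_selection), dtype=int)
    meas = mobile[meas_idx] @ rot.T + trans
    measure_rmsd = _rmsd(meas, reference[meas_idx])
    return SuperpositionResult(rotation=rot, translation=trans, fit_rmsd=fit_rmsd, measure_rmsd=measure_rmsd)


@dataclass
class RMSDSeries:
    """Per-frame measure-selection RMSD after a per-frame fit (nm)."""

    values: np.ndarray
    frame_times: np.ndarray | None = None
    final: float = field(init=False)
    mean: float = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.final = float(self.values[-1])
        self.mean = float(self.values.mean())


def rmsd_timeseries(trajectory, reference: np.ndarray, fit_selection, measure_selection) -> RMSDSeries:
    """RMSD of ``measure_selection`` vs a reference structure for every frame.

    Each frame is superposed on ``reference`` using ``fit_selection`` and the
    RMSD of ``measure_selection`` is recorded.  The headline value is the
    final-frame RMSD; the series mean is reported alongside.
    """
    vals = [
        kabsch_superpose(frame, reference, fit_selection, measure_selection).measure_rmsd
        for frame in trajectory.coordinates
    ]
    return RMSDSeries(values=np.array(vals), frame_times=trajectory.frame_times)
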