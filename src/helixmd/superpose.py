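"""Rigid-body superposition and deviation metrics.

Implements least-squares (Kabsch) superposition with reflection exclusion,
the rmsd(t) time series over a CA selection, the relative rmsd-increase
statistic %D contrasting a perturbed-condition series against a reference
series, and per-residue rmsf.

rmsd(t) = sqrt( (1/N) sum_i ||r_i(t) - r_i^ref||^2 )   over N selected atoms
%D(t)   = |rmsd_T(t) - rmsd_ref(t)| / rmsd_ref(t)
rmsf_i  = sqrt( (1/T) sum_j ||r_i(t_j) - r_i^ref||^2 )

Frames are superposed onto the reference over the same selection before the
metric is evaluated (fit=True), mirroring standard MD-analysis practice; the
fit can be disabled, in which case the algebraic identity
mean_t rmsd^2(t) == mean_i rmsf_i^2 holds exactly for a shared reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MolecularSystem, Selection, Trajectory

__all__ = [
    "RigidTransform",
    "DeviationSeries",
    "PercentIncreaseResult",
    "kabsch_fit",
    "rmsd_series",
    "percent_increase",
    "rmsf_per_residue",
]


@dataclass
class RigidTransform:
    """x -> rotation @ x + translation; proper rotation only (det = +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not rigid transforms")
        self.rotation = R
        self.translation = np.asarray(self.translation, float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass
class DeviationSeries:
    times: np.ndarray  # ns
    values: np.ndarray  # nm
    selection: Selection | None = None
    fitted: bool = True

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if len(self.times) != len(self.values):
            raise ValueError("times/values length mismatch")
        if np.any(self.values < 0):
            raise ValueError("deviation values must be non-negative")


def kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform minimising sum ||R m_i + t - q_i||^2.

    Reflections are excluded by the usual determinant sign correction.
    Requires >= 3 non-collinear points in each set.
    """
    m = np.asarray(mobile, float)
    q = np.asarray(target, float)
    if m.shape != q.shape or m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if m.shape[0] < 3:
        raise ValueError("need at least 3 points")
    mc = m.mean(axis=0)
    qc = q.mean(axis=0)
    H = (m - mc).T @ (q - qc)
    U, S, Vt = np.linalg.svd(H)
    rank_m = np.linalg.matrix_rank(m - mc, tol=1e-10)
    rank_q = np.linalg.matrix_rank(q - qc, tol=1e-10)
    if rank_m < 2 or rank_q < 2:
        raise ValueError("point set is rank-deficient (collinear)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ mc
    return RigidTransform(rotation=R, translation=t)


def _selected_frames(traj: Trajectory, selection: Selection) -> np.ndarray:
    idx = selection.indices(traj.topology)
    return traj.frames[:, idx, :]


def rmsd_series(
    traj: Trajectory,
    reference: MolecularSystem,
    selection: Selection,
    fit: bool = True,
) -> DeviationSeries:
    """rmsd(t) of the selected atoms against the reference structure."""
    if len(selection) == 0:
        raise ValueError("empty selection")
    ref = reference.coords()[selection.indices(reference)]
    mob = _selected_frames(traj, selection)
    values = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        x = mob[k]
        if fit:
            x = kabsch_fit(x, ref).apply(x)
        values[k] = np.sqrt(np.mean(np.sum((x - ref) ** 2, axis=1)))
    return DeviationSeries(times=traj.times.copy(), values=values,
                           selection=selection, fitted=fit)


@dataclass
class PercentIncreaseResult:
    """%D series as unitless fractions (multiply by 100 for percent)."""

    times: np.ndarray
    values: np.ndarray  # NaN where the reference rmsd vanishes
    mean: float  # time average over defined points
    n_undefined: int


def percent_increase(series_T: DeviationSeries, series_ref: DeviationSeries
                     ) -> PercentIncreaseResult:
    """Relative rmsd increase of a perturbed series over a reference series.

    Points where the reference rmsd is zero are undefined; they are excluded
    from the time average (with a warning) rather than clamped.
    """
    if len(series_T.values) != len(series_ref.values):
        raise ValueError("series length mismatch")
    if not np.allclose(series_T.times, series_ref.times):
        raise ValueError("series times do not match")
    ref = series_ref.values
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.abs(series_T.values - ref) / ref
    undefined = ref == 0.0
    vals = np.where(undefined, np.nan, vals)
    n_undef = int(undefined.sum())
    if n_undef:
        warnings.warn(f"%D undefined at {n_undef} point(s) with zero reference rmsd")
    defined = vals[~np.isnan(vals)]
    mean = float(defined.mean()) if defined.size else float("nan")
    return PercentIncreaseResult(times=series_T.times.copy(), values=vals,
                                 mean=mean, n_undefined=n_undef)


def rmsf_per_residue(
    traj: Trajectory,
    selection: Selection,
    reference_mode: str = "time_mean",
    chain_average: bool = False,
    fit: bool = True,
) -> pd.Series:
    """Per-residue rmsf (nm) over one atom (CA) per residue.

    Frames are first superposed onto the first frame over the full selection
    (fit=True); the fluctuation reference is either that first frame
    ("first_frame") or the time mean of the fitted coordinates ("time_mean").
    With chain_average=True values at the same residue index are averaged
    across chains and the result is indexed by residue index alone.
    """
    if traj.n_frames < 2:
        raise ValueError("rmsf requires at least 2 frames")
    if len(selection) == 0:
        raise ValueError("empty selection")
    keys = selection.residue_keys()
    if len(keys) != len(selection):
        raise ValueError("selection must contain exactly one atom per residue")
    if reference_mode not in ("first_frame", "time_mean"):
        raise ValueError("reference_mode must be 'first_frame' or 'time_mean'")

    mob = _selected_frames(traj, selection).copy()
    if fit:
        ref0 = mob[0]
        for k in range(1, traj.n_frames):
            mob[k] = kabsch_fit(mob[k], ref0).apply(mob[k])
    ref = mob[0] if reference_mode == "first_frame" else mob.mean(axis=0)
    sq = np.sum((mob - ref[None]) ** 2, axis=2)  # (frames, residues)
    rmsf = np.sqrt(sq.mean(axis=0))

    idx = pd.MultiIndex.from_tuples(keys, names=["chain", "res_index"])
    out = pd.Series(rmsf, index=idx, name="rmsf")
    if chain_average:
        out = out.groupby(level="res_index").mean()
    return out
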