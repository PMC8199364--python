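"""Helix-axis fitting and helix geometry metrics.

The axis is the principal component (largest-variance direction) of the CA
cloud, oriented from the first toward the last residue -- appropriate for the
short, straight helices of small bundles. With coordinates expressed in the
axis frame (axis = z through the CA centroid):

    d     rise per residue   = mean_i |z(i+1) - z(i)|              (nm)
    L     total helix length = d * n  (n = number of residues)     (nm)
    r     helix radius       = sqrt( mean_i (x_i^2 + y_i^2) )      (nm)
    theta twist angle        = |mean_i signed rotation about the
                               axis between consecutive CAs|       (deg)
    Ree   end-to-end         = first atom of first helix residue to
                               last atom of last helix residue     (nm)

Note L multiplies d by n, not (n - 1): the length is defined as the product
of average rise and residue count, so it slightly exceeds the geometric span
of the CA positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocking import block_average
from .core import MolecularSystem, RegionAnnotation, Trajectory

__all__ = ["HelixAxis", "HelixMetrics", "fit_axis", "helix_metrics",
           "end_to_end", "helix_metrics_series"]


@dataclass
class HelixAxis:
    direction: np.ndarray  # unit 3-vector
    point: np.ndarray  # centroid, nm

    def __post_init__(self):
        self.direction = np.asarray(self.direction, float)
        self.point = np.asarray(self.point, float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-12:
            raise ValueError("axis direction must be a unit vector")


@dataclass
class HelixMetrics:
    d: float  # nm
    L: float  # nm
    r: float  # nm
    theta: float  # deg
    n: int

    def __post_init__(self):
        if not (self.d > 0 and self.L > 0 and self.r > 0):
            raise ValueError("d, L, r must be positive")
        if not (0.0 < self.theta < 180.0):
            raise ValueError("theta must lie in (0, 180) deg")


def fit_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Principal axis of the CA cloud, oriented first -> last residue."""
    ca = np.asarray(ca_coords, float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError("ca_coords must be (n, 3)")
    if ca.shape[0] < 5:
        raise ValueError("need at least 5 CA positions to fit a helix axis")
    center = ca.mean(axis=0)
    _u, s, vt = np.linalg.svd(ca - center)
    if s[0] < 1e-12 or (s[1] / s[0] > 0.999 and s[2] / s[0] > 0.999):
        raise ValueError("degenerate (spherical) CA cloud: no unique axis")
    direction = vt[0]
    if np.dot(ca[-1] - ca[0], direction) < 0:
        direction = -direction
    return HelixAxis(direction=direction, point=center)


def helix_metrics(ca_coords: np.ndarray) -> HelixMetrics:
    """d, L, r, theta of one helix from its ordered CA coordinates."""
    ca = np.asarray(ca_coords, float)
    axis = fit_axis(ca)
    rel = ca - axis.point
    z = rel @ axis.direction
    perp = rel - np.outer(z, axis.direction)
    r = float(np.sqrt(np.mean(np.sum(perp ** 2, axis=1))))
    if r < 1e-6:
        raise ValueError("collinear CA positions: radius ~ 0, twist undefined")
    d = float(np.mean(np.abs(np.diff(z))))
    # signed rotation about the axis between consecutive CAs
    e1 = perp[0] / np.linalg.norm(perp[0])
    e2 = np.cross(axis.direction, e1)
    ang = np.degrees(np.arctan2(perp @ e2, perp @ e1))
    dtheta = np.diff(ang)
    dtheta = (dtheta + 180.0) % 360.0 - 180.0
    theta = float(abs(np.mean(dtheta)))
    n = ca.shape[0]
    return HelixMetrics(d=d, L=d * n, r=r, theta=theta, n=n)


def end_to_end(frame, system: MolecularSystem, chain_id: str,
               res_range: tuple[int, int]) -> float:
    """Distance between the first atom (file order) of the first helix residue
    and the last atom of the last helix residue (nm)."""
    a, b = res_range
    if b < a:
        raise ValueError("empty helix range")
    coords = np.asarray(frame, float)
    first_idx = [i for i, at in enumerate(system.atoms)
                 if at.chain_id == chain_id and at.res_index == a]
    last_idx = [i for i, at in enumerate(system.atoms)
                if at.chain_id == chain_id and at.res_index == b]
    if not first_idx or not last_idx:
        raise ValueError(f"helix range {res_range} not present in chain {chain_id}")
    return float(np.linalg.norm(coords[last_idx[-1]] - coords[first_idx[0]]))


def helix_metrics_series(traj: Trajectory, annotation: RegionAnnotation,
                         window: float | None = None, n_blocks: int = 5
                         ) -> pd.DataFrame:
    """Blocked per-helix metrics over a trajectory.

    One row per annotated helix with mean +/- std-over-blocks for d, L, r,
    theta and Ree.
    """
    system = traj.topology
    rows = []
    for (cid, label, a, b) in annotation.helix_ranges():
        ca_idx = [system.index_of(cid, r, "CA") for r in range(a, b + 1)
                  if system.has_atom(cid, r, "CA")]
        series = {m: np.empty(traj.n_frames) for m in ("d", "L", "r", "theta", "ree")}
        for k in range(traj.n_frames):
            hm = helix_metrics(traj.frames[k][ca_idx])
            series["d"][k] = hm.d
            series["L"][k] = hm.L
            series["r"][k] = hm.r
            series["theta"][k] = hm.theta
            series["ree"][k] = end_to_end(traj.frames[k], system, cid, (a, b))
        row = dict(chain=cid, helix=label, res_start=a, res_end=b, n=len(ca_idx))
        for m, vals in series.items():
            blk = block_average(traj.times, vals, window=window, n_blocks=n_blocks)
            row[f"{m}_mean"] = blk.mean
            row[f"{m}_err"] = blk.error
        rows.append(row)
    return pd.DataFrame(rows)
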