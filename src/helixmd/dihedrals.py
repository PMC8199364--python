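"""Backbone torsions and Ramachandran analysis.

phi(i) = C(i-1)-N(i)-CA(i)-C(i) and psi(i) = N(i)-CA(i)-C(i)-N(i+1), IUPAC
sign convention, wrapped to (-180, 180]. phi is undefined for a chain's first
residue and psi for its last.

Region classification uses explicit, disjoint (phi, psi) rectangles standing
in for density-derived Ramachandran regions: ALPHA (right-handed helix), BETA
(strand), LEFT_ALPHA, and OTHER for everything else. The rectangles are
intervals half-open on the right, except that an upper bound of 180 is
inclusive; they are configurable and verified disjoint at load time. All mean
torsions use circular statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import circmean

from .blocking import block_average_circular, trailing_window
from .core import MolecularSystem, RegionAnnotation, Trajectory
from .geometry import dihedrals, wrap_angle

__all__ = [
    "TorsionRecord",
    "RamaRegions",
    "backbone_torsions",
    "torsion_arrays",
    "classify",
    "region_percentages",
    "torsion_time_map",
    "helix_mean_torsions",
]


@dataclass(frozen=True)
class TorsionRecord:
    chain_id: str
    res_index: int
    phi: float  # deg in (-180, 180]; NaN if undefined
    psi: float
    frame: int


# -- region model ------------------------------------------------------------

Rect = tuple[float, float, float, float]  # (phi_min, phi_max, psi_min, psi_max)


def _in_interval(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    upper = (x <= hi) if hi >= 180.0 else (x < hi)
    return (x >= lo) & upper


def _intervals_overlap(lo1, hi1, lo2, hi2) -> bool:
    # half-open semantics: [lo, hi) unless hi == 180 (closed)
    c1 = hi1 >= 180.0
    c2 = hi2 >= 180.0
    if hi1 < lo2 or (hi1 == lo2 and not c1):
        return False
    if hi2 < lo1 or (hi2 == lo1 and not c2):
        return False
    return True


@dataclass
class RamaRegions:
    """Named, mutually disjoint (phi, psi) rectangle sets; OTHER is implicit."""

    regions: dict[str, list[Rect]] = field(default_factory=lambda: {
        "ALPHA": [(-180.0, 0.0, -120.0, 50.0)],
        "BETA": [(-180.0, -20.0, 50.0, 180.0), (-180.0, -20.0, -180.0, -150.0)],
        "LEFT_ALPHA": [(0.0, 180.0, -20.0, 90.0)],
    })

    def __post_init__(self):
        flat = [(name, r) for name, rects in self.regions.items() for r in rects]
        for i, (n1, r1) in enumerate(flat):
            for n2, r2 in flat[i + 1:]:
                if n1 == n2:
                    continue
                if _intervals_overlap(r1[0], r1[1], r2[0], r2[1]) and \
                        _intervals_overlap(r1[2], r1[3], r2[2], r2[3]):
                    raise ValueError(f"regions {n1} and {n2} overlap: {r1} vs {r2}")

    @property
    def labels(self) -> list[str]:
        return list(self.regions) + ["OTHER"]

    def classify_arrays(self, phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
        """Vectorised classification; NaN torsions yield ''."""
        phi = np.asarray(phi, float)
        psi = np.asarray(psi, float)
        out = np.full(phi.shape, "OTHER", dtype=object)
        for name, rects in self.regions.items():
            hit = np.zeros(phi.shape, dtype=bool)
            for (plo, phi_hi, slo, shi) in rects:
                hit |= _in_interval(phi, plo, phi_hi) & _in_interval(psi, slo, shi)
            out[hit] = name
        out[np.isnan(phi) | np.isnan(psi)] = ""
        return out


def classify(phi: float, psi: float, regions: RamaRegions | None = None) -> str:
    """Region label of one defined (phi, psi) pair."""
    if np.isnan(phi) or np.isnan(psi):
        raise ValueError("phi and psi must be defined")
    regions = regions or RamaRegions()
    return str(regions.classify_arrays(np.array([phi]), np.array([psi]))[0])


# -- torsion computation -----------------------------------------------------

def _backbone_indices(system: MolecularSystem, chain_id: str):
    """Per-residue (N, CA, C) indices (None where atoms are missing)."""
    res = system.residues(chain_id)
    idx = []
    for (_c, r, _n) in res:
        trip = []
        for name in ("N", "CA", "C"):
            trip.append(system.index_of(chain_id, r, name)
                        if system.has_atom(chain_id, r, name) else None)
        idx.append((r, trip))
    return idx


def backbone_torsions(frame, system: MolecularSystem, chain_id: str,
                      frame_index: int = 0) -> list[TorsionRecord]:
    """All (phi, psi) of one chain in one frame; undefined values are NaN."""
    if chain_id not in system.chains:
        raise ValueError(f"unknown chain {chain_id!r}")
    coords = np.asarray(frame, float)
    idx = _backbone_indices(system, chain_id)
    if len(idx) < 2:
        raise ValueError("chain must have at least 2 residues")
    out = []
    for pos, (r, (n_i, ca_i, c_i)) in enumerate(idx):
        phi = psi = np.nan
        ok_core = None not in (n_i, ca_i, c_i)
        if pos > 0 and ok_core:
            c_prev = idx[pos - 1][1][2]
            if c_prev is not None:
                phi = dihedrals(coords[c_prev][None], coords[n_i][None],
                                coords[ca_i][None], coords[c_i][None])[0]
        if pos < len(idx) - 1 and ok_core:
            n_next = idx[pos + 1][1][0]
            if n_next is not None:
                psi = dihedrals(coords[n_i][None], coords[ca_i][None],
                                coords[c_i][None], coords[n_next][None])[0]
        out.append(TorsionRecord(chain_id=chain_id, res_index=r,
                                 phi=float(wrap_angle(phi)) if not np.isnan(phi) else np.nan,
                                 psi=float(wrap_angle(psi)) if not np.isnan(psi) else np.nan,
                                 frame=frame_index))
    return out


def torsion_arrays(traj: Trajectory, chains: list[str] | None = None
                   ) -> tuple[list[tuple[str, int]], np.ndarray, np.ndarray]:
    """(phi, psi) for all frames at once.

    Returns (residue keys, phi, psi) with phi/psi of shape
    (n_frames, n_residues); torsions undefined at termini or for missing
    atoms are NaN. Water chains are skipped.
    """
    system = traj.topology
    if chains is None:
        chains = system.protein_chains()
    keys: list[tuple[str, int]] = []
    quads_phi = []  # (4,) atom index rows, -1 marks undefined
    quads_psi = []
    for cid in chains:
        idx = _backbone_indices(system, cid)
        for pos, (r, (n_i, ca_i, c_i)) in enumerate(idx):
            keys.append((cid, r))
            if pos > 0 and None not in (n_i, ca_i, c_i) and idx[pos - 1][1][2] is not None:
                quads_phi.append([idx[pos - 1][1][2], n_i, ca_i, c_i])
            else:
                quads_phi.append([-1] * 4)
            if pos < len(idx) - 1 and None not in (n_i, ca_i, c_i) \
                    and idx[pos + 1][1][0] is not None:
                quads_psi.append([n_i, ca_i, c_i, idx[pos + 1][1][0]])
            else:
                quads_psi.append([-1] * 4)

    def compute(quads):
        q = np.asarray(quads, dtype=int)
        valid = q[:, 0] >= 0
        vals = np.full((traj.n_frames, len(q)), np.nan)
        if valid.any():
            qv = q[valid]
            p = traj.frames[:, qv, :]  # (F, M, 4, 3)
            vals[:, valid] = dihedrals(p[:, :, 0], p[:, :, 1], p[:, :, 2], p[:, :, 3])
        return vals

    return keys, compute(quads_phi), compute(quads_psi)


# -- analyses ----------------------------------------------------------------

def region_percentages(traj: Trajectory, regions: RamaRegions | None = None,
                       chains: list[str] | None = None,
                       window: float | None = None, n_blocks: int | None = None
                       ) -> dict:
    """Percentage of defined (phi, psi) pairs in each region.

    Percentages are over all residues of all frames in the trailing analysis
    window and sum to exactly 100. When ``n_blocks`` is given, a std across
    per-block percentages is reported alongside.
    """
    regions = regions or RamaRegions()
    keys, phi, psi = torsion_arrays(traj, chains)
    t0, t1 = trailing_window(traj.times, window)
    mask = (traj.times >= t0 - 1e-12) & (traj.times <= t1 + 1e-12)
    phi, psi = phi[mask], psi[mask]
    times = traj.times[mask]
    labels = regions.classify_arrays(phi, psi)
    defined = labels != ""
    total = int(defined.sum())
    if total == 0:
        raise ValueError("no defined torsions in the analysis window")
    out: dict = {"percent": {}, "n_samples": total}
    for lab in regions.labels:
        out["percent"][lab] = 100.0 * float((labels == lab).sum()) / total
    if n_blocks:
        edges = np.linspace(times[0], times[-1], n_blocks + 1)
        per_block = {lab: [] for lab in regions.labels}
        for b in range(n_blocks):
            sel = (times >= edges[b] - 1e-12) & \
                  (times <= edges[b + 1] + 1e-12 if b == n_blocks - 1 else times < edges[b + 1])
            lb = labels[sel]
            nb = int((lb != "").sum())
            for lab in regions.labels:
                per_block[lab].append(100.0 * float((lb == lab).sum()) / max(nb, 1))
        out["block_std"] = {lab: float(np.std(v)) for lab, v in per_block.items()}
    return out


def torsion_time_map(traj: Trajectory, chain_id: str, res_index: int,
                     grid: float = 5.0) -> dict:
    """Time-resolved (phi, psi) record for one residue.

    Returns a DataFrame (time, phi, psi) plus the number of occupied cells of
    a ``grid`` x ``grid`` degree lattice -- the footprint area that broadens
    when the residue's conformational distribution widens.
    """
    keys, phi, psi = torsion_arrays(traj, [chain_id])
    try:
        j = keys.index((chain_id, res_index))
    except ValueError:
        raise ValueError(f"residue {(chain_id, res_index)} not found") from None
    p, s = phi[:, j], psi[:, j]
    if np.all(np.isnan(p)):
        raise ValueError(f"phi undefined for residue {(chain_id, res_index)} "
                         "(chain-first residue)")
    if np.all(np.isnan(s)):
        raise ValueError(f"psi undefined for residue {(chain_id, res_index)} "
                         "(chain-last residue)")
    df = pd.DataFrame({"time": traj.times, "phi": p, "psi": s})
    ok = ~(np.isnan(p) | np.isnan(s))
    cells = {(int(np.floor((x + 180.0) / grid)), int(np.floor((y + 180.0) / grid)))
             for x, y in zip(p[ok], s[ok])}
    return {"map": df, "footprint_cells": len(cells), "grid_deg": grid}


def helix_mean_torsions(traj: Trajectory, annotation: RegionAnnotation,
                        window: float | None = None, n_blocks: int = 5
                        ) -> pd.DataFrame:
    """Two-stage mean helix torsions: circular spatial mean over the helix at
    each frame, then blocked circular time average with std across blocks.

    One row per annotated helix with phi/psi mean and error (deg).
    """
    keys, phi, psi = torsion_arrays(traj)
    key_pos = {k: i for i, k in enumerate(keys)}
    rows = []
    for (cid, label, a, b) in annotation.helix_ranges():
        cols = [key_pos[(cid, r)] for r in range(a, b + 1) if (cid, r) in key_pos]
        ph = phi[:, cols]
        ps = psi[:, cols]

        def spatial_mean(x):
            out = np.empty(x.shape[0])
            for k in range(x.shape[0]):
                v = x[k][~np.isnan(x[k])]
                out[k] = circmean(v, high=180.0, low=-180.0) if v.size else np.nan
            return out

        phi_t = spatial_mean(ph)
        psi_t = spatial_mean(ps)
        bphi = block_average_circular(traj.times, phi_t, window=window, n_blocks=n_blocks)
        bpsi = block_average_circular(traj.times, psi_t, window=window, n_blocks=n_blocks)
        rows.append(dict(chain=cid, helix=label, res_start=a, res_end=b,
                         phi_mean=bphi.mean, phi_err=bphi.error,
                         psi_mean=bpsi.mean, psi_err=bpsi.error))
    return pd.DataFrame(rows)
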