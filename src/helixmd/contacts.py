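"""Hydrophobic-contact analysis: CB-CB radial distribution functions between
chains (or chain pairs) and distances between hydrophobic centres of mass.

g(r) is the cross-set pair-distance histogram normalised by the ideal-gas
expectation N_A * N_B * V_shell / V, averaged over frames; with a periodic box
distances use the minimum-image convention (orthorhombic boxes only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import MolecularSystem, RegionAnnotation, Selection, Trajectory

__all__ = ["RdfResult", "rdf", "cm_distance", "cm_distance_series", "hydrophobic_selection"]


@dataclass
class RdfResult:
    bin_centers: np.ndarray  # nm
    g: np.ndarray  # unitless
    counts: np.ndarray  # raw pair counts per bin, summed over frames
    bin_width: float
    r_max: float
    n_frames: int
    n_pairs: int  # N_A * N_B

    def __post_init__(self):
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")

    def coordination_integral(self, rho: float) -> float:
        """integral of g(r) * 4 pi r^2 * rho dr up to r_max."""
        return float(np.sum(self.g * 4.0 * np.pi * self.bin_centers ** 2 * rho
                            * self.bin_width))


def _min_image(diff: np.ndarray, box: np.ndarray) -> np.ndarray:
    return diff - box * np.round(diff / box)


def rdf(
    traj: Trajectory,
    setA: Selection,
    setB: Selection,
    bin_width: float = 0.01,
    r_max: float | None = None,
    periodic: bool = False,
    volume: float | None = None,
) -> RdfResult:
    """Cross-set radial distribution function averaged over frames.

    ``setA`` and ``setB`` must be disjoint. Without a periodic box the
    normalisation volume comes from ``volume``, the system box, or (last
    resort, with a warning) the bounding box of the coordinates.
    """
    ia = setA.indices(traj.topology)
    ib = setB.indices(traj.topology)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("empty selection")
    if set(ia.tolist()) & set(ib.tolist()):
        raise ValueError("setA and setB must be disjoint for a cross-set rdf")
    box = traj.topology.box
    if periodic:
        if box is None:
            raise ValueError("periodic rdf requires a box on the topology")
        half_min_edge = float(np.min(box)) / 2.0
        if r_max is None:
            r_max = min(2.0, half_min_edge)
        if r_max > half_min_edge + 1e-12:
            raise ValueError(
                f"r_max={r_max} nm exceeds half the minimum box edge ({half_min_edge} nm)"
            )
        vol = float(np.prod(box))
    else:
        if r_max is None:
            r_max = 2.0
        if volume is not None:
            vol = float(volume)
        elif box is not None:
            vol = float(np.prod(box))
        else:
            lo = traj.frames[:, np.concatenate([ia, ib]), :].min(axis=(0, 1))
            hi = traj.frames[:, np.concatenate([ia, ib]), :].max(axis=(0, 1))
            vol = float(np.prod(hi - lo))
            warnings.warn("no box/volume given; normalising g(r) by the bounding box")

    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    for k in range(traj.n_frames):
        a = traj.frames[k][ia]
        b = traj.frames[k][ib]
        diff = a[:, None, :] - b[None, :, :]
        if periodic:
            diff = _min_image(diff, box)
        d = np.sqrt(np.sum(diff ** 2, axis=-1)).ravel()
        h, _ = np.histogram(d, bins=edges)
        counts += h
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    expected = len(ia) * len(ib) * shell_vol / vol * traj.n_frames
    g = counts / expected
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RdfResult(bin_centers=centers, g=g, counts=counts, bin_width=bin_width,
                     r_max=float(r_max), n_frames=traj.n_frames,
                     n_pairs=len(ia) * len(ib))


def cm_distance(frame, system: MolecularSystem, setA: Selection, setB: Selection,
                mass_weighted: bool = False) -> float:
    """Distance between the centres of the two atom sets in one frame (nm).

    The default centre is geometric: the sets this analysis uses are all-CB
    and therefore equal-mass. ``mass_weighted`` switches to true centres of
    mass using element masses.
    """
    coords = np.asarray(frame, float)
    ia = setA.indices(system)
    ib = setB.indices(system)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("empty selection")
    if mass_weighted:
        m = system.masses()
        ca = np.average(coords[ia], axis=0, weights=m[ia])
        cb = np.average(coords[ib], axis=0, weights=m[ib])
    else:
        ca = coords[ia].mean(axis=0)
        cb = coords[ib].mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def cm_distance_series(traj: Trajectory, setA: Selection, setB: Selection,
                       mass_weighted: bool = False) -> np.ndarray:
    """cm_distance evaluated on every frame (for block averaging)."""
    return np.array([
        cm_distance(traj.frames[k], traj.topology, setA, setB, mass_weighted)
        for k in range(traj.n_frames)
    ])


def hydrophobic_selection(system: MolecularSystem, annotation: RegionAnnotation,
                          grouping: str = "per_chain") -> list[Selection]:
    """CB atoms of hydrophobic residues, grouped per chain or per chain pair.

    ``per_chain`` returns one Selection per protein chain (hairpin-dimer
    mode); ``per_pair`` requires exactly 4 chains and returns the {A,B} and
    {C,D} halves (tetramer mode).
    """
    chains = system.protein_chains()
    if grouping == "per_chain":
        groups = [[c] for c in chains]
    elif grouping == "per_pair":
        if len(chains) != 4:
            raise ValueError("per_pair grouping requires exactly 4 protein chains")
        groups = [chains[:2], chains[2:]]
    else:
        raise ValueError("grouping must be 'per_chain' or 'per_pair'")
    out = []
    for grp in groups:
        refs = []
        for a in system.atoms:
            if a.chain_id in grp and a.name == "CB" \
                    and annotation.is_hydrophobic(a.chain_id, a.res_index):
                refs.append(a.key)
        out.append(Selection(refs=refs))
    if all(len(s) == 0 for s in out):
        warnings.warn("no hydrophobic residues flagged in the annotation")
    return out
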