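"""Geometric hydrogen-bond detection and classification.

A hydrogen bond is a donor-H-acceptor triple with donor-acceptor distance
<= 0.35 nm and H-donor-acceptor angle <= 30 deg (the GROMACS convention;
configurable). Donors are backbone amide N-H groups (the amide H is
reconstructed by planar geometry when the input carries no hydrogens) and
water O-H; acceptors are backbone carbonyl O and water O.

Classification follows the bundle-analysis battery: protein-protein (P-P,
split interchain/intrachain), protein-water (P-W), water-water per water
molecule (W-W/W, where each bond counts toward both partner waters), the
intrachain bonds-per-residue rate, per-helix i->(i+4) backbone counts, and
the loop-residue-to-helix bridge table of hairpin chains.

Chemical exclusions: donor-acceptor pairs two covalent bonds apart
(same-residue N..O and N(i+1)..O(i)) can never count as hydrogen bonds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .blocking import BlockResult, block_average
from .core import MolecularSystem, RegionAnnotation, Trajectory
from .geometry import dihedral  # noqa: F401  (re-exported convenience)

__all__ = [
    "HBondCriterion",
    "HBondRecord",
    "HBondCensus",
    "find_hbonds",
    "census",
    "helix_i_to_i4",
    "loop_bridge_table",
    "reconstruct_amide_h",
]

_AMIDE_H_BOND = 0.100  # nm


@dataclass(frozen=True)
class HBondCriterion:
    max_da_distance: float = 0.35  # nm
    max_hda_angle: float = 30.0  # deg

    def __post_init__(self):
        if not (0.0 < self.max_da_distance < 1.0):
            raise ValueError("distance cutoff must lie in (0, 1) nm")
        if not (0.0 < self.max_hda_angle < 90.0):
            raise ValueError("angle cutoff must lie in (0, 90) deg")


@dataclass(frozen=True)
class HBondRecord:
    donor: tuple[str, int, str]
    hydrogen: tuple[str, int, str]  # reconstructed H keeps the donor key + "~H"
    acceptor: tuple[str, int, str]
    frame: int
    kind: str  # PP | PW | WW
    interchain: bool | None  # None for non-PP bonds
    distance: float
    angle: float


def reconstruct_amide_h(n_pos, c_prev_pos, ca_pos) -> np.ndarray:
    """Planar amide H: 0.10 nm from N, opposite the C(i-1)-N-CA bisector."""
    u = c_prev_pos - n_pos
    u = u / np.linalg.norm(u)
    v = ca_pos - n_pos
    v = v / np.linalg.norm(v)
    d = -(u + v)
    d = d / np.linalg.norm(d)
    return n_pos + _AMIDE_H_BOND * d


@dataclass
class _Donor:
    d_idx: int
    h_idx: int | None  # explicit H atom index, else reconstructed
    prev_c_idx: int | None  # for reconstruction
    ca_idx: int | None
    kind: str  # "P" or "W"
    chain: str
    res: int
    key: tuple[str, int, str]
    h_key: tuple[str, int, str]


@dataclass
class _Acceptor:
    a_idx: int
    kind: str
    chain: str
    res: int
    key: tuple[str, int, str]


class _HBTopology:
    """Donor/acceptor inventory for one system (cached per system object)."""

    def __init__(self, system: MolecularSystem):
        self.donors: list[_Donor] = []
        self.acceptors: list[_Acceptor] = []
        skipped: list[tuple[str, int]] = []
        for cid, res, res_name in system.residues():
            water = res_name in ("HOH", "SOL")
            if water:
                o_name = "OW" if system.has_atom(cid, res, "OW") else "O"
                o_idx = system.index_of(cid, res, o_name)
                self.acceptors.append(_Acceptor(o_idx, "W", cid, res, (cid, res, o_name)))
                for hname in ("HW1", "HW2", "H1", "H2"):
                    if system.has_atom(cid, res, hname):
                        self.donors.append(
                            _Donor(o_idx, system.index_of(cid, res, hname), None, None,
                                   "W", cid, res, (cid, res, o_name), (cid, res, hname))
                        )
                continue
            if system.has_atom(cid, res, "O"):
                self.acceptors.append(
                    _Acceptor(system.index_of(cid, res, "O"), "P", cid, res, (cid, res, "O"))
                )
            if res_name == "PRO" or not system.has_atom(cid, res, "N"):
                continue
            n_idx = system.index_of(cid, res, "N")
            h_idx = None
            for hname in ("H", "HN"):
                if system.has_atom(cid, res, hname):
                    h_idx = system.index_of(cid, res, hname)
                    h_key = (cid, res, hname)
                    break
            prev_c = ca = None
            if h_idx is None:
                if system.has_atom(cid, res - 1, "C") and system.has_atom(cid, res, "CA"):
                    prev_c = system.index_of(cid, res - 1, "C")
                    ca = system.index_of(cid, res, "CA")
                    h_key = (cid, res, "~H")
                else:
                    if res != 1:  # chain-first amide has no defined H direction
                        skipped.append((cid, res))
                    continue
            self.donors.append(
                _Donor(n_idx, h_idx, prev_c, ca, "P", cid, res, (cid, res, "N"), h_key)
            )
        if skipped:
            warnings.warn(
                f"amide H reconstruction skipped {len(skipped)} residue(s) "
                f"missing heavy atoms: {skipped[:5]}"
            )
        self.d_idx = np.array([d.d_idx for d in self.donors], dtype=int)
        self.a_idx = np.array([a.a_idx for a in self.acceptors], dtype=int)


_topology_cache: list = []  # [(weakref-to-system, _HBTopology)]


def _hb_topology(system: MolecularSystem) -> _HBTopology:
    import weakref

    for ref, topo in _topology_cache:
        if ref() is system:
            return topo
    topo = _HBTopology(system)
    _topology_cache.clear()  # keep at most one cached inventory
    try:
        _topology_cache.append((weakref.ref(system), topo))
    except TypeError:  # pragma: no cover
        pass
    return topo


def _h_position(donor: _Donor, coords: np.ndarray) -> np.ndarray:
    if donor.h_idx is not None:
        return coords[donor.h_idx]
    return reconstruct_amide_h(coords[donor.d_idx], coords[donor.prev_c_idx],
                               coords[donor.ca_idx])


def _excluded(d: _Donor, a: _Acceptor) -> bool:
    if d.chain == a.chain and d.res == a.res:
        return True  # same residue / same water
    # amide N(i+1) and carbonyl O(i) are two covalent bonds apart
    if d.kind == "P" and a.kind == "P" and d.chain == a.chain and d.res - a.res == 1:
        return True
    return False


def find_hbonds(frame, system: MolecularSystem, criterion: HBondCriterion | None = None,
                frame_index: int = 0) -> list[HBondRecord]:
    """All hydrogen bonds in one frame; each donor-acceptor pair at most once
    (the best H of a water donor is kept)."""
    crit = criterion or HBondCriterion()
    coords = np.asarray(frame, float)
    topo = _hb_topology(system)
    if len(topo.d_idx) == 0 or len(topo.a_idx) == 0:
        return []
    tree = cKDTree(coords[topo.a_idx])
    neighbours = tree.query_ball_point(coords[topo.d_idx], r=crit.max_da_distance)
    records: list[HBondRecord] = []
    best: dict[tuple[tuple, tuple], HBondRecord] = {}
    for di, acc_list in enumerate(neighbours):
        donor = topo.donors[di]
        if not acc_list:
            continue
        h = _h_position(donor, coords)
        dpos = coords[donor.d_idx]
        hd = h - dpos
        hd /= np.linalg.norm(hd)
        for ai in acc_list:
            acc = topo.acceptors[ai]
            if _excluded(donor, acc):
                continue
            da = coords[acc.a_idx] - dpos
            dist = np.linalg.norm(da)
            if dist < 1e-9:
                continue
            cosang = np.clip(np.dot(hd, da / dist), -1.0, 1.0)
            angle = np.degrees(np.arccos(cosang))
            if angle > crit.max_hda_angle:
                continue
            kind = donor.kind + acc.kind
            kind = {"PP": "PP", "PW": "PW", "WP": "PW", "WW": "WW"}[kind]
            rec = HBondRecord(
                donor=donor.key, hydrogen=donor.h_key, acceptor=acc.key,
                frame=frame_index, kind=kind,
                interchain=(donor.chain != acc.chain) if kind == "PP" else None,
                distance=float(dist), angle=float(angle),
            )
            pair = (donor.key, acc.key)
            prev = best.get(pair)
            if prev is None or rec.angle < prev.angle:
                best[pair] = rec
    records = sorted(best.values(), key=lambda r: (r.donor, r.acceptor))
    return records


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

@dataclass
class HBondCensus:
    """Per-frame hydrogen-bond counts by class plus blocked summaries.

    Water-dependent columns are None when the system has no water; W-W per
    water counts each bond toward both partner molecules (2 * N_WW / N_w).
    """

    times: np.ndarray
    pp_total: np.ndarray
    pp_interchain: np.ndarray
    pp_intrachain: np.ndarray
    pw: np.ndarray | None
    ww: np.ndarray | None
    n_waters: int
    n_protein_residues: int

    @property
    def ww_per_water(self) -> np.ndarray | None:
        if self.ww is None or self.n_waters == 0:
            return None
        return 2.0 * self.ww / self.n_waters

    @property
    def intrachain_per_residue(self) -> np.ndarray:
        return self.pp_intrachain / self.n_protein_residues

    def summary(self, window: float | None = None, n_blocks: int = 5
                ) -> dict[str, BlockResult | None]:
        def blk(series):
            if series is None:
                return None
            return block_average(self.times, series, window=window, n_blocks=n_blocks)

        return {
            "PP": blk(self.pp_total),
            "PP_interchain": blk(self.pp_interchain),
            "PP_intrachain": blk(self.pp_intrachain),
            "PP_intrachain_per_residue": blk(self.intrachain_per_residue),
            "PW": blk(self.pw),
            "WW_per_water": blk(self.ww_per_water),
        }


def census(traj: Trajectory, system: MolecularSystem | None = None,
           annotation: RegionAnnotation | None = None,
           criterion: HBondCriterion | None = None) -> HBondCensus:
    """Count hydrogen bonds per frame, partitioned by class."""
    system = system or traj.topology
    n_waters = len(system.water_residues())
    n_prot_res = sum(1 for (_c, _r, nm) in system.residues() if nm not in ("HOH", "SOL"))
    F = traj.n_frames
    pp_t = np.zeros(F)
    pp_inter = np.zeros(F)
    pp_intra = np.zeros(F)
    pw = np.zeros(F) if n_waters else None
    ww = np.zeros(F) if n_waters else None
    for k in range(F):
        for rec in find_hbonds(traj.frames[k], system, criterion, frame_index=k):
            if rec.kind == "PP":
                pp_t[k] += 1
                if rec.interchain:
                    pp_inter[k] += 1
                else:
                    pp_intra[k] += 1
            elif rec.kind == "PW" and pw is not None:
                pw[k] += 1
            elif rec.kind == "WW" and ww is not None:
                ww[k] += 1
    return HBondCensus(times=traj.times.copy(), pp_total=pp_t,
                       pp_interchain=pp_inter, pp_intrachain=pp_intra,
                       pw=pw, ww=ww, n_waters=n_waters,
                       n_protein_residues=n_prot_res)


# ---------------------------------------------------------------------------
# helix i -> i+4 pattern
# ---------------------------------------------------------------------------

def helix_i_to_i4(traj: Trajectory, system: MolecularSystem | None,
                  annotation: RegionAnnotation,
                  criterion: HBondCriterion | None = None,
                  window: float | None = None, n_blocks: int = 5,
                  ) -> dict[tuple[str, str], dict]:
    """Per-helix count of O(i) -> N(i+4) backbone bonds, block-averaged.

    Only pairs with both residues inside the same annotated helix range count.
    Returns {(chain, label): {"series": ..., "block": BlockResult}}.
    """
    system = system or traj.topology
    crit = criterion or HBondCriterion()
    out: dict[tuple[str, str], dict] = {}
    for (cid, label, a, b) in annotation.helix_ranges():
        if b - a + 1 < 5:
            warnings.warn(f"helix {cid}/{label} shorter than 5 residues; count is 0")
            out[(cid, label)] = {
                "series": np.zeros(traj.n_frames),
                "block": block_average(traj.times, np.zeros(traj.n_frames),
                                       window=window, n_blocks=n_blocks),
            }
            continue
        pairs = []  # (o_idx, n_idx, prev_c_idx, ca_idx)
        for i in range(a, b - 3):
            j = i + 4
            if not (system.has_atom(cid, i, "O") and system.has_atom(cid, j, "N")
                    and system.has_atom(cid, j - 1, "C") and system.has_atom(cid, j, "CA")):
                continue
            pairs.append((system.index_of(cid, i, "O"), system.index_of(cid, j, "N"),
                          system.index_of(cid, j - 1, "C"), system.index_of(cid, j, "CA")))
        series = np.zeros(traj.n_frames)
        if pairs:
            o_i, n_i, pc_i, ca_i = (np.array(x) for x in zip(*pairs))
            for k in range(traj.n_frames):
                c = traj.frames[k]
                da = c[o_i] - c[n_i]
                dist = np.linalg.norm(da, axis=1)
                u = c[pc_i] - c[n_i]
                u /= np.linalg.norm(u, axis=1, keepdims=True)
                v = c[ca_i] - c[n_i]
                v /= np.linalg.norm(v, axis=1, keepdims=True)
                hdir = -(u + v)
                hdir /= np.linalg.norm(hdir, axis=1, keepdims=True)
                cosang = np.clip(np.sum(hdir * da, axis=1) / np.maximum(dist, 1e-12),
                                 -1.0, 1.0)
                ang = np.degrees(np.arccos(cosang))
                series[k] = int(np.sum((dist <= crit.max_da_distance)
                                       & (ang <= crit.max_hda_angle)))
        out[(cid, label)] = {
            "series": series,
            "block": block_average(traj.times, series, window=window, n_blocks=n_blocks),
        }
    return out


# ---------------------------------------------------------------------------
# loop bridge table
# ---------------------------------------------------------------------------

def loop_bridge_table(traj: Trajectory, system: MolecularSystem | None,
                      annotation: RegionAnnotation,
                      criterion: HBondCriterion | None = None,
                      bridge_threshold: float = 0.05,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean HB count between each loop residue and each helix, plus bridges.

    Counts protein-protein bonds where the loop residue takes either role
    (donor or acceptor) and the partner residue lies inside a helix range;
    water is excluded. A loop residue is flagged as a "bridge" for a chain
    when its mean count to BOTH helices of that chain exceeds the threshold.

    Returns (table, bridges): the table is indexed by (chain, res_index,
    res_name) with one column per (chain, helix-label); bridges is a boolean
    frame indexed like the table with one column per hairpin chain.
    """
    system = system or traj.topology
    loops: list[tuple[str, int, str]] = []
    res_names = {(c, r): nm for (c, r, nm) in system.residues()}
    for cid in annotation.chains():
        if annotation.has_loop(cid):
            a, b = annotation.loop_range(cid)
            loops += [(cid, r, res_names.get((cid, r), "?")) for r in range(a, b + 1)]
    if not loops:
        raise ValueError("annotation has no LOOP region (hairpin topology required)")
    helices = annotation.helix_ranges()
    helix_cols = [(cid, lab) for (cid, lab, _a, _b) in helices]

    def helix_of(chain: str, res: int) -> tuple[str, str] | None:
        for (cid, lab, a, b) in helices:
            if cid == chain and a <= res <= b:
                return (cid, lab)
        return None

    loop_set = {(c, r) for (c, r, _n) in loops}
    counts = {(lk, hc): np.zeros(traj.n_frames) for lk in loop_set for hc in helix_cols}
    for k in range(traj.n_frames):
        for rec in find_hbonds(traj.frames[k], system, criterion, frame_index=k):
            if rec.kind != "PP":
                continue
            d_key = (rec.donor[0], rec.donor[1])
            a_key = (rec.acceptor[0], rec.acceptor[1])
            for loop_key, partner in ((d_key, a_key), (a_key, d_key)):
                if loop_key in loop_set:
                    hc = helix_of(*partner)
                    if hc is not None:
                        counts[(loop_key, hc)][k] += 1

    rows = {}
    for (cid, r, nm) in loops:
        rows[(cid, r, nm)] = {hc: counts[((cid, r), hc)].mean() for hc in helix_cols}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.names = ["chain", "res_index", "res_name"]
    table.columns = pd.MultiIndex.from_tuples(helix_cols, names=["chain", "helix"])

    hairpin_chains = sorted({c for (c, lab) in helix_cols if lab in ("HELIX1", "HELIX2")})
    bridges = pd.DataFrame(False, index=table.index, columns=hairpin_chains)
    for idx in table.index:
        for hc_chain in hairpin_chains:
            c1 = table.loc[idx, (hc_chain, "HELIX1")]
            c2 = table.loc[idx, (hc_chain, "HELIX2")]
            bridges.loc[idx, hc_chain] = bool(c1 > bridge_threshold and c2 > bridge_threshold)
    return table, bridges
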