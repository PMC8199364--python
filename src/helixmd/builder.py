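"""Synthetic structure and trajectory generator for helix-bundle analyses.

Builds ideal peptide backbones (N, CA, C, O plus CB for non-Gly) from internal
coordinates, assembles them into hairpin-dimer or four-helix-tetramer bundles
with region annotations, and produces noisy "thermal" trajectories with known
per-residue displacement amplitudes. These stand in for MD trajectories: every
analysis module can be validated against the generator's ground truth.

Side chains beyond CB are not built; every analysis in scope uses only
backbone, CB or water atoms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import AtomRecord, MolecularSystem, RegionAnnotation, Trajectory
from .geometry import place_atom

__all__ = [
    "BackboneGeometry",
    "NoiseModel",
    "build_chain",
    "build_bundle",
    "generate_trajectory",
    "place_waters",
    "HYDROPHOBIC_RESIDUES",
    "IDEAL_HELIX_PHI_PSI",
    "default_sigma_profile",
]

#: standard hydrophobic residue classification (configurable at call sites)
HYDROPHOBIC_RESIDUES = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP"})

#: textbook ideal alpha-helix backbone torsions (deg)
IDEAL_HELIX_PHI_PSI = (-60.0, -50.0)

_KNOWN_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass(frozen=True)
class BackboneGeometry:
    """Standard peptide internal coordinates (nm / degrees)."""

    n_ca: float = 0.1458
    ca_c: float = 0.1525
    c_n: float = 0.1329
    ang_n_ca_c: float = 110.0
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    omega: float = 180.0
    # carbonyl O and beta carbon placement
    c_o: float = 0.1231
    ang_ca_c_o: float = 120.5
    ca_cb: float = 0.1530
    ang_n_ca_cb: float = 110.5

    def __post_init__(self):
        for L in (self.n_ca, self.ca_c, self.c_n):
            if not (0.1 < L < 0.2):
                raise ValueError("backbone bond lengths must lie in (0.1, 0.2) nm")
        for A in (self.ang_n_ca_c, self.ang_ca_c_n, self.ang_c_n_ca):
            if not (90.0 < A < 140.0):
                raise ValueError("backbone bond angles must lie in (90, 140) deg")


@dataclass
class NoiseModel:
    """Gaussian positional noise with optional slow drift.

    ``sigma`` is either a scalar (nm, applied to every atom) or a mapping
    (chain_id, res_index) -> per-coordinate standard deviation in nm.
    ``drift_target`` interpolates the underlying conformation linearly from the
    reference to the target coordinates over the trajectory. The same seed
    always reproduces the same trajectory bit-for-bit.
    """

    sigma: float | dict[tuple[str, int], float] = 0.0
    seed: int = 0
    drift_target: np.ndarray | None = None

    def per_atom_sigma(self, system: MolecularSystem) -> np.ndarray:
        if np.isscalar(self.sigma):
            s = float(self.sigma)
            if s < 0:
                raise ValueError("sigma must be non-negative")
            return np.full(len(system), s)
        out = np.empty(len(system))
        for i, a in enumerate(system.atoms):
            try:
                s = float(self.sigma[(a.chain_id, a.res_index)])
            except KeyError as e:
                raise KeyError(f"no sigma for residue {(a.chain_id, a.res_index)}") from e
            if s < 0:
                raise ValueError("sigma must be non-negative")
            out[i] = s
        return out


# ---------------------------------------------------------------------------
# chain construction
# ---------------------------------------------------------------------------

def build_chain(
    sequence: list[str],
    torsions: list[tuple[float, float]],
    geometry: BackboneGeometry | None = None,
    chain_id: str = "A",
) -> MolecularSystem:
    """Grow a peptide backbone from (phi, psi) internal coordinates.

    The first residue's phi and the last residue's psi are undefined at the
    termini and are ignored. Measured backbone torsions of the result equal
    the inputs. CB is placed with the L-amino-acid hand (the improper
    N-CA-C-CB dihedral of built chains is negative, around -120 deg, the
    standard protein convention).
    """
    geo = geometry or BackboneGeometry()
    if len(sequence) != len(torsions):
        raise ValueError("sequence and torsions must have equal length")
    if len(sequence) < 2:
        raise ValueError("need at least 2 residues")
    for code in sequence:
        if code.upper() not in _KNOWN_RESIDUES:
            raise ValueError(f"unknown residue code {code!r}")
    sequence = [c.upper() for c in sequence]
    n = len(sequence)

    N = np.empty((n, 3))
    CA = np.empty((n, 3))
    C = np.empty((n, 3))

    # first residue in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (geo.n_ca, 0.0, 0.0)
    u = (N[0] - CA[0]) / geo.n_ca
    ang = np.radians(geo.ang_n_ca_c)
    C[0] = CA[0] + geo.ca_c * (np.cos(ang) * u + np.sin(ang) * np.array([0.0, 1.0, 0.0]))

    for i in range(1, n):
        psi_prev = torsions[i - 1][1]
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], geo.c_n, geo.ang_ca_c_n, psi_prev)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], geo.n_ca, geo.ang_c_n_ca, geo.omega)
        phi = torsions[i][0]
        C[i] = place_atom(C[i - 1], N[i], CA[i], geo.ca_c, geo.ang_n_ca_c, phi)

    atoms: list[AtomRecord] = []
    serial = 0

    def add(name: str, element: str, res: int, pos: np.ndarray):
        nonlocal serial
        serial += 1
        atoms.append(
            AtomRecord(serial=serial, name=name, element=element,
                       res_index=res + 1, res_name=sequence[res],
                       chain_id=chain_id, position=pos)
        )

    for i in range(n):
        add("N", "N", i, N[i])
        add("CA", "C", i, CA[i])
        add("C", "C", i, C[i])
        # carbonyl O anti to the following N (uses the provided psi for the
        # final residue, whose backbone psi is otherwise unused)
        psi_here = torsions[i][1]
        O = place_atom(N[i], CA[i], C[i], geo.c_o, geo.ang_ca_c_o, psi_here + 180.0)
        add("O", "O", i, O)
        if sequence[i] != "GLY":
            CB = place_atom(N[i], C[i], CA[i], geo.ca_cb, geo.ang_n_ca_cb, 122.6)
            add("CB", "C", i, CB)
    return MolecularSystem(atoms)


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------

def _heptad_helix_sequence(length: int, offset: int = 0) -> list[str]:
    """Amphipathic heptad pattern: hydrophobic a/d positions (LEU/ALA)."""
    pattern = ["LEU", "GLU", "GLN", "ALA", "LYS", "SER", "GLU"]
    return [pattern[(i + offset) % 7] for i in range(length)]


def _wtrop_like_layout(chain_length: int, loop_length: int):
    """Region layout (label, length) for an alpha-helical hairpin chain."""
    n_tail, c_tail = 2, 7
    rem = chain_length - n_tail - c_tail - loop_length
    if loop_length < 1:
        raise ValueError("wtrop_like requires loop_length >= 1")
    if rem < 10:
        raise ValueError("chain too short for two helices")
    h1 = rem // 2
    h2 = rem - h1
    return [("N_TAIL", n_tail), ("HELIX1", h1), ("LOOP", loop_length),
            ("HELIX2", h2), ("C_TAIL", c_tail)]


def _rm6_like_layout(chain_length: int):
    n_tail, c_tail = 4, 7
    h = chain_length - n_tail - c_tail
    if h < 5:
        raise ValueError("chain too short for a helix")
    return [("N_TAIL", n_tail), ("HELIX", h), ("C_TAIL", c_tail)]


#: loop sequence placing LEU-ASP-ALA-ASP at hairpin positions 29-32 for the
#: default 63-residue chain, echoing the loop residues of the wild-type hairpin
_LOOP9 = ["GLY", "GLY", "GLY", "SER", "LEU", "ASP", "ALA", "ASP", "GLY"]

_COIL_PHI_PSI = (-80.0, 80.0)


def _chain_spec(kind: str, chain_length: int, loop_length: int,
                helix_phi_psi: tuple[float, float]):
    """Sequence, torsions and labels for one chain of the requested topology."""
    if kind == "wtrop_like":
        layout = _wtrop_like_layout(chain_length, loop_length)
    elif kind == "rm6_like":
        layout = _rm6_like_layout(chain_length)
    else:
        raise ValueError("kind must be 'wtrop_like' or 'rm6_like'")
    sequence: list[str] = []
    torsions: list[tuple[float, float]] = []
    labels: list[str] = []
    for lab, ln in layout:
        if lab in ("HELIX1", "HELIX2", "HELIX"):
            sequence += _heptad_helix_sequence(ln)
            torsions += [helix_phi_psi] * ln
        elif lab == "LOOP":
            seq = _LOOP9 if ln == 9 else (["GLY", "SER"] * ln)[:ln]
            sequence += seq
            torsions += [_COIL_PHI_PSI] * ln
        else:  # tails
            sequence += (["GLY", "SER"] * ln)[:ln]
            torsions += [_COIL_PHI_PSI] * ln
        labels += [lab] * ln
    return sequence, torsions, labels


def _principal_axis_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation aligning the principal axis of `coords` with z, plus centroid."""
    center = coords.mean(axis=0)
    u, s, vt = np.linalg.svd(coords - center)
    axis = vt[0]
    if np.dot(coords[-1] - coords[0], axis) < 0:
        axis = -axis
    # rotation taking axis -> z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return R, center


_FLIP_X = np.diag([1.0, -1.0, -1.0])  # 180 deg about x: reverses z


def build_bundle(
    kind: str,
    chain_length: int | None = None,
    loop_length: int = 9,
    separation: float = 1.2,
    helix_phi_psi: tuple[float, float] = IDEAL_HELIX_PHI_PSI,
    geometry: BackboneGeometry | None = None,
    antiparallel: bool = True,
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_RESIDUES,
) -> tuple[MolecularSystem, RegionAnnotation]:
    """Assemble a helix bundle on a square lattice of side ``separation`` (nm).

    ``wtrop_like``: 2 chains x 63 residues, each an alpha-helical hairpin
    (HELIX1-LOOP-HELIX2 plus tails). ``rm6_like``: 4 chains x 58 residues,
    one long helix each. Chains alternate orientation (antiparallel) around
    the lattice; each chain keeps its own centroid on its lattice site.
    """
    if chain_length is None:
        chain_length = 63 if kind == "wtrop_like" else 58
    n_chains = 2 if kind == "wtrop_like" else 4
    sequence, torsions, labels = _chain_spec(kind, chain_length, loop_length, helix_phi_psi)

    sites = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)][:n_chains]
    chain_ids = ["A", "B", "C", "D"][:n_chains]
    systems = []
    ann_labels: dict[tuple[str, int], str] = {}
    ann_hydro: dict[tuple[str, int], bool] = {}
    for k, cid in enumerate(chain_ids):
        chain = build_chain(sequence, torsions, geometry, chain_id=cid)
        coords = chain.coords()
        R, center = _principal_axis_frame(coords)
        coords = (coords - center) @ R.T
        if antiparallel and k % 2 == 1:
            coords = coords @ _FLIP_X.T
        offx, offy = sites[k]
        coords += np.array([offx * separation, offy * separation, 0.0])
        systems.append(chain.with_coords(coords))
        for r, (lab, res) in enumerate(zip(labels, sequence), start=1):
            ann_labels[(cid, r)] = lab
            ann_hydro[(cid, r)] = res in hydrophobic_set

    from .core import combine_systems

    system = combine_systems(*systems)
    annotation = RegionAnnotation(labels=ann_labels, hydrophobic=ann_hydro)
    annotation.validate(system)
    return system, annotation


def default_sigma_profile(
    annotation: RegionAnnotation,
    helix: float = 0.012,
    loop: float = 0.030,
    tail: float = 0.050,
    scale: float = 1.0,
) -> dict[tuple[str, int], float]:
    """Per-residue noise amplitudes (nm): tails > loop > helices.

    Emulates the empirical fluctuation ordering of bundle trajectories, where
    terminal and loop residues move the most. ``scale`` multiplies the whole
    profile and is the knob the "temperature" tiers turn.
    """
    out = {}
    for key, lab in annotation.labels.items():
        base = {"N_TAIL": tail, "C_TAIL": tail, "LOOP": loop}.get(lab, helix)
        out[key] = base * scale
    return out


# ---------------------------------------------------------------------------
# trajectories and waters
# ---------------------------------------------------------------------------

def generate_trajectory(
    system: MolecularSystem,
    n_frames: int,
    noise: NoiseModel,
    dt: float = 0.1,
) -> Trajectory:
    """Reference (or drift-interpolated) conformation + i.i.d. Gaussian noise.

    Frame k carries per-coordinate displacement std sigma_i for every atom of
    residue i. Reproducible bit-for-bit for a fixed seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    sigma = noise.per_atom_sigma(system)
    ref = system.coords()
    rng = np.random.default_rng(noise.seed)
    frames = np.empty((n_frames, len(system), 3))
    for k in range(n_frames):
        if noise.drift_target is not None and n_frames > 1:
            alpha = k / (n_frames - 1)
            base = (1.0 - alpha) * ref + alpha * np.asarray(noise.drift_target, float)
        else:
            base = ref
        frames[k] = base + rng.normal(size=(len(system), 3)) * sigma[:, None]
    times = np.arange(n_frames) * float(dt)
    return Trajectory(topology=system, frames=frames, times=times)


def place_waters(
    box: np.ndarray,
    n_waters: int,
    min_dist: float = 0.30,
    seed: int = 0,
    chain_id: str = "W",
    max_tries: int = 10000,
) -> MolecularSystem:
    """Randomly place rigid 3-site waters (O-H 0.1 nm, H-O-H 109.47 deg).

    Oxygen positions are uniform in the box, rejected until all pairwise O-O
    distances are >= ``min_dist``; orientations are uniform random rotations.
    """
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    oh = 0.1
    half = np.radians(109.47 / 2.0)
    h1_local = oh * np.array([np.sin(half), 0.0, np.cos(half)])
    h2_local = oh * np.array([-np.sin(half), 0.0, np.cos(half)])

    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_waters:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"water placement failed after {max_tries} tries "
                f"({len(centers)}/{n_waters} placed)"
            )
        p = rng.uniform(0.0, 1.0, size=3) * box
        if all(np.linalg.norm(p - q) >= min_dist for q in centers):
            centers.append(p)

    from scipy.spatial.transform import Rotation

    atoms: list[AtomRecord] = []
    serial = 0
    for i, p in enumerate(centers, start=1):
        R = Rotation.random(rng=rng).as_matrix()
        for name, element, local in (
            ("OW", "O", np.zeros(3)),
            ("HW1", "H", h1_local),
            ("HW2", "H", h2_local),
        ):
            serial += 1
            atoms.append(
                AtomRecord(serial=serial, name=name, element=element,
                           res_index=i, res_name="SOL", chain_id=chain_id,
                           position=p + R @ local)
            )
    return MolecularSystem(atoms, box=box)
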