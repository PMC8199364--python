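"""Domain model and PDB/trajectory I/O.

Internal unit convention: every coordinate held in memory is in nm. The only
Angstrom<->nm conversion happens at PDB read/write time (PDB files are in A).

The supported trajectory dialect is multi-model PDB: MODEL/ENDMDL blocks over
one fixed topology. Residue indexing is 1-based per chain and must be
contiguous and ascending, which lets backbone connectivity follow from residue
order alone (no distance-based bond inference).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "MolecularSystem",
    "Trajectory",
    "RegionAnnotation",
    "Selection",
    "PDBParseError",
    "TopologyMismatchError",
    "WATER_RES_NAMES",
    "BACKBONE_ATOMS",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
    "read_annotation",
    "write_annotation",
    "combine_systems",
]

NM_PER_ANGSTROM = 0.1

WATER_RES_NAMES = frozenset({"HOH", "SOL"})
BACKBONE_ATOMS = ("N", "CA", "C", "O")
REGION_LABELS = ("N_TAIL", "HELIX1", "LOOP", "HELIX2", "C_TAIL", "HELIX")
HELIX_LABELS = ("HELIX1", "HELIX2", "HELIX")

#: atomic masses (u) for the elements the builder and water model emit
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


class PDBParseError(ValueError):
    """Raised for malformed or unsupported PDB content; carries a line number."""


class TopologyMismatchError(ValueError):
    """Raised when trajectory frames disagree on the shared topology."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    res_index: int  # 1-based within chain
    res_name: str
    chain_id: str
    position: np.ndarray  # (3,) nm

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_index, self.name)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_RES_NAMES


class MolecularSystem:
    """An ordered collection of atoms grouped into residues and chains."""

    def __init__(self, atoms: Sequence[AtomRecord], box: np.ndarray | None = None):
        self.atoms: list[AtomRecord] = list(atoms)
        if not self.atoms:
            raise ValueError("MolecularSystem requires at least one atom")
        self.box = None if box is None else np.asarray(box, dtype=float)
        if self.box is not None and self.box.shape != (3,):
            raise ValueError("box must be a 3-vector of edge lengths (nm)")
        seen_chains: dict[str, None] = {}
        for a in self.atoms:
            seen_chains.setdefault(a.chain_id, None)
        self.chains: list[str] = list(seen_chains)
        self._index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            if a.key in self._index:
                raise ValueError(f"duplicate atom {a.key}")
            self._index[a.key] = i
        self._validate_residue_order()

    def _validate_residue_order(self):
        for cid in self.chains:
            idx = [a.res_index for a in self.atoms if a.chain_id == cid]
            res_seq = []
            for r in idx:
                if not res_seq or res_seq[-1] != r:
                    res_seq.append(r)
            if any(b - a != 1 for a, b in zip(res_seq, res_seq[1:])):
                raise ValueError(
                    f"chain {cid}: residue indices must be contiguous and ascending"
                )

    # -- accessors -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in nm."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def index_of(self, chain_id: str, res_index: int, name: str) -> int:
        return self._index[(chain_id, res_index, name)]

    def has_atom(self, chain_id: str, res_index: int, name: str) -> bool:
        return (chain_id, res_index, name) in self._index

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int, str]]:
        """Ordered (chain_id, res_index, res_name) triples."""
        out, seen = [], set()
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            k = (a.chain_id, a.res_index)
            if k not in seen:
                seen.add(k)
                out.append((a.chain_id, a.res_index, a.res_name))
        return out

    def residue_count(self, chain_id: str) -> int:
        return len(self.residues(chain_id))

    def protein_chains(self) -> list[str]:
        out = []
        for cid in self.chains:
            if any(a.chain_id == cid and not a.is_water for a in self.atoms):
                out.append(cid)
        return out

    def water_residues(self) -> list[tuple[str, int]]:
        out, seen = [], set()
        for a in self.atoms:
            if a.is_water:
                k = (a.chain_id, a.res_index)
                if k not in seen:
                    seen.add(k)
                    out.append(k)
        return out

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(a.element, 12.011) for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "MolecularSystem":
        """Copy of the system with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [dataclasses.replace(a, position=coords[i]) for i, a in enumerate(self.atoms)]
        return MolecularSystem(atoms, box=self.box)


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology; times in ns."""

    topology: MolecularSystem
    frames: np.ndarray  # (n_frames, n_atoms, 3) nm
    times: np.ndarray  # (n_frames,) ns

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology):
            raise TopologyMismatchError(
                "every frame must carry one position per topology atom"
            )
        if len(self.times) != len(self.frames):
            raise ValueError("len(times) must equal len(frames)")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_system(self, k: int) -> MolecularSystem:
        return self.topology.with_coords(self.frames[k])


@dataclass
class RegionAnnotation:
    """Per-residue structural labels and hydrophobicity flags.

    ``labels`` maps (chain_id, res_index) -> one of N_TAIL, HELIX1, LOOP,
    HELIX2, C_TAIL, HELIX; ``hydrophobic`` flags residues whose side chains
    point into the bundle core.
    """

    labels: dict[tuple[str, int], str]
    hydrophobic: dict[tuple[str, int], bool] = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.labels.items():
            if v not in REGION_LABELS:
                raise ValueError(f"unknown region label {v!r} for residue {k}")

    def label(self, chain_id: str, res_index: int) -> str:
        return self.labels[(chain_id, res_index)]

    def is_hydrophobic(self, chain_id: str, res_index: int) -> bool:
        return bool(self.hydrophobic.get((chain_id, res_index), False))

    def chains(self) -> list[str]:
        out: dict[str, None] = {}
        for (cid, _r) in self.labels:
            out.setdefault(cid, None)
        return list(out)

    def segments(self, chain_id: str) -> list[tuple[str, int, int]]:
        """Contiguous (label, res_start, res_end) runs for one chain."""
        items = sorted(r for (c, r) in self.labels if c == chain_id)
        segs: list[tuple[str, int, int]] = []
        for r in items:
            lab = self.labels[(chain_id, r)]
            if segs and segs[-1][0] == lab and segs[-1][2] == r - 1:
                segs[-1] = (lab, segs[-1][1], r)
            else:
                segs.append((lab, r, r))
        return segs

    def helix_ranges(self, chain_id: str | None = None) -> list[tuple[str, str, int, int]]:
        """All helices as (chain_id, label, res_start, res_end)."""
        chains = [chain_id] if chain_id is not None else self.chains()
        out = []
        for cid in chains:
            for lab, a, b in self.segments(cid):
                if lab in HELIX_LABELS:
                    out.append((cid, lab, a, b))
        return out

    def loop_range(self, chain_id: str) -> tuple[int, int]:
        for lab, a, b in self.segments(chain_id):
            if lab == "LOOP":
                return (a, b)
        raise ValueError(f"chain {chain_id} has no LOOP region annotated")

    def has_loop(self, chain_id: str) -> bool:
        return any(lab == "LOOP" for lab, _a, _b in self.segments(chain_id))

    def validate(self, system: MolecularSystem) -> None:
        """Check labels partition each protein chain and hairpins have loops."""
        for cid in system.protein_chains():
            residues = [(c, r) for (c, r, _n) in system.residues(cid)]
            for k in residues:
                if k not in self.labels:
                    raise ValueError(f"residue {k} missing from annotation")
            segs = self.segments(cid)
            labs = [s[0] for s in segs]
            if "HELIX1" in labs and "HELIX2" in labs:
                i1, i2 = labs.index("HELIX1"), labs.index("HELIX2")
                if "LOOP" not in labs[i1:i2]:
                    raise ValueError(
                        f"chain {cid}: HELIX1/HELIX2 require a LOOP between them"
                    )


@dataclass
class Selection:
    """Deterministically ordered atom references into a MolecularSystem."""

    refs: list[tuple[str, int, str]]

    def __len__(self) -> int:
        return len(self.refs)

    def indices(self, system: MolecularSystem) -> np.ndarray:
        """Resolve references to integer atom indices (errors if unresolved)."""
        try:
            return np.array([system.index_of(*r) for r in self.refs], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise KeyError(f"selection reference {e} not found in system") from e

    def residue_keys(self) -> list[tuple[str, int]]:
        out, seen = [], set()
        for (c, r, _n) in self.refs:
            if (c, r) not in seen:
                seen.add((c, r))
                out.append((c, r))
        return out


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17]
        res_name = line[17:20].strip()
        chain_id = line[21:22].strip() or "A"
        res_seq = int(line[22:26])
        icode = line[26:27]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as e:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {e}") from e
    if icode not in (" ", ""):
        raise PDBParseError(f"line {lineno}: insertion codes are not supported")
    if altloc not in (" ", "", "A"):
        return None  # type: ignore[return-value]  # dropped altLoc
    if not element:
        element = "".join(ch for ch in name if ch.isalpha())[:1].upper()
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        res_index=res_seq,
        res_name=res_name,
        chain_id=chain_id,
        position=np.array([x, y, z]) * NM_PER_ANGSTROM,
    )


def _read_models(path) -> list[list[AtomRecord]]:
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    any_model_kw = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if in_model:
                    raise PDBParseError(f"line {lineno}: nested MODEL records")
                in_model = True
                any_model_kw = True
                current = []
            elif rec == "ENDMDL":
                if not in_model:
                    raise PDBParseError(f"line {lineno}: ENDMDL without MODEL")
                in_model = False
                models.append(current)
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line.rstrip("\n"), lineno)
                if atom is not None:
                    current.append(atom)
    if in_model:
        raise PDBParseError("file ended inside an unterminated MODEL block")
    if not any_model_kw:
        models = [current]
    if not models or not models[0]:
        raise PDBParseError("no ATOM/HETATM records found")
    return models


def _renumber_per_chain(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Map author residue numbering to contiguous 1-based per-chain indices."""
    mapping: dict[tuple[str, int], int] = {}
    counters: dict[str, int] = {}
    out = []
    for a in atoms:
        k = (a.chain_id, a.res_index)
        if k not in mapping:
            counters[a.chain_id] = counters.get(a.chain_id, 0) + 1
            mapping[k] = counters[a.chain_id]
        out.append(dataclasses.replace(a, res_index=mapping[k]))
    return out


def read_pdb(path, box: np.ndarray | None = None) -> MolecularSystem:
    """Read a PDB file (first model if multi-model); coordinates A -> nm.

    Alternate locations other than blank/'A' are dropped, insertion codes are
    rejected, and author residue numbers are renumbered to contiguous 1-based
    indices per chain.
    """
    models = _read_models(path)
    return MolecularSystem(_renumber_per_chain(models[0]), box=box)


def _format_atom_line(a: AtomRecord, serial: int) -> str:
    x, y, z = a.position / NM_PER_ANGSTROM
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {serial:5d} {name:<4s} {a.res_name:>3s} {a.chain_id:1s}"
        f"{a.res_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )


def _write_model(fh, system: MolecularSystem) -> None:
    serial = 0
    prev_chain = None
    last_atom = None
    for a in system.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            serial += 1
            fh.write(
                f"TER   {serial:5d}      {last_atom.res_name:>3s} "
                f"{last_atom.chain_id:1s}{last_atom.res_index:4d}\n"
            )
        serial += 1
        fh.write(_format_atom_line(a, serial) + "\n")
        prev_chain = a.chain_id
        last_atom = a
    serial += 1
    fh.write(
        f"TER   {serial:5d}      {last_atom.res_name:>3s} "
        f"{last_atom.chain_id:1s}{last_atom.res_index:4d}\n"
    )


def write_pdb(system: MolecularSystem, path) -> None:
    """Write a single-model PDB file (coordinates nm -> A, TER between chains)."""
    with open(path, "w") as fh:
        _write_model(fh, system)
        fh.write("END\n")


def read_trajectory(path, dt: float | None = None, times=None) -> Trajectory:
    """Read a multi-model PDB as a trajectory over a shared topology.

    Times come from ``times`` (explicit, ns) or ``dt`` (uniform spacing, ns),
    defaulting to the frame index in ns.
    """
    models = _read_models(path)
    topo_atoms = _renumber_per_chain(models[0])
    topology = MolecularSystem(topo_atoms)
    n = len(topo_atoms)
    frames = np.empty((len(models), n, 3))
    for k, model in enumerate(models):
        if len(model) != n:
            raise TopologyMismatchError(
                f"model {k + 1} has {len(model)} atoms, expected {n}"
            )
        frames[k] = [a.position for a in model]
    if times is None:
        step = 1.0 if dt is None else float(dt)
        times = np.arange(len(models)) * step
    return Trajectory(topology=topology, frames=frames, times=np.asarray(times, float))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB."""
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"MODEL     {k + 1:4d}\n")
            _write_model(fh, traj.topology.with_coords(traj.frames[k]))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_atoms(
    system: MolecularSystem,
    annotation: RegionAnnotation | None = None,
    atoms: Iterable[str] = ("CA",),
    chains: Iterable[str] | None = None,
    regions: Iterable[str] | None = None,
    exclude: Iterable[str] = (),
    hydrophobic_only: bool = False,
) -> Selection:
    """Build a deterministic Selection of atoms.

    ``exclude`` supports the tail conventions used throughout the analysis:
    "tail7" removes the last 7 residues of each chain and "head4" the first 4.
    ``regions``/``hydrophobic_only`` require an annotation.
    """
    atoms = set(atoms)
    exclude = set(exclude)
    unknown = exclude - {"tail7", "head4"}
    if unknown:
        raise ValueError(f"unknown exclusion rule(s): {sorted(unknown)}")
    if chains is not None:
        chains = list(chains)
        missing = [c for c in chains if c not in system.chains]
        if missing:
            raise ValueError(f"unknown chain(s) {missing}; system has {system.chains}")
        chain_set = set(chains)
    else:
        chain_set = set(system.chains)
    if (regions is not None or hydrophobic_only) and annotation is None:
        raise ValueError("region/hydrophobic filtering requires an annotation")

    drop: set[tuple[str, int]] = set()
    for cid in system.chains:
        if cid not in chain_set:
            continue
        res = [r for (_c, r, _n) in system.residues(cid)]
        if not res:
            continue
        if "tail7" in exclude:
            drop.update((cid, r) for r in res[-7:])
        if "head4" in exclude:
            drop.update((cid, r) for r in res[:4])

    refs = []
    for a in system.atoms:
        if a.chain_id not in chain_set or a.name not in atoms:
            continue
        if (a.chain_id, a.res_index) in drop:
            continue
        if regions is not None and annotation.label(a.chain_id, a.res_index) not in regions:
            continue
        if hydrophobic_only and not annotation.is_hydrophobic(a.chain_id, a.res_index):
            continue
        refs.append(a.key)
    return Selection(refs=refs)


# ---------------------------------------------------------------------------
# Annotation file I/O (plain-text table: chain res_start res_end label flag)
# ---------------------------------------------------------------------------

def write_annotation(annotation: RegionAnnotation, path) -> None:
    rows = []
    for cid in annotation.chains():
        for lab, a, b in annotation.segments(cid):
            hyd = [int(annotation.is_hydrophobic(cid, r)) for r in range(a, b + 1)]
            # split segments further if hydrophobicity varies inside a region
            start = a
            for r in range(a, b + 1):
                nxt = r + 1
                if nxt > b or annotation.is_hydrophobic(cid, nxt) != annotation.is_hydrophobic(cid, r):
                    rows.append(
                        dict(chain=cid, res_start=start, res_end=r, label=lab,
                             hydrophobic=int(annotation.is_hydrophobic(cid, r)))
                    )
                    start = nxt
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> RegionAnnotation:
    df = pd.read_csv(path, sep="\t")
    labels: dict[tuple[str, int], str] = {}
    hydrophobic: dict[tuple[str, int], bool] = {}
    for row in df.itertuples(index=False):
        for r in range(int(row.res_start), int(row.res_end) + 1):
            labels[(str(row.chain), r)] = str(row.label)
            hydrophobic[(str(row.chain), r)] = bool(row.hydrophobic)
    return RegionAnnotation(labels=labels, hydrophobic=hydrophobic)


def combine_systems(*systems: MolecularSystem, box: np.ndarray | None = None) -> MolecularSystem:
    """Concatenate systems; chain ids must not collide."""
    atoms: list[AtomRecord] = []
    serial = 0
    seen_chains: set[str] = set()
    for s in systems:
        if seen_chains & set(s.chains):
            raise ValueError("chain id collision when combining systems")
        seen_chains |= set(s.chains)
        for a in s.atoms:
            serial += 1
            atoms.append(dataclasses.replace(a, serial=serial))
    if box is None:
        boxes = [s.box for s in systems if s.box is not None]
        box = boxes[0] if boxes else None
    return MolecularSystem(atoms, box=box)
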