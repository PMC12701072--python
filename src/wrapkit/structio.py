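"""Structure, sequence and trajectory I/O with symmetry-aware assembly building.

Structures are stored column-wise (parallel numpy arrays) for speed, with an
:class:`AtomRecord` view available per atom.  Reading goes through gemmi for
PDB/mmCIF; trajectories are accepted either as a documented plain-text frame
format (used for fixtures) or, when available, through MDAnalysis readers.

Crystallographic symmetry expansion applies every space-group operator plus
lattice translations and keeps copies that approach a seed selection within a
radius, which is how the homotetramer and the continuous crystal-lattice DNA
helices are rebuilt from a deposited asymmetric unit.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "SequenceRecord",
    "read_structure",
    "write_structure",
    "read_sequences",
    "select_atoms",
    "expand_symmetry",
    "read_trajectory",
    "write_trajectory",
]

PROTEIN_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
DNA_RESNAMES = frozenset("DA DC DG DT".split())
PHOSPHATE_ATOMS = frozenset({"P", "OP1", "OP2", "O5'", "O3'"})
SUGAR_ATOMS = frozenset({"C1'", "C2'", "C3'", "C4'", "C5'", "O4'"})
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
_HYDROGEN = frozenset({"H", "D"})

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One atom as deposited: author chain/residue numbering, PDB atom naming."""

    chain: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN


class Structure:
    """A set of atoms with optional crystal metadata.

    Parameters
    ----------
    chain, residue_number, insertion_code, residue_name, atom_name, element :
        Per-atom metadata arrays (any sequence; stored as numpy arrays).
    xyz : (N, 3) float array, Å.
    cell : optional 6-tuple (a, b, c, alpha, beta, gamma) in Å / degrees.
    space_group : optional Hermann–Mauguin symbol.
    """

    def __init__(self, chain, residue_number, residue_name, atom_name, element,
                 xyz, insertion_code=None, cell=None, space_group=None):
        n = len(chain)
        self.chain = np.asarray(chain, dtype=object)
        self.residue_number = np.asarray(residue_number, dtype=np.int64)
        self.residue_name = np.asarray(residue_name, dtype=object)
        self.atom_name = np.asarray(atom_name, dtype=object)
        self.element = np.asarray(element, dtype=object)
        self.xyz = np.asarray(xyz, dtype=np.float64).reshape(n, 3)
        if insertion_code is None:
            insertion_code = [""] * n
        self.insertion_code = np.asarray(insertion_code, dtype=object)
        self.cell = tuple(float(x) for x in cell) if cell is not None else None
        self.space_group = space_group
        for arr in (self.residue_number, self.residue_name, self.atom_name,
                    self.element, self.insertion_code):
            if len(arr) != n:
                raise ValueError("field length mismatch")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.chain)

    @property
    def n_atoms(self) -> int:
        return len(self)

    @property
    def chains(self) -> list[str]:
        """Ordered unique chain identifiers (order of first appearance)."""
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(self.chain[i], int(self.residue_number[i]),
                       self.insertion_code[i], self.residue_name[i],
                       self.atom_name[i], self.element[i], self.xyz[i].copy())
            for i in range(len(self))
        ]

    def is_heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() not in _HYDROGEN for e in self.element], dtype=bool)

    def subset(self, indices) -> "Structure":
        idx = np.asarray(indices, dtype=np.int64)
        return Structure(self.chain[idx], self.residue_number[idx],
                         self.residue_name[idx], self.atom_name[idx],
                         self.element[idx], self.xyz[idx],
                         insertion_code=self.insertion_code[idx],
                         cell=self.cell, space_group=self.space_group)

    def copy(self) -> "Structure":
        return self.subset(np.arange(len(self)))

    def with_xyz(self, xyz: np.ndarray) -> "Structure":
        out = self.copy()
        out.xyz = np.asarray(xyz, dtype=np.float64).reshape(len(self), 3)
        return out

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, residue_number, insertion_code) keys."""
        seen: dict[tuple, None] = {}
        for i in range(len(self)):
            seen.setdefault((self.chain[i], int(self.residue_number[i]),
                             self.insertion_code[i]), None)
        return list(seen)

    @staticmethod
    def concatenate(parts: Sequence["Structure"], cell=None, space_group=None) -> "Structure":
        if not parts:
            raise ValueError("nothing to concatenate")
        return Structure(
            np.concatenate([p.chain for p in parts]),
            np.concatenate([p.residue_number for p in parts]),
            np.concatenate([p.residue_name for p in parts]),
            np.concatenate([p.atom_name for p in parts]),
            np.concatenate([p.element for p in parts]),
            np.vstack([p.xyz for p in parts]),
            insertion_code=np.concatenate([p.insertion_code for p in parts]),
            cell=cell, space_group=space_group)


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """A protein or DNA sequence with 1-based positions."""

    id: str
    kind: str  # "protein" | "dna"
    residues: str

    def __post_init__(self):
        alphabet = set("ACDEFGHIKLMNPQRSTVWY") if self.kind == "protein" else set("ACGT")
        bad = set(self.residues.upper()) - alphabet
        if self.kind not in ("protein", "dna"):
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        if bad:
            raise ValueError(f"residues {sorted(bad)} not allowed for kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.residues)


class Trajectory:
    """Topology plus an ordered stack of coordinate frames (Å) and times (ns)."""

    def __init__(self, topology: Structure, frames: np.ndarray, frame_times=None):
        frames = np.asarray(frames, dtype=np.float64)
        if frames.ndim == 2:
            frames = frames[None, :, :]
        if frames.ndim != 3 or frames.shape[1] != len(topology) or frames.shape[2] != 3:
            raise ValueError(
                f"frames shape {frames.shape} incompatible with topology of "
                f"{len(topology)} atoms")
        if frame_times is None:
            frame_times = np.arange(frames.shape[0], dtype=np.float64)
        frame_times = np.asarray(frame_times, dtype=np.float64)
        if frame_times.shape != (frames.shape[0],):
            raise ValueError("frame_times length mismatch")
        if frames.shape[0] > 1 and not np.all(np.diff(frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        self.topology = topology
        self.frames = frames
        self.frame_times = frame_times
        self.selection_masks: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return len(self)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _element_from_name(atom_name: str, residue_name: str) -> str:
    """Best-effort element from a PDB-style atom name."""
    name = atom_name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _from_gemmi(st: gemmi.Structure) -> Structure:
    chain, resnum, icode, resname, name, element, xyz = [], [], [], [], [], [], []
    if len(st) == 0:
        raise ValueError("structure contains no models")
    model = st[0]
    for ch in model:
        for res in ch:
            # alternate locations: keep the highest-occupancy conformer,
            # ties broken by file order
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                key = atom.name
                prev = best.get(key)
                if prev is None or atom.occ > prev.occ:
                    best[key] = atom
            for atom in best.values():
                chain.append(ch.name)
                resnum.append(res.seqid.num)
                icode.append(res.seqid.icode.strip())
                resname.append(res.name)
                name.append(atom.name)
                el = atom.element.name if atom.element.name not in ("", "X") else ""
                if not el:
                    el = _element_from_name(atom.name, res.name)
                    warnings.warn(
                        f"element missing for atom {atom.name} in {res.name} "
                        f"{res.seqid.num}; inferred {el}")
                element.append(el.upper())
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    cell = None
    sg = None
    uc = st.cell
    if uc is not None and uc.a > 0 and not (uc.a == uc.b == uc.c == 1.0):
        cell = (uc.a, uc.b, uc.c, uc.alpha, uc.beta, uc.gamma)
        sg = st.spacegroup_hm or None
    return Structure(chain, resnum, resname, name, element, np.array(xyz),
                     insertion_code=icode, cell=cell, space_group=sg)


def read_structure(path, fmt: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure` (first model only).

    Parameters
    ----------
    path : filesystem path.
    fmt : "pdb" | "mmcif" | None (inferred from extension).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc
    s = _from_gemmi(st)
    if len(s) == 0:
        raise ValueError(f"{path}: no atoms parsed")
    return s


_CHAIN_POOL = [chr(c) for c in
               list(range(ord("A"), ord("Z") + 1)) +
               list(range(ord("0"), ord("9") + 1)) +
               list(range(ord("a"), ord("z") + 1))]


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "wrapkit"
    if s.cell is not None:
        st.cell = gemmi.UnitCell(*s.cell)
    if s.space_group:
        st.spacegroup_hm = s.space_group
    model = gemmi.Model("1")
    cur_chain = None
    cur_res = None
    chain_obj = None
    res_obj = None
    for i in range(len(s)):
        if s.chain[i] != cur_chain:
            cur_chain = s.chain[i]
            chain_obj = gemmi.Chain(str(cur_chain))
            model.add_chain(chain_obj)
            chain_obj = model[-1]
            cur_res = None
        key = (int(s.residue_number[i]), s.insertion_code[i], s.residue_name[i])
        if key != cur_res:
            cur_res = key
            res_obj = gemmi.Residue()
            res_obj.name = s.residue_name[i]
            res_obj.seqid = gemmi.SeqId(int(s.residue_number[i]),
                                        s.insertion_code[i] or " ")
            chain_obj.add_residue(res_obj)
            res_obj = chain_obj[-1]
        atom = gemmi.Atom()
        atom.name = s.atom_name[i]
        atom.element = gemmi.Element(s.element[i])
        atom.pos = gemmi.Position(*s.xyz[i])
        atom.occ = 1.0
        res_obj.add_atom(atom)
    st.add_model(model)
    return st


def write_structure(s: Structure, path) -> None:
    """Write a Structure as PDB or mmCIF, inferred from the extension."""
    path = Path(path)
    st = _to_gemmi(s)
    st.setup_entities()
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        # PDB chain ids are one character; remap if needed
        names = [ch for ch in {c: None for c in s.chain}]
        if any(len(str(n)) > 1 for n in names):
            mapping = {n: _CHAIN_POOL[i % len(_CHAIN_POOL)] for i, n in enumerate(names)}
            for model in st:
                for ch in model:
                    ch.name = mapping[ch.name]
        st.write_pdb(str(path))


def read_sequences(path) -> list[SequenceRecord]:
    """Read FASTA records, auto-detecting protein vs DNA alphabets."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        kind = "dna" if set(seq) <= set("ACGT") else "protein"
        out.append(SequenceRecord(rec.id, kind, seq))
    return out


# ---------------------------------------------------------------------------
# atom selection
# ---------------------------------------------------------------------------

_CLASS_NAMES = ("protein", "dna", "heavy", "dna_phosphate", "dna_sugar",
                "dna_base", "protein_backbone", "protein_sidechain", "all")


def _class_mask(s: Structure, name: str) -> np.ndarray:
    heavy = s.is_heavy_mask()
    is_protein = np.array([r in PROTEIN_RESNAMES for r in s.residue_name], dtype=bool)
    is_dna = np.array([r in DNA_RESNAMES for r in s.residue_name], dtype=bool)
    if name == "all":
        return np.ones(len(s), dtype=bool)
    if name == "protein":
        return is_protein
    if name == "dna":
        return is_dna
    if name == "heavy":
        return heavy
    if name == "dna_phosphate":
        in_cls = np.array([a in PHOSPHATE_ATOMS for a in s.atom_name], dtype=bool)
        return is_dna & in_cls
    if name == "dna_sugar":
        in_cls = np.array([a in SUGAR_ATOMS for a in s.atom_name], dtype=bool)
        return is_dna & in_cls
    if name == "dna_base":
        named = np.array([a in PHOSPHATE_ATOMS or a in SUGAR_ATOMS
                          for a in s.atom_name], dtype=bool)
        return is_dna & heavy & ~named
    if name == "protein_backbone":
        in_cls = np.array([a in BACKBONE_ATOMS for a in s.atom_name], dtype=bool)
        return is_protein & in_cls
    if name == "protein_sidechain":
        in_cls = np.array([a in BACKBONE_ATOMS for a in s.atom_name], dtype=bool)
        return is_protein & heavy & ~in_cls
    raise ValueError(f"unknown selection class {name!r}")


def select_atoms(s: Structure, selector: str) -> np.ndarray:
    """Select atom indices with a small expression language.

    Terms are joined with ``and``; each term is either a named atom class
    (``protein``, ``dna``, ``heavy``, ``dna_phosphate``, ``dna_sugar``,
    ``dna_base``, ``protein_backbone``, ``protein_sidechain``, ``all``) or a
    field test: ``chain A``, ``resi 10-20`` (or ``resi 55``), ``resname ARG``,
    ``name CA``, ``element P``.  Multiple values may be comma-separated
    (``chain A,B``).  Returns a sorted integer index array; an empty selection
    is returned as an empty array, not an error.
    """
    mask = np.ones(len(s), dtype=bool)
    expr = selector.strip()
    if not expr:
        raise ValueError("empty selector")
    for term in (t.strip() for t in expr.split(" and ")):
        parts = term.split(None, 1)
        key = parts[0]
        if len(parts) == 1:
            mask &= _class_mask(s, key)
            continue
        values = [v.strip() for v in parts[1].split(",")]
        if key == "chain":
            mask &= np.isin(s.chain.astype(str), values)
        elif key == "resi":
            sub = np.zeros(len(s), dtype=bool)
            for v in values:
                if "-" in v[1:]:
                    lo, hi = v.rsplit("-", 1) if not v.startswith("-") else (v, v)
                    lo, hi = int(lo), int(hi)
                else:
                    lo = hi = int(v)
                sub |= (s.residue_number >= lo) & (s.residue_number <= hi)
            mask &= sub
        elif key == "resname":
            mask &= np.isin(s.residue_name.astype(str), [v.upper() for v in values])
        elif key == "name":
            mask &= np.isin(s.atom_name.astype(str), values)
        elif key == "element":
            mask &= np.isin(np.array([e.upper() for e in s.element]),
                            [v.upper() for v in values])
        else:
            raise ValueError(f"unknown selection term {term!r}")
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# symmetry expansion
# ---------------------------------------------------------------------------

def expand_symmetry(s: Structure, radius: float = 20.0,
                    seed_selection: np.ndarray | None = None) -> Structure:
    """Expand the asymmetric unit by space-group symmetry around a seed.

    All space-group operators combined with lattice translations are applied;
    a generated copy is kept when at least one of its atoms lies within
    ``radius`` Å of the seed selection (default: all atoms).  The identity
    copy is always retained, and copies are given fresh unique chain names.
    The default 20 Å radius reproduces the "symmetry mates within 20 Å"
    convention used when displaying crystal packing.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if s.cell is None or not s.space_group:
        raise ValueError(
            "structure lacks cell/space-group metadata; use a pre-expanded "
            "biological assembly instead")
    if seed_selection is None:
        seed_selection = np.arange(len(s))
    seed_selection = np.asarray(seed_selection, dtype=np.int64)
    if len(seed_selection) == 0:
        raise ValueError("empty seed selection")

    sg = gemmi.SpaceGroup(s.space_group)
    cell = gemmi.UnitCell(*s.cell)
    orth = np.array(cell.orth.mat.tolist(), dtype=float)
    frac = np.array(cell.frac.mat.tolist(), dtype=float)

    xyz = s.xyz
    fxyz = xyz @ frac.T
    seed_xyz = xyz[seed_selection]
    tree = cKDTree(seed_xyz)

    # lattice search range: enough cells to cover radius + structure extent
    span = xyz.max(axis=0) - xyz.min(axis=0)
    abc = np.array(s.cell[:3])
    nmax = np.ceil((radius + span.max()) / abc.min()).astype(int) + 1
    shifts = range(-nmax, nmax + 1)

    used_chain_names = set(s.chains)

    def fresh_names(k):
        names = []
        i = 0
        while len(names) < k:
            cand = _CHAIN_POOL[i % len(_CHAIN_POOL)] + (
                "" if i < len(_CHAIN_POOL) else str(i // len(_CHAIN_POOL)))
            i += 1
            if cand not in used_chain_names:
                used_chain_names.add(cand)
                names.append(cand)
        return names

    parts = [s.copy()]
    seen_positions = [np.round(xyz[0], 3).tobytes()]
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        base = fxyz @ rot.T + tran
        for na in shifts:
            for nb in shifts:
                for nc in shifts:
                    f2 = base + np.array([na, nb, nc], dtype=float)
                    x2 = f2 @ orth.T
                    key = np.round(x2[0], 3).tobytes()
                    if key in seen_positions:
                        continue
                    d, _ = tree.query(x2, k=1,
                                      distance_upper_bound=radius)
                    if not np.any(np.isfinite(d)):
                        continue
                    seen_positions.append(key)
                    copy = s.copy()
                    copy.xyz = x2
                    rename = dict(zip(copy.chains, fresh_names(len(copy.chains))))
                    copy.chain = np.array([rename[c] for c in copy.chain],
                                          dtype=object)
                    parts.append(copy)
    return Structure.concatenate(parts, cell=s.cell, space_group=s.space_group)


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Write frames in the plain-text fixture format.

    Format: for each frame a header line ``frame <time_ns>`` followed by one
    ``x y z`` line per atom (full double precision).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# wrapkit trajectory natoms={len(traj.topology)} "
                 f"nframes={len(traj)}\n")
        for t, frame in zip(traj.frame_times, traj.frames):
            fh.write(f"frame {float(t)!r}\n")
            for x, y, z in frame:
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")


def _read_text_frames(path) -> tuple[np.ndarray, np.ndarray]:
    times, frames, cur = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("frame"):
                if cur:
                    frames.append(cur)
                    cur = []
                times.append(float(line.split()[1]))
            else:
                cur.append([float(v) for v in line.split()])
    if cur:
        frames.append(cur)
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return np.array(frames, dtype=np.float64), np.array(times, dtype=np.float64)


def read_trajectory(topology: Structure, frames_path) -> Trajectory:
    """Read trajectory frames against a topology.

    Plain-text fixture files (see :func:`write_trajectory`) are read natively;
    XTC/TRR/DCD go through MDAnalysis.  Frame times default to a unit stride
    when the file carries none.
    """
    frames_path = Path(frames_path)
    suffix = frames_path.suffix.lower()
    if suffix in (".xtc", ".trr", ".dcd"):
        import MDAnalysis as mda

        u = mda.Universe.empty(len(topology), trajectory=True)
        u.load_new(str(frames_path))
        if u.trajectory.n_atoms != len(topology):
            raise ValueError(
                f"atom count mismatch: trajectory has {u.trajectory.n_atoms}, "
                f"topology has {len(topology)}")
        frames = np.array([ts.positions.copy() for ts in u.trajectory],
                          dtype=np.float64)
        times = np.array([ts.time for ts in u.trajectory], dtype=np.float64) / 1000.0
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            times = np.arange(len(frames), dtype=np.float64)
    else:
        frames, times = _read_text_frames(frames_path)
        if frames.shape[1] != len(topology):
            raise ValueError(
                f"atom count mismatch: trajectory has {frames.shape[1]}, "
                f"topology has {len(topology)}")
    return Trajectory(topology, frames, times)
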