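"""Seeded fixture generators with serialized ground truth.

These emulate the statistical structure the analysis assumes — a coarse
tetramer with named binding-site residues engaged or disengaged by known
heavy-atom pair placement, staircase-work pulling series, gel lanes from a
known log-linear migration model, and titration curves — so every analysis
stage is testable without any downloaded data.  Pseudo-atoms carry real PDB
atom names and elements so the production selection/contact code paths are
exercised unchanged.  None of this is force-field physics: the fixtures
validate statistics and geometry code, not biophysics.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy.spatial import cKDTree

from .assays import GENERULER_ULTRA_LOW_BP, LaneProfile
from .builder import DuplexSpec, build_bdna
from .structio import Structure, Trajectory
from .unwrap import PullingSeries

__all__ = [
    "ToySpec",
    "GroundTruth",
    "gen_toy_complex",
    "gen_smd_series",
    "gen_gel_lane",
    "gen_titration",
    "SITE_ANGLES",
]

# angular layout of the four binding sites around the toy tetramer (degrees);
# A-sites sit on the tetramerization interfaces, B-sites on the dimers
SITE_ANGLES = {"A-site 1": 0.0, "B-site 1": 90.0, "A-site 2": 180.0,
               "B-site 2": 270.0}
# monomer centers: dimer 1 = chains A (45°) + B (135°), dimer 2 = C (315°) +
# D (225°), so each chain sits between the two sites it contributes to
_MONOMER_ANGLES = {"A": 45.0, "B": 135.0, "C": 315.0, "D": 225.0}
_A_SITE_RESIDUES = {27: "THR", 29: "GLY", 54: "LYS", 56: "THR", 57: "THR",
                    59: "ARG"}
_B_SITE_RESIDUES = {13: "ALA", 14: "SER", 15: "LYS", 17: "LYS", 21: "LYS"}
_SITE_CHAINS = {"A-site 1": ("A", "C"), "A-site 2": ("B", "D"),
                "B-site 1": ("A", "B"), "B-site 2": ("C", "D")}


@dataclasses.dataclass(frozen=True)
class ToySpec:
    """Conditions of a toy complex ensemble.

    Defaults follow the study conditions: a 67-bp closed-arc duplex for the
    wrapping mode with all four sites engaged, or two straight 32-bp
    duplexes for the bridging mode with only the B-sites engaged.
    """

    mode: str = "wrapping"  # "wrapping" | "bridging"
    n_bp: int = 67
    engaged: tuple = ("A-site 1", "A-site 2", "B-site 1", "B-site 2")
    jitter: float = 0.3      # Å, Gaussian, per atom per frame
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("wrapping", "bridging"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        unknown = set(self.engaged) - set(SITE_ANGLES)
        if unknown:
            raise ValueError(f"unknown sites {sorted(unknown)}")
        if self.mode == "bridging" and set(self.engaged) == set(SITE_ANGLES):
            raise ValueError(
                "two separate straight segments cannot engage all four "
                "sites; drop the A-sites or use wrapping mode")

    @classmethod
    def bridging(cls, **kw) -> "ToySpec":
        kw.setdefault("mode", "bridging")
        kw.setdefault("n_bp", 32)
        kw.setdefault("engaged", ("B-site 1", "B-site 2"))
        return cls(**kw)


@dataclasses.dataclass
class GroundTruth:
    """What a generator planted, serializable alongside the fixture."""

    kind: str
    payload: dict

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))
        text = json.dumps({"kind": self.kind, "payload": self.payload},
                          default=default, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "GroundTruth":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            with open(text) as fh:
                text = fh.read()
        d = json.loads(text)
        return cls(d["kind"], d["payload"])


def _unit(deg: float) -> np.ndarray:
    a = np.radians(deg)
    return np.array([np.cos(a), np.sin(a), 0.0])


def _place_at_distance(direction: np.ndarray, z: float, tree: cKDTree,
                       target: float, r_max: float) -> np.ndarray:
    """Point along ``direction`` (at height z) whose distance to the tree
    is closest to ``target``."""
    radii = np.linspace(1.0, r_max, 400)
    pts = radii[:, None] * direction[None, :]
    pts[:, 2] = z
    d, _ = tree.query(pts, k=1)
    best = int(np.argmin(np.abs(d - target)))
    return pts[best]


def gen_toy_complex(spec: ToySpec) -> tuple[Trajectory, GroundTruth]:
    """Coarse tetramer + DNA ensemble with planted site engagement.

    Engaged sites receive heavy-atom pairs at 3.0–3.9 Å from the DNA,
    disengaged sites sit at ≥ 6 Å; Gaussian jitter of ``spec.jitter`` Å is
    applied per frame.  The wrapping mode lays the DNA on a closed arc, the
    bridging mode on two straight segments flanking the tetramer.
    """
    rng = np.random.default_rng(spec.seed)
    rise, twist = 3.4, 36.0

    seq = ("ATGCA" * (spec.n_bp // 5 + 1))[:spec.n_bp]
    if spec.mode == "wrapping":
        curvature = 2.0 * np.pi / (spec.n_bp * rise)
        duplex = build_bdna(DuplexSpec(seq, rise, twist, curvature),
                            chain_ids=("X", "Y"))
        # center the arc on the origin so the site angles line up
        radius = 1.0 / curvature
        duplex = duplex.with_xyz(duplex.xyz - np.array([radius, 0.0, 0.0]))
        dna_parts = [duplex]
    else:
        straight = DuplexSpec(seq, rise, twist, 0.0)
        half = straight.contour_length / 2.0
        y_axis_dist = 25.0
        segs = []
        for sign, chains in ((1.0, ("X", "Y")), (-1.0, ("W", "V"))):
            seg = build_bdna(straight, chain_ids=chains)
            # rotate axis z→x, place at y = ±25 Å
            rot = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
            seg = seg.with_xyz(seg.xyz @ rot.T +
                               np.array([-half, sign * y_axis_dist, 0.0]))
            segs.append(seg)
        dna_parts = segs

    dna = Structure.concatenate(dna_parts)
    tree = cKDTree(dna.xyz)

    chain, resnum, resname, aname, elem, xyz = [], [], [], [], [], []

    def add_atom(ch, num, rname, at, el, pos):
        chain.append(ch)
        resnum.append(num)
        resname.append(rname)
        aname.append(at)
        elem.append(el)
        xyz.append(np.asarray(pos, dtype=float))

    # monomer bodies: a few backbone pseudo-residues per chain so centroids,
    # principal axes and selections behave
    for ch, ang in _MONOMER_ANGLES.items():
        center = 10.0 * _unit(ang)
        for k, off in enumerate([(-1.5, 0, -1.0), (0, 0, 0), (1.5, 0, 1.0),
                                 (0, 1.5, -0.5)]):
            add_atom(ch, k + 1, "GLY", "CA", "C", center + np.array(off))
        # RD clamp: arginine guanidinium N and aspartate carboxylate O pair
        add_atom(ch, 55, "ARG", "NH1", "N", center + np.array([0.0, -1.5, 0.0]))
        add_atom(ch, 62, "ASP", "OD1", "O", center + np.array([0.0, -1.5, 3.2]))

    planted = []
    site_residues = {}
    for site, site_chains in _SITE_CHAINS.items():
        res_map = _A_SITE_RESIDUES if site.startswith("A") else _B_SITE_RESIDUES
        ang = SITE_ANGLES[site]
        engaged = site in spec.engaged
        j = 0
        for ch in site_chains:
            for num, rname in res_map.items():
                da = ang + (j - 2.5) * 2.0
                z = (j % 3 - 1) * 1.2
                if engaged:
                    target = 3.2 + 0.1 * (j % 6)  # within 3.0–3.9 Å
                else:
                    target = 8.0
                pos = _place_at_distance(_unit(da), z, tree, target, r_max=60.0)
                add_atom(ch, num, rname, "CA", "C", pos)
                site_residues.setdefault(site, []).append([ch, num])
                if engaged:
                    d, nearest = tree.query(pos, k=1)
                    planted.append({"site": site, "protein_atom": len(xyz) - 1,
                                    "dna_atom": int(nearest),
                                    "distance": float(d)})
                j += 1

    protein = Structure(chain, resnum, resname, aname, elem, np.array(xyz))
    topology = Structure.concatenate([protein] + dna_parts)
    # ground-truth pair indices refer to the concatenated topology
    n_prot = len(protein)
    for p in planted:
        p["dna_atom"] += n_prot

    base = topology.xyz
    frames = base[None, :, :] + rng.normal(
        0.0, spec.jitter, size=(spec.n_frames, len(topology), 3))
    traj = Trajectory(topology, frames, np.arange(spec.n_frames, dtype=float))
    traj.selection_masks["protein"] = np.arange(n_prot)
    traj.selection_masks["dna"] = np.arange(n_prot, len(topology))

    gt = GroundTruth("toy_complex", {
        "mode": spec.mode,
        "n_bp": spec.n_bp,
        "engaged": {s: (s in spec.engaged) for s in SITE_ANGLES},
        "planted_pairs": planted,
        "site_residues": site_residues,
        "jitter": spec.jitter,
        "seed": spec.seed,
        "n_frames": spec.n_frames,
    })
    return traj, gt


def gen_smd_series(barriers: list[tuple[float, float]] | None = None,
                   sites: list[str] | None = None,
                   noise: float = 0.0, seed: int = 0,
                   n_samples: int = 2000, xi_max: float | None = None,
                   bump_width: float = 2.0
                   ) -> tuple[PullingSeries, dict[str, np.ndarray], GroundTruth]:
    """Pulling series whose work integral is a staircase of planted barriers.

    ``barriers`` is a list of (ξ_position Å, height kJ/mol); the default is
    the two-barrier unwrapping scenario (≈500 kJ/mol at B-site 2 followed by
    ≈400 kJ/mol at A-site 2).  The force profile is a sum of Gaussian bumps
    whose integrals equal the planted heights; matching per-site contact
    series drop sigmoidally at each barrier so that attribution and release
    order are testable.
    """
    if barriers is None:
        barriers = [(15.0, 500.0), (40.0, 400.0)]
        sites = sites or ["B-site 2", "A-site 2"]
    if sites is None:
        sites = [f"site-{i}" for i in range(len(barriers))]
    if len(sites) != len(barriers):
        raise ValueError("sites and barriers lengths differ")
    rng = np.random.default_rng(seed)
    if xi_max is None:
        xi_max = max(x for x, _ in barriers) + 10.0 * bump_width
    xi = np.linspace(0.0, xi_max, n_samples)
    force = np.zeros_like(xi)
    for pos, height in barriers:
        force += height / (bump_width * np.sqrt(2 * np.pi)) * \
            np.exp(-0.5 * ((xi - pos) / bump_width) ** 2)
    if noise > 0:
        force = force + rng.normal(0.0, noise, size=force.shape)
    series = PullingSeries(time=xi / 10.0, xi=xi, force=force)
    contact = {}
    for name, (pos, _) in zip(sites, barriers):
        clean = 20.0 / (1.0 + np.exp((xi - pos) / bump_width))
        if noise > 0:
            clean = np.clip(clean + rng.normal(0.0, 0.5, size=xi.shape), 0, None)
        contact[name] = clean
    gt = GroundTruth("smd_series", {
        "barriers": [{"xi": float(x), "height": float(h), "site": s}
                     for (x, h), s in zip(barriers, sites)],
        "release_order": [s for _, s in sorted(
            zip([x for x, _ in barriers], sites))],
        "noise": noise, "seed": seed,
    })
    return series, contact, gt


def gen_gel_lane(fragment_sizes_bp: list[float],
                 marker_sizes_bp=GENERULER_ULTRA_LOW_BP,
                 intercept: float = 900.0, slope: float = 320.0,
                 band_width: float = 8.0, noise: float = 0.0, seed: int = 0,
                 n_pixels: int = 1000
                 ) -> tuple[LaneProfile, LaneProfile, GroundTruth]:
    """Sample and marker lanes from a log-linear migration model.

    Migration (pixels) = intercept − slope·log10(size bp); bands are
    Gaussian with the stated width.  Returns (sample_lane, marker_lane,
    ground truth).
    """
    rng = np.random.default_rng(seed)
    positions = np.arange(n_pixels, dtype=float)

    def lane(sizes):
        y = np.zeros_like(positions)
        for s in sizes:
            center = intercept - slope * np.log10(s)
            y += 1000.0 * np.exp(-0.5 * ((positions - center) / band_width) ** 2)
        if noise > 0:
            y = np.clip(y + rng.normal(0.0, noise, size=y.shape), 0.0, None)
        return LaneProfile(positions.copy(), y)

    sample = lane(fragment_sizes_bp)
    marker = lane(marker_sizes_bp)
    gt = GroundTruth("gel_lane", {
        "fragment_sizes_bp": list(map(float, fragment_sizes_bp)),
        "marker_sizes_bp": list(map(float, marker_sizes_bp)),
        "intercept": intercept, "slope": slope,
        "band_width": band_width, "noise": noise, "seed": seed,
    })
    return sample, marker, gt


def gen_titration(model: str = "logistic", params: dict | None = None,
                  noise: float = 0.0, seed: int = 0, n_points: int = 12
                  ) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Synthetic titration table (concentrations, response).

    ``model="logistic"`` emulates a TPM compaction curve (defaults: upper
    plateau 140 nm, lower plateau 80 nm, midpoint 1500 nM, slope 2 — the
    saturation regime observed around 6000 nM);  ``model="isotherm"``
    emulates a low-micromolar 1:1 binding curve (Kd 2 µM in nM units).
    """
    rng = np.random.default_rng(seed)
    if model == "logistic":
        p = {"rms0": 140.0, "rms_min": 80.0, "c_half": 1500.0, "k": 2.0}
        p.update(params or {})
        conc = np.concatenate([[0.0], np.geomspace(30.0, 30000.0, n_points - 1)])
        with np.errstate(divide="ignore"):
            ratio = np.where(conc > 0, (conc / p["c_half"]) ** p["k"], 0.0)
        resp = p["rms_min"] + (p["rms0"] - p["rms_min"]) / (1.0 + ratio)
    elif model == "isotherm":
        p = {"kd": 2000.0, "amplitude": 1.0, "baseline": 0.0, "hill": 1.0}
        p.update(params or {})
        conc = np.geomspace(10.0, 200000.0, n_points)
        fb = conc ** p["hill"] / (p["kd"] ** p["hill"] + conc ** p["hill"])
        resp = p["baseline"] + p["amplitude"] * fb
    else:
        raise ValueError(f"unknown titration model {model!r}")
    if noise > 0:
        resp = resp + rng.normal(0.0, noise, size=resp.shape)
    gt = GroundTruth("titration", {"model": model, "params": p,
                                   "noise": noise, "seed": seed})
    return conc, resp, gt
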