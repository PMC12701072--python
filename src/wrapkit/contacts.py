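"""Protein–DNA contact analytics over trajectories.

A binding contact is any protein/DNA heavy-atom pair within a cutoff
(4.0 Å by default, compared inclusively).  Contacts are counted per frame as
atom pairs — not residue pairs — and decomposed by named binding site, by
residue, and by chemical moiety (DNA phosphate/sugar/base × protein
backbone/sidechain).  The binding fluctuation of a series is its per-frame
deviation from the trajectory mean, optionally smoothed with a centered
moving average.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import (BACKBONE_ATOMS, PHOSPHATE_ATOMS, SUGAR_ATOMS,
                       Structure, Trajectory, select_atoms)

__all__ = [
    "ContactParams",
    "BindingSite",
    "ContactSeries",
    "SmoothingParams",
    "HBondCriteria",
    "define_canonical_sites",
    "count_contacts",
    "contact_series",
    "binding_fluctuation",
    "smooth",
    "classify_contact_moieties",
    "hbond_occupancy",
    "salt_bridge_occupancy",
]

# motif residues of the four canonical DNA-binding sites of an FtF histone
# tetramer: the beta-bridge loops (l1/l2), the paired-end-of-helices motif at
# the alpha-1 N-termini, and their flanking basic residues
BETA_BRIDGE_RESIDUES = (27, 29, 56, 57)       # T27, G29, T56, T57
PAIRED_END_RESIDUES = (13, 14, 15)            # A13, S14, K15
FLANKING_A_RESIDUES = (54, 59)                # K54, R59 (loop l2)
FLANKING_B_RESIDUES = (17, 21)                # K17, K21 (helix alpha-1)


@dataclasses.dataclass(frozen=True)
class ContactParams:
    cutoff: float = 4.0
    heavy_only: bool = True

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclasses.dataclass(frozen=True)
class BindingSite:
    name: str
    residues: frozenset  # of (chain, residue_number)

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"binding site {self.name!r} has no residues")

    def atom_indices(self, s: Structure, heavy_only: bool = True) -> np.ndarray:
        keys = {(c, int(r)) for c, r in self.residues}
        mask = np.array([(s.chain[i], int(s.residue_number[i])) in keys
                         for i in range(len(s))], dtype=bool)
        if heavy_only:
            mask &= s.is_heavy_mask()
        return np.flatnonzero(mask)


@dataclasses.dataclass(frozen=True)
class SmoothingParams:
    window: int = 100
    kind: str = "moving-average"

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.kind != "moving-average":
            raise ValueError(f"unknown smoothing kind {self.kind!r}")


@dataclasses.dataclass(frozen=True)
class HBondCriteria:
    """Hydrogen-bond / salt-bridge geometry.

    Defaults follow common MD practice: donor–acceptor distance ≤ 3.5 Å with
    a D–H···A angle ≥ 120° when hydrogens are available, charged-group N/O
    distance ≤ 4.0 Å for salt bridges, and 50% occupancy for persistence.
    """

    d_da: float = 3.5
    angle_min: float = 120.0
    salt_bridge_cutoff: float = 4.0
    persistence: float = 0.5

    def __post_init__(self):
        if self.d_da <= 0:
            raise ValueError("d_da must be positive")
        if not 0 < self.angle_min < 180:
            raise ValueError("angle_min must lie in (0, 180)")


def define_canonical_sites(tetramer: Structure,
                           residue_lists: dict[str, list] | None = None
                           ) -> dict[str, BindingSite]:
    """Map the four canonical binding sites onto a 4-chain tetramer.

    The default layout places the two A-sites on the tetramerization
    interfaces (each combining the β-bridge loop residues of two diagonal
    monomers plus the flanking l2 basics) and the two B-sites on the dimers
    (the paired-end-of-helices motif plus the flanking α1 lysines).

    ``residue_lists`` may override any site with explicit
    ``{site_name: [(chain, resnum), ...]}`` entries.
    """
    chains = tetramer.chains
    if residue_lists is None:
        if len(chains) < 4:
            raise ValueError("tetramer must have at least 4 chains")
        a, b, c, d = chains[:4]
        a_res = BETA_BRIDGE_RESIDUES + FLANKING_A_RESIDUES
        b_res = PAIRED_END_RESIDUES + FLANKING_B_RESIDUES
        residue_lists = {
            "A-site 1": [(ch, r) for ch in (a, c) for r in a_res],
            "A-site 2": [(ch, r) for ch in (b, d) for r in a_res],
            "B-site 1": [(ch, r) for ch in (a, b) for r in b_res],
            "B-site 2": [(ch, r) for ch in (c, d) for r in b_res],
        }
    present = set(zip(tetramer.chain, (int(r) for r in tetramer.residue_number)))
    sites = {}
    for name, pairs in residue_lists.items():
        for ch, r in pairs:
            if (ch, int(r)) not in present:
                raise ValueError(f"residue {ch}:{r} (site {name!r}) absent "
                                 "from structure")
        sites[name] = BindingSite(name, frozenset((ch, int(r)) for ch, r in pairs))
    canonical = [s for n, s in sites.items() if n.endswith(("1", "2"))]
    seen = set()
    for s in canonical:
        if s.residues & seen:
            raise ValueError("canonical sites must be pairwise disjoint")
        seen |= s.residues
    return sites


def count_contacts(frame: np.ndarray, set_a: np.ndarray, set_b: np.ndarray,
                   params: ContactParams = ContactParams()
                   ) -> tuple[int, list[tuple[int, int]]]:
    """Count unordered (a, b) atom pairs within the cutoff (inclusive).

    ``set_a`` and ``set_b`` are disjoint global atom index arrays into
    ``frame``; the returned pair list is sorted and uses global indices.
    """
    set_a = np.asarray(set_a, dtype=np.int64)
    set_b = np.asarray(set_b, dtype=np.int64)
    if np.intersect1d(set_a, set_b).size:
        raise ValueError("atom sets overlap; self-contacts are undefined")
    if len(set_a) == 0 or len(set_b) == 0:
        return 0, []
    frame = np.asarray(frame, dtype=float)
    tree_b = cKDTree(frame[set_b])
    pairs = []
    neighbors = tree_b.query_ball_point(frame[set_a], r=params.cutoff)
    for ia, nbrs in zip(set_a, neighbors):
        for jb in nbrs:
            pairs.append((int(ia), int(set_b[jb])))
    pairs.sort()
    return len(pairs), pairs


@dataclasses.dataclass
class ContactSeries:
    """Per-frame protein–DNA contact counts with site/residue decomposition."""

    total: np.ndarray                      # (F,) int
    per_site: dict[str, np.ndarray]        # site name -> (F,) int
    per_residue_mean: pd.Series            # (chain, resnum) -> mean count
    params: ContactParams

    @property
    def mean(self) -> float:
        return float(self.total.mean())

    @property
    def sd(self) -> float:
        return float(self.total.std())

    @property
    def fluctuation(self) -> np.ndarray:
        return binding_fluctuation(self.total)

    def site_summary(self) -> pd.DataFrame:
        rows = [(name, ser.mean(), ser.std())
                for name, ser in self.per_site.items()]
        return pd.DataFrame(rows, columns=["site", "mean", "sd"]).set_index("site")

    def to_frame(self) -> pd.DataFrame:
        data = {"total": self.total}
        data.update(self.per_site)
        return pd.DataFrame(data)


def contact_series(traj: Trajectory, sites: dict[str, BindingSite],
                   dna: np.ndarray, params: ContactParams = ContactParams()
                   ) -> ContactSeries:
    """Contact counts per frame: protein↔DNA overall, per site, per residue."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    top = traj.topology
    dna = np.asarray(dna, dtype=np.int64)
    prot = select_atoms(top, "protein and heavy" if params.heavy_only
                        else "protein")
    if params.heavy_only:
        heavy = top.is_heavy_mask()
        dna = dna[heavy[dna]]
    site_idx = {name: site.atom_indices(top, params.heavy_only)
                for name, site in sites.items()}
    res_keys = [(top.chain[i], int(top.residue_number[i])) for i in prot]
    res_of_atom = dict(zip(prot.tolist(), res_keys))

    total = np.zeros(len(traj), dtype=np.int64)
    per_site = {name: np.zeros(len(traj), dtype=np.int64) for name in sites}
    res_counts: dict[tuple, float] = {}
    for f, frame in enumerate(traj.frames):
        n, pairs = count_contacts(frame, prot, dna, params)
        total[f] = n
        for ia, _ in pairs:
            key = res_of_atom[ia]
            res_counts[key] = res_counts.get(key, 0.0) + 1.0
        tree_d = cKDTree(frame[dna])
        for name, idx in site_idx.items():
            if len(idx) == 0:
                continue
            nbrs = tree_d.query_ball_point(frame[idx], r=params.cutoff)
            per_site[name][f] = sum(len(x) for x in nbrs)
    per_res = pd.Series({k: v / len(traj) for k, v in res_counts.items()},
                        dtype=float).sort_index()
    return ContactSeries(total, per_site, per_res, params)


def binding_fluctuation(series: np.ndarray) -> np.ndarray:
    """Deviation of each frame's count from the mean across all frames."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    return series - series.mean()


def smooth(series: np.ndarray, params: SmoothingParams = SmoothingParams()
           ) -> np.ndarray:
    """Centered moving average; edges use truncated windows.

    Output length equals input length.  An even window is widened by one to
    stay centered.
    """
    series = np.asarray(series, dtype=float)
    w = params.window
    if w % 2 == 0:
        w += 1
    if w > series.size:
        raise ValueError(f"window {params.window} exceeds series length "
                         f"{series.size}")
    half = w // 2
    csum = np.concatenate([[0.0], np.cumsum(series)])
    n = series.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def classify_contact_moieties(pairs: list[tuple[int, int]], topology: Structure
                              ) -> pd.DataFrame:
    """3×2 contingency table of contacts: DNA moiety × protein moiety.

    Rows: phosphate / sugar / base; columns: backbone / sidechain.  Pair
    order is (protein atom, DNA atom) as returned by the contact counters.
    """
    rows = ("phosphate", "sugar", "base")
    cols = ("backbone", "sidechain")
    table = pd.DataFrame(0, index=rows, columns=cols)
    dna_mask = {}
    for ip, id_ in pairs:
        aname_p = topology.atom_name[ip]
        aname_d = topology.atom_name[id_]
        if topology.residue_name[id_] not in ("DA", "DC", "DG", "DT"):
            raise ValueError(f"atom {id_} ({aname_d}) is not a DNA atom")
        if aname_d in PHOSPHATE_ATOMS:
            row = "phosphate"
        elif aname_d in SUGAR_ATOMS:
            row = "sugar"
        else:
            row = "base"
        col = "backbone" if aname_p in BACKBONE_ATOMS else "sidechain"
        table.loc[row, col] += 1
    return table


def _occupancy_frame_pairs(traj, donors, acceptors, cutoff):
    donors = np.asarray(donors, dtype=np.int64)
    acceptors = np.asarray(acceptors, dtype=np.int64)
    occ: dict[tuple[int, int], int] = {}
    for frame in traj.frames:
        tree = cKDTree(frame[acceptors])
        nbrs = tree.query_ball_point(frame[donors], r=cutoff)
        for di, lst in zip(donors, nbrs):
            for aj in lst:
                occ[(int(di), int(acceptors[aj]))] = \
                    occ.get((int(di), int(acceptors[aj])), 0) + 1
    return occ


def hbond_occupancy(traj: Trajectory, donors: np.ndarray, acceptors: np.ndarray,
                    criteria: HBondCriteria = HBondCriteria(),
                    hydrogens: dict[int, np.ndarray] | None = None
                    ) -> tuple[pd.Series, list[tuple[int, int]]]:
    """Per donor–acceptor pair occupancy fraction and the persistent subset.

    Without hydrogens the test is distance-only (donor–acceptor ≤ d_DA);
    with ``hydrogens`` mapping donor index → hydrogen indices, frames must
    additionally satisfy the D–H···A angle criterion.
    """
    donors = np.asarray(donors, dtype=np.int64)
    acceptors = np.asarray(acceptors, dtype=np.int64)
    if len(donors) == 0 or len(acceptors) == 0:
        warnings.warn("no donors or acceptors selected; empty occupancy")
        return pd.Series(dtype=float), []
    if hydrogens is None:
        occ = _occupancy_frame_pairs(traj, donors, acceptors, criteria.d_da)
    else:
        occ = {}
        for frame in traj.frames:
            tree = cKDTree(frame[acceptors])
            nbrs = tree.query_ball_point(frame[donors], r=criteria.d_da)
            for di, lst in zip(donors, nbrs):
                hyd = hydrogens.get(int(di), ())
                for aj in lst:
                    ai = int(acceptors[aj])
                    ok = False
                    if len(hyd) == 0:
                        ok = True  # no hydrogen on this donor: distance-only
                    for hi in hyd:
                        v1 = frame[int(di)] - frame[int(hi)]
                        v2 = frame[ai] - frame[int(hi)]
                        cosang = v1 @ v2 / (np.linalg.norm(v1) *
                                            np.linalg.norm(v2) + 1e-30)
                        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                        if ang >= criteria.angle_min:
                            ok = True
                            break
                    if ok:
                        occ[(int(di), ai)] = occ.get((int(di), ai), 0) + 1
    frac = pd.Series({k: v / len(traj) for k, v in occ.items()},
                     dtype=float).sort_index()
    persistent = [k for k, v in frac.items() if v >= criteria.persistence]
    return frac, persistent


def salt_bridge_occupancy(traj: Trajectory, basic: np.ndarray,
                          acidic: np.ndarray,
                          criteria: HBondCriteria = HBondCriteria()
                          ) -> tuple[pd.Series, list[tuple[int, int]]]:
    """Charged-group N/O distance test (≤ salt_bridge_cutoff), no angles."""
    basic = np.asarray(basic, dtype=np.int64)
    acidic = np.asarray(acidic, dtype=np.int64)
    if len(basic) == 0 or len(acidic) == 0:
        warnings.warn("no charged-group atoms selected; empty occupancy")
        return pd.Series(dtype=float), []
    occ = _occupancy_frame_pairs(traj, basic, acidic,
                                 criteria.salt_bridge_cutoff)
    frac = pd.Series({k: v / len(traj) for k, v in occ.items()},
                     dtype=float).sort_index()
    persistent = [k for k, v in frac.items() if v >= criteria.persistence]
    return frac, persistent
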