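"""Steered-unwrapping post-processing.

The applied pulling force integrated over the pulling coordinate gives the
cumulative work profile W(ξ); rises of W across contiguous force-bearing
stretches are reported as unwrapping barriers and attributed to the binding
site whose contact count drops most across the stretch.  A cutoff-based
per-residue nonbonded energy (Coulomb + Lennard-Jones, mean over frames)
decomposes the total protein–DNA interaction energy into residue
contributions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .contacts import SmoothingParams, smooth
from .structio import Structure

__all__ = [
    "PullingSeries",
    "Barrier",
    "WorkProfile",
    "ResidueEnergyTable",
    "work_profile",
    "detect_barriers",
    "release_order",
    "residue_energy_decomposition",
    "read_xvg",
]

COULOMB_KJ_A = 1389.35458  # kJ/mol · Å · e⁻², Coulomb constant × N_A


@dataclasses.dataclass
class PullingSeries:
    """Time series of pulling coordinate and applied force.

    time : ns; xi : pulling coordinate, Å; force : kJ/mol/Å.
    ``xi`` must be monotone non-decreasing (smooth first if noisy).
    """

    time: np.ndarray
    xi: np.ndarray
    force: np.ndarray
    xi_unit: str = "A"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (self.time.shape == self.xi.shape == self.force.shape):
            raise ValueError("time/xi/force must be equal-length")
        if self.time.size < 2:
            raise ValueError("need at least 2 samples")
        if np.any(np.diff(self.xi) < -1e-9):
            raise ValueError("pulling coordinate must be monotone "
                             "non-decreasing (smooth it first)")


@dataclasses.dataclass(frozen=True)
class Barrier:
    xi_start: float
    xi_peak: float
    height: float  # kJ/mol
    site: str | None = None


@dataclasses.dataclass
class WorkProfile:
    xi: np.ndarray
    work: np.ndarray  # kJ/mol, cumulative, W(xi[0]) = 0
    barriers: list[Barrier] = dataclasses.field(default_factory=list)


def work_profile(p: PullingSeries) -> WorkProfile:
    """Cumulative work by trapezoidal integration of force over ξ."""
    w = np.concatenate([[0.0], np.cumsum(
        0.5 * (p.force[1:] + p.force[:-1]) * np.diff(p.xi))])
    return WorkProfile(p.xi.copy(), w)


def detect_barriers(profile: WorkProfile, min_height: float = 0.0,
                    site_contact_series: dict[str, np.ndarray] | None = None,
                    smoothing: SmoothingParams | None = None,
                    force_floor_frac: float = 0.05) -> list[Barrier]:
    """Find work barriers as rises of W over contiguous force-bearing stretches.

    The local slope dW/dξ (the force) is smoothed, then stretches where it
    exceeds ``force_floor_frac`` of its maximum are treated as single
    barriers; the rise of W across each stretch is its height, and only
    heights ≥ ``min_height`` are kept.  When per-site contact series (sampled
    on the same ξ grid) are supplied, each barrier is attributed to the site
    whose contact count drops most across its ξ-interval.
    """
    xi, w = profile.xi, profile.work
    dxi = np.gradient(xi)
    dxi[dxi == 0] = np.finfo(float).eps
    slope = np.gradient(w) / dxi
    if smoothing is None:
        smoothing = SmoothingParams(window=max(1, min(11, len(w))))
    win = min(smoothing.window, len(w))
    slope_s = smooth(slope, SmoothingParams(window=win))
    smax = slope_s.max()
    if smax <= 0:
        profile.barriers = []
        return []
    active = slope_s > force_floor_frac * smax
    # contiguous force-bearing stretches
    stretches = []
    i = 0
    n = len(active)
    while i < n:
        if not active[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and active[j + 1]:
            j += 1
        stretches.append((i, j))
        i = j + 1
    barriers: list[Barrier] = []
    for k, (i, j) in enumerate(stretches):
        # measure plateau-to-plateau so truncated force tails are not lost:
        # from the midpoint of the preceding quiet gap to that of the next
        prev_end = stretches[k - 1][1] if k > 0 else None
        next_start = stretches[k + 1][0] if k + 1 < len(stretches) else None
        lo = 0 if prev_end is None else (prev_end + i) // 2
        hi = n - 1 if next_start is None else (j + next_start) // 2
        height = w[hi] - w[lo]
        if height < min_height or height <= 0:
            continue
        peak = i + int(np.argmax(slope_s[i:j + 1]))
        site = None
        if site_contact_series:
            drops = {}
            for name, series in site_contact_series.items():
                series = np.asarray(series, dtype=float)
                drops[name] = series[lo] - series[hi]
            site = max(drops, key=drops.get)
        barriers.append(Barrier(float(xi[i]), float(xi[peak]),
                                float(height), site))
    profile.barriers = barriers
    return barriers


def release_order(xi: np.ndarray,
                  site_contact_series: dict[str, np.ndarray],
                  threshold: float = 0.25,
                  dwell: int = 5,
                  smoothing: SmoothingParams | None = None,
                  baseline_frames: int = 10
                  ) -> list[tuple[str, float]]:
    """Order sites by the ξ at which their contacts drop away for good.

    A site is released at the first ξ where its smoothed contact count falls
    below ``threshold`` × (its initial mean over ``baseline_frames``) and
    stays below for ``dwell`` consecutive samples.  Sites that never engage
    (initial mean ≈ 0) are excluded.
    """
    xi = np.asarray(xi, dtype=float)
    out = []
    for name, series in site_contact_series.items():
        series = np.asarray(series, dtype=float)
        if series.shape != xi.shape:
            raise ValueError(f"series {name!r} length mismatch with xi")
        if smoothing is not None:
            series = smooth(series, SmoothingParams(
                window=min(smoothing.window, len(series))))
        base = series[:max(1, min(baseline_frames, len(series)))].mean()
        if base <= 0:
            continue
        level = threshold * base
        below = series < level
        release_xi = None
        n = len(below)
        for i in range(n):
            if below[i] and np.all(below[i:min(i + dwell, n)]):
                release_xi = float(xi[i])
                break
        if release_xi is not None:
            out.append((name, release_xi))
    out.sort(key=lambda t: t[1])
    return out


@dataclasses.dataclass
class ResidueEnergyTable:
    """Per-residue mean interaction energies and magnitude fractions."""

    energies: pd.Series   # (chain, resnum) -> mean energy, kJ/mol
    fractions: pd.Series  # |E_i| / Σ|E_j| over attractive residues
    total: float          # Σ E_i, kJ/mol

    def top_fraction(self, k: int) -> float:
        """Summed fraction of the k largest attractive contributors."""
        return float(self.fractions.sort_values(ascending=False).head(k).sum())


def residue_energy_decomposition(frames: np.ndarray,
                                 topology: Structure,
                                 protein_idx: np.ndarray,
                                 dna_idx: np.ndarray,
                                 charges: np.ndarray,
                                 lj_sigma: np.ndarray | None = None,
                                 lj_epsilon: np.ndarray | None = None,
                                 cutoff: float = 12.0,
                                 dielectric: float = 1.0
                                 ) -> ResidueEnergyTable:
    """Cutoff-based nonbonded protein–DNA energy per protein residue.

    E_i = mean over frames of Σ over (residue-i atom, DNA atom) pairs within
    ``cutoff`` of  k_e q_a q_b / (ε_r r)  +  4 ε_ab [(σ_ab/r)¹² − (σ_ab/r)⁶],
    with Lorentz–Berthelot combination.  ``charges`` (e), ``lj_sigma`` (Å)
    and ``lj_epsilon`` (kJ/mol) are per-atom arrays over the full topology;
    omitted LJ parameters mean a Coulomb-only decomposition.  Fractions are
    reported on the magnitudes of the attractive (negative-energy) residues.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    protein_idx = np.asarray(protein_idx, dtype=np.int64)
    dna_idx = np.asarray(dna_idx, dtype=np.int64)
    charges = np.asarray(charges, dtype=float)
    if charges.shape[0] != len(topology):
        raise ValueError("charges must cover every atom of the topology; "
                         f"got {charges.shape[0]} for {len(topology)} atoms")
    use_lj = lj_sigma is not None and lj_epsilon is not None
    if use_lj:
        lj_sigma = np.asarray(lj_sigma, dtype=float)
        lj_epsilon = np.asarray(lj_epsilon, dtype=float)
        if lj_sigma.shape[0] != len(topology) or lj_epsilon.shape[0] != len(topology):
            raise ValueError("LJ parameter arrays must cover every atom")

    res_keys = np.array([f"{topology.chain[i]}:{int(topology.residue_number[i])}"
                         for i in protein_idx])
    acc: dict[str, float] = {k: 0.0 for k in dict.fromkeys(res_keys)}
    for frame in frames:
        tree = cKDTree(frame[dna_idx])
        nbrs = tree.query_ball_point(frame[protein_idx], r=cutoff)
        for a_local, lst in enumerate(nbrs):
            if not lst:
                continue
            ia = protein_idx[a_local]
            jb = dna_idx[np.asarray(lst, dtype=np.int64)]
            r = np.linalg.norm(frame[jb] - frame[ia], axis=1)
            e = COULOMB_KJ_A * charges[ia] * charges[jb] / (dielectric * r)
            if use_lj:
                sig = 0.5 * (lj_sigma[ia] + lj_sigma[jb])
                eps = np.sqrt(lj_epsilon[ia] * lj_epsilon[jb])
                sr6 = (sig / r) ** 6
                e = e + 4.0 * eps * (sr6 ** 2 - sr6)
            acc[res_keys[a_local]] += float(e.sum())
    nf = frames.shape[0]
    energies = pd.Series({k: v / nf for k, v in acc.items()}, dtype=float)
    attractive = energies[energies < 0]
    mag = attractive.abs()
    fractions = (mag / mag.sum()) if mag.sum() > 0 else mag
    return ResidueEnergyTable(energies, fractions, float(energies.sum()))


def read_xvg(path) -> np.ndarray:
    """Read a two/three-column whitespace or XVG-dialect text file."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line[0] in "#@&":
                continue
            rows.append([float(v) for v in line.split()])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.array(rows, dtype=float)
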