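"""Superposition, RMSD series, tetramer planarity, helix crossing angles,
wrap coverage, and 2-D free-energy landscapes.

All measures are purely geometric (heavy-atom coordinates in Å) and invariant
under global rigid-body motion.  The free-energy landscape follows the usual
Boltzmann inversion of a binned 2-D histogram, F = -kT ln(P / Pmax), with
empty bins left undefined (NaN) rather than infinite.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .structio import Structure, Trajectory, select_atoms

__all__ = [
    "SuperpositionResult",
    "FELGrid",
    "WrapReport",
    "superpose",
    "apply_transform",
    "rmsd",
    "dna_backbone_rmsd_series",
    "dihedral",
    "tetramer_planarity",
    "helix_crossing_angle",
    "wrap_coverage",
    "free_energy_landscape",
]

# Boltzmann constant times 310 K, kJ/mol
KT_310K = 0.0083144626 * 310.0


@dataclasses.dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # applied after rotation
    rmsd: float


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch) of ``mobile`` onto ``reference``.

    Atom correspondence is positional.  The optimal proper rotation is found
    via SVD of the covariance matrix with the usual determinant correction,
    so reflections are never returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    mc = (w[:, None] * mobile).sum(axis=0) / wsum
    rc = (w[:, None] * reference).sum(axis=0) / wsum
    a = mobile - mc
    b = reference - rc
    # collinearity check: rank of the centered mobile set
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise ValueError("points are collinear; rotation is underdetermined")
    h = (w[:, None] * a).T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ mc
    moved = a @ rot.T + rc
    val = float(np.sqrt((w * ((moved - reference) ** 2).sum(axis=1)).sum() / wsum))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=val)


def apply_transform(xyz: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return np.asarray(xyz, dtype=float) @ result.rotation.T + result.translation


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def dna_backbone_rmsd_series(traj: Trajectory, reference: np.ndarray | int,
                             fit_on: np.ndarray, measure_on: np.ndarray) -> np.ndarray:
    """Per-frame RMSD of a measured selection after fitting on another.

    Each frame is first superposed on the reference using ``fit_on`` (typically
    protein heavy atoms), then the RMSD is evaluated over ``measure_on``
    (typically the DNA phosphate + sugar backbone).  This separates DNA motion
    relative to the protein from overall tumbling.
    """
    fit_on = np.asarray(fit_on, dtype=np.int64)
    measure_on = np.asarray(measure_on, dtype=np.int64)
    if len(fit_on) == 0 or len(measure_on) == 0:
        raise ValueError("empty selections")
    if isinstance(reference, (int, np.integer)):
        ref = traj.frames[int(reference)]
    else:
        ref = np.asarray(reference, dtype=float)
    out = np.empty(len(traj))
    for i, frame in enumerate(traj.frames):
        sup = superpose(frame[fit_on], ref[fit_on])
        moved = apply_transform(frame[measure_on], sup)
        out[i] = rmsd(moved, ref[measure_on])
    return out


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) over four points."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        return float("nan")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def tetramer_planarity(traj: Trajectory, dimer1: tuple[str, str],
                       dimer2: tuple[str, str]) -> np.ndarray:
    """Per-frame inter-dimer dihedral (degrees) over monomer centroids.

    The four heavy-atom monomer centroids are taken in the order
    (dimer1[0], dimer1[1], dimer2[0], dimer2[1]); with the two monomers of
    dimer2 listed such that dimer2[0] faces dimer1[0] across the tetramer
    interface, a planar tetramer yields ±180° and out-of-plane bending moves
    the angle away from 180°.  Frames with collinear centroids return NaN.
    """
    top = traj.topology
    order = [dimer1[0], dimer1[1], dimer2[0], dimer2[1]]
    idx = []
    heavy = top.is_heavy_mask()
    for ch in order:
        sel = np.flatnonzero((top.chain == ch) & heavy)
        if len(sel) == 0:
            raise ValueError(f"chain {ch!r} not found or has no heavy atoms")
        idx.append(sel)
    out = np.empty(len(traj))
    for i, frame in enumerate(traj.frames):
        cents = [frame[s].mean(axis=0) for s in idx]
        out[i] = dihedral(*cents)
    return out


def _fit_axis(points: np.ndarray) -> np.ndarray:
    """Helix-axis direction from an ordered Cα trace, oriented first→last.

    Uses the cross products of successive radial bisector vectors
    u_i = (p_i − p_{i+1}) + (p_{i+2} − p_{i+1}), which are exactly
    perpendicular to the axis for an ideal helix, so their pairwise cross
    products all point along the axis regardless of sampling phase.  Falls
    back to the first principal component for very short traces.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    span = pts[-1] - pts[0]
    if n >= 5:
        u = pts[:-2] - 2 * pts[1:-1] + pts[2:]
        crosses = np.cross(u[:-1], u[1:])
        norms = np.linalg.norm(crosses, axis=1)
        good = norms > 1e-9
        if good.sum() >= 1:
            crosses = crosses[good] / norms[good, None]
            crosses[crosses @ span < 0] *= -1
            axis = crosses.mean(axis=0)
            nrm = np.linalg.norm(axis)
            if nrm > 1e-9:
                return axis / nrm
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    axis = vt[0]
    if axis @ span < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def helix_crossing_angle(s: Structure, helix_a: str, helix_b: str
                         ) -> tuple[float, bool]:
    """Crossing angle between two helix axes, folded to [0°, 90°].

    Each helix is given as a selector expression over Cα atoms (at least 6
    required); its axis is the first principal component of the Cα cloud,
    oriented N→C.  Returns ``(angle, antiparallel)`` where ``antiparallel``
    reports whether the raw inter-axis angle exceeded 90°.
    """
    angles = []
    axes = []
    for selector in (helix_a, helix_b):
        idx = select_atoms(s, selector)
        idx = idx[np.array([s.atom_name[i] == "CA" for i in idx], dtype=bool)]
        if len(idx) < 6:
            raise ValueError(f"selection {selector!r} has fewer than 6 Cα atoms")
        order = np.argsort(s.residue_number[idx], kind="stable")
        axes.append(_fit_axis(s.xyz[idx[order]]))
    cosang = float(np.clip(axes[0] @ axes[1], -1.0, 1.0))
    raw = np.degrees(np.arccos(cosang))
    antiparallel = raw > 90.0
    folded = min(raw, 180.0 - raw)
    return float(folded), bool(antiparallel)


@dataclasses.dataclass(frozen=True)
class WrapReport:
    bp_in_contact: int
    longest_run: int
    angular_coverage_deg: float
    wrapped_mask: np.ndarray


def wrap_coverage(frame: np.ndarray, bp_atom_groups: list[np.ndarray],
                  protein_idx: np.ndarray, cutoff: float = 4.0,
                  sector_deg: float = 10.0) -> WrapReport:
    """Count base pairs wrapped around the protein in one frame.

    A base pair counts as wrapped when any of its heavy atoms lies within
    ``cutoff`` Å of a protein heavy atom.  Angular coverage is measured by
    projecting wrapped base-pair centers onto the plane perpendicular to the
    protein principal axis and summing occupied angular sectors of width
    ``sector_deg``.
    """
    frame = np.asarray(frame, dtype=float)
    protein_idx = np.asarray(protein_idx, dtype=np.int64)
    if len(protein_idx) == 0:
        raise ValueError("empty protein selection")
    tree = cKDTree(frame[protein_idx])
    nbp = len(bp_atom_groups)
    wrapped = np.zeros(nbp, dtype=bool)
    centers = np.empty((nbp, 3))
    for i, grp in enumerate(bp_atom_groups):
        grp = np.asarray(grp, dtype=np.int64)
        pts = frame[grp]
        centers[i] = pts.mean(axis=0)
        d, _ = tree.query(pts, k=1, distance_upper_bound=cutoff)
        wrapped[i] = bool(np.any(np.isfinite(d)))
    # longest contiguous run of wrapped bp
    best = cur = 0
    for w in wrapped:
        cur = cur + 1 if w else 0
        best = max(best, cur)
    # angular coverage about the protein principal axis
    prot = frame[protein_idx]
    pc = prot.mean(axis=0)
    _, _, vt = np.linalg.svd(prot - pc)
    # the tetramer's symmetry axis is its *least* extended direction when the
    # DNA wraps in the tetramer plane; use the smallest principal component
    axis = vt[2]
    e1 = vt[0]
    e2 = np.cross(axis, e1)
    if np.any(wrapped):
        rel = centers[wrapped] - pc
        ang = np.degrees(np.arctan2(rel @ e2, rel @ e1)) % 360.0
        sectors = np.unique((ang // sector_deg).astype(int))
        coverage = float(len(sectors) * sector_deg)
    else:
        coverage = 0.0
    return WrapReport(int(wrapped.sum()), int(best), coverage, wrapped)


@dataclasses.dataclass
class FELGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray
    free_energy: np.ndarray  # kJ/mol, NaN where P = 0
    kT: float
    basin_location: tuple[float, float]
    basin_depth: float
    basin_area: float


def free_energy_landscape(cv1: np.ndarray, cv2: np.ndarray,
                          kT: float = KT_310K, bins: int = 40,
                          basin_threshold: float | None = None) -> FELGrid:
    """2-D free-energy landscape from two collective-variable series.

    F(x, y) = -kT ln(P / Pmax), so the global probability maximum sits at
    F = 0 and everything else is positive.  Empty bins are NaN.  The minimum
    basin is described by its location (bin centers at the maximum of P), its
    area at F < ``basin_threshold`` (default 1 kT), and its depth, defined as
    the median of the defined F values outside the basin.
    """
    cv1 = np.asarray(cv1, dtype=float)
    cv2 = np.asarray(cv2, dtype=float)
    if cv1.shape != cv2.shape or cv1.ndim != 1:
        raise ValueError("collective-variable series must be equal-length 1-D")
    if kT <= 0:
        raise ValueError("kT must be positive")
    if len(np.unique(cv1)) < 2 or len(np.unique(cv2)) < 2:
        raise ValueError("need at least 2 distinct samples on each axis")
    counts, xe, ye = np.histogram2d(cv1, cv2, bins=bins)
    p = counts / counts.sum()
    pmax = p.max()
    with np.errstate(divide="ignore"):
        f = np.where(p > 0, -kT * np.log(np.where(p > 0, p, 1.0) / pmax), np.nan)
    if basin_threshold is None:
        basin_threshold = kT
    imax = np.unravel_index(np.argmax(p), p.shape)
    xc = 0.5 * (xe[imax[0]] + xe[imax[0] + 1])
    yc = 0.5 * (ye[imax[1]] + ye[imax[1] + 1])
    cell_area = float((xe[1] - xe[0]) * (ye[1] - ye[0]))
    in_basin = np.nan_to_num(f, nan=np.inf) < basin_threshold
    area = float(in_basin.sum() * cell_area)
    outside = f[np.isfinite(f) & ~in_basin]
    depth = float(np.median(outside)) if outside.size else 0.0
    return FELGrid(xe, ye, p, f, float(kT), (float(xc), float(yc)),
                   depth, area)
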