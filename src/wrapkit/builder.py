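"""Idealized B-DNA duplex construction and wrapping/bridging model assembly.

Duplexes are built from rigid heavy-atom nucleotide templates placed along a
straight axis or a circular arc with a fixed rise and twist per base-pair
step.  Internal sugar/base geometry is simplified: downstream analyses use
heavy-atom positions and PDB atom-name classes only, never covalent
energetics, so the templates need to be topologically and sterically
sensible rather than force-field accurate.

Model assembly superposes crystal-derived protein–DNA interface templates
onto a target tetramer, reads off where the interfaces place DNA around the
protein, and lays a single continuous duplex along the fitted circular path
(wrapping) or one straight duplex per interface (bridging).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .geometry import apply_transform, superpose
from .structio import Structure, select_atoms

__all__ = [
    "DuplexSpec",
    "ComplexModel",
    "build_bdna",
    "duplex_bp_groups",
    "measure_rise_twist",
    "assemble_wrapping_model",
    "assemble_bridging_model",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Rigid nucleotide template, strand 1, in the local base-pair frame:
# origin on the helix axis, z along the axis, x the pseudo-dyad.
# Strand 2 is the complementary base mirrored through (x, -y, -z).
_SUGAR = {
    "C1'": (2.75, 5.30, 0.00),
    "C2'": (3.10, 5.90, 1.10),
    "C3'": (3.57, 6.71, 0.65),
    "C4'": (3.11, 6.38, -0.30),
    "O4'": (3.40, 5.40, -0.80),
}
_PHOSPHATE = {
    "O3'": (3.95, 7.30, 1.45),
    "C5'": (4.30, 6.40, -0.75),
    "O5'": (5.70, 5.60, -1.00),
    "P": (7.13, 4.81, -1.20),
    "OP1": (8.13, 5.41, -0.40),
    "OP2": (7.73, 4.31, -2.40),
}
_PURINE_RING = {
    "N9": (2.05, 4.05, 0.25),
    "C8": (1.05, 4.90, 0.30),
    "N7": (-0.15, 4.45, 0.30),
    "C5": (-0.28, 3.17, 0.20),
    "C4": (1.12, 3.10, 0.20),
    "N3": (1.69, 1.86, 0.20),
    "C2": (0.85, 0.76, 0.20),
    "N1": (-0.55, 0.83, 0.20),
    "C6": (-1.12, 2.07, 0.20),
}
_PYRIMIDINE_RING = {
    "N1": (2.05, 4.05, 0.25),
    "C2": (2.85, 2.93, 0.25),
    "N3": (2.29, 1.67, 0.25),
    "C4": (0.91, 1.53, 0.25),
    "C5": (0.11, 2.65, 0.25),
    "C6": (0.67, 3.91, 0.25),
}
_BASE_EXTRAS = {
    "A": {"N6": (-2.46, 2.14, 0.20)},
    "G": {"O6": (-2.46, 2.14, 0.20), "N2": (2.35, 0.15, 0.20)},
    "C": {"O2": (4.08, 3.06, 0.25), "N4": (0.36, 0.32, 0.25)},
    "T": {"O2": (4.08, 3.06, 0.25), "O4": (0.36, 0.32, 0.25),
          "C7": (-1.38, 2.50, 0.25)},
}


def _nucleotide_template(base: str) -> dict[str, np.ndarray]:
    ring = _PURINE_RING if base in "AG" else _PYRIMIDINE_RING
    tpl = {}
    for d in (_SUGAR, _PHOSPHATE, ring, _BASE_EXTRAS[base]):
        for name, xyz in d.items():
            tpl[name] = np.asarray(xyz, dtype=float)
    return tpl


_TEMPLATES = {b: _nucleotide_template(b) for b in "ACGT"}
_TERMINAL_DROP = ("P", "OP1", "OP2")  # 5'-OH terminus carries no phosphate


@dataclasses.dataclass(frozen=True)
class DuplexSpec:
    """Geometry of an idealized duplex.

    sequence : 5'→3' sequence of strand 1 (A/C/G/T).
    rise : Å per base-pair step (fibre B-DNA default 3.4).
    twist : degrees per base-pair step (10 bp/turn default 36.0; a
        10.5 bp/turn dialect is twist ≈ 34.29).
    curvature : 1/Å; 0 gives a straight axis, positive values bend the axis
        onto a circular arc of radius 1/curvature.
    """

    sequence: str
    rise: float = 3.4
    twist: float = 36.0
    curvature: float = 0.0

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence.upper()) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT symbols in sequence: {sorted(bad)}")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not 0 < self.twist < 60:
            raise ValueError("twist must lie in (0, 60) degrees")
        if self.curvature < 0:
            raise ValueError("curvature must be non-negative")
        contour = len(self.sequence) * self.rise
        if self.curvature * contour > 2 * np.pi + 1e-12:
            raise ValueError("curvature closes the arc on itself "
                             "(curvature × contour length > 2π)")

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def contour_length(self) -> float:
        """End-to-end axis length, (n_bp − 1) × rise."""
        return (self.n_bp - 1) * self.rise


def _rz(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _bp_placements(spec: DuplexSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-bp origin and orientation matrix in the canonical build frame.

    Straight axis: origins on the z axis, orientation Rz(i·twist).
    Arc: origins on a circle of radius 1/curvature in the x–y plane through
    the global origin (center at (R, 0, 0)), spaced by `rise` of arc length,
    with the twist applied about the local tangent.
    """
    n = spec.n_bp
    origins = np.empty((n, 3))
    rots = np.empty((n, 3, 3))
    if spec.curvature == 0.0:
        for i in range(n):
            origins[i] = (0.0, 0.0, i * spec.rise)
            rots[i] = _rz(i * spec.twist)
    else:
        radius = 1.0 / spec.curvature
        center = np.array([radius, 0.0, 0.0])
        for i in range(n):
            theta = i * spec.rise / radius
            origins[i] = center + radius * np.array(
                [-np.cos(theta), np.sin(theta), 0.0])
            xl = np.array([np.cos(theta), -np.sin(theta), 0.0])
            zl = np.array([np.sin(theta), np.cos(theta), 0.0])
            yl = np.cross(zl, xl)
            frame = np.column_stack([xl, yl, zl])
            rots[i] = frame @ _rz(i * spec.twist)
    return origins, rots


_MIRROR = np.diag([1.0, -1.0, -1.0])


def build_bdna(spec: DuplexSpec, origin=None, rotation=None,
               chain_ids: tuple[str, str] = ("D", "E")) -> Structure:
    """Build an idealized B-DNA duplex from a :class:`DuplexSpec`.

    Strand 1 carries ``spec.sequence`` 5'→3' (chain ``chain_ids[0]``,
    residues 1..n); strand 2 is its exact reverse complement, antiparallel
    (chain ``chain_ids[1]``, residues 1..n in its own 5'→3' order).
    5'-terminal nucleotides carry no phosphate group (5'-OH ends).
    ``origin``/``rotation`` rigidly place the finished duplex.
    """
    seq = spec.sequence.upper()
    n = spec.n_bp
    origins, rots = _bp_placements(spec)
    chain, resnum, resname, name, element, xyz = [], [], [], [], [], []

    def emit(ch, num, base, tpl_rot, tpl_origin, mirror, is_five_prime):
        tpl = _TEMPLATES[base]
        for aname, pos in tpl.items():
            if is_five_prime and aname in _TERMINAL_DROP:
                continue
            p = pos @ _MIRROR if mirror else pos
            chain.append(ch)
            resnum.append(num)
            resname.append("D" + base)
            name.append(aname)
            element.append(aname[0])
            xyz.append(tpl_origin + tpl_rot @ p)

    # strand 1: residue i+1 at bp i
    for i in range(n):
        emit(chain_ids[0], i + 1, seq[i], rots[i], origins[i], False, i == 0)
    # strand 2: residue j at bp (n - j), numbered 1..n along its own 5'→3'
    for j in range(1, n + 1):
        i = n - j
        base = COMPLEMENT[seq[i]]
        emit(chain_ids[1], j, base, rots[i], origins[i], True, j == 1)

    coords = np.array(xyz)
    if rotation is not None:
        coords = coords @ np.asarray(rotation, dtype=float).T
    if origin is not None:
        coords = coords + np.asarray(origin, dtype=float)
    return Structure(chain, resnum, resname, name, element, coords)


def duplex_bp_groups(s: Structure, chain_ids: tuple[str, str] = ("D", "E")
                     ) -> list[np.ndarray]:
    """Atom-index groups per base pair of a built duplex, 5'→3' of strand 1."""
    c1, c2 = chain_ids
    n = int(s.residue_number[s.chain == c1].max())
    groups = []
    for i in range(n):
        m = ((s.chain == c1) & (s.residue_number == i + 1)) | \
            ((s.chain == c2) & (s.residue_number == n - i))
        groups.append(np.flatnonzero(m))
    return groups


def _recover_bp_frames(s: Structure, chain_ids=("D", "E")):
    """Recover per-bp rigid frames by superposing the sugar template."""
    c1, c2 = chain_ids
    sugar_names = list(_SUGAR)
    tpl1 = np.array([_SUGAR[a] for a in sugar_names])
    tpl2 = tpl1 @ _MIRROR
    tpl = np.vstack([tpl1, tpl2])
    n = int(s.residue_number[s.chain == c1].max())
    origins, rotations = [], []
    for i in range(n):
        pts = []
        for ch, num in ((c1, i + 1), (c2, n - i)):
            m = (s.chain == ch) & (s.residue_number == num)
            lookup = {s.atom_name[k]: s.xyz[k] for k in np.flatnonzero(m)}
            pts.extend(lookup[a] for a in sugar_names)
        sup = superpose(tpl, np.array(pts))
        origins.append(sup.translation.copy())
        rotations.append(sup.rotation)
    return np.array(origins), np.array(rotations)


def bp_centers(s: Structure, chain_ids=("D", "E")) -> np.ndarray:
    """Per-base-pair helix-axis points, recovered by template superposition."""
    origins, _ = _recover_bp_frames(s, chain_ids)
    return origins


def _fit_circle(origins: np.ndarray):
    """Plane + algebraic circle fit; exact for points on a circle."""
    c0 = origins.mean(axis=0)
    _, sv, vt = np.linalg.svd(origins - c0)
    normal = vt[2]
    u, v = vt[0], vt[1]
    x = (origins - c0) @ u
    y = (origins - c0) @ v
    a_mat = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(a_mat, x ** 2 + y ** 2, rcond=None)
    cx, cy, c = sol
    radius = float(np.sqrt(c + cx ** 2 + cy ** 2))
    center = c0 + cx * u + cy * v
    return center, normal, u, v, radius


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) * c + s * k + (1 - c) * np.outer(axis, axis)


def measure_rise_twist(s: Structure, chain_ids=("D", "E")
                       ) -> tuple[float, float]:
    """Recover mean rise (Å) and twist (deg) from successive base-pair frames.

    Frames are recovered by rigid superposition of the sugar template onto
    each base pair.  For a straight duplex, rise is the inter-origin spacing
    and twist the rotation about the axis; for a curved duplex the axis curve
    is refit (plane + circle), rise is measured as arc length, and each frame
    is parallel-transported along the fitted arc before the residual twist
    about the local helix axis is read off.
    """
    origins, rotations = _recover_bp_frames(s, chain_ids)
    n = len(origins)
    if n < 2:
        raise ValueError("need at least 2 base pairs")
    centered = origins - origins.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    straight = n == 2 or sv[1] < 1e-6 * max(sv[0], 1.0)
    rises, twists = [], []
    if straight:
        for i in range(n - 1):
            rises.append(np.linalg.norm(origins[i + 1] - origins[i]))
            d = rotations[i].T @ rotations[i + 1]
            twists.append(np.degrees(np.arctan2(d[1, 0], d[0, 0])))
    else:
        center, normal, u, v, radius = _fit_circle(origins)
        rel = origins - center
        phi = np.arctan2(rel @ v, rel @ u)
        dphi = np.diff(phi)
        dphi = (dphi + np.pi) % (2 * np.pi) - np.pi
        for i in range(n - 1):
            rises.append(radius * abs(dphi[i]))
            transport = _axis_rotation(normal, dphi[i])
            d = (transport @ rotations[i]).T @ rotations[i + 1]
            twists.append(np.degrees(np.arctan2(d[1, 0], d[0, 0])))
    return float(np.mean(rises)), float(np.mean(twists))


# ---------------------------------------------------------------------------
# complex assembly
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ComplexModel:
    """A protein tetramer with one (wrapping) or two (bridging) DNA duplexes."""

    protein: Structure
    dna_segments: list[Structure]
    mode: str  # "wrapping" | "bridging"
    provenance: list[str]

    CLASH_CUTOFF = 2.0  # Å, heavy-atom protein–DNA

    def validate(self) -> None:
        expected = {"wrapping": 1, "bridging": 2}[self.mode]
        if len(self.dna_segments) != expected:
            raise ValueError(
                f"{self.mode} mode requires {expected} DNA segment(s), "
                f"got {len(self.dna_segments)}")
        prot = self.protein.xyz[self.protein.is_heavy_mask()]
        tree = cKDTree(prot)
        for seg in self.dna_segments:
            d, _ = tree.query(seg.xyz[seg.is_heavy_mask()], k=1)
            if d.min() < self.CLASH_CUTOFF:
                raise ValueError(
                    f"protein–DNA clash: minimum heavy-atom distance "
                    f"{d.min():.2f} Å < {self.CLASH_CUTOFF} Å")

    def min_protein_dna_distance(self) -> float:
        prot = self.protein.xyz[self.protein.is_heavy_mask()]
        tree = cKDTree(prot)
        return float(min(
            tree.query(seg.xyz[seg.is_heavy_mask()], k=1)[0].min()
            for seg in self.dna_segments))


def _match_template(tetramer: Structure, template: Structure):
    """Superpose a template's protein part onto the tetramer."""
    key_to_idx = {}
    prot_t = select_atoms(tetramer, "protein")
    for i in prot_t:
        key_to_idx[(tetramer.chain[i], int(tetramer.residue_number[i]),
                    tetramer.atom_name[i])] = i
    mob, ref = [], []
    for i in select_atoms(template, "protein"):
        key = (template.chain[i], int(template.residue_number[i]),
               template.atom_name[i])
        j = key_to_idx.get(key)
        if j is not None:
            mob.append(template.xyz[i])
            ref.append(tetramer.xyz[j])
    if len(mob) < 3:
        raise ValueError(
            "template protein shares fewer than 3 atoms (by chain/residue/"
            "atom name) with the tetramer")
    sup = superpose(np.array(mob), np.array(ref))
    dna_idx = select_atoms(template, "dna and heavy")
    if len(dna_idx) == 0:
        raise ValueError("template carries no DNA atoms")
    dna_xyz = apply_transform(template.xyz[dna_idx], sup)
    return dna_xyz


def _default_sequence(n_bp: int) -> str:
    # 40% GC repeating motif; binding is non-sequence-specific so only the
    # composition matters for realism
    motif = "ATGCA"
    return (motif * (n_bp // len(motif) + 1))[:n_bp]


def assemble_wrapping_model(tetramer: Structure,
                            interface_templates: list[Structure],
                            n_bp: int = 67,
                            sequence: str | None = None,
                            rise: float = 3.4, twist: float = 36.0
                            ) -> ComplexModel:
    """Lay a single continuous duplex around the tetramer.

    Interface templates (e.g. symmetry-expanded crystal complexes) are
    superposed onto the tetramer via their shared protein atoms; the
    transformed DNA centroids define anchor points through which a circle is
    fitted in the tetramer plane.  A curved duplex of ``n_bp`` is built along
    that circle and pushed radially outward, if needed, until it clears the
    protein.
    """
    if len(tetramer.chains) < 4:
        raise ValueError("tetramer must have 4 chains")
    if not interface_templates:
        raise ValueError("at least one interface template is required")
    anchors = np.array([
        _match_template(tetramer, t).mean(axis=0) for t in interface_templates])
    prot_heavy = tetramer.xyz[tetramer.is_heavy_mask()]
    pc = prot_heavy.mean(axis=0)
    if len(anchors) >= 3:
        _, _, vt = np.linalg.svd(anchors - anchors.mean(axis=0))
        normal = vt[2]
    else:
        _, _, vt = np.linalg.svd(prot_heavy - pc)
        normal = vt[2]
    in_plane = anchors - np.outer((anchors - pc) @ normal, normal)
    radii = np.linalg.norm(in_plane - pc, axis=1)
    radius = float(radii.mean())
    if radius <= 0:
        raise ValueError("anchors coincide with the tetramer center")
    if len(anchors) > 1 and np.max(np.abs(radii - radius)) > 0.5 * radius:
        raise ValueError(
            f"interface anchors are not co-circular (radial spread "
            f"{np.max(np.abs(radii - radius)):.1f} Å vs radius {radius:.1f} Å); "
            "the reconnection path would need a >90° kink")
    u0 = (in_plane[0] - pc)
    u0 = u0 - (u0 @ normal) * normal
    u0 /= np.linalg.norm(u0)
    seq = sequence or _default_sequence(n_bp)
    if len(seq) != n_bp:
        raise ValueError("sequence length must equal n_bp")
    # the full duplex must fit on a single turn: grow the circle to the
    # closure radius if the anchors sit tighter than n_bp can wrap
    radius = max(radius, n_bp * rise / (2.0 * np.pi))

    for _ in range(60):
        spec = DuplexSpec(seq, rise=rise, twist=twist, curvature=1.0 / radius)
        duplex = build_bdna(spec)
        # canonical frame: circle center (R,0,0), start at origin with
        # outward radial -x; map onto the fitted circle at the first anchor
        qx = -u0
        qz = normal
        qy = np.cross(qz, qx)
        q = np.column_stack([qx, qy, qz])
        coords = (duplex.xyz - np.array([radius, 0.0, 0.0])) @ q.T + pc
        duplex = duplex.with_xyz(coords)
        model = ComplexModel(tetramer.copy(), [duplex], "wrapping",
                             [f"template-{i}" for i in range(len(interface_templates))])
        if model.min_protein_dna_distance() >= ComplexModel.CLASH_CUTOFF:
            model.validate()
            return model
        radius += 0.5
    raise ValueError("could not place wrapping DNA clear of the protein")


def assemble_bridging_model(tetramer: Structure,
                            interface_templates: list[Structure],
                            n_bp: int = 32,
                            sequence: str | None = None,
                            rise: float = 3.4, twist: float = 36.0
                            ) -> ComplexModel:
    """Place one straight duplex per interface on two opposing faces.

    Each of the two templates receives its own ``n_bp`` duplex, extended
    along the transformed template DNA axis.  Segments must not approach the
    protein below 2 Å nor each other below 4 Å; if they do they are stepped
    radially outward.
    """
    if len(interface_templates) != 2:
        raise ValueError("bridging mode requires exactly 2 interface templates")
    if len(tetramer.chains) < 4:
        raise ValueError("tetramer must have 4 chains")
    seq = sequence or _default_sequence(n_bp)
    if len(seq) != n_bp:
        raise ValueError("sequence length must equal n_bp")
    prot_heavy = tetramer.xyz[tetramer.is_heavy_mask()]
    pc = prot_heavy.mean(axis=0)

    placements = []
    for t in interface_templates:
        dna_xyz = _match_template(tetramer, t)
        m = dna_xyz.mean(axis=0)
        _, _, vt = np.linalg.svd(dna_xyz - m)
        axis = vt[0] / np.linalg.norm(vt[0])
        radial = m - pc
        radial = radial - (radial @ axis) * axis
        nr = np.linalg.norm(radial)
        if nr < 1e-9:
            raise ValueError("template DNA centroid sits on the tetramer axis")
        placements.append((m, axis, radial / nr))

    spec = DuplexSpec(seq, rise=rise, twist=twist, curvature=0.0)
    offsets = [0.0, 0.0]
    for _ in range(80):
        segments = []
        for k, (m, axis, radial) in enumerate(placements):
            duplex = build_bdna(spec, chain_ids=("D", "E") if k == 0 else ("F", "G"))
            qx = -radial
            qz = axis
            qy = np.cross(qz, qx)
            q = np.column_stack([qx, qy, qz])
            mid = np.array([0.0, 0.0, spec.contour_length / 2.0])
            coords = (duplex.xyz - mid) @ q.T + m + offsets[k] * radial
            segments.append(duplex.with_xyz(coords))
        model = ComplexModel(tetramer.copy(), segments, "bridging",
                             ["template-0", "template-1"])
        a = segments[0].xyz[segments[0].is_heavy_mask()]
        b = segments[1].xyz[segments[1].is_heavy_mask()]
        inter = cKDTree(a).query(b, k=1)[0].min()
        if (model.min_protein_dna_distance() >= ComplexModel.CLASH_CUTOFF
                and inter > 4.0):
            model.validate()
            return model
        offsets = [o + 0.25 for o in offsets]
    raise ValueError("could not place bridging duplexes clear of the protein "
                     "and of each other")
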