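"""Superposition, RMSD series, planarity, crossing angles, wrap coverage, FEL."""

import numpy as np
import pytest
from scipy.optimize import minimize

from wrapkit.builder import DuplexSpec, build_bdna, duplex_bp_groups
from wrapkit.geometry import (dihedral, dna_backbone_rmsd_series,
                              free_energy_landscape, helix_crossing_angle,
                              superpose, tetramer_planarity, wrap_coverage)
from wrapkit.structio import Structure, Trajectory

from conftest import ideal_helix, make_structure, random_rotation


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        res = superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3))

    def test_exact_rotation_recovery(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        rot = np.array([[0.0, -1.0, 0], [1.0, 0.0, 0], [0, 0, 1.0]])  # 90° z
        moved = pts @ rot.T + [2.0, -1.0, 0.5]
        res = superpose(pts, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.rotation, rot, atol=1e-9)

    def test_matches_brute_force_minimization(self):
        """Kabsch equals numerical minimization over an Euler-angle
        parameterization on jittered data."""
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5, 3)) * 4.0
        target = pts @ random_rotation(rng).T + rng.normal(0, 0.3, size=(5, 3))

        def objective(params):
            a, b, c, tx, ty, tz = params
            ca, sa = np.cos(a), np.sin(a)
            cb, sb = np.cos(b), np.sin(b)
            cc, sc = np.cos(c), np.sin(c)
            rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
            ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            rx = np.array([[1, 0, 0], [0, cc, -sc], [0, sc, cc]])
            moved = pts @ (rz @ ry @ rx).T + [tx, ty, tz]
            return np.sqrt(((moved - target) ** 2).sum(1).mean())

        best = np.inf
        for trial in range(12):
            x0 = np.concatenate([rng.uniform(-np.pi, np.pi, 3),
                                 rng.normal(0, 1, 3)])
            r = minimize(objective, x0, method="Nelder-Mead",
                         options={"xatol": 1e-12, "fatol": 1e-14,
                                  "maxiter": 20000})
            best = min(best, r.fun)
        res = superpose(pts, target)
        assert res.rmsd == pytest.approx(best, abs=1e-6)

    def test_rmsd_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(12, 3))
        b = a @ random_rotation(rng).T + rng.normal(0, 0.5, size=(12, 3))
        assert superpose(a, b).rmsd == pytest.approx(superpose(b, a).rmsd,
                                                     abs=1e-9)

    def test_proper_rotation_only(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(6, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirrored: best proper rotation must not reflect
        res = superpose(a, b)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            superpose(pts, pts)


class TestRmsdSeries:
    def _toy(self):
        recs = [("A", i + 1, "GLY", "CA", "C", (i * 2.0, (i % 3) * 1.5, 0.0))
                for i in range(10)]
        recs += [("X", i + 1, "DA", "P", "P", (i * 2.0, 10.0 + (i % 2), 3.0))
                 for i in range(10)]
        return make_structure(recs)

    def test_copies_of_reference_are_zero(self):
        s = self._toy()
        traj = Trajectory(s, np.stack([s.xyz] * 5))
        out = dna_backbone_rmsd_series(traj, s.xyz, np.arange(10),
                                       np.arange(10, 20))
        assert np.allclose(out, 0.0, atol=1e-9)

    @pytest.mark.parametrize("d", [1.0, 2.5, 7.0])
    def test_translated_dna_reads_exactly_d(self, d):
        s = self._toy()
        frame = s.xyz.copy()
        frame[10:] += [0.0, 0.0, d]
        traj = Trajectory(s, frame[None])
        out = dna_backbone_rmsd_series(traj, s.xyz, np.arange(10),
                                       np.arange(10, 20))
        assert out[0] == pytest.approx(d, abs=1e-9)

    def test_gaussian_jitter_expectation(self):
        """Per-atom iid jitter of σ on the measured set gives RMSD → σ√3."""
        s = self._toy()
        sigma = 0.4
        rng = np.random.default_rng(8)
        frames = np.stack([s.xyz] * 1000)
        frames[:, 10:, :] += rng.normal(0, sigma, size=(1000, 10, 3))
        traj = Trajectory(s, frames)
        out = dna_backbone_rmsd_series(traj, s.xyz, np.arange(10),
                                       np.arange(10, 20))
        assert out.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_empty_selection_is_error(self):
        s = self._toy()
        traj = Trajectory(s, s.xyz[None])
        with pytest.raises(ValueError):
            dna_backbone_rmsd_series(traj, s.xyz, np.array([], dtype=int),
                                     np.arange(10, 20))


class TestPlanarity:
    def _square_tetramer(self, lift=0.0):
        recs = []
        for ch, ang in (("A", 45.0), ("B", 135.0), ("C", 315.0), ("D", 225.0)):
            c = 10.0 * np.array([np.cos(np.radians(ang)),
                                 np.sin(np.radians(ang)), 0.0])
            if ch == "A":
                c[2] += lift
            for j, off in enumerate([(-1, 0, 0), (1, 0, 0), (0, 1, 0)]):
                recs.append((ch, j + 1, "GLY", "CA", "C",
                             tuple(c + np.array(off))))
        return make_structure(recs)

    def test_coplanar_is_180(self):
        s = self._square_tetramer()
        traj = Trajectory(s, s.xyz[None])
        ang = tetramer_planarity(traj, ("A", "B"), ("C", "D"))
        assert abs(ang[0]) == pytest.approx(180.0, abs=1e-9)

    def test_lifted_centroid_matches_analytic_dihedral(self):
        s = self._square_tetramer(lift=4.0)
        traj = Trajectory(s, s.xyz[None])
        ang = tetramer_planarity(traj, ("A", "B"), ("C", "D"))
        cents = {ch: s.xyz[[i for i in range(len(s)) if s.chain[i] == ch]]
                 .mean(axis=0) for ch in "ABCD"}
        expected = dihedral(cents["A"], cents["B"], cents["C"], cents["D"])
        assert ang[0] == pytest.approx(expected, abs=1e-9)
        assert abs(abs(ang[0]) - 180.0) > 1.0

    def test_rigid_rotation_invariance(self):
        s = self._square_tetramer(lift=3.0)
        rng = np.random.default_rng(9)
        rot = random_rotation(rng)
        frames = np.stack([s.xyz, s.xyz @ rot.T + [4.0, 5.0, 6.0]])
        traj = Trajectory(s, frames)
        ang = tetramer_planarity(traj, ("A", "B"), ("C", "D"))
        assert ang[0] == pytest.approx(ang[1], abs=1e-9)


class TestCrossingAngle:
    def _structure_with_helices(self, angle_deg, n=18):
        a = np.radians(angle_deg)
        h1 = ideal_helix([0, 0, 1], n=n)
        h2 = ideal_helix([np.sin(a), 0, np.cos(a)], n=n, offset=(9.0, 0, 0))
        recs = [("A", i + 1, "ALA", "CA", "C", tuple(p))
                for i, p in enumerate(h1)]
        recs += [("B", i + 1, "ALA", "CA", "C", tuple(p))
                 for i, p in enumerate(h2)]
        return make_structure(recs)

    @pytest.mark.parametrize("angle", [20.0, 40.0, 75.0])
    def test_constructed_angle_recovery(self, angle):
        s = self._structure_with_helices(angle)
        out, antiparallel = helix_crossing_angle(s, "chain A", "chain B")
        assert out == pytest.approx(angle, abs=0.1)
        assert not antiparallel

    def test_parallel_helices(self):
        s = self._structure_with_helices(0.0)
        out, _ = helix_crossing_angle(s, "chain A", "chain B")
        assert out == pytest.approx(0.0, abs=1e-6)

    def test_antiparallel_reported(self):
        s = self._structure_with_helices(140.0)
        out, antiparallel = helix_crossing_angle(s, "chain A", "chain B")
        assert out == pytest.approx(40.0, abs=0.1)
        assert antiparallel

    def test_too_few_atoms_is_error(self):
        s = self._structure_with_helices(40.0, n=18)
        with pytest.raises(ValueError, match="6"):
            helix_crossing_angle(s, "chain A and resi 1-4", "chain B")


def _full_wrap_fixture(n=67, k_wrapped=None):
    """A duplex circle with protein pseudo-atoms planted 3 Å inside each of
    the first ``k_wrapped`` base pairs (all, if None)."""
    h = 3.4
    s = build_bdna(DuplexSpec(("ATGCA" * 14)[:n], rise=h,
                              curvature=2 * np.pi / (n * h)))
    radius = n * h / (2 * np.pi)
    dna = s.with_xyz(s.xyz - np.array([radius, 0.0, 0.0]))
    groups = duplex_bp_groups(dna)
    k = n if k_wrapped is None else k_wrapped
    prot_recs = []
    for i in range(k):
        pts = dna.xyz[groups[i]]
        centroid = pts.mean(axis=0)
        inner = pts[np.argmin(np.linalg.norm(pts[:, :2], axis=1))]
        direction = centroid - inner
        direction /= np.linalg.norm(direction)
        # place the pseudo-atom 3 Å away from the bp's innermost atom,
        # on the side away from the duplex body
        prot_recs.append(("P", i + 1, "GLY", "CA", "C",
                          tuple(inner - 3.0 * direction)))
    prot = make_structure(prot_recs)
    combined = Structure.concatenate([prot, dna])
    shifted_groups = [g + len(prot) for g in groups]
    return combined, shifted_groups, np.arange(len(prot))


class TestWrapCoverage:
    def test_fully_wrapped_circle(self):
        combined, groups, prot_idx = _full_wrap_fixture()
        rep = wrap_coverage(combined.xyz, groups, prot_idx, cutoff=4.0)
        assert rep.bp_in_contact == 67
        assert rep.longest_run == 67
        assert rep.angular_coverage_deg == pytest.approx(360.0)

    def test_displaced_dna_zero(self):
        combined, groups, prot_idx = _full_wrap_fixture()
        frame = combined.xyz.copy()
        for g in groups:
            frame[g] += [500.0, 0.0, 0.0]
        rep = wrap_coverage(frame, groups, prot_idx, cutoff=4.0)
        assert rep.bp_in_contact == 0
        assert rep.angular_coverage_deg == 0.0

    @pytest.mark.parametrize("k", [10, 33, 50])
    def test_partial_wrap_counts_exactly_k(self, k):
        combined, groups, prot_idx = _full_wrap_fixture(k_wrapped=k)
        rep = wrap_coverage(combined.xyz, groups, prot_idx, cutoff=4.0)
        assert rep.bp_in_contact == k
        assert rep.longest_run == k


class TestFreeEnergyLandscape:
    def test_single_occupied_bin(self):
        """All samples in one bin: F = 0 there, undefined elsewhere."""
        edges = np.linspace(0.0, 10.0, 6)
        cv1 = np.array([0.1, 0.2, 0.3, 0.15] * 5)
        cv2 = np.array([0.2, 0.1, 0.25, 0.3] * 5)
        fel = free_energy_landscape(cv1, cv2, kT=2.577, bins=edges)
        finite = np.isfinite(fel.free_energy)
        assert finite.sum() == 1
        assert fel.free_energy[finite][0] == 0.0

    def test_two_bin_closed_form(self):
        """P = {0.75, 0.25} gives ΔF = kT·ln 3."""
        kt = 2.577
        cv1 = np.array([0.0] * 75 + [1.0] * 25)
        cv2 = np.tile([0.0, 0.1], 50)  # distinct, but within one y-bin
        fel = free_energy_landscape(cv1, cv2, kT=kt,
                                    bins=[2, np.array([-1.0, 1.0, 3.0])])
        f = fel.free_energy[np.isfinite(fel.free_energy)]
        assert sorted(f) == pytest.approx([0.0, kt * np.log(3.0)], abs=1e-9)

    def test_probability_normalized(self):
        rng = np.random.default_rng(10)
        fel = free_energy_landscape(rng.normal(size=500),
                                    rng.normal(size=500), bins=12)
        assert fel.probability.sum() == pytest.approx(1.0, abs=1e-12)
        finite = fel.free_energy[np.isfinite(fel.free_energy)]
        assert (finite >= 0.0).all()

    def test_rescaled_counts_leave_f_invariant(self):
        """Scaling every bin count by a constant factor (e.g. sampling the
        same distribution longer) leaves F = -kT ln(P/Pmax) unchanged —
        the raw -kT ln P surface only shifts uniformly."""
        rng = np.random.default_rng(11)
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        kt = 2.577
        fel1 = free_energy_landscape(x, y, kT=kt, bins=8)
        fel3 = free_energy_landscape(np.repeat(x, 3), np.repeat(y, 3),
                                     kT=kt, bins=8)
        m = np.isfinite(fel1.free_energy)
        assert np.allclose(fel3.free_energy[m], fel1.free_energy[m],
                           atol=1e-9)

    def test_narrow_gaussian_has_smaller_basin(self):
        rng = np.random.default_rng(12)
        n = 20000
        edges = np.linspace(-6, 6, 41)
        narrow = free_energy_landscape(rng.normal(0, 0.5, n),
                                       rng.normal(0, 0.5, n), bins=edges)
        wide = free_energy_landscape(rng.normal(0, 2.0, n),
                                     rng.normal(0, 2.0, n), bins=edges)
        assert narrow.basin_area < wide.basin_area

    def test_degenerate_axis_is_error(self):
        with pytest.raises(ValueError):
            free_energy_landscape(np.zeros(10), np.arange(10.0))
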