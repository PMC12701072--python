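"""Contact counting, binding-site decomposition, fluctuation and smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wrapkit.contacts import (ContactParams, HBondCriteria, SmoothingParams,
                              binding_fluctuation, classify_contact_moieties,
                              contact_series, count_contacts,
                              define_canonical_sites, hbond_occupancy,
                              salt_bridge_occupancy, smooth)
from wrapkit.structio import Structure, Trajectory, select_atoms

from conftest import make_structure, random_rotation


def brute_force_count(frame, set_a, set_b, cutoff):
    """O(N²) all-pairs oracle."""
    a = frame[np.asarray(set_a)]
    b = frame[np.asarray(set_b)]
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return int((d <= cutoff).sum())


class TestCountContacts:
    def test_cutoff_boundary_is_inclusive(self):
        frame = np.array([[0.0, 0, 0], [3.99, 0, 0]])
        n, _ = count_contacts(frame, [0], [1], ContactParams(cutoff=4.0))
        assert n == 1
        frame[1, 0] = 4.01
        n, _ = count_contacts(frame, [0], [1], ContactParams(cutoff=4.0))
        assert n == 0

    def test_complete_bipartite(self):
        """3 A-atoms and 2 B-atoms all within the cutoff → 6 pairs."""
        a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        b = np.array([[0.5, 0.5, 1.0], [0.5, 0.5, -1.0]])
        frame = np.vstack([a, b])
        n, pairs = count_contacts(frame, [0, 1, 2], [3, 4])
        assert n == 6
        assert pairs == sorted(pairs)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        frame = rng.uniform(0, 20, size=(500, 3))
        set_a = np.arange(200)
        set_b = np.arange(200, 500)
        n, pairs = count_contacts(frame, set_a, set_b)
        assert n == brute_force_count(frame, set_a, set_b, 4.0)
        assert len(pairs) == n

    def test_overlapping_sets_rejected(self):
        frame = np.zeros((3, 3))
        with pytest.raises(ValueError, match="overlap"):
            count_contacts(frame, [0, 1], [1, 2])

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        frame = rng.uniform(0, 15, size=(120, 3))
        set_a, set_b = np.arange(60), np.arange(60, 120)
        n0, _ = count_contacts(frame, set_a, set_b)
        rot = random_rotation(rng)
        n1, _ = count_contacts(frame @ rot.T + [5.0, -3.0, 11.0],
                               set_a, set_b)
        assert n0 == n1


class TestBindingFluctuation:
    def test_constant_series(self):
        assert np.array_equal(binding_fluctuation([5, 5, 5]), [0, 0, 0])

    def test_two_point_arithmetic(self):
        assert np.array_equal(binding_fluctuation([1, 3]), [-1.0, 1.0])

    @given(st.lists(st.integers(min_value=0, max_value=10000), min_size=1,
                    max_size=300))
    @settings(max_examples=50, deadline=None)
    def test_sums_to_zero(self, counts):
        assert abs(binding_fluctuation(counts).sum()) < 1e-9 * max(
            1, sum(counts))


class TestSmooth:
    def test_constant_unchanged(self):
        s = np.full(50, 3.0)
        assert np.allclose(smooth(s, SmoothingParams(window=7)), s)

    def test_impulse_plateau(self):
        s = np.zeros(101)
        s[50] = 1.0
        w = 11
        out = smooth(s, SmoothingParams(window=w))
        assert out[50] == pytest.approx(1.0 / w)
        assert out[50 - w // 2] == pytest.approx(1.0 / w)
        assert out[50 + w // 2 + 1] == 0.0

    def test_matches_brute_force_windowed_mean(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=200)
        w = 9
        out = smooth(s, SmoothingParams(window=w))
        half = w // 2
        for i in range(len(s)):
            lo, hi = max(0, i - half), min(len(s), i + half + 1)
            assert out[i] == pytest.approx(s[lo:hi].mean(), abs=1e-12)

    def test_window_exceeding_length_is_error(self):
        with pytest.raises(ValueError, match="window"):
            smooth(np.zeros(5), SmoothingParams(window=100))

    def test_output_length_preserved(self):
        out = smooth(np.arange(30, dtype=float), SmoothingParams(window=100 // 10))
        assert out.shape == (30,)


class TestCanonicalSites:
    def test_four_disjoint_sites_on_toy_tetramer(self, wrap_toy):
        traj, _ = wrap_toy
        sites = define_canonical_sites(traj.topology)
        assert set(sites) == {"A-site 1", "A-site 2", "B-site 1", "B-site 2"}
        seen = set()
        for s in sites.values():
            assert not (s.residues & seen)
            seen |= s.residues

    def test_custom_single_residue_site(self, wrap_toy):
        traj, _ = wrap_toy
        sites = define_canonical_sites(traj.topology,
                                       {"custom": [("A", 55)]})
        assert len(sites["custom"].residues) == 1

    def test_missing_residue_is_error(self, wrap_toy):
        traj, _ = wrap_toy
        with pytest.raises(ValueError, match="999"):
            define_canonical_sites(traj.topology, {"bad": [("A", 999)]})


class TestContactSeries:
    def test_single_frame_sd_zero(self, wrap_toy):
        traj, _ = wrap_toy
        one = Trajectory(traj.topology, traj.frames[:1], traj.frame_times[:1])
        sites = define_canonical_sites(traj.topology)
        cs = contact_series(one, sites, traj.selection_masks["dna"])
        assert len(cs.total) == 1
        assert cs.sd == 0.0

    def test_wrapping_toy_engages_all_sites(self, wrap_toy):
        traj, gt = wrap_toy
        sites = define_canonical_sites(traj.topology)
        cs = contact_series(traj, sites, traj.selection_masks["dna"])
        for name, engaged in gt.payload["engaged"].items():
            assert engaged
            assert cs.per_site[name].mean() > 0

    def test_bridging_toy_engages_only_b_sites(self, bridge_toy):
        traj, gt = bridge_toy
        sites = define_canonical_sites(traj.topology)
        cs = contact_series(traj, sites, traj.selection_masks["dna"])
        for name, engaged in gt.payload["engaged"].items():
            if engaged:
                assert cs.per_site[name].mean() > 0
            else:
                assert cs.per_site[name].mean() == pytest.approx(0.0, abs=0.5)

    def test_site_sums_bounded_by_total(self, wrap_toy):
        traj, _ = wrap_toy
        sites = define_canonical_sites(traj.topology)
        cs = contact_series(traj, sites, traj.selection_masks["dna"])
        site_sum = sum(cs.per_site[n] for n in sites)
        assert (site_sum <= cs.total).all()

    def test_empty_trajectory_is_error(self, wrap_toy):
        traj, _ = wrap_toy
        sites = define_canonical_sites(traj.topology)
        empty = Trajectory(traj.topology, traj.frames[:1])
        empty.frames = traj.frames[:0]
        with pytest.raises(ValueError):
            contact_series(empty, sites, traj.selection_masks["dna"])


class TestMoieties:
    def test_single_phosphate_sidechain_pair(self):
        s = make_structure([
            ("A", 1, "LYS", "NZ", "N", (0, 0, 0)),
            ("X", 1, "DA", "P", "P", (3, 0, 0)),
        ])
        table = classify_contact_moieties([(0, 1)], s)
        assert table.loc["phosphate", "sidechain"] == 1
        assert table.values.sum() == 1

    def test_marginals_conserve_total(self, wrap_toy):
        traj, _ = wrap_toy
        top = traj.topology
        prot = select_atoms(top, "protein and heavy")
        dna = traj.selection_masks["dna"]
        n, pairs = count_contacts(traj.frames[0], prot, dna)
        table = classify_contact_moieties(pairs, top)
        assert table.values.sum() == n

    def test_sugar_only_contacts(self):
        """A frame whose only reachable DNA atoms are sugars puts every
        contact in the sugar row."""
        recs = [("X", 1, "DA", "C1'", "C", (0.0, 0.0, 0.0)),
                ("X", 1, "DA", "O4'", "O", (3.0, 0.0, 0.0)),
                ("X", 2, "DA", "C3'", "C", (6.0, 0.0, 0.0)),
                ("X", 2, "DA", "P", "P", (50.0, 0.0, 0.0))]  # out of reach
        dna = make_structure(recs)
        prot = make_structure([
            ("A", i + 1, "LYS", "NZ", "N", (3.0 * i, 0.0, 1.5))
            for i in range(3)])
        combined = Structure.concatenate([prot, dna])
        prot_idx = np.arange(len(prot))
        dna_idx = np.arange(len(prot), len(combined))
        n, pairs = count_contacts(combined.xyz, prot_idx, dna_idx,
                                  ContactParams(cutoff=2.0))
        table = classify_contact_moieties(pairs, combined)
        assert n == 3
        assert table.loc["sugar"].sum() == n
        assert table.drop(index="sugar").values.sum() == 0

    def test_rigid_motion_invariance(self, wrap_toy):
        traj, _ = wrap_toy
        top = traj.topology
        prot = select_atoms(top, "protein and heavy")
        dna = traj.selection_masks["dna"]
        _, pairs0 = count_contacts(traj.frames[0], prot, dna)
        rng = np.random.default_rng(5)
        rot = random_rotation(rng)
        moved = traj.frames[0] @ rot.T + [10.0, 0.0, -4.0]
        _, pairs1 = count_contacts(moved, prot, dna)
        t0 = classify_contact_moieties(pairs0, top)
        t1 = classify_contact_moieties(pairs1, top)
        assert pairs0 == pairs1
        assert (t0 == t1).all().all()


class TestOccupancy:
    def _two_atom_traj(self, distances):
        s = make_structure([
            ("A", 1, "LYS", "NZ", "N", (0, 0, 0)),
            ("X", 1, "DA", "OP1", "O", (1, 0, 0)),
        ])
        frames = np.array([[[0, 0, 0], [d, 0, 0]] for d in distances],
                          dtype=float)
        return s, Trajectory(s, frames)

    def test_always_within_criteria_is_persistent(self):
        s, traj = self._two_atom_traj([3.0] * 10)
        frac, persistent = hbond_occupancy(traj, [0], [1])
        assert frac.iloc[0] == 1.0
        assert persistent == [(0, 1)]

    def test_four_of_ten_not_persistent(self):
        s, traj = self._two_atom_traj([3.0] * 4 + [6.0] * 6)
        frac, persistent = hbond_occupancy(traj, [0], [1])
        assert frac.iloc[0] == pytest.approx(0.4)
        assert persistent == []

    def test_angle_criterion_filters(self):
        """A 90° D–H···A geometry fails the 120° angle test."""
        s = make_structure([
            ("A", 1, "LYS", "NZ", "N", (0, 0, 0)),
            ("A", 1, "LYS", "HZ1", "H", (1.0, 0, 0)),
            ("X", 1, "DA", "OP1", "O", (1.0, 2.0, 0)),
        ])
        frames = s.xyz[None]
        traj = Trajectory(s, frames)
        frac, _ = hbond_occupancy(traj, [0], [2], hydrogens={0: [1]})
        assert len(frac) == 0
        # linear geometry passes
        s2 = make_structure([
            ("A", 1, "LYS", "NZ", "N", (0, 0, 0)),
            ("A", 1, "LYS", "HZ1", "H", (1.0, 0, 0)),
            ("X", 1, "DA", "OP1", "O", (2.5, 0.0, 0)),
        ])
        traj2 = Trajectory(s2, s2.xyz[None])
        frac2, _ = hbond_occupancy(traj2, [0], [2], hydrogens={0: [1]})
        assert frac2.iloc[0] == 1.0

    def test_rd_clamp_salt_bridge_on_toy(self, wrap_toy):
        """The planted arginine–aspartate pair reads out ≤ 4 Å in every
        monomer."""
        traj, _ = wrap_toy
        top = traj.topology
        basic = select_atoms(top, "resname ARG and name NH1")
        acidic = select_atoms(top, "resname ASP and name OD1")
        frac, persistent = salt_bridge_occupancy(traj, basic, acidic)
        assert len(persistent) == 4  # one RD clamp per monomer

    def test_empty_selection_warns(self, wrap_toy):
        traj, _ = wrap_toy
        with pytest.warns(UserWarning):
            frac, persistent = hbond_occupancy(traj, [], [1])
        assert len(frac) == 0
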