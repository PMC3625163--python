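"""Folding-motif construction: occupancy, averaging, consensus, relaxation."""

import numpy as np
import pytest

import foldmotif as fm
from foldmotif.folding_motif import implied_support


class TestOccupancyCurve:
    def test_gap_free_alignment_constant_curve(self):
        s, _ = fm.make_ideal_fold(16, "hairpin", seed=0)
        copies = [fm.CalphaStructure(f"c{k}", "A", s.coords.copy(),
                                     s.res_numbers.copy()) for k in range(3)]
        aln = fm.align_structures(copies, mode="builtin")
        occ = fm.occupancy_curve(aln)
        assert (occ.k_curve[1:] == 16).all()

    def test_curve_non_increasing_and_top_counts_full_columns(self, family13):
        _, _, fam = family13
        occ = fm.occupancy_curve(fam.alignment)
        assert (np.diff(occ.k_curve[1:]) <= 0).all()
        full = int((fam.alignment.occupancy() == 13).sum())
        assert occ.at_least(13) == full

    def test_consistent_with_select_positions(self, family13):
        """k_curve evaluated at the implied support equals the number of
        selected positions (cross-module consistency)."""
        _, _, fam = family13
        occ = fm.occupancy_curve(fam.alignment)
        k = implied_support(13, 0.5)
        assert occ.at_least(k) == len(fm.select_positions(fam.alignment, 0.5))


class TestSelectPositions:
    def test_majority_rule_boundary(self):
        """13 members at the 50% rule: occupancy 7 selected, 6 rejected."""
        assert implied_support(13, 0.5) == 7
        rng = np.random.default_rng(0)
        coords = np.zeros((2, 3))
        coords[1, 0] = 3.8
        members = [fm.CalphaStructure(f"m{k}", "A",
                                      coords + rng.normal(scale=0.01, size=(2, 3)),
                                      np.array([1, 2])) for k in range(13)]
        # column 0: 7 members occupy; column 1: 6; column 2: all
        cols = np.full((3, 13), fm.GAP)
        cols[0, :7] = 0
        cols[1, 7:13] = 0
        cols[2, :] = 1
        aln = fm.StructuralAlignment(members, cols,
                                     [m.coords for m in members])
        sel = fm.select_positions(aln, 0.5)
        assert sel.tolist() == [0, 2]

    def test_all_gap_column_rejected_any_fraction(self, family13):
        _, _, fam = family13
        for frac in (0.1, 0.5, 0.9):
            sel = fm.select_positions(fam.alignment, frac)
            assert (fam.alignment.occupancy()[sel] > 0).all()

    def test_nothing_selected_raises(self):
        # two members with completely disjoint columns: max occupancy 1,
        # but a >50% rule needs 2
        coords = np.array([[0.0, 0, 0], [3.8, 0, 0]])
        a = fm.CalphaStructure("a", "A", coords, np.array([1, 2]))
        b = fm.CalphaStructure("b", "A", coords, np.array([1, 2]))
        cols = np.array([[0, fm.GAP], [1, fm.GAP], [fm.GAP, 0], [fm.GAP, 1]])
        aln = fm.StructuralAlignment([a, b], cols, [a.coords, b.coords])
        with pytest.raises(ValueError, match="[Ll]ower"):
            fm.select_positions(aln, 0.5)


class TestAverageCoordinates:
    def test_identical_members_average_is_member(self, family13):
        template, _, _ = family13
        spec = fm.FamilySpec(seed=0, noise_sigma=0.0, insertion_sites=(),
                             random_pose=False)
        fam = fm.make_family(template, fm.make_ideal_fold(24, "hairpin",
                                                          seed=2)[1], spec)
        cols = fm.select_positions(fam.alignment)
        raw = fm.average_coordinates(fam.alignment, cols)
        np.testing.assert_allclose(raw.coords, template.coords, atol=1e-9)

    def test_two_point_mean(self):
        coords = np.array([[0.0, 0, 0], [3.8, 0, 0]])
        a = fm.CalphaStructure("a", "A", coords, np.array([1, 2]))
        b = fm.CalphaStructure("b", "A", coords + [2.0, 0, 0],
                               np.array([1, 2]))
        aln = fm.StructuralAlignment([a, b], np.array([[0, 0], [1, 1]]),
                                     [a.coords, b.coords])
        raw = fm.average_coordinates(aln, np.array([0, 1]))
        np.testing.assert_allclose(raw.coords[0], [1.0, 0, 0])

    def test_noise_shrinks_as_sqrt_members(self):
        """Averaging 13 noisy copies: mean deviation from the true core is
        close to sigma/sqrt(13) (Monte-Carlo oracle for the mean of 13
        isotropic Gaussian points)."""
        template, tmap = fm.make_ideal_fold(24, "hairpin", seed=2)
        sigma = 0.3
        devs = []
        for seed in range(8):
            spec = fm.FamilySpec(seed=seed, noise_sigma=sigma,
                                 insertion_sites=(), random_pose=False)
            fam = fm.make_family(template, tmap, spec)
            cols = fm.select_positions(fam.alignment)
            raw = fm.average_coordinates(fam.alignment, cols)
            devs.append(np.linalg.norm(raw.coords - template.coords, axis=1))
        mean_dev = np.mean(devs)
        # E|N(0, (s^2/13) I3)| = s/sqrt(13) * sqrt(8/pi) * gamma(2)/gamma(1.5)
        expected = sigma / np.sqrt(13) * np.sqrt(8 / np.pi)
        assert mean_dev == pytest.approx(expected, rel=0.1)


class TestConsensusContactMap:
    def test_monotone_in_threshold(self, family13):
        _, _, fam = family13
        cols = fm.select_positions(fam.alignment)
        maps = {}
        for thr in (3, 4, 7, 13):
            maps[thr], _ = fm.consensus_contact_map(
                fam.alignment, fam.contact_maps, cols, thr)
        assert maps[4].pairs <= maps[3].pairs
        assert maps[7].pairs <= maps[4].pairs
        assert maps[13].pairs <= maps[7].pairs

    def test_exact_support_boundary(self):
        """A contact present in exactly 3 members is kept at threshold 3
        and dropped at threshold 4."""
        template, tmap = fm.make_ideal_fold(24, "hairpin", seed=2)
        spec = fm.FamilySpec(seed=1, noise_sigma=0.0, insertion_sites=(),
                             random_pose=False)
        fam = fm.make_family(template, tmap, spec)
        target = fam.contact_maps[0].contacts[0].pair
        pruned = []
        for k, cmap in enumerate(fam.contact_maps):
            keep = [c for c in cmap if c.pair != target] if k >= 3 else \
                list(cmap)
            pruned.append(fm.ContactMap(keep, cmap.n_residues))
        cols = fm.select_positions(fam.alignment)
        at3, sup3 = fm.consensus_contact_map(fam.alignment, pruned, cols, 3)
        at4, _ = fm.consensus_contact_map(fam.alignment, pruned, cols, 4)
        assert target in at3.pairs and target not in at4.pairs
        assert sup3[target] == 3

    def test_threshold_above_members_rejected(self, family13):
        _, _, fam = family13
        cols = fm.select_positions(fam.alignment)
        with pytest.raises(ValueError, match="exceeds"):
            fm.consensus_contact_map(fam.alignment, fam.contact_maps, cols, 14)


class TestChooseSupportThreshold:
    def test_single_candidate_returned(self, family13):
        _, _, fam = family13
        cols = fm.select_positions(fam.alignment)
        rows = fm.choose_support_threshold(fam.alignment, fam.contact_maps,
                                           cols, [4])
        assert len(rows) == 1 and rows[0]["threshold"] == 4

    def test_ranked_by_distance_to_median_with_bracketing(self, family13):
        _, _, fam = family13
        cols = fm.select_positions(fam.alignment)
        rows = fm.choose_support_threshold(fam.alignment, fam.contact_maps,
                                           cols, [3, 7, 13])
        dists = [r["distance_to_median"] for r in rows]
        assert dists == sorted(dists)
        marks = {r["bracket"] for r in rows}
        assert marks <= {"", "above", "below"}


class TestCheckAdjacency:
    def test_identical_members_no_violations(self, family13):
        _, _, fam = family13
        cols = fm.select_positions(fam.alignment)
        assert fm.check_adjacency(cols, fam.alignment) == []

    def test_constructed_violation_flagged(self):
        """Every member carries (its own) extra residue between the same
        two FM columns, so no member's backbone connects them: flagged."""
        rng = np.random.default_rng(0)
        base = np.zeros((5, 3))
        base[:, 0] = 3.8 * np.arange(5)
        members = [fm.CalphaStructure(f"m{k}", "A",
                                      base + rng.normal(scale=0.01,
                                                        size=(5, 3)),
                                      np.arange(1, 6)) for k in range(3)]
        # columns: core 0,1 | per-member insertion columns | core 3,4 — the
        # insertion residue of each member sits between FM columns 1 and 5
        cols = np.array([
            [0, 0, 0],
            [1, 1, 1],
            [2, fm.GAP, fm.GAP],
            [fm.GAP, 2, fm.GAP],
            [fm.GAP, fm.GAP, 2],
            [3, 3, 3],
            [4, 4, 4],
        ])
        aln = fm.StructuralAlignment(members, cols,
                                     [m.coords for m in members])
        selected = np.array([0, 1, 5, 6])
        violations = fm.check_adjacency(selected, aln)
        assert (1, 2) in violations
        # the connected pairs are not flagged
        assert (0, 1) not in violations and (2, 3) not in violations


class TestRelaxBackbone:
    def test_fixed_point(self):
        """A backbone already at 3.8 A bonds barely moves."""
        s, cmap = fm.make_ideal_fold(16, "hairpin", seed=1)
        relaxed, diag = fm.relax_backbone(s, cmap, seed=0)
        bonds = np.linalg.norm(np.diff(relaxed.coords, axis=0), axis=1)
        assert np.abs(bonds - 3.8).max() < 0.05
        assert diag["displacement"].max() < 0.5

    def test_distribution_tightens_loops_move_more(self, family13):
        """Noisy averaged backbone: >= 95% of bonds end within
        3.8 +- 0.15 A and variance drops; residue count and order fixed."""
        _, _, fam = family13
        cols = fm.select_positions(fam.alignment)
        raw = fm.average_coordinates(fam.alignment, cols)
        cmap, _ = fm.consensus_contact_map(fam.alignment, fam.contact_maps,
                                           cols, 7, backbone=raw)
        relaxed, diag = fm.relax_backbone(raw, cmap, seed=1)
        assert len(relaxed) == len(raw)
        assert relaxed.res_ids == raw.res_ids
        bonds = np.linalg.norm(np.diff(relaxed.coords, axis=0), axis=1)
        assert np.mean(np.abs(bonds - 3.8) < 0.15) >= 0.95
        assert diag["bond_std_after"] <= diag["bond_std_before"]

    def test_too_short_rejected(self):
        coords = np.array([[0.0, 0, 0], [3.8, 0.3, 0], [7.4, 0, 0.4]])
        s = fm.CalphaStructure("short", "A", coords, np.arange(1, 4))
        with pytest.raises(ValueError, match=">= 4"):
            fm.relax_backbone(s, fm.ContactMap([], 3))


class TestBuildFoldingMotif:
    def test_end_to_end_on_noiseless_family(self):
        template, tmap = fm.make_ideal_fold(24, "hairpin", seed=2)
        spec = fm.FamilySpec(seed=5, noise_sigma=0.0, insertion_sites=(),
                             random_pose=False)
        fam = fm.make_family(template, tmap, spec)
        motif = fm.build_folding_motif(fam.alignment, fam.contact_maps,
                                       support_threshold=13, relax=False)
        assert motif.n_residues == 24
        assert motif.contact_map.pairs == tmap.pairs
        np.testing.assert_allclose(motif.backbone.coords, template.coords,
                                   atol=1e-6)

    def test_provenance_and_support_recorded(self, family13):
        _, _, fam = family13
        motif = fm.build_folding_motif(fam.alignment, fam.contact_maps,
                                       support_threshold=7, seed=2)
        assert len(motif.position_provenance) == motif.n_residues
        assert all(p["occupancy"] >= 7 for p in motif.position_provenance)
        assert all(v >= 7 for v in motif.contact_support.values())
        assert motif.adjacency_violations == []
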