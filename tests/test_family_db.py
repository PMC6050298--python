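"""Family alignment, conservation profiling, segmentation, PSSMs, fragments."""

import copy
import math

import numpy as np
import pytest
import yaml

from barrelforge.family_db import (
    ConservationProfile,
    Segment,
    SegmentationScheme,
    align_family,
    build_pssm,
    conservation_profile,
    extract_fragments,
    fragment_rmsd,
    load_db,
    propose_boundaries,
    save_db,
)
from barrelforge.structure_io import AA1, from_internal, to_internal
from barrelforge.geometry import superpose


class TestAlignFamily:
    def test_exact_copies_map_identically(self, small_family):
        structs, _, _ = small_family
        ref = structs[0]
        copies = [copy.deepcopy(ref) for _ in range(3)]
        for i, c in enumerate(copies):
            c.id = f"copy{i}"
        aligned = align_family(copies, ref)
        assert len(aligned) == 3
        for m in aligned:
            assert m.ref_map == {i: i for i in range(1, len(ref) + 1)}
            assert superpose(m.ca_coords(), ref.ca_coords())[2] < 1e-6

    def test_rotated_member_superposes_back(self, small_family):
        structs, msa, _ = small_family
        ref = structs[0]
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [180, 30, 10], degrees=True).as_matrix()
        moved = structs[1].transformed(rot, np.array([20.0, -3.0, 5.0]))
        pre = float(np.linalg.norm(moved.ca_coords() - ref.ca_coords(), axis=1).mean())
        aligned = align_family([moved], ref, msa=msa)[0]
        post = float(np.linalg.norm(aligned.ca_coords() - ref.ca_coords(), axis=1).mean())
        assert post < pre

    def test_anchor_positions_map_correctly(self, small_family):
        """MSA-driven reference maps place planted anchors at themselves for
        members without indels."""
        structs, msa, truth = small_family
        aligned = align_family(structs, structs[0], msa=msa)
        n_ok = 0
        for m in aligned:
            inv = m.inv_ref_map()
            n_ok += all(p in inv for p in truth.anchors)
        assert n_ok >= 0.95 * len(aligned)


class TestConservationProfile:
    def test_identical_structures_profile_is_zero(self, small_family):
        structs, _, _ = small_family
        ref = structs[0]
        twins = []
        for i in range(3):
            t = copy.deepcopy(ref)
            t.id = f"t{i}"
            t.ref_map = {j: j for j in range(1, len(ref) + 1)}
            twins.append(t)
        prof = conservation_profile(twins, len(ref))
        assert np.nanmax(prof.mean_dev) < 1e-9
        assert np.all(prof.coverage == 1.0)

    def test_outlier_raises_deviation_everywhere(self, small_family):
        structs, _, _ = small_family
        ref = structs[0]
        twins = []
        for i in range(4):
            t = copy.deepcopy(ref)
            t.id = f"t{i}"
            t.ref_map = {j: j for j in range(1, len(ref) + 1)}
            twins.append(t)
        base = conservation_profile(twins, len(ref)).mean_dev
        outlier = copy.deepcopy(ref)
        outlier.id = "out"
        outlier.ref_map = {j: j for j in range(1, len(ref) + 1)}
        for r in outlier.residues:
            r.coords = {k: v + np.array([1.0, 1.0, 0.0]) for k, v in r.coords.items()}
        bumped = conservation_profile(twins + [outlier], len(ref)).mean_dev
        assert np.all(bumped > base - 1e-12)
        assert np.nanmean(bumped) > np.nanmean(base)

    def test_member_order_invariance(self, small_family):
        structs, msa, _ = small_family
        aligned = align_family(structs, structs[0], msa=msa)
        a = conservation_profile(aligned, len(structs[0])).mean_dev
        b = conservation_profile(aligned[::-1], len(structs[0])).mean_dev
        assert np.allclose(a, b, equal_nan=True)

    def test_needs_two_members(self, small_family):
        structs, _, _ = small_family
        with pytest.raises(ValueError):
            conservation_profile(structs[:1], len(structs[0]))


class TestProposeBoundaries:
    def test_cuts_at_strict_minima(self):
        dev = np.full(30, 2.0)
        dev[[5, 15, 25]] = 0.1
        prof = ConservationProfile(np.arange(1, 31), dev, np.ones(30))
        scheme = propose_boundaries(prof, [(3, 8), (13, 18), (23, 28)])
        starts = [s.ranges[0][0] for s in scheme.segments]
        assert starts == [6, 16, 26]

    def test_ties_resolve_to_lowermost_position(self):
        dev = np.full(20, 1.0)
        prof = ConservationProfile(np.arange(1, 21), dev, np.ones(20))
        scheme = propose_boundaries(prof, [(4, 8), (12, 16)])
        assert [s.ranges[0][0] for s in scheme.segments] == [4, 12]

    def test_too_many_requested_segments(self):
        prof = ConservationProfile(np.arange(1, 11), np.ones(10), np.ones(10))
        with pytest.raises(ValueError):
            propose_boundaries(prof, [(2, 4)], n_segments=3)

    def test_grouping_builds_discontinuous_segments(self):
        dev = np.full(40, 2.0)
        dev[[5, 15, 25, 35]] = 0.1
        prof = ConservationProfile(np.arange(1, 41), dev, np.ones(40))
        scheme = propose_boundaries(
            prof, [(3, 8), (13, 18), (23, 28), (33, 38)], groups=[[0, 2]]
        )
        grp = next(s for s in scheme.segments if len(s.ranges) == 2)
        assert grp.ranges == [(6, 15), (26, 35)]
        scheme.validate()

    def test_curated_barrel_scheme_parses(self, tmp_path):
        """A user scheme file with four beta-alpha units (135-169, 171-195,
        197-217, 219-254 in reference numbering) and six fixed metal-binding
        positions loads into 4 sampled segments plus a constant region."""
        doc = {
            "reference_id": "lyase_ref",
            "segments": [
                {"name": "unit4", "ranges": [[135, 169]]},
                {"name": "unit5", "ranges": [[171, 195]]},
                {"name": "unit6", "ranges": [[197, 217]]},
                {"name": "unit7", "ranges": [[219, 254]]},
            ],
            "constant_ranges": [[1, 134], [170, 170], [196, 196], [218, 218], [255, 290]],
            "catalytic": [
                {"position": p, "aa": a}
                for p, a in [(22, "K"), (24, "K"), (137, "E"), (170, "D"), (199, "H"), (256, "D")]
            ],
        }
        path = tmp_path / "scheme.yaml"
        path.write_text(yaml.safe_dump(doc))
        scheme = SegmentationScheme.load(path)
        assert len(scheme.segments) == 4
        assert scheme.segments[0].ranges == [(135, 169)]
        assert len(scheme.catalytic) == 6
        sampled = scheme.sampled_positions()
        assert 170 not in sampled and 196 not in sampled and 218 not in sampled

    def test_malformed_scheme_is_value_error(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump({"segments": [{"name": "a"}]}))
        with pytest.raises(ValueError):
            SegmentationScheme.load(path)

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            SegmentationScheme(
                "r", [Segment("a", [(1, 10)]), Segment("b", [(10, 20)])]
            ).validate()


class TestBuildPssm:
    def test_single_sequence_hand_computed_score(self):
        """One 'A' with uniform background and pseudocount 1:
        score = log2(((1 + 0.05) / 2) / 0.05) = log2(10.5) ~ 3.392 bits."""
        pssm = build_pssm(["A"])
        assert pssm.score(0, "A") == pytest.approx(math.log2(10.5), abs=1e-9)
        # absent identity: log2(((0 + 0.05) / 2) / 0.05) = -1
        assert pssm.score(0, "W") == pytest.approx(-1.0, abs=1e-9)

    def test_uniform_column_tends_to_zero(self):
        for n in (1, 5, 50):
            pssm = build_pssm([aa for aa in AA1] * n)
            col = pssm.scores[0]
            assert np.allclose(col, col[0])
        wide = build_pssm([aa for aa in AA1] * 500).scores[0]
        assert np.all(np.abs(wide) < 0.01)

    def test_score_monotone_in_count(self):
        prev = -np.inf
        for k in range(1, 6):
            seqs = ["A"] * k + ["C"] * 5
            s = build_pssm(seqs).score(0, "A")
            assert s > prev
            prev = s

    def test_normalization_identity(self):
        """Sum over aa of background * 2^score is exactly 1 for any column."""
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list(AA1), 7)) for _ in range(9)]
        pssm = build_pssm(seqs, pseudocount=1.7)
        total = (pssm.background[None, :] * np.exp2(pssm.scores)).sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            build_pssm([])
        with pytest.raises(ValueError):
            build_pssm(["AA", "A"])
        with pytest.raises(ValueError):
            build_pssm(["A"], pseudocount=0.0)


class TestExtractFragments:
    def test_identical_family_shares_every_sequence(self, small_family):
        structs, _, _ = small_family
        ref = structs[0]
        twins = []
        for i in range(4):
            t = copy.deepcopy(ref)
            t.id = f"tw{i}"
            twins.append(t)
        aligned = align_family(twins + [copy.deepcopy(ref)], ref)
        scheme = SegmentationScheme(ref.id, [Segment("s1", [(8, 20)]), Segment("s2", [(25, 40)])])
        db = extract_fragments(aligned, ref, scheme)
        for frs in db.fragments.values():
            assert len(frs) == 5
            for f in frs:
                assert fragment_rmsd(f, frs[0]) < 1e-9
                # every PSSM column is built from all five (identical) sequences
                expected = build_pssm([f.sequence] * 5)
                assert np.allclose(f.pssm_slice.scores, expected.scores)

    def test_conformation_dependent_pssm_uses_own_mode_only(self, small_family, small_db):
        """Fragments in one planted conformational mode get PSSMs built from
        exactly the same-mode members' sequences."""
        structs, _, truth = small_family
        name = "seg1"
        frags = small_db.fragments[name]
        mode_of = {mid: m[name] for mid, m in truth.member_modes.items()}
        for f in frags:
            mates = [g.sequence for g in frags if mode_of[g.source_id] == mode_of[f.source_id]]
            expected = build_pssm(mates)
            assert np.allclose(f.pssm_slice.scores, expected.scores)

    def test_fragment_regenerates_source_segment(self, small_family, small_db):
        """Rebuilding a fragment's torsions at the source's boundary frame
        reproduces the source coordinates exactly."""
        structs, msa, truth = small_family
        aligned = align_family(structs, structs[0], msa=msa)
        m = aligned[2]
        f = next(f for f in small_db.fragments["seg2"] if f.source_id == m.id)
        inv = m.inv_ref_map()
        s, e = f.ranges[0]
        i0, i1 = inv[s], inv[e]
        src = np.array([m.residues[i - 1].atom("CA") for i in range(i0, i1 + 1)])
        rebuilt = from_internal(f.range_residues[0]).ca_coords()
        assert superpose(src, rebuilt)[2] < 1e-9

    def test_serialization_round_trip_is_exact(self, small_db, tmp_path):
        p = tmp_path / "db.jsonl"
        save_db(small_db, p)
        back = load_db(p)
        assert back.segment_names == small_db.segment_names
        for name in small_db.segment_names:
            for a, b in zip(small_db.fragments[name], back.fragments[name]):
                assert a.source_id == b.source_id
                assert a.sequence == b.sequence
                for ra, rb in zip(a.range_residues[0], b.range_residues[0]):
                    for fld in ("phi", "psi", "omega", "d_n_ca", "a_n_ca_c"):
                        va, vb = getattr(ra, fld), getattr(rb, fld)
                        assert (math.isnan(va) and math.isnan(vb)) or va == vb
                assert np.array_equal(a.pssm_slice.scores, b.pssm_slice.scores)
        assert np.array_equal(back.anchor, small_db.anchor)

    def test_segment_with_no_fragments_errors(self, small_family):
        structs, msa, _ = small_family
        ref = structs[0]
        aligned = align_family(structs, ref, msa=msa)
        scheme = SegmentationScheme(ref.id, [Segment("ghost", [(900, 950)])])
        with pytest.raises(ValueError):
            extract_fragments(aligned, ref, scheme)
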