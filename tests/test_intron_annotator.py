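import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from guildnet import iupac
from guildnet._fold import fold_hairpin
from guildnet.intron_annotator import (
    AMBIGUOUS,
    BIPARTITE_TYPE,
    CLASS1,
    CLASS2,
    TRIPARTITE_TYPE,
    UNCLASSIFIED,
    IntronAnnotation,
    annotate_intron,
    classify_lineage,
    decompose_repeats,
    detect_signatures,
    locate_regions,
)
from ._oracles import exhaustive_max_pairs, exhaustive_tiling_max_repeats


class TestFoldHairpin:
    def test_simple_hairpin(self):
        f = fold_hairpin("GGGAAAACCC")
        assert f.n_pairs == 3
        assert f.loop == (3, 7)  # AAAA
        assert f.stem_length == 3

    def test_unpairable_sequence(self):
        f = fold_hairpin("AAAAAAAAAA")
        assert f.n_pairs == 0
        assert f.loop == (0, 10)

    def test_planted_perfect_stem(self):
        arm = "GCAGUCGGAAGC".replace("U", "T")  # 12 nt
        seq = arm + "AATCTTA" + iupac.revcomp(arm)
        f = fold_hairpin(seq)
        assert f.stem_length == 12
        assert f.loop == (12, 19)
        assert f.n_pairs == exhaustive_max_pairs(seq)

    def test_too_short_region_is_error(self):
        with pytest.raises(ValueError, match="short"):
            fold_hairpin("GGGAAACCC")

    def test_structure_validity_random(self):
        """Pairs are nested, WC/wobble only, hairpin loops >= 3."""
        from guildnet._fold import can_pair

        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(10, 40))
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
            f = fold_hairpin(seq)
            for i, j in f.pairing:
                assert can_pair(seq[i], seq[j])
                assert j - i > 3
            for (i1, j1) in f.pairing:
                for (i2, j2) in f.pairing:
                    if i1 < i2:  # nested or disjoint, never crossing
                        assert i2 > j1 or j2 < j1

    def test_matches_exhaustive_enumeration_short_regions(self):
        rng = np.random.default_rng(42)
        for _ in range(100)[:100]:
            n = int(rng.integers(10, 21))
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
            assert fold_hairpin(seq).n_pairs == exhaustive_max_pairs(seq)


class TestLocateRegions:
    def test_planted_intervals(self, default_dataset, profile):
        truth = default_dataset.truth
        for key in ("bi0_g0", "y0_g0", "x0_g0"):
            seq = truth.intron_genotypes[key]["sequence"]
            loc = locate_regions(seq, profile)
            # P5b: anchored after CORE5 (56 nt) + 8 nt flank, 16 nt stem loop
            assert loc.p5b_interval == (64, 80)
            a = seq.find(profile.p6b_flank5)
            b = seq.find(profile.p6b_flank3)
            assert loc.p6b_interval == (a + 8, b)
            assert len(loc.p6b_central_loop) == 7

    def test_missing_anchors_degrade_gracefully(self, profile):
        seq = "ACGT" * 60
        ann = annotate_intron(seq, "x", profile)
        assert ann.p6b_interval is None
        assert ann.repeat_class == UNCLASSIFIED
        assert ann.lineage_call == AMBIGUOUS

    def test_p5b_location_unaffected_by_p6b_length(self, default_dataset, profile):
        """Edits confined to P6b leave the P5b interval unchanged."""
        gts = default_dataset.truth.intron_genotypes
        locs = [locate_regions(gts[k]["sequence"], profile) for k in ("bi0_g0", "bi0_g1")]
        assert locs[0].p5b_interval == locs[1].p5b_interval


class TestDecomposeRepeats:
    def test_exact_consensus_copies(self, profile):
        unit = "ACCTAAC"  # Class 1 consensus, Y resolved to C
        reps, indels, klass = decompose_repeats(unit * 5, profile)
        assert len(reps) == 5 and not indels and klass == CLASS1
        assert all(r.score == 7 for r in reps)

    def test_foreign_insert_recovered(self, profile):
        insert = "GATCGGCAA"  # 9 nt catalogue element
        seq = "ACCTAAC" * 2 + insert + "ACCTAAT" * 2
        reps, indels, klass = decompose_repeats(seq, profile)
        assert len(reps) == 4
        assert [e.seq for e in indels] == [insert]
        assert indels[0].tag == "*"
        # optimal segmentation check: no tiling fits more repeat units
        def scorer(w):
            from guildnet.intron_annotator import _unit_score
            return _unit_score(w, profile)[0]
        assert len(reps) == exhaustive_tiling_max_repeats(
            seq, scorer, profile.repeat_match_threshold)

    def test_all_n_unclassified(self, profile):
        reps, indels, klass = decompose_repeats("N" * 28, profile)
        assert klass == UNCLASSIFIED and not reps

    def test_tiling_conservation(self, default_dataset, default_annotations):
        """|P6b| = 7 * repeats + sum of indel lengths + central loop."""
        checked = 0
        for ann in default_annotations.values():
            if ann.p6b_interval is None:
                continue
            p6b_len = ann.p6b_interval[1] - ann.p6b_interval[0]
            tiled = (7 * ann.n_repeats
                     + sum(len(e.seq) for e in ann.indel_elements)
                     + len(ann.p6b_central_loop))
            assert tiled == p6b_len
            checked += 1
        assert checked > 100


class TestSignaturesAndLineage:
    def _ann(self, loop, repeat_class=CLASS1):
        a = IntronAnnotation(seq_id="t", intron_length=300,
                             p6b_interval=(0, 10), p6b_central_loop=loop,
                             repeat_class=repeat_class)
        return a

    def test_3t_position_is_loop_relative(self, profile):
        a = detect_signatures(self._ann("CCTTAAG"), profile, "ACGT" * 20)
        assert a.sig_3T

    @pytest.mark.parametrize(
        "loop,expected", [("AGTCTTA", True), ("AGTCTTC", True), ("AGTCTTG", False)]
    )
    def test_agtcttm_iupac_semantics(self, profile, loop, expected):
        a = detect_signatures(self._ann(loop), profile, "ACGT" * 20)
        assert a.sig_AGTCTTM is expected

    def test_71t_via_anchored_offset(self, profile):
        pre = "A" * 20 + profile.p5b_flank5
        seq = pre + "CTGGTC" + "TGCA" + "ACGT" * 10  # offset 14 -> the T of TGCA
        a = detect_signatures(self._ann("CCCCCCC"), profile, seq)
        assert a.sig_71T
        seq2 = pre + "CTGGTC" + "AGCA" + "ACGT" * 10
        assert not detect_signatures(self._ann("CCCCCCC"), profile, seq2).sig_71T

    def test_lineage_rules(self):
        a = self._ann("CCTCCCC")
        a.sig_3T, a.sig_71T = True, True
        assert classify_lineage(a) == BIPARTITE_TYPE
        b = self._ann("AGTCTTA", repeat_class=CLASS2)
        b.sig_3T, b.sig_AGTCTTM, b.sig_71T = True, True, False
        assert classify_lineage(b) == TRIPARTITE_TYPE
        c = self._ann("CCTCCCC")
        c.sig_3T, c.sig_71T, c.sig_AGTCTTM = True, False, False
        assert classify_lineage(c) == AMBIGUOUS

    def test_rules_mutually_exclusive(self):
        """No signature combination satisfies both lineage rules."""
        import itertools

        for klass, s3, s71, sm in itertools.product(
            [CLASS1, CLASS2, UNCLASSIFIED], *[[True, False]] * 3
        ):
            bi = klass == CLASS1 and s3 and s71
            tri = sm and not s71
            assert not (bi and tri)

    def test_planted_lineages_recovered(self, default_dataset, profile):
        truth = default_dataset.truth
        for key, info in truth.intron_genotypes.items():
            ann = annotate_intron(info["sequence"], key, profile)
            assert ann.lineage_call == info["lineage"], key
            assert ann.repeat_class == info["repeat_class"], key


@settings(max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_fold_matches_oracle_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 21))
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
    assert fold_hairpin(seq).n_pairs == exhaustive_max_pairs(seq)
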