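import numpy as np
import pytest

from nonbscan.nonb_motifs import (
    MOTIF_CLASSES,
    MotifHit,
    MotifRuleSet,
    class_totals,
    combine_likelihoods,
    predict_motifs,
    stars_track,
)
from nonbscan.seqio import Contig, Interval, revcomp


def spans(hits):
    return {(h.interval.start, h.interval.end) for h in hits}


class TestG4:
    def test_canonical_four_runs_of_three(self):
        hits = predict_motifs(Contig("t", "GGGTTAGGGTTAGGGTTAGGG"), "G4")
        assert len(hits) == 1
        h = hits[0]
        assert (h.interval.start, h.interval.end) == (0, 21)
        assert h.interval.strand == "+" and h.stars == 2

    def test_strong_g4_three_stars(self):
        # 5 runs, run length 4, loops <= 3
        seq = "GGGGTAGGGGTAGGGGTAGGGGTAGGGG"
        (hit,) = predict_motifs(Contig("t", seq), "G4")
        assert hit.stars == 3

    def test_long_loop_downgrades(self):
        seq = "GGGTTTTTGGGTTAGGGTTAGGG"  # first loop is 5 > 3
        (hit,) = predict_motifs(Contig("t", seq), "G4")
        assert hit.stars == 2

    def test_no_g_runs(self):
        assert predict_motifs(Contig("t", "ACGT" * 13), "G4") == []

    def test_minus_strand_c_runs(self):
        seq = revcomp("GGGTTAGGGTTAGGGTTAGGG")
        (hit,) = predict_motifs(Contig("t", seq), "G4")
        assert hit.interval.strand == "-"
        assert (hit.interval.start, hit.interval.end) == (0, 21)

    def test_three_runs_insufficient(self):
        assert predict_motifs(Contig("t", "GGGTTAGGGTTAGGG"), "G4") == []

    def test_loop_of_eight_breaks_chain(self):
        seq = "GGGTTAGGGTTAGGGTTTTTTTTGGG"
        assert predict_motifs(Contig("t", seq), "G4") == []


class TestZdna:
    def test_pure_gc(self):
        (hit,) = predict_motifs(Contig("t", "GCGCGCGCGCGC"), "ZDNA")
        assert (hit.interval.start, hit.interval.end) == (0, 12)
        assert hit.stars == 3

    def test_mixed_gt_two_stars(self):
        (hit,) = predict_motifs(Contig("t", "GTGTGTGTGTGTGT"), "ZDNA")
        assert hit.stars == 2

    def test_eleven_bp_too_short(self):
        assert predict_motifs(Contig("t", "GCGCGCGCGCG"), "ZDNA") == []

    def test_at_alternation_excluded(self):
        assert predict_motifs(Contig("t", "ATATATATATATATAT"), "ZDNA") == []


class TestStr:
    def test_at_times_ten(self):
        (hit,) = predict_motifs(Contig("t", "AT" * 10), "STR")
        assert (hit.interval.start, hit.interval.end) == (0, 20)
        assert hit.stars == 3 and "unit=2" in hit.detail

    def test_five_copies_two_stars(self):
        (hit,) = predict_motifs(Contig("t", "CTG" * 5), "STR")
        assert hit.stars == 2 and "copies=5" in hit.detail

    def test_four_copies_rejected(self):
        assert predict_motifs(Contig("t", "ACGT" + "CTGA" * 4), "STR") == []

    def test_short_tract_rejected(self):
        # 7 copies of AT but only 14 bp < 15
        assert predict_motifs(Contig("t", "AT" * 7), "STR") == []

    def test_homopolymer_unit_one(self):
        (hit,) = predict_motifs(Contig("t", "A" * 15), "STR")
        assert "unit=1" in hit.detail

    def test_no_duplicate_at_multiple_of_period(self):
        hits = predict_motifs(Contig("t", "AT" * 10), "STR")
        assert len(hits) == 1

    def test_trailing_partial_copy_included(self):
        (hit,) = predict_motifs(Contig("t", "CTG" * 5 + "CT"), "STR")
        assert hit.interval.end == 17


class TestSlipped:
    def test_direct_repeat_with_spacer(self):
        unit = "ACGTTGCACAGG"
        seq = unit + "TTT" + unit
        (hit,) = predict_motifs(Contig("t", seq), "SLIPPED")
        assert (hit.interval.start, hit.interval.end) == (0, len(seq))
        assert hit.stars == 2

    def test_long_unit_three_stars(self):
        unit = "ACGTTGCACAGGATCGATCGAAC"  # 23 bp
        seq = unit + "TT" + unit
        (hit,) = predict_motifs(Contig("t", seq), "SLIPPED")
        assert hit.stars == 3

    def test_short_unit_rejected(self):
        unit = "ACGTTGCAC"  # 9 bp < 10
        assert predict_motifs(Contig("t", unit + "TTT" + unit), "SLIPPED") == []

    def test_str_not_reported_as_slipped(self):
        assert predict_motifs(Contig("t", "AT" * 20), "SLIPPED") == []


class TestHdna:
    def test_pure_purine_mirror(self):
        arm = "AAGGAGGAGG"
        seq = arm + "AA" + arm[::-1]
        (hit,) = predict_motifs(Contig("t", seq), "HDNA")
        assert (hit.interval.start, hit.interval.end) == (0, len(seq))
        assert hit.stars == 3

    def test_mixed_composition_rejected(self):
        arm = "ACGTACGTAC"
        seq = arm + "TT" + arm[::-1]
        assert predict_motifs(Contig("t", seq), "HDNA") == []

    def test_pyrimidine_mirror(self):
        arm = "CCTTCTTCCT"
        seq = arm + arm[::-1]
        hits = predict_motifs(Contig("t", seq), "HDNA")
        assert spans(hits) == {(0, len(seq))}

    def test_short_arm_rejected(self):
        arm = "AAGGAGGAG"  # 9 bp < 10, flanked so it cannot extend
        assert predict_motifs(Contig("t", "C" + arm + arm[::-1] + "T"), "HDNA") == []


class TestTfo:
    def test_g_rich_purine_tract(self):
        seq = "GGAGGAGGAGGAGGA"  # 15 bp, 9 G
        (hit,) = predict_motifs(Contig("t", seq), "TFO")
        assert (hit.interval.start, hit.interval.end) == (0, 15)
        assert hit.stars == 2

    def test_25bp_three_stars(self):
        seq = "GGAGGAGGAGGAGGAGGAGGAGGAG"
        hits = [h for h in predict_motifs(Contig("t", seq), "TFO") if h.interval.strand == "+"]
        assert hits[0].stars == 3

    def test_low_g_rejected(self):
        seq = "GAAAAGAAAAGAAAA"  # 3/15 G < 50%
        assert predict_motifs(Contig("t", seq), "TFO") == []

    def test_pyrimidine_reported_minus(self):
        seq = revcomp("GGAGGAGGAGGAGGA")
        (hit,) = predict_motifs(Contig("t", seq), "TFO")
        assert hit.interval.strand == "-"


class TestApr:
    def test_three_phased_tracts(self):
        seq = "AAAAA" + "CGTGC" + "AAAAA" + "CGTGC" + "AAAAA"
        (hit,) = predict_motifs(Contig("t", seq), "APR")
        assert (hit.interval.start, hit.interval.end) == (0, len(seq))
        assert hit.stars == 2

    def test_four_tracts_three_stars(self):
        seq = ("AAAAA" + "CGTGC") * 3 + "AAAAA"
        (hit,) = predict_motifs(Contig("t", seq), "APR")
        assert hit.stars == 3

    def test_out_of_phase_rejected(self):
        seq = "AAAAA" + "CGTGCCGT" + "AAAAA" + "CGTGCCGT" + "AAAAA"  # 13 bp apart
        assert predict_motifs(Contig("t", seq), "APR") == []

    def test_t_tracts_on_minus(self):
        seq = revcomp("AAAAA" + "CGTGC" + "AAAAA" + "CGTGC" + "AAAAA")
        (hit,) = predict_motifs(Contig("t", seq), "APR")
        assert hit.interval.strand == "-"


class TestGeneral:
    def test_unknown_class(self):
        with pytest.raises(ValueError):
            predict_motifs(Contig("t", "ACGT"), "IMOTIF")

    def test_invalid_rules(self):
        with pytest.raises(ValueError):
            MotifRuleSet(g4_loop_min=5, g4_loop_max=3)

    def test_n_matches_nothing(self):
        assert predict_motifs(Contig("t", "GGGNNAGGGNNAGGGNNAGGG"), "STR") == []
        assert predict_motifs(Contig("t", "N" * 40), "TFO") == []

    @pytest.mark.parametrize("motif_class", MOTIF_CLASSES)
    def test_strand_symmetry(self, motif_class, random_contig):
        for _ in range(5):
            c = random_contig(400)
            fwd = predict_motifs(c, motif_class)
            rc = Contig(c.id, revcomp(c.seq))
            rev = predict_motifs(rc, motif_class)
            n = c.length
            assert {(n - h.interval.end, n - h.interval.start) for h in fwd} == spans(
                rev
            )


class TestStarsTrack:
    def test_single_hit(self):
        c = Contig("t", "ACGTACGT")
        hit = MotifHit(Interval("t", 2, 5, "+"), "G4", 3)
        assert stars_track(c, [hit], "G4").tolist() == [0, 0, 3, 3, 3, 0, 0, 0]

    def test_within_class_max(self):
        c = Contig("t", "A" * 10)
        hits = [
            MotifHit(Interval("t", 0, 6, "+"), "STR", 2),
            MotifHit(Interval("t", 4, 10, "+"), "STR", 3),
        ]
        track = stars_track(c, hits, "STR")
        assert track[5] == 3 and track[1] == 2

    def test_no_hits_zero(self):
        c = Contig("t", "ACGT")
        assert stars_track(c, [], "G4").sum() == 0

    def test_class_mismatch(self):
        c = Contig("t", "ACGT")
        hit = MotifHit(Interval("t", 0, 2, "+"), "STR", 2)
        with pytest.raises(ValueError):
            stars_track(c, [hit], "G4")


class TestCombine:
    def test_cross_class_sum(self):
        tracks = {cls: np.zeros(4, dtype=int) for cls in MOTIF_CLASSES}
        tracks["G4"][1] = 3
        tracks["STR"][1] = 2
        combined = combine_likelihoods(tracks)
        assert combined[1] == 5 and combined[0] == 0

    def test_upper_bound_21(self):
        tracks = {cls: np.full(4, 3) for cls in MOTIF_CLASSES}
        assert combine_likelihoods(tracks).max() == 21

    def test_ge_each_track(self, random_contig):
        from nonbscan.nonb_motifs import predict_all

        c = random_contig(600)
        tracks = {
            cls: stars_track(c, hits, cls) for cls, hits in predict_all(c).items()
        }
        combined = combine_likelihoods(tracks)
        for t in tracks.values():
            assert np.all(combined >= t)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            combine_likelihoods({"G4": np.zeros(3), "STR": np.zeros(4)})


class TestClassTotals:
    def test_single_class(self):
        hits = {"G4": [MotifHit(Interval("t", 0, 21, "+"), "G4", 2)]}
        totals = class_totals(hits)
        assert totals["G4"]["bp"] == 21 and totals["G4"]["fraction"] == 1.0

    def test_union_not_sum(self):
        hits = {
            "STR": [
                MotifHit(Interval("t", 0, 20, "+"), "STR", 2),
                MotifHit(Interval("t", 10, 30, "+"), "STR", 2),
            ]
        }
        assert class_totals(hits)["STR"]["bp"] == 30

    def test_empty_flagged(self):
        totals = class_totals({})
        assert all(v["bp"] == 0 and v["undefined"] for v in totals.values())


class TestFalsePositiveBaseline:
    def test_random_background_rate_pinned(self):
        """Regression pin: chance hits per 10 kb of 50% GC background."""
        rng = np.random.default_rng(123)
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        c = Contig("t", seq)
        per_10kb = {
            cls: len(predict_motifs(c, cls)) / 5 for cls in MOTIF_CLASSES
        }
        # generous regression bounds; uniform background should be quiet
        assert per_10kb["G4"] <= 5
        assert per_10kb["ZDNA"] <= 5
        assert per_10kb["STR"] <= 5
        assert per_10kb["SLIPPED"] <= 5
        assert per_10kb["HDNA"] <= 10
        assert per_10kb["TFO"] <= 10
        assert per_10kb["APR"] <= 10
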