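"""Peak parsing, bead-grid arithmetic, mark/CTCF/promoter annotation."""

import numpy as np
import pytest

from toposim.annotation import (
    BeadTrack,
    CTCFOutcomes,
    GenomeFragment,
    MotifHit,
    PeakRecord,
    annotate_marks,
    annotate_promoters,
    call_ctcf_beads,
    export_track_beds,
    parse_peak_file,
    sample_ctcf_activation,
)


# -- parsing ----------------------------------------------------------------


def test_parse_bed3_minimal(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t1000\t2000\n")
    recs = parse_peak_file(p, "bed")
    assert recs == [PeakRecord("chr1", 1000, 2000, score=0.0)]


def test_parse_narrowpeak_signal_value(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text("chr1\t100\t900\tpk1\t0\t+\t14.2\t-1\t-1\t400\n")
    recs = parse_peak_file(p, "narrowPeak")
    assert recs[0].score == 14.2
    assert recs[0].strand == "+"
    assert recs[0].name == "pk1"


def test_parse_empty_and_comments(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("# comment\ntrack name=x\n\n")
    assert parse_peak_file(p, "bed") == []


def test_parse_malformed_line_names_lineno(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\nchr1\tnotanumber\t300\n")
    with pytest.raises(ValueError, match="line 2"):
        parse_peak_file(p, "bed")


def test_parse_unknown_dialect(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t1\t2\n")
    with pytest.raises(ValueError, match="dialect"):
        parse_peak_file(p, "gff")


def test_parse_sorted_output(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr2\t10\t20\nchr1\t500\t600\nchr1\t100\t200\n")
    recs = parse_peak_file(p, "bed")
    assert [(r.chrom, r.start) for r in recs] == [
        ("chr1", 100), ("chr1", 500), ("chr2", 10)]


# -- bead grid --------------------------------------------------------------


def test_bead_coordinate_round_trip(fragment):
    for bead in [0, 1, 17, fragment.n_beads - 1]:
        lo, hi = fragment.interval_of(bead)
        assert fragment.bead_of(lo) == bead
        assert fragment.bead_of(hi - 1) == bead
    with pytest.raises(ValueError):
        fragment.bead_of(fragment.end)
    with pytest.raises(ValueError):
        fragment.interval_of(fragment.n_beads)


def test_fragment_validation():
    with pytest.raises(ValueError):
        GenomeFragment("chr1", 100, 100)
    with pytest.raises(ValueError):
        GenomeFragment("chr1", 0, 5_000)  # < 10 beads


# -- marks ------------------------------------------------------------------


def test_annotate_single_peak_flags_overlapping_bead(fragment):
    track = annotate_marks(fragment, {"atac": [PeakRecord("chrT", 1500, 1600)]})
    assert track.mark_flags("atac").sum() == 1
    assert track.mark_flags("atac")[1]


def test_annotate_spanning_peak_flags_all_touched_beads(fragment):
    track = annotate_marks(fragment, {"h3k27ac": [PeakRecord("chrT", 900, 2100)]})
    assert list(np.flatnonzero(track.mark_flags("h3k27ac"))) == [0, 1, 2]


def test_annotate_no_peaks_all_false(fragment):
    track = annotate_marks(fragment, {"atac": []})
    assert not track.mark_flags("atac").any()


def test_annotate_unknown_assay(fragment):
    with pytest.raises(ValueError):
        annotate_marks(fragment, {"h3k4me1": []})


def test_annotation_order_independent_and_idempotent(fragment, rng):
    peaks = [PeakRecord("chrT", int(s), int(s) + 700)
             for s in rng.integers(0, 590_000, 40)]
    t1 = annotate_marks(fragment, {"atac": peaks})
    t2 = annotate_marks(fragment, {"atac": peaks[::-1]})
    t3 = annotate_marks(fragment, {"atac": peaks + peaks})
    assert (t1.mark_flags("atac") == t2.mark_flags("atac")).all()
    assert (t1.mark_flags("atac") == t3.mark_flags("atac")).all()


def test_bed_export_reannotation_round_trip(fragment, rng, tmp_path):
    peaks = {
        "atac": [PeakRecord("chrT", int(s), int(s) + 1500)
                 for s in rng.integers(0, 590_000, 25)],
        "h3k27me3": [PeakRecord("chrT", 40_000, 90_000)],
    }
    track = annotate_marks(fragment, peaks)
    paths = export_track_beds(track, tmp_path)
    re_peaks = {assay: parse_peak_file(path, "bed") for assay, path in paths.items()}
    track2 = annotate_marks(fragment, re_peaks)
    for assay in paths:
        assert (track.mark_flags(assay) == track2.mark_flags(assay)).all()


# -- CTCF -------------------------------------------------------------------


def _ctcf_setup(fragment, motif_strand="+", motif_scores=(15.0,),
                rad21_overlap=True):
    peak = PeakRecord("chrT", 100_000, 100_800, score=10.0, name="pk")
    rad_start = 100_400 if rad21_overlap else 200_000
    rad21 = [PeakRecord("chrT", rad_start, rad_start + 800, score=5.0)]
    hits = []
    strands = ["+", "-"] if motif_strand == "both" else [motif_strand]
    for strand, score in zip(strands * len(motif_scores), motif_scores):
        hits.append(MotifHit("chrT", 100_300, 100_319, strand, score, "pk"))
    return [peak], rad21, hits


def test_ctcf_forward_motif_gives_forward_bead(fragment):
    peaks, rad21, hits = _ctcf_setup(fragment)
    track = call_ctcf_beads(fragment, peaks, rad21, hits)
    assert track.ctcf[100].probs == {"forward": 1.0}


def test_ctcf_requires_rad21_overlap(fragment):
    peaks, rad21, hits = _ctcf_setup(fragment, rad21_overlap=False)
    track = call_ctcf_beads(fragment, peaks, rad21, hits)
    assert track.ctcf == {}


def test_ctcf_requires_motif(fragment):
    peaks, rad21, _ = _ctcf_setup(fragment)
    track = call_ctcf_beads(fragment, peaks, rad21, [])
    assert track.ctcf == {}


def test_ctcf_opposite_equal_scores_bidirectional(fragment):
    peak = PeakRecord("chrT", 100_000, 100_800, score=10.0, name="pk")
    rad21 = [PeakRecord("chrT", 100_100, 100_900)]
    hits = [MotifHit("chrT", 100_300, 100_319, "+", 15.0, "pk"),
            MotifHit("chrT", 100_400, 100_419, "-", 15.0, "pk")]
    track = call_ctcf_beads(fragment, [peak], rad21, hits)
    assert list(track.ctcf[100].probs) == ["bidirectional"]


def test_ctcf_clearly_stronger_reverse_motif_wins(fragment):
    peak = PeakRecord("chrT", 100_000, 100_800, score=10.0, name="pk")
    rad21 = [PeakRecord("chrT", 100_100, 100_900)]
    hits = [MotifHit("chrT", 100_300, 100_319, "+", 8.0, "pk"),
            MotifHit("chrT", 100_400, 100_419, "-", 15.0, "pk")]
    track = call_ctcf_beads(fragment, [peak], rad21, hits)
    assert list(track.ctcf[100].probs) == ["backward"]


def test_ctcf_activation_proportional_to_score(fragment):
    peaks = [PeakRecord("chrT", 100_000, 100_500, score=20.0, name="a"),
             PeakRecord("chrT", 200_000, 200_500, score=5.0, name="b")]
    rad21 = [PeakRecord("chrT", 100_000, 100_500),
             PeakRecord("chrT", 200_000, 200_500)]
    hits = [MotifHit("chrT", 100_100, 100_119, "+", 9.0, "a"),
            MotifHit("chrT", 200_100, 200_119, "-", 9.0, "b")]
    track = call_ctcf_beads(fragment, peaks, rad21, hits)
    assert track.ctcf[100].p_active == pytest.approx(1.0)
    assert track.ctcf[200].p_active == pytest.approx(0.25)


def test_ctcf_motif_outside_peak_warns_and_skips(fragment):
    peak = PeakRecord("chrT", 100_000, 100_800, score=10.0, name="pk")
    rad21 = [PeakRecord("chrT", 100_100, 100_900)]
    hits = [MotifHit("chrT", 99_000, 99_019, "+", 9.0, "pk")]
    with pytest.warns(UserWarning, match="outside peak"):
        track = call_ctcf_beads(fragment, [peak], rad21, hits)
    assert track.ctcf == {}


def test_ctcf_multiple_peaks_one_bead_enumerates_outcomes(fragment):
    peaks = [PeakRecord("chrT", 100_000, 100_400, score=20.0, name="f"),
             PeakRecord("chrT", 100_500, 100_900, score=10.0, name="r")]
    rad21 = [PeakRecord("chrT", 100_000, 101_000)]
    hits = [MotifHit("chrT", 100_100, 100_119, "+", 9.0, "f"),
            MotifHit("chrT", 100_600, 100_619, "-", 9.0, "r")]
    track = call_ctcf_beads(fragment, peaks, rad21, hits)
    probs = track.ctcf[100].probs
    # forward active w.p. 1.0, backward w.p. 0.5 -> both=bidirectional
    assert probs["bidirectional"] == pytest.approx(0.5)
    assert probs["forward"] == pytest.approx(0.5)
    assert "backward" not in probs
    assert track.ctcf[100].p_active <= 1.0 + 1e-12


def test_sample_activation_deterministic_extremes(fragment):
    track = BeadTrack(fragment)
    track.ctcf[10] = CTCFOutcomes({"forward": 1.0})
    track.ctcf[20] = CTCFOutcomes({"backward": 0.0})
    for seed in range(5):
        b = sample_ctcf_activation(track, seed)
        assert b.get(10) == "forward"
        assert 20 not in b


def test_sample_activation_binomial_fraction(fragment):
    track = BeadTrack(fragment)
    track.ctcf[10] = CTCFOutcomes({"forward": 0.5})
    rng = np.random.default_rng(42)
    hits = sum(10 in sample_ctcf_activation(track, rng) for _ in range(10_000))
    assert hits / 10_000 == pytest.approx(0.5, abs=0.02)


def test_sample_activation_reproducible(fragment):
    track = BeadTrack(fragment)
    for b in range(0, 100, 7):
        track.ctcf[b] = CTCFOutcomes({"forward": 0.3, "backward": 0.3})
    assert sample_ctcf_activation(track, 7) == sample_ctcf_activation(track, 7)


# -- promoters --------------------------------------------------------------


def test_promoter_midpoint_bead(fragment):
    track = annotate_promoters(fragment, [("g1", "chrT", 4500, 5500)])
    assert track.promoters == {"g1": 5}


def test_promoter_outside_fragment_dropped(fragment):
    with pytest.warns(UserWarning, match="outside fragment"):
        track = annotate_promoters(fragment, [("g1", "chrT", 700_000, 701_000)])
    assert track.promoters == {}


def test_two_genes_two_entries(fragment):
    track = annotate_promoters(
        fragment, [("g1", "chrT", 1000, 2000), ("g2", "chrT", 50_000, 51_000)])
    assert len(track.promoters) == 2


def test_duplicate_gene_errors(fragment):
    with pytest.raises(ValueError, match="duplicate"):
        annotate_promoters(
            fragment, [("g1", "chrT", 1000, 2000), ("g1", "chrT", 9000, 9900)])


def test_type_codes_bitmask(fragment):
    track = annotate_marks(fragment, {
        "atac": [PeakRecord("chrT", 0, 1000)],
        "h3k27ac": [PeakRecord("chrT", 0, 1000), PeakRecord("chrT", 2000, 3000)],
    })
    codes = track.type_codes()
    assert codes[0] == 3      # atac | h3k27ac
    assert codes[1] == 0
    assert codes[2] == 2      # h3k27ac only
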