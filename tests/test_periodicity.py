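import numpy as np
import pandas as pd
import pytest

from riboutr.annotation_io import TranscriptSequence
from riboutr.periodicity import (FrameStats, PSiteTrack, assign_psites,
                                 binomial_frame_pvalue, frame_stats,
                                 length_histogram, periodicity_pass)
from riboutr.synthetic_data import generate_genome, simulate_ribo
from tests.conftest import small_config


def _track(rows, sample="s"):
    df = pd.DataFrame(rows, columns=["chrom", "position", "strand",
                                     "read_length", "count"])
    return PSiteTrack.from_frame(sample, df)


def _tseq(length=60):
    return TranscriptSequence("t", "A" * length, np.arange(length))


class TestLengthHistogram:
    def test_exact_bins(self):
        t = _track([("c", i, "+", 28, 10) for i in range(1)]
                   + [("c", 5, "+", 29, 5)])
        h = length_histogram(t)
        assert h.counts == {28: 10, 29: 5}
        assert h.fraction_25_33 == 1.0

    def test_empty_track(self):
        h = length_histogram(PSiteTrack.empty("s"))
        assert h.counts == {} and h.available

    def test_missing_lengths_marked_unavailable(self):
        t = _track([("c", 1, "+", -1, 3)])
        h = length_histogram(t)
        assert not h.available and h.counts == {}

    def test_default_simulation_mass_in_25_33(self, default_run):
        stage = default_run.config.stage_names[0]
        h = length_histogram(default_run.stage_tracks[stage])
        assert h.fraction_25_33 >= 0.95


class TestFrameStats:
    def test_all_frame_zero_gives_tiny_pvalue(self):
        rows = [("c", 3 * i, "+", 28, 1) for i in range(30)]
        fs = frame_stats(_track(rows), _tseq(96), (0, 96), "c", "+")
        assert fs.n0 == 30 and fs.f0 == 1.0
        assert fs.pvalue == pytest.approx((1 / 3) ** 30, rel=1e-9)
        assert fs.pvalue < 1e-14

    def test_uniform_frames_are_not_significant(self):
        rows = []
        for i in range(10):
            for f in range(3):
                rows.append(("c", 3 * i + f, "+", 28, 1))
        fs = frame_stats(_track(rows), _tseq(), (0, 30), "c", "+")
        assert fs.f0 == pytest.approx(1 / 3)
        assert fs.pvalue > 0.4

    def test_empty_region_has_no_pvalue(self):
        fs = frame_stats(PSiteTrack.empty("s"), _tseq(), (0, 30), "c", "+")
        assert fs.n == 0 and fs.pvalue is None

    def test_fully_masked_region(self):
        rows = [("c", i, "+", 28, 1) for i in range(30)]
        fs = frame_stats(_track(rows), _tseq(), (0, 30), "c", "+",
                         mask=[(0, 30)])
        assert fs.n == 0 and fs.pvalue is None

    def test_mask_drops_overlapping_codons_only(self):
        rows = [("c", i, "+", 28, 1) for i in range(30)]
        fs = frame_stats(_track(rows), _tseq(), (0, 30), "c", "+",
                         mask=[(4, 8)])  # codons 1 and 2
        assert fs.n == 30 - 6

    def test_agrees_with_per_position_tally(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 60, size=200)
        rows = [("c", int(p), "+", 28, 1) for p in pos]
        fs = frame_stats(_track(rows), _tseq(), (0, 60), "c", "+")
        brute = np.zeros(3, dtype=int)
        for p in pos:
            brute[p % 3] += 1
        assert (fs.n0, fs.n1, fs.n2) == tuple(brute)

    def test_frame_is_relative_to_region_start(self):
        rows = [("c", 10, "+", 28, 7)]
        fs = frame_stats(_track(rows), _tseq(), (4, 16), "c", "+")
        assert fs.n0 == 7  # position 10 is frame (10-4) % 3 == 0

    def test_non_codon_span_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            frame_stats(PSiteTrack.empty("s"), _tseq(), (0, 31), "c", "+")


class TestPeriodicityPass:
    @pytest.mark.parametrize("n0,n1,n2,expected", [
        (27, 2, 1, True),     # n=30, f0=0.9, p tiny
        (5, 0, 0, False),     # below min_n
        (165, 70, 65, False), # n=300, f0=0.55 < 0.6 despite tiny p
    ])
    def test_threshold_rules(self, n0, n1, n2, expected):
        n = n0 + n1 + n2
        p = float(binomial_frame_pvalue(n0, n)) if n else None
        fs = FrameStats("r", n0, n1, n2, p)
        assert periodicity_pass(fs) is expected


class TestAssignPsites:
    def test_single_length_fixed_offset(self):
        # 60 coding transcripts, every 5' end exactly 12 nt upstream of start
        from riboutr.annotation_io import AnnotationSet, Gene, Transcript
        genes, txs, rows = {}, {}, []
        for i in range(60):
            g0 = 1000 * i + 100
            gid = f"g{i}"
            genes[gid] = Gene(gid, "c", "+", g0, g0 + 300)
            txs[f"{gid}.t"] = Transcript(f"{gid}.t", gid, "c", "+",
                                         exons=[(g0, g0 + 300)],
                                         cds=[(g0 + 90, g0 + 240)])
            rows.append(("c", g0 + 90 - 12, "+", 28, 2))
        annot = AnnotationSet({"c": 100000}, genes, txs)
        track, table = assign_psites(_track(rows), annot)
        assert table.set_index("read_length").loc[28, "offset"] == 12
        assert not table.set_index("read_length").loc[28, "fallback"]

    def test_missing_length_falls_back_to_default(self):
        from riboutr.annotation_io import AnnotationSet, Gene, Transcript
        genes, txs, rows = {}, {}, []
        for i in range(30):
            g0 = 1000 * i + 100
            gid = f"g{i}"
            genes[gid] = Gene(gid, "c", "+", g0, g0 + 300)
            txs[f"{gid}.t"] = Transcript(f"{gid}.t", gid, "c", "+",
                                         exons=[(g0, g0 + 300)],
                                         cds=[(g0 + 90, g0 + 240)])
            rows.append(("c", g0 + 90 - 12, "+", 28, 3))
        rows.append(("c", 150, "+", 33, 1))  # single read of length 33
        annot = AnnotationSet({"c": 100000}, genes, txs)
        track, table = assign_psites(_track(rows), annot)
        t = table.set_index("read_length")
        assert t.loc[33, "offset"] == 12 and bool(t.loc[33, "fallback"])

    def test_too_few_coding_transcripts_rejected(self):
        from riboutr.annotation_io import AnnotationSet, Gene, Transcript
        annot = AnnotationSet({"c": 1000},
                              {"g": Gene("g", "c", "+", 0, 100)},
                              {"t": Transcript("t", "g", "c", "+",
                                               exons=[(0, 100)],
                                               cds=[(10, 70)])})
        with pytest.raises(ValueError, match="coding transcripts"):
            assign_psites(_track([("c", 5, "+", 28, 1)]), annot)

    def test_round_trip_through_simulator(self):
        cfg = small_config(seed=3, n_genes=100, n_five=30, n_three=30, n_nc=30)
        genome, annot, truth = generate_genome(cfg)
        direct = simulate_ribo(cfg, annot, genome, truth)
        raw = simulate_ribo(cfg, annot, genome, truth, raw_placements=True)
        key = (cfg.stage_names[5], "rep1")
        rec, table = assign_psites(raw[key], annot)
        assert (table.loc[table["n_reads"] >= 50, "offset"] == 12).all()
        d = direct[key].frame.sort_values(
            ["chrom", "position", "strand", "read_length"]).reset_index(drop=True)
        r = rec.frame.sort_values(
            ["chrom", "position", "strand", "read_length"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(d, r)
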