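import io

import numpy as np
import pytest

from riboutr import annotation_io as aio
from riboutr.orf_discovery import enumerate_orfs
from riboutr.synthetic_data import (SimulationConfig, generate_genome,
                                    simulate_rna, simulate_ribo,
                                    simulate_variation_pair)
from tests.conftest import small_config


def _fasta_bytes(genome):
    buf = io.StringIO()
    for name in genome:
        buf.write(f">{name}\n{genome[name]}\n")
    return buf.getvalue()


class TestGenerateGenome:
    def test_same_seed_is_byte_identical(self, tmp_path):
        out = []
        for run in range(2):
            cfg = small_config(seed=5)
            genome, annot, truth = generate_genome(cfg)
            fa = tmp_path / f"g{run}.fa"
            gff = tmp_path / f"a{run}.gff3"
            aio.write_fasta(genome, str(fa))
            aio.write_gff3(annot, str(gff))
            out.append((fa.read_bytes(), gff.read_bytes()))
        assert out[0] == out[1]

    def test_no_planted_orfs_leaves_only_morf_candidates(self):
        cfg = small_config(seed=2, n_five=0, n_three=0, n_nc=0)
        genome, annot, truth = generate_genome(cfg)
        assert len(truth.orfs) == 0
        for tid, t in annot.transcripts.items():
            seq = aio.spliced_sequence(annot, genome, tid).seq
            spans = enumerate_orfs(seq, min_codons=2)
            utr5 = sum(e - s for s, e in t.utr5)
            assert spans == [(utr5, utr5 + t.cds_length)]

    def test_planted_three_prime_orf_stop_is_in_annotated_3utr(self, small_sim):
        cfg, genome, annot, truth = small_sim
        three = truth.orfs[truth.orfs["category"] == "three_prime_ORF"]
        assert len(three) > 0
        for _, row in three.iterrows():
            t = annot.transcripts[row["transcript_id"]]
            utr5 = sum(e - s for s, e in t.utr5)
            utr3_start = utr5 + t.cds_length
            assert row["tx_end"] - 3 >= utr3_start
            assert row["tx_end"] <= t.spliced_length

    def test_planted_orfs_begin_with_aug_and_end_with_stop(self, small_sim):
        cfg, genome, annot, truth = small_sim
        for _, row in truth.orfs.iterrows():
            seq = aio.spliced_sequence(annot, genome,
                                       row["transcript_id"]).seq
            s, e = int(row["tx_start"]), int(row["tx_end"])
            assert seq[s:s + 3] == "ATG"
            assert seq[e - 3:e] in ("TAA", "TAG", "TGA")
            # no internal in-frame stop
            body = seq[s + 3:e - 3]
            codons = [body[i:i + 3] for i in range(0, len(body), 3)]
            assert not any(c in ("TAA", "TAG", "TGA") for c in codons)

    def test_kozak_truth_matches_sequence_rule(self, small_sim):
        cfg, genome, annot, truth = small_sim
        for _, row in truth.orfs.iterrows():
            seq = aio.spliced_sequence(annot, genome,
                                       row["transcript_id"]).seq
            s = int(row["tx_start"])
            strong = seq[s - 3] in "AG" and seq[s + 3] == "G"
            assert strong == bool(row["kozak_strong"])


class TestSimulateRna:
    def test_zero_abundance_gives_zero_counts(self):
        cfg = small_config(seed=3)
        genome, annot, truth = generate_genome(cfg)
        truth.abundance.iloc[0, :] = 0.0
        counts = simulate_rna(cfg, truth)
        assert (counts.iloc[0] == 0).all()

    def test_doubling_depth_doubles_expected_counts(self):
        cfg = small_config(seed=4, n_genes=300, n_five=0, n_three=0, n_nc=0)
        genome, annot, truth = generate_genome(cfg)
        c1 = simulate_rna(cfg, truth)
        cfg2 = small_config(seed=4, n_genes=300, n_five=0, n_three=0, n_nc=0)
        cfg2.rna_depth = cfg.rna_depth * 2
        c2 = simulate_rna(cfg2, truth)
        # totals are Poisson sums; ratio of totals ~ 2 within 3 sd
        t1, t2 = c1.values.sum(), c2.values.sum()
        sd = np.sqrt(t2 + 4 * t1)
        assert abs(t2 - 2 * t1) < 3 * sd

    def test_replicate_log_count_correlation_exceeds_096(self, default_run):
        counts = default_run.rna_counts
        stage = default_run.config.stage_names[0]
        a = np.log(counts[(stage, "rep1")] + 1.0)
        b = np.log(counts[(stage, "rep2")] + 1.0)
        assert np.corrcoef(a, b)[0, 1] > 0.96


class TestSimulateRibo:
    def test_pure_frame_zero_when_p0_is_one(self):
        cfg = small_config(seed=6, n_genes=5, n_five=2, n_three=2, n_nc=2)
        cfg.frame_probs = (1.0, 0.0, 0.0)
        genome, annot, truth = generate_genome(cfg)
        truth.orfs["translated"] = True
        tracks = simulate_ribo(cfg, annot, genome, truth)
        track = next(iter(tracks.values()))
        maps = {tid: aio.spliced_sequence(annot, genome, tid)
                for tid in annot.transcripts}
        for _, row in truth.orfs.iterrows():
            m = maps[row["transcript_id"]]
            span = np.arange(int(row["tx_start"]), int(row["tx_end"]))
            gpos = m.genome_positions[span]
            counts = track.counts_at(row["chrom"], row["strand"],
                                     gpos).reshape(-1, 3)
            assert counts[:, 1].sum() == 0 and counts[:, 2].sum() == 0

    def test_untranslated_orfs_have_uniform_frames(self, default_run):
        truth = default_run.truth
        track = default_run.stage_tracks[default_run.config.stage_names[0]]
        n = np.zeros(3)
        for oid, row in truth.orfs[~truth.orfs["translated"]].iterrows():
            m = default_run.tseqs[row["transcript_id"]]
            span = np.arange(int(row["tx_start"]), int(row["tx_end"]))
            gpos = m.genome_positions[span]
            n += track.counts_at(row["chrom"], row["strand"],
                                 gpos).reshape(-1, 3).sum(axis=0)
        f = n / n.sum()
        assert np.allclose(f, 1 / 3, atol=3 * np.sqrt(1 / 9 / n.sum()) + 0.01)

    def test_translated_orf_frame_fraction_near_p0(self, default_run):
        truth = default_run.truth
        track = default_run.stage_tracks[default_run.config.stage_names[0]]
        checked = 0
        for oid, row in truth.orfs[truth.orfs["translated"]].iterrows():
            m = default_run.tseqs[row["transcript_id"]]
            span = np.arange(int(row["tx_start"]), int(row["tx_end"]))
            gpos = m.genome_positions[span]
            counts = track.counts_at(row["chrom"], row["strand"],
                                     gpos).reshape(-1, 3).sum(axis=0)
            if counts.sum() >= 200:
                assert abs(counts[0] / counts.sum() - 0.75) < 0.1
                checked += 1
        assert checked >= 20


class TestVariationPair:
    def test_log2_inflation_is_exact_in_expectation(self):
        rna, ribo = simulate_variation_pair(5000, ["s1", "s2"], 0.3, seed=0)
        vr = np.log2(rna + 1).var(axis=0, ddof=0)
        vb = np.log2(ribo + 1).var(axis=0, ddof=0)
        inc = 100 * (vb - vr) / vr
        assert np.allclose(inc, 30.0, atol=8.0)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(seed=9)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(str(p))
        back = SimulationConfig.from_yaml(str(p))
        assert back == cfg

    def test_invalid_frame_probs_rejected(self):
        cfg = small_config()
        cfg.frame_probs = (0.5, 0.5, 0.5)
        with pytest.raises(ValueError, match="frame_probs"):
            cfg.validate()
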