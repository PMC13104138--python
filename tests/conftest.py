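import numpy as np
import pandas as pd
import pytest

from riboutr import annotation_io as aio
from riboutr import orf_discovery as orfmod
from riboutr import quantification as quant
from riboutr.periodicity import PSiteTrack
from riboutr.synthetic_data import (SimulationConfig, generate_genome,
                                    simulate_rna, simulate_ribo)

GFF3_TOY = """##gff-version 3
##sequence-region chr1 1 200
chr1\ttest\tgene\t1\t70\t.\t+\t.\tID=gA
chr1\ttest\tmRNA\t1\t70\t.\t+\t.\tID=gA.t1;Parent=gA
chr1\ttest\texon\t1\t30\t.\t+\t.\tID=gA.t1.e1;Parent=gA.t1
chr1\ttest\texon\t41\t70\t.\t+\t.\tID=gA.t1.e2;Parent=gA.t1
chr1\ttest\tCDS\t11\t30\t.\t+\t0\tID=gA.t1.c;Parent=gA.t1
chr1\ttest\tCDS\t41\t60\t.\t+\t2\tID=gA.t1.c;Parent=gA.t1
chr1\ttest\tgene\t101\t160\t.\t-\t.\tID=gB
chr1\ttest\tmRNA\t101\t160\t.\t-\t.\tID=gB.t1;Parent=gB
chr1\ttest\texon\t101\t125\t.\t-\t.\tID=gB.t1.e1;Parent=gB.t1
chr1\ttest\texon\t136\t160\t.\t-\t.\tID=gB.t1.e2;Parent=gB.t1
chr1\ttest\tCDS\t106\t125\t.\t-\t0\tID=gB.t1.c;Parent=gB.t1
chr1\ttest\tCDS\t136\t151\t.\t-\t0\tID=gB.t1.c;Parent=gB.t1
"""


@pytest.fixture()
def toy_gff3(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(GFF3_TOY)
    return str(p)


@pytest.fixture()
def toy_annot(toy_gff3):
    return aio.read_gff3(toy_gff3)


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(42)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=200))}


def small_config(seed=11, n_genes=60, n_five=20, n_three=20, n_nc=20):
    cfg = SimulationConfig(seed=seed, n_genes=n_genes)
    cfg.orf_plan.n_five = n_five
    cfg.orf_plan.n_three = n_three
    cfg.orf_plan.n_nc = n_nc
    return cfg


@pytest.fixture(scope="session")
def small_sim():
    cfg = small_config()
    genome, annot, truth = generate_genome(cfg)
    return cfg, genome, annot, truth


class DefaultRun:
    """Default-scale simulation plus quantification and ORF calling, shared
    across tests to amortize the cost of the full study-condition run."""

    def __init__(self, seed=1):
        self.config = SimulationConfig(seed=seed)
        self.genome, self.annot, self.truth = generate_genome(self.config)
        self.rna_counts = simulate_rna(self.config, self.truth)
        self.tracks = simulate_ribo(self.config, self.annot, self.genome,
                                    self.truth)
        self.stage_tracks = {
            s: PSiteTrack.pooled([t for (ss, _), t in self.tracks.items()
                                  if ss == s], s)
            for s in self.config.stage_names}
        ribo_counts = pd.DataFrame({
            k: quant.count_features(t, self.annot, "CDS")
            for k, t in self.tracks.items()})
        ribo_counts.columns = pd.MultiIndex.from_tuples(self.tracks.keys())
        self.ribo_counts = ribo_counts.loc[self.rna_counts.index]
        self.expr = quant.build_expression_matrix(self.rna_counts,
                                                  self.ribo_counts, self.annot)
        self.te = quant.compute_te(self.expr)
        self.tseqs = {tid: aio.spliced_sequence(self.annot, self.genome, tid)
                      for tid in self.annot.transcripts}
        self.candidates = orfmod.find_candidates(self.annot, self.genome,
                                                 tseqs=self.tseqs)
        self.accepted = orfmod.accept_translated(
            self.candidates, self.stage_tracks, self.annot, self.tseqs)

    def truth_lookup(self):
        """(transcript, span) -> (translated, category) for planted ORFs."""
        return {(r["transcript_id"], int(r["tx_start"]), int(r["tx_end"])):
                (bool(r["translated"]), r["category"])
                for _, r in self.truth.orfs.iterrows()}


@pytest.fixture(scope="session")
def default_run():
    return DefaultRun(seed=1)
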