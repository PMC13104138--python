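"""End-to-end orchestration: simulate -> quantify -> QC -> ORF calling ->
TE classification -> clustering/enrichment -> corroboration.

Each step writes its outputs under the run directory and registers them in a
run manifest (sha256 per file, wall-clock per step).  All steps are
deterministic given the config seed, so a rerun with the same config
produces identical checksums for every output.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import annotation_io as aio
from . import cluster_enrich as ce
from . import corroboration as corr
from . import orf_discovery as orfmod
from . import periodicity as per
from . import quantification as quant
from . import synthetic_data as syn
from . import te_analysis as tea

STEPS = ["simulate", "quantify", "qc", "callorfs", "classify_te",
         "relations", "cluster", "corroborate"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config: dict
    seed: int
    steps: list[str] = field(default_factory=list)
    outputs: dict[str, dict] = field(default_factory=dict)  # step -> path -> sha
    elapsed: dict[str, float] = field(default_factory=dict)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @property
    def checksums(self) -> dict[str, str]:
        out = {}
        for step in sorted(self.outputs):
            out.update(self.outputs[step])
        return out


def _sha256(path: str) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def _counts_to_tsv(df: pd.DataFrame, path: str) -> None:
    flat = df.copy()
    flat.columns = [f"{s}:{r}" for s, r in df.columns]
    flat.to_csv(path, sep="\t")


def _counts_from_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = pd.MultiIndex.from_tuples(tuple(c.split(":", 1))
                                           for c in df.columns)
    return df


class PipelineRun:
    """Holds in-memory state while steps execute in order."""

    def __init__(self, config: syn.SimulationConfig, outdir: str):
        config.validate()
        self.config = config
        self.outdir = outdir
        os.makedirs(outdir, exist_ok=True)
        cfg_dict = asdict(config)
        cfg_dict["frame_probs"] = list(cfg_dict["frame_probs"])
        self.manifest = RunManifest(config=cfg_dict, seed=config.seed)
        # lazily populated state
        self.genome = None
        self.annot = None
        self.truth = None
        self.isoforms = None
        self.tracks = None
        self.stage_tracks = None
        self.rna_counts = None
        self.expr = None
        self.te = None
        self.orfs = None
        self.accepted = None
        self.te_classes = None

    # -- helpers -----------------------------------------------------------
    def _out(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    def _register(self, step: str, *paths: str) -> None:
        d = self.manifest.outputs.setdefault(step, {})
        for p in paths:
            d[os.path.basename(p)] = _sha256(p)

    # -- steps -------------------------------------------------------------
    def step_simulate(self) -> None:
        cfg = self.config
        self.genome, self.annot, self.truth = syn.generate_genome(cfg)
        self.isoforms = syn.build_isoform_models(cfg, self.annot, self.truth)
        self.rna_counts = syn.simulate_rna(cfg, self.truth)
        self.tracks = syn.simulate_ribo(cfg, self.annot, self.genome, self.truth)
        paths = [self._out("genome.fa"), self._out("annotation.gff3"),
                 self._out("isoforms.gff3"), self._out("rna_counts.tsv"),
                 self._out("config.yaml")]
        aio.write_fasta(self.genome, paths[0])
        aio.write_gff3(self.annot, paths[1])
        aio.write_gff3(self.isoforms, paths[2])
        _counts_to_tsv(self.rna_counts, paths[3])
        cfg.to_yaml(paths[4])
        self.truth.write(self._out("truth"))
        paths += [self._out(f"truth_{x}.tsv")
                  for x in ("genes", "abundance", "te", "orfs", "orf_levels")]
        for (stage, rep), track in self.tracks.items():
            p = self._out(f"psites_{stage}_{rep}.tsv")
            track.to_tsv(p)
            paths.append(p)
        self._register("simulate", *paths)

    def _pool_stages(self) -> None:
        if self.stage_tracks is None:
            self.stage_tracks = {}
            for stage in self.config.stage_names:
                reps = [t for (s, r), t in self.tracks.items() if s == stage]
                self.stage_tracks[stage] = per.PSiteTrack.pooled(
                    reps, sample=stage)

    def step_quantify(self) -> None:
        if self.tracks is None:
            raise PipelineError("quantify: no P-site tracks (run simulate or "
                                "provide --psites via ingest)")
        ribo_counts = pd.DataFrame({
            key: quant.count_features(track, self.annot, "CDS")
            for key, track in self.tracks.items()})
        ribo_counts.columns = pd.MultiIndex.from_tuples(self.tracks.keys())
        ribo_counts = ribo_counts.loc[self.rna_counts.index]
        self.expr = quant.build_expression_matrix(self.rna_counts, ribo_counts,
                                                  self.annot)
        self.te = quant.compute_te(self.expr)
        called = quant.call_expressed(self.expr)
        paths = [self._out("fpkm.tsv"), self._out("rpkm.tsv"),
                 self._out("te.tsv"), self._out("ribo_counts.tsv"),
                 self._out("expressed_summary.json")]
        self.expr.rna.to_csv(paths[0], sep="\t")
        self.expr.ribo.to_csv(paths[1], sep="\t")
        self.te.te.to_csv(paths[2], sep="\t")
        _counts_to_tsv(ribo_counts, paths[3])
        with open(paths[4], "w") as fh:
            json.dump(json.loads(called.summary.to_json(orient="index")), fh,
                      indent=2, sort_keys=True)
        self._register("quantify", *paths)

    def step_qc(self) -> None:
        self._pool_stages()
        rows = []
        for stage, track in self.stage_tracks.items():
            hist = per.length_histogram(track)
            for L, c in sorted((hist.counts or {}).items()):
                rows.append({"stage": stage, "read_length": L, "count": c,
                             "fraction_25_33": hist.fraction_25_33,
                             "fraction_25_30": hist.fraction_25_30})
        p1 = self._out("length_hist.tsv")
        pd.DataFrame(rows).to_csv(p1, sep="\t", index=False)
        # genome-wide per-stage frame fractions over annotated CDS
        maps = {tid: aio.spliced_sequence(self.annot, self.genome, tid)
                for tid in self.annot.transcripts}
        frows = []
        for stage, track in self.stage_tracks.items():
            n = np.zeros(3, dtype=int)
            for tid, t in self.annot.transcripts.items():
                if not t.cds:
                    continue
                utr5 = sum(e - s for s, e in t.utr5)
                fs = per.frame_stats(track, maps[tid],
                                     (utr5, utr5 + t.cds_length),
                                     t.chrom, t.strand, region_id=tid)
                n += np.array([fs.n0, fs.n1, fs.n2])
            tot = n.sum()
            frows.append({"stage": stage, "n0": n[0], "n1": n[1], "n2": n[2],
                          "f0": n[0] / tot if tot else np.nan})
        p2 = self._out("frame_fractions.tsv")
        pd.DataFrame(frows).to_csv(p2, sep="\t", index=False)
        self._register("qc", p1, p2)

    def step_callorfs(self, min_psites: int = 10, f0_min: float = 0.6,
                      alpha: float = 0.05) -> None:
        self._pool_stages()
        tseqs = {tid: aio.spliced_sequence(self.annot, self.genome, tid)
                 for tid in self.annot.transcripts}
        self.orfs = orfmod.find_candidates(self.annot, self.genome, tseqs=tseqs)
        self.accepted = orfmod.accept_translated(
            self.orfs, self.stage_tracks, self.annot, tseqs,
            min_psites=min_psites, f0_min=f0_min, alpha=alpha)
        paths = [self._out("orfs.tsv"), self._out("orfs.bed12"),
                 self._out("peptides.fa")]
        orfmod.orfs_to_frame(self.orfs).to_csv(paths[0], sep="\t")
        orfmod.write_bed12(self.accepted, paths[1])
        orfmod.write_peptides_fasta(self.accepted, paths[2])
        self._register("callorfs", *paths)

    def step_classify_te(self) -> None:
        if self.te is None:
            raise PipelineError("classify_te: quantify has not run")
        self.te_classes = tea.classify_te(self.expr, self.te,
                                          phase_map=self.config.phase_map)
        var = tea.expression_variation(self.expr.rna, self.expr.ribo)
        p1, p2 = self._out("te_classes.tsv"), self._out("variance_report.tsv")
        self.te_classes.to_csv(p1, sep="\t")
        var.table.to_csv(p2, sep="\t")
        self._register("classify_te", p1, p2)

    def step_relations(self) -> None:
        if self.accepted is None or self.te is None:
            raise PipelineError("relations: callorfs/quantify have not run")
        rel = tea.orf_te_relations(self.accepted, self.te)
        p1 = self._out("orf_te_relations.tsv")
        p2 = self._out("orf_te_relations.json")
        per_orf = rel["per_orf"]
        (per_orf if len(per_orf) else pd.DataFrame()).to_csv(p1, sep="\t")
        with open(p2, "w") as fh:
            json.dump({"group_tests": rel["group_tests"],
                       "length_correlation": rel["length_correlation"]},
                      fh, indent=2, sort_keys=True, default=float)
        self._register("relations", p1, p2)

    def step_cluster(self) -> None:
        if self.te is None:
            raise PipelineError("cluster: quantify has not run")
        coding = self.te.te.index[~self.te.te.isna().any(axis=1)]
        floor = np.minimum(self.expr.rna.loc[coding],
                           self.expr.ribo.loc[coding])
        profiles, excluded = ce.normalize_profiles(
            self.te.te.loc[coding], min_value=1.0, filter_on=floor)
        k = min(ce.KMEANS_K, max(2, len(profiles) // 5))
        if len(profiles) >= k:
            km = ce.kmeans_te(profiles, k=k, phase_map=self.config.phase_map)
            clusters = km.assignments.to_frame()
            clusters["phase"] = km.assignments.map(
                lambda c: km.phase_of_cluster.get(c) or "")
            centroids = km.centroids
        else:
            clusters = pd.DataFrame(columns=["cluster", "phase"])
            centroids = pd.DataFrame()
        dend = ce.hclust_stages(self.te.te.loc[coding])
        # demo term annotation from planted-ORF hosts, enrichment of TE classes
        paths = [self._out("clusters.tsv"), self._out("centroids.tsv"),
                 self._out("stage_dendrogram.nwk")]
        clusters.to_csv(paths[0], sep="\t")
        centroids.to_csv(paths[1], sep="\t")
        with open(paths[2], "w") as fh:
            fh.write(dend.newick() + "\n")
        if self.truth is not None and len(self.truth.orfs) \
                and self.te_classes is not None:
            terms = {
                f"hosts_{cat}": set(self.truth.orfs.loc[
                    self.truth.orfs["category"] == cat, "gene"])
                for cat in sorted(self.truth.orfs["category"].unique())}
            background = set(coding)
            enr_frames = []
            for cls in ("high", "very_high", "low", "fluctuating"):
                gene_set = set(self.te_classes.index[
                    self.te_classes["class"] == cls]) & background
                if not gene_set:
                    continue
                df = ce.hypergeom_enrich(gene_set,
                                         {t: g & background
                                          for t, g in terms.items()},
                                         background)
                df.insert(0, "gene_set", cls)
                enr_frames.append(df.reset_index())
            p = self._out("enrichment.tsv")
            (pd.concat(enr_frames, ignore_index=True) if enr_frames
             else pd.DataFrame()).to_csv(p, sep="\t", index=False)
            paths.append(p)
        self._register("cluster", *paths)

    def step_corroborate(self) -> None:
        if self.accepted is None:
            raise PipelineError("corroborate: callorfs has not run")
        supports = corr.isoform_support(self.accepted, self.isoforms)
        p1 = self._out("isoform_support.tsv")
        corr.support_table(supports).to_csv(p1, sep="\t", index=False)
        # synthetic peptide evidence: tryptic-like windows from a subset of
        # accepted ORF proteins, plus reversed decoys
        rng = np.random.default_rng((self.config.seed, 5))
        orf_peps = {o.id: o.peptide for o in self.accepted if len(o.peptide) >= 9}
        peptides, decoys = [], []
        for oid in sorted(orf_peps)[:50]:
            seq = orf_peps[oid]
            w = int(rng.integers(7, min(12, len(seq)) + 1))
            s = int(rng.integers(0, len(seq) - w + 1))
            peptides.append(seq[s:s + w])
            decoys.append(seq[s:s + w][::-1])
        matches, table = corr.match_peptides(peptides, orf_peps, decoys=decoys)
        p2 = self._out("peptide_matches.tsv")
        rows = [{"peptide": m.peptide, "orf_id": m.orf_id, "decoy": m.decoy,
                 "offsets": ",".join(map(str, m.offsets))} for m in matches]
        pd.DataFrame(rows, columns=["peptide", "orf_id", "decoy", "offsets"]) \
            .to_csv(p2, sep="\t", index=False)
        p3 = self._out("peptide_summary.tsv")
        table.to_csv(p3, sep="\t", index=False)
        self._register("corroborate", p1, p2, p3)


def run_pipeline(config: syn.SimulationConfig, outdir: str,
                 steps: list[str] | None = None) -> RunManifest:
    """Execute pipeline steps in order and write the run manifest.

    ``steps`` defaults to all steps; prerequisite state for a later step is
    produced by running the earlier steps, so a partial list must be a prefix
    of :data:`STEPS`.  A failing step aborts with its name; outputs of
    completed steps are preserved.
    """
    steps = steps or STEPS
    unknown = [s for s in steps if s not in STEPS]
    if unknown:
        raise PipelineError(f"unknown steps: {unknown}")
    run = PipelineRun(config, outdir)
    upto = max(STEPS.index(s) for s in steps)
    for step in STEPS[:upto + 1]:
        t0 = time.perf_counter()
        try:
            getattr(run, f"step_{step}")()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"step '{step}' failed: {exc}") from exc
        run.manifest.steps.append(step)
        run.manifest.elapsed[step] = round(time.perf_counter() - t0, 3)
    run.manifest.write(os.path.join(outdir, "manifest.json"))
    return run.manifest
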