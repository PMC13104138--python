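"""Synthetic staged Ribo-seq/RNA-seq data with planted UTR ORFs and ground truth.

The generator emulates the statistical structure of a staged anther
translatome experiment: ten developmental stages x two replicates, gene-level
mRNA abundance with gene- and stage-specific variation, gene-specific
translation efficiency (TE), ribosome footprints of 25-33 nt whose P-sites
are frame-biased on translated ORFs (default p = (0.75, 0.15, 0.10)) and
uniform elsewhere, and planted AUG-initiated ORFs in 5'UTRs, 3'UTRs and
intergenic noncoding transcripts, with and without a strong Kozak context.

Transcript sequences are constructed so that the only AUG trigrams present
are the planted start codons (main ORF plus planted UTR/nc ORFs); this makes
the ground truth exact: the candidate ORF set of a transcript is knowable in
advance, which is what the recovery tests rely on.

Counts are Poisson around their expected values; an initiation peak
(extra P-site weight on the start codon, emulating initiation pausing) gives
the metagene the 5'-end structure that offset calibration needs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .annotation_io import (AnnotationSet, Gene, Transcript, TranscriptSequence,
                            _infer_utrs, _tx_order, spliced_sequence,
                            tx_span_to_genome_blocks)
from .periodicity import PSiteTrack

STAGE_NAMES = ["0.5mm", "1.0mm", "1.3mm", "1.5mm", "2.0mm",
               "2.5mm", "3.0mm", "4.0mm", "5.0mm", "pollen"]
# five developmental phases over the ten stages
PHASE_MAP = {"0.5mm": "PI", "1.0mm": "PI", "1.3mm": "PI",
             "1.5mm": "PII", "2.0mm": "PII", "2.5mm": "PII", "3.0mm": "PII",
             "4.0mm": "PIII", "5.0mm": "PIV", "pollen": "PV"}

FOOTPRINT_LENGTH_PROBS = {25: 0.03, 26: 0.05, 27: 0.12, 28: 0.28, 29: 0.22,
                          30: 0.14, 31: 0.08, 32: 0.05, 33: 0.03}

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
# codons excluded from ORF bodies: stops (would truncate) and ATG (would nest)
_BODY_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                if a + b + c not in _STOPS and a + b + c != "ATG"]


@dataclass
class ORFPlan:
    """How many ORFs to plant where, and with what properties."""

    n_five: int = 160
    n_three: int = 160
    n_nc: int = 160
    min_codons: int = 15          # total codons including the stop
    max_codons: int = 60
    frac_strong_kozak: float = 0.5
    frac_translated: float = 0.5
    frac_isoform_backed: float = 0.3   # of 3' ORFs, get a matching isoform model
    level_log_mean: float = 3.2   # ln-scale ribosome occupancy of planted ORFs
    level_log_sd: float = 0.6
    stage_level_log_sd: float = 0.4


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions emulated."""

    seed: int = 0
    n_genes: int = 300
    n_stages: int = 10
    n_replicates: int = 2
    stage_names: list[str] = field(default_factory=lambda: list(STAGE_NAMES))
    phase_map: dict[str, str] = field(default_factory=lambda: dict(PHASE_MAP))
    mean_log_abundance: float = 3.0
    sd_log_abundance: float = 1.0
    stage_log_sd: float = 0.5     # per-stage abundance jitter around the gene mean
    # TE centered slightly above 1 so the simulated Ribo library (CDS-counted
    # reads) and RNA library (exon-counted, incl. noncoding transcripts) carry
    # comparable per-million scales: true and estimated TE then share units
    mean_log_te: float = 0.4
    sd_log_te: float = 0.5
    frame_probs: tuple[float, float, float] = (0.75, 0.15, 0.10)
    footprint_length_probs: dict[int, float] = field(
        default_factory=lambda: dict(FOOTPRINT_LENGTH_PROBS))
    rna_depth: float = 10.0       # expected RNA fragments per kb per abundance unit
    ribo_depth: float = 30.0      # expected P-sites per kb per (TE x abundance) unit
    init_peak_weight: float = 5.0
    utr5_range: tuple[int, int] = (200, 300)
    utr3_range: tuple[int, int] = (200, 300)
    cds_codon_range: tuple[int, int] = (150, 400)
    max_exons: int = 3
    intron_range: tuple[int, int] = (60, 150)
    intergap_range: tuple[int, int] = (200, 400)
    genes_per_chromosome: int = 50
    orf_plan: ORFPlan = field(default_factory=ORFPlan)
    length_te_slope: float = 0.0  # planted 3'ORF length -> host log-TE coupling
    psite_offset: int = 12        # true 5'end->P-site offset in raw-placement mode
    n_decoy_isoforms: int = 5

    def validate(self) -> None:
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        if len(self.stage_names) != self.n_stages:
            raise ValueError("stage_names length must equal n_stages")
        if abs(sum(self.frame_probs) - 1.0) > 1e-9:
            raise ValueError("frame_probs must sum to 1")
        if abs(sum(self.footprint_length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("footprint_length_probs must sum to 1")
        if self.rna_depth <= 0 or self.ribo_depth <= 0:
            raise ValueError("sequencing depth must be positive")
        p = self.orf_plan
        if p.n_five > self.n_genes or p.n_three > self.n_genes:
            raise ValueError("cannot plant more UTR ORFs than genes")

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["frame_probs"] = list(d["frame_probs"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "orf_plan" in d and isinstance(d["orf_plan"], dict):
            d["orf_plan"] = ORFPlan(**d["orf_plan"])
        for key in ("frame_probs", "utr5_range", "utr3_range", "cds_codon_range",
                    "intron_range", "intergap_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "footprint_length_probs" in d:
            d["footprint_length_probs"] = {
                int(k): float(v) for k, v in d["footprint_length_probs"].items()}
        return cls(**d)


@dataclass
class TruthTable:
    """Ground truth of a simulation run, the oracle for recovery tests."""

    genes: pd.DataFrame       # per gene: chrom, strand, transcript_id, kbs, noncoding
    abundance: pd.DataFrame   # gene x stage true mRNA abundance
    te: pd.DataFrame          # gene x stage true TE (NaN for noncoding hosts)
    orfs: pd.DataFrame        # per planted ORF: location, category, flags
    orf_levels: pd.DataFrame  # planted ORF x stage true ribosome occupancy

    def write(self, prefix: str) -> None:
        self.genes.to_csv(prefix + "_genes.tsv", sep="\t")
        self.abundance.to_csv(prefix + "_abundance.tsv", sep="\t")
        self.te.to_csv(prefix + "_te.tsv", sep="\t")
        self.orfs.to_csv(prefix + "_orfs.tsv", sep="\t")
        self.orf_levels.to_csv(prefix + "_orf_levels.tsv", sep="\t")


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list(_BASES), size=n))


def _scrub_atg(seq: list[str], protected: set[int],
               keep_starts: set[int]) -> None:
    """Remove every ATG trigram by substituting C at an unprotected base.

    A C substitution can neither create a stop codon nor a new ATG, so the
    scrub is safe regardless of reading frame.  Trigrams starting at an index
    in ``keep_starts`` are intentional start codons and are kept; bases in
    ``protected`` (planted starts/stops, Kozak bases) are never mutated.
    """
    i = 0
    while i <= len(seq) - 3:
        if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G" \
                and i not in keep_starts:
            for j in (i + 1, i, i + 2):
                if j not in protected:
                    seq[j] = "C"
                    break
            else:  # pragma: no cover - construction guarantees a free base
                raise RuntimeError("fully protected spurious ATG")
        i += 1


def _plant_orf(seq: list[str], start: int, n_codons: int, strong_kozak: bool,
               rng: np.random.Generator, protected: set[int],
               keep_starts: set[int]) -> None:
    """Write an AUG..stop ORF of n_codons into seq at transcript index start."""
    body = rng.choice(_BODY_CODONS, size=n_codons - 2)
    codons = ["ATG"] + list(body) + [str(rng.choice(_STOPS))]
    orf = "".join(codons)
    for k, base in enumerate(orf):
        seq[start + k] = base
    keep_starts.add(start)
    protected.update({start, start + 1, start + 2})
    stop0 = start + 3 * (n_codons - 1)
    protected.update({stop0, stop0 + 1, stop0 + 2})
    # Kozak context: -3 is 3 nt upstream of the A (index start-3), +4 is the
    # base right after the AUG (index start+3, the first base of codon 2).
    # Base choices avoid creating an ATG trigram the scrub could not touch.
    if start >= 3:
        if strong_kozak:
            m3 = str(rng.choice(["A", "G"]))
            if m3 == "A" and seq[start - 2] == "T" and seq[start - 1] == "G":
                m3 = "G"
        else:
            m3 = str(rng.choice(["C", "T"]))
        seq[start - 3] = m3
        protected.add(start - 3)
    seq[start + 3] = "G" if strong_kozak else "C"
    protected.add(start + 3)


def _split_exons(tx_len: int, rng: np.random.Generator, max_exons: int,
                 intron_range: tuple[int, int]) -> tuple[list[int], list[int]]:
    """Random exon lengths summing to tx_len, and intron lengths between them."""
    n_exons = int(rng.integers(1, max_exons + 1))
    n_exons = min(n_exons, max(1, tx_len // 50))
    if n_exons == 1:
        return [tx_len], []
    cuts = sorted(rng.choice(np.arange(25, tx_len - 25), size=n_exons - 1,
                             replace=False))
    bounds = [0] + [int(c) for c in cuts] + [tx_len]
    exon_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    introns = [int(rng.integers(intron_range[0], intron_range[1] + 1))
               for _ in range(n_exons - 1)]
    return exon_lens, introns


def generate_genome(config: SimulationConfig
                    ) -> tuple[dict[str, str], AnnotationSet, TruthTable]:
    """Build the toy genome, its annotation and the ground-truth table.

    Deterministic for a fixed ``config.seed``: the same config yields
    byte-identical FASTA/GFF3 output.
    """
    config.validate()
    rng = np.random.default_rng((config.seed, 1))
    plan = config.orf_plan
    stages = config.stage_names

    n_coding = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n_coding)]
    nc_ids = [f"nc{i:05d}" for i in range(plan.n_nc)]

    five_hosts = set(rng.choice(n_coding, size=plan.n_five, replace=False).tolist()) \
        if plan.n_five else set()
    three_hosts = set(rng.choice(n_coding, size=plan.n_three, replace=False).tolist()) \
        if plan.n_three else set()

    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    chrom_seqs: dict[str, list[str]] = {}
    gene_rows, orf_rows = [], []
    orf_counter = 0

    def new_orf_id() -> str:
        nonlocal orf_counter
        orf_counter += 1
        return f"orf{orf_counter:05d}"

    # interleave coding genes and nc transcripts onto chromosomes
    units: list[tuple[str, str]] = [("coding", gid) for gid in gene_ids] \
        + [("nc", nid) for nid in nc_ids]
    per_chrom = config.genes_per_chromosome
    for ui, (kind, uid) in enumerate(units):
        chrom = f"chr{ui // per_chrom + 1}"
        seq = chrom_seqs.setdefault(chrom, [])
        seq.extend(_random_seq(rng, int(rng.integers(*config.intergap_range))))
        strand = "+" if rng.random() < 0.5 else "-"
        protected: set[int] = set()
        keep_starts: set[int] = set()
        planted_here = []  # (category, start, n_codons, strong, translated)

        if kind == "coding":
            utr5 = int(rng.integers(*config.utr5_range))
            utr3 = int(rng.integers(*config.utr3_range))
            cds_codons = int(rng.integers(*config.cds_codon_range))
            cds_len = 3 * cds_codons
            tx_len = utr5 + cds_len + utr3
            tseq = _random_seq(rng, tx_len)
            # main ORF occupies the CDS exactly
            _plant_orf(tseq, utr5, cds_codons,
                       strong_kozak=bool(rng.random() < 0.7), rng=rng,
                       protected=protected, keep_starts=keep_starts)
            gi = int(uid[1:])
            if gi in five_hosts:
                nc_max = min(plan.max_codons, (utr5 - 7) // 3)
                ncod = int(rng.integers(plan.min_codons, nc_max + 1))
                s = int(rng.integers(3, utr5 - 3 * ncod + 1))
                strong = bool(rng.random() < plan.frac_strong_kozak)
                transl = bool(rng.random() < plan.frac_translated)
                _plant_orf(tseq, s, ncod, strong, rng, protected, keep_starts)
                planted_here.append(("five_prime_ORF", s, ncod, strong, transl))
            if gi in three_hosts:
                u3_start = utr5 + cds_len
                nc_max = min(plan.max_codons, (utr3 - 7) // 3)
                ncod = int(rng.integers(plan.min_codons, nc_max + 1))
                s = u3_start + int(rng.integers(3, utr3 - 3 * ncod + 1))
                strong = bool(rng.random() < plan.frac_strong_kozak)
                transl = bool(rng.random() < plan.frac_translated)
                _plant_orf(tseq, s, ncod, strong, rng, protected, keep_starts)
                planted_here.append(("three_prime_ORF", s, ncod, strong, transl))
            cds_tx = (utr5, utr5 + cds_len)
        else:
            nc_max = plan.max_codons
            ncod = int(rng.integers(plan.min_codons, nc_max + 1))
            flank5 = int(rng.integers(30, 120))
            flank3 = int(rng.integers(30, 120))
            tx_len = flank5 + 3 * ncod + flank3
            tseq = _random_seq(rng, tx_len)
            strong = bool(rng.random() < plan.frac_strong_kozak)
            transl = bool(rng.random() < plan.frac_translated)
            _plant_orf(tseq, flank5, ncod, strong, rng, protected, keep_starts)
            planted_here.append(("ncORF", flank5, ncod, strong, transl))
            cds_tx = None

        _scrub_atg(tseq, protected, keep_starts)

        exon_lens, introns = _split_exons(tx_len, rng, config.max_exons,
                                          config.intron_range)
        # assemble pre-mRNA in transcript orientation
        pre, exon_offsets, off = [], [], 0
        tpos = 0
        for k, el in enumerate(exon_lens):
            exon_offsets.append(off)
            pre.extend(tseq[tpos:tpos + el])
            tpos += el
            off += el
            if k < len(introns):
                pre.extend(_random_seq(rng, introns[k]))
                off += introns[k]
        pre_len = len(pre)
        g0 = len(seq)
        if strand == "+":
            seq.extend(pre)
            exons = [(g0 + exon_offsets[k], g0 + exon_offsets[k] + exon_lens[k])
                     for k in range(len(exon_lens))]
        else:
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            seq.extend(comp[b] for b in reversed(pre))
            exons = [(g0 + pre_len - exon_offsets[k] - exon_lens[k],
                      g0 + pre_len - exon_offsets[k])
                     for k in range(len(exon_lens))]
        exons = _tx_order(exons, strand)

        tid = uid + ".t1"
        if cds_tx is not None:
            cds = tx_span_to_genome_blocks(exons, strand, *cds_tx)
        else:
            cds = []
        utr5_iv, utr3_iv = _infer_utrs(sorted(exons), cds, strand)
        span_lo = min(s for s, _ in exons)
        span_hi = max(e for _, e in exons)
        genes[uid] = Gene(uid, chrom, strand, span_lo, span_hi)
        transcripts[tid] = Transcript(
            id=tid, gene_id=uid, chrom=chrom, strand=strand,
            exons=exons, cds=_tx_order(cds, strand),
            utr5=utr5_iv, utr3=utr3_iv, noncoding=(cds_tx is None))
        gene_rows.append({
            "gene": uid, "chrom": chrom, "strand": strand, "transcript_id": tid,
            "exon_kb": tx_len / 1000.0,
            "cds_kb": (cds_tx[1] - cds_tx[0]) / 1000.0 if cds_tx else 0.0,
            "noncoding": cds_tx is None})
        for cat, s, ncod, strong, transl in planted_here:
            orf_rows.append({
                "orf_id": new_orf_id(), "gene": uid, "transcript_id": tid,
                "chrom": chrom, "strand": strand, "category": cat,
                "tx_start": s, "tx_end": s + 3 * ncod, "n_codons": ncod,
                "kozak_strong": strong, "translated": transl,
                "isoform_backed": False})

    # trailing intergenic sequence so footprint 5' ends near chromosome-final
    # genes stay on-chromosome in raw-placement mode
    for c in sorted(chrom_seqs):
        chrom_seqs[c].extend(_random_seq(rng, int(rng.integers(
            *config.intergap_range))))
    chromosomes = {c: len(s) for c, s in chrom_seqs.items()}
    genome = {c: "".join(s) for c, s in chrom_seqs.items()}
    annot = AnnotationSet(chromosomes=chromosomes, genes=genes,
                          transcripts=transcripts, source="simulated")

    genes_df = pd.DataFrame(gene_rows).set_index("gene")
    orfs_df = pd.DataFrame(orf_rows).set_index("orf_id") if orf_rows else \
        pd.DataFrame(columns=["gene", "transcript_id", "chrom", "strand",
                              "category", "tx_start", "tx_end", "n_codons",
                              "kozak_strong", "translated", "isoform_backed"])
    if len(orfs_df):
        backed = orfs_df.index[
            (orfs_df["category"] == "three_prime_ORF")
            & (rng.random(len(orfs_df)) < plan.frac_isoform_backed)]
        orfs_df.loc[backed, "isoform_backed"] = True

    # true abundances and TE
    all_ids = list(genes_df.index)
    base = rng.normal(config.mean_log_abundance, config.sd_log_abundance,
                      size=len(all_ids))
    ab = np.exp(base[:, None]
                + rng.normal(0.0, config.stage_log_sd,
                             size=(len(all_ids), config.n_stages)))
    abundance = pd.DataFrame(ab, index=all_ids, columns=stages)
    te_vals = np.exp(rng.normal(config.mean_log_te, config.sd_log_te,
                                size=(len(all_ids), config.n_stages)))
    te = pd.DataFrame(te_vals, index=all_ids, columns=stages)
    te.loc[genes_df.index[genes_df["noncoding"]], :] = np.nan

    if config.length_te_slope != 0.0 and len(orfs_df):
        three = orfs_df[orfs_df["category"] == "three_prime_ORF"]
        if len(three) > 1:
            z = (three["n_codons"] - three["n_codons"].mean()) \
                / three["n_codons"].std()
            for oid, host in zip(three.index, three["gene"]):
                te.loc[host] = te.loc[host] * np.exp(
                    config.length_te_slope * z.loc[oid])

    # planted ORF ribosome occupancy per stage
    if len(orfs_df):
        base_lv = rng.normal(plan.level_log_mean, plan.level_log_sd,
                             size=len(orfs_df))
        lv = np.exp(base_lv[:, None]
                    + rng.normal(0.0, plan.stage_level_log_sd,
                                 size=(len(orfs_df), config.n_stages)))
        orf_levels = pd.DataFrame(lv, index=orfs_df.index, columns=stages)
    else:
        orf_levels = pd.DataFrame(columns=stages)

    truth = TruthTable(genes=genes_df, abundance=abundance, te=te,
                       orfs=orfs_df, orf_levels=orf_levels)
    _check_planted_starts(annot, genome, truth)
    return genome, annot, truth


def _check_planted_starts(annot: AnnotationSet, genome: dict[str, str],
                          truth: TruthTable) -> None:
    """Generator self-check: every ATG on a transcript is a planted start."""
    for tid, t in annot.transcripts.items():
        tseq = spliced_sequence(annot, genome, tid)
        expected = set()
        gid = t.gene_id
        if not t.noncoding:
            utr5_len = sum(e - s for s, e in t.utr5)
            expected.add(utr5_len)
        sub = truth.orfs[truth.orfs["transcript_id"] == tid]
        expected.update(int(x) for x in sub["tx_start"])
        found = {i for i in range(len(tseq.seq) - 2)
                 if tseq.seq[i:i + 3] == "ATG"}
        if found != expected:  # pragma: no cover - construction invariant
            raise RuntimeError(f"stray ATG in generated transcript {tid}")


def simulate_rna(config: SimulationConfig, truth: TruthTable) -> pd.DataFrame:
    """Per-gene RNA fragment counts with (stage, replicate) columns.

    count ~ Poisson(abundance x exon_kb x rna_depth), independent replicates.
    """
    rng = np.random.default_rng((config.seed, 2))
    cols, data = [], []
    exon_kb = truth.genes["exon_kb"]
    for stage in config.stage_names:
        mu = truth.abundance[stage] * exon_kb * config.rna_depth
        for rep in range(1, config.n_replicates + 1):
            cols.append((stage, f"rep{rep}"))
            data.append(rng.poisson(mu.to_numpy()))
    df = pd.DataFrame(np.array(data).T, index=truth.genes.index,
                      columns=pd.MultiIndex.from_tuples(cols))
    return df


def _transcript_maps(annot: AnnotationSet, genome: dict[str, str]
                     ) -> dict[str, TranscriptSequence]:
    return {tid: spliced_sequence(annot, genome, tid)
            for tid in annot.transcripts}


def simulate_ribo(config: SimulationConfig, annot: AnnotationSet,
                  genome: dict[str, str], truth: TruthTable,
                  raw_placements: bool = False
                  ) -> dict[tuple[str, str], PSiteTrack]:
    """P-site tracks per (stage, replicate).

    Main-ORF P-sites: total ~ Poisson(TE x abundance x CDS_kb x ribo_depth),
    positions multinomial over codons (start codon up-weighted by
    ``init_peak_weight``), within-codon frame multinomial with ``frame_probs``.
    Planted ORFs use their own occupancy level; untranslated planted ORFs get
    the same occupancy but uniform positions and frames (background binding
    without engaged elongation).  Footprint lengths are drawn from the
    configured 25-33 nt distribution.

    With ``raw_placements=True`` the emitted positions are genome-space 5'
    footprint ends, displaced from the P-site by ``psite_offset`` nt against
    the direction of translation; this mode exercises offset calibration.
    """
    config.validate()
    maps = _transcript_maps(annot, genome)
    lengths = np.array(sorted(config.footprint_length_probs))
    lprobs = np.array([config.footprint_length_probs[int(l)] for l in lengths])
    fprobs = np.asarray(config.frame_probs)
    tracks: dict[tuple[str, str], PSiteTrack] = {}

    regions = []  # (tid, tx_start, n_codons, translated, level source)
    for gid, row in truth.genes.iterrows():
        if row["noncoding"]:
            continue
        t = annot.transcripts[row["transcript_id"]]
        utr5_len = sum(e - s for s, e in t.utr5)
        n_codons = t.cds_length // 3
        regions.append((row["transcript_id"], utr5_len, n_codons, True,
                        ("gene", gid)))
    for oid, row in truth.orfs.iterrows():
        regions.append((row["transcript_id"], int(row["tx_start"]),
                        int(row["n_codons"]), bool(row["translated"]),
                        ("orf", oid)))

    for si, stage in enumerate(config.stage_names):
        for rep in range(1, config.n_replicates + 1):
            rng = np.random.default_rng((config.seed, 3, si, rep))
            chroms, strands, gposs, lens = [], [], [], []
            for tid, tx_start, n_codons, translated, (kind, key) in regions:
                t = annot.transcripts[tid]
                if kind == "gene":
                    mu = (truth.te.loc[key, stage] * truth.abundance.loc[key, stage]
                          * (3 * n_codons / 1000.0) * config.ribo_depth)
                else:
                    mu = (truth.orf_levels.loc[key, stage]
                          * (3 * n_codons / 1000.0) * config.ribo_depth)
                n = int(rng.poisson(mu))
                if n == 0:
                    continue
                if translated:
                    w = np.ones(n_codons)
                    w[0] = config.init_peak_weight
                    w /= w.sum()
                    codon = rng.choice(n_codons, size=n, p=w)
                    frame = rng.choice(3, size=n, p=fprobs)
                else:
                    codon = rng.integers(0, n_codons, size=n)
                    frame = rng.integers(0, 3, size=n)
                tpos = tx_start + 3 * codon + frame
                gpos = maps[tid].genome_positions[tpos]
                L = rng.choice(lengths, size=n, p=lprobs)
                if raw_placements:
                    sign = 1 if t.strand == "+" else -1
                    gpos = gpos - sign * config.psite_offset
                chroms.append(np.full(n, t.chrom, dtype=object))
                strands.append(np.full(n, t.strand, dtype=object))
                gposs.append(gpos)
                lens.append(L)
            sample = f"{stage}_rep{rep}"
            if not gposs:
                tracks[(stage, f"rep{rep}")] = PSiteTrack.empty(sample)
                continue
            df = pd.DataFrame({
                "chrom": np.concatenate(chroms),
                "position": np.concatenate(gposs),
                "strand": np.concatenate(strands),
                "read_length": np.concatenate(lens).astype(int)})
            df["count"] = 1
            df = df.groupby(["chrom", "position", "strand", "read_length"],
                            as_index=False)["count"].sum()
            tracks[(stage, f"rep{rep}")] = PSiteTrack.from_frame(sample, df)
    return tracks


def build_isoform_models(config: SimulationConfig, annot: AnnotationSet,
                         truth: TruthTable, flank: int = 30) -> AnnotationSet:
    """Isoform annotation: one transcript per isoform-backed planted 3'ORF.

    Each backed isoform reproduces the exon structure around its ORF (the ORF
    genome blocks, with flanks kept inside the host transcript's exons), so
    containment and frame checks hold exactly.  A few single-exon decoy
    isoforms over intergenic sequence are added as negatives.
    """
    rng = np.random.default_rng((config.seed, 4))
    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    for oid, row in truth.orfs.iterrows():
        if not row["isoform_backed"]:
            continue
        host = annot.transcripts[row["transcript_id"]]
        blocks = tx_span_to_genome_blocks(host.exons, host.strand,
                                          int(row["tx_start"]),
                                          int(row["tx_end"]))
        host_exons = sorted(host.exons)
        lo, hi = blocks[0][0], blocks[-1][1]
        for s, e in host_exons:
            if s <= lo < e:
                lo = max(s, lo - flank)
            if s < hi <= e:
                hi = min(e, hi + flank)
        ext = [list(b) for b in blocks]
        ext[0][0] = lo
        ext[-1][1] = hi
        exons = _tx_order([tuple(b) for b in ext], host.strand)
        iid = f"iso_{oid}"
        genes[iid] = Gene(iid, host.chrom, host.strand, lo, hi)
        transcripts[iid + ".t1"] = Transcript(
            id=iid + ".t1", gene_id=iid, chrom=host.chrom, strand=host.strand,
            exons=exons, noncoding=True)
    # decoys over intergenic space
    for k in range(config.n_decoy_isoforms):
        chrom = sorted(annot.chromosomes)[k % len(annot.chromosomes)]
        occupied = [(g.start, g.end) for g in annot.genes.values()
                    if g.chrom == chrom]
        occupied.sort()
        gaps = []
        prev = 0
        for s, e in occupied:
            if s - prev >= 120:
                gaps.append((prev, s))
            prev = max(prev, e)
        if not gaps:
            continue
        gs, ge = gaps[int(rng.integers(0, len(gaps)))]
        lo = int(rng.integers(gs, max(gs + 1, ge - 100)))
        hi = min(ge, lo + 100)
        iid = f"decoy{k:03d}"
        genes[iid] = Gene(iid, chrom, "+", lo, hi)
        transcripts[iid + ".t1"] = Transcript(
            id=iid + ".t1", gene_id=iid, chrom=chrom, strand="+",
            exons=[(lo, hi)], noncoding=True)
    return AnnotationSet(chromosomes=dict(annot.chromosomes), genes=genes,
                         transcripts=transcripts, source="simulated-isoforms")


def simulate_variation_pair(n_genes: int, stage_names: list[str],
                            inflation: float, seed: int,
                            mu: float = 5.0, sigma: float = 1.5
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched FPKM/RPKM matrices with a known translational variance inflation.

    On the log2(x+1) scale the translatome values equal the transcriptome
    values plus independent noise with variance ``inflation`` times the
    transcriptome variance, so the expected per-stage increase in expression
    variation is exactly ``100 * inflation`` percent.
    """
    rng = np.random.default_rng(seed)
    idx = [f"g{i:05d}" for i in range(n_genes)]
    y = rng.normal(mu, sigma, size=(n_genes, len(stage_names)))
    e = rng.normal(0.0, sigma * np.sqrt(inflation),
                   size=(n_genes, len(stage_names)))
    rna = pd.DataFrame(np.exp2(y) - 1.0, index=idx, columns=stage_names)
    ribo = pd.DataFrame(np.exp2(y + e) - 1.0, index=idx, columns=stage_names)
    return rna.clip(lower=0.0), ribo.clip(lower=0.0)


def simulate_te_archetypes(n_genes: int, stage_names: list[str],
                           phase_map: dict[str, str], seed: int,
                           noise_sd: float = 0.05
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Max-normalized TE profiles drawn from phase-specific archetypes.

    Each gene follows one of the phases' archetype profiles (high in the
    phase's stages, low elsewhere) plus Gaussian noise; returns the profile
    matrix and the true archetype labels, for clustering-recovery checks.
    """
    rng = np.random.default_rng(seed)
    phases = list(dict.fromkeys(phase_map[s] for s in stage_names))
    labels = [phases[i % len(phases)] for i in range(n_genes)]
    rows = []
    for lab in labels:
        prof = np.array([0.9 if phase_map[s] == lab else 0.15
                         for s in stage_names])
        rows.append(np.clip(prof + rng.normal(0, noise_sd, len(stage_names)),
                            0.0, 1.0))
    idx = [f"g{i:05d}" for i in range(n_genes)]
    return (pd.DataFrame(rows, index=idx, columns=stage_names),
            pd.Series(labels, index=idx, name="archetype"))
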