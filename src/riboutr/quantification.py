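"""Gene-level FPKM/RPKM, expressed/translated calling and translation efficiency.

FPKM (RNA-seq) and RPKM (Ribo-seq) follow the classic definition
``count / feature_kb / total_mapped_millions``, with gene exon length taken as
the union of exons over the gene's transcripts and CDS length as the union of
CDS intervals.  Replicates are normalized per library and then averaged;
translation efficiency is computed on the replicate means with a pseudocount
of 1 on both layers:

    TE = (RPKM + 1) / (FPKM + 1)

so TE = 1 exactly when a gene is silent in both layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import AnnotationSet
from .periodicity import PSiteTrack

PSEUDOCOUNT = 1.0
EXPRESSED_MIN = 1.0  # FPKM/RPKM threshold for calling a gene expressed/translated


def feature_lengths_kb(annot: AnnotationSet, feature: str) -> pd.Series:
    """Per-gene union length of exons or CDS, in kilobases."""
    vals = {}
    for gid in annot.genes:
        ivs = annot.gene_feature_intervals(gid, feature)
        vals[gid] = sum(e - s for s, e in ivs) / 1000.0
    return pd.Series(vals, name=f"{feature}_kb")


def count_features(track: PSiteTrack, annot: AnnotationSet,
                   feature: str = "CDS") -> pd.Series:
    """Count P-sites/placements per gene over exon or CDS unions, strand-matched.

    A position inside features of several genes contributes its full count to
    each of them (multi-overlap counting).  Positions outside any feature are
    not attributed.
    """
    known = set(annot.chromosomes)
    offenders = sorted(set(track.frame["chrom"]) - known)
    if offenders:
        raise ValueError(f"placements on unknown chromosomes: {offenders}")
    counts = {}
    for gid, gene in annot.genes.items():
        ivs = annot.gene_feature_intervals(gid, feature)
        if not ivs:
            counts[gid] = 0
            continue
        xs, cs = track.positions(gene.chrom, gene.strand)
        total = 0
        for s, e in ivs:
            i0, i1 = np.searchsorted(xs, [s, e])
            total += int(cs[i0:i1].sum())
        counts[gid] = total
    return pd.Series(counts, name="count")


def normalize(counts: pd.DataFrame | pd.Series, lengths_kb: pd.Series,
              total_millions: float | pd.Series) -> pd.DataFrame | pd.Series:
    """FPKM/RPKM: count / length_kb / total_mapped_millions."""
    lengths_kb = lengths_kb.reindex(counts.index)
    bad = lengths_kb[(lengths_kb.isna()) | (lengths_kb <= 0)]
    if len(bad):
        raise ValueError(f"zero/missing feature length for genes: "
                         f"{sorted(bad.index)[:5]}")
    return counts.div(lengths_kb, axis=0) / total_millions


@dataclass
class ExpressionMatrix:
    """Gene x stage expression with replicate provenance.

    ``rna_reps``/``ribo_reps`` carry one column per (stage, replicate) pair
    (MultiIndex columns); ``rna``/``ribo`` are the replicate means actually
    used downstream.  ``library_sizes`` records total counted
    placements per library in millions.
    """

    rna_reps: pd.DataFrame
    ribo_reps: pd.DataFrame
    exon_kb: pd.Series
    cds_kb: pd.Series
    library_sizes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.rna_reps.index.equals(self.ribo_reps.index):
            raise ValueError("RNA and Ribo matrices must share the gene index")

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(s for s, _ in self.rna_reps.columns))

    @property
    def rna(self) -> pd.DataFrame:
        return self.rna_reps.T.groupby(level=0).mean().T[self.stages]

    @property
    def ribo(self) -> pd.DataFrame:
        return self.ribo_reps.T.groupby(level=0).mean().T[self.stages]


@dataclass
class TEProfile:
    """Per-gene, per-stage translation efficiency (pseudocounted ratio)."""

    te: pd.DataFrame
    pseudocount: float = PSEUDOCOUNT


def build_expression_matrix(rna_counts: pd.DataFrame, ribo_counts: pd.DataFrame,
                            annot: AnnotationSet) -> ExpressionMatrix:
    """Normalize replicate count tables ((stage, rep) columns) into FPKM/RPKM."""
    exon_kb = feature_lengths_kb(annot, "exon")
    cds_kb = feature_lengths_kb(annot, "CDS")
    genes = rna_counts.index
    coding = cds_kb[cds_kb > 0].index.intersection(genes)
    lib_sizes = {}
    rna_norm, ribo_norm = {}, {}
    for col in rna_counts.columns:
        total_m = rna_counts[col].sum() / 1e6
        lib_sizes[("rna",) + tuple(col)] = total_m
        rna_norm[col] = normalize(rna_counts[col], exon_kb, total_m)
    for col in ribo_counts.columns:
        total_m = ribo_counts[col].sum() / 1e6
        lib_sizes[("ribo",) + tuple(col)] = total_m
        ribo_norm[col] = normalize(ribo_counts.loc[coding, col],
                                   cds_kb, total_m).reindex(genes, fill_value=0.0)
    rna_df = pd.DataFrame(rna_norm)
    ribo_df = pd.DataFrame(ribo_norm)
    rna_df.columns = pd.MultiIndex.from_tuples(rna_counts.columns)
    ribo_df.columns = pd.MultiIndex.from_tuples(ribo_counts.columns)
    return ExpressionMatrix(rna_reps=rna_df, ribo_reps=ribo_df,
                            exon_kb=exon_kb.loc[genes], cds_kb=cds_kb.loc[genes],
                            library_sizes=lib_sizes)


def compute_te(expr: ExpressionMatrix,
               pseudocount: float = PSEUDOCOUNT) -> TEProfile:
    """TE = (RPKM + pc) / (FPKM + pc), elementwise on replicate means."""
    te = (expr.ribo + pseudocount) / (expr.rna + pseudocount)
    return TEProfile(te=te, pseudocount=pseudocount)


@dataclass
class ExpressedCall:
    transcribed: dict[str, set]   # stage -> genes with FPKM >= threshold
    translated: dict[str, set]    # stage -> genes with RPKM >= threshold
    threshold: float
    summary: pd.DataFrame         # per stage: counts and mutual fractions


def call_expressed(expr: ExpressionMatrix,
                   threshold: float = EXPRESSED_MIN) -> ExpressedCall:
    """Per-stage transcribed (FPKM >= t) and translated (RPKM >= t) gene sets.

    The threshold is inclusive and applied to replicate means.  The summary
    reports, per stage, the fraction of transcribed genes that are translated
    and vice versa.
    """
    transcribed, translated, rows = {}, {}, []
    rna, ribo = expr.rna, expr.ribo
    for stage in expr.stages:
        tx = set(rna.index[rna[stage] >= threshold])
        tl = set(ribo.index[ribo[stage] >= threshold])
        transcribed[stage], translated[stage] = tx, tl
        both = tx & tl
        rows.append({
            "stage": stage, "n_transcribed": len(tx), "n_translated": len(tl),
            "frac_transcribed_translated": len(both) / len(tx) if tx else np.nan,
            "frac_translated_transcribed": len(both) / len(tl) if tl else np.nan,
        })
    return ExpressedCall(transcribed, translated, threshold,
                         pd.DataFrame(rows).set_index("stage"))
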