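"""TE-based gene classification, expression-variation statistics and
ORF-feature-vs-TE relationships.

Gene classes follow threshold semantics on the pseudocounted TE: a stage
qualifies for classification when the gene is well expressed there
(max(FPKM, RPKM) >= 50 by default); at qualifying stages TE > 2 marks "high"
and TE < 0.5 marks "low" translation relative to transcription.  Gene-level
labels: "high" (high at >= 1 stage), "very_high" (additionally phase-mean
TE > 5 in >= 1 phase), "low" (low somewhere, never high), "fluctuating"
(high at one stage and low at another), else "none".

Expression variation per stage is the population variance across genes of
log2(x+1)-transformed FPKM (transcriptome) or RPKM (translatome), computed
over the identical filtered gene set for both layers; the translatome-vs-
transcriptome percent increase summarizes how much translational regulation
adds to expression variation.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantification import ExpressionMatrix, TEProfile

TE_HIGH = 2.0
TE_VERY_HIGH = 5.0
TE_LOW = 0.5
EXPR_MIN = 50.0


def classify_te(expr: ExpressionMatrix, te: TEProfile,
                expr_min: float = EXPR_MIN, high: float = TE_HIGH,
                very_high: float = TE_VERY_HIGH, low: float = TE_LOW,
                phase_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-gene TE classification.

    Returns a frame indexed by gene with per-stage labels
    (high/low/none/unqualified), the gene-level class, the qualifying stages
    and whether the gene qualifies at any stage at all.
    """
    rna, ribo, tev = expr.rna, expr.ribo, te.te
    stages = list(tev.columns)
    phase_map = phase_map or {}
    qual = (rna >= expr_min) | (ribo >= expr_min)
    rows = []
    for gene in tev.index:
        labels = {}
        for s in stages:
            if not qual.loc[gene, s]:
                labels[s] = "unqualified"
            elif tev.loc[gene, s] > high:
                labels[s] = "high"
            elif tev.loc[gene, s] < low:
                labels[s] = "low"
            else:
                labels[s] = "none"
        any_high = any(v == "high" for v in labels.values())
        any_low = any(v == "low" for v in labels.values())
        if any_high and phase_map:
            phases = sorted({phase_map[s] for s in stages if s in phase_map})
            phase_means = {
                p: tev.loc[gene, [s for s in stages if phase_map.get(s) == p]].mean()
                for p in phases}
            is_very = any(m > very_high for m in phase_means.values())
        else:
            is_very = False
        if any_high and any_low:
            cls = "fluctuating"
        elif any_high:
            cls = "very_high" if is_very else "high"
        elif any_low:
            cls = "low"
        else:
            cls = "none"
        rows.append({"gene": gene, "class": cls,
                     "qualified_any_stage": bool(qual.loc[gene].any()),
                     "qualifying_stages": ",".join(
                         s for s in stages if qual.loc[gene, s]),
                     **{f"stage_{s}": labels[s] for s in stages}})
    return pd.DataFrame(rows).set_index("gene")


@dataclass
class VarianceReport:
    """Per-stage expression variation of the two layers over a shared gene set."""

    table: pd.DataFrame       # stage-indexed: var_rna, var_ribo, percent_increase
    genes_used: list[str]
    min_median: float
    transform: str


def expression_variation(rna: pd.DataFrame, ribo: pd.DataFrame,
                         min_median: float = 1.0,
                         log2_transform: bool = True) -> VarianceReport:
    """Expression variation across genes, per stage, for both layers.

    Genes are retained when their median across stages exceeds ``min_median``
    in *both* layers (the filters are intersected so the variance is computed
    over the identical gene set).  The variance is the population variance
    (denominator n).  With ``log2_transform`` values enter as log2(x+1);
    untransformed variances are reported alongside.
    """
    keep = rna.index[(rna.median(axis=1) > min_median)
                     & (ribo.median(axis=1) > min_median)]
    if len(keep) < 2:
        raise ValueError("fewer than 2 genes pass the median-expression filter")
    r = rna.loc[keep]
    b = ribo.loc[keep]
    rt = np.log2(r + 1.0) if log2_transform else r
    bt = np.log2(b + 1.0) if log2_transform else b
    table = pd.DataFrame({
        "var_rna": rt.var(axis=0, ddof=0),
        "var_ribo": bt.var(axis=0, ddof=0),
        "var_rna_raw": r.var(axis=0, ddof=0),
        "var_ribo_raw": b.var(axis=0, ddof=0),
    })
    table["percent_increase"] = 100.0 * (table["var_ribo"] - table["var_rna"]) \
        / table["var_rna"]
    table["percent_increase_raw"] = 100.0 * (table["var_ribo_raw"]
                                             - table["var_rna_raw"]) \
        / table["var_rna_raw"]
    table.index.name = "stage"
    return VarianceReport(table=table, genes_used=list(keep),
                          min_median=min_median,
                          transform="log2(x+1)" if log2_transform else "identity")


def tukey_letters(groups: list[np.ndarray], labels: list[str],
                  alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from pairwise Tukey HSD comparisons.

    Groups that are not significantly different share at least one letter.
    """
    res = stats.tukey_hsd(*groups)
    k = len(groups)
    different = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(k):
            if i != j and res.pvalue[i, j] < alpha:
                different[i, j] = True
    assigned: list[set[int]] = []  # letter -> member group indices
    for g in range(k):
        placed = False
        for members in assigned:
            if not any(different[g, m] for m in members):
                members.add(g)
                placed = True
        if not placed:
            assigned.append({g})
    out = {lab: "" for lab in labels}
    for li, members in enumerate(assigned):
        for m in sorted(members):
            out[labels[m]] += string.ascii_lowercase[li]
    return out


def _pearson_profile(x: pd.Series, y: pd.Series) -> float:
    mask = x.notna() & y.notna()
    if mask.sum() < 3:
        return np.nan
    xv, yv = x[mask].to_numpy(), y[mask].to_numpy()
    if np.std(xv) == 0 or np.std(yv) == 0:
        return np.nan
    return float(stats.pearsonr(xv, yv)[0])


def orf_te_relations(orfs, te: TEProfile,
                     classes: tuple[str, ...] = ("five_prime_ORF",
                                                 "three_prime_ORF")) -> dict:
    """Relate accepted UTR-ORF features to host-gene translation efficiency.

    Returns a dict with:

    ``per_orf``
        one row per ORF: Pearson r between its per-stage translation level
        and the host gene's per-stage TE (NaN when < 3 informative stages or
        a constant profile).
    ``group_tests``
        per ORF class: host-gene mean TE grouped by ORF count (0/1/2+) and by
        presence of a strong-Kozak ORF, with one-way ANOVA p-values and Tukey
        HSD letter displays.
    ``length_correlation``
        per ORF class: Spearman correlation between ORF length and host-gene
        mean TE.
    """
    stages = list(te.te.columns)
    per_orf_rows = []
    by_gene: dict[str, dict] = {}
    for o in orfs:
        if o.category not in classes:
            continue
        host = o.gene_id
        if host in te.te.index:
            levels = pd.Series({s: o.levels.get(s, np.nan) for s in stages})
            r = _pearson_profile(levels, te.te.loc[host, stages])
        else:
            r = np.nan
        per_orf_rows.append({"orf_id": o.id, "gene_id": host,
                             "category": o.category, "n_codons": o.n_codons,
                             "kozak_strong": o.kozak_strong,
                             "pearson_r_level_vs_te": r})
        rec = by_gene.setdefault(host, {c: 0 for c in classes}
                                 | {f"{c}_strong": False for c in classes}
                                 | {f"{c}_len": [] for c in classes})
        rec[o.category] += 1
        rec[f"{o.category}_len"].append(o.n_codons)
        if o.kozak_strong:
            rec[f"{o.category}_strong"] = True
    per_orf = pd.DataFrame(per_orf_rows).set_index("orf_id") \
        if per_orf_rows else pd.DataFrame()

    gene_mean_te = te.te.mean(axis=1)
    group_tests: dict[str, dict] = {}
    length_corr: dict[str, dict] = {}
    for cls in classes:
        counts = pd.Series({g: rec[cls] for g, rec in by_gene.items()})
        counts = counts.reindex(gene_mean_te.index, fill_value=0)
        buckets = {"0": gene_mean_te[counts == 0].to_numpy(),
                   "1": gene_mean_te[counts == 1].to_numpy(),
                   "2+": gene_mean_te[counts >= 2].to_numpy()}
        buckets = {k: v for k, v in buckets.items() if len(v) >= 2}
        entry: dict = {"n_per_bucket": {k: len(v) for k, v in buckets.items()}}
        if len(buckets) >= 2:
            f, p = stats.f_oneway(*buckets.values())
            entry["anova_p_by_count"] = float(p)
            entry["tukey_by_count"] = tukey_letters(
                list(buckets.values()), list(buckets))
        strong = pd.Series({g: rec[f"{cls}_strong"]
                            for g, rec in by_gene.items() if rec[cls] > 0})
        mask = strong.to_numpy(dtype=bool)
        kz = {"strong": gene_mean_te.loc[strong.index[mask]].to_numpy(),
              "weak": gene_mean_te.loc[strong.index[~mask]].to_numpy()}
        kz = {k: v for k, v in kz.items() if len(v) >= 2}
        if len(kz) == 2:
            f, p = stats.f_oneway(*kz.values())
            entry["anova_p_by_kozak"] = float(p)
            entry["tukey_by_kozak"] = tukey_letters(list(kz.values()), list(kz))
        group_tests[cls] = entry

        lens, tes = [], []
        for g, rec in by_gene.items():
            for L in rec[f"{cls}_len"]:
                if g in gene_mean_te.index:
                    lens.append(L)
                    tes.append(gene_mean_te[g])
        if len(lens) >= 3 and len(set(lens)) > 1:
            rho, p = stats.spearmanr(lens, tes)
            length_corr[cls] = {"spearman_rho": float(rho), "p": float(p),
                                "n": len(lens)}
        else:
            length_corr[cls] = {"spearman_rho": np.nan, "p": np.nan,
                                "n": len(lens)}
    return {"per_orf": per_orf, "group_tests": group_tests,
            "length_correlation": length_corr}
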