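import numpy as np
import pandas as pd
import pytest

from riboutr import quantification as quant
from riboutr import te_analysis as tea

STAGES = ["s1", "s2", "s3", "s4"]
PHASES = {"s1": "P1", "s2": "P1", "s3": "P2", "s4": "P2"}
BLAND = (10.0, 10.0)  # unqualified filler stage: TE == 1

# (gene, per-stage (FPKM, RPKM), expected class); hand-derived labels
GOLDEN = [
    ("g01", [(50, 150), BLAND, BLAND, BLAND], "high"),          # TE 2.96 once
    ("g02", [(20, 200), (20, 200), BLAND, BLAND], "very_high"), # P1 mean 9.57
    ("g03", [BLAND, BLAND, (100, 40), BLAND], "low"),           # TE 0.406
    ("g04", [(50, 150), BLAND, (100, 40), BLAND], "fluctuating"),
    ("g05", [(100, 100)] * 4, "none"),                          # TE ~ 1
    ("g06", [(30, 20)] * 4, "none"),                            # never qualifies
    ("g07", [(99, 199), BLAND, BLAND, BLAND], "none"),          # TE exactly 2
    ("g08", [(199, 99), BLAND, BLAND, BLAND], "none"),          # TE exactly 0.5
    ("g09", [BLAND, BLAND, (50, 150), (50, 150)], "high"),      # P2 mean 2.96
    ("g10", [(10, 40)] * 4, "none"),                            # TE 3.7, <50 expr
    ("g11", [(200, 50), (200, 50), BLAND, BLAND], "low"),       # TE 0.254 twice
    ("g12", [(20, 200), (20, 200), (100, 40), BLAND], "fluctuating"),
]


def _golden_expr():
    rna = pd.DataFrame({(s, "rep1"): {g: vals[i][0] for g, vals, _ in GOLDEN}
                        for i, s in enumerate(STAGES)})
    ribo = pd.DataFrame({(s, "rep1"): {g: vals[i][1] for g, vals, _ in GOLDEN}
                         for i, s in enumerate(STAGES)})
    rna.columns = pd.MultiIndex.from_tuples(rna.columns)
    ribo.columns = pd.MultiIndex.from_tuples(ribo.columns)
    kb = pd.Series(1.0, index=rna.index)
    return quant.ExpressionMatrix(rna, ribo, kb, kb)


class TestClassifyTe:
    def test_golden_twelve_gene_labels(self):
        expr = _golden_expr()
        te = quant.compute_te(expr)
        out = tea.classify_te(expr, te, phase_map=PHASES)
        for gene, _, expected in GOLDEN:
            assert out.loc[gene, "class"] == expected, gene

    def test_stage_labels_respect_qualification(self):
        expr = _golden_expr()
        te = quant.compute_te(expr)
        out = tea.classify_te(expr, te, phase_map=PHASES)
        assert out.loc["g06", "stage_s1"] == "unqualified"
        assert out.loc["g01", "stage_s1"] == "high"
        assert out.loc["g03", "stage_s3"] == "low"
        assert not out.loc["g06", "qualified_any_stage"]

    def test_very_high_requires_phase_mean(self):
        # high at one stage of a phase but phase mean diluted below 5
        rna = pd.DataFrame({("s1", "r"): {"g": 20.0}, ("s2", "r"): {"g": 20.0}})
        ribo = pd.DataFrame({("s1", "r"): {"g": 200.0}, ("s2", "r"): {"g": 40.0}})
        rna.columns = pd.MultiIndex.from_tuples(rna.columns)
        ribo.columns = pd.MultiIndex.from_tuples(ribo.columns)
        kb = pd.Series(1.0, index=["g"])
        expr = quant.ExpressionMatrix(rna, ribo, kb, kb)
        te = quant.compute_te(expr)
        # TE: 9.57 and 1.95 -> phase mean 5.76 > 5 in P1 -> very_high
        out = tea.classify_te(expr, te, phase_map={"s1": "P1", "s2": "P1"})
        assert out.loc["g", "class"] == "very_high"


class TestExpressionVariation:
    def test_constant_values_give_zero_variance(self):
        vals = pd.DataFrame({"s1": [1.0, 1.0, 1.0]}, index=list("abc"))
        rep = tea.expression_variation(vals + 5, vals + 5, min_median=0.0)
        assert rep.table.loc["s1", "var_rna"] == pytest.approx(0.0)

    def test_hand_computed_two_gene_variance(self):
        # raw {0, 2} -> log2 {0, 1.585}; population variance ~ 0.628
        rna = pd.DataFrame({"s1": [0.0, 2.0]}, index=["a", "b"])
        rep = tea.expression_variation(rna, rna, min_median=-1.0)
        assert rep.table.loc["s1", "var_rna"] == pytest.approx(0.6281, abs=1e-3)

    def test_matches_two_pass_variance_on_random_matrices(self):
        rng = np.random.default_rng(3)
        rna = pd.DataFrame(rng.gamma(2, 10, size=(200, 5)))
        ribo = pd.DataFrame(rng.gamma(2, 12, size=(200, 5)))
        rep = tea.expression_variation(rna, ribo)
        keep = rep.genes_used
        for j, stage in enumerate(rep.table.index):
            x = np.log2(rna.loc[keep, stage].to_numpy() + 1)
            mean = x.sum() / len(x)
            brute = sum((v - mean) ** 2 for v in x) / len(x)
            assert abs(rep.table.loc[stage, "var_rna"] - brute) < 1e-12

    def test_identical_gene_set_for_both_layers(self):
        rng = np.random.default_rng(4)
        rna = pd.DataFrame(rng.gamma(2, 5, size=(100, 4)))
        ribo = pd.DataFrame(rng.gamma(2, 5, size=(100, 4)))
        rep = tea.expression_variation(rna, ribo)
        keep = set(rep.genes_used)
        assert all(rna.loc[list(keep)].median(axis=1) > 1)
        assert all(ribo.loc[list(keep)].median(axis=1) > 1)

    def test_no_passing_genes_is_hard_error(self):
        rna = pd.DataFrame({"s1": [0.1, 0.2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="filter"):
            tea.expression_variation(rna, rna)


class TestCorrelationsAndLetters:
    def test_pearson_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = pd.Series(rng.normal(size=10))
            y = pd.Series(rng.normal(size=10))
            r = tea._pearson_profile(x, y)
            xm, ym = x - x.mean(), y - y.mean()
            brute = (xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
            assert abs(r - brute) < 1e-12

    def test_constant_profile_has_undefined_correlation(self):
        x = pd.Series([1.0, 1.0, 1.0, 1.0])
        y = pd.Series([1.0, 2.0, 3.0, 4.0])
        assert np.isnan(tea._pearson_profile(x, y))

    def test_tukey_letters_separate_distinct_groups(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0.1, 1, 50)
        c = rng.normal(8, 1, 50)
        letters = tea.tukey_letters([a, b, c], ["a", "b", "c"])
        assert set(letters["a"]) & set(letters["b"])      # a,b share a letter
        assert not set(letters["a"]) & set(letters["c"])  # c stands apart


class TestOrfTeRelations:
    def test_perfectly_scaled_orf_has_unit_correlation(self, default_run):
        te = default_run.te
        stages = list(te.te.columns)
        host = te.te.index[0]
        orf = next(o for o in default_run.accepted
                   if o.category in ("five_prime_ORF", "three_prime_ORF"))
        orf.gene_id = host
        orf.levels = {s: 3.5 * te.te.loc[host, s] for s in stages}
        rel = tea.orf_te_relations([orf], te)
        r = rel["per_orf"]["pearson_r_level_vs_te"].iloc[0]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_planted_negative_length_effect_is_recovered(self):
        from riboutr.synthetic_data import SimulationConfig, generate_genome

        cfg = SimulationConfig(seed=21, n_genes=220, length_te_slope=-0.6)
        cfg.orf_plan.n_five = 0
        cfg.orf_plan.n_nc = 0
        cfg.orf_plan.n_three = 200
        cfg.orf_plan.frac_translated = 1.0
        genome, annot, truth = generate_genome(cfg)
        # relate true planted lengths to true host TE, as the analysis would
        from riboutr.orf_discovery import ORFCall

        orfs = []
        for oid, row in truth.orfs.iterrows():
            o = ORFCall(id=oid, transcript_id=row["transcript_id"],
                        gene_id=row["gene"], chrom=row["chrom"],
                        strand=row["strand"], tx_start=int(row["tx_start"]),
                        tx_end=int(row["tx_end"]), genome_blocks=[],
                        category="three_prime_ORF", peptide="",
                        kozak_context="", kozak_strong=bool(row["kozak_strong"]))
            orfs.append(o)
        te = quant.TEProfile(te=truth.te.dropna())
        rel = tea.orf_te_relations(orfs, te)
        lc = rel["length_correlation"]["three_prime_ORF"]
        assert lc["n"] >= 200
        assert lc["spearman_rho"] < 0
        assert lc["p"] < 0.05
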