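import numpy as np
import pandas as pd
import pytest
from scipy import stats

from irscreen.quantify import SampleInfo
from irscreen.screen import (
    ScreenThresholds,
    association_table,
    condition_association,
    de_ratio_filter,
    rankl_induced_partition,
    screen_retained_introns,
)

from conftest import quant_from_counts

TH = ScreenThresholds()
SIDS = ["WT_none_1", "KO_none_1", "WT_RANKL_1", "WT_RANKL_2", "KO_RANKL_1", "KO_RANKL_2"]


def matrix(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=SIDS).rename_axis("gene_id")


class TestDeRatioFilter:
    def test_zero_floor_gives_large_ratio(self):
        m = matrix({"g": [0, 0, 0, 0, 0, 30]})  # (30+0.1)/0.1 = 301
        assert de_ratio_filter(m, TH) == ["g"]

    def test_constant_gene_fails(self):
        m = matrix({"g": [5] * 6})
        assert de_ratio_filter(m, TH) == []

    def test_ratio_exactly_three_fails_strict_inequality(self):
        m = matrix({"g": [0.9, 2.9, 0.9, 0.9, 0.9, 0.9]})  # 3.0/1.0 = 3.0
        assert de_ratio_filter(m, TH) == []


class TestConditionAssociation:
    def test_constant_values_give_p_one(self, six_design):
        res = condition_association([5.0] * 6, six_design, TH)
        assert res["p_rankl"] == 1.0 and res["p_genotype"] == 1.0
        assert not res["associated"]

    def test_stimulation_effect_detected(self, six_design):
        # log2(FPKM + 0.1): stimulated ~5, unstimulated ~1
        logs = {"WT_none_1": 1.0, "KO_none_1": 1.1, "WT_RANKL_1": 5.0,
                "WT_RANKL_2": 5.1, "KO_RANKL_1": 4.9, "KO_RANKL_2": 5.05}
        fpkms = [2 ** logs[s.sample_id] - 0.1 for s in six_design]
        res = condition_association(fpkms, six_design, TH)
        # independent Welch oracle on the log2 values
        a = np.array([5.0, 5.1, 4.9, 5.05])
        b = np.array([1.0, 1.1])
        se2 = a.var(ddof=1) / 4 + b.var(ddof=1) / 2
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / ((a.var(ddof=1) / 4) ** 2 / 3 + (b.var(ddof=1) / 2) ** 2 / 1)
        expected = 2 * stats.t.sf(abs(t), df)
        assert res["p_rankl"] == pytest.approx(expected)
        assert res["p_rankl"] < 0.05 and res["associated"]

    def test_genotype_only_effect_satisfies_disjunction(self, six_design):
        vals = {"WT_none_1": 100, "KO_none_1": 1, "WT_RANKL_1": 100,
                "WT_RANKL_2": 105, "KO_RANKL_1": 1, "KO_RANKL_2": 1.2}
        res = condition_association([vals[s.sample_id] for s in six_design], six_design, TH)
        assert res["p_genotype"] < 0.05 and res["associated"]

    def test_missing_factor_level_is_error(self):
        design = [SampleInfo("a", "WT", "RANKL", 1), SampleInfo("b", "KO", "RANKL", 1)]
        with pytest.raises(ValueError, match="stimulation"):
            condition_association([1.0, 2.0], design, TH)


class TestRanklInducedPartition:
    def test_hand_enumerated_partition(self, six_design):
        rows = {
            # induced and consistently higher in WT in both conditions
            "g_up_wt": [20, 1, 100, 110, 5, 6],
            # induction equal between genotypes
            "g_up_eq": [1, 1, 50, 52, 50, 51],
            # repressed by stimulation
            "g_down": [100, 100, 2, 2, 2, 2],
            # flat
            "g_flat": [20, 20, 20, 20, 20, 20],
        }
        m = matrix(rows)
        de = de_ratio_filter(m, TH)
        assert set(de) == {"g_up_wt", "g_up_eq", "g_down"}
        part = rankl_induced_partition(m, six_design, de, TH)
        assert set(part["induced"]) == {"g_up_wt", "g_up_eq"}
        assert part["wt_higher"] == ["g_up_wt"]

    def test_weak_genotype_difference_not_wt_higher(self, six_design):
        m = matrix({"g": [1, 1, 40, 41, 39, 40.5]})
        part = rankl_induced_partition(m, six_design, ["g"], TH)
        assert part["induced"] == ["g"] and part["wt_higher"] == []


def _cascade_fixture():
    """5 genes / 8 introns with written-out counts; FPKM == count numerically."""
    gene_counts = {
        "gA": [40, 40, 40, 40, 40, 40],
        "gB": [8, 8, 8, 8, 8, 8],
        "gC": [100, 100, 100, 100, 100, 100],
        "gD": [60, 60, 60, 60, 60, 60],
        "gE": [5, 5, 40, 40, 0, 0],
    }
    intron_counts = {
        "i1": {"gene": "gA", "counts": [1, 1, 4, 4, 16, 16]},
        "i2": {"gene": "gA", "counts": [12, 12, 12, 12, 12, 12]},
        "i3": {"gene": "gB", "counts": [50, 50, 50, 50, 50, 50]},
        "i4": {"gene": "gC", "counts": [9, 9, 9, 9, 9, 9]},
        "i5": {"gene": "gD", "counts": [5, 5, 30, 30, 20, 20]},
        "i6": {"gene": "gD", "counts": [1, 1, 2, 2, 30, 30]},
        "i7": {"gene": "gE", "counts": [0, 0, 0, 0, 12, 12]},
        "i8": {"gene": "gE", "counts": [11, 11, 11, 11, 11, 11]},
    }
    m = matrix(gene_counts)  # FPKM == count with 1 kb / 1e6 normalisation
    meta = [
        {"intron": k, "gene_id": v["gene"], "ordinal": j + 1, "chrom": "c",
         "start": 1000 * j, "end": 1000 * j + 1000, "strand": "+"}
        for j, (k, v) in enumerate(intron_counts.items())
    ]
    counts = {s: [intron_counts[k]["counts"][i] for k in intron_counts]
              for i, s in enumerate(SIDS)}
    quant = quant_from_counts(meta, counts, SIDS)
    return quant, m, intron_counts


def brute_force_cascade(intron_counts, gene_counts, th=TH):
    """Independent recomputation of the cascade from raw counts."""
    wt_stim, ko_stim = [2, 3], [4, 5]
    result = {}
    for key, rec in intron_counts.items():
        g = gene_counts[rec["gene"]]
        p1 = max(g) > th.gene_fpkm_min
        p2 = max(rec["counts"]) > th.intronic_fpkm_min
        ir = [(rec["counts"][i] + th.pseudocount) / (g[i] + th.pseudocount)
              for i in range(6)]
        wt = sum(ir[i] for i in wt_stim) / 2
        ko = sum(ir[i] for i in ko_stim) / 2
        p3 = (ko / wt) > th.ir_ratio_min
        result[key] = {"p1": p1, "p2": p2, "p3": p3, "selected": p1 and p2 and p3,
                       "ratio": ko / wt}
    return result


class TestScreenCascade:
    def test_hand_computed_selection(self, six_design):
        quant, m, _ = _cascade_fixture()
        calls, funnel = screen_retained_introns(quant, m, six_design)
        assert set(calls.index[calls["selected"]]) == {"i1", "i6", "i7", "i8"}
        # i1: IR 4.1/40.1 vs 16.1/40.1 -> ratio ~3.93
        assert calls.loc["i1", "ir_ratio"] == pytest.approx(16.1 / 4.1)
        assert funnel["introns_total"] == 8
        assert funnel["pass_gene_fpkm"] == 7          # i3 (gB, max FPKM 8) drops
        assert funnel["pass_intronic_fpkm"] == 6      # i4 (<=10 everywhere) drops

    def test_flags_match_brute_force(self, six_design):
        quant, m, intron_counts = _cascade_fixture()
        calls, _ = screen_retained_introns(quant, m, six_design)
        gene_counts = {g: m.loc[g].tolist() for g in m.index}
        brute = brute_force_cascade(intron_counts, gene_counts)
        for key, exp in brute.items():
            row = calls.loc[key]
            assert row["passed_gene_fpkm"] == exp["p1"], key
            assert row["passed_intronic_fpkm"] == exp["p2"], key
            assert row["passed_ratio"] == exp["p3"], key
            assert row["selected"] == exp["selected"], key
            assert row["ir_ratio"] == pytest.approx(exp["ratio"])

    def test_gene_below_fpkm_floor_excluded_despite_high_ir(self, six_design):
        quant, m, _ = _cascade_fixture()
        calls, _ = screen_retained_introns(quant, m, six_design)
        assert not calls.loc["i3", "selected"] and not calls.loc["i3", "passed_gene_fpkm"]

    def test_low_intronic_fpkm_excluded(self, six_design):
        quant, m, _ = _cascade_fixture()
        calls, _ = screen_retained_introns(quant, m, six_design)
        assert not calls.loc["i4", "passed_intronic_fpkm"]

    def test_requires_stimulated_samples_of_both_genotypes(self):
        quant, m, _ = _cascade_fixture()
        design = [SampleInfo("WT_none_1", "WT", "none", 1),
                  SampleInfo("KO_none_1", "KO", "none", 1),
                  SampleInfo("WT_RANKL_1", "WT", "RANKL", 1),
                  SampleInfo("WT_RANKL_2", "WT", "RANKL", 2)]
        with pytest.raises(ValueError, match="stimulated"):
            screen_retained_introns(quant, m, design)

    def test_threshold_monotonicity(self, six_design):
        quant, m, _ = _cascade_fixture()
        base, _ = screen_retained_introns(quant, m, six_design)
        stricter, _ = screen_retained_introns(
            quant, m, six_design, ScreenThresholds(ir_ratio_min=3.0))
        assert set(stricter.index[stricter["selected"]]) <= set(base.index[base["selected"]])
        looser, _ = screen_retained_introns(
            quant, m, six_design, ScreenThresholds(gene_fpkm_min=1.0))
        assert set(base.index[base["selected"]]) <= set(looser.index[looser["selected"]])


def test_thresholds_validation_and_file_round_trip(tmp_path):
    with pytest.raises(ValueError):
        ScreenThresholds(alpha=1.5)
    with pytest.raises(ValueError):
        ScreenThresholds(pseudocount=0)
    p = tmp_path / "th.cfg"
    p.write_text("# screen thresholds\nir_ratio_min = 2.0\ngene_fpkm_min = 5\n")
    th = ScreenThresholds.from_file(p)
    assert th.ir_ratio_min == 2.0 and th.gene_fpkm_min == 5.0 and th.de_ratio == 3.0
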