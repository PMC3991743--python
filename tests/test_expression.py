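"""Two-line fold-change DE calls, Venn regions, drought reversal, motifs."""

import numpy as np
import pandas as pd
import pytest

from mirtarkit.expression import (
    DECall,
    ExpressionMatrix,
    call_de,
    category_crosstab,
    drought_crosstab,
    scan_promoters,
    venn_counts,
)
from mirtarkit.simulate import ExpressionSpec, gen_expression


def tiny_matrix(rows: dict, floor=1.0) -> ExpressionMatrix:
    """Matrix with samples WT_r1, WT_r2, L1_r1, L1_r2, L2_r1, L2_r2."""
    cols = ["WT_r1", "WT_r2", "L1_r1", "L1_r2", "L2_r1", "L2_r2"]
    samples = pd.DataFrame(
        [
            {"sample": c, "group": "WT" if c.startswith("WT") else "OE",
             "line": c.split("_")[0], "replicate": int(c[-1])}
            for c in cols
        ]
    )
    signals = pd.DataFrame(rows, index=cols).T
    return ExpressionMatrix(signals=signals, samples=samples, floor=floor)


class TestCallDe:
    def test_two_fold_in_both_lines_is_up(self):
        m = tiny_matrix({"g1": [10, 10, 30, 30, 25, 25]})
        calls = call_de(m, fold=2.0)
        assert calls[0].call == "UP"
        assert calls[0].ratios == {"L1": 3.0, "L2": 2.5}

    def test_single_line_change_is_insufficient(self):
        m = tiny_matrix({"g1": [10, 10, 30, 30, 15, 15]})
        assert call_de(m, fold=2.0)[0].call == "NONE"

    def test_half_fold_in_both_lines_is_down(self):
        m = tiny_matrix({"g1": [40, 40, 10, 10, 20, 20]})
        assert call_de(m, fold=2.0)[0].call == "DOWN"

    def test_thresholds_inclusive(self):
        m = tiny_matrix({"up": [10, 10, 20, 20, 20, 20],
                         "down": [20, 20, 10, 10, 10, 10]})
        calls = {c.gene_id: c.call for c in call_de(m, fold=2.0)}
        assert calls == {"up": "UP", "down": "DOWN"}

    def test_missing_wt_is_design_error(self):
        samples = pd.DataFrame(
            [{"sample": "L1_r1", "group": "OE", "line": "L1", "replicate": 1}]
        )
        signals = pd.DataFrame({"L1_r1": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="WT"):
            ExpressionMatrix(signals=signals, samples=samples)

    def test_scaling_a_gene_leaves_its_call_unchanged(self):
        base = [10, 12, 45, 40, 33, 28]
        m1 = tiny_matrix({"g1": base})
        m2 = tiny_matrix({"g1": [100 * v for v in base]})
        assert call_de(m1)[0].call == call_de(m2)[0].call

    def test_signal_floor_prevents_ratio_blowup(self):
        m = tiny_matrix({"g1": [0.001, 0.001, 0.5, 0.5, 0.5, 0.5]})
        # both WT and OE floored to 1.0 -> ratio 0.5... wait OE floored too
        assert call_de(m)[0].ratios["L1"] == 1.0

    def test_per_replicate_mode_is_stricter(self):
        # line 2 has one replicate short of 2-fold
        m = tiny_matrix({"g1": [10, 10, 30, 30, 25, 15]})
        assert call_de(m, ratio_mode="mean")[0].call == "UP"
        assert call_de(m, ratio_mode="per_replicate")[0].call == "NONE"

    def test_recovers_planted_counts_at_moderate_noise(self):
        spec = ExpressionSpec(
            n_genes=1000, genotypes=("OE1",), n_up=50, n_down=80,
            fold=4.0, sigma=0.1,
        )
        matrices, _, truth = gen_expression(spec, seed=7)
        calls = call_de(matrices["OE1"])
        n_up = sum(c.call == "UP" for c in calls)
        n_down = sum(c.call == "DOWN" for c in calls)
        assert abs(n_up - 50) <= 0.05 * 50
        assert abs(n_down - 80) <= 0.05 * 80

    def test_sensitivity_and_specificity_at_planted_fold_four(self):
        spec = ExpressionSpec(
            n_genes=2000, genotypes=("OE1",), n_up=100, n_down=100,
            fold=4.0, sigma=0.05,
        )
        matrices, _, truth = gen_expression(spec, seed=13)
        calls = {c.gene_id: c.call for c in call_de(matrices["OE1"])}
        planted = dict(zip(truth["gene_id"], truth["planted_call"]))
        tp = sum(1 for g, c in planted.items() if calls[g] == c)
        sensitivity = tp / len(planted)
        negatives = [g for g in calls if g not in planted]
        tn = sum(1 for g in negatives if calls[g] == "NONE")
        specificity = tn / len(negatives)
        assert sensitivity >= 0.99
        assert specificity >= 0.99


class TestVennCounts:
    def test_identical_sets_fill_only_the_full_intersection(self):
        s = set(map(str, range(30)))
        regions = venn_counts({"A": s, "B": s, "C": s, "D": s})
        assert regions[("A", "B", "C", "D")] == 30
        assert all(v == 0 for k, v in regions.items() if len(k) < 4)

    def test_disjoint_sets_fill_only_exclusive_regions(self):
        sets = {n: {f"{n}{i}" for i in range(5 + j)}
                for j, n in enumerate("ABCD")}
        regions = venn_counts(sets)
        for j, n in enumerate("ABCD"):
            assert regions[(n,)] == 5 + j
        assert all(v == 0 for k, v in regions.items() if len(k) > 1)

    def test_regions_sum_to_union_on_random_sets(self, rng):
        for _ in range(20):
            sets = {
                n: set(map(int, rng.choice(200, size=rng.integers(10, 80),
                                           replace=False)))
                for n in "ABCD"
            }
            regions = venn_counts(sets)
            assert sum(regions.values()) == len(set.union(*sets.values()))

    def test_planted_common_core_recovered(self):
        spec = ExpressionSpec(
            n_genes=1500, genotypes=("A", "B", "C", "D"),
            n_up=10, n_down=20, n_common_up=11, n_common_down=79,
            fold=4.0, sigma=0.05,
        )
        matrices, _, _ = gen_expression(spec, seed=3)
        down_sets = {
            gt: {c.gene_id for c in call_de(m) if c.call == "DOWN"}
            for gt, m in matrices.items()
        }
        regions = venn_counts(down_sets)
        assert regions[("A", "B", "C", "D")] == 79


class TestDroughtCrosstab:
    def test_fully_reversed_annotation_gives_fraction_one(self):
        calls = [DECall("g1", {}, "UP"), DECall("g2", {}, "DOWN"),
                 DECall("g3", {}, "NONE")]
        annot = {"g1": "DOWN", "g2": "UP"}
        table, reversal = drought_crosstab({"OE1": calls}, annot)
        assert reversal["OE1"] == 1.0

    def test_marginals_equal_call_counts(self):
        calls = [DECall(f"g{i}", {}, "UP") for i in range(7)] + [
            DECall(f"h{i}", {}, "DOWN") for i in range(5)
        ]
        annot = {c.gene_id: "NONE" for c in calls}
        table, _ = drought_crosstab({"OE1": calls}, annot)
        up_total = table.loc[table["oe_call"] == "UP", "count"].sum()
        down_total = table.loc[table["oe_call"] == "DOWN", "count"].sum()
        assert (up_total, down_total) == (7, 5)

    def test_uncovered_genes_count_as_none(self):
        calls = [DECall("g1", {}, "UP")]
        table, reversal = drought_crosstab({"OE1": calls}, {})
        row = table[(table["oe_call"] == "UP") & (table["drought_response"] == "NONE")]
        assert int(row["count"].iloc[0]) == 1
        assert reversal["OE1"] == 0.0

    def test_independent_annotation_near_expected_fraction(self, rng):
        n = 3000
        calls = [DECall(f"g{i}", {}, "UP") for i in range(n)]
        p_down = 0.3
        annot = {
            f"g{i}": ("DOWN" if rng.random() < p_down else "NONE") for i in range(n)
        }
        _, reversal = drought_crosstab({"OE1": calls}, annot)
        sd = np.sqrt(p_down * (1 - p_down) / n)
        assert abs(reversal["OE1"] - p_down) <= 3 * sd

    def test_empty_call_list_gives_nan_fraction(self):
        table, reversal = drought_crosstab({"OE1": []}, {})
        assert table["count"].sum() == 0
        assert np.isnan(reversal["OE1"])

    def test_generator_reversal_probability_one(self):
        spec = ExpressionSpec(
            n_genes=500, genotypes=("OE1",), n_up=30, n_down=30,
            fold=4.0, sigma=0.0, reversal_prob=1.0,
        )
        matrices, drought, _ = gen_expression(spec, seed=21)
        calls = call_de(matrices["OE1"])
        _, reversal = drought_crosstab({"OE1": calls}, drought)
        assert reversal["OE1"] == 1.0


class TestCategoryCrosstab:
    def test_counts_by_category_with_unassigned_fallback(self):
        calls = [DECall("g1", {}, "UP"), DECall("g2", {}, "DOWN"),
                 DECall("g3", {}, "UP")]
        out = category_crosstab(calls, {"g1": "stress", "g2": "stress"})
        stress = out[out["category"] == "stress"].iloc[0]
        assert (stress["UP"], stress["DOWN"]) == (1, 1)
        assert out[out["category"] == "unassigned"].iloc[0]["UP"] == 1


class TestScanPromoters:
    def test_planted_plus_strand_motif_found_at_offset(self):
        hits = scan_promoters([("p1", "AAAA" + "CATGTG" + "TTTT")],
                              {"m": "CATGTG"})
        assert [(h.start, h.strand) for h in hits] == [(5, "+")]
        assert hits[0].matched_sequence == "CATGTG"

    def test_reverse_complement_plant_found_on_minus_strand(self):
        # reverse complement of CGTCAG is CTGACG
        hits = scan_promoters([("p1", "AA" + "CTGACG" + "TT")], {"m": "CGTCAG"})
        assert [(h.start, h.strand) for h in hits] == [(3, "-")]
        assert hits[0].matched_sequence == "CGTCAG"

    def test_absent_motif_yields_no_hits(self):
        assert scan_promoters([("p1", "AAAAAAAA")], {"m": "CACGTG"}) == []

    def test_iupac_degeneracy_expands(self):
        hits = scan_promoters([("p1", "ACGTAACGTC")], {"m": "ACGTM"})
        assert [h.start for h in hits if h.strand == "+"] == [1, 6]

    def test_overlapping_matches_all_reported(self):
        hits = scan_promoters([("p1", "AAAA")], {"m": "AA"})
        assert [h.start for h in hits if h.strand == "+"] == [1, 2, 3]

    def test_invalid_iupac_symbol_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_promoters([("p1", "ACGT")], {"m": "AXGT"})
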