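"""Ratio pipeline: dedup, mass adjustment, outlier calling, permutation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import knockmore as km
from knockmore.ratios import TAIL_SD_MULTIPLIER


def make_records(rows):
    defaults = {"mouse_id": "m0", "gene": "g1", "genotype": "mut",
                "zygosity": "hom", "sex": "f", "center": "C1",
                "T0": 100.0, "AUC": 2e4, "TG": 100.0, "BM": 25.0,
                "VO2": 80.0, "MR": 0.5, "RER": 0.85,
                "mean_body_mass": 25.0}
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestDedupe:
    def test_homozygote_preferred_over_heterozygote(self):
        rec = make_records(
            [{"zygosity": "hom", "sex": s} for s in "fm"]
            + [{"zygosity": "het", "sex": s} for s in "fm"])
        out = km.dedupe_strains(rec)
        assert set(out["zygosity"]) == {"hom"}

    def test_single_cohort_unchanged(self):
        rec = make_records([{"mouse_id": f"m{i}"} for i in range(5)])
        out = km.dedupe_strains(rec)
        assert len(out) == 5

    def test_both_sex_genotype_beats_homozygosity(self):
        rec = make_records(
            [{"zygosity": "het", "sex": s} for s in "fm"]
            + [{"zygosity": "hom", "sex": "f"}])
        out = km.dedupe_strains(rec)
        assert set(out["zygosity"]) == {"het"}

    def test_wild_types_pass_through(self):
        rec = make_records(
            [{"gene": "WT", "genotype": "wt", "zygosity": "wt"},
             {"zygosity": "hom"}, {"zygosity": "het"}])
        out = km.dedupe_strains(rec)
        assert (out["genotype"] == "wt").sum() == 1


class TestMassAdjustment:
    def _stratum(self, slope, n=40, seed=0):
        rng = np.random.default_rng(seed)
        mass = rng.uniform(20, 35, n)
        vo2 = 40 + slope * mass + rng.normal(0, 1.0, n)
        return make_records(
            [{"mouse_id": f"m{i}", "VO2": vo2[i], "mean_body_mass": mass[i]}
             for i in range(n)])

    def test_zero_slope_leaves_values_unchanged(self):
        rec = make_records(
            [{"mouse_id": f"m{i}", "VO2": 80.0,
              "mean_body_mass": 20.0 + i} for i in range(10)])
        out = km.adjust_mass_dependent(rec, "VO2")
        assert np.allclose(out["VO2"], rec["VO2"])

    def test_adjusted_values_uncorrelated_with_mass(self):
        rec = self._stratum(slope=1.5)
        out = km.adjust_mass_dependent(rec, "VO2")
        r = np.corrcoef(out["VO2"], out["mean_body_mass"])[0, 1]
        assert abs(r) < 1e-10

    def test_mean_preserved_and_idempotent(self):
        rec = self._stratum(slope=2.0, seed=1)
        once = km.adjust_mass_dependent(rec, "VO2")
        assert once["VO2"].mean() == pytest.approx(rec["VO2"].mean(),
                                                   rel=1e-12)
        twice = km.adjust_mass_dependent(once, "VO2")
        assert np.allclose(once["VO2"], twice["VO2"], atol=1e-9)

    def test_small_stratum_skipped_with_warning(self):
        rec = make_records([{"mouse_id": "m0"}, {"mouse_id": "m1"}])
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = km.adjust_mass_dependent(rec, "MR")
        assert np.allclose(out["MR"], rec["MR"])

    def test_only_calorimetry_parameters_adjustable(self):
        with pytest.raises(ValueError):
            km.adjust_mass_dependent(make_records([{}]), "TG")


class TestRatioTable:
    def test_ratio_arithmetic(self):
        rec = make_records(
            [{"mouse_id": f"m{i}", "TG": 2.0} for i in range(7)]
            + [{"mouse_id": f"w{i}", "gene": "WT", "genotype": "wt",
                "TG": 1.0} for i in range(7)])
        table = km.compute_ratio_table(rec)
        row = table[table.parameter == "TG"].iloc[0]
        assert row["ratio"] == pytest.approx(2.0)
        assert row["n_mut"] == 7

    def test_small_mutant_groups_dropped(self):
        rec = make_records(
            [{"mouse_id": f"m{i}"} for i in range(4)]
            + [{"mouse_id": f"w{i}", "gene": "WT", "genotype": "wt"}
               for i in range(7)])
        assert km.compute_ratio_table(rec, min_group_size=7).empty
        assert not km.compute_ratio_table(rec, min_group_size=3).empty

    def test_zero_wild_type_mean_rejected(self):
        rec = make_records(
            [{"mouse_id": f"m{i}"} for i in range(7)]
            + [{"mouse_id": f"w{i}", "gene": "WT", "genotype": "wt",
                "TG": 0.0} for i in range(7)])
        table = km.compute_ratio_table(rec)
        assert "TG" not in set(table["parameter"])
        assert any(r[1] == "TG" for r in table.attrs["rejected"])

    def test_qc_bounds_exclude_invalid_values(self):
        rec = make_records(
            [{"mouse_id": f"m{i}", "VO2": 80.0} for i in range(7)]
            + [{"mouse_id": "m7", "VO2": -999.0}]
            + [{"mouse_id": f"w{i}", "gene": "WT", "genotype": "wt",
                "VO2": 80.0} for i in range(7)])
        table = km.compute_ratio_table(rec, qc_bounds={"VO2": (0, 1e4)})
        row = table[table.parameter == "VO2"].iloc[0]
        assert row["n_mut"] == 7
        assert row["ratio"] == pytest.approx(1.0)


class TestThresholds:
    def test_arithmetic(self):
        assert km.sd_thresholds(1.0, 0.1) == pytest.approx((0.8355, 1.1645))

    def test_multiplier_is_normal_95_quantile(self):
        assert TAIL_SD_MULTIPLIER == pytest.approx(
            stats.norm.ppf(0.95), abs=5e-4)

    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValueError):
            km.sd_thresholds(1.0, 0.0)


def ratio_frame(param, sex, ratios, genes=None):
    genes = genes or [f"g{i}" for i in range(len(ratios))]
    return pd.DataFrame({
        "gene": genes, "parameter": param, "sex": sex, "center": "C1",
        "ratio": ratios, "n_mut": 7, "n_wt": 20})


class TestOutliers:
    def test_five_per_tail_with_distinct_ratios(self):
        table = ratio_frame("TG", "f", np.linspace(0.5, 1.5, 100))
        lists = km.call_outliers(table)
        assert len(lists.lists[("TG", "f", "low")]) == 5
        assert len(lists.lists[("TG", "f", "high")]) == 5
        low = set(lists.genes("TG", "f", "low"))
        high = set(lists.genes("TG", "f", "high"))
        assert not low & high

    def test_ties_at_cutoff_keep_flag_rate_bounded(self):
        # 20 genes, heavy ties exactly at both cutoffs
        ratios = [0.8] * 3 + [1.0] * 14 + [1.2] * 3
        table = ratio_frame("TG", "m", ratios)
        lists = km.call_outliers(table, min_genes=20)
        flagged = (len(lists.lists[("TG", "m", "low")])
                   + len(lists.lists[("TG", "m", "high")]))
        assert flagged <= 0.10 * len(table)

    def test_flag_rate_bounded_for_any_input(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            vals = np.round(rng.lognormal(0, 0.3, 200), 2)  # many ties
            lists = km.call_outliers(ratio_frame("T0", "f", vals))
            flagged = sum(len(df) for df in lists.lists.values())
            assert flagged <= 0.10 * 200

    def test_small_distributions_skipped(self):
        table = ratio_frame("TG", "f", np.linspace(0.9, 1.1, 10))
        with pytest.warns(UserWarning, match="fewer than"):
            lists = km.call_outliers(table)
        assert not lists.lists

    def test_strong_set_is_union_of_lists(self):
        t1 = ratio_frame("TG", "f", np.linspace(0.5, 1.5, 50))
        t2 = ratio_frame("T0", "m", np.linspace(0.5, 1.5, 50),
                         genes=[f"h{i}" for i in range(50)])
        lists = km.call_outliers(pd.concat([t1, t2]))
        union = set()
        for df in lists.lists.values():
            union |= set(df["gene"])
        assert lists.strong_genes == union


class TestPermutation:
    def test_all_genes_candidate_single_list_gives_p_one(self):
        table = ratio_frame("TG", "f", np.linspace(0.5, 1.5, 100))
        res = km.permutation_enrichment(list(table["gene"]), table,
                                        n_permutations=500, seed=1)
        assert res.p_value == pytest.approx(1.0)
        assert res.observed_fraction == pytest.approx(0.1)

    def test_agrees_with_hypergeometric_oracle(self):
        # single stratum, distinct ratios: the number of flagged candidates
        # is hypergeometric (N=200 rows, K=20 outliers, n=30 candidates)
        N, n_cand, n_perm = 200, 30, 10_000
        rng = np.random.default_rng(7)
        ratios = rng.permutation(np.linspace(0.5, 1.5, N))
        table = ratio_frame("TG", "f", ratios)
        flagged_genes = km.call_outliers(table, min_genes=10).strong_genes
        K = len(flagged_genes)  # 10 + 10
        candidates = (sorted(flagged_genes)[:6]
                      + sorted(set(table["gene"]) - flagged_genes)[:n_cand - 6])
        res = km.permutation_enrichment(candidates, table,
                                        n_permutations=n_perm, seed=3)
        observed_hits = round(res.observed_fraction * n_cand)
        assert observed_hits == 6
        p_exact = stats.hypergeom.sf(observed_hits - 1, N, K, n_cand)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(res.p_value - p_exact) <= 3 * se

    def test_deterministic_under_seed(self):
        table = ratio_frame("TG", "f", np.linspace(0.5, 1.5, 60))
        args = (["g0", "g1", "g59"], table)
        a = km.permutation_enrichment(*args, n_permutations=300, seed=9)
        b = km.permutation_enrichment(*args, n_permutations=300, seed=9)
        assert a == b

    def test_wider_band_flags_more(self):
        table = ratio_frame("TG", "f", np.linspace(0.5, 1.5, 100))
        cands = [f"g{i}" for i in range(0, 100, 7)]
        narrow = km.permutation_enrichment(cands, table, (0.05, 0.95),
                                           n_permutations=200, seed=2)
        wide = km.permutation_enrichment(cands, table, (0.20, 0.80),
                                         n_permutations=200, seed=2)
        assert wide.observed_fraction >= narrow.observed_fraction

    def test_empty_or_foreign_candidates_rejected(self):
        table = ratio_frame("TG", "f", np.linspace(0.5, 1.5, 30))
        with pytest.raises(ValueError):
            km.permutation_enrichment([], table)
        with pytest.raises(ValueError):
            km.permutation_enrichment(["nope"], table)


class TestNovelty:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "source", "metabolic",
                                           "impc"])

    def test_filter_cascade(self):
        ann = self.table([
            ("g_mp", "MP", True, False),
            ("g_go", "GO", True, False),
            ("g_mf", "GO", False, False),   # molecular function only
            ("g_impc", "MP", True, True),   # screen-derived, discarded
        ])
        out = km.annotate_novelty(
            ["g_mp", "g_go", "g_mf", "g_impc", "g_none"], ann)
        assert out == {"g_mp": "known-metabolic",
                       "g_go": "known-metabolic",
                       "g_mf": "known-nonmetabolic",
                       "g_impc": "unannotated",
                       "g_none": "unannotated"}

    def test_empty_tables_leave_all_unannotated(self):
        out = km.annotate_novelty(["a", "b"], self.table([]))
        assert set(out.values()) == {"unannotated"}

    def test_kegg_metabolism_counts_as_known_metabolic(self):
        ann = self.table([("g", "KEGG", True, False)])
        assert km.annotate_novelty(["g"], ann)["g"] == "known-metabolic"
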