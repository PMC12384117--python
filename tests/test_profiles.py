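"""Multilocus profiles, GRS, percentile classification, stratified tables."""

import numpy as np
import pandas as pd
import pytest

from riskprofiler import (MgProfile, RiskClassification, RiskProfileModel,
                          SampleRecord, VTE_WEIGHTS, azores_like_scenario,
                          build_profiles, classify, cross_risk_table,
                          group_frequency_table, grs,
                          simulate_hwe_cohort, weights_from_table)
from riskprofiler.panel import ValidationError
from tests.conftest import build_table

# synthetic example AT weights (plausible magnitudes, for exercising the
# machinery only; real weights are user-supplied config)
AT_WEIGHTS = {
    "rs12740374": 1.12, "rs3825807": 1.19, "rs11206510": 1.08,
    "rs562556": 1.10, "rs505151": 1.26, "rs405509": 1.13, "rs429358": 1.45,
    "rs439401": 1.11, "rs688": 1.16, "rs10757274": 1.29, "rs1333049": 1.31,
}


def vte_genotypes(f5="G/G", f2="G/G", c677="C/C", a1298="A/A"):
    return {"rs6025": f5, "rs1799963": f2, "rs1801133": c677,
            "rs1801131": a1298}


class TestGrs:
    def test_f5_f2_mthfr_heterozygote_score(self, vte_snps):
        vec = ["A/G", "A/G", "C/T", "A/A"]
        assert grs(vec, vte_snps, VTE_WEIGHTS) == pytest.approx(6.18)

    def test_f5_heterozygote_only(self, vte_snps):
        vec = ["A/G", "G/G", "C/C", "A/A"]
        assert grs(vec, vte_snps, VTE_WEIGHTS) == pytest.approx(4.38)

    def test_zero_risk_alleles(self, vte_snps):
        vec = ["G/G", "G/G", "C/C", "A/A"]
        assert grs(vec, vte_snps, VTE_WEIGHTS) == 0.0

    def test_unweighted_snps_contribute_nothing(self, vte_snps):
        # MTHFR carries risk alleles but no OR weight
        vec = ["G/G", "G/G", "T/T", "C/C"]
        assert grs(vec, vte_snps, VTE_WEIGHTS) == 0.0

    def test_log_mode_uses_log_weights(self, vte_snps):
        vec = ["A/G", "A/G", "C/C", "A/A"]
        expected = np.log(4.38) + np.log(1.80)
        assert grs(vec, vte_snps, VTE_WEIGHTS, "log_or") == pytest.approx(expected)

    def test_nonpositive_weight_rejected(self, vte_snps):
        with pytest.raises(ValidationError):
            grs(["A/G", "G/G", "C/C", "A/A"], vte_snps, {"rs6025": -2.0})

    def test_additivity_over_single_snp_subprofiles(self, vte_snps):
        vec = ["A/A", "A/G", "C/T", "C/C"]
        for mode in ("or", "log_or"):
            total = grs(vec, vte_snps, VTE_WEIGHTS, mode)
            parts = sum(grs([cell], (snp,), VTE_WEIGHTS, mode)
                        for snp, cell in zip(vte_snps, vec))
            assert total == pytest.approx(parts)

    def test_adding_risk_allele_never_decreases_score(self, vte_snps):
        base = ["G/G", "G/G", "C/C", "A/A"]
        for mode in ("or", "log_or"):
            prev = grs(base, vte_snps, VTE_WEIGHTS, mode)
            for i, het in enumerate(["A/G", "A/G", "C/T", "A/C"]):
                bumped = list(base)
                bumped[i] = het
                assert grs(bumped, vte_snps, VTE_WEIGHTS, mode) >= prev


class TestBuildProfiles:
    def test_vte_profile_counts(self, panel):
        gt = build_table(panel, {
            "s1": vte_genotypes("A/G", "A/G", "C/T", "A/A")})
        (p,) = build_profiles(gt, "VTE", VTE_WEIGHTS)
        assert p.profile_string == "A/G A/G C/T A/A"
        assert (p.rv, p.pv, p.hor) == (3, 0, 0)
        assert p.grs == pytest.approx(6.18)

    def test_all_identical_cohort_single_profile(self, panel):
        gt = build_table(panel, {f"s{i}": vte_genotypes() for i in range(5)})
        profiles = build_profiles(gt, "VTE")
        assert len(profiles) == 1
        assert profiles[0].relative_frequency == 1.0

    def test_distinct_count_matches_set_oracle(self, panel):
        rng = np.random.default_rng(3)
        rows = {}
        for i in range(80):
            rows[f"s{i}"] = vte_genotypes(
                f5=rng.choice(["G/G", "A/G"]),
                c677=rng.choice(["C/C", "C/T", "T/T"]),
                a1298=rng.choice(["A/A", "A/C"]),
            )
        profiles = build_profiles(gt := build_table(panel, rows), "VTE")
        oracle = {" ".join(rows[s][r] for r in
                           gt.panel.sub_panel("VTE").rsids) for s in rows}
        assert len(profiles) == len(oracle)

    def test_missing_subpanel_genotype_excludes_sample(self, panel):
        rows = {f"s{i}": vte_genotypes() for i in range(3)}
        del rows["s0"]["rs1801131"]
        gt = build_table(panel, rows)
        profiles = build_profiles(gt, "VTE")
        carriers = {sid for p in profiles for sid in p.carriers}
        assert carriers == {"s1", "s2"}

    def test_profile_invariants_on_simulated_cohort(self):
        gt = simulate_hwe_cohort(azores_like_scenario(seed=5))
        for group, size in (("AT", 15), ("VTE", 4)):
            profiles = build_profiles(gt, group, VTE_WEIGHTS)
            total = sum(p.relative_frequency for p in profiles)
            assert total == pytest.approx(1.0, abs=1e-12)
            for p in profiles:
                assert p.rv >= 2 * p.hor
                assert p.rv <= 2 * size
                assert p.rv + p.pv <= 2 * size


def _classification_from_scores(scores, group="AT", **kwargs):
    profiles = [
        MgProfile(profile_string=f"P{i}", disease_group=group, rv=0, pv=0,
                  hor=0, grs=s, carriers=(f"s{i}",),
                  relative_frequency=1.0 / len(scores))
        for i, s in enumerate(scores)
    ]
    return classify(profiles, **kwargs)


class TestClassify:
    def test_distinct_scores_pick_extreme_deciles(self):
        cls = _classification_from_scores(list(range(1, 11)))
        high = cls.categories[cls.categories == "high"].index
        low = cls.categories[cls.categories == "low"].index
        assert list(high) == ["s9"]   # score 10
        assert list(low) == ["s0"]    # score 1
        assert cls.q_high == pytest.approx(9.1)

    def test_boundary_ties_join_high_group(self):
        # 20 scores; three-way tie at the value on which the 0.9 quantile
        # lands: all tied samples are classified high
        scores = list(range(1, 18)) + [17.5, 17.5, 17.5]
        cls = _classification_from_scores(scores)
        assert cls.q_high == pytest.approx(17.5)
        n_high = (cls.categories == "high").sum()
        assert n_high == 3
        strict = _classification_from_scores(scores, ties="strict")
        assert (strict.categories == "high").sum() == 0

    def test_atom_spanning_both_deciles_goes_low(self):
        # mimic a VTE-like score distribution: 90% zeros, a few carriers
        scores = [0.0] * 18 + [4.38, 6.18]
        cls = _classification_from_scores(scores, group="VTE")
        counts = cls.counts()
        assert counts == {"high": 2, "intermediate": 0, "low": 18}

    def test_identical_scores_all_intermediate_with_warning(self):
        with pytest.warns(UserWarning):
            cls = _classification_from_scores([1.0] * 12)
        assert (cls.categories == "intermediate").all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            _classification_from_scores([1.0, 2.0])

    def test_high_group_size_range_on_simulated_cohorts(self):
        sizes = []
        for seed in range(20):
            gt = simulate_hwe_cohort(azores_like_scenario(seed=seed))
            res = RiskProfileModel(gt, "AT", AT_WEIGHTS).fit()
            sizes.append(res.classification.counts()["high"])
        assert all(10 <= s <= 34 for s in sizes)

    def test_or_and_log_or_classifications_agree(self):
        # consistency of the two weighting modes at these weight magnitudes
        for seed in (1, 2, 3):
            gt = simulate_hwe_cohort(azores_like_scenario(seed=seed))
            by_or = RiskProfileModel(gt, "VTE", VTE_WEIGHTS, "or").fit()
            by_log = RiskProfileModel(gt, "VTE", VTE_WEIGHTS, "log_or").fit()
            assert by_or.classification.categories.equals(
                by_log.classification.categories)


def _make_classification(n, n_high, n_low=0, group="AT", prefix="s"):
    ids = [f"{prefix}{i}" for i in range(n)]
    scores = pd.Series([2.0] * n, index=ids)
    cats = pd.Series("intermediate", index=ids, dtype=object)
    cats.iloc[:n_high] = "high"
    if n_low:
        cats.iloc[n - n_low:] = "low"
    scores.iloc[:n_high] = 10.0
    if n_low:
        scores.iloc[n - n_low:] = 0.0
    return RiskClassification(group, scores, 0.5, 9.5, cats, n)


class TestGroupFrequencyTable:
    def test_published_high_risk_fractions(self):
        mainland = _make_classification(108, 8, group="AT")
        samples = [SampleRecord(f"s{i}", population="mainland")
                   for i in range(108)]
        table = group_frequency_table(mainland, samples).table
        assert table.loc[("total", "Total"), "high"] == pytest.approx(
            0.074, abs=5e-4)

        azores = _make_classification(170, 7, group="VTE")
        samples = [SampleRecord(f"s{i}", population="azores")
                   for i in range(170)]
        table = group_frequency_table(azores, samples).table
        assert table.loc[("total", "Total"), "high"] == pytest.approx(
            0.041, abs=5e-4)

    def test_category_frequencies_partition_each_stratum(self):
        cls = _make_classification(170, 19, n_low=15)
        samples = [SampleRecord(f"s{i}", population="azores",
                                geographic_group="Eastern" if i < 70 else
                                "Central" if i < 140 else "Western",
                                sex="M" if i % 2 else "F")
                   for i in range(170)]
        gft = group_frequency_table(cls, samples)
        sums = gft.table[["high", "low", "intermediate"]].sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert "geographic_group" in gft.tests
        assert "sex" in gft.tests

    def test_empty_stratum_reported_absent_not_zero(self):
        cls = _make_classification(20, 2)
        # 7 female mainlanders classified, no azoreans: geographic strata absent
        samples = [SampleRecord(f"s{i}", population="mainland",
                                sex="F" if i < 7 else "M")
                   for i in range(20)]
        table = group_frequency_table(cls, samples).table
        assert ("geographic_group", "Eastern") not in table.index


class TestCrossRisk:
    def test_margins_equal_category_counts(self):
        at = _make_classification(100, 12)
        vte = _make_classification(100, 9, group="VTE")
        res = cross_risk_table(at, vte)
        assert res.table.sum(axis=1).tolist() == [12, 88]
        assert res.table.sum(axis=0).tolist() == [9, 91]

    def test_constructed_exclusion_gives_or_below_one(self):
        n = 200
        ids = [f"s{i}" for i in range(n)]
        # VTE-high samples (first 20) all carry minimal AT scores
        at_scores = pd.Series([0.0] * 20 + [5.0 + i * 0.01 for i in range(180)],
                              index=ids)
        at_cats = pd.Series(["low"] * 20 + ["intermediate"] * 160 + ["high"] * 20,
                            index=ids, dtype=object)
        at = RiskClassification("AT", at_scores, 1.0, 6.5, at_cats, n)
        vte_cats = pd.Series(["high"] * 20 + ["intermediate"] * 180,
                             index=ids, dtype=object)
        vte = RiskClassification("VTE", pd.Series(1.0, index=ids), 0, 0.5,
                                 vte_cats, n)
        res = cross_risk_table(at, vte)
        assert res.table.loc["AT_high", "VTE_high"] == 0
        assert res.mean_at_grs_vte_high < res.mean_at_grs_vte_other
        # negative association: cross-product ratio below 1
        t = res.table.to_numpy()
        assert t[0, 0] * t[1, 1] < t[0, 1] * t[1, 0]

    def test_disjoint_sample_sets_rejected(self):
        at = _make_classification(20, 2)
        vte = _make_classification(20, 2, group="VTE", prefix="t")
        with pytest.raises(ValidationError):
            cross_risk_table(at, vte)


class TestWeightsFromTable:
    def test_recovers_vte_weights_from_profile_scores(self, vte_snps):
        pairs = [
            ("A/G A/G C/T A/A", 6.18),
            ("A/G G/G C/T A/A", 4.38),
            ("A/G G/G C/C A/A", 4.38),
            ("G/G A/G C/C A/A", 1.80),
            ("G/G G/G T/T A/C", 0.00),
            ("G/G G/G C/T A/A", 0.00),
        ]
        weights = weights_from_table(pairs, vte_snps)
        assert weights["rs6025"] == pytest.approx(4.38, abs=1e-9)
        assert weights["rs1799963"] == pytest.approx(1.80, abs=1e-9)
        assert "rs1801133" not in weights  # fitted weight is zero
        assert "rs1801131" not in weights


class TestResultsFacade:
    def test_summary_mirrors_profile_fields(self):
        gt = simulate_hwe_cohort(azores_like_scenario(seed=2))
        res = RiskProfileModel(gt, "VTE", VTE_WEIGHTS).fit()
        summary = res.summary()
        assert list(summary.columns) == [
            "profile_id", "profile_string", "RV", "PV", "HoR", "GRS",
            "n_carriers", "relative_frequency", "category"]
        assert len(summary) == res.n_distinct_profiles
        assert summary["relative_frequency"].sum() == pytest.approx(1.0)
        # GRS column is sorted descending (published table layout)
        assert summary["GRS"].is_monotonic_decreasing
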