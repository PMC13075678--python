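import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heattrial.anova import (NP_SENTINEL, AnovaTable, UnbalancedDataError,
                             broad_sense_heritability, combined_anova, lsd,
                             per_condition_anova, screen_outliers,
                             variance_components)
from heattrial.dataset import TrialDataset
from heattrial.simulate import SyntheticConfig, TraitSpec, generate_trial, paper_scale_config


def brute_force_combined_ss(ds, trait):
    """Literal mean-decomposition oracle, written with plain loops."""
    t = ds.trait_table(trait)
    G = sorted(t["genotype"].unique())
    S = sorted(t["condition"].unique())
    Y = sorted(t["year"].unique())
    R = sorted(t["rep"].unique())
    val = {(r.genotype, r.condition, r.year, r.rep): r.value
           for r in t.itertuples()}
    m = lambda keys: np.mean([val[k] for k in keys])
    all_keys = list(itertools.product(G, S, Y, R))
    gm = m(all_keys)
    ss = {}
    ss["Y"] = len(G) * len(S) * len(R) * sum(
        (m([k for k in all_keys if k[2] == y]) - gm) ** 2 for y in Y)
    ss["SD"] = len(G) * len(Y) * len(R) * sum(
        (m([k for k in all_keys if k[1] == s]) - gm) ** 2 for s in S)
    ss["G"] = len(S) * len(Y) * len(R) * sum(
        (m([k for k in all_keys if k[0] == g]) - gm) ** 2 for g in G)
    ss["SD*Y"] = len(G) * len(R) * sum(
        (m([k for k in all_keys if k[1] == s and k[2] == y])
         - m([k for k in all_keys if k[1] == s])
         - m([k for k in all_keys if k[2] == y]) + gm) ** 2
        for s in S for y in Y)
    ss["G*SD"] = len(Y) * len(R) * sum(
        (m([k for k in all_keys if k[0] == g and k[1] == s])
         - m([k for k in all_keys if k[0] == g])
         - m([k for k in all_keys if k[1] == s]) + gm) ** 2
        for g in G for s in S)
    ss["G*Y"] = len(S) * len(R) * sum(
        (m([k for k in all_keys if k[0] == g and k[2] == y])
         - m([k for k in all_keys if k[0] == g])
         - m([k for k in all_keys if k[2] == y]) + gm) ** 2
        for g in G for y in Y)
    ss["Rep(SD*Y)"] = len(G) * sum(
        (m([k for k in all_keys if k[1] == s and k[2] == y and k[3] == r])
         - m([k for k in all_keys if k[1] == s and k[2] == y])) ** 2
        for s in S for y in Y for r in R)
    ss["G*SD*Y"] = len(R) * sum(
        (m([k for k in all_keys if k[0] == g and k[1] == s and k[2] == y])
         - m([k for k in all_keys if k[0] == g and k[1] == s])
         - m([k for k in all_keys if k[0] == g and k[2] == y])
         - m([k for k in all_keys if k[1] == s and k[2] == y])
         + m([k for k in all_keys if k[0] == g])
         + m([k for k in all_keys if k[1] == s])
         + m([k for k in all_keys if k[2] == y]) - gm) ** 2
        for g in G for s in S for y in Y)
    ss["total"] = sum((v - gm) ** 2 for v in val.values())
    ss["Residual"] = ss["total"] - sum(v for k, v in ss.items() if k != "total")
    return ss


class TestCombinedAnova:
    def test_matches_brute_force_oracle(self, tiny_trial):
        ds, _ = tiny_trial
        tab = combined_anova(ds, "GY")
        oracle = brute_force_combined_ss(ds, "GY")
        for src in ("Y", "SD", "SD*Y", "Rep(SD*Y)", "G", "G*SD", "G*Y",
                    "G*SD*Y", "Residual"):
            assert tab.row(src)["SS"] == pytest.approx(oracle[src], rel=1e-9), src

    def test_matches_statsmodels_type1(self, tiny_trial):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        ds, _ = tiny_trial
        t = ds.trait_table("GY")
        fit = smf.ols("value ~ C(year) + C(condition) + C(year):C(condition)"
                      " + C(rep):C(year):C(condition) + C(genotype)"
                      " + C(genotype):C(condition) + C(genotype):C(year)"
                      " + C(genotype):C(condition):C(year)", data=t).fit()
        sm_tab = anova_lm(fit, typ=1)
        tab = combined_anova(ds, "GY")
        pairs = {
            "C(year)": "Y", "C(condition)": "SD",
            "C(year):C(condition)": "SD*Y",
            "C(rep):C(year):C(condition)": "Rep(SD*Y)",
            "C(genotype)": "G", "C(genotype):C(condition)": "G*SD",
            "C(genotype):C(year)": "G*Y",
            "C(genotype):C(condition):C(year)": "G*SD*Y",
            "Residual": "Residual",
        }
        for sm_name, src in pairs.items():
            row = tab.row(src)
            assert sm_tab.loc[sm_name, "sum_sq"] == pytest.approx(
                row["SS"], rel=1e-8), src
            assert int(sm_tab.loc[sm_name, "df"]) == int(row["df"]), src

    def test_df_pattern_at_reference_scale(self):
        ds, _ = generate_trial(paper_scale_config(seed=1))
        tab = combined_anova(ds, "GY")
        assert int(tab.row("G")["df"]) == 155
        assert int(tab.row("G*SD")["df"]) == 155
        assert int(tab.row("Residual")["df"]) == 620
        assert int(tab.table["df"].sum()) == 1247

    def test_conservation_on_random_layouts(self):
        for seed, n_g in [(0, 3), (1, 6), (2, 10)]:
            ds, _ = generate_trial(paper_scale_config(seed=seed, n_genotypes=n_g))
            tab = combined_anova(ds, "GY")  # internal asserts check SS/df sums
            total = ((ds.trait_table("GY")["value"]
                      - ds.trait_table("GY")["value"].mean()) ** 2).sum()
            assert tab.table["SS"].sum() == pytest.approx(total, rel=1e-9)

    def test_noise_free_ss_zero_except_sd(self, noise_free_trial):
        ds, _ = noise_free_trial
        tab = combined_anova(ds, "GY")
        for _, row in tab.table.iterrows():
            if row["source"] == "SD":
                assert row["SS"] > 0
            else:
                assert row["SS"] == pytest.approx(0.0, abs=1e-6)

    def test_record_order_invariance(self, small_trial):
        ds, _ = small_trial
        shuffled = TrialDataset(
            ds.records.sample(frac=1.0, random_state=0).reset_index(drop=True))
        a = combined_anova(ds, "GY").table
        b = combined_anova(shuffled, "GY").table
        pd.testing.assert_frame_equal(a, b)

    def test_unbalanced_rejected(self, small_trial):
        ds, _ = small_trial
        broken = TrialDataset(ds.records.iloc[:-1].copy())
        with pytest.raises(UnbalancedDataError):
            combined_anova(broken, "GY")

    def test_cv_self_consistency(self, small_trial):
        ds, _ = small_trial
        tab = combined_anova(ds, "GY")
        assert tab.cv_percent == pytest.approx(
            100 * np.sqrt(tab.ms("Residual")) / tab.grand_mean, rel=1e-12)


class TestPerConditionAnova:
    def test_df_and_textbook_ss_identity(self, small_trial):
        ds, _ = small_trial
        tab = per_condition_anova(ds, "GY", "normal")
        d = ds.design
        assert int(tab.row("G")["df"]) == d["n_genotypes"] - 1
        t = ds.trait_table("GY")
        t = t[t["condition"] == "normal"]
        gmeans = t.groupby("genotype")["value"].mean()
        expected = d["n_reps"] * d["n_years"] * ((gmeans - gmeans.mean()) ** 2).sum()
        assert tab.row("G")["SS"] == pytest.approx(expected, rel=1e-10)

    def test_noise_free_f_sentinel(self):
        spec = TraitSpec(899.0, 0.25, var_G=400.0)
        ds, _ = generate_trial(SyntheticConfig(n_genotypes=5, yield_trait=spec, seed=3))
        tab = per_condition_anova(ds, "GY", "normal")
        assert np.isinf(tab.row("G")["F"])
        assert tab.row("G")["p"] == 0.0


class TestVarianceComponents:
    def test_tkw_like_printed_mean_squares(self):
        rows = pd.DataFrame({
            "source": ["Y", "Rep(Y)", "G", "G*Y", "Residual"],
            "df": [1, 2, 155, 155, 310],
            "SS": [0, 0, 118 * 155, 1.81 * 155, 3.27 * 310],
            "MS": [0, 0, 118.0, 1.81, 3.27],
            "F": np.nan, "p": np.nan, "error_term": ""})
        tab = AnovaTable(rows, grand_mean=40.0, r2=0.9, cv_percent=4.6)
        vc = variance_components(tab, n_years=2, n_reps=2)
        assert vc.sigma2_G == pytest.approx(29.0475)
        assert vc.sigma2_e == pytest.approx(3.27)
        assert vc.sigma2_GxY == 0.0
        assert vc.flags["sigma2_GxY"] == "truncated"
        assert vc.raw["sigma2_GxY"] == pytest.approx(-0.73)

    def test_truncation_flags_negative_genotypic_variance(self):
        rows = pd.DataFrame({
            "source": ["G", "G*Y", "Residual"], "df": [4, 4, 10],
            "SS": [4.0, 8.0, 10.0], "MS": [1.0, 2.0, 1.0],
            "F": np.nan, "p": np.nan, "error_term": ""})
        tab = AnovaTable(rows, 1.0, 0.5, 10.0)
        vc = variance_components(tab, 2, 2)
        assert vc.sigma2_G == 0.0
        assert vc.flags["sigma2_G"] == "truncated"
        assert vc.raw["sigma2_G"] == pytest.approx(-0.25)

    def test_recovery_within_monte_carlo_error(self):
        # per-condition genotypic variance = var_G + var_GxSD
        cfg = paper_scale_config(n_genotypes=60)
        truth_g = (cfg.yield_trait.var_G + cfg.yield_trait.var_GxSD)
        ests = []
        for seed in range(120):
            ds, _ = generate_trial(dataclasses.replace(cfg, seed=seed))
            tab = per_condition_anova(ds, "GY", "normal")
            ests.append(variance_components(tab, 2, 2).sigma2_G)
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - truth_g) < 3 * se


class TestHeritability:
    def test_np_sentinel_when_truncated(self):
        rows = pd.DataFrame({
            "source": ["G", "G*Y", "Residual"], "df": [4, 4, 10],
            "SS": [4.0, 8.0, 10.0], "MS": [1.0, 2.0, 1.0],
            "F": np.nan, "p": np.nan, "error_term": ""})
        vc = variance_components(AnovaTable(rows, 1.0, 0.5, 10.0), 2, 2)
        h2 = broad_sense_heritability(vc, 2, 2)
        assert h2.h2b == NP_SENTINEL

    def test_noiseless_limit_is_one(self):
        from heattrial.anova import VarianceComponents
        vc = VarianceComponents(5.0, 0.0, 0.0,
                                raw={"sigma2_G": 5.0}, flags={"sigma2_G": "ok"})
        assert broad_sense_heritability(vc, 2, 2).h2b == pytest.approx(1.0)

    def test_closed_form_from_generator_parameters(self):
        # var_G=400, var_GxY=100, var_e=1600, y=r=2 -> h2b ~ 400/850
        spec = TraitSpec(899.0, 0.25, var_G=400.0, var_GxY=100.0, var_e=1600.0)
        ests = []
        for seed in range(150):
            ds, _ = generate_trial(SyntheticConfig(n_genotypes=80, yield_trait=spec,
                                                   seed=seed))
            tab = per_condition_anova(ds, "GY", "normal")
            vc = variance_components(tab, 2, 2)
            h2 = broad_sense_heritability(vc, 2, 2)
            if not isinstance(h2.h2b, str):
                ests.append(h2.h2b)
        ests = np.asarray(ests)
        expected = 400.0 / (400.0 + 100.0 / 2 + 1600.0 / 4)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - expected) < 3 * se + 0.01


class TestLsd:
    def test_zero_error_is_zero(self):
        assert lsd(0.0, 620, 624) == 0.0

    def test_reference_scale_value_against_t_quantile(self):
        got = lsd(2358.0, 620, 624, alpha=0.05)
        expected = stats.t.ppf(0.975, 620) * np.sqrt(2 * 2358.0 / 624)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(5.40, abs=0.01)

    def test_sqrt_scaling(self):
        assert lsd(4 * 2358.0, 620, 624) == pytest.approx(2 * lsd(2358.0, 620, 624))

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            lsd(1.0, 0, 4)


class TestOutlierScreen:
    def test_injected_outlier_flagged(self, small_trial):
        ds, _ = small_trial
        rec = ds.records.copy()
        i = rec.index[(rec["trait"] == "GY")][0]
        rec.loc[i, "value"] += 3000.0
        flagged = screen_outliers(TrialDataset(rec), "GY")
        assert len(flagged) >= 1
        assert flagged.iloc[0]["genotype"] == rec.loc[i, "genotype"]

    def test_clean_data_unflagged(self, noise_free_trial):
        ds, _ = noise_free_trial
        assert len(screen_outliers(ds, "GY")) == 0
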