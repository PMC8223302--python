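"""Trait-table assembly and the four-stage drought-trait filter."""

import numpy as np
import pandas as pd
import pytest

from itrait.selection import (SelectionConfig, assemble_trait_table,
                              estimate_heritability, filter_outliers_3sigma,
                              mlp_importance_filter, run_selection,
                              ttest_filter, HeritabilityEstimate)


def long_records(values, trait="t1", modality="RGB"):
    """values: dict (accession, replicate, treatment, day) -> value."""
    rows = [{"accession": a, "replicate": r, "treatment": tr, "day": d,
             "modality": modality, "trait": trait, "value": v}
            for (a, r, tr, d), v in values.items()]
    return pd.DataFrame(rows)


class TestAssembleTraitTable:
    def test_ratio_is_ds_over_ww(self):
        recs = long_records({("a1", 1, "WW", 1): 2.0, ("a1", 1, "DS", 1): 4.0})
        tt = assemble_trait_table(recs)
        assert tt.wide.loc[("a1", 1), "t1_D1_R"] == pytest.approx(2.0)

    def test_zero_ww_missing_codes_the_ratio(self):
        recs = long_records({("a1", 1, "WW", 1): 0.0, ("a1", 1, "DS", 1): 4.0})
        tt = assemble_trait_table(recs)
        assert np.isnan(tt.wide.loc[("a1", 1), "t1_D1_R"])

    def test_ds_without_ww_has_no_ratio_column(self):
        recs = long_records({("a1", 1, "DS", 1): 4.0})
        tt = assemble_trait_table(recs)
        assert "t1_D1_R" not in tt.wide.columns
        assert "t1_D1_DS" in tt.wide.columns

    def test_column_count_formula_small_design(self):
        # 3 traits x 2 days x (WW, DS, ratio) = 18 columns
        values = {}
        for t in range(3):
            for d in (1, 2):
                for tr in ("WW", "DS"):
                    values[(f"a{t}", 1, tr, d)] = float(t + d)
        recs = pd.concat([long_records(
            {k: v for k, v in values.items()}, trait=f"t{t}")
            for t in range(3)], ignore_index=True)
        tt = assemble_trait_table(recs)
        assert tt.n_columns == 3 * 2 * 3

    def test_missing_required_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            assemble_trait_table(pd.DataFrame({"accession": ["a"]}))


class TestOutlierFilter:
    def test_small_sample_with_spike_removes_nothing(self):
        # oracle: mean 20, sample sd 44.7 -> 3-sigma bound 154 > 100
        x = np.array([0.0, 0.0, 0.0, 0.0, 100.0])
        mu, sd = x.mean(), x.std(ddof=1)
        assert 100.0 <= mu + 3 * sd  # the direct computation
        _, removed = filter_outliers_3sigma(x)
        assert removed == 0

    def test_true_outlier_removed(self):
        x = np.concatenate([np.zeros(50), [1.0], [100.0]])
        cleaned, removed = filter_outliers_3sigma(x)
        assert removed == 1
        assert np.isnan(cleaned.iloc[-1])

    def test_values_within_one_sigma_untouched(self, rng):
        x = rng.uniform(-1, 1, size=200)
        _, removed = filter_outliers_3sigma(x)
        assert removed == 0

    def test_zero_variance_removes_nothing(self):
        _, removed = filter_outliers_3sigma(np.full(10, 3.3))
        assert removed == 0

    def test_idempotent_with_frozen_stats(self, rng):
        x = rng.standard_t(3, size=5000)
        stats0 = (x.mean(), x.std(ddof=1))
        cleaned, removed = filter_outliers_3sigma(x, column_stats=stats0)
        assert removed > 0
        _, removed2 = filter_outliers_3sigma(cleaned, column_stats=stats0)
        assert removed2 == 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            filter_outliers_3sigma(np.array([1.0]))


class TestTTestFilter:
    def test_identical_groups_not_kept(self):
        x = np.arange(10.0)
        p, keep, _ = ttest_filter(x, x)
        assert p > 0.9
        assert not keep

    def test_overwhelming_effect_kept(self, rng):
        p, keep, _ = ttest_filter(rng.normal(0, 1, 50), rng.normal(5, 1, 50))
        assert keep and p < 1e-10

    def test_insufficient_observations_dropped_with_reason(self):
        p, keep, reason = ttest_filter([1.0], [1.0, 2.0])
        assert not keep and reason == "insufficient observations"

    def test_null_calibration(self, rng):
        kept = 0
        n_rep = 1000
        for _ in range(n_rep):
            _, keep, _ = ttest_filter(rng.normal(size=20),
                                      rng.normal(size=20), alpha=0.05)
            kept += keep
        ci = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert kept / n_rep == pytest.approx(0.05, abs=ci)


class TestMLPImportance:
    def test_perfect_separator_scores_100(self, rng):
        n = 120
        y = np.repeat(["WW", "DS"], n // 2)
        X = pd.DataFrame({
            "separator": (y == "DS").astype(float),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        })
        report, low_sep = mlp_importance_filter(X, y, n_repeats=2, seed=0)
        assert report.loc["separator", "importance_pct"] == pytest.approx(100.0)
        assert report.loc["separator", "keep"]
        assert not low_sep

    def test_pure_noise_completes_and_flags_low_separation(self, rng):
        n = 80
        y = np.repeat(["WW", "DS"], n // 2)
        X = pd.DataFrame(rng.normal(size=(n, 4)),
                         columns=[f"n{i}" for i in range(4)])
        report, low_sep = mlp_importance_filter(X, y, n_repeats=2, seed=1)
        assert len(report) == 4  # completes despite no signal

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            mlp_importance_filter(X, np.repeat("WW", 10))

    def test_default_repeat_count_is_five(self):
        import inspect

        sig = inspect.signature(mlp_importance_filter)
        assert sig.parameters["n_repeats"].default == 5


class TestHeritability:
    def test_formula_arithmetic(self):
        est = HeritabilityEstimate("t", sigma2_G=1.0, sigma2_e=1.0, r=2)
        assert est.H2 == pytest.approx(2.0 / 3.0)

    def test_identical_replicates_give_h2_one(self):
        df = pd.DataFrame({"accession": np.repeat([f"a{i}" for i in range(20)], 2),
                           "value": np.repeat(np.arange(20.0), 2)})
        est = estimate_heritability(df, r=2)
        assert est.sigma2_e == 0.0
        assert est.H2 == pytest.approx(1.0)

    def test_recovery_at_two_panel_sizes(self, small_genotypes):
        # estimator bias shrinks with accession count
        from itrait.simulate import simulate_genotypes, simulate_trait_panel

        for n_acc, tol in ((50, 0.2), (368, 0.08)):
            gm = (small_genotypes if n_acc == 150
                  else simulate_genotypes(n_acc, 100, seed=n_acc))
            estimates = []
            for s in range(20):
                panel = simulate_trait_panel(gm, h2=0.4, r=2, n_causal=5,
                                             seed=s)
                ww = panel.trait_values.query("treatment == 'WW'")
                estimates.append(
                    estimate_heritability(ww[["accession", "value"]], r=2).H2)
            assert np.mean(estimates) == pytest.approx(0.4, abs=tol)

    def test_single_replicate_flagged(self):
        df = pd.DataFrame({"accession": [f"a{i}" for i in range(10)],
                           "value": np.arange(10.0)})
        est = estimate_heritability(df, r=1)
        assert est.flagged

    def test_negative_component_truncated(self, rng):
        # pure noise: between-group MS can fall below within-group MS
        df = pd.DataFrame({"accession": np.repeat([f"a{i}" for i in range(5)], 4),
                           "value": rng.normal(size=20)})
        est = estimate_heritability(df, r=4)
        assert est.sigma2_G >= 0.0
        assert 0.0 <= est.H2 <= 1.0


@pytest.fixture(scope="module")
def planted_report():
    from itrait.simulate import simulate_genotypes, simulate_trait_panel

    gm = simulate_genotypes(120, 50, seed=21)
    panel = simulate_trait_panel(gm, h2=0.5, r=2, n_causal=5,
                                 treatment_effect=2.0, seed=22)
    rng = np.random.default_rng(23)
    dfA = panel.trait_values.rename(columns={"time": "day"})
    dfA = dfA.assign(trait="traitA", modality="RGB")
    dfB = dfA.assign(trait="traitB", value=rng.normal(size=len(dfA)))
    table = assemble_trait_table(pd.concat([dfA, dfB], ignore_index=True))
    return run_selection(table, config=SelectionConfig(seed=1))


class TestRunSelection:
    def test_planted_trait_kept_noise_dropped(self, planted_report):
        rep = planted_report.set_index("trait")
        assert rep.loc["traitA", "keep"]
        assert not rep.loc["traitB", "keep"]

    def test_keep_is_conjunction_of_stage_flags(self, planted_report):
        rep = planted_report
        assert (rep.keep == (rep.keep_ttest & rep.keep_mlp & rep.keep_h2)).all()

    def test_h2_cutoff_semantics(self):
        cfg = SelectionConfig()
        assert not (0.19 >= cfg.h2_cutoff)
        assert 0.21 >= cfg.h2_cutoff
        assert 0.2 >= cfg.h2_cutoff  # boundary kept (H2 >= 0.2)

    def test_empty_input_no_crash(self):
        empty = assemble_trait_table(pd.DataFrame(
            columns=["accession", "replicate", "treatment", "day",
                     "modality", "trait", "value"]))
        report = run_selection(empty)
        assert report.empty
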