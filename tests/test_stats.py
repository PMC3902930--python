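"""Statistical-layer tests: closed-form identities, hand-computed values
and cross-checks against independent implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nonbsplice.annotation import COUNT_KEYS
from nonbsplice.stats import (
    DESIGN_COLUMNS,
    DegenerateStatisticError,
    SeparationError,
    add_bh_column,
    build_design_matrix,
    fit_logistic,
    g_run_association,
    group_proportions,
    partial_pearson,
    proximal_comparison,
    significance_stars,
    two_sample_proportion_test,
)


def make_profiles(rows):
    """Profile frame from compact dicts; unspecified counts default to 0."""
    out = []
    for r in rows:
        base = {
            "entry_id": r["entry_id"],
            "label": r.get("label", "CONSTITUTIVE"),
            "region": r["region"],
            "intron_length": r.get("intron_length", 1000),
            "max_g_run_template": r.get("max_g_run_template", 0),
            "max_g_run_nontemplate": r.get("max_g_run_nontemplate", 0),
            "n_triplex_removed_ppt": 0,
        }
        for key in COUNT_KEYS:
            base[f"n_{key}"] = r.get(f"n_{key}", 0)
            base[f"prox_{key}"] = r.get(f"prox_{key}", 0)
        out.append(base)
    return pd.DataFrame(out)


class TestPartialPearson:
    def test_closed_form_identity(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.4 * x
            z = rng.normal(size=n) + 0.3 * x - 0.2 * y
            res = partial_pearson(x, y, z)
            rxy = np.corrcoef(x, y)[0, 1]
            rxz = np.corrcoef(x, z)[0, 1]
            ryz = np.corrcoef(y, z)[0, 1]
            want = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
            assert res.r == pytest.approx(want, abs=1e-12)
            assert res.df == n - 3

    def test_constant_control_reduces_to_plain_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        z = np.full(30, 7.0)
        res = partial_pearson(x, y, z)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_y_equal_to_z_degenerate(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        z = rng.normal(size=20)
        with pytest.raises(DegenerateStatisticError):
            partial_pearson(x, z, z)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = rng.normal(size=50) + 0.3 * x
        z = rng.normal(size=50) + 0.5 * x
        res = partial_pearson(x, y, z)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_p_value_from_t_distribution(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.5, 7.0])
        y = np.array([1.1, 2.3, 2.8, 4.5, 4.9, 6.6, 7.3])
        z = np.array([0.2, 0.1, 0.4, 0.3, 0.2, 0.5, 0.1])
        res = partial_pearson(x, y, z)
        t = res.r * np.sqrt(res.df / (1 - res.r**2))
        assert res.t_stat == pytest.approx(t)
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), res.df))


class TestProportionTest:
    def test_identical_proportions(self):
        res = two_sample_proportion_test(5, 10, 5, 10)
        assert res.z_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)

    def test_hand_computed_pooled_z(self):
        # p1=0.9, p2=0.1, pooled=0.5: z = 0.8 / sqrt(0.25 * 0.2)
        res = two_sample_proportion_test(9, 10, 1, 10)
        assert res.z_stat == pytest.approx(0.8 / np.sqrt(0.25 * 0.2), abs=1e-12)
        assert res.p_value == pytest.approx(sps.norm.sf(res.z_stat), abs=1e-15)
        assert res.p_value == pytest.approx(1.73e-4, rel=5e-3)

    def test_antisymmetry(self):
        a = two_sample_proportion_test(30, 100, 10, 80)
        b = two_sample_proportion_test(10, 80, 30, 100)
        assert b.z_stat == pytest.approx(-a.z_stat)
        assert b.p_value == pytest.approx(1.0 - a.p_value)

    def test_degenerate_pooled(self):
        with pytest.raises(DegenerateStatisticError):
            two_sample_proportion_test(0, 10, 0, 10)
        with pytest.raises(DegenerateStatisticError):
            two_sample_proportion_test(10, 10, 10, 10)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest

        res = two_sample_proportion_test(40, 200, 25, 180)
        z, p = proportions_ztest(
            [40, 25], [200, 180], alternative="larger"
        )
        assert res.z_stat == pytest.approx(float(z), abs=1e-12)
        assert res.p_value == pytest.approx(float(p), abs=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            two_sample_proportion_test(11, 10, 1, 10)


class TestGroupProportions:
    def test_all_skipped_stratum(self):
        profiles = make_profiles(
            [
                {"entry_id": "a", "label": "SKIPPED", "region": "upstream",
                 "n_zdna": 1},
                {"entry_id": "a", "label": "SKIPPED", "region": "downstream"},
                {"entry_id": "b", "label": "CONSTITUTIVE", "region": "upstream"},
                {"entry_id": "b", "label": "CONSTITUTIVE", "region": "downstream"},
            ]
        )
        table = group_proportions(profiles, background=0.5)
        row = table[(table.structure == "zdna") & (table.region == "upstream")]
        assert row.proportion.tolist() == [1.0]
        assert row.background.tolist() == [0.5]

    def test_exact_tally_against_truth(self):
        rng = np.random.default_rng(5)
        rows = []
        truth = {}
        for i in range(150):
            label = "SKIPPED" if rng.random() < 0.3 else "CONSTITUTIVE"
            for region in ("upstream", "downstream"):
                c = int(rng.poisson(0.7))
                rows.append(
                    {"entry_id": f"e{i}", "label": label, "region": region,
                     "n_triplex": c}
                )
                if c > 0:
                    key = (region, c)
                    n, k = truth.get(key, (0, 0))
                    truth[key] = (n + 1, k + (label == "SKIPPED"))
        table = group_proportions(make_profiles(rows), background=0.3)
        tri = table[table.structure == "triplex"]
        assert len(tri) == len(truth)
        for _, row in tri.iterrows():
            n, k = truth[(row.region, row["count"])]
            assert (row.n_exons, row.n_skipped) == (n, k)
            assert row.proportion == pytest.approx(k / n)

    def test_g_run_strata_keys(self):
        profiles = make_profiles(
            [
                {"entry_id": "a", "label": "SKIPPED", "region": "upstream",
                 "max_g_run_template": 4},
                {"entry_id": "a", "label": "SKIPPED", "region": "downstream",
                 "max_g_run_nontemplate": 3},
            ]
        )
        table = group_proportions(profiles, background=0.1, stratifier="g_run")
        assert set(table.columns) >= {"strand", "region", "g_run_length"}
        assert set(zip(table.strand, table.region, table.g_run_length)) == {
            ("template", "upstream", 4),
            ("nontemplate", "downstream", 3),
        }


class TestDesignMatrix:
    def make_pair(self, **counts):
        return make_profiles(
            [
                {"entry_id": "x", "label": "SKIPPED", "region": "upstream",
                 "intron_length": 1200, **counts},
                {"entry_id": "x", "label": "SKIPPED", "region": "downstream",
                 "intron_length": 800},
            ]
        )

    def test_column_order_and_count(self):
        X, y = build_design_matrix(self.make_pair())
        assert list(X.columns) == list(DESIGN_COLUMNS)
        assert X.shape[1] == 12
        assert y.tolist() == [1]

    def test_no_motifs_row(self):
        X, _ = build_design_matrix(self.make_pair())
        assert X.iloc[0, 0] == 1200.0
        assert X.iloc[0, 1] == 800.0
        assert (X.iloc[0, 2:] == 0).all()

    def test_g4_strands_summed(self):
        X, _ = build_design_matrix(
            self.make_pair(n_g4_template=1, n_g4_nontemplate=1)
        )
        assert X.loc["x", "upstream_g4"] == 2.0

    def test_unmerged_g4_has_14_columns(self):
        X, _ = build_design_matrix(
            self.make_pair(n_g4_template=1), merge_g4_strands=False
        )
        assert X.shape[1] == 14
        assert X.loc["x", "upstream_g4_template"] == 1.0

    def test_missing_region_raises(self):
        profiles = make_profiles(
            [{"entry_id": "x", "label": "SKIPPED", "region": "upstream"}]
        )
        with pytest.raises(ValueError):
            build_design_matrix(profiles)


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = np.zeros(400)
        y[:100] = 1.0  # mean 0.25
        X = pd.DataFrame(index=range(400))  # no predictors
        fit = fit_logistic(X, y)
        assert fit.coefficients["intercept"] == pytest.approx(
            np.log(0.25 / 0.75), abs=1e-8
        )

    def test_recovers_true_coefficients(self):
        rng = np.random.default_rng(11)
        n = 20_000
        X = pd.DataFrame(
            {"a": rng.poisson(0.5, size=n), "b": rng.normal(size=n)}
        )
        true = np.array([-1.5, 0.8, -0.4])
        logit = true[0] + X["a"] * true[1] + X["b"] * true[2]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        fit = fit_logistic(X, y)
        for name, beta in zip(["intercept", "a", "b"], true):
            est = fit.coefficients[name]
            se = fit.standard_errors[name]
            assert abs(est - beta) < 3 * se

    def test_perfect_separation_raises(self):
        X = pd.DataFrame({"x": np.concatenate([np.zeros(20), np.ones(20)])})
        y = np.concatenate([np.zeros(20), np.ones(20)])
        with pytest.raises(SeparationError):
            fit_logistic(X, y)

    def test_gradient_vanishes_at_optimum(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        n = 2000
        X = pd.DataFrame(
            {"a": rng.poisson(0.4, size=n), "b": rng.normal(size=n)}
        )
        y = (rng.random(n) < 0.2 + 0.1 * (X["a"] > 0)).astype(float)
        fit = fit_logistic(X, y)
        design = sm.add_constant(X, prepend=True)
        model = sm.Logit(y, design)
        score = model.score(fit.coefficients.to_numpy())
        assert np.linalg.norm(score) < 1e-6
        # an independent optimizer cannot beat our fit and agrees closely
        ref = model.fit(method="bfgs", disp=0)
        assert fit.log_likelihood >= ref.llf - 1e-8
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-5)

    def test_wald_z_definition(self):
        rng = np.random.default_rng(30)
        X = pd.DataFrame({"a": rng.normal(size=500)})
        y = (rng.random(500) < 0.3).astype(float)
        fit = fit_logistic(X, y)
        assert fit.wald_z["a"] == pytest.approx(
            fit.coefficients["a"] / fit.standard_errors["a"]
        )
        assert fit.p_values["a"] == pytest.approx(
            2 * sps.norm.sf(abs(fit.wald_z["a"]))
        )


class TestProximalComparison:
    def test_presence_absence_not_counts(self):
        rows = []
        for i in range(60):
            skip = i < 30
            rows.append(
                {"entry_id": f"e{i}", "label": "SKIPPED" if skip else "CONSTITUTIVE",
                 "region": "upstream",
                 # counts of 5 must contribute the same as counts of 1
                 "prox_zdna": (5 if skip else 1) if i % 2 == 0 else 0}
            )
            rows.append(
                {"entry_id": f"e{i}", "label": "SKIPPED" if skip else "CONSTITUTIVE",
                 "region": "downstream"}
            )
        table = proximal_comparison(make_profiles(rows))
        row = table[(table.structure == "zdna") & (table.region == "upstream")]
        assert row.skipped_pct.tolist() == [50.0]
        assert row.constitutive_pct.tolist() == [50.0]
        assert row.z_stat.tolist() == [pytest.approx(0.0)]

    def test_planted_enrichment_detected_only_where_planted(self):
        rng = np.random.default_rng(10)
        rows = []
        for i in range(400):
            skip = i < 200
            up_g4 = int(rng.random() < (0.5 if skip else 0.1))
            down_g4 = int(rng.random() < 0.1)
            label = "SKIPPED" if skip else "CONSTITUTIVE"
            rows.append({"entry_id": f"e{i}", "label": label,
                         "region": "upstream", "prox_g4_template": up_g4})
            rows.append({"entry_id": f"e{i}", "label": label,
                         "region": "downstream", "prox_g4_template": down_g4})
        table = proximal_comparison(make_profiles(rows))
        up = table[(table.structure == "g4_template") & (table.region == "upstream")]
        down = table[
            (table.structure == "g4_template") & (table.region == "downstream")
        ]
        assert up.p_value.iloc[0] < 1e-6
        assert down.p_value.iloc[0] > 0.01

    def test_single_class_input_rejected(self):
        rows = [
            {"entry_id": "a", "label": "SKIPPED", "region": "upstream"},
            {"entry_id": "a", "label": "SKIPPED", "region": "downstream"},
        ]
        with pytest.raises(ValueError):
            proximal_comparison(make_profiles(rows))


class TestGRunAssociation:
    def test_monotone_simulation_positive_r(self):
        rng = np.random.default_rng(12)
        rows = []
        for i in range(600):
            run = int(rng.integers(3, 8))
            p_skip = 0.05 + 0.08 * (run - 3)
            label = "SKIPPED" if rng.random() < p_skip else "CONSTITUTIVE"
            rows.append(
                {"entry_id": f"e{i}", "label": label, "region": "upstream",
                 "max_g_run_template": run,
                 "intron_length": int(rng.integers(500, 3000))}
            )
            rows.append({"entry_id": f"e{i}", "label": label,
                         "region": "downstream"})
        table, corr = g_run_association(make_profiles(rows), background=0.1)
        assert corr.r > 0
        assert corr.p_value < 1e-4
        assert set(table.strand) == {"template"}

    def test_constant_g_run_surfaces_degenerate_error(self):
        rows = []
        for i in range(20):
            rows.append(
                {"entry_id": f"e{i}",
                 "label": "SKIPPED" if i % 2 else "CONSTITUTIVE",
                 "region": "upstream", "max_g_run_template": 4}
            )
            rows.append({"entry_id": f"e{i}", "label": "SKIPPED" if i % 2
                         else "CONSTITUTIVE", "region": "downstream"})
        with pytest.raises(DegenerateStatisticError, match="G-run"):
            g_run_association(make_profiles(rows), background=0.5)


class TestReporting:
    def test_significance_stars_thresholds(self):
        assert significance_stars(0.5) == ""
        assert significance_stars(0.009) == "*"
        assert significance_stars(0.0009) == "**"
        assert significance_stars(0.00009) == "***"

    def test_bh_column_is_additive_only(self):
        table = pd.DataFrame({"p_value": [0.01, 0.02, 0.5, np.nan]})
        out = add_bh_column(table)
        assert len(out) == len(table)
        assert "q_value" in out.columns
        assert out.q_value.iloc[0] == pytest.approx(0.03)
        assert np.isnan(out.q_value.iloc[3])
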