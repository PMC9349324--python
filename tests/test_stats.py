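import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from octaquant.stats import (
    FORCED_COVARIATES,
    association_model,
    build_tables,
    gee_group_model,
    select_covariates,
    univariate_characteristic_test,
)
from octaquant.synthetic import default_cohort_config, generate_truth_table


def null_table(n_participants=30, rho=0.5, seed=0, delta=0.0):
    """Small clustered two-group table with configurable group effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, label in ((0, "control"), (1, "MS")):
        for i in range(n_participants):
            part = rng.standard_normal()
            for eye in ("OD", "OS"):
                y = delta * g + np.sqrt(rho) * part + np.sqrt(1 - rho) * rng.standard_normal()
                rows.append(
                    {
                        "participant_id": f"{label}{i}",
                        "group": label,
                        "eye": eye,
                        "y": y,
                        "duration_years": float(rng.uniform(1, 20)),
                        "age": float(rng.normal(40, 10)),
                    }
                )
    return pd.DataFrame(rows)


class TestCharacteristicTest:
    def test_type_one_error_of_gated_continuous_test(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            v = np.concatenate([rng.normal(0, 1, 40), rng.normal(0, 1, 40)])
            g = ["a"] * 40 + ["b"] * 40
            p, _ = univariate_characteristic_test(v, g, "continuous")
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.08

    def test_fisher_selected_for_sparse_table(self):
        # 2x2 table [[1, 9], [8, 2]]: expected counts < 5 -> Fisher
        values = ["x"] * 1 + ["y"] * 9 + ["x"] * 8 + ["y"] * 2
        group = ["a"] * 10 + ["b"] * 10
        p, test = univariate_characteristic_test(values, group, "categorical")
        assert test == "fisher"
        assert p < 0.05
        # independent hypergeometric oracle: two-sided exact probability
        oracle = sum(
            hypergeom.pmf(k, 20, 9, 10)
            for k in range(0, 10)
            if hypergeom.pmf(k, 20, 9, 10) <= hypergeom.pmf(1, 20, 9, 10) * (1 + 1e-9)
        )
        assert p == pytest.approx(oracle, rel=1e-6)

    def test_skewed_data_uses_kruskal(self):
        rng = np.random.default_rng(3)
        v = np.concatenate([rng.lognormal(0, 1, 60), rng.lognormal(0, 1, 60)])
        g = ["a"] * 60 + ["b"] * 60
        _, test = univariate_characteristic_test(v, g, "continuous")
        assert test == "kruskal-wallis"

    def test_degenerate_constant_samples(self):
        with pytest.warns(UserWarning):
            p, test = univariate_characteristic_test([1.0] * 5 + [1.0] * 5, ["a"] * 5 + ["b"] * 5)
        assert p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            univariate_characteristic_test([1, 2, 3], ["a", "a", "a"])


class TestGeeGroupModel:
    def test_singleton_clusters_reproduce_raw_means(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(40)],
                "group": ["MS"] * 20 + ["control"] * 20,
                "y": rng.normal(10, 2, 40),
            }
        )
        gc = gee_group_model(t, "y")
        assert gc.mean_se_ms[0] == pytest.approx(t[t.group == "MS"]["y"].mean(), abs=1e-8)
        assert gc.mean_se_control[0] == pytest.approx(t[t.group == "control"]["y"].mean(), abs=1e-8)

    def test_type_one_error_nominal(self):
        n_rep = 250
        rej = 0
        for rep in range(n_rep):
            t = null_table(n_participants=15, rho=0.5, seed=rep)
            gc = gee_group_model(t, "y")
            rej += gc.p_value < 0.05
        assert 0.02 <= rej / n_rep <= 0.09

    def test_group_effect_recovered(self):
        t = null_table(n_participants=60, rho=0.5, seed=5, delta=1.0)
        gc = gee_group_model(t, "y")
        est = gc.mean_se_ms[0] - gc.mean_se_control[0]
        assert est == pytest.approx(1.0, abs=2 * np.hypot(gc.mean_se_ms[1], gc.mean_se_control[1]) + 0.05)

    def test_robust_se_geq_naive_on_clustered_data(self):
        import statsmodels.api as sm

        ratio = []
        for rep in range(20):
            t = null_table(n_participants=25, rho=0.6, seed=100 + rep)
            t["_ms"] = (t.group == "MS").astype(float)
            X = sm.add_constant(t[["_ms"]])
            model = sm.GEE(
                t["y"], X, groups=t["participant_id"],
                family=sm.families.Gaussian(),
                cov_struct=sm.cov_struct.Independence(),
            )
            res = model.fit()
            robust = res.standard_errors(cov_type="robust")[1]
            naive = res.standard_errors(cov_type="naive")[1]
            ratio.append(robust / naive)
        assert np.mean(ratio) > 1.0

    def test_collinear_covariates_named(self):
        t = null_table(seed=9)
        t["age2"] = t["age"] * 2.0
        with pytest.raises(ValueError, match="age"):
            gee_group_model(t, "y", ["age", "age2"])


class TestSelectCovariates:
    def test_strong_candidate_always_included(self):
        t = null_table(seed=2)
        t["x"] = t["y"] * 3.0 + 0.01 * np.random.default_rng(0).standard_normal(len(t))
        for c in FORCED_COVARIATES:
            t[c] = np.random.default_rng(1).standard_normal(len(t))
        sel = select_covariates(t, "y", ["x"])
        assert "x" in sel

    def test_empty_candidates_gives_forced_set(self):
        t = null_table(seed=3)
        for c in FORCED_COVARIATES:
            t[c] = np.random.default_rng(2).standard_normal(len(t))
        assert select_covariates(t, "y", []) == list(FORCED_COVARIATES)

    def test_noise_candidate_inclusion_rate_near_ten_percent(self):
        rng = np.random.default_rng(4)
        included = 0
        n_rep = 150
        for rep in range(n_rep):
            t = null_table(n_participants=20, seed=400 + rep)
            t["noise"] = rng.standard_normal(len(t))
            sel = select_covariates(t, "y", ["noise"], forced=())
            included += "noise" in sel
        assert 0.05 <= included / n_rep <= 0.15


class TestAssociationModel:
    def test_exact_linear_relation(self):
        t = null_table(seed=6)
        ms = t.group == "MS"
        t.loc[ms, "y"] = 2.0 * t.loc[ms, "duration_years"]
        res = association_model(t, "y", "duration_years")
        assert res.beta == pytest.approx(2.0, abs=1e-8)
        assert res.ci_high - res.ci_low < 1e-6
        assert res.ci_low <= res.beta <= res.ci_high

    def test_zero_variance_predictor_rejected(self):
        t = null_table(seed=7)
        t["duration_years"] = 5.0
        with pytest.raises(ValueError):
            association_model(t, "y", "duration_years")

    def test_confidence_interval_coverage(self):
        n_rep = 200
        cover = 0
        for rep in range(n_rep):
            t = null_table(n_participants=50, seed=700 + rep)
            res = association_model(t, "y", "duration_years")
            cover += res.ci_low <= 0.0 <= res.ci_high
        assert 0.90 <= cover / n_rep <= 0.99

    def test_slope_sign_power(self):
        cfg = default_cohort_config(master_seed=0)
        hits = 0
        n_rep = 30
        for rep in range(n_rep):
            cfg = default_cohort_config(master_seed=1000 + rep)
            cfg.association_slopes = {"pd_dcp_pct": (0.5, 0.0)}
            t = generate_truth_table(cfg)
            res = association_model(t, "pd_dcp_pct", "duration_years")
            hits += res.beta > 0
        assert hits / n_rep >= 0.95


class TestBuildTables:
    @pytest.fixture(scope="class")
    def cohort(self):
        return generate_truth_table(default_cohort_config(master_seed=42))

    def test_report_schema(self, cohort):
        tabs = build_tables(cohort)
        assert set(tabs) == {"characteristics", "univariate", "multivariate", "duration", "episodes"}
        assert len(tabs["multivariate"]) == 10  # nine outcomes + RNFL row
        assert len(tabs["duration"]) == 9

    def test_determinism(self, cohort):
        t1 = build_tables(cohort)
        t2 = build_tables(cohort.copy())
        for k in t1:
            pd.testing.assert_frame_equal(t1[k], t2[k])

    def test_group_label_symmetry(self, cohort):
        swapped = cohort.copy()
        swapped["group"] = swapped["group"].map({"MS": "control", "control": "MS"})
        t1 = build_tables(cohort)["univariate"]
        t2 = build_tables(swapped)["univariate"]
        assert np.allclose(t1["p_value"], t2["p_value"], atol=1e-8)
        assert np.allclose(t1["ms_mean"], t2["control_mean"], atol=1e-8)

    def test_missing_outcome_column_rejected(self, cohort):
        with pytest.raises(ValueError, match="missing"):
            build_tables(cohort.drop(columns=["pd_dcp_pct"]))

    def test_single_group_rejected(self, cohort):
        with pytest.raises(ValueError):
            build_tables(cohort[cohort.group == "MS"])
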