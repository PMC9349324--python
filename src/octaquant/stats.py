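"""Cohort statistics with inter-eye clustering.

Both eyes of a participant are correlated, so all regression models are
linear generalized estimating equations (GEE, identity link, exchangeable
working correlation, clusters = participant) with bias-reduced (Mancl-
DeRouen) sandwich standard errors and a t reference distribution with
(clusters - parameters) degrees of freedom — the plain sandwich is
anticonservative at the cluster counts of a typical two-eye study.  Group comparisons report marginal (adjusted) means per group with
covariates held at their sample means, and a Wald P value on the group
coefficient.  Participant characteristics are compared with a
normality-gated rule: Shapiro-Wilk per group at alpha = 0.05 decides
between the independent t-test (both groups normal) and Kruskal-Wallis;
categorical variables use chi-square, switching to Fisher's exact test when
any expected cell count is below 5.

Covariate selection for the adjusted models keeps a forced set (age,
gender, hypertension, signal strength) and adds any candidate whose
univariate GEE P value is below 0.10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .metrics import OUTCOME_COLUMNS

__all__ = [
    "GroupComparison",
    "AssociationResult",
    "univariate_characteristic_test",
    "gee_group_model",
    "select_covariates",
    "association_model",
    "build_tables",
    "FORCED_COVARIATES",
    "OUTCOME_LABELS",
]

FORCED_COVARIATES = ("age", "gender", "hypertension", "signal_strength")

#: human-readable labels, in report order (RNFL first, as a reference row)
OUTCOME_LABELS = {
    "rnfl_um": "Peripapillary RNFL thickness (um)",
    "pd_scp_pct": "Perfusion density SCP (%)",
    "pd_scp_wo_lv_pct": "Perfusion density SCP w/o LV (%)",
    "pd_lv_pct": "Perfusion density LV (%)",
    "pd_dcp_pct": "Perfusion density DCP (%)",
    "faz_area_s_mm2": "FAZ area, superficial (mm^2)",
    "faz_circ_s": "FAZ circularity, superficial",
    "faz_area_d_mm2": "FAZ area, deep (mm^2)",
    "faz_circ_d": "FAZ circularity, deep",
    "fd_cc_pct": "Flow deficit CC (%)",
}
REPORT_OUTCOMES = tuple(OUTCOME_LABELS)


@dataclass
class GroupComparison:
    """Per-outcome group contrast: means +/- SE per group and a Wald P."""

    outcome: str
    mean_se_control: Tuple[float, float]
    mean_se_ms: Tuple[float, float]
    p_value: float
    covariates: List[str] = field(default_factory=list)
    coef_ms: float = float("nan")
    coef_se: float = float("nan")


@dataclass
class AssociationResult:
    """Univariate GEE slope of an outcome on an MS disease predictor."""

    outcome: str
    predictor: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float


# --------------------------------------------------------------------------
# characteristics


def univariate_characteristic_test(
    values: Sequence, group: Sequence, var_type: str = "continuous"
) -> Tuple[float, str]:
    """Compare one characteristic between two groups.

    Continuous: Shapiro-Wilk on each group (alpha 0.05) gates the choice of
    independent t-test (both normal) vs Kruskal-Wallis.  Categorical:
    chi-square on the contingency table, or Fisher's exact test when any
    expected cell count is below 5 (2x2 tables).  Returns ``(p, test_name)``.
    """
    values = pd.Series(list(values))
    group = pd.Series(list(group))
    levels = sorted(group.unique())
    if len(levels) < 2:
        raise ValueError("need two groups")
    if var_type == "continuous":
        samples = [pd.to_numeric(values[group == g]).to_numpy(dtype=float) for g in levels]
        if any(len(s) < 3 for s in samples):
            raise ValueError("need at least 3 observations per group")
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            warnings.warn("no variation in either group; returning P = 1")
            return 1.0, "degenerate"
        normal = []
        for s in samples:
            if np.ptp(s) == 0:
                normal.append(False)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normal.append(sps.shapiro(s).pvalue > 0.05)
        if all(normal):
            stat = sps.ttest_ind(samples[0], samples[1], equal_var=True)
            return float(stat.pvalue), "t-test"
        stat = sps.kruskal(*samples)
        return float(stat.pvalue), "kruskal-wallis"
    if var_type == "categorical":
        tab = pd.crosstab(values, group)
        if tab.shape[0] < 2:
            warnings.warn("single category; returning P = 1")
            return 1.0, "degenerate"
        expected = sps.contingency.expected_freq(tab.to_numpy())
        if (expected < 5).any() and tab.shape == (2, 2):
            _, p = sps.fisher_exact(tab.to_numpy())
            return float(p), "fisher"
        chi2 = sps.chi2_contingency(tab.to_numpy())
        return float(chi2.pvalue), "chi-square"
    raise ValueError(f"unknown var_type {var_type!r}")


# --------------------------------------------------------------------------
# GEE machinery


def _design(
    table: pd.DataFrame, terms: Sequence[str]
) -> Tuple[pd.DataFrame, List[str]]:
    """Numeric design columns for the given terms (no intercept).

    Binary string columns are dummy-coded; raises when two terms are
    perfectly collinear, naming the pair.
    """
    cols: Dict[str, np.ndarray] = {}
    for t in terms:
        v = table[t]
        if v.dtype == object or str(v.dtype) == "category":
            codes, uniques = pd.factorize(v, sort=True)
            if len(uniques) > 2:
                for lvl in uniques[1:]:
                    cols[f"{t}[{lvl}]"] = (v == lvl).astype(float).to_numpy()
            else:
                cols[t] = codes.astype(float)
        else:
            cols[t] = pd.to_numeric(v).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=table.index)
    arr = X.to_numpy()
    if arr.shape[1] >= 2:
        corr = np.corrcoef(arr, rowvar=False)
        for i in range(len(corr)):
            for j in range(i + 1, len(corr)):
                if abs(corr[i, j]) > 0.9999:
                    raise ValueError(
                        f"collinear covariates: {X.columns[i]!r} and {X.columns[j]!r}"
                    )
    return X, list(X.columns)


def _fit_gee(table: pd.DataFrame, outcome: str, terms: Sequence[str]):
    """Fit the clustered linear model; returns (result, design, V, df).

    ``V`` is the bias-reduced sandwich covariance of the coefficients and
    ``df`` the residual cluster degrees of freedom used for Wald tests.
    """
    X, names = _design(table, terms)
    X = sm.add_constant(X, prepend=True)
    y = pd.to_numeric(table[outcome]).to_numpy(dtype=float)
    groups = table["participant_id"].to_numpy()
    model = sm.GEE(
        y,
        X,
        groups=groups,
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(cov_type="bias_reduced")
    V = np.asarray(res.cov_robust_bc)
    if not np.all(np.isfinite(V)):
        V = np.asarray(res.cov_robust)
    n_clusters = pd.Series(groups).nunique()
    df = max(n_clusters - X.shape[1], 1)
    return res, X, V, df


def gee_group_model(
    table: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = (),
) -> GroupComparison:
    """Linear GEE of ``outcome`` on group membership, optionally adjusted.

    Adjusted group means are marginal predictions with every covariate held
    at its sample mean (binary covariates at their sample proportion);
    their SEs propagate the robust covariance of the coefficients.  The
    group P value is the Wald test on the MS indicator.
    """
    if outcome not in table:
        raise ValueError(f"outcome {outcome!r} not in table")
    work = table.copy()
    work["_ms"] = (work["group"] == "MS").astype(float)
    terms = ["_ms", *covariates]
    res, X, V, df = _fit_gee(work, outcome, terms)
    params = np.asarray(res.params)
    cols = list(X.columns)
    i_ms = cols.index("_ms")

    xbar = X.mean(axis=0).to_numpy()
    means = {}
    for g, label in ((0.0, "control"), (1.0, "MS")):
        x = xbar.copy()
        x[i_ms] = g
        mu = float(x @ params)
        se = float(np.sqrt(x @ V @ x))
        means[label] = (mu, se)
    tstat = params[i_ms] / np.sqrt(V[i_ms, i_ms])
    p = 2.0 * sps.t.sf(abs(tstat), df)
    return GroupComparison(
        outcome=outcome,
        mean_se_control=means["control"],
        mean_se_ms=means["MS"],
        p_value=float(p),
        covariates=list(covariates),
        coef_ms=float(params[i_ms]),
        coef_se=float(np.sqrt(V[i_ms, i_ms])),
    )


def select_covariates(
    table: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str] = (),
    forced: Sequence[str] = FORCED_COVARIATES,
    p_enter: float = 0.10,
) -> List[str]:
    """Forced covariates plus candidates with univariate GEE P < ``p_enter``."""
    selected = list(forced)
    for c in candidates:
        if c in selected:
            continue
        res, X, V, df = _fit_gee(table, outcome, [c])
        params = np.asarray(res.params)
        j = list(X.columns).index(c) if c in X.columns else 1
        tstat = params[j] / np.sqrt(V[j, j])
        p = 2.0 * sps.t.sf(abs(tstat), df)
        if p < p_enter:
            selected.append(c)
    return selected


def association_model(
    table: pd.DataFrame, outcome: str, predictor: str
) -> AssociationResult:
    """Univariate GEE of an outcome on an MS disease predictor (MS eyes only)."""
    ms = table[table["group"] == "MS"]
    if len(ms) == 0:
        raise ValueError("no MS eyes in table")
    x = pd.to_numeric(ms[predictor]).to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    res, X, V, df = _fit_gee(ms, outcome, [predictor])
    params = np.asarray(res.params)
    j = list(X.columns).index(predictor)
    beta = float(params[j])
    se = float(np.sqrt(V[j, j]))
    zcrit = float(sps.t.ppf(0.975, df))
    tstat = beta / se if se > 0 else np.inf * np.sign(beta)
    p = 2.0 * sps.t.sf(abs(tstat), df) if np.isfinite(tstat) else 0.0
    return AssociationResult(
        outcome=outcome,
        predictor=predictor,
        beta=beta,
        ci_low=beta - zcrit * se,
        ci_high=beta + zcrit * se,
        p_value=float(p),
    )


# --------------------------------------------------------------------------
# report tables


_CHARACTERISTICS = [
    ("age", "continuous", "Age (years)"),
    ("gender", "categorical", "Gender"),
    ("axial_length_mm", "continuous", "Axial length (mm)"),
    ("iop_mmHg", "continuous", "IOP (mmHg)"),
    ("hypertension", "categorical", "Hypertension"),
    ("signal_strength", "continuous", "Signal strength (/10)"),
]


def _mean_sd(v: pd.Series) -> str:
    return f"{v.mean():.1f} ± {v.std(ddof=1):.1f}"


def build_tables(
    table: pd.DataFrame,
    outcomes: Sequence[str] = REPORT_OUTCOMES,
    candidates: Sequence[str] = ("iop_mmHg", "axial_length_mm"),
) -> Dict[str, pd.DataFrame]:
    """Build the five report tables from a per-eye cohort table.

    Returns a dict with keys ``characteristics``, ``univariate``,
    ``multivariate``, ``duration`` and ``episodes``.  Group contrasts flag
    P < 0.05; characteristics flag P < 0.10.
    """
    required = {"participant_id", "group"} | set(outcomes)
    missing = sorted(required - set(table.columns))
    if missing:
        raise ValueError(f"missing columns: {missing}")
    groups = set(table["group"].unique())
    if groups != {"MS", "control"}:
        raise ValueError(f"need both an MS and a control group, got {sorted(groups)}")

    ctrl = table[table["group"] == "control"]
    ms = table[table["group"] == "MS"]

    char_rows = []
    for col, kind, label in _CHARACTERISTICS:
        if col not in table:
            continue
        p, test = univariate_characteristic_test(table[col], table["group"], kind)
        if kind == "continuous":
            dc, dm = _mean_sd(ctrl[col]), _mean_sd(ms[col])
        else:
            dc = " / ".join(f"{k}: {v}" for k, v in ctrl[col].value_counts().sort_index().items())
            dm = " / ".join(f"{k}: {v}" for k, v in ms[col].value_counts().sort_index().items())
        char_rows.append(
            {"characteristic": label, "control": dc, "MS": dm,
             "p_value": p, "test": test, "significant": p < 0.10}
        )
    characteristics = pd.DataFrame(char_rows)

    def comparison_frame(adjust: bool) -> pd.DataFrame:
        rows = []
        for out in outcomes:
            covs = select_covariates(table, out, candidates) if adjust else []
            gc = gee_group_model(table, out, covs)
            rows.append(
                {
                    "outcome": OUTCOME_LABELS.get(out, out),
                    "key": out,
                    "control_mean": gc.mean_se_control[0],
                    "control_se": gc.mean_se_control[1],
                    "ms_mean": gc.mean_se_ms[0],
                    "ms_se": gc.mean_se_ms[1],
                    "p_value": gc.p_value,
                    "significant": gc.p_value < 0.05,
                    "covariates": ",".join(gc.covariates),
                }
            )
        return pd.DataFrame(rows)

    univariate = comparison_frame(adjust=False)
    multivariate = comparison_frame(adjust=True)

    def association_frame(predictor: str) -> pd.DataFrame:
        rows = []
        for out in outcomes:
            if out == "rnfl_um":
                continue
            try:
                ar = association_model(table, out, predictor)
            except ValueError:
                rows.append({"outcome": OUTCOME_LABELS.get(out, out), "key": out,
                             "beta": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                             "p_value": np.nan, "significant": False})
                continue
            rows.append(
                {
                    "outcome": OUTCOME_LABELS.get(out, out),
                    "key": out,
                    "beta": ar.beta,
                    "ci_low": ar.ci_low,
                    "ci_high": ar.ci_high,
                    "p_value": ar.p_value,
                    "significant": ar.p_value < 0.05,
                }
            )
        return pd.DataFrame(rows)

    return {
        "characteristics": characteristics,
        "univariate": univariate,
        "multivariate": multivariate,
        "duration": association_frame("duration_years"),
        "episodes": association_frame("episodes"),
    }


def render_report(tables: Mapping[str, pd.DataFrame]) -> str:
    """Human-readable text rendering of the report tables."""
    out = []
    titles = {
        "characteristics": "Participant characteristics by disease status",
        "univariate": "OCTA parameters by group (unadjusted)",
        "multivariate": "OCTA parameters by group (covariate-adjusted)",
        "duration": "Association of OCTA parameters with MS duration",
        "episodes": "Association of OCTA parameters with MS episode count",
    }
    for key in ("characteristics", "univariate", "multivariate", "duration", "episodes"):
        if key not in tables:
            continue
        out.append(titles[key])
        out.append("=" * len(titles[key]))
        out.append(tables[key].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        out.append("")
    return "\n".join(out)
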