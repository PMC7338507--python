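"""Survival analysis: median dichotomization, Kaplan–Meier with log-rank,
and stratified multivariable Cox proportional-hazards model batteries.

The cohort table is a pandas DataFrame with one row per sample and a
controlled clinical vocabulary:

========== ===========================================
column      levels / units
========== ===========================================
age         years (continuous)
node_status positive | negative
tumor_size  >20mm | <=20mm
er_status   positive | negative   (>10% stained cells)
pr_status   positive | negative
her2        amplified | not
grade       1 | 2 | 3
pam50       basal | her2e | lumA | lumB | normal
chemo       yes | no
endocrine   yes | no
os_time     days; os_event 0|1
rfs_time    days; rfs_event 0|1
<gene>      log2-scale expression columns
========== ===========================================

Cox fits use the partial likelihood with Efron tie handling and a separate
baseline hazard per stratum combination (lifelines).  Age enters strata as
5-year bins; age-restricted subgroups (e.g. "age < 66") are row filters, not
strata.  Ig expression enters as a continuous covariate, z-scored per cohort
by default so hazard ratios are per standard deviation; missing data are
handled by complete-case exclusion per model, and the exclusion count is
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)


class SurvivalError(ValueError):
    pass


# Binary clinical codings: column -> (level coded 1, reference level coded 0).
BINARY_CODINGS: dict[str, tuple[str, str]] = {
    "node_status": ("positive", "negative"),
    "tumor_size": (">20mm", "<=20mm"),
    "er_status": ("positive", "negative"),
    "pr_status": ("positive", "negative"),
    "her2": ("amplified", "not"),
    "chemo": ("yes", "no"),
    "endocrine": ("yes", "no"),
}
PAM50_LEVELS = ["basal", "her2e", "lumA", "lumB", "normal"]
PAM50_REFERENCE = "lumA"
AGE_BIN_YEARS = 5

ENDPOINTS = {"OS": ("os_time", "os_event"), "RFS": ("rfs_time", "rfs_event")}


def dichotomize_median(values: pd.Series) -> pd.Series:
    """Label samples ``high`` if strictly above the median, else ``low``.

    The median is taken over non-missing values; ties at the median go to
    ``low``.  Missing inputs stay missing.
    """
    v = values.dropna()
    if len(v) < 2:
        raise SurvivalError("median dichotomization needs >=2 non-missing values")
    med = v.median()
    out = pd.Series(
        np.where(values > med, "high", "low"), index=values.index, dtype=object
    )
    out[values.isna()] = np.nan
    return out


def zscore(values: pd.Series) -> pd.Series:
    """Standardize to mean 0, sample SD 1 (ddof=1) over non-missing entries."""
    v = values.dropna()
    if v.nunique() < 2:
        raise SurvivalError("zero variance: cannot z-score")
    sd = v.std(ddof=1)
    return (values - v.mean()) / sd


def bin_age(age: pd.Series, width: int = AGE_BIN_YEARS) -> pd.Series:
    """Bin age into ``width``-year intervals (lower edge label)."""
    return (age // width) * width


@dataclass
class KMResult:
    """Per-group product-limit curves, at-risk counts, and the log-rank test."""

    groups: dict[str, pd.DataFrame]  # columns: time, survival, at_risk
    statistic: float
    p_value: float


def km_logrank(
    time: pd.Series, event: pd.Series, group: pd.Series
) -> KMResult:
    """Kaplan–Meier curves per group plus the two-group log-rank test.

    The chi-square log-rank statistic (1 df) is reported when both groups
    contain at least one event; otherwise curves are returned with the test
    set to NaN.
    """
    df = pd.DataFrame({"time": time, "event": event, "group": group}).dropna()
    if (df["time"] < 0).any():
        raise SurvivalError("negative survival times")
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise SurvivalError(f"need exactly 2 groups, got {levels}")
    curves: dict[str, pd.DataFrame] = {}
    events_per_group = {}
    for lev in levels:
        sub = df[df["group"] == lev]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        tab = kmf.event_table
        curves[str(lev)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tab["at_risk"].to_numpy(),
            }
        )
        events_per_group[lev] = int(sub["event"].sum())
    if min(events_per_group.values()) >= 1:
        a, b = (df[df["group"] == lev] for lev in levels)
        res = logrank_test(a["time"], b["time"], a["event"], b["event"])
        stat, p = float(res.test_statistic), float(res.p_value)
    else:
        stat, p = float("nan"), float("nan")
    return KMResult(groups=curves, statistic=stat, p_value=p)


@dataclass
class SurvModelSpec:
    """One Cox model: endpoint, covariates, strata, optional subgroup filter.

    ``continuous_vars`` enter as-is except those in ``zscore_vars`` which are
    standardized per cohort (hazard ratio per SD).  ``categorical_vars`` may
    contain binary-coded clinical columns (see BINARY_CODINGS), ``grade3``
    (grade 3 vs 1–2) or ``pam50`` (dummy-coded against luminal A).  ``strata``
    may contain any categorical column, ``age_bin`` (5-year bins) or
    ``grade``.
    """

    name: str
    endpoint: str = "OS"
    continuous_vars: Sequence[str] = ()
    categorical_vars: Sequence[str] = ()
    strata: Sequence[str] = ()
    subgroup_filter: Callable[[pd.DataFrame], pd.Series] | None = None
    zscore_vars: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise SurvivalError(f"unknown endpoint {self.endpoint!r}")
        overlap = set(self.continuous_vars + tuple(self.categorical_vars)) & set(
            self.strata
        )
        if overlap:
            raise SurvivalError(f"variables cannot also be strata: {sorted(overlap)}")


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald 95% CIs and p-values."""

    model: str
    table: pd.DataFrame  # index covariate; columns hr, ci_low, ci_high, p
    n: int
    events: int
    excluded: int
    fitted: bool = True
    message: str = ""


def _encode_covariate(df: pd.DataFrame, var: str) -> pd.DataFrame:
    """Numeric design columns for one covariate, named for the contrast."""
    if var in BINARY_CODINGS:
        pos, neg = BINARY_CODINGS[var]
        col = df[var]
        bad = set(col.dropna().unique()) - {pos, neg}
        if bad:
            raise SurvivalError(f"{var}: unexpected levels {sorted(bad)}")
        return pd.DataFrame({f"{var}_{pos}": (col == pos).astype(float).where(col.notna())})
    if var == "grade3":
        grade = pd.to_numeric(df["grade"])
        return pd.DataFrame({"grade3_vs_12": (grade == 3).astype(float).where(grade.notna())})
    if var == "pam50":
        col = df["pam50"]
        out = {}
        for lev in PAM50_LEVELS:
            if lev == PAM50_REFERENCE:
                continue
            out[f"pam50_{lev}"] = (col == lev).astype(float).where(col.notna())
        return pd.DataFrame(out)
    raise SurvivalError(f"no coding defined for categorical variable {var!r}")


def _stratum_column(df: pd.DataFrame, name: str) -> pd.Series:
    if name == "age_bin":
        return bin_age(df["age"]).rename("age_bin")
    return df[name]


def fit_cox(table: pd.DataFrame, spec: SurvModelSpec) -> CoxResult:
    """Fit one stratified Cox proportional-hazards model.

    Applies the subgroup filter, complete-case exclusion over every column
    the model touches, covariate encoding and per-model z-scoring, then fits
    the stratified partial likelihood (Efron ties).  Returns hazard ratios
    ``exp(beta)`` with Wald 95% CIs and p-values per covariate.
    """
    time_col, event_col = ENDPOINTS[spec.endpoint]
    df = table
    if spec.subgroup_filter is not None:
        df = df[spec.subgroup_filter(df).fillna(False).astype(bool)]
    n_input = len(df)

    design = pd.DataFrame(index=df.index)
    design["_time"] = pd.to_numeric(df[time_col])
    design["_event"] = pd.to_numeric(df[event_col])
    for var in spec.continuous_vars:
        design[var] = pd.to_numeric(df[var])
    for var in spec.categorical_vars:
        enc = _encode_covariate(df, var)
        design = design.join(enc)
    strata_cols = []
    for s in spec.strata:
        col = _stratum_column(df, s)
        design[f"_s_{s}"] = col
        strata_cols.append(f"_s_{s}")

    design = design.dropna()
    n_used = len(design)
    excluded = n_input - n_used
    if n_used == 0:
        return CoxResult(spec.name, pd.DataFrame(), 0, 0, excluded, False, "no complete cases")
    if (design["_time"] <= 0).any():
        raise SurvivalError("non-positive survival times")
    events = int(design["_event"].sum())

    for var in spec.zscore_vars:
        design[var] = zscore(design[var])

    # drop strata levels contributing no events (lifelines fits them but they
    # add nothing to the partial likelihood; empty-event strata can destabilize)
    if strata_cols:
        grp = design.groupby(strata_cols, observed=True)["_event"].transform("sum")
        dropped = int((grp == 0).sum())
        if dropped:
            logger.warning("dropping %d subjects in event-free strata", dropped)
            design = design[grp > 0]
            n_used = len(design)
            events = int(design["_event"].sum())

    cph = CoxPHFitter()
    try:
        cph.fit(
            design,
            duration_col="_time",
            event_col="_event",
            strata=strata_cols or None,
        )
    except Exception as exc:  # lifelines raises several convergence errors
        return CoxResult(
            spec.name, pd.DataFrame(), n_used, events, excluded, False, str(exc)
        )
    summ = cph.summary
    out = pd.DataFrame(
        {
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    out.index.name = "variable"
    return CoxResult(spec.name, out, n_used, events, excluded)


# -- model batteries ---------------------------------------------------------


def _age_below(limit: float) -> Callable[[pd.DataFrame], pd.Series]:
    return lambda d: d["age"] < limit


SUBGROUP_FILTERS: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "triple_negative": lambda d: (
        (d["er_status"] == "negative")
        & (d["pr_status"] == "negative")
        & (d["her2"] == "not")
    ),
    "er_pos_her2_neg": lambda d: (d["er_status"] == "positive") & (d["her2"] == "not"),
    "er_pos_her2_neg_age_lt66": lambda d: (
        (d["er_status"] == "positive") & (d["her2"] == "not") & (d["age"] < 66)
    ),
    "her2_pos": lambda d: d["her2"] == "amplified",
    "pam50_basal": lambda d: d["pam50"] == "basal",
    "pam50_her2e": lambda d: d["pam50"] == "her2e",
    "pam50_lumA": lambda d: d["pam50"] == "lumA",
    "pam50_lumA_age_lt65": lambda d: (d["pam50"] == "lumA") & (d["age"] < 65),
    "pam50_lumB": lambda d: d["pam50"] == "lumB",
    "pam50_lumB_age_lt66": lambda d: (d["pam50"] == "lumB") & (d["age"] < 66),
}

# ER/HER2-defined subgroups are additionally adjusted for grade.
_GRADE_ADJUSTED_SUBGROUPS = {
    "triple_negative", "er_pos_her2_neg", "er_pos_her2_neg_age_lt66", "her2_pos",
}

SINGLE_STRATA = ["age_bin", "node_status", "tumor_size", "er_status", "her2", "grade"]

BATTERIES = ("model1", "model2", "subgroups", "strata_single", "metagene_adjusted")


def build_battery_specs(
    battery: str,
    ig_vars: Sequence[str],
    metagene_cols: Sequence[str] = (),
) -> list[SurvModelSpec]:
    """Model specifications for one battery, one spec per (Ig variable, model).

    * ``model1`` — overall survival; Ig (per SD) plus node status, tumor
      size, ER, HER2 and grade 3-vs-1/2 as variables; stratified by 5-year
      age bins and chemotherapy.
    * ``model2`` — overall survival; Ig, node status, tumor size as
      variables; stratified by PAM50 subtype, age bins and chemotherapy.
    * ``subgroups`` — overall survival within clinically defined subgroups,
      adjusted for node status, tumor size, age and chemotherapy (plus grade
      for the ER/HER2-defined subgroups).
    * ``strata_single`` — recurrence-free survival; univariable Ig model
      stratified by a single clinical factor at a time.
    * ``metagene_adjusted`` — overall survival; Ig plus one immune metagene
      score, adjusted for node status, tumor size, age, chemotherapy and
      PAM50, for all cases and restricted to basal-like tumors.
    """
    specs: list[SurvModelSpec] = []
    for ig in ig_vars:
        if battery == "model1":
            specs.append(
                SurvModelSpec(
                    name=f"model1:{ig}",
                    endpoint="OS",
                    continuous_vars=(ig,),
                    zscore_vars=(ig,),
                    categorical_vars=("node_status", "tumor_size", "er_status", "her2", "grade3"),
                    strata=("age_bin", "chemo"),
                )
            )
        elif battery == "model2":
            specs.append(
                SurvModelSpec(
                    name=f"model2:{ig}",
                    endpoint="OS",
                    continuous_vars=(ig,),
                    zscore_vars=(ig,),
                    categorical_vars=("node_status", "tumor_size"),
                    strata=("pam50", "age_bin", "chemo"),
                )
            )
        elif battery == "strata_single":
            for stratum in SINGLE_STRATA:
                specs.append(
                    SurvModelSpec(
                        name=f"strata:{stratum}:{ig}",
                        endpoint="RFS",
                        continuous_vars=(ig,),
                        zscore_vars=(ig,),
                        strata=(stratum,),
                    )
                )
        elif battery == "subgroups":
            for sub, filt in SUBGROUP_FILTERS.items():
                cats = ["node_status", "tumor_size", "chemo"]
                if sub in _GRADE_ADJUSTED_SUBGROUPS:
                    cats.append("grade3")
                specs.append(
                    SurvModelSpec(
                        name=f"subgroup:{sub}:{ig}",
                        endpoint="OS",
                        continuous_vars=(ig, "age"),
                        zscore_vars=(ig,),
                        categorical_vars=tuple(cats),
                        subgroup_filter=filt,
                    )
                )
        elif battery == "metagene_adjusted":
            if not metagene_cols:
                raise SurvivalError("metagene_adjusted battery needs metagene columns")
            for mg in metagene_cols:
                specs.append(
                    SurvModelSpec(
                        name=f"metagene:{mg}:all:{ig}",
                        endpoint="OS",
                        continuous_vars=(ig, mg, "age"),
                        zscore_vars=(ig,),
                        categorical_vars=("node_status", "tumor_size", "chemo", "pam50"),
                    )
                )
                specs.append(
                    SurvModelSpec(
                        name=f"metagene:{mg}:basal:{ig}",
                        endpoint="OS",
                        continuous_vars=(ig, mg, "age"),
                        zscore_vars=(ig,),
                        categorical_vars=("node_status", "tumor_size", "chemo"),
                        subgroup_filter=SUBGROUP_FILTERS["pam50_basal"],
                    )
                )
        else:
            raise SurvivalError(f"unknown battery {battery!r}")
    return specs


def run_model_battery(
    table: pd.DataFrame,
    ig_vars: Sequence[str],
    battery: str,
    metagene_cols: Sequence[str] = (),
) -> list[CoxResult]:
    """Fit every model of a battery; unfit models are flagged, not fatal."""
    results = []
    for spec in build_battery_specs(battery, ig_vars, metagene_cols):
        try:
            results.append(fit_cox(table, spec))
        except SurvivalError as exc:
            results.append(CoxResult(spec.name, pd.DataFrame(), 0, 0, 0, False, str(exc)))
    return results


def battery_table(results: Sequence[CoxResult]) -> pd.DataFrame:
    """Flatten CoxResults into a tidy TSV-ready table."""
    rows = []
    for res in results:
        if not res.fitted:
            rows.append((res.model, "<unfit>", np.nan, np.nan, np.nan, np.nan,
                         res.n, res.events, res.message))
            continue
        for var, r in res.table.iterrows():
            rows.append((res.model, var, r["hr"], r["ci_low"], r["ci_high"], r["p"],
                         res.n, res.events, ""))
    return pd.DataFrame(
        rows,
        columns=["model", "variable", "hr", "ci_low", "ci_high", "p", "n", "events", "note"],
    )
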