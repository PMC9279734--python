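"""Survival verification pipeline.

Checks whether occult nodal disease left behind by a limited lymph-node
dissection shows up as a survival penalty:

1. registry-style eligibility filtering (histology, microcarcinoma size,
   M0, no prior malignancy, no lateral nodal stage, at least one node
   examined);
2. Kaplan-Meier overall-survival comparison between adequate (yield >=
   cutoff) and inadequate (1..cutoff-1) dissection groups, with a log-rank
   test and an elderly (age >= 55) subgroup;
3. a multivariable Cox proportional-hazards model in which the examined-
   node count (and continuous covariates) enter through restricted cubic
   splines, with the knot count chosen by AIC over 3-5 knots placed at
   fixed percentiles, and a joint Wald test on the spline block as the
   overall-association test.

The Cox partial-likelihood machinery delegates to ``lifelines`` (Efron tie
handling); the spline basis, knot selection, AIC comparison, Wald block
test and hazard-ratio curve are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "EligibilityRules",
    "KMCurve",
    "LogRankResult",
    "RCSCoxResult",
    "eligibility_filter",
    "stratify_by_yield",
    "subgroup_elderly",
    "km_estimate",
    "os_rates",
    "log_rank_test",
    "rcs_basis",
    "knot_percentiles",
    "place_knots",
    "select_knots_by_aic",
    "fit_cox_rcs",
]

#: Papillary-histology ICD-O-3 codes admitted to the survival cohort.
DEFAULT_HISTOLOGY_CODES = frozenset(
    {"8050/3", "8260/3", "8340/3", "8341/3", "8342/3", "8343/3"}
)


class SurvivalError(ValueError):
    pass


@dataclass
class EligibilityRules:
    """Cohort inclusion rules, applied in a fixed order with an audit tally."""

    allowed_histology_codes: frozenset = DEFAULT_HISTOLOGY_CODES
    max_tumor_size_mm: float = 10.0
    excluded_n_stages: frozenset = frozenset({"N1b"})
    excluded_m_stages: frozenset = frozenset({"M1"})
    exclude_prior_malignancy: bool = True
    min_nodes_examined: int = 1

    def __post_init__(self) -> None:
        if not self.allowed_histology_codes:
            raise SurvivalError("allowed_histology_codes must be non-empty")


_REQUIRED_FIELDS = (
    "histology_code",
    "tumor_size_mm",
    "m_stage",
    "prior_malignancy",
    "n_stage",
    "nodes_examined",
)


def eligibility_filter(
    records: pd.DataFrame, rules: EligibilityRules | None = None
) -> tuple[pd.DataFrame, dict]:
    """Apply inclusion rules in order; return kept rows and per-rule tally."""
    rules = rules or EligibilityRules()
    for col in _REQUIRED_FIELDS:
        if col not in records.columns:
            raise SurvivalError(f"missing required field {col!r}")
    tally = {}
    kept = records
    checks = [
        ("histology", lambda d: d["histology_code"].isin(rules.allowed_histology_codes)),
        ("tumor_size", lambda d: d["tumor_size_mm"] <= rules.max_tumor_size_mm),
        ("m_stage", lambda d: ~d["m_stage"].isin(rules.excluded_m_stages)),
        (
            "prior_malignancy",
            lambda d: (d["prior_malignancy"] == 0)
            if rules.exclude_prior_malignancy
            else pd.Series(True, index=d.index),
        ),
        ("n_stage", lambda d: ~d["n_stage"].isin(rules.excluded_n_stages)),
        ("nodes_examined", lambda d: d["nodes_examined"] >= rules.min_nodes_examined),
    ]
    for name, check in checks:
        mask = check(kept)
        tally[name] = int((~mask).sum())
        kept = kept[mask]
    return kept.reset_index(drop=True), tally


def stratify_by_yield(
    records: pd.DataFrame, cutoff: int = 7
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into adequate (m >= cutoff) and inadequate (1..cutoff-1) groups."""
    if cutoff < 2:
        raise SurvivalError("cutoff must be >= 2")
    if (records["nodes_examined"] < 1).any():
        raise SurvivalError("records with zero nodes examined must be filtered first")
    adequate = records[records["nodes_examined"] >= cutoff].reset_index(drop=True)
    inadequate = records[records["nodes_examined"] < cutoff].reset_index(drop=True)
    return adequate, inadequate


def subgroup_elderly(records: pd.DataFrame, age_min: float = 55.0) -> pd.DataFrame:
    """Keep patients aged >= age_min (boundary inclusive)."""
    return records[records["age_years"] >= age_min].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit survival curve (right-continuous step function)."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """S(t) by right-continuous step evaluation; 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def max_follow_up(self) -> float:
        candidates = [self.times.max(initial=0.0), self.censor_times.max(initial=0.0)]
        return float(max(candidates))


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier estimate from follow_up_months / vital_status columns."""
    if len(records) == 0:
        raise SurvivalError("empty group")
    t = records["follow_up_months"].to_numpy(dtype=float)
    e = (records["vital_status"] == "dead").to_numpy(dtype=int)
    if np.all(t == 0):
        raise SurvivalError("all follow-up times are zero")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    # lifelines includes t=0 as the leading row; keep event-time rows only
    sf = kmf.survival_function_["KM_estimate"]
    ev = kmf.event_table
    times = sf.index.to_numpy(dtype=float)
    keep = times > 0
    return KMCurve(
        times=times[keep],
        survival=sf.to_numpy(dtype=float)[keep],
        at_risk=ev["at_risk"].to_numpy(dtype=float)[keep],
        censor_times=np.sort(t[e == 0]),
        n=len(records),
    )


def os_rates(curve: KMCurve) -> dict:
    """5- and 10-year overall survival read off the curve at 60/120 months.

    A horizon beyond the longest follow-up is reported as None (the curve
    is undefined there).
    """
    out = {}
    for label, horizon in (("os_5yr", 60.0), ("os_10yr", 120.0)):
        out[label] = (
            curve.survival_at(horizon) if curve.max_follow_up >= horizon else None
        )
    return out


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    n_a: int
    n_b: int


def log_rank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> LogRankResult:
    """Two-group log-rank test (hypergeometric variance over event times)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise SurvivalError("both groups must be non-empty")
    res = logrank_test(
        group_a["follow_up_months"],
        group_b["follow_up_months"],
        event_observed_A=(group_a["vital_status"] == "dead").astype(int),
        event_observed_B=(group_b["vital_status"] == "dead").astype(int),
    )
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=1,
        p_value=float(res.p_value),
        n_a=len(group_a),
        n_b=len(group_b),
    )


# ---------------------------------------------------------------------------
# restricted cubic splines


def rcs_basis(values, knots) -> np.ndarray:
    """Harrell restricted-cubic-spline design columns.

    Column 0 is the variable itself; for j = 1..k-2 the nonlinear column is

        [(x - t_j)+^3 - (x - t_{k-1})+^3 (t_k - t_j)/(t_k - t_{k-1})
         + (x - t_k)+^3 (t_{k-1} - t_j)/(t_k - t_{k-1})] / (t_k - t_1)^2

    which is linear outside the boundary knots [t_1, t_k].
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(knots, dtype=float)
    if len(t) < 3:
        raise SurvivalError("at least 3 knots required")
    if np.any(np.diff(t) <= 0):
        raise SurvivalError("knots must be strictly increasing (no duplicates)")
    k = len(t)
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        tj, tkm1, tk = t[j], t[-2], t[-1]
        cub = lambda u: np.clip(u, 0.0, None) ** 3
        col = (
            cub(x - tj)
            - cub(x - tkm1) * (tk - tj) / (tk - tkm1)
            + cub(x - tk) * (tkm1 - tj) / (tk - tkm1)
        ) / norm
        cols.append(col)
    return np.column_stack(cols)


#: Fixed-percentile knot placements by knot count (Harrell's tables).
KNOT_PERCENTILES = {
    3: (10, 50, 90),
    4: (5, 35, 65, 95),
    5: (5, 27.5, 50, 72.5, 95),
}


def knot_percentiles(n_knots: int) -> tuple:
    try:
        return KNOT_PERCENTILES[n_knots]
    except KeyError:
        raise SurvivalError("knot count must be 3, 4 or 5") from None


def place_knots(values, n_knots: int) -> np.ndarray:
    """Knots at the fixed percentiles of the observed values."""
    pct = knot_percentiles(n_knots)
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < n_knots:
        raise SurvivalError(
            f"{n_knots}-knot placement needs at least {n_knots} distinct values"
        )
    knots = np.percentile(values, pct)
    if np.any(np.diff(knots) <= 0):
        raise SurvivalError(
            f"{n_knots}-knot placement produced duplicate knots; "
            "too few distinct values"
        )
    return knots


# ---------------------------------------------------------------------------
# Cox model with splines


@dataclass
class CoxRCSSpec:
    """Model specification for the spline Cox fit.

    ``main_variable`` enters through a restricted cubic spline and is the
    subject of the overall-association test.  Continuous covariates listed
    in ``spline_covariates`` also get splines; ``linear_covariates`` enter
    untransformed and ``categorical_covariates`` are dummy-coded against
    their first level.
    """

    main_variable: str = "nodes_examined"
    main_knots: np.ndarray | None = None  # default: chosen by AIC
    spline_covariates: tuple = ("age_years", "nodes_positive")
    spline_covariate_knots: int = 3
    linear_covariates: tuple = (
        "extrathyroidal_extension",
        "multifocality",
        "rai",
    )
    categorical_covariates: tuple = ("sex", "race", "surgery_extent")
    duration_col: str = "follow_up_months"
    event_col: str = "vital_status"
    reference_value: float | None = None  # default: first knot of the main spline


@dataclass
class RCSCoxResult:
    coefficients: pd.Series
    covariance: pd.DataFrame
    knots: dict
    log_partial_likelihood: float
    aic: float
    n_parameters: int
    n_used: int
    n_dropped_incomplete: int
    overall_association: dict
    hr_curve: pd.DataFrame
    reference_value: float


def _covariate_knots(records: pd.DataFrame, spec: CoxRCSSpec) -> tuple[dict, list]:
    """Percentile knots per spline covariate; collapsing ones fall back linear."""
    knots, linear_fallback = {}, []
    for var in spec.spline_covariates:
        try:
            knots[var] = place_knots(records[var], spec.spline_covariate_knots)
        except SurvivalError:
            warnings.warn(
                f"spline covariate {var!r} has too few distinct values for "
                "percentile knots; entering linearly", stacklevel=3)
            linear_fallback.append(var)
    return knots, linear_fallback


def _build_design(records: pd.DataFrame, spec: CoxRCSSpec, knots: dict,
                  extra_linear: list | None = None) -> pd.DataFrame:
    cols = {}
    for var in knots:
        basis = rcs_basis(records[var].to_numpy(dtype=float), knots[var])
        for j in range(basis.shape[1]):
            cols[f"{var}_rcs{j}"] = basis[:, j]
    for var in [*spec.linear_covariates, *(extra_linear or [])]:
        cols[var] = records[var].to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=records.index)
    for var in spec.categorical_covariates:
        dummies = pd.get_dummies(records[var], prefix=var, drop_first=True, dtype=float)
        design = pd.concat([design, dummies], axis=1)
    design["_duration"] = records[spec.duration_col].to_numpy(dtype=float)
    design["_event"] = (records[spec.event_col] == "dead").astype(int).to_numpy()
    return design


def _model_columns(spec: CoxRCSSpec) -> list[str]:
    return (
        [spec.main_variable, *spec.spline_covariates]
        + list(spec.linear_covariates)
        + list(spec.categorical_covariates)
        + [spec.duration_col, spec.event_col]
    )


def _fit_cox(design: pd.DataFrame) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(design, duration_col="_duration", event_col="_event")
    return cph


def select_knots_by_aic(
    records: pd.DataFrame,
    spec: CoxRCSSpec | None = None,
    candidate_counts: tuple = (3, 4, 5),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Choose the main-variable knot count minimising the full-model AIC.

    Each candidate count places knots at its fixed percentiles and fits the
    complete Cox model; AIC = -2 logPL + 2 * #parameters.  Ties break to
    fewer knots; candidates that cannot be placed (too few distinct values)
    are dropped with a warning.
    """
    spec = spec or CoxRCSSpec()
    records = records.dropna(subset=_model_columns(spec)).reset_index(drop=True)
    rows = []
    best = None
    for n_knots in sorted(candidate_counts):
        try:
            main_knots = place_knots(records[spec.main_variable], n_knots)
        except SurvivalError as exc:
            warnings.warn(f"dropping {n_knots}-knot candidate: {exc}", stacklevel=2)
            continue
        cov_knots, fallback = _covariate_knots(records, spec)
        knots = {spec.main_variable: main_knots, **cov_knots}
        design = _build_design(records, spec, knots, extra_linear=fallback)
        cph = _fit_cox(design)
        n_params = len(cph.params_)
        aic = -2.0 * cph.log_likelihood_ + 2.0 * n_params
        rows.append({"n_knots": n_knots, "aic": aic, "n_parameters": n_params,
                     "log_partial_likelihood": cph.log_likelihood_})
        if best is None or aic < best[0] - 1e-12:
            best = (aic, main_knots)
    if best is None:
        raise SurvivalError("no spline candidate could be placed")
    return best[1], pd.DataFrame(rows)


def fit_cox_rcs(records: pd.DataFrame, spec: CoxRCSSpec | None = None) -> RCSCoxResult:
    """Multivariable Cox fit with restricted-cubic-spline terms.

    Complete cases only (rows missing any model field are dropped and
    counted).  The overall-association test is a joint Wald chi-square on
    the main variable's spline coefficient block (df = number of spline
    columns); the hazard-ratio curve compares each main-variable value to
    the reference through the spline with delta-method confidence bands.
    """
    spec = spec or CoxRCSSpec()
    n_in = len(records)
    records = records.dropna(subset=_model_columns(spec)).reset_index(drop=True)
    n_dropped = n_in - len(records)
    if len(records) == 0:
        raise SurvivalError("no complete cases")

    if spec.main_knots is not None:
        main_knots = np.asarray(spec.main_knots, dtype=float)
    else:
        main_knots, _ = select_knots_by_aic(records, spec)
    cov_knots, fallback = _covariate_knots(records, spec)
    knots = {spec.main_variable: main_knots, **cov_knots}

    design = _build_design(records, spec, knots, extra_linear=fallback)
    cph = _fit_cox(design)
    params = cph.params_
    cov = cph.variance_matrix_
    n_params = len(params)
    aic = -2.0 * cph.log_likelihood_ + 2.0 * n_params

    block = [c for c in params.index if c.startswith(f"{spec.main_variable}_rcs")]
    b = params[block].to_numpy()
    V = cov.loc[block, block].to_numpy()
    wald = float(b @ np.linalg.solve(V, b))
    df_block = len(block)
    overall = {
        "statistic": wald,
        "df": df_block,
        "p_value": float(stats.chi2.sf(wald, df_block)),
        "test": "wald",
    }

    ref = spec.reference_value if spec.reference_value is not None else float(main_knots[0])
    grid = np.arange(
        max(1, int(records[spec.main_variable].min())),
        int(records[spec.main_variable].max()) + 1,
    )
    basis_grid = rcs_basis(grid, main_knots)
    basis_ref = rcs_basis(np.array([ref]), main_knots)
    delta = basis_grid - basis_ref  # contrast vs reference
    log_hr = delta @ b
    se = np.sqrt(np.einsum("ij,jk,ik->i", delta, V, delta))
    z = stats.norm.ppf(0.975)
    hr_curve = pd.DataFrame(
        {
            spec.main_variable: grid,
            "hr": np.exp(log_hr),
            "hr_lower": np.exp(log_hr - z * se),
            "hr_upper": np.exp(log_hr + z * se),
        }
    )

    return RCSCoxResult(
        coefficients=params,
        covariance=cov,
        knots={k: np.asarray(v).tolist() for k, v in knots.items()},
        log_partial_likelihood=float(cph.log_likelihood_),
        aic=float(aic),
        n_parameters=n_params,
        n_used=len(records),
        n_dropped_incomplete=n_dropped,
        overall_association=overall,
        hr_curve=hr_curve,
        reference_value=ref,
    )
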