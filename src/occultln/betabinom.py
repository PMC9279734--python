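"""Beta-binomial model of occult (residual) nodal disease.

The model treats each node-positive patient as carrying a latent per-node
positivity probability ``p ~ Beta(alpha, beta)``; given ``p``, the number of
positive nodes among ``m`` examined is ``Binomial(m, p)``.  Marginally the
positive-node count is beta-binomial, and the probability that a truly
node-positive patient shows *no* positive node among ``m`` examined is

    P0(m) = B(alpha, beta + m) / B(alpha, beta)
          = prod_{k=0}^{m-1} (beta + k) / (alpha + beta + k).

From P0(m) the package derives

* the detection probability ``1 - P0(m)`` — chance that at least one
  positive node is found in a truly positive patient;
* the *occult-disease* probability for an observed node-negative patient,
  the posterior ``pi * P0(m) / (pi * P0(m) + 1 - pi)`` where ``pi`` is the
  true nodal-disease prevalence;
* per-yield false-negative patient counts ``#FN_m = P0(m) * #TP_m / (1 - P0(m))``
  and the corrected prevalence ``sum_m(#TP_m + #FN_m) / N``;
* the minimum adequate yield: the smallest ``m`` at which the occult
  probability drops to a stated risk threshold.

All Beta-function ratios are evaluated through log-gamma differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma, gammaln

from .cohort import NodalCohort

__all__ = [
    "BetaBinomialParams",
    "FitResult",
    "OccultRiskProfile",
    "PrevalenceEstimate",
    "BootstrapResult",
    "GoodnessOfFitResult",
    "bb_pmf",
    "prob_all_negative",
    "detection_prob",
    "log_likelihood",
    "fit_mle",
    "occult_probability",
    "min_nodes_for_confidence",
    "estimate_fn_counts",
    "corrected_prevalence",
    "bootstrap_ci",
    "goodness_of_fit",
]

PARAM_CAP = 1e6  # divergence guard on alpha, beta


class ModelError(ValueError):
    """Raised on invalid model inputs or degenerate fits."""


@dataclass(frozen=True)
class BetaBinomialParams:
    """Shape parameters of the latent Beta positivity law."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ModelError("alpha and beta must be positive")


@dataclass
class FitResult:
    params: BetaBinomialParams
    log_likelihood: float
    converged: bool
    n_used: int
    truncated: bool
    message: str = ""


@dataclass
class PrevalenceEstimate:
    observed_prevalence: float
    corrected_prevalence: float
    total_fn: float
    n_patients: int


@dataclass
class OccultRiskProfile:
    """Per-yield risk table: P0(m), detection, occult probability, FN count."""

    table: pd.DataFrame = field(repr=False)
    params: BetaBinomialParams = None
    prevalence: float = float("nan")


@dataclass
class BootstrapResult:
    point_estimate: float
    ci_lower: float
    ci_upper: float
    n_replicates: int
    n_failed: int
    seed: int
    replicate_values: np.ndarray = field(repr=False)


@dataclass
class GoodnessOfFitResult:
    statistic: float
    df: int
    p_value: float
    cells: pd.DataFrame = field(repr=False)


# ---------------------------------------------------------------------------
# probability kernels


def _log_beta_ratio(alpha: float, beta: float, m) -> np.ndarray:
    """log[ B(alpha, beta + m) / B(alpha, beta) ] via log-gamma."""
    m = np.asarray(m, dtype=float)
    return (
        gammaln(beta + m)
        + gammaln(alpha + beta)
        - gammaln(alpha + beta + m)
        - gammaln(beta)
    )


def bb_pmf(x, m, params: BetaBinomialParams):
    """Beta-binomial probability mass C(m,x) B(a+x, b+m-x) / B(a,b).

    ``x`` and ``m`` may be scalars or broadcastable arrays; computation is
    in log space.
    """
    x = np.asarray(x)
    m = np.asarray(m)
    if np.any(m < 0):
        raise ModelError("m must be >= 0")
    if np.any((x < 0) | (x > m)):
        raise ModelError("x must satisfy 0 <= x <= m")
    a, b = params.alpha, params.beta
    logpmf = (
        gammaln(m + 1)
        - gammaln(x + 1)
        - gammaln(m - x + 1)
        + gammaln(a + x)
        + gammaln(b + m - x)
        - gammaln(a + b + m)
        + gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
    )
    out = np.exp(logpmf)
    return float(out) if out.ndim == 0 else out


def prob_all_negative(m, params: BetaBinomialParams):
    """P0(m): probability a truly node-positive patient shows 0/m positive."""
    m_arr = np.asarray(m)
    if np.any(m_arr < 0):
        raise ModelError("m must be >= 0")
    out = np.exp(_log_beta_ratio(params.alpha, params.beta, m_arr))
    out = np.where(m_arr == 0, 1.0, out)  # exact boundary, no round-off
    return float(out) if out.ndim == 0 else out


def detection_prob(m, params: BetaBinomialParams):
    """1 - P0(m): chance of detecting a truly node-positive patient."""
    return 1.0 - prob_all_negative(m, params)


def occult_probability(m, params: BetaBinomialParams, prevalence: float):
    """Occult-disease probability for an observed node-negative patient.

    Bayes' posterior on being truly node-positive given 0/m positive nodes:
    ``pi * P0(m) / (pi * P0(m) + 1 - pi)``.  At ``m = 0`` this is the prior
    ``pi`` exactly; it decreases to 0 as the yield grows.
    """
    if not (0.0 <= prevalence <= 1.0):
        raise ModelError("prevalence must lie in [0, 1]")
    p0 = prob_all_negative(m, params)
    num = prevalence * p0
    return num / (num + 1.0 - prevalence)


def min_nodes_for_confidence(
    params: BetaBinomialParams,
    prevalence: float,
    risk_threshold: float,
    m_max: int = 1000,
) -> int:
    """Smallest yield m with occult_probability(m) <= risk_threshold.

    Returns 0 when the threshold already covers the prior prevalence.
    """
    if not (0.0 < risk_threshold < 1.0):
        raise ModelError("risk_threshold must lie in (0, 1)")
    if risk_threshold >= prevalence:
        return 0
    m = np.arange(1, m_max + 1)
    ok = occult_probability(m, params, prevalence) <= risk_threshold
    if not ok.any():
        raise ModelError(f"threshold {risk_threshold} not reached by m_max={m_max}")
    return int(m[np.argmax(ok)])


# ---------------------------------------------------------------------------
# likelihood and fitting


def _aggregate(cohort: NodalCohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse the cohort to unique (m, x) cells with counts (for speed)."""
    m = cohort.nodes_examined
    x = cohort.nodes_positive
    # encode (m, x) pairs into one integer key; cheaper than a groupby
    key = m * (m.max() + 1) + x
    uniq, counts = np.unique(key, return_counts=True)
    mm = (uniq // (m.max() + 1)).astype(float)
    xx = (uniq % (m.max() + 1)).astype(float)
    return mm, xx, counts.astype(float)


def log_likelihood(
    cohort: NodalCohort, params: BetaBinomialParams, truncated: bool = False
) -> float:
    """Beta-binomial log likelihood of the cohort.

    With ``truncated=True`` the likelihood conditions on at least one
    positive node (zero-truncated beta-binomial); every record must then
    have ``nodes_positive >= 1``.
    """
    if len(cohort) == 0:
        raise ModelError("empty cohort")
    mm, xx, ww = _aggregate(cohort)
    if truncated and np.any(xx == 0):
        raise ModelError("truncated likelihood requires nodes_positive >= 1")
    ll = np.sum(ww * np.log(bb_pmf(xx, mm, params)))
    if truncated:
        p0 = prob_all_negative(mm, params)
        ll -= np.sum(ww * np.log1p(-p0))
    return float(ll)


def fit_mle(
    cohort: NodalCohort,
    truncated: bool = False,
    min_nodes: int = 2,
    require_positive: bool = True,
    start: tuple[float, float] = (1.0, 1.0),
    gtol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood fit of (alpha, beta).

    The optimisation runs unconstrained over (log alpha, log beta) with a
    quasi-Newton method.  The default fitting subset keeps node-positive
    patients with at least two nodes examined; the latent Beta law
    describes truly positive patients, so observed-negative patients are
    excluded by default.

    Raises
    ------
    ModelError
        On non-convergence or when the likelihood diverges (parameters
        escaping to the 1e6 cap, e.g. a point-mass positivity fraction).
    """
    sub = cohort.fitting_subset(min_nodes=min_nodes, require_positive=require_positive)
    if len(sub) == 0:
        raise ModelError("fitting subset is empty")
    mm, xx, ww = _aggregate(sub)
    if truncated and np.any(xx == 0):
        raise ModelError("truncated fit requires nodes_positive >= 1 in subset")

    log_comb = gammaln(mm + 1) - gammaln(xx + 1) - gammaln(mm - xx + 1)

    def nll(theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Negative log likelihood and its analytic gradient in (log a, log b)."""
        a, b = np.exp(theta)
        logpmf = (
            log_comb
            + gammaln(a + xx)
            + gammaln(b + mm - xx)
            - gammaln(a + b + mm)
            + gammaln(a + b)
            - gammaln(a)
            - gammaln(b)
        )
        ll = np.dot(ww, logpmf)
        dg_abm = digamma(a + b + mm)
        dg_ab = digamma(a + b)
        ga = np.dot(ww, digamma(a + xx) - dg_abm + dg_ab - digamma(a))
        gb = np.dot(ww, digamma(b + mm - xx) - dg_abm + dg_ab - digamma(b))
        if truncated:
            p0 = np.exp(_log_beta_ratio(a, b, mm))
            ll -= np.dot(ww, np.log1p(-p0))
            ratio = ww * p0 / (1.0 - p0)
            dL0_da = dg_ab - dg_abm
            dL0_db = digamma(b + mm) + dg_ab - dg_abm - digamma(b)
            ga += np.dot(ratio, dL0_da)
            gb += np.dot(ratio, dL0_db)
        # chain rule for the log-parameterisation
        return -ll, -np.array([ga * a, gb * b])

    res = optimize.minimize(
        nll,
        np.log(np.asarray(start, dtype=float)),
        method="BFGS",
        jac=True,
        options={"gtol": gtol, "maxiter": 500},
    )
    a_hat, b_hat = np.exp(res.x)
    if not np.isfinite([a_hat, b_hat]).all() or max(a_hat, b_hat) > PARAM_CAP:
        raise ModelError(
            "fit diverged (parameters exceeded cap); the positive-fraction "
            "distribution is degenerate for a Beta law"
        )
    # BFGS can stall on gtol near machine precision; accept if the gradient
    # is small relative to the objective scale.
    grad_ok = np.max(np.abs(res.jac)) < 1e-3 * max(1.0, abs(res.fun))
    if not (res.success or grad_ok):
        raise ModelError(f"fit did not converge: {res.message}")
    return FitResult(
        params=BetaBinomialParams(float(a_hat), float(b_hat)),
        log_likelihood=-float(res.fun),
        converged=True,
        n_used=len(sub),
        truncated=truncated,
        message=res.message,
    )


# ---------------------------------------------------------------------------
# false-negative correction


def _fn_counts_by_m(cohort: NodalCohort, params: BetaBinomialParams) -> pd.DataFrame:
    counts = cohort.counts_by_m()
    m = counts.index.to_numpy(dtype=float)
    p0 = prob_all_negative(m, params)
    fn = np.where(counts["n_tp"].to_numpy() > 0, p0 / (1.0 - p0) * counts["n_tp"], 0.0)
    counts = counts.copy()
    counts["p_all_negative"] = p0
    counts["fn_count"] = fn
    return counts


def corrected_prevalence(
    cohort: NodalCohort, params: BetaBinomialParams
) -> PrevalenceEstimate:
    """Correct the observed node-positive fraction for false negatives.

    ``corrected = sum_m(#TP_m + #FN_m) / N`` with ``#FN_m`` from the
    per-yield miss probability; the denominator is the fixed total patient
    count.
    """
    if len(cohort) == 0:
        raise ModelError("empty cohort")
    counts = _fn_counts_by_m(cohort, params)
    n = len(cohort)
    total_tp = float(counts["n_tp"].sum())
    total_fn = float(counts["fn_count"].sum())
    corrected = (total_tp + total_fn) / n
    if corrected > 1.0:
        warnings.warn("corrected prevalence exceeded 1; capping", stacklevel=2)
        corrected = 1.0
    return PrevalenceEstimate(
        observed_prevalence=total_tp / n,
        corrected_prevalence=corrected,
        total_fn=total_fn,
        n_patients=n,
    )


def estimate_fn_counts(
    cohort: NodalCohort,
    params: BetaBinomialParams,
    prevalence: float | None = None,
    m_max: int = 30,
) -> OccultRiskProfile:
    """Per-yield occult-risk profile for m = 1..m_max.

    ``fn_count`` applies the miss-probability odds ``P0/(1-P0)`` to the
    observed node-positive count at each yield; yields absent from the
    cohort get zero.  ``occult_prob`` uses ``prevalence`` (default: the
    cohort's corrected prevalence).
    """
    if prevalence is None:
        prevalence = corrected_prevalence(cohort, params).corrected_prevalence
    counts = cohort.counts_by_m()
    m = np.arange(1, m_max + 1)
    p0 = prob_all_negative(m, params)
    n_tp = counts["n_tp"].reindex(m, fill_value=0).to_numpy(dtype=float)
    table = pd.DataFrame(
        {
            "m": m,
            "p_all_negative": p0,
            "detection_prob": 1.0 - p0,
            "occult_prob": occult_probability(m, params, prevalence),
            "n_tp": n_tp.astype(int),
            "fn_count": p0 / (1.0 - p0) * n_tp,
        }
    )
    return OccultRiskProfile(table=table, params=params, prevalence=prevalence)


# ---------------------------------------------------------------------------
# bootstrap


def _named_statistic(name: str, truncated: bool, m: int | None) -> Callable:
    def stat(cohort: NodalCohort) -> float:
        if name in ("alpha", "beta"):
            fit = fit_mle(cohort, truncated=truncated)
            return getattr(fit.params, name)
        if name == "corrected_prevalence":
            fit = fit_mle(cohort, truncated=truncated)
            return corrected_prevalence(cohort, fit.params).corrected_prevalence
        if name == "occult_probability":
            if m is None:
                raise ModelError("occult_probability statistic needs m")
            fit = fit_mle(cohort, truncated=truncated)
            prev = corrected_prevalence(cohort, fit.params).corrected_prevalence
            return float(occult_probability(m, fit.params, prev))
        raise ModelError(f"unknown statistic {name!r}")

    return stat


def bootstrap_ci(
    cohort: NodalCohort,
    statistic: str | Callable[[NodalCohort], float],
    n_replicates: int = 2000,
    seed: int = 0,
    truncated: bool = False,
    m: int | None = None,
    max_failure_fraction: float = 0.10,
) -> BootstrapResult:
    """Percentile bootstrap CI by patient-level resampling.

    Each replicate resamples patients with replacement at the original
    cohort size and recomputes the statistic (refitting alpha, beta when
    the statistic depends on them); the CI is the 2.5/97.5 percentile of
    the replicate values.  Replicates whose fit fails are dropped and
    counted; more than ``max_failure_fraction`` failures is an error.
    """
    if n_replicates < 1:
        raise ModelError("n_replicates must be >= 1")
    stat = (
        _named_statistic(statistic, truncated, m) if isinstance(statistic, str) else statistic
    )
    point = float(stat(cohort))
    rng = np.random.default_rng(seed)
    values, n_failed = [], 0
    for _ in range(n_replicates):
        rep = cohort.resample(rng)
        try:
            values.append(float(stat(rep)))
        except ModelError:
            n_failed += 1
    if n_failed > max_failure_fraction * n_replicates:
        raise ModelError(f"{n_failed}/{n_replicates} bootstrap replicates failed")
    vals = np.asarray(values)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return BootstrapResult(
        point_estimate=point,
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_replicates=n_replicates,
        n_failed=n_failed,
        seed=seed,
        replicate_values=vals,
    )


# ---------------------------------------------------------------------------
# goodness of fit


def goodness_of_fit(
    cohort: NodalCohort,
    params: BetaBinomialParams,
    truncated: bool = True,
    min_nodes: int = 2,
    require_positive: bool = True,
    min_expected: float = 5.0,
) -> GoodnessOfFitResult:
    """Pearson chi-square test of the (zero-truncated) beta-binomial fit.

    Within each yield stratum m, observed counts of x are compared with
    model-expected counts; cells with expected count below ``min_expected``
    are pooled into their neighbour (upward within the stratum, the last
    cell folding back).  Degrees of freedom: #cells - 1 - 2 fitted shapes.
    """
    sub = cohort.fitting_subset(min_nodes=min_nodes, require_positive=require_positive)
    if len(sub) == 0:
        raise ModelError("empty fitting subset")
    rows = []
    for m_val, grp in sub.table.groupby("nodes_examined"):
        n_m = len(grp)
        x_lo = 1 if truncated else 0
        xs = np.arange(x_lo, m_val + 1)
        pmf = bb_pmf(xs, np.full_like(xs, m_val), params)
        if truncated:
            pmf = pmf / (1.0 - prob_all_negative(int(m_val), params))
        obs = grp["nodes_positive"].value_counts().reindex(xs, fill_value=0).to_numpy()
        exp = n_m * pmf
        # pool low-expectation cells left-to-right within the stratum
        pooled_obs, pooled_exp, acc_o, acc_e = [], [], 0.0, 0.0
        for o, e in zip(obs, exp):
            acc_o += o
            acc_e += e
            if acc_e >= min_expected:
                pooled_obs.append(acc_o)
                pooled_exp.append(acc_e)
                acc_o = acc_e = 0.0
        if acc_e > 0:
            if pooled_exp:
                pooled_obs[-1] += acc_o
                pooled_exp[-1] += acc_e
            else:
                pooled_obs.append(acc_o)
                pooled_exp.append(acc_e)
        for o, e in zip(pooled_obs, pooled_exp):
            rows.append({"m": int(m_val), "observed": o, "expected": e})
    cells = pd.DataFrame(rows)
    if len(cells) < 3:
        raise ModelError("fewer than 3 cells after pooling; test undefined")
    chi2 = float(((cells["observed"] - cells["expected"]) ** 2 / cells["expected"]).sum())
    df = len(cells) - 1 - 2
    if df < 1:
        raise ModelError("non-positive degrees of freedom after pooling")
    p = float(stats.chi2.sf(chi2, df))
    return GoodnessOfFitResult(statistic=chi2, df=df, p_value=p, cells=cells)
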