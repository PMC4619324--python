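"""Survival analysis: Kaplan-Meier, log-rank, Cox PH, treatment interaction.

Thin, validated surface over lifelines.  Cox fits use Efron tie handling.
The centrepiece for treatment-specific biomarkers is ``interaction_lrt``:
a likelihood-ratio test between nested Cox models with and without the
marker x treatment term(s), which asks whether the marker's hazard ratio
differs across treatment arms (e.g. carboplatin versus cisplatin).
Complete-case handling per model; dropped rows are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .cohort_io import ValidationError

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """A survival model could not be estimated."""


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    Censoring at an event time is handled with the usual convention:
    censored subjects remain at risk for deaths at the same time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.event_times, "survival": self.survival, "at_risk": self.at_risk}
        )

    def survival_at(self, t: float) -> float:
        """S(t): step function value at time t."""
        s = 1.0
        for et, sv in zip(self.event_times, self.survival):
            if et <= t:
                s = sv
            else:
                break
        return s


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``table`` rows are covariates with columns coef, hazard_ratio, ci_lower,
    ci_upper, wald_p, z.  ``lrt_p`` is the likelihood-ratio test of the whole
    model against the null (no-covariate) model.
    """

    table: pd.DataFrame
    log_likelihood: float
    null_log_likelihood: float
    lrt_p: float
    n: int
    n_events: int
    tie_method: str = "efron"

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hazard_ratio"])


@dataclass
class InteractionResult:
    """Likelihood-ratio test of marker x treatment interaction."""

    lrt_statistic: float
    df: int
    p: float
    full: CoxFit
    null: CoxFit


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("km_estimate: empty input")
    if np.any(times <= 0) or not set(np.unique(events)) <= {0, 1}:
        raise ValidationError("times must be > 0 and events binary")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.unique(times[events == 1])
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times])
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return KMCurve(
        event_times=event_times,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(times[events == 0]),
    )


def logrank_test(
    times_a: Sequence[float], events_a: Sequence[int],
    times_b: Sequence[float], events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic with 1 df, p-value)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValidationError("log-rank test undefined without any events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _complete_cases(
    times: Sequence[float], events: Sequence[int], covariates: pd.DataFrame
) -> pd.DataFrame:
    df = covariates.copy().reset_index(drop=True)
    df["time"] = np.asarray(times, dtype=float)
    df["event"] = np.asarray(events, dtype=int)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("complete-case analysis drops %d of %d rows", n0 - len(df), n0)
    return df


def cox_fit(
    times: Sequence[float],
    events: Sequence[int],
    covariates: pd.DataFrame,
    ties: str = "efron",
) -> CoxFit:
    """Fit a Cox proportional-hazards model (Efron tie handling).

    Raises with the offending name for constant covariates, with a
    rank-deficiency message for collinear ones, and advises penalization on
    monotone-likelihood non-convergence.
    """
    if ties != "efron":
        raise ValidationError(f"unsupported tie method {ties!r}; only 'efron' is implemented")
    covariates = pd.DataFrame(covariates)
    df = _complete_cases(times, events, covariates)
    if df["event"].sum() < 1:
        raise ValidationError("cox_fit needs at least one event")
    cov_cols = [c for c in df.columns if c not in ("time", "event")]
    for c in cov_cols:
        if df[c].nunique() <= 1:
            raise FitError(f"covariate {c!r} is constant after complete-case filtering")
    X = df[cov_cols].to_numpy(dtype=float)
    if len(cov_cols) > 1 and np.linalg.matrix_rank(X - X.mean(axis=0)) < len(cov_cols):
        raise FitError(f"covariates {cov_cols} are rank-deficient (collinear)")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise FitError(
            "Cox partial likelihood did not converge (possibly monotone likelihood / "
            "complete separation); consider a penalized fit"
        ) from exc
    summary = cph.summary
    table = pd.DataFrame(
        {
            "coef": summary["coef"],
            "hazard_ratio": summary["exp(coef)"],
            "ci_lower": np.exp(summary["coef lower 95%"]),
            "ci_upper": np.exp(summary["coef upper 95%"]),
            "wald_p": summary["p"],
            "z": summary["z"],
        }
    )
    ll = float(cph.log_likelihood_)
    lr = cph.log_likelihood_ratio_test()
    return CoxFit(
        table=table,
        log_likelihood=ll,
        null_log_likelihood=ll - float(lr.test_statistic) / 2.0,
        lrt_p=float(lr.p_value),
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def select_covariates(
    times: Sequence[float],
    events: Sequence[int],
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    min_available: float = 0.8,
) -> list[str]:
    """Keep candidates significant in univariate Cox analysis (LRT p < alpha).

    Candidates observed in fewer than ``min_available`` of samples are
    dropped up front with a warning.
    """
    candidates = pd.DataFrame(candidates)
    kept: list[str] = []
    for col in candidates.columns:
        avail = candidates[col].notna().mean()
        if avail < min_available:
            logger.warning("covariate %r available for only %.0f%% of samples; dropped", col, 100 * avail)
            continue
        try:
            fit = cox_fit(times, events, candidates[[col]])
        except (FitError, ValidationError) as exc:
            logger.warning("covariate %r not testable: %s", col, exc)
            continue
        if fit.lrt_p < alpha:
            kept.append(col)
    return kept


def interaction_lrt(
    times: Sequence[float],
    events: Sequence[int],
    marker: Sequence[int],
    treatment: Sequence[str],
    covariates: pd.DataFrame | None = None,
) -> InteractionResult:
    """LRT for marker x treatment interaction in a Cox model.

    Null model: marker + treatment dummies (+ covariates).  Full model adds
    marker x treatment product terms, one per non-reference arm.  The
    statistic 2(ll_full - ll_null) is referred to chi-square with df = the
    number of added interaction parameters.
    """
    marker = np.asarray(marker, dtype=int)
    treatment = np.asarray(treatment, dtype=object)
    arms = sorted(pd.unique(treatment))
    if len(set(marker)) < 2 or len(arms) < 2:
        raise ValidationError("need both marker levels and >= 2 treatment arms")
    events_arr = np.asarray(events, dtype=int)
    empty = [
        (int(m), str(a))
        for m in (0, 1)
        for a in arms
        if ((marker == m) & (treatment == a)).any()
        and events_arr[(marker == m) & (treatment == a)].sum() == 0
    ]
    if empty:
        raise FitError(f"no events in marker x treatment cell(s) {empty}: interaction inestimable")

    base = pd.DataFrame({"marker": marker})
    ref = arms[0]
    for a in arms[1:]:
        base[f"treat_{a}"] = (treatment == a).astype(int)
    if covariates is not None:
        base = pd.concat([base.reset_index(drop=True), pd.DataFrame(covariates).reset_index(drop=True)], axis=1)
    full = base.copy()
    inter_cols = []
    for a in arms[1:]:
        col = f"marker_x_{a}"
        full[col] = base["marker"] * base[f"treat_{a}"]
        inter_cols.append(col)

    fit_null = cox_fit(times, events, base)
    fit_full = cox_fit(times, events, full)
    lrt = 2.0 * (fit_full.log_likelihood - fit_null.log_likelihood)
    df = len(inter_cols)
    return InteractionResult(
        lrt_statistic=max(float(lrt), 0.0),
        df=df,
        p=float(stats.chi2.sf(max(lrt, 0.0), df)),
        full=fit_full,
        null=fit_null,
    )
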