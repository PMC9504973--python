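"""Time-to-onset (TTO) computation and Weibull failure-profile analysis.

Days to onset for a (case, drug, event) pair are defined as

    days = (onset date - chosen treatment start date) + 0.5

where the half-day offset makes a same-day onset count as 0.5 d.  Both dates
must be known to day precision; among a case's start dates for the drug, the
earliest day-precision start on or before the onset is used (configurable to
the most recent such start, since multi-administration records are genuinely
ambiguous).  Onsets more than ``cap_days`` (default 730 d, two years) after
the start are excluded.  Every examined pair yields either an observation or
a machine-readable exclusion reason.

The uncensored observations for a drug-event pair are fitted to a
two-parameter Weibull distribution, F(t) = 1 - exp(-(t/alpha)^beta), by
maximum likelihood.  The shape parameter beta describes the hazard trend:
beta < 1, decreasing hazard (early failure); beta = 1, constant;
beta > 1, increasing hazard (wear-out).  The classification is made on the
95% CI of beta: early failure only when the whole CI lies below 1, wear-out
only when it lies above 1, otherwise "random" (constant-hazard-compatible).

Log-likelihood (all observations uncensored):

    l(alpha, beta) = sum_i [ ln beta - beta ln alpha
                             + (beta - 1) ln t_i - (t_i/alpha)^beta ]

The MLE is found by profiling: for fixed beta the scale has the closed form
alpha(beta) = (mean t^beta)^(1/beta), leaving a monotone one-dimensional
score in beta solved by Brent's method on a bounded interval.  Wald CIs are
computed on (ln alpha, ln beta) from the observed information and
exponentiated, guaranteeing positive bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .srs_io import PartialDate, iso_precision

__all__ = [
    "OnsetResult",
    "WeibullFit",
    "FitError",
    "onset_days",
    "compute_onsets",
    "summarize_tto",
    "weibull_fit",
    "weibull_loglik",
    "weibull_median",
    "classify_failure_type",
    "tto_table",
]

#: bounded search interval for the shape parameter; the upper cap makes
#: degenerate (all-equal) samples deterministic instead of divergent
BETA_BOUNDS = (0.05, 50.0)

EXCLUSION_REASONS = (
    "onset_not_day_precision",
    "no_day_precision_start",
    "no_start_on_or_before_onset",
    "exceeds_cap",
)


class FitError(RuntimeError):
    """Weibull fit could not be computed (too few data or singular info)."""


@dataclass(frozen=True)
class OnsetResult:
    days: float | None
    reason: str | None

    @property
    def excluded(self) -> bool:
        return self.days is None


@dataclass(frozen=True)
class WeibullFit:
    """MLE of the Weibull TTO model plus raw-data summaries."""

    alpha: float
    beta: float
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    n: int
    failure_type: str
    median_days: float
    iqr_days: tuple[float, float]
    loglik: float


# ---------------------------------------------------------------------------
# Onset-day computation
# ---------------------------------------------------------------------------


def _as_partial(date) -> PartialDate:
    if isinstance(date, PartialDate):
        return date
    return PartialDate.parse(date)


def onset_days(
    onset_date,
    start_dates,
    cap_days: float = 730.0,
    start_rule: str = "earliest",
) -> OnsetResult:
    """Days to onset for one pair, or an exclusion with its reason.

    ``start_rule='earliest'`` uses the earliest day-precision start on or
    before the onset; ``'latest'`` uses the most recent one.
    """
    onset = _as_partial(onset_date)
    if onset.precision != "day":
        return OnsetResult(None, "onset_not_day_precision")
    starts = [_as_partial(s) for s in start_dates]
    day_starts = [s for s in starts if s.precision == "day"]
    if not day_starts:
        return OnsetResult(None, "no_day_precision_start")
    onset_d = onset.to_date()
    eligible = [s.to_date() for s in day_starts if s.to_date() <= onset_d]
    if not eligible:
        return OnsetResult(None, "no_start_on_or_before_onset")
    chosen = min(eligible) if start_rule == "earliest" else max(eligible)
    days = (onset_d - chosen).days + 0.5
    if days > cap_days:
        return OnsetResult(None, "exceeds_cap")
    return OnsetResult(days, None)


def compute_onsets(
    pairs: pd.DataFrame,
    cap_days: float = 730.0,
    start_rule: str = "earliest",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply :func:`onset_days` to every pair.

    Returns ``(observations, exclusions)``; their row counts always add up
    to ``len(pairs)``.  Observations have columns (case_id, drug_name, pt,
    days); exclusions have (case_id, drug_name, pt, reason).
    """
    obs_rows, exc_rows = [], []
    for row in pairs.itertuples(index=False):
        res = onset_days(row.onset_date, row.start_dates, cap_days, start_rule)
        if res.excluded:
            exc_rows.append((row.case_id, row.drug_name, row.pt, res.reason))
        else:
            obs_rows.append((row.case_id, row.drug_name, row.pt, res.days))
    obs = pd.DataFrame(obs_rows, columns=["case_id", "drug_name", "pt", "days"])
    exc = pd.DataFrame(exc_rows, columns=["case_id", "drug_name", "pt", "reason"])
    return obs, exc


def summarize_tto(days) -> dict:
    """Median and IQR (type-7 linear-interpolation quantiles) of raw days."""
    t = np.asarray(days, dtype=float)
    if t.size == 0:
        raise ValueError("summarize_tto requires at least one observation")
    q1, med, q3 = np.percentile(t, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3), "n": int(t.size)}


# ---------------------------------------------------------------------------
# Weibull fitting
# ---------------------------------------------------------------------------


def weibull_loglik(days, alpha: float, beta: float) -> float:
    """Uncensored Weibull log-likelihood at (alpha, beta)."""
    t = np.asarray(days, dtype=float)
    return float(
        np.sum(
            np.log(beta)
            - beta * np.log(alpha)
            + (beta - 1.0) * np.log(t)
            - (t / alpha) ** beta
        )
    )


def weibull_median(alpha: float, beta: float) -> float:
    return alpha * math.log(2.0) ** (1.0 / beta)


def _profile_alpha(t_scaled: np.ndarray, tmax: float, beta: float) -> float:
    # alpha(beta) = (mean t^beta)^(1/beta); computed on t/tmax for stability
    return tmax * float(np.mean(t_scaled**beta)) ** (1.0 / beta)


def _profile_score(t_scaled: np.ndarray, logt: np.ndarray, beta: float) -> float:
    # d/dbeta of the profile log-likelihood (up to factor n)
    w = t_scaled**beta
    return 1.0 / beta + float(logt.mean()) - float((w * logt).sum() / w.sum())


def weibull_fit(days, alpha_level: float = 0.05) -> WeibullFit:
    """Maximum-likelihood Weibull fit with Wald CIs on the log parameters.

    Requires at least 3 strictly positive observations.  The shape search is
    bounded to :data:`BETA_BOUNDS`; a degenerate sample (all values equal)
    lands deterministically on the upper bound with a collapsed CI.
    """
    t = np.asarray(days, dtype=float)
    if t.size < 3:
        raise FitError(f"need >= 3 observations, got {t.size}")
    if np.any(t <= 0):
        raise FitError("all observations must be positive")
    logt = np.log(t)
    tmax = float(t.max())
    ts = t / tmax
    lo_b, hi_b = BETA_BOUNDS
    f_lo = _profile_score(ts, logt, lo_b)
    f_hi = _profile_score(ts, logt, hi_b)
    if f_lo * f_hi < 0:
        beta = float(optimize.brentq(lambda b: _profile_score(ts, logt, b), lo_b, hi_b, xtol=1e-12))
        degenerate = False
    else:
        # no interior stationary point: take the better-likelihood bound
        cand = []
        for b in (lo_b, hi_b):
            a = _profile_alpha(ts, tmax, b)
            cand.append((weibull_loglik(t, a, b), a, b))
        _, alpha_b, beta = max(cand)
        degenerate = True
    alpha = _profile_alpha(ts, tmax, beta)

    ll = weibull_loglik(t, alpha, beta)
    summ = summarize_tto(t)
    z = stats.norm.ppf(1.0 - alpha_level / 2.0)
    theta = np.array([math.log(alpha), math.log(beta)])

    def negll(th: np.ndarray) -> float:
        return -weibull_loglik(t, math.exp(th[0]), math.exp(th[1]))

    cov = None
    if not degenerate:
        hess = _numeric_hessian(negll, theta)
        try:
            cov = np.linalg.inv(hess)
            if cov[0, 0] <= 0 or cov[1, 1] <= 0:
                cov = None
        except np.linalg.LinAlgError:
            cov = None
    if cov is None:
        # collapsed/singular information: report point-mass intervals
        alpha_ci = (alpha, alpha)
        beta_ci = (beta, beta)
    else:
        se_la, se_lb = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
        alpha_ci = (alpha * math.exp(-z * se_la), alpha * math.exp(z * se_la))
        beta_ci = (beta * math.exp(-z * se_lb), beta * math.exp(z * se_lb))

    fit = WeibullFit(
        alpha=alpha,
        beta=beta,
        alpha_ci=alpha_ci,
        beta_ci=beta_ci,
        n=int(t.size),
        failure_type="",
        median_days=summ["median"],
        iqr_days=(summ["q1"], summ["q3"]),
        loglik=ll,
    )
    return WeibullFit(**{**fit.__dict__, "failure_type": classify_failure_type(fit)})


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian (parameters are log-scaled, so a
    fixed absolute step is well conditioned)."""
    n = x.size
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            if i == j:
                val = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h**2
            else:
                val = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h**2)
            hess[i, j] = hess[j, i] = val
    return hess


def plot_tto_boxes(observations: pd.DataFrame, path=None, title: str = ""):
    """Optional box-plot of onset days per PT (requires matplotlib).

    ``observations`` is the frame returned by :func:`compute_onsets`.
    Boxes show median and quartiles, whiskers 1.5 IQR, as in published
    time-to-onset figures.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = observations.groupby("pt")["days"]
    labels = sorted(groups.groups)
    data = [groups.get_group(pt).to_numpy() for pt in labels]
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(labels) + 1.5))
    ax.boxplot(data, tick_labels=labels, vert=False, whis=1.5)
    ax.set_xlabel("days to onset")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def classify_failure_type(fit) -> str:
    """Failure-type label from the 95% CI of the shape parameter.

    ``early_failure`` when the CI upper limit is below 1 (decreasing
    hazard), ``wear_out`` when the lower limit is above 1 (increasing
    hazard), ``random`` otherwise.  Accepts a :class:`WeibullFit` or a
    ``(low, high)`` CI tuple.
    """
    lo, hi = fit.beta_ci if hasattr(fit, "beta_ci") else fit
    if hi < 1.0:
        return "early_failure"
    if lo > 1.0:
        return "wear_out"
    return "random"


# ---------------------------------------------------------------------------
# Per-drug reporting
# ---------------------------------------------------------------------------


def tto_table(
    pairs: pd.DataFrame,
    drug: str,
    pts=None,
    cap_days: float = 730.0,
    start_rule: str = "earliest",
    alpha_level: float = 0.05,
    min_n_fit: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-PT TTO summary and Weibull fit table for one drug.

    Returns ``(table, exclusions)``.  PTs with fewer than ``min_n_fit``
    usable onsets keep their raw summary but no fit (NaN parameters, empty
    failure type).
    """
    sub = pairs[pairs["drug_name"] == drug]
    if pts is not None:
        sub = sub[sub["pt"].isin(list(pts))]
    obs, exc = compute_onsets(sub, cap_days=cap_days, start_rule=start_rule)
    rows = []
    order = pts if pts is not None else sorted(sub["pt"].unique())
    for pt in order:
        days = obs.loc[obs["pt"] == pt, "days"].to_numpy()
        row = {
            "drug": drug,
            "pt": pt,
            "n": int(days.size),
            "median": np.nan,
            "q1": np.nan,
            "q3": np.nan,
            "alpha": np.nan,
            "alpha_lo": np.nan,
            "alpha_hi": np.nan,
            "beta": np.nan,
            "beta_lo": np.nan,
            "beta_hi": np.nan,
            "failure_type": "",
        }
        if days.size:
            row.update({k: v for k, v in summarize_tto(days).items() if k != "n"})
        if days.size >= min_n_fit:
            try:
                fit = weibull_fit(days, alpha_level=alpha_level)
            except FitError:
                fit = None
            if fit is not None:
                row.update(
                    alpha=fit.alpha,
                    alpha_lo=fit.alpha_ci[0],
                    alpha_hi=fit.alpha_ci[1],
                    beta=fit.beta,
                    beta_lo=fit.beta_ci[0],
                    beta_hi=fit.beta_ci[1],
                    failure_type=fit.failure_type,
                )
        rows.append(row)
    table = pd.DataFrame(
        rows,
        columns=[
            "drug", "pt", "n", "median", "q1", "q3",
            "alpha", "alpha_lo", "alpha_hi", "beta", "beta_lo", "beta_hi",
            "failure_type",
        ],
    )
    return table, exc
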