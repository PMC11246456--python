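"""Time-to-onset (TTO) analysis with the Weibull shape parameter test.

TTO is the whole-day delay between therapy start and adverse-event
onset.  Under a two-parameter Weibull model with scale α (days) and
shape β, the hazard of onset decreases over time when β < 1, is
constant when β = 1, and increases when β > 1.  The shape-parameter
test classifies the fitted hazard as:

* ``early``    — β < 1 and the 95% CI upper bound < 1 (risk front-loaded
  after initiation);
* ``wear_out`` — β > 1 and the 95% CI lower bound > 1 (risk grows with
  continued exposure);
* ``random``   — otherwise (CI includes 1; hazard compatible with
  constant).

Maximum likelihood is computed by solving the one-dimensional profile
score equation for β (Brent root-finding on a bracketed, monotone
function, tolerance 1e-8), with α then available in closed form:
α̂ = (Σ xᵢ^β̂ / n)^(1/β̂).  95% CIs come from the observed information
(Wald intervals on the log-parameter scale, back-transformed).

Zero-day onsets (event on the day therapy started) sit outside the
support of the continuous Weibull likelihood; they are shifted to 0.5
days for fitting by default (``zero_handling="shift"``) or dropped
(``"drop"``).  Medians and IQRs always use the raw values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from ._dates import days_between
from .cohort import CohortConfig, _earliest_start
from .faers import CaseReport

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054
MIN_FIT_N = 10


@dataclass(frozen=True)
class TTOSample:
    """Onset delays in whole days (≥ 0; 0 means same-day onset)."""

    values: Tuple[float, ...]
    n_available: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values):
            raise ValueError("negative TTO value")


@dataclass(frozen=True)
class WeibullFit:
    alpha: float  # scale, days
    alpha_ci: Tuple[float, float]
    beta: float  # shape, dimensionless
    beta_ci: Tuple[float, float]
    n_used: int
    failure_type: str = ""
    error: Optional[str] = None


def compute_tto(cases: Sequence[CaseReport], config: CohortConfig) -> TTOSample:
    """Per-case onset delay for the suspect drug.

    Uses the DEMO event date and the earliest full-precision therapy
    start date among the suspect drug's THER rows; cases lacking either
    at day precision contribute nothing.  Negative delays are assumed
    to have been removed by the date-error exclusion and are skipped
    defensively here.
    """
    values: List[float] = []
    for case in cases:
        event = case.demo.event_dt
        if event is None or not event.is_full:
            continue
        start = _earliest_start(case, config)
        if start is None:
            continue
        delta = days_between(start, event)
        if delta < 0:
            logger.warning(
                "case %s: negative TTO (%d days) skipped", case.caseid, delta
            )
            continue
        values.append(float(delta))
    return TTOSample(values=tuple(values), n_available=len(values))


def median_iqr(
    sample: TTOSample,
) -> Tuple[float, float, float, float, float]:
    """(median, q1, q3, min, max) with linear-interpolation quartiles."""
    if not sample.values:
        raise ValueError("empty TTO sample")
    arr = np.asarray(sample.values, dtype=float)
    return (
        float(np.median(arr)),
        float(np.percentile(arr, 25)),
        float(np.percentile(arr, 75)),
        float(arr.min()),
        float(arr.max()),
    )


def _profile_score(beta: float, x: np.ndarray, logx: np.ndarray) -> float:
    # d/dβ of the profile log-likelihood (α at its conditional MLE):
    #   1/β + mean(ln x) − Σ x^β ln x / Σ x^β
    # Strictly decreasing in β, so a sign-changing bracket is reliable.
    # Powers are computed on a rescaled sample upstream to avoid overflow.
    xb = np.power(x, beta)
    return 1.0 / beta + logx.mean() - float((xb * logx).sum() / xb.sum())


def _loglik(log_alpha: float, log_beta: float, x: np.ndarray, logx: np.ndarray) -> float:
    beta = math.exp(log_beta)
    n = len(x)
    z = np.exp(beta * (logx - log_alpha))
    return n * log_beta - n * beta * log_alpha + (beta - 1) * logx.sum() - z.sum()


def fit_weibull_mle(
    sample: TTOSample | Sequence[float],
    zero_handling: str = "shift",
) -> WeibullFit:
    """Two-parameter Weibull MLE with Wald 95% CIs.

    Parameters
    ----------
    sample
        TTO values in days.
    zero_handling
        ``"shift"`` replaces zero-day values with 0.5 before fitting;
        ``"drop"`` removes them.  Fitted values must end up positive.

    Returns an error fit (``error`` set) when fewer than 10 usable
    values remain, when the data are degenerate (all equal), or when
    root bracketing fails.
    """
    values = sample.values if isinstance(sample, TTOSample) else tuple(sample)
    if zero_handling == "shift":
        fit_vals = [v if v > 0 else 0.5 for v in values]
    elif zero_handling == "drop":
        fit_vals = [v for v in values if v > 0]
    else:
        raise ValueError(f"unknown zero_handling {zero_handling!r}")
    n = len(fit_vals)
    nan_ci = (math.nan, math.nan)
    if n < MIN_FIT_N:
        return WeibullFit(
            math.nan, nan_ci, math.nan, nan_ci, n, error=f"need >= {MIN_FIT_N} values, got {n}"
        )
    x = np.asarray(fit_vals, dtype=float)
    if np.allclose(x, x[0]):
        return WeibullFit(
            math.nan, nan_ci, math.nan, nan_ci, n, error="degenerate sample (all values equal)"
        )
    # Rescale by the geometric mean so x**beta stays in range while
    # expanding the bracket; scale equivariance makes this exact.
    gm = math.exp(float(np.log(x).mean()))
    xs = x / gm
    logxs = np.log(xs)
    lo, hi = 1e-3, 1.0
    f_lo = _profile_score(lo, xs, logxs)
    f_hi = _profile_score(hi, xs, logxs)
    while f_lo * f_hi > 0 and hi < 1e3:
        lo, f_lo = hi, f_hi
        hi *= 2.0
        f_hi = _profile_score(hi, xs, logxs)
    if f_lo * f_hi > 0:
        return WeibullFit(
            math.nan, nan_ci, math.nan, nan_ci, n, error="profile score has no root in (0.001, 1000)"
        )
    beta = optimize.brentq(
        _profile_score, lo, hi, args=(xs, logxs), xtol=1e-8, rtol=8.9e-16
    )
    alpha_s = float(np.power(xs, beta).mean()) ** (1.0 / beta)
    alpha = alpha_s * gm

    # Observed information on (log alpha, log beta) by central differences.
    la, lb = math.log(alpha_s), math.log(beta)
    h = 1e-5
    def ll(p, q):  # noqa: E306
        return _loglik(p, q, xs, logxs)
    f0 = ll(la, lb)
    d2a = (ll(la + h, lb) - 2 * f0 + ll(la - h, lb)) / h**2
    d2b = (ll(la, lb + h) - 2 * f0 + ll(la, lb - h)) / h**2
    dab = (
        ll(la + h, lb + h) - ll(la + h, lb - h) - ll(la - h, lb + h) + ll(la - h, lb - h)
    ) / (4 * h**2)
    info = -np.array([[d2a, dab], [dab, d2b]])
    try:
        cov = np.linalg.inv(info)
        se_la, se_lb = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    except (np.linalg.LinAlgError, ValueError):
        return WeibullFit(
            alpha, nan_ci, beta, nan_ci, n, error="observed information not invertible"
        )
    alpha_ci = (
        alpha * math.exp(-Z_95 * se_la),
        alpha * math.exp(Z_95 * se_la),
    )
    beta_ci = (beta * math.exp(-Z_95 * se_lb), beta * math.exp(Z_95 * se_lb))
    fit = WeibullFit(alpha, alpha_ci, beta, beta_ci, n)
    return WeibullFit(
        alpha, alpha_ci, beta, beta_ci, n, failure_type=classify_failure(fit)
    )


def classify_failure(fit: WeibullFit) -> str:
    """early / random / wear_out from β and its 95% CI (see module docs)."""
    if fit.error is not None:
        raise ValueError(f"cannot classify failed fit: {fit.error}")
    beta, (lo, hi) = fit.beta, fit.beta_ci
    if beta < 1 and hi < 1:
        return "early"
    if beta > 1 and lo > 1:
        return "wear_out"
    return "random"


def summarize_tto_group(
    group: str,
    n_pts: int,
    values: Sequence[float],
    zero_handling: str = "shift",
) -> dict:
    """One tto.csv row: descriptives plus the Weibull fit for a group."""
    sample = TTOSample(values=tuple(values), n_available=len(values))
    row = {
        "group": group,
        "n_pts": n_pts,
        "n_cases": sample.n_available,
        "median": math.nan,
        "q1": math.nan,
        "q3": math.nan,
        "min": math.nan,
        "max": math.nan,
        "alpha": math.nan,
        "alpha_ci_low": math.nan,
        "alpha_ci_high": math.nan,
        "beta": math.nan,
        "beta_ci_low": math.nan,
        "beta_ci_high": math.nan,
        "failure_type": "",
        "error": "",
    }
    if sample.values:
        row["median"], row["q1"], row["q3"], row["min"], row["max"] = median_iqr(sample)
    fit = fit_weibull_mle(sample, zero_handling=zero_handling)
    if fit.error is not None:
        row["error"] = fit.error
        return row
    row.update(
        alpha=fit.alpha,
        alpha_ci_low=fit.alpha_ci[0],
        alpha_ci_high=fit.alpha_ci[1],
        beta=fit.beta,
        beta_ci_low=fit.beta_ci[0],
        beta_ci_high=fit.beta_ci[1],
        failure_type=fit.failure_type,
    )
    return row
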