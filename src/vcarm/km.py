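"""Kaplan-Meier estimation, Greenwood variance and yearly two-sample Z tests.

The product-limit estimator is implemented directly because the comparison
pipeline needs plain Wald (symmetric) confidence intervals, S +- z*SE with a
fixed critical value, evaluated on a yearly grid by carrying the last step
forward — conventions that transformed-interval defaults in general survival
libraries do not reproduce.

Conventions: deaths tied at one time form a single risk-set step with d > 1;
censorings at a death time remain in that time's risk set (censored after
deaths).  Where the estimate reaches 0 the Greenwood sum is undefined and the
SE is reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import EVENT_CENSORED, EVENT_DEATH  # noqa: F401

DEFAULT_Z_CRIT = 1.96  # fixed rather than Phi^-1(0.975) to more digits


class KMError(Exception):
    """Invalid input to a survival estimation or comparison routine."""


class DegenerateComparisonError(KMError):
    """Both SEs are zero while the estimates differ: Z is undefined."""


@dataclass
class SurvivalCurve:
    """Survival estimates on an evaluation grid with Greenwood SEs.

    ``times`` are the evaluation times (strictly increasing, in years);
    ``estimates`` the product-limit values S(t); ``se`` the Greenwood
    standard errors; ``ci_low``/``ci_high`` pointwise Wald bounds clipped to
    [0, 1]; ``n_at_risk`` the number of subjects still under observation at
    each evaluation time.
    """

    times: np.ndarray
    estimates: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray
    n_subjects: int = 0
    # internal step function (distinct death times and values), used by at()
    _step_times: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    _step_surv: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def at(self, t: float) -> tuple[float, float]:
        """(estimate, SE) at time ``t``; exact on the evaluation grid."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            raise KMError(f"time {t} precedes the evaluation grid")
        if self.times[idx] != t and t > self.times[-1]:
            raise KMError(f"time {t} exceeds the curve's support")
        return float(self.estimates[idx]), float(self.se[idx])


def km_curve(
    times,
    events,
    eval_times=None,
    z_crit: float = DEFAULT_Z_CRIT,
) -> SurvivalCurve:
    """Product-limit survival curve with Greenwood variance.

    Parameters
    ----------
    times, events
        Equal-length follow-up times (years, >= 0) and event indicators
        (1 = death, 0 = censored).
    eval_times
        Grid on which to report the curve; defaults to ``0..floor(max time)``
        yearly.  At each grid point the estimate is the value at the largest
        event time <= t (the KM step function, plateau carried forward).
    z_crit
        Critical value for the pointwise Wald CIs.

    All-censored input yields S = 1, SE = 0 everywhere; empty input raises.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise KMError("empty input")
    if t.shape != e.shape:
        raise KMError("times and events must have equal length")
    if np.any(t < 0):
        raise KMError("negative follow-up time")

    if eval_times is None:
        eval_times = np.arange(0.0, np.floor(t.max()) + 1.0)
    grid = np.asarray(eval_times, dtype=float)

    # distinct death times with death counts d_j and risk sets n_j
    death_times = np.unique(t[e == EVENT_DEATH]) if (e == 1).any() else np.empty(0)
    surv = np.ones(death_times.size)
    gw_sum = np.zeros(death_times.size)  # cumulative sum d/(n(n-d))
    s = 1.0
    acc = 0.0
    for j, dt in enumerate(death_times):
        n_j = int(np.sum(t >= dt))  # censored at dt still at risk
        d_j = int(np.sum((t == dt) & (e == 1)))
        s *= 1.0 - d_j / n_j
        if n_j > d_j:
            acc += d_j / (n_j * (n_j - d_j))
        else:
            acc = np.inf  # curve hits 0; variance undefined past this point
        surv[j] = s
        gw_sum[j] = acc

    # evaluate step function on the grid
    if death_times.size:
        idx = np.searchsorted(death_times, grid, side="right") - 1
        est = np.where(idx >= 0, surv[np.maximum(idx, 0)], 1.0)
        cum = np.where(idx >= 0, gw_sum[np.maximum(idx, 0)], 0.0)
    else:  # all censored: empty product
        est = np.ones_like(grid)
        cum = np.zeros_like(grid)
    with np.errstate(invalid="ignore"):
        var = est**2 * cum  # 0 * inf where the curve reached 0
    se = np.sqrt(np.where(np.isfinite(var), var, 0.0))
    se[est == 0.0] = 0.0

    ci_low = np.clip(est - z_crit * se, 0.0, 1.0)
    ci_high = np.clip(est + z_crit * se, 0.0, 1.0)
    n_at_risk = np.array([int(np.sum(t >= g)) for g in grid])

    return SurvivalCurve(
        times=grid,
        estimates=est,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        n_at_risk=n_at_risk,
        n_subjects=int(t.size),
        _step_times=death_times,
        _step_surv=surv,
    )


def two_sample_z(s_a: float, se_a: float, s_b: float, se_b: float) -> tuple[float, float]:
    """Two-sided two-sample Z test for a difference of survival estimates.

    z = (s_a - s_b) / sqrt(se_a^2 + se_b^2); p = 2 (1 - Phi(|z|)).
    The p-value is symmetric in the order of the two samples.
    """
    if se_a < 0 or se_b < 0:
        raise KMError("negative standard error")
    denom = float(np.hypot(se_a, se_b))
    if denom == 0.0:
        if s_a == s_b:
            return 0.0, 1.0
        raise DegenerateComparisonError(
            "estimates differ but both standard errors are zero"
        )
    z = (s_a - s_b) / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_arms_by_year(
    observed: SurvivalCurve,
    predicted: SurvivalCurve,
    horizon: int = 15,
) -> pd.DataFrame:
    """Year-by-year comparison of an observed arm against its virtual arm.

    Returns one row per year 1..horizon with estimates, CIs, risk-set sizes,
    the Z statistic and the two-sided p-value.  No multiplicity adjustment
    is applied; each year is tested marginally.
    """
    for curve, name in ((observed, "observed"), (predicted, "predicted")):
        if horizon > curve.times[-1]:
            raise KMError(
                f"horizon {horizon} exceeds the {name} curve's grid "
                f"(max {curve.times[-1]})"
            )
    rows = []
    for year in range(1, horizon + 1):
        so, seo = observed.at(year)
        sp, sep = predicted.at(year)
        z, p = two_sample_z(so, seo, sp, sep)
        i_o = int(np.searchsorted(observed.times, year))
        i_p = int(np.searchsorted(predicted.times, year))
        rows.append(
            {
                "year": year,
                "n_at_risk_observed": int(observed.n_at_risk[i_o]),
                "observed": so,
                "observed_ci_low": float(observed.ci_low[i_o]),
                "observed_ci_high": float(observed.ci_high[i_o]),
                "n_at_risk_predicted": int(predicted.n_at_risk[i_p]),
                "predicted": sp,
                "predicted_ci_low": float(predicted.ci_low[i_p]),
                "predicted_ci_high": float(predicted.ci_high[i_p]),
                "z": z,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def format_p(p: float, floor: float = 0.001) -> str:
    """Render a p-value to 3 decimals, with small values as ``<0.001``."""
    return f"<{floor}" if p < floor else f"{p:.3f}"


def format_comparison(comparison: pd.DataFrame) -> pd.DataFrame:
    """Human-readable report table: year, n, estimate (CI) per arm, p."""
    def cell(s, lo, hi):
        return f"{s:.3f} ({lo:.3f}-{hi:.3f})"

    out = pd.DataFrame(
        {
            "year": comparison["year"],
            "n_at_risk": comparison["n_at_risk_observed"],
            "observed (95% CI)": [
                cell(r.observed, r.observed_ci_low, r.observed_ci_high)
                for r in comparison.itertuples()
            ],
            "predicted (95% CI)": [
                cell(r.predicted, r.predicted_ci_low, r.predicted_ci_high)
                for r in comparison.itertuples()
            ],
            "p": [format_p(p) for p in comparison["p_value"]],
        }
    )
    return out


def plot_comparison(
    observed: SurvivalCurve,
    predicted: SurvivalCurve,
    title: str = "",
    ax=None,
):
    """Step plot of observed vs predicted (virtual) survival with CIs."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    for curve, label, color in (
        (observed, "observed", "C0"),
        (predicted, "predicted (virtual)", "C1"),
    ):
        ax.step(curve.times, curve.estimates, where="post", label=label, color=color)
        ax.fill_between(
            curve.times, curve.ci_low, curve.ci_high,
            step="post", alpha=0.2, color=color,
        )
    ax.set_xlabel("years since diagnosis")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax


__all__ = [
    "SurvivalCurve",
    "km_curve",
    "two_sample_z",
    "compare_arms_by_year",
    "format_p",
    "format_comparison",
    "plot_comparison",
    "KMError",
    "DegenerateComparisonError",
    "DEFAULT_Z_CRIT",
]
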