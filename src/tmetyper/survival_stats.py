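"""First-principles survival and group-comparison statistics.

Implements the statistical machinery the subtype comparisons rest on:
the unpaired (pooled-variance) Student t-test, the Kaplan-Meier
product-limit estimator, the two-group log-rank test, univariate Cox
proportional-hazards regression with Breslow (default) or Efron tie
handling, and the conventional significance-star mapping.

Only distribution tail functions are taken from :mod:`scipy.stats`;
estimators and test statistics are computed here explicitly so that
each one can be validated against hand-worked examples and against
independent reference implementations.

Survival records are plain :class:`pandas.DataFrame` objects with
columns ``time`` (positive float), ``event`` (bool, True = death
observed) and ``group`` (two levels, conventionally ``"A"``/``"B"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TTestResult",
    "LogrankResult",
    "CoxFit",
    "t_test",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "significance_stars",
]

#: Normal quantile used for 95% confidence intervals (forest-plot convention).
Z_95 = 1.96

#: Newton-Raphson convergence tolerance on |delta beta| and iteration cap.
COX_TOL = 1e-8
COX_MAX_ITER = 50

#: |beta| beyond which the partial likelihood is treated as monotone
#: (complete separation of events); the estimate is capped here.
COX_BETA_CAP = 20.0

SMALL_SAMPLE_N = 30


@dataclass(frozen=True)
class TTestResult:
    """Two-sample t-test outcome.

    ``degenerate`` is set when the pooled variance is zero, in which
    case ``p`` is 1 for equal means and 0 otherwise.
    """

    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float
    degenerate: bool = False


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p: float
    n_events: int
    defined: bool = True


@dataclass
class CoxFit:
    """Univariate Cox regression fit for a binary group covariate.

    ``beta`` is the log hazard ratio of the indicator-1 group relative
    to the indicator-0 group; ``hr = exp(beta)`` with a 95% Wald CI.
    ``converged`` is False when the partial likelihood is monotone
    (e.g. all events in one group), in which case ``beta`` is capped.
    """

    beta: float
    se: float
    p: float
    n_iterations: int
    converged: bool
    n: int
    n_events: int
    ties: str = "breslow"

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - Z_95 * self.se)),
            float(np.exp(self.beta + Z_95 * self.se)),
        )


def t_test(x, y, *, equal_var: bool = True) -> TTestResult:
    """Unpaired two-sample Student t-test (pooled variance by default).

    Welch's unequal-variance form is available via ``equal_var=False``.
    Each arm needs at least two finite observations. Arms smaller than
    30 trigger a small-sample warning (the test is still computed).

    Degenerate inputs (zero pooled variance) yield ``t = 0, p = 1``
    when the means are equal and ``p = 0`` (flagged) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("t_test requires at least 2 observations per arm")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("t_test requires finite values")
    if min(x.size, y.size) < SMALL_SAMPLE_N:
        warnings.warn(
            f"small sample (n={min(x.size, y.size)} < {SMALL_SAMPLE_N}); "
            "t-test computed anyway",
            stacklevel=2,
        )
    nx, ny = x.size, y.size
    mx, my = float(x.mean()), float(y.mean())
    vx = float(x.var(ddof=1))
    vy = float(y.var(ddof=1))

    if equal_var:
        df = nx + ny - 2
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = np.sqrt(pooled * (1.0 / nx + 1.0 / ny))
    else:
        se = np.sqrt(vx / nx + vy / ny)
        if se > 0:  # Welch-Satterthwaite
            df = (vx / nx + vy / ny) ** 2 / (
                (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            )
        else:
            df = nx + ny - 2

    if se == 0.0:
        if mx == my:
            return TTestResult(0.0, df, 1.0, mx, my, degenerate=True)
        warnings.warn("zero pooled variance with unequal means", stacklevel=2)
        t = np.inf if mx > my else -np.inf
        return TTestResult(float(t), df, 0.0, mx, my, degenerate=True)

    t = (mx - my) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), mx, my)


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event", "group"):
        if col not in records.columns:
            raise ValueError(f"survival records missing column {col!r}")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    return records


def km_estimate(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit survival curve per group.

    Returns one step-function table per group level with columns
    ``time``, ``n_at_risk``, ``n_events``, ``n_censored`` and
    ``survival``; a leading row at time 0 carries S(0) = 1. Censored
    observations shrink the risk set without dropping the curve.
    """
    records = _check_records(records)
    out: dict[str, pd.DataFrame] = {}
    for level, sub in records.groupby("group", sort=True):
        times = sub["time"].to_numpy(dtype=float)
        events = sub["event"].to_numpy(dtype=bool)
        order = np.argsort(times, kind="stable")
        times, events = times[order], events[order]
        uniq = np.unique(times)
        n = times.size
        rows = [(0.0, n, 0, 0, 1.0)]
        surv = 1.0
        for t in uniq:
            at = times == t
            d = int(events[at].sum())
            c = int((~events[at]).sum())
            n_risk = int((times >= t).sum())
            if d > 0:
                surv *= 1.0 - d / n_risk
            rows.append((float(t), n_risk, d, c, surv))
        out[level] = pd.DataFrame(
            rows, columns=["time", "n_at_risk", "n_events", "n_censored", "survival"]
        )
    return out


def logrank_test(records: pd.DataFrame) -> LogrankResult:
    """Two-group log-rank test.

    Observed-minus-expected events in one group accumulated over event
    times, with the hypergeometric variance of the per-time event split;
    the statistic is chi-square with 1 df. With zero events the test is
    undefined and flagged (``defined=False``, p = NaN).
    """
    records = _check_records(records)
    levels = sorted(records["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(levels)}")
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=bool)
    g1 = (records["group"] == levels[1]).to_numpy()

    n_events = int(event.sum())
    if n_events == 0:
        warnings.warn("no events; log-rank statistic undefined", stacklevel=2)
        return LogrankResult(np.nan, np.nan, 0, defined=False)

    # Risk-set sizes via sorted searchsorted rather than per-time scans.
    st_all = np.sort(time)
    st_g1 = np.sort(time[g1])
    ev_times = time[event]
    uniq = np.unique(ev_times)
    n_at = st_all.size - np.searchsorted(st_all, uniq, side="left")
    n1_at = st_g1.size - np.searchsorted(st_g1, uniq, side="left")
    d_at = np.bincount(np.searchsorted(uniq, ev_times), minlength=uniq.size)
    d1_at = np.bincount(
        np.searchsorted(uniq, time[event & g1]), minlength=uniq.size
    )

    expected = d_at * n1_at / n_at
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (
            d_at
            * (n1_at / n_at)
            * (1.0 - n1_at / n_at)
            * (n_at - d_at)
            / np.maximum(n_at - 1, 1)
        )
    o_minus_e = float((d1_at - expected).sum())
    v = float(var.sum())
    if v == 0.0:
        warnings.warn("zero log-rank variance; statistic undefined", stacklevel=2)
        return LogrankResult(np.nan, np.nan, n_events, defined=False)
    chi2 = o_minus_e**2 / v
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(float(chi2), p, n_events)


def _cox_derivatives(beta, uniq, d_at, s1_at, n_at, n1_at, ties):
    """Breslow/Efron log-partial-likelihood derivatives for a 0/1 covariate.

    Risk-set sums over exp(beta*x) reduce to counts: sum_R e^{bx} =
    n0 + n1*e^b, sum_R x e^{bx} = n1*e^b.
    """
    eb = np.exp(beta)
    n0_at = n_at - n1_at
    if ties == "breslow":
        denom = n0_at + n1_at * eb
        xbar = n1_at * eb / denom
        grad = float((s1_at - d_at * xbar).sum())
        info = float((d_at * xbar * (1.0 - xbar)).sum())
        return grad, info
    # Efron: within a tie of d events (d1 of them in group 1), the l-th
    # denominator subtracts l/d of the tied-event contribution.
    grad = 0.0
    info = 0.0
    for j in range(uniq.size):
        d = int(d_at[j])
        d1 = float(s1_at[j])
        r0 = float(n0_at[j])
        r1 = float(n1_at[j]) * eb
        grad += d1
        # tied-event risk contribution: d1 events in group1, d-d1 in group0
        for ell in range(d):
            frac = ell / d
            den = r0 + r1 - frac * ((d - d1) + d1 * eb)
            num = r1 - frac * d1 * eb
            xbar = num / den
            grad -= xbar
            info += xbar * (1.0 - xbar)
    return grad, info


def cox_univariate(records: pd.DataFrame, *, ties: str = "breslow") -> CoxFit:
    """Univariate Cox regression on the two-level ``group`` covariate.

    Maximizes the partial likelihood by Newton-Raphson (tolerance 1e-8
    on the step, at most 50 iterations); the covariate is the indicator
    of the lexicographically larger group level, so ``hr`` is that
    group's hazard relative to the other. Standard error from the
    inverse observed information; p-value is the Wald test.

    A monotone likelihood (complete separation of events, e.g. every
    event in one group) cannot be maximized in the interior: ``beta``
    is capped at +/-20, ``converged`` is False and a warning is emitted.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie handling {ties!r}")
    records = _check_records(records)
    levels = sorted(records["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"Cox regression needs exactly 2 groups, got {len(levels)}")
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=bool)
    x1 = (records["group"] == levels[1]).to_numpy()

    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("Cox regression needs at least one event")

    st_all = np.sort(time)
    st_g1 = np.sort(time[x1])
    ev_times = time[event]
    uniq = np.unique(ev_times)
    n_at = st_all.size - np.searchsorted(st_all, uniq, side="left")
    n1_at = st_g1.size - np.searchsorted(st_g1, uniq, side="left")
    d_at = np.bincount(np.searchsorted(uniq, ev_times), minlength=uniq.size)
    s1_at = np.bincount(
        np.searchsorted(uniq, time[event & x1]), minlength=uniq.size
    ).astype(float)

    beta = 0.0
    converged = False
    it = 0
    for it in range(1, COX_MAX_ITER + 1):
        grad, info = _cox_derivatives(beta, uniq, d_at, s1_at, n_at, n1_at, ties)
        if info <= 1e-12:
            break
        step = grad / info
        # Damp huge steps so a monotone likelihood walks to the cap
        # instead of overflowing exp().
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(beta) > COX_BETA_CAP:
            beta = float(np.sign(beta) * COX_BETA_CAP)
            break
        if abs(step) < COX_TOL:
            converged = True
            break

    grad, info = _cox_derivatives(beta, uniq, d_at, s1_at, n_at, n1_at, ties)
    se = float(1.0 / np.sqrt(info)) if info > 1e-12 else np.inf
    if not converged:
        warnings.warn(
            "Cox partial likelihood is monotone (complete separation of "
            f"events); beta capped at {beta:+.1f}",
            stacklevel=2,
        )
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxFit(
        beta=float(beta),
        se=se,
        p=p,
        n_iterations=it,
        converged=converged,
        n=int(records.shape[0]),
        n_events=n_events,
        ties=ties,
    )


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star label.

    ns for p >= 0.05, then ``*`` (<0.05), ``**`` (<0.01), ``***``
    (<0.001), ``****`` (<0.0001); all bands use strict inequalities at
    the lower edge.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
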