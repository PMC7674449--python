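"""Survival and competing-risks estimators used throughout the pipeline.

Implements the product-limit (Kaplan-Meier) estimator with Greenwood
variance, the K-group log-rank test, the Aalen-Johansen cumulative
incidence estimator for competing risks, Gray's subdistribution-hazard
test for equality of cumulative incidence functions, and univariate Cox
proportional-hazards regression with Breslow tie handling.

Conventions
-----------
* Event codes for competing risks: 0 = censored, 1 = relapse (cause of
  interest), 2 = death without relapse (competing cause).
* At tied times, events are processed before censorings (both remain in
  the risk set for that time point).
* Curves are right-continuous step functions; evaluation beyond the last
  observed time returns the last value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "CIFCurve",
    "TestResult",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cif_estimate",
    "gray_test",
    "cox_univariate",
    "curve_at",
]


@dataclass
class SurvivalCurve:
    """Product-limit survival curve on the grid of distinct observed times."""

    times: np.ndarray
    survival: np.ndarray
    se: np.ndarray          # Greenwood standard errors
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)


@dataclass
class CIFCurve:
    """Aalen-Johansen cumulative incidence, one curve per cause."""

    times: np.ndarray
    cif: dict[int, np.ndarray]
    causes: tuple[int, ...] = (1, 2)
    cause_labels: dict[int, str] = field(
        default_factory=lambda: {1: "relapse", 2: "death-without-relapse"}
    )


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class CoxFit:
    log_hr: float
    hr: float
    ci95: tuple[float, float]
    se: float
    converged: bool
    n_iter: int


def _validate_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty input: no observations")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and non-negative")
    return t


def km_estimate(times, event_flags) -> SurvivalCurve:
    """Kaplan-Meier estimate with Greenwood standard errors.

    Parameters
    ----------
    times : array-like of follow-up times (>= 0).
    event_flags : array-like of {0, 1}; 1 = event, 0 = censored.
    """
    t = _validate_times(times)
    e = np.asarray(event_flags, dtype=int)
    if e.shape != t.shape:
        raise ValueError("times and event_flags must have equal length")

    grid = np.unique(t)
    n = t.size
    surv, se, at_risk, events = [], [], [], []
    s = 1.0
    green = 0.0  # running Greenwood sum d / (n (n - d))
    for tt in grid:
        y = int(np.sum(t >= tt))
        d = int(np.sum((t == tt) & (e == 1)))
        if d > 0:
            s *= 1.0 - d / y
            if y > d:
                green += d / (y * (y - d))
        surv.append(s)
        se.append(s * math.sqrt(green) if y > d or d == 0 else 0.0)
        at_risk.append(y)
        events.append(d)
    return SurvivalCurve(
        times=grid,
        survival=np.array(surv),
        se=np.array(se),
        at_risk=np.array(at_risk, dtype=int),
        events=np.array(events, dtype=int),
    )


def curve_at(curve, t: float, cause: int = 1) -> float:
    """Evaluate a survival or CIF curve at time ``t`` (right-continuous).

    Survival curves start at S(0-) = 1, CIF curves at 0; beyond the last
    observed time the final value is carried forward.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if isinstance(curve, SurvivalCurve):
        times, values, baseline = curve.times, curve.survival, 1.0
    elif isinstance(curve, CIFCurve):
        times, values, baseline = curve.times, curve.cif[cause], 0.0
    else:
        raise TypeError(f"unsupported curve type: {type(curve)!r}")
    idx = np.searchsorted(times, t, side="right") - 1
    if idx < 0:
        return baseline
    return float(values[idx])


def logrank_test(times, events, group) -> TestResult:
    """K-group log-rank test (chi-square, df = K - 1)."""
    t = _validate_times(times)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group)
    labels = np.unique(g)
    k = labels.size
    if k < 2:
        raise ValueError("logrank_test requires at least two groups")
    if int(e.sum()) == 0:
        raise ValueError("logrank_test requires at least one event")

    z = np.zeros(k)
    cov = np.zeros((k, k))
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        y = int(at_risk.sum())
        d = int(np.sum((t == tt) & (e == 1)))
        if y == 0 or d == 0:
            continue
        yk = np.array([int(np.sum(at_risk & (g == lab))) for lab in labels], dtype=float)
        dk = np.array(
            [int(np.sum((t == tt) & (e == 1) & (g == lab))) for lab in labels],
            dtype=float,
        )
        p = yk / y
        z += dk - d * p
        if y > 1:
            c = d * (y - d) / (y - 1)
            cov += c * (np.diag(p) - np.outer(p, p))
    zr, covr = z[:-1], cov[:-1, :-1]
    stat = float(zr @ np.linalg.pinv(covr) @ zr)
    df = k - 1
    return TestResult(statistic=max(stat, 0.0), df=df,
                      p_value=float(stats.chi2.sf(max(stat, 0.0), df)))


def cif_estimate(times, event_type, causes=(1, 2)) -> CIFCurve:
    """Aalen-Johansen cumulative incidence with competing risks.

    CIF_k(t) = sum over event times u <= t of S(u-) d_k(u) / n(u), where S
    is the all-cause Kaplan-Meier estimate.
    """
    t = _validate_times(times)
    e = np.asarray(event_type, dtype=int)
    if not np.all(np.isin(e, [0, *causes])):
        raise ValueError(f"event_type codes must be 0 or one of {causes}")

    grid = np.unique(t)
    s_minus = 1.0
    cif = {c: [] for c in causes}
    acc = {c: 0.0 for c in causes}
    for tt in grid:
        y = int(np.sum(t >= tt))
        d_all = int(np.sum((t == tt) & (e != 0)))
        for c in causes:
            d_c = int(np.sum((t == tt) & (e == c)))
            if d_c > 0:
                acc[c] += s_minus * d_c / y
            cif[c].append(acc[c])
        if d_all > 0:
            s_minus *= 1.0 - d_all / y
    return CIFCurve(times=grid, cif={c: np.array(v) for c, v in cif.items()},
                    causes=tuple(causes))


def gray_test(times, event_type, group, cause: int = 1, rho: float = 0.0) -> TestResult:
    """Gray's test for equality of cumulative incidence functions.

    Score test on the subdistribution hazard of ``cause`` across K groups
    (chi-square, df = K - 1).  The per-group effective risk set at time t
    is R_k(t) = Y_k(t) * (1 - F_k(t-)) / S_k(t-), with F_k the group's
    cumulative incidence for the cause of interest and S_k its all-cause
    Kaplan-Meier estimate; events of competing causes therefore keep
    contributing to the risk set through the (1 - F_k)/S_k inflation.
    With no competing events the statistic reduces exactly to the
    log-rank test.  The variance is the hypergeometric-style plug-in on
    the effective risk sets; see the methods note for calibration.
    """
    t = _validate_times(times)
    e = np.asarray(event_type, dtype=int)
    g = np.asarray(group)
    labels = np.unique(g)
    k = labels.size
    if k < 2:
        raise ValueError("gray_test requires at least two groups")
    if int(np.sum(e == cause)) == 0:
        raise ValueError(f"gray_test requires at least one event of cause {cause}")

    # per-group running state: at-risk count, S_k(t-), F_k(t-)
    y = np.array([int(np.sum(g == lab)) for lab in labels], dtype=float)
    s_km = np.ones(k)
    f_cif = np.zeros(k)
    # pooled state (enters only through the rho weight)
    s_pooled = 1.0
    f_pooled = 0.0

    z = np.zeros(k)
    cov = np.zeros((k, k))
    for tt in np.unique(t):
        here = t == tt
        d1 = np.array([int(np.sum(here & (e == cause) & (g == lab))) for lab in labels],
                      dtype=float)
        d_all = np.array([int(np.sum(here & (e != 0) & (g == lab))) for lab in labels],
                         dtype=float)
        c_cens = np.array([int(np.sum(here & (e == 0) & (g == lab))) for lab in labels],
                          dtype=float)
        d1_tot = d1.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(s_km > 0, y * (1.0 - f_cif) / s_km, 0.0)
        r_tot = r.sum()
        if d1_tot > 0 and r_tot > 0:
            w = (1.0 - f_pooled) ** rho
            p = r / r_tot
            z += w * (d1 - d1_tot * p)
            if r_tot > 1:
                c = w * w * d1_tot * (r_tot - d1_tot) / (r_tot - 1)
                cov += max(c, 0.0) * (np.diag(p) - np.outer(p, p))
        # pooled CIF / KM updates (left limits feed the next iteration)
        y_tot = y.sum()
        if y_tot > 0:
            if d1_tot > 0:
                f_pooled += s_pooled * d1_tot / y_tot
            if d_all.sum() > 0:
                s_pooled *= 1.0 - d_all.sum() / y_tot
        # per-group updates: events first, then censorings leave
        for i in range(k):
            if y[i] > 0:
                if d1[i] > 0:
                    f_cif[i] += s_km[i] * d1[i] / y[i]
                if d_all[i] > 0:
                    s_km[i] *= 1.0 - d_all[i] / y[i]
            y[i] -= d_all[i] + c_cens[i]

    zr, covr = z[:-1], cov[:-1, :-1]
    stat = float(zr @ np.linalg.pinv(covr) @ zr) if np.any(covr) else 0.0
    df = k - 1
    return TestResult(statistic=max(stat, 0.0), df=df,
                      p_value=float(stats.chi2.sf(max(stat, 0.0), df)))


def cox_univariate(times, events, covariate, max_iter: int = 50,
                   tol: float = 1e-9) -> CoxFit:
    """Univariate Cox proportional-hazards fit (Breslow ties, Wald CI).

    Newton-Raphson maximization of the partial likelihood.  Monotone
    separation (the likelihood increases without bound) is reported via
    ``converged=False`` rather than raising.
    """
    t = _validate_times(times)
    e = np.asarray(events, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if int(e.sum()) == 0:
        raise ValueError("cox_univariate requires at least one event")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")

    # sort descending by time so risk sets are cumulative prefixes
    order = np.argsort(-t, kind="stable")
    ts, es, xs = t[order], e[order], x[order]

    beta = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.exp(beta * xs)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * xs)
        s2 = np.cumsum(w * xs * xs)
        # risk set for an event at time ts[i]: all j with ts[j] >= ts[i];
        # with ties, the whole tied block is at risk -> use the last index
        # of the tied block in the descending order.
        uniq, last_idx = {}, np.empty(ts.size, dtype=int)
        for i in range(ts.size):
            uniq[ts[i]] = i
        for i in range(ts.size):
            last_idx[i] = uniq[ts[i]]
        ev = es == 1
        li = last_idx[ev]
        u = float(np.sum(xs[ev] - s1[li] / s0[li]))
        info = float(np.sum(s2[li] / s0[li] - (s1[li] / s0[li]) ** 2))
        if info <= 0 or not math.isfinite(u):
            break
        step = u / info
        beta += step
        if abs(beta) > 50 or not math.isfinite(beta):
            break
        if abs(step) < tol:
            converged = True
            break

    if not converged:
        beta = min(max(beta, -50.0), 50.0)
    w = np.exp(beta * xs)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * xs)
    s2 = np.cumsum(w * xs * xs)
    ev = es == 1
    uniq = {}
    for i in range(ts.size):
        uniq[ts[i]] = i
    li = np.array([uniq[tt] for tt in ts[ev]], dtype=int)
    info = float(np.sum(s2[li] / s0[li] - (s1[li] / s0[li]) ** 2))
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    return CoxFit(
        log_hr=beta,
        hr=math.exp(beta),
        ci95=(math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)),
        se=se,
        converged=converged,
        n_iter=it,
    )
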