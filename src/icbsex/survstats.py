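"""Survival and association statistics for ICB-treated cohorts.

The univariate Cox model is a direct partial-likelihood Newton–Raphson
implementation (Efron tie correction by default, Breslow behind a flag),
vectorized so that simulation studies can run tens of thousands of fits.
Kaplan–Meier and the two-group log-rank test are likewise implemented from
the product-limit / hypergeometric forms. Fisher's exact test (two-sided
minimum-likelihood rule) and the Mann–Whitney–Wilcoxon test delegate to
scipy.stats; MWW uses exact enumeration for small untied samples and the
tie- and continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

Z_95 = 1.959964


class SurvivalError(ValueError):
    pass


@dataclass(frozen=True)
class CoxFit:
    hr: float
    ci_lo: float
    ci_hi: float
    log_hr: float
    se_log_hr: float
    p_value: float
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.hr <= self.ci_hi):
            raise SurvivalError("Cox CI does not bracket HR")


@dataclass(frozen=True)
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    effect: float | None = None


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise SurvivalError("empty survival input")
    if np.any(t < 0):
        raise SurvivalError("negative survival times")
    if not np.all(np.isin(e, [0.0, 1.0])):
        raise SurvivalError("events must be 0/1")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimate at each distinct event time."""
    t, e = _check_surv(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, et in enumerate(event_times):
        n_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / n_risk
        surv[i] = s
        at_risk[i] = n_risk
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk)


def logrank_test(times_a, events_a, times_b, events_b) -> TestResult:
    """Two-group log-rank χ² (1 df) with the hypergeometric variance."""
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size), np.ones(tb.size)])
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="logrank")
    obs_b = 0.0
    exp_b = 0.0
    var_b = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n_b = (at_risk & (g == 1)).sum()
        d = ((t == et) & (e == 1)).sum()
        d_b = ((t == et) & (e == 1) & (g == 1)).sum()
        obs_b += d_b
        exp_b += d * n_b / n
        if n > 1:
            var_b += d * (n_b / n) * (1 - n_b / n) * (n - d) / (n - 1)
    if var_b == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="logrank")
    chi2 = (obs_b - exp_b) ** 2 / var_b
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult(statistic=float(chi2), p_value=p, method="logrank")


def _cox_loglik_grad_hess(beta: float, prep: dict, ties: str):
    x = prep["x"]
    t = prep["t"]
    exb = np.exp(x * beta)
    # reverse cumulative sums over patients sorted by ascending time give
    # risk-set sums at each position (risk set = all with time >= t_i)
    rc0 = np.cumsum(exb[::-1])[::-1]
    rc1 = np.cumsum((x * exb)[::-1])[::-1]
    rc2 = np.cumsum((x * x * exb)[::-1])[::-1]

    first_idx = prep["first_idx"]  # index of first patient at each distinct event time
    S0 = rc0[first_idx]
    S1 = rc1[first_idx]
    S2 = rc2[first_idx]

    # tied-event sums per distinct event time
    grp = prep["event_group"]
    n_groups = prep["n_groups"]
    ev = prep["event_rows"]
    s0 = np.bincount(grp, weights=exb[ev], minlength=n_groups)
    s1 = np.bincount(grp, weights=(x * exb)[ev], minlength=n_groups)
    s2 = np.bincount(grp, weights=(x * x * exb)[ev], minlength=n_groups)
    d_k = prep["d_k"]

    if ties == "efron":
        frac = prep["frac"]  # l/d for l=0..d-1, concatenated over groups
        rep = prep["rep"]  # group index repeated d_k times
        den0 = S0[rep] - frac * s0[rep]
        den1 = S1[rep] - frac * s1[rep]
        den2 = S2[rep] - frac * s2[rep]
    elif ties == "breslow":
        rep = prep["rep"]
        den0 = S0[rep]
        den1 = S1[rep]
        den2 = S2[rep]
    else:
        raise ValueError(f"unknown tie method {ties!r}")

    loglik = float(beta * prep["event_x_sum"] - np.sum(np.log(den0)))
    grad = float(prep["event_x_sum"] - np.sum(den1 / den0))
    hess = float(-np.sum(den2 / den0 - (den1 / den0) ** 2))
    return loglik, grad, hess


def _cox_prepare(times: np.ndarray, events: np.ndarray, x: np.ndarray) -> dict:
    order = np.argsort(times, kind="stable")
    t, e, xv = times[order], events[order], x[order]
    ev = np.flatnonzero(e == 1)
    ev_times = t[ev]
    uniq, grp = np.unique(ev_times, return_inverse=True)
    n_groups = uniq.size
    # first patient index (in ascending-time order) with time >= each event time
    first_idx = np.searchsorted(t, uniq, side="left")
    d_k = np.bincount(grp, minlength=n_groups)
    rep = np.repeat(np.arange(n_groups), d_k)
    within = np.concatenate([np.arange(d) for d in d_k]) if n_groups else np.array([])
    frac = within / np.repeat(d_k, d_k)
    return {
        "t": t,
        "x": xv,
        "event_rows": ev,
        "event_group": grp,
        "n_groups": n_groups,
        "first_idx": first_idx,
        "d_k": d_k,
        "rep": rep,
        "frac": frac,
        "event_x_sum": float(np.sum(xv[ev])),
    }


def cox_univariate(times, events, x, ties: str = "efron") -> CoxFit:
    """Univariate Cox proportional-hazards fit by Newton–Raphson.

    With ``x`` the female indicator, HR > 1 means a higher death hazard
    (worse OS) for females. Wald CI and two-sided p. Raises on a constant
    covariate, on no events, and on monotone likelihood (complete
    separation of the covariate with respect to event order).
    """
    t, e = _check_surv(times, events)
    xv = np.asarray(x, dtype=float)
    if xv.shape != t.shape:
        raise SurvivalError("x length mismatch")
    n_events = int(e.sum())
    if n_events < 1:
        raise SurvivalError("no events")
    if np.ptp(xv) == 0:
        raise SurvivalError("covariate is constant")
    # center for numerical stability; HR is shift-invariant
    shift = xv.mean()
    prep = _cox_prepare(t, e, xv - shift)

    beta = 0.0
    loglik, grad, hess = _cox_loglik_grad_hess(beta, prep, ties)
    for _ in range(60):
        if hess >= 0:
            raise SurvivalError("non-concave partial likelihood")
        step = -grad / hess
        new_beta = beta + step
        if not math.isfinite(new_beta) or abs(new_beta) > 30:
            raise SurvivalError(
                "monotone partial likelihood (complete separation); "
                "consider exact or penalized methods"
            )
        # step-halving to guarantee ascent
        for _ in range(30):
            new_ll, new_grad, new_hess = _cox_loglik_grad_hess(new_beta, prep, ties)
            if math.isfinite(new_ll) and new_ll >= loglik - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        converged = abs(new_beta - beta) < 1e-10
        beta, loglik, grad, hess = new_beta, new_ll, new_grad, new_hess
        if converged:
            break
    else:
        raise SurvivalError("Cox Newton-Raphson did not converge")

    se = math.sqrt(-1.0 / hess)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxFit(
        hr=math.exp(beta),
        ci_lo=math.exp(beta - Z_95 * se),
        ci_hi=math.exp(beta + Z_95 * se),
        log_hr=beta,
        se_log_hr=se,
        p_value=p,
        n=int(t.size),
        n_events=n_events,
    )


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test (minimum-likelihood rule) on a 2×2 table.

    The odds ratio is the sample ad/bc; zero or infinite ORs are returned
    as-is with the exact p.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or np.any(tab < 0) or np.any(tab != np.floor(tab)):
        raise ValueError("table must be 2x2 nonnegative integers")
    a, b, c, d = tab.ravel()
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return TestResult(statistic=math.nan, p_value=1.0, method="fisher", effect=None)
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    res = stats.fisher_exact(tab.astype(int), alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(res.pvalue), method="fisher", effect=float(odds))


def mww_test(x, y, exact_max_product: int = 400) -> TestResult:
    """Two-sided Mann–Whitney–Wilcoxon test.

    Exact enumeration when n_x·n_y ≤ ``exact_max_product`` and there are no
    ties across the pooled sample; otherwise the normal approximation with
    tie and continuity corrections.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    if xa.size * ya.size <= exact_max_product and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        xa, ya, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method=f"mww-{method}",
        effect=float(res.statistic),
    )


def significance_band(p: float, direction: str) -> str:
    """Heatmap band: 'strong' (p < 0.05), 'weak' (0.05 ≤ p < 0.2), 'none'."""
    if not (0 <= p <= 1):
        raise ValueError(f"p outside [0,1]: {p}")
    if direction not in ("female", "male"):
        raise ValueError(f"direction must be 'female' or 'male', got {direction!r}")
    if p < 0.05:
        return "strong"
    if p < 0.2:
        return "weak"
    return "none"
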