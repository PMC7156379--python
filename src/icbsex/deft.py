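"""Within-trial female:male interaction meta-analysis (the deft approach).

Across-trial comparison of sex subgroups confounds sex with trial; the deft
("difference in effect of treatment") approach instead estimates the
treatment × sex interaction *within* each trial as the log ratio of
sex-specific hazard ratios,

    d_i = ln(HR_female,i) − ln(HR_male,i),    se_i² = se_f,i² + se_m,i²,

and pools the d_i with a random-effects model d_i ~ N(μ, se_i² + τ²).
τ² is estimated by restricted maximum likelihood (DerSimonian–Laird as the
initializer). exp(μ) > 1 means the treatment's survival benefit is larger in
males (the female hazard ratio is closer to 1 or above it), exp(μ) < 1 the
reverse.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from icbsex.dataio import TrialRecord

logger = logging.getLogger(__name__)

#: two-sided 95% normal quantile, fixed for bit-stable confidence intervals
Z_95 = 1.959964


class MetaAnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionEstimate:
    """One trial's log female:male ratio of hazard ratios and its SE."""

    trial_id: str
    d: float
    se: float
    se_female: float
    se_male: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.d):
            raise MetaAnalysisError(f"trial {self.trial_id}: non-finite interaction")
        expected = math.hypot(self.se_female, self.se_male)
        if abs(self.se - expected) > 1e-12 * max(self.se, 1.0):
            raise MetaAnalysisError(
                f"trial {self.trial_id}: se inconsistent with per-sex SEs"
            )


@dataclass(frozen=True)
class PooledResult:
    """Pooled female:male HR ratio with CI, heterogeneity and method tag."""

    ratio: float
    ci_lo: float
    ci_hi: float
    p_value: float
    tau2: float
    q_stat: float
    i2: float
    k: int
    method: str

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.ratio <= self.ci_hi):
            raise MetaAnalysisError("pooled CI does not bracket the ratio")
        if self.tau2 < 0 or self.k < 2:
            raise MetaAnalysisError("invalid pooled result")


def se_from_ci(hr: float, lo: float, hi: float, level: float = 0.95) -> float:
    """Recover the log-HR standard error from a reported Wald CI.

    se = (ln hi − ln lo) / (2 z), z the normal quantile at (1+level)/2.
    """
    if not (0 < level < 1):
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    if min(hr, lo, hi) <= 0:
        raise ValueError("HR and CI bounds must be positive")
    if lo == hi:
        raise ValueError("degenerate CI: lo == hi")
    if not (lo <= hr <= hi):
        warnings.warn(
            f"CI [{lo}, {hi}] does not bracket HR {hr}; SE computed from bounds anyway",
            stacklevel=2,
        )
    z = Z_95 if level == 0.95 else stats.norm.ppf(0.5 + level / 2)
    return (math.log(hi) - math.log(lo)) / (2.0 * z)


def trial_interaction(trial: TrialRecord, level: float = 0.95) -> InteractionEstimate:
    """The within-trial treatment × sex interaction on the log-HR scale."""
    try:
        se_f = se_from_ci(trial.hr_female, trial.ci_female_lo, trial.ci_female_hi, level)
        se_m = se_from_ci(trial.hr_male, trial.ci_male_lo, trial.ci_male_hi, level)
    except ValueError as exc:
        raise MetaAnalysisError(f"trial {trial.trial_id}: {exc}") from exc
    d = math.log(trial.hr_female) - math.log(trial.hr_male)
    return InteractionEstimate(
        trial_id=trial.trial_id,
        d=d,
        se=math.hypot(se_f, se_m),
        se_female=se_f,
        se_male=se_m,
    )


def _as_arrays(estimates: Sequence[InteractionEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if len(estimates) < 2:
        raise MetaAnalysisError(f"need >=2 estimates to pool, got {len(estimates)}")
    d = np.array([e.d for e in estimates], dtype=float)
    v = np.array([e.se for e in estimates], dtype=float) ** 2
    return d, v


def dl_tau2(estimates: Sequence[InteractionEstimate]) -> float:
    """DerSimonian–Laird moment estimator of the between-trial variance."""
    d, v = _as_arrays(estimates)
    w = 1.0 / v
    d_bar = np.sum(w * d) / np.sum(w)
    q = float(np.sum(w * (d - d_bar) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    k = len(d)
    if c <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / c)


def reml_tau2(
    estimates: Sequence[InteractionEstimate],
    init: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> float:
    """Restricted-maximum-likelihood τ² via the standard fixed-point iteration.

    τ²_{t+1} = Σ w²[(d−μ)² − v] / Σ w² + 1/Σ w, with w = 1/(v + τ²_t) and μ
    the current weighted mean; the 1/Σw term corrects for estimating μ.
    Truncated at zero; converged when successive iterates differ by < tol.
    """
    d, v = _as_arrays(estimates)
    tau2 = dl_tau2(estimates) if init is None else float(init)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * d) / np.sum(w)
        new = float(np.sum(w**2 * ((d - mu) ** 2 - v)) / np.sum(w**2) + 1.0 / np.sum(w))
        new = max(0.0, new)
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    raise MetaAnalysisError(
        f"REML did not converge in {max_iter} iterations (last iterate {tau2:.6g})"
    )


def pool(
    estimates: Sequence[InteractionEstimate],
    tau2: float,
    method: str = "REML",
    knapp_hartung: bool = False,
) -> PooledResult:
    """Inverse-variance pooling of the interactions with a given τ².

    Reports the pooled ratio exp(μ) with a Wald z interval by default, the
    two-sided normal p for μ = 0, and Cochran's Q / I² computed with
    fixed-effect weights (the conventional heterogeneity report). With
    ``knapp_hartung=True`` the variance is scaled by the weighted residual
    mean square and a t(k−1) reference replaces the normal — wider
    intervals with better small-k coverage.
    """
    d, v = _as_arrays(estimates)
    w_star = 1.0 / (v + tau2)
    mu = float(np.sum(w_star * d) / np.sum(w_star))
    se_mu = float(np.sqrt(1.0 / np.sum(w_star)))
    if knapp_hartung:
        scale = float(np.sum(w_star * (d - mu) ** 2) / (len(d) - 1))
        se_mu *= math.sqrt(scale)
        crit = float(stats.t.ppf(0.975, len(d) - 1))
        p = float(2.0 * stats.t.sf(abs(mu / se_mu), len(d) - 1))
    else:
        crit = Z_95
        p = float(2.0 * stats.norm.sf(abs(mu / se_mu)))
    w_fe = 1.0 / v
    d_bar = np.sum(w_fe * d) / np.sum(w_fe)
    q = float(np.sum(w_fe * (d - d_bar) ** 2))
    k = len(d)
    i2 = max(0.0, 100.0 * (q - (k - 1)) / q) if q > 0 else 0.0
    return PooledResult(
        ratio=math.exp(mu),
        ci_lo=math.exp(mu - crit * se_mu),
        ci_hi=math.exp(mu + crit * se_mu),
        p_value=p,
        tau2=float(tau2),
        q_stat=q,
        i2=i2,
        k=k,
        method=method,
    )


def deft_pool(
    trials: Iterable[TrialRecord],
    subset: Callable[[TrialRecord], bool] | None = None,
    method: str = "REML",
    knapp_hartung: bool = False,
) -> PooledResult:
    """Full deft pipeline: interactions → τ² (REML, DL init) → pooled ratio.

    ``subset`` filters trials (e.g. by therapy class or control arm) before
    pooling; selecting fewer than two trials is an error.
    """
    all_trials = list(trials)
    selected = [t for t in all_trials if subset is None or subset(t)]
    if len(selected) < 2:
        matched = [t.trial_id for t in selected]
        raise MetaAnalysisError(
            f"subset selected {len(selected)} trial(s) ({matched}); need >=2"
        )
    estimates = [trial_interaction(t) for t in selected]
    if method == "REML":
        tau2 = reml_tau2(estimates, init=dl_tau2(estimates))
    elif method == "DL":
        tau2 = dl_tau2(estimates)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pool(estimates, tau2, method=method, knapp_hartung=knapp_hartung)


def subset_by(**field_values: str) -> Callable[[TrialRecord], bool]:
    """Predicate factory: ``subset_by(control_arm="placebo")`` etc."""

    def predicate(trial: TrialRecord) -> bool:
        return all(getattr(trial, k) == v for k, v in field_values.items())

    return predicate


def count_directions(
    trials: Sequence[TrialRecord],
    group_by: str = "cancer_type",
) -> pd.DataFrame:
    """Per-group tallies of the within-trial interaction direction.

    exp(d) > 1 is an OS advantage of the treatment in males (the female HR is
    the larger), exp(d) < 1 an advantage in females; exact ties are counted
    in their own column rather than assigned to either side.
    """
    if not trials:
        raise MetaAnalysisError("no trials to count")
    if not hasattr(trials[0], group_by):
        raise MetaAnalysisError(f"unknown trial field {group_by!r}")
    rows: dict[str, list[int]] = {}
    for t in trials:
        d = trial_interaction(t).d
        counts = rows.setdefault(str(getattr(t, group_by)), [0, 0, 0])
        if d > 0:
            counts[0] += 1
        elif d < 0:
            counts[1] += 1
        else:
            counts[2] += 1
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["n_male_advantage", "n_female_advantage", "n_tied"]
    )
    out.index.name = group_by
    return out.sort_index()


def forest_table(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Per-trial ratios, CIs and inverse-variance weight shares for plotting."""
    ests = [trial_interaction(t) for t in trials]
    w = np.array([1.0 / e.se**2 for e in ests])
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "cancer_type": [t.cancer_type for t in trials],
            "ratio": [math.exp(e.d) for e in ests],
            "ci_lo": [math.exp(e.d - Z_95 * e.se) for e in ests],
            "ci_hi": [math.exp(e.d + Z_95 * e.se) for e in ests],
            "weight_pct": 100.0 * w / w.sum(),
        }
    )
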