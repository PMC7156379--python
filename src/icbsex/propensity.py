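"""Matching-weight propensity screen for sex-biased immune features.

Observational cohorts confound sex with age, smoking, stage, histology,
race and tumor purity; a raw female-vs-male comparison of an immune feature
therefore mixes the sex effect with those covariates. The screen

1. fits a logistic propensity model e_i = P(female | covariates),
2. reweights patients with matching weights
   MW_i = min(e_i, 1−e_i) / [Z_i e_i + (1−Z_i)(1−e_i)]  (Z=1 female),
   which emulate 1:1 matching while keeping every patient and bound every
   weight by 1,
3. checks balance with standardized mean differences before/after,
4. tests each feature: weighted least squares of feature on the female
   indicator with heteroskedasticity-robust (HC0) standard errors for
   continuous features, Fisher's exact test for binary indicators,
5. adjusts p-values by Benjamini–Hochberg within each
   (cancer type × feature family) and labels direction and significance
   band.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from icbsex.dataio import FeatureMatrix
from icbsex.survstats import fisher_exact_2x2, mww_test, significance_band

logger = logging.getLogger(__name__)

SCORE_CLIP = 1e-6
BALANCE_SMD = 0.1  # conventional |SMD| threshold for calling a covariate balanced


class PropensityError(ValueError):
    pass


@dataclass
class PropensityModel:
    """Fitted logistic propensity model for P(female | covariates)."""

    coefficients: pd.Series
    scores: pd.Series  # e_i in (0,1), indexed by patient_id
    group: pd.Series  # Z_i: 1 female, 0 male
    covariates: list[str]
    n_dropped: int = 0
    ridged: bool = False

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.group.index):
            raise PropensityError("scores and group must share a patient index")
        if ((self.scores <= 0) | (self.scores >= 1)).any():
            raise PropensityError("propensity scores must lie strictly in (0,1)")


@dataclass
class BalanceReport:
    """Standardized differences before/after weighting plus score overlap."""

    table: pd.DataFrame  # index: covariate term; columns smd_before, smd_after, ...
    overlap: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap <= 1.0):
            raise PropensityError(f"overlap outside [0,1]: {self.overlap}")

    @property
    def balanced(self) -> bool:
        return bool((self.table["smd_after"].abs() < BALANCE_SMD).all())


@dataclass(frozen=True)
class ScreenResult:
    cancer_type: str
    feature: str
    beta: float
    se: float
    p_value: float
    fdr: float
    direction: str  # female-bias | male-bias
    band: str  # strong | weak | none
    n_female: int
    n_male: int
    test: str  # weighted-linear | fisher | mww


def eligible_cohorts(
    cohorts: Mapping[str, pd.DataFrame],
    min_per_group: int = 20,
) -> dict[str, pd.DataFrame]:
    """Retain cancer types with at least ``min_per_group`` of each sex."""
    if min_per_group < 1:
        raise ValueError("min_per_group must be >= 1")
    kept = {}
    for name, cohort in cohorts.items():
        counts = cohort["sex"].value_counts()
        if counts.get("female", 0) >= min_per_group and counts.get("male", 0) >= min_per_group:
            kept[name] = cohort
    return kept


def _design_matrix(
    cohort: pd.DataFrame, covariates: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete-case design: standardized continuous terms, one-hot
    categoricals with the most frequent level as reference.

    Returns (design with intercept, complete-case cohort rows).
    """
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise PropensityError(f"covariates not in cohort: {missing}")
    cc = cohort.dropna(subset=list(covariates))
    n_dropped = len(cohort) - len(cc)
    if n_dropped:
        logger.info("complete-case filter dropped %d patient(s)", n_dropped)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cc))}
    for cov in covariates:
        vals = cc[cov]
        if pd.api.types.is_numeric_dtype(vals):
            arr = vals.to_numpy(dtype=float)
            sd = arr.std(ddof=1)
            cols[cov] = (arr - arr.mean()) / sd if sd > 0 else np.zeros(len(arr))
        else:
            ref = vals.value_counts().idxmax()
            for level in sorted(vals.unique()):
                if level == ref:
                    continue
                cols[f"{cov}[{level}]"] = (vals == level).to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=cc.index)
    return design, cc


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 100, tol: float = 1e-10
) -> np.ndarray:
    """Plain IRLS for logistic regression with an optional L2 penalty
    (intercept unpenalized). Used directly — it is the same algorithm
    statsmodels runs for a binomial GLM — because the separation fallback
    needs a ridge path that statsmodels' GLM does not expose."""
    p = X.shape[1]
    beta = np.zeros(p)
    pen = np.full(p, ridge)
    pen[0] = 0.0
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        grad = X.T @ (y - mu) - pen * beta
        hess = (X.T * w) @ X + np.diag(pen)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta
        if np.max(np.abs(beta)) > 1e6:
            raise FloatingPointError("diverging IRLS")
    raise FloatingPointError("IRLS did not converge")


def fit_propensity(cohort: pd.DataFrame, covariates: Sequence[str]) -> PropensityModel:
    """Logistic propensity model of female membership on the covariates.

    Complete-case rows only; continuous covariates are standardized and
    categoricals one-hot coded. Perfect separation triggers an automatic
    small ridge penalty (logged warning). Scores are clipped away from 0/1
    so matching weights stay finite.
    """
    design, cc = _design_matrix(cohort, covariates)
    z = (cc["sex"] == "female").astype(float)
    if z.sum() < 2 or (1 - z).sum() < 2:
        raise PropensityError("need >=2 usable patients per sex after complete-case filter")
    X = design.to_numpy()
    y = z.to_numpy()
    ridged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", RuntimeWarning)
            beta = _irls_logistic(X, y, ridge=0.0)
    except (FloatingPointError, np.linalg.LinAlgError, RuntimeWarning):
        logger.warning("propensity fit unstable (separation?); refitting with ridge=1e-3")
        ridged = True
        beta = _irls_logistic(X, y, ridge=1e-3)
    scores = 1.0 / (1.0 + np.exp(-(X @ beta)))
    scores = np.clip(scores, SCORE_CLIP, 1.0 - SCORE_CLIP)
    idx = cc["patient_id"] if "patient_id" in cc.columns else cc.index
    return PropensityModel(
        coefficients=pd.Series(beta, index=design.columns),
        scores=pd.Series(scores, index=pd.Index(idx, name="patient_id")),
        group=pd.Series(y.astype(int), index=pd.Index(idx, name="patient_id")),
        covariates=list(covariates),
        n_dropped=len(cohort) - len(cc),
        ridged=ridged,
    )


def matching_weights(model: PropensityModel) -> pd.Series:
    """MW_i = min(e, 1−e) / [Z e + (1−Z)(1−e)]; always in (0, 1]."""
    e = model.scores.to_numpy()
    z = model.group.to_numpy()
    denom = z * e + (1 - z) * (1 - e)
    w = np.minimum(e, 1 - e) / denom
    return pd.Series(w, index=model.scores.index, name="matching_weight")


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    wsum = w.sum()
    mean = float(np.sum(w * x) / wsum)
    denom = wsum**2 - np.sum(w**2)  # zero for a single effective observation
    if denom <= 0:
        return mean, 0.0
    # frequency-weight style variance with the standard finite correction
    var = float(np.sum(w * (x - mean) ** 2) / wsum * wsum**2 / denom)
    return mean, var


def standardized_difference(values, group, weights=None) -> float:
    """Standardized mean difference (female − male) / pooled SD.

    With weights, both the means and the variances are weighted (the
    convention for post-weighting balance checks). Zero pooled SD returns 0
    when the means agree and raises otherwise.
    """
    x = np.asarray(values, dtype=float)
    z = np.asarray(group, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if (z == 1).sum() == 0 or (z == 0).sum() == 0:
        raise PropensityError("both groups must be nonempty")
    mf, vf = _weighted_mean_var(x[z == 1], w[z == 1])
    mm, vm = _weighted_mean_var(x[z == 0], w[z == 0])
    pooled = math.sqrt((vf + vm) / 2.0)
    if pooled == 0:
        if math.isclose(mf, mm, abs_tol=1e-12):
            return 0.0
        raise PropensityError("degenerate covariate: zero pooled SD, unequal means")
    return (mf - mm) / pooled


def _balance_terms(cohort: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Expand covariates into numeric balance terms (indicators per level)."""
    out = {}
    for cov in covariates:
        vals = cohort[cov]
        if pd.api.types.is_numeric_dtype(vals):
            out[cov] = vals.to_numpy(dtype=float)
        else:
            for level in sorted(vals.dropna().unique()):
                out[f"{cov}[{level}]"] = (vals == level).to_numpy(dtype=float)
    return pd.DataFrame(out, index=cohort.index)


def overlap_coefficient(scores: pd.Series, group: pd.Series, bins: int = 50) -> float:
    """Histogram overlap of female vs male propensity-score distributions."""
    e = scores.to_numpy()
    z = group.to_numpy()
    edges = np.linspace(e.min(), e.max() + 1e-12, bins + 1)
    hf, _ = np.histogram(e[z == 1], bins=edges)
    hm, _ = np.histogram(e[z == 0], bins=edges)
    if hf.sum() == 0 or hm.sum() == 0:
        return 0.0
    return float(np.minimum(hf / hf.sum(), hm / hm.sum()).sum())


def balance_report(
    cohort: pd.DataFrame,
    model: PropensityModel,
    weights: pd.Series,
) -> BalanceReport:
    """SMD before (unweighted) and after (matching-weighted) per term."""
    _, cc = _design_matrix(cohort, model.covariates)
    terms = _balance_terms(cc, model.covariates)
    z = (cc["sex"] == "female").astype(float).to_numpy()
    w = weights.to_numpy()
    rows = {}
    for term in terms.columns:
        x = terms[term].to_numpy()
        try:
            before = standardized_difference(x, z)
        except PropensityError:
            before = 0.0
        try:
            after = standardized_difference(x, z, w)
        except PropensityError:
            after = 0.0
        rows[term] = {
            "smd_before": before,
            "smd_after": after,
            "mean_female_weighted": float(np.sum(w[z == 1] * x[z == 1]) / np.sum(w[z == 1])),
            "mean_male_weighted": float(np.sum(w[z == 0] * x[z == 0]) / np.sum(w[z == 0])),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "term"
    return BalanceReport(table=table, overlap=overlap_coefficient(model.scores, model.group))


def weighted_feature_test(feature, group, weights) -> tuple[float, float, float]:
    """Weighted least squares of feature on the female indicator with HC0 SEs.

    For the intercept + indicator design this has the closed form
    beta = weighted female mean − weighted male mean and the sandwich
    variance Σ w²e²/(Σw)² summed over the two groups; identical to
    statsmodels WLS(...).fit(cov_type="HC0") on the same data.
    Returns (beta, se, two-sided normal p).
    """
    x = np.asarray(feature, dtype=float)
    z = np.asarray(group, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = ~np.isnan(x)
    x, z, w = x[keep], z[keep], w[keep]
    if x.size == 0 or np.unique(x).size < 2:
        raise PropensityError("feature untestable: <2 distinct values after dropping missing")
    if (z == 1).sum() == 0 or (z == 0).sum() == 0:
        raise PropensityError("both groups must be nonempty")
    var = 0.0
    means = {}
    for g in (0, 1):
        sel = z == g
        wsum = w[sel].sum()
        mu = np.sum(w[sel] * x[sel]) / wsum
        resid = x[sel] - mu
        var += np.sum((w[sel] * resid) ** 2) / wsum**2
        means[g] = mu
    beta = float(means[1] - means[0])
    se = float(math.sqrt(var))
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    return beta, se, p


def discrete_feature_test(indicator, group, weights=None) -> tuple[float, float]:
    """Fisher exact test on the 2×2 sex × indicator table.

    The exact test is unweighted; matching weights are accepted for
    interface symmetry and ignored (noted in the screen output's test tag).
    Returns (odds ratio, p).
    """
    x = np.asarray(indicator, dtype=float)
    z = np.asarray(group, dtype=float)
    keep = ~np.isnan(x)
    x, z = x[keep], z[keep]
    if not np.all(np.isin(x, [0.0, 1.0])):
        raise PropensityError("discrete feature must be a 0/1 indicator")
    table = [
        [int(np.sum((z == 1) & (x == 1))), int(np.sum((z == 1) & (x == 0)))],
        [int(np.sum((z == 0) & (x == 1))), int(np.sum((z == 0) & (x == 0)))],
    ]
    res = fisher_exact_2x2(table)
    odds = res.effect if res.effect is not None else math.nan
    return odds, res.p_value


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def sex_bias_screen(
    cohorts: Mapping[str, pd.DataFrame],
    features: Mapping[str, FeatureMatrix],
    covariates: Sequence[str],
    fdr_threshold: float = 0.2,
    min_per_group: int = 20,
    feature_families: Mapping[str, str] | None = None,
    continuous_test: str = "weighted-linear",
) -> tuple[list[ScreenResult], pd.DataFrame, dict[str, BalanceReport]]:
    """Run the full per-cancer-type screen.

    ``features`` maps cancer type → FeatureMatrix indexed by patient_id.
    ``feature_families`` assigns each feature to a BH-correction family
    (default: one family per cancer type). ``continuous_test`` selects the
    matching-weight linear test (default) or an unweighted
    Mann–Whitney–Wilcoxon comparison (``"mww"``, the convention for ICB
    cohorts analysed without propensity adjustment).

    Returns (results, summary ordered by female-minus-male significant
    counts, balance reports per cancer type). Per-cohort failures are
    logged and skipped; the screen continues.
    """
    if continuous_test not in ("weighted-linear", "mww"):
        raise ValueError(f"unknown continuous test {continuous_test!r}")
    usable = eligible_cohorts(cohorts, min_per_group)
    results: list[ScreenResult] = []
    balances: dict[str, BalanceReport] = {}
    for cancer_type, cohort in usable.items():
        fm = features.get(cancer_type)
        if fm is None:
            logger.warning("no feature matrix for %s; skipped", cancer_type)
            continue
        try:
            model = fit_propensity(cohort, covariates)
            weights = matching_weights(model)
            balances[cancer_type] = balance_report(cohort, model, weights)
        except PropensityError as exc:
            logger.warning("cohort %s failed: %s", cancer_type, exc)
            continue
        ids = model.scores.index
        vals = fm.values.reindex(ids)
        z = model.group.to_numpy()
        w = weights.to_numpy()
        partial: list[dict] = []
        for feat in vals.columns:
            x = vals[feat].to_numpy(dtype=float)
            try:
                if fm.is_discrete(feat):
                    odds, p = discrete_feature_test(x, z)
                    beta = math.log(odds) if odds not in (0.0, math.inf) and not math.isnan(odds) else math.nan
                    se = math.nan
                    test = "fisher"
                elif continuous_test == "mww":
                    keep = ~np.isnan(x)
                    res = mww_test(x[keep][z[keep] == 1], x[keep][z[keep] == 0])
                    med_f = float(np.nanmedian(x[z == 1]))
                    med_m = float(np.nanmedian(x[z == 0]))
                    beta, se, p, test = med_f - med_m, math.nan, res.p_value, "mww"
                else:
                    beta, se, p = weighted_feature_test(x, z, w)
                    test = "weighted-linear"
            except PropensityError as exc:
                logger.info("%s / %s untestable: %s", cancer_type, feat, exc)
                continue
            keep = ~np.isnan(x)
            partial.append(
                {
                    "feature": feat,
                    "beta": beta,
                    "se": se,
                    "p": p,
                    "test": test,
                    "n_female": int(np.sum(z[keep] == 1)),
                    "n_male": int(np.sum(z[keep] == 0)),
                    "family": (feature_families or {}).get(feat, "features"),
                }
            )
        # BH within each (cancer type, feature family)
        frame = pd.DataFrame(partial)
        if frame.empty:
            continue
        frame["fdr"] = np.nan
        for _, idx in frame.groupby("family").groups.items():
            frame.loc[idx, "fdr"] = bh_adjust(frame.loc[idx, "p"].to_numpy())
        for _, row in frame.iterrows():
            direction = "female-bias" if row["beta"] > 0 else "male-bias"
            band = significance_band(row["p"], "female" if row["beta"] > 0 else "male")
            results.append(
                ScreenResult(
                    cancer_type=cancer_type,
                    feature=row["feature"],
                    beta=float(row["beta"]),
                    se=float(row["se"]),
                    p_value=float(row["p"]),
                    fdr=float(row["fdr"]),
                    direction=direction,
                    band=band,
                    n_female=int(row["n_female"]),
                    n_male=int(row["n_male"]),
                    test=str(row["test"]),
                )
            )
    summary = summarize_screen(results, fdr_threshold)
    return results, summary, balances


def summarize_screen(results: Sequence[ScreenResult], fdr_threshold: float = 0.2) -> pd.DataFrame:
    """Per cancer type: significant female-biased minus male-biased counts,
    ordered descending (the ordering used for the screen's overview panel)."""
    rows: dict[str, list[int]] = {}
    for r in results:
        counts = rows.setdefault(r.cancer_type, [0, 0])
        if r.fdr < fdr_threshold and not math.isnan(r.fdr):
            if r.direction == "female-bias":
                counts[0] += 1
            else:
                counts[1] += 1
    summary = pd.DataFrame.from_dict(
        rows, orient="index", columns=["n_female_biased", "n_male_biased"]
    )
    summary.index.name = "cancer_type"
    summary["score"] = summary["n_female_biased"] - summary["n_male_biased"]
    return summary.sort_values("score", ascending=False)


def screen_to_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Long-format heatmap-ready table."""
    return pd.DataFrame([vars(r) for r in results])
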