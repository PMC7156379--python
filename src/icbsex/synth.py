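"""Generators for synthetic trial panels, confounded cohorts and expression.

Each generator draws every random quantity from a single seeded
``numpy.random.Generator`` and returns a *truth record* carrying the
generating parameters, so recovery can be scored without re-reading the
spec. Survival is exponential (constant hazard), which makes the true
hazard ratio exactly the specified ratio and turns Cox recovery into a
clean oracle; censoring is independent uniform over a horizon solved
numerically to hit the requested censoring fraction.

The generators are statistical stand-ins for the structures the analysis
assumes (sex confounded with covariates, features with known
post-adjustment sex effects, trial panels with a sex × treatment
interaction); they make no attempt to forge real cohort distributions or
gene–gene correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from icbsex.dataio import FeatureMatrix, GeneSet, TrialRecord
from icbsex.survstats import SurvivalError, cox_univariate


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# trial panels


@dataclass(frozen=True)
class TrialSimSpec:
    """Conditions for a simulated panel of two-arm ICB trials."""

    k: int = 30
    n_per_arm: int = 500
    base_hr: float = 0.8  # ICB vs control hazard ratio in males
    interaction: float = 1.0  # true female:male HR ratio, exp(mu)
    censoring_rate: float = 0.3
    tau: float = 0.0  # between-trial SD of the log interaction
    baseline_rate: float = 0.1  # control-arm event hazard per unit time
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.n_per_arm < 4:
            raise SimulationError("k >= 1 and n_per_arm >= 4 required")
        if min(self.base_hr, self.interaction, self.baseline_rate) <= 0:
            raise SimulationError("hazard parameters must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise SimulationError("censoring_rate must be in [0,1)")
        if self.tau < 0:
            raise SimulationError("tau must be nonnegative")


def _censoring_horizon(rates: np.ndarray, target: float) -> float:
    """Horizon H for C ~ U(0,H) achieving the target mean censoring fraction.

    For an exponential T with rate λ, P(C < T) = (1 − e^{−λH}) / (λH);
    averaged over the hazard cells and solved by bisection.
    """

    def frac(h: float) -> float:
        lh = rates * h
        return float(np.mean((1.0 - np.exp(-lh)) / lh))

    return brentq(lambda h: frac(h) - target, 1e-9, 1e9, xtol=1e-10, rtol=1e-12)


def _simulate_one_trial(
    rng: np.random.Generator,
    trial_id: str,
    delta: float,
    n_per_arm: int,
    base_hr: float,
    censoring_rate: float,
    baseline_rate: float,
    cancer_type: str = "synthetic",
    therapy_class: str = "anti-PD-1/PD-L1",
    control_arm: str = "chemotherapy",
    max_retries: int = 10,
) -> TrialRecord:
    """One trial: exponential survival per arm × sex, per-sex Cox fits."""
    lam0 = baseline_rate
    hr_f_true = base_hr * math.exp(delta)
    for _ in range(max_retries):
        n = 2 * n_per_arm
        arm = np.repeat([0, 1], n_per_arm)  # 1 = ICB
        female = rng.random(n) < 0.5
        rate = np.where(
            arm == 1, np.where(female, lam0 * hr_f_true, lam0 * base_hr), lam0
        )
        t_event = rng.exponential(1.0 / rate)
        if censoring_rate > 0:
            horizon = _censoring_horizon(np.unique(rate), censoring_rate)
            t_cens = rng.uniform(0.0, horizon, size=n)
            time = np.minimum(t_event, t_cens)
            event = (t_event <= t_cens).astype(float)
        else:
            time, event = t_event, np.ones(n)
        ok = True
        for sex_mask in (female, ~female):
            for a in (0, 1):
                if event[sex_mask & (arm == a)].sum() < 2:
                    ok = False
        if not ok:
            continue
        try:
            fit_f = cox_univariate(time[female], event[female], arm[female])
            fit_m = cox_univariate(time[~female], event[~female], arm[~female])
        except SurvivalError:
            continue
        return TrialRecord(
            trial_id=trial_id,
            cancer_type=cancer_type,
            therapy_class=therapy_class,
            control_arm=control_arm,
            hr_female=fit_f.hr,
            ci_female_lo=fit_f.ci_lo,
            ci_female_hi=fit_f.ci_hi,
            hr_male=fit_m.hr,
            ci_male_lo=fit_m.ci_lo,
            ci_male_hi=fit_m.ci_hi,
            n_female=int(female.sum()),
            n_male=int((~female).sum()),
        )
    raise SimulationError(f"trial {trial_id}: too few events after {max_retries} retries")


def simulate_trials(spec: TrialSimSpec) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Simulate a panel of trials under a random-effects interaction model.

    Each trial's log interaction is drawn Normal(ln(interaction), tau²);
    the truth record carries the drawn per-trial values.
    """
    rng = np.random.default_rng(spec.seed)
    mu = math.log(spec.interaction)
    records = []
    truths = []
    for i in range(spec.k):
        delta = float(rng.normal(mu, spec.tau))
        rec = _simulate_one_trial(
            rng,
            trial_id=f"trial_{i + 1:02d}",
            delta=delta,
            n_per_arm=spec.n_per_arm,
            base_hr=spec.base_hr,
            censoring_rate=spec.censoring_rate,
            baseline_rate=spec.baseline_rate,
        )
        records.append(rec)
        truths.append({"trial_id": rec.trial_id, "delta_true": delta})
    truth = pd.DataFrame(truths)
    truth.attrs.update({"mu_true": mu, "tau_true": spec.tau})
    return records, truth


# fixed composition of the published 27-trial ICB panel: cancer type,
# therapy class, control arm, and which sex each trial's point estimate
# favored (+1 male advantage, -1 female advantage)
_PANEL_LAYOUT: list[tuple[str, str, str, int]] = [
    # 7 melanoma trials, 6 favoring males
    ("melanoma", "anti-CTLA-4", "gp100-vaccine", +1),
    ("melanoma", "anti-CTLA-4", "placebo", +1),
    ("melanoma", "anti-CTLA-4", "dacarbazine", +1),
    ("melanoma", "anti-PD-1/PD-L1", "chemotherapy", +1),
    ("melanoma", "anti-PD-1/PD-L1", "ipilimumab", +1),
    ("melanoma", "anti-PD-1/PD-L1", "ipilimumab", +1),
    ("melanoma", "combination", "ipilimumab", -1),
    # 11 NSCLC trials, 6 male / 5 female
    ("NSCLC", "anti-PD-1/PD-L1", "docetaxel", +1),
    ("NSCLC", "anti-PD-1/PD-L1", "docetaxel", +1),
    ("NSCLC", "anti-PD-1/PD-L1", "docetaxel", +1),
    ("NSCLC", "anti-PD-1/PD-L1", "docetaxel", -1),
    ("NSCLC", "anti-PD-1/PD-L1", "docetaxel", -1),
    ("NSCLC", "anti-PD-1/PD-L1", "chemotherapy", +1),
    ("NSCLC", "anti-PD-1/PD-L1", "chemotherapy", +1),
    ("NSCLC", "anti-PD-1/PD-L1", "chemotherapy", -1),
    ("NSCLC", "anti-PD-1/PD-L1", "chemotherapy", -1),
    ("NSCLC", "anti-CTLA-4", "placebo", +1),
    ("NSCLC", "combination", "chemotherapy", -1),
    # 2 SCLC
    ("SCLC", "anti-CTLA-4", "placebo", +1),
    ("SCLC", "combination", "chemotherapy", -1),
    # 2 HNSC
    ("HNSC", "anti-PD-1/PD-L1", "chemotherapy", +1),
    ("HNSC", "anti-PD-1/PD-L1", "chemotherapy", -1),
    # 2 ccRCC
    ("ccRCC", "anti-PD-1/PD-L1", "everolimus", -1),
    ("ccRCC", "combination", "sunitinib", +1),
    # 1 each: mesothelioma, urothelial, GEJC
    ("mesothelioma", "anti-CTLA-4", "placebo", +1),
    ("urothelial", "anti-PD-1/PD-L1", "chemotherapy", +1),
    ("GEJC", "anti-PD-1/PD-L1", "chemotherapy", -1),
]

PANEL_SEED = 20200414  # frozen: the panel is a fixed synthetic input table


def synthetic_trial_panel(seed: int = PANEL_SEED) -> list[TrialRecord]:
    """A deterministic SYNTHETIC stand-in for the published 27-trial panel.

    The composition mirrors what is public about the panel — 27 ICB trials
    (7 melanoma, 11 NSCLC, 2 SCLC, 2 HNSC, 2 ccRCC, 1 each mesothelioma /
    urothelial / GEJC), 5 docetaxel-control and 4 placebo-control trials,
    and per-trial interaction directions (melanoma 6-of-7 male-advantage,
    NSCLC 6 male vs 5 female) — but every hazard ratio is simulated, so the
    pooled estimates are NOT the published ones. Intended as a realistic
    fixture for exercising and cross-checking the deft pipeline.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i, (cancer, therapy, control, sign) in enumerate(_PANEL_LAYOUT):
        delta = 0.6 * sign
        records.append(
            _simulate_one_trial(
                rng,
                trial_id=f"{cancer}_{i + 1:02d}",
                delta=delta,
                n_per_arm=400,
                base_hr=0.75,
                censoring_rate=0.3,
                baseline_rate=0.1,
                cancer_type=cancer,
                therapy_class=therapy,
                control_arm=control,
            )
        )
    return records


# ---------------------------------------------------------------------------
# confounded cohorts


@dataclass(frozen=True)
class CohortSimSpec:
    """Conditions for one confounded observational cohort.

    ``confounder_effects`` maps covariate terms to effects on the female
    log-odds: plain names (``"age"``, ``"purity"``) act on the standardized
    continuous covariate, ``"cov=level"`` keys act on a category indicator.
    ``feature_effects`` maps feature name → (sex_effect, loadings, noise_sd)
    where loadings reuse the same term syntax.
    """

    n: int = 400
    female_fraction: float = 0.5
    confounder_effects: Mapping[str, float] = field(default_factory=dict)
    feature_effects: Mapping[str, tuple[float, Mapping[str, float], float]] = field(
        default_factory=dict
    )
    survival: tuple[float, float] = (0.05, 0.0)  # (baseline rate, sex log-HR)
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise SimulationError("n >= 4 required")
        if not (0 < self.female_fraction < 1):
            raise SimulationError("female_fraction must be in (0,1)")


_CATEGORICALS = {
    "race": (["white", "black", "asian"], [0.70, 0.15, 0.15]),
    "smoking": (["never", "former", "current"], [0.40, 0.35, 0.25]),
    "stage": (["I", "II", "III", "IV"], [0.30, 0.30, 0.25, 0.15]),
    "histology": (["type_a", "type_b", "type_c"], [0.50, 0.30, 0.20]),
}


def _covariate_term(cov_frame: pd.DataFrame, term: str) -> np.ndarray:
    if "=" in term:
        cov, level = term.split("=", 1)
        if cov not in cov_frame.columns:
            raise SimulationError(f"unknown covariate in term {term!r}")
        return (cov_frame[cov] == level).to_numpy(dtype=float)
    if term not in cov_frame.columns:
        raise SimulationError(f"unknown covariate {term!r}")
    x = cov_frame[term].to_numpy(dtype=float)
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_cohort(
    spec: CohortSimSpec,
) -> tuple[pd.DataFrame, FeatureMatrix, dict]:
    """One cohort: covariates, sex confounded with them, features, survival.

    Age is Normal(60, 10), purity Beta(5, 2); race, smoking, stage and
    histology are fixed multinomials. Sex is drawn from a logistic model on
    the covariates with intercept logit(female_fraction), so zero
    confounder effects give scores near the female prevalence. Features are
    linear in the sex indicator and covariate terms with Gaussian noise;
    survival is exponential with the given sex log-HR.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    cov = pd.DataFrame(
        {
            "age": rng.normal(60.0, 10.0, n),
            "purity": rng.beta(5.0, 2.0, n),
        }
    )
    for name, (levels, probs) in _CATEGORICALS.items():
        cov[name] = rng.choice(levels, size=n, p=probs)

    lp = np.full(n, math.log(spec.female_fraction / (1 - spec.female_fraction)))
    for term, effect in spec.confounder_effects.items():
        lp += effect * _covariate_term(cov, term)
    z = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
    if z.sum() < 2 or (1 - z).sum() < 2:
        raise SimulationError("degenerate cohort: fewer than 2 patients of one sex")

    base_rate, sex_log_hr = spec.survival
    rate = base_rate * np.exp(sex_log_hr * z)
    t_event = rng.exponential(1.0 / rate)
    if spec.censoring_rate > 0:
        horizon = _censoring_horizon(np.unique(rate), spec.censoring_rate)
        t_cens = rng.uniform(0.0, horizon, n)
        os_time = np.minimum(t_event, t_cens)
        os_event = (t_event <= t_cens).astype(int)
    else:
        os_time, os_event = t_event, np.ones(n, dtype=int)

    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "sex": np.where(z == 1, "female", "male"),
            "os_time": os_time,
            "os_event": os_event,
        }
    )
    cohort = pd.concat([cohort, cov], axis=1)

    feats = {}
    for name, (sex_effect, loadings, noise_sd) in spec.feature_effects.items():
        x = sex_effect * z.astype(float) + rng.normal(0.0, noise_sd, n)
        for term, loading in loadings.items():
            x += loading * _covariate_term(cov, term)
        feats[name] = x
    features = FeatureMatrix(
        values=pd.DataFrame(feats, index=pd.Index(cohort["patient_id"], name="patient_id"))
    )
    truth = {
        "female_fraction": spec.female_fraction,
        "confounder_effects": dict(spec.confounder_effects),
        "feature_sex_effects": {k: v[0] for k, v in spec.feature_effects.items()},
        "survival": spec.survival,
        "seed": spec.seed,
    }
    return cohort, features, truth


def default_cohort_spec(
    seed: int,
    n: int = 400,
    n_null: int = 45,
    n_signal: int = 5,
    sex_effect: float = 0.5,
    confounding: float = 0.5,
    confounder_loading: float = 0.5,
) -> CohortSimSpec:
    """The study conditions used throughout the tests: a cohort of 400 with
    sex–age confounding (age raises the female log-odds by ``confounding``
    per SD), null features that load on age, and a handful of features with
    a genuine half-SD post-adjustment female shift."""
    feature_effects: dict[str, tuple[float, dict[str, float], float]] = {}
    for i in range(n_null):
        feature_effects[f"null_{i + 1:02d}"] = (0.0, {"age": confounder_loading}, 1.0)
    for i in range(n_signal):
        feature_effects[f"signal_{i + 1:02d}"] = (
            sex_effect,
            {"age": confounder_loading},
            1.0,
        )
    return CohortSimSpec(
        n=n,
        female_fraction=0.5,
        confounder_effects={"age": confounding, "smoking=current": -0.5},
        feature_effects=feature_effects,
        survival=(0.05, 0.0),
        censoring_rate=0.3,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# expression matrices


def make_gene_sets(
    n_sets: int,
    set_size: int,
    universe: Sequence[str],
    seed: int = 0,
    disjoint: bool = True,
) -> list[GeneSet]:
    """Random gene sets over a gene universe (disjoint by default)."""
    rng = np.random.default_rng(seed)
    if disjoint and n_sets * set_size > len(universe):
        raise SimulationError("universe too small for disjoint sets")
    pool = list(universe)
    rng.shuffle(pool)
    sets = []
    for i in range(n_sets):
        if disjoint:
            genes = pool[i * set_size : (i + 1) * set_size]
        else:
            genes = list(rng.choice(pool, size=set_size, replace=False))
        sets.append(
            GeneSet(name=f"set_{i + 1:02d}", description="synthetic", genes=tuple(genes))
        )
    return sets


def simulate_expression(
    n_genes: int,
    n_samples: int,
    sets: Sequence[GeneSet],
    shift: float,
    target_samples: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Log-normal expression with gene sets up-shifted in target samples.

    Baseline log-expression is Normal(mu_g, 1) with gene means mu_g drawn
    Normal(3, 1); ``shift`` is added on the log scale for in-set genes in
    the target samples, once per set membership (additive when sets
    overlap). Returns (genes × samples matrix, truth record).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    gene_index = {g: i for i, g in enumerate(genes)}
    for s in sets:
        missing = [g for g in s.genes if g not in gene_index]
        if missing:
            raise SimulationError(f"set {s.name}: genes outside universe: {missing[:3]}")
    if target_samples is None:
        target_samples = samples[: n_samples // 2]
    unknown = [s for s in target_samples if s not in samples]
    if unknown:
        raise SimulationError(f"unknown target samples: {unknown[:3]}")

    mu = rng.normal(3.0, 1.0, n_genes)
    log_expr = rng.normal(mu[:, None], 1.0, (n_genes, n_samples))
    target_mask = np.isin(samples, list(target_samples))
    for s in sets:
        rows = [gene_index[g] for g in s.genes]
        log_expr[np.ix_(rows, np.flatnonzero(target_mask))] += shift
    expr = pd.DataFrame(np.exp(log_expr), index=genes, columns=samples)
    truth = {
        "shift": shift,
        "target_samples": list(target_samples),
        "sets": {s.name: list(s.genes) for s in sets},
        "seed": seed,
    }
    return expr, truth
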