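"""Synthetic patient-level cohort generator.

The published study deposited no patient-level data, so this module generates
cohorts with the statistical structure the analysis assumes: the observed
marginal frequencies, and cross-variable dependence induced by a single
latent severity variable.

Generative model (per patient):

1. ``occupational_exposure ~ Bernoulli(p_exposure)``;
2. latent severity ``z ~ Normal(beta_exp * exposure, 1)``;
3. each severity-linked binary trait (advanced TNM stage, PD-L1 positivity,
   p63 positivity, presence of any comorbidity, aggressive histology) is
   ``Bernoulli(logistic(gamma0_j + gamma1_j * z))``;
4. EGFR mutation is an independent ``Bernoulli(p_egfr)`` with a fixed exon
   split; when mutated, the PD-L1 logit is reduced by a coupling constant,
   reproducing the observed inverse EGFR/PD-L1 relationship;
5. conditional splits turn the binary traits into full categories (stage IV
   vs III given advanced, specific comorbidity, specific histological group);
6. sex, residence and smoking are independent draws from their marginals;
   age is truncated normal; Ki-67 is truncated normal (loosely constrained).

Default intercepts are version-pinned constants obtained once by
Gauss-Hermite moment matching so that, at the default slope, every marginal
hits its target frequency; they are not re-fit at runtime
(:func:`calibrate_intercept` reproduces them).  Everything is reproducible
from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import Cohort, PatientRecord

__all__ = [
    "GeneratorConfig",
    "default_config",
    "independence_config",
    "generate_cohort",
    "calibrate_intercept",
]

#: Severity-linked binary traits, in generation order.
SEVERITY_COMPONENTS: tuple[str, ...] = (
    "advanced_stage",
    "pdl1_positive",
    "p63_positive",
    "has_comorbidity",
    "aggressive_histology",
)

#: Marginal target frequencies (study cohort, n = 131).
_TARGETS: dict[str, float] = {
    "advanced_stage": 120 / 131,       # TNM III or IV
    "pdl1_positive": 0.598,            # among EGFR wild-type patients
    "p63_positive": 84 / 131,
    "has_comorbidity": 108 / 131,
    "aggressive_histology": 57 / 131,  # small-cell or neuroendocrine
}

#: Intercepts pinned from one-off moment matching at slope 0.7,
#: exposure effect 1.0, exposure probability 75/131.
_PINNED_INTERCEPTS: dict[str, float] = {
    "advanced_stage": 2.231754,
    "pdl1_positive": 0.049163,
    "p63_positive": 0.256624,
    "has_comorbidity": 1.329256,
    "aggressive_histology": -0.697852,
}

_DEFAULT_SLOPE = 0.7
_DEFAULT_BETA_EXP = 1.0
#: logit(0.598) - logit(0.263): PD-L1 positivity drop for EGFR-mutated patients.
_DEFAULT_COUPLING = 1.42757


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the generator; defaults emulate the 131-patient cohort."""

    n: int = 131
    seed: int = 0
    # independent marginals
    p_male: float = 78 / 131
    p_urban: float = 77 / 131
    p_smoker: float = 90 / 131
    p_exposure: float = 75 / 131
    p_egfr_mutated: float = 19 / 131
    #: exon probabilities given a mutation (19, 21, 20, 18).
    egfr_exon_split: tuple[float, ...] = (9 / 19, 5 / 19, 3 / 19, 2 / 19)
    #: per-component (intercept, slope) on the latent severity.
    severity_links: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            k: (_PINNED_INTERCEPTS[k], _DEFAULT_SLOPE) for k in SEVERITY_COMPONENTS
        }
    )
    exposure_effect: float = _DEFAULT_BETA_EXP
    egfr_pdl1_coupling: float = _DEFAULT_COUPLING
    #: stage IV probability given advanced disease (89/120); non-advanced is II.
    p_stage4_given_advanced: float = 89 / 120
    #: small-cell probability given aggressive histology (else neuroendocrine).
    p_smallcell_given_aggressive: float = 30 / 57
    #: adenocarcinoma probability given non-aggressive (else squamous).
    p_adeno_given_nonaggressive: float = 45 / 74
    #: comorbidity type split given any comorbidity (asthma, copd, heart, diabetes).
    comorbidity_split: tuple[float, ...] = (8 / 108, 48 / 108, 29 / 108, 23 / 108)
    #: (mean, sd, lower, upper) truncated normal, years.
    age_model: tuple[float, float, float, float] = (62.82, 12.67, 40.0, 85.0)
    #: (mean, sd, lower, upper) truncated normal, percent; loosely constrained.
    ki67_model: tuple[float, float, float, float] = (60.0, 25.0, 1.0, 99.0)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        for name in ("p_male", "p_urban", "p_smoker", "p_exposure", "p_egfr_mutated"):
            p = getattr(self, name)
            if not 0 < p < 1:
                raise ValueError(f"{name}={p} outside (0, 1)")
        for split_name in ("egfr_exon_split", "comorbidity_split"):
            split = getattr(self, split_name)
            if abs(sum(split) - 1.0) > 1e-9 or min(split) < 0:
                raise ValueError(f"{split_name} must be a probability vector")
        missing = set(SEVERITY_COMPONENTS) - set(self.severity_links)
        if missing:
            raise ValueError(f"severity_links missing components: {sorted(missing)}")


def default_config(n: int = 131, seed: int = 0) -> GeneratorConfig:
    """The study conditions: published marginals plus latent-severity links."""
    return GeneratorConfig(n=n, seed=seed)


def independence_config(n: int = 131, seed: int = 0) -> GeneratorConfig:
    """All severity slopes, the exposure effect and the EGFR/PD-L1 coupling
    set to zero, with intercepts reset so marginals stay on target — every
    pair of variables is independent.  Used for type-I-error calibration."""
    links = {k: (float(logit(_TARGETS[k])), 0.0) for k in SEVERITY_COMPONENTS}
    return GeneratorConfig(
        n=n,
        seed=seed,
        severity_links=links,
        exposure_effect=0.0,
        egfr_pdl1_coupling=0.0,
    )


def calibrate_intercept(
    target: float,
    slope: float,
    exposure_effect: float,
    p_exposure: float,
    n_nodes: int = 61,
) -> float:
    """Intercept gamma0 such that E[logistic(gamma0 + slope * z)] = target,
    where z is the latent-severity mixture N(0,1)/N(exposure_effect,1) with
    mixing weight ``p_exposure``.  Deterministic Gauss-Hermite quadrature;
    used once to pin the default constants."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    weights = weights / weights.sum()

    def marginal(g0: float) -> float:
        p0 = float(expit(g0 + slope * nodes) @ weights)
        p1 = float(expit(g0 + slope * (nodes + exposure_effect)) @ weights)
        return (1 - p_exposure) * p0 + p_exposure * p1

    return float(brentq(lambda g: marginal(g) - target, -30.0, 30.0))


def _truncnorm(rng, mean, sd, lower, upper, size):
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    config: GeneratorConfig | None = None, return_latent: bool = False
):
    """Generate a synthetic cohort; byte-identical given the same config/seed.

    With ``return_latent=True`` also returns the latent severity draws
    (useful for parameter-recovery studies: refitting the logistic links
    against the returned z should recover the configured slopes).
    """
    cfg = config or default_config()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    exposure = rng.random(n) < cfg.p_exposure
    z = rng.normal(cfg.exposure_effect * exposure, 1.0)

    def link(component: str, offset: np.ndarray | float = 0.0) -> np.ndarray:
        g0, g1 = cfg.severity_links[component]
        p = expit(g0 + g1 * z + offset)
        return rng.random(n) < p

    advanced = link("advanced_stage")
    p63 = link("p63_positive")
    comorbid = link("has_comorbidity")
    aggressive = link("aggressive_histology")

    egfr_mut = rng.random(n) < cfg.p_egfr_mutated
    exon_labels = np.array(["exon19", "exon21", "exon20", "exon18"])
    exons = exon_labels[rng.choice(4, size=n, p=list(cfg.egfr_exon_split))]
    egfr = np.where(egfr_mut, exons, "none")

    pdl1 = link("pdl1_positive", offset=np.where(egfr_mut, -cfg.egfr_pdl1_coupling, 0.0))

    stage = np.where(
        advanced,
        np.where(rng.random(n) < cfg.p_stage4_given_advanced, "IV", "III"),
        "II",
    )
    group = np.where(
        aggressive,
        np.where(rng.random(n) < cfg.p_smallcell_given_aggressive, "G2", "G3"),
        np.where(rng.random(n) < cfg.p_adeno_given_nonaggressive, "G1a", "G1b"),
    )
    comorbidity_labels = np.array(["asthma", "copd", "heart_disease", "diabetes"])
    comorbidity_type = comorbidity_labels[
        rng.choice(4, size=n, p=list(cfg.comorbidity_split))
    ]
    comorbidity = np.where(comorbid, comorbidity_type, "none")

    sex = np.where(rng.random(n) < cfg.p_male, "male", "female")
    residence = np.where(rng.random(n) < cfg.p_urban, "urban", "rural")
    smoker = np.where(rng.random(n) < cfg.p_smoker, "yes", "no")
    ages = np.rint(_truncnorm(rng, *cfg.age_model, n)).astype(int)
    ki67 = np.round(_truncnorm(rng, *cfg.ki67_model, n), 1)

    width = max(3, int(math.log10(n)) + 1)
    records = [
        PatientRecord(
            patient_id=f"SYN{i:0{width}d}",
            sex=str(sex[i]),
            residence=str(residence[i]),
            smoker=str(smoker[i]),
            comorbidity=str(comorbidity[i]),
            occupational_exposure="yes" if exposure[i] else "no",
            diagnostic_group=str(group[i]),
            tnm_stage=str(stage[i]),
            p63="positive" if p63[i] else "negative",
            pdl1="positive" if pdl1[i] else "negative",
            egfr=str(egfr[i]),
            age_years=int(ages[i]),
            ki67_percent=float(ki67[i]),
        )
        for i in range(n)
    ]
    cohort = Cohort(records)
    if return_latent:
        return cohort, z
    return cohort
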