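"""Synthetic longitudinal dementia cohorts with planted drug-response heterogeneity.

The generator emulates the structure of routinely collected memory-clinic
records: MMSE/MoCA scores on the 0-30 scale, irregular visit spacing,
four-drug prescriptions dominated by donepezil, and heavy "not available"
levels in the categorical demographics.  On top of that structure it plants a
per-patient best drug — a latent 4-vector of decline-slowing effects
(points/year) determined by patient covariates — which gives downstream
recommendation code a ground truth that real observational data cannot
provide.

Each record starts at first contact, optionally with a short run of
pre-initiation visits (no drug prescribed, decline at the untreated base
rate), then the initiation visit and on-drug follow-ups.  Post-initiation::

    score(t) = score(t_init) - (base_decline - effect[assigned drug]) * max(0, t - t_init - plateau) + noise

with scores clamped to [0, 30] and (by default) rounded to integers, both
scales being integer 0-30 instruments.  The plateau term emulates the
3-6 month post-initiation stabilisation seen in real trajectories; the
pre-initiation visits mirror records that begin before the first
prescription and keep the prediction-time drug input identifiable (the
assigned drug is otherwise constant across a patient's record).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "DRUGS",
    "SEX_LEVELS",
    "ETHNICITY_LEVELS",
    "MARITAL_LEVELS",
    "CohortConfig",
    "CohortConfigError",
    "DrugResponseProfile",
    "Patient",
    "Visit",
    "simulate_cohort",
    "planted_best_drug",
    "profiles_to_frame",
    "profiles_from_frame",
]

#: Canonical drug order; every 4-vector in the package uses it and all
#: argmax tie-breaks resolve to the earliest drug in this tuple.
DRUGS: tuple[str, ...] = ("donepezil", "galantamine", "rivastigmine", "memantine")

SEX_LEVELS: tuple[str, ...] = ("M", "F")
ETHNICITY_LEVELS: tuple[str, ...] = ("white", "Asian", "black", "other", "not_available")
MARITAL_LEVELS: tuple[str, ...] = ("married", "separated", "single", "widowed", "not_available")

#: Conditional level frequencies for observed (non-missing) categoricals,
#: patterned on a UK memory-clinic case mix.
_ETHNICITY_OBSERVED_PROBS = (0.96, 0.015, 0.01, 0.015)
_MARITAL_OBSERVED_PROBS = (0.565, 0.058, 0.041, 0.336)
_MALE_FRACTION = 0.40


class CohortConfigError(ValueError):
    """Raised for invalid simulator configurations."""


@dataclass(frozen=True)
class DrugResponseProfile:
    """Latent per-patient decline-slowing effect (points/year) per drug."""

    patient_id: str
    effects: tuple[float, float, float, float]


@dataclass(frozen=True)
class Patient:
    id: str
    sex: str
    ethnicity: str
    marital_status: str
    birth_offset: float  # age in years at first contact


@dataclass(frozen=True)
class Visit:
    time: float  # years from first contact
    age: float
    scale_kind: str
    score: float | None
    drug: str  # one of DRUGS or "none"
    duration: float  # years since previous visit, 0 at first visit


@dataclass
class CohortConfig:
    """All knobs of the cohort generator.

    Defaults reproduce the case mix of a large single-scale memory-clinic
    cohort: MMSE baseline 21.1 [5.41], age 80.5 [7.6] within the 59-102
    inclusion window, ~20%/25% missing ethnicity/marital status, and a
    prescription policy skewed towards donepezil.
    """

    n_patients: int = 500
    age_mean: float = 80.5
    age_sd: float = 7.6
    age_range: tuple[float, float] = (59.0, 102.0)
    scale_kind: str = "MMSE"
    baseline_score_mean: float = 21.1
    baseline_score_sd: float = 5.41
    base_decline_rate_mean: float = 1.5  # points/year without treatment
    base_decline_rate_sd: float = 0.6
    drug_effect_rule: str = "sex_severity"
    base_drug_effect: float = 0.5  # points/year of decline-slowing shared by all drugs
    heterogeneity: float = 2.0  # extra decline-slowing of each patient's preferred drug
    noise_sd: float = 1.5
    plateau_years: float = 0.5  # post-initiation stabilisation window
    visit_interval_mean: float = 0.55  # years; intervals are log-normal (right-skewed)
    visit_interval_sigma: float = 0.6  # log-scale spread of intervals
    n_visits_range: tuple[int, int] = (2, 6)  # on-drug visits (initiation + follow-ups)
    n_pre_visits_probs: tuple[float, ...] = (0.3, 0.4, 0.3)  # P(0, 1, 2, ... pre-initiation visits)
    missingness_rates: dict = field(
        default_factory=lambda: {"ethnicity": 0.20, "marital_status": 0.25}
    )
    drug_assignment_probs: tuple[float, float, float, float] = (0.6, 0.15, 0.15, 0.1)
    confounded_assignment: bool = False
    integer_scores: bool = True
    horizon_years: float | None = None
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.age_range
        if not (59.0 <= lo < hi <= 102.0):
            raise CohortConfigError("age_range must lie within the 59-102 inclusion window")
        if self.scale_kind not in ("MMSE", "MoCA"):
            raise CohortConfigError(f"unknown scale_kind {self.scale_kind!r}")
        probs = np.asarray(self.drug_assignment_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or (probs > 1).any():
            raise CohortConfigError("drug_assignment_probs must be four probabilities")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise CohortConfigError("drug_assignment_probs must sum to 1")
        for name in ("age_sd", "baseline_score_sd", "base_decline_rate_sd", "noise_sd",
                     "base_drug_effect", "visit_interval_sigma"):
            if getattr(self, name) < 0:
                raise CohortConfigError(f"{name} must be non-negative")
        if self.heterogeneity < 0:
            raise CohortConfigError("heterogeneity must be >= 0")
        for fname, rate in self.missingness_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise CohortConfigError(f"missingness rate for {fname} outside [0,1]")
        if self.n_patients < 1:
            raise CohortConfigError("n_patients must be >= 1")
        nmin, nmax = self.n_visits_range
        if not (1 <= nmin <= nmax):
            raise CohortConfigError("invalid n_visits_range")
        if self.visit_interval_mean <= 0:
            raise CohortConfigError("visit_interval_mean must be positive")
        pre = np.asarray(self.n_pre_visits_probs, dtype=float)
        if (pre < 0).any() or abs(pre.sum() - 1.0) > 1e-12:
            raise CohortConfigError("n_pre_visits_probs must be a probability vector")
        if self.drug_effect_rule not in _EFFECT_RULES:
            raise CohortConfigError(
                f"unknown drug_effect_rule {self.drug_effect_rule!r}; "
                f"valid: {sorted(_EFFECT_RULES)}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("age_range", "drug_assignment_probs", "n_pre_visits_probs"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "n_visits_range" in d:
            d["n_visits_range"] = tuple(int(v) for v in d["n_visits_range"])
        return cls(**d)


def planted_best_drug(profile: DrugResponseProfile) -> str:
    """Ground-truth best drug: argmax of effects, canonical-order tie-break."""
    effects = np.asarray(profile.effects, dtype=float)
    if not np.all(np.isfinite(effects)):
        raise ValueError(f"non-finite effects for patient {profile.patient_id}")
    return DRUGS[int(np.argmax(effects))]  # argmax takes the first maximum


# ---------------------------------------------------------------------------
# drug-effect rules: (config, latents) -> 4-vector of decline-slowing
# ---------------------------------------------------------------------------

def _rule_sex_severity(config: CohortConfig, latents: dict) -> np.ndarray:
    """Preferred drug depends on sex and baseline severity.

    Four strata — (F, mild) -> donepezil, (F, severe) -> galantamine,
    (M, mild) -> rivastigmine, (M, severe) -> memantine — each stratum's
    preferred drug gains ``heterogeneity`` extra points/year of
    decline-slowing over the shared base effect.  Sex and score level are
    exactly the effect modifiers a recommender can see at treatment
    initiation, and memantine preferring the more severely impaired mirrors
    its real-world moderate-to-severe indication.
    """
    severe = latents["baseline"] < config.baseline_score_mean
    male = latents["sex"] == "M"
    preferred = 2 * int(male) + int(severe)
    effects = np.full(4, config.base_drug_effect, dtype=float)
    effects[preferred] += config.heterogeneity
    return effects


def _rule_severity_progression(config: CohortConfig, latents: dict) -> np.ndarray:
    """Preferred drug depends on baseline severity and decline speed.

    Like the sex/severity rule but with the speed of untreated decline as
    the second stratum factor — (slow, mild) -> donepezil, (slow, severe) ->
    galantamine, (fast, mild) -> rivastigmine, (fast, severe) -> memantine.
    Decline speed is only expressed through the longitudinal score sequence,
    so this rule makes recovery genuinely depend on the visit history (and
    is accordingly much harder when recommending at the initiation visit).
    """
    severe = latents["baseline"] < config.baseline_score_mean
    fast = latents["decline_rate"] > config.base_decline_rate_mean
    preferred = 2 * int(fast) + int(severe)
    effects = np.full(4, config.base_drug_effect, dtype=float)
    effects[preferred] += config.heterogeneity
    return effects


def _rule_uniform(config: CohortConfig, latents: dict) -> np.ndarray:
    """All four drugs equally effective (degenerate null rule)."""
    return np.full(4, config.base_drug_effect, dtype=float)


_EFFECT_RULES: dict[str, Callable[[CohortConfig, dict], np.ndarray]] = {
    "sex_severity": _rule_sex_severity,
    "severity_progression": _rule_severity_progression,
    "uniform": _rule_uniform,
}


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, list[DrugResponseProfile]]:
    """Draw a cohort table (one row per visit) plus ground-truth profiles.

    Deterministic given ``config`` (including its seed).  Columns:
    patient_id, visit_time, age, sex, ethnicity, marital_status, scale_kind,
    score, drug, duration.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rule = _EFFECT_RULES[config.drug_effect_rule]
    probs = np.asarray(config.drug_assignment_probs, dtype=float)
    probs = probs / probs.sum()

    rows: list[dict] = []
    profiles: list[DrugResponseProfile] = []
    n_digits = max(4, len(str(config.n_patients)))
    for i in range(config.n_patients):
        pid = f"P{i:0{n_digits}d}"
        age0 = _truncated_normal(rng, config.age_mean, config.age_sd, *config.age_range)
        sex = "M" if rng.random() < _MALE_FRACTION else "F"
        ethnicity = str(rng.choice(ETHNICITY_LEVELS[:4], p=_ETHNICITY_OBSERVED_PROBS))
        marital = str(rng.choice(MARITAL_LEVELS[:4], p=_MARITAL_OBSERVED_PROBS))
        if rng.random() < config.missingness_rates.get("ethnicity", 0.0):
            ethnicity = "not_available"
        if rng.random() < config.missingness_rates.get("marital_status", 0.0):
            marital = "not_available"

        baseline = float(np.clip(
            rng.normal(config.baseline_score_mean, config.baseline_score_sd), 0.0, 30.0))
        decline_rate = max(0.0, rng.normal(config.base_decline_rate_mean,
                                           config.base_decline_rate_sd))
        effects = rule(config, {"baseline": baseline, "decline_rate": decline_rate, "sex": sex})
        profiles.append(DrugResponseProfile(pid, tuple(float(e) for e in effects)))

        if config.confounded_assignment:
            pref = int(np.argmax(effects))
            p = 0.5 * probs + 0.5 * np.eye(4)[pref]
        else:
            p = probs
        drug = DRUGS[int(rng.choice(4, p=p))]
        net_decline = decline_rate - effects[DRUGS.index(drug)]

        n_pre = int(rng.choice(len(config.n_pre_visits_probs),
                               p=np.asarray(config.n_pre_visits_probs)))
        n_on = int(rng.integers(config.n_visits_range[0], config.n_visits_range[1] + 1))
        n_total = n_pre + n_on
        mu = np.log(config.visit_interval_mean) - 0.5 * config.visit_interval_sigma ** 2
        intervals = np.exp(rng.normal(mu, config.visit_interval_sigma, size=max(0, n_total - 1)))
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        if config.horizon_years is not None:
            times = times[times <= config.horizon_years]
        # first prescribed visit; a hard horizon can leave a patient untreated
        t_init = times[n_pre] if len(times) > n_pre else np.inf

        prev_t = 0.0
        for k, t in enumerate(times):
            if t <= t_init:
                # untreated decline from first contact up to drug initiation
                score = baseline - decline_rate * t
            else:
                eff_t = max(0.0, t - t_init - config.plateau_years)
                score = baseline - decline_rate * t_init - net_decline * eff_t
            if k > 0 and config.noise_sd > 0:
                score += rng.normal(0.0, config.noise_sd)
            score = float(np.clip(score, 0.0, 30.0))
            if config.integer_scores:
                score = float(round(score))
            rows.append({
                "patient_id": pid,
                "visit_time": float(t),
                "age": float(age0 + t),
                "sex": sex,
                "ethnicity": ethnicity,
                "marital_status": marital,
                "scale_kind": config.scale_kind,
                "score": score,
                "drug": "none" if k < n_pre else drug,
                "duration": float(t - prev_t),
            })
            prev_t = t

    cohort = pd.DataFrame(rows)
    return cohort, profiles


def profiles_to_frame(profiles: list[DrugResponseProfile]) -> pd.DataFrame:
    """Ground-truth table: one row per patient, effect columns + best drug."""
    return pd.DataFrame([
        {
            "patient_id": p.patient_id,
            **{f"effect_{d}": e for d, e in zip(DRUGS, p.effects)},
            "best_drug": planted_best_drug(p),
        }
        for p in profiles
    ])


def profiles_from_frame(frame: pd.DataFrame) -> list[DrugResponseProfile]:
    cols = [f"effect_{d}" for d in DRUGS]
    return [
        DrugResponseProfile(str(row["patient_id"]), tuple(float(row[c]) for c in cols))
        for _, row in frame.iterrows()
    ]
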