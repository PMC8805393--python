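"""Cohort filtering, visit encoding, sequence windowing and patient splits.

Inclusion/exclusion mirrors the standard longitudinal-prescription cleanup:
patients outside the 59-102 age window, patients on more than one
anti-dementia drug, and patients left with fewer than two observations are
excluded; follow-up is truncated two years after the first prescription.

Visits are encoded as fixed layouts of one-hot blocks (with an explicit
"not available" level per categorical — missingness is a category, never
imputed) plus continuous age, inter-visit duration and score.  Sequences are
fixed-length windows of consecutive visits, left-zero-padded when a patient
has fewer visits than the window, predicting the score at the visit that
follows the window; that target visit's drug and the time gap to it are
appended to the last real step, which is what makes counterfactual drug
substitution well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sim import (DRUGS, ETHNICITY_LEVELS, MARITAL_LEVELS, SEX_LEVELS,
                  Patient, Visit)

__all__ = [
    "FilterReport",
    "NoPatientsRetainedError",
    "EncodingError",
    "VisitEncoder",
    "EncodedSequence",
    "apply_inclusion_filters",
    "build_sequence",
    "build_sequence_pool",
    "build_training_sequences",
    "build_evaluation_sequences",
    "split_train_validation",
]

AGE_WINDOW = (59.0, 102.0)
FOLLOWUP_CAP_YEARS = 2.0
DRUG_LEVELS = ("none",) + DRUGS  # per-visit prescription column


class NoPatientsRetainedError(RuntimeError):
    """Raised when inclusion filters leave no patients."""


class EncodingError(ValueError):
    """Raised for a categorical value outside the configured level set."""


@dataclass(frozen=True)
class FilterReport:
    n_input_patients: int
    n_excluded_age: int
    n_excluded_polypharmacy: int
    n_excluded_single_observation: int
    n_visits_truncated_2y: int
    n_output_patients: int

    def __post_init__(self):
        expected = (self.n_input_patients - self.n_excluded_age
                    - self.n_excluded_polypharmacy - self.n_excluded_single_observation)
        assert self.n_output_patients == expected, "filter accounting mismatch"


def apply_inclusion_filters(cohort: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the inclusion/exclusion rules; idempotent.

    Order: age window, polypharmacy, 2-year follow-up cap from first
    prescription, then the minimum-two-observations rule (so a patient whose
    late visits were truncated away may still drop out).  The cap applies
    only from drug initiation; patients never prescribed anything keep all
    visits.
    """
    cohort = cohort.sort_values(["patient_id", "visit_time"], kind="stable")
    n_input = cohort["patient_id"].nunique()
    n_age = n_poly = n_single = n_trunc = 0
    kept: list[pd.DataFrame] = []
    for _, g in cohort.groupby("patient_id", sort=True):
        if not ((g["age"] >= AGE_WINDOW[0]) & (g["age"] <= AGE_WINDOW[1])).all():
            n_age += 1
            continue
        drugs = set(g["drug"]) - {"none"}
        if len(drugs) > 1:
            n_poly += 1
            continue
        on_drug = g["drug"] != "none"
        if on_drug.any():
            t0 = g.loc[on_drug, "visit_time"].iloc[0]
            within = g["visit_time"] <= t0 + FOLLOWUP_CAP_YEARS
            n_trunc += int((~within).sum())
            g = g[within]
        if len(g) < 2:
            n_single += 1
            continue
        kept.append(g)
    report = FilterReport(n_input, n_age, n_poly, n_single, n_trunc,
                          n_input - n_age - n_poly - n_single)
    if not kept:
        raise NoPatientsRetainedError("no patients retained after inclusion filters")
    return pd.concat(kept, ignore_index=True), report


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VisitEncoder:
    """Deterministic fixed-layout visit encoder.

    Step-vector layout: ``[sex | ethnicity | marital | drug(+none) | age |
    duration | score (| score_missing) | target_drug | duration_to_target]``.
    The per-visit part (everything before the target block) is what
    :meth:`encode_visit` emits; the target block is filled only on the last
    real step of a sequence.  Continuous columns are scaled to roughly unit
    range: age/100, duration in years, score/30 when ``scale_norm``.
    """

    sex_levels: tuple = SEX_LEVELS
    ethnicity_levels: tuple = ETHNICITY_LEVELS
    marital_levels: tuple = MARITAL_LEVELS
    drug_levels: tuple = DRUG_LEVELS
    scale_norm: bool = True
    score_missing_indicator: bool = False

    # -- layout -------------------------------------------------------------
    @property
    def visit_dim(self) -> int:
        n = (len(self.sex_levels) + len(self.ethnicity_levels)
             + len(self.marital_levels) + len(self.drug_levels) + 3)
        return n + (1 if self.score_missing_indicator else 0)

    @property
    def step_dim(self) -> int:
        return self.visit_dim + len(DRUGS) + 1

    @property
    def target_drug_slice(self) -> slice:
        return slice(self.visit_dim, self.visit_dim + len(DRUGS))

    @property
    def blocks(self) -> dict[str, list[int]]:
        """Column indices of the 7 predictors over the full step vector."""
        i = 0
        out: dict[str, list[int]] = {}
        for name, levels in (("sex", self.sex_levels),
                             ("ethnicity", self.ethnicity_levels),
                             ("marital_status", self.marital_levels),
                             ("medication", self.drug_levels)):
            out[name] = list(range(i, i + len(levels)))
            i += len(levels)
        out["age"] = [i]
        out["duration"] = [i + 1]
        out["score"] = [i + 2]
        i += 3
        if self.score_missing_indicator:
            out["score"].append(i)
            i += 1
        # the counterfactual drug slot and the gap to the target visit belong
        # to the medication and duration predictors respectively
        out["medication"] += list(range(i, i + len(DRUGS)))
        out["duration"].append(i + len(DRUGS))
        return out

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return ("age", "sex", "ethnicity", "marital_status", "duration",
                "score", "medication")

    # -- encode / decode ----------------------------------------------------
    def _onehot(self, value: str, levels: tuple, fname: str) -> np.ndarray:
        v = np.zeros(len(levels))
        try:
            v[levels.index(value)] = 1.0
        except ValueError:
            raise EncodingError(
                f"unknown level {value!r} for field {fname!r}; valid: {levels}"
            ) from None
        return v

    def encode_visit(self, visit: Visit, patient: Patient) -> np.ndarray:
        parts = [
            self._onehot(patient.sex, self.sex_levels, "sex"),
            self._onehot(patient.ethnicity, self.ethnicity_levels, "ethnicity"),
            self._onehot(patient.marital_status, self.marital_levels, "marital_status"),
            self._onehot(visit.drug, self.drug_levels, "drug"),
        ]
        missing = visit.score is None or (isinstance(visit.score, float) and np.isnan(visit.score))
        score = 0.0 if missing else float(visit.score)
        if self.scale_norm:
            score /= 30.0
        cont = [visit.age / 100.0, visit.duration, score]
        if self.score_missing_indicator:
            cont.append(1.0 if missing else 0.0)
        parts.append(np.asarray(cont))
        return np.concatenate(parts)

    def decode(self, vector: np.ndarray) -> dict[str, str]:
        """Recover the categorical fields from an encoded visit vector."""
        out = {}
        i = 0
        for name, levels in (("sex", self.sex_levels),
                             ("ethnicity", self.ethnicity_levels),
                             ("marital_status", self.marital_levels),
                             ("drug", self.drug_levels)):
            block = vector[i:i + len(levels)]
            out[name] = levels[int(np.argmax(block))]
            i += len(levels)
        return out


@dataclass
class EncodedSequence:
    """A left-zero-padded window of encoded visits plus its prediction target."""

    patient_id: str
    steps: np.ndarray  # (window_length, step_dim)
    target_score: float  # raw scale points
    target_drug: str
    n_real_steps: int
    scale_kind: str = "MMSE"
    target_time: float = field(default=np.nan)

    @property
    def window_length(self) -> int:
        return self.steps.shape[0]


def _patient_from_group(g: pd.DataFrame) -> Patient:
    r = g.iloc[0]
    return Patient(str(r["patient_id"]), str(r["sex"]), str(r["ethnicity"]),
                   str(r["marital_status"]), float(r["age"]))


def _visits_from_group(g: pd.DataFrame) -> list[Visit]:
    return [
        Visit(float(r["visit_time"]), float(r["age"]), str(r["scale_kind"]),
              None if pd.isna(r["score"]) else float(r["score"]),
              str(r["drug"]), float(r["duration"]))
        for _, r in g.iterrows()
    ]


def build_sequence(visits: list[Visit], patient: Patient, window_length: int,
                   encoder: VisitEncoder, target_index: int) -> EncodedSequence:
    """Encode the window of up to ``window_length`` visits preceding
    ``target_index``, left-zero-padded, with the target visit's drug and the
    duration to it written into the last real step's target block."""
    if len(visits) < 2:
        raise ValueError("patient must have at least 2 visits")
    if not 1 <= target_index < len(visits):
        raise ValueError("target_index must have at least one preceding visit")
    start = max(0, target_index - window_length)
    real = visits[start:target_index]
    steps = np.zeros((window_length, encoder.step_dim))
    for j, v in enumerate(real):
        offset = window_length - len(real)
        steps[offset + j, :encoder.visit_dim] = encoder.encode_visit(v, patient)
    target = visits[target_index]
    if target.drug not in DRUGS:
        raise ValueError(
            f"target visit of patient {patient.id} has no anti-dementia drug")
    if target.score is None:
        raise ValueError(f"target visit of patient {patient.id} has no score")
    tslice = encoder.target_drug_slice
    steps[-1, tslice.start + DRUGS.index(target.drug)] = 1.0
    steps[-1, encoder.step_dim - 1] = target.time - real[-1].time
    return EncodedSequence(patient.id, steps, float(target.score), target.drug,
                           len(real), target.scale_kind, target.time)


def _eligible_targets(visits: list[Visit]) -> list[int]:
    return [j for j in range(1, len(visits))
            if visits[j].drug in DRUGS and visits[j].score is not None]


def build_sequence_pool(cohort: pd.DataFrame, encoder: VisitEncoder,
                        window_length: int) -> list[list[EncodedSequence]]:
    """Every eligible window of every patient, grouped per patient.

    One inner list per retained patient, one entry per eligible target visit
    (a visit with a prescribed drug, a score, and at least one preceding
    visit).  Feeding the pool to training resamples one window per patient
    per epoch — the augmentation counterpart of drawing a single random run.
    """
    pool: list[list[EncodedSequence]] = []
    for _, g in cohort.groupby("patient_id", sort=True):
        visits = _visits_from_group(g)
        patient = _patient_from_group(g)
        eligible = _eligible_targets(visits)
        if not eligible:
            continue
        pool.append([build_sequence(visits, patient, window_length, encoder, j)
                     for j in eligible])
    return pool


def build_training_sequences(cohort: pd.DataFrame, encoder: VisitEncoder,
                             window_length: int, rng: np.random.Generator,
                             ) -> list[EncodedSequence]:
    """One window per patient: a uniformly random contiguous run of
    ``window_length`` visits (all visits, padded, when the patient has
    fewer), predicting the following visit's score."""
    out = []
    for _, g in cohort.groupby("patient_id", sort=True):
        visits = _visits_from_group(g)
        patient = _patient_from_group(g)
        eligible = _eligible_targets(visits)
        if not eligible:
            continue
        if len(visits) - 1 >= window_length:
            starts = [j - window_length for j in eligible if j >= window_length]
            if starts:
                start = starts[int(rng.integers(len(starts)))]
                target = start + window_length
            else:
                target = eligible[int(rng.integers(len(eligible)))]
        else:
            target = eligible[-1]
        out.append(build_sequence(visits, patient, window_length, encoder, target))
    return out


def build_evaluation_sequences(cohort: pd.DataFrame, encoder: VisitEncoder,
                               window_length: int, mode: str = "initiation",
                               rng: np.random.Generator | None = None,
                               ) -> list[EncodedSequence]:
    """Evaluation windows: ``initiation`` predicts the first visit after drug
    initiation from the record up to initiation; ``random`` draws a uniform
    eligible target visit per patient (requires ``rng``)."""
    if mode not in ("initiation", "random"):
        raise ValueError(f"unknown evaluation mode {mode!r}")
    if mode == "random" and rng is None:
        raise ValueError("random evaluation mode needs an rng")
    out = []
    for _, g in cohort.groupby("patient_id", sort=True):
        visits = _visits_from_group(g)
        patient = _patient_from_group(g)
        eligible = _eligible_targets(visits)
        if not eligible:
            continue
        if mode == "initiation":
            init = next((j for j, v in enumerate(visits) if v.drug in DRUGS), None)
            candidates = [j for j in eligible if j > init]
            if not candidates:
                continue
            target = candidates[0]
        else:
            target = eligible[int(rng.integers(len(eligible)))]
        out.append(build_sequence(visits, patient, window_length, encoder, target))
    return out


def split_train_validation(patient_ids, fraction: float, seed: int,
                           ) -> tuple[list[str], list[str]]:
    """Patient-level split; |train| = round-half-up(fraction * n)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    ids = sorted(pd.unique(pd.Series(list(patient_ids)).astype(str)))
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    n_train = int(np.floor(fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train = sorted(ids[i] for i in perm[:n_train])
    validation = sorted(ids[i] for i in perm[n_train:])
    return train, validation
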