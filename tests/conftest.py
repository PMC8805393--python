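"""Shared fixtures: toy tables and one expensive planted-cohort study run.

The session-scoped ``planted_run`` fixture simulates the reference synthetic
study (2000 patients, sex-by-severity drug response with a 2.0 points/year
best-vs-rest gap, observation noise SD 1.5), trains the recurrent predictor
once and exposes the cohort, ground truth, model and recommendations to
every test that needs a realistically trained system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from nntoc import (CohortConfig, ModelSpec, VisitEncoder,
                   apply_inclusion_filters, build_evaluation_sequences,
                   build_sequence_pool, recommend_batch, simulate_cohort,
                   split_train_validation, train_score_model)


def make_cohort_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a cohort table from terse row dicts, filling common defaults."""
    defaults = {"age": 80.0, "sex": "F", "ethnicity": "white",
                "marital_status": "married", "scale_kind": "MMSE",
                "score": 22.0, "drug": "donepezil", "duration": 0.0}
    return pd.DataFrame([{**defaults, **r} for r in rows])


@dataclass
class StudyRun:
    config: CohortConfig
    cohort: pd.DataFrame
    filtered: pd.DataFrame
    profiles: list
    encoder: VisitEncoder
    train_ids: list
    val_ids: list
    model: object
    eval_sequences: list
    recommendations: list


@pytest.fixture(scope="session")
def planted_run() -> StudyRun:
    """Reference synthetic study: simulate, filter, split 60/40, train the
    LSTM on pooled windows, recommend for validation patients at a random
    evaluation visit."""
    config = CohortConfig(n_patients=2000, seed=42)
    cohort, profiles = simulate_cohort(config)
    filtered, _ = apply_inclusion_filters(cohort)
    encoder = VisitEncoder()
    train_ids, val_ids = split_train_validation(filtered["patient_id"], 0.60, 43)
    pool = build_sequence_pool(
        filtered[filtered["patient_id"].isin(train_ids)], encoder, 4)
    model = train_score_model(pool, ModelSpec(epochs=600, patience=100, seed=3),
                              encoder=encoder)
    val_cohort = filtered[filtered["patient_id"].isin(val_ids)]
    eval_sequences = build_evaluation_sequences(
        val_cohort, encoder, 4, mode="random", rng=np.random.default_rng(49))
    recommendations = recommend_batch(model, eval_sequences)
    return StudyRun(config, cohort, filtered, profiles, encoder,
                    train_ids, val_ids, model, eval_sequences, recommendations)


@pytest.fixture(scope="session")
def noise_free_run() -> StudyRun:
    """Deterministic-outcome limit cohort: no observation noise, unrounded
    scores, no stabilisation plateau, balanced prescriptions — the clean
    setting for verifying that counterfactual ranking recovers the planted
    ordering."""
    config = CohortConfig(n_patients=1200, seed=7, noise_sd=0.0,
                          integer_scores=False, plateau_years=0.0,
                          drug_assignment_probs=(0.25, 0.25, 0.25, 0.25))
    cohort, profiles = simulate_cohort(config)
    filtered, _ = apply_inclusion_filters(cohort)
    encoder = VisitEncoder()
    train_ids, val_ids = split_train_validation(filtered["patient_id"], 0.60, 8)
    pool = build_sequence_pool(
        filtered[filtered["patient_id"].isin(train_ids)], encoder, 4)
    model = train_score_model(pool, ModelSpec(epochs=500, patience=80, seed=9),
                              encoder=encoder)
    val_cohort = filtered[filtered["patient_id"].isin(val_ids)]
    eval_sequences = build_evaluation_sequences(val_cohort, encoder, 4,
                                                mode="initiation")
    recommendations = recommend_batch(model, eval_sequences)
    return StudyRun(config, cohort, filtered, profiles, encoder,
                    train_ids, val_ids, model, eval_sequences, recommendations)
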