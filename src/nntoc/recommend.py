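"""Turning counterfactual per-drug predictions into a treatment of choice.

For each patient the fitted predictor is re-run once per candidate drug with
that drug substituted into the target slot; the drug with the highest
predicted next-visit score (smallest predicted decline) is the treatment of
choice.  Ties resolve to the earliest drug in canonical order.  Patients
split into concordant (prescribed the recommended drug) and discordant
groups, and a shuffled-recommendation null reassigns each patient another
patient's recommendation to probe whether recommendations are personalised.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .models import TrainedModel, predict_scores
from .prep import EncodedSequence
from .sim import DRUGS

__all__ = [
    "ACHEI_DRUGS",
    "Recommendation",
    "recommend",
    "recommend_batch",
    "shuffle_recommendations",
    "concordance_split",
    "recommendations_to_frame",
]

ACHEI_DRUGS: tuple[str, ...] = ("donepezil", "galantamine", "rivastigmine")


@dataclass(frozen=True)
class Recommendation:
    patient_id: str
    drug_set: tuple[str, ...]
    predicted_scores: tuple[float, ...]  # aligned with drug_set (canonical order)
    nntoc: str
    prescribed: str

    @property
    def concordant(self) -> bool:
        return self.nntoc == self.prescribed


def _canonical_drug_set(drug_set) -> tuple[str, ...]:
    ds = tuple(d for d in DRUGS if d in set(drug_set))
    if not ds:
        raise ValueError("drug_set must contain at least one known drug")
    unknown = set(drug_set) - set(DRUGS)
    if unknown:
        raise ValueError(f"unknown drugs in drug_set: {sorted(unknown)}")
    return ds


def recommend_batch(model: TrainedModel, sequences: list[EncodedSequence],
                    drug_set=DRUGS) -> list[Recommendation]:
    """Vectorised recommendation for many patients at once."""
    ds = _canonical_drug_set(drug_set)
    preds = np.column_stack([predict_scores(model, sequences, drug=d) for d in ds])
    out = []
    for i, s in enumerate(sequences):
        row = preds[i]
        out.append(Recommendation(
            patient_id=s.patient_id,
            drug_set=ds,
            predicted_scores=tuple(float(v) for v in row),
            nntoc=ds[int(np.argmax(row))],  # first maximum = canonical tie-break
            prescribed=s.target_drug,
        ))
    return out


def recommend(model: TrainedModel, sequence: EncodedSequence,
              drug_set=DRUGS) -> Recommendation:
    """Per-drug counterfactual prediction and argmax treatment of choice."""
    return recommend_batch(model, [sequence], drug_set)[0]


def shuffle_recommendations(recommendations: list[Recommendation],
                            seed: int = 0) -> list[Recommendation]:
    """Assign each patient the recommendation of a randomly chosen other
    patient (a uniform permutation; fixed points allowed).  The multiset of
    recommended drugs is preserved and concordance flags follow the new
    labels."""
    if len(recommendations) < 2:
        raise ValueError("need at least 2 recommendations to shuffle")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(recommendations))
    return [replace(r, nntoc=recommendations[j].nntoc)
            for r, j in zip(recommendations, perm)]


def concordance_split(recommendations: list[Recommendation],
                      ) -> tuple[list[str], list[str], float]:
    """Partition patient ids by concordance; rate = |concordant| / n."""
    conc = [r.patient_id for r in recommendations if r.concordant]
    disc = [r.patient_id for r in recommendations if not r.concordant]
    rate = len(conc) / len(recommendations) if recommendations else float("nan")
    return conc, disc, rate


def recommendations_to_frame(recommendations: list[Recommendation]) -> pd.DataFrame:
    rows = []
    for r in recommendations:
        row = {"patient_id": r.patient_id, "nntoc": r.nntoc,
               "prescribed": r.prescribed, "concordant": r.concordant}
        for d, v in zip(r.drug_set, r.predicted_scores):
            row[f"pred_{d}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
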