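"""Model checkpointing for the CLI: numpy archive + JSON sidecar metadata."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .models import ModelSpec, TrainedModel
from .prep import VisitEncoder

__all__ = ["save_model", "load_model"]


def save_model(model: TrainedModel, path) -> None:
    if model.spec.kind not in ("lstm", "cnn1d"):
        raise ValueError("only network models are checkpointable; refit "
                         "scikit-learn baselines from their spec instead")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **{k: v.data for k, v in model.params.items()})
    enc = dataclasses.asdict(model.encoder)
    for k in ("sex_levels", "ethnicity_levels", "marital_levels", "drug_levels"):
        enc[k] = list(enc[k])
    meta = {
        "spec": model.spec.to_dict(),
        "encoder": enc,
        "window_length": model.window_length,
        "training_loss_trace": model.training_loss_trace,
        "scale_kinds": list(model.scale_kinds),
        "n_outputs": model.n_outputs,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_model(path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with np.load(path) as arch:
        params = {k: Tensor(arch[k], requires_grad=True) for k in arch.files}
    enc = dict(meta["encoder"])
    for k in ("sex_levels", "ethnicity_levels", "marital_levels", "drug_levels"):
        enc[k] = tuple(enc[k])
    return TrainedModel(
        spec=ModelSpec.from_dict(meta["spec"]),
        encoder=VisitEncoder(**enc),
        window_length=int(meta["window_length"]),
        params=params,
        training_loss_trace=list(meta["training_loss_trace"]),
        scale_kinds=tuple(meta["scale_kinds"]),
        n_outputs=int(meta["n_outputs"]),
    )
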