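"""Score predictors: the recurrent model and its comparison baselines.

The main predictor is a front-end stack of fully connected layers (a feature
extractor over the clinical/demographic encoding) feeding a two-layer LSTM
whose final hidden state maps linearly to the predicted next-visit score.
Training minimises mean squared error on the scale-normalised score; scores
are reported in raw points and clamped to the 0-30 instrument range.

Baselines: ridge regression and a random forest on the flattened window
(scikit-learn), and a one-dimensional CNN convolving along the visit axis.
A multitask variant carries one output head per scale (MMSE, MoCA) and masks
the absent scale's head out of the loss sample-by-sample.

Counterfactual mechanism: the target visit's drug is an input feature (a
one-hot block on the last real step), so per-drug predictions are produced
by re-running the forward pass with each drug substituted into that block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge

from .autodiff import Adam, Tensor, glorot
from .prep import EncodedSequence, VisitEncoder
from .sim import DRUGS

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "DivergenceError",
    "train_score_model",
    "train_baseline",
    "train_multitask",
    "predict_score",
    "predict_scores",
    "oversample_minority",
    "grid_search",
]

SCALE_INDEX = {"MMSE": 0, "MoCA": 1}
SCORE_MAX = 30.0


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class ModelSpec:
    kind: str = "lstm"  # lstm | ridge | random_forest | cnn1d
    frontend_widths: tuple[int, ...] = (32, 16)
    recurrent_hidden: int = 32
    recurrent_layers: int = 2
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 64
    weight_decay: float = 1e-4
    patience: int = 20
    l2_penalty: float = 1.0  # ridge
    n_trees: int = 200  # random forest
    max_depth: int | None = None
    kernel_width: int = 2  # cnn1d
    channels: int = 16
    ablate_drug_input: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("lstm", "ridge", "random_forest", "cnn1d"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "lstm" and self.recurrent_layers != 2:
            raise ValueError("the recurrent core is fixed at 2 layers")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs and batch_size must be positive")
        if any(w < 1 for w in self.frontend_widths) or self.recurrent_hidden < 1:
            raise ValueError("layer widths must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if "frontend_widths" in d:
            d["frontend_widths"] = tuple(d["frontend_widths"])
        return cls(**d)


@dataclass
class TrainedModel:
    spec: ModelSpec
    encoder: VisitEncoder
    window_length: int
    params: dict | object  # tensor dict (lstm/cnn1d) or fitted sklearn estimator
    training_loss_trace: list[float] = field(default_factory=list)
    scale_kinds: tuple[str, ...] = ("MMSE",)
    n_outputs: int = 1

    # ------------------------------------------------------------------
    def _forward_net(self, X: np.ndarray) -> np.ndarray:
        """Forward pass without gradient tape; X is (N, T, D)."""
        params = {k: Tensor(v.data if isinstance(v, Tensor) else v)
                  for k, v in self.params.items()}
        if self.spec.kind == "lstm":
            out = _lstm_forward(params, X, self.spec)
        else:
            out = _cnn_forward(params, X, self.spec)
        return out.data

    def predict_normalised(self, X: np.ndarray) -> np.ndarray:
        """Raw model output on the normalised score scale, shape (N, n_outputs)."""
        if X.shape[2] != self.encoder.step_dim:
            raise ValueError(
                f"encoding dimension mismatch: model expects {self.encoder.step_dim}, "
                f"got {X.shape[2]}")
        if self.spec.ablate_drug_input:
            X = X.copy()
            X[:, :, self.encoder.blocks["medication"]] = 0.0
        if self.spec.kind in ("lstm", "cnn1d"):
            return self._forward_net(X)
        flat = X.reshape(X.shape[0], -1)
        return np.asarray(self.params.predict(flat)).reshape(X.shape[0], -1)


def _stack(sequences: list[EncodedSequence]) -> np.ndarray:
    return np.stack([s.steps for s in sequences])


def _substitute_drug(X: np.ndarray, encoder: VisitEncoder, drug: str) -> np.ndarray:
    """Patient-level counterfactual: put ``drug`` into the target slot and
    into the per-step prescription one-hot of every on-drug step.

    A patient's record carries one drug throughout, so the target slot and
    the historical prescription features are collinear in training; swapping
    both asks the well-posed question "what if this patient had been on
    ``drug``" and is insensitive to how the fit attributed the effect
    between the two routes."""
    if drug not in DRUGS:
        raise ValueError(f"unknown drug {drug!r}")
    X = X.copy()
    sl = encoder.target_drug_slice
    X[:, -1, sl] = 0.0
    X[:, -1, sl.start + DRUGS.index(drug)] = 1.0
    med = encoder.blocks["medication"][:len(encoder.drug_levels)]
    hist = X[:, :, med]
    on = hist[:, :, 1:].sum(axis=2) > 0  # steps with any prescribed drug
    hist[:, :, 1:] = 0.0
    hist[:, :, 1 + DRUGS.index(drug)] = on.astype(float)
    X[:, :, med] = hist
    return X


def predict_scores(model: TrainedModel, sequences: list[EncodedSequence],
                   drug: str | None = None, scale_kind: str | None = None,
                   ) -> np.ndarray:
    """Predicted next-visit scores in raw points, clamped to [0, 30].

    ``drug`` substitutes a counterfactual drug into every sequence's target
    slot; ``None`` keeps each sequence's encoded (prescribed) drug.
    """
    X = _stack(sequences)
    if X.shape[2] != model.encoder.step_dim:
        raise ValueError(
            f"encoding dimension mismatch: model expects {model.encoder.step_dim}, "
            f"got {X.shape[2]}")
    if drug is not None:
        X = _substitute_drug(X, model.encoder, drug)
    out = model.predict_normalised(X)
    if model.n_outputs == 1:
        cols = out[:, 0]
    else:
        idx = [SCALE_INDEX[scale_kind or s.scale_kind] for s in sequences]
        cols = out[np.arange(len(sequences)), idx]
    return np.clip(cols * SCORE_MAX, 0.0, SCORE_MAX)


def predict_score(model: TrainedModel, sequence: EncodedSequence, drug: str) -> float:
    """Counterfactual single-sequence prediction (points, clamped to [0, 30])."""
    return float(predict_scores(model, [sequence], drug=drug)[0])


# ---------------------------------------------------------------------------
# network forward passes
# ---------------------------------------------------------------------------

def _frontend(params: dict, x: Tensor, spec: ModelSpec) -> Tensor:
    for i in range(len(spec.frontend_widths)):
        x = (x @ params[f"f{i}_W"] + params[f"f{i}_b"]).relu()
    return x


def _lstm_forward(params: dict, X: np.ndarray, spec: ModelSpec) -> Tensor:
    N, T, _ = X.shape
    H = spec.recurrent_hidden
    h = [Tensor(np.zeros((N, H))) for _ in range(spec.recurrent_layers)]
    c = [Tensor(np.zeros((N, H))) for _ in range(spec.recurrent_layers)]
    for t in range(T):
        x = _frontend(params, Tensor(X[:, t, :]), spec)
        for l in range(spec.recurrent_layers):
            z = x @ params[f"l{l}_Wx"] + h[l] @ params[f"l{l}_Wh"] + params[f"l{l}_b"]
            gi = z.cols(0, H).sigmoid()
            gf = z.cols(H, 2 * H).sigmoid()
            gg = z.cols(2 * H, 3 * H).tanh()
            go = z.cols(3 * H, 4 * H).sigmoid()
            c[l] = gf * c[l] + gi * gg
            h[l] = go * c[l].tanh()
            x = h[l]
    return h[-1] @ params["head_W"] + params["head_b"]


def _cnn_forward(params: dict, X: np.ndarray, spec: ModelSpec) -> Tensor:
    N, T, _ = X.shape
    k = min(spec.kernel_width, T)
    pooled = None
    n_pos = T - k + 1
    for p in range(n_pos):
        z = params["conv_b"] + Tensor(np.zeros((N, spec.channels)))
        for j in range(k):
            z = z + Tensor(X[:, p + j, :]) @ params[f"conv_W{j}"]
        a = z.relu()
        pooled = a if pooled is None else pooled + a
    pooled = pooled / n_pos
    hid = (pooled @ params["mid_W"] + params["mid_b"]).relu()
    return hid @ params["head_W"] + params["head_b"]


def _init_lstm_params(spec: ModelSpec, in_dim: int, n_out: int,
                      rng: np.random.Generator) -> dict[str, Tensor]:
    params: dict[str, Tensor] = {}
    d = in_dim
    for i, w in enumerate(spec.frontend_widths):
        params[f"f{i}_W"] = Tensor(glorot(rng, d, w), requires_grad=True)
        params[f"f{i}_b"] = Tensor(np.zeros(w), requires_grad=True)
        d = w
    H = spec.recurrent_hidden
    for l in range(spec.recurrent_layers):
        params[f"l{l}_Wx"] = Tensor(glorot(rng, d, 4 * H), requires_grad=True)
        params[f"l{l}_Wh"] = Tensor(glorot(rng, H, 4 * H), requires_grad=True)
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias
        params[f"l{l}_b"] = Tensor(b, requires_grad=True)
        d = H
    params["head_W"] = Tensor(glorot(rng, H, n_out), requires_grad=True)
    params["head_b"] = Tensor(np.zeros(n_out), requires_grad=True)
    return params


def _init_cnn_params(spec: ModelSpec, in_dim: int, n_out: int, window: int,
                     rng: np.random.Generator) -> dict[str, Tensor]:
    params: dict[str, Tensor] = {}
    k = min(spec.kernel_width, window)
    for j in range(k):
        params[f"conv_W{j}"] = Tensor(glorot(rng, in_dim, spec.channels), requires_grad=True)
    params["conv_b"] = Tensor(np.zeros(spec.channels), requires_grad=True)
    params["mid_W"] = Tensor(glorot(rng, spec.channels, 16), requires_grad=True)
    params["mid_b"] = Tensor(np.zeros(16), requires_grad=True)
    params["head_W"] = Tensor(glorot(rng, 16, n_out), requires_grad=True)
    params["head_b"] = Tensor(np.zeros(n_out), requires_grad=True)
    return params


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _targets(sequences: list[EncodedSequence], n_out: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalised target matrix and per-head loss mask."""
    y = np.zeros((len(sequences), n_out))
    mask = np.zeros((len(sequences), n_out))
    for i, s in enumerate(sequences):
        col = 0 if n_out == 1 else SCALE_INDEX[s.scale_kind]
        y[i, col] = s.target_score / SCORE_MAX
        mask[i, col] = 1.0
    return y, mask


def _flatten(sequences) -> tuple[list[EncodedSequence], list[np.ndarray]]:
    """Normalise flat lists and per-patient pools to (flat sequences, groups)."""
    if sequences and isinstance(sequences[0], (list, tuple)):
        flat: list[EncodedSequence] = []
        groups = []
        for inner in sequences:
            groups.append(np.arange(len(flat), len(flat) + len(inner)))
            flat.extend(inner)
        return flat, groups
    flat = list(sequences)
    return flat, [np.array([i]) for i in range(len(flat))]


def _train_network(sequences, spec: ModelSpec, seed: int,
                   val_sequences: list[EncodedSequence] | None,
                   encoder: VisitEncoder, n_out: int) -> TrainedModel:
    flat, groups = _flatten(sequences)
    if not flat:
        raise ValueError("need at least one training sequence")
    rng = np.random.default_rng(seed)
    X = _stack(flat)
    if spec.ablate_drug_input:
        X = X.copy()
        X[:, :, encoder.blocks["medication"]] = 0.0
    y, mask = _targets(flat, n_out)
    window = X.shape[1]

    # groups are sampling units (patients); carve the early-stopping split at
    # that level so no patient's windows leak across it
    if val_sequences is None:
        if len(groups) >= 10:
            n_val = max(1, len(groups) // 10)
            perm = rng.permutation(len(groups))
            val_idx = np.array([groups[i][0] for i in perm[:n_val]])
            train_groups = [groups[i] for i in perm[n_val:]]
        else:
            val_idx = np.concatenate(groups)
            train_groups = groups
    else:
        train_groups = groups
        val_idx = None

    if spec.kind == "lstm":
        params = _init_lstm_params(spec, X.shape[2], n_out, rng)
        forward = _lstm_forward
    else:
        params = _init_cnn_params(spec, X.shape[2], n_out, window, rng)
        forward = _cnn_forward
    opt = Adam(params, lr=spec.learning_rate, weight_decay=spec.weight_decay)

    model = TrainedModel(spec=spec, encoder=encoder, window_length=window,
                         params=params, scale_kinds=tuple(SCALE_INDEX)[:n_out],
                         n_outputs=n_out)
    if val_sequences is not None:
        Xv = _stack(val_sequences)
        if spec.ablate_drug_input:
            Xv = Xv.copy()
            Xv[:, :, encoder.blocks["medication"]] = 0.0
        yv, mv = _targets(val_sequences, n_out)
    else:
        Xv, yv, mv = X[val_idx], y[val_idx], mask[val_idx]

    best_val = np.inf
    best_params = None
    bad_epochs = 0
    trace: list[float] = []
    group_sizes = np.array([len(g) for g in train_groups])
    resample = bool((group_sizes > 1).any())
    static_idx = np.concatenate(train_groups) if not resample else None
    for epoch in range(spec.epochs):
        if resample:  # one freshly drawn window per patient per epoch
            tr_idx = np.array([g[rng.integers(len(g))] for g in train_groups])
        else:
            tr_idx = static_idx
        order = rng.permutation(len(tr_idx))
        epoch_losses = []
        for start in range(0, len(order), spec.batch_size):
            idx = tr_idx[order[start:start + spec.batch_size]]
            pred = forward(params, X[idx], spec)
            diff = pred - Tensor(y[idx])
            m = Tensor(mask[idx])
            loss = (diff * diff * m).sum() / max(mask[idx].sum(), 1.0)
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            opt.zero_grad()
            epoch_losses.append(float(loss.data))
        trace.append(float(np.mean(epoch_losses)))

        pv = forward({k: Tensor(v.data) for k, v in params.items()}, Xv, spec).data
        val_mae = float(np.abs((pv - yv) * mv).sum() / max(mv.sum(), 1.0)) * SCORE_MAX
        if val_mae < best_val - 1e-9:
            best_val = val_mae
            best_params = {k: v.data.copy() for k, v in params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= spec.patience:
                break
    if best_params is not None:
        for k, v in params.items():
            v.data = best_params[k]
    model.training_loss_trace = trace
    return model


def train_score_model(sequences, spec: ModelSpec,
                      seed: int | None = None, encoder: VisitEncoder | None = None,
                      val_sequences: list[EncodedSequence] | None = None,
                      ) -> TrainedModel:
    """Train the recurrent single-scale score predictor.

    ``sequences`` is either a flat list of windows (one per patient, the
    strict mode) or a per-patient pool from
    :func:`nntoc.prep.build_sequence_pool`, in which case one window per
    patient is freshly drawn every epoch.
    """
    spec.validate()
    if spec.kind != "lstm":
        raise ValueError("train_score_model trains the recurrent model; "
                         "use train_baseline for other kinds")
    return _train_network(sequences, spec, spec.seed if seed is None else seed,
                          val_sequences, encoder or VisitEncoder(), n_out=1)


def train_multitask(sequences: list[EncodedSequence], spec: ModelSpec,
                    seed: int | None = None, encoder: VisitEncoder | None = None,
                    val_sequences: list[EncodedSequence] | None = None,
                    ) -> TrainedModel:
    """Two-headed model over MMSE and MoCA; each sample trains only the head
    of its own scale (the other head's error is masked out of the loss)."""
    spec.validate()
    flat, _ = _flatten(sequences)
    for s in flat:
        if s.scale_kind not in SCALE_INDEX:
            raise ValueError(f"sequence for {s.patient_id} has unknown scale "
                             f"{s.scale_kind!r}")
    return _train_network(sequences, spec, spec.seed if seed is None else seed,
                          val_sequences, encoder or VisitEncoder(), n_out=2)


def train_baseline(kind: str, sequences: list[EncodedSequence], spec: ModelSpec,
                   seed: int | None = None, encoder: VisitEncoder | None = None,
                   val_sequences: list[EncodedSequence] | None = None,
                   ) -> TrainedModel:
    """Ridge / random forest on the flattened window, or the 1-D CNN."""
    if kind not in ("ridge", "random_forest", "cnn1d"):
        raise ValueError(f"unknown baseline kind {kind!r}")
    spec = ModelSpec.from_dict({**spec.to_dict(), "kind": kind})
    spec.validate()
    seed = spec.seed if seed is None else seed
    encoder = encoder or VisitEncoder()
    if kind == "cnn1d":
        return _train_network(sequences, spec, seed, val_sequences, encoder, n_out=1)
    seqs, _ = _flatten(sequences)  # ridge/forest train on every pooled window
    if not seqs:
        raise ValueError("need at least one training sequence")
    X = _stack(seqs)
    if spec.ablate_drug_input:
        X = X.copy()
        X[:, :, encoder.blocks["medication"]] = 0.0
    flat = X.reshape(X.shape[0], -1)
    y = np.array([s.target_score for s in seqs]) / SCORE_MAX
    if kind == "ridge":
        est = Ridge(alpha=spec.l2_penalty).fit(flat, y)
    else:
        est = RandomForestRegressor(n_estimators=spec.n_trees,
                                    max_depth=spec.max_depth,
                                    random_state=seed).fit(flat, y)
    return TrainedModel(spec=spec, encoder=encoder, window_length=X.shape[1],
                        params=est, training_loss_trace=[], n_outputs=1)


def grid_search(kind: str, grid: dict[str, list], sequences, val_sequences,
                base_spec: ModelSpec | None = None, seed: int = 0,
                encoder: VisitEncoder | None = None,
                ) -> tuple[ModelSpec, list[dict]]:
    """Exhaustive search over a declared hyperparameter grid, selecting the
    spec with the lowest validation MAE."""
    base = (base_spec or ModelSpec(kind=kind)).to_dict()
    keys = sorted(grid)
    combos = [{}]
    for k in keys:
        combos = [{**c, k: v} for c in combos for v in grid[k]]
    results = []
    best = (np.inf, None)
    for combo in combos:
        spec = ModelSpec.from_dict({**base, **combo, "kind": kind})
        if kind == "lstm":
            model = train_score_model(sequences, spec, seed, encoder, val_sequences)
        else:
            model = train_baseline(kind, sequences, spec, seed, encoder, val_sequences)
        pred = predict_scores(model, val_sequences)
        mae = float(np.mean(np.abs(pred - np.array([s.target_score
                                                    for s in val_sequences]))))
        results.append({**combo, "val_mae": mae})
        if mae < best[0]:
            best = (mae, spec)
    return best[1], results


def oversample_minority(sequences, seed: int = 0):
    """Duplicate training units of minority target drugs until every
    represented drug matches the majority count; originals are all retained
    and duplicates are exact copies.

    Works on flat sequence lists and on per-patient pools (where the unit
    duplicated is the whole patient, keyed by the prescribed drug)."""
    rng = np.random.default_rng(seed)
    pooled = bool(sequences) and isinstance(sequences[0], (list, tuple))
    by_drug: dict[str, list] = {}
    for s in sequences:
        key = s[0].target_drug if pooled else s.target_drug
        by_drug.setdefault(key, []).append(s)
    n_max = max(len(v) for v in by_drug.values())
    out = list(sequences)
    for drug in sorted(by_drug):
        members = by_drug[drug]
        deficit = n_max - len(members)
        if deficit > 0:
            picks = rng.integers(0, len(members), size=deficit)
            out.extend(members[i] for i in picks)
    return out
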