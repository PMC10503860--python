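"""Dual-loss Siamese network for longitudinal cognitive-decline learning.

Two volumes of a pair pass through one shared embedding network G_w (a small
3D CNN). Two heads are trained jointly:

* a regression head on the first time point's embedding, with MSE loss
  against the actual ADAS-Cog13 score there — this anchors the embedding to
  the cognitive scale and counteracts baseline differences between pairs;
* a contrastive head on the Euclidean distance D_w between the two
  embeddings, ``L = (1-Y) D^2 + Y max(0, m - D)^2``, where Y=1 marks pairs
  whose score change is clinically significant and m is the minimum distance
  different-class pairs should reach.

Training uses Adam (default initial learning rate 1e-4), mini-batches of 4
pairs, and a step scheduler multiplying the rate by 0.1 every 10 epochs.
The train/validation split is by subject (70/30); the selected checkpoint
minimizes the validation sum of MSE and contrastive loss. After training,
the shared regression head is applied to each image independently and the
pair's predicted slope is the difference of the two predicted scores over
the time gap — the model's estimate of normal-aging decline.

Regression targets are z-standardized internally using training-split
statistics (predictions are mapped back to ADAS points); the logged MSE is
on the standardized scale, the one the selection criterion sums.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .nn import Adam, Dense, Flatten, PatchConv3d, ReLU, Sequential, get_weights, set_weights


@dataclass
class HyperParams:
    """Training hyperparameters; defaults follow the published protocol
    except the backbone size, which defaults to a CPU-scale network."""

    margin: float = 1.0
    learning_rate: float = 1e-4
    batch_size: int = 4
    epochs: int = 200
    decay_factor: float = 0.1
    decay_every: int = 10
    mse_weight: float = 1.0
    contrastive_weight: float = 1.0
    conv_widths: tuple[int, ...] = (8, 16, 32)
    embed_dim: int = 16
    patch_k: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if not (0.0 < self.decay_factor <= 1.0):
            raise ValueError("decay_factor must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1 or self.decay_every < 1:
            raise ValueError("batch_size and decay_every must be >= 1")


@dataclass
class ModelState:
    """Trained Siamese model: shared weights, heads, scaling, training log."""

    hyperparams: HyperParams
    input_shape: tuple[int, int, int]
    weights: list[np.ndarray] = field(repr=False)
    target_mean: float
    target_std: float
    log: pd.DataFrame = field(repr=False)
    selected_epoch: int

    _net: Sequential | None = field(default=None, repr=False, compare=False)

    def network(self) -> Sequential:
        if self._net is None:
            net = build_network(self.input_shape, self.hyperparams)
            set_weights(net, self.weights)
            self._net = net
        return self._net

    def save(self, path) -> None:
        meta = {
            "hyperparams": asdict(self.hyperparams),
            "input_shape": list(self.input_shape),
            "target_mean": self.target_mean,
            "target_std": self.target_std,
            "selected_epoch": int(self.selected_epoch),
            "log": self.log.to_dict(orient="list"),
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "ModelState":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
        hp = dict(meta["hyperparams"])
        hp["conv_widths"] = tuple(hp["conv_widths"])
        return cls(
            hyperparams=HyperParams(**hp),
            input_shape=tuple(meta["input_shape"]),
            weights=weights,
            target_mean=meta["target_mean"],
            target_std=meta["target_std"],
            log=pd.DataFrame(meta["log"]),
            selected_epoch=meta["selected_epoch"],
        )


def build_network(input_shape, hp: HyperParams) -> Sequential:
    """Shared backbone + both heads as one parameter-holding network.

    Layout: [conv+ReLU]*len(conv_widths) -> flatten -> dense embedding; a
    final 1-unit dense layer is the regression head applied to the
    embedding. Flattening (rather than global pooling) keeps spatial
    location in the embedding, which matters because atrophy-like signal is
    regional.
    """
    rng = np.random.default_rng(np.random.SeedSequence((hp.seed, 0xC0FFEE)))
    layers: list = []
    c_in = 1
    shape = np.asarray(input_shape)
    for width in hp.conv_widths:
        if np.any(shape % hp.patch_k):
            raise ValueError(
                f"volume shape {tuple(input_shape)} not divisible by patch_k^depth"
            )
        layers.append(PatchConv3d(c_in, width, hp.patch_k, rng))
        layers.append(ReLU())
        c_in = width
        shape //= hp.patch_k
    layers.append(Flatten())
    layers.append(Dense(c_in * int(np.prod(shape)), hp.embed_dim, rng))
    backbone = Sequential(layers)
    head = Dense(hp.embed_dim, 1, rng)
    return Sequential([backbone, head])  # [0]=G_w, [1]=regression head


# --------------------------------------------------------------------- losses


def pair_distance(e1: np.ndarray, e2: np.ndarray) -> float:
    """Euclidean distance between two embedding vectors."""
    e1, e2 = np.asarray(e1, float), np.asarray(e2, float)
    if e1.shape != e2.shape:
        raise ValueError("embedding length mismatch")
    return float(np.linalg.norm(e1 - e2))


def contrastive_loss(d: float, y: int, margin: float) -> float:
    """(1-Y) D^2 + Y max(0, m - D)^2 for one pair."""
    if y not in (0, 1):
        raise ValueError("Y must be 0 or 1")
    if margin <= 0:
        raise ValueError("margin must be > 0")
    if y == 0:
        return float(d) ** 2
    return max(0.0, margin - float(d)) ** 2


def regression_loss(predicted, actual) -> float:
    """Mean squared error over a batch."""
    predicted = np.asarray(predicted, float).ravel()
    actual = np.asarray(actual, float).ravel()
    if predicted.size == 0:
        raise ValueError("empty batch")
    if not (np.isfinite(predicted).all() and np.isfinite(actual).all()):
        raise ValueError("non-finite inputs")
    return float(np.mean((predicted - actual) ** 2))


# ------------------------------------------------------------ volume handling


def preprocess_volume(vol: np.ndarray) -> np.ndarray:
    """Min-max scale one volume to [0, 1] (constant volumes map to 0)."""
    vol = np.asarray(vol, dtype=float)
    lo, hi = vol.min(), vol.max()
    if hi > lo:
        vol = (vol - lo) / (hi - lo)
    else:
        vol = np.zeros_like(vol)
    return vol


def _stack(volumes: dict[str, np.ndarray], scan_ids, input_shape) -> np.ndarray:
    out = np.empty((len(scan_ids), 1, *input_shape), dtype=float)
    for i, sid in enumerate(scan_ids):
        vol = volumes[sid]
        if vol.shape != tuple(input_shape):
            raise ValueError(f"volume {sid} shape {vol.shape} != expected {input_shape}")
        out[i, 0] = preprocess_volume(vol)
    return out


def embed(volume: np.ndarray, state: ModelState) -> np.ndarray:
    """Embedding vector of one (raw) volume under the shared subnetwork."""
    x = _stack({"_": volume}, ["_"], state.input_shape)
    net = state.network()
    e, _ = net.layers[0].forward(x)
    return e[0]


def predict_score(volume: np.ndarray, state: ModelState) -> float:
    """Regression-head ADAS-Cog13 prediction for one volume (raw points)."""
    x = _stack({"_": volume}, ["_"], state.input_shape)
    out, _ = state.network().forward(x)
    return float(out[0, 0] * state.target_std + state.target_mean)


def predict_pair_slope(state: ModelState, pair, volumes: dict[str, np.ndarray]) -> float:
    """Predicted aging slope of one pair: (yhat_j - yhat_i) / delta_t."""
    yhat_i = predict_score(volumes[pair["scan_id_i"]], state)
    yhat_j = predict_score(volumes[pair["scan_id_j"]], state)
    return (yhat_j - yhat_i) / pair["delta_t_years"]


def normalized_predicted_error(predicted_i, actual_i, delta_t_years):
    """Per-pair NPE (yhat_i - y_i)/dt and its (mean, sd) aggregate."""
    predicted_i = np.asarray(predicted_i, float)
    actual_i = np.asarray(actual_i, float)
    delta_t_years = np.asarray(delta_t_years, float)
    if np.any(delta_t_years <= 0):
        raise ValueError("delta_t_years must be positive")
    npe = (predicted_i - actual_i) / delta_t_years
    return npe, (float(npe.mean()), float(npe.std(ddof=1)) if npe.size > 1 else 0.0)


# ------------------------------------------------------------------- training


def split_subjects(subject_ids, split_fraction: float, rng: np.random.Generator):
    """Random subject-level split; floor(n * fraction) subjects train."""
    subjects = np.asarray(sorted(set(subject_ids)))
    order = rng.permutation(len(subjects))
    n_train = int(math.floor(len(subjects) * split_fraction))
    train = set(subjects[order[:n_train]])
    val = set(subjects[order[n_train:]])
    if train & val:
        raise ValueError("subject overlap between train and validation splits")
    return train, val


def _epoch_losses(net, x_i, x_j, y_std, labels, hp) -> tuple[float, float]:
    backbone, head = net.layers
    e_i, _ = backbone.forward(x_i)
    e_j, _ = backbone.forward(x_j)
    yhat, _ = head.forward(e_i)
    mse = float(np.mean((yhat[:, 0] - y_std) ** 2))
    d = np.linalg.norm(e_i - e_j, axis=1)
    closs = float(
        np.mean(
            np.where(labels == 0, d**2, np.maximum(0.0, hp.margin - d) ** 2)
        )
    )
    return mse, closs


def train(
    pairs: pd.DataFrame,
    volumes: dict[str, np.ndarray],
    hp: HyperParams,
    split_fraction: float = 0.7,
) -> ModelState:
    """Train the dual-loss Siamese network on a labelled pair table.

    ``pairs`` needs columns subject_id, scan_id_i, scan_id_j, score_i,
    delta_t_years, label; ``volumes`` maps scan ids to raw 3D arrays.
    Returns the checkpoint minimizing validation MSE + contrastive loss.
    """
    if pairs.empty:
        raise ValueError("empty pair table")
    first = next(iter(volumes.values()))
    input_shape = first.shape

    rng = np.random.default_rng(np.random.SeedSequence((hp.seed, 0x5EED)))
    train_subj, val_subj = split_subjects(pairs["subject_id"], split_fraction, rng)
    tr = pairs[pairs["subject_id"].isin(train_subj)].reset_index(drop=True)
    va = pairs[pairs["subject_id"].isin(val_subj)].reset_index(drop=True)
    if tr.empty or va.empty:
        raise ValueError("train or validation split has no pairs")

    x_tr_i = _stack(volumes, tr["scan_id_i"], input_shape)
    x_tr_j = _stack(volumes, tr["scan_id_j"], input_shape)
    x_va_i = _stack(volumes, va["scan_id_i"], input_shape)
    x_va_j = _stack(volumes, va["scan_id_j"], input_shape)

    t_mean = float(tr["score_i"].mean())
    t_std = float(tr["score_i"].std(ddof=0)) or 1.0
    y_tr = ((tr["score_i"] - t_mean) / t_std).to_numpy()
    y_va = ((va["score_i"] - t_mean) / t_std).to_numpy()
    lab_tr = tr["label"].to_numpy()
    lab_va = va["label"].to_numpy()

    net = build_network(input_shape, hp)
    backbone, head = net.layers
    opt = Adam(net.params(), hp.learning_rate)

    log_rows = []
    best = (np.inf, 1, get_weights(net))
    n_tr = len(tr)
    for epoch in range(1, hp.epochs + 1):
        opt.set_epoch(epoch, hp.decay_factor, hp.decay_every)
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            bi, bj = x_tr_i[idx], x_tr_j[idx]
            by, blab = y_tr[idx], lab_tr[idx]
            b = len(idx)

            opt.zero_grad()
            e_i, cache_i = backbone.forward(bi)
            e_j, cache_j = backbone.forward(bj)
            yhat, cache_h = head.forward(e_i)

            # regression branch
            dyhat = (2.0 / b) * hp.mse_weight * (yhat - by[:, None])
            de_i = head.backward(dyhat, cache_h)

            # contrastive branch
            diff = e_i - e_j
            d = np.linalg.norm(diff, axis=1)
            safe = np.where(d > 0, d, 1.0)
            unit = diff / safe[:, None]
            grad_d = np.where(
                blab == 0, 2.0 * d, np.where(d < hp.margin, -2.0 * (hp.margin - d), 0.0)
            )
            dcon = (hp.contrastive_weight / b) * grad_d[:, None] * unit
            de_i = de_i + dcon
            de_j = -dcon

            backbone.backward(de_i, cache_i)
            backbone.backward(de_j, cache_j)
            opt.step()

        tr_mse, tr_con = _epoch_losses(net, x_tr_i, x_tr_j, y_tr, lab_tr, hp)
        va_mse, va_con = _epoch_losses(net, x_va_i, x_va_j, y_va, lab_va, hp)
        total = va_mse + va_con
        log_rows.append((epoch, opt.lr, tr_mse, tr_con, va_mse, va_con, total))
        if total < best[0]:
            best = (total, epoch, get_weights(net))

    log = pd.DataFrame(
        log_rows,
        columns=[
            "epoch", "lr", "train_mse", "train_contrastive",
            "val_mse", "val_contrastive", "val_total",
        ],
    )
    state = ModelState(
        hyperparams=hp,
        input_shape=tuple(input_shape),
        weights=best[2],
        target_mean=t_mean,
        target_std=t_std,
        log=log,
        selected_epoch=best[1],
    )
    state.log.attrs["train_subjects"] = sorted(train_subj)
    state.log.attrs["val_subjects"] = sorted(val_subj)
    return state


def predict_cohort(
    state: ModelState, pairs: pd.DataFrame, volumes: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-pair predicted slopes, measured slopes, and NPE for all pairs."""
    scan_ids = sorted(set(pairs["scan_id_i"]) | set(pairs["scan_id_j"]))
    x = _stack(volumes, scan_ids, state.input_shape)
    out, _ = state.network().forward(x)
    yhat = out[:, 0] * state.target_std + state.target_mean
    score = dict(zip(scan_ids, yhat))

    res = pairs.copy()
    res["predicted_score_i"] = res["scan_id_i"].map(score)
    res["predicted_score_j"] = res["scan_id_j"].map(score)
    res["predicted_slope"] = (
        res["predicted_score_j"] - res["predicted_score_i"]
    ) / res["delta_t_years"]
    res["measured_slope"] = res["delta_score"] / res["delta_t_years"]
    res["npe"] = (res["predicted_score_i"] - res["score_i"]) / res["delta_t_years"]
    return res
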