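"""The five VO₂ prediction architectures, training and cross-validation.

Every model shares one skeleton with two input paths.  The dynamic path
takes the 10×d window (10 one-second steps of d dynamic features); for all
variants except the plain LSTM it first passes a same-padded 1-D
convolution over time (64 filters, kernel 3, ReLU), optionally an attention
block on the resulting 10×64 map, then a single 128-unit LSTM whose final
hidden state summarises the window.  The static path is the 6-feature
subject vector, concatenated with that hidden state before a single linear
output unit that predicts VO₂ in L/min.

Variants:
    lstm      — dynamic input straight into the LSTM (no conv, no attention)
    cnn_lstm  — conv + LSTM (the baseline hybrid)
    clta      — conv + temporal (SE) attention + LSTM
    clsa      — conv + spatial attention + LSTM
    clsta     — conv + cascaded spatial→temporal attention + LSTM

Training minimises mean squared error with Adam (lr 0.001, batch 32) and
early-stops on validation RMSE.  Splits are always subject-wise; a window
from one subject never appears on both sides of a split.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import Tensor, concat
from ._autodiff import conv1d_same
from . import attention as attn
from .evaluate import Metrics
from .preprocess import Scaler, WindowSet, zscore_apply, zscore_fit

VARIANTS = ("lstm", "cnn_lstm", "clsa", "clta", "clsta")


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "cnn_lstm"
    n_dynamic: int = 5
    n_static: int = 6
    window_len: int = 10
    cnn_filters: int = 64
    cnn_kernel: int = 3
    lstm_units: int = 128
    sam_kernel: int = 7
    se_ratio: int = 2
    attention_order: str = "sam_first"
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 20
    rng_seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.window_len % self.se_ratio != 0:
            raise ValueError("se_ratio must divide the window length")
        if self.sam_kernel % 2 != 1:
            raise ValueError("sam_kernel must be odd")

    @property
    def has_cnn(self) -> bool:
        return self.variant != "lstm"

    @property
    def has_sam(self) -> bool:
        return self.variant in ("clsa", "clsta")

    @property
    def has_tam(self) -> bool:
        return self.variant in ("clta", "clsta")


class SubjectOverlapError(ValueError):
    """Raised when train/validation/test share a subject (leakage guard)."""


class ScalerMismatchError(ValueError):
    """Raised when windows were standardized with a different scaler."""


def _glorot(rng, shape):
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    if len(shape) == 3:  # conv weight (out, in, k)
        fan_in, fan_out = shape[1] * shape[2], shape[0] * shape[2]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class VO2Model:
    """One architecture instance: parameter store plus the forward graph."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        p: dict[str, Tensor] = {}
        c = config
        lstm_in = c.cnn_filters if c.has_cnn else c.n_dynamic
        if c.has_cnn:
            p["conv_w"] = Tensor(_glorot(rng, (c.cnn_filters, c.n_dynamic,
                                               c.cnn_kernel)), True)
            p["conv_b"] = Tensor(np.zeros(c.cnn_filters), True)
        if c.has_sam:
            k = min(c.sam_kernel, c.cnn_filters)
            if k % 2 == 0:
                k -= 1
            p["sam_w"] = Tensor(_glorot(rng, (1, 2, k)), True)
            p["sam_b"] = Tensor(np.zeros(1), True)
        if c.has_tam:
            # SE bottleneck over the C=window_len time channels.
            cdim, r = c.window_len, c.se_ratio
            p["tam_w1"] = Tensor(_glorot(rng, (cdim // r, cdim)), True)
            p["tam_w2"] = Tensor(_glorot(rng, (cdim, cdim // r)), True)
        h = c.lstm_units
        p["lstm_wx"] = Tensor(_glorot(rng, (lstm_in, 4 * h)), True)
        p["lstm_wh"] = Tensor(_glorot(rng, (h, 4 * h)), True)
        p["lstm_b"] = Tensor(np.zeros(4 * h), True)
        p["out_w"] = Tensor(_glorot(rng, (h + c.n_static, 1)), True)
        p["out_b"] = Tensor(np.zeros(1), True)
        self.params = p

    @property
    def num_params(self) -> int:
        return sum(t.data.size for t in self.params.values())

    def forward(self, dynamic: np.ndarray, static: np.ndarray) -> Tensor:
        """dynamic: (N, 10, d); static: (N, 6) → predictions (N,)."""
        c, p = self.config, self.params
        n = dynamic.shape[0]
        x = Tensor(dynamic)
        if c.has_cnn:
            # conv over time: channels = features
            z = conv1d_same(x.transpose((0, 2, 1)), p["conv_w"], p["conv_b"])
            f = z.relu().transpose((0, 2, 1))        # (N, C=10, W=filters)
            if c.variant == "clsa":
                f, _ = attn.sam_forward(f, p["sam_w"], p["sam_b"])
            elif c.variant == "clta":
                f, _ = attn.tam_forward(f, p["tam_w1"], p["tam_w2"])
            elif c.variant == "clsta":
                f, _, _ = attn.stam_forward(f, p["sam_w"], p["sam_b"],
                                            p["tam_w1"], p["tam_w2"],
                                            order=c.attention_order)
            seq = f
        else:
            seq = x
        h = self._lstm(seq, n)
        fused = concat([h, Tensor(static)], axis=1)
        out = fused @ p["out_w"] + p["out_b"]
        return out.reshape(n)

    def _lstm(self, seq: Tensor, n: int) -> Tensor:
        c, p = self.config, self.params
        hdim = c.lstm_units
        h = Tensor(np.zeros((n, hdim)))
        cell = Tensor(np.zeros((n, hdim)))
        for t in range(c.window_len):
            x_t = seq[:, t, :]
            gates = x_t @ p["lstm_wx"] + h @ p["lstm_wh"] + p["lstm_b"]
            i = gates[:, 0 * hdim:1 * hdim].sigmoid()
            f = gates[:, 1 * hdim:2 * hdim].sigmoid()
            g = gates[:, 2 * hdim:3 * hdim].tanh()
            o = gates[:, 3 * hdim:4 * hdim].sigmoid()
            cell = f * cell + i * g
            h = o * cell.tanh()
        return h

    # -- parameter plumbing for the optimizer / checkpoints ----------------

    def get_state(self) -> dict:
        return {k: t.data.copy() for k, t in self.params.items()}

    def set_state(self, state: dict) -> None:
        for k, t in self.params.items():
            t.data = state[k].copy()


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict, lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedModel:
    config: ModelConfig
    state: dict
    history: pd.DataFrame        # epoch, train_rmse, val_rmse
    scaler: Scaler
    best_epoch: int

    def _model(self) -> VO2Model:
        m = VO2Model(self.config)
        m.set_state(self.state)
        return m

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{f"param_{k}": v for k, v in self.state.items()})
        meta = {"config": asdict(self.config),
                "scaler": self.scaler.to_dict(),
                "best_epoch": self.best_epoch,
                "history": self.history.to_dict(orient="list")}
        path.with_suffix(".json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = Path(path)
        data = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = ModelConfig(**meta["config"])
        state = {k[len("param_"):]: data[k] for k in data.files}
        return cls(config=cfg, state=state,
                   history=pd.DataFrame(meta["history"]),
                   scaler=Scaler.from_dict(meta["scaler"]),
                   best_epoch=meta["best_epoch"])


def _check_disjoint(*window_sets: WindowSet) -> None:
    seen: set[str] = set()
    for ws in window_sets:
        subjects = set(ws.subjects)
        if seen & subjects:
            raise SubjectOverlapError(
                f"subjects {sorted(seen & subjects)} appear in multiple splits")
        seen |= subjects


def _check_scaler(scaler: Scaler, windows: WindowSet) -> None:
    ws = windows.scaler
    if ws is None:
        raise ScalerMismatchError("windows are not standardized")
    same = (np.array_equal(ws.dynamic_mean, scaler.dynamic_mean)
            and np.array_equal(ws.dynamic_std, scaler.dynamic_std)
            and np.array_equal(ws.static_mean, scaler.static_mean)
            and np.array_equal(ws.static_std, scaler.static_std))
    if not same:
        raise ScalerMismatchError("windows standardized with a different scaler")


def build_model(config: ModelConfig) -> VO2Model:
    return VO2Model(config)


def _rmse_on(model: VO2Model, ws: WindowSet) -> float:
    pred = model.forward(ws.dynamic, ws.static).data
    return float(np.sqrt(np.mean((pred - ws.labels) ** 2)))


def train(config: ModelConfig, train_windows: WindowSet,
          val_windows: WindowSet) -> TrainedModel:
    """Fit one model with Adam + early stopping on validation RMSE.

    Both window sets must be standardized with the same (train-fit) scaler;
    the train and validation subject sets must be disjoint.  Fully seeded:
    parameter init and batch order derive from config.rng_seed.
    """
    _check_disjoint(train_windows, val_windows)
    if train_windows.scaler is None or val_windows.scaler is None:
        raise ScalerMismatchError("windows must be standardized before training")
    _check_scaler(train_windows.scaler, val_windows)

    model = VO2Model(config)
    opt = Adam(model.params, config.learning_rate)
    rng = np.random.default_rng(config.rng_seed + 1)
    n = len(train_windows)
    best_val, best_state, best_epoch = np.inf, model.get_state(), 0
    rows = []
    patience = config.early_stop_patience
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            pred = model.forward(train_windows.dynamic[idx],
                                 train_windows.static[idx])
            err = pred - Tensor(train_windows.labels[idx])
            loss = (err * err).mean()
            loss.backward()
            opt.step()
        tr = _rmse_on(model, train_windows)
        va = _rmse_on(model, val_windows)
        rows.append({"epoch": epoch, "train_rmse": tr, "val_rmse": va})
        if va < best_val - 1e-12:
            best_val, best_state, best_epoch = va, model.get_state(), epoch
        elif epoch - best_epoch >= patience:
            break
    model.set_state(best_state)
    return TrainedModel(config=config, state=best_state,
                        history=pd.DataFrame(rows),
                        scaler=train_windows.scaler, best_epoch=best_epoch)


def predict(trained: TrainedModel, windows: WindowSet) -> np.ndarray:
    """Per-window VO₂ estimates (L/min); deterministic given the checkpoint."""
    _check_scaler(trained.scaler, windows)
    model = trained._model()
    return model.forward(windows.dynamic, windows.static).data.copy()


# ---------------------------------------------------------------------------
# Subject-wise cross-validation.

@dataclass(frozen=True)
class FoldReport:
    """Per-variant cross-validation outcome mirroring a train/val/test table."""

    variant: str
    rows: pd.DataFrame          # variant, split, fold, rmse, mae, r2, n
    test_predictions: np.ndarray  # fold-mean prediction per test window
    test_labels: np.ndarray
    test_subjects: tuple


def split_subjects(subjects: list[str], k: int, n_test: int,
                   seed: int) -> tuple[list[str], list[list[str]]]:
    """Seeded hold-out of `n_test` subjects + k validation folds of the rest."""
    subjects = sorted(subjects)
    if len(subjects) < k + n_test:
        raise ValueError(f"need at least {k + n_test} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    test = sorted(order[:n_test])
    rest = order[n_test:]
    folds = [sorted(rest[i::k]) for i in range(k)]
    return test, folds


def crossvalidate(windows: WindowSet, variants=("cnn_lstm",), k: int = 6,
                  n_test_subjects: int = 3, seed: int = 0,
                  config: ModelConfig | None = None,
                  scaler_scope: str = "train_only") -> dict[str, FoldReport]:
    """Hold out a fixed test set, then k-fold cross-validate the rest.

    Per fold, the scaler is fit on the training subjects only (default) or
    on all windows when scaler_scope="all"; metrics for train, validation
    and test splits are reported per fold plus mean-over-folds and pooled
    aggregates.  The test prediction reported per window is the mean over
    the k fold models.
    """
    if scaler_scope not in ("train_only", "all"):
        raise ValueError("scaler_scope must be 'train_only' or 'all'")
    base = config or ModelConfig(n_dynamic=windows.dynamic.shape[-1])
    test_subj, folds = split_subjects(windows.subjects, k, n_test_subjects, seed)
    test_ws = windows.for_subjects(test_subj)
    reports = {}
    for vi, variant in enumerate(variants):
        rows, test_preds = [], []
        pooled: dict[str, list] = {"train": [], "val": [], "test": []}
        for fi, val_subj in enumerate(folds):
            train_subj = [s for fold in folds for s in fold if fold is not folds[fi]]
            tr_ws = windows.for_subjects(train_subj)
            va_ws = windows.for_subjects(val_subj)
            fit_on = windows if scaler_scope == "all" else tr_ws
            scaler = zscore_fit(fit_on)
            tr_s, va_s, te_s = (zscore_apply(scaler, w)
                                for w in (tr_ws, va_ws, test_ws))
            cfg = replace(base, variant=variant,
                          n_dynamic=windows.dynamic.shape[-1],
                          rng_seed=base.rng_seed + 1000 * vi + fi)
            trained = train(cfg, tr_s, va_s)
            for split, ws in (("train", tr_s), ("val", va_s), ("test", te_s)):
                pred = predict(trained, ws)
                m = Metrics.compute(ws.labels, pred)
                rows.append({"variant": variant, "split": split, "fold": fi,
                             "rmse": m.rmse, "mae": m.mae, "r2": m.r2, "n": m.n})
                pooled[split].append((ws.labels, pred))
                if split == "test":
                    test_preds.append(pred)
        df = pd.DataFrame(rows)
        agg = []
        for split in ("train", "val", "test"):
            sub = df[df["split"] == split]
            agg.append({"variant": variant, "split": split, "fold": "mean",
                        "rmse": sub["rmse"].mean(), "mae": sub["mae"].mean(),
                        "r2": sub["r2"].mean(), "n": int(sub["n"].mean())})
            y = np.concatenate([a for a, _ in pooled[split]])
            p = np.concatenate([b for _, b in pooled[split]])
            m = Metrics.compute(y, p)
            agg.append({"variant": variant, "split": split, "fold": "pooled",
                        "rmse": m.rmse, "mae": m.mae, "r2": m.r2, "n": m.n})
        df = pd.concat([df, pd.DataFrame(agg)], ignore_index=True)
        reports[variant] = FoldReport(
            variant=variant, rows=df,
            test_predictions=np.mean(test_preds, axis=0),
            test_labels=test_ws.labels.copy(),
            test_subjects=tuple(test_subj))
    return reports
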