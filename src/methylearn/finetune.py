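"""Transfer-learning prediction heads on top of a pretrained encoder.

A trained VAE's encoder (hidden stack + mu projection) is copied — not
shared — into a prediction network and fine-tuned end-to-end together with
a freshly initialised ReLU head.  Supported tasks:

* classification — softmax output, cross-entropy loss;
* regression — linear output, mean squared error (targets z-scored
  internally from the training set, predictions un-scored);
* multi-output regression — one output per component; with
  ``simplex_constrain`` the outputs pass through a softmax so predicted
  rows are non-negative and sum to one (cell-type proportions), with MSE
  computed on the simplex outputs.

Early stopping and best-validation-epoch snapshotting follow the same
rules as VAE training.  ``train_mlp_baseline`` trains the identical
architecture from random initialisation (no pretraining) for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrays import MethylationArray
from .errors import ConfigError, ContractError, DataError
from .nn import FineTuneNet, run_training, softmax
from .vae import TrainConfig, VAEEmbedder, EncoderTopology

TASK_KINDS = ("classification", "regression", "multi_output")


@dataclass
class PredictionTask:
    """What to predict: task kind, pheno target column(s), output width."""

    kind: str
    target_cols: list[str]
    n_outputs: int
    simplex_constrain: bool = False

    def __post_init__(self):
        if self.kind not in TASK_KINDS:
            raise ConfigError(f"kind must be one of {TASK_KINDS}, got {self.kind!r}")
        if self.n_outputs < 1:
            raise ConfigError(f"n_outputs must be >= 1, got {self.n_outputs}")
        if isinstance(self.target_cols, str):
            self.target_cols = [self.target_cols]
        if self.kind == "classification" and len(self.target_cols) != 1:
            raise ConfigError("classification uses exactly one target column")


@dataclass
class Predictions:
    """Prediction output bundle (fields populated per task kind)."""

    values: np.ndarray
    probabilities: pd.DataFrame | None = None
    labels: np.ndarray | None = None

    def to_frame(self, sample_ids) -> pd.DataFrame:
        if self.probabilities is not None:
            out = self.probabilities.copy()
            out.index = sample_ids
            out["predicted"] = self.labels
            return out
        return pd.DataFrame(self.values, index=sample_ids)


class FineTuneModel:
    """Encoder + prediction head; scikit-learn style fit/predict surface.

    Build with :func:`build_finetune_model` (encoder copied from a trained
    VAE) or :func:`train_mlp_baseline` (random encoder).  Fitted attributes:
    ``training_log_``, ``best_epoch_``, ``classes_`` (classification),
    ``y_mean_`` / ``y_std_`` (regression standardisation).
    """

    def __init__(self, net: FineTuneNet, task: PredictionTask, head_widths,
                 pretrained: bool = True):
        self.net = net
        self.task = task
        self.head_widths = list(head_widths)
        self.pretrained = pretrained
        self.loss_weights = None  # optional per-class CE weights

    # -- target encoding -------------------------------------------------
    def _targets(self, arr: MethylationArray, fit_scaler: bool = False) -> np.ndarray:
        missing = [c for c in self.task.target_cols if c not in arr.pheno.columns]
        if missing:
            raise DataError(f"target columns missing from pheno: {missing}")
        raw = arr.pheno[self.task.target_cols]
        if self.task.kind == "classification":
            col = raw.iloc[:, 0]
            if col.isna().any():
                bad = list(arr.beta.index[col.isna()])
                raise DataError(f"NaN targets for samples {bad}")
            if fit_scaler or not hasattr(self, "classes_"):
                self.classes_ = np.array(sorted(col.astype(str).unique()))
                if len(self.classes_) != self.task.n_outputs:
                    raise DataError(
                        f"{len(self.classes_)} classes in data but task.n_outputs="
                        f"{self.task.n_outputs}"
                    )
            lut = {c: i for i, c in enumerate(self.classes_)}
            try:
                idx = np.array([lut[str(v)] for v in col])
            except KeyError as e:
                raise DataError(f"unseen class label {e.args[0]!r}") from e
            Y = np.zeros((len(idx), self.task.n_outputs))
            Y[np.arange(len(idx)), idx] = 1.0
            return Y
        Y = raw.to_numpy(dtype=float)
        if not np.isfinite(Y).all():
            bad = list(arr.beta.index[~np.isfinite(Y).all(axis=1)])
            raise DataError(f"NaN targets for samples {bad}")
        if self.task.kind == "regression":
            if fit_scaler:
                self.y_mean_ = Y.mean(axis=0)
                self.y_std_ = Y.std(axis=0)
                self.y_std_[self.y_std_ == 0] = 1.0
            Y = (Y - self.y_mean_) / self.y_std_
        elif self.task.simplex_constrain:
            if (Y < -1e-9).any() or np.abs(Y.sum(axis=1) - 1.0).max() > 1e-6:
                raise DataError("simplex targets must be non-negative and sum to 1")
        return Y

    # -- training --------------------------------------------------------
    def fit(self, train: MethylationArray, val: MethylationArray,
            config: TrainConfig) -> "FineTuneModel":
        if train.cpg_ids != val.cpg_ids:
            raise ContractError("train/val CpG sets differ")
        if train.n_cpgs != self.net.input_dim:
            raise ContractError(
                f"data has {train.n_cpgs} CpGs, encoder expects {self.net.input_dim}"
            )
        Xtr, Xva = train.values, val.values
        Ytr = self._targets(train, fit_scaler=True)
        Yva = self._targets(val)

        net = self.net

        def train_step(idx, rng):
            loss, fwd = net.loss(Xtr[idx], Ytr[idx])
            grads = net.backward(Xtr[idx], Ytr[idx], fwd)
            return loss, grads

        def val_metrics():
            loss, _ = net.loss(Xva, Yva)
            return {"val_loss": loss}

        log, _, best_epoch = run_training(net, Xtr, train_step, val_metrics, config)
        self.training_log_ = log
        self.best_epoch_ = best_epoch
        self.cpg_ids_ = train.cpg_ids
        return self

    # -- inference -------------------------------------------------------
    def _check(self, arr) -> np.ndarray:
        X = arr.values if isinstance(arr, MethylationArray) else np.asarray(arr, dtype=float)
        if X.shape[1] != self.net.input_dim:
            raise ContractError(
                f"input has {X.shape[1]} CpGs, model expects {self.net.input_dim}"
            )
        return X

    def embed(self, arr) -> np.ndarray:
        """Fine-tuned encoder embedding (posterior-mean projection)."""
        return self.net.embed(self._check(arr))

    def raw_outputs(self, arr) -> np.ndarray:
        out, _ = self.net.forward(self._check(arr))
        return out

    def predict_proba(self, arr) -> np.ndarray:
        if self.net.out_kind != "softmax":
            raise ContractError("predict_proba requires a softmax head")
        return softmax(self.raw_outputs(arr))

    def predict(self, arr) -> Predictions:
        out = self.raw_outputs(arr)
        if self.task.kind == "classification":
            probs = softmax(out)
            labels = self.classes_[probs.argmax(axis=1)]
            return Predictions(
                values=probs,
                probabilities=pd.DataFrame(probs, columns=list(self.classes_)),
                labels=labels,
            )
        if self.task.kind == "multi_output" and self.task.simplex_constrain:
            return Predictions(values=softmax(out))
        if self.task.kind == "regression":
            return Predictions(values=out * self.y_std_ + self.y_mean_)
        return Predictions(values=out)

    def input_gradients(self, arr, output_index) -> np.ndarray:
        """Gradient of the selected raw output (logit for classifiers)
        with respect to the input betas; used by expected-gradients SHAP."""
        return self.net.input_gradients(self._check(arr), output_index)

    # -- persistence -----------------------------------------------------
    def save(self, path):
        """Single-file HDF5 checkpoint (weights, task descriptor, scalers)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["checkpoint_version"] = "1"
            f.attrs["kind"] = "finetune"
            f.attrs["task_kind"] = self.task.kind
            f.attrs["target_cols"] = list(self.task.target_cols)
            f.attrs["n_outputs"] = self.task.n_outputs
            f.attrs["simplex_constrain"] = self.task.simplex_constrain
            f.attrs["pretrained"] = self.pretrained
            f.attrs["input_dim"] = self.net.input_dim
            f.attrs["encoder_widths"] = list(self.net.encoder_widths)
            f.attrs["latent_dim"] = self.net.latent_dim
            f.attrs["head_widths"] = list(self.net.head_widths)
            f.attrs["out_kind"] = self.net.out_kind
            f.attrs["loss_kind"] = getattr(self.net, "loss_kind", "ce")
            if hasattr(self, "best_epoch_"):
                f.attrs["best_epoch"] = self.best_epoch_
            if hasattr(self, "classes_"):
                f.create_dataset("classes", data=np.array(self.classes_, dtype=object),
                                 dtype=h5py.string_dtype())
            if hasattr(self, "y_mean_"):
                f.create_dataset("y_mean", data=self.y_mean_)
                f.create_dataset("y_std", data=self.y_std_)
            g = f.create_group("weights")
            for i, p in enumerate(self.net.parameters()):
                g.create_dataset(str(i), data=p)
            if hasattr(self, "training_log_") and self.training_log_:
                lg = f.create_group("log")
                for key in self.training_log_[0]:
                    lg.create_dataset(key, data=[e[key] for e in self.training_log_])
        return path

    @classmethod
    def load(cls, path) -> "FineTuneModel":
        import h5py

        with h5py.File(path, "r") as f:
            task = PredictionTask(
                kind=str(f.attrs["task_kind"]),
                target_cols=[str(c) for c in f.attrs["target_cols"]],
                n_outputs=int(f.attrs["n_outputs"]),
                simplex_constrain=bool(f.attrs["simplex_constrain"]),
            )
            net = FineTuneNet(
                int(f.attrs["input_dim"]),
                [int(w) for w in f.attrs["encoder_widths"]],
                int(f.attrs["latent_dim"]),
                [int(w) for w in f.attrs["head_widths"]],
                int(f.attrs["n_outputs"]),
                str(f.attrs["out_kind"]),
                np.random.default_rng(0),
            )
            net.loss_kind = str(f.attrs["loss_kind"])
            state = [np.asarray(f["weights"][str(i)])
                     for i in range(len(net.parameters()))]
            net.set_state(state)
            model = cls(net, task, list(net.head_widths),
                        pretrained=bool(f.attrs["pretrained"]))
            if "classes" in f:
                model.classes_ = np.array(
                    [s.decode() if isinstance(s, bytes) else str(s) for s in f["classes"]]
                )
            if "y_mean" in f:
                model.y_mean_ = np.asarray(f["y_mean"])
                model.y_std_ = np.asarray(f["y_std"])
            if "best_epoch" in f.attrs:
                model.best_epoch_ = int(f.attrs["best_epoch"])
            if "log" in f:
                lg = f["log"]
                keys = list(lg.keys())
                n = len(lg[keys[0]])
                model.training_log_ = [
                    {k: (int(lg[k][i]) if k == "epoch" else float(lg[k][i]))
                     for k in keys} for i in range(n)
                ]
        return model


# ---------------------------------------------------------------------------
# Constructors / functional wrappers
# ---------------------------------------------------------------------------

def _out_kind(task: PredictionTask) -> tuple[str, str]:
    if task.kind == "classification":
        return "softmax", "ce"
    if task.kind == "multi_output" and task.simplex_constrain:
        return "softmax", "mse"
    return "linear", "mse"


def build_finetune_model(vae: VAEEmbedder, head_widths, task: PredictionTask,
                         seed: int = 0) -> FineTuneModel:
    """Copy a trained VAE's encoder into a fresh prediction network.

    The encoder weights are deep-copied (mutating the fine-tuned model never
    touches the source VAE); the head is randomly initialised from ``seed``
    with small output weights so a fresh classifier starts near uniform.
    """
    if not head_widths:
        raise ConfigError("head_widths must be non-empty")
    if not hasattr(vae, "net_"):
        raise ConfigError("vae must be trained before building a fine-tune model")
    out_kind, loss_kind = _out_kind(task)
    rng = np.random.default_rng(seed)
    net = FineTuneNet.from_vae(vae.net_, list(head_widths), task.n_outputs,
                               out_kind, rng)
    net.loss_kind = loss_kind
    return FineTuneModel(net, task, head_widths, pretrained=True)


def train_finetune(model: FineTuneModel, train: MethylationArray,
                   val: MethylationArray, config: TrainConfig) -> FineTuneModel:
    """Fine-tune encoder + head end-to-end; snapshot at best validation loss."""
    return model.fit(train, val, config)


def predict(model: FineTuneModel, arr: MethylationArray) -> Predictions:
    return model.predict(arr)


def train_mlp_baseline(train: MethylationArray, val: MethylationArray,
                       topology: EncoderTopology, task: PredictionTask,
                       config: TrainConfig, head_widths=(32,)) -> FineTuneModel:
    """Same architecture and training as fine-tuning, but the encoder is
    randomly initialised — the no-transfer-learning baseline."""
    out_kind, loss_kind = _out_kind(task)
    rng = np.random.default_rng(config.seed)
    net = FineTuneNet(train.n_cpgs, list(topology.hidden_widths),
                      topology.latent_dim, list(head_widths), task.n_outputs,
                      out_kind, rng)
    net.loss_kind = loss_kind
    model = FineTuneModel(net, task, head_widths, pretrained=False)
    return model.fit(train, val, config)
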