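"""Neural surrogate signal generators.

Two fully connected networks learn to reproduce Bloch-McConnell signal
trajectories orders of magnitude faster than numerical integration:

* :class:`DynamicSurrogate` — an autoregressive per-element network.  Each
  inference cycle receives the tissue parameters, the scanner parameters of
  the element being predicted (B1, offset, Tp, Trec, FA, B0) and the
  previous signal element, and emits the next element; rollouts therefore
  work for any schedule length.
* :class:`AppOptimizedSurrogate` — a whole-trajectory network for one fixed
  acquisition schedule; a single pass emits all N elements at once.

Both use the same architecture: input, two hidden layers of 256 units with
sigmoid activations, and a linear output layer, trained with ADAM on a mean
squared error loss (learning rate 1e-4, batch size 2048, 90/10
train/validation split, early stopping).  Training is delegated to
scikit-learn's MLPRegressor; inference is a plain forward pass over the
extracted weights so saved models are framework-independent.

The first inference cycle of the dynamic network is seeded with a reserved
previous-signal constant of 1.0 plus a binary first-cycle flag, both part of
the serialized feature codec.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.neural_network import MLPRegressor

from .dictionary import Dictionary
from .metrics import evaluate_trajectories
from .sequences import Protocol

CHECKPOINT_SCHEMA = "cestgen-surrogate-1"
#: per-element scanner features of the dynamic network, in codec order
DYNAMIC_SCAN_FEATURES = ("b1_ut", "offset_ppm", "tp_s", "trec_s", "fa_deg", "b0_t")
#: scan scalars of the application-optimized network
STATIC_SCAN_FEATURES = ("tp_s", "trec_s", "b0_t", "n_p")
#: reserved previous-signal input of the first dynamic inference cycle
BOOTSTRAP_SIGNAL = 1.0


# ---------------------------------------------------------------------------
# feature codec


#: a positive feature range wider than this many decades is log-compressed
LOG_DECADES = 2.0


@dataclass
class FeatureCodec:
    """Scaling of named features onto the unit interval.

    Each feature is scaled affinely between its declared bounds; features
    whose declared range is positive and spans more than two decades (e.g.
    exchange rates of 5-1500 1/s, volume fractions of 2e-4-0.27) are
    log10-compressed first, so the network resolves the physically dense
    low end of those axes.  The same codec is applied at training and
    inference time and is serialized with the model.  Features outside the
    declared range are clamped to the bounds with a warning (never silently
    extrapolated).  Constant features (lo == hi) map to 0.5.
    """

    names: Tuple[str, ...]
    lo: np.ndarray
    hi: np.ndarray
    log_features: Tuple[str, ...] = ()

    def __post_init__(self):
        self.names = tuple(self.names)
        self.lo = np.asarray(self.lo, float)
        self.hi = np.asarray(self.hi, float)
        self.log_features = tuple(self.log_features)
        if not (len(self.names) == self.lo.size == self.hi.size):
            raise ValueError("codec names/bounds disagree")
        if (self.hi < self.lo).any():
            raise ValueError("codec bounds must satisfy lo <= hi")
        unknown = set(self.log_features) - set(self.names)
        if unknown:
            raise ValueError(f"unknown log features {sorted(unknown)}")
        self._log_mask = np.array([n in self.log_features for n in self.names])
        if self._log_mask.any() and (self.lo[self._log_mask] <= 0).any():
            raise ValueError("log-scaled features need positive bounds")

    @classmethod
    def auto_log_features(cls, names, lo, hi) -> Tuple[str, ...]:
        """Features with positive bounds spanning > ``LOG_DECADES`` decades."""
        out = []
        for n, a, b in zip(names, lo, hi):
            if a > 0 and b / a > 10.0**LOG_DECADES:
                out.append(n)
        return tuple(out)

    @property
    def n_features(self) -> int:
        return len(self.names)

    def transform(self, x: np.ndarray, warn_clip: bool = True) -> np.ndarray:
        x = np.asarray(x, float)
        if x.shape[-1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {x.shape[-1]}"
            )
        lo, hi = self.lo.copy(), self.hi.copy()
        if self._log_mask.any():
            x = x.copy()
            m = self._log_mask
            with np.errstate(divide="ignore", invalid="ignore"):
                x[..., m] = np.log10(np.maximum(x[..., m], 1e-300))
            lo[m] = np.log10(self.lo[m])
            hi[m] = np.log10(self.hi[m])
        span = hi - lo
        const = span == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            xs = (x - lo) / np.where(const, 1.0, span)
        xs[..., const] = 0.5
        if warn_clip:
            out = (xs < -1e-9) | (xs > 1 + 1e-9)
            if out.any():
                bad = [self.names[j] for j in np.unique(np.nonzero(out)[-1])]
                warnings.warn(
                    f"{int(out.sum())} feature value(s) outside the codec "
                    f"range were clamped: {bad}", stacklevel=2,
                )
        return np.clip(xs, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {"names": list(self.names), "lo": self.lo.tolist(),
                "hi": self.hi.tolist(),
                "log_features": list(self.log_features)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureCodec":
        return cls(tuple(d["names"]), np.asarray(d["lo"]), np.asarray(d["hi"]),
                   tuple(d.get("log_features", ())))


def tissue_columns(params: pd.DataFrame) -> List[str]:
    """Tissue-parameter columns are the dotted ``<pool>.<field>`` names."""
    return [c for c in params.columns if "." in c]


def _codec_from_dictionary(d: Dictionary, feature_names, extra=()) -> FeatureCodec:
    """Bounds come from the dictionary's declared ranges where available,
    otherwise from the empirical span of the data."""
    sched = d.element_schedule()
    lo, hi = [], []
    for name in feature_names:
        if name in d.ranges:
            a, b = d.ranges[name]
        elif name == "b0_t":
            vals = d.params["b0_t"].to_numpy(float)
            a, b = (3.0, 11.7) if vals.min() != vals.max() else (vals[0], vals[0])
        elif name in sched:
            arr = np.asarray(sched[name], float)
            a, b = float(arr.min()), float(arr.max())
        elif name in d.params.columns:
            arr = d.params[name].to_numpy(float)
            a, b = float(arr.min()), float(arr.max())
        else:
            raise KeyError(f"no range source for feature {name!r}")
        lo.append(a)
        hi.append(b)
    names = tuple(feature_names) + tuple(n for n, _, _ in extra)
    lo += [a for _, a, _ in extra]
    hi += [b for _, _, b in extra]
    log_feats = FeatureCodec.auto_log_features(names, lo, hi)
    return FeatureCodec(names, np.asarray(lo), np.asarray(hi), log_feats)


# ---------------------------------------------------------------------------
# training pairs


def make_training_pairs(d: Dictionary, variant: str):
    """Assemble raw (unscaled) feature/target tables from a dictionary.

    dynamic
        One pair per trajectory element: features are the tissue parameters,
        the scanner parameters of the predicted element, the previous signal
        element (reserved constant for the first cycle) and the first-cycle
        flag; the target is that element's signal.  N pairs per trajectory.
    app-optimized
        One pair per trajectory: tissue + scan scalars -> the full N-vector.

    Returns ``(feature_names, X, y)``.
    """
    b, n = d.signals.shape
    t_cols = tissue_columns(d.params)
    if variant == "dynamic":
        if n < 2:
            raise ValueError("dynamic pairing needs trajectories of length >= 2")
        sched = d.element_schedule()
        blocks = [np.repeat(d.params[c].to_numpy(float), n) for c in t_cols]
        blocks += [np.asarray(sched[c], float).reshape(-1)
                   for c in DYNAMIC_SCAN_FEATURES]
        s_prev = np.hstack(
            [np.full((b, 1), BOOTSTRAP_SIGNAL), d.signals[:, :-1]]
        ).reshape(-1)
        first = np.hstack([np.ones((b, 1)), np.zeros((b, n - 1))]).reshape(-1)
        blocks += [s_prev, first]
        names = t_cols + list(DYNAMIC_SCAN_FEATURES) + ["s_prev", "first_cycle"]
        return names, np.column_stack(blocks), d.signals.reshape(-1)
    if variant == "app-optimized":
        cols = t_cols + list(STATIC_SCAN_FEATURES)
        x = np.column_stack([d.params[c].to_numpy(float) for c in cols])
        return cols, x, d.signals.copy()
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# estimators


class _SurrogateBase(BaseEstimator):
    """Shared training loop and forward pass."""

    variant: str = ""

    def __init__(
        self,
        hidden_layer_sizes=(256, 256),
        activation="logistic",
        learning_rate_init=1e-4,
        batch_size=2048,
        max_epochs=200,
        patience=10,
        validation_fraction=0.1,
        early_stopping=True,
        tol=1e-8,
        random_state=0,
        verbose=False,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.learning_rate_init = learning_rate_init
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.early_stopping = early_stopping
        self.tol = tol
        self.random_state = random_state
        self.verbose = verbose

    # -- fitting -----------------------------------------------------------
    def _fit_mlp(self, xs: np.ndarray, y: np.ndarray) -> None:
        mlp = MLPRegressor(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            activation=self.activation,
            solver="adam",
            learning_rate_init=self.learning_rate_init,
            batch_size=self.batch_size,
            max_iter=self.max_epochs,
            early_stopping=self.early_stopping,
            validation_fraction=self.validation_fraction,
            n_iter_no_change=self.patience,
            tol=self.tol,
            shuffle=True,
            random_state=self.random_state,
            verbose=self.verbose,
        )
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            mlp.fit(xs, y)
        if not np.isfinite(mlp.loss_):
            raise RuntimeError(
                f"training diverged (loss={mlp.loss_}); inputs scaled? "
                f"lr={self.learning_rate_init}, batch={self.batch_size}"
            )
        self.weights_ = [(w.copy(), c.copy())
                         for w, c in zip(mlp.coefs_, mlp.intercepts_)]
        self.loss_curve_ = list(mlp.loss_curve_)
        if self.early_stopping:
            self.validation_scores_ = list(mlp.validation_scores_)
            self.best_validation_score_ = float(mlp.best_validation_score_)
        else:
            self.validation_scores_ = []
            self.best_validation_score_ = float("nan")
        self.n_epochs_ = int(mlp.n_iter_)

    def _forward(self, xs: np.ndarray) -> np.ndarray:
        h = xs
        for w, c in self.weights_[:-1]:
            h = expit(h @ w + c)
        w, c = self.weights_[-1]
        return h @ w + c

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise RuntimeError("model is not fitted")

    # -- element-wise scan feature assembly --------------------------------
    @staticmethod
    def _scan_arrays(params, b1_ut, offset_ppm, tp_s=None, trec_s=None,
                     fa_deg=None):
        b1 = np.atleast_2d(np.asarray(b1_ut, float))
        off = np.atleast_2d(np.asarray(offset_ppm, float))
        b = len(params)
        n = max(b1.shape[-1], off.shape[-1])

        def col(name, override):
            if override is not None:
                return np.broadcast_to(np.atleast_2d(np.asarray(override, float)),
                                       (b, n))
            return np.broadcast_to(
                params[name].to_numpy(float)[:, None], (b, n)
            )

        return {
            "b1_ut": np.broadcast_to(b1, (b, n)),
            "offset_ppm": np.broadcast_to(off, (b, n)),
            "tp_s": col("tp_s", tp_s),
            "trec_s": col("trec_s", trec_s),
            "fa_deg": col("fa_deg", fa_deg),
            "b0_t": np.broadcast_to(params["b0_t"].to_numpy(float)[:, None],
                                    (b, n)),
        }


class DynamicSurrogate(_SurrogateBase):
    """Autoregressive per-element surrogate (any schedule length)."""

    variant = "dynamic"

    def fit(self, dictionary: Dictionary, y=None) -> "DynamicSurrogate":
        names, x, targets = make_training_pairs(dictionary, "dynamic")
        self.feature_names_ = tuple(names)
        self.codec_ = _codec_from_dictionary(
            dictionary, names[:-2],
            extra=[("s_prev", 0.0, 1.0), ("first_cycle", 0.0, 1.0)],
        )
        xs = self.codec_.transform(x, warn_clip=False)
        self._fit_mlp(xs, targets)
        self.n_features_in_ = xs.shape[1]
        self.tissue_columns_ = tuple(names[: -2 - len(DYNAMIC_SCAN_FEATURES)])
        return self

    def predict_signals(
        self,
        params: pd.DataFrame,
        b1_ut,
        offset_ppm,
        tp_s=None,
        trec_s=None,
        fa_deg=None,
    ) -> np.ndarray:
        """Roll out trajectories for a parameter table.

        ``b1_ut`` / ``offset_ppm`` are per-element arrays, (N,) shared or
        (n_rows, N); scan scalars default to the table columns.  The
        predicted element is fed back as the next cycle's input; outputs are
        clipped to the physical range [0, 1].
        """
        self._check_fitted()
        scan = self._scan_arrays(params, b1_ut, offset_ppm, tp_s, trec_s, fa_deg)
        b, n = scan["b1_ut"].shape
        tissue = np.column_stack(
            [params[c].to_numpy(float) for c in self.tissue_columns_]
        )
        out = np.empty((b, n))
        s_prev = np.full(b, BOOTSTRAP_SIGNAL)
        for i in range(n):
            x = np.column_stack(
                [tissue]
                + [scan[c][:, i] for c in DYNAMIC_SCAN_FEATURES]
                + [s_prev, np.full(b, 1.0 if i == 0 else 0.0)]
            )
            s_i = self._forward(self.codec_.transform(x)).ravel()
            out[:, i] = s_prev = np.clip(s_i, 0.0, 1.0)
        return out

    def predict(self, dictionary: Dictionary) -> np.ndarray:
        """Rollout on the parameter table and schedules of ``dictionary``
        (its signals are ignored)."""
        sched = dictionary.element_schedule()
        return self.predict_signals(
            dictionary.params, dictionary.b1_ut, dictionary.offset_ppm,
            tp_s=sched["tp_s"], trec_s=sched["trec_s"], fa_deg=sched["fa_deg"],
        )


class AppOptimizedSurrogate(_SurrogateBase):
    """Whole-trajectory surrogate for one fixed schedule length."""

    variant = "app-optimized"

    def fit(self, dictionary: Dictionary, y=None) -> "AppOptimizedSurrogate":
        names, x, targets = make_training_pairs(dictionary, "app-optimized")
        self.feature_names_ = tuple(names)
        self.codec_ = _codec_from_dictionary(dictionary, names)
        xs = self.codec_.transform(x, warn_clip=False)
        self._fit_mlp(xs, targets)
        self.n_features_in_ = xs.shape[1]
        self.n_outputs_ = targets.shape[1]
        self.tissue_columns_ = tuple(
            n for n in names if n not in STATIC_SCAN_FEATURES
        )
        return self

    def infer_static(self, params: pd.DataFrame) -> np.ndarray:
        """Single-pass inference of all N elements for each table row."""
        self._check_fitted()
        x = np.column_stack(
            [params[c].to_numpy(float) for c in self.feature_names_]
        )
        return np.clip(self._forward(self.codec_.transform(x)), 0.0, 1.0)

    def predict_signals(self, params, b1_ut=None, offset_ppm=None, **_):
        return self.infer_static(params)

    def predict(self, dictionary: Dictionary) -> np.ndarray:
        return self.infer_static(dictionary.params)


# ---------------------------------------------------------------------------
# module-level operations


def train(dictionary: Dictionary, variant: str = "dynamic", **config):
    """Train a surrogate of the requested variant on a dictionary."""
    cls = {"dynamic": DynamicSurrogate, "app-optimized": AppOptimizedSurrogate}
    if variant not in cls:
        raise ValueError(f"unknown variant {variant!r}")
    return cls[variant](**config).fit(dictionary)


def rollout_dynamic(model: DynamicSurrogate, params, protocol: Protocol):
    """Roll out the dynamic surrogate over an arbitrary protocol."""
    if isinstance(params, dict):
        params = pd.DataFrame([params])
    t = protocol.to_table()
    if "b0_t" not in params.columns:
        params = params.assign(b0_t=protocol.b0_t)
    return model.predict_signals(
        params,
        t["b1_ut"].to_numpy(float),
        t["offset_ppm"].to_numpy(float),
        tp_s=t["tp_s"].to_numpy(float),
        trec_s=t["trec_s"].to_numpy(float),
        fa_deg=t["fa_deg"].to_numpy(float),
    )


def infer_static(model: AppOptimizedSurrogate, params) -> np.ndarray:
    if isinstance(params, dict):
        params = pd.DataFrame([params])
    return model.infer_static(params)


#: pooled agreement metrics (NRMSE, Pearson r/p) between trajectory sets
evaluate = evaluate_trajectories


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: _SurrogateBase, path) -> None:
    """Single-file checkpoint: weights + codec + architecture + provenance."""
    model._check_fitted()
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "variant": model.variant,
        "params": model.get_params(),
        "codec": model.codec_.to_dict(),
        "feature_names": list(model.feature_names_),
        "tissue_columns": list(model.tissue_columns_),
        "n_outputs": int(getattr(model, "n_outputs_", 1)),
        "n_epochs": model.n_epochs_,
        "best_validation_score": model.best_validation_score_,
    }
    arrays = {}
    for i, (w, c) in enumerate(model.weights_):
        arrays[f"w{i}"] = w
        arrays[f"c{i}"] = c
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path):
    with np.load(path, allow_pickle=False) as zf:
        meta = json.loads(str(zf["meta"]))
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise RuntimeError(f"{path}: not a {CHECKPOINT_SCHEMA} checkpoint")
        cls = {"dynamic": DynamicSurrogate,
               "app-optimized": AppOptimizedSurrogate}[meta["variant"]]
        model = cls(**meta["params"])
        n_layers = sum(1 for k in zf.files if k.startswith("w"))
        model.weights_ = [(zf[f"w{i}"], zf[f"c{i}"]) for i in range(n_layers)]
    model.codec_ = FeatureCodec.from_dict(meta["codec"])
    model.feature_names_ = tuple(meta["feature_names"])
    model.tissue_columns_ = tuple(meta["tissue_columns"])
    model.n_features_in_ = model.codec_.n_features
    if meta["variant"] == "app-optimized":
        model.n_outputs_ = meta["n_outputs"]
    model.n_epochs_ = meta["n_epochs"]
    model.best_validation_score_ = meta["best_validation_score"]
    return model
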