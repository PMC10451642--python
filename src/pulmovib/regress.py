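"""Regression of pulmonary artery pressure parameters from valve sounds.

Two predictors are provided, both mapping to the three per-cycle pressure
parameters (PASP [mmHg], MRR and MFR [mmHg/ms]):

* a feature-based backward-propagation network — a fully connected
  7-10-10-3 multilayer perceptron over the seven retained sound features
  (``stats.TABLE_FEATURES``), and
* a waveform-based deep model — per-cycle tricuspid and pulmonary sound
  windows resampled to a fixed length feed a small CNN + bidirectional
  LSTM encoder with a 3-output dense head.

Validation is leave-one-group-out over the recording runs: each run is
held out once while the model trains on the others; input and target
standardisation is fit on the training folds only, so no information
leaks from the held-out run.  The figure of merit is the pooled mean
absolute error per parameter over all folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from pulmovib._deepnet import CNNBiLSTM
from pulmovib.stats import PRESSURE_PARAMS, TABLE_FEATURES

__all__ = [
    "BPNNSpec",
    "DeepSpec",
    "EvalResult",
    "train_bpnn",
    "train_deep",
    "leave_one_group_out",
    "evaluate",
    "waveform_dataset",
]


@dataclass
class BPNNSpec:
    """Architecture and training settings of the feature-based network."""

    n_in: int = 7
    hidden: tuple[int, int] = (10, 10)
    n_out: int = 3
    seed: int = 42
    max_iter: int = 2000


@dataclass
class DeepSpec:
    """Reduced-scale waveform model settings (CPU-trainable)."""

    seq_len: int = 256
    conv_filters: tuple[int, int] = (16, 32)
    lstm_hidden: int = 32
    n_out: int = 3
    epochs: int = 40
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 42


@dataclass
class EvalResult:
    """Held-out predictions of one validation fold."""

    fold: int
    measured: np.ndarray   # (n, 3)
    predicted: np.ndarray  # (n, 3)
    mae: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.mae = {
            name: float(np.mean(np.abs(self.predicted[:, j] - self.measured[:, j])))
            for j, name in enumerate(PRESSURE_PARAMS)
        }


class _ScaledModel:
    """Any regressor wrapped with train-fold-only standardisation."""

    def __init__(self, core, x_scaler, y_scaler, flatten):
        self._core = core
        self._xs = x_scaler
        self._ys = y_scaler
        self._flatten = flatten

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self._transform_x(X)
        pred = self._core.predict(Xs)
        return self._ys.inverse_transform(np.asarray(pred))

    def _transform_x(self, X: np.ndarray) -> np.ndarray:
        if self._flatten:
            return self._xs.transform(X)
        # waveform input (n, C, L): standardize per channel
        mu, sd = self._xs
        return (X - mu[None, :, None]) / sd[None, :, None]


def train_bpnn(
    features: pd.DataFrame | np.ndarray,
    targets: pd.DataFrame | np.ndarray,
    spec: BPNNSpec | None = None,
) -> _ScaledModel:
    """Train the fully connected 7-10-10-3 regressor.

    Inputs and targets are standardised (statistics from this training
    set only); the network trains to convergence with L-BFGS, which is
    deterministic for a fixed seed.
    """
    spec = spec or BPNNSpec()
    X = np.asarray(features, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[1] != spec.n_in:
        raise ValueError(f"expected {spec.n_in} feature columns")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite values in features or targets")
    xs = StandardScaler().fit(X)
    ys = StandardScaler().fit(Y)
    net = MLPRegressor(
        hidden_layer_sizes=spec.hidden,
        activation="tanh",  # sigmoidal hidden units
        solver="lbfgs",
        max_iter=spec.max_iter,
        random_state=spec.seed,
    )
    with warnings.catch_warnings():
        # L-BFGS hitting max_iter is fine here: the fit is already at the
        # noise floor and the optimizer is deterministic either way
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(xs.transform(X), ys.transform(Y))
    return _ScaledModel(net, xs, ys, flatten=True)


def train_deep(
    waveforms: np.ndarray,
    targets: np.ndarray,
    spec: DeepSpec | None = None,
) -> _ScaledModel:
    """Train the CNN + Bi-LSTM model on per-cycle waveform pairs.

    ``waveforms`` has shape (n, 2, seq_len): both valve-sound channels,
    already resampled to the fixed length (see :func:`waveform_dataset`).
    """
    spec = spec or DeepSpec()
    X = np.asarray(waveforms, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if X.ndim != 3 or X.shape[2] != spec.seq_len:
        raise ValueError(
            f"waveforms must be (n, channels, {spec.seq_len}); resample first"
        )
    mu = X.mean(axis=(0, 2))
    sd = X.std(axis=(0, 2)) + 1e-12
    ys = StandardScaler().fit(Y)
    net = CNNBiLSTM(
        n_in_channels=X.shape[1], seq_len=spec.seq_len, n_out=spec.n_out,
        conv_filters=spec.conv_filters, lstm_hidden=spec.lstm_hidden,
        seed=spec.seed,
    )
    Xs = (X - mu[None, :, None]) / sd[None, :, None]
    net.fit(Xs, ys.transform(Y), epochs=spec.epochs,
            batch_size=spec.batch_size, lr=spec.lr)
    return _ScaledModel(net, (mu, sd), ys, flatten=False)


def evaluate(pred: np.ndarray, measured: np.ndarray) -> dict:
    """Per-parameter mean absolute error plus the raw scatter pairs."""
    pred = np.asarray(pred, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if pred.shape != measured.shape:
        raise ValueError("prediction/measurement shape mismatch")
    mae = {
        name: float(np.mean(np.abs(pred[:, j] - measured[:, j])))
        for j, name in enumerate(PRESSURE_PARAMS)
    }
    return {"MAE": mae, "pairs": np.stack([measured, pred], axis=-1)}


def leave_one_group_out(
    groups_X: list[np.ndarray],
    groups_Y: list[np.ndarray],
    train_fn,
) -> tuple[list[EvalResult], dict[str, float]]:
    """Rotate each recording run out as the validation set.

    ``train_fn(X, Y)`` must return a fitted model with ``predict``.
    Returns the per-fold results and the pooled MAE per parameter
    (pooling concatenates all held-out predictions before averaging).
    """
    if len(groups_X) < 2:
        raise ValueError("need at least two groups")
    results = []
    all_pred, all_meas = [], []
    for k in range(len(groups_X)):
        if len(groups_X[k]) == 0:
            continue
        X_tr = np.concatenate([g for i, g in enumerate(groups_X) if i != k])
        Y_tr = np.concatenate([g for i, g in enumerate(groups_Y) if i != k])
        model = train_fn(X_tr, Y_tr)
        pred = model.predict(groups_X[k])
        results.append(EvalResult(fold=k, measured=groups_Y[k], predicted=pred))
        all_pred.append(pred)
        all_meas.append(groups_Y[k])
    pred = np.concatenate(all_pred)
    meas = np.concatenate(all_meas)
    pooled = {
        name: float(np.mean(np.abs(pred[:, j] - meas[:, j])))
        for j, name in enumerate(PRESSURE_PARAMS)
    }
    return results, pooled


# ---------------------------------------------------------------------------
# waveform dataset assembly
# ---------------------------------------------------------------------------


def waveform_dataset(
    recording,
    segments,
    seq_len: int = 256,
    denoised: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (2, seq_len) waveform pairs and (3,) pressure targets.

    Each cycle's span of the two (denoised) sound channels is resampled
    by FFT to ``seq_len`` samples; burst timing relative to the cycle
    start, amplitude and carrier content all survive the resampling
    (carriers stay far below the new Nyquist rate).
    """
    from pulmovib import sigproc  # deferred: avoids import cycle

    if denoised is None:
        snd_t = sigproc.denoise_vibration(recording.snd_tricuspid)
        snd_p = sigproc.denoise_vibration(recording.snd_pulmonary)
    else:
        snd_t, snd_p = denoised
    fs = recording.fs
    X, Y = [], []
    for seg in segments:
        i0 = int(round(seg.rise_t * fs))
        i1 = int(round(seg.next_rise_t * fs))
        if i1 > len(snd_t):
            continue
        pair = np.stack([
            _signal.resample(snd_t[i0:i1], seq_len),
            _signal.resample(snd_p[i0:i1], seq_len),
        ])
        X.append(pair)
        Y.append([seg.pasp, seg.mrr, seg.mfr])
    return np.asarray(X), np.asarray(Y)
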