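"""Per-muscle feedforward surrogates mapping kinematics to muscle force.

The supervised dataset pairs a 12-dimensional feature vector — the nine
torso-frame coordinates of the TP/LH/RH head markers plus the three
anthropometric parameters (neck length, shoulder width, head mass) —
with per-muscle forces solved by the enhanced static optimization.  One
small feedforward network (12 → 64 → 32 → 1, ReLU hidden layers, linear
output) is trained per muscle: muscle-specific force scales and roles
favour specialized models over a single multi-output net.

Features and per-muscle labels are Z-score standardized with statistics
fitted on the training split only; the data are split 80/20 into
train+validation vs. test, then the 80% is split 80/20 again, giving
64/16/20 overall.  Training defaults to full-batch L-BFGS (reliable for
nets this small on skewed force targets; an adaptive-moment mini-batch
mode is available) with early stopping on the explicit validation split.

:class:`MuscleForceSurrogate` follows the scikit-learn estimator
protocol (``fit``/``predict``/``get_params``); trained weights are kept
as plain arrays so prediction is an explicit numpy forward pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .anthropometry import AnthroProfile
from .model import NeckModel, MotionTrajectory, forward_markers, scale_model
from .staticopt import SOConfig, solve_trajectory

__all__ = [
    "FEATURE_NAMES",
    "ZScoreNormalizer",
    "SplitIndices",
    "split_dataset",
    "build_dataset",
    "MuscleNet",
    "MuscleForceSurrogate",
    "r2",
    "nrmse",
    "evaluate",
]

#: fixed feature order: marker coordinates then anthropometry
FEATURE_NAMES = [
    "TP_x", "TP_y", "TP_z",
    "LH_x", "LH_y", "LH_z",
    "RH_x", "RH_y", "RH_z",
    "neck_length", "shoulder_width", "head_mass",
]


class ZScoreNormalizer(BaseEstimator):
    """Column-wise Z-score standardization (population SD convention).

    Degenerate columns (σ = 0) get scale 1 so they map to all-zeros
    instead of dividing by zero; a warning is emitted.
    """

    def fit(self, X: np.ndarray) -> "ZScoreNormalizer":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot fit a normalizer on empty data")
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)               # ddof=0
        if np.any(scale == 0):
            warnings.warn("constant feature column(s); scale set to 1", stacklevel=2)
            scale = np.where(scale == 0, 1.0, scale)
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def split_dataset(n_rows: int, seed: int, groups: np.ndarray | None = None) -> SplitIndices:
    """Two-stage shuffled split: 20% test, then 20% of the rest validation.

    With ``groups`` (e.g. per-row model ids) the split is performed on
    whole groups, so no model's frames leak between splits — used for
    the across-anthropometry generalization check.
    """
    if n_rows < 5:
        raise ValueError("need at least 5 rows to split")
    rng = np.random.default_rng(seed)
    if groups is None:
        perm = rng.permutation(n_rows)
        n_test = int(round(0.2 * n_rows))
        n_val = int(round(0.2 * (n_rows - n_test)))
        test = perm[:n_test]
        val = perm[n_test:n_test + n_val]
        train = perm[n_test + n_val:]
        return SplitIndices(np.sort(train), np.sort(val), np.sort(test))
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    perm = rng.permutation(len(uniq))
    n_test = max(int(round(0.2 * len(uniq))), 1)
    n_val = max(int(round(0.2 * (len(uniq) - n_test))), 1)
    gtest = set(uniq[perm[:n_test]])
    gval = set(uniq[perm[n_test:n_test + n_val]])
    idx = np.arange(n_rows)
    in_test = np.array([g in gtest for g in groups])
    in_val = np.array([g in gval for g in groups])
    return SplitIndices(idx[~in_test & ~in_val], idx[in_val], idx[in_test])


def build_dataset(
    profiles: list[AnthroProfile],
    motion: MotionTrajectory,
    base_model: NeckModel,
    so_config: SOConfig | None = None,
    drop_unconverged: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every profile through the motion and assemble the dataset.

    For each profile the base model is rescaled, marker trajectories are
    computed by forward kinematics and muscle forces by inverse dynamics
    plus static optimization.  Rows are profiles × frames; frames whose
    solve did not converge are flagged and (by default) dropped.

    Returns ``(features, labels)``; features carry a ``model_id`` column
    ahead of the 12 canonical feature columns.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    so_config = so_config or SOConfig()
    feat_blocks, label_blocks = [], []
    for pid, profile in enumerate(profiles):
        m = scale_model(base_model, profile)
        markers = np.array([forward_markers(m, qi) for qi in motion.q])
        forces = solve_trajectory(m, motion, so_config)
        feats = pd.DataFrame(
            markers.reshape(motion.n_frames, 9), columns=FEATURE_NAMES[:9]
        )
        feats["neck_length"] = profile.neck_length
        feats["shoulder_width"] = profile.shoulder_width
        feats["head_mass"] = profile.head_mass
        feats.insert(0, "model_id", pid)
        feats["converged"] = forces.converged
        labels = forces.to_frame().drop(columns="time")
        if drop_unconverged:
            keep = forces.converged
            feats, labels = feats[keep], labels[keep]
        feat_blocks.append(feats)
        label_blocks.append(labels)
    features = pd.concat(feat_blocks, ignore_index=True)
    labels = pd.concat(label_blocks, ignore_index=True)
    return features, labels


@dataclass
class MuscleNet:
    """Trained per-muscle network: plain-array weights + label statistics."""

    muscle: str
    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    label_mean: float
    label_scale: float
    seed: int
    epochs_run: int = 0
    best_epoch: int = 0

    def forward(self, X_std: np.ndarray) -> np.ndarray:
        """Forward pass on standardized features; returns forces in N."""
        h = np.asarray(X_std, dtype=float)
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        out = (h @ self.coefs[-1] + self.intercepts[-1]).ravel()
        return out * self.label_scale + self.label_mean


class MuscleForceSurrogate(BaseEstimator, RegressorMixin):
    """Ensemble of per-muscle 12-64-32-1 networks with shared normalization.

    Parameters mirror the training hyperparameters: adaptive-moment
    gradient descent, learning rate 1e-3, mini-batch 256, at most
    ``max_epochs`` passes with early stopping (patience ``patience``) on
    an explicit validation split.  Each muscle's net is seeded with
    ``seed + muscle_index`` so runs are reproducible.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple = (64, 32),
        solver: str = "lbfgs",
        learning_rate_init: float = 1e-3,
        batch_size: int = 256,
        max_epochs: int = 800,
        patience: int = 200,
        eval_interval: int = 100,
        seed: int = 0,
        standardize_features: bool = True,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.solver = solver
        self.learning_rate_init = learning_rate_init
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.eval_interval = eval_interval
        self.seed = seed
        self.standardize_features = standardize_features

    def fit(self, X, Y, muscle_names=None, validation=None):
        """Train one network per label column.

        ``validation=(X_val, Y_val)`` enables early stopping on the
        explicit validation loss; without it all epochs run (useful for
        memorization checks).
        """
        X = np.asarray(X, dtype=float)
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != X.shape[0]:
            Y = Y.T
        if not np.all(np.isfinite(Y)):
            raise ValueError("labels must be finite")
        if muscle_names is None:
            muscle_names = [f"m{i}" for i in range(Y.shape[1])]
        self.muscle_names_ = list(muscle_names)
        self.normalizer_ = ZScoreNormalizer().fit(X)
        Xs = self.normalizer_.transform(X) if self.standardize_features else X
        if validation is not None:
            Xv, Yv = validation
            Xv = np.asarray(Xv, dtype=float)
            Yv = np.atleast_2d(np.asarray(Yv, dtype=float))
            if Yv.shape[0] != Xv.shape[0]:
                Yv = Yv.T
            Xvs = self.normalizer_.transform(Xv) if self.standardize_features else Xv
        self.nets_ = []
        for k, name in enumerate(self.muscle_names_):
            y = Y[:, k]
            mu, sd = float(y.mean()), float(y.std())
            sd = sd if sd > 0 else 1.0
            ys = (y - mu) / sd
            yv = ((Yv[:, k] - mu) / sd) if validation is not None else None
            net = self._train_one(Xs, ys, Xvs if validation is not None else None,
                                  yv, self.seed + k)
            net.muscle = name
            net.label_mean, net.label_scale = mu, sd
            self.nets_.append(net)
        return self

    def _train_one(self, Xs, ys, Xvs, yvs, seed) -> MuscleNet:
        # Full-batch L-BFGS is the default: for a ~3k-parameter net this
        # converges far more reliably than first-order mini-batching on
        # the skewed, episodic force targets (muscles silent for most of
        # a motion and sharply recruited in short bursts).  The optimizer
        # runs in chunks of ``eval_interval`` iterations with early
        # stopping on the explicit validation loss between chunks.
        kwargs = dict(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            activation="relu",
            solver=self.solver,
            warm_start=True,
            random_state=seed,
            tol=0.0,
        )
        if self.solver == "adam":
            kwargs.update(
                learning_rate_init=self.learning_rate_init,
                batch_size=min(self.batch_size, Xs.shape[0]),
                shuffle=True,
            )
        chunk = max(min(self.eval_interval, self.max_epochs), 1)
        mlp = MLPRegressor(max_iter=chunk, **kwargs)
        best = (np.inf, None, None, 0)
        stall = 0
        iters = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for it in range(chunk, self.max_epochs + 1, chunk):
                mlp.fit(Xs, ys)
                iters = it
                if Xvs is None:
                    continue
                val_loss = float(np.mean((mlp.predict(Xvs) - yvs) ** 2))
                if val_loss < best[0] - 1e-12:
                    best = (
                        val_loss,
                        [W.copy() for W in mlp.coefs_],
                        [b.copy() for b in mlp.intercepts_],
                        it,
                    )
                    stall = 0
                else:
                    stall += chunk
                    if stall >= self.patience:
                        break
        if Xvs is not None and best[1] is not None:
            coefs, intercepts, best_epoch = best[1], best[2], best[3]
        else:
            coefs = [W.copy() for W in mlp.coefs_]
            intercepts = [b.copy() for b in mlp.intercepts_]
            best_epoch = iters
        return MuscleNet("", coefs, intercepts, 0.0, 1.0, seed, iters, best_epoch)

    def predict(self, X, muscles: list[str] | None = None) -> np.ndarray:
        """Predict forces (N); negative raw outputs are clipped to zero."""
        X = np.asarray(X, dtype=float)
        Xs = self.normalizer_.transform(X) if self.standardize_features else X
        names = muscles if muscles is not None else self.muscle_names_
        by_name = {n.muscle: n for n in self.nets_}
        missing = [m for m in names if m not in by_name]
        if missing:
            raise KeyError(f"no trained network for muscle(s) {missing}")
        out = np.column_stack([by_name[m].forward(Xs) for m in names])
        return np.maximum(out, 0.0)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {
            "feature_mean": self.normalizer_.mean_,
            "feature_scale": self.normalizer_.scale_,
        }
        meta = []
        for i, net in enumerate(self.nets_):
            for l, (W, b) in enumerate(zip(net.coefs, net.intercepts)):
                arrays[f"W_{i}_{l}"] = W
                arrays[f"b_{i}_{l}"] = b
            meta.append([net.muscle, net.label_mean, net.label_scale, net.seed,
                         net.epochs_run, net.best_epoch, len(net.coefs)])
        arrays["meta"] = np.array(meta, dtype=object)
        arrays["params"] = np.array(
            [repr(self.get_params())], dtype=object
        )
        np.savez(path, **arrays, allow_pickle=True)

    @classmethod
    def load(cls, path) -> "MuscleForceSurrogate":
        data = np.load(path, allow_pickle=True)
        params = eval(data["params"][0])  # noqa: S307 - our own repr round-trip
        obj = cls(**params)
        obj.normalizer_ = ZScoreNormalizer()
        obj.normalizer_.mean_ = data["feature_mean"]
        obj.normalizer_.scale_ = data["feature_scale"]
        obj.nets_ = []
        obj.muscle_names_ = []
        for i, row in enumerate(data["meta"]):
            name, mu, sd, seed, epochs, best_epoch, n_layers = row
            coefs = [data[f"W_{i}_{l}"] for l in range(int(n_layers))]
            intercepts = [data[f"b_{i}_{l}"] for l in range(int(n_layers))]
            obj.nets_.append(MuscleNet(str(name), coefs, intercepts, float(mu),
                                       float(sd), int(seed), int(epochs),
                                       int(best_epoch)))
            obj.muscle_names_.append(str(name))
        return obj


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def r2(pred, ref) -> float:
    """Coefficient of determination, 1 − SS_res / SS_tot."""
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.shape != ref.shape or ref.size < 2:
        raise ValueError("pred and ref must be equal-length with >= 2 points")
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("reference is constant; R^2 undefined")
    return 1.0 - float(np.sum((pred - ref) ** 2)) / ss_tot


def nrmse(pred, ref) -> float:
    """Root-mean-square error normalized by the reference range."""
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must be equal-length")
    rng = float(ref.max() - ref.min())
    if rng == 0:
        raise ValueError("reference range is zero; NRMSE undefined")
    return float(np.sqrt(np.mean((pred - ref) ** 2))) / rng


def evaluate(
    surrogate: MuscleForceSurrogate, X_test, Y_test
) -> pd.DataFrame:
    """Per-muscle test-set metrics (muscle, NRMSE, R²)."""
    Y_test = np.atleast_2d(np.asarray(Y_test, dtype=float))
    if Y_test.shape[0] != np.asarray(X_test).shape[0]:
        Y_test = Y_test.T
    pred = surrogate.predict(X_test)
    rows = []
    for k, name in enumerate(surrogate.muscle_names_):
        rows.append({
            "muscle": name,
            "NRMSE": nrmse(pred[:, k], Y_test[:, k]),
            "R2": r2(pred[:, k], Y_test[:, k]),
        })
    return pd.DataFrame(rows)
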