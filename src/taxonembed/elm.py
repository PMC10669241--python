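"""Extreme learning machines and the two-stage multilabel chain.

An ELM is a single-hidden-layer network whose input weights W_in and
biases b are drawn once at random and never updated; only the output
weight matrix (here ``beta``, the field's ϖ) is learned, in one
least-squares solve via the Moore-Penrose pseudo-inverse.  The chain
stacks two ELMs: the first maps encoded features to soft per-label
scores, the second maps those scores toward the true binary labels, and
per-label thresholds calibrated on a validation split convert final
scores to hard labels.

The model/results split follows statsmodels conventions:
``MLELMChain(features, targets).fit()`` returns an
:class:`MLELMChainResults` carrying the learned weights, thresholds,
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

_ACTIVATIONS = {
    "sigmoid": expit,
    "identity": lambda z: z,
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}


class ELMModel:
    """Single ELM with fixed random input weights.

    W_in and b are ~ Uniform(-1, 1), seeded, and are bit-identical before
    and after fitting; ``beta`` is the learned output weight matrix.
    """

    def __init__(self, n_features: int, n_hidden: int, activation: str = "sigmoid",
                 seed: int = 0):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        rng = np.random.default_rng(seed)
        self.W_in = rng.uniform(-1.0, 1.0, size=(n_features, n_hidden))
        self.b = rng.uniform(-1.0, 1.0, size=n_hidden)
        self.activation = activation
        self.beta: np.ndarray | None = None

    def hidden(self, X: np.ndarray) -> np.ndarray:
        return elm_hidden(X, self)

    def fit(self, X: np.ndarray, T: np.ndarray, ridge: float = 0.0) -> "ELMModel":
        self.beta = elm_fit(self.hidden(X), T, ridge=ridge)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.beta is None:
            raise RuntimeError("ELM not fitted")
        return self.hidden(X) @ self.beta


def elm_hidden(X: np.ndarray, model: ELMModel) -> np.ndarray:
    """Hidden-layer output H = activation(X W_in + b) for all rows in one batch."""
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] != model.W_in.shape[0]:
        raise ValueError(
            f"feature width {X.shape[-1] if X.ndim == 2 else X.shape} does not match "
            f"W_in rows {model.W_in.shape[0]}"
        )
    return _ACTIVATIONS[model.activation](X @ model.W_in + model.b)


def elm_fit(H: np.ndarray, T: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Minimum-norm least-squares output weights: beta = H^+ T.

    With ``ridge`` > 0 the regularized normal equations
    (H'H + ridge I) beta = H'T are solved instead, trading a little bias
    for conditioning.
    """
    H = np.asarray(H, float)
    T = np.asarray(T, float)
    if not np.isfinite(H).all():
        raise ValueError("non-finite entries in hidden matrix H")
    if H.shape[0] != T.shape[0]:
        raise ValueError("H and targets disagree on sample count")
    if ridge > 0.0:
        n_hidden = H.shape[1]
        return np.linalg.solve(H.T @ H + ridge * np.eye(n_hidden), H.T @ T)
    return np.linalg.pinv(H) @ T


def _f1_binary(truth: np.ndarray, pred: np.ndarray) -> float:
    tp = float(np.sum(truth & pred))
    fp = float(np.sum(~truth & pred))
    fn = float(np.sum(truth & ~pred))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def calibrate_thresholds(scores: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per-label threshold maximizing F1 on a calibration split.

    The candidate grid is the 99 percentiles (1..99) of the observed
    scores per label; ties are broken toward the lowest threshold.
    """
    scores = np.asarray(scores, float)
    targets = np.asarray(targets).astype(bool)
    n_labels = scores.shape[1]
    thresholds = np.empty(n_labels)
    pct = np.arange(1, 100)
    for c in range(n_labels):
        grid = np.unique(np.percentile(scores[:, c], pct))
        best_f1, best_t = -1.0, grid[0]
        for t in grid:
            f1 = _f1_binary(targets[:, c], scores[:, c] >= t)
            if f1 > best_f1 + 1e-12:
                best_f1, best_t = f1, t
        thresholds[c] = best_t
    return thresholds


class MLELMChain:
    """Two-stage multilabel ELM chain model.

    Parameters
    ----------
    features : (n, f) array
        Encoded training features.
    targets : (n, C) binary array
        Multilabel targets (one column per label).
    label_names : sequence of str, optional
        Column names used in summaries and error messages.
    n_hidden1, n_hidden2 : int, optional
        Hidden nodes per stage; default twice the stage's input width.
    """

    def __init__(self, features, targets, *, label_names=None, n_hidden1=None,
                 n_hidden2=None, activation: str = "sigmoid", ridge: float = 0.0,
                 seed: int = 0):
        self.features = np.asarray(features, float)
        self.targets = np.asarray(targets, float)
        if self.targets.ndim != 2:
            raise ValueError("targets must be a 2-D binary matrix")
        if not np.isin(self.targets, (0.0, 1.0)).all():
            raise ValueError("targets must be binary")
        self.n_labels = self.targets.shape[1]
        self.label_names = (list(label_names) if label_names is not None
                            else [f"label{i}" for i in range(self.n_labels)])
        self.n_hidden1 = n_hidden1 or 2 * self.features.shape[1]
        self.n_hidden2 = n_hidden2 or 2 * self.n_labels
        self.activation = activation
        self.ridge = ridge
        self.seed = seed

    def fit(self, validation_features=None, validation_targets=None,
            validation_fraction: float = 0.2) -> "MLELMChainResults":
        """Fit both stages and calibrate thresholds.

        If no explicit validation split is given, a seeded fraction of the
        training rows is held out for threshold calibration only (both ELM
        solves still use all training rows).
        """
        never_active = np.flatnonzero(self.targets.sum(axis=0) == 0)
        if never_active.size:
            names = [self.label_names[i] for i in never_active]
            raise ValueError(f"labels never active in training: {names}")
        rng = np.random.default_rng(self.seed)
        elm1 = ELMModel(self.features.shape[1], self.n_hidden1, self.activation,
                        seed=int(rng.integers(2**31)))
        elm2 = ELMModel(self.n_labels, self.n_hidden2, self.activation,
                        seed=int(rng.integers(2**31)))
        elm1.fit(self.features, self.targets, ridge=self.ridge)
        soft = elm1.predict(self.features)
        elm2.fit(soft, self.targets, ridge=self.ridge)
        if validation_features is None:
            n = self.features.shape[0]
            held = rng.permutation(n)[: max(1, int(round(validation_fraction * n)))]
            validation_features = self.features[held]
            validation_targets = self.targets[held]
        validation_targets = np.asarray(validation_targets)
        active = validation_targets.sum(axis=0)
        if (active < 2).any():
            sparse = [self.label_names[i] for i in np.flatnonzero(active < 2)]
            warnings.warn(f"labels with <2 active calibration samples: {sparse}")
        val_scores = elm2.predict(elm1.predict(np.asarray(validation_features, float)))
        thresholds = calibrate_thresholds(val_scores, validation_targets)
        return MLELMChainResults(self, elm1, elm2, thresholds)


@dataclass
class MLELMChainResults:
    """Fitted chain: weights, calibrated thresholds, and prediction methods."""

    model: MLELMChain
    elm1: ELMModel
    elm2: ELMModel
    thresholds: np.ndarray

    def predict_soft(self, features) -> np.ndarray:
        """Final-stage soft scores (no thresholding)."""
        features = np.asarray(features, float)
        return self.elm2.predict(self.elm1.predict(features))

    def predict_hard(self, features, blocks: list[slice] | None = None) -> np.ndarray:
        """Threshold soft scores to binary labels.

        ``blocks`` marks groups of columns (e.g. the host block) in which
        every row must carry at least one active label; rows with none get
        the block's argmax as a fallback.
        """
        scores = self.predict_soft(features)
        hard = (scores >= self.thresholds).astype(int)
        if blocks:
            for blk in blocks:
                none = hard[:, blk].sum(axis=1) == 0
                if none.any():
                    arg = np.argmax(scores[none, blk], axis=1)
                    hard[np.flatnonzero(none), blk.start + arg] = 1
        return hard

    def summary(self) -> str:
        train_scores = self.predict_soft(self.model.features)
        hard = (train_scores >= self.thresholds).astype(int)
        rows = []
        truth = self.model.targets.astype(bool)
        for c, name in enumerate(self.model.label_names):
            rows.append({
                "label": name,
                "threshold": self.thresholds[c],
                "train_F1": _f1_binary(truth[:, c], hard[:, c].astype(bool)),
                "prevalence": truth[:, c].mean(),
            })
        frame = pd.DataFrame(rows)
        head = (
            "Multilabel ELM chain\n"
            f"  stage 1: {self.model.features.shape[1]} features -> "
            f"{self.model.n_hidden1} hidden -> {self.model.n_labels} scores\n"
            f"  stage 2: {self.model.n_labels} scores -> "
            f"{self.model.n_hidden2} hidden -> {self.model.n_labels} labels\n"
            f"  activation: {self.model.activation}; ridge: {self.model.ridge}\n"
        )
        return head + frame.to_string(index=False, float_format=lambda v: f"{v:.4f}")

    def save(self, prefix: str) -> None:
        np.savez(
            prefix + ".npz",
            w_in1=self.elm1.W_in, b1=self.elm1.b, beta1=self.elm1.beta,
            w_in2=self.elm2.W_in, b2=self.elm2.b, beta2=self.elm2.beta,
            thresholds=self.thresholds,
            label_names=np.array(self.model.label_names),
        )


def fit_chain(features, targets, n_hidden1=None, n_hidden2=None,
              validation_features=None, validation_targets=None, seed: int = 0,
              label_names=None, ridge: float = 0.0) -> MLELMChainResults:
    """Functional wrapper: build an :class:`MLELMChain` and fit it."""
    model = MLELMChain(features, targets, label_names=label_names,
                       n_hidden1=n_hidden1, n_hidden2=n_hidden2, ridge=ridge,
                       seed=seed)
    return model.fit(validation_features, validation_targets)
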