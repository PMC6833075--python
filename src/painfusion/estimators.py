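"""Scikit-learn-style estimators wrapping the NumPy CNN engine.

All estimators share the optimisation contract: Adam, softmax cross-entropy
(fused with the output layer), mini-batches reshuffled each epoch, and full
determinism given ``random_state``.  Inputs are raw 1152-sample windows;
``standardize=True`` (default) z-scores each modality with scalar statistics
computed on the training set, which the published preprocessing leaves to
the model but plainly helps trainability.

Modality order for the fusion estimators is fixed as (EDA, EMG, ECG) along
axis 1 of ``X`` with shape ``(n_samples, 3, window_len)`` - the same order
as the aggregation weights (alpha_1 EDA, alpha_2 EMG, alpha_3 ECG).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import DataError, ValidationError
from .models import (
    ArchitectureSpec,
    FusionWeights,
    LossWeights,
    build_eda_arch,
    build_early_fusion_arch,
    build_emg_ecg_arch,
    build_mid_fusion_arch,
    build_late_fusion_arch,
)
from .nn.network import build_network
from .nn.ops import cross_entropy, softmax
from .nn.optim import Adam

__all__ = [
    "MODALITY_ORDER",
    "CNNClassifier",
    "EarlyFusionCNN",
    "MidFusionCNN",
    "LateFusionCNN",
]

MODALITY_ORDER = ("eda", "emg", "ecg")


class _BaseDeepEstimator(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing for all CNN estimators."""

    def __init__(
        self,
        learning_rate: float = 1e-5,
        epochs: int = 100,
        batch_size: int = 100,
        dropout_rate: float = 0.25,
        standardize: bool = True,
        random_state: int | None = None,
    ):
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.dropout_rate = dropout_rate
        self.standardize = standardize
        self.random_state = random_state

    # -- label handling ----------------------------------------------------

    def _encode_y(self, y):
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise DataError(
                f"training data must contain >= 2 classes, got {self.classes_}"
            )
        onehot = np.zeros((len(y_idx), len(self.classes_)), dtype=np.float32)
        onehot[np.arange(len(y_idx)), y_idx] = 1.0
        return onehot

    def _check_fitted(self):
        if not hasattr(self, "classes_"):
            raise ValidationError("estimator is not fitted; call fit() first")

    # -- scaling -----------------------------------------------------------

    def _fit_scaler_single(self, X):
        if self.standardize:
            self.mean_ = float(X.mean())
            self.scale_ = float(X.std()) or 1.0
        else:
            self.mean_, self.scale_ = 0.0, 1.0
        return (X - self.mean_) / self.scale_

    def _fit_scaler_multi(self, X):
        # X: (n, 3, L); scalar stats per modality
        if self.standardize:
            self.mean_ = X.mean(axis=(0, 2))
            scale = X.std(axis=(0, 2))
            scale[scale == 0] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(3)
            self.scale_ = np.ones(3)
        return (X - self.mean_[None, :, None]) / self.scale_[None, :, None]

    def _transform_single(self, X):
        return (X - self.mean_) / self.scale_

    def _transform_multi(self, X):
        return (X - self.mean_[None, :, None]) / self.scale_[None, :, None]

    # -- batching ----------------------------------------------------------

    def _batches(self, n, rng):
        perm = rng.permutation(n)
        for start in range(0, n, self.batch_size):
            yield perm[start : start + self.batch_size]

    def predict(self, X):
        scores = self.decision_scores(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def predict_proba(self, X):
        scores = self.decision_scores(X)
        return scores / scores.sum(axis=1, keepdims=True)

    def decision_scores(self, X):  # pragma: no cover - overridden
        raise NotImplementedError


def _as_windows(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 3 and X.shape[-1] == 1:
        X = X[..., 0]
    if X.ndim != 2:
        raise ValidationError(
            f"expected X of shape (n, window_len) or (n, window_len, 1); got {X.shape}"
        )
    return X


def _as_multimodal(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 4 and X.shape[-1] == 1:
        X = X[..., 0]
    if X.ndim != 3 or X.shape[1] != 3:
        raise ValidationError(
            f"expected X of shape (n, 3, window_len); got {X.shape}"
        )
    return X


class CNNClassifier(_BaseDeepEstimator):
    """Uni-modal 1D CNN on fixed-length physiological windows.

    ``architecture="eda"`` selects the kernel-3 layout, ``"emg_ecg"`` the
    kernel-11 layout with extra dropout.
    """

    def __init__(
        self,
        architecture: str = "eda",
        learning_rate: float = 1e-5,
        epochs: int = 100,
        batch_size: int = 100,
        dropout_rate: float = 0.25,
        standardize: bool = True,
        random_state: int | None = None,
    ):
        super().__init__(
            learning_rate=learning_rate,
            epochs=epochs,
            batch_size=batch_size,
            dropout_rate=dropout_rate,
            standardize=standardize,
            random_state=random_state,
        )
        self.architecture = architecture

    def _build_spec(self, c: int, window_len: int) -> ArchitectureSpec:
        if self.architecture == "eda":
            return build_eda_arch(c, window_len)
        if self.architecture in ("emg_ecg", "emg", "ecg"):
            return build_emg_ecg_arch(c, window_len)
        raise ValidationError(f"unknown architecture {self.architecture!r}")

    def fit(self, X, y):
        X = _as_windows(X)
        Y = self._encode_y(y)
        X = np.asarray(self._fit_scaler_single(X), dtype=np.float32)
        c = len(self.classes_)
        self.architecture_spec_ = self._build_spec(c, X.shape[1])
        rng = np.random.default_rng(self.random_state)
        net = build_network(
            self.architecture_spec_.layers, self.architecture_spec_.input_shape, rng
        )
        opt = Adam(net.params(), learning_rate=self.learning_rate)
        n = X.shape[0]
        losses = []
        for _epoch in range(self.epochs):
            epoch_loss = 0.0
            for idx in self._batches(n, rng):
                xb = X[idx][:, :, None]
                yb = Y[idx]
                logits = net.forward(xb, training=True, rng=rng)
                p = softmax(logits)
                epoch_loss += cross_entropy(yb, p) * len(idx)
                net.backward(((p - yb) / len(idx)).astype(np.float32))
                opt.step(net.grads())
            losses.append(epoch_loss / n)
        self.network_ = net
        self.loss_curve_ = losses
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X):
        self._check_fitted()
        X = self._transform_single(_as_windows(X))
        logits = self.network_.forward(X[:, :, None].astype(np.float32), training=False)
        return softmax(logits)


class EarlyFusionCNN(_BaseDeepEstimator):
    """2D-CNN early fusion over the modality-stacked (3, window, 1) input."""

    def fit(self, X, y):
        X = _as_multimodal(X)
        Y = self._encode_y(y)
        X = np.asarray(self._fit_scaler_multi(X), dtype=np.float32)
        c = len(self.classes_)
        self.architecture_spec_ = build_early_fusion_arch(c, X.shape[2])
        rng = np.random.default_rng(self.random_state)
        net = build_network(
            self.architecture_spec_.layers, self.architecture_spec_.input_shape, rng
        )
        opt = Adam(net.params(), learning_rate=self.learning_rate)
        n = X.shape[0]
        losses = []
        for _epoch in range(self.epochs):
            epoch_loss = 0.0
            for idx in self._batches(n, rng):
                xb = X[idx][..., None]
                yb = Y[idx]
                logits = net.forward(xb, training=True, rng=rng)
                p = softmax(logits)
                epoch_loss += cross_entropy(yb, p) * len(idx)
                net.backward(((p - yb) / len(idx)).astype(np.float32))
                opt.step(net.grads())
            losses.append(epoch_loss / n)
        self.network_ = net
        self.loss_curve_ = losses
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def decision_scores(self, X):
        self._check_fitted()
        X = self._transform_multi(_as_multimodal(X))
        logits = self.network_.forward(X[..., None].astype(np.float32), training=False)
        return softmax(logits)


class MidFusionCNN(_BaseDeepEstimator):
    """Mid-level fusion: concatenated 512-unit branch representations."""

    def fit(self, X, y):
        X = _as_multimodal(X)
        Y = self._encode_y(y)
        X = np.asarray(self._fit_scaler_multi(X), dtype=np.float32)
        c = len(self.classes_)
        window_len = X.shape[2]
        self.architecture_spec_ = build_mid_fusion_arch(
            c,
            (
                build_eda_arch(c, window_len),
                build_emg_ecg_arch(c, window_len),
                build_emg_ecg_arch(c, window_len),
            ),
        )
        rng = np.random.default_rng(self.random_state)
        trunks = [
            build_network(b.layers, b.input_shape, rng)
            for b in self.architecture_spec_.branches
        ]
        from .nn.layers import Dense

        head = Dense(3 * 512, c, rng)
        params = [p for t in trunks for p in t.params()] + head.params()
        grads = lambda: [g for t in trunks for g in t.grads()] + head.grads()
        opt = Adam(params, learning_rate=self.learning_rate)
        n = X.shape[0]
        losses = []
        for _epoch in range(self.epochs):
            epoch_loss = 0.0
            for idx in self._batches(n, rng):
                yb = Y[idx]
                hs = [
                    trunks[i].forward(X[idx, i, :, None], training=True, rng=rng)
                    for i in range(3)
                ]
                h = np.concatenate(hs, axis=1)
                logits = head.forward(h, training=True)
                p = softmax(logits)
                epoch_loss += cross_entropy(yb, p) * len(idx)
                dh = head.backward(((p - yb) / len(idx)).astype(np.float32))
                for i, t in enumerate(trunks):
                    t.backward(dh[:, i * 512 : (i + 1) * 512])
                opt.step(grads())
            losses.append(epoch_loss / n)
        self.trunks_ = trunks
        self.head_ = head
        self.loss_curve_ = losses
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def decision_scores(self, X):
        self._check_fitted()
        X = self._transform_multi(_as_multimodal(X)).astype(np.float32)
        hs = [
            self.trunks_[i].forward(X[:, i, :, None], training=False) for i in range(3)
        ]
        logits = self.head_.forward(np.concatenate(hs, axis=1), training=False)
        return softmax(logits)


class LateFusionCNN(_BaseDeepEstimator):
    """Late fusion with a constrained trainable weighted-average layer.

    Three uni-modal softmax branches are aggregated as ``e_j = (1/3) *
    sum_i alpha_i theta_ij`` with the weights alpha kept non-negative and
    sum-to-one by a softmax-over-logits parameterisation (initialised to
    equal weights).  The total loss is ``sum_i lambda_i L_i + lambda_agg
    L_agg`` with every term a cross-entropy; training is end-to-end, and
    prediction of unseen samples uses only the aggregation output.

    Fitted attributes include ``fusion_weights_`` (the learned alpha) and
    ``fusion_logits_``.
    """

    def __init__(
        self,
        learning_rate: float = 1e-5,
        epochs: int = 100,
        batch_size: int = 100,
        dropout_rate: float = 0.25,
        standardize: bool = True,
        random_state: int | None = None,
        lambda_modalities: tuple[float, float, float] = (0.2, 0.2, 0.2),
        lambda_agg: float = 0.4,
        average_factor: bool = True,
    ):
        super().__init__(
            learning_rate=learning_rate,
            epochs=epochs,
            batch_size=batch_size,
            dropout_rate=dropout_rate,
            standardize=standardize,
            random_state=random_state,
        )
        self.lambda_modalities = lambda_modalities
        self.lambda_agg = lambda_agg
        self.average_factor = average_factor

    def fit(self, X, y):
        X = _as_multimodal(X)
        Y = self._encode_y(y)
        X = np.asarray(self._fit_scaler_multi(X), dtype=np.float32)
        c = len(self.classes_)
        window_len = X.shape[2]
        loss_w = LossWeights(
            lambda_modalities=tuple(self.lambda_modalities), lambda_agg=self.lambda_agg
        )
        self.architecture_spec_ = build_late_fusion_arch(
            c,
            (
                build_eda_arch(c, window_len),
                build_emg_ecg_arch(c, window_len),
                build_emg_ecg_arch(c, window_len),
            ),
            loss_weights=loss_w,
        )
        rng = np.random.default_rng(self.random_state)
        branches = [
            build_network(b.layers, b.input_shape, rng)
            for b in self.architecture_spec_.branches
        ]
        a_logits = np.zeros(3, dtype=np.float32)  # alpha = (1/3, 1/3, 1/3)
        params = [p for b in branches for p in b.params()] + [a_logits]
        opt = Adam(params, learning_rate=self.learning_rate)
        factor = 1.0 / 3.0 if self.average_factor else 1.0
        lam = np.asarray(loss_w.lambda_modalities, dtype=float)
        lam_agg = float(loss_w.lambda_agg)
        n = X.shape[0]
        losses = []
        for _epoch in range(self.epochs):
            epoch_loss = 0.0
            for idx in self._batches(n, rng):
                yb = Y[idx]
                B = len(idx)
                thetas = [
                    softmax(
                        branches[i].forward(X[idx, i, :, None], training=True, rng=rng)
                    )
                    for i in range(3)
                ]
                alpha = softmax(a_logits.astype(np.float64))
                e = factor * sum(alpha[i] * thetas[i] for i in range(3))
                branch_ls = [cross_entropy(yb, th) for th in thetas]
                agg_l = cross_entropy(yb, e)
                total = float(np.dot(lam, branch_ls) + lam_agg * agg_l)
                epoch_loss += total * B
                # gradient of the aggregation cross-entropy w.r.t. e
                dE = -lam_agg * yb / np.clip(e, 1e-12, None) / B
                d_alpha = np.array(
                    [factor * float((dE * thetas[i]).sum()) for i in range(3)]
                )
                da = alpha * (d_alpha - float(np.dot(d_alpha, alpha)))
                for i in range(3):
                    dtheta = factor * alpha[i] * dE
                    # softmax jacobian-vector product for the aggregation path
                    dz = thetas[i] * (
                        dtheta - (dtheta * thetas[i]).sum(axis=1, keepdims=True)
                    )
                    dz = dz + lam[i] * (thetas[i] - yb) / B
                    branches[i].backward(dz.astype(np.float32))
                grads = [g for b in branches for g in b.grads()] + [
                    da.astype(np.float32)
                ]
                opt.step(grads)
            losses.append(epoch_loss / n)
        self.branches_ = branches
        self.fusion_logits_ = a_logits
        self.fusion_weights_ = FusionWeights.from_logits(a_logits)
        self.loss_curve_ = losses
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def decision_scores(self, X):
        """Aggregation-layer outputs ``e`` (the only signal used to predict)."""
        self._check_fitted()
        X = self._transform_multi(_as_multimodal(X)).astype(np.float32)
        thetas = [
            softmax(self.branches_[i].forward(X[:, i, :, None], training=False))
            for i in range(3)
        ]
        alpha = self.fusion_weights_.as_array()
        factor = 1.0 / 3.0 if self.average_factor else 1.0
        return factor * sum(alpha[i] * thetas[i] for i in range(3))

    def branch_probabilities(self, X):
        """Per-branch class probabilities theta_i, shape (3, n, c)."""
        self._check_fitted()
        X = self._transform_multi(_as_multimodal(X)).astype(np.float32)
        return np.stack(
            [
                softmax(self.branches_[i].forward(X[:, i, :, None], training=False))
                for i in range(3)
            ]
        )
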