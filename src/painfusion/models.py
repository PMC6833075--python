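"""Declarative CNN architectures and the fusion/loss arithmetic.

Four architectures are defined:

* two **uni-modal 1D CNNs** (one layout for EDA with kernel size 3; one for
  EMG/ECG with kernel size 11 and extra dropout after each pooled block),
  each: seven conv/batch-norm/max-pool blocks with 16,16,32,32,64,64,128
  kernels, then dense 1024 -> dense 512 -> dense c with softmax;
* an **early fusion** 2D CNN over the (3, 1152, 1) modality-stacked input,
  whose two leading 2x11 'valid'-row convolutions collapse the modality axis
  3 -> 2 -> 1;
* a **mid-level fusion** network concatenating the three 512-unit
  penultimate representations into one softmax output layer;
* a **late fusion** network whose three softmax branches are combined by a
  constrained trainable aggregation layer
  ``e_j = (1/3) * sum_i alpha_i * theta_ij`` with ``alpha_i >= 0`` and
  ``sum_i alpha_i = 1`` (enforced by a softmax-over-logits
  parameterisation), trained end-to-end with the combined loss
  ``L = sum_i lambda_i L_i + lambda_agg L_agg`` where every term is a
  cross-entropy.

ELU (alpha = 1) activates every convolutional and dense layer except the
final softmax layer; the dropout rate is 0.25 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .nn.ops import cross_entropy, elu, softmax

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "FusionWeights",
    "LossWeights",
    "TrainConfig",
    "elu",
    "softmax",
    "cross_entropy",
    "build_eda_arch",
    "build_emg_ecg_arch",
    "build_early_fusion_arch",
    "build_mid_fusion_arch",
    "build_late_fusion_arch",
    "aggregate_outputs",
    "combined_loss",
    "count_trainable_parameters",
    "train",
]

DROPOUT_RATE = 0.25


@dataclass(frozen=True)
class LayerSpec:
    """One declarative layer: kind, size, stride, activation."""

    kind: str  # conv1d | conv2d | batch_norm | max_pool | dropout | flatten | dense
    n: int | None = None  # kernels or units
    size: int | tuple[int, int] | None = None  # kernel or pool size
    stride: int | tuple[int, int] | None = None
    activation: str | None = None  # elu | softmax | linear
    dropout_rate: float | None = None

    def __post_init__(self) -> None:
        if self.kind in ("conv1d", "conv2d", "dense"):
            if self.activation not in ("elu", "softmax", "linear"):
                raise ConfigurationError(
                    f"{self.kind} layer requires an activation, got {self.activation!r}"
                )
            if self.n is None or self.n < 1:
                raise ConfigurationError(f"{self.kind} layer needs a positive size")
        if self.kind == "dropout" and not (0.0 <= (self.dropout_rate or 0.0) < 1.0):
            raise ConfigurationError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class LossWeights:
    """Weights of the late-fusion multi-term loss (Adam sees their sum)."""

    lambda_modalities: tuple[float, float, float] = (0.2, 0.2, 0.2)
    lambda_agg: float = 0.4

    def __post_init__(self) -> None:
        if min(self.lambda_modalities) < 0 or self.lambda_agg < 0:
            raise ConfigurationError("loss weights must be non-negative")


@dataclass(frozen=True)
class FusionWeights:
    """Non-negative, sum-to-one modality weights (alpha_EDA, alpha_EMG, alpha_ECG)."""

    alpha: tuple[float, float, float]

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.shape != (3,):
            raise ValidationError("alpha must have exactly three components")
        if np.any(a < -1e-9):
            raise ValidationError("alpha components must be non-negative")
        if abs(a.sum() - 1.0) > 1e-6:
            raise ValidationError(f"alpha must sum to 1, got {a.sum()}")

    @classmethod
    def from_logits(cls, logits: Sequence[float]) -> "FusionWeights":
        a = softmax(np.asarray(logits, dtype=float))
        return cls(alpha=tuple(float(v) for v in a))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.alpha, dtype=float)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (Adam, lr 1e-5, 100 epochs, batch 100 by default)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-5
    epochs: int = 100
    batch_size: int = 100
    dropout_rate: float = DROPOUT_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    """A named, ordered layer list (optionally with fusion branches)."""

    name: str
    input_shape: tuple[int, ...]
    layers: tuple[LayerSpec, ...]
    n_classes: int
    branches: tuple["ArchitectureSpec", ...] = ()
    fusion: str | None = None  # None | "concat" | "weighted_average"
    loss_weights: LossWeights | None = None


def _check_classes(c: int) -> None:
    if c < 2:
        raise ConfigurationError(f"need at least 2 classes, got {c}")


_CONV_KERNELS = (16, 16, 32, 32, 64, 64, 128)


def _dense_head(c: int, leading_dropout: bool) -> list[LayerSpec]:
    head = [LayerSpec("flatten")]
    if leading_dropout:
        head.append(LayerSpec("dropout", dropout_rate=DROPOUT_RATE))
    head += [
        LayerSpec("dense", n=1024, activation="elu"),
        LayerSpec("dropout", dropout_rate=DROPOUT_RATE),
        LayerSpec("dense", n=512, activation="elu"),
        LayerSpec("dropout", dropout_rate=DROPOUT_RATE),
        LayerSpec("dense", n=c, activation="softmax"),
    ]
    return head


def build_eda_arch(c: int, window_len: int = 1152) -> ArchitectureSpec:
    """Kernel-3 uni-modal CNN (EDA column of the architecture table)."""
    _check_classes(c)
    layers: list[LayerSpec] = []
    for nk in _CONV_KERNELS:
        layers += [
            LayerSpec("conv1d", n=nk, size=3, stride=1, activation="elu"),
            LayerSpec("batch_norm"),
            LayerSpec("max_pool", size=2, stride=2),
        ]
    layers += _dense_head(c, leading_dropout=False)
    return ArchitectureSpec(
        name="eda", input_shape=(window_len, 1), layers=tuple(layers), n_classes=c
    )


def build_emg_ecg_arch(c: int, window_len: int = 1152) -> ArchitectureSpec:
    """Kernel-11 uni-modal CNN (EMG & ECG column: dropout after each pooled
    block except the last, and around every dense layer)."""
    _check_classes(c)
    layers: list[LayerSpec] = []
    for i, nk in enumerate(_CONV_KERNELS):
        layers += [
            LayerSpec("conv1d", n=nk, size=11, stride=1, activation="elu"),
            LayerSpec("batch_norm"),
            LayerSpec("max_pool", size=2, stride=2),
        ]
        if i < len(_CONV_KERNELS) - 1:
            layers.append(LayerSpec("dropout", dropout_rate=DROPOUT_RATE))
    layers += _dense_head(c, leading_dropout=True)
    return ArchitectureSpec(
        name="emg_ecg", input_shape=(window_len, 1), layers=tuple(layers), n_classes=c
    )


def build_early_fusion_arch(c: int, window_len: int = 1152) -> ArchitectureSpec:
    """2D CNN over the (3, window, 1) stacked input.

    The two leading 2x11 convolutions are 'valid' along the 3-row modality
    axis (3 -> 2 -> 1) and 'same' along time; subsequent 1x11 blocks with
    32,32,64,64 kernels pool only along time.
    """
    _check_classes(c)
    layers: list[LayerSpec] = [
        LayerSpec("conv2d", n=16, size=(2, 11), stride=(1, 1), activation="elu"),
        LayerSpec("conv2d", n=16, size=(2, 11), stride=(1, 1), activation="elu"),
        LayerSpec("batch_norm"),
        LayerSpec("max_pool", size=(1, 2), stride=(1, 2)),
        LayerSpec("dropout", dropout_rate=DROPOUT_RATE),
    ]
    for nk in (32, 32, 64, 64):
        layers += [
            LayerSpec("conv2d", n=nk, size=(1, 11), stride=(1, 1), activation="elu"),
            LayerSpec("batch_norm"),
            LayerSpec("max_pool", size=(1, 2), stride=(1, 2)),
            LayerSpec("dropout", dropout_rate=DROPOUT_RATE),
        ]
    # the table's last block has no dropout between pooling and flatten
    layers = layers[:-1]
    layers += _dense_head(c, leading_dropout=True)
    return ArchitectureSpec(
        name="early_fusion",
        input_shape=(3, window_len, 1),
        layers=tuple(layers),
        n_classes=c,
    )


def _trunk(spec: ArchitectureSpec) -> ArchitectureSpec:
    """A uni-modal spec truncated after the second dense layer's dropout."""
    assert spec.layers[-1].kind == "dense"
    return ArchitectureSpec(
        name=spec.name + "_trunk",
        input_shape=spec.input_shape,
        layers=spec.layers[:-1],
        n_classes=spec.n_classes,
    )


def build_mid_fusion_arch(
    c: int, uni_specs: Sequence[ArchitectureSpec] | None = None
) -> ArchitectureSpec:
    """Concatenate the three 512-unit representations into one softmax layer."""
    _check_classes(c)
    if uni_specs is None:
        uni_specs = (build_eda_arch(c), build_emg_ecg_arch(c), build_emg_ecg_arch(c))
    if len(uni_specs) != 3:
        raise ConfigurationError("mid-level fusion requires exactly 3 branches")
    if any(s.n_classes != c for s in uni_specs):
        raise ConfigurationError("branch class counts must all equal c")
    return ArchitectureSpec(
        name="mid_fusion",
        input_shape=(3, uni_specs[0].input_shape[0], 1),
        layers=(LayerSpec("dense", n=c, activation="softmax"),),
        n_classes=c,
        branches=tuple(_trunk(s) for s in uni_specs),
        fusion="concat",
    )


def build_late_fusion_arch(
    c: int,
    uni_specs: Sequence[ArchitectureSpec] | None = None,
    loss_weights: LossWeights | None = None,
) -> ArchitectureSpec:
    """Three softmax branches + constrained trainable aggregation weights.

    The aggregation layer's weights start at (1/3, 1/3, 1/3) and remain on
    the simplex throughout training; unseen samples are classified from the
    aggregation output alone.
    """
    _check_classes(c)
    if uni_specs is None:
        uni_specs = (build_eda_arch(c), build_emg_ecg_arch(c), build_emg_ecg_arch(c))
    if len(uni_specs) != 3:
        raise ConfigurationError("late fusion requires exactly 3 branches")
    if any(s.n_classes != c for s in uni_specs):
        raise ConfigurationError("branch class counts must all equal c")
    return ArchitectureSpec(
        name="late_fusion",
        input_shape=(3, uni_specs[0].input_shape[0], 1),
        layers=(),
        n_classes=c,
        branches=tuple(uni_specs),
        fusion="weighted_average",
        loss_weights=loss_weights or LossWeights(),
    )


def aggregate_outputs(
    theta: np.ndarray, weights: FusionWeights, average_factor: bool = True
) -> np.ndarray:
    """Late-fusion aggregation ``e_j = (1/3) * sum_i alpha_i * theta_ij``.

    ``theta`` is the 3 x c matrix of branch class probabilities (each row
    must sum to 1 within 1e-6).  The linear output activation is the
    identity, so the returned scores are the aggregation layer's outputs;
    their argmax is the predicted class.  With ``average_factor=False`` the
    literal 1/3 factor is dropped (the scores then sum to 1).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape[0] != 3:
        raise ValidationError(f"theta must have 3 rows, got {theta.shape}")
    sums = theta.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValidationError(f"each theta row must sum to 1; row sums {sums}")
    factor = 1.0 / 3.0 if average_factor else 1.0
    return factor * np.einsum("i,i...j->...j", weights.as_array(), theta)


def combined_loss(
    branch_losses: Sequence[float], agg_loss: float, weights: LossWeights | None = None
) -> float:
    """``L = sum_i lambda_i L_i + lambda_agg L_agg`` (defaults 0.2/0.2/0.2/0.4)."""
    weights = weights or LossWeights()
    if len(branch_losses) != 3:
        raise ValidationError("expected exactly 3 branch losses")
    return float(
        sum(l * w for l, w in zip(branch_losses, weights.lambda_modalities))
        + weights.lambda_agg * agg_loss
    )


def count_trainable_parameters(spec: ArchitectureSpec) -> int:
    """Trainable weight/bias count (+2 per batch-norm channel, +3 fusion logits)."""
    from .nn.network import infer_shapes

    total = 0
    branch_out_widths = []
    for branch in spec.branches:
        total += count_trainable_parameters(branch)
        *_, (last, _si, so) = infer_shapes(branch.layers, branch.input_shape)
        branch_out_widths.append(int(np.prod(so)))
    if spec.fusion == "weighted_average":
        total += 3  # the constrained aggregation logits
    head_input: tuple[int, ...]
    if spec.fusion == "concat":
        head_input = (sum(branch_out_widths),)
    else:
        head_input = spec.input_shape
    for lay, shape_in, _shape_out in infer_shapes(spec.layers, head_input):
        if lay.kind == "conv1d":
            total += lay.n * (lay.size * shape_in[-1] + 1)
        elif lay.kind == "conv2d":
            kh, kw = lay.size
            total += lay.n * (kh * kw * shape_in[-1] + 1)
        elif lay.kind == "batch_norm":
            total += 2 * shape_in[-1]
        elif lay.kind == "dense":
            total += lay.n * (shape_in[0] + 1)
    return total


def train(spec: ArchitectureSpec, X: np.ndarray, y: np.ndarray, cfg: TrainConfig):
    """Fit the estimator matching ``spec`` on (X, y); returns the fitted model.

    Thin functional wrapper over the scikit-learn-style estimators in
    :mod:`painfusion.estimators`.
    """
    from . import estimators as est

    kwargs = dict(
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        dropout_rate=cfg.dropout_rate,
        random_state=cfg.seed,
    )
    if spec.name in ("eda", "emg_ecg"):
        model = est.CNNClassifier(architecture=spec.name, **kwargs)
    elif spec.name == "early_fusion":
        model = est.EarlyFusionCNN(**kwargs)
    elif spec.name == "mid_fusion":
        model = est.MidFusionCNN(**kwargs)
    elif spec.name == "late_fusion":
        lw = spec.loss_weights or LossWeights()
        model = est.LateFusionCNN(
            lambda_modalities=lw.lambda_modalities, lambda_agg=lw.lambda_agg, **kwargs
        )
    else:
        raise ConfigurationError(f"unknown architecture {spec.name!r}")
    return model.fit(X, y)
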