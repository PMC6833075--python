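"""Raw recordings -> labelled fixed-length model inputs.

Pipeline (per modality): Butterworth filtering at the native sampling rate,
downsampling to 256 Hz, windowing 4.5 s segments shifted 4 s past each
elicitation onset (1152 samples at 256 Hz), per-segment fifth-degree
polynomial detrending for ECG, and time-shift augmentation (+-250 ms steps
up to +-1 s) for training material.

Filter bands: EDA low-pass 0.2 Hz (order 3); EMG band-pass 20-250 Hz
(order 4); ECG band-pass 0.1-250 Hz (order 3).  The 250 Hz upper edges
exceed the Nyquist limit of the 256 Hz analysis rate, so filtering happens
*before* downsampling whenever the native rate allows it; on data already at
a rate too low for the stated band, the upper cutoff is clipped to
``0.45 * fs`` with a logged warning.  All filtering is zero-phase
(forward-backward), which preserves onset timing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Mapping

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import signal as _sig

from .errors import ConfigurationError, SegmentationError, ValidationError
from .io import SegmentSet, TrialLabel
from .synthetic import MODALITIES, MultiModalRecording

__all__ = [
    "FilterSpec",
    "SegmentationConfig",
    "AugmentationConfig",
    "default_filter_specs",
    "resample",
    "design_filter",
    "apply_filter",
    "preprocess_recording",
    "detrend_poly",
    "segment",
    "augment",
]

NYQUIST_CLIP_FRACTION = 0.45


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter: order, kind and band in Hz at a sampling rate."""

    order: int
    kind: str  # "lowpass" | "bandpass"
    band_hz: tuple[float, ...]
    fs_hz: float
    family: str = "butterworth"

    def validate(self) -> None:
        if self.family != "butterworth":
            raise ConfigurationError(f"unsupported filter family {self.family!r}")
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")
        if self.kind not in ("lowpass", "bandpass"):
            raise ConfigurationError(f"unsupported filter kind {self.kind!r}")
        expected = 1 if self.kind == "lowpass" else 2
        if len(self.band_hz) != expected:
            raise ConfigurationError(
                f"{self.kind} filter needs {expected} cutoff(s), got {self.band_hz}"
            )
        if any(c <= 0 for c in self.band_hz):
            raise ConfigurationError("cutoff frequencies must be positive")
        if self.fs_hz <= 0:
            raise ConfigurationError("fs_hz must be positive")

    def clipped(self) -> "FilterSpec":
        """Clip cutoffs at/above Nyquist down to ``0.45 * fs`` (with warning)."""
        self.validate()
        nyq = self.fs_hz / 2.0
        band = list(self.band_hz)
        if band[-1] >= nyq:
            clipped = NYQUIST_CLIP_FRACTION * self.fs_hz
            warnings.warn(
                f"upper cutoff {band[-1]} Hz >= Nyquist ({nyq} Hz); "
                f"clipping to {clipped} Hz",
                stacklevel=2,
            )
            band[-1] = clipped
        if len(band) == 2 and band[0] >= band[1]:
            raise ConfigurationError(
                f"empty band {tuple(band)} after Nyquist clipping at fs={self.fs_hz}"
            )
        return replace(self, band_hz=tuple(band))


def default_filter_specs(fs_hz: float) -> dict[str, FilterSpec]:
    """The per-modality filter bank (before any Nyquist clipping)."""
    return {
        "eda": FilterSpec(order=3, kind="lowpass", band_hz=(0.2,), fs_hz=fs_hz),
        "emg": FilterSpec(order=4, kind="bandpass", band_hz=(20.0, 250.0), fs_hz=fs_hz),
        "ecg": FilterSpec(order=3, kind="bandpass", band_hz=(0.1, 250.0), fs_hz=fs_hz),
    }


@dataclass(frozen=True)
class SegmentationConfig:
    """4.5 s windows shifted 4 s past the elicitation onset, at 256 Hz."""

    window_s: float = 4.5
    onset_shift_s: float = 4.0
    fs_hz: float = 256.0

    def validate(self) -> None:
        if self.window_s <= 0:
            raise ConfigurationError("window_s must be positive")
        if self.fs_hz <= 0:
            raise ConfigurationError("fs_hz must be positive")

    @property
    def window_len(self) -> int:
        return int(round(self.window_s * self.fs_hz))


@dataclass(frozen=True)
class AugmentationConfig:
    """Window-shift augmentation: +-step_s increments up to +-max_shift_s."""

    step_s: float = 0.25
    max_shift_s: float = 1.0

    def validate(self) -> None:
        if self.step_s <= 0:
            raise ConfigurationError("step_s must be positive")
        k = self.max_shift_s / self.step_s
        if abs(k - round(k)) > 1e-9 or round(k) < 1:
            raise ConfigurationError(
                "max_shift_s must be a positive integer multiple of step_s"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.max_shift_s / self.step_s))

    @property
    def shifts_s(self) -> tuple[float, ...]:
        ks = range(1, self.n_steps + 1)
        return tuple(-k * self.step_s for k in reversed(ks)) + tuple(
            k * self.step_s for k in ks
        )


# --------------------------------------------------------------------------
# resampling and filtering


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased downsampling; output length = round(len * fs_out / fs_in)."""
    if fs_out <= 0 or fs_in <= 0:
        raise ConfigurationError("sampling rates must be positive")
    if fs_out > fs_in:
        raise ConfigurationError(
            f"upsampling ({fs_in} -> {fs_out} Hz) is not supported"
        )
    x = np.asarray(x, dtype=float)
    if fs_out == fs_in:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    y = _sig.resample_poly(x, frac.numerator, frac.denominator)
    target = int(round(len(x) * fs_out / fs_in))
    return y[:target] if len(y) >= target else np.pad(y, (0, target - len(y)))


def design_filter(spec: FilterSpec):
    """Second-order-section Butterworth coefficients for ``spec`` (clipped)."""
    spec = spec.clipped()
    band = spec.band_hz[0] if spec.kind == "lowpass" else list(spec.band_hz)
    return _sig.butter(spec.order, band, btype=spec.kind, fs=spec.fs_hz, output="sos")


def apply_filter(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Zero-phase (forward-backward) application; length-preserving."""
    x = np.asarray(x, dtype=float)
    padlen = 3 * (2 * len(sos) + 1)
    if len(x) <= padlen:
        raise ValidationError(
            f"signal of length {len(x)} too short for zero-phase filtering "
            f"(needs > {padlen} samples)"
        )
    return _sig.sosfiltfilt(sos, x)


def preprocess_recording(
    rec: MultiModalRecording,
    specs: Mapping[str, FilterSpec] | None = None,
    target_fs_hz: float = 256.0,
) -> MultiModalRecording:
    """Filter each modality at the native rate, then downsample to 256 Hz."""
    if specs is None:
        specs = default_filter_specs(rec.fs_hz)
    out = {}
    for mod in MODALITIES:
        y = apply_filter(design_filter(specs[mod]), rec.modality(mod))
        out[mod] = resample(y, rec.fs_hz, target_fs_hz)
    return MultiModalRecording(
        subject_id=rec.subject_id,
        fs_hz=target_fs_hz,
        eda=out["eda"],
        ecg=out["ecg"],
        emg=out["emg"],
        schedule=rec.schedule,
    )


# --------------------------------------------------------------------------
# detrending and segmentation


def detrend_poly(segment: np.ndarray, degree: int = 5) -> np.ndarray:
    """Subtract the degree-``degree`` least-squares polynomial fit.

    Removes any polynomial of degree <= ``degree`` exactly (to numerical
    tolerance) and is a projection.  Applied to ECG windows to strip the
    EDA-correlated baseline wander.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValidationError("detrend_poly expects a 1-D segment")
    if len(segment) <= degree + 1:
        raise ValidationError(
            f"segment of length {len(segment)} too short for degree {degree} fit"
        )
    x = np.linspace(-1.0, 1.0, len(segment))  # scaled abscissa for conditioning
    coeffs = npoly.polyfit(x, segment, degree)
    return segment - npoly.polyval(x, coeffs)


def _window_bounds(onset_s: float, cfg: SegmentationConfig, shift_s: float = 0.0):
    start = int(round((onset_s + cfg.onset_shift_s + shift_s) * cfg.fs_hz))
    return start, start + cfg.window_len


def _extract_windows(
    rec: MultiModalRecording,
    labels: list[TrialLabel],
    cfg: SegmentationConfig,
    shifts_s: tuple[float, ...],
    on_oob: str,
    detrend_degree: int = 5,
) -> dict[str, SegmentSet]:
    cfg.validate()
    if abs(rec.fs_hz - cfg.fs_hz) > 1e-6:
        raise ValidationError(
            f"recording rate {rec.fs_hz} Hz does not match segmentation "
            f"config rate {cfg.fs_hz} Hz; preprocess first"
        )
    n = rec.n_samples
    rows: list[tuple[int, TrialLabel, bool]] = []
    for lab in labels:
        for shift in shifts_s:
            start, end = _window_bounds(lab.onset_s, cfg, shift)
            if start < 0 or end > n:
                if on_oob == "error":
                    raise SegmentationError(
                        f"window [{start}, {end}) for trial {lab.trial_index} "
                        f"(subject {lab.subject_id}, shift {shift:+.3g} s) exceeds "
                        f"recording of {n} samples"
                    )
                warnings.warn(
                    f"skipping out-of-bounds augmented window for trial "
                    f"{lab.trial_index} (subject {lab.subject_id}, shift "
                    f"{shift:+.3g} s)",
                    stacklevel=2,
                )
                continue
            rows.append((start, lab, shift != 0.0))
    out = {}
    w = cfg.window_len
    for mod in MODALITIES:
        sig = rec.modality(mod)
        data = np.empty((len(rows), w), dtype=float)
        for i, (start, _lab, _aug) in enumerate(rows):
            win = sig[start : start + w]
            data[i] = detrend_poly(win, detrend_degree) if mod == "ecg" else win
        out[mod] = SegmentSet(
            modality=mod.upper(),
            data=data[:, :, None],
            labels=np.array([lab.level for _s, lab, _a in rows]),
            subject_ids=np.array([lab.subject_id for _s, lab, _a in rows]),
            is_augmented=np.array([aug for _s, _l, aug in rows]),
            trial_indices=np.array([lab.trial_index for _s, lab, _a in rows]),
            fs_hz=cfg.fs_hz,
            window_s=cfg.window_s,
        )
    return out


def segment(
    rec: MultiModalRecording,
    labels: list[TrialLabel],
    cfg: SegmentationConfig | None = None,
) -> dict[str, SegmentSet]:
    """One 1152-sample window per trial per modality (ECG windows detrended).

    Window start index = ``round((onset_s + onset_shift_s) * fs_hz)``;
    windows are half-open ``[start, start + window_len)``.  A window falling
    outside the recording raises :class:`SegmentationError` naming the trial.
    """
    cfg = cfg or SegmentationConfig()
    return _extract_windows(rec, labels, cfg, (0.0,), on_oob="error")


def augment(
    rec: MultiModalRecording,
    labels: list[TrialLabel],
    seg_cfg: SegmentationConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
) -> dict[str, SegmentSet]:
    """Base window plus time-shifted copies per trial, augmented ones flagged.

    At defaults this yields 9 windows per trial (1 base + 8 shifted by
    +-{0.25, 0.5, 0.75, 1.0} s), all carrying the base trial's level label.
    Shifted windows falling outside the recording are skipped with a warning;
    an out-of-bounds *base* window is still an error.
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    aug_cfg = aug_cfg or AugmentationConfig()
    aug_cfg.validate()
    base = _extract_windows(rec, labels, seg_cfg, (0.0,), on_oob="error")
    shifted = _extract_windows(rec, labels, seg_cfg, aug_cfg.shifts_s, on_oob="skip")
    out = {}
    for mod in MODALITIES:
        b, s = base[mod], shifted[mod]
        out[mod] = SegmentSet(
            modality=b.modality,
            data=np.concatenate([b.data, s.data]),
            labels=np.concatenate([b.labels, s.labels]),
            subject_ids=np.concatenate([b.subject_ids, s.subject_ids]),
            is_augmented=np.concatenate([b.is_augmented, s.is_augmented]),
            trial_indices=np.concatenate([b.trial_indices, s.trial_indices]),
            fs_hz=b.fs_hz,
            window_s=b.window_s,
        )
    return out
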