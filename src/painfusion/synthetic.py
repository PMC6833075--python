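"""Synthetic tri-modal physiological recordings with a heat-pain protocol structure.

The generator emulates the statistical layout of a calibrated heat-pain
stimulation study: every subject receives ``reps_per_level`` elicitations of
each of five stimulation levels (T0 baseline ... T4 pain tolerance), each
held for a 4 s plateau and followed by an 8-12 s rest at baseline, while
electrodermal activity (EDA, uS), electrocardiogram (ECG, uV) and trapezius
electromyogram (EMG, uV) are recorded.

Signal phenomenology:

* **EDA** - a tonic baseline plus a slow drift, with a phasic
  skin-conductance response (SCR, bi-exponential Bateman-type kernel) added
  after every elicitation; SCR amplitude grows monotonically with the level.
* **ECG** - a Gaussian R-wave pulse train whose instantaneous rate rises with
  the level during/after the plateau, plus a low-frequency baseline wander
  injected as a scaled copy of the standardized EDA trace (emulating the
  EDA-correlated wander the preprocessing stage must remove).
* **EMG** - zero-mean band-limited (20-120 Hz) noise whose variance scales
  with the level around each plateau.

By construction EDA carries the strongest level-dependent effect, EMG a weak
one and ECG the weakest, so that a multi-modal fusion model has a well-posed
"most informative modality" to discover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as _sig

from .errors import ConfigurationError

__all__ = [
    "LEVELS",
    "GeneratorConfig",
    "SubjectProfile",
    "StimulusSchedule",
    "MultiModalRecording",
    "make_schedule",
    "scr_kernel",
    "sample_profile",
    "simulate_subject",
    "simulate_cohort",
    "simulate_cohort_arrays",
]

#: Ordered stimulation levels: baseline, pain threshold, two intermediates,
#: pain tolerance.
LEVELS: tuple[str, ...] = ("T0", "T1", "T2", "T3", "T4")

MODALITIES: tuple[str, ...] = ("eda", "emg", "ecg")


def _default_effect_profile() -> dict[str, tuple[float, ...]]:
    # Monotone per-level effect sizes, T0 = 0 by definition.  EDA dominates,
    # EMG is weakly informative, ECG weakest: chosen once so that a trivial
    # threshold classifier separates T0/T4 best on EDA (separability
    # ordering), mirroring the modality ranking reported for real data.
    return {
        "eda": (0.0, 0.3, 0.6, 1.0, 1.5),
        "emg": (0.0, 0.06, 0.12, 0.2, 0.3),
        "ecg": (0.0, 0.12, 0.25, 0.38, 0.5),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generation parameters.

    ``fs_hz`` defaults to 512 so that the 256 Hz downsampling path of the
    preprocessing stage is exercised; pass 256 to generate directly at the
    analysis rate.
    """

    n_subjects: int = 87
    levels: tuple[str, ...] = LEVELS
    reps_per_level: int = 20
    plateau_s: float = 4.0
    rest_range_s: tuple[float, float] = (8.0, 12.0)
    fs_hz: float = 512.0
    effect_profile: dict[str, tuple[float, ...]] = field(
        default_factory=_default_effect_profile
    )
    effect_scale: float = 1.0
    wander_gain: float = 150.0  # uV of ECG wander per SD of the EDA trace
    lead_in_s: float = 6.0
    tail_s: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.rest_range_s
        if not (0.0 <= lo <= hi):
            raise ConfigurationError(
                f"invalid rest interval {self.rest_range_s}: lower must be "
                "non-negative and <= upper"
            )
        if self.fs_hz <= 0:
            raise ConfigurationError("fs_hz must be positive")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.reps_per_level < 1:
            raise ConfigurationError("reps_per_level must be >= 1")
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError("levels must be unique")
        if not set(self.levels) <= set(LEVELS):
            raise ConfigurationError(f"levels must be a subset of {LEVELS}")
        for mod, prof in self.effect_profile.items():
            if len(prof) != len(LEVELS):
                raise ConfigurationError(
                    f"effect_profile[{mod!r}] must have one entry per level in {LEVELS}"
                )
            if abs(prof[0]) > 0:
                raise ConfigurationError(
                    f"effect_profile[{mod!r}] must be 0 at the reference level"
                )
            if any(b < a for a, b in zip(prof, prof[1:])):
                raise ConfigurationError(
                    f"effect_profile[{mod!r}] must be non-decreasing"
                )

    @property
    def trials_per_subject(self) -> int:
        return self.reps_per_level * len(self.levels)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject random effects (inter-subject variability)."""

    subject_id: str
    scr_gain: float  # uS amplitude multiplier of the per-level EDA effect
    scr_latency_s: float  # stimulus-to-SCR-onset delay
    tonic_level: float  # uS tonic skin conductance
    hr_baseline_bpm: float
    hr_gain_bpm_per_level: float  # bpm increment at unit effect size
    emg_gain: float  # EMG noise-variance multiplier at unit effect size
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"eda": 0.02, "emg": 8.0, "ecg": 15.0, "eda_drift": 0.2}
    )

    def validate(self) -> None:
        if min(self.scr_gain, self.hr_gain_bpm_per_level, self.emg_gain) < 0:
            raise ConfigurationError("subject gains must be non-negative")
        if not 40.0 <= self.hr_baseline_bpm <= 120.0:
            raise ConfigurationError("hr_baseline_bpm must lie in [40, 120] bpm")


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered elicitation plan: (onset_s, level, plateau_s) triples."""

    entries: tuple[tuple[float, str, float], ...]
    total_duration_s: float

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries])

    @property
    def levels(self) -> list[str]:
        return [e[1] for e in self.entries]


@dataclass
class MultiModalRecording:
    """Synchronized EDA/ECG/EMG sample arrays for one subject."""

    subject_id: str
    fs_hz: float
    eda: np.ndarray
    ecg: np.ndarray
    emg: np.ndarray
    schedule: StimulusSchedule | None = None

    def __post_init__(self) -> None:
        n = len(self.eda)
        if len(self.ecg) != n or len(self.emg) != n:
            raise ConfigurationError("modality arrays must have identical length")
        for name in MODALITIES:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ConfigurationError(f"{name} contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.eda)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def modality(self, name: str) -> np.ndarray:
        return getattr(self, name)


def _rng(config_seed: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config_seed,) + streams))


def make_schedule(config: GeneratorConfig, subject_seed: int) -> StimulusSchedule:
    """Draw a seeded random elicitation order with protocol-conform gaps.

    Each level occurs exactly ``reps_per_level`` times in a random
    permutation; consecutive plateaus are separated by a rest drawn uniformly
    from ``rest_range_s``.  Deterministic given ``(config.seed,
    subject_seed)``.
    """
    config.validate()
    rng = _rng(config.seed, subject_seed, 0)
    order = np.repeat(np.arange(len(config.levels)), config.reps_per_level)
    rng.shuffle(order)
    entries = []
    t = config.lead_in_s
    lo, hi = config.rest_range_s
    for li in order:
        entries.append((float(t), config.levels[li], config.plateau_s))
        t += config.plateau_s + rng.uniform(lo, hi)
    total = entries[-1][0] + config.plateau_s + config.tail_s
    return StimulusSchedule(entries=tuple(entries), total_duration_s=float(total))


def scr_kernel(
    t: np.ndarray, tau_rise: float = 0.75, tau_decay: float = 2.0
) -> np.ndarray:
    """Unit-amplitude phasic skin-conductance-response kernel.

    Bateman-type difference of exponentials ``exp(-t/tau_decay) -
    exp(-t/tau_rise)``, zero for t < 0, normalized so its analytic peak is 1.
    """
    if not 0 < tau_rise < tau_decay:
        raise ConfigurationError(
            f"require 0 < tau_rise < tau_decay, got {tau_rise}, {tau_decay}"
        )
    t = np.asarray(t, dtype=float)
    raw = np.where(t >= 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    return np.maximum(raw / peak, 0.0)


def sample_profile(
    config: GeneratorConfig, subject_seed: int, subject_id: str
) -> SubjectProfile:
    """Draw per-subject random effects (log-normal gains, uniform baselines)."""
    rng = _rng(config.seed, subject_seed, 1)
    profile = SubjectProfile(
        subject_id=subject_id,
        scr_gain=float(rng.lognormal(mean=math.log(2.0), sigma=0.25)),
        scr_latency_s=float(rng.uniform(1.5, 3.0)),
        tonic_level=float(rng.uniform(3.0, 7.0)),
        hr_baseline_bpm=float(rng.uniform(60.0, 85.0)),
        hr_gain_bpm_per_level=float(rng.lognormal(mean=math.log(6.0), sigma=0.25)),
        emg_gain=float(rng.lognormal(mean=math.log(1.0), sigma=0.3)),
        noise_sd={
            "eda": 0.02,
            "emg": float(rng.uniform(6.0, 10.0)),
            "ecg": 15.0,
            "eda_drift": float(rng.uniform(0.05, 0.15)),
        },
    )
    profile.validate()
    return profile


def _level_index(config: GeneratorConfig, level: str) -> int:
    # effect profiles are always indexed over the full T0..T4 scale, even
    # when a config administers only a subset of levels
    return LEVELS.index(level)


def _gaussian_pulse(fs: float, sigma_s: float = 0.012, half_width_sigmas: float = 4.0):
    half = int(round(half_width_sigmas * sigma_s * fs))
    tt = np.arange(-half, half + 1) / fs
    return np.exp(-0.5 * (tt / sigma_s) ** 2), half


def _add_at(target: np.ndarray, start: int, chunk: np.ndarray) -> None:
    """Add ``chunk`` into ``target`` starting at ``start``, clipping at edges."""
    lo = max(start, 0)
    hi = min(start + len(chunk), len(target))
    if hi > lo:
        target[lo:hi] += chunk[lo - start : hi - start]


def simulate_subject(
    profile: SubjectProfile,
    schedule: StimulusSchedule,
    config: GeneratorConfig,
    seed: int = 0,
) -> MultiModalRecording:
    """Synthesize one subject's tri-modal recording from a stimulus schedule.

    Deterministic given ``(config.seed, seed)``; all three modality arrays
    have length ``ceil(total_duration_s * fs_hz)``.
    """
    config.validate()
    profile.validate()
    fs = config.fs_hz
    n = math.ceil(schedule.total_duration_s * fs)
    t = np.arange(n) / fs
    rng = _rng(config.seed, seed, 2)
    scale = config.effect_scale

    # ---- EDA: tonic + slow drift + level-scaled SCRs + noise -------------
    eda = np.full(n, profile.tonic_level)
    drift_amp = profile.noise_sd.get("eda_drift", 0.0)
    if drift_amp > 0:
        for period in (97.0, 211.0):
            phase = rng.uniform(0, 2 * math.pi)
            eda += drift_amp * np.sin(2 * math.pi * t / period + phase)
    else:
        rng.uniform(0, 2 * math.pi, size=2)  # keep stream alignment
    kernel_t = np.arange(int(round(15.0 * fs))) / fs
    kernel = scr_kernel(kernel_t)
    eda_profile = config.effect_profile.get("eda", (0.0,) * len(LEVELS))
    for onset, level, _plateau in schedule.entries:
        amp = profile.scr_gain * eda_profile[_level_index(config, level)] * scale
        if amp > 0:
            start = int(round((onset + profile.scr_latency_s) * fs))
            _add_at(eda, start, amp * kernel)
    if profile.noise_sd.get("eda", 0.0) > 0:
        eda = eda + rng.normal(0.0, profile.noise_sd["eda"], size=n)
    else:
        rng.normal(0.0, 1.0, size=0)

    # ---- ECG: Gaussian R-wave train + EDA-correlated wander + noise ------
    rate_bpm = np.full(n, profile.hr_baseline_bpm)
    ecg_profile = config.effect_profile.get("ecg", (0.0,) * len(LEVELS))
    for onset, level, plateau in schedule.entries:
        bump = (
            profile.hr_gain_bpm_per_level
            * ecg_profile[_level_index(config, level)]
            * scale
        )
        if bump > 0:
            i0 = int(round(onset * fs))
            i1 = min(int(round((onset + plateau + 4.0) * fs)), n)
            rate_bpm[i0:i1] += bump
    phase = np.cumsum(rate_bpm / 60.0) / fs
    beat_idx = np.flatnonzero(np.diff(np.floor(phase)) > 0) + 1
    pulse, half = _gaussian_pulse(fs)
    ecg = np.zeros(n)
    for bi in beat_idx:
        _add_at(ecg, bi - half, pulse)
    ecg *= 800.0  # R-wave amplitude in uV
    if config.wander_gain != 0:
        sd = eda.std()
        if sd > 1e-12:
            ecg = ecg + config.wander_gain * (eda - eda.mean()) / sd
    if profile.noise_sd.get("ecg", 0.0) > 0:
        ecg = ecg + rng.normal(0.0, profile.noise_sd["ecg"], size=n)

    # ---- EMG: band-limited noise with level-scaled variance --------------
    emg_sd = profile.noise_sd.get("emg", 0.0)
    if emg_sd > 0:
        white = rng.normal(0.0, 1.0, size=n)
        hi_edge = min(120.0, 0.45 * fs)
        sos = _sig.butter(4, [20.0, hi_edge], btype="bandpass", fs=fs, output="sos")
        band = _sig.sosfilt(sos, white)
        band = band / band.std()
        envelope = np.ones(n)
        emg_profile = config.effect_profile.get("emg", (0.0,) * len(LEVELS))
        for onset, level, plateau in schedule.entries:
            boost = (
                profile.emg_gain * emg_profile[_level_index(config, level)] * scale
            )
            if boost > 0:
                i0 = int(round(onset * fs))
                i1 = min(int(round((onset + plateau + 2.0) * fs)), n)
                envelope[i0:i1] = math.sqrt(1.0 + boost)
        emg = emg_sd * envelope * band
    else:
        emg = np.zeros(n)

    return MultiModalRecording(
        subject_id=profile.subject_id,
        fs_hz=fs,
        eda=eda,
        ecg=ecg,
        emg=emg,
        schedule=schedule,
    )


def _labels_for(schedule: StimulusSchedule, subject_id: str):
    from .io import TrialLabel

    return [
        TrialLabel(subject_id=subject_id, trial_index=i, level=level, onset_s=onset)
        for i, (onset, level, _p) in enumerate(schedule.entries)
    ]


def simulate_cohort_arrays(
    config: GeneratorConfig,
) -> list[tuple[MultiModalRecording, list]]:
    """Simulate a cohort in memory; returns (recording, labels) per subject."""
    config.validate()
    out = []
    for i in range(config.n_subjects):
        sid = f"S{i:03d}"
        schedule = make_schedule(config, i)
        profile = sample_profile(config, i, sid)
        rec = simulate_subject(profile, schedule, config, seed=i)
        out.append((rec, _labels_for(schedule, sid)))
    return out


def simulate_cohort(
    config: GeneratorConfig, out_dir: str | Path, write_signals: bool = True
):
    """Simulate a cohort and write it to ``out_dir`` in the package layout.

    Label files and the manifest are always written; ``write_signals=False``
    skips synthesizing and writing the (large) per-sample recording CSVs,
    which makes full-cohort protocol/label accounting cheap.  Per-subject
    seeds are derived from ``config.seed``, so two calls with the same config
    produce byte-identical label files.
    """
    from . import io as pio

    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = []
    for i in range(config.n_subjects):
        sid = f"S{i:03d}"
        schedule = make_schedule(config, i)
        labels = _labels_for(schedule, sid)
        label_file = f"{sid}_labels.csv"
        pio.write_labels(labels, out_dir / label_file)
        rec_file = f"{sid}_recording.csv"
        if write_signals:
            profile = sample_profile(config, i, sid)
            rec = simulate_subject(profile, schedule, config, seed=i)
            pio.write_recording(rec, out_dir / rec_file)
        subjects.append((sid, rec_file, label_file))
    manifest = pio.DatasetManifest(
        root=out_dir,
        subjects=tuple(subjects),
        fs_hz=config.fs_hz,
        created_with={
            "n_subjects": config.n_subjects,
            "reps_per_level": config.reps_per_level,
            "levels": list(config.levels),
            "fs_hz": config.fs_hz,
            "seed": config.seed,
            "effect_scale": config.effect_scale,
            "signals_written": bool(write_signals),
        },
    )
    pio.write_manifest(manifest, out_dir / "manifest.json")
    return manifest


def null_config(config: GeneratorConfig | None = None, **overrides) -> GeneratorConfig:
    """A copy of ``config`` with all level effects and wander removed.

    Under this configuration the five levels are statistically identical, so
    any classifier's held-out accuracy should sit at chance.
    """
    base = config if config is not None else GeneratorConfig()
    return replace(base, effect_scale=0.0, wander_gain=0.0, **overrides)
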