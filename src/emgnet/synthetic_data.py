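"""Synthetic 8-channel sEMG generator with controllable class separation.

Each gesture is a row of per-channel activation amplitudes.  A recording
is amplitude x band-limited zero-mean Gaussian carrier (white noise
band-pass filtered with a zero-phase Butterworth filter) plus optional
baseline noise, with an optional linear amplitude ramp at both segment
ends standing in for gesture-transition intervals.

Not a physiological simulator — it exists so the whole downstream pipeline
(segmentation, scalograms, classifiers) is exercisable with known class
structure and zero downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .signal_io import Recording, write_recording_dir

__all__ = [
    "MIN_SEPARATION_FLOOR",
    "ActivationMatrix",
    "SynthConfig",
    "make_activation_profiles",
    "generate_recording",
    "generate_dataset",
    "write_dataset",
]

#: Documented floor on the pairwise Euclidean distance between activation
#: rows; profiles are re-sampled until every pair clears it.
MIN_SEPARATION_FLOOR = 0.4


@dataclass(frozen=True)
class ActivationMatrix:
    """Per-gesture, per-channel non-negative activation amplitudes."""

    values: np.ndarray  # (n_gestures, n_channels)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be (n_gestures, n_channels)")
        if np.any(vals < 0):
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "values", vals)

    @property
    def min_separation(self) -> float:
        """Smallest pairwise Euclidean row distance; +inf for one row."""
        n = self.values.shape[0]
        if n < 2:
            return float("inf")
        dists = [
            float(np.linalg.norm(self.values[i] - self.values[j]))
            for i in range(n)
            for j in range(i + 1, n)
        ]
        return min(dists)


@dataclass(frozen=True)
class SynthConfig:
    n_gestures: int = 7
    n_channels: int = 8
    sample_rate: float = 200.0
    duration_per_repetition: float = 5.0
    repetitions_per_gesture: int = 3
    carrier_band: tuple[float, float] = (20.0, 95.0)
    baseline_noise_sd: float = 0.01
    transition_ms: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_gestures < 1 or self.n_channels < 1:
            raise ValueError("counts must be >= 1")
        if self.repetitions_per_gesture < 1:
            raise ValueError("repetitions_per_gesture must be >= 1")
        if self.sample_rate <= 0 or self.duration_per_repetition <= 0:
            raise ValueError("sample_rate and duration must be positive")
        low, high = self.carrier_band
        if not (0 < low < high < self.sample_rate / 2):
            raise ValueError(
                f"carrier_band {self.carrier_band} must lie inside "
                f"(0, {self.sample_rate / 2}) with low < high"
            )
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be >= 0")
        if self.transition_ms < 0:
            raise ValueError("transition_ms must be >= 0")


def make_activation_profiles(
    n_gestures: int, n_channels: int, seed: int
) -> ActivationMatrix:
    """Seeded uniform(0.2, 1) profiles, greedily re-sampled for separation.

    Rows are re-drawn until each clears :data:`MIN_SEPARATION_FLOOR`
    against every previously accepted row, so pairwise distinctness is
    guaranteed by construction.  Deterministic given the seed.
    """
    if n_gestures < 1 or n_channels < 1:
        raise ValueError("n_gestures and n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    for _ in range(n_gestures):
        for attempt in range(10_000):
            cand = rng.uniform(0.2, 1.0, size=n_channels)
            if all(
                np.linalg.norm(cand - r) >= MIN_SEPARATION_FLOOR for r in rows
            ):
                rows.append(cand)
                break
        else:
            raise ValueError(
                f"could not place {n_gestures} profiles at separation "
                f">= {MIN_SEPARATION_FLOOR} in {n_channels} channels"
            )
    return ActivationMatrix(np.stack(rows))


def _bandlimited_carrier(
    n_samples: int, sample_rate: float, band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-phase band-pass filtered standard Gaussian noise."""
    nyq = sample_rate / 2.0
    sos = butter(4, [band[0] / nyq, band[1] / nyq], btype="bandpass", output="sos")
    white = rng.standard_normal(n_samples)
    return sosfiltfilt(sos, white)


def generate_recording(
    profile_row,
    config: SynthConfig,
    gesture_label,
    subject_id: str = "synth",
    seed: int = 0,
) -> Recording:
    """One labelled repetition of a gesture.

    Per channel: ``amplitude * carrier + baseline_noise``.  The transition
    ramp (when ``transition_ms > 0``) multiplies only the activation
    component — the baseline noise floor persists through transitions.
    """
    profile = np.asarray(profile_row, dtype=float).ravel()
    if profile.size != config.n_channels:
        raise ValueError(
            f"profile has {profile.size} channels, config expects "
            f"{config.n_channels}"
        )
    rng = np.random.default_rng(seed)
    n = int(round(config.duration_per_repetition * config.sample_rate))
    signal = np.empty((config.n_channels, n))
    envelope = _transition_envelope(n, config)
    for c in range(config.n_channels):
        if profile[c] == 0.0:
            # keep the stream position independent of amplitudes
            carrier = np.zeros(n)
            rng.standard_normal(n)
        else:
            carrier = _bandlimited_carrier(
                n, config.sample_rate, config.carrier_band, rng
            )
        signal[c] = profile[c] * carrier * envelope
    if config.baseline_noise_sd > 0:
        signal += config.baseline_noise_sd * rng.standard_normal(signal.shape)
    return Recording(signal, config.sample_rate, gesture_label, subject_id)


def _transition_envelope(n: int, config: SynthConfig) -> np.ndarray:
    ramp_len = int(round(config.transition_ms * config.sample_rate / 1000.0))
    env = np.ones(n)
    if ramp_len == 0:
        return env
    ramp_len = min(ramp_len, n // 2)
    ramp = np.linspace(0.0, 1.0, ramp_len, endpoint=False)
    env[:ramp_len] = ramp
    env[n - ramp_len :] = ramp[::-1]
    return env


def generate_dataset(config: SynthConfig) -> list[Recording]:
    """All gestures x repetitions, deterministic given ``config.seed``.

    Per-recording seeds are drawn from a seed sequence derived from the
    dataset seed, so recordings are mutually independent yet reproducible.
    """
    profiles = make_activation_profiles(
        config.n_gestures, config.n_channels, config.seed
    )
    n_total = config.n_gestures * config.repetitions_per_gesture
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n_total)
    recordings = []
    i = 0
    for g in range(config.n_gestures):
        for rep in range(config.repetitions_per_gesture):
            recordings.append(
                generate_recording(
                    profiles.values[g],
                    config,
                    gesture_label=g,
                    subject_id=f"synth{rep}",
                    seed=int(child_seeds[i]),
                )
            )
            i += 1
    return recordings


def write_dataset(config: SynthConfig, directory) -> list[Recording]:
    """Generate and persist a dataset in the delimited-text layout."""
    recordings = generate_dataset(config)
    write_recording_dir(recordings, directory)
    return recordings
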