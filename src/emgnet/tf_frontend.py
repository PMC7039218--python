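"""Time-frequency frontend: Mexican-hat CWT scalograms and STFT spectrograms.

Each 8x52 analysis window is mapped, channel by channel, to a 32x52
Mexican-hat scalogram which is then mean-pooled (3x3 kernel, stride 2, no
padding) down to 15x25.  Stacking the 8 channels yields the (8, 15, 25)
model input tensor.

CWT convention
--------------
With translation ``b`` and scale ``a`` the coefficient is

    X(a, b) = (1 / norm(a)) * sum_t x[t] * psi((t - b) / a)

over the window's own samples only (zero extension outside the window).
``norm(a)`` is ``a`` under the default ``"eq3"`` convention and ``sqrt(a)``
under ``"unit-energy"``.  The fast path evaluates this as a single matrix
product against a precomputed wavelet bank; tests check it against a direct
triple-loop summation oracle.
"""

from __future__ import annotations

import functools
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .signal_io import WindowSample

__all__ = [
    "MEXH_PEAK",
    "DEFAULT_SCALES",
    "mexican_hat",
    "cwt_scalogram",
    "stft_spectrogram",
    "downsample_half",
    "FrontendConfig",
    "Scalogram",
    "ScalogramTensor",
    "SpectrogramMatrix",
    "window_to_tensor",
    "windows_to_tensors",
    "fit_standardizer",
    "save_tensor_dataset",
    "load_tensor_dataset",
]

#: Peak value of the Mexican hat: psi(0) = 2 / (sqrt(3) * pi^(1/4)).
MEXH_PEAK = 2.0 / (np.sqrt(3.0) * np.pi**0.25)

#: Default scale ladder: integers 1..32, in samples.
DEFAULT_SCALES: tuple[int, ...] = tuple(range(1, 33))


def mexican_hat(t, scale: float = 1.0) -> np.ndarray | float:
    """Mexican-hat mother wavelet evaluated at ``t / scale``.

    psi(u) = (2 / (sqrt(3) * pi^(1/4))) * (1 - u^2) * exp(-u^2 / 2)
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    u = np.asarray(t, dtype=float) / scale
    out = MEXH_PEAK * (1.0 - u**2) * np.exp(-(u**2) / 2.0)
    return float(out) if np.isscalar(t) else out


@dataclass(frozen=True)
class Scalogram:
    """CWT coefficient matrix (n_scales x n_samples) with its scale ladder."""

    coefficients: np.ndarray
    scales: tuple[float, ...]

    def __post_init__(self):
        if self.coefficients.shape[0] != len(self.scales):
            raise ValueError("one coefficient row per scale required")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite scalogram coefficients")


@dataclass(frozen=True)
class ScalogramTensor:
    """Stacked per-channel downsampled scalograms plus the gesture label."""

    tensor: np.ndarray  # (n_channels, rows, cols)
    gesture_label: object = None

    def __post_init__(self):
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be (channels, rows, cols)")


@dataclass(frozen=True)
class SpectrogramMatrix:
    """Squared-magnitude STFT (n_freq_bins x n_frames)."""

    power: np.ndarray
    window_function: str
    hop: int

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("spectrogram power must be non-negative")


@functools.lru_cache(maxsize=8)
def _wavelet_bank(
    scales: tuple[float, ...], n_samples: int, normalization: str
) -> np.ndarray:
    """(n_scales * n_samples, n_samples) bank: row (a,b) holds psi((t-b)/a)/norm."""
    t = np.arange(n_samples, dtype=float)
    offsets = t[None, :] - t[:, None]  # offsets[b, t] = t - b
    rows = []
    for a in scales:
        if normalization == "eq3":
            norm = a
        elif normalization == "unit-energy":
            norm = np.sqrt(a)
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        rows.append(mexican_hat(offsets, scale=a) / norm)
    return np.concatenate(rows, axis=0)


def cwt_scalogram(
    signal,
    scales=DEFAULT_SCALES,
    normalization: str = "eq3",
) -> Scalogram:
    """Continuous wavelet transform of one single-channel window.

    Zero extension at the boundaries: only the window's own samples enter
    the sum.  Linear in the signal.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty signal")
    scales = tuple(float(a) for a in scales)
    if len(scales) == 0:
        raise ValueError("empty scale ladder")
    if any(a <= 0 for a in scales):
        raise ValueError("all scales must be positive")
    bank = _wavelet_bank(scales, x.size, normalization)
    coeffs = (bank @ x).reshape(len(scales), x.size)
    return Scalogram(coefficients=coeffs, scales=scales)


def stft_spectrogram(
    signal,
    window_function: str = "hann",
    window_length: int = 16,
    hop: int = 4,
) -> SpectrogramMatrix:
    """Squared-magnitude short-time Fourier transform.

    Frames start at 0, hop, 2*hop, ...; the incomplete tail is dropped.
    Rows are the non-negative frequency bins of the real FFT.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if window_length > x.size:
        raise ValueError(
            f"window_length {window_length} exceeds signal length {x.size}"
        )
    if hop < 1:
        raise ValueError("hop must be >= 1")
    taper = get_window(window_function, window_length, fftbins=True)
    starts = range(0, x.size - window_length + 1, hop)
    frames = np.stack([x[s : s + window_length] * taper for s in starts], axis=1)
    power = np.abs(np.fft.rfft(frames, axis=0)) ** 2
    return SpectrogramMatrix(power=power, window_function=window_function, hop=hop)


def downsample_half(mat) -> np.ndarray:
    """Mean pooling with a 3x3 kernel, stride 2, no padding.

    Maps a 32x52 scalogram to exactly 15x25; generally
    (floor((H-3)/2)+1, floor((W-3)/2)+1).
    """
    m = np.asarray(mat, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 3:
        raise ValueError(f"input must be at least 3x3, got {m.shape}")
    return sliding_window_view(m, (3, 3))[::2, ::2].mean(axis=(2, 3))


@dataclass(frozen=True)
class FrontendConfig:
    """Scalogram frontend settings.

    ``standardize_mean`` / ``standardize_sd`` are per-channel statistics
    estimated on the training split (see :func:`fit_standardizer`); when
    left ``None`` no standardization is applied.
    """

    scales: tuple[float, ...] = DEFAULT_SCALES
    normalization: str = "eq3"
    #: pool |coefficients| rather than the signed coefficients — a scalogram
    #: is conventionally a magnitude image, and the signed coefficients of a
    #: stochastic signal average out under mean pooling
    magnitude: bool = True
    standardize_mean: tuple[float, ...] | None = None
    standardize_sd: tuple[float, ...] | None = None

    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "scales": list(self.scales),
                "normalization": self.normalization,
                "magnitude": self.magnitude,
                "standardize_mean": None
                if self.standardize_mean is None
                else list(self.standardize_mean),
                "standardize_sd": None
                if self.standardize_sd is None
                else list(self.standardize_sd),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def window_to_tensor(
    window: WindowSample, config: FrontendConfig = FrontendConfig()
) -> ScalogramTensor:
    """Per-channel CWT + downsampling, channels stacked in input order."""
    sig = np.asarray(window.window, dtype=float)
    channels = []
    for c in range(sig.shape[0]):
        coeffs = cwt_scalogram(
            sig[c], config.scales, config.normalization
        ).coefficients
        if config.magnitude:
            coeffs = np.abs(coeffs)
        channels.append(downsample_half(coeffs))
    tensor = np.stack(channels, axis=0)
    tensor = _maybe_standardize(tensor, config)
    return ScalogramTensor(tensor=tensor, gesture_label=window.gesture_label)


def _maybe_standardize(tensor: np.ndarray, config: FrontendConfig) -> np.ndarray:
    if config.standardize_mean is None:
        return tensor
    mean = np.asarray(config.standardize_mean)[:, None, None]
    sd = np.asarray(config.standardize_sd)[:, None, None]
    return (tensor - mean) / np.where(sd > 0, sd, 1.0)


def windows_to_tensors(
    windows, config: FrontendConfig = FrontendConfig()
) -> tuple[np.ndarray, list]:
    """Vectorized batch transform.

    Returns ``(tensors, labels)`` where ``tensors`` has shape
    ``(n_windows, n_channels, rows, cols)``.  Identical output to mapping
    :func:`window_to_tensor` over the windows, but all CWTs are evaluated
    in one matrix product against the wavelet bank.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("empty window list")
    sigs = np.stack([np.asarray(w.window, dtype=float) for w in windows])
    n_win, n_ch, n_samp = sigs.shape
    scales = tuple(float(a) for a in config.scales)
    bank = _wavelet_bank(scales, n_samp, config.normalization)
    flat = sigs.reshape(n_win * n_ch, n_samp)
    coeffs = (flat @ bank.T).reshape(n_win, n_ch, len(scales), n_samp)
    if config.magnitude:
        coeffs = np.abs(coeffs)
    pooled = sliding_window_view(coeffs, (3, 3), axis=(2, 3))[
        :, :, ::2, ::2
    ].mean(axis=(4, 5))
    out = np.stack([_maybe_standardize(p, config) for p in pooled])
    return out, [w.gesture_label for w in windows]


def fit_standardizer(tensors: np.ndarray) -> tuple[tuple, tuple]:
    """Per-channel mean/SD over a (n, channels, rows, cols) training array."""
    t = np.asarray(tensors, dtype=float)
    mean = t.mean(axis=(0, 2, 3))
    sd = t.std(axis=(0, 2, 3))
    return tuple(float(m) for m in mean), tuple(float(s) for s in sd)


def save_tensor_dataset(path, tensors: np.ndarray, labels, config: FrontendConfig):
    """Persist a tensor dataset with labels and the config fingerprint."""
    np.savez(
        path,
        tensors=np.asarray(tensors, dtype=float),
        labels=np.asarray(labels),
        fingerprint=np.array(config.fingerprint()),
    )


def load_tensor_dataset(path) -> tuple[np.ndarray, np.ndarray, str]:
    with np.load(path, allow_pickle=False) as data:
        return data["tensors"], data["labels"], str(data["fingerprint"])
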