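"""Classical per-window feature sets and the LDA/SVM baseline harness.

Feature sets (per channel, concatenated in channel order):

* ``td`` — Hudgins time-domain set: MAV, ZC, SSC, WL.
* ``enhanced_td`` — TD + RMS + 4 autoregressive coefficients.
* ``ninapro`` — RMS + TD + 3-level marginal wavelet magnitudes
  (sum of absolute db7 detail coefficients per decomposition level).
* ``sampen`` — sample entropy + RMS + WL.

Thresholded counts (ZC, SSC) default to threshold 0, i.e. pure sign /
slope counting; thresholds stay configurable for noisy data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz

from .signal_io import WindowSample

__all__ = [
    "FeatureVector",
    "BaselineModel",
    "FEATURE_SET_NAMES",
    "td_features",
    "rms",
    "ar_coefficients",
    "sample_entropy",
    "dwt_detail_marginals",
    "extract_feature_set",
    "features_per_channel",
    "feature_names",
    "fit_baseline",
    "predict",
    "export_features_csv",
    "DB7_DEC_LO",
]

FEATURE_SET_NAMES = ("td", "enhanced_td", "ninapro", "sampen")

DEFAULT_AR_ORDER = 4
DEFAULT_DWT_LEVELS = 3

# Daubechies-7 decomposition low-pass filter (14 taps, sum = sqrt(2)).
# Orthonormality and vanishing-moment properties are asserted in the tests.
DB7_DEC_LO = np.array(
    [
        3.5371379997452024e-04, -1.8016407040474908e-03,
        4.2957797292136651e-04, 1.2550998556099840e-02,
        -1.6574541630666881e-02, -3.8029936935014413e-02,
        8.0612609151083078e-02, 7.1309219266830259e-02,
        -2.2403618499387498e-01, -1.4390600392856498e-01,
        4.6978228740519312e-01, 7.2913209084623509e-01,
        3.9653931948191729e-01, 7.7852054085009184e-02,
    ]
)
# Quadrature-mirror high-pass filter: hi[k] = (-1)^(k+1) * lo[N-1-k].
DB7_DEC_HI = DB7_DEC_LO[::-1] * np.array(
    [(-1.0) ** (k + 1) for k in range(DB7_DEC_LO.size)]
)


@dataclass(frozen=True)
class FeatureVector:
    """Flat per-window feature vector, channel-major."""

    values: np.ndarray
    set_name: str
    gesture_label: object = None

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(vals)):
            raise ValueError("feature vector contains non-finite values")
        if self.set_name not in FEATURE_SET_NAMES:
            raise ValueError(f"unknown feature set {self.set_name!r}")
        object.__setattr__(self, "values", vals)


def td_features(
    x, zc_threshold: float = 0.0, ssc_threshold: float = 0.0
) -> tuple[float, int, int, float]:
    """Hudgins time-domain features of one channel: (MAV, ZC, SSC, WL).

    ZC counts consecutive pairs with strictly opposite signs whose
    amplitude step clears ``zc_threshold``; SSC counts interior local
    extrema whose larger neighbouring step clears ``ssc_threshold``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise ValueError(f"window must have >= 3 samples, got {x.size}")
    mav = float(np.abs(x).mean())
    sign_flip = np.sign(x[:-1]) * np.sign(x[1:]) < 0  # avoids product underflow
    big_step = np.abs(np.diff(x)) >= zc_threshold
    zc = int(np.count_nonzero(sign_flip & big_step))
    d_prev = x[1:-1] - x[:-2]
    d_next = x[1:-1] - x[2:]
    extremum = d_prev * d_next > 0
    big = np.maximum(np.abs(d_prev), np.abs(d_next)) >= ssc_threshold
    ssc = int(np.count_nonzero(extremum & big))
    wl = float(np.abs(np.diff(x)).sum())
    return mav, zc, ssc, wl


def rms(x) -> float:
    """Root mean square amplitude."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty signal")
    return float(np.sqrt(np.mean(x**2)))


def ar_coefficients(x, order: int = DEFAULT_AR_ORDER) -> np.ndarray:
    """Yule-Walker autoregressive coefficients (autocorrelation method).

    Solves the order-p Toeplitz system R a = r by Levinson recursion, with
    the predictor sign convention ``x_t ~ sum_k a_k x_{t-k}``.  A
    zero-variance signal yields all-zero coefficients with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    if order < 1:
        raise ValueError("order must be >= 1")
    if x.size <= order:
        raise ValueError(f"need more than {order} samples, got {x.size}")
    x = x - x.mean()
    n = x.size
    r = np.array(
        [float(np.dot(x[: n - k], x[k:])) / n for k in range(order + 1)]
    )
    if r[0] <= 0:
        warnings.warn("zero-variance signal: AR coefficients set to zero")
        return np.zeros(order)
    return solve_toeplitz(r[:order], r[1 : order + 1])


def sample_entropy(x, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) under Chebyshev distance, self-matches excluded.

    Both counts use the same N-m templates (indices 0..N-m-1); B counts
    pairs matching over m points, A the same pairs over m+1 points.
    Conventions: B == 0 -> 0.0; A == 0 (with B > 0) -> +inf.  When ``r``
    is None it defaults to 0.2 x SD(x), falling back to a small epsilon
    for constant signals.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {x.size}")
    if r is None:
        sd = float(x.std())
        r = 0.2 * sd if sd > 0 else 1e-12
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    n_templates = x.size - m
    # (n_templates, m+1) embedding; the m-point templates are its prefix.
    emb = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templates]
    diff = np.abs(emb[:, None, :] - emb[None, :, :])
    iu = np.triu_indices(n_templates, k=1)
    match_m = (diff[:, :, :m].max(axis=2) <= r)[iu]
    match_m1 = (diff.max(axis=2) <= r)[iu]
    b = int(np.count_nonzero(match_m))
    a = int(np.count_nonzero(match_m1))
    if b == 0:
        return 0.0
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


def dwt_detail_marginals(
    x, levels: int = DEFAULT_DWT_LEVELS
) -> np.ndarray:
    """Sum of absolute db7 detail coefficients at each decomposition level.

    Zero-padded discrete wavelet transform: per level the running
    approximation is convolved (full) with the decomposition filters and
    downsampled by keeping odd output indices.
    """
    a = np.asarray(x, dtype=float).ravel()
    if a.size < 2:
        raise ValueError("signal too short for a wavelet decomposition")
    out = np.empty(levels)
    for lvl in range(levels):
        detail = np.convolve(a, DB7_DEC_HI, mode="full")[1::2]
        a = np.convolve(a, DB7_DEC_LO, mode="full")[1::2]
        out[lvl] = np.abs(detail).sum()
    return out


def features_per_channel(set_name: str) -> int:
    return len(_channel_feature_names(set_name))


def _channel_feature_names(set_name: str) -> list[str]:
    if set_name == "td":
        return ["mav", "zc", "ssc", "wl"]
    if set_name == "enhanced_td":
        return ["mav", "zc", "ssc", "wl", "rms"] + [
            f"ar{k}" for k in range(1, DEFAULT_AR_ORDER + 1)
        ]
    if set_name == "ninapro":
        return ["rms", "mav", "zc", "ssc", "wl"] + [
            f"dwt{k}" for k in range(1, DEFAULT_DWT_LEVELS + 1)
        ]
    if set_name == "sampen":
        return ["sampen", "rms", "wl"]
    raise ValueError(f"unknown feature set {set_name!r}")


def feature_names(set_name: str, n_channels: int) -> list[str]:
    """Header names: ``ch{c}_{feature}`` in channel-major order."""
    return [
        f"ch{c}_{name}"
        for c in range(n_channels)
        for name in _channel_feature_names(set_name)
    ]


def _channel_features(x: np.ndarray, set_name: str) -> list[float]:
    if set_name == "td":
        return list(td_features(x))
    if set_name == "enhanced_td":
        mav, zc, ssc, wl = td_features(x)
        return [mav, zc, ssc, wl, rms(x), *ar_coefficients(x)]
    if set_name == "ninapro":
        mav, zc, ssc, wl = td_features(x)
        return [rms(x), mav, zc, ssc, wl, *dwt_detail_marginals(x)]
    if set_name == "sampen":
        s = sample_entropy(x)
        _, _, _, wl = td_features(x)
        # +inf sentinel (no m+1 matches) is capped for classifier safety
        return [min(s, 1e6), rms(x), wl]
    raise ValueError(f"unknown feature set {set_name!r}")


def extract_feature_set(window: WindowSample, set_name: str) -> FeatureVector:
    """Per-channel features concatenated in channel order."""
    if set_name not in FEATURE_SET_NAMES:
        raise ValueError(
            f"unknown feature set {set_name!r}; choose from {FEATURE_SET_NAMES}"
        )
    sig = np.asarray(window.window, dtype=float)
    values = [v for c in range(sig.shape[0]) for v in _channel_features(sig[c], set_name)]
    return FeatureVector(
        values=np.asarray(values), set_name=set_name,
        gesture_label=window.gesture_label,
    )


@dataclass
class BaselineModel:
    """Fitted classical classifier with its scaler and class list."""

    kind: str  # "lda" | "svm"
    pipeline: object
    classes: np.ndarray


def fit_baseline(features, kind: str = "lda") -> BaselineModel:
    """Standardize then fit an LDA or RBF-SVM on labelled feature vectors.

    LDA uses the least-squares solver without shrinkage; the SVM uses an
    RBF kernel with C=1 and gamma = 1 / (n_features * feature variance).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    kind = kind.lower()
    if kind not in ("lda", "svm"):
        raise ValueError(f"kind must be 'lda' or 'svm', got {kind!r}")
    features = list(features)
    x = np.stack([f.values for f in features])
    y = np.asarray([f.gesture_label for f in features])
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to fit a baseline")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    clf = (
        LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None)
        if kind == "lda"
        else SVC(kernel="rbf", C=1.0, gamma="scale")
    )
    pipeline = Pipeline([("scale", StandardScaler()), ("clf", clf)])
    pipeline.fit(x, y)
    return BaselineModel(kind=kind, pipeline=pipeline, classes=classes)


def predict(model: BaselineModel, features) -> np.ndarray:
    """One predicted label per input feature vector."""
    x = np.stack([f.values for f in features])
    return model.pipeline.predict(x)


def export_features_csv(features, path) -> None:
    """Write feature vectors as CSV with a self-describing header."""
    features = list(features)
    if not features:
        raise ValueError("no features to export")
    set_name = features[0].set_name
    n_per = features_per_channel(set_name)
    n_channels = features[0].values.size // n_per
    header = ["gesture_label"] + feature_names(set_name, n_channels)
    lines = [",".join(header)]
    for f in features:
        lines.append(
            ",".join([str(f.gesture_label)] + [f"{v:.10g}" for v in f.values])
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
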