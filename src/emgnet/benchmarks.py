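"""Standard synthetic benchmarks used by the acceptance suite and CLI report.

The "standard benchmark" is a fully synthetic N-gesture problem with high
class separation and moderate noise: per gesture, several 5-second
repetitions are generated, segmented into 52-sample windows, and pushed
through both the scalogram+CNN route and the classical-feature baselines
on one shared split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classic_features import extract_feature_set, fit_baseline, predict
from .network import EMGNetConfig, build_emgnet
from .signal_io import segment_windows
from .synthetic_data import SynthConfig, generate_dataset
from .tf_frontend import FrontendConfig, windows_to_tensors
from .training import TrainPolicy, evaluate, split_dataset, train

__all__ = ["BenchmarkData", "make_benchmark", "run_cnn", "run_baseline"]


@dataclass
class BenchmarkData:
    windows: list
    labels: np.ndarray
    split: object
    n_gestures: int

    def windows_per_gesture(self) -> int:
        return int(np.bincount(self.labels).min())


def make_benchmark(
    n_gestures: int = 7,
    seed: int = 0,
    repetitions: int = 5,
    duration: float = 5.0,
    noise_sd: float = 0.05,
    stride: int = 15,
) -> BenchmarkData:
    """Generate windows and a shared 60/10/30 split for one benchmark run.

    Defaults give floor((1000-52)/15)+1 = 64 windows per repetition, i.e.
    320 windows per gesture at 5 repetitions.
    """
    config = SynthConfig(
        n_gestures=n_gestures,
        repetitions_per_gesture=repetitions,
        duration_per_repetition=duration,
        baseline_noise_sd=noise_sd,
        seed=seed,
    )
    windows = [
        w for rec in generate_dataset(config) for w in segment_windows(rec, stride=stride)
    ]
    labels = np.asarray([w.gesture_label for w in windows], dtype=int)
    split = split_dataset(labels, seed=seed)
    return BenchmarkData(
        windows=windows, labels=labels, split=split, n_gestures=n_gestures
    )


def run_cnn(
    data: BenchmarkData,
    policy: TrainPolicy | None = None,
    frontend: FrontendConfig = FrontendConfig(),
    seed: int = 0,
    standardize: bool = True,
) -> float:
    """Scalogram + CNN test accuracy (%) on the benchmark split.

    When ``standardize`` is set, per-channel mean/SD are estimated on the
    training split only and applied to every tensor.
    """
    from .tf_frontend import fit_standardizer

    policy = policy if policy is not None else TrainPolicy(seed=seed)
    tensors, _ = windows_to_tensors(data.windows, frontend)
    if standardize:
        mean, sd = fit_standardizer(tensors[data.split.indices("train")])
        tensors = (tensors - np.asarray(mean)[:, None, None]) / np.where(
            np.asarray(sd)[:, None, None] > 0, np.asarray(sd)[:, None, None], 1.0
        )
    model = build_emgnet(EMGNetConfig(n_classes=data.n_gestures), seed=seed)
    train(model, data.split, tensors, data.labels, policy)
    test_idx = data.split.indices("test")
    return evaluate(model, tensors[test_idx], data.labels[test_idx]).accuracy


def run_baseline(
    data: BenchmarkData, set_name: str = "td", kind: str = "lda"
) -> float:
    """Classical feature-set + LDA/SVM test accuracy (%) on the same split."""
    features = [extract_feature_set(w, set_name) for w in data.windows]
    train_idx = data.split.indices("train")
    test_idx = data.split.indices("test")
    model = fit_baseline([features[i] for i in train_idx], kind=kind)
    preds = predict(model, [features[i] for i in test_idx])
    truth = data.labels[test_idx]
    return 100.0 * float((preds == truth).mean())
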