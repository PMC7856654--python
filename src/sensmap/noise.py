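"""Baseline (pre-stimulus) noise recordings and per-channel noise variances.

Real studies estimate the sensor noise variance s_k^2 from the pretrigger
baseline of evoked recordings; here white Gaussian baselines with realistic
orders of magnitude (~10 uV^2 for EEG, ~1e4 fT^2 for MEG) are generated
instead, and the estimator recovers the per-channel variances from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensors import SensorSet

__all__ = ["BaselineRecording", "NoiseModel", "synth_noise_baseline", "estimate_noise_variance"]


@dataclass
class BaselineRecording:
    """Channels x samples baseline segment; EEG rows in uV, MEG rows in fT."""

    eeg: np.ndarray          # (N_eeg, n_samples) uV
    meg: np.ndarray          # (N_meg, n_samples) fT
    sfreq: float = 1000.0    # Hz, metadata only
    seed: int | None = None

    def __post_init__(self) -> None:
        self.eeg = np.atleast_2d(np.asarray(self.eeg, dtype=float))
        self.meg = np.atleast_2d(np.asarray(self.meg, dtype=float))
        if not (np.isfinite(self.eeg).all() and np.isfinite(self.meg).all()):
            raise ValueError("baseline contains non-finite samples")


@dataclass
class NoiseModel:
    """Per-channel noise variances s_k^2: EEG in uV^2, MEG in fT^2."""

    eeg_variance: np.ndarray  # (N_eeg,)
    meg_variance: np.ndarray  # (N_meg,)

    def __post_init__(self) -> None:
        self.eeg_variance = np.atleast_1d(np.asarray(self.eeg_variance, dtype=float))
        self.meg_variance = np.atleast_1d(np.asarray(self.meg_variance, dtype=float))

    def validate_positive(self) -> None:
        if np.any(self.eeg_variance <= 0) or np.any(self.meg_variance <= 0):
            raise ValueError("noise variances must be strictly positive")


def synth_noise_baseline(
    sensors: SensorSet,
    eeg_variance: float = 10.0,
    meg_variance: float = 1.0e4,
    n_samples: int = 10_000,
    seed: int = 0,
    channel_jitter: float = 0.0,
) -> BaselineRecording:
    """Zero-mean white Gaussian baseline with the requested channel variances.

    ``channel_jitter`` (relative, e.g. 0.2) draws per-channel variances
    log-uniformly within +-jitter of the nominal value, emulating channel-to-
    channel noise heterogeneity.
    """
    if eeg_variance <= 0 or meg_variance <= 0:
        raise ValueError("variances must be positive")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)

    def channel_vars(nominal: float, n: int) -> np.ndarray:
        if channel_jitter == 0:
            return np.full(n, nominal)
        lo, hi = np.log(1 - channel_jitter), np.log(1 + channel_jitter)
        return nominal * np.exp(rng.uniform(lo, hi, size=n))

    ve = channel_vars(eeg_variance, sensors.n_eeg)
    vm = channel_vars(meg_variance, sensors.n_meg)
    eeg = rng.standard_normal((sensors.n_eeg, n_samples)) * np.sqrt(ve)[:, None]
    meg = rng.standard_normal((sensors.n_meg, n_samples)) * np.sqrt(vm)[:, None]
    return BaselineRecording(eeg=eeg, meg=meg, seed=seed)


def estimate_noise_variance(baseline: BaselineRecording) -> NoiseModel:
    """Unbiased per-channel sample variance of a baseline recording."""
    if baseline.eeg.shape[1] < 2 or baseline.meg.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel")
    return NoiseModel(
        eeg_variance=baseline.eeg.var(axis=1, ddof=1),
        meg_variance=baseline.meg.var(axis=1, ddof=1),
    )
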