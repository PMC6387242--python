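"""Synthetic two-class motor-imagery EEG generator.

Produces labeled multi-channel trials with the statistical structure that
motor-imagery classifiers assume: a Gaussian broadband background
(band-limited to the 0.5-100 Hz recording band) carrying mu (~6-13 Hz) and
beta (~17-30 Hz) rhythms whose amplitudes are modulated during the task
window.  Imagining a hand movement suppresses mu power (event-related
desynchronization, ERD) and boosts beta power (event-related
synchronization, ERS) over the *contralateral* motor cortex: a left-hand
trial modulates the right-hemisphere electrodes (C4, C2), a right-hand
trial the left-hemisphere electrodes (C3, C1), and the midline Cz receives
half the modulation depth.

The oscillatory components are fixed-frequency sinusoids with a uniformly
random phase per trial and channel, so ERD/ERS power ratios are analytically
exact: scaling the amplitude by sqrt(1 - erd_depth) scales the band power by
exactly (1 - erd_depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "SynthParams",
    "RawTrial",
    "TrialSet",
    "generate_trial",
    "generate_dataset",
    "band_power",
    "LABELS",
]

#: canonical class labels, index order defines the integer encoding (left=0)
LABELS = ("left", "right")

#: electrode laterality over the motor strip
_LEFT_HEMI = frozenset({"C3", "C1"})
_RIGHT_HEMI = frozenset({"C2", "C4"})
_MONTAGES = {3: ("C3", "Cz", "C4"), 5: ("C3", "C1", "Cz", "C2", "C4")}


@dataclass(frozen=True)
class SynthParams:
    """Generator settings.

    Amplitudes and the noise level are in microvolts.  The defaults put
    roughly a third of the baseline variance into the two rhythms, which is
    weak enough that single-channel amplitude samples still pass a
    Lilliefors normality test (as real resting EEG does) yet strong enough
    that ERD/ERS band-power contrasts are clearly measurable.
    """

    fs: float = 250.0
    n_channels: int = 3
    channel_names: tuple[str, ...] = ()
    trial_len_s: float = 6.0
    mu_band: tuple[float, float] = (6.0, 13.0)
    beta_band: tuple[float, float] = (17.0, 30.0)
    erd_depth: float = 0.6
    ers_gain: float = 0.5
    mu_amp: float = 1.0
    beta_amp: float = 0.7
    noise_sd: float = 1.5
    task_onset_s: float = 3.0
    task_dur_s: float = 3.0
    background_band: tuple[float, float] = (0.5, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels not in _MONTAGES:
            raise ValueError(f"n_channels must be 3 or 5, got {self.n_channels}")
        if not self.channel_names:
            object.__setattr__(self, "channel_names", _MONTAGES[self.n_channels])
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"channel_names {self.channel_names} does not match "
                f"n_channels={self.n_channels}"
            )
        if not 0.0 <= self.erd_depth < 1.0:
            raise ValueError(f"erd_depth must be in [0, 1), got {self.erd_depth}")
        if self.ers_gain < 0.0:
            raise ValueError(f"ers_gain must be >= 0, got {self.ers_gain}")
        nyq = self.fs / 2.0
        for name, (lo, hi) in (("mu_band", self.mu_band), ("beta_band", self.beta_band)):
            if not (0.0 < lo < hi < nyq):
                raise ValueError(
                    f"{name}=({lo}, {hi}) must satisfy 0 < f_lo < f_hi < fs/2={nyq}"
                )
        if self.noise_sd < 0 or self.mu_amp < 0 or self.beta_amp < 0:
            raise ValueError("amplitudes and noise_sd must be non-negative")
        if self.task_onset_s < 0 or self.task_dur_s <= 0:
            raise ValueError("task window must have positive duration within the trial")
        if self.task_onset_s + self.task_dur_s > self.trial_len_s + 1e-9:
            raise ValueError("task window exceeds trial length")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_len_s * self.fs))


@dataclass(frozen=True)
class RawTrial:
    """One labeled EEG epoch: ``data`` is channels x samples, in microvolts."""

    data: np.ndarray
    fs: float
    label: str
    channel_names: tuple[str, ...]
    onset_s: float

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channel_names)} channels"
            )
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialSet:
    """An ordered collection of consistent trials."""

    trials: list[RawTrial]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trials:
            first = self.trials[0]
            for i, t in enumerate(self.trials):
                if (
                    t.fs != first.fs
                    or t.channel_names != first.channel_names
                    or t.n_samples != first.n_samples
                ):
                    raise ValueError(f"trial {i} inconsistent with trial 0")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.trials]

    @property
    def label_codes(self) -> np.ndarray:
        return np.array([LABELS.index(t.label) for t in self.trials], dtype=np.int64)

    def data_array(self) -> np.ndarray:
        """Stack to an (n_trials, channels, samples) float array."""
        return np.stack([t.data for t in self.trials]).astype(np.float32)


def _modulation_weight(channel: str, label: str) -> float:
    """Fractional ERD/ERS depth applied to ``channel`` for class ``label``."""
    contra = _RIGHT_HEMI if label == "left" else _LEFT_HEMI
    if channel in contra:
        return 1.0
    if channel == "Cz":
        return 0.5
    return 0.0


def generate_trial(params: SynthParams, label: str, seed: int) -> RawTrial:
    """Generate one labeled trial; bit-identical for identical arguments.

    The background is white Gaussian noise band-passed to
    ``params.background_band`` with a 4th-order zero-phase Butterworth
    filter.  Mu and beta sinusoids (band-center frequencies, random phase)
    are added on every channel; during [onset, onset+dur] their amplitudes
    on modulated channels are scaled by sqrt(1 - w*erd_depth) and
    sqrt(1 + w*ers_gain) respectively, where w is 1 contralaterally, 0.5 on
    Cz and 0 ipsilaterally.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    rng = np.random.default_rng(seed)
    n = params.n_samples
    nch = params.n_channels
    t = np.arange(n) / params.fs

    noise = rng.standard_normal((nch, n)) * params.noise_sd
    lo, hi = params.background_band
    hi = min(hi, 0.99 * params.fs / 2.0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=params.fs, output="sos")
    background = sps.sosfiltfilt(sos, noise, axis=1)

    f_mu = 0.5 * (params.mu_band[0] + params.mu_band[1])
    f_beta = 0.5 * (params.beta_band[0] + params.beta_band[1])
    on = int(round(params.task_onset_s * params.fs))
    off = int(round((params.task_onset_s + params.task_dur_s) * params.fs))
    off = min(off, n)

    data = background
    for c, ch in enumerate(params.channel_names):
        phase_mu, phase_beta = rng.uniform(0.0, 2.0 * np.pi, size=2)
        w = _modulation_weight(ch, label)
        mu_env = np.full(n, params.mu_amp)
        beta_env = np.full(n, params.beta_amp)
        mu_env[on:off] *= np.sqrt(1.0 - w * params.erd_depth)
        beta_env[on:off] *= np.sqrt(1.0 + w * params.ers_gain)
        data[c] += mu_env * np.sin(2.0 * np.pi * f_mu * t + phase_mu)
        data[c] += beta_env * np.sin(2.0 * np.pi * f_beta * t + phase_beta)

    return RawTrial(
        data=data,
        fs=params.fs,
        label=label,
        channel_names=tuple(params.channel_names),
        onset_s=params.task_onset_s,
    )


def generate_dataset(params: SynthParams, n_per_class: int, seed: int | None = None) -> TrialSet:
    """Generate a balanced, class-interleaved set of 2*n_per_class trials.

    Trial ``i`` uses seed ``master_seed + i`` so any subset is reproducible
    independently of the rest.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    master = params.seed if seed is None else seed
    trials = []
    for i in range(2 * n_per_class):
        label = LABELS[i % 2]
        trials.append(generate_trial(params, label, seed=master + i))
    meta = {"n_per_class": n_per_class, "seed": master, "params": params}
    return TrialSet(trials=trials, meta=meta)


def band_power(
    trial: RawTrial,
    channel: str,
    band: Sequence[float],
    window: Sequence[float],
) -> float:
    """Periodogram power of one channel segment integrated over ``band``.

    Used as the independent oracle for ERD/ERS checks: for a sinusoid of
    amplitude A inside the band it returns approximately A^2/2; for white
    noise of standard deviation s it returns approximately
    s^2 * bandwidth / (fs/2).
    """
    if channel not in trial.channel_names:
        raise ValueError(
            f"unknown channel {channel!r}; trial has {trial.channel_names}"
        )
    lo, hi = band
    if not (0.0 <= lo < hi <= trial.fs / 2.0):
        raise ValueError(f"band ({lo}, {hi}) outside [0, Nyquist]")
    t0, t1 = window
    i0, i1 = int(round(t0 * trial.fs)), int(round(t1 * trial.fs))
    if not (0 <= i0 < i1 <= trial.n_samples):
        raise ValueError(f"window ({t0}, {t1}) s outside trial bounds")
    seg = trial.data[trial.channel_names.index(channel), i0:i1]
    freqs, pxx = sps.periodogram(seg, fs=trial.fs)
    mask = (freqs >= lo) & (freqs <= hi)
    df = freqs[1] - freqs[0]
    return float(np.sum(pxx[mask]) * df)
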