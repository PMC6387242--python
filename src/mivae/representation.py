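"""Time-frequency-channel input images for motor-imagery EEG.

A 2-s epoch (500 samples at 250 Hz) is turned into one image per trial:

* STFT with a 64-sample window hopping by 14 samples gives 32 frames over
  the first 498 samples (the trailing 2 samples are discarded) and, with a
  512-point zero-padded FFT, 257 one-sided frequency rows.
* The mu block (6-13 Hz -> 16 rows) and beta block (17-30 Hz -> 23 rows,
  cubically resized to 15 rows) are cropped from each channel's spectrogram
  and stacked vertically: 16 + 15 = 31 rows per channel.
* Channels are stacked in anatomical order (C3 [, C1], Cz [, C2], C4, top
  to bottom), giving a 93 x 32 image for 3 channels or 155 x 32 for 5.

Row 0 is the top of the image: the lowest mu frequency of the first
channel.  All sample indexing is 0-based with half-open epoch windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import get_window

from .synth import LABELS, RawTrial, TrialSet

__all__ = [
    "StftParams",
    "BandSpec",
    "Spectrogram",
    "InputImage",
    "ImageSet",
    "RepresentationConfig",
    "extract_epoch",
    "stft_spectrogram",
    "extract_band_image",
    "resize_rows",
    "assemble_input_image",
    "build_inputs",
    "default_bands",
]

_MONTAGES = {3: ("C3", "Cz", "C4"), 5: ("C3", "C1", "Cz", "C2", "C4")}


@dataclass(frozen=True)
class StftParams:
    """Spectrogram settings.

    ``n_frames`` caps the number of STFT frames; with the 64/14 defaults on
    a 500-sample epoch the cap is exactly reached (32 frames).  With the
    shorter 32/7 window of 5-channel recordings the raw frame count (67) is
    truncated to the same 32 so the image width the network expects is
    preserved.  ``mode`` selects linear magnitude (default), power or
    log-magnitude pixels.
    """

    window_len: int = 64
    hop: int = 14
    nfft: int = 512
    window_fn: str = "hamming"
    fs: float = 250.0
    n_frames: int | None = 32
    mode: str = "magnitude"

    def __post_init__(self) -> None:
        if self.hop < 1:
            raise ValueError(f"hop must be >= 1, got {self.hop}")
        if self.window_len > self.nfft:
            raise ValueError(
                f"window_len={self.window_len} must not exceed nfft={self.nfft}"
            )
        if self.mode not in ("magnitude", "power", "log"):
            raise ValueError(f"unknown spectrogram mode {self.mode!r}")

    @property
    def n_freq_bins(self) -> int:
        return self.nfft // 2 + 1


@dataclass(frozen=True)
class BandSpec:
    """A frequency band to crop from the spectrogram.

    ``raw_rows`` is the bin count the selection rule must produce;
    ``final_rows`` the row count after cubic resizing (mu is kept as-is,
    beta is shrunk so that mu.final_rows + beta.final_rows = 31).
    """

    name: str
    f_lo: float
    f_hi: float
    raw_rows: int
    final_rows: int

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: f_lo must be < f_hi")
        if self.final_rows > self.raw_rows:
            raise ValueError(f"band {self.name}: final_rows must be <= raw_rows")


def default_bands() -> tuple[BandSpec, BandSpec]:
    """The mu (6-13 Hz, 16 rows) and beta (17-30 Hz, 23->15 rows) bands."""
    return (
        BandSpec("mu", 6.0, 13.0, raw_rows=16, final_rows=16),
        BandSpec("beta", 17.0, 30.0, raw_rows=23, final_rows=15),
    )


@dataclass(frozen=True)
class Spectrogram:
    """One-sided STFT magnitudes: ``values`` is freq_bins x frames."""

    values: np.ndarray
    bin_freqs: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.bin_freqs), len(self.frame_times)):
            raise ValueError("values shape inconsistent with axes")


@dataclass(frozen=True)
class InputImage:
    """The stacked band-spectrogram image for one trial."""

    pixels: np.ndarray
    channel_order: tuple[str, ...]
    band_layout: dict  # (channel, band-name) -> (row_start, row_stop)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageSet:
    """Images plus integer labels (left=0, right=1), trial order preserved."""

    images: np.ndarray  # n x Nh x Nt, float32
    labels: np.ndarray  # n, int64
    channel_order: tuple[str, ...]
    band_layout: dict

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx: np.ndarray) -> "ImageSet":
        return ImageSet(
            images=self.images[idx],
            labels=self.labels[idx],
            channel_order=self.channel_order,
            band_layout=self.band_layout,
        )


@dataclass(frozen=True)
class RepresentationConfig:
    """Epoching + spectrogram + band settings for ``build_inputs``.

    ``epoch_start_s`` is measured from the task cue (trial ``onset_s``); the
    3-channel protocol uses 0.5-2.5 s post-cue, the 5-channel one 1-3 s.
    """

    stft: StftParams = field(default_factory=StftParams)
    bands: tuple[BandSpec, ...] = field(default_factory=default_bands)
    epoch_start_s: float = 0.5
    epoch_len_s: float = 2.0

    @property
    def rows_per_channel(self) -> int:
        return sum(b.final_rows for b in self.bands)

    @property
    def n_frames(self) -> int:
        return self.stft.n_frames if self.stft.n_frames is not None else 0

    def image_shape(self, n_channels: int) -> tuple[int, int]:
        return (self.rows_per_channel * n_channels, self.n_frames)


def extract_epoch(trial: RawTrial, start_s: float, len_s: float) -> np.ndarray:
    """Copy the half-open window [start, start+len) of all channels.

    ``start_s`` is relative to the trial start; at fs=250 and len_s=2 the
    result has 500 samples per channel.
    """
    fs = trial.fs
    i0 = int(round(start_s * fs))
    n = len_s * fs
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"len_s * fs = {n} is not integral")
    i1 = i0 + int(round(n))
    if i0 < 0 or i1 > trial.n_samples:
        raise ValueError(
            f"epoch [{start_s}, {start_s + len_s}) s exceeds trial bounds "
            f"(0, {trial.n_samples / fs}) s"
        )
    return trial.data[:, i0:i1].copy()


def stft_spectrogram(x: np.ndarray, p: StftParams) -> Spectrogram:
    """Magnitude spectrogram of a 1-D signal under the fixed frame rule.

    Frames start every ``hop`` samples; the count is
    floor((len - window)/hop) + 1, truncated to ``p.n_frames`` when larger.
    Samples beyond the last full window are discarded.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("stft_spectrogram expects a 1-D signal")
    if len(x) < p.window_len:
        raise ValueError(
            f"signal length {len(x)} shorter than window_len {p.window_len}"
        )
    n_frames = (len(x) - p.window_len) // p.hop + 1
    if p.n_frames is not None:
        n_frames = min(n_frames, p.n_frames)
    frames = np.lib.stride_tricks.sliding_window_view(x, p.window_len)[:: p.hop][
        :n_frames
    ]
    taper = get_window(p.window_fn, p.window_len, fftbins=True)
    spec = np.abs(np.fft.rfft(frames * taper, n=p.nfft, axis=1)).T
    if p.mode == "power":
        spec = spec**2
    elif p.mode == "log":
        spec = np.log1p(spec)
    bin_freqs = np.fft.rfftfreq(p.nfft, d=1.0 / p.fs)
    centers = (np.arange(n_frames) * p.hop + p.window_len / 2.0) / p.fs
    return Spectrogram(values=spec, bin_freqs=bin_freqs, frame_times=centers)


def _band_row_range(band: BandSpec, nfft: int, fs: float) -> tuple[int, int]:
    """Inclusive bin-index range for ``band`` after symmetric trimming.

    The base rule keeps bins with index in
    [floor(f_lo*nfft/fs), ceil(f_hi*nfft/fs)].  When that yields more than
    ``raw_rows`` bins the excess is trimmed half from each edge (the odd
    leftover from the top), pinning the cropped block to its nominal size.
    """
    lo = int(np.floor(band.f_lo * nfft / fs))
    hi = int(np.ceil(band.f_hi * nfft / fs))
    n_bins = nfft // 2 + 1
    if hi >= n_bins:
        raise ValueError(
            f"band {band.name} ({band.f_lo}-{band.f_hi} Hz) exceeds Nyquist "
            f"for nfft={nfft}, fs={fs}"
        )
    count = hi - lo + 1
    excess = count - band.raw_rows
    if excess < 0:
        raise ValueError(
            f"band {band.name}: selection rule yields {count} rows, fewer "
            f"than the required raw_rows={band.raw_rows}"
        )
    trim_bottom = excess // 2
    trim_top = excess - trim_bottom
    return lo + trim_bottom, hi - trim_top


def extract_band_image(
    spec: Spectrogram, band: BandSpec, *, nfft: int | None = None, fs: float | None = None
) -> np.ndarray:
    """Crop ``band.raw_rows`` contiguous frequency rows from a spectrogram."""
    n_bins = spec.values.shape[0]
    if nfft is None:
        nfft = 2 * (n_bins - 1)
    if fs is None:
        fs = float(2.0 * spec.bin_freqs[-1])
    lo, hi = _band_row_range(band, nfft, fs)
    return spec.values[lo : hi + 1]


def resize_rows(img: np.ndarray, new_rows: int) -> np.ndarray:
    """Resize along the frequency axis by column-wise cubic interpolation."""
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] < 1:
        raise ValueError("resize_rows expects a non-empty 2-D image")
    if new_rows < 1:
        raise ValueError(f"new_rows must be >= 1, got {new_rows}")
    rows = img.shape[0]
    if new_rows == rows:
        return img.copy()
    kind = "cubic" if rows >= 4 else "linear"
    f = interp1d(np.arange(rows), img, kind=kind, axis=0)
    return f(np.linspace(0.0, rows - 1.0, new_rows))


def assemble_input_image(
    epoch: np.ndarray,
    p: StftParams,
    bands: Sequence[BandSpec] = (),
    channel_names: Sequence[str] | None = None,
) -> InputImage:
    """Build the stacked Nh x Nt image from a channels x samples epoch.

    Per channel the cropped mu block and the resized beta block are stacked
    (mu on top), then channels are stacked top-to-bottom in anatomical
    order, which must match the configured 3- or 5-channel montage.
    """
    epoch = np.asarray(epoch)
    if epoch.ndim != 2:
        raise ValueError("epoch must be channels x samples")
    nc = epoch.shape[0]
    if nc not in _MONTAGES:
        raise ValueError(f"channel count must be 3 or 5, got {nc}")
    expected = _MONTAGES[nc]
    if channel_names is None:
        channel_names = expected
    if tuple(channel_names) != expected:
        raise ValueError(
            f"channel order {tuple(channel_names)} does not match the "
            f"required montage {expected}"
        )
    if not bands:
        bands = default_bands()

    blocks = []
    layout: dict = {}
    row = 0
    for c, ch in enumerate(channel_names):
        spec = stft_spectrogram(epoch[c], p)
        for band in bands:
            block = extract_band_image(spec, band, nfft=p.nfft, fs=p.fs)
            if band.final_rows != band.raw_rows:
                block = resize_rows(block, band.final_rows)
            blocks.append(block)
            layout[(ch, band.name)] = (row, row + band.final_rows)
            row += band.final_rows
    pixels = np.vstack(blocks)
    return InputImage(
        pixels=pixels, channel_order=tuple(channel_names), band_layout=layout
    )


def build_inputs(ts: TrialSet, cfg: RepresentationConfig) -> ImageSet:
    """One InputImage per trial, in trial order."""
    images = []
    layout: dict = {}
    order: tuple[str, ...] = ()
    for i, trial in enumerate(ts.trials):
        try:
            start = trial.onset_s + cfg.epoch_start_s
            epoch = extract_epoch(trial, start, cfg.epoch_len_s)
            img = assemble_input_image(
                epoch, cfg.stft, cfg.bands, trial.channel_names
            )
        except ValueError as exc:
            raise ValueError(f"trial {i}: {exc}") from exc
        images.append(img.pixels)
        layout = img.band_layout
        order = img.channel_order
    n = len(images)
    if n == 0:
        shape = (0, 0, 0)
        arr = np.zeros(shape, dtype=np.float32)
    else:
        arr = np.stack(images).astype(np.float32)
    labels = np.array([LABELS.index(t.label) for t in ts.trials], dtype=np.int64)
    return ImageSet(images=arr, labels=labels, channel_order=order, band_layout=layout)
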