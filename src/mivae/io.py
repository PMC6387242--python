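"""Array-store persistence for trials and images, plus optional raw readers.

Trials and image sets persist to HDF5: datasets ``data``
(n x channels x samples, float32) / ``images`` (n x Nh x Nt, float32) and
``labels`` (0=left, 1=right), with sampling rate, channel names and
epoching metadata as attributes.  GDF/EDF+ reading for competition-style
recordings is an optional extra that requires ``mne``; nothing in the core
package or test suite depends on it.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .representation import ImageSet
from .synth import LABELS, RawTrial, TrialSet

__all__ = [
    "save_trials",
    "load_trials",
    "save_images",
    "load_images",
    "read_raw_eeg",
]


def save_trials(ts: TrialSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data_array())
        f.create_dataset("labels", data=ts.label_codes)
        first = ts.trials[0]
        f.attrs["fs"] = first.fs
        f.attrs["channel_names"] = json.dumps(list(first.channel_names))
        f.attrs["onset_s"] = first.onset_s


def load_trials(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        labels = f["labels"][()]
        fs = float(f.attrs["fs"])
        names = tuple(json.loads(f.attrs["channel_names"]))
        onset = float(f.attrs["onset_s"])
    trials = [
        RawTrial(
            data=np.asarray(data[i], dtype=np.float64),
            fs=fs,
            label=LABELS[int(labels[i])],
            channel_names=names,
            onset_s=onset,
        )
        for i in range(len(data))
    ]
    return TrialSet(trials=trials, meta={"source": str(path)})


def save_images(imgs: ImageSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=imgs.images.astype(np.float32))
        f.create_dataset("labels", data=imgs.labels)
        f.attrs["channel_order"] = json.dumps(list(imgs.channel_order))
        f.attrs["band_layout"] = json.dumps(
            [[list(k), list(v)] for k, v in imgs.band_layout.items()]
        )


def load_images(path) -> ImageSet:
    with h5py.File(path, "r") as f:
        images = f["images"][()]
        labels = f["labels"][()]
        order = tuple(json.loads(f.attrs["channel_order"]))
        layout = {
            tuple(k): tuple(v) for k, v in json.loads(f.attrs["band_layout"])
        }
    return ImageSet(images=images, labels=labels, channel_order=order, band_layout=layout)


def read_raw_eeg(
    path,
    format: str = "array-store",
    *,
    montage: tuple[str, ...] = ("C3", "Cz", "C4"),
    trial_len_s: float = 4.0,
    pre_cue_s: float = 0.0,
) -> TrialSet:
    """Load labeled trials from an array-store file or a GDF/EDF recording.

    For ``gdf``/``edf`` the file's cue annotations (codes 769/770 for
    left/right hand) segment the recording into trials starting
    ``pre_cue_s`` before each cue; the channel subset is restricted to
    ``montage``.  Requires the optional ``mne`` dependency.
    """
    if format == "array-store":
        return load_trials(path)
    if format not in ("gdf", "edf"):
        raise ValueError(f"unknown format {format!r}")
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError(
            "reading GDF/EDF files requires the optional 'mne' dependency"
        ) from exc
    reader = mne.io.read_raw_gdf if format == "gdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    missing = [ch for ch in montage if not any(ch in name for name in raw.ch_names)]
    if missing:
        raise ValueError(
            f"channels {missing} not found; file has {raw.ch_names}"
        )
    picks = [next(n for n in raw.ch_names if ch in n) for ch in montage]
    raw.pick(picks)
    fs = float(raw.info["sfreq"])
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    cue_codes = {}
    for name, code in event_id.items():
        if "769" in name:
            cue_codes[code] = "left"
        elif "770" in name:
            cue_codes[code] = "right"
    if not cue_codes:
        raise ValueError(
            f"no left/right cue annotations (769/770) found; "
            f"annotations present: {sorted(event_id)}"
        )
    data = raw.get_data() * 1e6  # volts -> microvolts
    n_samp = int(round(trial_len_s * fs))
    pre = int(round(pre_cue_s * fs))
    trials = []
    for sample, _, code in events:
        if code not in cue_codes:
            continue
        start = sample - pre
        if start < 0 or start + n_samp > data.shape[1]:
            continue
        trials.append(
            RawTrial(
                data=data[:, start : start + n_samp].copy(),
                fs=fs,
                label=cue_codes[code],
                channel_names=tuple(montage),
                onset_s=pre_cue_s,
            )
        )
    if not trials:
        raise ValueError("no complete cue-aligned trials could be extracted")
    return TrialSet(trials=trials, meta={"source": str(path), "format": format})
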