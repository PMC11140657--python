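"""Data model and I/O for sleep-EEG recordings, hypnograms, and cue logs.

The in-memory containers are deliberately thin: a recording is a channels x
samples float array in microvolts plus a sampling rate and channel labels; a
hypnogram is a sequence of 30-s stage labels; a cue log is a table of cue
onsets. Standard interchange formats (EDF, BrainVision) are read through MNE;
a single-file HDF5 "fixture" container is provided so test sessions round-trip
without touching real-EEG formats.

Conventions: sample indexing is 0-based and intervals are half-open
``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

STAGES = ("W", "N1", "N2", "N3", "REM")
NREM_STAGES = frozenset({"N2", "N3"})
CUE_CATEGORIES = ("negative", "neutral", "control")
EPOCH_LEN_S = 30.0


@dataclass
class Recording:
    """Multichannel EEG time series in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names (10-20 montage names, mastoids M1/M2, EOG, EMG).
    reference : str
        Label of the current reference scheme (free-form, e.g. "common",
        "mastoid-average").
    annotations : list of (onset_s, duration_s, label) tuples
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    reference: str = "common"
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel label")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(),
            self.fs,
            list(self.channel_labels),
            self.reference,
            list(self.annotations),
        )


@dataclass
class Hypnogram:
    """Sleep stages scored in fixed 30-s epochs."""

    stages: list[str]
    epoch_length_s: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage label(s): {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length_s

    def stage_at(self, t_s: float) -> str | None:
        """Stage at time ``t_s``, or None if beyond the scored span."""
        idx = int(t_s // self.epoch_length_s)
        if 0 <= idx < self.n_epochs:
            return self.stages[idx]
        return None

    def minutes_in(self, stages: Sequence[str]) -> float:
        wanted = set(stages)
        return sum(s in wanted for s in self.stages) * self.epoch_length_s / 60.0


@dataclass
class EventLog:
    """Cue onsets with category and delivery context.

    Each event is (onset_sample, category, stage_at_onset, block_index).
    Onsets must be strictly increasing.
    """

    events: list[tuple[int, str, str, int]]

    def __post_init__(self) -> None:
        onsets = [e[0] for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        for _, cat, stage, _ in self.events:
            if cat not in CUE_CATEGORIES:
                raise ValueError(f"unknown cue category {cat!r}")
            if stage not in STAGES:
                raise ValueError(f"unknown stage label {stage!r}")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e[0] for e in self.events], dtype=np.int64)

    @property
    def categories(self) -> list[str]:
        return [e[1] for e in self.events]

    def select(self, categories: Sequence[str]) -> "EventLog":
        wanted = set(categories)
        return EventLog([e for e in self.events if e[1] in wanted])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.events, columns=["onset_sample", "category", "stage", "block"]
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_fixture(path: str | Path, rec: Recording) -> None:
    """Write a recording to the single-file HDF5 fixture container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["fs"] = rec.fs
        f.attrs["reference"] = rec.reference
        f.create_dataset(
            "channel_labels",
            data=np.array(rec.channel_labels, dtype=h5py.string_dtype()),
        )
        if rec.annotations:
            f.create_dataset(
                "annot_onsets", data=[a[0] for a in rec.annotations]
            )
            f.create_dataset(
                "annot_durations", data=[a[1] for a in rec.annotations]
            )
            f.create_dataset(
                "annot_labels",
                data=np.array(
                    [a[2] for a in rec.annotations], dtype=h5py.string_dtype()
                ),
            )


def _read_fixture(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        labels = [s.decode() if isinstance(s, bytes) else s for s in f["channel_labels"][()]]
        reference = str(f.attrs.get("reference", "common"))
        annotations = []
        if "annot_onsets" in f:
            lab = [
                s.decode() if isinstance(s, bytes) else s
                for s in f["annot_labels"][()]
            ]
            annotations = list(
                zip(
                    (float(x) for x in f["annot_onsets"][()]),
                    (float(x) for x in f["annot_durations"][()]),
                    lab,
                )
            )
    return Recording(data, fs, labels, reference, annotations)


def _read_mne(path: Path, format: str) -> Recording:
    import mne

    if format == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        for companion in (path.with_suffix(".eeg"), path.with_suffix(".vmrk")):
            if not companion.exists():
                raise FileNotFoundError(
                    f"missing companion file: {companion.name}"
                )
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel label in file")
    # MNE loads in SI units (volts); the package works in microvolts.
    data = raw.get_data() * 1e6
    annotations = [
        (float(a["onset"]), float(a["duration"]), str(a["description"]))
        for a in raw.annotations
    ]
    return Recording(data, float(raw.info["sfreq"]), labels, "as-recorded", annotations)


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from EDF, BrainVision (.vhdr), or the HDF5 fixture.

    ``format`` is inferred from the extension when omitted.
    """
    path = Path(path)
    if format is None:
        format = {".edf": "edf", ".vhdr": "brainvision"}.get(
            path.suffix.lower(), "fixture"
        )
    if format not in {"edf", "brainvision", "fixture"}:
        raise ValueError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fixture":
        return _read_fixture(path)
    return _read_mne(path, format)


def write_hypnogram(path: str | Path, hyp: Hypnogram) -> None:
    pd.DataFrame(
        {"epoch_index": range(hyp.n_epochs), "stage": hyp.stages}
    ).to_csv(path, sep="\t", index=False)


def read_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path, sep="\t", dtype={"stage": str})
    df = df.sort_values("epoch_index")
    return Hypnogram(list(df["stage"]))


def write_events(path: str | Path, log: EventLog) -> None:
    log.to_frame().to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> EventLog:
    df = pd.read_csv(path, sep="\t", dtype={"category": str, "stage": str})
    return EventLog(
        [
            (int(r.onset_sample), r.category, r.stage, int(r.block))
            for r in df.itertuples()
        ]
    )


def stage_mask(
    hyp: Hypnogram, stages: Sequence[str], fs: float, n_samples: int | None = None
) -> np.ndarray:
    """Boolean per-sample mask that is True inside epochs of the given stages.

    The mask covers ``n_samples`` samples (default: the scored span). Samples
    beyond the scored hypnogram are unscored and always False.
    """
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stage label(s): {sorted(bad)}")
    scored = int(round(hyp.n_epochs * hyp.epoch_length_s * fs))
    if n_samples is None:
        n_samples = scored
    mask = np.zeros(n_samples, dtype=bool)
    epoch_samp = int(round(hyp.epoch_length_s * fs))
    wanted = set(stages)
    for i, s in enumerate(hyp.stages):
        if s in wanted:
            lo = i * epoch_samp
            hi = min((i + 1) * epoch_samp, n_samples)
            if lo < n_samples:
                mask[lo:hi] = True
    return mask
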