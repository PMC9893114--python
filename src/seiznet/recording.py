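"""Multichannel recording container and file readers/writers.

Conventions used throughout the package: sample indices are 0-based and all
windows are half-open ``[start, end)`` in samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, SeizNetError

PHASE_LABELS = ("interictal", "preictal", "ictal", "postictal")

#: accepted aliases for phase labels in annotation files
_LABEL_ALIASES = {"seizure": "ictal", "pre-ictal": "preictal", "post-ictal": "postictal"}


def canonical_phase_label(label: str) -> str:
    """Map an annotation label onto the fixed phase vocabulary."""
    lab = label.strip().lower()
    lab = _LABEL_ALIASES.get(lab, lab)
    if lab not in PHASE_LABELS:
        raise ConfigurationError(f"unknown phase label: {label!r}")
    return lab


@dataclass(frozen=True)
class PhaseWindow:
    """One annotated seizure-phase window, half-open in samples."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", canonical_phase_label(self.label))
        if not (0 <= self.start < self.end):
            raise ConfigurationError(
                f"invalid phase window [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Recording:
    """A channels x samples multichannel recording.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``; must be finite.
    fs
        Sampling rate in samples per second.
    channel_names
        One label per channel; defaults to ``ch00, ch01, ...``.
    annotations
        Optional phase windows covering (parts of) the recording.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    annotations: list[PhaseWindow] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if not np.isfinite(self.data).all():
            raise SeizNetError("recording contains non-finite values")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ConfigurationError("channel_names length != number of channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset(self, channels: Sequence[int] | Sequence[str]) -> "Recording":
        """Return a new Recording restricted to the given channels (by index or name)."""
        idx = []
        for c in channels:
            if isinstance(c, str):
                if c not in self.channel_names:
                    raise ConfigurationError(f"channel {c!r} not in recording")
                idx.append(self.channel_names.index(c))
            else:
                if not (0 <= int(c) < self.n_channels):
                    raise ConfigurationError(f"channel index {c} out of range")
                idx.append(int(c))
        return Recording(
            data=self.data[idx].copy(),
            fs=self.fs,
            channel_names=[self.channel_names[i] for i in idx],
            annotations=list(self.annotations) if self.annotations else None,
        )


# ---------------------------------------------------------------------------
# Delimited-text round trip
# ---------------------------------------------------------------------------

def write_recording_text(recording: Recording, path: str | Path) -> Path:
    """Write the data matrix as delimited text (one row per channel).

    A JSON sidecar ``<path>.json`` stores the sampling rate and channel names.
    """
    path = Path(path)
    np.savetxt(path, recording.data, delimiter="\t")
    sidecar = {"fs": recording.fs, "channel_names": recording.channel_names}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
    return path


def read_recording_text(path: str | Path, fs: float | None = None) -> Recording:
    """Read a delimited-text matrix (one channel per row).

    The sampling rate comes from the JSON sidecar written by
    :func:`write_recording_text`, or from ``fs`` when no sidecar exists.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise SeizNetError(f"empty recording file: {path}")
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    channel_names: list[str] = []
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        fs = sidecar.get("fs", fs)
        channel_names = list(sidecar.get("channel_names", []))
    if fs is None:
        raise ConfigurationError(
            f"no sampling rate: pass fs= or provide sidecar {sidecar_path.name}"
        )
    return Recording(data=data, fs=float(fs), channel_names=channel_names)


def write_annotations(windows: Sequence[PhaseWindow], path: str | Path) -> Path:
    """Write phase windows as ``label,start_sample,end_sample`` CSV."""
    path = Path(path)
    lines = ["label,start_sample,end_sample"]
    lines += [f"{w.label},{w.start},{w.end}" for w in windows]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_annotations(path: str | Path) -> list[PhaseWindow]:
    """Read phase windows written by :func:`write_annotations`."""
    path = Path(path)
    windows = []
    for ln, line in enumerate(path.read_text().strip().splitlines()):
        if ln == 0 and line.lower().startswith("label"):
            continue
        if not line.strip():
            continue
        label, start, end = line.split(",")
        windows.append(PhaseWindow(label, int(start), int(end)))
    return windows


def read_recording_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (requires the optional mne dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise SeizNetError("EDF reading requires mne (pip install seiznet[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )


def read_recording(path: str | Path, format: str = "auto", fs: float | None = None) -> Recording:
    """Read a recording from EDF or delimited text.

    ``format`` is one of ``edf``, ``delimited`` or ``auto`` (by extension).
    """
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return read_recording_edf(path)
    if format == "delimited":
        return read_recording_text(path, fs=fs)
    raise ConfigurationError(f"unknown recording format: {format!r}")
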