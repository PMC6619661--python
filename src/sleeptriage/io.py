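"""PSG recording, hypnogram, and review-list I/O.

Recordings travel as EDF (16-bit European Data Format, the lingua franca of
polysomnography). Reading goes through :func:`mne.io.read_raw_edf`; writing
uses a small built-in EDF writer (1-second data records, per-channel physical
scaling) because this package must be able to emit its own synthetic fixtures.

Hypnograms are plain text — one stage token (``W/N1/N2/N3/R``) per line — or
CSV with an ``epoch_index,stage`` header. Numeric aliases ``0,1,2,3,5`` are
accepted on read (5 = REM, the common PSG convention; 4 is unused under AASM).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ChannelResolutionError,
    FormatError,
    HypnogramParseError,
    InsufficientDataError,
)

logger = logging.getLogger(__name__)

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

#: numeric aliases accepted when reading hypnograms (AASM leaves 4 unused)
NUMERIC_ALIASES: dict[str, str] = {"0": "W", "1": "N1", "2": "N2", "3": "N3", "5": "R"}

ROLES = ("EEG", "EOG", "EMG")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Channel:
    """One PSG channel: label, functional role, sample rate, samples in µV."""

    label: str
    role: str
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"channel {self.label!r}: fs must be > 0, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError(f"channel {self.label!r}: no samples")
        if self.role not in ROLES:
            raise ValueError(f"channel {self.label!r}: unknown role {self.role!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class Recording:
    """Multi-channel PSG recording with per-channel sample rates."""

    channels: list[Channel]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("recording has no channels")
        durations = [c.duration for c in self.channels]
        ref = durations[0]
        for c, d in zip(self.channels, durations):
            if abs(d - ref) > 1.0 / c.fs + 1e-9:
                raise ValueError(
                    f"channel {c.label!r} duration {d:.3f}s differs from "
                    f"{self.channels[0].label!r} ({ref:.3f}s)"
                )

    @property
    def duration(self) -> float:
        return min(c.duration for c in self.channels)

    def by_role(self, role: str) -> Channel:
        """Primary channel for a role (first matching; C3-M2 preferred for EEG)."""
        matches = [c for c in self.channels if c.role == role]
        if not matches:
            raise ChannelResolutionError(
                f"no {role} channel; available labels: "
                f"{[c.label for c in self.channels]}"
            )
        if role == "EEG":
            for c in matches:
                if "C3" in c.label.upper():
                    return c
        return matches[0]


@dataclass
class EpochGrid:
    """Partition of a recording into contiguous fixed-length scoring epochs."""

    recording: Recording
    epoch_seconds: float = 30.0
    n_epochs: int = field(init=False)

    def __post_init__(self) -> None:
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be > 0")
        if self.recording.duration < self.epoch_seconds:
            raise InsufficientDataError(
                f"recording of {self.recording.duration:.1f}s is shorter than "
                f"one {self.epoch_seconds:.0f}s epoch"
            )
        self.n_epochs = int(self.recording.duration // self.epoch_seconds)

    def slice(self, epoch_index: int, channel: Channel) -> np.ndarray:
        """Samples of ``channel`` within epoch ``epoch_index`` (trailing rest dropped)."""
        if not 0 <= epoch_index < self.n_epochs:
            raise IndexError(f"epoch {epoch_index} out of range [0, {self.n_epochs})")
        spe = int(round(self.epoch_seconds * channel.fs))
        return channel.samples[epoch_index * spe:(epoch_index + 1) * spe]

    def epoch_channels(self, epoch_index: int) -> dict[str, np.ndarray]:
        """Primary EEG/EOG/EMG slices for one epoch, keyed by role."""
        return {
            role: self.slice(epoch_index, self.recording.by_role(role))
            for role in ROLES
        }


@dataclass
class Hypnogram:
    """Sequence of AASM stage labels, one per scoring epoch."""

    stages: list[str]
    epoch_seconds: float = 30.0

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"invalid stage labels: {sorted(set(bad))}")
        self.stages = list(self.stages)

    def __len__(self) -> int:
        return len(self.stages)

    def __getitem__(self, i):
        return self.stages[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, Hypnogram) and self.stages == other.stages

    def __iter__(self):
        return iter(self.stages)


# ---------------------------------------------------------------------------
# EDF read / write
# ---------------------------------------------------------------------------

_ROLE_HINTS = {
    "EEG": ("C3", "C4", "F3", "F4", "O1", "O2", "EEG"),
    "EOG": ("EOG", "LOC", "ROC", "E1", "E2"),
    "EMG": ("EMG", "CHIN", "MENT"),
}


def _infer_role(label: str) -> str | None:
    upper = label.upper()
    for role in ("EOG", "EMG", "EEG"):  # EOG/EMG hints first: "EEG" is greedy
        if any(h in upper for h in _ROLE_HINTS[role]):
            return role
    return None


def read_edf(path: str | Path, channel_map: Mapping[str, str] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` in physical units (µV).

    Parameters
    ----------
    path
        EDF file path.
    channel_map
        Optional ``{channel label: role}`` mapping overriding the built-in
        label heuristics (C3/C4 → EEG, EOG/LOC/ROC → EOG, EMG/chin → EMG).
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted exception types on bad files
        raise FormatError(f"cannot read {path} as EDF: {exc}") from exc

    channels: list[Channel] = []
    for name in raw.ch_names:
        role = (channel_map or {}).get(name) or _infer_role(name)
        if role is None:
            logger.debug("skipping channel %r: no role", name)
            continue
        data = raw.get_data(picks=[name])[0] * 1e6  # mne stores SI volts
        channels.append(Channel(label=name, role=role, fs=float(raw.info["sfreq"]),
                                samples=data))

    rec = Recording(channels=channels) if channels else None
    if rec is None or not any(c.role == "EEG" for c in channels):
        raise ChannelResolutionError(
            f"no EEG channel resolvable in {path.name}; "
            f"available labels: {raw.ch_names}"
        )
    return rec


def _edf_field(values: Iterable, width: int) -> bytes:
    out = b""
    for v in values:
        s = str(v).encode("ascii")[:width]
        out += s.ljust(width)
    return out


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` to EDF (16-bit, 1-second data records).

    Each channel gets a symmetric physical range spanning its extrema, so the
    quantization step is ``range / 65535``. Duration is truncated to whole
    seconds (EDF records are fixed-length).
    """
    path = Path(path)
    chans = recording.channels
    n_sig = len(chans)
    n_rec = int(min(c.duration for c in chans))
    if n_rec < 1:
        raise InsufficientDataError("recording shorter than one EDF record (1 s)")

    pmaxs = []
    for c in chans:
        m = float(np.max(np.abs(c.samples)))
        pmaxs.append(m * 1.0001 if m > 0 else 1.0)

    hdr = b"0".ljust(8)
    hdr += b"X".ljust(80)                      # patient id
    hdr += b"Startdate X".ljust(80)            # recording id
    hdr += b"01.01.20" + b"00.00.00"
    hdr += str(256 * (n_sig + 1)).encode().ljust(8)
    hdr += b"".ljust(44)
    hdr += str(n_rec).encode().ljust(8)
    hdr += b"1".ljust(8)                       # record duration: 1 s
    hdr += str(n_sig).encode().ljust(4)
    hdr += _edf_field((c.label for c in chans), 16)
    hdr += _edf_field([""] * n_sig, 80)        # transducer
    hdr += _edf_field(["uV"] * n_sig, 8)
    hdr += _edf_field((f"{-m:.6g}" for m in pmaxs), 8)
    hdr += _edf_field((f"{m:.6g}" for m in pmaxs), 8)
    hdr += _edf_field([-32768] * n_sig, 8)
    hdr += _edf_field([32767] * n_sig, 8)
    hdr += _edf_field([""] * n_sig, 80)        # prefiltering
    hdr += _edf_field((int(round(c.fs)) for c in chans), 8)
    hdr += _edf_field([""] * n_sig, 32)

    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            for c, pm in zip(chans, pmaxs):
                spr = int(round(c.fs))
                chunk = c.samples[r * spr:(r + 1) * spr]
                dig = np.round((chunk + pm) / (2 * pm) * 65535.0 - 32768.0)
                f.write(np.clip(dig, -32768, 32767).astype("<i2").tobytes())


# ---------------------------------------------------------------------------
# epoch segmentation
# ---------------------------------------------------------------------------

def segment_epochs(recording: Recording, epoch_seconds: float = 30.0) -> EpochGrid:
    """Partition a recording into contiguous non-overlapping scoring epochs.

    A trailing remainder shorter than ``epoch_seconds`` is discarded — the
    AASM scoring grid is fixed at whole 30-s epochs.
    """
    return EpochGrid(recording=recording, epoch_seconds=epoch_seconds)


# ---------------------------------------------------------------------------
# hypnogram read / write
# ---------------------------------------------------------------------------

def _parse_stage(token: str, line_no: int) -> str:
    t = token.strip().upper()
    if t in STAGES:
        return t
    if t in NUMERIC_ALIASES:
        return NUMERIC_ALIASES[t]
    raise HypnogramParseError(
        f"unknown stage token {token.strip()!r} at line {line_no}", line=line_no
    )


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a hypnogram from one-token-per-line text or ``epoch_index,stage`` CSV."""
    path = Path(path)
    lines = path.read_text().splitlines()
    stages: list[str] = []
    for i, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if "," in line:
            parts = [p.strip() for p in line.split(",")]
            if i == 1 and parts[0].lower() in ("epoch_index", "epoch", "index"):
                continue  # CSV header
            token = parts[1] if len(parts) > 1 else parts[0]
        else:
            token = line
        stages.append(_parse_stage(token, i))
    if not stages:
        raise HypnogramParseError(f"{path}: no stage tokens found")
    return Hypnogram(stages=stages)


def write_hypnogram(h: Hypnogram, path: str | Path,
                    annotations: Sequence | None = None) -> None:
    """Write a hypnogram; with annotations, emits the CSV dialect with
    reliability columns, otherwise one canonical token per line."""
    path = Path(path)
    if annotations is None:
        path.write_text("\n".join(h.stages) + "\n")
        return
    if len(annotations) != len(h):
        raise ValueError(f"{len(annotations)} annotations for {len(h)} epochs")
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["epoch_index", "stage", "reliability", "scd", "scf", "swr_vote"])
        for i, (stage, a) in enumerate(zip(h.stages, annotations)):
            w.writerow([i, stage, a.label, a.scd, a.scf, a.swr_vote])


def write_review_list(annotations: Sequence, h: Hypnogram,
                      path: str | Path, epoch_seconds: float = 30.0) -> int:
    """Write the expert review list: one row per *low-reliability* epoch.

    Columns: 0-based ``epoch_index``, 1-based ``epoch_number`` (for the human
    scorer), epoch start time in seconds, the automatic stage, and the
    reliability evidence (SCD, SCF, SWR vote, total votes). Rows are sorted by
    epoch index regardless of input order. Returns the number of rows written.
    """
    if not len(annotations):
        raise ValueError("annotations must be non-empty")
    low = sorted((a for a in annotations if a.label == "low"),
                 key=lambda a: a.epoch_index)
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["epoch_index", "epoch_number", "start_seconds", "auto_stage",
                    "scd", "scf", "swr_vote", "votes"])
        for a in low:
            w.writerow([a.epoch_index, a.epoch_index + 1,
                        a.epoch_index * epoch_seconds, h[a.epoch_index],
                        a.scd, a.scf, a.swr_vote, a.total_votes])
    return len(low)
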