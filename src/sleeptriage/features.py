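"""Per-epoch spectral and duration features for rule-based sleep staging.

Twelve features per 30-s epoch, drawn from the three staging channels:

========  =======  ==================================================
name      source   definition
========  =======  ==================================================
p0_30_E   EEG      total power 0–30 Hz (µV²)
p0_30_M   EMG      total power 0–30 Hz (µV²)
r0_4_E    EEG      power ratio 0–4 / 0–30 Hz (delta fraction)
r8_13_E   EEG      power ratio 8–13 / 0–30 Hz (alpha fraction)
r22_30_E  EEG      power ratio 22–30 / 0–30 Hz (beta fraction)
r0_4_O    EOG      power ratio 0–4 / 0–30 Hz
mf_E      EEG      mean (centroid) frequency of 0–30 Hz (Hz)
mf_M      EMG      mean (centroid) frequency of 0–30 Hz (Hz)
alpha_E   EEG      alpha duration ratio (fraction of epoch)
spindle_E EEG      spindle duration ratio
sws_E     EEG      slow-wave duration ratio
amp_M     EMG      mean rectified amplitude (µV)
========  =======  ==================================================

Spectra come from Welch's method with 2-s Hamming windows at 50% overlap
(0.5 Hz resolution, adequate for the 0–4 / 8–13 / 22–30 Hz bands). The
duration-ratio detectors slide a 1-s window in 0.5-s steps and apply AASM
amplitude/band criteria; see :data:`DetectorConfig` for the thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ChannelResolutionError

logger = logging.getLogger(__name__)

#: denominator floor (µV²) guarding power ratios against 0/0
POWER_FLOOR = 1e-12

FEATURE_NAMES: tuple[str, ...] = (
    "p0_30_E", "p0_30_M", "r0_4_E", "r8_13_E", "r22_30_E", "r0_4_O",
    "mf_E", "mf_M", "alpha_E", "spindle_E", "sws_E", "amp_M",
)


@dataclass(frozen=True)
class EpochFeatures:
    """The 12 feature values of one 30-s epoch (see module docstring)."""

    p0_30_E: float
    p0_30_M: float
    r0_4_E: float
    r8_13_E: float
    r22_30_E: float
    r0_4_O: float
    mf_E: float
    mf_M: float
    alpha_E: float
    spindle_E: float
    sws_E: float
    amp_M: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds of the sliding-window duration-ratio detectors.

    A 1-s window (0.5-s step) counts toward the ratio when:

    * **alpha** — relative 8–13 Hz power > ``alpha_rel_power`` and the 8–13 Hz
      band-passed peak-to-peak amplitude exceeds ``alpha_min_pp`` µV;
    * **spindle** — relative 11–16 Hz power > ``spindle_rel_power`` (the 1-s
      window itself satisfies the AASM ≥ 0.5 s spindle duration);
    * **sws** — the 0.5–2 Hz band-passed peak-to-peak amplitude exceeds
      ``sws_min_pp`` µV (AASM slow-wave criterion, 75 µV).

    Relative power for the alpha/spindle rules is taken against the
    ``rel_power_band`` (default 4–30 Hz): both rhythms are scored against the
    non-delta background — AASM counts a spindle even when it rides on a slow
    wave — so delta activity must not dilute the ratio.
    """

    window_seconds: float = 1.0
    step_seconds: float = 0.5
    rel_power_band: tuple[float, float] = (4.0, 30.0)
    alpha_band: tuple[float, float] = (8.0, 13.0)
    alpha_rel_power: float = 0.5
    alpha_min_pp: float = 10.0
    spindle_band: tuple[float, float] = (11.0, 16.0)
    spindle_rel_power: float = 0.5
    sws_band: tuple[float, float] = (0.5, 2.0)
    sws_min_pp: float = 75.0


DEFAULT_DETECTORS = DetectorConfig()


# ---------------------------------------------------------------------------
# spectral primitives
# ---------------------------------------------------------------------------

def _welch_psd(samples: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(samples, dtype=float)
    nperseg = min(int(round(2 * fs)), x.size)
    freqs, psd = signal.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                              noverlap=nperseg // 2, detrend=False)
    return freqs, psd


def band_power(samples: np.ndarray, fs: float, f_lo: float, f_hi: float) -> float:
    """Integrated power (µV²) of the spectral density over ``[f_lo, f_hi)``.

    Uses Welch's method (2-s Hamming windows, 50% overlap). Requires at least
    2 s of signal and a band inside the Nyquist range.
    """
    x = np.asarray(samples, dtype=float)
    if not (0 <= f_lo < f_hi <= fs / 2):
        raise ValueError(f"band [{f_lo}, {f_hi}) outside [0, Nyquist={fs / 2}]")
    if x.size < 2 * fs:
        raise ValueError(f"need >= 2 s of samples, got {x.size / fs:.2f} s")
    freqs, psd = _welch_psd(x, fs)
    df = freqs[1] - freqs[0]
    mask = (freqs >= f_lo) & (freqs < f_hi)
    return float(np.sum(psd[mask]) * df)


def power_ratio(samples: np.ndarray, fs: float,
                numerator_band: tuple[float, float],
                denominator_band: tuple[float, float]) -> float:
    """``band_power(numerator) / band_power(denominator)``, clipped to [0, 1].

    Returns 0 when the denominator power is below the floor
    :data:`POWER_FLOOR` (an all-flat epoch has no meaningful band fraction).
    """
    n_lo, n_hi = numerator_band
    d_lo, d_hi = denominator_band
    if not (d_lo <= n_lo and n_hi <= d_hi):
        raise ValueError(
            f"numerator band {numerator_band} not contained in {denominator_band}")
    den = band_power(samples, fs, d_lo, d_hi)
    if den < POWER_FLOOR:
        return 0.0
    return float(np.clip(band_power(samples, fs, n_lo, n_hi) / den, 0.0, 1.0))


def mean_frequency(samples: np.ndarray, fs: float,
                   f_lo: float = 0.0, f_hi: float = 30.0) -> float:
    """Spectral centroid Σ f·P(f) / Σ P(f) over ``[f_lo, f_hi)`` in Hz.

    Returns 0 (with a logged warning) for a zero-power signal.
    """
    x = np.asarray(samples, dtype=float)
    if not (0 <= f_lo < f_hi <= fs / 2):
        raise ValueError(f"band [{f_lo}, {f_hi}) outside [0, Nyquist={fs / 2}]")
    freqs, psd = _welch_psd(x, fs)
    mask = (freqs >= f_lo) & (freqs < f_hi)
    total = float(np.sum(psd[mask]))
    if total < POWER_FLOOR:
        logger.warning("mean_frequency: zero total power in [%g, %g) Hz", f_lo, f_hi)
        return 0.0
    return float(np.sum(freqs[mask] * psd[mask]) / total)


def mean_amplitude(samples: np.ndarray) -> float:
    """Mean of absolute sample values (µV); the EMG tone feature."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample array")
    return float(np.mean(np.abs(x)))


# ---------------------------------------------------------------------------
# duration-ratio detectors
# ---------------------------------------------------------------------------

def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    nyq = fs / 2
    sos = signal.butter(4, [max(lo, 0.01) / nyq, min(hi, nyq * 0.99) / nyq],
                        btype="band", output="sos")
    return signal.sosfiltfilt(sos, x)


def _window_rel_power(win: np.ndarray, fs: float, band: tuple[float, float],
                      ref_band: tuple[float, float]) -> float:
    # periodogram on the raw 1-s window: 1 Hz bins, enough for band fractions
    freqs, psd = signal.periodogram(win, fs=fs, window="hamming", detrend=False)
    total = float(np.sum(psd[(freqs >= ref_band[0]) & (freqs <= ref_band[1])]))
    if total < POWER_FLOOR:
        return 0.0
    sel = float(np.sum(psd[(freqs >= band[0]) & (freqs <= band[1])]))
    return min(sel / total, 1.0)


def duration_ratio(samples: np.ndarray, fs: float, detector: str,
                   config: DetectorConfig = DEFAULT_DETECTORS) -> float:
    """Fraction of the epoch covered by windows satisfying a detector.

    ``detector`` is one of ``alpha``, ``spindle``, ``sws``. A 1-s window
    slides in 0.5-s steps; the ratio is the union of qualifying window spans
    divided by the epoch duration, hence in [0, 1].
    """
    if detector not in ("alpha", "spindle", "sws"):
        raise ValueError(f"unknown detector {detector!r}")
    x = np.asarray(samples, dtype=float)
    win = int(round(config.window_seconds * fs))
    step = int(round(config.step_seconds * fs))
    if x.size < win:
        raise ValueError("need at least one detector window of samples")

    if detector == "alpha":
        band, filt = config.alpha_band, _bandpass(x, fs, config.alpha_band)
    elif detector == "spindle":
        band, filt = config.spindle_band, _bandpass(x, fs, config.spindle_band)
    else:
        band, filt = config.sws_band, _bandpass(x, fs, config.sws_band)

    n_half = x.size // step           # 0.5-s coverage slots
    covered = np.zeros(n_half, dtype=bool)
    slots_per_win = max(1, win // step)
    for start in range(0, x.size - win + 1, step):
        w_raw = x[start:start + win]
        w_filt = filt[start:start + win]
        pp = float(np.max(w_filt) - np.min(w_filt))
        if detector == "alpha":
            ok = (_window_rel_power(w_raw, fs, band, config.rel_power_band)
                  > config.alpha_rel_power and pp > config.alpha_min_pp)
        elif detector == "spindle":
            ok = (_window_rel_power(w_raw, fs, band, config.rel_power_band)
                  > config.spindle_rel_power)
        else:
            ok = pp > config.sws_min_pp
        if ok:
            s = start // step
            covered[s:s + slots_per_win] = True
    return float(np.sum(covered)) / n_half


# ---------------------------------------------------------------------------
# per-epoch extraction and recording-level normalization
# ---------------------------------------------------------------------------

def extract_features(epoch_channels: dict[str, tuple[np.ndarray, float]],
                     detectors: DetectorConfig = DEFAULT_DETECTORS) -> EpochFeatures:
    """Compute the 12 features for one epoch.

    ``epoch_channels`` maps each role (``EEG``, ``EOG``, ``EMG``) to a
    ``(samples µV, fs Hz)`` pair. All three roles must be present.
    """
    missing = [r for r in ("EEG", "EOG", "EMG") if r not in epoch_channels]
    if missing:
        raise ChannelResolutionError(f"missing channel role(s): {missing}")
    eeg, fs_e = epoch_channels["EEG"]
    eog, fs_o = epoch_channels["EOG"]
    emg, fs_m = epoch_channels["EMG"]

    full = (0.0, 30.0)
    return EpochFeatures(
        p0_30_E=band_power(eeg, fs_e, *full),
        p0_30_M=band_power(emg, fs_m, *full),
        r0_4_E=power_ratio(eeg, fs_e, (0.0, 4.0), full),
        r8_13_E=power_ratio(eeg, fs_e, (8.0, 13.0), full),
        r22_30_E=power_ratio(eeg, fs_e, (22.0, 30.0), full),
        r0_4_O=power_ratio(eog, fs_o, (0.0, 4.0), full),
        mf_E=mean_frequency(eeg, fs_e, *full),
        mf_M=mean_frequency(emg, fs_m, *full),
        alpha_E=duration_ratio(eeg, fs_e, "alpha", detectors),
        spindle_E=duration_ratio(eeg, fs_e, "spindle", detectors),
        sws_E=duration_ratio(eeg, fs_e, "sws", detectors),
        amp_M=mean_amplitude(emg),
    )


def extract_recording_features(grid, detectors: DetectorConfig = DEFAULT_DETECTORS
                               ) -> pd.DataFrame:
    """Feature table for every epoch of an :class:`~sleeptriage.io.EpochGrid`.

    Returns a DataFrame indexed by ``epoch_index`` with the 12 feature columns.
    """
    rec = grid.recording
    chans = {role: rec.by_role(role) for role in ("EEG", "EOG", "EMG")}
    rows = []
    for i in range(grid.n_epochs):
        epoch = {role: (grid.slice(i, ch), ch.fs) for role, ch in chans.items()}
        rows.append(extract_features(epoch, detectors).as_dict())
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df.index.name = "epoch_index"
    return df


def normalize_features(features: pd.DataFrame,
                       lo_pct: float = 2.5, hi_pct: float = 97.5) -> pd.DataFrame:
    """Map each feature column to [0, 1] by robust min-max within a recording.

    The 2.5th–97.5th percentiles define the range (robust against artifact
    epochs while keeping minority stages — a night may hold < 5% wake or
    REM — inside the unclipped span); values beyond are clipped. A constant
    column maps to 0.5. Rank order within the unclipped range is preserved.
    """
    if len(features) < 2:
        raise ValueError("normalization needs at least 2 epochs")
    out = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        lo, hi = np.percentile(x, [lo_pct, hi_pct])
        if hi - lo < 1e-15:
            out[col] = np.full_like(x, 0.5)
        else:
            out[col] = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    norm = pd.DataFrame(out, index=features.index)
    norm.index.name = features.index.name
    return norm
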