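"""Per-epoch reliability triage for automatically scored hypnograms.

Interscorer disagreement in sleep staging concentrates at stage transitions
and at the fuzzy N2/N3 boundary. Three per-epoch signals capture this:

* **SWR** (slow-wave-related) — for epochs staged N2 or N3, three features
  (EEG 0–30 Hz total power, slow-wave duration ratio, EOG 0–4/0–30 Hz power
  ratio) are checked against a boundary range ``[mean_N2 + std_N2,
  mean_N3 − std_N3]`` learned from labeled training epochs. A feature inside
  the range means the epoch sits where N2 and N3 overlap.
* **SCD** (stage change distance) — distance in epochs to the nearest epoch
  of a different stage.
* **SCF** (stage change frequency) — number of stage transitions inside the
  11-epoch window centered on the epoch (±5, truncated at record edges).

Each signal casts a high-reliability vote (1) or not (0); an epoch with at
least 2 of 3 votes is *high* reliability, otherwise *low* and queued for
expert rescoring. Two operational modes set the SCD/SCF cuts: level1
(normal; SCD > 5, SCF ≤ 2) and level2 (less stringent; SCD > 4, SCF ≤ 3).
An alternative 2-signal OR rule (high iff SCD or SCF alone passes) is
exposed via ``rule="or"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationError
from .io import Hypnogram

logger = logging.getLogger(__name__)

#: the three slow-wave-related features checked at the N2/N3 boundary
SWR_FEATURES: tuple[str, ...] = ("p0_30_E", "sws_E", "r0_4_O")


# ---------------------------------------------------------------------------
# configuration and annotation types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeConfig:
    """SCD/SCF cut points of one operational mode.

    ``scd_vote = 1`` iff SCD > ``scd_high_min``;
    ``scf_vote = 1`` iff SCF < ``scf_high_max``.
    """

    name: str
    scd_high_min: int
    scf_high_max: int


LEVEL1 = ModeConfig(name="level1", scd_high_min=5, scf_high_max=3)
LEVEL2 = ModeConfig(name="level2", scd_high_min=4, scf_high_max=4)

MODES = {"level1": LEVEL1, "level2": LEVEL2}


@dataclass(frozen=True)
class SwrBoundary:
    """Boundary range of one SWR feature between the N2 and N3 populations."""

    feature: str
    mean_n2: float
    std_n2: float
    mean_n3: float
    std_n3: float
    lo: float
    hi: float
    inverted: bool  # True when mean_N2+std_N2 > mean_N3-std_N3 (overlap)

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi  # inclusive at both ends


@dataclass
class SwrCalibration:
    """N2/N3 statistics and boundary ranges for the three SWR features."""

    boundaries: dict[str, SwrBoundary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.boundaries) != set(SWR_FEATURES):
            raise ValueError(f"calibration must cover exactly {SWR_FEATURES}")

    def as_dict(self) -> dict:
        return {f: vars(b) for f, b in self.boundaries.items()}

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SwrCalibration":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(boundaries={f: SwrBoundary(**d) for f, d in data.items()})


@dataclass(frozen=True)
class ReliabilityAnnotation:
    """The triage verdict and its evidence for one epoch."""

    epoch_index: int
    scd: int
    scf: int
    swr_vote: int
    scd_vote: int
    scf_vote: int

    @property
    def total_votes(self) -> int:
        return self.swr_vote + self.scd_vote + self.scf_vote

    @property
    def label(self) -> str:
        return "high" if self.total_votes >= 2 else "low"


# ---------------------------------------------------------------------------
# SWR calibration and vote
# ---------------------------------------------------------------------------

def calibrate_swr(features: pd.DataFrame, labels: Hypnogram) -> SwrCalibration:
    """Learn the N2/N3 boundary ranges of the three SWR features.

    For each feature the boundary is ``[mean_N2 + std_N2, mean_N3 − std_N3]``
    (Bessel-corrected sample std). When the two populations overlap so strongly that
    the bounds invert, the interval is canonicalized to ``[min, max]`` and
    flagged ``inverted``. Needs ≥ 2 epochs each of N2 and N3.
    """
    if len(features) != len(labels):
        raise ValueError(f"{len(features)} feature rows vs {len(labels)} labels")
    y = np.asarray(labels.stages)
    n2, n3 = y == "N2", y == "N3"
    for stage, mask in (("N2", n2), ("N3", n3)):
        if mask.sum() < 2:
            raise CalibrationError(
                f"stage {stage} has {int(mask.sum())} epochs; need >= 2")

    boundaries = {}
    for feat in SWR_FEATURES:
        x = features[feat].to_numpy(dtype=float)
        m2, s2 = float(np.mean(x[n2])), float(np.std(x[n2], ddof=1))
        m3, s3 = float(np.mean(x[n3])), float(np.std(x[n3], ddof=1))
        lo, hi = m2 + s2, m3 - s3
        inverted = lo > hi
        if inverted:
            logger.warning("SWR feature %s: N2/N3 boundary inverted "
                           "([%.4g, %.4g]); canonicalizing", feat, lo, hi)
            lo, hi = hi, lo
        boundaries[feat] = SwrBoundary(feat, m2, s2, m3, s3, lo, hi, inverted)
    return SwrCalibration(boundaries=boundaries)


def swr_vote(features, cal: SwrCalibration, stage: str,
             other_stage_default: int = 0) -> int:
    """High-reliability vote (1) of the SWR check for one epoch.

    The boundary-range check is defined only for epochs staged N2 or N3: a
    per-feature bit is 1 when the value lies *outside* its boundary range
    (clear of the N2/N3 overlap zone); the vote is 1 iff ≥ 2 of 3 bits are 1.

    For all other stages the check carries no evidence and the vote defaults
    to ``other_stage_default`` (0). With a defaulted 0, a W/N1/R epoch is
    high-reliability only when *both* stage-change votes pass — appropriate
    because the wake/N1 and REM boundaries are themselves high-disagreement
    territory and no slow-wave evidence vouches for them. Pass
    ``other_stage_default=1`` to let such epochs fall back on SCD/SCF alone.
    """
    if stage not in ("N2", "N3"):
        return other_stage_default
    bits = 0
    for feat in SWR_FEATURES:
        v = float(features[feat] if not hasattr(features, feat)
                  else getattr(features, feat))
        if not cal.boundaries[feat].contains(v):
            bits += 1
    return 1 if bits >= 2 else 0


# ---------------------------------------------------------------------------
# stage-change statistics
# ---------------------------------------------------------------------------

def stage_change_distance(h: Hypnogram) -> np.ndarray:
    """SCD per epoch: distance to the nearest epoch of a different stage.

    A single-stage hypnogram has no stage change anywhere; every epoch gets
    the sentinel value ``len(h)``, which exceeds any plausible cut point.
    """
    y = np.asarray(h.stages)
    n = y.size
    scd = np.full(n, n, dtype=int)
    # forward sweep: distance to the last differing epoch on the left
    last = -1
    for i in range(n):
        if i > 0 and y[i] != y[i - 1]:
            last = i - 1
        if last >= 0:
            scd[i] = i - last
    # backward sweep
    nxt = -1
    for i in range(n - 1, -1, -1):
        if i < n - 1 and y[i] != y[i + 1]:
            nxt = i + 1
        if nxt >= 0:
            scd[i] = min(scd[i], nxt - i)
    return scd


def stage_change_frequency(h: Hypnogram, half_width: int = 5) -> np.ndarray:
    """SCF per epoch: stage transitions within the centered (2·hw+1)-epoch window.

    Counts adjacent pairs ``(j, j+1)`` with differing stages for ``j`` in
    ``[max(0, i−hw), min(n−1, i+hw))``; the window truncates at the edges.
    """
    y = np.asarray(h.stages)
    n = y.size
    change = np.zeros(n, dtype=int)          # change[j] = 1 iff y[j] != y[j+1]
    if n > 1:
        change[:-1] = (y[:-1] != y[1:]).astype(int)
    csum = np.concatenate([[0], np.cumsum(change)])
    scf = np.empty(n, dtype=int)
    for i in range(n):
        lo = max(0, i - half_width)
        hi = min(n - 1, i + half_width)      # pairs (j, j+1), j in [lo, hi)
        scf[i] = csum[hi] - csum[lo]
    return scf


# ---------------------------------------------------------------------------
# voting
# ---------------------------------------------------------------------------

def vote(swr: int, scd: int, scf: int, mode: ModeConfig = LEVEL1,
         epoch_index: int = 0) -> ReliabilityAnnotation:
    """Combine the three reliability signals into one annotation.

    ``scd_vote = 1`` iff SCD exceeds the mode's cut (level1: SCD > 5, i.e.
    low reliability iff SCD < 6); ``scf_vote = 1`` iff SCF is below the
    mode's cut (level1: SCF ≤ 2). The epoch is high reliability iff at least
    2 of the 3 votes are 1.
    """
    if scd < 0 or scf < 0:
        raise ValueError(f"scd/scf must be non-negative, got {scd}, {scf}")
    if swr not in (0, 1):
        raise ValueError(f"swr vote must be 0 or 1, got {swr}")
    return ReliabilityAnnotation(
        epoch_index=epoch_index, scd=scd, scf=scf, swr_vote=swr,
        scd_vote=1 if scd > mode.scd_high_min else 0,
        scf_vote=1 if scf < mode.scf_high_max else 0,
    )


def annotate(h: Hypnogram, features: pd.DataFrame, cal: SwrCalibration,
             mode: ModeConfig = LEVEL1, rule: str = "vote",
             ) -> list[ReliabilityAnnotation]:
    """Annotate every epoch of an auto-scored hypnogram with its reliability.

    ``rule="vote"`` is the primary 3-way majority vote (SWR + SCD + SCF);
    ``rule="or"`` reproduces the simpler 2-signal rule in which an epoch is
    high reliability iff SCD or SCF alone passes its cut (the SWR vote is
    forced to agree with that disjunction so 2-of-3 voting realizes the OR).
    """
    if len(features) != len(h):
        raise ValueError(f"{len(features)} feature rows vs {len(h)} epochs")
    if rule not in ("vote", "or"):
        raise ValueError(f"unknown rule {rule!r}")
    scd = stage_change_distance(h)
    scf = stage_change_frequency(h)
    out = []
    for i in range(len(h)):
        row = features.iloc[i]
        sv = swr_vote(row, cal, h[i])
        a = vote(sv, int(scd[i]), int(scf[i]), mode, epoch_index=i)
        if rule == "or":
            forced = 1 if (a.scd_vote or a.scf_vote) else 0
            a = ReliabilityAnnotation(i, a.scd, a.scf, forced,
                                      a.scd_vote, a.scf_vote)
        out.append(a)
    return out


def annotations_frame(annotations: list[ReliabilityAnnotation],
                      h: Hypnogram) -> pd.DataFrame:
    """Tabular export of annotations (one row per epoch)."""
    return pd.DataFrame({
        "epoch_index": [a.epoch_index for a in annotations],
        "stage": [h[a.epoch_index] for a in annotations],
        "scd": [a.scd for a in annotations],
        "scf": [a.scf for a in annotations],
        "swr_vote": [a.swr_vote for a in annotations],
        "scd_vote": [a.scd_vote for a in annotations],
        "scf_vote": [a.scf_vote for a in annotations],
        "total_votes": [a.total_votes for a in annotations],
        "label": [a.label for a in annotations],
    })


def read_annotations(path) -> list[ReliabilityAnnotation]:
    """Read back an annotation CSV written from :func:`annotations_frame`."""
    df = pd.read_csv(path)
    return [ReliabilityAnnotation(int(r.epoch_index), int(r.scd), int(r.scf),
                                  int(r.swr_vote), int(r.scd_vote), int(r.scf_vote))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# merging expert corrections
# ---------------------------------------------------------------------------

def merge_rescored(auto: Hypnogram,
                   annotations: list[ReliabilityAnnotation],
                   expert_labels: dict[int, str],
                   strict: bool = False) -> Hypnogram:
    """Merge expert rescorings of low-reliability epochs into the auto scoring.

    ``expert_labels`` maps epoch index → stage. Labels on high-reliability
    epochs are rejected with an error when ``strict`` (the expert was only
    asked about the review list), otherwise applied with a warning.
    """
    if len(annotations) != len(auto):
        raise ValueError(f"{len(annotations)} annotations for {len(auto)} epochs")
    low = {a.epoch_index for a in annotations if a.label == "low"}
    stages = list(auto.stages)
    for idx, stage in sorted(expert_labels.items()):
        if not 0 <= idx < len(auto):
            raise ValueError(f"epoch index {idx} out of range [0, {len(auto)})")
        if idx not in low:
            msg = f"expert label on high-reliability epoch {idx}"
            if strict:
                raise ValueError(msg)
            logger.warning("%s; applying anyway", msg)
        stages[idx] = stage
    return Hypnogram(stages, epoch_seconds=auto.epoch_seconds)
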