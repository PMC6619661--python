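"""Agreement metrics between two hypnograms.

Epoch-by-epoch percent agreement (overall and within the high/low-reliability
subsets), unweighted Cohen's kappa, the 5×5 stage confusion matrix, sleep
efficiency, and the fraction of scorer disagreements captured by the
low-reliability triage. Kappa is unweighted because stage labels are nominal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedValueError
from .io import Hypnogram, STAGES


def _check_lengths(a: Hypnogram, b: Hypnogram) -> None:
    if len(a) != len(b):
        raise ValueError(f"hypnogram lengths differ: {len(a)} vs {len(b)}")


def agreement(a: Hypnogram, b: Hypnogram,
              subset: set[int] | None = None) -> float:
    """Percent of epochs with identical stages, optionally within a subset."""
    _check_lengths(a, b)
    idx = sorted(subset) if subset is not None else range(len(a))
    idx = list(idx)
    if not idx:
        raise UndefinedValueError("agreement over an empty epoch subset")
    if subset is not None and (min(idx) < 0 or max(idx) >= len(a)):
        raise ValueError("subset index out of range")
    match = sum(1 for i in idx if a[i] == b[i])
    return 100.0 * match / len(idx)


def cohen_kappa(a: Hypnogram, b: Hypnogram) -> float:
    """Unweighted Cohen's kappa: κ = (p_o − p_e) / (1 − p_e).

    Chance agreement p_e comes from the product of the two scorers' marginal
    stage frequencies. When p_e = 1 (both scorers constant on the same
    stage), κ is defined as 1 for identical sequences.
    """
    _check_lengths(a, b)
    n = len(a)
    if n == 0:
        raise ValueError("empty hypnograms")
    cm = confusion(a, b).to_numpy(dtype=float)
    p_o = np.trace(cm) / n
    p_e = float(np.sum(cm.sum(axis=1) * cm.sum(axis=0))) / n**2
    if abs(1.0 - p_e) < 1e-12:
        return 1.0 if a.stages == b.stages else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def confusion(a: Hypnogram, b: Hypnogram) -> pd.DataFrame:
    """5×5 stage confusion counts; rows = first scorer, columns = second."""
    _check_lengths(a, b)
    idx = {s: i for i, s in enumerate(STAGES)}
    cm = np.zeros((5, 5), dtype=int)
    for s1, s2 in zip(a.stages, b.stages):
        cm[idx[s1], idx[s2]] += 1
    return pd.DataFrame(cm, index=list(STAGES), columns=list(STAGES))


def sleep_efficiency(h: Hypnogram) -> float:
    """Percent of scored epochs spent asleep (any stage other than W)."""
    if len(h) == 0:
        raise ValueError("empty hypnogram")
    asleep = sum(1 for s in h.stages if s != "W")
    return 100.0 * asleep / len(h)


def disagreement_capture(auto: Hypnogram, ref: Hypnogram,
                         annotations) -> float:
    """Fraction of auto/reference disagreements flagged low-reliability.

    The triage is useful precisely to the extent that the epochs it sends to
    the expert are the ones the scorers would dispute. Raises when the two
    hypnograms agree everywhere (the fraction is undefined).
    """
    _check_lengths(auto, ref)
    if len(annotations) != len(auto):
        raise ValueError(f"{len(annotations)} annotations for {len(auto)} epochs")
    dis = [i for i in range(len(auto)) if auto[i] != ref[i]]
    if not dis:
        raise UndefinedValueError("no disagreements between the hypnograms")
    low = {a.epoch_index for a in annotations if a.label == "low"}
    return sum(1 for i in dis if i in low) / len(dis)


@dataclass
class AgreementReport:
    """Bundled agreement evaluation of two hypnograms.

    ``high_rel_pct`` / ``low_rel_pct`` are only present when reliability
    annotations are supplied; the overall agreement always equals the
    subset-size-weighted mean of the two.
    """

    overall_pct: float
    kappa: float
    confusion: pd.DataFrame
    n_epochs: int
    n_low: int | None = None
    high_rel_pct: float | None = None
    low_rel_pct: float | None = None

    def as_dict(self) -> dict:
        d = {"overall_pct": self.overall_pct, "kappa": self.kappa,
             "n_epochs": self.n_epochs}
        if self.n_low is not None:
            d.update(n_low=self.n_low, high_rel_pct=self.high_rel_pct,
                     low_rel_pct=self.low_rel_pct)
        return d


def report(a: Hypnogram, b: Hypnogram, annotations=None) -> AgreementReport:
    """Full agreement report; with annotations, adds the HR/LR decomposition."""
    _check_lengths(a, b)
    rep = AgreementReport(
        overall_pct=agreement(a, b),
        kappa=cohen_kappa(a, b),
        confusion=confusion(a, b),
        n_epochs=len(a),
    )
    if annotations is not None:
        low = {x.epoch_index for x in annotations if x.label == "low"}
        high = set(range(len(a))) - low
        rep.n_low = len(low)
        rep.high_rel_pct = agreement(a, b, high) if high else None
        rep.low_rel_pct = agreement(a, b, low) if low else None
    return rep
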