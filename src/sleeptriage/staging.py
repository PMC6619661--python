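"""Rule-based sleep staging: a layered decision tree plus temporal smoothing.

The classifier is a short decision tree over the 12 normalized features.
Stages that are easy to recognize sit in the upper layers (W with its alpha
rhythm and high muscle tone, then N3 with its slow waves), harder stages
below (R, N2), and N1 — the stage with the lowest interscorer agreement —
is the fall-through terminal. Node thresholds live in the tree object and
serialize to YAML/JSON, so a site can ship a recalibrated tree without
touching code.

``calibrate_tree`` rebuilds the thresholds from a labeled recording: at each
node it picks the feature whose class-conditional histogram is farthest
(total-variation distance over 20 bins on [0, 1]) from the remaining stages,
and places the cut at the point of maximal CDF separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import CalibrationError
from .features import FEATURE_NAMES
from .io import Hypnogram, STAGES

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tree structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeNode:
    """One binary decision: ``feature <op> threshold`` → branch targets.

    ``if_true`` / ``if_false`` are either a node id (int) or a terminal stage
    label (str).
    """

    id: int
    feature: str
    op: str                    # "<" or ">"
    threshold: float
    if_true: int | str
    if_false: int | str

    def test(self, value: float) -> bool:
        return value > self.threshold if self.op == ">" else value < self.threshold


@dataclass
class StagingTree:
    """An ordered, acyclic set of decision nodes rooted at the first node."""

    nodes: list[TreeNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_id = {n.id: n for n in self.nodes}
        for n in self.nodes:
            if n.feature not in FEATURE_NAMES:
                raise ValueError(f"node {n.id}: unknown feature {n.feature!r}")
            for target in (n.if_true, n.if_false):
                if isinstance(target, str):
                    if target not in STAGES:
                        raise ValueError(f"node {n.id}: bad terminal {target!r}")
                elif target not in by_id:
                    raise ValueError(f"node {n.id}: dangling branch to {target}")
        # acyclicity: DFS from every node over both branches
        def walk(nid: int, path: frozenset) -> None:
            if nid in path:
                raise ValueError(f"cycle through node {nid}")
            node = by_id[nid]
            for target in (node.if_true, node.if_false):
                if isinstance(target, int):
                    walk(target, path | {nid})

        for n in self.nodes:
            walk(n.id, frozenset())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def terminals(self) -> set[str]:
        return {t for n in self.nodes for t in (n.if_true, n.if_false)
                if isinstance(t, str)}

    def to_yaml(self, path) -> None:
        data = [{"id": n.id, "feature": n.feature, "op": n.op,
                 "threshold": float(n.threshold),
                 "if_true": n.if_true, "if_false": n.if_false}
                for n in self.nodes]
        with open(path, "w") as f:
            yaml.safe_dump(data, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StagingTree":
        with open(path) as f:
            data = yaml.safe_load(f)
        return cls(nodes=[TreeNode(**d) for d in data])


def default_tree() -> StagingTree:
    """The shipped default tree on normalized features (8 decision nodes).

    Layered easiest-first: W (alpha rhythm or high muscle tone), N3 (slow
    waves or dominant delta), R (atonia with low EMG frequency content and
    slow EOG activity), N2 (spindles or a slow-leaning EEG without wake
    signs), N1 fall-through.
    """
    W, N1, N2, N3, R = STAGES
    return StagingTree(nodes=[
        TreeNode(0, "alpha_E", ">", 0.60, W, 1),
        TreeNode(1, "amp_M", ">", 0.70, W, 2),
        TreeNode(2, "sws_E", ">", 0.75, N3, 3),
        TreeNode(3, "r0_4_E", ">", 0.85, N3, 4),
        TreeNode(4, "amp_M", "<", 0.25, 5, 7),
        TreeNode(5, "mf_M", "<", 0.45, 6, 7),
        TreeNode(6, "r0_4_O", ">", 0.15, R, 7),
        TreeNode(7, "spindle_E", ">", 0.50, 8, N1),
        TreeNode(8, "p0_30_E", ">", 0.03, N2, N1),
    ])


def classify(features, tree: StagingTree) -> str:
    """Classify one epoch's normalized features with a staging tree.

    ``features`` is anything with the 12 feature names accessible by key or
    attribute (an :class:`~sleeptriage.features.EpochFeatures`, a dict, or a
    DataFrame row). Deterministic; a NaN feature raises naming the feature.
    """
    def get(name: str) -> float:
        v = features[name] if not hasattr(features, name) else getattr(features, name)
        v = float(v)
        if not np.isfinite(v):
            raise ValueError(f"feature {name!r} is not finite: {v}")
        return v

    by_id = {n.id: n for n in tree.nodes}
    cur: int | str = tree.nodes[0].id
    for _ in range(tree.n_nodes + 1):
        node = by_id[cur]
        cur = node.if_true if node.test(get(node.feature)) else node.if_false
        if isinstance(cur, str):
            return cur
    raise RuntimeError("tree did not terminate")  # unreachable for valid trees


def classify_epochs(features: pd.DataFrame, tree: StagingTree,
                    epoch_seconds: float = 30.0) -> Hypnogram:
    """Classify every row of a normalized feature table into a hypnogram."""
    return Hypnogram([classify(row, tree) for _, row in features.iterrows()],
                     epoch_seconds=epoch_seconds)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

#: node decision order — easy stages first, N1 is the fall-through
CALIBRATION_ORDER = ("W", "N3", "R", "N2")

_TV_BINS = 20
_MIN_DISTANCE = 0.05   # below this the classes are indistinguishable; warn


def _tv_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Total-variation distance between two samples, over 20 bins on [0, 1]."""
    edges = np.linspace(0.0, 1.0, _TV_BINS + 1)
    ha, _ = np.histogram(np.clip(a, 0, 1), bins=edges)
    hb, _ = np.histogram(np.clip(b, 0, 1), bins=edges)
    pa = ha / max(ha.sum(), 1)
    pb = hb / max(hb.sum(), 1)
    return float(0.5 * np.sum(np.abs(pa - pb)))


def _best_cut(target: np.ndarray, rest: np.ndarray) -> tuple[float, str]:
    """Threshold and direction minimizing class overlap (max CDF gap)."""
    cuts = np.linspace(0.0, 1.0, 201)
    # fraction of each class below the cut
    f_t = np.searchsorted(np.sort(target), cuts, side="right") / target.size
    f_r = np.searchsorted(np.sort(rest), cuts, side="right") / rest.size
    gap = f_t - f_r
    i = int(np.argmax(np.abs(gap)))
    # target mass mostly below the cut → target is the "<" side
    op = "<" if gap[i] > 0 else ">"
    return float(cuts[i]), op


def calibrate_tree(features: pd.DataFrame, labels: Hypnogram) -> StagingTree:
    """Fit node features and thresholds from a labeled recording.

    Follows the fixed stage-separation order W | N3 | R | N2 (N1 remains the
    fall-through). At each node, the feature maximizing the total-variation
    histogram distance between the node's target stage and the remaining
    stages is selected, and the threshold is placed at the minimal-overlap
    cut. Requires ≥ 5 epochs of every stage.
    """
    if len(features) != len(labels):
        raise ValueError(f"{len(features)} feature rows vs {len(labels)} labels")
    y = np.asarray(labels.stages)
    for stage in STAGES:
        if np.sum(y == stage) < 5:
            raise CalibrationError(
                f"stage {stage} has {int(np.sum(y == stage))} epochs; need >= 5")

    nodes: list[TreeNode] = []
    remaining = np.ones(len(y), dtype=bool)
    for node_id, stage in enumerate(CALIBRATION_ORDER):
        tgt_mask = remaining & (y == stage)
        rest_mask = remaining & (y != stage)
        best_feat, best_dist = None, -1.0
        for feat in FEATURE_NAMES:
            x = features[feat].to_numpy(dtype=float)
            d = _tv_distance(x[tgt_mask], x[rest_mask])
            if d > best_dist:
                best_feat, best_dist = feat, d
        x = features[best_feat].to_numpy(dtype=float)
        if best_dist < _MIN_DISTANCE:
            logger.warning(
                "calibration node %d (%s): all feature distances ~0 "
                "(best %.3f on %s); keeping default threshold 0.5",
                node_id, stage, best_dist, best_feat)
            cut, op = 0.5, ">"
        else:
            cut, op = _best_cut(x[tgt_mask], x[rest_mask])
        is_last = node_id == len(CALIBRATION_ORDER) - 1
        nodes.append(TreeNode(node_id, best_feat, op, cut, stage,
                              "N1" if is_last else node_id + 1))
        # epochs routed to the terminal no longer inform deeper nodes
        vals = features[best_feat].to_numpy(dtype=float)
        hit = np.array([nodes[-1].test(v) for v in vals])
        remaining &= ~hit
    return StagingTree(nodes=nodes)


def resubstitution_accuracy(features: pd.DataFrame, labels: Hypnogram,
                            tree: StagingTree) -> float:
    """Fraction of epochs the tree reproduces from their own features."""
    pred = classify_epochs(features, tree)
    return float(np.mean(np.asarray(pred.stages) == np.asarray(labels.stages)))


# ---------------------------------------------------------------------------
# temporal smoothing
# ---------------------------------------------------------------------------

def smooth(h: Hypnogram) -> Hypnogram:
    """Context smoothing of a hypnogram, run to a fixed point.

    Two rewrite rules, applied in order until the sequence stops changing:

    (a) *singleton-island removal* — an epoch differing from two identical
        flanking neighbors takes the neighbor stage (sleep stages do not
        flicker for a single epoch between identical context);
    (b) *N1 bridging* — an N1 run of length ≤ 2 flanked by N2 on both sides
        becomes N2 (AASM continuity: N2 persists until evidence of another
        stage).

    No new stage labels are introduced and the length is preserved.
    Hypnograms shorter than 3 epochs are returned unchanged with a warning.
    """
    if len(h) < 3:
        logger.warning("smooth: hypnogram of length %d returned unchanged", len(h))
        return Hypnogram(list(h.stages), epoch_seconds=h.epoch_seconds)

    s = list(h.stages)
    for _ in range(len(s)):
        before = list(s)
        # (a) sequential left-to-right island removal
        for i in range(1, len(s) - 1):
            if s[i - 1] == s[i + 1] != s[i]:
                s[i] = s[i - 1]
        # (b) N1 runs of length <= 2 flanked by N2
        i = 0
        while i < len(s):
            if s[i] == "N1":
                j = i
                while j < len(s) and s[j] == "N1":
                    j += 1
                if (j - i <= 2 and i > 0 and j < len(s)
                        and s[i - 1] == "N2" and s[j] == "N2"):
                    for k in range(i, j):
                        s[k] = "N2"
                i = j
            else:
                i += 1
        if s == before:
            break
    return Hypnogram(s, epoch_seconds=h.epoch_seconds)
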