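import itertools

import numpy as np
import pandas as pd
import pytest

from sleeptriage import Hypnogram
from sleeptriage.errors import CalibrationError
from sleeptriage.features import FEATURE_NAMES
from sleeptriage.reliability import (
    LEVEL1, LEVEL2, SWR_FEATURES, ReliabilityAnnotation, SwrCalibration,
    annotate, calibrate_swr, merge_rescored, stage_change_distance,
    stage_change_frequency, swr_vote, vote,
)

STAGES = ("W", "N1", "N2", "N3", "R")


def feature_table(values_by_feature, n):
    """Constant feature table with chosen SWR feature values."""
    df = pd.DataFrame(0.5, index=range(n), columns=list(FEATURE_NAMES))
    for feat, v in values_by_feature.items():
        df[feat] = v
    df.index.name = "epoch_index"
    return df


def swr_cal(lo=0.3, hi=0.7):
    """Calibration whose three boundary ranges are all exactly [lo, hi]
    (zero-variance N2 samples at lo, N3 samples at hi)."""
    df = feature_table({f: [lo, lo, hi, hi] for f in SWR_FEATURES}, 4)
    return calibrate_swr(df, Hypnogram(["N2", "N2", "N3", "N3"]))


class TestCalibrateSwr:
    def test_zero_variance_boundary(self):
        df = feature_table({f: [0.2, 0.2, 0.8, 0.8] for f in SWR_FEATURES}, 4)
        cal = calibrate_swr(df, Hypnogram(["N2", "N2", "N3", "N3"]))
        for f in SWR_FEATURES:
            b = cal.boundaries[f]
            assert (b.lo, b.hi) == (0.2, 0.8)
            assert not b.inverted

    def test_hand_computed_sample_statistics(self):
        df = feature_table({f: [0.1, 0.3, 0.7, 0.9] for f in SWR_FEATURES}, 4)
        cal = calibrate_swr(df, Hypnogram(["N2", "N2", "N3", "N3"]))
        for f in SWR_FEATURES:
            b = cal.boundaries[f]
            assert b.lo == pytest.approx(0.2 + 0.14142, abs=1e-3)
            assert b.hi == pytest.approx(0.8 - 0.14142, abs=1e-3)

    def test_overlapping_classes_canonicalized_and_flagged(self):
        df = feature_table({f: [0.1, 0.9, 0.2, 0.8] for f in SWR_FEATURES}, 4)
        cal = calibrate_swr(df, Hypnogram(["N2", "N2", "N3", "N3"]))
        for f in SWR_FEATURES:
            b = cal.boundaries[f]
            assert b.inverted
            assert b.lo <= b.hi

    def test_too_few_epochs_of_a_stage(self):
        df = feature_table({}, 4)
        with pytest.raises(CalibrationError, match="N3"):
            calibrate_swr(df, Hypnogram(["N2", "N2", "N2", "N3"]))

    def test_yaml_round_trip(self, tmp_path):
        df = feature_table({f: [0.1, 0.3, 0.7, 0.9] for f in SWR_FEATURES}, 4)
        cal = calibrate_swr(df, Hypnogram(["N2", "N2", "N3", "N3"]))
        p = tmp_path / "cal.yaml"
        cal.to_yaml(p)
        back = SwrCalibration.from_yaml(p)
        assert back.as_dict() == cal.as_dict()


class TestSwrVote:
    def test_all_outside_is_high(self):
        cal = swr_cal()
        row = {f: 0.95 for f in SWR_FEATURES}
        assert swr_vote(row, cal, "N2") == 1

    def test_all_inside_is_low(self):
        cal = swr_cal()
        row = {f: 0.5 for f in SWR_FEATURES}
        assert swr_vote(row, cal, "N3") == 0

    def test_exhaustive_bit_patterns(self):
        # vote = 1 iff at least two features sit OUTSIDE their ranges
        cal = swr_cal()
        for bits in itertools.product([0, 1], repeat=3):
            row = {f: (0.95 if outside else 0.5)
                   for f, outside in zip(SWR_FEATURES, bits)}
            expected = 1 if sum(bits) >= 2 else 0
            assert swr_vote(row, cal, "N2") == expected

    def test_boundary_membership_is_inclusive(self):
        cal = swr_cal(lo=0.3, hi=0.7)
        row = {f: 0.3 for f in SWR_FEATURES}
        assert swr_vote(row, cal, "N2") == 0
        row = {f: 0.7 for f in SWR_FEATURES}
        assert swr_vote(row, cal, "N2") == 0

    def test_non_nrem_deep_stage_defaults(self):
        cal = swr_cal()
        row = {f: 0.95 for f in SWR_FEATURES}
        for stage in ("W", "N1", "R"):
            assert swr_vote(row, cal, stage) == 0
            assert swr_vote(row, cal, stage, other_stage_default=1) == 1


def brute_scd(stages):
    n = len(stages)
    out = []
    for i in range(n):
        dists = [abs(i - j) for j in range(n) if stages[j] != stages[i]]
        out.append(min(dists) if dists else n)
    return out


def brute_scf(stages, hw=5):
    n = len(stages)
    out = []
    for i in range(n):
        lo, hi = max(0, i - hw), min(n - 1, i + hw)
        out.append(sum(stages[j] != stages[j + 1] for j in range(lo, hi)))
    return out


class TestStageChangeDistance:
    def test_two_run_example(self):
        h = Hypnogram(["W", "W", "W", "N1", "N1"])
        assert stage_change_distance(h).tolist() == [3, 2, 1, 1, 2]

    def test_uniform_sentinel(self):
        assert stage_change_distance(Hypnogram(["N2"] * 10)).tolist() == [10] * 10

    def test_alternating(self):
        assert stage_change_distance(Hypnogram(["W", "N1", "W"])).tolist() == \
            [1, 1, 1]

    def test_matches_brute_force(self, random_hypnogram_suite):
        for stages in random_hypnogram_suite[:300]:
            got = stage_change_distance(Hypnogram(stages)).tolist()
            assert got == brute_scd(stages)


class TestStageChangeFrequency:
    def test_uniform_is_zero(self):
        assert stage_change_frequency(Hypnogram(["R"] * 15)).tolist() == [0] * 15

    def test_alternating_interior_saturates(self):
        stages = ["W", "N1"] * 8
        scf = stage_change_frequency(Hypnogram(stages))
        assert scf[8] == 10  # 11-epoch window holds 10 differing pairs

    def test_single_change_window(self):
        h = Hypnogram(["W"] * 6 + ["N1"] * 6)
        assert stage_change_frequency(h)[5] == 1

    def test_matches_brute_force(self, random_hypnogram_suite):
        for stages in random_hypnogram_suite[:300]:
            got = stage_change_frequency(Hypnogram(stages)).tolist()
            assert got == brute_scf(stages)

    def test_translation_of_uniform_prefix(self, random_hypnogram_suite):
        for stages in random_hypnogram_suite[:50]:
            if len(set(stages)) < 2:
                continue
            k = 4
            shifted = [stages[0]] * k + stages
            scd0 = stage_change_distance(Hypnogram(stages))
            scd1 = stage_change_distance(Hypnogram(shifted))
            scf0 = stage_change_frequency(Hypnogram(stages))
            scf1 = stage_change_frequency(Hypnogram(shifted))
            first_change = next(i for i in range(len(stages) - 1)
                                if stages[i] != stages[i + 1])
            for i in range(first_change + 1, len(stages)):
                assert scd1[i + k] == scd0[i]
                if i >= first_change + 6:
                    assert scf1[i + k] == scf0[i]


class TestVote:
    def test_high_via_swr_and_scd(self):
        a = vote(1, 10, 5, LEVEL1)
        assert (a.swr_vote, a.scd_vote, a.scf_vote) == (1, 1, 0)
        assert a.total_votes == 2 and a.label == "high"

    def test_all_votes_fail(self):
        a = vote(0, 1, 6, LEVEL1)
        assert (a.swr_vote, a.scd_vote, a.scf_vote) == (0, 0, 0)
        assert a.label == "low"

    def test_scd_and_scf_pass_in_both_modes(self):
        for mode in (LEVEL1, LEVEL2):
            a = vote(0, 8, 1, mode)
            assert (a.scd_vote, a.scf_vote) == (1, 1)
            assert a.label == "high"

    def test_level1_cut_points(self):
        # low reliability iff SCD < 6; high-SCF vote iff SCF <= 2
        assert vote(0, 5, 0, LEVEL1).scd_vote == 0
        assert vote(0, 6, 0, LEVEL1).scd_vote == 1
        assert vote(0, 10, 2, LEVEL1).scf_vote == 1
        assert vote(0, 10, 3, LEVEL1).scf_vote == 0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            vote(0, -1, 0, LEVEL1)
        with pytest.raises(ValueError):
            vote(0, 0, -2, LEVEL1)


class TestAnnotate:
    def test_single_change_forces_scd_votes_off_nearby(self):
        stages = ["N2"] * 20 + ["N3"] * 20
        h = Hypnogram(stages)
        feats = feature_table({f: 0.95 for f in SWR_FEATURES}, 40)
        cal = swr_cal()
        ann = annotate(h, feats, cal, LEVEL1)
        for i in range(15, 25):   # SCD <= 5 on both sides of the change
            assert ann[i].scd_vote == 0
        assert ann[14].scd_vote == 1 and ann[25].scd_vote == 1
        assert ann[0].scd_vote == 1 and ann[39].scd_vote == 1

    def test_uniform_outside_ranges_all_high(self):
        h = Hypnogram(["N2"] * 30)
        feats = feature_table({f: 0.95 for f in SWR_FEATURES}, 30)
        ann = annotate(h, feats, swr_cal(), LEVEL1)
        assert all(a.label == "high" for a in ann)

    def test_alternating_all_low_regardless_of_swr(self):
        h = Hypnogram(["N2", "N3"] * 15)
        for v in (0.5, 0.95):
            feats = feature_table({f: v for f in SWR_FEATURES}, 30)
            ann = annotate(h, feats, swr_cal(), LEVEL1)
            assert all(a.label == "low" for a in ann)

    def test_or_rule_is_disjunction_of_scd_scf(self):
        stages = ["N2"] * 10 + ["N3"] * 10
        h = Hypnogram(stages)
        feats = feature_table({f: 0.5 for f in SWR_FEATURES}, 20)  # swr inside
        ann_or = annotate(h, feats, swr_cal(), LEVEL1, rule="or")
        for a in ann_or:
            assert (a.label == "high") == bool(a.scd_vote or a.scf_vote)

    def test_level1_high_subset_of_level2(self, random_hypnogram_suite):
        cal = swr_cal()
        for stages in random_hypnogram_suite[:100]:
            h = Hypnogram(stages)
            feats = feature_table({f: 0.95 for f in SWR_FEATURES}, len(stages))
            high1 = {a.epoch_index for a in annotate(h, feats, cal, LEVEL1)
                     if a.label == "high"}
            high2 = {a.epoch_index for a in annotate(h, feats, cal, LEVEL2)
                     if a.label == "high"}
            assert high1 <= high2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            annotate(Hypnogram(["W"] * 5),
                     feature_table({}, 4), swr_cal(), LEVEL1)


def _low_ann(i):
    return ReliabilityAnnotation(i, 1, 9, 0, 0, 0)


def _high_ann(i):
    return ReliabilityAnnotation(i, 10, 0, 1, 1, 1)


class TestMergeRescored:
    def test_no_answers_returns_auto(self):
        auto = Hypnogram(["N2"] * 10)
        anns = [_low_ann(i) for i in range(10)]
        assert merge_rescored(auto, anns, {}) == auto

    def test_low_epochs_relabeled(self):
        auto = Hypnogram(["N2"] * 10)
        anns = [_low_ann(i) if i < 5 else _high_ann(i) for i in range(10)]
        out = merge_rescored(auto, anns, {0: "W", 4: "N3"})
        assert out.stages == ["W", "N2", "N2", "N2", "N3"] + ["N2"] * 5

    def test_strict_mode_rejects_high_reliability_answer(self):
        auto = Hypnogram(["N2"] * 4)
        anns = [_high_ann(i) for i in range(4)]
        with pytest.raises(ValueError, match="high-reliability"):
            merge_rescored(auto, anns, {1: "W"}, strict=True)
        out = merge_rescored(auto, anns, {1: "W"}, strict=False)
        assert out[1] == "W"

    def test_out_of_range_index(self):
        auto = Hypnogram(["N2"] * 4)
        anns = [_low_ann(i) for i in range(4)]
        with pytest.raises(ValueError):
            merge_rescored(auto, anns, {7: "W"})
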