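"""PSG agreement machinery: hypnogram collapse, 30s-to-15s alignment,
confusion metrics, PABAK, Landis-Koch bands, Bland-Altman, paired tests."""

import itertools
import math
from datetime import datetime, timedelta

import numpy as np
import pytest
from scipy import stats as sps

from actisleep.core import (
    AlignmentError,
    ConfusionTable,
    Hypnogram,
    SleepWakeSeries,
    ValidationError,
)
from actisleep.validation import (
    AlignedPairSeries,
    agreement_stats,
    align_to_15s,
    bland_altman,
    collapse_hypnogram,
    confusion_table,
    interpret_kappa,
    pabak,
    pabak_from_accuracy,
    paired_tests,
    per_subject_summary,
    psg_minute_labels,
)

T0 = datetime(2023, 6, 1, 22, 0)


def sw(asleep, epoch=15, start=T0):
    return SleepWakeSeries(
        subject_id="s1", start_time=start, epoch_length_s=epoch,
        asleep=np.asarray(asleep, dtype=bool), algorithm="test",
    )


def aligned(psg_bits, act_bits):
    return AlignedPairSeries(
        subject_id="s1", span_start=T0,
        span_end=T0 + timedelta(seconds=15 * len(psg_bits)),
        psg_asleep=np.asarray(psg_bits, dtype=bool),
        act_asleep=np.asarray(act_bits, dtype=bool),
    )


class TestCollapseHypnogram:
    def test_stage_dichotomy_and_onset_offset(self):
        h = Hypnogram("s", T0, ("W", "N1", "N2", "R", "W"))
        labels, onset, offset = collapse_hypnogram(h)
        assert list(labels.asleep) == [False, True, True, True, False]
        assert onset == T0 + timedelta(seconds=30)
        assert offset == T0 + timedelta(seconds=120)  # end of epoch 3

    def test_all_wake_is_an_error(self):
        with pytest.raises(ValidationError, match="no sleep"):
            collapse_hypnogram(Hypnogram("s", T0, ("W",) * 12))

    def test_all_sleep_spans_the_whole_recording(self):
        h = Hypnogram("s", T0, ("N2",) * 8)
        _, onset, offset = collapse_hypnogram(h)
        assert onset == T0
        assert offset == h.end_time

    def test_onset_respects_lights_out(self):
        h = Hypnogram(
            "s", T0, ("N2", "W", "N2", "N2"),
            lights_out=T0 + timedelta(seconds=30),
        )
        _, onset, _ = collapse_hypnogram(h)
        assert onset == T0 + timedelta(seconds=60)


class TestAlign:
    def test_duplication_of_psg_epochs(self):
        pairs = align_to_15s(sw([1, 0], epoch=30), sw([1, 1, 0, 0]))
        assert list(pairs.psg_asleep) == [True, True, False, False]
        assert list(pairs.act_asleep) == [True, True, False, False]
        assert len(pairs) == 4

    def test_late_actigraphy_trims_the_overlap(self):
        act = sw([1, 1, 0, 0, 0, 0], start=T0 + timedelta(seconds=30))
        pairs = align_to_15s(sw([1, 0, 0, 0], epoch=30), act)
        assert pairs.span_start == T0 + timedelta(seconds=30)
        assert len(pairs) == 6  # PSG epochs 2-4 duplicated

    def test_misaligned_grid_is_rejected(self):
        act = sw([1] * 8, start=T0 + timedelta(seconds=7))
        with pytest.raises(AlignmentError):
            align_to_15s(sw([1, 1], epoch=30), act)

    def test_disjoint_spans_are_rejected(self):
        act = sw([1] * 8, start=T0 + timedelta(hours=5))
        with pytest.raises(AlignmentError):
            align_to_15s(sw([1, 1], epoch=30), act)


class TestConfusionAndMetrics:
    def test_exhaustive_four_pair_count(self):
        t = confusion_table(aligned([1, 1, 0, 0], [1, 0, 0, 1]))
        assert (t.true_sleep, t.false_sleep, t.true_wake, t.false_wake) == (1, 1, 1, 1)

    def test_perfect_agreement(self):
        t = confusion_table(aligned([1, 1, 1, 0], [1, 1, 1, 0]))
        assert (t.true_sleep, t.false_sleep, t.true_wake, t.false_wake) == (3, 0, 1, 0)
        s = agreement_stats(t)
        assert (s.sensitivity_pct, s.specificity_pct, s.accuracy_pct) == (100, 100, 100)
        assert s.pabak == pytest.approx(1.0)

    def test_cells_conserve_pair_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 50))
            t = confusion_table(aligned(rng.random(n) < 0.8, rng.random(n) < 0.8))
            assert t.total == n

    def test_swapping_streams_swaps_false_cells_and_sens_spec(self):
        rng = np.random.default_rng(1)
        p, a = rng.random(60) < 0.7, rng.random(60) < 0.7
        t = confusion_table(aligned(p, a))
        t_swapped = confusion_table(aligned(a, p))
        assert t_swapped.false_sleep == t.false_wake
        assert t_swapped.false_wake == t.false_sleep
        s, s2 = agreement_stats(t), agreement_stats(t_swapped)
        assert s2.accuracy_pct == s.accuracy_pct

    def test_even_split_table(self):
        s = agreement_stats(ConfusionTable(1, 1, 1, 1))
        assert (s.sensitivity_pct, s.specificity_pct, s.accuracy_pct) == (50, 50, 50)
        assert s.pabak == pytest.approx(0.0)

    def test_missing_psg_wake_flags_specificity_undefined(self):
        s = agreement_stats(ConfusionTable(10, 0, 0, 2))
        assert s.specificity_pct is None
        assert s.sensitivity_pct is not None


class TestPabak:
    def test_observed_agreement_882_gives_0_76(self):
        value, _ = pabak(ConfusionTable(841, 59, 41, 59))  # p_o = 0.882
        assert value == pytest.approx(2 * 0.882 - 1)
        assert round(value, 2) == 0.76

    def test_perfect_and_chance_level(self):
        assert pabak(ConfusionTable(5, 0, 5, 0))[0] == pytest.approx(1.0)
        assert pabak(ConfusionTable(1, 1, 1, 1))[0] == pytest.approx(0.0)

    def test_identity_with_accuracy_for_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            cells = rng.integers(0, 500, size=4)
            if cells.sum() == 0:
                continue
            t = ConfusionTable(*map(int, cells))
            s = agreement_stats(t)
            assert s.pabak == pytest.approx(2 * s.accuracy_pct / 100 - 1, abs=1e-12)

    def test_ci_is_clipped_and_ordered(self):
        value, (lo, hi) = pabak(ConfusionTable(9, 0, 1, 0))
        assert -1.0 <= lo <= value <= hi <= 1.0

    def test_pabak_from_accuracy(self):
        assert pabak_from_accuracy(88.2) == pytest.approx(0.764)


class TestLandisKoch:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.76, "substantial agreement"),
            (0.81, "almost perfect agreement"),
            (0.0, "poor agreement"),
            (-0.4, "poor agreement"),
            (0.20, "slight agreement"),
            (0.21, "fair agreement"),
            (0.60, "moderate agreement"),
            (1.0, "almost perfect agreement"),
        ],
    )
    def test_band_edges(self, value, label):
        assert interpret_kappa(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            interpret_kappa(1.2)


class TestBlandAltman:
    def test_identical_vectors(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (ba.mean_diff, ba.sd_diff, ba.loa_low, ba.loa_high) == (0, 0, 0, 0)

    def test_hand_computed_limits(self):
        ba = bland_altman([0.0, 10.0, 30.0], [10.0, 10.0, 20.0])  # diffs -10,0,10
        assert ba.mean_diff == 0.0
        assert ba.sd_diff == pytest.approx(10.0)
        assert ba.loa_low == pytest.approx(-19.6)
        assert ba.loa_high == pytest.approx(19.6)

    def test_translation_shifts_bias_and_both_limits(self):
        rng = np.random.default_rng(2)
        dev, ref = rng.normal(600, 40, 12), rng.normal(590, 40, 12)
        base, shifted = bland_altman(dev, ref), bland_altman(dev + 25, ref)
        assert shifted.mean_diff == pytest.approx(base.mean_diff + 25)
        assert shifted.loa_low == pytest.approx(base.loa_low + 25)
        assert shifted.loa_high == pytest.approx(base.loa_high + 25)

    def test_single_pair_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0], [2.0])


class TestPairedTests:
    def test_zero_differences_flag_zero_variance(self):
        r = paired_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "paired_t")
        assert (r.statistic, r.p_value, r.zero_variance) == (0.0, 1.0, True)

    def test_t_statistic_against_closed_form_oracle(self):
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r = paired_tests(d, np.zeros(5), "paired_t")
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(5))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), df=4)
        assert r.statistic == pytest.approx(t_oracle)
        assert t_oracle == pytest.approx(4.2426, abs=1e-4)
        assert r.p_value == pytest.approx(p_oracle)
        assert p_oracle == pytest.approx(0.0132, abs=5e-4)

    def test_wilcoxon_symmetric_small_sample(self):
        # exact enumeration over all sign assignments at n=4: symmetric
        # differences put the statistic at its null mean, so exact p = 1
        d = np.array([-2.0, -1.0, 1.0, 2.0])
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        null = [
            sum(r for r, keep in zip(ranks, signs) if keep)
            for signs in itertools.product([False, True], repeat=4)
        ]
        mean_w = np.mean(null)
        p_exact = np.mean([abs(w - mean_w) >= abs(w_obs - mean_w) for w in null])
        assert p_exact == 1.0
        r = paired_tests(d, np.zeros(4), "wilcoxon_signed_rank")
        assert r.p_value > 0.8

    def test_wilcoxon_all_zero_differences(self):
        r = paired_tests([3.0, 3.0], [3.0, 3.0], "wilcoxon_signed_rank")
        assert r.p_value == 1.0 and r.zero_variance


class TestPerSubjectSummary:
    def test_single_subject_pooled_equals_subject_level(self):
        t = ConfusionTable(80, 5, 10, 5)
        out = per_subject_summary({"a": t}, seed=0)
        pooled, subj = out["pooled"], out["subject_mean"]
        assert pooled.accuracy_pct == subj.accuracy_pct
        assert subj.accuracy_ci[0] == pytest.approx(subj.accuracy_ci[1])

    def test_identical_subjects_leave_pooled_unchanged(self):
        t = ConfusionTable(80, 5, 10, 5)
        one = per_subject_summary({"a": t}, seed=0)["pooled"]
        two = per_subject_summary({"a": t, "b": t}, seed=0)["pooled"]
        assert one.accuracy_pct == two.accuracy_pct
        assert one.sensitivity_pct == two.sensitivity_pct

    def test_bootstrap_is_seed_reproducible(self):
        rng = np.random.default_rng(6)
        tables = {
            f"s{i}": ConfusionTable(*map(int, rng.integers(1, 200, 4)))
            for i in range(8)
        }
        a = per_subject_summary(tables, seed=42)["subject_mean"]
        b = per_subject_summary(tables, seed=42)["subject_mean"]
        assert a.sensitivity_ci == b.sensitivity_ci
        assert a.accuracy_ci == b.accuracy_ci


def test_psg_minute_collapse_wake_wins():
    labels = sw([1, 1, 1, 0, 0, 0, 1, 1], epoch=30)
    minutes = psg_minute_labels(labels)
    assert list(minutes.asleep) == [True, False, False, True]
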