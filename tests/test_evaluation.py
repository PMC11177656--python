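import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbrtqc.core_model import PerformanceReport, QualityRiskEvent, ValidationError
from pbrtqc.evaluation import (
    compute_anped,
    confusion_counts,
    event_metrics,
    label_stream,
    roc_auc_from_scores,
    select_optimal,
)
from pbrtqc.examples import worked_example_reports


def mann_whitney_auc(scores, labels):
    """Pairwise-concordance oracle: P(score_pos > score_neg) + 0.5 ties."""
    pos = scores[labels]
    neg = scores[~labels]
    gt = sum((p > n) for p in pos for n in neg)
    eq = sum((p == n) for p in pos for n in neg)
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def event(onset, closure, cause="x"):
    return QualityRiskEvent(cause, pd.Timestamp(onset), pd.Timestamp(closure), "fix")


class TestLabelStream:
    def test_onset_inclusive_closure_exclusive(self, stream_factory):
        stream = stream_factory([1.0] * 5, start="2022-06-01", freq="1D")
        ev = event("2022-06-02", "2022-06-04")
        labeled = label_stream(stream, [ev])
        assert labeled.labels.tolist() == [False, True, True, False, False]

    def test_no_events_all_negative(self, stream_factory):
        labeled = label_stream(stream_factory([1.0] * 4), [])
        assert not labeled.labels.any()
        assert labeled.n_negative == 4

    def test_overlap_resolves_to_earliest_onset(self, stream_factory):
        stream = stream_factory([1.0] * 6, start="2022-06-01", freq="1D")
        early = event("2022-06-01", "2022-06-05", "early")
        late = event("2022-06-03", "2022-06-06", "late")
        labeled = label_stream(stream, [late, early])  # declaration order irrelevant
        # events are indexed by position in the input list: early is index 1
        assert labeled.event_ids[2] == 1
        assert labeled.labels[:5].all()

    def test_labels_only_accepted_samples(self, stream_factory):
        import dataclasses

        stream = stream_factory([1.0] * 4, start="2022-06-01", freq="1D")
        stream.results[1] = dataclasses.replace(
            stream.results[1], excluded=True, exclusion_reason="truncated"
        )
        labeled = label_stream(stream, [event("2022-06-01", "2022-06-03")])
        assert len(labeled) == 3


class TestEventMetrics:
    def _labeled(self, stream_factory, n=10, windows=()):
        stream = stream_factory([1.0] * n, start="2022-06-01", freq="1D")
        return label_stream(stream, [event(a, b) for a, b in windows])

    def test_eight_of_nine_detected(self, stream_factory):
        # nine one-day windows over 30 days; alarm inside the first eight
        windows = [(f"2022-06-{d:02d}", f"2022-06-{d + 1:02d}") for d in range(1, 28, 3)]
        labeled = self._labeled(stream_factory, n=30, windows=windows)
        mask = np.zeros(30, dtype=bool)
        for k in range(8):
            mask[np.flatnonzero(labeled.event_ids == k)[0]] = True
        ped, fnr, _ = event_metrics(mask, labeled)
        assert ped == pytest.approx(100 * 8 / 9, abs=0.005)
        assert fnr == pytest.approx(100 - 100 * 8 / 9, abs=0.005)

    def test_sample_fpr(self, stream_factory):
        labeled = self._labeled(stream_factory, n=100, windows=())
        mask = np.zeros(100, dtype=bool)
        mask[:5] = True
        _, _, fpr = event_metrics(mask, labeled)
        assert fpr == pytest.approx(5.0)

    def test_zero_events_ped_undefined(self, stream_factory):
        labeled = self._labeled(stream_factory, n=10, windows=())
        ped, fnr, fpr = event_metrics(np.zeros(10, dtype=bool), labeled)
        assert ped is None and fnr is None and fpr == 0.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_ped_plus_fnr_is_100(self, seed):
        from conftest import make_stream

        rng = np.random.default_rng(seed)
        n = 60
        stream = make_stream(rng.uniform(1, 2, n), freq="1D")
        n_ev = rng.integers(1, 5)
        starts = np.sort(rng.integers(0, n - 2, n_ev))
        events = [
            event(
                pd.Timestamp("2022-01-01") + pd.Timedelta(days=int(s)),
                pd.Timestamp("2022-01-01") + pd.Timedelta(days=int(s) + 1 + int(rng.integers(0, 5))),
            )
            for s in starts
        ]
        labeled = label_stream(stream, events)
        mask = rng.random(n) < 0.3
        ped, fnr, _ = event_metrics(mask, labeled)
        assert ped + fnr == pytest.approx(100.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_confusion_conservation(self, seed):
        from conftest import make_stream

        rng = np.random.default_rng(seed)
        n = 50
        stream = make_stream(rng.uniform(1, 2, n), freq="1D")
        labeled = label_stream(stream, [event("2022-01-10", "2022-01-20")])
        mask = rng.random(n) < 0.4
        cc = confusion_counts(mask, labeled)
        assert cc.total == n
        assert cc.tp + cc.fn == labeled.n_positive
        assert cc.fp + cc.tn == labeled.n_negative


class TestAnped:
    def test_counts_from_onset_inclusive(self, stream_factory):
        stream = stream_factory([1.0] * 120, start="2022-06-01", freq="1h")
        ev = event("2022-06-02", "2022-06-05")
        labeled = label_stream(stream, [ev])
        window = np.flatnonzero(labeled.event_ids == 0)
        mask = np.zeros(120, dtype=bool)
        mask[window[7]] = True  # 8th in-window accepted sample
        assert compute_anped(mask, labeled) == 8

    def test_mean_over_detected_events(self, stream_factory):
        stream = stream_factory([1.0] * 40, start="2022-06-01", freq="1D")
        evs = [event("2022-06-05", "2022-06-15"), event("2022-06-20", "2022-06-30")]
        labeled = label_stream(stream, evs)
        mask = np.zeros(40, dtype=bool)
        mask[np.flatnonzero(labeled.event_ids == 0)[1]] = True  # 2 samples in
        mask[np.flatnonzero(labeled.event_ids == 1)[3]] = True  # 4 samples in
        assert compute_anped(mask, labeled) == 3

    def test_undefined_when_nothing_detected(self, stream_factory):
        stream = stream_factory([1.0] * 10, start="2022-06-01", freq="1D")
        labeled = label_stream(stream, [event("2022-06-02", "2022-06-05")])
        assert compute_anped(np.zeros(10, dtype=bool), labeled) is None


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.3, 5.0, 6.0, 7.0])
        labels = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        curve, auc = roc_auc_from_scores(scores, labels)
        assert auc == pytest.approx(1.0)
        assert (curve.points[0] == [0.0, 0.0]).all()
        assert (curve.points[-1] == [1.0, 1.0]).all()

    def test_curve_monotone(self):
        rng = np.random.default_rng(42)
        scores = rng.exponential(1.0, 300)
        labels = rng.random(300) < 0.4
        curve, _ = roc_auc_from_scores(scores, labels)
        assert np.all(np.diff(curve.points[:, 0]) >= 0)
        assert np.all(np.diff(curve.points[:, 1]) >= -1e-12)

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(7)
        scores = np.abs(rng.normal(0, 1, 10000))
        labels = np.zeros(10000, dtype=bool)
        labels[rng.permutation(10000)[:5000]] = True
        _, auc = roc_auc_from_scores(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_mann_whitney_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        scores = np.round(np.abs(rng.normal(0, 2, n)), 1)  # induce ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        _, auc = roc_auc_from_scores(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-9)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(8)
        scores = np.abs(rng.normal(0, 1, 500))
        labels = rng.random(500) < 0.3
        _, a1 = roc_auc_from_scores(scores, labels)
        _, a2 = roc_auc_from_scores(np.expm1(3.0 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(ValidationError):
            roc_auc_from_scores(np.ones(5), np.ones(5, dtype=bool))


class TestSelectOptimal:
    def test_worked_example_amh(self):
        sel = select_optimal(worked_example_reports("AMH"))["AMH"]
        assert not sel.provisional
        assert sel.selected.lam == 0.02
        assert sel.selected.arm == "bv_heuristic"

    def test_no_survivors_flagged_provisional(self):
        rows = [
            PerformanceReport("X", "traditional", 0.02, 50.0, 1.0, 50.0, 5, 0.95),
            PerformanceReport("X", "traditional", 0.03, 60.0, 1.0, 40.0, 5, 0.80),
        ]
        sel = select_optimal(rows)["X"]
        assert sel.provisional
        assert sel.selected.auc == 0.95  # best AUC still reported

    def test_auc_tie_prefers_smaller_lambda(self):
        rows = [
            PerformanceReport("X", "traditional", 0.05, 95.0, 1.0, 5.0, 5, 0.9),
            PerformanceReport("X", "traditional", 0.02, 95.0, 1.0, 5.0, 5, 0.9),
        ]
        sel = select_optimal(rows)["X"]
        assert sel.selected.lam == 0.02

    def test_boundary_values_excluded(self):
        # ped must exceed 90 and fpr must be under 5, strictly
        rows = [
            PerformanceReport("X", "traditional", 0.02, 90.0, 1.0, 10.0, 5, 0.99),
            PerformanceReport("X", "traditional", 0.03, 95.0, 5.0, 5.0, 5, 0.99),
            PerformanceReport("X", "traditional", 0.05, 91.0, 4.9, 9.0, 5, 0.5),
        ]
        sel = select_optimal(rows)["X"]
        assert not sel.provisional and sel.selected.lam == 0.05
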