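import numpy as np
import pytest
from lifelines.utils import concordance_index as lifelines_cindex

from bifuse import evaluation as ev
from bifuse.evaluation import (
    ConfusionCounts,
    PreprocessConfig,
    classification_metrics,
    concordance_index,
    confusion,
    cross_validate,
    kaplan_meier,
    logrank,
    metrics_at_specificity,
    roc_auc,
)
from bifuse.io import make_folds
from bifuse.preprocess import derive_labels
from bifuse.simulate import SimConfig, generate
from conftest import tiny_config


def pair_counting_auc(scores, labels):
    """Independent AUC oracle: (concordant + ties/2) / (n_pos * n_neg)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    num = 0.0
    for sp in pos:
        for sn in neg:
            num += 1.0 if sp > sn else 0.5 if sp == sn else 0.0
    return num / (len(pos) * len(neg))


def brute_force_cindex(scores, times, events):
    """Independent C-index oracle by explicit pair enumeration."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


class TestConfusion:
    def test_hand_tally(self):
        scores = np.array([0.9, 0.8, 0.4, 0.6, 0.2, 0.7, 0.1, 0.3, 0.55, 0.45])
        labels = np.array([1, 1, 1, 0, 0, 1, 0, 1, 0, 0])
        c = confusion(scores, labels)
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 2, 2, 3)
        assert c.total == 10

    def test_perfect_scores(self):
        c = confusion(np.array([1.0, 1.0, 0.0]), np.array([1, 1, 0]))
        assert c.fp == 0 and c.fn == 0

    def test_all_negative_calls(self):
        c = confusion(np.zeros(4), np.array([1, 1, 0, 0]), threshold=0.5)
        assert c.tp == 0 and c.fn == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([]), np.array([]))


class TestClassificationMetrics:
    def test_worked_example(self):
        m = classification_metrics(ConfusionCounts(tp=9, fn=1, tn=8, fp=2))
        assert m["sn"] == pytest.approx(0.9)
        assert m["sp"] == pytest.approx(0.8)
        assert m["acc"] == pytest.approx(0.85)
        assert m["pre"] == pytest.approx(9 / 11)
        assert m["f1"] == pytest.approx(2 * (9 / 11) * 0.9 / (9 / 11 + 0.9))

    def test_perfect_classifier_all_ones(self):
        m = classification_metrics(ConfusionCounts(tp=5, fn=0, tn=5, fp=0))
        assert all(m[k] == 1.0 for k in ("sn", "sp", "acc", "pre", "f1"))

    def test_undefined_precision_is_nan_not_zero(self):
        m = classification_metrics(ConfusionCounts(tp=0, fn=3, tn=4, fp=0))
        assert np.isnan(m["pre"]) and np.isnan(m["f1"])

    def test_f1_is_harmonic_mean_of_pre_and_sn(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 20, size=4)
            m = classification_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            if not (np.isnan(m["pre"]) or np.isnan(m["sn"]) or m["pre"] + m["sn"] == 0):
                assert m["f1"] == pytest.approx(
                    2 * m["pre"] * m["sn"] / (m["pre"] + m["sn"])
                )


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        _, auc = roc_auc(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0]))
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.random(n), 2)  # induces ties
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                labels[:2] = [0, 1]
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-10)

    def test_permutation_invariance(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        perm = rng.permutation(30)
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(scores[perm], labels[perm])
        assert a1 == pytest.approx(a2)


class TestOperatingPoints:
    def test_perfect_separation_keeps_full_sensitivity(self):
        out = metrics_at_specificity(
            np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]), 0.95
        )
        assert out["sn"] == 1.0
        assert out["achieved_sp"] == 1.0

    def test_zero_target_is_degenerate(self):
        out = metrics_at_specificity(
            np.array([0.9, 0.1, 0.5, 0.7]), np.array([1, 0, 0, 1]), 0.0
        )
        assert out["sn"] == 1.0

    def test_matches_exhaustive_threshold_sweep(self, rng):
        scores = np.round(rng.random(20), 2)
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        for target in (0.90, 0.95):
            out = metrics_at_specificity(scores, labels, target)
            # brute force: smallest threshold with Sp >= target
            best = None
            for thr in sorted(np.concatenate([np.unique(scores), [2.0]])):
                c = confusion(scores, labels, thr)
                if c.tn / (c.tn + c.fp) >= target:
                    best = thr
                    break
            assert out["threshold"] == pytest.approx(best)


class TestConcordance:
    def test_perfect_risk_ranking(self):
        times = np.array([10.0, 20, 30, 40])
        scores = np.array([0.9, 0.7, 0.4, 0.1])  # higher risk, shorter survival
        assert concordance_index(scores, times, np.ones(4, dtype=int)) == 1.0

    def test_toy_censored_case_equals_pair_enumeration(self):
        scores = np.array([0.8, 0.6, 0.55, 0.3, 0.2])
        times = np.array([12.0, 25.0, 25.0, 40.0, 60.0])
        events = np.array([1, 0, 1, 1, 0])
        expected = brute_force_cindex(scores, times, events)
        assert concordance_index(scores, times, events) == pytest.approx(expected)

    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 25))
            scores = np.round(rng.random(n), 1)
            times = np.round(rng.exponential(50, n), 0) + 1
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                events[0] = 1
            try:
                ours = concordance_index(scores, times, events)
            except ValueError:
                continue  # no admissible pairs in this draw
            assert ours == pytest.approx(brute_force_cindex(scores, times, events))

    def test_agrees_with_lifelines(self, rng):
        n = 60
        scores = rng.random(n)
        times = rng.exponential(50, n) + 1
        events = rng.integers(0, 2, size=n)
        # lifelines counts concordance of predicted *survival*, so negate risk
        theirs = lifelines_cindex(times, -scores, events)
        assert concordance_index(scores, times, events) == pytest.approx(theirs)

    def test_random_scores_near_half(self, rng):
        n = 2000
        scores = rng.random(n)
        times = rng.exponential(50, n) + 1
        events = rng.integers(0, 2, size=n)
        assert 0.45 < concordance_index(scores, times, events) < 0.55

    def test_no_admissible_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_index(np.array([0.1, 0.2]), np.array([5.0, 6.0]), np.array([0, 0]))


class TestSurvivalCurves:
    def test_no_events_constant_survival(self):
        curve = kaplan_meier(np.array([10.0, 20, 30]), np.array([0, 0, 0]))
        assert (curve[:, 1] == 1.0).all()

    def test_textbook_product_limit_values(self):
        # events at 6, 10, 15; censored at 8, 12
        times = np.array([6.0, 8.0, 10.0, 12.0, 15.0])
        events = np.array([1, 0, 1, 0, 1])
        curve = dict(zip(*kaplan_meier(times, events).T.tolist()))
        assert curve[6.0] == pytest.approx(4 / 5)
        assert curve[10.0] == pytest.approx(4 / 5 * 2 / 3)
        assert curve[15.0] == pytest.approx(0.0)

    def test_identical_groups_null_logrank(self):
        times = np.array([5.0, 10, 15, 20])
        events = np.array([1, 1, 0, 1])
        stat, p = logrank(times, events, times, events)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_clearly_separated_groups_small_p(self, rng):
        t_short = rng.exponential(5, 60) + 0.1
        t_long = rng.exponential(100, 60) + 0.1
        stat, p = logrank(t_short, np.ones(60, int), t_long, np.ones(60, int))
        assert p < 1e-6


@pytest.fixture(scope="module")
def cv_run():
    cohort = generate(SimConfig(n=80, l=6, gamma_inter=0.4, censor_rate=0.1, seed=3))
    summary = derive_labels(cohort.records)
    records = summary.records
    ids = [r.patient_id for r in records]
    g = cohort.g_matrix.subset_samples(ids)
    p = cohort.p_matrix.subset_samples(ids)
    folds = make_folds(records, k=4, seed=0)
    cfg = tiny_config(l=6, epochs=3)
    pcfg = PreprocessConfig(top_k=6)
    pooled, report, fold_reports = cross_validate(g, p, records, cfg, folds, pcfg)
    return records, folds, pooled, report, fold_reports


class TestCrossValidation:
    def test_every_patient_scored_exactly_once(self, cv_run):
        records, _, pooled, _, _ = cv_run
        assert sorted(pooled.patient_ids) == sorted(r.patient_id for r in records)

    def test_pooled_metrics_equal_recomputation_from_concatenated_scores(self, cv_run):
        records, _, pooled, report, _ = cv_run
        _, auc = roc_auc(pooled.scores, pooled.labels)
        assert report.auc == pytest.approx(auc)
        by_id = {r.patient_id: r for r in records}
        times = np.array([by_id[p].time for p in pooled.patient_ids])
        events = np.array([by_id[p].event for p in pooled.patient_ids])
        assert report.c_index == pytest.approx(
            concordance_index(pooled.scores, times, events)
        )

    def test_fold_ids_respect_assignment(self, cv_run):
        _, folds, pooled, _, _ = cv_run
        for pid, f in zip(pooled.patient_ids, pooled.folds):
            assert folds.assignment[pid] == f

    def test_report_carries_operating_points_and_fold_means(self, cv_run):
        _, _, _, report, fold_reports = cv_run
        assert set(report.operating_points) == {"0.90", "0.95"}
        assert "fold_mean_auc" in report.extras
        assert report.extras["fold_mean_auc"] == pytest.approx(
            np.mean([r.auc for r in fold_reports])
        )
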