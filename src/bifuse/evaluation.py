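"""Survival-aware evaluation: confusion metrics, ROC/AUC, Harrell's C-index,
fixed-specificity operating points, Kaplan-Meier / log-rank, and the pooled
k-fold cross-validation protocol.

The cross-validation protocol pools the out-of-fold prediction scores from
every test split into one set (each patient scored exactly once) and computes
all metrics on that pooled set; per-fold metrics and their means are reported
alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import preprocess as pp
from .io import FeatureMatrix, FoldAssignment, SurvivalRecord
from .network import ModelConfig, PredictionSet, build_model, predict, train

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "classification_metrics",
    "roc_auc",
    "metrics_at_specificity",
    "concordance_index",
    "kaplan_meier",
    "logrank",
    "PreprocessConfig",
    "fit_fold_pipeline",
    "cross_validate",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the 2x2 table; positive call iff score >= threshold.

    Positive class = label 1 = shorter-term survivor.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("no samples to tally")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    calls = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((calls & pos).sum()),
        tn=int((~calls & ~pos).sum()),
        fp=int((calls & ~pos).sum()),
        fn=int((~calls & pos).sum()),
    )


def _ratio(num: int, den: int) -> float:
    """A metric ratio; NaN marks an undefined (zero-denominator) value."""
    return num / den if den > 0 else float("nan")


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sn, Sp, Acc, Pre and F1 from confusion counts.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total, Pre = TP/(TP+FP),
    F1 = harmonic mean of Pre and Sn.  Undefined ratios are NaN, never 0.
    """
    sn = _ratio(c.tp, c.tp + c.fn)
    sp = _ratio(c.tn, c.tn + c.fp)
    acc = _ratio(c.tp + c.tn, c.total)
    pre = _ratio(c.tp, c.tp + c.fp)
    if np.isnan(pre) or np.isnan(sn) or (pre + sn) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * pre * sn / (pre + sn)
    return {"sn": sn, "sp": sp, "acc": acc, "pre": pre, "f1": f1}


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve (threshold, FPR, TPR rows) and trapezoidal AUC.

    Equals the Mann-Whitney concordance probability of scores for positives
    versus negatives, with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    curve = np.column_stack([thresholds, fpr, tpr])
    return curve, auc


def metrics_at_specificity(scores, labels, sp_target: float) -> dict[str, float]:
    """Operating-point metrics at a stringent specificity level (e.g. 0.90, 0.95).

    Chooses the smallest threshold whose specificity is >= sp_target and
    reports Sn/Acc/Pre/F1 there, together with the achieved specificity and
    the threshold itself.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_neg = int((labels == 0).sum())
    if n_neg == 0 or (labels == 1).sum() == 0:
        raise ValueError("operating point needs both classes present")
    best = None
    # candidate thresholds: all unique scores plus one above the maximum
    candidates = np.concatenate([np.unique(scores), [scores.max() + 1.0]])
    for thr in candidates:
        c = confusion(scores, labels, threshold=thr)
        sp = c.tn / (c.tn + c.fp)
        if sp >= sp_target:
            best = (thr, c)
            break
    if best is None:
        raise ValueError(f"specificity target {sp_target} is unattainable")
    thr, c = best
    out = classification_metrics(c)
    out["threshold"] = float(thr)
    out["achieved_sp"] = c.tn / (c.tn + c.fp)
    return out


def concordance_index(scores, times, events) -> float:
    """Harrell's concordance index of a risk score against censored survival.

    A pair (i, j) is admissible when the shorter observed time carries an
    event (the earlier patient is known to have died first).  It is
    concordant when that patient has the higher risk score; score ties count
    1/2.  0.5 is an uninformative ranking, 1.0 a perfect one.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (len(scores) == len(times) == len(events)):
        raise ValueError("scores, times and events must be aligned")
    # pair (i, j): admissible iff t_i < t_j and event_i == 1
    ti = times[:, None]
    tj = times[None, :]
    admissible = (ti < tj) & (events[:, None] == 1)
    si = scores[:, None]
    sj = scores[None, :]
    concordant = (admissible & (si > sj)).sum()
    tied = (admissible & (si == sj)).sum()
    n_pairs = admissible.sum()
    if n_pairs == 0:
        raise ValueError("no admissible pairs (all censored or all times tied)")
    return float((concordant + 0.5 * tied) / n_pairs)


def kaplan_meier(times, events) -> np.ndarray:
    """Product-limit survival estimate; rows are (time, survival probability)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty group")
    km = KaplanMeierFitter()
    km.fit(times, event_observed=events)
    sf = km.survival_function_
    return np.column_stack([sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy()])


def logrank(
    times_a, events_a, times_b, events_b
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic with 1 df, p-value)."""
    if len(np.asarray(times_a)) == 0 or len(np.asarray(times_b)) == 0:
        raise ValueError("empty group")
    res = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class MetricsReport:
    """Everything reported for one evaluation (pooled or per fold)."""

    sn: float
    sp: float
    acc: float
    pre: float
    f1: float
    auc: float
    c_index: float
    operating_points: dict[str, dict[str, float]]
    logrank_p: float
    logrank_stat: float
    n: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "pre": self.pre,
            "f1": self.f1,
            "auc": self.auc,
            "c_index": self.c_index,
            "operating_points": self.operating_points,
            "logrank_p": self.logrank_p,
            "logrank_stat": self.logrank_stat,
            "n": self.n,
        }
        d.update(self.extras)
        return d


def evaluate_predictions(
    pred: PredictionSet,
    records: list[SurvivalRecord],
    threshold: float = 0.5,
    sp_targets: tuple[float, ...] = (0.90, 0.95),
) -> MetricsReport:
    """All metrics for one prediction set (survival joined by patient id)."""
    by_id = {r.patient_id: r for r in records}
    times = np.array([by_id[p].time for p in pred.patient_ids])
    events = np.array([by_id[p].event for p in pred.patient_ids])
    cls = classification_metrics(confusion(pred.scores, pred.labels, threshold))
    _, auc = roc_auc(pred.scores, pred.labels)
    cindex = concordance_index(pred.scores, times, events)
    ops = {}
    for tgt in sp_targets:
        try:
            ops[f"{tgt:.2f}"] = metrics_at_specificity(pred.scores, pred.labels, tgt)
        except ValueError:
            ops[f"{tgt:.2f}"] = {}
    # risk-group split at the pooled median score for the log-rank comparison
    median = float(np.median(pred.scores))
    high = pred.scores >= median
    if high.all() or (~high).all():
        stat, p = float("nan"), float("nan")
    else:
        stat, p = logrank(times[high], events[high], times[~high], events[~high])
    return MetricsReport(
        sn=cls["sn"], sp=cls["sp"], acc=cls["acc"], pre=cls["pre"], f1=cls["f1"],
        auc=auc, c_index=cindex, operating_points=ops,
        logrank_p=p, logrank_stat=stat, n=len(pred.scores),
    )


@dataclass
class PreprocessConfig:
    """Per-fold preprocessing knobs (see the preprocess module)."""

    na_threshold: float = 0.10
    z_lo: float = -1.0
    z_hi: float = 1.0
    top_k: int = 32
    fit_scope: str = "train_fold"  # or "full_cohort"
    discretize: bool = True

    def __post_init__(self) -> None:
        if self.fit_scope not in ("train_fold", "full_cohort"):
            raise ValueError(f"unknown fit_scope {self.fit_scope!r}")


def fit_fold_pipeline(m: FeatureMatrix, labels: np.ndarray, cfg: PreprocessConfig):
    """Fit the NA-filter/impute/z-score/discretize/rank/select chain on one matrix."""
    m = pp.drop_high_missing_features(m, cfg.na_threshold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        means = np.nanmean(m.values, axis=0)
    m = pp.impute_missing(m, means)
    stats = pp.zscore_fit(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        z = pp.zscore_apply(m, stats)
    d = pp.discretize(z, cfg.z_lo, cfg.z_hi) if cfg.discretize else z
    ranking = pp.rank_features(d, labels)
    top_k = min(cfg.top_k, d.n_features)
    selected = pp.select_top_features(d, ranking, top_k)

    def apply(test: FeatureMatrix) -> FeatureMatrix:
        t = test.subset_features(m.feature_ids)
        t = pp.impute_missing(t, means)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            tz = pp.zscore_apply(t, stats)
        td = pp.discretize(tz, cfg.z_lo, cfg.z_hi) if cfg.discretize else tz
        return td.subset_features(selected.feature_ids)

    return selected, apply


def cross_validate(
    g_matrix: FeatureMatrix,
    p_matrix: FeatureMatrix,
    records: list[SurvivalRecord],
    config: ModelConfig,
    folds: FoldAssignment,
    preprocess_config: PreprocessConfig | None = None,
) -> tuple[PredictionSet, MetricsReport, list[MetricsReport]]:
    """Pooled k-fold cross-validation of one model variant.

    Per fold: fit preprocessing on the training split only (unless
    ``fit_scope='full_cohort'``), train the model, and score the held-out
    split.  The pooled out-of-fold scores (each patient exactly once) feed
    every pooled metric; per-fold reports are returned as well.
    """
    pcfg = preprocess_config or PreprocessConfig()
    by_id = {r.patient_id: r for r in records}
    if any(r.label is None for r in records):
        raise ValueError("cross_validate requires derived labels (see derive_labels)")

    full_g = full_p = None
    if pcfg.fit_scope == "full_cohort":
        ids = [r.patient_id for r in records]
        y_all = np.array([by_id[p].label for p in ids], dtype=int)
        sel_g, apply_g = fit_fold_pipeline(g_matrix.subset_samples(ids), y_all, pcfg)
        sel_p, apply_p = fit_fold_pipeline(p_matrix.subset_samples(ids), y_all, pcfg)
        full_g, full_p = (sel_g, apply_g), (sel_p, apply_p)

    pooled_ids: list[str] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    pooled_folds: list[np.ndarray] = []
    fold_reports: list[MetricsReport] = []

    for fold in range(folds.k):
        test_ids = [r.patient_id for r in records if folds.assignment[r.patient_id] == fold]
        train_ids = [r.patient_id for r in records if folds.assignment[r.patient_id] != fold]
        y_train = np.array([by_id[p].label for p in train_ids], dtype=int)
        y_test = np.array([by_id[p].label for p in test_ids], dtype=int)
        if len(np.unique(y_train)) < 2:
            warnings.warn(f"fold {fold}: single-class training labels", stacklevel=2)

        if pcfg.fit_scope == "full_cohort":
            (sel_g, apply_g), (sel_p, apply_p) = full_g, full_p
            g_train = apply_g(g_matrix.subset_samples(train_ids))
            p_train = apply_p(p_matrix.subset_samples(train_ids))
        else:
            g_train, apply_g = fit_fold_pipeline(
                g_matrix.subset_samples(train_ids), y_train, pcfg
            )
            p_train, apply_p = fit_fold_pipeline(
                p_matrix.subset_samples(train_ids), y_train, pcfg
            )
        g_test = apply_g(g_matrix.subset_samples(test_ids))
        p_test = apply_p(p_matrix.subset_samples(test_ids))

        fold_cfg = ModelConfig(
            **{**config.__dict__, "l": g_train.n_features, "seed": config.seed + fold}
        )
        model = build_model(fold_cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = train(model, g_train.values, p_train.values, y_train)
        pred = predict(
            model, g_test.values, p_test.values,
            patient_ids=test_ids, labels=y_test, fold=fold,
        )
        pooled_ids.extend(test_ids)
        pooled_scores.append(pred.scores)
        pooled_labels.append(y_test)
        pooled_folds.append(np.full(len(test_ids), fold))
        try:
            fold_reports.append(evaluate_predictions(pred, records))
        except ValueError:
            pass  # degenerate fold (single class in test split)

    pooled = PredictionSet(
        patient_ids=pooled_ids,
        scores=np.concatenate(pooled_scores),
        labels=np.concatenate(pooled_labels),
        folds=np.concatenate(pooled_folds),
    )
    report = evaluate_predictions(pooled, records)
    if fold_reports:
        report.extras["fold_mean_auc"] = float(np.mean([r.auc for r in fold_reports]))
        report.extras["fold_mean_c_index"] = float(np.mean([r.c_index for r in fold_reports]))
    return pooled, report, fold_reports
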