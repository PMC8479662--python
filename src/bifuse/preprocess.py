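"""Preprocessing chain for the two feature modalities.

Label derivation from follow-up (5-year rule), missing-value filtering and
imputation, z-score normalization, ternary discretization, tile-density
scoring for histology image patches, and information-gain feature ranking
with top-k selection.

All fit/apply pairs (normalization statistics, feature ranking) are split so
that inside cross-validation they can be fitted on training folds only; a
``fit_scope`` of ``full_cohort`` is available for protocols that preprocess
once before splitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import FeatureMatrix, SurvivalRecord

__all__ = [
    "LabelSummary",
    "NormStats",
    "FeatureRanking",
    "derive_labels",
    "drop_high_missing_features",
    "impute_missing",
    "zscore_fit",
    "zscore_apply",
    "discretize",
    "load_tile",
    "tile_density",
    "select_densest_tiles",
    "rank_features",
    "select_top_features",
]

HORIZON_MONTHS = 60.0


@dataclass
class LabelSummary:
    """Outcome of label derivation: labelled records plus explicit exclusions."""

    records: list[SurvivalRecord]
    excluded: list[SurvivalRecord]

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def derive_labels(
    records: list[SurvivalRecord], horizon: float = HORIZON_MONTHS
) -> LabelSummary:
    """Assign the binary 5-year prognosis label.

    label 1 (shorter-term / poor prognosis): death observed before ``horizon``.
    label 0 (longer-term): follow-up reaches ``horizon`` alive or not.
    Patients censored before the horizon have indeterminable 5-year status and
    are excluded — returned separately, never silently dropped.
    """
    kept: list[SurvivalRecord] = []
    excluded: list[SurvivalRecord] = []
    for r in records:
        if r.time >= horizon:
            kept.append(SurvivalRecord(r.patient_id, r.time, r.event, 0))
        elif r.event == 1:
            kept.append(SurvivalRecord(r.patient_id, r.time, r.event, 1))
        else:
            excluded.append(r)
    return LabelSummary(records=kept, excluded=excluded)


def drop_high_missing_features(
    m: FeatureMatrix, max_na_fraction: float = 0.10
) -> FeatureMatrix:
    """Delete features missing in strictly more than ``max_na_fraction`` of samples.

    Mirrors the 10%-NA gene filter: a feature with missing fraction exactly at
    the threshold is kept.  Surviving missing entries are NOT imputed here;
    see :func:`impute_missing`.
    """
    if not (0 <= max_na_fraction < 1):
        raise ValueError(f"max_na_fraction must be in [0, 1), got {max_na_fraction}")
    na_frac = np.isnan(m.values).mean(axis=0)
    keep = na_frac <= max_na_fraction
    if not keep.any():
        raise ValueError("all features exceed the missingness threshold")
    kept_ids = [f for f, k in zip(m.feature_ids, keep) if k]
    return FeatureMatrix(m.sample_ids, kept_ids, m.values[:, keep], m.modality)


def impute_missing(m: FeatureMatrix, feature_means: np.ndarray | None = None) -> FeatureMatrix:
    """Fill remaining NA cells with the per-feature mean.

    ``feature_means`` fitted on a training fold may be supplied to avoid
    leakage; defaults to the matrix's own column means (ignoring NA).
    """
    if feature_means is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NA columns
            feature_means = np.nanmean(m.values, axis=0)
    feature_means = np.asarray(feature_means, dtype=float)
    if np.isnan(feature_means).any():
        bad = m.feature_ids[int(np.flatnonzero(np.isnan(feature_means))[0])]
        raise ValueError(f"feature {bad!r} has no observed values to impute from")
    values = np.where(np.isnan(m.values), feature_means[None, :], m.values)
    return FeatureMatrix(m.sample_ids, m.feature_ids, values, m.modality)


@dataclass
class NormStats:
    """Per-feature mean and population standard deviation for z-scoring."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have equal length")
        if (self.sd < 0).any():
            raise ValueError("standard deviation must be >= 0")


def zscore_fit(m: FeatureMatrix) -> NormStats:
    """Fit per-feature mean and population sd. Requires a complete matrix."""
    if np.isnan(m.values).any():
        raise ValueError("impute missing values before z-scoring")
    return NormStats(mean=m.values.mean(axis=0), sd=m.values.std(axis=0, ddof=0))


def zscore_apply(m: FeatureMatrix, stats: NormStats) -> FeatureMatrix:
    """Standardize each feature with the fitted statistics.

    Zero-variance features map to all-zeros (with a warning) rather than NaN.
    """
    if len(stats.mean) != m.n_features:
        raise ValueError("statistics length does not match feature count")
    zero = stats.sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature(s) mapped to all-zeros",
            stacklevel=2,
        )
    sd = np.where(zero, 1.0, stats.sd)
    values = (m.values - stats.mean[None, :]) / sd[None, :]
    values[:, zero] = 0.0
    return FeatureMatrix(m.sample_ids, m.feature_ids, values, m.modality)


def discretize(m: FeatureMatrix, lo: float = -1.0, hi: float = 1.0) -> FeatureMatrix:
    """Ternarize z-scored values: under-expression (-1), baseline (0), over-expression (1).

    Strict thresholds: v > hi -> 1, v < lo -> -1, otherwise 0 (boundary values
    are baseline).
    """
    if lo >= hi:
        raise ValueError(f"lo must be < hi, got lo={lo}, hi={hi}")
    values = np.where(m.values > hi, 1.0, np.where(m.values < lo, -1.0, 0.0))
    return FeatureMatrix(m.sample_ids, m.feature_ids, values, m.modality)


def load_tile(path) -> np.ndarray:
    """Read an image tile (PNG/TIFF, 8-bit) as an (H, W, 3) RGB array."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def tile_density(img: np.ndarray) -> float:
    """Tissue density of an image tile: fraction of non-white pixels.

    A pixel is non-white when all of R, G, B are strictly below 200 in 8-bit
    RGB.  Accepts an (H, W, 3) uint8 array (e.g. ``numpy.asarray(PIL.Image)``).
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty raster")
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {img.shape}")
    dark = (img[:, :, :3] < 200).all(axis=2)
    return float(dark.mean())


def select_densest_tiles(
    tiles: list[tuple[str, float]], n: int = 10
) -> list[str]:
    """Keep the n densest tiles of a series; ties broken by id order."""
    for tid, d in tiles:
        if not (0 <= d <= 1):
            raise ValueError(f"tile {tid!r}: density {d} outside [0, 1]")
    if len(tiles) < n:
        warnings.warn(
            f"only {len(tiles)} tiles available, fewer than requested {n}; keeping all",
            stacklevel=2,
        )
    ranked = sorted(tiles, key=lambda t: (-t[1], t[0]))
    return [tid for tid, _ in ranked[:n]]


@dataclass
class FeatureRanking:
    """Features ordered by informativeness score, descending."""

    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(not np.isfinite(s) or s < 0 for s in scores):
            raise ValueError("ranking scores must be finite and >= 0")

    @property
    def feature_ids(self) -> list[str]:
        return [f for f, _ in self.entries]


def _entropy(counts: np.ndarray) -> float:
    """Natural-log entropy of a count vector."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def information_gain(x: np.ndarray, y: np.ndarray) -> float:
    """Information gain of binary labels y given a discrete feature x.

    IG = H(Y) - sum_v p(x=v) H(Y | x=v), entropy in nats.
    """
    x = np.asarray(x)
    y = np.asarray(y, dtype=int)
    h_y = _entropy(np.bincount(y))
    cond = 0.0
    n = len(y)
    for v in np.unique(x):
        mask = x == v
        cond += mask.sum() / n * _entropy(np.bincount(y[mask]))
    gain = h_y - cond
    return max(gain, 0.0)  # clamp -0.0 / rounding noise


def rank_features(m: FeatureMatrix, labels: np.ndarray) -> FeatureRanking:
    """Rank discretized features by information gain of the prognosis label.

    Descending by score; ties broken lexicographically by feature id so the
    ranking is deterministic.  With single-class labels every score is 0.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != m.n_samples:
        raise ValueError("labels must align with the matrix's samples")
    if len(np.unique(labels)) < 2:
        warnings.warn("labels contain a single class; all scores are 0", stacklevel=2)
        entries = sorted((f, 0.0) for f in m.feature_ids)
        return FeatureRanking(entries)
    scored = [
        (f, information_gain(m.values[:, j], labels)) for j, f in enumerate(m.feature_ids)
    ]
    scored.sort(key=lambda e: (-e[1], e[0]))
    return FeatureRanking(scored)


def select_top_features(m: FeatureMatrix, r: FeatureRanking, n: int = 32) -> FeatureMatrix:
    """Restrict the matrix to the n top-ranked features, in ranking order."""
    if n > m.n_features:
        raise ValueError(f"cannot select {n} features from {m.n_features}")
    return m.subset_features(r.feature_ids[:n])
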