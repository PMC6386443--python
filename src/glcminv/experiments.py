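"""Cross-quantization classification experiments.

The experiments quantify how well logistic-regression classifiers built on
texture features transfer between gray-level quantizations:

* **Random-quantization training** -- many classifiers are trained, each
  with every training image quantized to an independently random number of
  gray-levels, then evaluated on the test set at every quantization.  The
  mean and standard deviation of the accuracy per test quantization show
  how robust a feature set is when training data mix quantizations.

* **Fixed-quantization training** -- one classifier per training
  quantization, with greedy forward feature selection on a validation
  set, evaluated on the test set at every quantization.  The resulting
  train-by-test accuracy heatmap has high off-diagonal values only if the
  features transfer across quantizations.

Features computed from the invariant (density) GLCM normalization are
approximately quantization-independent, so both experiments favor them
over the original PMF features whenever the train and test quantizations
differ.

Classifiers are logistic regressions with a weak ridge penalty, fit on
z-scored features (training-set statistics); both choices are for
numerical stability since original-variant features span many orders of
magnitude across quantizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .features import DEFAULT_FEATURE_NAMES, compute_all
from .glcm import QuantizationSpec, cooccurrence_counts, normalize_density, normalize_pmf, quantize, standard_offsets
from .synthetic import TextureSampleSet

__all__ = [
    "SweepConfig",
    "AccuracyGrid",
    "feature_table",
    "forward_select",
    "scenario_random_quantization",
    "scenario_fixed_quantization",
]

DEFAULT_QUANTIZATIONS = tuple(range(8, 257, 8))


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a quantization sweep and classification run.

    ``limits`` are the global lower/upper quantization limits shared by
    every image in the dataset; fixed global limits keep the gray-level
    mapping comparable across images.  ``split`` gives the
    train/validation/test fractions; the random-quantization scenario
    merges validation into test (it performs no feature selection).
    """

    quantizations: Tuple[int, ...] = DEFAULT_QUANTIZATIONS
    variant: str = "invariant"
    limits: Tuple[float, float] = (-4.0, 4.0)
    split: Tuple[float, float, float] = (0.5, 0.25, 0.25)
    n_models: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        q = tuple(int(v) for v in self.quantizations)
        object.__setattr__(self, "quantizations", q)
        if any(b <= a for a, b in zip(q, q[1:])) or any(v < 2 for v in q):
            raise ValueError("quantizations must be strictly increasing integers >= 2")
        if self.variant not in ("original", "invariant"):
            raise ValueError(f"variant must be 'original' or 'invariant', got {self.variant!r}")
        if not self.limits[1] > self.limits[0]:
            raise ValueError("upper limit must exceed lower limit")
        if abs(sum(self.split) - 1.0) > 1e-9 or any(f < 0 for f in self.split):
            raise ValueError("split fractions must be non-negative and sum to 1")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


@dataclass(frozen=True)
class AccuracyGrid:
    """Mean (and optionally std) accuracy per training x test quantization."""

    train_levels: Tuple[Union[int, str], ...]
    test_levels: Tuple[int, ...]
    mean: np.ndarray
    std: Optional[np.ndarray]
    baseline: float

    def off_diagonal_mean(self) -> float:
        """Mean accuracy over cells whose train and test quantization differ."""
        m = np.asarray(self.mean, dtype=float)
        vals = [
            m[r, c]
            for r, tr in enumerate(self.train_levels)
            for c, te in enumerate(self.test_levels)
            if tr != te
        ]
        return float(np.mean(vals))

    def diagonal_mean(self) -> float:
        m = np.asarray(self.mean, dtype=float)
        vals = [
            m[r, c]
            for r, tr in enumerate(self.train_levels)
            for c, te in enumerate(self.test_levels)
            if tr == te
        ]
        return float(np.mean(vals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.mean, index=[str(t) for t in self.train_levels], columns=list(self.test_levels)
        )


def feature_table(samples: TextureSampleSet, config: SweepConfig) -> pd.DataFrame:
    """Compute the full (sample x quantization) feature table.

    Returns one row per sample and quantization with columns
    ``sample_id``, ``label``, ``n_levels`` and the 19 default features.
    Degenerate samples (constant within the quantization limits, so the
    GLCM has a single occupied level) are excluded with a warning.
    """
    if len(samples.images) == 0:
        raise ValueError("sample set is empty")
    lo, hi = config.limits
    offsets2 = standard_offsets(2, semi_invariant=True)
    rows = []
    for sid, (img, label) in enumerate(zip(samples.images, samples.labels)):
        offsets = offsets2 if np.ndim(img) == 2 else standard_offsets(3, semi_invariant=True)
        for n in config.quantizations:
            spec = QuantizationSpec(n_levels=n, lower=lo, upper=hi)
            q = quantize(img, spec)
            counts = cooccurrence_counts(q, offsets, n)
            glcm = (
                normalize_pmf(counts) if config.variant == "original" else normalize_density(counts)
            )
            try:
                fv = compute_all(glcm)
            except ValueError as exc:
                warnings.warn(
                    f"sample {sid} at N={n} excluded (degenerate GLCM): {exc}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            row = {"sample_id": sid, "label": int(label), "n_levels": n}
            row.update(fv.values)
            rows.append(row)
    return pd.DataFrame(rows)


def _make_classifier() -> object:
    # weak, fixed ridge penalty; lbfgs handles the small dense problems here
    return make_pipeline(StandardScaler(), LogisticRegression(C=1.0, max_iter=2000))


def _majority_accuracy(labels: np.ndarray) -> float:
    labels = np.asarray(labels)
    return float(np.bincount(labels).max() / labels.size)


def _fit_eval(
    train_X: np.ndarray, train_y: np.ndarray, test_sets: Sequence[Tuple[np.ndarray, np.ndarray]]
) -> List[float]:
    clf = _make_classifier()
    clf.fit(train_X, train_y)
    return [float(np.mean(clf.predict(X) == y)) for X, y in test_sets]


def split_indices(
    labels: np.ndarray, fractions: Tuple[float, float, float], seed: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation/test index split."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = idx.size
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        train.extend(idx[:n_train])
        val.extend(idx[n_train : n_train + n_val])
        test.extend(idx[n_train + n_val :])
    return np.sort(train), np.sort(val), np.sort(test)


def forward_select(
    train_table: pd.DataFrame,
    val_table: pd.DataFrame,
    feature_names: Sequence[str] = DEFAULT_FEATURE_NAMES,
) -> List[str]:
    """Greedy forward feature selection maximizing mean validation accuracy.

    Starting from the empty set, the feature whose addition most improves
    the mean accuracy over all validation quantizations is added; the
    procedure stops when no addition gives a strictly positive
    improvement.  Ties are broken in favor of the earlier feature in
    canonical table order.  The empty list is returned when no single
    feature beats the majority-class baseline.
    """
    if train_table.empty or val_table.empty:
        raise ValueError("train and validation tables must be non-empty")
    feature_names = [f for f in feature_names if f in train_table.columns]
    train_y = train_table["label"].to_numpy()
    val_groups = [
        (g, g["label"].to_numpy()) for _, g in val_table.groupby("n_levels", sort=True)
    ]

    def score(subset: List[str]) -> float:
        if not subset:
            return _majority_accuracy(np.concatenate([y for _, y in val_groups]))
        clf = _make_classifier()
        clf.fit(train_table[subset].to_numpy(), train_y)
        accs = [
            float(np.mean(clf.predict(g[subset].to_numpy()) == y)) for g, y in val_groups
        ]
        return float(np.mean(accs))

    selected: List[str] = []
    current = score(selected)
    remaining = list(feature_names)
    while remaining:
        best_feat, best_score = None, current
        for feat in remaining:
            s = score(selected + [feat])
            if s > best_score + 1e-12:
                best_feat, best_score = feat, s
        if best_feat is None:
            break
        selected.append(best_feat)
        remaining.remove(best_feat)
        current = best_score
    return selected


def _table_by_level(table: pd.DataFrame, idx: np.ndarray) -> Dict[int, pd.DataFrame]:
    sub = table[table["sample_id"].isin(idx)]
    return {int(n): g for n, g in sub.groupby("n_levels", sort=True)}


def scenario_random_quantization(
    samples: TextureSampleSet, config: SweepConfig, table: Optional[pd.DataFrame] = None
) -> AccuracyGrid:
    """Train ``n_models`` classifiers on randomly quantized training images.

    Each repetition assigns every training image an independently random
    quantization from ``config.quantizations``, fits a logistic model on
    those feature rows (all features, no selection), and evaluates its
    accuracy on the test set at every quantization.  The grid holds the
    mean and standard deviation over repetitions.
    """
    if table is None:
        table = feature_table(samples, config)
    feats = [f for f in DEFAULT_FEATURE_NAMES if f in table.columns]
    rng = np.random.default_rng(config.seed)
    # scenario uses a plain train/test split: validation fraction folds into test
    train_idx, val_idx, test_idx = split_indices(
        samples.labels, (config.split[0], 0.0, config.split[1] + config.split[2]), config.seed
    )
    train_by_level = _table_by_level(table, train_idx)
    test_by_level = _table_by_level(table, test_idx)
    levels = list(config.quantizations)
    test_sets = [
        (test_by_level[n][feats].to_numpy(), test_by_level[n]["label"].to_numpy())
        for n in levels
    ]
    baseline = _majority_accuracy(test_by_level[levels[0]]["label"].to_numpy())

    per_sample = {
        n: g.set_index("sample_id") for n, g in train_by_level.items()
    }
    accs = np.empty((config.n_models, len(levels)))
    for rep in range(config.n_models):
        while True:
            assigned = rng.choice(levels, size=train_idx.size)
            rows_X = np.stack(
                [per_sample[n].loc[s, feats].to_numpy(dtype=float) for s, n in zip(train_idx, assigned)]
            )
            rows_y = np.array([per_sample[n].loc[s, "label"] for s, n in zip(train_idx, assigned)])
            if np.unique(rows_y).size > 1:
                break
            warnings.warn("single-class training draw; re-drawing", RuntimeWarning, stacklevel=2)
        accs[rep] = _fit_eval(rows_X, rows_y, test_sets)

    return AccuracyGrid(
        train_levels=("random",),
        test_levels=tuple(levels),
        mean=accs.mean(axis=0, keepdims=True),
        std=accs.std(axis=0, ddof=0, keepdims=True),
        baseline=baseline,
    )


def scenario_fixed_quantization(
    samples: TextureSampleSet, config: SweepConfig, table: Optional[pd.DataFrame] = None
) -> AccuracyGrid:
    """Train one classifier per training quantization; evaluate at every test quantization.

    For each training quantization, forward selection on the validation
    set picks the feature subset, a logistic model is fit on the training
    rows at that quantization, and its accuracy is measured on the test
    rows at every quantization.  An empty selection falls back to the
    majority-class predictor.
    """
    if table is None:
        table = feature_table(samples, config)
    feats = [f for f in DEFAULT_FEATURE_NAMES if f in table.columns]
    train_idx, val_idx, test_idx = split_indices(samples.labels, config.split, config.seed)
    train_by_level = _table_by_level(table, train_idx)
    val_sub = table[table["sample_id"].isin(val_idx)]
    test_by_level = _table_by_level(table, test_idx)
    levels = list(config.quantizations)
    baseline = _majority_accuracy(test_by_level[levels[0]]["label"].to_numpy())

    mean = np.empty((len(levels), len(levels)))
    for r, n_train in enumerate(levels):
        tr = train_by_level[n_train]
        selected = forward_select(tr, val_sub, feats)
        if not selected:
            majority = int(np.bincount(tr["label"].to_numpy()).argmax())
            for c, n_test in enumerate(levels):
                y = test_by_level[n_test]["label"].to_numpy()
                mean[r, c] = float(np.mean(y == majority))
            continue
        clf = _make_classifier()
        clf.fit(tr[selected].to_numpy(), tr["label"].to_numpy())
        for c, n_test in enumerate(levels):
            g = test_by_level[n_test]
            mean[r, c] = float(
                np.mean(clf.predict(g[selected].to_numpy()) == g["label"].to_numpy())
            )

    return AccuracyGrid(
        train_levels=tuple(levels),
        test_levels=tuple(levels),
        mean=mean,
        std=None,
        baseline=baseline,
    )
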