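"""Per-fold oncRNA feature selection and count normalization.

The selection pipeline, run on training-set samples only, is:

1. prevalence: keep features detected (count > 0) in at least 2% of the
   training samples of *each* supplier;
2. enrichment: keep features whose presence/absence log odds ratio for
   cancer vs control is strictly positive within *every* supplier
   (Haldane–Anscombe +0.5 correction for zero cells);
3. importance: 8 rounds of gradient-boosted-tree classification, each round
   setting aside every feature with non-zero impurity-gain importance and
   removing it from the candidate pool before the next round.

Baseline (non-VAE) learners operate on counts normalized by the endogenous
smRNA library total:  1000 * x_ij / sum_m r_im.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .containers import EndogenousCountMatrix, OncCountMatrix, SampleAnnotations

__all__ = [
    "SelectionConfig",
    "SelectedFeatures",
    "prevalence_filter",
    "logodds_filter",
    "importance_rounds",
    "normalize_counts",
    "select_features",
    "make_baseline",
]


@dataclass
class SelectionConfig:
    min_prevalence: float = 0.02
    importance_rounds: int = 8
    per_group_column: str = "supplier"

    def __post_init__(self):
        if not (0.0 < self.min_prevalence < 1.0):
            raise ValueError("min_prevalence must be in (0, 1)")
        if self.importance_rounds < 1:
            raise ValueError("importance_rounds must be >= 1")


@dataclass
class SelectedFeatures:
    feature_ids: np.ndarray
    feature_indices: np.ndarray
    round_selected: dict[str, int] = field(default_factory=dict)
    rounds_run: int = 0

    def __len__(self) -> int:
        return len(self.feature_ids)


def _presence(x) -> np.ndarray:
    dense = x.dense() if isinstance(x, OncCountMatrix) else np.asarray(x)
    return dense > 0


def prevalence_filter(x, annotations: SampleAnnotations,
                      config: SelectionConfig | None = None) -> np.ndarray:
    """Features detected in >= min_prevalence of samples of every supplier."""
    config = config or SelectionConfig()
    present = _presence(x)
    groups = annotations.df[config.per_group_column].to_numpy()
    mask = np.ones(present.shape[1], dtype=bool)
    for g in np.unique(groups):
        rows = present[groups == g]
        if rows.shape[0] == 0:
            raise ValueError(f"empty group '{g}' in prevalence filter")
        mask &= rows.mean(axis=0) >= config.min_prevalence
    return mask


def logodds_filter(x, annotations: SampleAnnotations,
                   config: SelectionConfig | None = None) -> np.ndarray:
    """Features over-represented (log OR > 0) in cancer, within every supplier."""
    config = config or SelectionConfig()
    present = _presence(x)
    labels = annotations.labels
    groups = annotations.df[config.per_group_column].to_numpy()
    mask = np.ones(present.shape[1], dtype=bool)
    for g in np.unique(groups):
        sel = groups == g
        y = labels[sel]
        if len(np.unique(y)) < 2:
            raise ValueError(f"supplier '{g}' lacks one label class")
        p = present[sel]
        a = p[y == 1].sum(axis=0).astype(float)   # cancer, present
        b = (y == 1).sum() - a                    # cancer, absent
        c = p[y == 0].sum(axis=0).astype(float)   # control, present
        d = (y == 0).sum() - c                    # control, absent
        zero_cell = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        a, b, c, d = (v + 0.5 * zero_cell for v in (a, b, c, d))
        log_or = np.log(a * d) - np.log(b * c)
        mask &= log_or > 0
    return mask


def normalize_counts(x, r) -> np.ndarray:
    """1000 * x / (per-sample endogenous read total); depth-invariant."""
    dense = x.dense() if isinstance(x, OncCountMatrix) else np.asarray(x, float)
    r_vals = r.values if isinstance(r, EndogenousCountMatrix) else np.asarray(r, float)
    sums = r_vals.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("zero endogenous row sum")
    return 1000.0 * dense / sums[:, None]


def importance_rounds(x_norm: np.ndarray, labels: np.ndarray,
                      config: SelectionConfig | None = None,
                      seed: int = 0,
                      feature_ids: np.ndarray | None = None) -> SelectedFeatures:
    """Iterative tree-importance selection over the remaining feature pool."""
    config = config or SelectionConfig()
    x_norm = np.asarray(x_norm, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    d = x_norm.shape[1]
    if feature_ids is None:
        feature_ids = np.array([str(j) for j in range(d)])
    remaining = np.arange(d)
    chosen: list[int] = []
    round_selected: dict[str, int] = {}
    rounds_run = 0
    for rnd in range(1, config.importance_rounds + 1):
        if len(remaining) == 0:
            break
        clf = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
        clf.fit(x_norm[:, remaining], labels)
        imp = clf.feature_importances_
        hit = imp > 0
        rounds_run = rnd
        if not hit.any():
            break
        for j in remaining[hit]:
            chosen.append(int(j))
            round_selected[str(feature_ids[j])] = rnd
        remaining = remaining[~hit]
    idx = np.array(sorted(chosen), dtype=np.intp)
    return SelectedFeatures(
        feature_ids=feature_ids[idx],
        feature_indices=idx,
        round_selected=round_selected,
        rounds_run=rounds_run,
    )


def select_features(x, r, annotations: SampleAnnotations,
                    config: SelectionConfig | None = None,
                    seed: int = 0) -> SelectedFeatures:
    """Composed pipeline: prevalence -> per-supplier log-OR -> tree rounds.

    Pure function of (training split, seed): rerunning reproduces the
    identical feature list.
    """
    config = config or SelectionConfig()
    mask = prevalence_filter(x, annotations, config)
    mask &= logodds_filter(x, annotations, config)
    cand = np.flatnonzero(mask)
    if isinstance(x, OncCountMatrix):
        feature_ids = np.asarray(x.feature_ids)
    else:
        feature_ids = np.array([str(j) for j in range(np.asarray(x).shape[1])])
    if len(cand) == 0:
        return SelectedFeatures(feature_ids=feature_ids[:0],
                                feature_indices=cand, rounds_run=0)
    x_norm = normalize_counts(x, r)[:, cand]
    sel = importance_rounds(x_norm, annotations.labels, config, seed,
                            feature_ids=feature_ids[cand])
    abs_idx = np.sort(cand[sel.feature_indices])
    return SelectedFeatures(
        feature_ids=feature_ids[abs_idx],
        feature_indices=abs_idx,
        round_selected=sel.round_selected,
        rounds_run=sel.rounds_run,
    )


def make_baseline(name: str, seed: int = 0):
    """Reference learners fitted on normalized, per-fold-standardized counts."""
    from sklearn.linear_model import LogisticRegressionCV
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if name == "elasticnet":
        clf = LogisticRegressionCV(
            cv=2, penalty="elasticnet", solver="saga",
            l1_ratios=[0, 0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1],
            max_iter=2000, random_state=seed,
        )
    elif name == "svm":
        clf = SVC(probability=True, random_state=seed)
    elif name == "knn":
        clf = KNeighborsClassifier()
    elif name == "xgboost":
        clf = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
    else:
        raise ValueError(f"unknown baseline '{name}'")
    return make_pipeline(StandardScaler(), clf)
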