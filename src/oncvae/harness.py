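"""Splitting, cross-validated training, thresholding, metrics and the
robustness experiments (batch AUROC, in silico dilution, feature
perturbation).

The splitting rules mirror clinical liquid-biopsy practice: 20% of
*patients* are held out with stratification on label and supplier, the
remainder is split patient-grouped k-fold, and all replicates of a patient
travel together.  Each fold trains several models with different seeds;
tuning-set scores are averaged over the fold's seeds and held-out scores
over all folds x seeds.  The operating cutoff is frozen on cross-validated
training scores at a target specificity and only then applied to held-out
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, matthews_corrcoef, roc_auc_score

from .containers import EndogenousCountMatrix, OncCountMatrix, SampleAnnotations
from .features import SelectionConfig, select_features
from .model_core import ModelConfig, Orion, TrainOpts
from .simdata import SimulatedCohort

__all__ = [
    "SplitPlan",
    "ScoreTable",
    "ThresholdPolicy",
    "MetricReport",
    "make_splits",
    "cross_validate",
    "choose_cutoff",
    "compute_metrics",
    "bootstrap_ci",
    "batch_auc",
    "downsample_counts",
    "dilution_experiment",
    "ablate_features",
    "permute_features",
    "rank_features_by_attribution",
    "ensemble_predict",
]


# ------------------------------------------------------------------ splitting
@dataclass
class SplitPlan:
    heldout_patients: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train patients, tune patients)
    n_folds: int
    seeds_per_fold: int = 5
    held_out_fraction: float = 0.2

    def training_patients(self) -> np.ndarray:
        return np.concatenate([f[1] for f in self.folds])


def make_splits(annotations: SampleAnnotations, held_out_fraction: float = 0.2,
                n_folds: int = 10, seeds_per_fold: int = 5, seed: int = 0,
                strat_cols: tuple[str, ...] = ("label", "supplier")) -> SplitPlan:
    """Patient-grouped, stratified held-out split plus k-fold plan."""
    df = annotations.df
    pat = df.groupby("patient_id", sort=True).first().reset_index()
    rng = np.random.default_rng(seed)

    strata = pat[list(strat_cols)].astype(str).agg("|".join, axis=1).to_numpy()
    counts = pd.Series(strata).value_counts()
    small = set(counts[counts < 2].index)
    if small:
        warnings.warn(f"strata too small to stratify, merged: {sorted(small)}")
        strata = np.array([s if s not in small else "_merged" for s in strata])

    heldout: list[str] = []
    fold_of: dict[str, int] = {}
    offset = 0
    for s in np.unique(strata):
        pids = pat.loc[strata == s, "patient_id"].to_numpy()
        pids = pids[rng.permutation(len(pids))]
        n_held = int(round(held_out_fraction * len(pids)))
        heldout.extend(pids[:n_held])
        for i, pid in enumerate(pids[n_held:]):
            fold_of[pid] = (i + offset) % n_folds
        offset += len(pids) - n_held
    train_pats = np.array(sorted(fold_of))
    folds = []
    for f in range(n_folds):
        tune = np.array(sorted(p for p in train_pats if fold_of[p] == f))
        train = np.array(sorted(p for p in train_pats if fold_of[p] != f))
        folds.append((train, tune))
    return SplitPlan(
        heldout_patients=np.array(sorted(heldout)),
        folds=folds,
        n_folds=n_folds,
        seeds_per_fold=seeds_per_fold,
        held_out_fraction=held_out_fraction,
    )


# ------------------------------------------------------------- cross-validate
@dataclass
class ScoreTable:
    """Per-model and averaged scores with fold/seed provenance."""

    long: pd.DataFrame     # sample_id, split, fold, seed, score
    summary: pd.DataFrame  # one row per sample: averaged score + metadata

    def cv_scores(self, representative_only: bool = True) -> pd.DataFrame:
        out = self.summary[self.summary["split"] == "cv"]
        if representative_only:
            out = out[out["representative"]]
        return out

    def heldout_scores(self, representative_only: bool = True) -> pd.DataFrame:
        out = self.summary[self.summary["split"] == "heldout"]
        if representative_only:
            out = out[out["representative"]]
        return out


def _sample_indices(annotations: SampleAnnotations, patients: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.isin(annotations.patient_ids, patients))


def _mark_representatives(df: pd.DataFrame) -> pd.DataFrame:
    # deterministic: first sample_id (sorted) per patient reports performance
    rep = df.sort_values("sample_id").groupby("patient_id")["sample_id"].first()
    df = df.copy()
    df["representative"] = df["sample_id"].isin(set(rep))
    return df


def cross_validate(cohort: SimulatedCohort | tuple, splits: SplitPlan,
                   model_config: ModelConfig,
                   train_opts: TrainOpts | None = None,
                   selection: SelectionConfig | None = None,
                   base_seed: int = 0,
                   return_models: bool = False):
    """Train seeds_per_fold models per fold; average scores per the plan.

    Feature selection, when requested, is re-run inside each fold on that
    fold's training samples only.
    """
    if isinstance(cohort, SimulatedCohort):
        x, r, ann = cohort.x, cohort.r, cohort.annotations
    else:
        x, r, ann = cohort
    heldout_idx = _sample_indices(ann, splits.heldout_patients)
    records: list[dict] = []
    heldout_acc = np.zeros(len(heldout_idx))
    heldout_models = 0
    models: dict[tuple[int, int], tuple[Orion, np.ndarray]] = {}

    for f, (train_p, tune_p) in enumerate(splits.folds):
        tr_idx = _sample_indices(ann, train_p)
        tu_idx = _sample_indices(ann, tune_p)
        x_tr, r_tr, ann_tr = x.subset_samples(tr_idx), r.subset_samples(tr_idx), ann.subset(tr_idx)
        if selection is not None:
            sel = select_features(x_tr, r_tr, ann_tr, selection,
                                  seed=base_seed + f)
            feat_idx = sel.feature_indices
            if len(feat_idx) == 0:
                warnings.warn(f"fold {f}: selection kept no features; using all")
                feat_idx = np.arange(x.n_features)
        else:
            feat_idx = np.arange(x.n_features)
        cfg_f = replace(model_config, d=len(feat_idx))
        x_tr_f = x_tr.subset_features(feat_idx)

        tune_scores = []
        for s in range(splits.seeds_per_fold):
            seed = (base_seed + 1000 * f + s) % (2**31 - 1)
            cfg_fs = replace(cfg_f, seed=seed)
            model = Orion(cfg_fs)
            try:
                model.fit(x_tr_f, r_tr, ann_tr, train_opts)
            except RuntimeError as err:
                warnings.warn(f"fold {f} seed {s} diverged and is excluded: {err}")
                continue
            sc_tu = model.predict(x.subset_samples(tu_idx).subset_features(feat_idx),
                                  r.subset_samples(tu_idx))
            tune_scores.append(sc_tu)
            for i, sc in zip(tu_idx, sc_tu):
                records.append(dict(sample_id=ann.df.loc[i, "sample_id"],
                                    split="cv", fold=f, seed=s, score=sc))
            if len(heldout_idx):
                sc_ho = model.predict(
                    x.subset_samples(heldout_idx).subset_features(feat_idx),
                    r.subset_samples(heldout_idx))
                heldout_acc += sc_ho
                heldout_models += 1
                for i, sc in zip(heldout_idx, sc_ho):
                    records.append(dict(sample_id=ann.df.loc[i, "sample_id"],
                                        split="heldout", fold=f, seed=s, score=sc))
            if return_models:
                models[(f, s)] = (model, feat_idx)

    long = pd.DataFrame.from_records(records)
    cv_avg = (long[long["split"] == "cv"].groupby("sample_id")["score"]
              .agg(["mean", "count"]).reset_index()
              .rename(columns={"mean": "score", "count": "n_models"}))
    cv_avg["split"] = "cv"
    rows = [cv_avg]
    if heldout_models:
        ho = pd.DataFrame({
            "sample_id": ann.df.loc[heldout_idx, "sample_id"].to_numpy(),
            "score": heldout_acc / heldout_models,
            "n_models": heldout_models,
        })
        ho["split"] = "heldout"
        rows.append(ho)
    summary = pd.concat(rows, ignore_index=True).merge(
        ann.df[["sample_id", "patient_id", "label", "supplier"]], on="sample_id"
    )
    summary = _mark_representatives(summary)
    table = ScoreTable(long=long, summary=summary)
    return (table, models) if return_models else table


# ----------------------------------------------------------------- thresholds
@dataclass
class ThresholdPolicy:
    target_specificity: float
    cutoff: float
    source: str = "cv"


def choose_cutoff(scores: np.ndarray, labels: np.ndarray,
                  target_specificity: float) -> ThresholdPolicy:
    """Smallest cutoff with training specificity >= target.

    A sample is called positive when score > cutoff; the cutoff is the
    midpoint between the bracketing control scores (or between the largest
    control score and 1.0 when every control must fall below it).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    controls = np.sort(scores[labels == 0])
    n = len(controls)
    if n == 0:
        raise ValueError("no control samples to set a specificity cutoff")
    k = int(np.ceil(target_specificity * n - 1e-12))
    if k <= 0:
        cutoff = controls[0] - 1e-12
    elif k >= n:
        cutoff = 0.5 * (controls[-1] + 1.0)
    else:
        cutoff = 0.5 * (controls[k - 1] + controls[k])
    return ThresholdPolicy(target_specificity=target_specificity,
                           cutoff=float(cutoff))


# -------------------------------------------------------------------- metrics
@dataclass
class MetricReport:
    auroc: float
    sensitivity: float | None = None
    specificity: float | None = None
    f1: float | None = None
    mcc: float | None = None
    per_stratum_sensitivity: dict = field(default_factory=dict)
    cis: dict = field(default_factory=dict)


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    cutoff: float | None = None,
                    strata: dict[str, np.ndarray] | None = None) -> MetricReport:
    """AUROC (rank statistic, ties = 0.5) plus cutoff metrics if given."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined for single-class input")
    rep = MetricReport(auroc=float(roc_auc_score(labels, scores)))
    if cutoff is not None:
        pred = (scores > cutoff).astype(int)
        pos, neg = labels == 1, labels == 0
        rep.sensitivity = float(pred[pos].mean())
        rep.specificity = float(1.0 - pred[neg].mean())
        rep.f1 = float(f1_score(labels, pred))
        rep.mcc = float(matthews_corrcoef(labels, pred))
        if strata:
            for name, mask in strata.items():
                m = np.asarray(mask) & pos
                if m.any():
                    rep.per_stratum_sensitivity[name] = float(pred[m].mean())
    return rep


def bootstrap_ci(metric_fn, scores: np.ndarray, labels: np.ndarray,
                 patients: np.ndarray | None = None, n_boot: int = 1000,
                 seed: int = 0, scores2: np.ndarray | None = None,
                 level: float = 0.95) -> tuple[float, float, float]:
    """Percentile bootstrap CI with patient-level resampling.

    With `scores2`, the statistic is the paired difference
    metric_fn(scores) - metric_fn(scores2) on identical resamples.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    if patients is None:
        patients = np.arange(len(scores))
    patients = np.asarray(patients)
    unique_p = np.unique(patients)
    rows_of = {p: np.flatnonzero(patients == p) for p in unique_p}

    def stat(idx):
        if scores2 is None:
            return metric_fn(scores[idx], labels[idx])
        return (metric_fn(scores[idx], labels[idx])
                - metric_fn(np.asarray(scores2)[idx], labels[idx]))

    point = stat(np.arange(len(scores)))
    vals = []
    tries = 0
    while len(vals) < n_boot and tries < 20 * n_boot:
        tries += 1
        chosen = rng.choice(unique_p, size=len(unique_p), replace=True)
        idx = np.concatenate([rows_of[p] for p in chosen])
        if len(np.unique(labels[idx])) < 2:
            continue  # degenerate resample: redraw
        vals.append(stat(idx))
    lo, hi = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(point), float(hi)


def batch_auc(scores: np.ndarray, suppliers: np.ndarray) -> float:
    """AUROC of control scores against the supplier label; 0.5 = no leakage."""
    suppliers = np.asarray(suppliers)
    uniq = np.unique(suppliers)
    if len(uniq) != 2:
        raise ValueError("batch AUROC needs exactly two suppliers")
    return float(roc_auc_score((suppliers == uniq[1]).astype(int), scores))


# ------------------------------------------------------------------- dilution
def downsample_counts(x_row: np.ndarray, r_row: np.ndarray, rate: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Joint without-replacement downsampling of one sample's reads.

    The oncRNA and endogenous counts are pooled and a hypergeometric
    partition keeps round(rate * total) reads, the count-level equivalent
    of subsampling the read stream.
    """
    joint = np.concatenate([np.asarray(x_row), np.asarray(r_row)]).astype(np.int64)
    total = int(joint.sum())
    keep = int(round(rate * total))
    kept = rng.multivariate_hypergeometric(joint, keep, method="marginals")
    d = len(x_row)
    return kept[:d], kept[d:]


def dilution_experiment(x: OncCountMatrix, r: EndogenousCountMatrix,
                        annotations: SampleAnnotations, scores: np.ndarray,
                        predict_fn, ratios=(0.8, 0.6, 0.4, 0.2),
                        n_per_side: int = 10, seed: int = 0) -> pd.DataFrame:
    """Complementary in silico mixtures of cancer and control samples.

    Per supplier: after excluding samples below the 10th or above the 90th
    read-depth percentile, take the `n_per_side` highest-scoring cancer and
    lowest-scoring control samples; downsample a cancer sample at rate rho
    and a control at 1 - rho and pool them.  Every cancer/control pair in
    the same supplier is mixed at every ratio.
    """
    rng = np.random.default_rng(seed)
    labels = annotations.labels
    suppliers = annotations.suppliers
    x_dense = x.dense().astype(np.int64)
    r_dense = np.asarray(r.values).astype(np.int64)
    depth = x_dense.sum(axis=1) + r_dense.sum(axis=1)

    rows = []
    for sup in np.unique(suppliers):
        sel = suppliers == sup
        lo, hi = np.percentile(depth[sel], [10, 90])
        eligible = sel & (depth >= lo) & (depth <= hi)
        canc = np.flatnonzero(eligible & (labels == 1))
        ctrl = np.flatnonzero(eligible & (labels == 0))
        if len(canc) < n_per_side or len(ctrl) < n_per_side:
            raise ValueError(
                f"supplier {sup}: fewer than {n_per_side} eligible samples per class"
            )
        canc = canc[np.argsort(scores[canc])[::-1][:n_per_side]]
        ctrl = ctrl[np.argsort(scores[ctrl])[:n_per_side]]
        for rho in ratios:
            canc_ds = {i: downsample_counts(x_dense[i], r_dense[i], rho, rng)
                       for i in canc}
            ctrl_ds = {j: downsample_counts(x_dense[j], r_dense[j], 1.0 - rho, rng)
                       for j in ctrl}
            for i in canc:
                for j in ctrl:
                    xm = canc_ds[i][0] + ctrl_ds[j][0]
                    rm = canc_ds[i][1] + ctrl_ds[j][1]
                    rows.append(dict(
                        supplier=sup,
                        cancer_id=annotations.df.loc[i, "sample_id"],
                        control_id=annotations.df.loc[j, "sample_id"],
                        ratio=rho, x=xm, r=rm,
                    ))
    out = pd.DataFrame(rows)
    xs = np.stack(out.pop("x").to_numpy())
    rs = np.stack(out.pop("r").to_numpy())
    out["score"] = predict_fn(xs, rs)
    return out


# --------------------------------------------------------------- perturbation
def _feature_index(x: OncCountMatrix, feature_ids) -> np.ndarray:
    lookup = {fid: i for i, fid in enumerate(x.feature_ids)}
    try:
        return np.array([lookup[f] for f in feature_ids], dtype=np.intp)
    except KeyError as err:
        raise KeyError(f"unknown feature id {err.args[0]!r}") from None


def ablate_features(x: OncCountMatrix, feature_ids) -> OncCountMatrix:
    """Zero the listed feature columns for every sample."""
    idx = _feature_index(x, feature_ids)
    dense = x.dense()
    dense[:, idx] = 0
    return OncCountMatrix(dense.astype(np.int64), x.feature_ids, x.sample_ids)


def permute_features(x: OncCountMatrix, feature_ids, seed: int = 0) -> OncCountMatrix:
    """Independently permute each listed column across samples."""
    idx = _feature_index(x, feature_ids)
    dense = x.dense()
    rng = np.random.default_rng(seed)
    for j in idx:
        dense[:, j] = dense[rng.permutation(dense.shape[0]), j]
    return OncCountMatrix(dense.astype(np.int64), x.feature_ids, x.sample_ids)


def rank_features_by_attribution(models, x: OncCountMatrix,
                                 r: EndogenousCountMatrix,
                                 backend: str = "grad_x_input") -> pd.DataFrame:
    """Per-feature attribution averaged over fold models, ranked descending.

    The default backend multiplies the gradient of the positive-class score
    with the (log1p) input, a fast Shapley-style local attribution; other
    estimators can be plugged in by passing a callable.
    """
    if callable(backend):
        attr_fn = backend
    elif backend == "grad_x_input":
        def attr_fn(model, x_dense, r_dense):
            return model.input_attribution(x_dense, r_dense)
    else:
        raise ValueError(f"unknown attribution backend '{backend}'")

    if isinstance(models, Orion):
        models = [models]
    total = np.zeros(x.n_features)
    n_models = 0
    r_dense = np.asarray(r.values, dtype=float)
    for item in models:
        model, feat_idx = item if isinstance(item, tuple) else (item, np.arange(x.n_features))
        if not model.fitted:
            raise RuntimeError("attribution requires trained models")
        x_dense = x.dense()[:, feat_idx]
        attr = attr_fn(model, x_dense, r_dense)
        contrib = np.zeros(x.n_features)
        contrib[feat_idx] = attr.mean(axis=0)
        total += contrib
        n_models += 1
    mean_attr = total / n_models
    order = np.argsort(mean_attr)[::-1]
    return pd.DataFrame({
        "feature_id": np.asarray(x.feature_ids)[order],
        "feature_index": order,
        "attribution": mean_attr[order],
    })


def ensemble_predict(models, x: OncCountMatrix, r: EndogenousCountMatrix) -> np.ndarray:
    """Average the positive-class score of all fold/seed models."""
    scores = []
    for item in models:
        model, feat_idx = item if isinstance(item, tuple) else (item, np.arange(x.n_features))
        scores.append(model.predict(x.dense()[:, feat_idx], r.values))
    return np.mean(scores, axis=0)
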