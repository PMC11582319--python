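"""Replicated ablation and robustness experiment protocols.

These drivers bundle the package's headline experiments at desk scale:

* batch-effect removal: train the model with and without the triplet margin
  loss on a supplier-confounded cohort and compare the supplier AUROC of
  control-sample scores (0.5 = no leakage);
* generative sampling: at a small training size, compare test cross-entropy
  of the eta-draw classifier against the expected-value-only variant;
* frozen-cutoff transfer: freeze the score cutoff at a target specificity
  on cross-validated training scores and measure the specificity realized
  on held-out patients;
* dilution and perturbation: score complementary cancer/control count
  mixtures, and ablate or permute top-attributed features;
* selection recovery: plant a handful of informative features among nulls
  and ask the selection pipeline to find them.

Every experiment uses a reduced architecture (k = 16, hidden 128) and a
few hundred samples so a full replicate set runs in minutes on one CPU.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .features import SelectionConfig, select_features
from .harness import (
    batch_auc,
    choose_cutoff,
    compute_metrics,
    cross_validate,
    dilution_experiment,
    ensemble_predict,
    make_splits,
    ablate_features,
    permute_features,
    rank_features_by_attribution,
)
from .model_core import LossWeights, ModelConfig, Orion, TrainOpts
from .simdata import SimConfig, simulate_cohort

__all__ = [
    "reduced_config",
    "batch_removal_experiment",
    "generative_sampling_experiment",
    "cutoff_transfer_experiment",
    "dilution_perturbation_experiment",
    "selection_recovery_experiment",
]


def reduced_config(d: int, m: int, seed: int, tml_weight: float | None = None,
                   generative_sampling: bool = True) -> ModelConfig:
    """Desk-scale architecture: k=16, hidden 128, full eta sampling."""
    lw = LossWeights() if tml_weight is None else LossWeights(tml=tml_weight)
    return ModelConfig(d=d, m=m, k=16, hidden_onc=128, hidden_lib=64,
                       hidden_dec=128, eta=100, seed=seed, loss_weights=lw,
                       generative_sampling=generative_sampling)


def _binary_ce(scores: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(scores, 1e-12, 1.0 - 1e-12)
    y = np.asarray(labels)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def batch_removal_experiment(base_seed: int = 500, n_replicates: int = 5,
                             n_epochs: int = 30) -> dict:
    """Triplet-loss ablation on supplier-confounded cohorts.

    Per replicate, one model with the default triplet weight and one with
    the loss ablated are trained on the same 80% patient split; supplier
    AUROC of control scores and label AUROC are measured on the remaining
    patients.
    """
    rows = []
    for rep in range(n_replicates):
        co = simulate_cohort(SimConfig(seed=base_seed + rep))
        ann = co.annotations
        splits = make_splits(ann, held_out_fraction=0.2, n_folds=5, seed=rep)
        train_p, tune_p = splits.folds[0]
        tr = np.flatnonzero(np.isin(ann.patient_ids, train_p))
        ev = np.flatnonzero(np.isin(
            ann.patient_ids, np.concatenate([tune_p, splits.heldout_patients])
        ))
        lab = ann.labels
        rec = {"replicate": rep}
        for tag, tml_w in (("tml", None), ("ablated", 0.0)):
            cfg = reduced_config(co.x.n_features, co.r.values.shape[1],
                                 seed=rep, tml_weight=tml_w)
            model = Orion(cfg)
            model.fit(co.x.subset_samples(tr), co.r.subset_samples(tr),
                      ann.subset(tr), TrainOpts(n_epochs=n_epochs))
            s = model.predict(co.x.subset_samples(ev), co.r.subset_samples(ev))
            ctl = lab[ev] == 0
            rec[f"batch_auc_{tag}"] = batch_auc(s[ctl], ann.suppliers[ev][ctl])
            rec[f"label_auc_{tag}"] = compute_metrics(s, lab[ev]).auroc
        rec["tml_wins"] = (abs(rec["batch_auc_tml"] - 0.5)
                           < abs(rec["batch_auc_ablated"] - 0.5))
        rows.append(rec)
    return {
        "replicates": rows,
        "tml_wins": int(sum(r["tml_wins"] for r in rows)),
        "mean_batch_auc_tml": float(np.mean([r["batch_auc_tml"] for r in rows])),
        "mean_batch_auc_ablated": float(
            np.mean([r["batch_auc_ablated"] for r in rows])
        ),
        "mean_label_auc_tml": float(np.mean([r["label_auc_tml"] for r in rows])),
    }


def generative_sampling_experiment(base_seed: int = 600, n_replicates: int = 5,
                                   n_train: int = 150, n_epochs: int = 60,
                                   effect_logfc: float = 1.0) -> dict:
    """Small-sample benefit of eta-draw classifier training.

    Uses a weaker-signal cohort so the task is data-limited at `n_train`
    samples, the regime where posterior-sampling augmentation matters.
    """
    rows = []
    for rep in range(n_replicates):
        co = simulate_cohort(SimConfig(effect_logfc=effect_logfc,
                                       seed=base_seed + rep))
        ann = co.annotations
        rng = np.random.default_rng(rep)
        pats = np.unique(ann.patient_ids)
        rng.shuffle(pats)
        tr_p, count = [], 0
        for p in pats:
            tr_p.append(p)
            count += int((ann.patient_ids == p).sum())
            if count >= n_train:
                break
        tr = np.flatnonzero(np.isin(ann.patient_ids, tr_p))
        te = np.flatnonzero(~np.isin(ann.patient_ids, tr_p))
        rec = {"replicate": rep}
        for tag, gen in (("generative", True), ("expected", False)):
            cfg = reduced_config(co.x.n_features, co.r.values.shape[1],
                                 seed=rep, generative_sampling=gen)
            model = Orion(cfg)
            model.fit(co.x.subset_samples(tr), co.r.subset_samples(tr),
                      ann.subset(tr), TrainOpts(n_epochs=n_epochs))
            s = model.predict(co.x.subset_samples(te), co.r.subset_samples(te))
            rec[f"test_ce_{tag}"] = _binary_ce(s, ann.labels[te])
        rec["generative_wins"] = rec["test_ce_generative"] <= rec["test_ce_expected"]
        rows.append(rec)
    return {
        "replicates": rows,
        "generative_wins": int(sum(r["generative_wins"] for r in rows)),
        "mean_test_ce_generative": float(
            np.mean([r["test_ce_generative"] for r in rows])
        ),
        "mean_test_ce_expected": float(
            np.mean([r["test_ce_expected"] for r in rows])
        ),
    }


def _transfer_sim_config(seed: int) -> SimConfig:
    return SimConfig(n_samples=400, d_onc=600, m_endo=15, signal_features=60,
                     seed=seed)


def cutoff_transfer_experiment(base_seed: int = 800, n_replicates: int = 5,
                               target_specificity: float = 0.90) -> dict:
    """CV-frozen specificity cutoff applied to held-out patients."""
    rows = []
    for rep in range(n_replicates):
        co = simulate_cohort(_transfer_sim_config(base_seed + rep))
        splits = make_splits(co.annotations, held_out_fraction=0.2, n_folds=3,
                             seeds_per_fold=2, seed=rep)
        cfg = ModelConfig(d=600, m=15, k=8, hidden_onc=64, hidden_lib=32,
                          hidden_dec=64, eta=50, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = cross_validate(
                co, splits, cfg, TrainOpts(n_epochs=30),
                selection=SelectionConfig(importance_rounds=2), base_seed=rep,
            )
        cv = table.cv_scores()
        ho = table.heldout_scores()
        policy = choose_cutoff(cv["score"].to_numpy(), cv["label"].to_numpy(),
                               target_specificity)
        rep_metrics = compute_metrics(ho["score"].to_numpy(),
                                      ho["label"].to_numpy(), policy.cutoff)
        rows.append({
            "replicate": rep,
            "cutoff": policy.cutoff,
            "heldout_specificity": rep_metrics.specificity,
            "heldout_sensitivity": rep_metrics.sensitivity,
            "heldout_auroc": rep_metrics.auroc,
        })
    return {
        "replicates": rows,
        "mean_heldout_specificity": float(
            np.mean([r["heldout_specificity"] for r in rows])
        ),
        "in_band": int(sum(0.80 <= r["heldout_specificity"] <= 0.98
                           for r in rows)),
    }


def dilution_perturbation_experiment(seed: int = 900, n_top: int = 50) -> dict:
    """Train a small ensemble, then run the mixture and perturbation assays."""
    co = simulate_cohort(_transfer_sim_config(seed))
    ann = co.annotations
    splits = make_splits(ann, held_out_fraction=0.3, n_folds=3,
                         seeds_per_fold=1, seed=0)
    tr = np.flatnonzero(np.isin(ann.patient_ids, splits.folds[0][0]))
    ev = np.flatnonzero(np.isin(
        ann.patient_ids,
        np.concatenate([splits.folds[0][1], splits.heldout_patients]),
    ))
    models = []
    for s in range(2):
        cfg = ModelConfig(d=600, m=15, k=8, hidden_onc=64, hidden_lib=32,
                          hidden_dec=64, eta=50, seed=s)
        model = Orion(cfg)
        model.fit(co.x.subset_samples(tr), co.r.subset_samples(tr),
                  ann.subset(tr), TrainOpts(n_epochs=30))
        models.append(model)

    def predict_fn(xs, rs):
        return np.mean([m.predict(xs, rs) for m in models], axis=0)

    x_ev = co.x.subset_samples(ev)
    r_ev = co.r.subset_samples(ev)
    ann_ev = ann.subset(ev)
    scores = predict_fn(x_ev.dense(), r_ev.values)
    lab = ann_ev.labels

    mixtures = dilution_experiment(x_ev, r_ev, ann_ev, scores, predict_fn,
                                   seed=seed + 1)
    by_ratio = mixtures.groupby("ratio")["score"].mean().to_dict()
    anchors = mixtures["cancer_id"].unique()
    a_idx = np.flatnonzero(np.isin(ann_ev.df["sample_id"], anchors))
    by_ratio[1.0] = float(scores[a_idx].mean())

    ranking = rank_features_by_attribution(models, x_ev, r_ev)
    top = ranking.head(n_top)["feature_id"]
    s_ablate = predict_fn(ablate_features(x_ev, top).dense(), r_ev.values)
    s_permute = predict_fn(permute_features(x_ev, top, seed=seed + 2).dense(),
                           r_ev.values)
    return {
        "n_mixtures": int(len(mixtures)),
        "mean_mixture_score_by_ratio": {
            float(k): float(v) for k, v in sorted(by_ratio.items())
        },
        "cancer_mean_before_ablation": float(scores[lab == 1].mean()),
        "cancer_mean_after_ablation": float(s_ablate[lab == 1].mean()),
        "control_mean_before_permutation": float(scores[lab == 0].mean()),
        "control_mean_after_permutation": float(s_permute[lab == 0].mean()),
        "signal_fraction_in_top_decile": float(
            np.isin(co.truth.signal_indices,
                    ranking.head(co.x.n_features // 10)["feature_index"]).mean()
        ),
    }


def selection_recovery_experiment(seed: int = 1000, n_signal: int = 10,
                                  selection_seed: int = 0) -> dict:
    """Plant `n_signal` informative features among nulls; recover them."""
    co = simulate_cohort(SimConfig(signal_features=n_signal, seed=seed))
    cfg = SelectionConfig()
    sel1 = select_features(co.x, co.r, co.annotations, cfg, seed=selection_seed)
    sel2 = select_features(co.x, co.r, co.annotations, cfg, seed=selection_seed)
    return {
        "n_selected": int(len(sel1)),
        "n_recovered": int(
            np.isin(co.truth.signal_indices, sel1.feature_indices).sum()
        ),
        "n_planted": n_signal,
        "reproducible": bool(
            np.array_equal(sel1.feature_indices, sel2.feature_indices)
        ),
        "rounds_run": sel1.rounds_run,
    }
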