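"""Splitting audits, thresholding, metrics oracles, robustness operations."""

import numpy as np
import pandas as pd
import pytest

from oncvae import (
    OncCountMatrix,
    SimConfig,
    ablate_features,
    batch_auc,
    bootstrap_ci,
    choose_cutoff,
    compute_metrics,
    dilution_experiment,
    downsample_counts,
    make_splits,
    permute_features,
    simulate_cohort,
)


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(SimConfig(n_samples=300, d_onc=60, m_endo=8,
                                     n_patients=260, signal_features=10, seed=41))


# ------------------------------------------------------------------- splitting
def test_splits_are_patient_grouped_and_exhaustive(cohort):
    ann = cohort.annotations
    plan = make_splits(ann, held_out_fraction=0.2, n_folds=5, seed=0)
    held = set(plan.heldout_patients)
    for train_p, tune_p in plan.folds:
        assert not (set(train_p) & set(tune_p))
        assert not (set(train_p) & held)
        assert not (set(tune_p) & held)
    all_tune = np.concatenate([f[1] for f in plan.folds])
    assert len(all_tune) == len(set(all_tune))  # each patient tunes once
    assert len(held) + len(all_tune) == ann.df["patient_id"].nunique()


def test_fold_sizes_balanced(cohort):
    plan = make_splits(cohort.annotations, held_out_fraction=0.2, n_folds=5, seed=0)
    sizes = [len(f[1]) for f in plan.folds]
    assert max(sizes) - min(sizes) <= len(np.unique(
        cohort.annotations.df[["label", "supplier"]].astype(str).agg("|".join, axis=1)
    ))


def test_stratification_balance(cohort):
    ann = cohort.annotations
    plan = make_splits(ann, held_out_fraction=0.2, n_folds=5, seed=0)
    pat = ann.df.groupby("patient_id").first()
    held = pat.loc[sorted(plan.heldout_patients)]
    train = pat.loc[sorted(np.concatenate([f[1] for f in plan.folds]))]
    for col in ("label", "supplier"):
        for val in pat[col].unique():
            p_h = (held[col] == val).mean()
            p_t = (train[col] == val).mean()
            assert abs(p_h - p_t) < 0.10


def test_replicates_travel_together(cohort):
    ann = cohort.annotations
    plan = make_splits(ann, held_out_fraction=0.2, n_folds=5, seed=3)
    side = {}
    for p in plan.heldout_patients:
        side[p] = "held"
    for f, (_, tune_p) in enumerate(plan.folds):
        for p in tune_p:
            side[p] = f
    df = ann.df
    for _, grp in df.groupby("patient_id"):
        assignments = {side[p] for p in grp["patient_id"]}
        assert len(assignments) == 1


# ------------------------------------------------------------------ thresholds
def test_choose_cutoff_midpoint_convention():
    scores = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 0.99])
    labels = np.array([0] * 10 + [1])
    pol = choose_cutoff(scores, labels, 0.90)
    assert pol.cutoff == pytest.approx(0.95)  # midpoint of 0.9 and 1.0


def test_choose_cutoff_target_one_above_max_control():
    scores = np.array([0.2, 0.4, 0.9])
    labels = np.array([0, 0, 1])
    pol = choose_cutoff(scores, labels, 1.0)
    assert pol.cutoff > 0.4


def test_choose_cutoff_specificity_always_met():
    rng = np.random.default_rng(5)
    for _ in range(100):
        n = rng.integers(10, 60)
        scores = rng.random(n)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            continue
        target = rng.uniform(0.5, 1.0)
        pol = choose_cutoff(scores, labels, target)
        controls = scores[labels == 0]
        realized = np.mean(controls <= pol.cutoff)
        assert realized >= target - 1e-12


# --------------------------------------------------------------------- metrics
def test_metrics_perfect_separation():
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    labels = np.array([0, 0, 1, 1])
    rep = compute_metrics(scores, labels, cutoff=0.5)
    assert rep.auroc == 1.0
    assert rep.mcc == 1.0
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0


def test_metrics_all_tied_scores():
    rep = compute_metrics(np.full(6, 0.4), np.array([0, 1] * 3))
    assert rep.auroc == 0.5


def test_auroc_equals_pair_counting_oracle():
    scores = np.array([0.3, 0.7, 0.7, 0.1, 0.9, 0.5])
    labels = np.array([0, 1, 0, 0, 1, 1])
    rep = compute_metrics(scores, labels)
    conc = 0.0
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    for i in pos:
        for j in neg:
            conc += 1.0 if scores[i] > scores[j] else (0.5 if scores[i] == scores[j] else 0.0)
    assert rep.auroc == pytest.approx(conc / (len(pos) * len(neg)))


def test_metrics_single_class_rejected():
    with pytest.raises(ValueError):
        compute_metrics(np.array([0.1, 0.9]), np.array([1, 1]))


def test_per_stratum_sensitivity():
    scores = np.array([0.9, 0.2, 0.95, 0.8])
    labels = np.array([1, 1, 1, 0])
    rep = compute_metrics(scores, labels, cutoff=0.5,
                          strata={"early": np.array([True, True, False, False])})
    assert rep.per_stratum_sensitivity["early"] == 0.5


# ------------------------------------------------------------------- bootstrap
def test_bootstrap_deterministic_and_contains_point():
    rng = np.random.default_rng(2)
    scores = rng.random(80)
    labels = rng.integers(0, 2, size=80)
    from sklearn.metrics import roc_auc_score
    fn = lambda s, y: roc_auc_score(y, s)
    ci1 = bootstrap_ci(fn, scores, labels, n_boot=200, seed=9)
    ci2 = bootstrap_ci(fn, scores, labels, n_boot=200, seed=9)
    assert ci1 == ci2
    lo, point, hi = ci1
    assert lo <= point <= hi


def test_bootstrap_self_delta_centered_at_zero():
    rng = np.random.default_rng(4)
    scores = rng.random(60)
    labels = rng.integers(0, 2, size=60)
    from sklearn.metrics import roc_auc_score
    fn = lambda s, y: roc_auc_score(y, s)
    lo, point, hi = bootstrap_ci(fn, scores, labels, n_boot=150, seed=1,
                                 scores2=scores)
    assert point == 0.0
    assert lo <= 0.0 <= hi


def test_bootstrap_requires_enough_draws():
    with pytest.raises(ValueError):
        bootstrap_ci(lambda s, y: 0.0, np.zeros(4), np.array([0, 1, 0, 1]), n_boot=10)


# ------------------------------------------------------------------- batch AUC
def test_batch_auc_trivial_cases():
    sup = np.array(["a", "a", "b", "b"])
    ind = np.array([0.0, 0.0, 1.0, 1.0])
    assert batch_auc(ind, sup) == 1.0
    assert batch_auc(1.0 - ind, sup) == 0.0
    with pytest.raises(ValueError):
        batch_auc(ind, np.array(["a"] * 4))


def test_batch_auc_near_half_when_independent():
    rng = np.random.default_rng(3)
    n = 4000
    sup = np.where(rng.random(n) < 0.5, "a", "b")
    scores = rng.random(n)
    n1 = (sup == "a").sum()
    n2 = n - n1
    se = np.sqrt((n + 1) / (12 * n1 * n2))
    assert abs(batch_auc(scores, sup) - 0.5) < 3 * se


# -------------------------------------------------------------- downsampling
def test_downsample_conserves_totals_and_margins():
    rng = np.random.default_rng(6)
    x_row = rng.poisson(3, size=50)
    r_row = rng.poisson(100, size=5)
    total = x_row.sum() + r_row.sum()
    xd, rd = downsample_counts(x_row, r_row, 0.4, rng)
    assert xd.sum() + rd.sum() == int(round(0.4 * total))
    assert (xd <= x_row).all() and (rd <= r_row).all()
    xd1, rd1 = downsample_counts(x_row, r_row, 1.0, rng)
    np.testing.assert_array_equal(xd1, x_row)
    np.testing.assert_array_equal(rd1, r_row)


def test_dilution_structure_and_conservation(cohort):
    """10+10 per supplier x 4 ratios x 2 suppliers -> 800 mixtures."""
    co = cohort
    ann = co.annotations
    # cheap deterministic scorer: normalized signal content
    sig = co.truth.signal_indices

    def predict_fn(xs, rs):
        return np.asarray(xs)[:, sig].sum(axis=1) / (np.asarray(xs).sum(axis=1) + 1)

    scores = predict_fn(co.x.dense(), co.r.values)
    out = dilution_experiment(co.x, co.r, ann, scores, predict_fn, seed=0)
    assert len(out) == 800
    assert set(out["ratio"]) == {0.8, 0.6, 0.4, 0.2}
    counts = out.groupby(["supplier", "ratio"]).size()
    assert (counts == 100).all()
    # mean mixture score decreases with the cancer fraction
    means = out.groupby("ratio")["score"].mean()
    assert means.loc[0.8] > means.loc[0.2]


def test_dilution_rejects_small_cohorts():
    co = simulate_cohort(SimConfig(n_samples=40, d_onc=30, m_endo=5,
                                   signal_features=5, seed=2))
    scores = np.linspace(0, 1, 40)
    with pytest.raises(ValueError):
        dilution_experiment(co.x, co.r, co.annotations, scores,
                            lambda xs, rs: np.zeros(len(xs)), n_per_side=10)


# -------------------------------------------------------------- ensembling
def test_seed_ensembling_improves_tuning_auc():
    """Averaging scores over per-fold seeds beats the median single seed."""
    import warnings

    from sklearn.metrics import roc_auc_score

    from oncvae import ModelConfig, TrainOpts, cross_validate

    co = simulate_cohort(SimConfig(n_samples=400, d_onc=600, m_endo=15,
                                   signal_features=60, seed=820))
    plan = make_splits(co.annotations, held_out_fraction=0.2, n_folds=3,
                       seeds_per_fold=2, seed=0)
    cfg = ModelConfig(d=600, m=15, k=8, hidden_onc=64, hidden_lib=32,
                      hidden_dec=64, eta=50, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = cross_validate(co, plan, cfg, TrainOpts(n_epochs=30),
                               selection=None, base_seed=0)
    cv = table.cv_scores(representative_only=False)
    ens_auc = roc_auc_score(cv["label"], cv["score"])
    long = table.long[table.long.split == "cv"].merge(
        co.annotations.df[["sample_id", "label"]], on="sample_id"
    )
    seed_aucs = [roc_auc_score(g["label"], g["score"])
                 for _, g in long.groupby("seed")]
    assert ens_auc >= np.median(seed_aucs)
    # every tuning sample is scored by exactly seeds_per_fold models
    assert (long.groupby("sample_id").size() == 2).all()


# --------------------------------------------------------------- perturbation
def test_ablate_features_identity_and_full(cohort):
    x = cohort.x
    same = ablate_features(x, [])
    assert (same.values != x.values).nnz == 0
    allz = ablate_features(x, list(x.feature_ids))
    assert allz.values.nnz == 0
    one = ablate_features(x, [x.feature_ids[3]])
    assert one.dense()[:, 3].sum() == 0
    untouched = np.delete(np.arange(x.n_features), 3)
    np.testing.assert_array_equal(one.dense()[:, untouched], x.dense()[:, untouched])
    with pytest.raises(KeyError):
        ablate_features(x, ["no_such_feature"])


def test_permute_features_preserves_column_multisets(cohort):
    x = cohort.x
    feats = list(x.feature_ids[:5])
    xp = permute_features(x, feats, seed=1)
    for j in range(5):
        assert sorted(xp.dense()[:, j]) == sorted(x.dense()[:, j])
    np.testing.assert_array_equal(xp.dense()[:, 5:], x.dense()[:, 5:])
    xp2 = permute_features(x, feats, seed=1)
    np.testing.assert_array_equal(xp.dense(), xp2.dense())
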