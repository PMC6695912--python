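"""LOPO folds, classifiers, covariates and majority-vote aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from emgmh.classify import (ModelSpec, TOP_MOTIONS, age_category,
                            append_covariates, bmi_category, drop_covariates,
                            evaluate_per_motion, fit_predict,
                            fold_training_statistics, lopo_folds,
                            lopo_predictions, majority_vote,
                            weighted_vote_nested)


def _paired_matrix(n_patients, sep=0.0, reps=3, seed=0, motion="EF"):
    """Paired-limb matrix: per-patient offset shared by both limbs,
    class separation `sep` on one feature."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        off = rng.normal(0, 0.5)
        for limb, label in (("healthy", "healthy"), ("injured", "injured")):
            for r in range(reps):
                val = off + rng.normal(0, 1) + (sep if label == "injured" else 0)
                rows.append({"patient": f"P{p:03d}", "limb": limb,
                             "motion": motion, "repetition": r, "label": label,
                             "BB__F": val, "PT__F": rng.normal()})
    return pd.DataFrame(rows)


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(classifier="mlp")
    with pytest.raises(ValueError):
        ModelSpec(rf_trees=0)
    with pytest.raises(ValueError):
        ModelSpec(svm_cost=0.0)


def test_lopo_fold_structure():
    m = _paired_matrix(5)
    folds = list(lopo_folds(m))
    assert len(folds) == 5
    for pid, train_ix, test_ix in folds:
        assert set(m.loc[test_ix, "patient"]) == {pid}
        assert pid not in set(m.loc[train_ix, "patient"])
        assert len(test_ix) == 6  # 2 limbs x 3 reps
    # every instance predicted exactly once
    all_test = np.concatenate([t for _, _, t in folds])
    assert len(all_test) == len(m) and len(set(all_test)) == len(m)


def test_lopo_needs_three_patients():
    with pytest.raises(ValueError):
        list(lopo_folds(_paired_matrix(2)))


def test_27_patient_fold_counts():
    m = _paired_matrix(27)
    assert len(m) == 162
    assert len(list(lopo_folds(m))) == 27


@pytest.mark.parametrize("clf", ["lda", "svm", "rf"])
def test_separated_gaussians_classified(clf):
    """d=2, 6-sigma separation: Bayes error ~0.13%, accuracy must be high."""
    rng = np.random.default_rng(1)
    rows = []
    for p in range(20):
        for limb, label, mu in (("healthy", "healthy", 0.0), ("injured", "injured", 6.0)):
            for r in range(5):
                rows.append({"patient": f"P{p:03d}", "limb": limb, "motion": "EF",
                             "repetition": r, "label": label,
                             "BB__F": mu + rng.normal(), "PT__F": rng.normal()})
    m = pd.DataFrame(rows)
    preds = lopo_predictions(m, ModelSpec(classifier=clf, seed=0))
    assert (preds["y_true"] == preds["y_pred"]).mean() >= 0.99


def test_lda_symmetric_threshold():
    """1-D symmetric classes: the midpoint separates them exactly."""
    train = pd.DataFrame({
        "patient": [f"P{i}" for i in range(8)],
        "limb": "healthy", "motion": "EF", "repetition": 0,
        "label": ["A"] * 4 + ["B"] * 4,
        "BB__F": [-1.2, -1.0, -0.8, -1.0, 0.8, 1.0, 1.2, 1.0],
    })
    test = train.copy()
    test["BB__F"] = [-0.1, 0.1, -2.0, 2.0, -0.5, 0.5, -3.0, 3.0]
    pred = fit_predict(train, test, ModelSpec("lda"))
    assert list(pred) == ["A", "B", "A", "B", "A", "B", "A", "B"]


def test_single_class_training_fold_rejected():
    m = _paired_matrix(4)
    m["label"] = "healthy"
    with pytest.raises(ValueError):
        fit_predict(m, m, ModelSpec("lda"))


def test_chance_level_with_permuted_labels():
    """Identical class distributions: LOPO accuracy falls in the 99%
    binomial chance band (~40-60% at 162 instances)."""
    from scipy.stats import binom

    m = _paired_matrix(27, sep=0.0, seed=7)
    preds = lopo_predictions(m, ModelSpec("lda"))
    acc = (preds["y_true"] == preds["y_pred"]).mean()
    n = len(m)
    lo, hi = binom.ppf([0.005, 0.995], n, 0.5) / n
    assert lo <= acc <= hi


def test_missing_cells_imputed_not_fatal():
    m = _paired_matrix(6, sep=3.0)
    m.loc[m.index[:4], "PT__F"] = np.nan
    preds = lopo_predictions(m, ModelSpec("lda"))
    assert len(preds) == len(m)


# ---------------------------------------------------------------------------
# votes

def _pred_frame(decisions):
    """decisions: {motion: label} for one instance, truth 'injured'."""
    return pd.DataFrame([
        {"patient": "P000", "limb": "injured", "repetition": 0,
         "motion": m, "y_true": "injured", "y_pred": lab}
        for m, lab in decisions.items()
    ])


def test_plain_majority():
    dec = {m: ("injured" if i < 6 else "healthy")
           for i, m in enumerate("EF EE P S WF WE UD RD HO HC".split())}
    rep = majority_vote(_pred_frame(dec))
    assert rep.decisions["y_vote"].iloc[0] == "injured"
    assert rep.accuracy_pct == 100.0


def test_weighted_vote_follows_heavier_model():
    """Worked example: weights EF = 62.3, EE = 65.4; on disagreement the
    decision follows EE."""
    dec = {"EF": "healthy", "EE": "injured"}
    rep = majority_vote(_pred_frame(dec), weights={"EF": 62.3, "EE": 65.4})
    assert rep.decisions["y_vote"].iloc[0] == "injured"
    rep2 = majority_vote(_pred_frame({"EF": "injured", "EE": "healthy"}),
                         weights={"EF": 62.3, "EE": 65.4})
    assert rep2.decisions["y_vote"].iloc[0] == "healthy"


def test_equal_weights_reduce_to_plain_vote():
    dec = {m: ("injured" if i < 6 else "healthy")
           for i, m in enumerate("EF EE P S WF WE UD RD HO HC".split())}
    plain = majority_vote(_pred_frame(dec))
    weighted = majority_vote(_pred_frame(dec), weights={m: 50.0 for m in dec})
    assert (plain.decisions["y_vote"] == weighted.decisions["y_vote"]).all()


def test_unweighted_tie_defaults_to_injured():
    dec = {m: ("injured" if i < 5 else "healthy")
           for i, m in enumerate("EF EE P S WF WE UD RD HO HC".split())}
    rep = majority_vote(_pred_frame(dec))
    assert rep.decisions["y_vote"].iloc[0] == "injured"


def test_top_motion_preset():
    assert TOP_MOTIONS == ("EF", "EE", "P", "S", "WF", "UD", "HC")
    dec = {m: "healthy" for m in "EF EE P S WF UD HC".split()}
    dec.update({m: "injured" for m in ("WE", "RD", "HO")})
    rep = majority_vote(_pred_frame(dec), motions_used=TOP_MOTIONS)
    assert rep.decisions["y_vote"].iloc[0] == "healthy"  # excluded motions ignored


def test_per_motion_and_nested_vote_on_separable_cohort():
    matrices = {m: _paired_matrix(8, sep=4.0, seed=i, motion=m)
                for i, m in enumerate(("EF", "EE", "P"))}
    preds, acc = evaluate_per_motion(matrices, ModelSpec("lda"))
    assert all(a >= 90.0 for a in acc.values())
    rep = weighted_vote_nested(matrices, ModelSpec("lda"))
    assert rep.accuracy_pct >= 90.0
    assert len(rep.decisions) == 8 * 2 * 3


# ---------------------------------------------------------------------------
# covariates

def test_covariate_categories():
    assert age_category(28) == 1
    assert age_category(38) == 2
    assert age_category(60) == 3
    assert bmi_category(22) == 1
    assert bmi_category(27) == 2
    assert bmi_category(32) == 3


def test_append_and_drop_covariates_round_trip():
    m = _paired_matrix(3)
    cov = {f"P{p:03d}": {"sex": 1, "age_cat": age_category(28), "bmi_cat": 2}
           for p in range(3)}
    m2 = append_covariates(m, cov)
    assert (m2["cov__age_cat"] == 1).all()
    # both limbs of one patient share covariates
    for pid, grp in m2.groupby("patient"):
        assert grp["cov__bmi_cat"].nunique() == 1
    pd.testing.assert_frame_equal(drop_covariates(m2), m)
    with pytest.raises(ValueError):
        append_covariates(m, {"P000": {"sex": 1}})


# ---------------------------------------------------------------------------
# leakage

def test_training_statistics_blind_to_heldout_labels():
    """Flipping a held-out patient's labels changes no training-fold
    statistic (imputer medians, scaler moments, fitted coefficients)."""
    m = _paired_matrix(6, sep=1.0, seed=2)
    for clf in ("lda", "svm"):
        spec = ModelSpec(clf)
        before = fold_training_statistics(m, spec)
        flipped = m.copy()
        mask = flipped["patient"] == "P002"
        flipped.loc[mask, "label"] = flipped.loc[mask, "label"].map(
            {"healthy": "injured", "injured": "healthy"})
        after = fold_training_statistics(flipped, spec)
        assert before["P002"] == after["P002"]
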