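"""Per-motion classifiers, leave-one-patient-out CV, and majority votes.

Models: LDA (pooled covariance with a small ridge/shrinkage), linear SVM
(training-fold standardization), and a 200-tree random forest.  Evaluation
is leave-one-patient-out (LOPO): each fold holds out every instance of one
patient (both limbs, all repetitions), so patient identity can never leak.

Vote aggregation combines the ten per-motion models per instance key
(patient, limb, repetition):

* all      -- plain majority over all motions,
* top      -- plain majority over the top motions (EF, EE, P, S, WF, UD, HC),
* weighted -- each motion votes with a weight equal to its model accuracy;
  the decision is the label with the larger weight sum.

By default weighted-vote weights are recomputed inside each training fold
(inner LOPO), which keeps the procedure leak-free; in-sample weighting
(whole-dataset per-motion accuracies, via :func:`majority_vote` with a
precomputed weight table) is available for comparison but leaks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import ID_COLUMNS, LABEL_COLUMN, feature_columns

TOP_MOTIONS = ("EF", "EE", "P", "S", "WF", "UD", "HC")
POSITIVE_LABEL = "injured"  # conservative tie fallback for a screening context


@dataclass(frozen=True)
class ModelSpec:
    classifier: str = "lda"  # lda | svm | rf
    rf_trees: int = 200
    svm_cost: float = 1.0
    lda_shrinkage: float = 1e-4
    seed: int = 0
    covariates: tuple[str, ...] = ()
    label_scheme: str = "healthy-vs-injured"

    def __post_init__(self) -> None:
        if self.classifier not in ("lda", "svm", "rf"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be > 0")


def build_model(spec: ModelSpec) -> Pipeline:
    steps: list[tuple] = [("impute", SimpleImputer(strategy="median"))]
    if spec.classifier == "lda":
        steps.append(("clf", LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=spec.lda_shrinkage)))
    elif spec.classifier == "svm":
        steps.append(("scale", StandardScaler()))
        steps.append(("clf", SVC(kernel="linear", C=spec.svm_cost,
                                 decision_function_shape="ovr")))
    else:
        steps.append(("clf", RandomForestClassifier(
            n_estimators=spec.rf_trees, max_features="sqrt",
            random_state=spec.seed)))
    return Pipeline(steps)


def lopo_folds(matrix: pd.DataFrame):
    """Yield (patient, train_index, test_index); one fold per patient."""
    patients = sorted(matrix["patient"].unique())
    if len(patients) < 3:
        raise ValueError("leave-one-patient-out requires >= 3 patients")
    if matrix.index.duplicated().any():
        raise ValueError("matrix index must uniquely identify instances")
    for pid in patients:
        test = matrix.index[matrix["patient"] == pid]
        train = matrix.index[matrix["patient"] != pid]
        yield pid, train, test


def fit_predict(train: pd.DataFrame, test: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Fit on the training matrix, predict labels for the test matrix."""
    cols = feature_columns(train)
    y = train[LABEL_COLUMN].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training fold contains a single class")
    model = build_model(spec)
    model.fit(train[cols].to_numpy(float), y)
    return model.predict(test[cols].to_numpy(float))


def lopo_predictions(matrix: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """LOPO predictions for one motion matrix: id columns + y_true, y_pred."""
    out = []
    for pid, train_ix, test_ix in lopo_folds(matrix):
        pred = fit_predict(matrix.loc[train_ix], matrix.loc[test_ix], spec)
        part = matrix.loc[test_ix, ID_COLUMNS + [LABEL_COLUMN]].copy()
        part = part.rename(columns={LABEL_COLUMN: "y_true"})
        part["y_pred"] = pred
        out.append(part)
    res = pd.concat(out, ignore_index=True)
    assert len(res) == len(matrix), "every instance predicted exactly once"
    return res


def accuracy(pred: pd.DataFrame) -> float:
    return float((pred["y_true"] == pred["y_pred"]).mean())


def evaluate_per_motion(
    matrices: dict[str, pd.DataFrame], spec: ModelSpec
) -> tuple[pd.DataFrame, dict[str, float]]:
    """LOPO-evaluate each motion model.

    Returns (long predictions frame with a ``motion`` column, per-motion
    accuracy in percent).
    """
    preds = []
    acc: dict[str, float] = {}
    for motion, matrix in matrices.items():
        p = lopo_predictions(matrix, spec)
        p["motion"] = motion
        preds.append(p)
        acc[motion] = 100.0 * accuracy(p)
    return pd.concat(preds, ignore_index=True), acc


@dataclass
class VoteReport:
    scheme: str
    decisions: pd.DataFrame  # per instance key: y_true, y_vote
    accuracy_pct: float
    motions_used: tuple[str, ...]
    weights: dict[str, float] | None = None


def majority_vote(
    predictions: pd.DataFrame,
    motions_used: tuple[str, ...] | None = None,
    weights: dict[str, float] | None = None,
    per_limb: bool = False,
) -> VoteReport:
    """Aggregate per-motion predictions into one decision per instance key.

    ``predictions`` is the long frame from :func:`evaluate_per_motion`.
    Unweighted ties fall back to the weighted rule when weights are given,
    else to the positive (injured) class.  ``per_limb=True`` additionally
    aggregates the repetitions of a limb by majority.
    """
    df = predictions
    if motions_used is not None:
        df = df[df["motion"].isin(motions_used)]
    motions = tuple(sorted(df["motion"].unique()))
    keys = ["patient", "limb"] + ([] if per_limb else ["repetition"])

    rows = []
    for key, grp in df.groupby(keys, sort=True):
        labels = grp["y_pred"].to_numpy()
        uniq, counts = np.unique(labels, return_counts=True)
        order = np.argsort(counts)
        if len(uniq) > 1 and counts[order[-1]] == counts[order[-2]]:
            if weights is not None:
                sums = {
                    lab: float(sum(weights.get(m, 0.0)
                                   for m in grp.loc[grp["y_pred"] == lab, "motion"]))
                    for lab in uniq
                }
                decision = max(sums, key=lambda lab: (sums[lab], lab == POSITIVE_LABEL))
            else:
                decision = POSITIVE_LABEL
        elif weights is not None:
            sums = {
                lab: float(sum(weights.get(m, 0.0)
                               for m in grp.loc[grp["y_pred"] == lab, "motion"]))
                for lab in uniq
            }
            decision = max(sums, key=lambda lab: (sums[lab], lab == POSITIVE_LABEL))
        else:
            decision = uniq[order[-1]]
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row["y_true"] = grp["y_true"].iloc[0]
        row["y_vote"] = decision
        rows.append(row)
    dec = pd.DataFrame(rows)
    acc = 100.0 * float((dec["y_true"] == dec["y_vote"]).mean())
    scheme = "weighted" if weights is not None else (
        "top" if motions_used == TOP_MOTIONS else "all")
    return VoteReport(scheme, dec, acc, motions, dict(weights) if weights else None)


def weighted_vote_nested(
    matrices: dict[str, pd.DataFrame], spec: ModelSpec, per_limb: bool = False
) -> VoteReport:
    """Leak-free weighted vote: per-motion weights from inner LOPO on each
    training fold; per-motion models retrained per fold."""
    all_keys = ["patient", "limb", "repetition"]
    rows = []
    any_matrix = next(iter(matrices.values()))
    for pid, _, _ in lopo_folds(any_matrix):
        fold_preds = []
        weights: dict[str, float] = {}
        for motion, matrix in matrices.items():
            train = matrix[matrix["patient"] != pid]
            test = matrix[matrix["patient"] == pid]
            inner = lopo_predictions(train, spec)
            weights[motion] = 100.0 * accuracy(inner)
            part = test[all_keys + [LABEL_COLUMN]].rename(columns={LABEL_COLUMN: "y_true"})
            part = part.copy()
            part["y_pred"] = fit_predict(train, test, spec)
            part["motion"] = motion
            fold_preds.append(part)
        fold_df = pd.concat(fold_preds, ignore_index=True)
        vote = majority_vote(fold_df, weights=weights, per_limb=per_limb)
        rows.append(vote.decisions)
    dec = pd.concat(rows, ignore_index=True)
    acc = 100.0 * float((dec["y_true"] == dec["y_vote"]).mean())
    return VoteReport("weighted", dec, acc, tuple(sorted(matrices)), None)


# ---------------------------------------------------------------------------
# covariates

AGE_EDGES = (30.0, 45.0)       # categories: <30, 30-45, >45
BMI_EDGES = (25.0, 30.0)       # normal 18.5-25, overweight 25-30, obese >30


def age_category(age: float) -> int:
    return 1 if age < AGE_EDGES[0] else (2 if age <= AGE_EDGES[1] else 3)


def bmi_category(bmi: float) -> int:
    return 1 if bmi <= BMI_EDGES[0] else (2 if bmi <= BMI_EDGES[1] else 3)


def append_covariates(matrix: pd.DataFrame, covariates: dict[str, dict]) -> pd.DataFrame:
    """Append ordinal covariate columns (cov__*) per patient, both limbs alike."""
    missing = set(matrix["patient"].unique()) - set(covariates)
    if missing:
        raise ValueError(f"missing covariates for patients: {sorted(missing)}")
    out = matrix.copy()
    names = sorted({k for cov in covariates.values() for k in cov})
    for name in names:
        out[f"cov__{name}"] = matrix["patient"].map(
            lambda p: covariates[p][name]).astype(float)
    return out


def drop_covariates(matrix: pd.DataFrame) -> pd.DataFrame:
    return matrix[[c for c in matrix.columns if not c.startswith("cov__")]]


# ---------------------------------------------------------------------------
# leakage audit

def fold_training_statistics(matrix: pd.DataFrame, spec: ModelSpec) -> dict[str, str]:
    """Hash of every fitted training-fold statistic, keyed by held-out patient.

    Used to audit that held-out instances never influence imputation,
    standardization, or the fitted model.
    """
    hashes: dict[str, str] = {}
    cols = feature_columns(matrix)
    for pid, train_ix, _ in lopo_folds(matrix):
        model = build_model(spec)
        train = matrix.loc[train_ix]
        model.fit(train[cols].to_numpy(float), train[LABEL_COLUMN].to_numpy())
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(model.named_steps["impute"].statistics_).tobytes())
        if "scale" in model.named_steps:
            h.update(np.ascontiguousarray(model.named_steps["scale"].mean_).tobytes())
            h.update(np.ascontiguousarray(model.named_steps["scale"].scale_).tobytes())
        clf = model.named_steps["clf"]
        if hasattr(clf, "coef_"):
            h.update(np.ascontiguousarray(clf.coef_).tobytes())
        elif hasattr(clf, "feature_importances_"):
            h.update(np.ascontiguousarray(clf.feature_importances_).tobytes())
        hashes[pid] = h.hexdigest()
    return hashes
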