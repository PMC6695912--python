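"""Per-motion LOPO classification and majority-vote aggregation.

For each requested feature set and classifier, evaluates the ten per-motion
models under leave-one-patient-out cross-validation, then combines them
with the all-motion, top-motion and (leak-free) weighted majority votes.
Tables go to results/accuracy/.
"""

import argparse
from pathlib import Path

import pandas as pd

from emgmh.classify import (ModelSpec, TOP_MOTIONS, evaluate_per_motion,
                            majority_vote, weighted_vote_nested)
from emgmh.io import read_feature_matrix

ap = argparse.ArgumentParser()
ap.add_argument("--features-dir", default="results/features")
ap.add_argument("--feature-sets", default="FS4,FS5")
ap.add_argument("--classifiers", default="lda,svm,rf")
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out", default="results/accuracy")
args = ap.parse_args()

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)
acc_rows, vote_rows = [], []
for fs in args.feature_sets.split(","):
    matrix = read_feature_matrix(Path(args.features_dir) / f"{fs}.csv")
    by_motion = {m: g.reset_index(drop=True) for m, g in matrix.groupby("motion")}
    for clf in args.classifiers.split(","):
        spec = ModelSpec(classifier=clf, seed=args.seed)
        preds, acc = evaluate_per_motion(by_motion, spec)
        for motion, a in acc.items():
            acc_rows.append({"feature_set": fs, "motion": motion,
                             "classifier": clf, "accuracy_pct": a})
        vote_rows.append({"feature_set": fs, "classifier": clf, "scheme": "all",
                          "accuracy_pct": majority_vote(preds).accuracy_pct})
        vote_rows.append({"feature_set": fs, "classifier": clf, "scheme": "top",
                          "accuracy_pct": majority_vote(
                              preds, motions_used=TOP_MOTIONS).accuracy_pct})
        vote_rows.append({"feature_set": fs, "classifier": clf,
                          "scheme": "weighted",
                          "accuracy_pct": weighted_vote_nested(
                              by_motion, spec).accuracy_pct})
        print(f"{fs} + {clf}: per-motion "
              f"{min(acc.values()):.1f}-{max(acc.values()):.1f}%, "
              f"weighted vote {vote_rows[-1]['accuracy_pct']:.1f}%")

per_motion = pd.DataFrame(acc_rows).pivot(
    index=["feature_set", "motion"], columns="classifier", values="accuracy_pct")
votes = pd.DataFrame(vote_rows).pivot(
    index=["feature_set", "scheme"], columns="classifier", values="accuracy_pct")
per_motion.round(1).to_csv(out / "per_motion.csv")
votes.round(1).to_csv(out / "votes.csv")
print(f"tables -> {out}/per_motion.csv, {out}/votes.csv")
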