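"""ReliefF feature weighting and feature-set reduction.

ReliefF rewards a feature when its value is close to the feature's value in
nearby same-class instances (hits) and far from nearby other-class instances
(misses).  For each sampled instance the k nearest hits and k nearest misses
(total range-normalised Manhattan distance) are found and

    W[f] += sum_miss diff(f) / (n k)  -  sum_hit diff(f) / (n k),

with diff(f, a, b) = |a_f - b_f| / (max_f - min_f), so weights lie in
[-1, 1] and a good feature gets a positive weight.

Multi-dimensional features (AR4 etc.) and the seven per-muscle copies of a
feature are ranked as a block via the maximum weight over their columns, so
selection operates at the level of named features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ModelSpec, evaluate_per_motion, majority_vote
from .features import column_base_feature
from .io import LABEL_COLUMN, feature_columns


@dataclass(frozen=True)
class ReliefParams:
    k_neighbors: int = 10
    n_sampled: int | None = None  # None = all instances
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def relieff_weights(matrix: pd.DataFrame, p: ReliefParams | None = None) -> pd.Series:
    """Per-column ReliefF weights for a binary-labelled feature matrix."""
    p = p or ReliefParams()
    cols = feature_columns(matrix)
    y = matrix[LABEL_COLUMN].to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("relieff_weights requires binary labels")
    x = matrix[cols].to_numpy(float)
    # NaN sentinels would poison distances; impute by column median up front
    if np.isnan(x).any():
        med = np.nanmedian(x, axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        x = np.where(np.isnan(x), med, x)

    n, d = x.shape
    for c in classes:
        if (y == c).sum() <= p.k_neighbors:
            raise ValueError(
                f"class {c!r} has <= k_neighbors={p.k_neighbors} instances")

    rng = np.random.default_rng(p.seed)
    span = x.max(axis=0) - x.min(axis=0)
    span[span == 0] = 1.0  # constant feature: all diffs zero anyway
    xn = (x - x.min(axis=0)) / span

    if p.n_sampled is None or p.n_sampled >= n:
        sampled = np.arange(n)
    else:
        sampled = rng.choice(n, size=p.n_sampled, replace=False)

    w = np.zeros(d)
    k = p.k_neighbors
    m = sampled.size
    for i in sampled:
        diffs = np.abs(xn - xn[i])          # [n, d]
        dist = diffs.sum(axis=1)
        dist[i] = np.inf                    # exclude self
        same = y == y[i]
        hit_ix = np.flatnonzero(same)
        miss_ix = np.flatnonzero(~same)
        hits = hit_ix[np.argsort(dist[hit_ix], kind="stable")[:k]]
        misses = miss_ix[np.argsort(dist[miss_ix], kind="stable")[:k]]
        w += diffs[misses].sum(axis=0) / (m * k)
        w -= diffs[hits].sum(axis=0) / (m * k)
    return pd.Series(w, index=cols, name="weight")


def block_weights(weights: pd.Series) -> pd.Series:
    """Aggregate per-column weights to per-feature blocks (max over columns)."""
    base = weights.groupby(weights.index.map(column_base_feature)).max()
    return base.sort_values(ascending=False)


@dataclass
class FeatureRanking:
    per_motion_weights: pd.DataFrame  # features x motions (block weights)
    mean_rank: pd.Series              # ascending = better
    selected: list[str]
    stability: float                  # fraction of seeds agreeing with `selected`


def select_within_set(
    matrices_by_motion: dict[str, pd.DataFrame],
    p: ReliefParams | None = None,
    m_select: int = 3,
    n_stability_runs: int = 0,
) -> FeatureRanking:
    """Run ReliefF per motion; aggregate by mean rank; return top-m features.

    Features "consistently ranked among the best for all motions" are
    operationalised as lowest mean rank across the per-motion runs; rank
    ties break by mean weight.
    """
    p = p or ReliefParams()
    per_motion = {}
    for motion, matrix in matrices_by_motion.items():
        per_motion[motion] = block_weights(relieff_weights(matrix, p))
    table = pd.DataFrame(per_motion)
    ranks = table.rank(ascending=False, axis=0)
    mean_rank = ranks.mean(axis=1)
    mean_weight = table.mean(axis=1)
    order = sorted(table.index, key=lambda f: (mean_rank[f], -mean_weight[f]))
    selected = order[:m_select]

    stability = 1.0
    if n_stability_runs > 1:
        agree = 0
        for run in range(n_stability_runs):
            sub = select_within_set(
                {mo: mx.sample(frac=0.8, random_state=p.seed + 1 + run)
                 for mo, mx in matrices_by_motion.items()},
                ReliefParams(p.k_neighbors, p.n_sampled, p.seed + 1 + run),
                m_select=m_select,
            )
            agree += set(sub.selected) == set(selected)
        stability = agree / n_stability_runs
    return FeatureRanking(table, mean_rank.sort_values(), selected, stability)


def rank_features_individually(
    matrices_by_motion_by_feature: dict[str, dict[str, pd.DataFrame]],
    specs: list[ModelSpec],
    per_limb: bool = False,
) -> pd.DataFrame:
    """Across-motion majority-vote LOPO accuracy of each feature on its own.

    ``matrices_by_motion_by_feature`` maps feature -> motion -> matrix, each
    matrix holding only that feature's per-channel columns.  Returns a table
    of accuracies (%) per classifier, ordered by LDA accuracy, the
    conventional presentation of individual-feature rankings.
    """
    rows = {}
    for feat, matrices in matrices_by_motion_by_feature.items():
        row = {}
        for spec in specs:
            preds, _ = evaluate_per_motion(matrices, spec)
            vote = majority_vote(preds, per_limb=per_limb)
            row[spec.classifier] = vote.accuracy_pct
        rows[feat] = row
    out = pd.DataFrame(rows).T
    sort_col = "lda" if "lda" in out.columns else out.columns[0]
    return out.sort_values(sort_col, ascending=False)


def split_matrix_by_feature(matrix: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a full feature matrix into single-feature matrices (id cols kept)."""
    from .io import ID_COLUMNS

    id_cols = ID_COLUMNS + [LABEL_COLUMN]
    cols = feature_columns(matrix)
    by_feat: dict[str, list[str]] = {}
    for c in cols:
        by_feat.setdefault(column_base_feature(c), []).append(c)
    return {f: matrix[id_cols + fcols].copy() for f, fcols in by_feat.items()}
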