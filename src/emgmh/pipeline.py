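"""End-to-end orchestration: simulate/load -> segment -> extract -> classify.

These helpers tie the stages together for the analysis drivers, the CLI and
the acceptance checks; every stage is importable and individually testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import (ModelSpec, TOP_MOTIONS, evaluate_per_motion,
                       majority_vote, weighted_vote_nested)
from .cohort import CohortSpec, EffectSpec, SimulatedCohort, simulate_cohort
from .features import FEATURE_SETS, FeatureParams, extract_matrix
from .io import ID_COLUMNS, Recording
from .preprocessing import MotionSegment, SegmenterParams, bandpass_notch, segment_trial


@dataclass
class SegmentationResult:
    segments: list[MotionSegment]
    qc: pd.DataFrame  # one row per trial: n_segments, flags, onset error if truth known


def segment_recordings(
    trials: list[tuple[dict, Recording]],
    params: SegmenterParams | None = None,
    mover_map: dict[str, tuple[str, ...]] | str | None = "default",
) -> SegmentationResult:
    """Segment every trial; detection on the raw path, cutting on the
    band-pass + notch path.  QC flags are collected, never dropped.

    ``mover_map`` maps motion code -> primary-mover channels used to drive
    onset detection (the per-motion override; quiet channels only dilute
    the detection envelope).  ``"default"`` uses the built-in anatomy map
    when the trial's motion is known; ``None`` sums all channels.
    """
    params = params or SegmenterParams()
    if mover_map == "default":
        from .cohort import PRIMARY_MOVERS

        mover_map = PRIMARY_MOVERS
    segments: list[MotionSegment] = []
    qc_rows = []
    for entry, rec in trials:
        filtered = bandpass_notch(rec, params)
        override = None
        if "manual_onset" in entry and "manual_offset" in entry:
            override = (int(entry["manual_onset"]), int(entry["manual_offset"]))
        p_trial = params
        motion = entry.get("motion")
        if (mover_map and motion in mover_map
                and params.detection_channel is None):
            movers = tuple(ch for ch in mover_map[motion] if ch in rec.channel_names)
            if movers:
                p_trial = replace(params, detection_channel=movers)
        segs = segment_trial(rec, p_trial, expected_bursts=1,
                             manual_override=override, filtered=filtered)
        flags = sorted({f for s in segs for f in s.qc})
        onset_err = np.nan
        if segs and "true_onset" in entry:
            onset_err = abs(segs[0].onset_index - entry["true_onset"]) / rec.sampling_rate
        for s in segs:
            s.meta.update({k: entry[k] for k in ID_COLUMNS + ["label"] if k in entry})
            segments.append(s)
        qc_rows.append({
            **{k: entry.get(k) for k in ID_COLUMNS},
            "n_segments": len(segs),
            "flags": ";".join(flags) if segs else "no-onset-found",
            "onset_error_s": onset_err,
        })
    return SegmentationResult(segments, pd.DataFrame(qc_rows))


def segment_cohort(cohort: SimulatedCohort,
                   params: SegmenterParams | None = None) -> SegmentationResult:
    return segment_recordings(list(cohort), params)


def matrices_by_motion(
    segments: list[MotionSegment],
    feature_set: str | tuple[str, ...] = "FS4",
    fp: FeatureParams | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-motion feature matrices with a unique instance index."""
    by_motion: dict[str, list[MotionSegment]] = {}
    for s in segments:
        by_motion.setdefault(s.meta["motion"], []).append(s)
    out = {}
    for motion, segs in sorted(by_motion.items()):
        m = extract_matrix(segs, fp, feature_set)
        m = m.reset_index(drop=True)
        out[motion] = m
    return out


def simulate_matrices(
    spec: CohortSpec,
    effect: EffectSpec | None = None,
    feature_set: str | tuple[str, ...] = "FS4",
    seg_params: SegmenterParams | None = None,
    fp: FeatureParams | None = None,
) -> tuple[dict[str, pd.DataFrame], SegmentationResult]:
    """Simulate a cohort and take it through segmentation and extraction."""
    cohort = simulate_cohort(spec, effect)
    seg = segment_cohort(cohort, seg_params)
    return matrices_by_motion(seg.segments, feature_set, fp), seg


@dataclass
class ReportBundle:
    """All tables of one full run; every number traces to a stored frame."""

    per_motion_accuracy: pd.DataFrame   # rows (feature_set, motion) x classifiers
    vote_accuracy: pd.DataFrame         # rows (feature_set, scheme) x classifiers
    qc_summary: pd.DataFrame
    config: dict = field(default_factory=dict)
    individual_ranking: pd.DataFrame | None = None


def run_pipeline(
    spec: CohortSpec,
    effect: EffectSpec | None = None,
    feature_sets: tuple[str, ...] = ("FS1", "FS4"),
    classifiers: tuple[str, ...] = ("lda",),
    vote_schemes: tuple[str, ...] = ("all", "top", "weighted"),
    seg_params: SegmenterParams | None = None,
    fp: FeatureParams | None = None,
    seed: int = 0,
) -> ReportBundle:
    """Simulated-cohort end-to-end run producing the report tables."""
    unknown = [f for f in feature_sets if f not in FEATURE_SETS]
    if unknown:
        raise ValueError(f"unknown feature sets: {unknown}")
    cohort = simulate_cohort(spec, effect)
    seg = segment_cohort(cohort, seg_params)

    acc_rows = []
    vote_rows = []
    for fs in feature_sets:
        matrices = matrices_by_motion(seg.segments, fs, fp)
        for clf in classifiers:
            mspec = ModelSpec(classifier=clf, seed=seed)
            preds, acc = evaluate_per_motion(matrices, mspec)
            for motion, a in acc.items():
                acc_rows.append({"feature_set": fs, "motion": motion,
                                 "classifier": clf, "accuracy_pct": a})
            for scheme in vote_schemes:
                if scheme == "all":
                    rep = majority_vote(preds)
                elif scheme == "top":
                    rep = majority_vote(preds, motions_used=TOP_MOTIONS)
                elif scheme == "weighted":
                    rep = weighted_vote_nested(matrices, mspec)
                else:
                    raise ValueError(f"unknown vote scheme {scheme!r}")
                vote_rows.append({"feature_set": fs, "scheme": scheme,
                                  "classifier": clf, "accuracy_pct": rep.accuracy_pct})

    acc_tbl = (pd.DataFrame(acc_rows)
               .pivot(index=["feature_set", "motion"], columns="classifier",
                      values="accuracy_pct"))
    vote_tbl = (pd.DataFrame(vote_rows)
                .pivot(index=["feature_set", "scheme"], columns="classifier",
                       values="accuracy_pct"))
    config = {
        "n_patients": spec.n_patients, "seed": spec.seed,
        "feature_sets": list(feature_sets), "classifiers": list(classifiers),
        "vote_schemes": list(vote_schemes), "model_seed": seed,
    }
    return ReportBundle(acc_tbl, vote_tbl, seg.qc, config)
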