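"""Segment every trial of the simulated cohort.

Runs the TKEO double-threshold segmenter on the cohort written by
01_simulate_cohort.py and reports how well detected onsets match the
generator's ground truth (a QC table goes to results/segmentation_qc.csv).
"""

import argparse
from pathlib import Path

from emgmh.io import iter_recordings, read_manifest
from emgmh.pipeline import segment_recordings
from emgmh.reporting import qc_counts

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", default="results/cohort")
ap.add_argument("--out", default="results/segmentation_qc.csv")
args = ap.parse_args()

manifest = read_manifest(Path(args.cohort) / "manifest.json")
res = segment_recordings(list(iter_recordings(manifest)))
res.qc.to_csv(args.out, index=False)

err = res.qc["onset_error_s"].dropna()
print(f"{len(res.segments)} segments from {len(res.qc)} trials")
print(f"onsets within 25 ms of ground truth: {100 * (err <= 0.025).mean():.1f}%")
print("QC flags:")
print(qc_counts(res.qc).to_string())
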