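"""Extract the per-motion feature matrices.

Re-runs segmentation in memory (cheap next to extraction) and computes the
requested feature sets over every motion segment, one CSV per feature set
under results/features/.  FS4 (MFL, MYOP) and FS5 (the nine per-category
winners) are what the downstream classification and selection steps use.
"""

import argparse
import time
from pathlib import Path

import pandas as pd

from emgmh.io import iter_recordings, read_manifest, write_feature_matrix
from emgmh.pipeline import matrices_by_motion, segment_recordings

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", default="results/cohort")
ap.add_argument("--feature-sets", default="FS4,FS5")
ap.add_argument("--out", default="results/features")
args = ap.parse_args()

manifest = read_manifest(Path(args.cohort) / "manifest.json")
segments = segment_recordings(list(iter_recordings(manifest))).segments
out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)

for fs in args.feature_sets.split(","):
    t0 = time.time()
    matrices = matrices_by_motion(segments, fs)
    table = pd.concat(matrices.values(), ignore_index=True)
    path = write_feature_matrix(table, out / f"{fs}.csv")
    n_feat = table.shape[1] - 6  # id columns + label + qc flag
    print(f"{fs}: {len(table)} instances x {n_feat} feature columns "
          f"-> {path} ({time.time() - t0:.0f} s)")
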