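"""Simulate the study cohort and write it to disk.

Generates a paired cohort (default 12 patients x 2 limbs x 10 motions x
3 repetitions, 7 channels at 1925.93 Hz) with the large planted
healthy-vs-injured effect, and writes one CSV per trial plus a JSON
manifest with ground-truth onsets under results/cohort/.
"""

import argparse

from emgmh.cohort import CohortSpec, EFFECT_PROFILES, simulate_cohort, write_cohort

ap = argparse.ArgumentParser()
ap.add_argument("--n-patients", type=int, default=12)
ap.add_argument("--seed", type=int, default=303)
ap.add_argument("--effect-profile", default="large",
                choices=sorted(EFFECT_PROFILES))
ap.add_argument("--out", default="results/cohort")
args = ap.parse_args()

spec = CohortSpec(n_patients=args.n_patients, seed=args.seed)
cohort = simulate_cohort(spec, EFFECT_PROFILES[args.effect_profile])
manifest = write_cohort(cohort, args.out)
print(f"wrote {len(cohort.recordings)} trials "
      f"({spec.n_patients} patients x 2 limbs x {len(spec.motions)} motions "
      f"x {spec.n_repetitions} reps); manifest: {manifest}")
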