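#!/usr/bin/env python
"""Calibration and power of the inference chain (reduced problem sizes).

Runs (a) null cohorts to estimate the group-level type-I error rate and the
uniformity of subject-level permutation p-values, and (b) grid-signal
cohorts at the default amplitude calibration to estimate recovery power.
Writes results/inference/calibration.json.  Scaled-down sizes here keep the
script interactive; tests and scripts/acceptance.py use the full protocol
sizes (50/200 cohorts).
"""

import json
from pathlib import Path

from hexdir import experiments

OUT = Path("results/inference")
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    null = experiments.null_calibration_summary(SEED, n_cohorts=60,
                                                n_perm_subjects=60, n_perm=500)
    power = experiments.recovery_summary(SEED + 1, n_cohorts=20)
    payload = {"null": null, "recovery": power}
    with open(OUT / "calibration.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    print(f"null group rejection rate (alpha .05): "
          f"{null['null_group_rejection_rate']:.3f} over {null['n_cohorts']} cohorts")
    print(f"subject permutation-p uniformity (KS p): "
          f"{null['subject_perm_p_ks_pvalue']:.3f}")
    print(f"grid recovery rate: {power['recovery_rate_pmEC_like']:.2f}, "
          f"alEC-like false positives: {power['false_positive_rate_alEC_like']:.2f}")
    print(f"mean cohort effect size d = {power['mean_cohort_cohens_d']:.2f}")


if __name__ == "__main__":
    main()
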