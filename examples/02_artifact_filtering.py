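"""Filtering systematic artifacts using negative-delay prior knowledge.

Synthetic beamline data: two oscillatory artifact spectra fluctuate at
every delay (including before time zero, where no real signal can exist)
on top of a smoothly rising solvent-heating signal.  The artifact shapes
are estimated by SVD of the pre-time-zero columns, combined with three
whole-data singular components, pruned for linear dependence, fit, and
subtracted from the raw data.
"""

import warnings

import numpy as np

from sanod import (
    MockConfig,
    SANODConfig,
    artifact_components_from_negative_delays,
    filter_contributions,
    generate_xfel_scenario,
    run_sanod,
    subset_by_delay,
)

warnings.simplefilter("ignore")

dataset, truth = generate_xfel_scenario(MockConfig.xfel(seed=7))
artifacts = artifact_components_from_negative_delays(dataset, cutoff=-2e-12, n=2)
print(f"artifact components from delays < -2 ps: {artifacts.labels}")

result = run_sanod(dataset, artifacts, SANODConfig(n_svd_components=3))
print("\ndependence report (remainder fraction; < 0.05 means redundant):")
for rec in result.dependence.records:
    mark = "discarded" if rec.flagged else "retained"
    print(f"  {rec.label:10s} {rec.remainder_fraction:6.3f}  {mark}")

filtered = filter_contributions(dataset, result, list(artifacts.labels))
raw_neg = subset_by_delay(dataset, t_max=-2e-12)
fil_neg = subset_by_delay(filtered, t_max=-2e-12)
rms_raw = float(np.sqrt(np.mean(raw_neg.signal**2)))
rms_fil = float(np.sqrt(np.mean(fil_neg.signal**2)))
print(f"\nnegative-delay RMS: raw {rms_raw:.4f} -> filtered {rms_fil:.4f} "
      f"(injected noise RMS {truth.noise_rms:.4f})")

print("\nAfter filtering, the pre-time-zero columns are pure noise: the "
      "artifact contribution has been removed without touching the signal.")
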