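"""Retrieving the physical heating spectrum from a singular component.

The whole-data singular vector that carries the solvent-heating signal is
not the heating spectrum itself — it mixes in artifact directions.  Under
the constraint that artifact chronograms should only fluctuate around
zero, the physical spectrum is the singular component plus a closed-form
linear combination of the artifact components.
"""

import warnings

from sanod import (
    MockConfig,
    SANODConfig,
    artifact_components_from_negative_delays,
    generate_xfel_scenario,
    retrieve_physical_spectrum,
    run_sanod,
)
from sanod.metrics import cosine_similarity

warnings.simplefilter("ignore")

dataset, truth = generate_xfel_scenario(MockConfig.xfel(seed=7))
artifacts = artifact_components_from_negative_delays(dataset, cutoff=-2e-12, n=2)
result = run_sanod(dataset, artifacts, SANODConfig(n_svd_components=3))

target = [l for l in result.retained_labels() if l not in artifacts.labels][0]
spectrum, betas = retrieve_physical_spectrum(result, target, artifacts.labels)

true_heating = truth.components.column("heating")
print(f"signal-carrying component: {target}")
print("mixing coefficients:", {k: round(v, 4) for k, v in betas.items()})
print(f"|cos| (raw component   vs true heating): "
      f"{cosine_similarity(result.components.column(target), true_heating, signless=True):.4f}")
print(f"|cos| (retrieved curve vs true heating): "
      f"{cosine_similarity(spectrum, true_heating, signless=True):.4f}")

print("\nThe retrieved curve aligns with the generator's heating spectrum to "
      "better than 1% in angle, while the bare singular component does not.")
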