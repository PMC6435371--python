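"""Linear-combination fitting with known components vs blind SVD.

Builds a mock time-resolved scattering dataset of a two-step sequential
photoreaction — four spectral components (intermediate, product, systematic
artifact, solvent heating) driven by known kinetics plus 6% noise — then
decomposes it twice: with the true components via the direct fit, and
blindly via SVD.  The fit recovers every chronogram almost perfectly; the
singular vectors, being merely orthogonal, do not track any single species.
"""

import numpy as np

from sanod import MockConfig, generate_mock_trxl, lcf_fit, svd_decompose
from sanod.metrics import r_squared

dataset, truth = generate_mock_trxl(MockConfig(seed=1))
print(f"dataset: {dataset.n_spectral} spectral points x {dataset.n_time} delays, "
      f"noise RMS {truth.noise_rms:.4f}")

fit = lcf_fit(dataset, truth.components)
print("\nchronogram recovery (R^2 of fitted vs true weights):")
for label in truth.components.labels:
    r2 = r_squared(truth.chronograms.row(label), fit.chronograms.row(label))
    print(f"  {label:12s} {r2:.4f}")

svd = svd_decompose(dataset)
print("\nleading singular values:", np.round(svd.singvals[:6], 2))
print("best |correlation| of each true chronogram with any of the top-4 RSVs:")
for label in truth.components.labels:
    best = max(
        abs(np.corrcoef(truth.chronograms.row(label), svd.rsv[:, j])[0, 1])
        for j in range(4)
    )
    print(f"  {label:12s} {best:.3f}")

print("\nAn R^2 near 1 means the direct fit reproduces each species' kinetics "
      "on the correct scale; the RSVs correlate less well and, being shared "
      "orthogonal mixtures, assign no unique component to any species.")
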