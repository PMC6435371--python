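"""Seeded generators of synthetic time-resolved datasets with full ground truth.

Three scenarios, each returning a :class:`~sanod.core.Dataset` together
with the exact components, chronograms and noise matrix used to build it
(``signal = components @ chronograms + noise`` bitwise):

* ``generate_mock_trxl`` — a hypothetical two-step sequential reaction
  observed by time-resolved X-ray scattering: intermediate and product
  difference curves, a systematic artifact present throughout the time
  range, solvent heating, and ~6% additive Gaussian noise on a 145 x 111
  grid (10 linear negative delays, 101 log-spaced positive delays);
* ``generate_xfel_scenario`` — beam-instability artifacts: two fixed
  oscillatory spectra with independent random amplitudes at *all* delays
  (including negative) on top of a smoothly rising solvent-heating signal;
* ``generate_sequential_with_heating`` — two intermediates and a stable
  photoproduct with well-separated time constants plus heating that rises
  with each kinetic step, the playground for stationary-zone detection.

Component shapes are parametric families (damped sinusoids and Gaussian
bumps over the spectral grid) chosen to be mutually non-orthogonal and
similar in character to difference-scattering curves; the attached ground
truth defines correctness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import Chronograms, ComponentSet, Dataset, SpectralAxis, TimeAxis

__all__ = [
    "MockConfig",
    "MockGroundTruth",
    "sequential_kinetics",
    "generate_mock_trxl",
    "generate_xfel_scenario",
    "generate_sequential_with_heating",
]


@dataclass(frozen=True)
class MockConfig:
    """Shared knobs of the synthetic scenarios.

    Times are seconds.  ``noise_fraction`` sets the Gaussian noise RMS as a
    fraction of the RMS of the noiseless signal matrix (0.06 reproduces the
    "about 6%" mock-data convention).  ``rank3`` ties the heating
    chronogram to product formation so that the four-component mock has
    only three independent temporal directions — the variant in which SVD
    finds just three significant components.
    """

    n_spectral: int = 145
    q_min: float = 0.5
    q_max: float = 8.5
    unit: str = "inverse-angstrom"
    n_negative: int = 10
    neg_start: float = -10e-12
    neg_stop: float = -2e-12
    n_positive: int = 101
    pos_start: float = 100e-15
    pos_stop: float = 100e-9
    tau1: float = 100e-12
    tau2: float | None = None
    tau_heat: float = 30e-12
    artifact_level: float = 0.7
    artifact_drift: float = 0.3
    artifact_amplitude: float = 1.0
    heating_amplitude: float = 1.0
    noise_fraction: float = 0.06
    sigma_model: str = "constant"
    rank3: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if self.tau1 <= 0 or (self.tau2 is not None and self.tau2 <= 0):
            raise ValueError("time constants must be positive")
        if self.n_spectral < 2 or (self.n_negative + self.n_positive) < 2:
            raise ValueError("grid dimensions must be >= 2")
        if self.sigma_model not in ("constant", "proportional"):
            raise ValueError("sigma_model must be 'constant' or 'proportional'")

    @classmethod
    def xfel(cls, seed: int = 0, **overrides) -> "MockConfig":
        """Defaults of the beam-instability scenario.

        A finer spectral grid (200 points, typical XFEL detector binning),
        a denser block of negative delays (25; time scans at XFEL
        facilities sample pre-time-zero generously precisely because it
        calibrates the artifacts), a slower heating rise (100 ps), additive
        random noise of 3% (the shot-averaged random noise; the dominant
        corruption of this scenario is the systematic artifacts, not the
        additive noise) and a heating amplitude whose coherent chronogram
        gives it the largest singular value of the data, so that the
        leading whole-data singular vector carries the sample signal while
        the later ones are redundant with the negative-delay artifact
        components.
        """
        base = dict(n_spectral=200, n_negative=25, noise_fraction=0.03,
                    tau_heat=100e-12, heating_amplitude=2.0, seed=seed)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def sequential(cls, seed: int = 0, **overrides) -> "MockConfig":
        """Defaults of the two-intermediate kinetics scenario.

        All-positive log grid 3 ps - 100 ns; steps at tau1 = 10 ps and
        tau2 = 3 ns so that plateaus exist between the steps and after
        completion, while the grid starts well inside the first decay so
        the earliest delays are never mistaken for a plateau.
        """
        base = dict(n_negative=0, n_positive=111, pos_start=3e-12, pos_stop=100e-9,
                    tau1=10e-12, tau2=3e-9, seed=seed)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class MockGroundTruth:
    """The simulator's answer key: signal = components @ chronograms + noise."""

    components: ComponentSet
    chronograms: Chronograms
    noise: np.ndarray
    noise_rms: float
    seed: int

    def component_set(self, labels) -> ComponentSet:
        """Sub-selection of true components, e.g. the heating prior."""
        return self.components.subset(labels)


def _spectral_axis(config: MockConfig) -> SpectralAxis:
    return SpectralAxis(
        values=np.linspace(config.q_min, config.q_max, config.n_spectral),
        unit=config.unit,
        label="q",
    )


def _time_axis(config: MockConfig) -> TimeAxis:
    parts = []
    if config.n_negative:
        parts.append(np.linspace(config.neg_start, config.neg_stop, config.n_negative))
    parts.append(
        np.geomspace(config.pos_start, config.pos_stop, config.n_positive)
    )
    return TimeAxis(np.concatenate(parts))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _damped_sine(q, freq, phase, decay):
    return _unit(np.sin(freq * q + phase) * np.exp(-decay * q))


def _heating_shape(q):
    # negative low-q dip and positive bump, the character of a solvent
    # temperature-difference curve
    return _unit(
        -np.exp(-((q - 1.6) ** 2) / (2 * 0.55**2))
        + 0.8 * np.exp(-((q - 3.2) ** 2) / (2 * 0.9**2))
    )


def sequential_kinetics(times: TimeAxis, tau1: float, tau2: float | None = None):
    """Populations of a sequentially reacting pair after instantaneous excitation.

    Without ``tau2``: the intermediate forms at t = 0 and decays as
    ``exp(-t/tau1)`` into the product, ``1 - exp(-t/tau1)``.  With
    ``tau2`` the standard A -> B -> C forms are used: the returned pair is
    (A, B) with ``A = exp(-k1 t)`` and
    ``B = k1/(k2-k1) (exp(-k1 t) - exp(-k2 t))``.  Both are zero before
    time zero and stay within [0, 1].
    """
    if tau1 <= 0 or (tau2 is not None and tau2 <= 0):
        raise ValueError("time constants must be positive")
    t = times.delays
    pos = t >= 0
    intermediate = np.zeros_like(t)
    product = np.zeros_like(t)
    tp = t[pos]
    k1 = 1.0 / tau1
    intermediate[pos] = np.exp(-k1 * tp)
    if tau2 is None:
        product[pos] = 1.0 - np.exp(-k1 * tp)
    else:
        k2 = 1.0 / tau2
        if np.isclose(k1, k2):
            product[pos] = k1 * tp * np.exp(-k1 * tp)
        else:
            product[pos] = k1 / (k2 - k1) * (np.exp(-k1 * tp) - np.exp(-k2 * tp))
    return intermediate, product


def _emit(config, axis, times, comp_matrix, labels, chron, extra_meta=None):
    """Assemble Dataset + MockGroundTruth with calibrated additive noise."""
    rng = np.random.default_rng(config.seed)
    noiseless = comp_matrix @ chron
    scale = float(np.sqrt(np.mean(noiseless**2)))
    noise_rms = config.noise_fraction * scale
    noise = rng.normal(0.0, noise_rms, size=noiseless.shape) if noise_rms > 0 else np.zeros_like(noiseless)
    signal = noiseless + noise
    if config.sigma_model == "proportional":
        sigma = config.noise_fraction * np.abs(noiseless) + 0.1 * max(noise_rms, 1e-30)
    else:
        sigma = np.full_like(signal, max(noise_rms, 1e-30))
    components = ComponentSet(
        axis=axis,
        matrix=comp_matrix,
        labels=labels,
        provenance=tuple("prior" for _ in labels),
    )
    chronograms = Chronograms(times=times, weights=chron, labels=labels)
    dataset = Dataset(axis=axis, times=times, signal=signal, sigma=sigma,
                      meta=dict(extra_meta or {}))
    truth = MockGroundTruth(
        components=components, chronograms=chronograms, noise=noise,
        noise_rms=noise_rms, seed=config.seed,
    )
    return dataset, truth


def generate_mock_trxl(config: MockConfig | None = None):
    """Four-component mock dataset of a two-step sequential photoreaction.

    Components: intermediate difference curve, product difference curve,
    systematic artifact (present over the whole time range, with a slow
    deterministic drift in weight) and solvent heating rising with the
    energy release.  By default the four chronograms are linearly
    independent (rank 4); ``rank3=True`` ties heating to product formation.
    """
    if config is None:
        config = MockConfig()
    axis = _spectral_axis(config)
    times = _time_axis(config)
    t = times.delays
    q = axis.values

    comp = np.column_stack([
        _damped_sine(q, 2.0, 0.3, 0.25),
        _damped_sine(q, 3.2, 1.2, 0.30),
        _damped_sine(q, 5.5, 0.0, 0.15),
        _heating_shape(q),
    ])
    labels = ("intermediate", "product", "artifact", "heating")

    intermediate, product = sequential_kinetics(times, config.tau1, config.tau2)
    idx = np.arange(t.size)
    artifact = config.artifact_level * (
        1.0 + config.artifact_drift * np.sin(2.0 * np.pi * idx / t.size)
    )
    if config.rank3:
        heating = config.heating_amplitude * product
    else:
        heating = np.where(
            t >= 0, config.heating_amplitude * (1.0 - np.exp(-np.maximum(t, 0) / config.tau_heat)), 0.0
        )
    chron = np.vstack([intermediate, product, artifact, heating])
    return _emit(config, axis, times, comp, labels, chron,
                 extra_meta={"scenario": "mock-trxl"})


def generate_xfel_scenario(config: MockConfig | None = None):
    """Beam-instability artifacts on top of a rising solvent-heating signal.

    Two fixed oscillatory artifact spectra carry independent Gaussian
    per-delay amplitudes at every delay, negative ones included; the
    heating chronogram is zero before time zero and rises smoothly after.
    The default spectral grid is finer (200 points) than the mock reaction
    scenario, as typical of XFEL detector binning; see
    :meth:`MockConfig.xfel` for the amplitude rationale.
    """
    if config is None:
        config = MockConfig.xfel()
    if config.n_negative < 5:
        raise ValueError("XFEL scenario needs at least 5 negative delays")
    axis = _spectral_axis(config)
    times = _time_axis(config)
    t = times.delays
    q = axis.values

    comp = np.column_stack([
        _damped_sine(q, 6.0, 0.0, 0.10),
        _damped_sine(q, 8.5, 1.1, 0.12),
        _heating_shape(q),
    ])
    labels = ("artifact1", "artifact2", "heating")

    amp_rng = np.random.default_rng(config.seed + 1_000_003)
    a1 = amp_rng.normal(0.0, config.artifact_amplitude, size=t.size)
    a2 = amp_rng.normal(0.0, config.artifact_amplitude, size=t.size)
    heating = np.where(
        t >= 0, config.heating_amplitude * (1.0 - np.exp(-np.maximum(t, 0) / config.tau_heat)), 0.0
    )
    chron = np.vstack([a1, a2, heating])
    return _emit(config, axis, times, comp, labels, chron,
                 extra_meta={"scenario": "xfel"})


def generate_sequential_with_heating(config: MockConfig | None = None):
    """Two intermediates and a stable photoproduct, plus stepwise heating.

    Kinetics: the first intermediate forms instantaneously, converts to the
    second with ``tau1`` (default 10 ps), which converts to the product
    with ``tau2`` (default 3 ns); populations are the standard sequential
    forms, so plateaus exist between the steps and after completion.  The
    heating chronogram rises with each step and is monotone non-decreasing.
    All four chronograms live in the temporal span of
    {1, exp(-t/tau1), exp(-t/tau2)}, so the data rank is 3: one heating
    prior plus two SVD components suffice for an exact-rank fit.

    The time grid is all-positive (default 2 ps - 100 ns): with negative
    delays every chronogram would be flat at zero before time zero, which
    is a trivial stationary zone of no kinetic interest.  The default grid
    is 3 ps - 100 ns (see :meth:`MockConfig.sequential`).
    """
    if config is None:
        config = MockConfig.sequential()
    if config.tau2 is None:
        config = replace(config, tau2=3e-9)
    axis = _spectral_axis(config)
    times = _time_axis(config)
    t = times.delays
    q = axis.values

    # distinct oscillation periods keep the species curves well separated
    # (pairwise overlaps ~0.05-0.11) while still mutually non-orthogonal
    comp = np.column_stack([
        _damped_sine(q, 2.0, 0.3, 0.25),
        _damped_sine(q, 3.8, 0.0, 0.30),
        _damped_sine(q, 6.4, 2.4, 0.22),
        _heating_shape(q),
    ])
    labels = ("intermediate1", "intermediate2", "product", "heating")

    c1, c2 = sequential_kinetics(times, config.tau1, config.tau2)
    c3 = np.where(t >= 0, 1.0 - c1 - c2, 0.0)
    pos = np.maximum(t, 0)
    heating = np.where(
        t >= 0,
        config.heating_amplitude
        * (0.6 * (1.0 - np.exp(-pos / config.tau1)) + 0.4 * (1.0 - np.exp(-pos / config.tau2))),
        0.0,
    )
    chron = np.vstack([c1, c2, c3, heating])
    return _emit(config, axis, times, comp, labels, chron,
                 extra_meta={"scenario": "sequential-heating"})
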