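"""Core containers for time-resolved difference-signal data.

A pump-probe measurement produces a matrix of difference signals
``signal[i, j] = dS(q_i, t_j)``: one column per time delay, one row per
point of the spectral grid (momentum transfer q for scattering,
wavelength for optical spectra).  Everything downstream — SVD screening,
linear-combination fitting, artifact filtering — operates on these
containers, so validation is strict here and assumed elsewhere.

Conventions
-----------
* spectral dimension = rows, time = columns, for every matrix;
* time delays are stored in seconds (negative values are pre-time-zero);
* a component set never resamples: it must live on the identical
  spectral grid as the dataset it is fit against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralAxis",
    "TimeAxis",
    "Dataset",
    "ComponentSet",
    "Chronograms",
    "DecompositionResult",
    "DependenceRecord",
    "DependenceReport",
    "subset_by_delay",
    "UNITS",
    "PROVENANCE_TAGS",
]

UNITS = ("inverse-angstrom", "nanometer", "arbitrary")
PROVENANCE_TAGS = ("prior", "svd_global", "svd_negative", "derived")

#: relative tolerance for declaring two spectral grids identical
AXIS_RTOL = 1e-12

#: sigma entries below this are treated as degenerate and rejected
SIGMA_FLOOR = 1e-300


def _as_float_array(values, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing spectral grid (q in A^-1, wavelength in nm, ...)."""

    values: np.ndarray
    unit: str = "arbitrary"
    label: str = "q"

    def __post_init__(self):
        values = _as_float_array(self.values, "spectral axis", 1)
        object.__setattr__(self, "values", values)
        if values.size < 2:
            raise ValueError("spectral axis needs at least 2 points")
        if not np.all(np.isfinite(values)):
            raise ValueError("spectral axis contains non-finite values")
        if not np.all(np.diff(values) > 0):
            raise ValueError("spectral axis must be strictly increasing")
        if self.unit not in UNITS:
            raise ValueError(f"unknown spectral unit {self.unit!r}; expected one of {UNITS}")

    def __len__(self) -> int:
        return self.values.size

    def matches(self, other: "SpectralAxis") -> bool:
        """Element-wise identity within ``AXIS_RTOL`` relative tolerance."""
        if len(self) != len(other):
            return False
        scale = np.maximum(np.abs(self.values), np.abs(other.values))
        return bool(np.all(np.abs(self.values - other.values) <= AXIS_RTOL * np.maximum(scale, 1e-30)))


@dataclass(frozen=True)
class TimeAxis:
    """Pump-probe delays in seconds, sorted non-decreasing; negatives allowed."""

    delays: np.ndarray

    def __post_init__(self):
        delays = _as_float_array(self.delays, "time axis", 1)
        object.__setattr__(self, "delays", delays)
        if not np.all(np.isfinite(delays)):
            raise ValueError("time axis contains non-finite values")
        if delays.size and not np.all(np.diff(delays) >= 0):
            raise ValueError("time delays must be sorted non-decreasing")
        if delays.size != np.unique(delays).size:
            warnings.warn("time axis contains duplicate delays (repeated measurements)", stacklevel=3)

    def __len__(self) -> int:
        return self.delays.size


@dataclass(frozen=True)
class Dataset:
    """Difference-signal matrix with optional per-point standard deviations.

    Parameters
    ----------
    axis : SpectralAxis
        Common spectral grid of all columns.
    times : TimeAxis
        One delay per column.
    signal : ndarray, shape (n_spectral, n_time)
        Difference signals dS(q, t).
    sigma : ndarray or None
        Experimental standard deviations, same shape, strictly positive.
    meta : dict
        Free-form provenance notes (filter history etc.); not validated.
    """

    axis: SpectralAxis
    times: TimeAxis
    signal: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        signal = _as_float_array(self.signal, "signal", 2)
        object.__setattr__(self, "signal", signal)
        expected = (len(self.axis), len(self.times))
        if signal.shape != expected:
            raise ValueError(f"signal shape {signal.shape} != (n_spectral, n_time) = {expected}")
        if not np.all(np.isfinite(signal)):
            raise ValueError("signal contains non-finite values")
        if self.sigma is not None:
            sigma = _as_float_array(self.sigma, "sigma", 2)
            object.__setattr__(self, "sigma", sigma)
            if sigma.shape != expected:
                raise ValueError(f"sigma shape {sigma.shape} does not match signal shape {expected}")
            if not np.all(np.isfinite(sigma)):
                raise ValueError("sigma contains non-finite values")
            if not np.all(sigma > SIGMA_FLOOR):
                raise ValueError("non-positive sigma (standard deviations must be strictly positive)")

    @property
    def n_spectral(self) -> int:
        return len(self.axis)

    @property
    def n_time(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ComponentSet:
    """Ordered collection of spectral components on a common grid.

    ``matrix`` holds one component per column; ``provenance`` records where
    each came from: a physical prior ("prior"), the whole-data SVD
    ("svd_global"), the negative-delay SVD ("svd_negative") or a posterior
    construction ("derived").
    """

    axis: SpectralAxis
    matrix: np.ndarray
    labels: tuple
    provenance: tuple

    def __post_init__(self):
        matrix = _as_float_array(self.matrix, "component matrix", 2)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        object.__setattr__(self, "provenance", tuple(str(p) for p in self.provenance))
        if matrix.shape[0] != len(self.axis):
            raise ValueError(
                f"component matrix has {matrix.shape[0]} rows but axis has {len(self.axis)} points"
            )
        n_comp = matrix.shape[1]
        if len(self.labels) != n_comp or len(self.provenance) != n_comp:
            raise ValueError("labels/provenance length must equal the number of components")
        if len(set(self.labels)) != n_comp:
            raise ValueError("component labels must be unique")
        for tag in self.provenance:
            if tag not in PROVENANCE_TAGS:
                raise ValueError(f"unknown provenance tag {tag!r}; expected one of {PROVENANCE_TAGS}")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("component matrix contains non-finite values")
        norms = np.linalg.norm(matrix, axis=0)
        if np.any(norms == 0):
            bad = [self.labels[i] for i in np.flatnonzero(norms == 0)]
            raise ValueError(f"components with zero norm: {bad}")

    @property
    def n_comp(self) -> int:
        return self.matrix.shape[1]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown component label {label!r}") from None

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.index_of(label)]

    def subset(self, labels) -> "ComponentSet":
        idx = [self.index_of(l) for l in labels]
        return ComponentSet(
            axis=self.axis,
            matrix=self.matrix[:, idx],
            labels=tuple(self.labels[i] for i in idx),
            provenance=tuple(self.provenance[i] for i in idx),
        )

    @staticmethod
    def empty(axis: SpectralAxis) -> "ComponentSet":
        return ComponentSet(axis=axis, matrix=np.empty((len(axis), 0)), labels=(), provenance=())


@dataclass(frozen=True)
class Chronograms:
    """Time-dependent weights alpha_i(t_j), one row per component."""

    times: TimeAxis
    weights: np.ndarray
    labels: tuple

    def __post_init__(self):
        weights = _as_float_array(self.weights, "chronogram weights", 2)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if weights.shape != (len(self.labels), len(self.times)):
            raise ValueError(
                f"chronogram shape {weights.shape} != (n_comp, n_time) = "
                f"({len(self.labels)}, {len(self.times)})"
            )

    def row(self, label: str) -> np.ndarray:
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown chronogram label {label!r}") from None
        return self.weights[i]


@dataclass(frozen=True)
class DependenceRecord:
    """Linear-dependence diagnostics for one component in assembly order."""

    label: str
    provenance: str
    remainder_fraction: float
    flagged: bool


@dataclass(frozen=True)
class DependenceReport:
    """Outcome of the orthogonalization pruning step.

    ``remainder_fraction`` is the norm of the component after projecting out
    all previously retained components, divided by its own norm; a value
    near zero means the component is (numerically) a linear combination of
    the earlier ones and must be discarded to keep the fit unique.
    """

    records: tuple
    tolerance: float

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        for rec in self.records:
            if not -1e-9 <= rec.remainder_fraction <= 1 + 1e-9:
                raise ValueError(f"remainder_fraction out of [0, 1]: {rec.remainder_fraction}")
            if rec.flagged != (rec.remainder_fraction < self.tolerance):
                raise ValueError("flag inconsistent with tolerance")

    @property
    def flagged_labels(self) -> tuple:
        return tuple(r.label for r in self.records if r.flagged)

    @property
    def retained_labels(self) -> tuple:
        return tuple(r.label for r in self.records if not r.flagged)

    @property
    def n_flagged(self) -> int:
        return sum(r.flagged for r in self.records)


@dataclass(frozen=True)
class DecompositionResult:
    """Components, chronograms and residual of a linear-combination fit.

    The defining identity is ``reconstructed + residual == signal`` exactly
    (the residual is computed as the difference, so the identity holds to
    floating-point additivity).  ``per_delay_misfit`` is the squared
    Euclidean norm of each residual column, or the chi-square when the fit
    was sigma-weighted.
    """

    components: ComponentSet
    chronograms: Chronograms
    reconstructed: np.ndarray
    residual: np.ndarray
    per_delay_misfit: np.ndarray
    weighted: bool
    n_retained: int

    def __post_init__(self):
        for name in ("reconstructed", "residual"):
            arr = _as_float_array(getattr(self, name), name, 2)
            object.__setattr__(self, name, arr)
        misfit = _as_float_array(self.per_delay_misfit, "per_delay_misfit", 1)
        object.__setattr__(self, "per_delay_misfit", misfit)
        if np.any(misfit < 0):
            raise ValueError("per-delay misfit must be non-negative")

    @property
    def total_misfit(self) -> float:
        return float(np.sum(self.per_delay_misfit))


def subset_by_delay(dataset: Dataset, t_min: float = -np.inf, t_max: float = np.inf) -> Dataset:
    """Select the columns whose delay lies in the half-open interval [t_min, t_max).

    The half-open convention makes consecutive selections composable and
    duplicate-safe.  Raises ``ValueError`` if no delay falls in the interval.
    """
    mask = (dataset.times.delays >= t_min) & (dataset.times.delays < t_max)
    if not np.any(mask):
        raise ValueError(f"no time delay in [{t_min!r}, {t_max!r})")
    return Dataset(
        axis=dataset.axis,
        times=TimeAxis(dataset.times.delays[mask]),
        signal=dataset.signal[:, mask],
        sigma=None if dataset.sigma is None else dataset.sigma[:, mask],
        meta=dict(dataset.meta),
    )
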