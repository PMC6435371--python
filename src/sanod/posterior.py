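"""Posterior analyses after a SANOD fit.

Four operations that turn a fit into physics:

* retrieve a physically meaningful spectrum from an SVD-supplied component
  under the constraint that artifact chronograms should only fluctuate
  around zero (the whole-data singular vector mixes the physical shape
  with artifact directions; the constraint fixes the mixture);
* check that the chronogram of the third component is invariant under
  replacing the singular vector by the physical spectrum, when the latter
  lies in the span of the retained components (an exact least-squares
  identity under a basis change);
* correct an erroneous prior spectrum from the fit residual (the residual
  concentrates the part of the data the wrong prior cannot absorb);
* detect stationary time zones — delay intervals over which all
  chronograms are flat — and average zone spectra after removing solvent
  contributions, the pseudo-PCA route to species-associated spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ComponentSet, Chronograms, Dataset, DecompositionResult
from .lcf import lcf_fit
from .svd import first_lag_autocorrelation, _signed_svd

__all__ = [
    "StationaryZone",
    "CorrectedPrior",
    "retrieve_physical_spectrum",
    "chronogram_equivalence_check",
    "correct_prior_from_residual",
    "detect_stationary_zones",
    "zone_spectra",
]


def _decomposition(result) -> DecompositionResult:
    # accept either a SANODResult or a bare DecompositionResult
    return getattr(result, "decomposition", result)


@dataclass(frozen=True)
class StationaryZone:
    """Maximal run of delays over which every considered chronogram is flat."""

    start_index: int
    end_index: int  # inclusive
    start_time: float
    end_time: float
    flatness: float


@dataclass(frozen=True)
class CorrectedPrior:
    """Outcome of the residual-based prior correction.

    ``applied`` is False when the residual is indistinguishable from noise,
    in which case ``spectrum`` is the prior unchanged and ``gamma`` is 0.
    """

    spectrum: np.ndarray
    gamma: float
    applied: bool
    note: str = ""


def retrieve_physical_spectrum(result, target_label: str, artifact_labels):
    """Physical spectrum behind an SVD component, by the zero-fluctuation constraint.

    Returns ``(P, betas)`` with ``P(q) = C_target(q) + sum_k beta_k C_k(q)``
    where ``beta_k = <alpha_k, alpha_target> / <alpha_target, alpha_target>``
    (inner products over all delays).  This is the closed-form minimizer of
    the post-substitution artifact-chronogram energy
    ``sum_t (alpha_k(t) - beta_k alpha_target(t))^2``: after rewriting the
    fit in terms of ``{artifacts, P}``, the artifact chronograms keep only
    their zero-mean fluctuation and P inherits alpha_target unchanged.
    """
    dec = _decomposition(result)
    artifact_labels = list(artifact_labels)
    alpha_t = dec.chronograms.row(target_label)
    denom = float(np.dot(alpha_t, alpha_t))
    if denom == 0.0:
        raise ValueError(f"target chronogram {target_label!r} is identically zero")
    betas = {}
    spectrum = dec.components.column(target_label).copy()
    for label in artifact_labels:
        alpha_k = dec.chronograms.row(label)
        beta = float(np.dot(alpha_k, alpha_t) / denom)
        betas[label] = beta
        spectrum += beta * dec.components.column(label)
    return spectrum, betas


def chronogram_equivalence_check(
    dataset: Dataset,
    known_artifacts: ComponentSet,
    candidate_spectrum,
    svd_component,
    dep_tol: float = 0.05,
) -> float:
    """Max |delta alpha_3(t)| / max |alpha_3| between two third-component choices.

    Fits the data twice — artifacts plus the SVD component, then artifacts
    plus the candidate physical spectrum — and compares the chronogram of
    the third component.  When the candidate is an exact linear combination
    of the retained components with unit coefficient on the SVD component,
    the two chronograms are identical (least-squares basis-change identity)
    and the returned value is at rounding level.
    """
    candidate_spectrum = np.asarray(candidate_spectrum, dtype=float)
    svd_component = np.asarray(svd_component, dtype=float)
    axis = dataset.axis

    def _fit_third(third, label):
        comps = ComponentSet(
            axis=axis,
            matrix=np.column_stack([known_artifacts.matrix, third]),
            labels=known_artifacts.labels + (label,),
            provenance=known_artifacts.provenance + ("derived",),
        )
        return lcf_fit(dataset, comps, dep_tol).chronograms.row(label)

    alpha_u = _fit_third(svd_component, "third-svd")
    alpha_p = _fit_third(candidate_spectrum, "third-candidate")
    scale = float(np.max(np.abs(alpha_u)))
    if scale == 0.0:
        return float(np.max(np.abs(alpha_u - alpha_p)))
    return float(np.max(np.abs(alpha_u - alpha_p)) / scale)


def correct_prior_from_residual(
    result,
    prior_label: str,
    sv_ratio_floor: float = 3.0,
    ac_floor: float = 0.6,
) -> CorrectedPrior:
    """Correct an erroneous prior spectrum using the fit residual.

    When the prior shape is wrong, the part of the data it cannot absorb
    piles up in the residual with the prior's own kinetics.  The residual's
    first singular component rho(q) is taken as the correction direction;
    its temporal trace (singular value times right singular vector) is
    regressed onto the prior's chronogram to get the correction amplitude
    gamma, and ``corrected = C_prior + gamma * rho``.  If the residual's
    first component fails the significance screen, the prior is returned
    unchanged.
    """
    dec = _decomposition(result)
    prior = dec.components.column(prior_label).copy()
    alpha_p = dec.chronograms.row(prior_label)
    if float(np.dot(alpha_p, alpha_p)) == 0.0:
        raise ValueError(f"prior chronogram {prior_label!r} is identically zero")
    lsv, singvals, rsv = _signed_svd(dec.residual.copy())
    r = singvals.size
    floor = sv_ratio_floor * float(np.median(singvals[r // 2:]))
    significant = (
        singvals[0] > floor
        and first_lag_autocorrelation(lsv[:, 0]) > ac_floor
        and (rsv.shape[0] < 3 or first_lag_autocorrelation(rsv[:, 0]) > ac_floor)
    )
    if not significant:
        return CorrectedPrior(
            spectrum=prior, gamma=0.0, applied=False,
            note="residual indistinguishable from noise; prior returned unchanged",
        )
    rho = lsv[:, 0]
    trace = singvals[0] * rsv[:, 0]
    gamma = float(np.dot(trace, alpha_p) / np.dot(alpha_p, alpha_p))
    return CorrectedPrior(spectrum=prior + gamma * rho, gamma=gamma, applied=True)


def detect_stationary_zones(
    chronograms: Chronograms,
    exclude_labels=(),
    window: int = 5,
    tol: float = 0.05,
) -> list:
    """Find maximal delay intervals over which all considered chronograms are flat.

    A window of ``window`` consecutive delays is stationary when, for every
    chronogram not excluded, its within-window range divided by its global
    dynamic range stays below ``tol``.  Stationary windows that overlap or
    touch (contiguous index coverage) merge into maximal zones; each
    zone's ``flatness`` is the worst window-level
    normalized deviation inside it.  Normalizing per chronogram makes the
    detection invariant to affine rescaling; monotone backgrounds such as
    solvent heating should be excluded, since they never go flat and would
    mask every zone.
    """
    exclude = set(exclude_labels)
    n_time = len(chronograms.times)
    if window > n_time:
        raise ValueError(f"window {window} larger than the number of delays {n_time}")
    if window < 2:
        raise ValueError("window must span at least 2 delays")
    rows = [i for i, label in enumerate(chronograms.labels) if label not in exclude]
    if not rows:
        raise ValueError("all chronograms excluded")
    w = chronograms.weights[rows, :]
    ranges = w.max(axis=1) - w.min(axis=1)
    if np.any(ranges == 0):
        bad = [chronograms.labels[rows[i]] for i in np.flatnonzero(ranges == 0)]
        raise ValueError(f"chronogram(s) with zero dynamic range: {bad}")

    n_win = n_time - window + 1
    deviation = np.empty(n_win)
    for s in range(n_win):
        block = w[:, s:s + window]
        deviation[s] = np.max((block.max(axis=1) - block.min(axis=1)) / ranges)
    stationary = deviation < tol

    # merge overlapping/contiguous stationary windows [s, s+window-1]
    zones: list[StationaryZone] = []
    delays = chronograms.times.delays
    current: list[int] | None = None  # [start, end, first_win, last_win]
    for s in np.flatnonzero(stationary):
        s = int(s)
        lo, hi = s, s + window - 1
        if current is not None and lo <= current[1] + 1:
            current[1] = hi
            current[3] = s
        else:
            if current is not None:
                zones.append(current)
            current = [lo, hi, s, s]
    if current is not None:
        zones.append(current)
    return [
        StationaryZone(
            start_index=lo,
            end_index=hi,
            start_time=float(delays[lo]),
            end_time=float(delays[hi]),
            flatness=float(np.max(deviation[w0:w1 + 1][stationary[w0:w1 + 1]])),
        )
        for lo, hi, w0, w1 in zones
    ]


def zone_spectra(dataset: Dataset, result, zones, solvent_labels=(),
                 sigma_weighted: bool = False) -> ComponentSet:
    """Average the data columns of each zone after removing solvent contributions.

    Within a stationary zone the solute composition is constant, so the
    zone-averaged, solvent-free curve approximates the species-associated
    spectrum of whatever is present there (noise averages down with the
    zone width).  Returns one spectrum per zone, tagged ``derived``.
    """
    zones = list(zones)
    if not zones:
        raise ValueError("empty zone list")
    dec = _decomposition(result)
    cleaned = dataset.signal.copy()
    for label in solvent_labels:
        cleaned -= np.outer(dec.components.column(label), dec.chronograms.row(label))
    columns = []
    for zone in zones:
        sl = slice(zone.start_index, zone.end_index + 1)
        if sigma_weighted and dataset.sigma is not None:
            w = 1.0 / dataset.sigma[:, sl] ** 2
            columns.append(np.sum(cleaned[:, sl] * w, axis=1) / np.sum(w, axis=1))
        else:
            columns.append(np.mean(cleaned[:, sl], axis=1))
    return ComponentSet(
        axis=dataset.axis,
        matrix=np.column_stack(columns),
        labels=tuple(f"zone{i + 1}" for i in range(len(zones))),
        provenance=tuple("derived" for _ in zones),
    )
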