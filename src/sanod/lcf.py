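"""Direct-method linear-combination fitting via QR decomposition.

Every time-delay column of the data is decomposed as a weighted sum of
fixed, not necessarily orthogonal, spectral components.  The weights come
from a direct (non-iterative) linear-algebra solve: orthonormalize the
components once by QR, project each data column, back-substitute.  The
solution is identical to unweighted least squares.  A sigma-weighted
variant minimizes the chi-square instead, at the cost of redoing the QR at
every delay because the row scaling changes with the column.

Linear dependence among the components would make the weights non-unique,
so orthogonalization doubles as a detector: a component whose remainder —
after projecting out all previously retained components — is a small
fraction of its own norm is flagged and excluded from the fit (it receives
weight zero but keeps its row in the chronogram matrix so shapes stay
stable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .core import (
    Chronograms,
    ComponentSet,
    Dataset,
    DecompositionResult,
    DependenceRecord,
    DependenceReport,
)

__all__ = [
    "OrthoBasis",
    "qr_orthonormalize",
    "lcf_fit",
    "lcf_fit_weighted",
    "residual_summary",
]


@dataclass(frozen=True)
class OrthoBasis:
    """Orthonormalized retained components O and the triangular factor R.

    ``ortho @ rmatrix`` reproduces the retained component columns; the
    dependence report records the remainder fraction of every input
    component in assembly order.
    """

    ortho: np.ndarray
    rmatrix: np.ndarray
    retained_indices: tuple
    report: DependenceReport


def qr_orthonormalize(components: ComponentSet, dep_tol: float = 0.05) -> OrthoBasis:
    """Gram-Schmidt orthonormalization with linear-dependence pruning.

    Components are processed in set order (physical priors first by
    convention of the assembly step), so dependence is always charged to
    the later, SVD-supplied components.  ``dep_tol`` is the remainder
    fraction below which a component counts as a linear combination of its
    predecessors; 5% is far above double-precision rounding yet well below
    the distinctness of genuine signal components.
    """
    if not 0.0 < dep_tol < 1.0:
        raise ValueError("dep_tol must lie in (0, 1)")
    if components.n_comp == 0:
        raise ValueError("no components to orthonormalize")
    C = components.matrix
    n = C.shape[0]
    ortho_cols: list[np.ndarray] = []
    retained: list[int] = []
    records: list[DependenceRecord] = []
    for j in range(components.n_comp):
        c = C[:, j]
        v = c.copy()
        # modified Gram-Schmidt with one re-orthogonalization pass
        for _ in range(2):
            for o in ortho_cols:
                v -= np.dot(o, v) * o
        frac = float(np.linalg.norm(v) / np.linalg.norm(c))
        flagged = frac < dep_tol
        records.append(
            DependenceRecord(
                label=components.labels[j],
                provenance=components.provenance[j],
                remainder_fraction=min(frac, 1.0),
                flagged=flagged,
            )
        )
        if not flagged:
            ortho_cols.append(v / np.linalg.norm(v))
            retained.append(j)
    if not retained:
        raise ValueError("all components flagged as linearly dependent; nothing retained")
    ortho = np.column_stack(ortho_cols) if ortho_cols else np.empty((n, 0))
    rmatrix = np.triu(ortho.T @ C[:, retained])
    return OrthoBasis(
        ortho=ortho,
        rmatrix=rmatrix,
        retained_indices=tuple(retained),
        report=DependenceReport(records=tuple(records), tolerance=dep_tol),
    )


def _check_axis(dataset: Dataset, components: ComponentSet):
    if not dataset.axis.matches(components.axis):
        raise ValueError("component set and dataset are on different spectral grids")


def _assemble_result(dataset, components, basis, weights_retained, weighted, misfit=None):
    weights = np.zeros((components.n_comp, dataset.n_time))
    weights[list(basis.retained_indices), :] = weights_retained
    reconstructed = components.matrix @ weights
    residual = dataset.signal - reconstructed
    if misfit is None:
        misfit = np.sum(residual**2, axis=0)
    return DecompositionResult(
        components=components,
        chronograms=Chronograms(times=dataset.times, weights=weights, labels=components.labels),
        reconstructed=reconstructed,
        residual=residual,
        per_delay_misfit=misfit,
        weighted=weighted,
        n_retained=len(basis.retained_indices),
    )


def lcf_fit(dataset: Dataset, components: ComponentSet, dep_tol: float = 0.05,
            basis: OrthoBasis | None = None) -> DecompositionResult:
    """Unweighted direct-method fit: one QR, reused for every delay.

    Returns the least-squares weights of the retained components for each
    time-delay column; flagged components get weight zero.  Pass a
    precomputed ``basis`` to skip re-orthonormalization.
    """
    _check_axis(dataset, components)
    if basis is None:
        basis = qr_orthonormalize(components, dep_tol)
    if basis.report.n_flagged:
        warnings.warn(
            f"{basis.report.n_flagged} linearly dependent component(s) discarded from the fit: "
            f"{basis.report.flagged_labels}",
            stacklevel=2,
        )
    projected = basis.ortho.T @ dataset.signal
    weights_retained = solve_triangular(basis.rmatrix, projected, lower=False)
    return _assemble_result(dataset, components, basis, weights_retained, weighted=False)


def lcf_fit_weighted(dataset: Dataset, components: ComponentSet,
                     dep_tol: float = 0.05) -> DecompositionResult:
    """Chi-square (sigma-weighted) direct-method fit, QR redone per delay.

    For each delay the component matrix and the data column are scaled row-
    wise by 1/sigma(q, t) before the QR solve, so the weights minimize
    ``chi2(t) = sum_q ((dS - sum_i a_i C_i) / sigma)^2``.  Pruning is
    decided once on the unscaled components so the model dimension is the
    same at every delay.
    """
    _check_axis(dataset, components)
    if dataset.sigma is None:
        raise ValueError("weighted fit requires a sigma matrix")
    basis = qr_orthonormalize(components, dep_tol)
    if basis.report.n_flagged:
        warnings.warn(
            f"{basis.report.n_flagged} linearly dependent component(s) discarded from the fit: "
            f"{basis.report.flagged_labels}",
            stacklevel=2,
        )
    C_ret = components.matrix[:, list(basis.retained_indices)]
    n_ret = C_ret.shape[1]
    weights_retained = np.empty((n_ret, dataset.n_time))
    chi2 = np.empty(dataset.n_time)
    for t in range(dataset.n_time):
        w = 1.0 / dataset.sigma[:, t]
        Cw = C_ret * w[:, None]
        yw = dataset.signal[:, t] * w
        q, r = np.linalg.qr(Cw)
        a = solve_triangular(r, q.T @ yw, lower=False)
        weights_retained[:, t] = a
        chi2[t] = float(np.sum((yw - Cw @ a) ** 2))
    return _assemble_result(dataset, components, basis, weights_retained,
                            weighted=True, misfit=chi2)


def residual_summary(result: DecompositionResult) -> pd.DataFrame:
    """Per-delay misfit table: misfit, residual RMS, reduced chi-square.

    The reduced chi-square column (weighted fits only) divides by
    ``n_spectral - n_retained`` degrees of freedom.
    """
    n_spectral = result.residual.shape[0]
    if result.n_retained >= n_spectral:
        raise ValueError("no residual degrees of freedom: n_retained >= n_spectral")
    table = pd.DataFrame(
        {
            "delay_s": result.chronograms.times.delays,
            "misfit": result.per_delay_misfit,
            "residual_rms": np.sqrt(np.mean(result.residual**2, axis=0)),
        }
    )
    if result.weighted:
        table["reduced_chi2"] = result.per_delay_misfit / (n_spectral - result.n_retained)
    return table
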