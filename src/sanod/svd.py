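"""Singular value decomposition of a dataset and significance screening.

SVD factors the data matrix into left singular vectors (time-independent
spectral shapes), right singular vectors (their temporal weights) and
singular values (their magnitudes).  The singular vectors are mathematically
orthogonal but not physically meaningful individually; here they are used
(i) to count and extract the significant directions of the data and (ii) to
supply components for the non-orthogonal decomposition downstream.

Significance of a singular component is judged by two standard screens:
its singular value relative to the noise floor of the singular spectrum,
and the first-lag autocorrelation of both of its singular vectors (signal
vectors are smooth, noise vectors are not).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import ComponentSet, Dataset, SpectralAxis

__all__ = [
    "SignificanceRecord",
    "SVDResult",
    "svd_decompose",
    "first_lag_autocorrelation",
    "select_significant",
    "components_from_svd",
]


@dataclass(frozen=True)
class SignificanceRecord:
    index: int
    singular_value: float
    lsv_autocorrelation: float
    rsv_autocorrelation: float
    selected: bool


@dataclass(frozen=True)
class SVDResult:
    """Thin SVD of a dataset with per-component screening statistics.

    ``lsv`` is (n_spectral, r) with unit-norm columns, ``rsv`` is
    (n_time, r); ``lsv @ diag(singvals) @ rsv.T`` reconstructs the signal.
    A deterministic sign convention is applied: each LSV is flipped so that
    its largest-magnitude element is positive (the paired RSV flips with
    it), making repeated decompositions bitwise reproducible.
    """

    axis: SpectralAxis
    lsv: np.ndarray
    singvals: np.ndarray
    rsv: np.ndarray
    significance: tuple

    @property
    def rank(self) -> int:
        return self.singvals.size

    def selected_indices(self) -> list:
        return [rec.index for rec in self.significance if rec.selected]


def first_lag_autocorrelation(v) -> float:
    """Sum of products of neighbouring elements over the sum of squares.

    ``sum_i v_i v_{i+1} / sum_i v_i^2`` — close to +1 for smooth vectors,
    near 0 for white noise, negative for alternating vectors.  Requires
    length >= 3.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("first-lag autocorrelation needs a 1-D vector of length >= 3")
    denom = float(np.dot(v, v))
    if denom == 0.0:
        return 0.0
    return float(np.dot(v[:-1], v[1:]) / denom)


def _signed_svd(matrix: np.ndarray):
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    # deterministic sign: largest-|value| element of each LSV made positive
    for j in range(s.size):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
            vt[j, :] = -vt[j, :]
    return u, s, vt.T


def svd_decompose(dataset: Dataset) -> SVDResult:
    """Full thin SVD of the signal matrix with screening statistics attached.

    Selection is *not* applied here; call :func:`select_significant` (or use
    a rank override) to mark significant components.
    """
    if dataset.n_spectral < 2 or dataset.n_time < 2:
        raise ValueError("degenerate dataset: both dimensions must be >= 2")
    lsv, singvals, rsv = _signed_svd(dataset.signal)
    significance = tuple(
        SignificanceRecord(
            index=j,
            singular_value=float(singvals[j]),
            lsv_autocorrelation=first_lag_autocorrelation(lsv[:, j]),
            rsv_autocorrelation=(
                first_lag_autocorrelation(rsv[:, j]) if rsv.shape[0] >= 3 else 0.0
            ),
            selected=False,
        )
        for j in range(singvals.size)
    )
    return SVDResult(axis=dataset.axis, lsv=lsv, singvals=singvals, rsv=rsv,
                     significance=significance)


def select_significant(
    svdres: SVDResult,
    rank_override: int | None = None,
    sv_ratio_floor: float = 3.0,
    ac_floor: float = 0.6,
) -> list:
    """Indices of significant singular components.

    With ``rank_override`` the first that many components are taken — the
    escape hatch for the common practice of fixing the count by inspection.
    Otherwise a component is significant when its singular value exceeds
    ``sv_ratio_floor`` times the median of the trailing half of the singular
    spectrum (a robust noise floor) *and* both of its singular vectors have
    first-lag autocorrelation above ``ac_floor``.

    The selection is recorded in ``svdres.significance`` in place of the
    previous flags.
    """
    r = svdres.rank
    if rank_override is not None:
        if not 0 <= rank_override <= r:
            raise ValueError(f"rank_override {rank_override} exceeds available components ({r})")
        selected = list(range(rank_override))
    else:
        floor = sv_ratio_floor * float(np.median(svdres.singvals[r // 2:]))
        selected = [
            rec.index
            for rec in svdres.significance
            if rec.singular_value > floor
            and rec.lsv_autocorrelation > ac_floor
            and rec.rsv_autocorrelation > ac_floor
        ]
    new_records = tuple(
        replace(rec, selected=(rec.index in selected)) for rec in svdres.significance
    )
    object.__setattr__(svdres, "significance", new_records)
    return selected


def components_from_svd(
    svdres: SVDResult,
    indices,
    provenance_tag: str,
    label_prefix: str = "LSV",
) -> ComponentSet:
    """Copy selected left singular vectors into a ComponentSet.

    Components are labelled ``{prefix}1``, ``{prefix}2``, ... in
    singular-value order and tagged ``svd_global`` or ``svd_negative``.
    """
    indices = list(indices)
    if not indices:
        raise ValueError("empty index list")
    for i in indices:
        if not 0 <= i < svdres.rank:
            raise ValueError(f"singular-component index {i} out of range")
    return ComponentSet(
        axis=svdres.axis,
        matrix=svdres.lsv[:, indices].copy(),
        labels=tuple(f"{label_prefix}{i + 1}" for i in indices),
        provenance=tuple(provenance_tag for _ in indices),
    )
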