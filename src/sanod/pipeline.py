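"""The SANOD workflow: assemble priors with SVD components, prune, fit, filter.

SANOD (SVD-aided non-orthogonal decomposition) fills the gap between the
components one actually knows — solvent heating signals, artifact shapes
measured at negative delays, scattering curves of known species — and the
full set needed to describe the data.  Known components {K_i} come first;
significant left singular vectors {U_j} of the whole data are appended to
cover the unknown remainder; linearly dependent members of the combined set
(always the later, SVD-supplied ones by construction of the ordering) are
discarded; and the data are fit by the direct method.  Contributions of
designated components (typically artifacts) can then be subtracted from the
raw data column by column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ComponentSet, Dataset, DecompositionResult, DependenceReport, subset_by_delay
from .lcf import lcf_fit, lcf_fit_weighted, qr_orthonormalize
from .svd import components_from_svd, select_significant, svd_decompose

__all__ = [
    "SANODConfig",
    "SANODResult",
    "assemble_components",
    "artifact_components_from_negative_delays",
    "run_sanod",
    "filter_contributions",
]

log = logging.getLogger(__name__)

AUTO = "auto"


@dataclass(frozen=True)
class SANODConfig:
    """Knobs of one SANOD run.

    ``n_svd_components`` is m of the method — how many whole-data singular
    components to append after the known set ("auto" uses the significance
    screen; the demonstrations in the field usually fix it by inspection).
    ``negative_delay_cutoff`` (seconds), when set, is only used by the
    artifact-extraction helper; -2 ps is the customary choice for XFEL data.
    """

    n_svd_components: int | str = AUTO
    negative_delay_cutoff: float | None = None
    n_artifact_components: int | str = AUTO
    dep_tol: float = 0.05
    weighted: bool = False
    sv_ratio_floor: float = 3.0
    ac_floor: float = 0.6

    def __post_init__(self):
        if self.n_svd_components != AUTO:
            if int(self.n_svd_components) < 0:
                raise ValueError("n_svd_components must be >= 0 or 'auto'")
        if not 0.0 < self.dep_tol < 1.0:
            raise ValueError("dep_tol must lie in (0, 1)")


@dataclass(frozen=True)
class SANODResult:
    """Decomposition plus the bookkeeping needed to trace every component."""

    decomposition: DecompositionResult
    dependence: DependenceReport
    provenance: dict
    config: SANODConfig
    svd_significance: tuple = field(default_factory=tuple)

    @property
    def chronograms(self):
        return self.decomposition.chronograms

    @property
    def components(self):
        return self.decomposition.components

    def retained_labels(self) -> tuple:
        return self.dependence.retained_labels


def _uniquify(labels) -> list:
    seen: dict[str, int] = {}
    out = []
    for label in labels:
        if label not in seen:
            seen[label] = 1
            out.append(label)
        else:
            seen[label] += 1
            candidate = f"{label}-{seen[label]}"
            while candidate in seen:
                seen[label] += 1
                candidate = f"{label}-{seen[label]}"
            seen[candidate] = 1
            out.append(candidate)
    return out


def assemble_components(known: ComponentSet, svd_components: ComponentSet) -> ComponentSet:
    """Concatenate known components (first) with SVD-supplied components.

    Labels are uniquified on collision ("LSV1" -> "LSV1-2"); provenance is
    preserved per component.
    """
    if not known.axis.matches(svd_components.axis):
        raise ValueError("known and SVD components are on different spectral grids")
    labels = _uniquify(list(known.labels) + list(svd_components.labels))
    if len(set(labels)) != len(labels):
        raise ValueError("label collision could not be resolved")
    return ComponentSet(
        axis=known.axis,
        matrix=np.concatenate([known.matrix, svd_components.matrix], axis=1),
        labels=tuple(labels),
        provenance=known.provenance + svd_components.provenance,
    )


def artifact_components_from_negative_delays(
    dataset: Dataset,
    cutoff: float = -2e-12,
    n: int | str = AUTO,
    sv_ratio_floor: float = 3.0,
    ac_floor: float = 0.6,
    label_prefix: str = "negLSV",
) -> ComponentSet:
    """Extract systematic-artifact shapes from the pre-time-zero data.

    Before time zero the reaction has not started, so anything structured
    there is an artifact of the setup.  The columns with delay < ``cutoff``
    are decomposed by SVD and the first ``n`` (or the automatically
    significant) left singular vectors are returned, tagged
    ``svd_negative``.  With "auto" and artifact-free data the returned set
    is empty.
    """
    negatives = subset_by_delay(dataset, -np.inf, cutoff)
    if negatives.n_time < 3:
        raise ValueError(
            f"only {negatives.n_time} delays before cutoff {cutoff!r}; need at least 3"
        )
    svdres = svd_decompose(negatives)
    if n == AUTO:
        indices = select_significant(svdres, sv_ratio_floor=sv_ratio_floor, ac_floor=ac_floor)
    else:
        indices = select_significant(svdres, rank_override=int(n))
    if not indices:
        return ComponentSet.empty(dataset.axis)
    return components_from_svd(svdres, indices, "svd_negative", label_prefix=label_prefix)


def run_sanod(dataset: Dataset, known: ComponentSet, config: SANODConfig | None = None) -> SANODResult:
    """The SANOD method proper.

    Whole-data SVD -> select m significant components -> assemble with the
    known set (known first) -> orthogonalize and prune -> direct-method fit
    (chi-square-weighted when configured).  The result records which
    components were discarded and where every retained component came from.
    """
    if config is None:
        config = SANODConfig()
    if config.weighted and dataset.sigma is None:
        raise ValueError("weighted SANOD requires a dataset with sigma")

    m = config.n_svd_components
    svd_significance: tuple = ()
    if m == AUTO or int(m) > 0:
        svdres = svd_decompose(dataset)
        if m == AUTO:
            indices = select_significant(
                svdres, sv_ratio_floor=config.sv_ratio_floor, ac_floor=config.ac_floor
            )
        else:
            indices = select_significant(svdres, rank_override=int(m))
        svd_significance = svdres.significance
        if indices:
            svd_set = components_from_svd(svdres, indices, "svd_global")
        else:
            svd_set = ComponentSet.empty(dataset.axis)
    else:
        svd_set = ComponentSet.empty(dataset.axis)

    combined = assemble_components(known, svd_set)
    if combined.n_comp == 0:
        raise ValueError("nothing to fit: no known components and no SVD components selected")
    basis = qr_orthonormalize(combined, config.dep_tol)
    if basis.report.n_flagged:
        log.info(
            "discarded %d linearly dependent component(s): %s",
            basis.report.n_flagged,
            ", ".join(basis.report.flagged_labels),
        )
    if config.weighted:
        decomposition = lcf_fit_weighted(dataset, combined, config.dep_tol)
    else:
        decomposition = lcf_fit(dataset, combined, config.dep_tol, basis=basis)
    provenance = dict(zip(combined.labels, combined.provenance))
    return SANODResult(
        decomposition=decomposition,
        dependence=basis.report,
        provenance=provenance,
        config=config,
        svd_significance=svd_significance,
    )


def filter_contributions(dataset: Dataset, result: SANODResult, component_labels) -> Dataset:
    """Subtract fitted contributions of the named components from the data.

    ``signal'(q, t) = signal(q, t) - sum_i alpha_i(t) C_i(q)`` over the
    requested labels, using the chronograms of the reported fit (no refit).
    Sigma is carried unchanged.  Filtering every retained component leaves
    exactly the fit residual.
    """
    labels = list(component_labels)
    retained = set(result.retained_labels())
    for label in labels:
        if label not in result.components.labels:
            raise KeyError(f"unknown component label {label!r}")
        if label not in retained:
            raise ValueError(f"component {label!r} was discarded from the fit; nothing to filter")
    signal = dataset.signal.copy()
    for label in labels:
        contribution = np.outer(
            result.components.column(label), result.chronograms.row(label)
        )
        signal -= contribution
    meta = dict(dataset.meta)
    note = "filtered: " + ", ".join(labels) if labels else "filtered: (none)"
    meta["filter_history"] = meta.get("filter_history", []) + [note]
    return Dataset(axis=dataset.axis, times=dataset.times, signal=signal,
                   sigma=dataset.sigma, meta=meta)
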