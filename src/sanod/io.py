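"""Delimited-text readers and writers for datasets, components and chronograms.

One dialect serves all files: optional ``#`` comment lines, then a header
row, then one row per spectral point (or per delay, for chronogram tables).
Whitespace- and comma-separated files are auto-detected.  For a data matrix
the header is the axis label followed by one delay (in seconds) per column;
each data row is the axis value followed by the signal values.  Component
files put one component per column with its label in the header.  Values are
written with 17 significant digits so write/read round-trips are exact to
double precision.
"""

from __future__ import annotations

import numpy as np

from .core import Chronograms, ComponentSet, Dataset, SpectralAxis, TimeAxis, UNITS

__all__ = [
    "load_dataset",
    "save_dataset",
    "load_components",
    "save_components",
    "load_chronograms",
    "save_chronograms",
]

_FMT = "%.17g"


def _parse_table(path):
    """Return (comments, header_tokens, ndarray of body rows)."""
    comments: list[str] = []
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line[1:].strip())
                continue
            sep = "," if "," in line else None
            tokens = [t for t in (line.split(sep)) if t.strip()]
            tokens = [t.strip() for t in tokens]
            if header is None:
                header = tokens
                continue
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if len(tokens) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: row has {len(tokens)} fields, header has {len(header)}"
                )
    if header is None:
        raise ValueError(f"{path}: missing header row")
    body = np.asarray(rows, dtype=float) if rows else np.empty((0, len(header)))
    return comments, header, body


def _comment_value(comments, key):
    prefix = key + ":"
    for c in comments:
        if c.startswith(prefix):
            return c[len(prefix):].strip()
    return None


def _header_floats(header, path):
    try:
        return np.asarray([float(t) for t in header[1:]], dtype=float)
    except ValueError:
        raise ValueError(f"{path}: malformed header (non-numeric delay)") from None


def _axis_from_table(comments, header, body) -> SpectralAxis:
    unit = _comment_value(comments, "unit")
    if unit not in UNITS:
        unit = "arbitrary"
    return SpectralAxis(values=body[:, 0], unit=unit, label=header[0])


def load_dataset(matrix_path, sigma_path=None) -> Dataset:
    """Read a difference-signal matrix (and optional sigma matrix) from disk.

    The sigma file must use the identical dialect and match the signal's
    shape; non-positive sigma entries are rejected.
    """
    comments, header, body = _parse_table(matrix_path)
    delays = _header_floats(header, matrix_path)
    if body.shape[0] == 0:
        raise ValueError(f"{matrix_path}: empty dataset (no data rows)")
    axis = _axis_from_table(comments, header, body)
    signal = body[:, 1:]
    sigma = None
    if sigma_path is not None:
        s_comments, s_header, s_body = _parse_table(sigma_path)
        s_delays = _header_floats(s_header, sigma_path)
        if s_body.shape != body.shape or s_delays.size != delays.size:
            raise ValueError(
                f"sigma file {sigma_path} shape {s_body.shape} does not match signal {body.shape}"
            )
        sigma = s_body[:, 1:]
    return Dataset(axis=axis, times=TimeAxis(delays), signal=signal, sigma=sigma)


def save_dataset(dataset: Dataset, matrix_path, sigma_path=None) -> None:
    """Write a dataset (and optionally its sigma matrix) in the text dialect."""
    if dataset.n_time == 0:
        raise ValueError("empty dataset")
    _write_matrix(matrix_path, dataset.axis, dataset.times.delays, dataset.signal,
                  kind="difference-signal matrix")
    if sigma_path is not None:
        if dataset.sigma is None:
            raise ValueError("dataset has no sigma matrix to save")
        _write_matrix(sigma_path, dataset.axis, dataset.times.delays, dataset.sigma,
                      kind="standard-deviation matrix")


def _token(text: str) -> str:
    return "_".join(str(text).split()) or "x"


def _write_matrix(path, axis, delays, matrix, kind):
    with open(path, "w") as fh:
        fh.write(f"# {kind}: rows = spectral points, columns = time delays (s)\n")
        fh.write(f"# unit: {axis.unit}\n")
        header = [_token(axis.label)] + [_FMT % t for t in delays]
        fh.write(" ".join(header) + "\n")
        for i, q in enumerate(axis.values):
            fh.write(" ".join([_FMT % q] + [_FMT % v for v in matrix[i]]) + "\n")


def load_components(path, default_provenance: str = "prior") -> ComponentSet:
    """Read a component file: header = axis label + component labels.

    Provenance tags round-trip through a ``# provenance:`` comment; absent
    that, every component is tagged with ``default_provenance``.
    """
    comments, header, body = _parse_table(path)
    if body.shape[0] == 0:
        raise ValueError(f"{path}: empty component file")
    axis = _axis_from_table(comments, header, body)
    labels = tuple(header[1:])
    prov_text = _comment_value(comments, "provenance")
    if prov_text:
        provenance = tuple(prov_text.split())
        if len(provenance) != len(labels):
            raise ValueError(f"{path}: provenance comment does not match component count")
    else:
        provenance = tuple(default_provenance for _ in labels)
    return ComponentSet(axis=axis, matrix=body[:, 1:], labels=labels, provenance=provenance)


def save_components(components: ComponentSet, path) -> None:
    if components.n_comp == 0:
        raise ValueError("empty component set")
    with open(path, "w") as fh:
        fh.write("# spectral components: one column per component\n")
        fh.write(f"# unit: {components.axis.unit}\n")
        fh.write("# provenance: " + " ".join(components.provenance) + "\n")
        header = [_token(components.axis.label)] + [_token(l) for l in components.labels]
        fh.write(" ".join(header) + "\n")
        for i, q in enumerate(components.axis.values):
            fh.write(" ".join([_FMT % q] + [_FMT % v for v in components.matrix[i]]) + "\n")


def load_chronograms(path) -> Chronograms:
    """Read a chronogram table: first column delay (s), one column per component."""
    _comments, header, body = _parse_table(path)
    if body.shape[0] == 0:
        raise ValueError(f"{path}: empty chronogram table")
    return Chronograms(
        times=TimeAxis(body[:, 0]),
        weights=body[:, 1:].T,
        labels=tuple(header[1:]),
    )


def save_chronograms(chronograms: Chronograms, path) -> None:
    with open(path, "w") as fh:
        fh.write("# chronograms: per-component time-dependent weights\n")
        header = ["t"] + [_token(l) for l in chronograms.labels]
        fh.write(" ".join(header) + "\n")
        for j, t in enumerate(chronograms.times.delays):
            fh.write(" ".join([_FMT % t] + [_FMT % w for w in chronograms.weights[:, j]]) + "\n")
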