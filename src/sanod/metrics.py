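"""Small comparison metrics shared by examples, tests and validation scripts."""

from __future__ import annotations

import numpy as np

__all__ = ["r_squared", "pearson_r2", "cosine_similarity"]


def r_squared(truth, estimate) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot of estimate vs truth.

    Scale-sensitive: an estimate that reproduces the truth only up to a
    multiplicative factor scores low.  The truth must have nonzero variance.
    """
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("truth has zero variance; R^2 undefined")
    return 1.0 - float(np.sum((truth - estimate) ** 2)) / ss_tot


def pearson_r2(a, b) -> float:
    """Squared Pearson correlation — scale- and offset-free agreement."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def cosine_similarity(a, b, signless: bool = False) -> float:
    """Cosine of the angle between two vectors; |cos| with ``signless``.

    ``signless`` is the right choice when one side carries an arbitrary
    sign convention (e.g. singular vectors).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return abs(c) if signless else c
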