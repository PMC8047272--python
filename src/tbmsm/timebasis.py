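"""Flexible time bases for pooled logistic models.

Sixty interval dummies are unstable at a few hundred subjects, so time
enters the treatment, censoring and outcome models through a restricted
(natural) cubic spline by default; interval dummies remain available for
small numbers of intervals.
"""

from __future__ import annotations

import numpy as np
from patsy import dmatrix

__all__ = ["natural_spline_basis", "time_basis"]


def natural_spline_basis(t: np.ndarray, df: int = 4) -> np.ndarray:
    """Natural cubic spline basis (no intercept column) evaluated at ``t``.

    Knots are placed at quantiles of ``t``.  When ``t`` has too few
    distinct values to support ``df`` spline terms, falls back to
    treating time as categorical (one dummy per level beyond the first),
    which is then saturated rather than under-determined.
    """
    t = np.asarray(t, dtype=float)
    uniq = np.unique(t)
    if len(uniq) == 1:
        return np.empty((len(t), 0))
    if len(uniq) <= df + 1:
        return (t[:, None] == uniq[1:][None, :]).astype(float)
    # cr() spans the constant; ask for one extra column and drop it so the
    # basis is full-rank next to an explicit intercept
    basis = np.asarray(dmatrix("cr(x, df=%d) - 1" % (df + 1), {"x": t},
                               return_type="matrix"))
    return basis[:, 1:]


def time_basis(t: np.ndarray, kind: str = "spline", df: int = 4) -> np.ndarray:
    """Dispatch on basis kind: ``spline`` (default), ``linear`` or ``dummies``."""
    t = np.asarray(t, dtype=float)
    if kind == "spline":
        return natural_spline_basis(t, df=df)
    if kind == "linear":
        return t[:, None]
    if kind == "dummies":
        uniq = np.unique(t)
        return (t[:, None] == uniq[1:][None, :]).astype(float)
    raise ValueError(f"unknown time basis kind: {kind!r}")
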