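"""ParCorr: the linear partial-correlation conditional-independence test.

This is the statistical primitive of both causal-discovery steps.  The partial
correlation of x and y given a condition matrix Z is computed residually:
regress x on Z and y on Z by ordinary least squares (with intercept) and take
the Pearson correlation of the two residual vectors.  This regress-then-
correlate route is numerically robust to near-collinear conditions; its
equivalence to the precision-matrix formula is retained as a test oracle.

Significance uses the standard Student-t transform
``t = r * sqrt(df / (1 - r^2))`` with ``df = n_eff - |Z| - 2`` degrees of
freedom, two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError

__all__ = ["CITestResult", "partial_corr", "parcorr_test"]

_RESIDUAL_VAR_FLOOR = 1e-12
_STAT_CAP = 1.0 - 1e-12


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one conditional-independence test."""

    stat: float  # partial correlation in [-1, 1]
    pvalue: float
    df: int
    n_eff: int
    cond_dim: int


def _as_condition_matrix(Z, n: int) -> np.ndarray:
    if Z is None:
        return np.empty((n, 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != n:
        raise ValueError("Z must have the same number of rows as x and y")
    return Z


def _standardize(a: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=0)
    sd = a.std(axis=0)
    # near-constant columns stay centered; the intercept absorbs them anyway
    sd = np.where(sd > 1e-15, sd, 1.0)
    return a / sd


def residualize(xy: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of ``xy`` on [1, Z]."""
    design = np.column_stack([np.ones(Z.shape[0]), Z])
    beta, *_ = np.linalg.lstsq(design, xy, rcond=None)
    return xy - design @ beta


def partial_corr(x, y, Z=None) -> float:
    """Partial correlation of x and y given Z (plain Pearson for empty Z)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    Z = _as_condition_matrix(Z, n)
    if n < Z.shape[1] + 3:
        raise ValueError(f"need at least |Z| + 3 = {Z.shape[1] + 3} samples, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(Z).all()):
        raise ValueError("inputs must be finite")
    xy = _standardize(np.column_stack([x, y]))
    res = residualize(xy, _standardize(Z)) if Z.shape[1] else xy
    var = (res**2).mean(axis=0)
    if (var < _RESIDUAL_VAR_FLOOR).any():
        which = "x" if var[0] < _RESIDUAL_VAR_FLOOR else "y"
        raise DegenerateDataError(
            f"residual variance of {which} below {_RESIDUAL_VAR_FLOOR:g}; "
            "variable is (conditionally) constant"
        )
    r = float(res[:, 0] @ res[:, 1] / np.sqrt(var[0] * var[1]) / res.shape[0])
    return float(np.clip(r, -1.0, 1.0))


def parcorr_test(x, y, Z=None, n_eff: int | None = None) -> CITestResult:
    """ParCorr test of x vs y given Z, two-sided Student-t p-value.

    ``n_eff`` overrides the sample count entering the degrees of freedom, for
    callers whose rows come from an overlapping lagged window.
    """
    x = np.asarray(x, dtype=float).ravel()
    Zm = _as_condition_matrix(Z, x.size)
    cond_dim = Zm.shape[1]
    n = x.size if n_eff is None else int(n_eff)
    df = n - cond_dim - 2
    if df < 1:
        raise ValueError(f"degrees of freedom {df} < 1 (n_eff={n}, |Z|={cond_dim})")
    r = partial_corr(x, y, Z)
    r_capped = float(np.clip(r, -_STAT_CAP, _STAT_CAP))
    t = r_capped * np.sqrt(df / (1.0 - r_capped**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CITestResult(stat=r, pvalue=min(p, 1.0), df=df, n_eff=n, cond_dim=cond_dim)
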