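"""Validation statistics for correlation-weight QSAR models.

Implements the full metric suite used to judge a univariate model
``y = c0 + c1 * DCW``:

* ``r2`` (squared Pearson correlation) and ``mae``;
* IIC — the index of ideality of correlation: the correlation coefficient
  scaled by ``min(MAE-, MAE+) / max(MAE-, MAE+)``, where ``MAE-`` averages
  the absolute residuals with ``observed - calculated < 0`` and ``MAE+``
  those with ``observed - calculated >= 0``.  One-sided residual clouds
  give IIC = 0; symmetric clouds give IIC = r.
* CII — the correlation intensity index ``1 - sum_k max(0, R2_{-k} - R2)``,
  summing each point's "protest": the improvement of the determination
  coefficient when the point is deleted.  Collinear data give CII = 1,
  and CII <= 1 always.
* Q2 (leave-one-out cross-validated determination coefficient of the
  univariate fit), the external criteria Q2_F1, Q2_F2, Q2_F3, the averaged
  Roy metric <Rm2>, and the Fisher F-ratio.

All functions take plain 1-D arrays (observed, calculated); ``nan`` never
propagates silently — degenerate inputs either raise ``ZeroVarianceError``
or return the documented edge value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DegenerateDescriptorError, ZeroVarianceError

__all__ = [
    "r2",
    "mae",
    "iic",
    "cii",
    "q2_loo",
    "q2f_family",
    "rm2_average",
    "f_ratio",
    "target_function",
    "MetricReport",
    "compute_report",
]

_EPS = 1e-14


def _as_xy(obs, calc) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(obs, dtype=float)
    y = np.asarray(calc, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("observed and calculated must be 1-D arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in prediction set")
    return x, y


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    if n < 2:
        raise ZeroVarianceError("need at least 2 points for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx <= _EPS * n or syy <= _EPS * n:
        raise ZeroVarianceError("zero variance in correlation input")
    return float((xc @ yc) / math.sqrt(sxx * syy))


def r2(obs, calc) -> float:
    """Determination coefficient: squared Pearson correlation."""
    x, y = _as_xy(obs, calc)
    return _pearson(x, y) ** 2


def mae(obs, calc) -> float:
    """Mean absolute error of the predictions."""
    x, y = _as_xy(obs, calc)
    if len(x) == 0:
        raise ValueError("empty prediction set")
    return float(np.abs(x - y).mean())


def iic(obs, calc) -> float:
    """Index of ideality of correlation.

    ``r * min(MAE-, MAE+) / max(MAE-, MAE+)`` with residuals
    ``delta = observed - calculated`` split at zero (``delta >= 0`` counts
    on the positive side).  Edge cases: a perfect fit returns 1.0; an
    empty residual side gives ratio 0 hence IIC 0; if the correlation is
    undefined (constant input) and the fit is not perfect, returns 0.0.
    IIC keeps the sign of r, so negative correlations yield negative IIC.
    """
    x, y = _as_xy(obs, calc)
    delta = x - y
    if np.all(np.abs(delta) <= _EPS):
        return 1.0
    neg = delta < 0
    pos = ~neg
    mae_neg = float(np.abs(delta[neg]).mean()) if neg.any() else 0.0
    mae_pos = float(np.abs(delta[pos]).mean()) if pos.any() else 0.0
    hi = max(mae_neg, mae_pos)
    lo = min(mae_neg, mae_pos)
    ratio = lo / hi if hi > 0 else 1.0
    try:
        r = _pearson(x, y)
    except ZeroVarianceError:
        return 0.0
    return r * ratio


def cii(obs, calc) -> float:
    """Correlation intensity index ``1 - sum of protests`` (vectorized).

    A point's protest is ``max(0, R2_{-k} - R2)``: how much the
    determination coefficient rises when that point is removed.  A
    leave-one-out subset with zero variance contributes 0.  Equivalent to
    the direct O(n^2) recomputation loop to ~1e-12.
    """
    x, y = _as_xy(obs, calc)
    n = len(x)
    if n < 3:
        raise ValueError("CII needs at least 3 points")
    r2_full = _pearson(x, y) ** 2

    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = float(x @ x), float(y @ y), float(x @ y)
    m = n - 1
    # leave-one-out centered sums, one point deleted at a time
    sxx_k = (sxx - x * x) - (sx - x) ** 2 / m
    syy_k = (syy - y * y) - (sy - y) ** 2 / m
    sxy_k = (sxy - x * y) - (sx - x) * (sy - y) / m
    den = sxx_k * syy_k
    ok = den > _EPS * m
    r2_k = np.zeros(n)
    r2_k[ok] = sxy_k[ok] ** 2 / den[ok]
    protests = np.maximum(0.0, r2_k - r2_full)
    protests[~ok] = 0.0
    return float(1.0 - protests.sum())


def q2_loo(y, x) -> float:
    """Leave-one-out cross-validated Q2 of the univariate OLS fit of y on x.

    ``1 - PRESS / SS_tot`` using the hat-matrix shortcut
    ``e_loo = e / (1 - h)``; identical to refitting without each point.
    """
    x, y = _as_xy(x, y)  # reuse validation; order irrelevant there
    n = len(x)
    if n < 3:
        raise ValueError("Q2 needs at least 3 points")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= _EPS * n:
        raise DegenerateDescriptorError("zero variance in descriptor")
    c1 = float(xc @ (y - y.mean())) / sxx
    c0 = float(y.mean() - c1 * x.mean())
    resid = y - (c0 + c1 * x)
    h = 1.0 / n + xc**2 / sxx
    if np.any(1.0 - h <= _EPS):
        raise DegenerateDescriptorError("leverage 1 point: LOO refit degenerate")
    press = float(((resid / (1.0 - h)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= _EPS * n:
        raise ZeroVarianceError("constant endpoint")
    return 1.0 - press / ss_tot


def q2f_family(
    obs_ext, calc_ext, train_endpoints
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """External-set criteria (Q2_F1, Q2_F2, Q2_F3).

    Q2_F1 = 1 - SSE_ext / sum_ext (y - mean(y_train))^2
    Q2_F2 = 1 - SSE_ext / sum_ext (y - mean(y_ext))^2
    Q2_F3 = 1 - [SSE_ext / n_ext] / [sum_train (y - mean(y_train))^2 / n_train]

    A zero denominator marks that criterion not-applicable (None).
    """
    x, y = _as_xy(obs_ext, calc_ext)
    yt = np.asarray(train_endpoints, dtype=float)
    sse = float(((x - y) ** 2).sum())
    d1 = float(((x - yt.mean()) ** 2).sum())
    d2 = float(((x - x.mean()) ** 2).sum())
    d3 = float(((yt - yt.mean()) ** 2).sum())
    f1 = 1.0 - sse / d1 if d1 > _EPS else None
    f2 = 1.0 - sse / d2 if d2 > _EPS else None
    f3 = (
        1.0 - (sse / len(x)) / (d3 / len(yt)) if d3 > _EPS else None
    )
    return f1, f2, f3


def _rm2(x: np.ndarray, y: np.ndarray) -> float:
    """Roy's rm^2 for predicting y from x: r2 * (1 - sqrt(|r2 - r0^2|)).

    r0^2 is the through-origin determination coefficient of the fit
    y = k*x with k = sum(xy)/sum(x^2).
    """
    rsq = _pearson(x, y) ** 2
    sxx = float(x @ x)
    if sxx <= _EPS:
        raise ZeroVarianceError("all-zero regressor in through-origin fit")
    k = float(x @ y) / sxx
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= _EPS:
        raise ZeroVarianceError("constant response in through-origin fit")
    r0sq = 1.0 - float(((y - k * x) ** 2).sum()) / ss_tot
    return rsq * (1.0 - math.sqrt(abs(rsq - r0sq)))


def rm2_average(obs, calc) -> Optional[float]:
    """Mean of rm^2 over both regression directions; None if degenerate."""
    x, y = _as_xy(obs, calc)
    if len(x) < 3:
        raise ValueError("<Rm2> needs at least 3 points")
    try:
        return 0.5 * (_rm2(x, y) + _rm2(y, x))
    except ZeroVarianceError:
        return None


def f_ratio(obs, calc) -> Optional[float]:
    """Fisher F-ratio ``r2 (n-2) / (1 - r2)`` of the univariate model."""
    x, y = _as_xy(obs, calc)
    n = len(x)
    if n < 3:
        raise ValueError("F-ratio needs at least 3 points")
    rsq = _pearson(x, y) ** 2
    if 1.0 - rsq <= _EPS:
        return None
    return rsq * (n - 2) / (1.0 - rsq)


def target_function(
    r2_a: float, r2_p: float, index_c: float, coefficient: float = 0.3
) -> float:
    """Monte Carlo objective: ``R2_A + R2_P - |R2_A - R2_P| + coeff * index_C``.

    ``index_C`` is either IIC or CII evaluated on the calibration set; the
    0.3 default coefficient is the empirically chosen weighting.
    """
    return r2_a + r2_p - abs(r2_a - r2_p) + coefficient * index_c


@dataclass
class MetricReport:
    """One table row of per-set statistics; None marks not-applicable."""

    n: int
    r2: Optional[float] = None
    mae: Optional[float] = None
    iic: Optional[float] = None
    cii: Optional[float] = None
    q2_loo: Optional[float] = None
    q2f1: Optional[float] = None
    q2f2: Optional[float] = None
    q2f3: Optional[float] = None
    rm2_avg: Optional[float] = None
    f_ratio: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def compute_report(obs, calc, train_endpoints=None) -> MetricReport:
    """All applicable statistics for one (observed, calculated) set.

    ``train_endpoints`` (active-training endpoints) switches on the
    external Q2_F family.  Statistics whose preconditions fail are left
    as None rather than raising.
    """
    x, y = _as_xy(obs, calc)
    rep = MetricReport(n=len(x))
    rep.mae = mae(x, y)

    def _try(fn, *args):
        try:
            return fn(*args)
        except (ValueError, ZeroVarianceError, DegenerateDescriptorError):
            return None

    rep.r2 = _try(r2, x, y)
    rep.iic = _try(iic, x, y)
    rep.cii = _try(cii, x, y)
    rep.q2_loo = _try(q2_loo, x, y)
    rep.rm2_avg = _try(rm2_average, x, y)
    rep.f_ratio = _try(f_ratio, x, y)
    if train_endpoints is not None:
        out = _try(q2f_family, x, y, train_endpoints)
        if out is not None:
            rep.q2f1, rep.q2f2, rep.q2f3 = out
    return rep
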