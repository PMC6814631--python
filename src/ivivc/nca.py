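"""Noncompartmental analysis of a single concentration-time profile.

Cmax/Tmax are read directly off the data (earliest time on ties). AUC to
the last quantifiable sample uses the linear trapezoidal rule. The
terminal rate constant lambda_z (beta) is the negative slope of the
least-squares regression of ln C on t over the terminal window chosen by
best adjusted R-squared among all candidate windows of >= 3 quantifiable
points strictly after Tmax (more points win ties within a small
tolerance). AUC_inf adds C_last/lambda_z, and t_half = ln(2)/lambda_z.

Censored (below-LLOQ) samples before the first quantifiable concentration
count as 0 in the trapezoid; embedded or trailing censored samples are
excluded from both the trapezoid and the lambda_z regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import ConcentrationProfile
from .errors import ProfileError

__all__ = ["NCAResult", "compute_nca", "trapezoid_auc", "geometric_mean", "harmonic_mean"]


@dataclass
class NCAResult:
    subject_id: str
    regimen: str
    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float  # NaN if no terminal slope could be estimated
    lambda_z: float
    t_half: float
    n_lambda_points: int
    r2_adj: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def trapezoid_auc(times: np.ndarray, conc: np.ndarray) -> float:
    """Linear trapezoidal AUC over the supplied points."""
    return float(np.trapezoid(conc, times))


def geometric_mean(values) -> float:
    """exp(mean(ln x)); all values must be strictly positive."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("geometric_mean of empty collection")
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("geometric_mean requires finite positive values")
    return float(np.exp(np.mean(np.log(v))))


def harmonic_mean(values) -> float:
    """n / sum(1/x) — the conventional summary for terminal half-lives."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.any(v <= 0):
        raise ValueError("harmonic_mean requires positive values")
    return float(v.size / np.sum(1.0 / v))


def _lambda_z(
    t: np.ndarray, c: np.ndarray, tmax: float, min_points: int, r2_tol: float
) -> tuple[float, int, float]:
    """Best-adjusted-R2 terminal regression. Returns (lambda_z, n, r2_adj);
    lambda_z is NaN when no candidate window has a positive elimination slope."""
    after = np.nonzero((t > tmax) & (c > 0))[0]
    if after.size < min_points:
        return math.nan, 0, math.nan
    best = (math.nan, 0, -np.inf)
    # candidate windows run from each start point through the last point
    for i in range(after.size - min_points + 1):
        idx = after[i:]
        x, y = t[idx], np.log(c[idx])
        n = idx.size
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        # strictly-better rule: longer windows (iterated first) win ties
        if r2_adj > best[2] + r2_tol:
            best = (-slope, n, r2_adj)
    if not math.isfinite(best[2]):
        return math.nan, 0, math.nan
    return best


def compute_nca(
    profile: ConcentrationProfile,
    min_lambda_points: int = 3,
    r2_tol: float = 1e-4,
) -> NCAResult:
    """Noncompartmental parameters for one profile."""
    t_all, c_all, bql = profile.times, profile.concentrations, profile.bql
    quant = profile.quantifiable
    if np.count_nonzero(quant) < 4:
        raise ProfileError(
            f"NCA needs >= 4 quantifiable concentrations "
            f"({profile.subject_id}/{profile.regimen})"
        )
    first_q = int(np.nonzero(quant)[0][0])
    last_q = int(np.nonzero(quant)[0][-1])

    # leading censored values count as 0; embedded/trailing are dropped
    keep = np.zeros(t_all.size, dtype=bool)
    keep[: first_q + 1] = True  # leading BQL (as 0) + first quantifiable
    keep[first_q : last_q + 1] |= quant[first_q : last_q + 1]
    t = t_all[keep]
    c = np.where(bql[keep], 0.0, c_all[keep])

    imax = int(np.argmax(c))  # argmax returns the earliest index on ties
    cmax, tmax = float(c[imax]), float(t[imax])
    auc_last = trapezoid_auc(t, c)

    lam, n_lam, r2_adj = _lambda_z(t, c, tmax, min_lambda_points, r2_tol)
    if math.isnan(lam):
        auc_inf = math.nan
        t_half = math.nan
    else:
        c_last = float(c[-1])
        auc_inf = auc_last + c_last / lam
        t_half = math.log(2.0) / lam

    return NCAResult(
        subject_id=profile.subject_id,
        regimen=profile.regimen,
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
        auc_inf=auc_inf,
        lambda_z=lam,
        t_half=t_half,
        n_lambda_points=n_lam,
        r2_adj=r2_adj,
    )
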