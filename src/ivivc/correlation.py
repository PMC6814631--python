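"""Stage-2 level-A correlation: fraction absorbed vs fraction dissolved.

The default model is a nonlinear Emax time scaling that maps the in vivo
clock onto the in vitro dissolution clock,

    T_vitro = A1 * T_vivo / (A2 + T_vivo) - B2        (clamped at 0),

with one common (A1, A2, B2) for all formulations and *no* absorption
scale factor, so that

    Fa_pred(t) = F_diss,vitro(T_vitro(t)).

A1 - B2 is the asymptotic in vitro time: only release occurring before
that in vitro time is ever absorbed. Negative mapped times (early t_vivo,
where the B2 offset dominates) clamp to 0, i.e. zero dissolved.

Classical linear variants — Fa(t) = abs_scale * F_diss(time_scale * (t -
time_shift)) — are provided for comparison; on data with a genuinely
nonlinear time relationship they systematically under-predict Cmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .deconv import AbsorptionProfile
from .dissolution import DissolutionFit
from .errors import FitError

__all__ = [
    "TimeScaleModel",
    "LinearIVIVC",
    "map_time",
    "fit_emax_timescale",
    "fit_linear_ivivc",
    "predict_fa",
    "DEFAULT_STARTS",
]

# canonical multi-start ladder for (A1, A2, B2), hours
DEFAULT_STARTS = ((15.0, 5.0, 8.0), (16.0, 6.0, 10.0))


@dataclass
class TimeScaleModel:
    """Fitted Emax time-scale constants (hours) with standard errors."""

    a1: float
    a2: float
    b2: float
    se: tuple[float, float, float]
    sse: float
    n_obs: int

    def __post_init__(self):
        if self.a1 <= 0 or self.a2 <= 0:
            raise FitError("A1 and A2 must be positive")
        if self.a1 - self.b2 <= 0:
            raise FitError(
                f"degenerate time scale: asymptotic in vitro time A1 - B2 = "
                f"{self.a1 - self.b2:.3g} h must be positive"
            )

    def map_time(self, t_vivo) -> np.ndarray:
        return map_time(self, t_vivo)

    def predict_fa(self, dissolution_fit: DissolutionFit, grid) -> AbsorptionProfile:
        return predict_fa(self, dissolution_fit, grid)


@dataclass
class LinearIVIVC:
    """Linear stage-2 model Fa(t) = abs_scale * F_diss(time_scale*(t - time_shift))."""

    abs_scale: float
    time_scale: float
    time_shift: float
    sse: float
    variant: str = "abs-scale+scale+shift"

    def __post_init__(self):
        if self.time_scale <= 0:
            raise FitError("time_scale must be positive")

    def predict_fa(self, dissolution_fit: DissolutionFit, grid) -> AbsorptionProfile:
        grid = np.asarray(grid, dtype=float)
        t_vitro = np.maximum(self.time_scale * (grid - self.time_shift), 0.0)
        fa = self.abs_scale * dissolution_fit.predict(t_vitro)
        return AbsorptionProfile(
            subject_id=None,
            formulation_id=dissolution_fit.formulation_id,
            times=grid,
            fa=fa,
            dose_er=np.nan,
        )


def map_time(model: TimeScaleModel, t_vivo) -> np.ndarray:
    """Emax map from in vivo time to in vitro time, clamped at 0."""
    t = np.asarray(t_vivo, dtype=float)
    return np.maximum(model.a1 * t / (model.a2 + t) - model.b2, 0.0)


def _stack(fa_profiles, dissolution_fits):
    pairs = []
    for form in sorted(fa_profiles):
        if form not in dissolution_fits:
            raise FitError(f"no dissolution fit for formulation {form!r}")
        p = fa_profiles[form]
        pairs.append((form, p.times, p.fa, dissolution_fits[form]))
    return pairs


def _residual_builder(pairs, observation_model):
    """Residual function: observed Fa vs the model curve, either pointwise
    or through the deconvolution-discretization operator (bias-matched)."""

    def fa_model(dfit, t_vitro):
        return dfit.predict(t_vitro)

    def resid(warp):
        # warp(t) maps in vivo time to in vitro time for the current params
        out = []
        for form, t, fa, dfit in pairs:
            if observation_model is not None and form in observation_model:
                fine, op = observation_model[form]
                pred = op @ np.diff(fa_model(dfit, warp(fine)))
            else:
                pred = fa_model(dfit, warp(t))
            out.append(pred - fa)
        return np.concatenate(out)

    return resid


def fit_emax_timescale(
    fa_profiles: Mapping[str, AbsorptionProfile],
    dissolution_fits: Mapping[str, DissolutionFit],
    starts=DEFAULT_STARTS,
    observation_model: Mapping | None = None,
) -> TimeScaleModel:
    """Fit one common (A1, A2, B2) to all supplied formulations.

    Minimizes the pooled squared error between observed Fa and the
    time-scaled dissolution curve, with no absorption scale factor.
    Multi-start over ``starts`` plus +/-50% perturbations of each.

    ``observation_model`` optionally maps each formulation to a
    ``(fine_grid, operator)`` pair from
    :func:`ivivc.deconv.observation_operator`; the model curve is then
    passed through the same deconvolution discretization that produced
    the observed Fa, so the discretization bias cancels instead of
    propagating into the parameters.
    """
    if len(fa_profiles) < 1:
        raise FitError("need at least one formulation to fit the time scale")
    pairs = _stack(fa_profiles, dissolution_fits)
    n_obs = sum(t.size for _, t, _, _ in pairs)
    base_resid = _residual_builder(pairs, observation_model)

    def resid(x):
        a1, a2, b2 = x
        return base_resid(lambda t: np.maximum(a1 * t / (a2 + t) - b2, 0.0))

    lo = np.array([1e-6, 1e-6, -np.inf])
    hi = np.array([np.inf, np.inf, np.inf])
    all_starts = []
    for s in starts:
        all_starts.append(np.asarray(s, dtype=float))
        all_starts.append(np.asarray(s, dtype=float) * 1.5)
        all_starts.append(np.asarray(s, dtype=float) * 0.5)
    best = None
    for x0 in all_starts:
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("Emax time-scale fit did not converge from any start")

    sse = float(2 * best.cost)
    dof = max(n_obs - 3, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * (sse / dof)
        se = tuple(float(s) for s in np.sqrt(np.maximum(np.diag(cov), 0.0)))
    except np.linalg.LinAlgError:
        se = (np.nan, np.nan, np.nan)
    return TimeScaleModel(
        a1=float(best.x[0]),
        a2=float(best.x[1]),
        b2=float(best.x[2]),
        se=se,
        sse=sse,
        n_obs=n_obs,
    )


_LINEAR_VARIANTS = {
    "scale": ("time_scale",),
    "scale+shift": ("time_scale", "time_shift"),
    "abs-scale+scale+shift": ("abs_scale", "time_scale", "time_shift"),
}


def fit_linear_ivivc(
    fa_profiles: Mapping[str, AbsorptionProfile],
    dissolution_fits: Mapping[str, DissolutionFit],
    variant: str = "abs-scale+scale+shift",
    observation_model: Mapping | None = None,
) -> LinearIVIVC:
    """Fit a classical linear correlation (shared across formulations)."""
    if variant not in _LINEAR_VARIANTS:
        raise ValueError(f"unknown linear variant {variant!r}")
    free = _LINEAR_VARIANTS[variant]
    pairs = _stack(fa_profiles, dissolution_fits)

    def unpack(x):
        params = {"abs_scale": 1.0, "time_scale": 1.0, "time_shift": 0.0}
        for name, v in zip(free, x):
            params[name] = v
        return params

    def resid(x):
        p = unpack(x)
        out = []
        for form, t, fa, dfit in pairs:
            if observation_model is not None and form in observation_model:
                fine, op = observation_model[form]
                t_vitro = np.maximum(p["time_scale"] * (fine - p["time_shift"]), 0.0)
                pred = op @ np.diff(p["abs_scale"] * dfit.predict(t_vitro))
            else:
                t_vitro = np.maximum(p["time_scale"] * (t - p["time_shift"]), 0.0)
                pred = p["abs_scale"] * dfit.predict(t_vitro)
            out.append(pred - fa)
        return np.concatenate(out)

    x0 = np.array([{"abs_scale": 1.0, "time_scale": 1.0, "time_shift": 0.0}[f] for f in free])
    lo = np.array([{"abs_scale": 1e-6, "time_scale": 1e-6, "time_shift": -np.inf}[f] for f in free])
    best = None
    for fac in (1.0, 0.5, 2.0):
        start = np.where(np.isfinite(x0 * fac), x0 * fac, x0)
        start = np.maximum(start, lo + 1e-9) if np.all(np.isfinite(lo)) else start
        try:
            sol = least_squares(resid, np.clip(start, lo + 1e-9, None),
                                bounds=(lo, np.inf), method="trf", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("linear IVIVC fit did not converge")
    p = unpack(best.x)
    return LinearIVIVC(
        abs_scale=float(p["abs_scale"]),
        time_scale=float(p["time_scale"]),
        time_shift=float(p["time_shift"]),
        sse=float(2 * best.cost),
        variant=variant,
    )


def predict_fa(
    model: TimeScaleModel, dissolution_fit: DissolutionFit, grid
) -> AbsorptionProfile:
    """Predicted fraction absorbed on ``grid``: F_diss(map_time(t))."""
    grid = np.asarray(grid, dtype=float)
    fa = dissolution_fit.predict(map_time(model, grid))
    return AbsorptionProfile(
        subject_id=None,
        formulation_id=dissolution_fit.formulation_id,
        times=grid,
        fa=fa,
        dose_er=np.nan,
    )
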