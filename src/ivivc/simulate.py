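"""Synthetic crossover-study generator with known ground truth.

Emulates a five-period, single-dose crossover bioavailability study in
N healthy subjects: one oral immediate-release (IR) reference arm and
four extended-release (ER) arms of the same drug differing only in the
release-controlling polymer (HPMC) load, plus the matching in vitro
dissolution profiles.

Per subject, a polyexponential disposition is drawn with lognormal
between-subject variability. The IR arm follows first-order absorption
(rate ka, lag t_lag) into that disposition. Each ER arm's cumulative
in vivo input is composed exactly as the level-A correlation model
assumes: the formulation's true Weibull dissolution curve warped by the
Emax time scale,

    Fa(t) = F_rel * F_diss,vitro(A1*t/(A2 + t) - B2),

scaled by the ER dose, and convolved with the subject's *stripped*
disposition kernel (the impulse response the strip-Ka analysis recovers).
Proportional (lognormal) residual error and LLOQ censoring are then
applied. A model-misspecification mode replaces the composed input with
an explicit two-stage absorption profile (fast early phase, change-point,
slow late phase) to probe robustness.

Subject-level parameters are drawn from a stream keyed by ``spec.seed``
while measurement noise uses a separate stream, so re-simulating with a
different noise seed perturbs the data but not the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .datatypes import ConcentrationProfile, DissolutionProfile, StudyDataset
from .dissolution import weibull

__all__ = ["FormulationSpec", "GeneratorSpec", "GroundTruth", "generate_study", "paper_like_spec"]

# study sampling schedules (hours)
PLASMA_TIMES = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0,
                10.0, 12.0, 16.0, 24.0, 36.0, 48.0, 72.0)
DISSOLUTION_TIMES = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 20.0, 24.0)

_FINE_DT = 0.0125  # h; every plasma sampling time is a multiple of this


@dataclass
class FormulationSpec:
    """True Weibull release curve and bioavailability of one ER formulation."""

    formulation_id: str
    hpmc_pct: float
    mdt: float  # h
    b: float
    rel_bioavailability: float = 1.0


@dataclass
class GeneratorSpec:
    """Study conditions of the simulated crossover (defaults = the
    emulated study design: N=20, 24 mg IR reference, 30 mg ER arms)."""

    n_subjects: int = 20
    ir_dose: float = 24.0  # mg
    er_dose: float = 30.0  # mg
    ir_regimen: str = "IR"
    # population disposition: bolus kernel sum c_i*exp(-alpha_i*t), ng/mL per mg
    disposition_coeffs: tuple = (10.0, 0.9)
    disposition_rates: tuple = (0.8, 0.0693)
    ir_ka: float = 3.0  # 1/h
    t_lag: float = 0.0  # h
    bsv_cv: float = 0.25  # lognormal CV on c_i, alpha_i, ka
    formulations: list[FormulationSpec] = field(default_factory=list)
    timescale: tuple = (11.6, 2.66, 3.49)  # (A1, A2, B2), h
    residual_cv: float = 0.10
    dissolution_sd: float = 0.01  # additive SD, fraction of label
    lloq: float = 0.05  # ng/mL
    sampling_times: tuple = PLASMA_TIMES
    dissolution_times: tuple = DISSOLUTION_TIMES
    seed: int = 12345
    absorption_mode: str = "ivivc"  # {"ivivc", "two_stage"}
    # two-stage mode: Fa = w1*(1-exp(-k1*t)) + w2*(1-exp(-k2*max(t-tc,0)))
    two_stage_params: tuple = (0.6, 0.6, 0.35, 0.08, 4.5)  # (w1, k1, w2, k2, tc)


@dataclass
class SubjectTruth:
    subject_id: str
    coeffs: np.ndarray  # bolus disposition c_i
    rates: np.ndarray  # alpha_i
    ka: float
    t_lag: float
    kernel_coeffs: np.ndarray  # stripped kernel c_i*ka/(ka - alpha_i)


@dataclass
class GroundTruth:
    timescale: tuple
    formulations: list[FormulationSpec]
    subjects: dict[str, SubjectTruth]
    spec: GeneratorSpec

    def fa_true(self, formulation_id: str, t) -> np.ndarray:
        """True cumulative fraction absorbed (relative to reference scale)."""
        f = next(f for f in self.formulations if f.formulation_id == formulation_id)
        t = np.asarray(t, dtype=float)
        if self.spec.absorption_mode == "two_stage":
            w1, k1, w2, k2, tc = self.spec.two_stage_params
            fa = w1 * (1 - np.exp(-k1 * t)) + w2 * (1 - np.exp(-k2 * np.maximum(t - tc, 0)))
        else:
            a1, a2, b2 = self.timescale
            t_vitro = np.maximum(a1 * t / (a2 + t) - b2, 0.0)
            fa = weibull(t_vitro, f.mdt, f.b)
        return f.rel_bioavailability * fa


def paper_like_spec(seed: int = 12345, **overrides) -> GeneratorSpec:
    """The canonical study fixture.

    Four ER formulations whose Weibull release curves reach 80% dissolved
    by about 6, 8, 10 and 16 h (HPMC 10/15/20/35%), the final Emax time
    scale (11.6, 2.66, 3.49) h as generating truth, and a biexponential
    disposition giving an IR terminal half-life near 10 h with median
    Tmax near 1 h. With b = 1.2 the 80%-release time is 1.487*MDT.
    """
    t80 = {"A": 6.0, "B": 8.0, "C": 10.0, "D": 16.0}
    hpmc = {"A": 10.0, "B": 15.0, "C": 20.0, "D": 35.0}
    b = 1.2
    factor = math.log(5.0) ** (1.0 / b)  # t80 / MDT for a Weibull
    formulations = [
        FormulationSpec(fid, hpmc[fid], mdt=t80[fid] / factor, b=b)
        for fid in ("A", "B", "C", "D")
    ]
    spec = GeneratorSpec(formulations=formulations, seed=seed)
    return replace(spec, **overrides) if overrides else spec


def _convolve_rate(rate: np.ndarray, coeffs, rates, dt: float) -> np.ndarray:
    """Convolve a piecewise-linear rate (on a uniform grid) with a sum of
    exponentials, exactly per linear segment."""
    out = np.zeros_like(rate)
    n = np.arange(rate.size)
    for c, a in zip(coeffs, rates):
        e = math.exp(-a * dt)
        i0 = (1.0 - e) / a
        j = (dt - i0) / a
        b0, b1 = j / dt, i0 - j / dt
        y = lfilter([b0, b1], [1.0, -e], rate)
        y -= b0 * rate[0] * e**n  # enforce y(0) = 0
        out += c * y
    return out


def _ir_profile(t: np.ndarray, dose: float, subj: SubjectTruth) -> np.ndarray:
    tau = np.maximum(t - subj.t_lag, 0.0)
    out = np.zeros_like(tau)
    for ci, ai in zip(subj.coeffs, subj.rates):
        out += ci * subj.ka / (subj.ka - ai) * (np.exp(-ai * tau) - np.exp(-subj.ka * tau))
    return dose * out


def _er_rate_on_grid(spec: GeneratorSpec, form: FormulationSpec, fine_t: np.ndarray) -> np.ndarray:
    """d/dt of the true cumulative absorbed amount (mg/h), per mg of dose."""
    if spec.absorption_mode == "two_stage":
        w1, k1, w2, k2, tc = spec.two_stage_params
        r = w1 * k1 * np.exp(-k1 * fine_t) + np.where(
            fine_t >= tc, w2 * k2 * np.exp(-k2 * np.maximum(fine_t - tc, 0.0)), 0.0
        )
    else:
        a1, a2, b2 = spec.timescale
        t_vitro = a1 * fine_t / (a2 + fine_t) - b2
        dmap = a1 * a2 / (a2 + fine_t) ** 2
        u = np.maximum(t_vitro, 0.0) / form.mdt
        with np.errstate(invalid="ignore"):
            dfd = (form.b / form.mdt) * u ** (form.b - 1.0) * np.exp(-(u**form.b))
        dfd = np.where(t_vitro > 0, dfd, 0.0)
        dfd = np.nan_to_num(dfd, nan=0.0, posinf=0.0)
        r = dfd * dmap
    return form.rel_bioavailability * r


def _draw_subjects(spec: GeneratorSpec, rng: np.random.Generator) -> dict[str, SubjectTruth]:
    sigma = math.sqrt(math.log(1.0 + spec.bsv_cv**2))
    subjects = {}
    for i in range(spec.n_subjects):
        sid = f"S{i + 1:02d}"
        mult = lambda: float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
        coeffs = np.array([c * mult() for c in spec.disposition_coeffs])
        rates = np.array([a * mult() for a in spec.disposition_rates])
        ka = spec.ir_ka * mult()
        # keep absorption faster than the fastest disposition phase so the
        # stripped-kernel coefficients stay positive (no flip-flop subjects)
        ka = max(ka, 1.3 * float(np.max(rates)))
        kernel = coeffs * ka / (ka - rates)
        subjects[sid] = SubjectTruth(
            subject_id=sid,
            coeffs=coeffs,
            rates=rates,
            ka=ka,
            t_lag=spec.t_lag,
            kernel_coeffs=kernel,
        )
    return subjects


def generate_study(
    spec: GeneratorSpec, noise_seed: int | None = None
) -> tuple[StudyDataset, GroundTruth]:
    """Simulate one complete study.

    Returns the dataset (plasma + dissolution profiles, censored and
    noisy) and the ground-truth bundle. ``noise_seed`` (default:
    ``spec.seed``) controls only the measurement-noise stream.
    """
    if not spec.formulations:
        raise ValueError("GeneratorSpec.formulations must not be empty")
    rng_structure = np.random.default_rng([spec.seed, 11])
    rng_noise = np.random.default_rng([spec.seed if noise_seed is None else noise_seed, 73])

    subjects = _draw_subjects(spec, rng_structure)
    t_obs = np.asarray(spec.sampling_times, dtype=float)
    fine_t = np.arange(0.0, t_obs[-1] + _FINE_DT / 2, _FINE_DT)
    obs_idx = np.rint(t_obs / _FINE_DT).astype(int)
    if not np.allclose(fine_t[obs_idx], t_obs):
        raise ValueError("sampling times must be multiples of the fine grid step")

    sigma_res = math.sqrt(math.log(1.0 + spec.residual_cv**2)) if spec.residual_cv > 0 else 0.0

    def add_noise(c: np.ndarray) -> np.ndarray:
        if sigma_res == 0:
            return c.copy()
        return c * np.exp(rng_noise.normal(0.0, sigma_res, size=c.shape))

    profiles = []
    regimens = [spec.ir_regimen] + [f.formulation_id for f in spec.formulations]
    er_rates = {
        f.formulation_id: spec.er_dose * _er_rate_on_grid(spec, f, fine_t)
        for f in spec.formulations
    }
    for sid, subj in subjects.items():
        period_of = {
            reg: p + 1 for p, reg in enumerate(rng_structure.permutation(regimens))
        }
        # IR reference arm: closed-form oral polyexponential
        c_ir = _ir_profile(t_obs, spec.ir_dose, subj)
        arms = {spec.ir_regimen: (spec.ir_dose, c_ir)}
        for f in spec.formulations:
            c_fine = _convolve_rate(
                er_rates[f.formulation_id], subj.kernel_coeffs, subj.rates, _FINE_DT
            )
            arms[f.formulation_id] = (spec.er_dose, c_fine[obs_idx])
        for reg in regimens:
            dose, c_true = arms[reg]
            c_noisy = add_noise(c_true)
            bql = c_noisy < spec.lloq
            profiles.append(
                ConcentrationProfile(
                    subject_id=sid,
                    period=period_of[reg],
                    regimen=reg,
                    dose_mg=dose,
                    times=t_obs,
                    concentrations=c_noisy,
                    lloq=spec.lloq,
                    bql=bql,
                )
            )

    t_diss = np.asarray(spec.dissolution_times, dtype=float)
    dissolution = []
    for f in spec.formulations:
        frac = weibull(t_diss, f.mdt, f.b)
        if spec.dissolution_sd > 0:
            frac = frac + rng_noise.normal(0.0, spec.dissolution_sd, size=frac.shape)
        frac = np.clip(frac, 0.0, 1.05)
        frac[0] = 0.0
        dissolution.append(
            DissolutionProfile(
                formulation_id=f.formulation_id,
                times=t_diss,
                fraction_dissolved=frac,
                hpmc_pct=f.hpmc_pct,
            )
        )

    internal = [f.formulation_id for f in spec.formulations if f.formulation_id != "B"]
    external = [f.formulation_id for f in spec.formulations if f.formulation_id == "B"]
    dataset = StudyDataset(
        profiles=profiles,
        dissolution=dissolution,
        reference_regimen=spec.ir_regimen,
        internal_formulations=internal,
        external_formulations=external,
    )
    truth = GroundTruth(
        timescale=spec.timescale,
        formulations=list(spec.formulations),
        subjects=subjects,
        spec=spec,
    )
    return dataset, truth
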