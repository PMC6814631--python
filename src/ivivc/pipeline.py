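"""End-to-end orchestration of the level-A IVIVC workflow.

Stages, in order: (1) fit dissolution models per formulation; (2) fit
each subject's strip-Ka UIR from the reference arm; (3) deconvolve every
ER profile and average per formulation; (4) fit the stage-2 correlation
on the internal formulations; (5) predict plasma profiles by convolution
and evaluate the FDA/EMA prediction-error criteria (internal + external).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ivivc_io
from .correlation import fit_emax_timescale, fit_linear_ivivc
from .datatypes import AnalysisConfig, StudyDataset
from .deconv import deconvolve, mean_absorption_profile
from .dissolution import fit_dissolution, select_dissolution_model
from .errors import IvivcError
from .nca import compute_nca
from .uir import fit_uir
from .validation import ValidationReport, leave_one_out, validate

log = logging.getLogger("ivivc")

__all__ = ["PipelineArtifacts", "RunManifest", "run_ivivc", "run_loo"]


@dataclass
class PipelineArtifacts:
    """All persisted intermediates of one run."""

    dissolution_fits: dict
    uirs: dict
    fa_subject: dict  # (subject, formulation) -> AbsorptionProfile
    fa_mean: dict  # formulation -> AbsorptionProfile
    model: object
    report: ValidationReport


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_timings: dict = field(default_factory=dict)
    output_paths: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _config_hash(config: AnalysisConfig) -> str:
    payload = {k: (list(v) if isinstance(v, np.ndarray) else v)
               for k, v in vars(config).items()}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _stage(name, manifest, t0):
    dt = time.perf_counter() - t0
    manifest.stage_timings[name] = round(dt, 3)
    log.info("stage %-16s %.2fs", name, dt)


def fit_stage_dissolution(dataset: StudyDataset, config: AnalysisConfig) -> dict:
    fits = {}
    for form in dataset.formulations():
        profiles = dataset.dissolution_for(form)
        # mean profile across replicates (the default analysis level)
        prof = profiles[0]
        if len(profiles) > 1:
            from .datatypes import DissolutionProfile

            prof = DissolutionProfile(
                formulation_id=form,
                times=profiles[0].times,
                fraction_dissolved=np.mean([p.fraction_dissolved for p in profiles], axis=0),
                hpmc_pct=profiles[0].hpmc_pct,
            )
        if config.dissolution_model == "auto":
            fits[form] = select_dissolution_model(prof)
        else:
            fits[form] = fit_dissolution(prof, config.dissolution_model)
        log.info(
            "dissolution %s: %s MDT=%.3f h b=%.3f AIC=%.1f",
            form, fits[form].model, fits[form].mdt, fits[form].b, fits[form].aic,
        )
    return fits


def fit_stage_uir(dataset: StudyDataset, config: AnalysisConfig) -> dict:
    rng = np.random.default_rng([config.seed, 5])
    uirs = {}
    for sid in dataset.subjects():
        ref = dataset.reference_profile(sid)
        uirs[sid] = fit_uir(ref, max_exp=config.max_uir_exponentials, rng=rng)
    return uirs


def stage_deconvolve(dataset: StudyDataset, uirs: dict, config: AnalysisConfig):
    fa_subject = {}
    for prof in dataset.er_profiles():
        fa_subject[(prof.subject_id, prof.regimen)] = deconvolve(
            prof,
            uirs[prof.subject_id],
            grid=config.deconvolution_grid,
            smoothing=config.deconvolution_smoothing,
        )
    fa_mean = {}
    for form in dataset.formulations():
        fa_mean[form] = mean_absorption_profile(
            [fa for (sid, f), fa in fa_subject.items() if f == form]
        )
    return fa_subject, fa_mean


def build_observation_model(dataset: StudyDataset, uirs: dict,
                            formulations, config: AnalysisConfig) -> dict:
    """(fine_grid, operator) per formulation for bias-matched stage-2 fitting."""
    from .deconv import observation_operator

    obs_model = {}
    for form in formulations:
        profs = dataset.er_profiles(form)
        horizon = max(float(p.times[-1]) for p in profs)
        fine = np.arange(0.0, horizon + config.stage2_fine_step / 2, config.stage2_fine_step)
        obs_model[form] = (fine, observation_operator(profs, uirs, fine))
    return obs_model


def fit_stage_correlation(fa_mean: dict, dissolution_fits: dict,
                          dataset: StudyDataset, config: AnalysisConfig,
                          uirs: dict | None = None):
    internal = dataset.internal_formulations or dataset.formulations()
    fa_internal = {f: fa_mean[f] for f in internal}
    diss_internal = {f: dissolution_fits[f] for f in internal}
    obs_model = None
    if config.stage2_bias_matched and uirs is not None:
        obs_model = build_observation_model(dataset, uirs, internal, config)
    if config.correlation_model == "emax_timescale":
        model = fit_emax_timescale(fa_internal, diss_internal,
                                   observation_model=obs_model)
        log.info("Emax time scale: A1=%.3f A2=%.3f B2=%.3f (SE %s)",
                 model.a1, model.a2, model.b2,
                 "/".join(f"{s:.3f}" for s in model.se))
    else:
        model = fit_linear_ivivc(fa_internal, diss_internal, variant=config.linear_variant,
                                 observation_model=obs_model)
        log.info("linear IVIVC (%s): abs=%.3f scale=%.3f shift=%.3f",
                 model.variant, model.abs_scale, model.time_scale, model.time_shift)
    return model


def run_ivivc(
    config: AnalysisConfig,
    dataset: StudyDataset,
    out_dir=None,
) -> tuple[ValidationReport, PipelineArtifacts]:
    """Execute the full workflow and (optionally) persist all artifacts."""
    manifest = RunManifest(config_hash=_config_hash(config), seed=config.seed)
    t0 = time.perf_counter()
    dissolution_fits = fit_stage_dissolution(dataset, config)
    _stage("dissolution", manifest, t0)

    t0 = time.perf_counter()
    uirs = fit_stage_uir(dataset, config)
    _stage("uir", manifest, t0)

    t0 = time.perf_counter()
    fa_subject, fa_mean = stage_deconvolve(dataset, uirs, config)
    _stage("deconvolution", manifest, t0)

    t0 = time.perf_counter()
    model = fit_stage_correlation(fa_mean, dissolution_fits, dataset, config, uirs=uirs)
    _stage("correlation", manifest, t0)

    t0 = time.perf_counter()
    report = validate(
        dataset, model, dissolution_fits, uirs,
        fa_grid_step=config.prediction_grid_step,
    )
    _stage("validation", manifest, t0)

    artifacts = PipelineArtifacts(
        dissolution_fits=dissolution_fits,
        uirs=uirs,
        fa_subject=fa_subject,
        fa_mean=fa_mean,
        model=model,
        report=report,
    )
    if out_dir is not None:
        persist_artifacts(artifacts, dataset, manifest, out_dir)
    return report, artifacts


def run_loo(config: AnalysisConfig, dataset: StudyDataset, out_dir=None):
    """Leave-one-formulation-out cross-validation (delegates stage 1-3
    artifacts from a standard run, then refits stage 2 per block)."""
    report, artifacts = run_ivivc(config, dataset)
    obs_model = None
    if config.stage2_bias_matched:
        obs_model = build_observation_model(
            dataset, artifacts.uirs, dataset.formulations(), config
        )
    blocks = leave_one_out(
        dataset,
        artifacts.fa_mean,
        artifacts.dissolution_fits,
        artifacts.uirs,
        fa_grid_step=config.prediction_grid_step,
        observation_model=obs_model,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "loo_report.txt").write_text(format_loo(blocks))
        loo_frame(blocks).to_csv(out / "loo_report.csv", index=False, float_format="%.10g")
    return blocks


def loo_frame(blocks) -> pd.DataFrame:
    rows = []
    for blk in blocks:
        for section, records in (("internal", blk.report.internal),
                                 ("external", blk.report.external)):
            for r in records:
                rows.append({
                    "held_out": blk.external_formulation,
                    "section": section,
                    "formulation": r.formulation_id,
                    "parameter": r.parameter,
                    "observed": r.observed,
                    "predicted": r.predicted,
                    "pe_pct": r.pe_pct,
                })
    return pd.DataFrame(rows)


def format_loo(blocks) -> str:
    lines = ["Leave-one-out cross-validation", "=============================="]
    for blk in blocks:
        m = blk.model
        lines.append("")
        lines.append(
            f"Model developed without formulation {blk.external_formulation} "
            f"(external validation on {blk.external_formulation})"
        )
        lines.append(
            "  initial estimates: "
            + "; ".join(f"A1={s[0]:g} h, A2={s[1]:g} h, B2={s[2]:g} h" for s in blk.initial_estimates)
        )
        lines.append(f"  final estimates:   A1={m.a1:.1f} h, A2={m.a2:.2f} h, B2={m.b2:.2f} h")
        for r in blk.report.internal + blk.report.external:
            lines.append(
                f"    {r.formulation_id:>2s} {r.parameter:8s} obs={r.observed:8.1f} "
                f"pred={r.predicted:8.1f} %PE={r.pe_pct:7.2f}"
            )
        lines.append(f"  internal pass: {blk.report.internal_pass}; "
                     f"external pass: {blk.report.external_pass}")
    return "\n".join(lines) + "\n"


def persist_artifacts(artifacts: PipelineArtifacts, dataset: StudyDataset,
                      manifest: RunManifest, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    diss_rows = [
        {"formulation": f, "model": ft.model, "mdt_h": ft.mdt, "b": ft.b,
         "f_inf": ft.f_inf, "sse": ft.sse, "aic": ft.aic}
        for f, ft in sorted(artifacts.dissolution_fits.items())
    ]
    pd.DataFrame(diss_rows).to_csv(out / "dissolution_fits.csv", index=False,
                                   float_format="%.10g")

    uir_rows = []
    for sid, u in sorted(artifacts.uirs.items()):
        row = {"subject": sid, "n_exp": u.n_exp, "ka": u.ka, "t_lag": u.t_lag,
               "aic": u.aic, "r2": u.r2, "dose_ref": u.dose_ref}
        for i, (c, a) in enumerate(zip(u.coefficients, u.rates), start=1):
            row[f"A{i}_per_mg"] = c
            row[f"alpha{i}"] = a
        uir_rows.append(row)
    pd.DataFrame(uir_rows).to_csv(out / "uir_fits.csv", index=False, float_format="%.10g")

    fa_rows = []
    for (sid, form), fa in sorted(artifacts.fa_subject.items()):
        for t, v in zip(fa.times, fa.fa):
            fa_rows.append({"subject": sid, "formulation": form, "time_h": t, "fa": v})
    pd.DataFrame(fa_rows).to_csv(out / "fa_subject.csv", index=False, float_format="%.10g")

    m = artifacts.model
    if hasattr(m, "a1"):
        model_df = pd.DataFrame(
            [{"parameter": p, "estimate": v, "se": s}
             for p, v, s in zip(("A1", "A2", "B2"), (m.a1, m.a2, m.b2), m.se)]
        )
    else:
        model_df = pd.DataFrame(
            [{"parameter": p, "estimate": getattr(m, p), "se": np.nan}
             for p in ("abs_scale", "time_scale", "time_shift")]
        )
    model_df.to_csv(out / "correlation_model.csv", index=False, float_format="%.10g")

    ivivc_io.write_report(artifacts.report, out / "validation_report.csv")
    manifest.output_paths = sorted(str(p.name) for p in out.iterdir())
    manifest.write(out / "manifest.json")


def nca_table(dataset: StudyDataset) -> pd.DataFrame:
    """Per-subject NCA summary of all observed profiles."""
    rows = []
    for p in dataset.profiles:
        try:
            res = compute_nca(p)
        except IvivcError:
            continue
        rows.append(res.as_dict())
    return pd.DataFrame(rows)
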