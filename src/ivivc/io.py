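"""Tidy CSV I/O for dissolution tables, plasma profiles and reports.

Long (tidy) CSV is the canonical interchange format. Dissolution files
carry percent dissolved (converted to fraction on read); concentration
files carry ng/mL with below-LLOQ samples written as ``BQL``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ConcentrationProfile, DissolutionProfile, StudyDataset
from .errors import ProfileError, SchemaError

DISSOLUTION_COLUMNS = {
    "formulation": "formulation",
    "time": "time_h",
    "percent": "pct_dissolved",
    "replicate": "replicate",  # optional
    "hpmc": "hpmc_pct",  # optional
}

CONCENTRATION_COLUMNS = ["subject", "period", "regimen", "dose_mg", "time_h", "conc_ng_ml"]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_dissolution(path, layout: dict | None = None) -> list[DissolutionProfile]:
    """Read a tidy dissolution CSV into profiles.

    The file must contain formulation, time and percent-dissolved columns
    (default names ``formulation``, ``time_h``, ``pct_dissolved``); an
    optional ``replicate`` column groups replicate vessels and an optional
    ``hpmc_pct`` column carries polymer load metadata. Percent is converted
    to fraction.
    """
    cols = dict(DISSOLUTION_COLUMNS)
    if layout:
        cols.update(layout)
    df = pd.read_csv(path)
    _require_columns(df, [cols["formulation"], cols["time"], cols["percent"]], path)
    has_rep = cols["replicate"] in df.columns
    has_hpmc = cols["hpmc"] in df.columns

    profiles = []
    group_keys = [cols["formulation"]] + ([cols["replicate"]] if has_rep else [])
    for key, g in df.groupby(group_keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        g = g.reset_index(drop=True)
        times = g[cols["time"]].to_numpy(dtype=float)
        dup = np.nonzero(np.diff(times) <= 0)[0]
        if dup.size:
            raise ProfileError(
                f"{path}: non-monotone or duplicate time for formulation {key[0]!r} "
                f"at row {int(g.index[dup[0] + 1])}"
            )
        profiles.append(
            DissolutionProfile(
                formulation_id=str(key[0]),
                times=times,
                fraction_dissolved=g[cols["percent"]].to_numpy(dtype=float) / 100.0,
                hpmc_pct=float(g[cols["hpmc"]].iloc[0]) if has_hpmc else None,
                replicate_id=str(key[1]) if has_rep else None,
            )
        )
    return profiles


def write_dissolution(profiles: list[DissolutionProfile], path) -> None:
    rows = []
    for p in profiles:
        for t, f in zip(p.times, p.fraction_dissolved):
            row = {"formulation": p.formulation_id, "time_h": t, "pct_dissolved": 100.0 * f}
            if p.replicate_id is not None:
                row["replicate"] = p.replicate_id
            if p.hpmc_pct is not None:
                row["hpmc_pct"] = p.hpmc_pct
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_concentrations(
    path,
    lloq: float,
    reference_regimen: str = "IR",
    internal_formulations: list[str] | None = None,
    external_formulations: list[str] | None = None,
) -> StudyDataset:
    """Read a long-format crossover concentration CSV into a StudyDataset.

    Concentrations below ``lloq`` (or written literally as ``BQL``) are
    flagged as censored, not dropped. Quantifiable values are stored
    unaltered.
    """
    df = pd.read_csv(path, dtype={"subject": str, "regimen": str})
    _require_columns(df, CONCENTRATION_COLUMNS, path)

    profiles = []
    for (subj, period, regimen), g in df.groupby(["subject", "period", "regimen"], sort=True):
        g = g.sort_values("time_h").reset_index(drop=True)
        raw = g["conc_ng_ml"].astype(str).str.strip()
        is_bql_text = raw.str.upper().eq("BQL")
        # element-wise float() parsing is correctly rounded (full precision)
        conc = raw.where(~is_bql_text).astype(float).to_numpy()
        bql = is_bql_text.to_numpy() | (conc < lloq)
        profiles.append(
            ConcentrationProfile(
                subject_id=str(subj),
                period=int(period),
                regimen=str(regimen),
                dose_mg=float(g["dose_mg"].iloc[0]),
                times=g["time_h"].to_numpy(dtype=float),
                concentrations=conc,
                lloq=lloq,
                bql=bql,
            )
        )
    regimens = {p.regimen for p in profiles}
    ers = sorted(regimens - {reference_regimen})
    return StudyDataset(
        profiles=profiles,
        dissolution=[],
        reference_regimen=reference_regimen,
        internal_formulations=internal_formulations if internal_formulations is not None else ers,
        external_formulations=external_formulations or [],
    )


def write_concentrations(profiles: list[ConcentrationProfile], path) -> None:
    rows = []
    for p in profiles:
        for t, c, b in zip(p.times, p.concentrations, p.bql):
            rows.append(
                {
                    "subject": p.subject_id,
                    "period": p.period,
                    "regimen": p.regimen,
                    "dose_mg": p.dose_mg,
                    "time_h": t,
                    "conc_ng_ml": "BQL" if b else np.format_float_positional(c, trim="-"),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def report_frame(report) -> pd.DataFrame:
    """Machine-readable validation table: one row per formulation x parameter,
    plus one average row per parameter over the internal set."""
    rows = []
    for rec in report.internal:
        rows.append(
            {
                "formulation": rec.formulation_id,
                "parameter": rec.parameter,
                "observed": rec.observed,
                "predicted": rec.predicted,
                "pe_pct": rec.pe_pct,
                "criterion": "internal |%PE| <= 15",
                "pass": abs(rec.pe_pct) <= 15.0,
            }
        )
    for param, avg in sorted(report.internal_avg_abs_pe.items()):
        rows.append(
            {
                "formulation": "average",
                "parameter": param,
                "observed": np.nan,
                "predicted": np.nan,
                "pe_pct": avg,
                "criterion": "internal avg |%PE| <= 10",
                "pass": avg <= 10.0,
            }
        )
    for rec in report.external:
        rows.append(
            {
                "formulation": rec.formulation_id,
                "parameter": rec.parameter,
                "observed": rec.observed,
                "predicted": rec.predicted,
                "pe_pct": rec.pe_pct,
                "criterion": "external |%PE| <= 10",
                "pass": abs(rec.pe_pct) <= 10.0,
            }
        )
    columns = ["formulation", "parameter", "observed", "predicted", "pe_pct", "criterion", "pass"]
    return pd.DataFrame(rows, columns=columns)


def format_report(report) -> str:
    """Human-readable validation summary (deterministic formatting)."""
    buf = _io.StringIO()
    df = report_frame(report)
    buf.write("IVIVC validation report\n")
    buf.write("=======================\n")
    with pd.option_context("display.float_format", lambda v: f"{v:.2f}"):
        buf.write(df.to_string(index=False))
    buf.write("\n\n")
    buf.write(f"internal criteria pass: {report.internal_pass}\n")
    for form, ok in sorted(report.external_pass.items()):
        buf.write(f"external criteria pass ({form}): {ok}\n")
    return buf.getvalue()


def write_report(report, path) -> None:
    """Write the CSV table and a sibling ``.txt`` human-readable summary."""
    path = Path(path)
    report_frame(report).to_csv(path, index=False, float_format="%.10g")
    path.with_suffix(".txt").write_text(format_report(report))
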