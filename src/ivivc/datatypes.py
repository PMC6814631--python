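"""Core domain types shared by every pipeline stage.

Units are fixed throughout the package: time in hours, concentrations in
ng/mL, doses in mg. Dissolution is carried as a *fraction* of label claim
(assay scatter may push individual points slightly above 1).

Below-LLOQ concentrations are *flagged*, never dropped: the numeric slot
holds NaN and the ``bql`` mask records the censoring, so no downstream fit
can accidentally consume a censored value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DatasetError, ProfileError

__all__ = [
    "DissolutionProfile",
    "ConcentrationProfile",
    "StudyDataset",
    "AnalysisConfig",
]


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _check_strictly_increasing(times: np.ndarray, what: str) -> None:
    d = np.diff(times)
    if np.any(d <= 0):
        idx = int(np.nonzero(d <= 0)[0][0]) + 1
        raise ProfileError(
            f"{what}: times must be strictly increasing; violation at row {idx} "
            f"(t={times[idx]} after t={times[idx - 1]})"
        )


@dataclass
class DissolutionProfile:
    """Cumulative fraction dissolved vs time for one formulation.

    Parameters
    ----------
    formulation_id :
        Label of the formulation (e.g. ``"A"``).
    times :
        Sampling times in hours, strictly increasing, first point 0.
    fraction_dissolved :
        Cumulative fraction of label claim dissolved, in [0, 1.05].
    hpmc_pct :
        Nominal release-controlling polymer load (metadata only).
    replicate_id :
        Optional vessel/replicate label; ``None`` for a mean profile.
    """

    formulation_id: str
    times: np.ndarray
    fraction_dissolved: np.ndarray
    hpmc_pct: float | None = None
    replicate_id: str | None = None

    def __post_init__(self):
        self.times = _as_float_array(self.times)
        self.fraction_dissolved = _as_float_array(self.fraction_dissolved)
        if self.times.shape != self.fraction_dissolved.shape:
            raise ProfileError("times and fraction_dissolved must have equal length")
        if self.times.size < 5:
            raise ProfileError(
                f"dissolution profile {self.formulation_id!r} needs >= 5 timepoints, "
                f"got {self.times.size}"
            )
        _check_strictly_increasing(self.times, f"dissolution {self.formulation_id!r}")
        if self.times[0] != 0:
            raise ProfileError(
                f"dissolution profile {self.formulation_id!r}: first timepoint must be 0"
            )
        if abs(self.fraction_dissolved[0]) > 0.01:
            raise ProfileError(
                f"dissolution profile {self.formulation_id!r}: fraction at t=0 must be "
                f"0 within 0.01, got {self.fraction_dissolved[0]:.4f}"
            )
        if np.any(self.fraction_dissolved < -1e-12) or np.any(self.fraction_dissolved > 1.05):
            raise ProfileError(
                f"dissolution profile {self.formulation_id!r}: fractions must lie in [0, 1.05]"
            )

    @property
    def percent_dissolved(self) -> np.ndarray:
        return 100.0 * self.fraction_dissolved


@dataclass
class ConcentrationProfile:
    """One subject/period plasma concentration-time profile.

    ``concentrations`` holds NaN wherever ``bql`` is True (below the lower
    limit of quantitation); quantifiable values are untouched.
    """

    subject_id: str
    period: int
    regimen: str
    dose_mg: float
    times: np.ndarray
    concentrations: np.ndarray
    lloq: float = 0.0
    bql: np.ndarray | None = None

    def __post_init__(self):
        self.times = _as_float_array(self.times)
        self.concentrations = _as_float_array(self.concentrations)
        if self.times.shape != self.concentrations.shape:
            raise ProfileError("times and concentrations must have equal length")
        if np.any(self.times < 0):
            raise ProfileError(f"profile {self.subject_id}/{self.regimen}: negative times")
        _check_strictly_increasing(self.times, f"profile {self.subject_id}/{self.regimen}")
        if self.bql is None:
            self.bql = np.zeros(self.times.shape, dtype=bool)
        else:
            self.bql = np.asarray(self.bql, dtype=bool)
            if self.bql.shape != self.times.shape:
                raise ProfileError("bql mask must match times in length")
        self.concentrations = np.where(self.bql, np.nan, self.concentrations)
        quant = self.concentrations[~self.bql]
        if np.any(np.isnan(quant)):
            raise ProfileError(
                f"profile {self.subject_id}/{self.regimen}: unflagged NaN concentration"
            )
        if np.any(quant < 0):
            raise ProfileError(
                f"profile {self.subject_id}/{self.regimen}: negative concentration"
            )

    @property
    def quantifiable(self) -> np.ndarray:
        """Boolean mask of usable (non-censored) samples."""
        return ~self.bql

    def n_quantifiable(self) -> int:
        return int(np.count_nonzero(self.quantifiable))


@dataclass
class StudyDataset:
    """All plasma and dissolution profiles of one crossover study."""

    profiles: list[ConcentrationProfile]
    dissolution: list[DissolutionProfile]
    reference_regimen: str
    internal_formulations: list[str] = field(default_factory=list)
    external_formulations: list[str] = field(default_factory=list)

    def __post_init__(self):
        ref_count: dict[str, int] = {}
        er_subjects: set[str] = set()
        for p in self.profiles:
            if p.regimen == self.reference_regimen:
                ref_count[p.subject_id] = ref_count.get(p.subject_id, 0) + 1
            else:
                er_subjects.add(p.subject_id)
        multiple = sorted(s for s, n in ref_count.items() if n > 1)
        if multiple:
            raise DatasetError(
                f"reference regimen appears more than once for subjects: {multiple}"
            )
        missing = sorted(er_subjects - set(ref_count))
        if missing:
            raise DatasetError(
                f"subjects with ER data but no {self.reference_regimen!r} reference arm: "
                f"{missing}"
            )

    # -- convenience accessors -------------------------------------------------
    def subjects(self) -> list[str]:
        return sorted({p.subject_id for p in self.profiles})

    def formulations(self) -> list[str]:
        return sorted({p.regimen for p in self.profiles if p.regimen != self.reference_regimen})

    def reference_profile(self, subject_id: str) -> ConcentrationProfile:
        for p in self.profiles:
            if p.subject_id == subject_id and p.regimen == self.reference_regimen:
                return p
        raise DatasetError(f"no reference profile for subject {subject_id!r}")

    def er_profiles(self, formulation_id: str | None = None) -> list[ConcentrationProfile]:
        out = [p for p in self.profiles if p.regimen != self.reference_regimen]
        if formulation_id is not None:
            out = [p for p in out if p.regimen == formulation_id]
        return out

    def dissolution_for(self, formulation_id: str) -> list[DissolutionProfile]:
        out = [d for d in self.dissolution if d.formulation_id == formulation_id]
        if not out:
            raise DatasetError(f"no dissolution profile for formulation {formulation_id!r}")
        return out


@dataclass
class AnalysisConfig:
    """Tunable knobs of the end-to-end analysis.

    Defaults reproduce the canonical workflow: automatic Weibull/Hill
    selection by AIC, up to three UIR exponentials, deconvolution on the
    observation grid, and the nonlinear Emax time-scale correlation.
    """

    dissolution_model: str = "auto"  # {"hill", "weibull", "auto"}
    max_uir_exponentials: int = 3
    deconvolution_grid: Sequence[float] | None = None  # None -> observation times
    deconvolution_smoothing: float = 0.0
    correlation_model: str = "emax_timescale"  # {"linear", "emax_timescale"}
    linear_variant: str = "abs-scale+scale+shift"
    # fit stage 2 against the model curve passed through the deconvolution
    # discretization (cancels the point-area discretization bias)
    stage2_bias_matched: bool = True
    stage2_fine_step: float = 0.1  # h, model-curve sampling for the operator
    lambda_z_min_points: int = 3
    lambda_z_r2_tol: float = 1e-4
    prediction_grid_step: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.dissolution_model not in {"hill", "weibull", "auto"}:
            raise ValueError(f"invalid dissolution_model {self.dissolution_model!r}")
        if self.correlation_model not in {"linear", "emax_timescale"}:
            raise ValueError(f"invalid correlation_model {self.correlation_model!r}")
        if not 1 <= int(self.max_uir_exponentials) <= 3:
            raise ValueError("max_uir_exponentials must be in 1..3")
        if self.deconvolution_grid is not None:
            g = np.asarray(self.deconvolution_grid, dtype=float)
            if np.any(np.diff(g) <= 0):
                raise ValueError("deconvolution_grid must be strictly increasing")
            self.deconvolution_grid = g
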