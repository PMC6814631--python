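"""Shared fixtures: one seeded paper-like study (noisy and noiseless)
run through the full pipeline once per session."""

import numpy as np
import pytest

from ivivc.datatypes import AnalysisConfig, ConcentrationProfile
from ivivc.pipeline import run_ivivc
from ivivc.simulate import PLASMA_TIMES, generate_study, paper_like_spec

STUDY_SEED = 12345  # canonical fixture seed


@pytest.fixture(scope="session")
def paper_study():
    spec = paper_like_spec(seed=STUDY_SEED)
    dataset, truth = generate_study(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def paper_run(paper_study):
    spec, dataset, truth = paper_study
    report, artifacts = run_ivivc(AnalysisConfig(seed=STUDY_SEED), dataset)
    return report, artifacts, truth


@pytest.fixture(scope="session")
def noiseless_study():
    spec = paper_like_spec(seed=STUDY_SEED, residual_cv=0.0, dissolution_sd=0.0)
    dataset, truth = generate_study(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def noiseless_run(noiseless_study):
    spec, dataset, truth = noiseless_study
    report, artifacts = run_ivivc(AnalysisConfig(seed=STUDY_SEED), dataset)
    return report, artifacts, truth


@pytest.fixture
def study_times():
    return np.array(PLASMA_TIMES)


def make_profile(times, conc, subject="S01", regimen="IR", dose=24.0, lloq=0.0, bql=None):
    return ConcentrationProfile(
        subject_id=subject,
        period=1,
        regimen=regimen,
        dose_mg=dose,
        times=np.asarray(times, dtype=float),
        concentrations=np.asarray(conc, dtype=float),
        lloq=lloq,
        bql=bql,
    )
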