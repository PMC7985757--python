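"""Shared fixtures: small synthetic datasets for the mixture model."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from symtraj import SimulationConfig, TV_COVARIATES, TrajectorySpec, fit_gbtm
from symtraj.preprocess import LongitudinalDataset


def direct_dataset(n_patients, obs_per_patient, group_means, group_probs, sigma,
                   seed, spacing=1.5):
    """LongitudinalDataset drawn directly from the flat mixture (no item
    rounding): the precise path for fitter unit tests.  Returns
    (dataset, true group labels 1-based)."""
    rng = np.random.default_rng(seed)
    groups = rng.choice(len(group_means), n_patients, p=list(group_probs))
    rows = []
    for i in range(n_patients):
        t = np.arange(obs_per_patient) * spacing
        y = group_means[groups[i]] + rng.normal(0.0, sigma, obs_per_patient)
        for tt, yy in zip(t, y):
            rows.append({"patient_id": f"P{i:04d}", "months": tt,
                         "tsds_raw": np.nan, "y": yy})
    obs = pd.DataFrame(rows)
    for c in TV_COVARIATES:
        obs[c] = 0
    patients = pd.DataFrame(
        {"patient_id": sorted(obs["patient_id"].unique())}).set_index("patient_id")
    return LongitudinalDataset(obs=obs, patients=patients), groups + 1


def flat_sim_config(group_means, group_probs, sigma, n_patients, obs_per_patient,
                    seed):
    """Simulator config for flat groups with no covariate effects, deaths
    or injected pathologies (obs count forced to ``obs_per_patient``)."""
    J = len(group_means)
    return SimulationConfig(
        n_patients=n_patients,
        group_probs=tuple(group_probs),
        group_coefficients=tuple((m,) for m in group_means),
        residual_sd=sigma,
        mean_assessments=obs_per_patient + 30,   # cap binds: exact count
        max_assessments=obs_per_patient,
        visit_spacing=1.0,
        covariate_probs=tuple((0.0,) * 4 for _ in range(J)),
        covariate_effects=tuple((0.0,) * 4 for _ in range(J)),
        item_missing_rate=0.0,
        dup_rate=0.0,
        frac_under3=0.0,
        frac_allzero=0.0,
        frac_income_missing=0.0,
        death_hazard=(0.0,) * J,
        followup_months=200.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def two_group_dataset():
    """200 patients x 10 obs, flat transformed means 2 and 8,
    sigma = 0.5, pi = (0.4, 0.6)."""
    ds, truth = direct_dataset(200, 10, (2.0, 8.0), (0.4, 0.6), 0.5, seed=20240101)
    return ds, truth


@pytest.fixture(scope="session")
def two_group_fit(two_group_dataset):
    ds, _ = two_group_dataset
    spec = TrajectorySpec(n_groups=2, orders=(0, 0))
    return fit_gbtm(ds, spec, n_starts=4, seed=7)
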