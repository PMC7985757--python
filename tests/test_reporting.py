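"""Profile tables, chi-square tests, sensitivity analyses, ED rates, plots."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist
from scipy.stats import chi2_contingency

from symtraj import (
    TrajectorySpec,
    baseline_median_sensitivity,
    characteristics_table,
    death_imputation_sensitivity,
    ed_visit_rate,
    export_trajectory_plot,
    fit_gbtm,
)
from symtraj.preprocess import LongitudinalDataset
from symtraj.reporting import percent, round_half_up
from symtraj.transforms import TRANSFORMED_MAX

from conftest import direct_dataset


def test_published_style_percentages():
    assert percent(77, 89) == 86.52
    assert percent(329, 338) == 97.34
    assert round_half_up(0.125, 2) == 0.13      # half goes up


def test_percent_matches_rounding_convention():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n, tot = int(rng.integers(0, 100)), int(rng.integers(100, 400))
        got = percent(n, tot)
        assert got == round_half_up(100.0 * n / tot, 2)


def test_pearson_chi_square_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        table = rng.integers(5, 60, size=(3, 4)).astype(float)
        chi2, _, dof, _ = chi2_contingency(table, correction=False)
        # textbook Pearson formula
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        hand = float(((table - expected) ** 2 / expected).sum())
        assert chi2 == pytest.approx(hand, abs=1e-10)
        assert dof == (table.shape[0] - 1) * (table.shape[1] - 1)


def _one_shot_dataset(baselines, pids=None):
    pids = pids or [f"P{i:03d}" for i in range(len(baselines))]
    obs = pd.DataFrame({"patient_id": pids, "months": 0.0,
                        "tsds_raw": baselines,
                        "y": np.asarray(baselines, dtype=float) / 10.0})
    for c in ("chemotherapy", "radiotherapy", "home_care", "palliative_care"):
        obs[c] = 0
    patients = pd.DataFrame({"patient_id": pids}).set_index("patient_id")
    return LongitudinalDataset(obs=obs, patients=patients)


def test_baseline_median_sensitivity_hand_table():
    # 40 high-baseline, 40 low; 30/10 vs 10/30 in the high-burden groups:
    # expected counts all 20 -> chi-square 20, df 1
    baselines = [10.0] * 40 + [0.0] * 40
    ds = _one_shot_dataset(baselines)
    assignments = np.array([2] * 30 + [1] * 10 + [2] * 10 + [1] * 30)
    res = baseline_median_sensitivity(ds, assignments, high_groups=(2,))
    assert res.chi2 == pytest.approx(20.0, abs=1e-10)
    assert res.df == 1


def test_baseline_sensitivity_degenerate_margin():
    ds = _one_shot_dataset([5.0] * 10)
    with pytest.raises(ValueError, match="degenerate"):
        baseline_median_sensitivity(ds, np.ones(10, dtype=int), high_groups=(2,))


def test_baseline_sensitivity_type_one_error_and_power():
    rng = np.random.default_rng(3)
    rejections = 0
    n_reps = 400
    for _ in range(n_reps):
        baselines = rng.integers(0, 60, 120).astype(float)
        ds = _one_shot_dataset(baselines)
        assignments = rng.choice([1, 2], 120)          # independent of baseline
        try:
            res = baseline_median_sensitivity(ds, assignments, high_groups=(2,))
        except ValueError:
            continue
        rejections += res.p < 0.05
    assert abs(rejections / n_reps - 0.05) <= 0.025

    strong = 0
    for _ in range(20):
        baselines = rng.integers(0, 60, 200).astype(float)
        high = baselines >= np.median(baselines)
        flip = rng.random(200) < 0.1
        assignments = np.where(high ^ flip, 2, 1)      # strong dependence
        res = baseline_median_sensitivity(ds := _one_shot_dataset(baselines),
                                          assignments, high_groups=(2,))
        strong += res.p < 0.001
    assert strong >= 19


def test_characteristics_table_counts_and_merging():
    rng = np.random.default_rng(5)
    n = 300
    patients = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "rurality": rng.choice(["Urban", "Rural"], n, p=[0.9, 0.1]),
        "charlson": rng.choice(["0", "1-3"], n, p=[0.95, 0.05]),
        "constant": ["x"] * n,
    }).set_index("patient_id")
    assignments = rng.choice([1, 2, 3, 4], n, p=[0.05, 0.15, 0.4, 0.4])
    prof = characteristics_table(patients, assignments,
                                 ["rurality", "charlson", "constant"])
    # counts per covariate sum to group totals; percents from the half-up rule
    for cov in ("rurality",):
        cells = prof.cells[prof.cells["covariate"] == cov]
        for g, sub in cells.groupby("group"):
            total = sub["count"].sum()
            for _, row in sub.iterrows():
                assert row["percent"] == percent(row["count"], total)
    # low-count charlson level in the 5% group forces merging
    assert "charlson" in prof.merge_map
    tests = prof.tests.set_index("covariate")
    assert "skipped" in tests.loc["constant", "note"]
    assert np.isfinite(tests.loc["rurality", "chi2"])


def test_identical_group_proportions_give_zero_chi_square():
    patients = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(80)],
        "flag": (["yes"] * 10 + ["no"] * 10) * 4,
    }).set_index("patient_id")
    assignments = np.repeat([1, 2, 3, 4], 20)
    prof = characteristics_table(patients, assignments, ["flag"], merge_threshold=0)
    row = prof.tests.iloc[0]
    assert row["chi2"] == pytest.approx(0.0, abs=1e-12)
    assert row["p"] == pytest.approx(1.0)


def test_ed_visit_rate_values_and_exact_poisson_oracle():
    assert ed_visit_rate([0, 0, 0], [10, 10, 10]).rate == 0.0
    r = ed_visit_rate([5, 7], [40, 60])
    assert r.rate == pytest.approx(0.12, abs=1e-10)
    # 500 events: Wald CI close to the exact (chi-square inversion) interval
    events, months = 500, 4000.0
    res = ed_visit_rate([events], [months])
    lo_exact = chi2_dist.ppf(0.025, 2 * events) / 2 / months
    hi_exact = chi2_dist.ppf(0.975, 2 * (events + 1)) / 2 / months
    width_exact = hi_exact - lo_exact
    width_wald = res.ci[1] - res.ci[0]
    assert width_wald == pytest.approx(width_exact, rel=0.05)
    assert res.se == pytest.approx(res.rate / np.sqrt(events), rel=1e-6)


def test_ed_visit_rate_rejects_nonpositive_exposure():
    with pytest.raises(ValueError):
        ed_visit_rate([1], [0.0])


@pytest.fixture(scope="module")
def small_two_group():
    ds, truth = direct_dataset(80, 8, (2.0, 6.5), (0.5, 0.5), 0.5, seed=31,
                               spacing=2.0)
    fit = fit_gbtm(ds, TrajectorySpec(2, (0, 0)), n_starts=2, seed=1)
    return ds, truth, fit


def test_death_sensitivity_no_deaths_is_identity(small_two_group):
    ds, _, fit = small_two_group
    deaths = pd.Series(np.nan, index=ds.patient_ids)
    res = death_imputation_sensitivity(ds, fit.spec, deaths, fit)
    assert "no deaths" in res.note
    assert np.allclose(res.trajectory_shift["max_abs_delta"], 0.0)


def test_death_sensitivity_pulls_trajectories_toward_maximum(small_two_group):
    ds, _, fit = small_two_group
    before = ds.obs.copy(deep=True)
    # everyone dies at month 1: imputed maxima dominate the refit
    deaths = pd.Series(1.0, index=ds.patient_ids)
    spec = TrajectorySpec(2, (1, 1))
    base = fit_gbtm(ds, spec, n_starts=2, seed=2)
    res = death_imputation_sensitivity(ds, spec, deaths, base,
                                       followup_months=24.0, seed=3)
    assert res.trajectory_shift["max_abs_delta"].max() > 1.0
    pd.testing.assert_frame_equal(ds.obs, before)     # inputs not mutated


def test_trajectory_plot_written(tmp_path, small_two_group):
    ds, _, fit = small_two_group
    out = tmp_path / "trajectories.png"
    export_trajectory_plot(fit, ds, out)
    assert out.exists() and out.stat().st_size > 0
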