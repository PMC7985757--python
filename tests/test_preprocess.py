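"""Preprocessing rules: TSDS, imputation, dedupe, filters, dataset build."""

import numpy as np
import pandas as pd
import pytest

from symtraj import (
    SimulationConfig,
    compute_service_flags,
    compute_tsds,
    dedupe_same_day,
    generate_cohort,
    inject_artifacts,
    preprocess_cohort,
)
from symtraj.preprocess import (
    apply_patient_filters,
    build_longitudinal_dataset,
)
from symtraj.simulate import ESAS_ITEMS
from symtraj.transforms import boxcox_transform

NA = float("nan")


def _assessment(pid, date, scores, **extra):
    row = {"patient_id": pid, "date": pd.Timestamp(date)}
    row.update(dict(zip(ESAS_ITEMS, scores)))
    row.update(extra)
    return row


@pytest.mark.parametrize("scores, expected", [
    ([0] * 9, 0.0),                                   # floor
    ([10] * 9, 90.0),                                 # ceiling
    ([2, 4, 6, 0, 8, NA, NA, NA, NA], 36.0),          # mean(4) x 9 imputation
    ([1, 2, 3, 4, NA, NA, NA, NA, NA], NA),           # >50% missing: excluded
    ([3, 3, 3, 3, 3, 3, 3, 3, NA], 27.0),             # single missing item
])
def test_tsds_summation_and_imputation(scores, expected):
    got = compute_tsds(scores)
    if np.isnan(expected):
        assert np.isnan(got)
    else:
        assert got == pytest.approx(expected)


def test_tsds_rejects_out_of_range_scores():
    with pytest.raises(ValueError):
        compute_tsds([11] + [0] * 8)
    with pytest.raises(ValueError):
        compute_tsds([0] * 8)  # wrong length


def test_same_day_duplicate_keeps_higher_score():
    df = pd.DataFrame([
        _assessment("A", "2012-03-01", [2, 2, 2, 2, 2, 1, 1, 0, 0]),   # 12
        _assessment("A", "2012-03-01", [4, 4, 4, 4, 4, 4, 3, 2, 1]),   # 30
        _assessment("A", "2012-03-05", [1, 0, 0, 0, 0, 0, 0, 0, 0]),   # 1
    ])
    out, n_removed = dedupe_same_day(df)
    assert n_removed == 1
    assert out["tsds_raw"].tolist() == [30.0, 1.0]


def test_same_day_tie_keeps_first_listed():
    df = pd.DataFrame([
        _assessment("A", "2012-03-01", [4, 4, 4, 4, 4, 0, 0, 0, 0], marker="first"),
        _assessment("A", "2012-03-01", [0, 0, 0, 0, 4, 4, 4, 4, 4], marker="second"),
    ])
    out, _ = dedupe_same_day(df)
    assert out["marker"].tolist() == ["first"]
    assert out["tsds_raw"].iloc[0] == 20.0


def test_no_duplicates_passes_through():
    df = pd.DataFrame([
        _assessment("A", "2012-03-01", [1] * 9),
        _assessment("A", "2012-03-08", [2] * 9),
    ])
    out, n_removed = dedupe_same_day(df)
    assert n_removed == 0
    assert len(out) == 2


def test_patient_filters_log_reasons():
    assessments = pd.DataFrame(
        # A: 2 assessments -> under_3
        [_assessment("A", "2012-01-01", [1] * 9),
         _assessment("A", "2012-02-01", [1] * 9)]
        # B: 3 all-zero assessments -> all_zero
        + [_assessment("B", f"2012-0{k}-01", [0] * 9) for k in (1, 2, 3)]
        # C: valid
        + [_assessment("C", f"2012-0{k}-01", [2] * 9) for k in (1, 2, 3)]
        # D: valid but missing income
        + [_assessment("D", f"2012-0{k}-01", [2] * 9) for k in (1, 2, 3)])
    patients = pd.DataFrame({
        "patient_id": ["A", "B", "C", "D"],
        "income_quintile": [3.0, 3.0, 3.0, np.nan],
    })
    from symtraj.preprocess import add_tsds

    kept_a, kept_p, log = apply_patient_filters(add_tsds(assessments), patients)
    reasons = dict(zip(log["patient_id"], log["reason"]))
    assert reasons == {"A": "under_3", "B": "all_zero", "D": "missing_income"}
    assert kept_p["patient_id"].tolist() == ["C"]
    assert set(kept_a["patient_id"]) == {"C"}


def test_service_flags_respect_seven_day_window():
    assessments = pd.DataFrame([_assessment("A", "2012-06-15", [1] * 9)])
    services = pd.DataFrame([
        {"patient_id": "A", "service": "chemotherapy", "date": "2012-06-12"},   # day -3
        {"patient_id": "A", "service": "radiotherapy", "date": "2012-06-07"},   # day -8
        {"patient_id": "A", "service": "home_care", "date": "2012-06-15"},      # day 0
        {"patient_id": "A", "service": "palliative_care", "date": "2012-06-08"},  # day -7
    ])
    out = compute_service_flags(assessments, services)
    assert out["chemotherapy"].iloc[0] == 1
    assert out["radiotherapy"].iloc[0] == 0
    assert out["home_care"].iloc[0] == 1
    assert out["palliative_care"].iloc[0] == 1


def test_dataset_limits_to_first_thirty_and_zero_origin():
    dates = pd.date_range("2012-01-01", periods=35, freq="10D")
    assessments = pd.DataFrame([_assessment("A", d, [2] * 9) for d in dates])
    patients = pd.DataFrame({"patient_id": ["A"],
                             "diagnosis_date": [pd.Timestamp("2012-01-01")],
                             "income_quintile": [2.0]})
    ds = build_longitudinal_dataset(assessments, patients)
    assert len(ds.obs) == 30
    assert ds.obs["months"].iloc[0] == 0.0
    # the retained 30 are the earliest by date
    assert ds.obs["months"].max() == pytest.approx(29 * 10 / 30.4375)


def test_assessment_before_diagnosis_rejected():
    assessments = pd.DataFrame([_assessment("A", "2011-12-25", [2] * 9)])
    patients = pd.DataFrame({"patient_id": ["A"],
                             "diagnosis_date": [pd.Timestamp("2012-01-01")],
                             "income_quintile": [2.0]})
    with pytest.raises(ValueError, match="before diagnosis"):
        build_longitudinal_dataset(assessments, patients)


def test_pipeline_invariants_on_pathological_cohort():
    cfg = SimulationConfig(n_patients=120, seed=21)
    assessments, patients, _ = generate_cohort(cfg)
    assessments = inject_artifacts(assessments, cfg)
    ds, log = preprocess_cohort(assessments, patients)
    counts = ds.obs.groupby("patient_id").size()
    assert counts.min() >= 3 and counts.max() <= 30
    # transformed outcome consistent with the raw score
    np.testing.assert_allclose(ds.obs["y"],
                               boxcox_transform(ds.obs["tsds_raw"].to_numpy()))
    # injected under-3 patients are all excluded
    under3 = set(assessments.loc[assessments["artifact"].str.contains("under3"),
                                 "patient_id"])
    assert under3.isdisjoint(set(ds.patient_ids))
    assert set(log["reason"]) >= {"under_3"}
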