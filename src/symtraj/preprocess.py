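"""ESAS preprocessing: assessment filters, TSDS, and the modeling dataset.

Pipeline (matching the cohort-construction rules of the analysis):

1. TSDS per assessment: sum of the nine item scores.  If 1-4 items
   (<=50%) are missing, impute as mean(present) x 9; if 5+ items (>50%)
   are missing the assessment is excluded.
2. Same-day duplicates: keep the assessment with the higher raw TSDS
   (first-listed on ties).
3. Patient filters: drop patients with <3 surviving assessments,
   patients whose every item score on every assessment is zero, and
   patients missing the income quintile.  Removals are logged by reason.
4. Modeling dataset: time in months since diagnosis (days / 30.4375),
   at most the first 30 assessments per patient, transformed TSDS, and
   the four binary time-varying covariate flags (service receipt in the
   closed window [date - 7 days, date]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import DAYS_PER_MONTH, ESAS_ITEMS, TV_COVARIATES
from .transforms import boxcox_transform

N_ITEMS = len(ESAS_ITEMS)
MAX_ASSESSMENTS = 30
WINDOW_DAYS = 7


@dataclass
class LongitudinalDataset:
    """Post-filter modeling dataset.

    ``obs`` is a long table with columns ``patient_id``, ``months``,
    ``tsds_raw``, ``y`` (transformed TSDS) and one 0/1 column per
    time-varying covariate; ``patients`` carries the baseline covariates
    indexed by ``patient_id``.
    """

    obs: pd.DataFrame
    patients: pd.DataFrame
    tv_covariates: tuple = TV_COVARIATES

    @property
    def n_patients(self) -> int:
        return self.patients.shape[0]

    @property
    def patient_ids(self) -> np.ndarray:
        return self.patients.index.to_numpy()

    def arrays(self, covariates=None):
        """Return (y, t_months, patient_index, W, patient_ids) arrays.

        ``patient_index`` maps each observation row to 0..n_patients-1 in
        the order of ``patient_ids``; ``W`` holds the requested covariate
        columns (n_obs x n_cov, possibly zero columns).
        """
        covariates = list(self.tv_covariates if covariates is None else covariates)
        ids = self.patient_ids
        pos = {p: k for k, p in enumerate(ids)}
        pat_idx = self.obs["patient_id"].map(pos).to_numpy(dtype=int)
        y = self.obs["y"].to_numpy(dtype=float)
        t = self.obs["months"].to_numpy(dtype=float)
        W = (self.obs[covariates].to_numpy(dtype=float) if covariates
             else np.zeros((len(self.obs), 0)))
        return y, t, pat_idx, W, ids

    def copy(self) -> "LongitudinalDataset":
        return LongitudinalDataset(self.obs.copy(deep=True), self.patients.copy(deep=True),
                                   self.tv_covariates)


def compute_tsds(item_scores) -> float:
    """Raw TSDS for one assessment, or NaN if >50% of items are missing.

    ``item_scores`` is a length-9 sequence of values in {0,...,10} with
    NaN for missing.  With 1-4 missing items the score is imputed as the
    mean of the present items scaled to the nine-item total.
    """
    arr = np.asarray(item_scores, dtype=float)
    if arr.shape != (N_ITEMS,):
        raise ValueError(f"expected {N_ITEMS} item scores, got shape {arr.shape}")
    present = ~np.isnan(arr)
    vals = arr[present]
    if np.any((vals < 0) | (vals > 10)):
        raise ValueError("item scores must be in [0, 10]")
    n_missing = N_ITEMS - int(present.sum())
    if n_missing == 0:
        return float(vals.sum())
    if n_missing <= N_ITEMS // 2:  # 1-4 missing: <=50%
        return float(vals.mean() * N_ITEMS)
    return float("nan")


def add_tsds(assessments: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`compute_tsds` over an assessment table.

    Adds ``tsds_raw`` (NaN when the assessment is excluded for >50%
    missing items) and ``n_items_missing`` columns.
    """
    items = assessments[list(ESAS_ITEMS)].to_numpy(dtype=float)
    if np.nanmin(items, initial=0) < 0 or np.nanmax(items, initial=0) > 10:
        raise ValueError("item scores must be in [0, 10]")
    n_missing = np.isnan(items).sum(axis=1)
    mean_present = np.nanmean(np.where(np.isnan(items), np.nan, items), axis=1,
                              where=~np.isnan(items))
    sums = np.nansum(items, axis=1)
    tsds = np.where(n_missing == 0, sums,
                    np.where(n_missing <= N_ITEMS // 2, mean_present * N_ITEMS, np.nan))
    out = assessments.copy()
    out["tsds_raw"] = tsds
    out["n_items_missing"] = n_missing
    return out


def drop_overmissing(assessments: pd.DataFrame):
    """Drop assessments with >50% missing items (NaN ``tsds_raw``)."""
    if "tsds_raw" not in assessments:
        assessments = add_tsds(assessments)
    keep = assessments["tsds_raw"].notna()
    return assessments.loc[keep].copy(), int((~keep).sum())


def dedupe_same_day(assessments: pd.DataFrame):
    """Keep one assessment per patient-day: the higher raw TSDS wins.

    Ties keep the first-listed record (stable input order).  Returns
    (deduped table, number of removed duplicates).
    """
    if "tsds_raw" not in assessments:
        assessments = add_tsds(assessments)
    df = assessments.reset_index(drop=True)
    day = pd.to_datetime(df["date"]).dt.normalize()
    # idxmax is stable: first occurrence of the per-day maximum wins
    keep = df.groupby([df["patient_id"], day])["tsds_raw"].idxmax().sort_values()
    return df.loc[keep].reset_index(drop=True), len(df) - len(keep)


def apply_patient_filters(assessments: pd.DataFrame, patients: pd.DataFrame):
    """Patient-level exclusions; returns (assessments, patients, log).

    Patients are removed (with the first matching reason logged) when
    they have fewer than three surviving assessments (``under_3``), every
    item score on every assessment is zero (``all_zero``), or the income
    quintile is missing (``missing_income``).
    """
    counts = assessments.groupby("patient_id").size()
    items = assessments[list(ESAS_ITEMS)]
    nonzero_any = (items.fillna(0.0) > 0).any(axis=1)
    has_nonzero = nonzero_any.groupby(assessments["patient_id"]).any()

    log_rows = []
    excluded = set()
    for pid in patients["patient_id"]:
        n = int(counts.get(pid, 0))
        if n < 3:
            log_rows.append({"patient_id": pid, "reason": "under_3"})
            excluded.add(pid)
        elif not bool(has_nonzero.get(pid, False)):
            log_rows.append({"patient_id": pid, "reason": "all_zero"})
            excluded.add(pid)
    income = patients.set_index("patient_id")["income_quintile"]
    for pid in patients["patient_id"]:
        if pid not in excluded and pd.isna(income.get(pid)):
            log_rows.append({"patient_id": pid, "reason": "missing_income"})
            excluded.add(pid)

    keep_p = ~patients["patient_id"].isin(excluded)
    keep_a = ~assessments["patient_id"].isin(excluded)
    log = pd.DataFrame(log_rows, columns=["patient_id", "reason"])
    return assessments.loc[keep_a].copy(), patients.loc[keep_p].copy(), log


def compute_service_flags(assessments: pd.DataFrame, services: pd.DataFrame,
                          window_days: int = WINDOW_DAYS) -> pd.DataFrame:
    """Derive 0/1 time-varying covariate flags from a service-event table.

    ``services`` has columns (patient_id, service, date); the flag for an
    assessment is 1 iff an event of that service occurred in the closed
    window [assessment date - window_days, assessment date].
    """
    out = assessments.copy()
    a_dates = pd.to_datetime(out["date"]).dt.normalize()
    sv = services.copy()
    sv["date"] = pd.to_datetime(sv["date"]).dt.normalize()
    for name in TV_COVARIATES:
        ev = sv.loc[sv["service"] == name]
        by_pat = {pid: grp["date"].to_numpy() for pid, grp in ev.groupby("patient_id")}
        flags = np.zeros(len(out), dtype=int)
        for k, (pid, ad) in enumerate(zip(out["patient_id"], a_dates)):
            dates = by_pat.get(pid)
            if dates is None:
                continue
            delta = (np.asarray(ad, dtype="datetime64[D]") - dates.astype("datetime64[D]"))
            days = delta.astype("timedelta64[D]").astype(int)
            if np.any((days >= 0) & (days <= window_days)):
                flags[k] = 1
        out[name] = flags
    return out


def build_longitudinal_dataset(assessments: pd.DataFrame, patients: pd.DataFrame,
                               max_assessments: int = MAX_ASSESSMENTS) -> LongitudinalDataset:
    """Assemble the modeling dataset from filtered tables.

    Time is months since diagnosis (days / 30.4375); only each patient's
    first ``max_assessments`` assessments (by date) are retained; ``y``
    is the Box-Cox transformed TSDS.  Raises on assessments dated before
    diagnosis.
    """
    if "tsds_raw" not in assessments:
        assessments = add_tsds(assessments)
    pat = patients.set_index("patient_id")
    df = assessments.sort_values(["patient_id", "date"], kind="mergesort").copy()
    diag = df["patient_id"].map(pat["diagnosis_date"])
    days = (pd.to_datetime(df["date"]) - pd.to_datetime(diag)).dt.days
    if (days < 0).any():
        bad = df.loc[days < 0, "patient_id"].iloc[0]
        raise ValueError(f"assessment before diagnosis date for patient {bad}")
    df["months"] = days / DAYS_PER_MONTH
    df = df.groupby("patient_id", group_keys=False).head(max_assessments)
    df["y"] = boxcox_transform(df["tsds_raw"].to_numpy())
    for name in TV_COVARIATES:
        if name not in df:
            df[name] = 0
    cols = ["patient_id", "months", "tsds_raw", "y"] + list(TV_COVARIATES)
    obs = df[cols].reset_index(drop=True)
    keep = pat.loc[pat.index.isin(obs["patient_id"].unique())]
    return LongitudinalDataset(obs=obs, patients=keep)


def preprocess_cohort(assessments: pd.DataFrame, patients: pd.DataFrame,
                      max_assessments: int = MAX_ASSESSMENTS):
    """Full pipeline: filters -> dedupe -> patient filters -> dataset.

    Returns (LongitudinalDataset, exclusion_log) where the log is a
    one-row-per-removal table with columns (stage, patient_id, reason, n).
    """
    with_tsds = add_tsds(assessments)
    kept, n_overmiss = drop_overmissing(with_tsds)
    deduped, n_dups = dedupe_same_day(kept)
    filt_a, filt_p, plog = apply_patient_filters(deduped, patients)
    ds = build_longitudinal_dataset(filt_a, filt_p, max_assessments=max_assessments)
    log = pd.concat([
        pd.DataFrame([{"stage": "assessment", "patient_id": "", "reason": "over_50pct_missing",
                       "n": n_overmiss},
                      {"stage": "assessment", "patient_id": "", "reason": "same_day_duplicate",
                       "n": n_dups}]),
        plog.assign(stage="patient", n=1)[["stage", "patient_id", "reason", "n"]],
    ], ignore_index=True)
    return ds, log
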