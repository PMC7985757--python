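"""Synthetic cohort generator for the symptom-trajectory analysis.

Emulates a population-based metastatic breast cancer cohort in which
patients complete the nine-item ESAS at ambulatory visits: latent group
membership drives a polynomial mean trajectory of the transformed total
symptom distress score (TSDS) over months since diagnosis, with normal
residual noise, binary time-varying treatment/care covariates shifting
the group mean, per-group death hazards, administrative censoring, and
the data pathologies the preprocessing rules exist for (same-day
duplicate assessments, missing item scores, patients with fewer than
three assessments, all-zero patients, missing income quintile).

The defaults encode the study conditions this package analyses:
~1,000 patients averaging ~16 assessments each, six groups (three
changing, three flat) on the transformed 0-8.35 scale, group
probabilities and covariate effect sizes at the magnitudes reported for
the cohort, and death hazards back-derived from per-group three-year
mortality.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .transforms import boxcox_inverse, boxcox_transform

ESAS_ITEMS = (
    "pain",
    "tiredness",
    "drowsiness",
    "nausea",
    "appetite",
    "dyspnea",
    "depression",
    "anxiety",
    "wellbeing",
)

TV_COVARIATES = ("chemotherapy", "radiotherapy", "home_care", "palliative_care")

DAYS_PER_MONTH = 30.4375

#: age-group labels and baseline marginal frequencies (normalized)
AGE_GROUPS = ("18-39", "40-49", "50-59", "60-69", "70-79", "80-99")
_age_p = np.array([0.0714, 0.1729, 0.2553, 0.2422, 0.1709, 0.0874])
AGE_PROBS = tuple(_age_p / _age_p.sum())

_DEFAULT_GROUP_PROBS = (0.1149, 0.0986, 0.1210, 0.2463, 0.2648, 0.1544)

# Quartic (months axis, intercept first) shapes for the three changing,
# lower-burden groups; flat levels for the three high-burden groups.
_DEFAULT_COEFFS = (
    (3.2, -0.112159, 0.000839153, 4.2328e-05, -4.65608e-07),
    (2.0, 0.0127778, 0.00175926, -2.71605e-05, 8.23045e-08),
    (5.0, -0.129889, 0.000622751, 4.14815e-05, -4.86772e-07),
    (4.6,),
    (5.8,),
    (7.0,),
)

# Visit-level receipt probability of each time-varying covariate, per group
# (chemotherapy, radiotherapy, home care, palliative care).
_DEFAULT_COV_PROBS = (
    (0.35, 0.08, 0.12, 0.10),
    (0.35, 0.08, 0.12, 0.12),
    (0.35, 0.08, 0.12, 0.12),
    (0.30, 0.08, 0.15, 0.18),
    (0.25, 0.08, 0.15, 0.22),
    (0.25, 0.08, 0.15, 0.28),
)

# Additive effect of each flag on the group mean (transformed scale).
_DEFAULT_COV_EFFECTS = (
    (-0.10, 0.60, 0.35, 0.38),
    (-0.15, 0.43, 0.11, 0.12),
    (-0.06, 0.43, 0.02, 0.37),
    (-0.07, 0.25, 0.17, 0.34),
    (-0.16, 0.24, 0.22, 0.15),
    (0.01, 0.30, -0.14, -0.004),
)

# Monthly death hazard per group: -ln(1 - p_death_3y)/36 at the per-group
# three-year mortality levels of the cohort.
_DEFAULT_DEATH_HAZARD = (0.0166, 0.0059, 0.0062, 0.0147, 0.0177, 0.0234)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    All rates/fractions are probabilities in [0, 1]; times are months;
    trajectory coefficients live on the transformed TSDS scale with time
    in raw months (intercept first, up to quartic).
    """

    n_patients: int = 995
    group_probs: tuple = _DEFAULT_GROUP_PROBS
    group_coefficients: tuple = _DEFAULT_COEFFS
    residual_sd: float = 0.65
    mean_assessments: float = 21.0
    max_assessments: int = 35
    visit_spacing: float = 1.25
    covariate_probs: tuple = _DEFAULT_COV_PROBS
    covariate_effects: tuple = _DEFAULT_COV_EFFECTS
    item_missing_rate: float = 0.005
    dup_rate: float = 0.037
    frac_under3: float = 0.20
    frac_allzero: float = 0.005
    frac_income_missing: float = 0.0024
    death_hazard: tuple = _DEFAULT_DEATH_HAZARD
    followup_months: float = 72.0
    ed_rate: float = 0.12
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.group_probs)

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field."""
        p = np.asarray(self.group_probs, dtype=float)
        if p.ndim != 1 or p.size < 1 or np.any(p < 0):
            raise ValueError("group_probs: must be a non-negative vector")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("group_probs: must sum to 1 within 1e-12")
        if self.n_patients < 1:
            raise ValueError("n_patients: must be >= 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd: must be >= 0")
        if len(self.group_coefficients) != self.n_groups:
            raise ValueError("group_coefficients: need one coefficient tuple per group")
        for name in ("item_missing_rate", "dup_rate", "frac_under3", "frac_allzero",
                     "frac_income_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must be in [0, 1]")
        if len(self.covariate_probs) != self.n_groups:
            raise ValueError("covariate_probs: need one row per group")
        if len(self.covariate_effects) != self.n_groups:
            raise ValueError("covariate_effects: need one row per group")
        for row in self.covariate_probs:
            if len(row) != len(TV_COVARIATES) or any(not 0 <= q <= 1 for q in row):
                raise ValueError("covariate_probs: rows must be 4 probabilities")
        if len(self.death_hazard) != self.n_groups or any(h < 0 for h in self.death_hazard):
            raise ValueError("death_hazard: need one non-negative hazard per group")
        if self.mean_assessments < 1:
            raise ValueError("mean_assessments: must be >= 1")
        if self.max_assessments < 1:
            raise ValueError("max_assessments: must be >= 1")
        if self.visit_spacing <= 0:
            raise ValueError("visit_spacing: must be > 0")
        if self.followup_months <= 0:
            raise ValueError("followup_months: must be > 0")
        if self.ed_rate < 0:
            raise ValueError("ed_rate: must be >= 0")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")

        def _tup(v):
            return tuple(_tup(x) for x in v) if isinstance(v, (list, tuple)) else v

        return cls(**{k: _tup(v) for k, v in raw.items()})

    def to_yaml(self, path) -> None:
        def _li(v):
            return [_li(x) for x in v] if isinstance(v, tuple) else v

        with open(path, "w") as fh:
            yaml.safe_dump({k: _li(v) for k, v in dataclasses.asdict(self).items()}, fh,
                           sort_keys=False)


def _poly_eval(coeffs, t):
    out = np.zeros_like(np.asarray(t, dtype=float))
    for i, c in enumerate(coeffs):
        out += c * np.asarray(t, dtype=float) ** i
    return out


def allocate_items(total: int, rng: np.random.Generator) -> np.ndarray:
    """Split a raw TSDS total (0-90) across the nine items, each capped at 10.

    Multinomial split with uniform item probabilities; overflow above 10
    is pushed onto the items with the most slack, so the sum is preserved
    exactly.
    """
    total = int(total)
    if not 0 <= total <= 90:
        raise ValueError("total: must be in [0, 90]")
    items = rng.multinomial(total, np.full(9, 1.0 / 9.0))
    while np.any(items > 10):
        over = items > 10
        excess = int(np.sum(items[over] - 10))
        items[over] = 10
        slack = 10 - items
        # deterministic redistribution: fill the largest-slack items first
        order = np.argsort(-slack, kind="stable")
        for idx in order:
            if excess == 0:
                break
            add = min(excess, int(slack[idx]))
            items[idx] += add
            excess -= add
    return items


def generate_cohort(config: SimulationConfig):
    """Generate (assessment table, patient table, truth table).

    Deterministic given ``config.seed``: the same config yields
    byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    J = config.n_groups
    cov_probs = np.asarray(config.covariate_probs, dtype=float)
    cov_eff = np.asarray(config.covariate_effects, dtype=float)

    study_end = pd.Timestamp("2015-12-31")
    year_starts = {y: pd.Timestamp(f"{y}-01-01") for y in range(2010, 2015)}

    assess_rows = []
    patient_rows = []
    truth_rows = []
    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        g = int(rng.choice(J, p=np.asarray(config.group_probs, dtype=float)))
        year = int(rng.integers(2010, 2015))
        diag = year_starts[year] + pd.Timedelta(days=int(rng.integers(0, 365)))
        admin_horizon = min(config.followup_months,
                            (study_end - diag).days / DAYS_PER_MONTH)
        h = config.death_hazard[g]
        t_death = rng.exponential(1.0 / h) if h > 0 else np.inf
        death_month = t_death if t_death <= admin_horizon else np.nan
        horizon = min(t_death, admin_horizon)

        n_target = int(min(config.max_assessments,
                           1 + rng.poisson(max(config.mean_assessments - 1.0, 0.0))))
        times = [0.0]
        while len(times) < n_target:
            gap = max(0.25, round(rng.exponential(config.visit_spacing) / 0.25) * 0.25)
            t_next = times[-1] + gap
            if t_next > horizon:
                break
            times.append(t_next)

        for t in times:
            flags = (rng.random(len(TV_COVARIATES)) < cov_probs[g]).astype(int)
            mu = float(_poly_eval(config.group_coefficients[g], t)) + float(flags @ cov_eff[g])
            latent = mu + (rng.normal(0.0, config.residual_sd) if config.residual_sd > 0 else 0.0)
            raw = int(np.clip(np.rint(boxcox_inverse(latent)), 0, 90))
            items = allocate_items(raw, rng)
            date = diag + pd.Timedelta(days=int(round(t * DAYS_PER_MONTH)))
            row = {"patient_id": pid, "date": date, "tsds_latent": latent, "artifact": ""}
            row.update({name: float(v) for name, v in zip(ESAS_ITEMS, items)})
            row.update({name: int(v) for name, v in zip(TV_COVARIATES, flags)})
            assess_rows.append(row)

        income = int(rng.integers(1, 6))
        income_out = np.nan if rng.random() < config.frac_income_missing else income
        obs_months = horizon
        patient_rows.append({
            "patient_id": pid,
            "diagnosis_date": diag,
            "death_date": (diag + pd.Timedelta(days=int(round(t_death * DAYS_PER_MONTH)))
                           if not np.isnan(death_month) else pd.NaT),
            "age_group": AGE_GROUPS[int(rng.choice(len(AGE_GROUPS), p=AGE_PROBS))],
            "income_quintile": income_out,
            "rurality": "Rural" if rng.random() < 0.1156 else "Urban",
            "diagnosis_year": year,
            "charlson": "0" if rng.random() < 0.9538 else "1-3",
            "ed_visits": int(rng.poisson(config.ed_rate * max(obs_months, 0.0))),
            "observation_months": obs_months,
        })
        truth_rows.append({"patient_id": pid, "true_group": g + 1, "death_month": death_month})

    assessments = pd.DataFrame(assess_rows)
    cols = (["patient_id", "date"] + list(ESAS_ITEMS) + list(TV_COVARIATES)
            + ["tsds_latent", "artifact"])
    assessments = assessments[cols].sort_values(
        ["patient_id", "date"], kind="mergesort").reset_index(drop=True)
    patients = pd.DataFrame(patient_rows)
    truth = pd.DataFrame(truth_rows)
    return assessments, patients, truth


def inject_artifacts(assessments: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Add the configured data pathologies to an assessment table.

    Injects, in order: truncation of a fraction of patients to <3
    assessments, all-zero item scores for a fraction of patients,
    same-day duplicate assessments, and item-level missingness.  Injected
    rows are tagged in the ``artifact`` provenance column.  The input
    table is not mutated.
    """
    config.validate()
    out = assessments.copy(deep=True)
    if (config.dup_rate == 0 and config.item_missing_rate == 0
            and config.frac_under3 == 0 and config.frac_allzero == 0):
        return out
    rng = np.random.default_rng([config.seed, 1])
    item_cols = list(ESAS_ITEMS)

    def _tag(mask_or_idx, tag):
        cur = out.loc[mask_or_idx, "artifact"]
        out.loc[mask_or_idx, "artifact"] = np.where(cur == "", tag, cur + "+" + tag)

    pids = out["patient_id"].unique()
    under3 = set(pids[rng.random(len(pids)) < config.frac_under3])
    keep_idx = []
    for pid in pids:
        idx = out.index[out["patient_id"] == pid]
        if pid in under3:
            k = int(rng.integers(1, 3))  # 1 or 2 surviving assessments
            keep_idx.extend(idx[:k])
        else:
            keep_idx.extend(idx)
    if under3:
        out = out.loc[keep_idx].copy()
        _tag(out["patient_id"].isin(under3), "under3")

    remaining = np.array([p for p in pids if p not in under3])
    allzero = set(remaining[rng.random(len(remaining)) < config.frac_allzero])
    if allzero:
        m = out["patient_id"].isin(allzero)
        out.loc[m, item_cols] = 0.0
        out.loc[m, "tsds_latent"] = 0.0
        _tag(m, "allzero")

    if config.dup_rate > 0:
        dup_mask = rng.random(len(out)) < config.dup_rate
        dups = out.loc[dup_mask].copy()
        if len(dups):
            latent = dups["tsds_latent"].to_numpy() + rng.normal(
                0.0, config.residual_sd, len(dups))
            raws = np.clip(np.rint(boxcox_inverse(latent)), 0, 90).astype(int)
            items = np.array([allocate_items(r, rng) for r in raws], dtype=float)
            dups.loc[:, item_cols] = items
            dups.loc[:, "tsds_latent"] = latent
            dups.loc[:, "artifact"] = np.where(dups["artifact"] == "", "duplicate",
                                               dups["artifact"] + "+duplicate")
            out = pd.concat([out, dups], ignore_index=True)

    if config.item_missing_rate > 0:
        eligible = ~out["patient_id"].isin(allzero)
        miss = (rng.random((len(out), len(item_cols))) < config.item_missing_rate)
        miss &= eligible.to_numpy()[:, None]
        vals = out[item_cols].to_numpy(dtype=float)
        vals[miss] = np.nan
        out.loc[:, item_cols] = vals
        _tag(out.index[miss.any(axis=1)], "item_missing")

    return out.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)


def write_cohort(outdir, assessments, patients, truth) -> None:
    """Write the three cohort tables as CSV under ``outdir``."""
    import pathlib

    p = pathlib.Path(outdir)
    p.mkdir(parents=True, exist_ok=True)
    assessments.to_csv(p / "assessments.csv", index=False)
    patients.to_csv(p / "patients.csv", index=False)
    truth.to_csv(p / "truth.csv", index=False)


def read_cohort(outdir):
    """Read tables written by :func:`write_cohort`."""
    import pathlib

    p = pathlib.Path(outdir)
    assessments = pd.read_csv(p / "assessments.csv", parse_dates=["date"])
    if "artifact" in assessments:
        assessments["artifact"] = assessments["artifact"].fillna("")
    patients = pd.read_csv(p / "patients.csv",
                           parse_dates=["diagnosis_date", "death_date"])
    truth = pd.read_csv(p / "truth.csv")
    return assessments, patients, truth
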