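"""Model selection for the trajectory mixture.

The search mirrors the two-phase procedure used for the cohort analysis:

* Phase one grows the number of groups J from 1, all groups quartic,
  and keeps adding groups while the log Bayes factor against the J-1
  model exceeds 10 (strong evidence).
* Phase two, at the chosen J, steps each group's polynomial order down
  while the group's highest-order coefficient is non-significant at
  ``alpha`` (Wald test), scanning groups left to right.

BIC follows the Nagin convention, loglik - (k/2) ln N with N the number
of patients, so *higher* BIC is better and twice the BIC difference
approximates the log Bayes factor.  Adequacy of the selected model is
summarized per group by the average posterior probability of assigned
members (AvePP, threshold 0.7), the odds of correct classification
(OCC, threshold 5), the gap between estimated probability and assigned
proportion |pi - P| (should be near 0), and membership share (>= 5%
advisory).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gbtm import FitError, GbtmFit, GbtmParams, TrajectorySpec, fit_gbtm

AVEPP_THRESHOLD = 0.7
OCC_THRESHOLD = 5.0
MIN_MEMBERSHIP = 0.05
LBF_THRESHOLD = 10.0


def bic_score(fit: GbtmFit) -> float:
    """BIC = loglik - (k/2) ln(n_patients); higher is better."""
    if not fit.converged:
        raise ValueError("BIC requires a converged fit")
    return fit.loglik - 0.5 * fit.n_params * np.log(fit.n_patients)


def log_bayes_factor(bic_simple: float, bic_complex: float) -> float:
    """Approximate log Bayes factor: 2 x (BIC_complex - BIC_simple)."""
    return 2.0 * (bic_complex - bic_simple)


@dataclass(eq=False)
class Candidate:
    spec: TrajectorySpec
    fit: GbtmFit | None
    bic: float
    lbf_vs_previous: float | None
    note: str = ""

    @property
    def order_string(self):
        return self.spec.order_string


@dataclass
class ModelLadder:
    """Ordered record of every candidate visited plus the selection."""

    candidates: list
    selected: int
    selection_notes: list = field(default_factory=list)

    @property
    def selected_fit(self) -> GbtmFit:
        return self.candidates[self.selected].fit

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, c in enumerate(self.candidates):
            rows.append({
                "n_groups": c.spec.n_groups,
                "orders": c.order_string,
                "bic": c.bic,
                "log_bayes_factor": c.lbf_vs_previous,
                "selected": k == self.selected,
                "note": c.note,
            })
        return pd.DataFrame(rows)


@dataclass
class AdequacyReport:
    """Per-group classification diagnostics of a fitted model."""

    table: pd.DataFrame
    avepp_threshold: float = AVEPP_THRESHOLD
    occ_threshold: float = OCC_THRESHOLD

    @property
    def all_pass(self) -> bool:
        ok = self.table["avepp_pass"] & self.table["occ_pass"]
        return bool(ok.all())


def adequacy_diagnostics(fit: GbtmFit) -> AdequacyReport:
    """AvePP / OCC / |pi - P| / membership-share diagnostics.

    AvePP_j averages the posterior of group j over patients assigned to
    j; OCC_j = [AvePP_j/(1-AvePP_j)] / [pi_j/(1-pi_j)].  A group with no
    assigned patients gets NaN AvePP/OCC and a note.
    """
    J = fit.spec.n_groups
    post = fit.posterior
    assigned = fit.assigned_group
    pi = fit.pi_hat
    rows = []
    for j in range(J):
        members = assigned == j + 1
        p_assigned = members.mean()
        if members.any():
            avepp = float(post[members, j].mean())
            denom_odds = pi[j] / (1.0 - pi[j]) if pi[j] < 1.0 else np.inf
            if avepp >= 1.0:
                occ = np.inf
            else:
                occ = (avepp / (1.0 - avepp)) / denom_odds
            note = ""
        else:
            avepp = occ = np.nan
            note = "empty group: OCC undefined"
        rows.append({
            "group": j + 1,
            "avepp": avepp,
            "occ": occ,
            "pi_hat": pi[j],
            "p_assigned": p_assigned,
            "abs_pi_minus_p": abs(pi[j] - p_assigned),
            "membership_pct": 100.0 * p_assigned,
            "avepp_pass": bool(avepp > AVEPP_THRESHOLD) if not np.isnan(avepp) else False,
            "occ_pass": bool(occ > OCC_THRESHOLD) if not np.isnan(occ) else False,
            "membership_ge_5pct": bool(p_assigned >= MIN_MEMBERSHIP),
            "note": note,
        })
    return AdequacyReport(table=pd.DataFrame(rows))


def _highest_order_pvalues(fit: GbtmFit) -> list:
    """Wald p of each group's highest-order polynomial term (NaN for flat)."""
    tab = fit.coef_table()
    out = []
    for j in range(fit.spec.n_groups):
        o = fit.spec.orders[j]
        if o == 0:
            out.append(np.nan)
            continue
        row = tab[(tab["group"] == j + 1) & (tab["term"] == f"t^{o}")]
        out.append(float(row["p"].iloc[0]))
    return out


def select_model(data, max_groups: int = 8, max_order: int = 4, alpha: float = 0.05,
                 n_starts: int = 4, seed: int = 0, tol: float = 1e-6,
                 max_iter: int = 500) -> ModelLadder:
    """Iterative group-number / polynomial-order search (see module docs).

    Deterministic given ``data`` and ``seed``; per-candidate fit seeds
    are derived from the master seed.  Failed candidate fits are
    recorded in the ladder and the search continues.
    """
    candidates = []
    notes = []
    prev_bic = None
    best_grow_idx = 0

    # phase 1: grow J with all-quartic orders
    for J in range(1, max_groups + 1):
        spec = TrajectorySpec(n_groups=J, orders=(max_order,) * J)
        try:
            fit = fit_gbtm(data, spec, n_starts=n_starts, tol=tol, max_iter=max_iter,
                           seed=seed + 1000 * J)
        except (FitError, ValueError) as exc:
            candidates.append(Candidate(spec, None, np.nan, None, note=f"fit failed: {exc}"))
            notes.append(f"J={J}: fit failed ({exc}); ladder continues")
            continue
        bic = bic_score(fit)
        lbf = None if prev_bic is None else log_bayes_factor(prev_bic, bic)
        candidates.append(Candidate(spec, fit, bic, lbf))
        if lbf is None or lbf > LBF_THRESHOLD:
            best_grow_idx = len(candidates) - 1
            prev_bic = bic
        else:
            notes.append(f"stopped growing at J={J}: log Bayes factor {lbf:.2f} <= 10")
            break
    chosen = candidates[best_grow_idx]
    notes.append(f"chosen number of groups: {chosen.spec.n_groups}")

    # phase 2: step down polynomial orders, left to right
    current = chosen
    step_seed = seed + 50_000
    while True:
        pvals = _highest_order_pvalues(current.fit)
        target = None
        for j, p in enumerate(pvals):
            if current.spec.orders[j] > 0 and (np.isnan(p) or p >= alpha):
                target = j
                break
        if target is None:
            break
        new_orders = list(current.spec.orders)
        new_orders[target] -= 1
        spec = TrajectorySpec(n_groups=current.spec.n_groups, orders=tuple(new_orders),
                              cnorm_min=current.spec.cnorm_min,
                              cnorm_max=current.spec.cnorm_max,
                              tv_covariates=current.spec.tv_covariates)
        # warm start: incumbent parameters with the top coefficient dropped
        old = current.fit.params
        warm = GbtmParams(
            gamma=old.gamma.copy(),
            betas=[b[:spec.orders[j] + 1].copy() for j, b in enumerate(old.betas)],
            alphas=[a.copy() for a in old.alphas],
            sigma=old.sigma,
        )
        step_seed += 1
        try:
            fit = fit_gbtm(data, spec, n_starts=2, tol=tol, max_iter=max_iter,
                           seed=step_seed, init_params=warm)
        except (FitError, ValueError) as exc:
            candidates.append(Candidate(spec, None, np.nan, None, note=f"fit failed: {exc}"))
            notes.append(f"orders {spec.order_string}: fit failed ({exc})")
            break
        bic = bic_score(fit)
        lbf = log_bayes_factor(current.bic, bic)
        cand = Candidate(fit.spec, fit, bic, lbf,
                         note=f"step-down group {target + 1}")
        candidates.append(cand)
        current = cand

    selected = candidates.index(current)
    adequacy = adequacy_diagnostics(current.fit)
    for _, row in adequacy.table.iterrows():
        if not row["membership_ge_5pct"]:
            notes.append(f"group {int(row['group'])}: membership "
                         f"{row['membership_pct']:.1f}% < 5% (advisory)")
    if not adequacy.all_pass:
        notes.append("adequacy thresholds not met for all groups")
    return ModelLadder(candidates=candidates, selected=selected, selection_notes=notes)
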