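"""Multinomial logistic regression of trajectory-group membership.

Stage 2 of the covariate-modeling procedure: regress hard group
assignments on time-fixed baseline covariates to screen for predictors
of membership.  Stage 3 (joint estimation) re-enters the screened
covariates into the mixture's membership logits; the design matrix for
that is produced by :func:`membership_design` and passed to
``fit_gbtm(membership_design=...)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm


class SeparationError(RuntimeError):
    """Degenerate or separated design; names the offending covariate."""


def _build_design(baseline: pd.DataFrame, covariates):
    """Dummy-coded design with intercept (first level of each covariate
    is the reference)."""
    parts = [pd.Series(1.0, index=baseline.index, name="const")]
    for cov in covariates:
        col = baseline[cov]
        if col.nunique(dropna=True) < 2:
            raise SeparationError(f"covariate {cov!r} has a single level")
        if col.dtype.kind in "ifu" and col.nunique() > 6:
            parts.append(col.astype(float).rename(cov))
        else:
            dummies = pd.get_dummies(col.astype("category"), prefix=cov,
                                     drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def membership_design(baseline: pd.DataFrame, covariates):
    """(Z, names) membership design for joint (stage-3) estimation."""
    X = _build_design(baseline, covariates)
    return X.to_numpy(dtype=float), tuple(X.columns)


def membership_model(assignments, baseline: pd.DataFrame, covariates=None) -> pd.DataFrame:
    """Multinomial logit of group assignment on baseline covariates.

    ``assignments`` is a per-patient group label aligned with
    ``baseline``'s rows (group 1 is the reference outcome).  Returns a
    tidy table with estimate, SE, Wald z and p per (group, term).
    Raises :class:`SeparationError` when a covariate separates the
    outcome (diverging estimates).
    """
    y = pd.Series(np.asarray(assignments), index=baseline.index, name="group")
    if y.nunique() < 2:
        raise ValueError("need at least two groups present")
    covariates = list(covariates) if covariates is not None else list(baseline.columns)
    X = _build_design(baseline, covariates) if covariates else pd.DataFrame(
        {"const": np.ones(len(y))}, index=baseline.index)
    endog = pd.Categorical(y)
    model = sm.MNLogit(np.asarray(endog.codes), X.to_numpy(dtype=float))
    try:
        import warnings as _warnings

        with np.errstate(all="ignore"), _warnings.catch_warnings():
            # convergence is reported via the result attrs instead
            _warnings.simplefilter("ignore")
            res = model.fit(method="newton", maxiter=200, disp=0)
    except np.linalg.LinAlgError as exc:
        raise SeparationError(
            f"separation or singular design over terms {list(X.columns)!r}") from exc
    params = np.asarray(res.params)          # (n_terms, J-1)
    bse = np.asarray(res.bse)
    if not np.all(np.isfinite(bse)) or np.any(np.abs(params) > 30):
        bad = np.unravel_index(int(np.nanargmax(np.abs(params))), params.shape)
        raise SeparationError(
            f"separation or degenerate design involving term {X.columns[bad[0]]!r}")
    groups = list(endog.categories)
    rows = []
    for k in range(params.shape[1]):
        for i, term in enumerate(X.columns):
            est, se = params[i, k], bse[i, k]
            z = est / se
            rows.append({"group": groups[k + 1], "term": term, "estimate": est,
                         "se": se, "z": z,
                         "p": 2.0 * (1.0 - _norm_cdf(abs(z)))})
    out = pd.DataFrame(rows)
    out.attrs["reference_group"] = groups[0]
    out.attrs["fitted_probs"] = np.asarray(res.predict(X.to_numpy(dtype=float)))
    # overall association of the covariates with membership (LR test vs the
    # intercept-only model): the calibrated screen for stage-2 selection
    out.attrs["llr_p"] = float(res.llr_pvalue)
    out.attrs["converged"] = bool(res.mle_retvals.get("converged", True))
    return out


def _norm_cdf(x):
    from scipy.stats import norm

    return norm.cdf(x)
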