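"""Censored-normal group-based trajectory model (GBTM).

The model: each patient i belongs to one of J latent groups with
probability pi_j (multinomial logit, optionally on baseline covariates);
conditional on group j, the transformed TSDS at time t is

    y_it = poly_j(t) + alpha_j . w_it + eps_it,   eps ~ N(0, sigma^2),

with poly_j a polynomial of group-specific order (0-4) in scaled time
and w_it the binary time-varying covariate flags.  The outcome follows
the CNORM convention: a normal density between censoring bounds
(cmin, cmax) with probability mass Phi((cmin-mu)/sigma) at y <= cmin and
Phi((mu-cmax)/sigma) at y >= cmax.  With bounds outside the observed
range (the default) the censored terms are inactive and the model is an
ordinary normal mixture.

The marginal log-likelihood sums, per patient, the log of the
pi-weighted product of conditional densities over that patient's
assessments.  Fitting maximizes it directly by L-BFGS-B with an analytic
gradient and multiple starts; time is internally scaled (months / 10)
before powering so quartic terms stay well conditioned.  After fitting,
groups are relabeled in ascending order of time-averaged trajectory
level (Group 1 lowest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

TIME_SCALE = 10.0
LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class FitError(RuntimeError):
    """All optimizer starts failed; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class TrajectorySpec:
    """Model structure: group count, per-group polynomial orders,
    censoring bounds (None = observed range +/- 1) and the time-varying
    covariates entering each group's mean."""

    n_groups: int
    orders: tuple
    cnorm_min: float | None = None
    cnorm_max: float | None = None
    tv_covariates: tuple = ()

    def __post_init__(self):
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if len(self.orders) != self.n_groups:
            raise ValueError("orders must have one entry per group")
        if any(o not in (0, 1, 2, 3, 4) for o in self.orders):
            raise ValueError("polynomial orders must be in 0..4")
        if (self.cnorm_min is not None and self.cnorm_max is not None
                and not self.cnorm_min < self.cnorm_max):
            raise ValueError("cnorm_min must be < cnorm_max")

    @property
    def order_string(self) -> str:
        return "".join(str(o) for o in self.orders)


@dataclass
class GbtmParams:
    """Parameter set: membership coefficients ``gamma`` (p x (J-1), last
    group is the reference), per-group polynomial coefficients ``betas``
    on the scaled time axis, per-group covariate effects ``alphas`` and
    the shared residual SD ``sigma``."""

    gamma: np.ndarray
    betas: list
    alphas: list
    sigma: float

    @property
    def n_groups(self) -> int:
        return len(self.betas)

    def membership_probs(self, Z=None) -> np.ndarray:
        """pi (per patient when a membership design is given)."""
        if Z is None:
            Z = np.ones((1, self.gamma.shape[0]))
        eta = np.column_stack([Z @ self.gamma, np.zeros(Z.shape[0])])
        logpi = eta - logsumexp(eta, axis=1, keepdims=True)
        return np.exp(logpi)

    @property
    def pi(self) -> np.ndarray:
        """Marginal group probabilities (intercept-only membership)."""
        return self.membership_probs()[0]


@dataclass
class GbtmFit:
    """A fitted trajectory model."""

    spec: TrajectorySpec
    params: GbtmParams
    loglik: float
    n_patients: int
    n_obs: int
    posterior: np.ndarray
    assigned_group: np.ndarray          # 1-based hard assignments
    patient_ids: np.ndarray
    converged: bool
    n_starts_used: int
    history: list
    cnorm_bounds: tuple
    time_scale: float = TIME_SCALE
    time_range: tuple = (0.0, 0.0)
    membership_names: tuple = ("const",)
    packed: np.ndarray | None = None
    slices: dict | None = None
    cov: np.ndarray | None = None
    standard_errors: np.ndarray | None = None
    _pi_rows: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return len(self.packed)

    @property
    def pi_hat(self) -> np.ndarray:
        """Estimated group probabilities averaged over patients."""
        if self._pi_rows is None:
            return self.params.pi
        return self._pi_rows.mean(axis=0)

    def coef_table(self) -> pd.DataFrame:
        """Tidy (group, term, estimate, se, z, p) table."""
        rows = []
        se = (self.standard_errors if self.standard_errors is not None
              else np.full(self.n_params, np.nan))
        x = self.packed
        sl = self.slices
        J = self.spec.n_groups
        for j in range(J - 1):
            for k, name in enumerate(self.membership_names):
                idx = sl["gamma"].start + k * (J - 1) + j
                rows.append((j + 1, f"membership:{name}", x[idx], se[idx]))
        for j in range(J):
            for k in range(self.spec.orders[j] + 1):
                idx = sl["beta"][j].start + k
                rows.append((j + 1, f"t^{k}", x[idx], se[idx]))
            for k, name in enumerate(self.spec.tv_covariates):
                idx = sl["alpha"][j].start + k
                rows.append((j + 1, name, x[idx], se[idx]))
        idx = sl["log_sigma"]
        rows.append((0, "log_sigma", x[idx], se[idx]))
        df = pd.DataFrame(rows, columns=["group", "term", "estimate", "se"])
        with np.errstate(divide="ignore", invalid="ignore"):
            df["z"] = df["estimate"] / df["se"]
        df["p"] = 2.0 * norm.sf(np.abs(df["z"]))
        return df


# ---------------------------------------------------------------------------
# likelihood machinery

def _basis(t_months: np.ndarray, max_order: int) -> np.ndarray:
    u = np.asarray(t_months, dtype=float) / TIME_SCALE
    return np.vander(u, max_order + 1, increasing=True)


def _resolve_bounds(spec: TrajectorySpec, y: np.ndarray) -> tuple:
    lo = spec.cnorm_min if spec.cnorm_min is not None else float(np.min(y)) - 1.0
    hi = spec.cnorm_max if spec.cnorm_max is not None else float(np.max(y)) + 1.0
    if not lo < hi:
        raise ValueError("cnorm_min must be < cnorm_max")
    return float(lo), float(hi)


class _Prepared:
    """Cached arrays for one (dataset, spec, membership design) triple."""

    def __init__(self, data, spec, membership_design=None):
        covs = tuple(spec.tv_covariates)
        y, t, pat_idx, W, ids = data.arrays(covs)
        if len(y) == 0:
            raise ValueError("empty dataset")
        n_pat = len(ids)
        if spec.n_groups > n_pat:
            raise ValueError("more groups than patients")
        self.y, self.t, self.pat_idx, self.W, self.ids = y, t, pat_idx, W, ids
        self.n_pat, self.n_obs = n_pat, len(y)
        self.spec = spec
        self.B = _basis(t, max(spec.orders))
        self.cmin, self.cmax = _resolve_bounds(spec, y)
        self.left = y <= self.cmin
        self.right = y >= self.cmax
        self.interior = ~(self.left | self.right)
        if membership_design is None:
            self.Z = np.ones((n_pat, 1))
            self.membership_names = ("const",)
        else:
            Z, names = membership_design
            Z = np.asarray(Z, dtype=float)
            if Z.shape[0] != n_pat:
                raise ValueError("membership design must have one row per patient")
            self.Z = Z
            self.membership_names = tuple(names)
        self.p_mem = self.Z.shape[1]
        # packing layout
        J = spec.n_groups
        pos = 0
        n_gamma = self.p_mem * (J - 1)
        self.sl_gamma = slice(pos, pos + n_gamma)
        pos += n_gamma
        self.sl_beta, self.sl_alpha = [], []
        ncov = len(covs)
        for j in range(J):
            nb = spec.orders[j] + 1
            self.sl_beta.append(slice(pos, pos + nb))
            pos += nb
            self.sl_alpha.append(slice(pos, pos + ncov))
            pos += ncov
        self.idx_lsig = pos
        self.n_params = pos + 1

    def pack(self, params: GbtmParams) -> np.ndarray:
        x = np.empty(self.n_params)
        x[self.sl_gamma] = np.asarray(params.gamma, dtype=float).ravel()
        for j in range(self.spec.n_groups):
            x[self.sl_beta[j]] = params.betas[j]
            x[self.sl_alpha[j]] = params.alphas[j]
        x[self.idx_lsig] = np.log(params.sigma)
        return x

    def unpack(self, x: np.ndarray) -> GbtmParams:
        J = self.spec.n_groups
        gamma = x[self.sl_gamma].reshape(self.p_mem, J - 1) if J > 1 else \
            np.zeros((self.p_mem, 0))
        betas = [x[self.sl_beta[j]].copy() for j in range(J)]
        alphas = [x[self.sl_alpha[j]].copy() for j in range(J)]
        return GbtmParams(gamma=gamma, betas=betas, alphas=alphas,
                          sigma=float(np.exp(x[self.idx_lsig])))

    # ---- core computation ----

    def _log_membership(self, x):
        J = self.spec.n_groups
        if J == 1:
            return np.zeros((self.n_pat, 1))
        gamma = x[self.sl_gamma].reshape(self.p_mem, J - 1)
        eta = np.column_stack([self.Z @ gamma, np.zeros(self.n_pat)])
        return eta - logsumexp(eta, axis=1, keepdims=True)

    def component_logliks(self, x, want_derivs=False):
        """Per-patient conditional log-likelihood L (n_pat x J); with
        ``want_derivs`` also per-obs d log f/d mu and sigma * d log f/d sigma."""
        J = self.spec.n_groups
        sigma = float(np.exp(x[self.idx_lsig]))
        L = np.zeros((self.n_pat, J))
        dmu = np.zeros((self.n_obs, J)) if want_derivs else None
        dls = np.zeros((self.n_obs, J)) if want_derivs else None
        for j in range(J):
            mu = self.B[:, :self.spec.orders[j] + 1] @ x[self.sl_beta[j]]
            if self.W.shape[1]:
                mu = mu + self.W @ x[self.sl_alpha[j]]
            logf = np.empty(self.n_obs)
            z = (self.y - mu) / sigma
            it = self.interior
            logf[it] = -np.log(sigma) - 0.5 * z[it] ** 2 - LOG_SQRT_2PI
            if want_derivs:
                dmu[it, j] = z[it] / sigma
                dls[it, j] = z[it] ** 2 - 1.0          # sigma * dlogf/dsigma
            if self.left.any():
                a = (self.cmin - mu[self.left]) / sigma
                lc = norm.logcdf(a)
                logf[self.left] = lc
                if want_derivs:
                    ratio = np.exp(norm.logpdf(a) - lc)
                    dmu[self.left, j] = -ratio / sigma
                    dls[self.left, j] = -a * ratio
            if self.right.any():
                b = (mu[self.right] - self.cmax) / sigma
                lc = norm.logcdf(b)
                logf[self.right] = lc
                if want_derivs:
                    ratio = np.exp(norm.logpdf(b) - lc)
                    dmu[self.right, j] = ratio / sigma
                    dls[self.right, j] = -b * ratio
            L[:, j] = np.bincount(self.pat_idx, weights=logf, minlength=self.n_pat)
        return (L, dmu, dls) if want_derivs else L

    def loglik(self, x) -> float:
        M = self._log_membership(x) + self.component_logliks(x)
        return float(np.sum(logsumexp(M, axis=1)))

    def posterior(self, x) -> np.ndarray:
        M = self._log_membership(x) + self.component_logliks(x)
        return np.exp(M - logsumexp(M, axis=1, keepdims=True))

    def nll_grad(self, x):
        J = self.spec.n_groups
        logpi = self._log_membership(x)
        L, dmu, dls = self.component_logliks(x, want_derivs=True)
        M = logpi + L
        ll_i = logsumexp(M, axis=1)
        R = np.exp(M - ll_i[:, None])
        g = np.zeros_like(x)
        if J > 1:
            resid = R[:, :-1] - np.exp(logpi[:, :-1])
            g[self.sl_gamma] = (self.Z.T @ resid).ravel()
        w_obs = R[self.pat_idx]
        for j in range(J):
            wj = w_obs[:, j] * dmu[:, j]
            g[self.sl_beta[j]] = self.B[:, :self.spec.orders[j] + 1].T @ wj
            if self.W.shape[1]:
                g[self.sl_alpha[j]] = self.W.T @ wj
        g[self.idx_lsig] = float(np.sum(w_obs * dls))
        return -float(np.sum(ll_i)), -g


def cnorm_loglik(params: GbtmParams, data, spec: TrajectorySpec,
                 membership_design=None) -> float:
    """Marginal censored-normal mixture log-likelihood.

    Sum over patients of log sum_j pi_j prod_t f_j(y_it), with f_j the
    CNORM density/mass for group j.  Raises on an empty dataset or a
    non-finite result.
    """
    prep = _Prepared(data, spec, membership_design)
    val = prep.loglik(prep.pack(params))
    if not np.isfinite(val):
        raise FloatingPointError(
            f"non-finite log-likelihood (sigma={params.sigma}, "
            f"bounds={prep.cmin, prep.cmax})")
    return val


# ---------------------------------------------------------------------------
# fitting

def _patient_features(prep: _Prepared) -> np.ndarray:
    """Per-patient (early mean, late mean) of y: a crude shape summary
    that separates level and direction of change for initialization."""
    t_mid = 0.5 * (prep.t.min() + prep.t.max())
    feats = np.empty((prep.n_pat, 2))
    overall = np.bincount(prep.pat_idx, weights=prep.y, minlength=prep.n_pat) / \
        np.bincount(prep.pat_idx, minlength=prep.n_pat)
    for half, mask in enumerate((prep.t <= t_mid, prep.t > t_mid)):
        s = np.bincount(prep.pat_idx[mask], weights=prep.y[mask], minlength=prep.n_pat)
        c = np.bincount(prep.pat_idx[mask], minlength=prep.n_pat)
        feats[:, half] = np.where(c > 0, s / np.maximum(c, 1), overall)
    return feats


def _kmeans_assign(feats, centers, n_iter=10):
    for _ in range(n_iter):
        d = ((feats[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d.argmin(axis=1)
        for j in range(centers.shape[0]):
            if np.any(assign == j):
                centers[j] = feats[assign == j].mean(axis=0)
    return assign


def _initial_points(prep: _Prepared, n_starts: int, rng: np.random.Generator,
                    init_params=None):
    """Shape-aware k-means split start plus randomly perturbed variants."""
    J = prep.spec.n_groups
    feats = _patient_features(prep)
    pmeans = feats.mean(axis=1)
    order = np.argsort(pmeans, kind="stable")
    splits = np.array_split(order, J)
    base_centers = np.array([feats[s].mean(axis=0) if len(s) else feats.mean(axis=0)
                             for s in splits])
    spread = max(float(feats.std()), 1e-3)
    starts = []
    if init_params is not None:
        starts.append(prep.pack(init_params))
    k = 0
    while len(starts) < n_starts:
        centers = base_centers.copy()
        if k > 0:
            centers = centers + rng.normal(0.0, 0.45 * spread, centers.shape)
        assign = _kmeans_assign(feats, centers)
        x = np.zeros(prep.n_params)
        props = np.maximum(np.bincount(assign, minlength=J) / prep.n_pat, 1e-3)
        if J > 1:
            gamma = np.zeros((prep.p_mem, J - 1))
            gamma[0] = np.log(props[:-1] / props[-1])
            x[prep.sl_gamma] = gamma.ravel()
        group_mean = np.empty(J)
        t_span = max(prep.t.max() - prep.t.min(), 1e-9) / TIME_SCALE
        for j in range(J):
            beta = np.zeros(prep.spec.orders[j] + 1)
            m = assign == j
            early, late = (feats[m].mean(axis=0) if np.any(m) else centers[j])
            group_mean[j] = 0.5 * (early + late)
            beta[0] = early
            if prep.spec.orders[j] >= 1:
                beta[1] = (late - early) / t_span
            x[prep.sl_beta[j]] = beta
        resid_sq = np.mean((prep.y - group_mean[assign][prep.pat_idx]) ** 2)
        x[prep.idx_lsig] = 0.5 * np.log(max(resid_sq, 1e-4))
        starts.append(x)
        k += 1
    return starts


def _relabel(prep: _Prepared, x: np.ndarray, data, membership_design):
    """Permute groups into ascending time-averaged trajectory level.

    Returns (prep, x): when per-group orders differ the permutation
    changes the packing layout, so the spec's orders are permuted along
    with the parameters and a fresh prepared instance is built.
    """
    spec = prep.spec
    J = spec.n_groups
    if J == 1:
        return prep, x
    levels = np.empty(J)
    for j in range(J):
        levels[j] = float(np.mean(prep.B[:, :spec.orders[j] + 1] @ x[prep.sl_beta[j]]))
    perm = np.argsort(levels, kind="stable")
    if np.array_equal(perm, np.arange(J)):
        return prep, x
    params = permute_groups(prep.unpack(x), perm)
    new_orders = tuple(spec.orders[p] for p in perm)
    if new_orders != tuple(spec.orders):
        spec = TrajectorySpec(n_groups=J, orders=new_orders, cnorm_min=spec.cnorm_min,
                              cnorm_max=spec.cnorm_max, tv_covariates=spec.tv_covariates)
        prep = _Prepared(data, spec, membership_design)
    return prep, prep.pack(params)


def _numerical_hessian(fun_grad, x, rel_step=1e-5):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        h = rel_step * (1.0 + abs(x[i]))
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        _, gp = fun_grad(xp)
        _, gm = fun_grad(xm)
        H[i] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_gbtm(data, spec: TrajectorySpec, n_starts: int = 10, tol: float = 1e-6,
             max_iter: int = 500, seed: int = 0, membership_design=None,
             init_params: GbtmParams | None = None, compute_se: bool = True,
             relabel: bool = True) -> GbtmFit:
    """Maximum-likelihood fit by multi-start L-BFGS-B.

    ``n_starts`` local optimizations are run (a deterministic
    quantile-split initialization, perturbed per start); the best local
    optimum is polished at tight tolerance.  ``converged`` reflects the
    optimizer's relative log-likelihood criterion ``tol``.  Standard
    errors come from the observed information (numerical Hessian of the
    analytic gradient) at the optimum.
    """
    prep = _Prepared(data, spec, membership_design)
    rng = np.random.default_rng(seed)
    starts = _initial_points(prep, n_starts, rng, init_params)

    best = None
    diagnostics = []
    histories = []
    for x0 in starts:
        hist = []

        def cb(xk, _hist=hist):
            _hist.append(-prep.nll_grad(xk)[0])

        res = minimize(prep.nll_grad, x0, jac=True, method="L-BFGS-B",
                       callback=cb,
                       options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6})
        diagnostics.append({"fun": float(res.fun), "status": int(res.status),
                            "message": str(res.message), "nit": int(res.nit)})
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
            histories = hist
    if best is None:
        raise FitError("all optimizer starts failed", diagnostics)

    polish = minimize(prep.nll_grad, best.x, jac=True, method="L-BFGS-B",
                      options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8})
    x = polish.x if np.isfinite(polish.fun) and polish.fun <= best.fun + 1e-8 else best.x
    converged = bool(best.success or polish.success)
    if relabel:
        prep, x = _relabel(prep, x, data, membership_design)

    loglik = prep.loglik(x)
    posterior = prep.posterior(x)
    assigned = posterior.argmax(axis=1) + 1          # ties -> lowest index
    params = prep.unpack(x)

    cov = se = None
    if compute_se:
        H = _numerical_hessian(prep.nll_grad, x)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        d = np.diag(cov).copy()
        with np.errstate(invalid="ignore"):
            se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)

    fit = GbtmFit(
        spec=prep.spec, params=params, loglik=loglik, n_patients=prep.n_pat,
        n_obs=prep.n_obs, posterior=posterior, assigned_group=assigned,
        patient_ids=prep.ids, converged=converged, n_starts_used=len(starts),
        history=histories, cnorm_bounds=(prep.cmin, prep.cmax),
        time_range=(float(prep.t.min()), float(prep.t.max())),
        membership_names=prep.membership_names, packed=x,
        slices={"gamma": prep.sl_gamma, "beta": prep.sl_beta,
                "alpha": prep.sl_alpha, "log_sigma": prep.idx_lsig},
        cov=cov, standard_errors=se,
        _pi_rows=params.membership_probs(prep.Z),
    )
    return fit


def posterior_matrix(fit: GbtmFit, data=None) -> np.ndarray:
    """Posterior membership probabilities; rows sum to one.

    Entry (i, j) = pi_j L_ij / sum_k pi_k L_ik.  With ``data`` omitted,
    the matrix computed at fit time is returned.
    """
    if data is None:
        return fit.posterior
    prep = _Prepared(data, fit.spec)
    return prep.posterior(prep.pack(fit.params))


def predict_trajectory(fit: GbtmFit, group: int, times, covariate_profile=None):
    """Mean trajectory and pointwise 95% CI for one group.

    ``times`` are months since diagnosis; ``covariate_profile`` maps
    covariate name -> 0/1 (default all zero).  The CI uses the delta
    method on the (beta, alpha) block of the parameter covariance.
    Times outside the fitted range trigger an extrapolation warning.
    """
    if not 1 <= group <= fit.spec.n_groups:
        raise ValueError("group out of range")
    t = np.asarray(times, dtype=float)
    lo_t, hi_t = fit.time_range
    if np.any((t < lo_t - 1e-9) | (t > hi_t + 1e-9)):
        warnings.warn("requested times outside the fitted range; extrapolating",
                      UserWarning, stacklevel=2)
    j = group - 1
    order = fit.spec.orders[j]
    X = _basis(t, order)
    w = np.array([float((covariate_profile or {}).get(name, 0.0))
                  for name in fit.spec.tv_covariates])
    beta = fit.params.betas[j]
    alpha = fit.params.alphas[j]
    mean = X @ beta + (w @ alpha if len(w) else 0.0)
    if fit.cov is not None:
        idx = np.r_[np.arange(fit.slices["beta"][j].start, fit.slices["beta"][j].stop),
                    np.arange(fit.slices["alpha"][j].start, fit.slices["alpha"][j].stop)]
        C = fit.cov[np.ix_(idx, idx)]
        Xw = np.column_stack([X, np.tile(w, (len(t), 1))]) if len(w) else X
        var = np.einsum("ij,jk,ik->i", Xw, C, Xw)
        se = np.sqrt(np.clip(var, 0.0, None))
    else:
        se = np.full(len(t), np.nan)
    return pd.DataFrame({"months": t, "mean": mean,
                         "lo": mean - 1.96 * se, "hi": mean + 1.96 * se})


def permute_groups(params: GbtmParams, perm) -> GbtmParams:
    """Relabel groups by ``perm`` (new index -> old index); the
    likelihood is invariant under this relabeling."""
    perm = list(perm)
    J = params.n_groups
    gamma_aug = np.column_stack([params.gamma, np.zeros(params.gamma.shape[0])])
    permuted = gamma_aug[:, perm]
    gamma = permuted[:, :-1] - permuted[:, -1:]
    return GbtmParams(
        gamma=gamma,
        betas=[params.betas[p].copy() for p in perm],
        alphas=[params.alphas[p].copy() for p in perm],
        sigma=params.sigma,
    )
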