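"""Censored-normal mixture: likelihood oracle, fitting, posteriors, CIs."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from symtraj import (
    GbtmParams,
    TrajectorySpec,
    cnorm_loglik,
    fit_gbtm,
    permute_groups,
    posterior_matrix,
    predict_trajectory,
)
from symtraj.gbtm import TIME_SCALE, _Prepared
from symtraj.preprocess import LongitudinalDataset

from conftest import direct_dataset


def _tiny_dataset(values, times):
    """Dataset from {patient: [(t, y), ...]} style input."""
    rows = []
    for pid, series in values.items():
        for t, y in series:
            rows.append({"patient_id": pid, "months": t, "tsds_raw": np.nan, "y": y})
    obs = pd.DataFrame(rows)
    for c in ("chemotherapy", "radiotherapy", "home_care", "palliative_care"):
        obs[c] = 0
    patients = pd.DataFrame(
        {"patient_id": sorted(values)}).set_index("patient_id")
    return LongitudinalDataset(obs=obs, patients=patients)


def _brute_force_loglik(values, params, cmin, cmax):
    """Enumerate the mixture per patient with plain math calls."""
    pis = params.pi
    total = 0.0
    for pid, series in values.items():
        mix = 0.0
        for j, pi_j in enumerate(pis):
            prod = 1.0
            for t, y in series:
                u = t / TIME_SCALE
                mu = sum(b * u ** k for k, b in enumerate(params.betas[j]))
                if y <= cmin:
                    f = norm.cdf((cmin - mu) / params.sigma)
                elif y >= cmax:
                    f = 1.0 - norm.cdf((cmax - mu) / params.sigma)
                else:
                    z = (y - mu) / params.sigma
                    f = math.exp(-0.5 * z * z) / (params.sigma * math.sqrt(2 * math.pi))
                prod *= f
            mix += pi_j * prod
        total += math.log(mix)
    return total


@pytest.mark.parametrize("cmin, cmax", [(-np.inf, np.inf), (0.5, 5.5)])
def test_loglik_matches_enumeration_oracle(cmin, cmax):
    values = {"A": [(0.0, 1.2), (2.0, 3.4)], "B": [(0.0, 5.5), (2.0, 0.5)]}
    ds = _tiny_dataset(values, None)
    spec = TrajectorySpec(2, (1, 1), cnorm_min=cmin, cnorm_max=cmax)
    params = GbtmParams(gamma=np.array([[0.4]]),
                        betas=[np.array([1.0, 0.5]), np.array([4.0, -0.8])],
                        alphas=[np.zeros(0), np.zeros(0)], sigma=0.9)
    got = cnorm_loglik(params, ds, spec)
    want = _brute_force_loglik(values, params, cmin, cmax)
    assert got == pytest.approx(want, abs=1e-10)


def test_single_component_equals_pooled_normal_loglik():
    rng = np.random.default_rng(3)
    values = {f"P{i}": [(t, float(rng.normal(2, 1))) for t in (0.0, 1.0, 2.0)]
              for i in range(5)}
    ds = _tiny_dataset(values, None)
    spec = TrajectorySpec(1, (0,), cnorm_min=-np.inf, cnorm_max=np.inf)
    params = GbtmParams(gamma=np.zeros((1, 0)), betas=[np.array([2.0])],
                        alphas=[np.zeros(0)], sigma=1.3)
    y = np.array([v for s in values.values() for _, v in s])
    want = float(norm.logpdf(y, 2.0, 1.3).sum())
    assert cnorm_loglik(params, ds, spec) == pytest.approx(want, abs=1e-10)


def test_inactive_bounds_equal_infinite_bounds():
    values = {"A": [(0.0, 2.0), (1.0, 3.0)], "B": [(0.0, 4.0), (1.0, 5.0)]}
    ds = _tiny_dataset(values, None)
    params = GbtmParams(gamma=np.array([[0.0]]),
                        betas=[np.array([2.0]), np.array([4.5])],
                        alphas=[np.zeros(0), np.zeros(0)], sigma=0.8)
    wide = cnorm_loglik(params, ds, TrajectorySpec(2, (0, 0), cnorm_min=-50.0,
                                                   cnorm_max=50.0))
    inf = cnorm_loglik(params, ds, TrajectorySpec(2, (0, 0), cnorm_min=-np.inf,
                                                  cnorm_max=np.inf))
    assert wide == pytest.approx(inf, abs=1e-12)


def test_label_permutation_leaves_loglik_unchanged():
    values = {"A": [(0.0, 1.0), (3.0, 2.0)], "B": [(0.0, 6.0), (3.0, 7.0)],
              "C": [(0.0, 4.0), (3.0, 4.5)]}
    ds = _tiny_dataset(values, None)
    spec = TrajectorySpec(3, (0, 0, 0))
    params = GbtmParams(gamma=np.array([[0.3, -0.2]]),
                        betas=[np.array([1.5]), np.array([6.5]), np.array([4.2])],
                        alphas=[np.zeros(0)] * 3, sigma=0.7)
    base = cnorm_loglik(params, ds, spec)
    for perm in ((1, 0, 2), (2, 1, 0), (1, 2, 0)):
        assert cnorm_loglik(permute_groups(params, perm), ds, spec) == \
            pytest.approx(base, abs=1e-10)


def test_closed_form_single_group_mle(two_group_dataset):
    ds, _ = two_group_dataset
    fit = fit_gbtm(ds, TrajectorySpec(1, (0,)), n_starts=1, seed=0)
    y = ds.obs["y"].to_numpy()
    assert fit.params.betas[0][0] == pytest.approx(y.mean(), abs=1e-4)
    assert fit.params.sigma == pytest.approx(y.std(ddof=0), abs=1e-4)


def test_two_group_parameter_recovery(two_group_fit, two_group_dataset):
    ds, truth = two_group_dataset
    fit = two_group_fit
    means = sorted(b[0] for b in fit.params.betas)
    assert means[0] == pytest.approx(2.0, abs=0.1)
    assert means[1] == pytest.approx(8.0, abs=0.1)
    assert fit.params.sigma == pytest.approx(0.5, abs=0.05)
    assert np.all(np.abs(np.sort(fit.pi_hat) - np.array([0.4, 0.6])) <= 0.05)
    # fitted optimum at least as good as the generating truth
    true_params = GbtmParams(gamma=np.array([[np.log(0.4 / 0.6)]]),
                             betas=[np.array([2.0]), np.array([8.0])],
                             alphas=[np.zeros(0)] * 2, sigma=0.5)
    assert fit.loglik >= cnorm_loglik(true_params, ds, fit.spec) - 1e-6


def test_posterior_rows_normalized_and_symmetric():
    values = {f"P{i}": [(0.0, float(v))] for i, v in enumerate((1.0, 2.5, 4.0))}
    ds = _tiny_dataset(values, None)
    spec = TrajectorySpec(2, (0, 0))
    same = GbtmParams(gamma=np.array([[np.log(0.3 / 0.7)]]),
                      betas=[np.array([2.0]), np.array([2.0])],
                      alphas=[np.zeros(0)] * 2, sigma=1.0)
    prep = _Prepared(ds, spec)
    post = prep.posterior(prep.pack(same))
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)
    # identical components: every row equals pi
    np.testing.assert_allclose(post, np.tile([0.3, 0.7], (3, 1)), atol=1e-10)


def test_well_separated_posteriors_near_certain(two_group_fit):
    assert two_group_fit.posterior.max(axis=1).mean() > 0.99


def test_optimizer_history_monotone(two_group_dataset):
    ds, _ = two_group_dataset
    fit = fit_gbtm(ds, TrajectorySpec(2, (0, 0)), n_starts=1, seed=1)
    hist = np.array(fit.history)
    assert len(hist) >= 2
    assert np.all(np.diff(hist) >= -1e-8)


def test_flat_group_prediction_and_zero_profile(two_group_fit):
    pred = predict_trajectory(two_group_fit, 1, np.linspace(0, 13.5, 7))
    assert np.allclose(pred["mean"], pred["mean"].iloc[0])      # order-0: flat
    assert np.all(pred["lo"] <= pred["mean"]) and np.all(pred["mean"] <= pred["hi"])
    with pytest.warns(UserWarning, match="extrapolat"):
        predict_trajectory(two_group_fit, 1, [1000.0])


def test_ci_width_shrinks_with_sample_size():
    ds_small, _ = direct_dataset(60, 6, (3.0,), (1.0,), 1.0, seed=5)
    ds_big, _ = direct_dataset(600, 6, (3.0,), (1.0,), 1.0, seed=6)
    spec = TrajectorySpec(1, (0,))
    f_small = fit_gbtm(ds_small, spec, n_starts=1, seed=0)
    f_big = fit_gbtm(ds_big, spec, n_starts=1, seed=0)
    w_small = np.ptp(predict_trajectory(f_small, 1, [3.0])[["lo", "hi"]].to_numpy())
    w_big = np.ptp(predict_trajectory(f_big, 1, [3.0])[["lo", "hi"]].to_numpy())
    ratio = w_small / w_big
    assert ratio == pytest.approx(np.sqrt(10.0), rel=0.25)


def test_posterior_matrix_recompute_matches(two_group_fit, two_group_dataset):
    ds, _ = two_group_dataset
    np.testing.assert_allclose(posterior_matrix(two_group_fit, ds),
                               two_group_fit.posterior, atol=1e-8)


def test_spec_validation():
    with pytest.raises(ValueError):
        TrajectorySpec(2, (0,))                      # orders length mismatch
    with pytest.raises(ValueError):
        TrajectorySpec(1, (5,))                      # order out of range
    with pytest.raises(ValueError):
        TrajectorySpec(1, (0,), cnorm_min=2.0, cnorm_max=1.0)


def test_fit_rejects_degenerate_inputs(two_group_dataset):
    ds, _ = two_group_dataset
    with pytest.raises(ValueError, match="more groups"):
        fit_gbtm(ds, TrajectorySpec(300, (0,) * 300))
    empty = LongitudinalDataset(obs=ds.obs.iloc[:0], patients=ds.patients.iloc[:0])
    with pytest.raises(ValueError, match="empty"):
        fit_gbtm(empty, TrajectorySpec(1, (0,)))
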