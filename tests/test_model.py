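"""Hierarchical detection-nondetection model: likelihood, fitting, CV."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.special import expit

from occabund.model import (
    Dataset,
    FitConfig,
    ModelParams,
    RandomEffects,
    crossvalidate_auc,
    detection_prob,
    fit,
    linear_predictors,
    marginal_loglik,
    rank_auc,
    species_cell_loglik,
    zi_detection_prob,
)
from occabund.model import _Structure, _pair_ll_vector, _base_predictors
from occabund.simulate import SimulationConfig, simulate_dataset


# --------------------------------------------------------------------------
# Detection probability
# --------------------------------------------------------------------------


def test_detection_prob_values():
    assert detection_prob(0.0, 100.0) == 0.0
    assert detection_prob(0.01, 100.0) == pytest.approx(1 - math.exp(-1), rel=1e-12)
    with pytest.raises(ValueError):
        detection_prob(-0.1, 10.0)


def test_detection_prob_poisson_simulation_oracle():
    # fraction of nonzero Poisson(d*a) draws at d=0.002, a=250
    rng = np.random.default_rng(12345)
    n = 10 ** 6
    frac = np.mean(rng.poisson(0.002 * 250, n) > 0)
    p = detection_prob(0.002, 250.0)
    mc_sd = math.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 3 * mc_sd


@given(
    st.floats(min_value=1e-8, max_value=3.0),
    st.floats(min_value=1e-8, max_value=3.0),
)
@settings(max_examples=100, deadline=None)
def test_detection_prob_monotone_and_bounded(d, a):
    p = detection_prob(d, a)
    assert 0.0 <= p < 1.0
    assert detection_prob(d * 1.5, a) >= p
    assert detection_prob(d, a * 1.5) >= p


def test_detection_prob_small_intensity_linearisation():
    # p -> d*a as d*a -> 0 (first-order behaviour of 1 - exp(-x))
    p = detection_prob(1e-6, 1.0)
    assert abs(p - 1e-6) / 1e-6 < 1e-5


def test_zi_detection_prob():
    assert zi_detection_prob(0, 5.0, 100.0) == 0.0
    assert zi_detection_prob(1, 0.01, 100.0) == pytest.approx(1 - math.exp(-1), rel=1e-12)
    assert zi_detection_prob(1, 0.0, 0.0) == 0.0
    with pytest.raises(ValueError):
        zi_detection_prob(2, 1.0, 1.0)


# --------------------------------------------------------------------------
# Linear predictors
# --------------------------------------------------------------------------


def _effects(I, J, e1=None, u1=None, e2=None, u2=None):
    return RandomEffects(
        e1=np.zeros(I) if e1 is None else np.asarray(e1, float),
        u1=np.zeros(I) if u1 is None else np.asarray(u1, float),
        e2=np.zeros(J) if e2 is None else np.asarray(e2, float),
        u2=np.zeros(J) if u2 is None else np.asarray(u2, float),
        e3=np.zeros(0),
        e3_pairs=np.zeros((0, 2), dtype=int),
    )


def test_linear_predictors_constant_case():
    cells = pd.DataFrame({"x1": [0.3, -0.8], "x2": [1.1, 0.2]})
    p = ModelParams(mu=-2.0)
    log_d, logit_psi = linear_predictors(p, _effects(3, 2), cells)
    assert np.allclose(np.exp(log_d), math.exp(-2.0))
    assert np.allclose(expit(logit_psi), 0.5)  # eta = 0


def test_linear_predictors_match_direct_formula():
    rng = np.random.default_rng(7)
    cells = pd.DataFrame({"x1": rng.normal(size=2), "x2": rng.normal(size=2)})
    p = ModelParams(
        mu=0.4, beta1=-0.7, beta2=0.2, beta3=0.9,
        eta=-0.3, gamma1=0.5, gamma2=-0.2, gamma3=0.1,
    )
    e1, u1 = rng.normal(size=3), rng.normal(size=3)
    e2, u2 = rng.normal(size=2), rng.normal(size=2)
    log_d, logit_psi = linear_predictors(p, _effects(3, 2, e1, u1, e2, u2), cells)
    for i in range(3):
        for j in range(2):
            x1, x2 = cells.x1[j], cells.x2[j]
            v = p.mu + p.beta1 * x1 + p.beta2 * x2 + p.beta3 * x1 * x2 + e1[i] + e2[j]
            w = p.eta + p.gamma1 * x1 + p.gamma2 * x2 + p.gamma3 * x1 * x2 + u1[i] + u2[j]
            assert log_d[i, j] == pytest.approx(v, rel=1e-12)
            assert logit_psi[i, j] == pytest.approx(w, rel=1e-12)


# --------------------------------------------------------------------------
# Per-(species, cell) likelihood contribution
# --------------------------------------------------------------------------


def test_species_cell_loglik_known_absent():
    ll = species_cell_loglik([0, 0], [100.0, 100.0], d=5.0, psi=0.3, aux_state="absence")
    assert ll == pytest.approx(math.log(0.7), rel=1e-12)


def test_species_cell_loglik_no_plots_unknown_z():
    assert species_cell_loglik([], [], d=5.0, psi=0.4, aux_state=None) == pytest.approx(0.0, abs=1e-14)


def test_species_cell_loglik_marginalises_z():
    # K = 2 nondetections, psi = 0.4, expected counts 0.5 and 1.0 (per-km2 scale)
    ll = species_cell_loglik(
        [0, 0], [0.5 / 1e-6, 1.0 / 1e-6], d=1.0, psi=0.4, aux_state=None
    )
    assert ll == pytest.approx(math.log(0.4 * math.exp(-1.5) + 0.6), rel=1e-12)


def test_species_cell_loglik_equals_logsumexp_over_z():
    rng = np.random.default_rng(0)
    for _ in range(20):
        k = rng.integers(1, 5)
        areas = rng.uniform(10, 1000, k)
        d = rng.lognormal(7, 1)
        psi = rng.uniform(0.05, 0.95)
        y = np.zeros(k, dtype=int)  # marginalisation only applies when all y = 0
        c = d * areas * 1e-6
        branch1 = math.log(psi) + float(np.sum(-c))
        branch0 = math.log1p(-psi)
        expected = np.logaddexp(branch1, branch0)
        got = species_cell_loglik(y, areas, d, psi, None)
        assert got == pytest.approx(expected, rel=1e-12)


def test_species_cell_loglik_detection_with_absence_is_error():
    with pytest.raises(ValueError):
        species_cell_loglik([1], [100.0], d=1.0, psi=0.5, aux_state="absence")


# --------------------------------------------------------------------------
# Marginal likelihood
# --------------------------------------------------------------------------


def test_marginal_loglik_degenerate_equals_direct_sum(small_dataset):
    # all SDs zero: no integration; equals summed per-pair contributions
    data = small_dataset.data
    p = ModelParams(mu=math.log(1000), beta1=0.3, eta=0.2, gamma1=-0.1)
    ll = marginal_loglik(p, data)
    st_ = _Structure(data, occupancy=True, covariates=True)
    vf, wf = st_.cell_predictors(p)
    v, w = _base_predictors(st_, vf, wf)
    assert ll == pytest.approx(float(_pair_ll_vector(st_, p, v, w).sum()), rel=1e-12)


def test_marginal_loglik_agq_matches_quadrature_oracle(tiny_e3_dataset):
    # only e3 active: the marginal factorises; compare against adaptive
    # numerical integration of each pair's 1-D integral
    data = tiny_e3_dataset.data
    p = ModelParams(mu=math.log(1500), beta1=0.4, eta=0.2, gamma1=-0.3, sigma3=0.6)
    ll = marginal_loglik(p, data)  # auto -> adaptive Gauss-Hermite
    st_ = _Structure(data, occupancy=True, covariates=True)
    vf, wf = st_.cell_predictors(p)
    v0, w0 = _base_predictors(st_, vf, wf)
    sig = p.sigma3
    total = 0.0
    for pr in range(st_.P):
        if st_.v_active[pr]:
            def integrand(t, pr=pr):
                vv = v0.copy()
                vv[pr] = v0[pr] + t
                return math.exp(
                    _pair_ll_vector(st_, p, vv, w0)[pr] - 0.5 * t ** 2 / sig ** 2
                ) / math.sqrt(2 * math.pi * sig ** 2)
            val, err = integrate.quad(integrand, -10 * sig, 10 * sig, limit=200)
            total += math.log(val)
        else:
            total += float(_pair_ll_vector(st_, p, v0, w0)[pr])
    assert ll == pytest.approx(total, rel=1e-9)


def test_laplace_close_to_quadrature_on_tiny_problem(tiny_e3_dataset):
    data = tiny_e3_dataset.data
    p = ModelParams(mu=math.log(1500), beta1=0.4, eta=0.2, gamma1=-0.3, sigma3=0.6)
    ll_agq = marginal_loglik(p, data, method="agq")
    ll_lap = marginal_loglik(p, data, method="laplace")
    assert abs(ll_lap - ll_agq) / abs(ll_agq) < 0.01


def test_marginal_loglik_reduces_to_cloglog_glmm(small_dataset):
    # psi structurally ~1 and aux ignored: the integrated likelihood equals
    # the plain Bernoulli cloglog GLMM with offset at the same density params
    data = Dataset(small_dataset.data.detections, small_dataset.data.cells, aux=None)
    p_int = ModelParams(mu=7.0, beta1=0.3, beta2=-0.2, beta3=0.1, eta=30.0,
                        sigma1=0.8, sigma2=0.5)
    p_base = ModelParams(mu=7.0, beta1=0.3, beta2=-0.2, beta3=0.1,
                         sigma1=0.8, sigma2=0.5)
    # detections imply presence; undetected pairs keep a log(psi)+... mixture
    # that collapses as psi -> 1
    ll_int = marginal_loglik(p_int, data, model_spec="integrated")
    ll_base = marginal_loglik(p_base, data, model_spec="baseline_glmm")
    assert ll_int == pytest.approx(ll_base, abs=1e-6)


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------


def test_fit_requires_detections(small_dataset):
    det = small_dataset.data.detections.copy()
    det["y"] = 0
    with pytest.raises(ValueError):
        fit(Dataset(det, small_dataset.data.cells), model_spec="baseline_glmm")


def test_fit_empty_table_errors(small_dataset):
    det = small_dataset.data.detections.iloc[0:0]
    with pytest.raises(ValueError):
        fit(Dataset(det, small_dataset.data.cells))


def test_fit_is_deterministic(small_dataset):
    cfg = FitConfig(compute_se=False)
    f1 = fit(small_dataset.data, config=cfg)
    f2 = fit(small_dataset.data, config=cfg)
    assert f1.loglik == f2.loglik
    assert f1.params.to_dict() == f2.params.to_dict()


def test_fit_predictions_in_range(small_dataset):
    f = fit(small_dataset.data, config=FitConfig(compute_se=False))
    assert np.all(f.d_hat > 0)
    assert np.all((f.psi_hat > 0) & (f.psi_hat < 1))
    # known presences / absences are carried through unchanged
    assert np.all(f.z_known[f.m == 0] == 0)


# --------------------------------------------------------------------------
# Dataset validation
# --------------------------------------------------------------------------


def _mini_tables():
    det = pd.DataFrame(
        {
            "species_id": ["a", "a", "b", "b"],
            "cell_id": ["c1", "c1", "c1", "c1"],
            "plot_id": [0, 1, 0, 1],
            "y": [1, 0, 0, 0],
            "area_m2": [100.0, 50.0, 100.0, 50.0],
        }
    )
    cells = pd.DataFrame({"cell_id": ["c1"], "habitat_area_km2": [30.0], "x1": [0.0], "x2": [0.0]})
    return det, cells


def test_dataset_rejects_duplicates():
    det, cells = _mini_tables()
    det2 = pd.concat([det, det.iloc[[0]]])
    with pytest.raises(ValueError):
        Dataset(det2, cells)


def test_dataset_rejects_zero_area():
    det, cells = _mini_tables()
    det.loc[0, "area_m2"] = 0.0
    with pytest.raises(ValueError):
        Dataset(det, cells)


def test_dataset_rejects_detection_contradicting_absence():
    det, cells = _mini_tables()
    aux = pd.DataFrame(
        {"species_id": ["a"], "cell_id": ["c1"], "state": ["absence"], "source": ["map"]}
    )
    with pytest.raises(ValueError):
        Dataset(det, cells, aux)


def test_dataset_conflict_resolves_to_presence():
    det, cells = _mini_tables()
    aux = pd.DataFrame(
        {
            "species_id": ["b", "b"],
            "cell_id": ["c1", "c1"],
            "state": ["presence", "absence"],
            "source": ["herbarium", "map"],
        }
    )
    ds = Dataset(det, cells, aux)
    resolved = ds.aux_resolved
    assert (resolved["state"] == "presence").all()


# --------------------------------------------------------------------------
# AUC and cross-validation
# --------------------------------------------------------------------------


def test_rank_auc_perfect_and_null():
    y = np.array([0, 0, 1, 1])
    assert rank_auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
    assert rank_auc(y, np.array([0.5, 0.5, 0.5, 0.5])) == 0.5
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 4000)
    s = rng.random(4000)
    assert abs(rank_auc(y, s) - 0.5) < 0.03
    with pytest.raises(ValueError):
        rank_auc(np.ones(5), np.random.rand(5))


def test_crossvalidation_auc_on_strong_signal():
    p = ModelParams(
        mu=math.log(3000), beta1=0.8, beta2=-0.5, beta3=0.3, eta=0.5,
        gamma1=0.8, gamma2=-0.6, gamma3=0.2, sigma1=1.2, sigma2=0.6, sigma3=0.5,
        tau1=1.2, tau2=0.6, rho=0.5,
    )
    cfg = SimulationConfig(n_species=12, n_cells=20, plots_per_cell=8, true_params=p, seed=10)
    ds = simulate_dataset(cfg)
    mean_auc, sd_auc, per_fold = crossvalidate_auc(ds.data, n_folds=3, seed=1)
    assert mean_auc > 0.8
    assert len(per_fold) == 3
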