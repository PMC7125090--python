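"""Neutral-theory SAD machinery: octaves, likelihoods, fits, conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from occabund.simulate import simulate_neutral_sad
from occabund.untb import (
    MetacommunitySAD,
    akaike_weights,
    composite_loglik,
    ewens_expected_richness,
    ewens_loglik,
    fit_pln,
    fit_pms,
    fit_ps,
    fit_rfs,
    pln_logpmf,
    pm_expected_octaves,
    pm_expected_sad,
    preston_octaves,
    ps_expected_octaves,
    ps_expected_sad,
    ps_mu_tau,
    rf_equilibrium_logprob,
    speciation_rate,
    species_lifetime,
)
from conftest import integer_partitions


# --------------------------------------------------------------------------
# Preston octaves
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "abund, expected",
    [
        ([1, 1], [2]),
        ([2, 3], [0, 2]),  # 2 <= n < 4 is octave 2
        ([1, 2, 3, 4, 7, 8], [1, 2, 2, 1]),
        ([1.5, 2.0, 3.99], [1, 2]),  # continuous abundances, same boundaries
    ],
)
def test_preston_octave_binning(abund, expected):
    assert preston_octaves(abund).tolist() == expected


def test_preston_octaves_reject_nonpositive():
    with pytest.raises(ValueError):
        preston_octaves([1, 0, 2])


@given(st.lists(st.integers(min_value=1, max_value=10**6), min_size=1, max_size=200))
@settings(max_examples=50, deadline=None)
def test_octave_binning_conserves_species(ns):
    assert preston_octaves(ns).sum() == len(ns)


# --------------------------------------------------------------------------
# Ewens sampling formula
# --------------------------------------------------------------------------


def test_ewens_j2_configurations():
    # J_M = 2: P({2}) = 1/(1+theta), P({1,1}) = theta/(1+theta)
    theta = 1.7
    p2 = math.exp(ewens_loglik(np.array([2.0]), theta))
    p11 = math.exp(ewens_loglik(np.array([1.0, 1.0]), theta))
    assert p2 == pytest.approx(1 / (1 + theta), rel=1e-12)
    assert p11 == pytest.approx(theta / (1 + theta), rel=1e-12)


@pytest.mark.parametrize("j_m,theta", [(4, 1.0), (6, 0.6), (8, 2.5)])
def test_ewens_normalises_over_partitions(j_m, theta):
    total = sum(
        math.exp(ewens_loglik(np.array(p, dtype=float), theta))
        for p in integer_partitions(j_m)
    )
    assert total == pytest.approx(1.0, abs=1e-10)


def test_ewens_single_species_limit():
    # theta -> 0 with one species of abundance J_M: probability -> 1
    ll = ewens_loglik(np.array([1000.0]), 1e-12)
    assert abs(ll) < 1e-8


def test_ewens_stable_at_huge_metacommunity():
    sad = np.array([1e9, 5e8, 1e8, 3e7] + [1e6] * 50)
    ll = ewens_loglik(sad, 30.0)
    assert np.isfinite(ll)


def test_pms_mle_satisfies_score_equation():
    sad = simulate_neutral_sad("point_mutation", {"theta": 20.0}, 100_000, seed=1)
    f = fit_pms(sad)
    assert abs(ewens_expected_richness(f.theta, sad.j_m) - sad.s) < 1e-4


def test_pms_recovery_over_replicates():
    # theta-hat scatters around the generating value
    thetas = [fit_pms(simulate_neutral_sad("point_mutation", {"theta": 20.0}, 50_000, seed=s)).theta
              for s in range(8)]
    m = np.mean(thetas)
    se = np.std(thetas, ddof=1) / math.sqrt(len(thetas))
    assert abs(m - 20.0) < 3 * se + 1.0


def test_pms_single_species_boundary():
    f = fit_pms(MetacommunitySAD(np.array([500.0])))
    assert f.boundary and f.theta == 0.0


# --------------------------------------------------------------------------
# Point-mutation expected SAD
# --------------------------------------------------------------------------


def test_pm_expected_sad_identities():
    theta, j_m = 5.0, 2000
    ns = np.arange(1, j_m + 1)
    es = pm_expected_sad(theta, j_m, ns)
    assert es.sum() == pytest.approx(ewens_expected_richness(theta, j_m), rel=1e-6)
    assert pm_expected_sad(2.0, 1, [1])[0] == pytest.approx(1.0, rel=1e-12)


def test_pm_expected_octaves_match_urn_simulation():
    theta, j_m = 5.0, 1000
    reps = 400
    octs = []
    for s in range(reps):
        sad = simulate_neutral_sad("point_mutation", {"theta": theta}, j_m, seed=s)
        o = sad.octaves()
        octs.append(np.pad(o, (0, 11 - len(o))).astype(float))
    mean_oct = np.mean(octs, axis=0)
    se_oct = np.std(octs, axis=0, ddof=1) / math.sqrt(reps)
    expected = pm_expected_octaves(theta, j_m)
    expected = np.pad(expected, (0, 11 - len(expected)))
    assert np.all(np.abs(mean_oct - expected) <= 3 * se_oct + 0.02)


# --------------------------------------------------------------------------
# Random fission
# --------------------------------------------------------------------------


@pytest.mark.parametrize("j_m,theta", [(5, 1.5), (7, 2.7), (8, 4.0)])
def test_rf_equilibrium_normalises_over_partitions(j_m, theta):
    total = sum(
        math.exp(rf_equilibrium_logprob(np.array(p, dtype=float), theta))
        for p in integer_partitions(j_m)
    )
    assert total == pytest.approx(1.0, abs=1e-10)


def test_rfs_theta_close_to_richness_for_large_metacommunity():
    # the MLE sits near S - 1/4 when J_M >> S
    rng = np.random.default_rng(3)
    ab = rng.pareto(1.2, 300) * 1e4 + 1
    sad = MetacommunitySAD(np.round(ab * (1e8 / ab.sum())) + 1)
    f = fit_rfs(sad)
    assert abs(f.theta - (sad.s - 0.25)) < 0.2


def test_rf_logprob_finite_at_billion_individuals():
    rng = np.random.default_rng(0)
    ab = np.round(rng.lognormal(10, 2, 400))
    ab = ab * (1e9 / ab.sum())
    sad = MetacommunitySAD(np.maximum(ab, 1.0))
    ll = rf_equilibrium_logprob(sad, 400.0)
    assert np.isfinite(ll)


# --------------------------------------------------------------------------
# Protracted speciation
# --------------------------------------------------------------------------


def test_ps_reduces_to_logseries_in_small_tau_limit():
    j_m, theta = 1e6, 50.0
    beta = (j_m - 1) / (1 + 1e-6)  # tau ~ 1e-6
    ps = ps_expected_octaves(theta, beta, j_m)
    pm = pm_expected_octaves(theta, j_m)
    m = min(len(ps), len(pm))
    keep = pm[:m] > 1.0  # ignore the finite-size tail the difference-logseries lacks
    rel = np.abs(ps[:m][keep] - pm[:m][keep]) / pm[:m][keep]
    assert np.max(rel) < 0.02


def test_ps_self_consistency_recovers_parameters():
    j_m, theta, beta = 1e7, 50.0, 1e3
    target = ps_expected_octaves(theta, beta, j_m)
    # synthetic SAD only supplies J_M; the octaves come from the expectation
    sad = MetacommunitySAD(np.full(100, j_m / 100))
    f = fit_ps(sad, octaves=target, n_starts=6, seed=0)
    assert f.theta == pytest.approx(theta, rel=1e-2)
    assert f.beta == pytest.approx(beta, rel=1e-2)
    assert f.ss_octaves < 1e-6


def test_ps_expected_sad_decreasing_at_large_abundance():
    j_m = 1e6
    es = ps_expected_sad(40.0, 1e3, j_m, np.geomspace(100, j_m / 2, 50))
    assert np.all(np.isfinite(es))
    assert np.all(np.diff(es) < 0)


def test_ps_total_species_finite():
    total = ps_expected_octaves(40.0, 1e3, 1e6).sum()
    assert np.isfinite(total) and total > 0


# --------------------------------------------------------------------------
# Poisson-lognormal
# --------------------------------------------------------------------------


def test_pln_parameter_recovery():
    sad = simulate_neutral_sad(
        "poisson_lognormal", {"mean_log": 3.0, "sd_log": 1.5, "n_species": 500}, seed=3
    )
    f = fit_pln(sad)
    assert f.pln_mean_log == pytest.approx(3.0, abs=0.25)
    assert f.pln_sd_log == pytest.approx(1.5, abs=0.25)


def test_pln_loglik_is_local_optimum():
    sad = simulate_neutral_sad(
        "poisson_lognormal", {"mean_log": 2.0, "sd_log": 1.0, "n_species": 200}, seed=4
    )
    f = fit_pln(sad)
    n = np.round(sad.abundance)
    best = np.sum(pln_logpmf(n, f.pln_mean_log, f.pln_sd_log))
    for dm, ds in ((0.05, 0), (-0.05, 0), (0, 0.05), (0, -0.05)):
        assert np.sum(pln_logpmf(n, f.pln_mean_log + dm, f.pln_sd_log + ds)) <= best + 1e-9


def test_pln_pmf_normalises():
    lp = pln_logpmf(np.arange(1, 4000), 2.0, 0.8, truncated=True)
    assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-6)


# --------------------------------------------------------------------------
# Composite likelihood, AIC, weights
# --------------------------------------------------------------------------


def test_composite_loglik_matches_direct_formula():
    n = np.array([1.0, 2.0, 5.0])
    e = np.array([3.0, 2.0, 0.5])
    total = 10.0
    expected = np.sum(np.log(e / total))
    assert composite_loglik(n, e, total) == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        composite_loglik(n, np.array([1.0, 0.0, 1.0]), total)


def test_akaike_weights_cases():
    w = akaike_weights([5.0, 5.0, 5.0])
    assert np.allclose(w, 1 / 3)
    w2 = akaike_weights([0.0, 20.0])
    assert w2[0] == pytest.approx(1 / (1 + math.exp(-10)), rel=1e-9)
    assert w2[1] == pytest.approx(math.exp(-10) / (1 + math.exp(-10)), rel=1e-6)


def test_aic_ranking_invariant_to_constant_rescaling():
    # rescaling every expected SAD by c shifts all composite logliks by -S log c,
    # so AIC differences (and hence weights) are unchanged
    n = np.array([1.0, 4.0, 9.0, 20.0])
    e1 = np.array([5.0, 3.0, 1.0, 0.2])
    e2 = np.array([4.0, 3.5, 1.5, 0.1])
    d0 = composite_loglik(n, e1, e1.sum()) - composite_loglik(n, e2, e2.sum())
    d1 = composite_loglik(n, 7 * e1, 7 * e1.sum()) - composite_loglik(n, 7 * e2, 7 * e2.sum())
    assert d0 == pytest.approx(d1, abs=1e-10)


# --------------------------------------------------------------------------
# Conversions
# --------------------------------------------------------------------------


def test_speciation_rate_round_trips():
    rng = np.random.default_rng(1)
    for _ in range(20):
        j_m = 10 ** rng.uniform(4, 10)
        nu = 10 ** rng.uniform(-9, -2)
        theta = nu / (1 - nu) * (j_m - 1)
        assert speciation_rate("PMS", theta, j_m) == pytest.approx(nu, rel=1e-10)
        theta_rf = math.sqrt(nu) * j_m
        assert speciation_rate("RFS", theta_rf, j_m) == pytest.approx(nu, rel=1e-10)
        tau = 10 ** rng.uniform(1, 5)
        mu = (1 + tau) * nu
        if mu >= 1:
            continue
        theta_ps = mu / (1 - mu) * (j_m - 1)
        beta = (j_m - 1) / (1 + tau)
        assert speciation_rate("PS", theta_ps, j_m, beta=beta) == pytest.approx(nu, rel=1e-10)


def test_speciation_rate_boundaries():
    with pytest.raises(ValueError):
        speciation_rate("RFS", 1e6, 1e6)  # theta = J_M -> nu = 1
    with pytest.raises(ValueError):
        speciation_rate("PMS", -1.0, 1e6)


def test_species_lifetime_formulas():
    assert species_lifetime("PMS", math.exp(-10.0)) == pytest.approx(10.0, rel=1e-12)
    assert species_lifetime("RFS", 1e-8) == pytest.approx(1e4, rel=1e-12)
    mu, tau = 1e-6, 1e3
    assert species_lifetime("PS", 1e-9, tau_ps=tau, mu_ps=mu) == pytest.approx(
        -tau * math.log(tau * mu), rel=1e-12
    )
    with pytest.raises(ValueError):
        species_lifetime("PS", 1e-9, tau_ps=1e7, mu_ps=1e-3)  # tau*mu >= 1


def test_lifetime_monotone_decreasing_in_nu():
    nus = np.geomspace(1e-12, 1e-2, 30)
    for model in ("PMS", "RFS"):
        ls = [species_lifetime(model, nu) for nu in nus]
        assert np.all(np.diff(ls) < 0)


def test_ps_mu_tau_inversion():
    theta, j_m = 113.5, 1.65e10
    nu = 2.72e-13
    mu, tau = ps_mu_tau(theta, nu, j_m)
    assert mu == pytest.approx(theta / (j_m - 1 + theta), rel=1e-12)
    assert (1 + tau) * nu == pytest.approx(mu, rel=1e-12)
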