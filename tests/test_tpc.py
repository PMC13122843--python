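"""Briere curve, posterior, HPD intervals, sampler behaviour."""

import math

import numpy as np
import pytest

from mirevtd import (
    InferenceError,
    MCMCConfig,
    PriorSpec,
    TPCModel,
    briere,
    compare_fits,
    dataset_to_xy,
    derived_tpk,
    fit_tpc,
    hpd_interval,
    log_posterior,
    summarize_chain,
)
from mirevtd.synthetic import SimulationConfig, simulate_individual_dataset
from mirevtd.tpc import PosteriorSummary


# -- curve ----------------------------------------------------------------

def test_briere_is_zero_at_and_outside_the_limits():
    assert briere(10.0, 1.0, 10.0, 38.0) == 0.0
    assert briere(38.0, 1.0, 10.0, 38.0) == 0.0
    assert briere(5.0, 1.0, 10.0, 38.0) == 0.0
    assert briere(40.0, 1.0, 10.0, 38.0) == 0.0


def test_briere_hand_computed_value():
    # 25 * 15 * sqrt(13)
    assert briere(25.0, 1.0, 10.0, 38.0) == pytest.approx(25 * 15 * math.sqrt(13))


def test_briere_nonnegative_inside():
    grid = np.linspace(10, 38, 200)
    assert np.all(briere(grid, 3e-5, 10.0, 38.0) >= 0)


def test_briere_rejects_unordered_limits():
    with pytest.raises(InferenceError):
        briere(20.0, 1.0, 38.0, 10.0)


# -- peak temperature ------------------------------------------------------

def _grid_argmax(q, t_min, t_max):
    grid = np.arange(t_min, t_max, 1e-4)
    return float(grid[np.argmax(briere(grid, q, t_min, t_max))])


@pytest.mark.parametrize("t_min,t_max", [(10.0, 38.0), (0.0, 30.0), (-5.0, 45.0)])
def test_tpk_matches_grid_maximization(t_min, t_max):
    model = TPCModel(q=1.0, t_min=t_min, t_max=t_max, sigma=1.0)
    assert derived_tpk(model) == pytest.approx(_grid_argmax(1.0, t_min, t_max), abs=2e-4)
    assert t_min < derived_tpk(model) < t_max


def test_tpk_closed_form_limit_and_q_invariance():
    assert derived_tpk(TPCModel(1.0, 0.0, 30.0, 1.0)) == pytest.approx(24.0)  # 0.8*t_max
    a = derived_tpk(TPCModel(1.0, 10.0, 38.0, 1.0))
    b = derived_tpk(TPCModel(7.0, 10.0, 38.0, 1.0))
    assert a == b
    assert a == pytest.approx(31.588, abs=1e-3)


# -- log posterior ---------------------------------------------------------

PRIORS = PriorSpec()


def test_out_of_support_is_minus_inf():
    params = TPCModel(q=0.5, t_min=20.0, t_max=55.0, sigma=1.0)  # t_max > prior hi
    assert log_posterior(params, [(20.0, 1.0)], PRIORS) == -math.inf


def test_single_on_curve_observation_gives_normal_constant():
    params = TPCModel(q=1e-4, t_min=10.0, t_max=38.0, sigma=1.0)
    y = briere(25.0, params.q, params.t_min, params.t_max)
    lp = log_posterior(params, [(25.0, y)], PRIORS)
    assert lp == pytest.approx(-0.5 * math.log(2 * math.pi))


def test_doubling_the_data_doubles_the_likelihood_term():
    params = TPCModel(q=1e-4, t_min=10.0, t_max=38.0, sigma=0.5)
    data = [(20.0, 0.01), (30.0, 0.05), (35.0, 0.03)]
    lp1 = log_posterior(params, data, PRIORS)
    lp2 = log_posterior(params, data + data, PRIORS)
    assert lp2 == pytest.approx(2 * lp1)


# -- HPD -------------------------------------------------------------------

def _brute_force_hpd(samples, prob):
    arr = sorted(samples)
    n = len(arr)
    m = math.ceil(prob * n)
    best = None
    for start in range(n - m + 1):
        width = arr[start + m - 1] - arr[start]
        if best is None or width < best[0]:
            best = (width, arr[start], arr[start + m - 1])
    return best[1], best[2]


def test_hpd_known_examples():
    assert hpd_interval(list(range(1, 101)), 0.95) == (1.0, 95.0)
    assert hpd_interval([3.0] * 10, 0.5) == (3.0, 3.0)
    assert hpd_interval([0.0, 0.0, 0.0, 10.0], 0.5) == (0.0, 0.0)


def test_hpd_matches_brute_force_on_random_samples():
    rng = np.random.default_rng(5)
    for _ in range(20):
        samples = rng.gamma(2.0, 1.0, size=rng.integers(5, 80))
        for prob in (0.5, 0.9, 0.95):
            assert hpd_interval(samples, prob) == _brute_force_hpd(samples, prob)


def test_hpd_rejects_bad_input():
    with pytest.raises(ValueError):
        hpd_interval([], 0.95)
    with pytest.raises(ValueError):
        hpd_interval([1.0], 1.5)


# -- sampler ---------------------------------------------------------------

def _sim_data(**kw):
    cfg = SimulationConfig(**kw)
    return dataset_to_xy(simulate_individual_dataset(cfg))


def test_same_seed_gives_identical_chain():
    data = _sim_data(n_per_temp=3, seed=9)
    priors = PriorSpec.for_data([y for _, y in data])
    cfg = MCMCConfig(n_iter=500, n_burn=300, seed=4)
    c1 = fit_tpc(data, priors, cfg)
    c2 = fit_tpc(data, priors, cfg)
    assert np.array_equal(c1.samples, c2.samples)
    assert c1.acceptance_rate == c2.acceptance_rate


def test_too_few_temperatures_rejected():
    data = [(20.0, 0.1), (25.0, 0.2), (30.0, 0.15)]
    with pytest.raises(InferenceError, match="distinct temperatures"):
        fit_tpc(data, PRIORS, MCMCConfig(n_iter=10, n_burn=10, seed=0))


def test_near_noiseless_dense_data_recovers_thermal_limits():
    """With tiny noise and 15 dense temperatures the posterior medians land
    within half a degree of the generating limits."""
    truth = TPCModel(q=7e-5, t_min=10.0, t_max=38.0, sigma=1e-4)
    data = _sim_data(tpc_truth=truth,
                     temperatures=tuple(np.linspace(12, 37.5, 15)),
                     n_per_temp=50, seed=13)
    priors = PriorSpec.for_data([y for _, y in data])
    # the near-noiseless posterior is extremely peaked; give the adaptive
    # burn-in time to find and scale to it
    chain = fit_tpc(data, priors, MCMCConfig(n_iter=6000, n_burn=20000, seed=13))
    summary = summarize_chain(chain)
    assert chain.ok
    assert summary.params["t_min"].median == pytest.approx(10.0, abs=0.5)
    assert summary.params["t_max"].median == pytest.approx(38.0, abs=0.5)


def test_summary_invariants_hold_on_a_real_chain():
    data = _sim_data(n_per_temp=5, seed=3)
    priors = PriorSpec.for_data([y for _, y in data])
    chain = fit_tpc(data, priors, MCMCConfig(n_iter=2000, n_burn=1500, seed=3))
    summary = summarize_chain(chain)
    for name, p in summary.params.items():
        assert p.hpd_low <= p.median <= p.hpd_high, name
    tpk = chain.tpk_samples()
    assert np.all(chain.get("t_min") < tpk) and np.all(tpk < chain.get("t_max"))


def test_pinned_parameters_stay_fixed():
    data = _sim_data(n_per_temp=2, seed=1)
    priors = PriorSpec(q=(7e-5, 7e-5), t_min=(10.0, 10.0),
                       t_max=(25.0, 50.0), sigma=(0.01, 0.01))
    chain = fit_tpc(data, priors, MCMCConfig(n_iter=500, n_burn=300, seed=2))
    assert np.all(chain.get("q") == 7e-5)
    assert np.all(chain.get("sigma") == 0.01)
    assert chain.get("t_max").std() > 0


# -- comparison ------------------------------------------------------------

def test_identical_fits_compare_as_identity():
    data = _sim_data(n_per_temp=3, seed=2)
    priors = PriorSpec.for_data([y for _, y in data])
    chain = fit_tpc(data, priors, MCMCConfig(n_iter=800, n_burn=400, seed=5))
    s = summarize_chain(chain)
    comp = compare_fits(s, s)
    assert all(d == 0.0 for d in comp.median_diff.values())
    assert all(r == 1.0 for r in comp.width_ratio.values())


def test_comparison_and_summary_serialize_losslessly():
    data = _sim_data(n_per_temp=3, seed=2)
    priors = PriorSpec.for_data([y for _, y in data])
    s = summarize_chain(fit_tpc(data, priors, MCMCConfig(n_iter=400, n_burn=300, seed=6)))
    assert PosteriorSummary.from_json(s.to_json()) == s
    comp = compare_fits(s, s)
    assert comp.from_json(comp.to_json()) == comp
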