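"""Modulated Poisson model: moments, likelihood, gain fitting, screening."""

import numpy as np
import pytest
from scipy.integrate import quad as sciquad
from scipy.stats import norm, poisson

from popcurv import response_model as rm
from popcurv.response_model import (GainCovariance,
                                    GoodnessOfFit, SpikeCountDataset,
                                    count_loglik, counts_from_spike_times,
                                    fit_gain_covariance, goodness_of_fit,
                                    predicted_covariance, simulate)


# ------------------------------------------------------------ gain structure

def test_gain_unit_mean_and_derived_quantities(rng):
    gains = GainCovariance.shared(6, 0.2, 0.05, rank=2)
    g = gains.sample_gains(200_000, rng)
    np.testing.assert_allclose(g.mean(axis=0), 1.0, rtol=0.01)
    np.testing.assert_allclose(gains.gain_variances(),
                               np.diag(gains.gain_covariance()), atol=1e-12)
    assert np.all(np.linalg.eigvalsh(gains.sigma_eps()) > -1e-12)


def test_gain_covariance_validation():
    with pytest.raises(ValueError):
        GainCovariance(np.array([-0.1, 0.2]), np.zeros((2, 0)))
    diag = GainCovariance.shared(4, 0.1, 0.02, rank=1).diagonal()
    assert diag.rank == 0
    np.testing.assert_allclose(
        diag.gain_variances(),
        GainCovariance.shared(4, 0.1, 0.02, rank=1).gain_variances())


# ----------------------------------------------------------------- simulate

def test_simulate_poisson_limit():
    rates = np.array([[2.0, 6.0]])
    ds = simulate(rates, GainCovariance.zero(2), 100_000, seed=0)
    counts = ds.counts[:, 0, :]
    np.testing.assert_allclose(counts.mean(axis=0), rates[0], rtol=0.02)
    np.testing.assert_allclose(counts.var(axis=0), rates[0], rtol=0.03)


def test_simulate_determinism(small_gains):
    rates = np.full((3, small_gains.n_units), 4.0)
    a = simulate(rates, small_gains, 10, seed=42)
    b = simulate(rates, small_gains, 10, seed=42)
    np.testing.assert_array_equal(a.counts, b.counts)


def test_simulate_mean_conservation_and_fano(small_gains):
    """E[n] = lambda for any gain structure; counts are over-dispersed."""
    rates = np.array([np.linspace(1, 10, small_gains.n_units)])
    ds = simulate(rates, small_gains, 50_000, seed=3)
    counts = ds.counts[:, 0, :]
    np.testing.assert_allclose(counts.mean(axis=0), rates[0], rtol=0.03)
    fano = counts.var(axis=0) / counts.mean(axis=0)
    expected = 1.0 + small_gains.gain_variances() * rates[0]
    np.testing.assert_allclose(fano, expected, rtol=0.05)
    assert np.all(fano > 1.0)


def test_predicted_covariance_cases():
    np.testing.assert_allclose(
        predicted_covariance(np.array([[1.0, 1.0]]), GainCovariance.zero(2),
                             0), np.eye(2))
    # scalar case: variance = lam + sigma_g^2 lam^2 = 2 + 0.5 * 4 = 4
    g = GainCovariance.independent([np.log1p(0.5)])
    assert predicted_covariance(np.array([[2.0]]), g, 0)[0, 0] == \
        pytest.approx(4.0)


def test_covariance_matches_simulation(small_gains):
    """Empirical covariance at large K matches the model prediction."""
    rng = np.random.default_rng(1)
    rates = rng.uniform(2, 8, (1, small_gains.n_units))
    ds = simulate(rates, small_gains, 50_000, seed=11)
    emp = np.cov(ds.counts[:, 0, :].T)
    pred = predicted_covariance(rates, small_gains, 0)
    assert np.abs(emp - pred).max() / np.abs(pred).max() < 0.02


# ---------------------------------------------------------------- likelihood

def test_count_loglik_poisson_limit():
    g0 = GainCovariance.zero(1)
    assert count_loglik(np.array([0]), np.array([1.0]), g0) == \
        pytest.approx(-1.0)
    n = np.array([3])
    assert count_loglik(n, np.array([2.5]), g0) == \
        pytest.approx(poisson.logpmf(3, 2.5))


def test_count_loglik_matches_dense_quadrature():
    """1-unit marginal likelihood agrees with adaptive 1-D integration."""
    s2, lam, n = 0.3, 2.5, 3
    gains = GainCovariance.independent([s2])
    val = count_loglik(np.array([n]), np.array([lam]), gains, n_inner=41)
    oracle, _ = sciquad(
        lambda e: norm.pdf(e, -s2 / 2, np.sqrt(s2))
        * poisson.pmf(n, lam * np.exp(e)), -8, 8)
    assert val == pytest.approx(np.log(oracle), abs=1e-8)


def test_count_loglik_likelihood_dominance(small_gains, rng):
    """Data are on average more likely under the generating rates."""
    rates = rng.uniform(2, 8, (4, small_gains.n_units))
    ds = simulate(rates, small_gains, 200, seed=5)
    ll_true = count_loglik(ds.counts, rates, small_gains)
    ll_pert = count_loglik(ds.counts, rates * 1.5, small_gains)
    assert ll_true > ll_pert


def test_count_table_batched_consistency(small_gains, rng):
    """The batched path equals summed per-vector evaluations."""
    rates = rng.uniform(1, 6, (2, 5))
    gains = GainCovariance.shared(5, 0.09, 0.01, rank=1)
    ds = simulate(rates, gains, 3, seed=9)
    total = count_loglik(ds.counts, rates, gains)
    single = sum(
        count_loglik(ds.counts[k, t], rates[t], gains)
        for k in range(3) for t in range(2))
    assert total == pytest.approx(single, rel=1e-10)


# ------------------------------------------------------------------ gain fit

def test_fit_gain_covariance_recovers_rank2():
    rng = np.random.default_rng(0)
    D, K = 8, 120
    gains_true = GainCovariance.shared(D, 0.2, 0.02, rank=2)
    rates = rng.uniform(3, 12, (4, D))
    ds = simulate(rates, gains_true, K, seed=1)
    gains_fit, info = fit_gain_covariance(ds, ranks=(0, 1, 2), n_folds=3,
                                          n_iter=400, seed=0, n_outer=5,
                                          n_inner=3)
    assert info["rank"] == 2
    assert np.all(np.linalg.eigvalsh(gains_fit.sigma_eps()) > -1e-12)
    # shared-gain magnitude recovered within a factor
    true_off = np.mean(gains_true.gain_covariance()[np.triu_indices(D, 1)])
    fit_off = np.mean(gains_fit.gain_covariance()[np.triu_indices(D, 1)])
    assert fit_off == pytest.approx(true_off, rel=0.5)


def test_fit_gain_covariance_independent_gains():
    rng = np.random.default_rng(2)
    D, K = 6, 120
    gains_true = GainCovariance.independent(np.full(D, 0.15))
    rates = rng.uniform(3, 12, (4, D))
    ds = simulate(rates, gains_true, K, seed=3)
    gains_fit, info = fit_gain_covariance(ds, ranks=(0, 1), n_folds=3,
                                          n_iter=300, seed=0, n_outer=5,
                                          n_inner=3)
    off = gains_fit.gain_covariance()[np.triu_indices(D, 1)]
    assert np.abs(off).max() < 0.05


def test_fit_gain_covariance_needs_trials(small_gains):
    ds = simulate(np.full((2, small_gains.n_units), 3.0), small_gains, 3,
                  seed=0)
    with pytest.raises(ValueError):
        fit_gain_covariance(ds, n_folds=5)


# ------------------------------------------------------------------ fit check

def test_goodness_of_fit_thresholds():
    """Inclusion requires all three correlation criteria simultaneously."""
    assert GoodnessOfFit(np.sqrt(0.8), np.sqrt(0.6), np.sqrt(0.3)).included
    assert not GoodnessOfFit(np.sqrt(0.70), 0.99, 0.99).included
    assert not GoodnessOfFit(0.99, np.sqrt(0.49), 0.99).included
    assert not GoodnessOfFit(0.99, 0.99, np.sqrt(0.24)).included


def test_goodness_of_fit_self_consistency(small_gains, rng):
    """A dataset simulated from the tested rates passes all criteria."""
    rates = rng.uniform(1, 9, (6, small_gains.n_units))
    ds = simulate(rates, small_gains, 400, seed=21)
    gof = goodness_of_fit(ds, rates, small_gains)
    assert gof.r_mean ** 2 > 0.9
    assert gof.r_var ** 2 > 0.8
    assert gof.r_cov ** 2 > 0.25
    assert gof.included


def test_goodness_of_fit_silent_unit_warns(small_gains, rng):
    rates = rng.uniform(1, 9, (4, small_gains.n_units))
    rates[:, 0] = 0.0
    ds = simulate(rates, small_gains, 100, seed=2)
    with pytest.warns(RuntimeWarning, match="silent"):
        goodness_of_fit(ds, rates, small_gains)


# ---------------------------------------------------------- spike-time counts

def _synthetic_spikes(rng, rates, onsets, frame_ids, latency, window):
    spikes = []
    for m, on in enumerate(onsets):
        n = rng.poisson(rates[frame_ids[m]] * window)
        spikes.extend(on + latency + window * rng.random(n))
    return np.sort(np.array(spikes))


def test_latency_recovery():
    rng = np.random.default_rng(7)
    onsets = np.arange(0, 90, 0.3)
    frame_ids = np.tile(np.arange(5), 60)
    trial_ids = np.repeat(np.arange(60), 5)
    rates = np.array([1.0, 4.0, 30.0, 10.0, 2.0])
    st = _synthetic_spikes(rng, rates, onsets, frame_ids, 0.05, 0.2)
    ds, lats = counts_from_spike_times([st], onsets, frame_ids, trial_ids,
                                       window=0.2)
    assert abs(lats[0] - 0.05) <= 0.01 + 1e-12
    np.testing.assert_allclose(ds.counts[:, :, 0].mean(axis=0),
                               rates * 0.2, rtol=0.2, atol=0.06)


def test_single_latency_grid_direct_counts():
    rng = np.random.default_rng(8)
    onsets = np.arange(0, 30, 0.3)
    frame_ids = np.tile(np.arange(2), 50)
    trial_ids = np.repeat(np.arange(50), 2)
    st = _synthetic_spikes(rng, np.array([5.0, 15.0]), onsets, frame_ids,
                           0.0, 0.2)
    ds, lats = counts_from_spike_times([st], onsets, frame_ids, trial_ids,
                                       window=0.2, latency_grid=[0.0])
    lo = np.searchsorted(st, onsets)
    hi = np.searchsorted(st, onsets + 0.2)
    assert ds.counts[:, :, 0].sum() == (hi - lo).sum()
    assert lats[0] == 0.0


def test_shuffled_labels_conserve_spikes():
    rng = np.random.default_rng(9)
    onsets = np.arange(0, 30, 0.3)
    frame_ids = np.tile(np.arange(2), 50)
    trial_ids = np.repeat(np.arange(50), 2)
    st = _synthetic_spikes(rng, np.array([5.0, 15.0]), onsets, frame_ids,
                           0.0, 0.28)
    shuffled = rng.permutation(frame_ids)
    ds1, _ = counts_from_spike_times([st], onsets, frame_ids, trial_ids,
                                     window=0.28, latency_grid=[0.0])
    ds2, _ = counts_from_spike_times([st], onsets, shuffled, trial_ids,
                                     window=0.28, latency_grid=[0.0])
    assert ds1.counts.sum() == ds2.counts.sum()


def test_empty_spike_train_warns():
    with pytest.warns(RuntimeWarning, match="no spikes"):
        ds, _ = counts_from_spike_times(
            [np.array([])], np.arange(0, 3, 0.3), np.tile(np.arange(2), 5),
            np.repeat(np.arange(5), 2), window=0.2)
    assert ds.counts.sum() == 0


def test_dataset_hdf5_round_trip(tmp_path, small_gains):
    ds = simulate(np.full((3, small_gains.n_units), 4.0), small_gains, 5,
                  seed=1)
    ds.to_hdf5(tmp_path / "ds.h5")
    back = SpikeCountDataset.from_hdf5(tmp_path / "ds.h5")
    np.testing.assert_array_equal(back.counts, ds.counts)
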