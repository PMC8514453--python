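"""Variational curvature inference: decoder, priors, ELBO and recovery."""

import numpy as np
import pytest

from popcurv import geometry, response_model as rm
from popcurv.curvature_inference import (FitConfig, GlobalParams,
                                         VariationalPosterior, decode, elbo,
                                         fit, fit_pseudo, map_trajectory,
                                         prior_logdensity)
from popcurv.fisher_embedding import embed
from popcurv.pipeline import constant_curvature_rates
from tests.conftest import make_dataset


def random_latents(rng, T=5, n=4, D=8):
    za = rng.standard_normal((T - 1, n))
    zE = rng.standard_normal((D, n))
    return {"zd": rng.standard_normal(T) * 0.3 + 1.0,
            "zc": rng.uniform(0.2, 1.5, T - 1),
            "za": za, "zE": zE, "zb": rng.uniform(3, 5, D)}


def test_decode_is_isometric(rng):
    """The orthonormalized embedding preserves all pairwise distances."""
    from scipy.spatial.distance import pdist

    z = random_latents(rng)
    traj, x = decode(z, np.full(8, 0.3))
    np.testing.assert_allclose(pdist(traj.points), pdist(x), atol=1e-8)


def test_decode_constant_curvature(rng):
    z = random_latents(rng)
    z["zc"][:] = np.radians(70.0)
    traj, x = decode(z, np.full(8, 0.3))
    np.testing.assert_allclose(geometry.local_curvatures(x), 70.0, atol=1e-6)
    np.testing.assert_allclose(geometry.local_curvatures(traj.points), 70.0,
                               atol=1e-6)


def test_decode_step_lengths_follow_softplus(rng):
    z = random_latents(rng)
    _, x = decode(z, np.full(8, 0.3))
    np.testing.assert_allclose(
        np.linalg.norm(np.diff(x, axis=0), axis=1),
        np.logaddexp(0.0, z["zd"]), atol=1e-8)


def test_prior_logdensity_matches_direct_sum(rng):
    """Against an independent summation of scalar normal log-pdfs."""
    from scipy.stats import norm

    z = random_latents(rng)
    theta = GlobalParams(d_star=1.2, c_star_deg=40.0, sigma_d=0.3,
                         sigma_c=0.25, accel_scale=0.6, accel_decay=0.8)
    total = prior_logdensity(z, theta)
    m_d = np.log(np.expm1(1.2))
    expected = norm.logpdf(z["zd"], m_d, 0.3).sum()
    expected += norm.logpdf(z["zc"], np.radians(40.0), 0.25).sum()
    sig_a = 0.6 * 0.8 ** (np.arange(4) / 2.0)
    expected += norm.logpdf(z["za"], 0, sig_a[None, :]).sum()
    expected += norm.logpdf(z["zE"]).sum()
    expected += norm.logpdf(z["zb"], 0, 5.0).sum()
    assert total == pytest.approx(expected, rel=1e-9)


def test_prior_density_peaks_at_prior_mean(rng):
    theta = GlobalParams(d_star=1.0, c_star_deg=30.0, sigma_d=0.3,
                         sigma_c=0.2)
    z = random_latents(rng)
    z["zc"][:] = np.radians(30.0)
    base = prior_logdensity(z, theta)
    for delta in (0.1, 0.3, 0.6):
        z2 = {**z, "zc": z["zc"] + delta}
        assert prior_logdensity(z2, theta) < base
    assert prior_logdensity({**z, "zc": z["zc"] + 0.6}, theta) < \
        prior_logdensity({**z, "zc": z["zc"] + 0.3}, theta)


def test_global_params_validation():
    with pytest.raises(ValueError):
        GlobalParams(d_star=-1.0, c_star_deg=10, sigma_d=0.1, sigma_c=0.1)
    with pytest.raises(ValueError):
        GlobalParams(d_star=1.0, c_star_deg=200, sigma_d=0.1, sigma_c=0.1)


def _phi_at_prior(theta, T, n, D):
    mu = {"zd": np.full(T, np.log(np.expm1(theta.d_star))),
          "zc": np.full(T - 1, np.radians(theta.c_star_deg)),
          "za": np.zeros((T - 1, n)), "zE": np.zeros((D, n)),
          "zb": np.zeros(D)}
    ls = {"zd": np.full(T, np.log(theta.sigma_d)),
          "zc": np.full(T - 1, np.log(theta.sigma_c)),
          "za": np.log(theta.accel_scale
                       * theta.accel_decay ** (np.arange(n) / 2.0))
          * np.ones((T - 1, n)),
          "zE": np.zeros((D, n)), "zb": np.full(D, np.log(5.0))}
    ls["za"] = np.tile(np.log(theta.accel_scale
                              * theta.accel_decay ** (np.arange(n) / 2.0)),
                       (T - 1, 1))
    return VariationalPosterior(mu=mu, log_sigma=ls)


def test_elbo_kl_term_vanishes_when_q_equals_prior(small_gains):
    """With q == p(z|theta) the ELBO is the plain MC likelihood average."""
    from popcurv import _ad as ad
    from popcurv.curvature_inference import _params_from, _total_kl

    theta = GlobalParams(d_star=1.0, c_star_deg=45.0, sigma_d=0.2,
                         sigma_c=0.3, accel_scale=0.5, accel_decay=0.8)
    T, n, D = 4, 4, small_gains.n_units
    phi = _phi_at_prior(theta, T, n, D)
    p = {k: ad.Tensor(v) for k, v in _params_from(theta, phi).items()}
    kl = float(ad.value(_total_kl(p, n)))
    assert kl == pytest.approx(0.0, abs=1e-10)


def test_elbo_deterministic_given_seed(small_gains, fast_fit_config):
    rates, ds = make_dataset(small_gains, seed=4)
    theta = GlobalParams(d_star=1.5, c_star_deg=90.0, sigma_d=0.2,
                         sigma_c=0.3)
    phi = _phi_at_prior(theta, ds.n_frames - 1,
                        min(ds.n_frames - 1, ds.n_units), ds.n_units)
    a = elbo(theta, phi, ds, small_gains, n_mc=3, seed=11)
    b = elbo(theta, phi, ds, small_gains, n_mc=3, seed=11)
    c = elbo(theta, phi, ds, small_gains, n_mc=3, seed=12)
    assert a == b
    assert a != c


def test_elbo_bounded_by_marginal_likelihood():
    """ELBO <= log marginal likelihood on a tiny Poisson instance.

    The marginal over all latents is estimated by brute-force Monte-Carlo
    integration against the prior (log-mean-exp of the conditional
    likelihood over many prior draws), feasible because the instance is
    tiny and gain-free.
    """
    from popcurv import _ad as ad
    from popcurv.curvature_inference import (_decode_core, _params_from,
                                             prior_logdensity)
    from popcurv.response_model import CountTable, _quadrature_shifts

    gains = rm.GainCovariance.zero(2)
    rates = np.array([[2.0, 4.0], [3.0, 3.0], [4.0, 2.0]])
    ds = rm.simulate(rates, gains, 4, seed=0)
    theta = GlobalParams(d_star=1.0, c_star_deg=60.0, sigma_d=0.3,
                         sigma_c=0.4, accel_scale=0.5, accel_decay=0.9)
    T, n, D = 2, 2, 2
    sigma = np.full(D, 1e-6)
    table = CountTable(ds.counts)
    quad = _quadrature_shifts(gains.private_var, gains.U, 1, 1)

    # brute-force log marginal: log E_{z~prior}[P(N|z)]
    rng = np.random.default_rng(123)
    S = 200_000
    zd = np.log(np.expm1(theta.d_star)) + 0.3 * rng.standard_normal((S, T))
    zc = np.radians(60.0) + 0.4 * rng.standard_normal((S, T - 1))
    za = (0.5 * 0.9 ** (np.arange(n) / 2.0)
          * rng.standard_normal((S, T - 1, n)))
    zE = rng.standard_normal((S, D, n))
    zb = 5.0 * rng.standard_normal((S, D))
    lls = []
    for lo in range(0, S, 20_000):
        hi = lo + 20_000
        _, _, lam = _decode_core(zd[lo:hi], zc[lo:hi], za[lo:hi],
                                 zE[lo:hi], zb[lo:hi], sigma)
        lls.append(np.asarray(ad.value(table.loglik(ad.value(lam), quad,
                                                    1, 1))))
    ll = np.concatenate(lls)
    m = ll.max()
    log_ml = m + np.log(np.mean(np.exp(ll - m)))
    weights = np.exp(ll - m)
    se = weights.std() / (weights.mean() * np.sqrt(S))

    phi = _phi_at_prior(theta, T, n, D)
    phi.log_sigma["zb"][:] = np.log(5.0)
    bound = elbo(theta, phi, ds, gains, n_mc=64, seed=5)
    assert bound <= log_ml + 3 * se


def test_elbo_variance_shrinks_with_more_mc_samples(small_gains):
    """More reparameterized samples reduce the ELBO estimator's variance."""
    rates, ds = make_dataset(small_gains, n_frames=5, n_trials=10, seed=2)
    theta = GlobalParams(d_star=1.5, c_star_deg=90.0, sigma_d=0.2,
                         sigma_c=0.3)
    phi = _phi_at_prior(theta, 4, 4, small_gains.n_units)
    few = [elbo(theta, phi, ds, small_gains, n_mc=1, seed=s)
           for s in range(25)]
    many = [elbo(theta, phi, ds, small_gains, n_mc=16, seed=s)
            for s in range(25)]
    assert np.var(many) < np.var(few)


def test_population_and_pseudo_estimates_diverge_under_shared_gain():
    """With strong shared gain, ignoring correlations changes estimates."""
    gains = rm.GainCovariance.shared(10, shared_var=0.25, private_var=0.01,
                                     rank=1)
    cfg = FitConfig(n_iter=200, lr=0.03, n_mc=2, n_outer=5, n_inner=1,
                    start_shrink=(1.0,))
    diffs = []
    for i in range(4):
        rates = constant_curvature_rates(gains, 6, 1.5, 60.0, seed=20 + i)
        ds = rm.simulate(rates, gains, 25, seed=30 + i)
        cfg.seed = i
        c_pop = fit(ds, gains, cfg)[2].c_neural_deg
        c_pse = fit_pseudo(ds, gains, cfg)[2].c_neural_deg
        diffs.append(c_pop - c_pse)
    assert np.max(np.abs(diffs)) > 1.0


def test_fit_deterministic(small_gains, fast_fit_config):
    _, ds = make_dataset(small_gains, seed=6)
    cfg = FitConfig(**{**fast_fit_config.__dict__, "n_iter": 60, "seed": 3})
    a = fit(ds, small_gains, cfg)[2]
    b = fit(ds, small_gains, cfg)[2]
    assert a.c_neural_deg == b.c_neural_deg
    assert a.d_star == b.d_star


def test_recovery_high_snr(study_gains, fast_fit_config):
    """Constant 90-degree curvature at strong signal is recovered closely."""
    rates = constant_curvature_rates(study_gains, 11, 2.0, 90.0, seed=1)
    ds = rm.simulate(rates, study_gains, 50, seed=2)
    _, _, est = fit(ds, study_gains, fast_fit_config)
    assert est.reliable
    assert abs(est.c_neural_deg - 90.0) < 10.0


def test_reliability_flag_fires_on_weak_signal(small_gains, fast_fit_config):
    """Near-constant rates leave d* below the 0.25 d' threshold."""
    rates = np.tile(np.linspace(2, 5, small_gains.n_units), (6, 1))
    ds = rm.simulate(rates, small_gains, 200, seed=1)
    cfg = FitConfig(**{**fast_fit_config.__dict__, "n_iter": 250})
    _, _, est = fit(ds, small_gains, cfg)
    assert est.d_star < 0.25
    assert not est.reliable


def test_estimate_invariant_to_unit_relabeling(small_gains, fast_fit_config):
    """Permuting units permutes nothing that curvature depends on."""
    rates, ds = make_dataset(small_gains, seed=8)
    cfg = FitConfig(**{**fast_fit_config.__dict__, "n_iter": 200})
    est = fit(ds, small_gains, cfg)[2]
    perm = np.random.default_rng(1).permutation(small_gains.n_units)
    gains_p = rm.GainCovariance(small_gains.private_var[perm],
                                small_gains.U[perm])
    ds_p = rm.SpikeCountDataset(counts=ds.counts[:, :, perm])
    est_p = fit(ds_p, gains_p, cfg)[2]
    assert est_p.c_neural_deg == pytest.approx(est.c_neural_deg, abs=3.0)


def test_fit_pseudo_matches_fit_for_diagonal_gains(fast_fit_config):
    gains = rm.GainCovariance.independent(np.full(10, 0.1))
    rates = constant_curvature_rates(gains, 7, 1.5, 60.0, seed=3)
    ds = rm.simulate(rates, gains, 30, seed=4)
    cfg = FitConfig(**{**fast_fit_config.__dict__, "n_iter": 200})
    est_pop = fit(ds, gains, cfg)[2]
    est_pse = fit_pseudo(ds, gains, cfg)[2]
    assert est_pse.c_neural_deg == pytest.approx(est_pop.c_neural_deg,
                                                 abs=1e-9)


def test_map_trajectory_properties(small_gains, fast_fit_config):
    rates, ds = make_dataset(small_gains, d_star=2.0, seed=10)
    cfg = FitConfig(**{**fast_fit_config.__dict__, "n_iter": 250})
    theta, phi, est = fit(ds, small_gains, cfg)
    lam = map_trajectory(phi, small_gains)
    assert lam.shape == rates.shape
    assert np.all(lam >= 0)
    # recovered rates track the generating rates on the log scale
    r = np.corrcoef(np.log(lam + 0.1).ravel(),
                    np.log(rates + 0.1).ravel())[0, 1]
    assert r > 0.9
    # embedding round trip: embed(map_trajectory) == decoded mean trajectory
    traj, _ = decode(phi.mu, np.sqrt(small_gains.gain_variances()))
    np.testing.assert_allclose(embed(lam, small_gains).points, traj.points,
                               atol=1e-6)
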