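"""LN-LN cascade: tuning curves, filters, response rules and fitting."""

import numpy as np
import pytest

from popcurv.lnln import (LNLNNeuron, PixelGrid, dissect, f1f0,
                          fit_filter_params, fit_pooling_weights,
                          grating_response, make_filters,
                          predict_population_curvature, psth_to_grating,
                          respond, rf_center, ori_tuning, sf_tuning)
from popcurv.response_model import GainCovariance
from popcurv.stimuli import make_fade, synthesize_clip

GRID = PixelGrid((64, 64), 0.05)


def grating_image(theta_deg, sf, phase_rad, contrast=1.0, grid=GRID):
    yy, xx = grid.coords()
    th = np.radians(theta_deg)
    arg = 2 * np.pi * sf * (yy * np.sin(th) + xx * np.cos(th)) + phase_rad
    return 0.5 * (1 + contrast * np.cos(arg))


# ------------------------------------------------------------- tuning curves

def test_sf_tuning_peaks_at_preferred():
    w = np.geomspace(0.1, 10, 301)
    for b in (1.0, 2.0, 4.0):
        r = sf_tuning(w, 2.0, b)
        assert w[np.argmax(r)] == pytest.approx(2.0, rel=0.02)
        assert sf_tuning(2.0, 2.0, b) == pytest.approx(1.0)
        assert r.max() <= 1.0 + 1e-12
    assert sf_tuning(1e-6, 2.0, 2.0) < 1e-10
    assert sf_tuning(50.0, 2.0, 2.0) < 1e-10


def test_sf_tuning_narrows_with_order():
    """Higher derivative order means narrower bandwidth (numeric width)."""
    w = np.geomspace(0.1, 10, 2001)

    def halfwidth(b):
        r = sf_tuning(w, 2.0, b)
        above = w[r >= 0.5]
        return np.log2(above.max() / above.min())

    widths = [halfwidth(b) for b in (1.0, 2.0, 4.0, 8.0)]
    assert all(a > b for a, b in zip(widths, widths[1:]))


def test_ori_tuning_properties():
    th = np.arange(0.0, 360.0, 1.0)
    r = ori_tuning(th, 40.0, 0.5, 2.0, 0.4)
    assert th[np.argmax(r)] == pytest.approx(40.0)
    # anti-preferred direction scaled by (1 - d)
    assert ori_tuning(220.0, 40.0, 0.5, 2.0, 0.4) == pytest.approx(
        0.6 * ori_tuning(40.0, 40.0, 0.5, 2.0, 0.4))
    assert ori_tuning(220.0, 40.0, 0.5, 2.0, 1.0) == 0.0
    # alpha = 1 collapses the Gaussian factor to a pure |cos|^b envelope
    r1 = ori_tuning(th, 40.0, 1.0, 3.0, 0.0)
    cosd = np.cos(np.radians(th - 40.0))
    np.testing.assert_allclose(r1, np.abs(cosd) ** 3, atol=1e-12)


# ------------------------------------------------------------------ filters

def test_filters_quadrature_structure():
    nrn = LNLNNeuron(theta0=30.0, omega0=2.0, phase=20.0, alpha=0.6, b=2.0)
    f = make_filters(nrn, GRID)
    assert f.shape == (4, 64, 64)
    np.testing.assert_allclose(f[2], -f[0], atol=1e-12)
    np.testing.assert_allclose(f[3], -f[1], atol=1e-12)
    np.testing.assert_allclose(f.sum(axis=(1, 2)), 0.0, atol=1e-9)
    # energy of the quadrature pair is phase-invariant for gratings
    energies = []
    for ph in np.linspace(0, 2 * np.pi, 12, endpoint=False):
        img = 2 * (grating_image(30.0, 2.0, ph) - 0.5)
        L = np.tensordot(f[:2], img, axes=([1, 2], [0, 1]))
        energies.append(np.sum(L ** 2))
    assert np.ptp(energies) / np.mean(energies) < 0.01


def test_filters_rf_outside_image_raises():
    nrn = LNLNNeuron(rf_center=(5.0, 0.0))
    with pytest.raises(ValueError):
        make_filters(nrn, GRID)


# ------------------------------------------------------------------ respond

def test_blank_image_gives_spontaneous_rate():
    nrn = LNLNNeuron(eps=0.73)
    assert respond(nrn, np.full((64, 64), 0.42), GRID) == 0.73


def test_equal_weights_phase_invariant_image_response():
    """Rectified-squared quadrature channels with equal weights sum to the
    phase-invariant energy; the small residual ripple comes from the
    discrete stimulus (non-integer cycle counts modulate its RMS contrast),
    not from the model."""
    nrn = LNLNNeuron(theta0=0.0, omega0=2.0, weights=[0.25] * 4, eps=0.5,
                     beta=20.0)
    rates = [respond(nrn, grating_image(0.0, 2.0, ph), GRID)
             for ph in np.linspace(0, 2 * np.pi, 8, endpoint=False)]
    assert np.ptp(rates) / np.mean(rates) < 0.03


def test_single_weight_phase_modulated():
    nrn = LNLNNeuron(theta0=0.0, omega0=2.0, weights=[1, 0, 0, 0], eps=0.5,
                     beta=20.0)
    psth = grating_response(nrn, 0.0, 2.0)
    assert f1f0(psth) > 1.0


def test_grating_and_image_domains_agree():
    """Static-frame responses match the frequency-domain formulation."""
    nrn = LNLNNeuron(theta0=30.0, omega0=2.0, alpha=0.6, b=2.0, d=0.0,
                     eps=0.5, beta=30.0)
    for th in (0.0, 30.0, 75.0, 120.0):
        for sf in (1.0, 2.0, 4.0):
            img = np.mean([respond(nrn, grating_image(th, sf, ph), GRID)
                           for ph in np.linspace(0, 2 * np.pi, 8,
                                                 endpoint=False)])
            four = grating_response(nrn, th, sf).mean()
            assert img == pytest.approx(four, rel=0.02, abs=0.02)


def test_contrast_saturation():
    nrn = LNLNNeuron(theta0=0.0, omega0=2.0, eps=0.0, beta=20.0)
    r_full = respond(nrn, grating_image(0.0, 2.0, 0.3, 1.0), GRID)
    r_half = respond(nrn, grating_image(0.0, 2.0, 0.3, 0.5), GRID)
    assert r_full / r_half < 4.0
    no_norm = dissect([nrn], "no-normalization")[0]
    r_full_n = respond(no_norm, grating_image(0.0, 2.0, 0.3, 1.0), GRID)
    r_half_n = respond(no_norm, grating_image(0.0, 2.0, 0.3, 0.5), GRID)
    assert r_full_n / r_half_n == pytest.approx(4.0, rel=1e-6)


# --------------------------------------------------------------------- f1f0

def test_f1f0_reference_waveforms():
    t = np.linspace(0, 1, 2000, endpoint=False)
    assert f1f0(np.full(100, 3.0)) == pytest.approx(0.0, abs=1e-12)
    assert f1f0(1.0 + np.cos(2 * np.pi * t)) == pytest.approx(1.0, rel=1e-6)
    assert f1f0(np.maximum(0.0, np.sin(2 * np.pi * t))) == pytest.approx(
        np.pi / 2, rel=1e-3)
    with pytest.warns(RuntimeWarning):
        assert np.isnan(f1f0(np.zeros(100)))


# ------------------------------------------------------------------ fitting

def test_filter_parameter_recovery():
    """theta0 within 10 degrees, omega0 within half an octave at K=50."""
    rng = np.random.default_rng(0)
    true = LNLNNeuron(theta0=120.0, omega0=1.5, alpha=0.6, b=2.5, d=0.6,
                      eps=1.0, beta=40.0)
    directions = np.arange(0, 360, 22.5)
    sfs = np.geomspace(0.25, 8, 6)
    rates = np.array([[grating_response(true, th, sf).mean() for sf in sfs]
                      for th in directions])
    g = np.exp(-0.05 + np.sqrt(0.1)
               * rng.standard_normal(rates.shape + (50,)))
    counts = rng.poisson(rates[:, :, None] * g)
    fitted = fit_filter_params(counts, directions, sfs, seed=1, n_starts=6,
                               maxiter=300)
    dtheta = abs((fitted.theta0 - true.theta0 + 180) % 360 - 180)
    assert dtheta < 10.0
    assert abs(np.log2(fitted.omega0 / true.omega0)) < 0.5


def test_filter_fit_determinism_and_silent_unit():
    rng = np.random.default_rng(1)
    directions = np.arange(0, 360, 45.0)
    sfs = np.geomspace(0.5, 4, 3)
    true = LNLNNeuron(theta0=45.0, omega0=1.0, eps=0.5, beta=20.0)
    rates = np.array([[grating_response(true, th, sf).mean() for sf in sfs]
                      for th in directions])
    counts = rng.poisson(np.repeat(rates[:, :, None], 10, axis=2))
    a = fit_filter_params(counts, directions, sfs, seed=3, n_starts=3,
                          maxiter=120)
    b = fit_filter_params(counts, directions, sfs, seed=3, n_starts=3,
                          maxiter=120)
    assert a.theta0 == b.theta0 and a.omega0 == b.omega0
    with pytest.raises(ValueError, match="silent"):
        fit_filter_params(np.zeros((8, 3, 10), dtype=int), directions, sfs)


@pytest.mark.parametrize("weights", [
    [1.0, 0.0, 0.0, 0.0],
    [0.25, 0.25, 0.25, 0.25],
    [0.5, 0.3, 0.1, 0.1],
])
def test_pooling_weight_recovery(weights):
    true = LNLNNeuron(weights=weights, eps=1.0, beta=40.0)
    psth = psth_to_grating(true)
    if np.ptp(psth) < 1e-8:
        with pytest.warns(RuntimeWarning):
            fitted = fit_pooling_weights(true, psth)
    else:
        fitted = fit_pooling_weights(true, psth)
    np.testing.assert_allclose(fitted.weights, weights, atol=0.02)
    assert fitted.weights.sum() == pytest.approx(1.0)
    assert np.all(fitted.weights >= 0)


def test_rf_center_recovery(rng):
    pos = np.array([(y, x) for y in np.linspace(-1, 1, 9)
                    for x in np.linspace(-1, 1, 9)])
    resp = 2 + 8 * np.exp(-((pos[:, 0] - 0.3) ** 2
                            + (pos[:, 1] + 0.2) ** 2) / (2 * 0.3 ** 2))
    resp = resp + 0.3 * rng.standard_normal(len(pos))
    cy, cx = rf_center(pos, resp)
    assert abs(cy - 0.3) < 0.25 and abs(cx + 0.2) < 0.25
    # symmetric profile centered at origin
    resp_sym = np.exp(-(pos ** 2).sum(axis=1) / 0.5)
    cy0, cx0 = rf_center(pos, resp_sym)
    assert abs(cy0) < 1e-6 and abs(cx0) < 1e-6


# ------------------------------------------------------------------ dissect

def test_dissect_rules():
    rng = np.random.default_rng(5)
    neurons = [LNLNNeuron(weights=np.diag([1.0] * 4)[i] * 0.7 + 0.075,
                          theta0=45.0 * i) for i in range(4)]
    comp = dissect(neurons, "all-complex")
    assert all(np.allclose(n.weights, 0.25) for n in comp)
    simp = dissect(neurons, "all-simple")
    for orig, s in zip(neurons, simp):
        assert np.argmax(s.weights) == np.argmax(orig.weights)
        assert sorted(s.weights) == [0.0, 0.0, 0.0, 1.0]
    nn = dissect(neurons, "no-normalization")
    assert all(not n.normalize for n in nn)
    assert all(n.normalize for n in neurons)  # originals untouched
    with pytest.raises(ValueError):
        dissect(neurons, "half-wave")


def test_all_complex_phase_invariance_and_all_simple_modulation():
    neurons = [LNLNNeuron(theta0=t, omega0=2.0,
                          weights=[0.6, 0.2, 0.1, 0.1])
               for t in (0.0, 45.0)]
    for n in dissect(neurons, "all-complex"):
        psth = grating_response(n, n.theta0, n.omega0)
        assert np.ptp(psth) / np.mean(psth) < 0.01
    for n in dissect(neurons, "all-simple"):
        assert f1f0(grating_response(n, n.theta0, n.omega0)) > 1.0


# ------------------------------------------------------------ population

def test_predict_population_curvature_deterministic_and_shaped():
    rng = np.random.default_rng(6)
    neurons = [LNLNNeuron(theta0=rng.uniform(0, 180),
                          omega0=float(rng.uniform(0.8, 3.0)),
                          rf_center=(float(rng.uniform(-0.3, 0.3)),
                                     float(rng.uniform(-0.3, 0.3))),
                          eps=0.5, beta=20.0)
               for _ in range(6)]
    gains = GainCovariance.shared(6, 0.09, 0.01, rank=1)
    seq = synthesize_clip(3, 5, shape=(64, 64))
    out1 = predict_population_curvature(neurons, seq, gains)
    out2 = predict_population_curvature(neurons, seq, gains)
    assert out1["c_model_deg"] == out2["c_model_deg"]
    assert out1["rates"].shape == (5, 6)
    assert 0.0 <= out1["c_model_deg"] <= 180.0
    assert out1["relative_deg"] == pytest.approx(
        out1["c_model_deg"] - out1["c_pixel_deg"])


def test_complex_population_entangles_fades():
    """Fades are straight in pixels but typically curved for a nonlinear
    complex-cell population (the entangling direction)."""
    rng = np.random.default_rng(7)
    votes = 0
    for seed in range(3):
        neurons = [LNLNNeuron(theta0=rng.uniform(0, 180),
                              omega0=float(rng.uniform(0.8, 3.0)),
                              weights=[0.25] * 4, eps=0.5, beta=20.0)
                   for _ in range(8)]
        gains = GainCovariance.shared(8, 0.09, 0.01, rank=1)
        fade = make_fade(synthesize_clip(seed, 5, shape=(64, 64)))
        out = predict_population_curvature(neurons, fade, gains)
        if out["relative_deg"] > 0:
            votes += 1
    assert votes >= 2
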