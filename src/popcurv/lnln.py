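"""Image-computable LN-LN cascade model of V1 neurons.

A static grayscale image is processed by four oriented Gaussian-derivative
filters in quadrature (phases 90 degrees apart), identical in orientation
and spatial-frequency tuning.  Filter outputs are half-wave rectified and
squared, linearly pooled with non-negative weights summing to one, and
divisively normalized by a constant plus the stimulus's root-mean-square
contrast; a spontaneous rate and a response scalar map the result to spikes
per window.  The pooling weights set the cell's phase sensitivity: equal
weights give a phase-invariant complex cell (F1/F0 < 1), a single weight a
phase-modulated simple cell.

The model has 11 free parameters: preferred orientation, spatial frequency
and phase, aspect ratio, derivative order, direction selectivity, three
free pooling weights, spontaneous rate and response scale.  Filter and
response-range parameters are fit to drifting-grating responses by maximum
likelihood under the modulated Poisson spike-count model; pooling weights by
least squares on the temporal response modulation to the preferred grating;
the receptive-field center by a 2-D Gaussian fit to sparse-bar responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit, minimize
from scipy.special import gammaln

from . import geometry
from .fisher_embedding import embed
from .stimuli import FrameSequence

__all__ = ["LNLNNeuron", "PixelGrid", "sf_tuning", "ori_tuning",
           "make_filters", "respond", "grating_response", "psth_to_grating",
           "fit_filter_params", "fit_pooling_weights", "rf_center", "f1f0",
           "predict_population_curvature", "dissect"]

SIGMA_NORM = 0.15  # stimulus-independent normalization constant


@dataclass
class PixelGrid:
    """Mapping between image pixels and degrees of visual angle."""

    shape: tuple = (64, 64)
    deg_per_pixel: float = 0.05

    def coords(self):
        """Pixel-center coordinates (degrees), origin at the image center."""
        H, W = self.shape
        y = (np.arange(H) - (H - 1) / 2) * self.deg_per_pixel
        x = (np.arange(W) - (W - 1) / 2) * self.deg_per_pixel
        return np.meshgrid(y, x, indexing="ij")

    @property
    def extent_deg(self):
        return (self.shape[0] * self.deg_per_pixel,
                self.shape[1] * self.deg_per_pixel)


@dataclass
class LNLNNeuron:
    """Parameters of one LN-LN cascade neuron.

    Orientation ``theta0`` and phase are degrees; ``omega0`` is cycles per
    degree; ``weights`` lie on the simplex; ``d`` in [0, 1] scales the
    anti-preferred direction by (1 - d); ``eps`` is the spontaneous rate and
    ``beta`` the response scale (spikes per counting window); ``rf_center``
    is in degrees of visual angle.  ``normalize=False`` removes the divisive
    normalization (denominator set to one), used by model dissection.
    """

    theta0: float = 0.0
    omega0: float = 2.0
    phase: float = 0.0
    alpha: float = 0.5
    b: float = 2.0
    d: float = 0.0
    weights: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    eps: float = 0.5
    beta: float = 30.0
    rf_center: tuple = (0.0, 0.0)
    sigma_norm: float = SIGMA_NORM
    normalize: bool = True

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (4,) or np.any(self.weights < -1e-9):
            raise ValueError("need 4 non-negative pooling weights")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("pooling weights must sum to one")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("direction selectivity d must lie in [0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("aspect ratio alpha must lie in (0, 1]")
        if self.b < 1.0 or self.omega0 <= 0:
            raise ValueError("derivative order must be >= 1 and omega0 > 0")


# ------------------------------------------------------------- tuning curves

def sf_tuning(omega, omega0: float, b: float):
    """Relative spatial-frequency tuning, peak-normalized to one.

    Proportional to ``[(w/w0) exp(-(w/w0)^2 / 2)]^b``; the peak sits at
    ``omega0`` for every derivative order b, and larger b narrows the curve.
    """
    omega = np.asarray(omega, dtype=float)
    x = omega / omega0
    peak = np.exp(-0.5)  # value of x e^{-x^2/2} at x = 1
    return (x * np.exp(-0.5 * x ** 2) / peak) ** b


def ori_tuning(theta_deg, theta0: float, alpha: float, b: float, d: float):
    """Relative orientation/direction tuning.

    The orientation envelope is ``[cos(dt) exp(-(1 - alpha^2) cos^2(dt)/2)]^b``
    (dt the angle to the preferred direction, response zero beyond +/-90
    degrees); the anti-preferred direction is scaled by ``(1 - d)``.
    Peak-normalized to one at the preferred direction.
    """
    dt = np.radians(np.asarray(theta_deg, dtype=float) - theta0)
    cosd = np.cos(dt)
    env = np.where(np.abs(cosd) > 0,
                   (np.abs(cosd)
                    * np.exp(-0.5 * (1 - alpha ** 2) * cosd ** 2)) ** b, 0.0)
    env = env / np.exp(-0.5 * (1 - alpha ** 2)) ** b
    dir_factor = 1.0 + 0.5 * d * (np.sign(cosd) - 1.0)
    return env * dir_factor


# ------------------------------------------------------------------ filters

def make_filters(neuron: LNLNNeuron, grid: PixelGrid) -> np.ndarray:
    """The quadrature set of four spatial filters on the pixel grid.

    Filters are constructed from the one-sided Fourier amplitude spectrum
    implied by the neuron's tuning (so grating responses match the
    frequency-domain formulation by construction), shifted to the
    receptive-field center, at phases phi, phi+90, phi+180 and phi+270.
    Each filter is zero-mean, and is normalized so a full-contrast preferred
    grating at the matched phase drives a unit linear response.
    """
    H, W = grid.shape
    cy, cx = neuron.rf_center
    half_h = grid.extent_deg[0] / 2
    half_w = grid.extent_deg[1] / 2
    if not (-half_h <= cy <= half_h and -half_w <= cx <= half_w):
        raise ValueError("receptive-field center lies outside the image")
    fy = np.fft.fftfreq(H, d=grid.deg_per_pixel)[:, None]
    fx = np.fft.fftfreq(W, d=grid.deg_per_pixel)[None, :]
    omega = np.hypot(fy, fx)
    ang = np.degrees(np.arctan2(fy, fx))
    with np.errstate(invalid="ignore"):
        amp = np.where(omega > 0,
                       sf_tuning(np.where(omega > 0, omega, 1.0),
                                 neuron.omega0, neuron.b), 0.0)
    # one-sided orientation lobe (direction selectivity is temporal and does
    # not enter the static spatial filter)
    dtheta = np.radians(ang - neuron.theta0)
    cosd = np.cos(dtheta)
    lobe = np.where(cosd > 1e-12,
                    (np.maximum(cosd, 0.0)
                     * np.exp(-0.5 * (1 - neuron.alpha ** 2) * cosd ** 2))
                    ** neuron.b, 0.0)
    lobe = lobe / np.exp(-0.5 * (1 - neuron.alpha ** 2)) ** neuron.b
    spectrum = amp * lobe
    # place the kernel at the RF center (the raw inverse FFT centers it on
    # the first pixel, so shift by the image half-extent as well)
    y0 = cy + (H - 1) / 2 * grid.deg_per_pixel
    x0 = cx + (W - 1) / 2 * grid.deg_per_pixel
    ramp = np.exp(2j * np.pi * (fy * y0 + fx * x0))
    kernel = np.fft.ifft2(spectrum * ramp)
    # normalize: unit quadrature response to a full-contrast preferred grating
    yy, xx = grid.coords()
    th = np.radians(neuron.theta0)
    arg = 2 * np.pi * neuron.omega0 * ((yy - cy) * np.sin(th)
                                       + (xx - cx) * np.cos(th))
    g = np.cos(arg)
    energy = np.hypot(np.sum(np.real(kernel) * g),
                      np.sum(-np.imag(kernel) * g))
    kernel = kernel / (energy + 1e-30)
    phases = np.radians(neuron.phase) + np.array([0, 0.5, 1.0, 1.5]) * np.pi
    filters = np.stack([np.real(np.exp(1j * ph) * kernel) for ph in phases])
    return filters - filters.mean(axis=(1, 2), keepdims=True)


def _contrast_image(image: np.ndarray) -> np.ndarray:
    """Signed contrast pattern: a full-range grating maps to amplitude 1."""
    image = np.asarray(image, dtype=float)
    return 2.0 * (image - image.mean())


def _rate_from_channels(neuron: LNLNNeuron, L: np.ndarray, c_rms):
    num = np.sum(neuron.weights * np.maximum(0.0, L) ** 2, axis=-1)
    if neuron.normalize:
        den = neuron.sigma_norm ** 2 + np.asarray(c_rms) ** 2
    else:
        den = 1.0
    return neuron.eps + neuron.beta * num / den


def respond(neuron: LNLNNeuron, image: np.ndarray,
            grid: PixelGrid | None = None) -> float:
    """Firing rate of the neuron to a static grayscale image in [0, 1].

    The image is converted to a signed contrast pattern, cross-correlated
    with the quadrature filters at the RF center, and the channel responses
    are rectified, squared, pooled and divisively normalized; a blank image
    returns exactly the spontaneous rate.
    """
    image = np.asarray(image, dtype=float)
    if grid is None:
        grid = PixelGrid(shape=image.shape)
    filters = make_filters(neuron, grid)
    contrast = _contrast_image(image)
    L = np.tensordot(filters, contrast, axes=([1, 2], [0, 1]))
    c_rms = np.sqrt(np.mean(contrast ** 2))
    return float(_rate_from_channels(neuron, L, c_rms))


# ------------------------------------------------- frequency-domain gratings

def grating_response(neuron: LNLNNeuron, direction_deg: float, sf: float,
                     contrast: float = 1.0, n_phases: int = 64):
    """Response time course to one cycle of a drifting grating.

    Channel responses follow the closed-form tuning (spatial frequency,
    orientation envelope and direction selectivity); the grating's phase
    advances through a full cycle in ``n_phases`` steps.  Returns the
    (n_phases,) firing-rate waveform; its mean is the tuning-curve value
    and its first harmonic the temporal modulation.
    """
    amp = (contrast * sf_tuning(sf, neuron.omega0, neuron.b)
           * ori_tuning(direction_deg, neuron.theta0, neuron.alpha,
                        neuron.b, neuron.d))
    psi = 2 * np.pi * np.arange(n_phases) / n_phases
    phases = np.radians(neuron.phase) + np.array([0, 0.5, 1.0, 1.5]) * np.pi
    L = amp * np.cos(psi[:, None] - phases[None, :])
    c_rms = contrast / np.sqrt(2.0)
    return _rate_from_channels(neuron, L, c_rms)


def psth_to_grating(neuron: LNLNNeuron, direction_deg: float = None,
                    sf: float = None, contrast: float = 1.0,
                    n_bins: int = 80):
    """PSTH (rate per bin) over one cycle of the (by default preferred)
    drifting grating, at the 12.5 ms-style binning used for weight fits."""
    if direction_deg is None:
        direction_deg = neuron.theta0
    if sf is None:
        sf = neuron.omega0
    return grating_response(neuron, direction_deg, sf, contrast,
                            n_phases=n_bins)


def f1f0(psth, n_cycles: int = 1) -> float:
    """Temporal-modulation index of a PSTH spanning whole grating cycles.

    Ratio of the first-harmonic amplitude (at the grating's temporal
    frequency) to the mean rate; below one indicates phase-invariant
    (complex) responses, above one phase-modulated (simple) responses.
    """
    psth = np.asarray(psth, dtype=float)
    f0 = psth.mean()
    if f0 <= 0:
        warnings.warn("zero mean rate: F1/F0 undefined", RuntimeWarning,
                      stacklevel=2)
        return np.nan
    t = np.arange(len(psth)) / len(psth)
    f1 = 2.0 * np.abs(np.mean(psth * np.exp(-2j * np.pi * n_cycles * t)))
    return float(f1 / f0)


# ------------------------------------------------------------------ fitting

def _mod_poisson_loglik(counts, rates, gain_var: float = 0.1,
                        n_nodes: int = 15) -> float:
    """Single-unit modulated Poisson log-likelihood (log-normal gain)."""
    counts = np.asarray(counts, dtype=float)
    rates = np.maximum(np.asarray(rates, dtype=float), 1e-9)
    h, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / w.sum()
    delta = -0.5 * gain_var + np.sqrt(gain_var) * h          # (Q,)
    eta = np.log(rates)[..., None] + delta                   # (..., Q)
    logpmf = (counts[..., None] * eta - np.exp(eta)
              - gammaln(counts + 1.0)[..., None])
    m = logpmf.max(axis=-1, keepdims=True)
    return float(np.sum(m[..., 0] + np.log(np.sum(w * np.exp(logpmf - m),
                                                  axis=-1))))


def _tuning_grid_rates(neuron, directions, sfs, contrast=1.0,
                       n_phases: int = 32):
    """Mean-rate predictions over the direction x spatial-frequency grid."""
    amp = (contrast
           * ori_tuning(directions, neuron.theta0, neuron.alpha, neuron.b,
                        neuron.d)[:, None]
           * sf_tuning(sfs, neuron.omega0, neuron.b)[None, :])
    psi = 2 * np.pi * np.arange(n_phases) / n_phases
    phases = np.radians(neuron.phase) + np.array([0, 0.5, 1.0, 1.5]) * np.pi
    L = amp[:, :, None, None] * np.cos(psi[None, None, :, None]
                                       - phases[None, None, None, :])
    num = np.sum(neuron.weights * np.maximum(0.0, L) ** 2, axis=-1)
    den = (neuron.sigma_norm ** 2 + (contrast / np.sqrt(2.0)) ** 2
           if neuron.normalize else 1.0)
    return neuron.eps + neuron.beta * num.mean(axis=-1) / den


def fit_filter_params(counts, directions, sfs, seed: int = 0,
                      n_starts: int = 10, gain_var: float = 0.1,
                      maxiter: int = 400) -> LNLNNeuron:
    """Fit filter and response-range parameters to grating responses.

    ``counts`` is (n_directions, n_sfs, K): spike counts per presentation of
    each drifting grating.  Maximizes the modulated Poisson likelihood of
    the mean-rate predictions over (theta0, omega0, b, alpha, d, eps, beta)
    with equal pooling weights, using multi-start Nelder-Mead simplex with
    semi-randomized starting values.  Deterministic given ``seed``.
    """
    counts = np.asarray(counts)
    if counts.ndim != 3:
        raise ValueError("counts must be (n_directions, n_sfs, n_trials)")
    mean_counts = counts.mean(axis=2)
    if mean_counts.max() <= 0:
        raise ValueError("silent unit: cannot fit grating parameters")
    directions = np.asarray(directions, dtype=float)
    sfs = np.asarray(sfs, dtype=float)
    rng = np.random.default_rng(seed)

    def unpack(x):
        return LNLNNeuron(
            theta0=x[0] % 360.0,
            omega0=float(np.exp(np.clip(x[1], -3, 4))),
            b=1.0 + float(np.exp(np.clip(x[2], -6, 3))),
            alpha=float(1.0 / (1.0 + np.exp(-x[3]))),
            d=float(1.0 / (1.0 + np.exp(-x[4]))),
            eps=float(np.exp(np.clip(x[5], -8, 6))),
            beta=float(np.exp(np.clip(x[6], -8, 10))))

    def nll(x):
        neuron = unpack(x)
        rates = _tuning_grid_rates(neuron, directions, sfs)
        return -_mod_poisson_loglik(counts, rates[:, :, None], gain_var)

    # semi-randomized starts around the empirically best grating
    i0, j0 = np.unravel_index(np.argmax(mean_counts), mean_counts.shape)
    peak = max(mean_counts.max(), 0.5)
    base = max(np.median(mean_counts), 0.05)
    starts = []
    for k in range(n_starts):
        starts.append(np.array([
            directions[i0] + (0 if k < 2 else rng.uniform(-60, 60)),
            np.log(sfs[j0]) + (0 if k % 2 == 0 else rng.uniform(-0.7, 0.7)),
            np.log(rng.uniform(0.5, 3.0)),
            rng.uniform(-1, 1),
            rng.uniform(-2, 0),
            np.log(base),
            np.log(max(peak - base, 0.1) * 4.0 * rng.uniform(0.5, 2.0)),
        ]))
    best, best_val = None, np.inf
    for x0 in starts:
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-3,
                                "fatol": 1e-3})
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    return unpack(best)


def _project_simplex(w: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(w)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / (np.arange(len(w)) + 1) > 0)[0][-1]
    return np.maximum(w - css[rho] / (rho + 1.0), 0.0)


def fit_pooling_weights(neuron: LNLNNeuron, psth,
                        flat_tol: float = 1e-8) -> LNLNNeuron:
    """Fit the four pooling weights to the temporal response modulation.

    ``psth`` is the firing-rate waveform over whole cycles of the preferred
    drifting grating (12.5 ms-scale bins).  Each channel's rectified-squared
    waveform forms a regression basis; least-squares weights are projected
    onto the simplex.  A flat PSTH is uninformative and yields equal
    weights.
    """
    psth = np.asarray(psth, dtype=float)
    n_bins = len(psth)
    if np.ptp(psth) < flat_tol:
        warnings.warn("flat temporal modulation: defaulting to equal "
                      "pooling weights", RuntimeWarning, stacklevel=2)
        return replace(neuron, weights=np.full(4, 0.25))
    # per-channel rate waveforms at the preferred grating
    amp = sf_tuning(neuron.omega0, neuron.omega0, neuron.b) \
        * ori_tuning(neuron.theta0, neuron.theta0, neuron.alpha,
                     neuron.b, neuron.d)
    psi = 2 * np.pi * np.arange(n_bins) / n_bins
    phases = np.radians(neuron.phase) + np.array([0, 0.5, 1.0, 1.5]) * np.pi
    L = amp * np.cos(psi[:, None] - phases[None, :])
    den = (neuron.sigma_norm ** 2 + 0.5) if neuron.normalize else 1.0
    basis = neuron.beta * np.maximum(0.0, L) ** 2 / den
    target = psth - neuron.eps
    w, *_ = np.linalg.lstsq(basis, target, rcond=None)
    return replace(neuron, weights=_project_simplex(w))


def rf_center(positions, responses, polarities=None):
    """Receptive-field center from sparse-bar responses.

    Fits a 2-D Gaussian (pooled over bar polarities) to the spatial response
    profile; ``positions`` is (n, 2) in degrees, ``responses`` the mean
    rates.  Falls back to the response-weighted centroid if the fit does not
    converge.
    """
    positions = np.asarray(positions, dtype=float)
    responses = np.asarray(responses, dtype=float)

    def gauss2d(pos, amp, y0, x0, sy, sx, base):
        y, x = pos
        return base + amp * np.exp(-0.5 * (((y - y0) / sy) ** 2
                                           + ((x - x0) / sx) ** 2))

    w = np.maximum(responses - responses.min(), 0)
    centroid = (w @ positions) / max(w.sum(), 1e-12)
    try:
        span = np.ptp(positions, axis=0).max()
        p0 = [np.ptp(responses), centroid[0], centroid[1],
              span / 4, span / 4, responses.min()]
        popt, _ = curve_fit(gauss2d, (positions[:, 0], positions[:, 1]),
                            responses, p0=p0, maxfev=5000)
        return float(popt[1]), float(popt[2])
    except RuntimeError:
        warnings.warn("2-D Gaussian fit did not converge: using centroid",
                      RuntimeWarning, stacklevel=2)
        return float(centroid[0]), float(centroid[1])


# --------------------------------------------------------- population level

def predict_population_curvature(neurons, seq: FrameSequence, gains,
                                 grid: PixelGrid | None = None):
    """Model-predicted curvature of the population trajectory for a clip.

    Each neuron responds to each frame; the rate trajectory is passed
    through the same variance-stabilizing transform as the recorded data
    and its discrete curvature computed.  Returns a dict with the model
    curvature, the pixel curvature, and their difference (the model's
    relative curvature; the stimulus-computable pipeline has no estimation
    bias, so the pixel value plays the role of the null expectation).
    """
    from .stimuli import pixel_curvature

    if grid is None:
        grid = PixelGrid(shape=seq.frame_shape)
    filters = np.stack([make_filters(nrn, grid) for nrn in neurons])
    rates = np.empty((seq.n_frames, len(neurons)))
    for t, frame in enumerate(seq.frames):
        contrast = _contrast_image(frame)
        c_rms = np.sqrt(np.mean(contrast ** 2))
        L = np.tensordot(filters, contrast, axes=([2, 3], [0, 1]))
        rates[t] = [float(_rate_from_channels(nrn, L[j], c_rms))
                    for j, nrn in enumerate(neurons)]
    c_model = geometry.global_curvature(embed(rates, gains).points)
    c_pix, _ = pixel_curvature(seq)
    return {"c_model_deg": float(c_model), "c_pixel_deg": float(c_pix),
            "relative_deg": float(c_model - c_pix), "rates": rates}


def dissect(neurons, variant: str):
    """Restricted model variants for dissecting the cascade.

    ``no-normalization`` sets the divisive denominator to one;
    ``all-complex`` sets every pooling weight to 0.25 (phase-invariant);
    ``all-simple`` sets each cell's highest pooling weight to one and the
    others to zero.  Returns modified copies; the originals are untouched.
    """
    if variant == "no-normalization":
        return [replace(n, normalize=False) for n in neurons]
    if variant == "all-complex":
        return [replace(n, weights=np.full(4, 0.25)) for n in neurons]
    if variant == "all-simple":
        out = []
        for n in neurons:
            w = np.zeros(4)
            w[int(np.argmax(n.weights))] = 1.0
            out.append(replace(n, weights=w))
        return out
    raise ValueError(f"unknown variant: {variant!r}")
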