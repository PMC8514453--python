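"""Fisher-metric embedding of rate trajectories.

Under the modulated Poisson model with independent gain per neuron, the
Fisher information about the rate of unit i is ``1 / (lambda_i + sigma_i^2
lambda_i^2)``, where ``sigma_i^2`` is the gain variance.  The
variance-stabilizing transform

    y = (2 / sigma) * asinh(sigma * sqrt(lambda))

maps rates into coordinates whose Fisher information is unity everywhere, so
Euclidean distances between transformed rate vectors measure discriminability
in units of d'.  As the gain variance vanishes this reduces to the classical
Poisson stabilizer ``y = 2 sqrt(lambda)``.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import _ad as ad

__all__ = ["fisher_diag", "stabilize", "unstabilize", "embed",
           "EmbeddedTrajectory"]

_SIGMA_TINY = 1e-6


def fisher_diag(lam, sigma_sq):
    """Diagonal Fisher-metric entries 1/(lambda + sigma^2 lambda^2).

    Zero rates carry infinite information about themselves; those entries are
    returned as ``+inf`` with a warning.
    """
    lam = np.asarray(lam, dtype=float)
    sigma_sq = np.asarray(sigma_sq, dtype=float)
    if np.any(lam < 0) or np.any(sigma_sq < 0):
        raise ValueError("rates and gain variances must be non-negative")
    denom = lam + sigma_sq * lam ** 2
    if np.any(denom == 0):
        warnings.warn("zero rate: Fisher information is infinite there",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore"):
        return np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0), np.inf)


def stabilize(lam, sigma):
    """Variance-stabilized coordinate y = (2/sigma) asinh(sigma sqrt(lambda)).

    ``sigma`` may be a scalar or broadcastable array of per-unit gain
    standard deviations; ``sigma -> 0`` uses the limit ``2 sqrt(lambda)``.
    """
    lam = np.asarray(lam, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(lam < 0):
        raise ValueError("rates must be non-negative")
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    root = np.sqrt(lam)
    small = sigma < _SIGMA_TINY
    sig = np.where(small, 1.0, sigma)
    return np.where(small, 2.0 * root, 2.0 / sig * np.arcsinh(sig * root))


def unstabilize(y, sigma):
    """Exact inverse of :func:`stabilize`: lambda = [sinh(sigma y / 2)/sigma]^2.

    Accepts autodiff tensors for ``y`` (used inside the variational decoder);
    ``sigma`` must then be strictly positive constants.
    """
    if isinstance(y, ad.Tensor):
        return ad.square(ad.sinh(ad.mul(y, sigma / 2.0)) / sigma)
    y = np.asarray(y, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    small = sigma < _SIGMA_TINY
    sig = np.where(small, 1.0, sigma)
    return np.where(small, (y / 2.0) ** 2, (np.sinh(sig * y / 2.0) / sig) ** 2)


class EmbeddedTrajectory:
    """Variance-stabilized rate trajectory.

    Attributes
    ----------
    points : (T+1, D) stabilized coordinates; Euclidean distances between
        rows approximate the discriminability (d') of the corresponding
        response distributions.
    sigma : (D,) per-unit gain standard deviations used in the transform.
    """

    def __init__(self, points: np.ndarray, sigma: np.ndarray):
        self.points = np.asarray(points, dtype=float)
        self.sigma = np.asarray(sigma, dtype=float)

    def rates(self) -> np.ndarray:
        """Invert the embedding back to rates, (T+1, D)."""
        return unstabilize(self.points, self.sigma)

    def distances(self) -> np.ndarray:
        """Successive-point Euclidean distances (d' units)."""
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)


def embed(rates, gains) -> EmbeddedTrajectory:
    """Embed a rate trajectory so distances equal discriminability.

    Parameters
    ----------
    rates : (T+1, D) non-negative rate vectors per frame.
    gains : :class:`popcurv.response_model.GainCovariance`; only the diagonal
        of its log-gain covariance enters (the independent-gain
        approximation), via ``sigma_i^2 = exp([Sigma_eps]_ii) - 1``.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    sigma = np.sqrt(gains.gain_variances())
    return EmbeddedTrajectory(stabilize(rates, sigma[None, :]), sigma)
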