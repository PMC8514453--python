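"""Curvature under the full Fisher metric, without the independent-gain
closed form.

Local discriminability between nearby rate vectors is the Mahalanobis
distance under the average of their model-predicted spike-count covariances.
For distant rate vectors, discriminability is the geodesic distance: the
minimal summed local distance over discretized paths through rate space.
Converting the geodesic distances between successive frames (and frames once
removed) to angles via the law of cosines yields a curvature estimate that
does not rely on the diagonal (independent-gain) approximation.  With the
covariances restricted to their diagonal, this numerical estimate coincides
with the closed-form variance-stabilized embedding, which is the check that
justifies using the analytic transform everywhere else.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import _ad as ad
from ._optim import Adam
from .fisher_embedding import stabilize
from .geometry import angle_from_distances
from .response_model import GainCovariance

__all__ = ["fisher_distance", "geodesic_distance", "numerical_curvature"]


def _count_covariances(lam, Sg, mode: str):
    """Model-predicted spike-count covariances for rate rows (I, D).

    Returns (I, D, D) in full mode or the diagonal (I, D) in diag mode.
    Accepts autodiff tensors for ``lam``.
    """
    if mode == "diag":
        return ad.add(lam, ad.mul(ad.square(lam), np.diag(Sg)))
    eye = np.eye(np.asarray(Sg).shape[0])
    lam_i = ad.reshape(lam, ad.value(lam).shape + (1,))
    lam_j = ad.reshape(lam, ad.value(lam).shape[:-1] + (1,) + (ad.value(lam).shape[-1],))
    outer = ad.mul(lam_i, lam_j)
    return ad.add(ad.mul(eye, lam_i), ad.mul(Sg, outer))


def _segment_lengths(lam, Sg, mode: str, ridge: float = 0.0):
    """d' lengths of the I segments of a path of rate rows (I+1, D)."""
    cov = _count_covariances(lam, Sg, mode)
    delta = ad.sub(lam[1:], lam[:-1])
    if mode == "diag":
        m = ad.mul(ad.add(cov[1:], cov[:-1]), 0.5)
        d2 = ad.sum(ad.div(ad.square(delta), ad.add(m, ridge)), axis=-1)
    else:
        m = ad.mul(ad.add(cov[1:], cov[:-1]), 0.5)
        if ridge:
            m = ad.add(m, ridge * np.eye(ad.value(delta).shape[-1]))
        x = ad.solve(m, delta)
        d2 = ad.sum(ad.mul(delta, x), axis=-1)
    return ad.sqrt(ad.add(d2, 1e-18))


def fisher_distance(lam_a, lam_b, gains: GainCovariance,
                    mode: str = "full") -> float:
    """Local Fisher discriminability (d') between two nearby rate vectors.

    ``d^2 = (lam_a - lam_b)^T [ (Sigma_a + Sigma_b)/2 ]^{-1} (lam_a - lam_b)``
    with the spike-count covariances predicted by the modulated Poisson
    model.  ``mode='diag'`` keeps only the covariance diagonals
    (independent-gain approximation).  Valid as a discriminability measure
    only locally; use :func:`geodesic_distance` for distant vectors.
    """
    if mode not in ("full", "diag"):
        raise ValueError("mode must be 'full' or 'diag'")
    lam = np.stack([np.asarray(lam_a, float), np.asarray(lam_b, float)])
    if np.any(lam < 0):
        raise ValueError("rates must be non-negative")
    Sg = gains.gain_covariance()
    ridge = 0.0
    if mode == "full":
        cov = np.asarray(ad.value(_count_covariances(lam, Sg, "full")))
        m = 0.5 * (cov[0] + cov[1])
        if np.linalg.cond(m) > 1e12 or not np.all(np.isfinite(np.linalg.cond(m))):
            ridge = 1e-8 * max(np.trace(m) / len(m), 1.0)
            warnings.warn("singular averaged covariance: ridge-regularized",
                          RuntimeWarning, stacklevel=2)
    elif np.any((lam[0] == 0) & (lam[1] == 0)):
        ridge = 1e-12
    return float(ad.value(_segment_lengths(lam, Sg, mode, ridge))[0])


def geodesic_distance(lam_a, lam_b, gains: GainCovariance,
                      n_segments: int = 20, mode: str = "full",
                      n_iter: int = 200, lr: float = 0.05) -> float:
    """Geodesic discriminability between two rate vectors.

    A discretized path of ``n_segments`` steps from ``lam_a`` to ``lam_b``
    is optimized (interior points free, endpoints fixed) to minimize the
    summed local Fisher lengths.  The path is parameterized in
    variance-stabilized coordinates, which keeps rates non-negative and
    makes the straight chord the exact geodesic in diag mode; optimization
    uses adaptive-moment gradient descent on the path length.  If the
    optimizer fails to improve on the initial chord, the chord length is
    returned.
    """
    if n_segments < 2:
        raise ValueError("need at least 2 path segments")
    lam_a = np.asarray(lam_a, dtype=float)
    lam_b = np.asarray(lam_b, dtype=float)
    if np.allclose(lam_a, lam_b):
        return 0.0
    Sg = gains.gain_covariance()
    sigma = np.maximum(np.sqrt(gains.gain_variances()), 1e-9)
    u_a, u_b = stabilize(lam_a, sigma), stabilize(lam_b, sigma)
    w = np.linspace(0.0, 1.0, n_segments + 1)[1:-1, None]
    u_init = (1 - w) * u_a + w * u_b

    def path_length(u_interior):
        u = ad.concatenate([u_a[None], u_interior, u_b[None]], axis=0)
        lam = ad.square(ad.div(ad.sinh(ad.mul(u, sigma / 2.0)), sigma))
        return ad.sum(_segment_lengths(lam, Sg, mode))

    chord = float(ad.value(path_length(u_init)))
    opt = Adam({"u": u_init}, lr=lr)
    best = chord
    best_u = u_init.copy()
    for _ in range(n_iter):
        u = ad.Tensor(opt.params["u"], requires_grad=True)
        length = path_length(u)
        ad.backward(length)
        opt.step({"u": u.grad})
        val = float(ad.value(length))
        if val < best:
            best, best_u = val, opt.params["u"].copy()
    return min(best, float(ad.value(path_length(best_u))))


def numerical_curvature(rates, gains: GainCovariance, mode: str = "full",
                        n_segments: int = 20, n_iter: int = 200):
    """Global curvature of a rate trajectory under the Fisher metric.

    Computes geodesic distances between all successive rate vectors and all
    vectors once removed, converts each triple to a turning angle with the
    law of cosines, and returns ``(global_deg, locals_deg)``.  Triangle
    violations from finite optimizer tolerance are clipped to the degenerate
    angle with a warning; violations beyond 5% raise.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    F = rates.shape[0]
    if F < 3:
        raise ValueError("curvature needs at least 3 frames")
    d1 = [geodesic_distance(rates[t], rates[t + 1], gains, n_segments, mode,
                            n_iter) for t in range(F - 1)]
    d2 = [geodesic_distance(rates[t], rates[t + 2], gains, n_segments, mode,
                            n_iter) for t in range(F - 2)]
    locals_deg = []
    for t in range(F - 2):
        a, b, c13 = d1[t], d1[t + 1], d2[t]
        excess = c13 - (a + b)
        if excess > 0.05 * (a + b):
            raise ValueError(
                f"geodesic distances at frame {t + 1} violate the triangle "
                f"inequality by {excess:.3g}")
        if excess > 0:
            warnings.warn("small triangle violation clipped to a straight "
                          "angle", RuntimeWarning, stacklevel=2)
            c13 = a + b
        locals_deg.append(angle_from_distances(a, b, c13, tol=1e-6))
    locals_deg = np.asarray(locals_deg)
    return float(np.mean(locals_deg)), locals_deg
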