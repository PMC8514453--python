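"""Modulated Poisson population model with shared multiplicative gain.

Spike counts are conditionally Poisson given a stimulus-driven rate vector
and a trial-specific multiplicative gain, with the gain log-normal:
``g = exp(eps)``, ``eps ~ N(mu_eps, Sigma_eps)`` and ``mu_eps = -diag(Sigma_eps)/2``
so the gain has unit mean.  ``Sigma_eps`` is the sum of a diagonal matrix
(private gain) and a low-rank matrix (gain shared across units), which
produces trial-to-trial noise correlations.  The module simulates counts,
evaluates the gain-marginalized count likelihood by Gauss-Hermite quadrature,
fits the gain covariance (rank chosen by cross-validation), computes the
predicted spike-count covariance, and scores goodness of fit with the
inclusion rules applied to each dataset.

This module doubles as the synthetic-data generator for the rest of the
package: :func:`simulate` draws complete trial x frame x unit count arrays
from known rate trajectories and gain covariances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import pearsonr

from . import _ad as ad
from ._optim import Adam

__all__ = [
    "GainCovariance", "SpikeCountDataset", "GoodnessOfFit",
    "simulate", "predicted_covariance", "count_loglik",
    "fit_gain_covariance", "goodness_of_fit", "counts_from_spike_times",
]

# generator defaults: a single gain factor shared by the whole population
# with ~30% gain variability, plus weak private gain, typical of V1 counts
DEFAULT_SHARED_VAR = 0.09
DEFAULT_PRIVATE_VAR = 0.01


@dataclass
class GainCovariance:
    """Log-gain covariance Sigma_eps = diag(private_var) + U U^T.

    Attributes
    ----------
    private_var : (D,) non-negative private log-gain variances.
    U : (D, r) low-rank factor of the shared log-gain covariance.
    """

    private_var: np.ndarray
    U: np.ndarray

    def __post_init__(self):
        self.private_var = np.atleast_1d(np.asarray(self.private_var, float))
        self.U = np.asarray(self.U, dtype=float)
        if self.U.ndim == 1:
            self.U = self.U[:, None]
        if self.U.size == 0:
            self.U = np.zeros((self.n_units, 0))
        if np.any(self.private_var < 0):
            raise ValueError("private gain variances must be non-negative "
                             "(Sigma_eps must be positive semidefinite)")
        if self.U.shape[0] != self.n_units:
            raise ValueError("U must have one row per unit")

    # -- constructors -------------------------------------------------
    @classmethod
    def zero(cls, n_units: int) -> "GainCovariance":
        """No gain modulation: the model reduces to pure Poisson."""
        return cls(np.zeros(n_units), np.zeros((n_units, 0)))

    @classmethod
    def independent(cls, variances) -> "GainCovariance":
        """Private gain only (diagonal Sigma_eps)."""
        variances = np.atleast_1d(np.asarray(variances, float))
        return cls(variances, np.zeros((len(variances), 0)))

    @classmethod
    def shared(cls, n_units: int, shared_var: float = DEFAULT_SHARED_VAR,
               private_var: float = DEFAULT_PRIVATE_VAR,
               rank: int = 1) -> "GainCovariance":
        """Uniform shared gain of the given rank plus uniform private gain."""
        U = np.full((n_units, rank), np.sqrt(shared_var / max(rank, 1)))
        if rank >= 2:  # make extra factors sign-alternating so they differ
            for j in range(1, rank):
                U[:, j] *= np.where(np.arange(n_units) % (j + 1) == 0, 1.0, -1.0)
        return cls(np.full(n_units, private_var), U)

    # -- derived quantities -------------------------------------------
    @property
    def n_units(self) -> int:
        return len(self.private_var)

    @property
    def rank(self) -> int:
        return self.U.shape[1]

    def sigma_eps(self) -> np.ndarray:
        """Full log-gain covariance matrix (D, D)."""
        return np.diag(self.private_var) + self.U @ self.U.T

    def mu_eps(self) -> np.ndarray:
        """Log-gain mean enforcing unit-mean gain: -diag(Sigma_eps)/2."""
        return -0.5 * (self.private_var + np.sum(self.U ** 2, axis=1))

    def gain_variances(self) -> np.ndarray:
        """Per-unit gain variances sigma_i^2 = exp([Sigma_eps]_ii) - 1."""
        return np.exp(self.private_var + np.sum(self.U ** 2, axis=1)) - 1.0

    def gain_covariance(self) -> np.ndarray:
        """Gain covariance Sigma_g = exp(Sigma_eps) - 1, element-wise."""
        return np.exp(self.sigma_eps()) - 1.0

    def diagonal(self) -> "GainCovariance":
        """Same marginal gain variances, independence across units."""
        return GainCovariance.independent(
            self.private_var + np.sum(self.U ** 2, axis=1))

    def sample_gains(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n unit-mean gain vectors, (n, D)."""
        eps = rng.standard_normal((n, self.rank)) @ self.U.T
        eps += np.sqrt(self.private_var) * rng.standard_normal((n, self.n_units))
        return np.exp(self.mu_eps() + eps)


@dataclass
class SpikeCountDataset:
    """Trial-by-trial spike counts: K trials x (T+1) frames x D units."""

    counts: np.ndarray
    frame_labels: np.ndarray = None
    unit_ids: np.ndarray = None
    trial_ids: np.ndarray = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (trials, frames, units)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        K, F, D = self.counts.shape
        if K < 2:
            raise ValueError("need at least 2 trials")
        if self.frame_labels is None:
            self.frame_labels = np.arange(F)
        if self.unit_ids is None:
            self.unit_ids = np.arange(D)
        if self.trial_ids is None:
            self.trial_ids = np.arange(K)

    @property
    def n_trials(self):
        return self.counts.shape[0]

    @property
    def n_frames(self):
        return self.counts.shape[1]

    @property
    def n_units(self):
        return self.counts.shape[2]

    def trial_mean(self) -> np.ndarray:
        """Trial-averaged counts per frame and unit, (T+1, D)."""
        return self.counts.mean(axis=0)

    def to_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=self.counts)
            f.create_dataset("frame_ids", data=self.frame_labels)
            f.create_dataset("unit_ids", data=self.unit_ids)
            f.create_dataset("trial_ids", data=self.trial_ids)

    @classmethod
    def from_hdf5(cls, path) -> "SpikeCountDataset":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(counts=f["counts"][...], frame_labels=f["frame_ids"][...],
                       unit_ids=f["unit_ids"][...], trial_ids=f["trial_ids"][...])


def simulate(rates, gains: GainCovariance, n_trials: int,
             seed=None) -> SpikeCountDataset:
    """Draw a spike-count dataset from the modulated Poisson model.

    Each trial and frame gets an independent log-normal gain draw shared
    within the population; counts are Poisson at rate ``lambda * g``.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if gains.n_units != rates.shape[1]:
        raise ValueError("gain covariance and rates disagree on unit count")
    rng = np.random.default_rng(seed)
    F, D = rates.shape
    g = gains.sample_gains(n_trials * F, rng).reshape(n_trials, F, D)
    counts = rng.poisson(rates[None] * g)
    return SpikeCountDataset(counts=counts)


def predicted_covariance(rates, gains: GainCovariance, frame: int) -> np.ndarray:
    """Model-predicted spike-count covariance at one frame.

    ``Sigma_t = diag(lambda_t) + Sigma_g (.) lambda_t lambda_t^T`` where
    ``Sigma_g`` is the element-wise gain covariance and ``(.)`` the
    element-wise product.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    lam = rates[frame]
    return np.diag(lam) + gains.gain_covariance() * np.outer(lam, lam)


# ------------------------------------------------------------------ likelihood

def _gauss_hermite(n: int):
    """Nodes/weights for E[f(x)], x ~ N(0,1)."""
    h, w = np.polynomial.hermite_e.hermegauss(n)
    return h, w / np.sum(w)


def _outer_grid(rank: int, n_nodes: int):
    """Tensor-product standard-normal grid over the shared-gain factors.

    Returns S (rank, O) node matrix and log-weights (O,).
    """
    if rank == 0:
        return np.zeros((0, 1)), np.zeros(1)
    h, w = _gauss_hermite(n_nodes)
    grids = np.meshgrid(*([h] * rank), indexing="ij")
    S = np.stack([g.ravel() for g in grids], axis=0)
    logw = np.zeros(S.shape[1])
    wg = np.meshgrid(*([np.log(w)] * rank), indexing="ij")
    for g in wg:
        logw = logw + g.ravel()
    return S, logw


def _quadrature_shifts(private_var, U, n_outer: int, n_inner: int):
    """Log-gain offsets delta (D, O, Q) plus log-weights for both levels.

    Works on numpy arrays or autodiff tensors (`private_var` (D,), `U`
    (D, r)); node locations are constants, so the result is differentiable
    with respect to the gain parameters.
    """
    rank = ad.value(U).shape[1]
    S, logw_outer = _outer_grid(rank, n_outer)
    x_in, w_in = _gauss_hermite(n_inner)
    mu = ad.mul(ad.add(private_var, ad.sum(ad.square(U), axis=1)), -0.5)
    shared = ad.matmul(U, S) if rank > 0 else np.zeros((ad.value(U).shape[0], 1))
    # delta[i, o, q] = mu_i + (U S)_{i,o} + sqrt(private_i) x_q
    d_shared = ad.add(ad.reshape(mu, (-1, 1)), shared)  # (D, O)
    priv = ad.mul(ad.reshape(ad.sqrt(private_var), (-1, 1)), x_in[None, :])  # (D, Q)
    delta = ad.add(ad.reshape(d_shared, (ad.value(d_shared).shape[0],
                                         ad.value(d_shared).shape[1], 1)),
                   ad.reshape(priv, (ad.value(priv).shape[0], 1, -1)))
    return delta, logw_outer, np.log(w_in)


class CountTable:
    """Precomputed per-dataset structures for fast repeated likelihoods.

    Groups the trial counts per (frame, unit) into a one-hot table over count
    values so the expensive quadrature table is independent of the number of
    trials.
    """

    def __init__(self, counts: np.ndarray):
        counts = np.asarray(counts)
        if counts.ndim == 1:
            counts = counts[None, None, :]
        elif counts.ndim == 2:
            counts = counts[None]
        if counts.ndim != 3:
            raise ValueError("counts must be at most (trials, frames, units)")
        self.counts = counts.astype(np.int64)
        self.n_max = int(self.counts.max(initial=0))
        K, F, D = self.counts.shape
        self.onehot = np.zeros((K, F, D, self.n_max + 1))
        k_idx, f_idx, d_idx = np.indices((K, F, D))
        self.onehot[k_idx, f_idx, d_idx, self.counts] = 1.0
        self.n_vals = np.arange(self.n_max + 1, dtype=float)
        self.log_factorial = gammaln(self.counts + 1.0).sum(axis=2)  # (K, F)

    def loglik(self, rates, gains_or_delta, n_outer: int = 9,
               n_inner: int = 9, per_trial: bool = False):
        """Gain-marginalized log-likelihood of the stored counts.

        ``rates`` may be (F, D) or carry one leading batch axis (S, F, D) and
        may be an autodiff tensor.  ``gains_or_delta`` is a
        :class:`GainCovariance` or a precomputed ``(delta, logw_outer,
        logw_inner)`` triple from :func:`_quadrature_shifts`.
        """
        if isinstance(gains_or_delta, GainCovariance):
            delta, logw_o, logw_i = _quadrature_shifts(
                gains_or_delta.private_var, gains_or_delta.U, n_outer, n_inner)
        else:
            delta, logw_o, logw_i = gains_or_delta
        batched = ad.value(rates).ndim == 3
        log_lam = ad.log(ad.maximum(rates, 1e-12))
        if not batched:
            log_lam = ad.reshape(log_lam, (1,) + ad.value(log_lam).shape)
        # eta[s, f, d, o, q] = log lambda + delta
        delta_b = ad.reshape(delta, (1, 1) + ad.value(delta).shape)
        eta = ad.add(ad.reshape(log_lam, ad.value(log_lam).shape + (1, 1)),
                     delta_b)
        # log pmf over the count grid: n * eta - exp(eta)   (n! handled later)
        lam_g = ad.exp(eta)
        table = ad.sub(ad.mul(ad.reshape(eta, ad.value(eta).shape + (1,)),
                              self.n_vals),
                       ad.reshape(lam_g, ad.value(lam_g).shape + (1,)))
        # marginalize private gain: logsumexp over q with weights
        A = ad.logsumexp(table, axis=4,
                         b=np.exp(logw_i)[None, None, None, None, :, None])
        # sum log A over units at each trial's observed counts
        C = ad.einsum2("sfdon,kfdn->skfo", A, self.onehot)
        # marginalize shared gain: logsumexp over outer nodes
        ll = ad.logsumexp(C, axis=3, b=np.exp(logw_o)[None, None, None, :])
        ll = ad.sub(ll, self.log_factorial[None])  # (S, K, F)
        if per_trial:
            return ll if batched else ll[0]
        total = ad.sum(ll, axis=(1, 2))
        return total if batched else total[0]


def count_loglik(counts, rates, gains: GainCovariance,
                 n_outer: int = 9, n_inner: int = 9):
    """Log-probability of spike counts under the gain-marginalized model.

    The log-normal gain integral has no closed form; it is evaluated by
    Gauss-Hermite quadrature, with a tensor-product grid over the shared
    (low-rank) gain factors and an independent 1-D grid per unit for the
    private gain.  With ``Sigma_eps = 0`` this reduces exactly to the Poisson
    log-likelihood.

    ``counts`` may be a single (D,) vector, a (F, D) frame stack, or a full
    (K, F, D) dataset array; the returned value sums over all of them.
    """
    table = CountTable(np.asarray(counts))
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    if gains.rank == 0 and np.max(gains.private_var, initial=0.0) < 1e-14:
        n_outer, n_inner = 1, 1
    return float(table.loglik(rates, gains, n_outer=n_outer, n_inner=n_inner))


# ------------------------------------------------------------------ gain fit

def _fit_rank(counts_list, rank: int, n_iter: int, seed,
              n_outer: int, n_inner: int, lr: float = 0.05):
    """Jointly fit per-dataset log-rates and a rank-r gain covariance by
    maximum marginal likelihood (Adam on the quadrature objective)."""
    rng = np.random.default_rng(seed)
    D = counts_list[0].shape[2]
    tables = [CountTable(c) for c in counts_list]
    n_total = float(np.sum([c.size for c in counts_list]))
    params = {"psi_raw": np.full(D, -3.0),
              "U": 0.05 * rng.standard_normal((D, rank))}
    for j, c in enumerate(counts_list):
        params[f"log_lam_{j}"] = np.log(np.maximum(c.mean(axis=0), 0.05))
    opt = Adam(params, lr=lr)
    for _ in range(n_iter):
        p = {k: ad.Tensor(v, requires_grad=True) for k, v in opt.params.items()}
        psi = ad.softplus(p["psi_raw"])
        quad = _quadrature_shifts(psi, p["U"], n_outer, n_inner)
        obj = 0.0
        for j, table in enumerate(tables):
            obj = ad.add(obj, table.loglik(ad.exp(p[f"log_lam_{j}"]), quad,
                                           n_outer, n_inner))
        loss = ad.mul(obj, -1.0 / n_total)
        ad.backward(loss)
        opt.step({k: t.grad for k, t in p.items()})
    psi = np.logaddexp(0.0, opt.params["psi_raw"])
    gains = GainCovariance(psi, opt.params["U"])
    rates = {j: np.exp(opt.params[f"log_lam_{j}"]) for j in range(len(tables))}
    return gains, rates


def fit_gain_covariance(datasets, ranks=(0, 1, 2, 3), n_folds: int = 5,
                        n_iter: int = 500, seed=0, n_outer: int = 7,
                        n_inner: int = 5):
    """Fit the shared gain covariance, selecting its rank by cross-validation.

    For each candidate rank, trials are split into folds; rates and gain
    parameters are fit on the training folds by maximizing the marginalized
    likelihood, and the held-out trials are scored with the trained
    parameters.  The rank with the best summed held-out log-likelihood wins
    and the model is refit on all trials.  The gain covariance is shared
    across all datasets (frames and movies), as a stable population property.

    Returns ``(GainCovariance, info)`` with per-rank CV scores in ``info``.
    """
    if isinstance(datasets, SpikeCountDataset):
        datasets = [datasets]
    counts_list = [d.counts for d in datasets]
    K = counts_list[0].shape[0]
    if K < n_folds:
        raise ValueError(f"need at least {n_folds} trials for {n_folds}-fold CV")
    folds = np.array_split(np.random.default_rng(seed).permutation(K), n_folds)
    cv_scores = {}
    for rank in ranks:
        score = 0.0
        for f, heldout in enumerate(folds):
            train = np.setdiff1d(np.arange(K), heldout)
            gains, rates = _fit_rank([c[train] for c in counts_list], rank,
                                     n_iter, seed + f, n_outer, n_inner)
            for j, c in enumerate(counts_list):
                score += count_loglik(c[heldout], rates[j], gains,
                                      n_outer, n_inner)
        cv_scores[rank] = score
    best = max(cv_scores, key=cv_scores.get)
    gains, rates = _fit_rank(counts_list, best, n_iter, seed, n_outer, n_inner)
    info = {"cv_scores": cv_scores, "rank": best, "fitted_rates": rates}
    return gains, info


# ------------------------------------------------------------------ fit check

@dataclass
class GoodnessOfFit:
    """Pearson correlations of predicted vs measured response statistics."""

    r_mean: float
    r_var: float
    r_cov: float
    included: bool = field(init=False)

    def __post_init__(self):
        # inclusion thresholds applied independently to the three statistics
        self.included = (self.r_mean ** 2 >= 0.75 and self.r_var ** 2 >= 0.5
                         and self.r_cov ** 2 >= 0.25)


def _log_floor(x):
    pos = x[x > 0]
    floor = 0.5 * pos.min() if pos.size else 1e-3
    return np.log(x + floor)


def goodness_of_fit(dataset: SpikeCountDataset, map_rates,
                    gains: GainCovariance) -> GoodnessOfFit:
    """Correlate model-predicted and empirical response statistics.

    ``r_mean`` compares log fitted rates with log trial-average rates;
    ``r_var`` compares log predicted variances (Poisson plus gain term) with
    log empirical variances; ``r_cov`` compares predicted and empirical
    off-diagonal covariances, excluding non-positive entries before the log.
    A dataset is included when r_mean^2 >= 0.75, r_var^2 >= 0.5 and
    r_cov^2 >= 0.25 all hold.
    """
    map_rates = np.atleast_2d(np.asarray(map_rates, dtype=float))
    counts = dataset.counts.astype(float)
    emp_mean = counts.mean(axis=0)
    keep = ~np.all(emp_mean == 0, axis=0)
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} silent unit(s) excluded from "
                      "goodness-of-fit statistics", RuntimeWarning, stacklevel=2)
    lam = map_rates[:, keep]
    counts = counts[:, :, keep]
    emp_mean = emp_mean[:, keep]
    Sg = gains.gain_covariance()[np.ix_(keep, keep)]

    r_mean = pearsonr(_log_floor(lam).ravel(), _log_floor(emp_mean).ravel())[0]

    pred_var = lam + np.diag(Sg)[None, :] * lam ** 2
    emp_var = counts.var(axis=0, ddof=1)
    r_var = pearsonr(_log_floor(pred_var).ravel(), _log_floor(emp_var).ravel())[0]

    iu = np.triu_indices(lam.shape[1], k=1)
    pred_cov, emp_cov = [], []
    for t in range(lam.shape[0]):
        pc = (Sg * np.outer(lam[t], lam[t]))[iu]
        centered = counts[:, t, :] - emp_mean[t]
        ec = (centered.T @ centered / (dataset.n_trials - 1))[iu]
        pred_cov.append(pc)
        emp_cov.append(ec)
    pred_cov = np.concatenate(pred_cov)
    emp_cov = np.concatenate(emp_cov)
    ok = (pred_cov > 0) & (emp_cov > 0)
    if ok.sum() >= 3:
        r_cov = pearsonr(np.log(pred_cov[ok]), np.log(emp_cov[ok]))[0]
    else:
        r_cov = 0.0
    return GoodnessOfFit(r_mean=float(r_mean), r_var=float(r_var),
                         r_cov=float(r_cov))


# -------------------------------------------------------- latency extraction

def counts_from_spike_times(spike_times, onsets, frame_ids, trial_ids,
                            window: float,
                            latency_grid=None) -> SpikeCountDataset:
    """Bin spike times into a count dataset with per-unit response latency.

    For each unit, a latency is chosen from ``latency_grid`` (default 0-150 ms
    in 10 ms steps) by maximizing the across-frame variance of the mean
    counts; spikes are then counted in ``[onset + latency, onset + latency +
    window)`` for every presentation.  Returns ``(dataset, latencies)`` with
    the selected per-unit latencies in seconds.
    """
    onsets = np.asarray(onsets, dtype=float)
    frame_ids = np.asarray(frame_ids)
    trial_ids = np.asarray(trial_ids)
    if latency_grid is None:
        latency_grid = np.arange(0.0, 0.1501, 0.010)
    frames = np.unique(frame_ids)
    trials = np.unique(trial_ids)
    f_idx = np.searchsorted(frames, frame_ids)
    k_idx = np.searchsorted(trials, trial_ids)
    D = len(spike_times)
    counts = np.zeros((len(trials), len(frames), D), dtype=np.int64)
    latencies = np.zeros(D)
    for i, st in enumerate(spike_times):
        st = np.sort(np.asarray(st, dtype=float))
        if st.size == 0:
            warnings.warn(f"unit {i} has no spikes; counts are zero",
                          RuntimeWarning, stacklevel=2)
            continue
        best_var, best_c, best_lat = -np.inf, None, 0.0
        for lat in np.atleast_1d(latency_grid):
            lo = np.searchsorted(st, onsets + lat)
            hi = np.searchsorted(st, onsets + lat + window)
            c = np.zeros((len(trials), len(frames)), dtype=np.int64)
            np.add.at(c, (k_idx, f_idx), hi - lo)
            v = c.mean(axis=0).var()
            if v > best_var:
                best_var, best_c, best_lat = v, c, float(lat)
        counts[:, :, i] = best_c
        latencies[i] = best_lat
    return SpikeCountDataset(counts=counts, frame_labels=frames,
                             trial_ids=trials), latencies
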