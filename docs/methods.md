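# Methods

`popcurv` estimates the discrete curvature of the trajectory that a neural
population's responses trace through response space as an image sequence
unfolds, and compares it with the curvature of the same sequence in pixel
space. Negative relative curvature (neural below the null expectation)
means the population *straightens* the sequence; positive means it
*entangles* it. This note documents the model, the estimator, the
synthetic-data generator, the numerical choices, and the limitations that
the test suite does and does not probe.

## Discrete curvature

A sequence of T+1 points x_0..x_T has local curvature
c_t = angle(v_t, v_{t+1}) between successive unit displacement vectors, and
global curvature equal to the mean of the local angles. The implementation
computes the angle as `2*atan2(|v1 - v2|, |v1 + v2|)`, which is
algebraically the arccos of the dot product but numerically exact at 0 and
180 degrees, where the arccos form loses half the available precision.
Curvature is invariant to rigid motions and uniform scaling, and is fully
determined by pairwise distances; `angle_from_distances` recovers the local
angle from the three distances around a vertex via the law of cosines
(turning angle = 180 deg minus the interior angle).

Trajectories convert losslessly to intrinsic coordinates (step lengths d_t,
turning angles c_t, and unit acceleration directions a_t orthogonal to the
previous displacement, with v_t = cos(c_t) v_{t-1} + sin(c_t) a_t); this
parameterization is both the generative model of the variational estimator
and the tool the null model uses to swap curvatures while holding
everything else fixed.

## Response model

Spike counts are conditionally Poisson given a stimulus-driven rate vector
and a multiplicative, trial- and frame-specific gain shared across the
population: g = exp(eps), eps ~ N(mu, Sigma_eps) with
mu = -diag(Sigma_eps)/2 so E[g] = 1. Sigma_eps = diag (private gain) +
low-rank (shared gain); the shared part produces trial-to-trial noise
correlations. The predicted count covariance at one frame is
`diag(lambda) + Sigma_g .* lambda lambda^T` with
Sigma_g = exp(Sigma_eps) - 1 elementwise.

The gain-marginalized count likelihood has no closed form. It is evaluated
by Gauss-Hermite quadrature: a tensor grid over the shared factors (rank r,
`n_outer` nodes per factor) and an independent per-unit grid over the
private gain (`n_inner` nodes), with counts grouped per (frame, unit) into
a table over count values so the cost is independent of the number of
trials. Defaults are 7 and 5 nodes; the simulation studies use 5 and 1
(the generator's private-gain variance is 0.01, for which a single node is
accurate to ~1e-3 nats per count). With Sigma_eps = 0 the likelihood is
exactly Poisson.

`fit_gain_covariance` maximizes this marginal likelihood jointly over
per-frame log rates and the gain parameters with adaptive-moment gradients,
and selects the shared rank by K-fold cross-validation over trials (default
5 folds, ranks 0-3). The gain covariance is treated as a stable population
property shared across frames and sequences.

Spike-time input is supported through `counts_from_spike_times`, which
picks a per-unit response latency from a 0-150 ms grid (10 ms steps) by
maximizing the across-frame variance of mean counts before binning.

## Embedding: distances as discriminability

Under an independent-gain approximation the discriminability metric is
diagonal with entries 1/(lambda_i + sigma_i^2 lambda_i^2), the inverse
spike-count variance, where sigma_i^2 = exp([Sigma_eps]_ii) - 1 is the
unit's gain variance. The transform

    y = (2 / sigma) * asinh(sigma * sqrt(lambda))

equalizes this metric: Euclidean distances between transformed rate vectors
measure discriminability in d' units, and sigma -> 0 recovers the Poisson
stabilizer 2*sqrt(lambda). The transform is inverted exactly by
lambda = [sinh(sigma y / 2) / sigma]^2.

One caveat is verified numerically in the test suite: the inverse variance
equals the exact Fisher information of the gain-marginalized count
distribution only in the weak-gain limit. Dense-quadrature computation
puts the exact score variance of the stabilized coordinate at 1.00 for
sigma = 0.1 at all rates, 1.07 at (sigma = 0.5, lambda = 20), and 1.37 at
(sigma = 1, lambda = 20). The embedding is therefore exactly a d'
(distance over standard deviation) equalizer, and approximately an
information equalizer, with the approximation degrading as sigma * lambda
grows. Typical fitted gain levels (sigma ~ 0.3) sit comfortably in the
accurate regime.

## Variational curvature inference

The embedded trajectory is parameterized by local latents z: step-length
pre-images (softplus-rectified), turning angles, raw acceleration
directions (projected onto the orthogonal complement of the previous
direction and normalized), an embedding pre-image orthonormalized by
Gram-Schmidt, and an affine offset in response space. Global parameters
theta = {d*, c*, sigma_d, sigma_c, Sigma_a} supply hierarchical Gaussian
priors; Sigma_a is diagonal with geometrically decaying entries
(scale^2 * decay^j), controlling the trajectory's effective dimensionality.
The global curvature estimate is c*, the prior mean of the local angles.

Two departures from the minimal parameterization were forced by
well-definedness:

- An affine offset latent (broad Gaussian prior, sd 5 d') accompanies the
  linear embedding. T+1 points span a T-dimensional *affine* subspace;
  without the offset the decoded trajectory would pass through the origin
  of response space and frame 0 would be forced to zero rates.
- The trajectory starts at the origin with its first step along the first
  basis vector; curvature is invariant to this gauge fixing, and the
  orthonormal embedding absorbs the rotation.

Inference maximizes the evidence lower bound over theta and a
diagonal-Gaussian posterior phi jointly: the expected log-likelihood is a
reparameterized Monte-Carlo average (vectorized across samples), the KL to
the prior is closed form, and optimization uses adaptive-moment gradients
(default: learning rate 1e-2, up to 3000 iterations, 8 samples, early stop
when the 200-iteration smoothed ELBO changes by less than 1e-5 relative).
The four scalar prior parameters (d*, c*, sigma_d, sigma_c), on which the
ELBO depends only through the KL term, are updated in closed form after
each gradient step (variational EM); this markedly accelerates convergence
of the hierarchy and changes no optimum.

Initialization is a two-step pilot: trial-mean rates -> stabilized points
-> SVD projection to the trajectory subspace -> intrinsic coordinates,
rotated into the canonical gauge. The pilot is known to be biased -- in
high dimensions, trial-mean noise masquerades as turning, inflating angles
toward the high-dimensional noise attractor (~95-100 deg) -- so it serves
only as a starting point.

**Multi-start and the noise-turning basin.** Gradient descent from the
pilot cannot un-turn a trajectory whose apparent curvature is pure noise:
the likelihood locally prefers tracking the noisy trial means, and the
diagonal posterior cannot represent the direction uncertainty that would
devalue that solution. The fit therefore runs one optimization per element
of `start_shrink` (default: the plain pilot and a start with local angles
shrunk by 0.25, re-anchored to the data by an orthogonal Procrustes refit
of the embedding and offset), and keeps the solution with the higher
common-noise ELBO. On synthetic ground truths this selection reliably
picks the straight basin when the truth is straight and the curved basin
when it is curved, reducing the median recovery error at (c = 0, d* = 2,
D = 30, T = 10, K = 50) from ~35 deg to ~7 deg.

Populations whose fitted mean step length d* falls below 0.25 d' are
flagged unreliable and excluded from summaries. The pseudo-population
variant re-runs the identical machinery with the off-diagonal gain
covariance zeroed.

## Null model and relative curvature

Estimates remain biased at realistic data sizes (the noise-turning effect
above). Calibration simulates a population matched to the fitted one in
every respect -- same units, gain covariance, trial count, step lengths,
embedding, start -- except that its true local curvatures are the
pixel-domain ones. The fitted acceleration directions are retained and
re-orthogonalized against the evolving direction sequence (swapping the
angles changes it); this is the strictest available reading of "identical
in all regards". If the angle swap pushes stabilized coordinates negative
(where the rate map stops being monotone) the trajectory is translated up,
preserving curvature and step lengths exactly and warning about the rate
shift. Each of M replicates (default 100) simulates a fresh dataset from
the null rates and runs the full estimator; relative curvature is the
empirical estimate minus the null mean, with a two-sided add-one-smoothed
tail p-value and significance defined by the central 95% interval.

Because the null replicates traverse the same estimator, the calibration is
exact by construction up to Monte-Carlo error: on data generated under the
null, the type-I rate of the 95% criterion lands within the binomial error
band of 5% and relative curvature centers on zero, even at sizes where the
raw estimates are strongly biased.

## Numerical curvature (full covariance)

To check the independent-gain approximation, discriminability is computed
without it: local distance is the Mahalanobis form under the average of the
two model-predicted count covariances, and distant rate vectors get the
geodesic distance, minimized over discretized paths (20 segments,
initialized on the straight chord in stabilized coordinates -- which also
enforces non-negative rates -- and optimized with adaptive-moment descent).
Chordal discretizations underestimate Riemannian length, so refining the
grid increases the minimized length toward the true geodesic; the
20-segment value is converged to well under 1% on the scales tested.
Curvature follows from the law of cosines on distances between successive
and once-removed frames; triangle violations from finite optimizer
tolerance are clipped with a warning (violations beyond 5% raise). With
diagonal covariances this numerical estimate agrees with the closed-form
embedded curvature to well under one degree, and full-mode estimates sit
close to diagonal ones at fitted gain scales, which is what justifies the
analytic transform everywhere else.

## LN-LN cascade

A static image is analyzed by four oriented Gaussian-derivative filters in
quadrature (phases 90 deg apart), half-wave rectified and squared, pooled
with simplex-constrained weights, and divisively normalized by
sigma_norm^2 + c_rms^2 where sigma_norm = 0.15 and c_rms is the stimulus's
root-mean-square contrast (the pooled-population term is approximated by
stimulus contrast). A spontaneous rate and response scale map the result
to spikes per window; a blank stimulus returns exactly the spontaneous
rate. Equal pooling weights give a phase-invariant complex cell
(F1/F0 < 1), a single weight a phase-modulated simple cell.

Filters are constructed in the Fourier domain from the closed-form tuning
curves -- spatial frequency [(w/w0) e^{-(w/w0)^2/2}]^b, orientation
[cos(dt) e^{-(1-alpha^2) cos^2(dt)/2}]^b with the anti-preferred direction
scaled by (1 - d) -- on a 0.05 deg/pixel grid, shifted to the cell's
receptive-field center, zero-mean, and normalized to unit quadrature
response at the preferred full-contrast grating. Static spatial filters
have Hermitian spectra and cannot express direction selectivity; d enters
only the frequency-domain drifting-grating predictions used for fitting.
With that convention the image-computable and frequency-domain responses
agree to better than 1% on grating grids (the residual comes from
non-integer cycle counts on the finite grid).

Fitting follows the staged protocol: filter and response-range parameters
by maximum likelihood over a 16-direction x 6-spatial-frequency grating
grid under a single-gain modulated Poisson likelihood (gain variance fixed
at 0.1), with multi-start Nelder-Mead (semi-randomized starts seeded at the
empirically best grating); pooling weights by least squares on the
temporal response waveform at the preferred grating, projected onto the
simplex (flat waveforms default to equal weights with a warning);
receptive-field centers by a 2-D Gaussian fit to sparse-bar response
profiles with a centroid fallback. Synthetic-neuron recovery lands the
preferred orientation within ~1 deg and spatial frequency within ~0.01
octave at 50 trials per grating.

Population predictions transform model rates with the same
variance-stabilizing map and take the discrete curvature of the result.
Because this stimulus-computable pipeline involves no inference from finite
trials, its relative curvature is reported against the pixel value directly
rather than against a simulation null. Model dissection follows the three
rules exactly: denominator set to one; all weights 0.25; each cell's
largest weight set to one.

## Synthetic-data generator

`response_model.simulate` is the study generator: trial x frame x unit
counts from any rate trajectory and gain covariance. Default gain
structure is a single population-wide shared gain factor (log-gain variance
0.09, gain CV ~ 0.3, the scale the modulated-Poisson literature reports
for V1) plus weak private gain (0.01); the shared rank is a free argument
and rank selection by cross-validation supports 0-3. Ground-truth
trajectories (`pipeline.constant_curvature_rates`, `ground_truth_rates`)
live in the embedded space: constant step length, prescribed local angles
(a constant, or the pixel-domain angles plus an offset), random unit
acceleration directions, a random orthonormal embedding, and per-unit
baselines centered near 4 spikes/window with every stabilized coordinate
floored at 0.5 so rates stay within a physiological band regardless of how
elongated the trajectory is.

What the generator emulates: Poisson discharge with realistic shared-gain
noise correlations, frame counts (11 and 6), population sizes and trial
counts in the experimental range, and trajectories whose curvature is
known exactly. What it does not emulate: stimulus-locked temporal dynamics
within the counting window, adaptation or other history dependence across
presentations, non-Poisson dispersion beyond the gain mechanism,
inhomogeneous per-unit gain coupling, and eye-movement or sorting
artifacts. Passing tests therefore certify the statistical machinery under
the model's own assumptions, not robustness to every violation real
recordings can produce.

## Study sizes and reproducibility

Simulation studies run at desk scale: estimator recovery uses 3 datasets
per condition on the c in {0, 45, 90, 135} deg x d* in {0.5, 1, 2} grid at
D = 30, T = 10, K = 50 with a 350-iteration, 2-sample,
(5, 1)-node fit budget; null calibration uses 100 null replicates plus 100
test datasets at D = 8, T = 5, K = 20 with single-start fits (the same
estimator configuration on both sides is what calibration requires).
Every random stage takes an explicit seed, and same-seed runs are
bit-identical.

## Known limitations

- At step lengths near the noise floor (d* = 0.5 with D = 30, K = 50,
  i.e. per-step displacement below the trial-mean noise norm) curvature is
  weakly identified: estimates collapse toward the high-dimensional noise
  angle regardless of the truth, and the multi-start ELBO selection cannot
  separate the basins because the bound genuinely favors the noise-tracking
  solution there. The d* < 0.25 reliability flag catches the extreme of
  this regime; between 0.25 and ~1 the null model, not the raw estimate,
  carries the inference (which is how the method is meant to be used).
- The diagonal posterior underestimates direction uncertainty, the root of
  the residual low-curvature bias; a structured posterior is out of scope.
- The quantization-induced curvature of 8-bit fades scales inversely with
  per-step contrast: ~3 deg on 6-frame synthetic fades, 5-7 deg on
  11-frame ones whose steps span few gray levels.
- Geodesic distances rely on a local optimizer; the reported metric-axiom
  and equivalence checks hold to optimizer tolerance, not exactly.
- At intermediate signal (d* near 1 with tens of units and trials) the
  estimate also depends mildly on the optimization budget: the ELBO
  optimum under the diagonal posterior sits somewhat below strongly curved
  truths, and iterates approach it from above through the true value.
  The study budget (350 iterations) is chosen once and shared by the null
  replicates, so the calibrated relative curvature is unaffected.
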