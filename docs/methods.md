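# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `attncov`. Everything quantitative stated here is computed
by the test suite, the analysis drivers, or `scripts/acceptance.py`.

## 1. The rank-one model of covariance modulation

Spike counts of N simultaneously recorded units over a fixed window give,
per attention condition, a sample covariance matrix (unbiased, n−1
denominator). The model states that attention rescales shared variability
through per-neuron *covariance gains* g_i:

    C_A(i, j) = g_i g_j C_U(i, j),   i ≠ j.

Diagonals are excluded throughout: the statistic isolates covariance
modulation from variance modulation. For N > 3 the system of N(N−1)/2
equations in N unknowns is overdetermined; g is estimated by minimizing

    f(g) = Σ_{i<j} ( g_i C_U(i,j) g_j − C_A(i,j) )²

with BFGS (analytic gradient, gradient-norm tolerance 1e-8), initialized
at all-ones (the identity-modulation prior) plus `n_restarts`
multiplicative lognormal perturbations (σ = 0.2), keeping the lowest
residual. The objective is invariant under g → −g; the solution is
reported with nonnegative mean (gains are physically positive). Fit
quality ρ is the Pearson correlation between measured and predicted
attended covariances over strictly-upper entries.

**Cross-validation.** Leave-one-equation-out: remove equation (a, b),
refit (warm-started from the full solution), predict
C_A(a,b) = g(a) g(b) C_U(a,b). min(1000, N(N−1)/2) systems are evaluated,
sampled uniformly without replacement when the pair count exceeds the cap.

**Shuffle null.** Take the principal square root of C_A (eigendecomposition
with eigenvalues clipped at 0), permute its strictly-upper entries
(diagonal fixed, lower triangle mirrored), and square the result — a
positive-semidefinite matrix with the same spectrum-scale but no relation
to C_U. Fitting the rank-one model against it measures how much apparent
structure the estimator finds in nothing.

Two properties of this null are worth knowing. First, the fit family
{v vᵀ restricted off-diagonal} has an intrinsic *overfitting floor*: its
best Pearson correlation against a structureless symmetric target is the
top-eigenvector alignment of a random symmetric matrix, ≈ 2/√N (≈ 0.20 at
N = 100). ρ_shuf therefore decays toward zero like c/√N but cannot drop
below that floor at finite N. Second, when all covariances are positive
(the loading has one sign, as in real data), the square of the shuffled
root retains row-scale and row-sum structure that the multiplicative model
can fit, and ρ_shuf plateaus well above the floor (~0.37 at N = 100 under
the generator defaults). The clean c/√N collapse appears for generic
mixed-sign loadings — the "random covariance matrix" regime — which is the
construction used when the collapse itself is being demonstrated.

**Finite-trial upper bound.** The fitted prediction Ĉ_A decomposes
perfectly by construction. Resampling it as M correlated-Poisson trials
(attended mean counts as marginals, Poisson variance on the diagonal),
re-estimating the covariance and refitting yields ρ_ub < 1 purely from
estimation noise; ρ_ub → 1 as M → ∞ (measured 0.999 at M = 1e5, N = 20).
Session performance is reported normalized: ρ/ρ̄_ub and ρ̄_shuf/ρ̄_ub.

**Gain intrinsicness.** `split_population_g` fits two unit sets that
overlap in a single neuron and compares its two gain estimates;
`g_vs_rate_modulation` correlates gains with the per-unit rate ratio
(independent axes in the generator, and nearly so in the fits).

## 2. The synthetic-session generator

No recordings ship with the package; sessions are generated with known
ground truth. Counts are Poisson over 200 ms windows at 10–40 sp/s (mean
counts 2–8). The unattended covariance is rank-one-plus-diagonal,

    C_U = diag(private) + x xᵀ,

so the attended off-diagonal (g∘x)(g∘x)ᵀ equals g_i g_j C_U(i,j) exactly —
the rank-one modulation is exactly realizable as a valid covariance, which
arbitrary (C_U, g) pairs would not guarantee. Diagonals equal the Poisson
count variance, with private = λ − x² keeping the decomposition
consistent.

Sampling uses a Gaussian copula with Poisson marginals. For each pair the
latent normal correlation that produces the target count correlation is
found by inverting the exact copula map — count covariance written as a
double sum of bivariate-normal upper-quadrant probabilities, evaluated by
Gauss–Legendre quadrature, inverted with an Illinois (regula-falsi)
iteration to 1e-3 — with unattainable targets clipped to the attainable
boundary (with a warning). The pairwise latent matrix is repaired to the
nearest positive-semidefinite correlation matrix by eigenvalue clipping
and diagonal renormalization; a repair that moves any latent correlation
by more than 0.1 aborts with the worst pair named.

Defaults (chosen once, fixed):

* `rate_range = (10, 40)` sp/s, `window_s = 0.2` — the recording regime
  being emulated.
* `presentations_per_trial = 3` — each behavioral trial contributes three
  exchangeable 200 ms windows, so "1000 trials" means 3000 covariance
  samples per condition, matching array-recording session geometry.
* `g ~ uniform(0.5, 1.1)` — most gains below one: attention reduces
  shared variability; the fitted-gain histogram has most mass below 1.
* `loading_scale = 0.45` with uniform(0.6, 1.4) heterogeneity — mean
  unattended noise correlation ≈ 0.2. Per-unit gain identifiability
  scales as loading² · √windows and is *rate-independent*, so at weaker
  mean correlations (≈ 0.065, loading ≈ 0.25) gains are only weakly
  identifiable at session scale (recovery correlation ≈ 0.7): a session
  of a thousand trials simply does not pin down per-neuron gains when the
  shared component is that small. The default favors identifiability at
  the upper end of cortical correlation values; `loading_scale` is an
  ordinary argument for studying the weaker regime.
* An independent attentional rate modulation ~ uniform(0.95, 1.20) (≈ +7%
  mean), uncorrelated with g by construction.

What the generator does **not** emulate: non-Poisson dispersion
(data Fano factors are typically > 1), spike timing, slow drifts and
day-to-day nonstationarity, higher-rank shared structure, and negative
noise correlations. Passing tests therefore show that the estimators do
what they claim under a one-latent-dimension Poisson world, not that real
data satisfies the rank-one model.

## 3. The E–I mean-field model

Two population rates obey

    τ_a dr_a/dt = −r_a + f_a(μ_a + J_aE r_E − J_aI r_I + noise_a),

with f the stationary rate of a leaky integrate-and-fire neuron driven by
white noise (Ricciardi first-passage integral), evaluated through
erfcx = exp(z²)erfc(z) so nothing overflows, by adaptive quadrature at
relative tolerance 1e-11; deeply subthreshold inputs underflow to rate 0.
The slope L = df/dI is computed analytically (the derivative of the
reciprocal integral is a difference of erfcx values at the limits) —
finite differences are kept as a test oracle only.

**Units.** Rates are dimensionless (spikes per membrane time constant
τ_m = 10 ms); display conversion divides by τ_m (r = 0.206 ↔ 20.6 sp/s).
This is the only reading under which the reference parameter set
(thresholds ≈ 1, couplings 1.5/3, biases ≈ 0.6) is self-consistent with
20–40 sp/s operating points. Population time constants are 1.

**Reference parameters.** τ_m = 0.01 s, V_T = 1, V_R = 0, μ_EB = 0.6089,
μ_IB = 0.5388, Δμ_E = 0.2624, Δμ_I = 0.3608, J_E = 1.5, J_I = 3,
σ_E = 0.3, σ_I = 0.35, χ = 1, k_E = 1, k_I = 0. Attention enters as
μ_a = μ_aB + A·Δμ_a; a stimulus as k_a·s.

**η calibration.** The LIF input-noise intensity η that shapes f is not
determined by the rest of the parameter set. `calibrate_eta` adjusts a
single shared η so the unattended excitatory rate hits a target;
targeting 20.6 sp/s (the unattended mean of the data regime being
modeled) gives η = 0.5937, frozen as the default. Choices of η across the
plausible 15–30 sp/s band leave every qualitative attention result intact
except one fine detail noted below.

**Fixed points** by damped iteration (damping 0.5, five starts spanning
low/high rates) with a Newton polish (analytic Jacobian) to residual
1e-11; distinct roots deduplicated, multistability flagged, sweeps
continue the root from the previous grid point.

**Fluctuations.** Linearizing about a stable fixed point gives a 2-D
Ornstein–Uhlenbeck process dδr = M δr dt + D dW, with
M = [[−1+L_E J_EE, −L_E J_EI], [L_I J_IE, −1−L_I J_II]] and D loading
private and common noise by χ. The stationary covariance is the 2×2
Lyapunov solution in closed form,

    Σ = −[det M · Q + (M − trM·I) Q (M − trM·I)ᵀ] / (2 trM det M),  Q = DDᵀ,

positive-definite for stable M (we derived the sign so that
MΣ + ΣMᵀ + Q = 0 holds, and verify that residual at 1e-9 on every call).
Lagged autocovariance C̃(s) = e^{Ms}Σ; long-window (zero-frequency)
covariance C = M⁻¹Q M⁻ᵀ, whose (E,E) element is the population variance
V_E. With symmetric coupling the familiar closed forms follow:
λ = {−1, −1 − J_I L_I + J_E L_E}, V_E = L_E²(J_I L_I(σ_E−σ_I)+σ_E)² /
(1+J_I L_I−J_E L_E)² at χ = 1, and G_E = L_E(k_E + J_I L_I(k_E−k_I)) /
(1+J_I L_I−J_E L_E). The general-χ second moments are implemented from
the same matrix route; in our algebra the V_I expansion's middle term is
−2 J_E L_E σ_I(σ_I − σ_E χ) (sign verified against the matrix route to
machine precision).

**Attention path (reference parameters, η = 0.5937).** From A = 0 to 1:
r_E 20.6 → 23.7 sp/s, r_I 16.9 → 25.4 sp/s, leading eigenvalue −1.67 →
−1.95, V_E −29%, G_E +4%. Variance falls because enhanced inhibitory gain
deepens stability faster than the gains amplify the noise. In the
(Δμ_E, Δμ_I) plane the variance-decreasing region lies essentially below
the diagonal — reducing variance requires recruiting inhibition at least
as strongly as excitation. The zero-change boundary tracks the diagonal
to within a few percent, and *which side* of the diagonal it sits on
depends on η within the calibration band (it crosses at η ≈ 0.73); at the
frozen calibration sampled diagonal points show marginal (≤ 7%) variance
decreases, so the strict form "every decreasing modulation has
Δμ_I > Δμ_E" holds only up to that margin.

**Simulation.** `simulate_linear` uses the exact OU discretization
(matrix-exponential propagator, exact one-step noise covariance — exact
at any dt). The long-window variance estimator uses windows of length
50/|λ₁|. `simulate_nonlinear` integrates the full rate equations
(Euler–Maruyama, spline-tabulated transfer) with the white noises
regularized as OU processes of correlation time τ_x normalized so their
autocovariance integrates to one (the white-noise limit the linear theory
assumes). Caveat: at the reference σ the white-noise-limit process has
large instantaneous variance (σ·√(1/2τ_x) ≈ 1 for τ_x = 0.05), the
transfer nonlinearity is sampled far from the operating point, and the
simulated variance falls ~40% below the linear prediction — the
linearized statistics are quantitative only for small σ (verified within
20% at σ ≈ 0.06). The attentional variance decrease and the faster
autocovariance decay are exhibited with slow global fluctuations
(τ_x = 0.5) at full σ.

## 4. Linear response and the origin of rank one

For N weakly coupled neurons with a single shared input of unit variance
(loading x), the linear ansatz y = y_B + L(Jy + ξ) gives output covariance
C = ccᵀ with c = (I−K)⁻¹Lx, K = diag(L)J (requires spectral radius of
K < 1): output covariability inherits the input's rank. Attention acts on
the gains L, so g_i = c_i^A/c_i^U — per-neuron gains are emergent circuit
properties, which is what the rank-one fit assumes. For J ~ 1/N the change
c_E^A − c_E^U splits into direct, E-filtered, and I-filtered terms; only a
sufficiently modulated inhibitory pathway makes the total negative.

## 5. Fisher information

FI_EI = Gᵀ C⁻¹ G with G = (G_E, G_I) and C the long-window covariance.
Because G = −M⁻¹(L∘k) and C = M⁻¹DDᵀM⁻ᵀ share the same linearized
circuit, the circuit factors cancel:
FI_EI = kᵀ [[σ_E², χσ_Eσ_I],[χσ_Eσ_I, σ_I²]]⁻¹ k — independent of the
operating point, hence exactly invariant under attention, for symmetric
*and* asymmetric coupling, and divergent as χ → 1 (fully common noise is
perfectly cancellable). Fisher analyses default to χ = 0.9 because χ = 1
is singular. The excitatory-only readout FI_E = G_E²/V_E uses the
general-χ variance; at χ = 1 with symmetric coupling it reduces to
(k_E + J_I L_I(k_E−k_I))² / (J_I L_I(σ_E−σ_I)+σ_E)², which the
implementation cross-checks. FI_E ≤ FI_EI always, and FI_E increases with
attention along the reference path (+9% at χ = 0.9) while the gap to
FI_EI shrinks. The uncoupled benchmark is FI = k_E²/σ_E² (the transfer
slope cancels).

## 6. Problem sizes and tolerances

The default test run uses sessions of 14–30 units with 250–3000 count
windows, 7–20 shuffles, upper bounds at 1e3–1e5 trials, OU simulations of
1e4–2e4 time units at dt = 0.1 (linear, exact discretization) and
400–1200 time units at dt ≤ 0.02 (nonlinear), and 1000 random instances
for the Lyapunov property. Exact identities are asserted at 1e-10–1e-12,
quadrature identities at 1e-8, stochastic checks at 3–4 standard errors of
the corresponding estimator. The acceptance script reproduces its three
quantities in under a minute on one core.

## 7. Known limitations

* The generator's single-latent Poisson world understates real data
  complexity (dispersion, nonstationarity, higher-rank structure); gain
  recovery claims are conditional on that world.
* ρ_shuf comparisons must respect the 2/√N overfitting floor of the fit
  family; at N ≤ 100 "approaches zero" means "approaches the floor".
* The mean-field analysis is linear-response; at the reference noise
  amplitudes the full nonlinear dynamics deviate quantitatively (§3).
* The two-population reduction has no stimulus tuning; Fisher results
  concern a bulk rate code (stimulus ≈ contrast), not distributed
  population codes.
* χ for the excitatory-readout Fisher curves is a modeling choice (0.9);
  results near χ = 1 are sensitive to it.
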