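# Methods

`hemovasc` implements a three-layer stack for systemic-circulation
modelling: a mechanistic 1D pulse-wave solver on a network of compliant
arteries with structured-tree outflow boundary conditions, a per-vessel
physics-informed neural emulator of that solver over space, time, and
biophysical parameters, and a Bayesian calibration layer that infers
vessel-stiffness parameters from noisy flow waveforms under a
Gaussian-process model-discrepancy likelihood.  This note records the
models, the numerical choices, and the limits of what the fixture-scale
experiments demonstrate.

## 1. Mechanistic model

**Large vessels.**  Each vessel is a compliant axisymmetric tube carrying
cross-sectionally averaged flow q(x,t) (mL/s), pressure p(x,t), and area
A(x,t).  Mass and momentum balance read

    A_t + q_x = 0
    q_t + (q^2/A)_x + (A/rho) p_x = -(2 pi nu R / delta) (q/A),

with blood density rho = 1.057 g/cm^3, viscosity mu = 0.032 g/(cm s),
nu = mu/rho, R = sqrt(A/pi), and a Stokes boundary layer of thickness
delta = sqrt(nu T / 2 pi) supplying the friction term (T is the cardiac
period).  The wall is elastic with a linear stress-strain law,

    p - p0 = (4/3) (Eh/r0) (sqrt(A/A0) - 1),
    Eh/r0 = f1 exp(-f2 r0) + f3,

so smaller vessels are stiffer.  Internally all pressures are CGS gauge
(barye); mmHg appears only at I/O (1 mmHg = 1333.22 barye).  p0 defaults to
zero gauge.

**Small vessels.**  Each terminal vessel feeds a self-similar binary tree
with daughter radii alpha*r and beta*r (beta = 0.60 < alpha < 1, length =
lrr * r0 with lrr = 50), truncated below a minimum radius rmin.  In each
small vessel the linearised equations are solved in the frequency domain,
giving the input impedance of a vessel from its outlet impedance through
the travelling-wave formula with compliance C = 3 A0 / (2 Eh/r0), complex
wave speed c = sqrt(A0 (1 - F_J) / (rho C)), and the Womersley factor
F_J = 2 J1(w0) / (w0 J0(w0)), w0 = i^{3/2} r0 sqrt(omega/nu).  At omega = 0
the vessel contributes the Poiseuille resistance 8 mu lrr / (pi r0^3).
Daughters combine in parallel; leaves terminate with zero outlet impedance,
and a vessel whose daughters would fall below rmin is treated as terminal.
Since subtrees with equal root radius are identical, the recursion is
memoised on the exponent pair (i, j) with r = alpha^i beta^j r_root; a
brute-force enumeration oracle pins the memoised result in the tests.

Two practical points about the tree that the literature states rarely and
the tests encode explicitly:

- *rmin is physical, not numerical.*  The rmin -> 0 limit of the root
  resistance exists only when alpha^3 + beta^3 > 1 (parallel conductance
  growth beats per-vessel resistance growth).  With beta = 0.60 that holds
  near the top of alpha's physiological range (e.g. 0.94) but not at 0.90,
  where the resistance grows slowly without bound as rmin shrinks.  rmin is
  therefore an arteriolar cutoff scale to be fixed per vessel (1e-3 cm for
  the descending aorta's tree, 1e-4 cm elsewhere), not a refinement knob.
- *Bessel evaluation.*  F_J uses the power series below |w0| = 1e-4 and the
  asymptotic tail 2i/w0 above |w0| = 600, where direct evaluation would
  overflow; both switchovers are far from the physiological range.

The root impedance Z(omega_k) is evaluated at the m harmonics
omega_k = 2 pi k / T (conjugate-symmetric completion, real-forced Nyquist
bin) and inverted to a real convolution kernel z(t) with the convention
that Dt times the circular discrete convolution approximates the continuous
periodic convolution p(L,t) = int q(L, t - tau) z(tau) d tau.

## 2. Solver numerics

The hyperbolic system is integrated in conservative form with the two-step
(Richtmyer) Lax-Wendroff scheme; the pressure-gradient term integrates
exactly into the flux B(A) = 4 f A^{3/2} / (9 rho sqrt(A0)) because f and
A0 are constant within a vessel.  Boundaries are closed with Riemann
invariants w+- = u +- 4c, c = sqrt(2 f / 3 rho) (A/A0)^{1/4}:

- *Inlet:* prescribed flow; area from the outgoing invariant (scalar
  Newton).
- *Junctions:* flow conservation and pressure continuity coupled with the
  three outgoing invariants; 3x3 Newton on the areas with an analytic
  Jacobian, converged to ~1e-13 relative, which leaves junction residuals
  at machine precision in the converged fields.
- *Terminal vessels:* the boundary pressure equals the running discrete
  convolution over the trailing period of flow history, with the newest
  flow sample entering implicitly; a scalar Newton solves it jointly with
  the outgoing invariant.  An alternative frozen-cycle formulation (convolve
  only the previous cycle's history, iterate cycle to cycle) was tested and
  rejected: its cycle-to-cycle Picard map is not contractive for these
  trees and the iteration diverges.  The running-history form preserves the
  passivity of the impedance and converges unconditionally in our runs.

All boundary characteristic traces use a predictor-corrector (midpoint)
integration of the foot position and of the friction source, which keeps
the scheme second order up to the boundary: the measured convergence order
of midpoint pressure under joint dx, dt halving is 2.0 on the single-vessel
fixture.  Scheme-order measurements use a fixed-time protocol from smooth
compatible initial data (inflow pulse centred mid-cycle so q_in(0) ~ 0);
an impulsive start excites physical ringing whose resolution-dependent decay
masks the asymptotic order.

Runs start from (A, q) = (A0, 0) and repeat cardiac cycles until the
normalised wall-strain field changes by less than `cycle_tol` (default
1e-3) between cycles; the converged cycle is returned on an m x n grid.
The time step is derived from a conservative CFL bound and rounded so the
output stride divides it; a CFL audit runs every step.  Periodic
convergence below ~1e-6 is slow (a lightly damped fundamental-frequency
mode circulates between the flow-clamped inlet and the partially
reflecting tree), which is why physical audits (mass conservation, DC
consistency) rather than strict periodicity at machine precision are the
solver's acceptance checks.  Measured on the fixtures: per-period mass
defect ~1e-5 of inflow volume; mean terminal pressure under constant
inflow within 1e-8 relative of q * Z(0).

## 3. Inflow surrogate

The inlet waveform is a Gaussian-process fit to sampled flow: time is
embedded on the unit circle, t -> (cos 2 pi t/T, sin 2 pi t/T), and a
Matern 5/2 kernel acts on chordal distance, making the posterior mean
exactly T-periodic and twice differentiable.  Hyperparameters (signal
variance, lengthscale, noise) maximise the marginal likelihood with
multi-start L-BFGS (scikit-learn); the mean's time derivative is evaluated
analytically and checked against central differences.  The synthetic
inflow generator is a periodised two-Gaussian systolic pulse (peak ~190
mL/s at 0.16 T, secondary wave ~30 mL/s at 0.40 T, mean ~38 mL/s over a
1 s period), sized so the single-trunk fixtures sit in a normal pressure
range (~55-145 mmHg).

## 4. Physics-informed emulator

One tanh network per vessel maps (x/L, cos 2 pi t/T, sin 2 pi t/T,
theta-normalised) to (q_hat, p_hat), standardised by per-vessel simulation
statistics.  Periodicity is exact by the time embedding.  On the root
vessel, flow is mixed with the inflow surrogate,
q_tilde = cos(pi x/2L) q_in(t) + sin(pi x/2L) q_hat, so the inlet condition
holds identically.  Area follows from predicted pressure through the wall
law, with the stiffness evaluated at the per-sample theta.  Architecture
variants: a modified MLP (two input-encoder streams mixed into every hidden
layer) and random weight factorisation (W = diag(exp(s)) V, s ~ N(0.5,
0.1) at initialisation); the base 13-input, 5x128 configuration with biased
hidden layers and a bias-free linear head counts exactly 68,096 trainable
scalars per vessel (612,864 for nine vessels, 1,157,632 for seventeen);
`count_parameters` reports encoder and RWF scale parameters separately from
that base count.

Four losses: junction flow/pressure continuity; PDE residuals (mass and
momentum, nondimensionalised per vessel by q_std/L and q_std/T); outflow
mismatch between predicted terminal pressure and the convolution of
predicted terminal flow with impedance kernels precomputed on a Latin
hypercube over theta; and mean-squared mismatch with solver midpoint data.
Input derivatives for the PDE residuals are exact: the networks propagate
forward-mode tangents along the x and t directions, and the reverse pass is
hand-derived through the joint activation/tangent computation, so training
receives exact weight gradients of derivative-dependent losses.  The
environment provides no deep-learning framework, so this machinery is
implemented directly in numpy and pinned against finite differences in the
tests.

Loss weights follow the gradient-norm balancing rule: every 5 steps,
lambda_i,new = (sum_j ||grad L_j||) / ||grad L_i||, blended by an
exponential moving average with decay 0.9.  Optimisation is Adam with a
cosine-decayed learning rate (1e-3 -> 1e-4, mini-batches of 512 points at
full scale; fixture studies use 256), optionally followed by a full-batch
L-BFGS polish with the weights frozen: on desk-scale problems mini-batch
Adam stalls on the stiff composite objective well above the residual floor,
and the deterministic quasi-Newton phase reduces the total loss by another
order of magnitude.  Training-budget defaults at fixture scale (1500 Adam
steps plus up to a few thousand L-BFGS iterations, width 32, depth 3) keep
a full study within minutes on one CPU; they are choices of study size, and
§7 discusses what they do and do not reach.  A data-free mode drops the
simulator loss; a data-only mode drops the physics losses and serves as the
equal-architecture, purely data-driven baseline.  Warm-starting from a
checkpoint (transfer to a perturbed geometry) is supported through
checkpoints keyed to a topology hash.

## 5. Experiment designs and synthetic observations

Parameter designs are maximin-improved Latin hypercubes over the
physiological box (f2 in [25, 45] 1/cm, f3 in [2e5, 9e5] g/cm/s^2 per
group, alpha in [0.85, 0.94]; f1 = 2e8 fixed).  Simulation datasets store
flow and pressure at vessel midpoints at 20 equidistant times, mirroring
clinically realistic waveform sampling; failed solver runs at extreme
parameter corners are excluded and logged, since exclusions bias the
design's coverage.  Synthetic "measured" flow is a solver run at a known
theta plus correlated noise drawn from the same Matern 3/2 discrepancy
process the likelihood assumes: per-vessel sigma_i^2 targets a
signal-to-noise ratio of 10 (waveform variance over sigma^2), the
lengthscale is shared at T/4, and white noise tau = 0.1 sigma_i^2.  These
noise settings define the synthetic study conditions and are recorded with
every generated observation set.

## 6. Bayesian inverse UQ

The likelihood per observed vessel is multivariate normal with mean the
forward map's 20-point flow waveform and covariance
Sigma_i = K_disc,i + tau_i I, K_disc the Matern 3/2 kernel — a
Kennedy-O'Hagan style discrepancy term capturing time-correlated model
error and noise-model mismatch.  Priors: theta uniform over its box
(sampled through a logit transform with Jacobian), l_i ~ U(0, T),
sigma_i^2 ~ Exponential(scale = observed range), log tau_i ~ N(-2, 1).
The fixture studies fix the noise hyperparameters at their generating
values to isolate emulator-driven error in parameter recovery, mirroring a
controlled synthetic-validation design.

Sampling: a No-U-Turn sampler written for this package (dual-averaging
step-size adaptation to 0.8 target acceptance, diagonal mass matrix from
the second half of warmup, slice-variable tree building with a divergence
guard) when gradients are available — the emulator supplies exact
d flow/d theta through its forward-mode tangents; and Haario-style adaptive
Metropolis for gradient-free forward maps, used for the
solver-in-the-loop reference posterior.  Convergence is monitored by the
potential scale reduction factor (arviz) with a 1.1 threshold, after which
further draws can be appended.  The NUTS implementation is validated
against analytic conjugate posteriors and prior-recovery KS tests.

Posterior summaries: push-forward credible bands evaluate the forward map
at subsampled draws (50 by default); prediction bands add noise replicates
(several per draw, stabilising the tail quantiles).  Divergence between
posteriors is reported as moment-matched Gaussian KL by default — the
estimator is named with every result — with a 1-nearest-neighbour
estimator as a cross-check; both are validated on Gaussian pairs with known
KL.

## 7. Fixture-scale results and limitations

The study sizes are deliberately small (single-vessel and three-vessel
networks, 2-3 inferable parameters, tens to a few hundred solver runs,
minutes of CPU) so the full stack runs end to end in a test suite.  At this
scale:

- Parameter recovery is well calibrated: pooled 95% credible-interval
  coverage over 20 repeated synthetic experiments is at or above nominal,
  and push-forward 95% prediction bands cover fresh noisy replicates.
- The emulator-based posterior sits very close to the solver-in-the-loop
  posterior: moment-matched KLs of a few hundredths of a nat for both the
  16- and 64-simulation emulators.  At that level the 16 -> 64 ordering is
  within estimator and Monte-Carlo noise and can invert between seeds;
  the acceptance study exercises the full comparison machinery, but a
  robust KL-versus-training-data trend needs problems hard enough that the
  small-data emulator is visibly biased.
- Whether physics losses beat data-only training *at equal data* (32
  simulations each) depends on the optimisation budget: against a
  mini-batch-only data fit the physics-informed emulator wins clearly,
  while a data-only fit given the same full-batch quasi-Newton polish can
  interpolate 32 runs of this smooth low-dimensional map to a similar
  floor.  Both RMSEs are reported rather than summarised into a claim.
- The desk-scale physics-informed emulator does *not* overtake a
  converged purely data-driven surrogate trained on 4x the simulations.
  With a 3-dimensional smooth parameter-to-waveform map and 20 fixed output
  times, 128 Latin-hypercube runs essentially interpolate the map to its
  floor (~1 mL/s total RMSE here), while surpassing that floor requires
  driving PDE residuals to near-solver fidelity — a training budget orders
  of magnitude beyond minutes on one CPU.  The data-budget advantage of
  physics-informed training is therefore expected to emerge with larger
  parameter dimension and training horizons, not at this fixture scale, and
  the corresponding comparison in the acceptance suite documents the
  measured gap rather than hiding it.

Other known limitations: the synthetic data generator shares its noise
process with the likelihood (no structural misspecification is exercised);
inflow and geometry are treated as known, so their measurement uncertainty
is not propagated; the solver's boundary treatment is a reconstruction
validated through physical audits rather than against an external
reference implementation; and no viscoelastic wall behaviour, vessel
taper within a segment, or shock capture is modelled (none is expected
under physiological flow).
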