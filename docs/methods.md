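# Methods

## Model

### Neurons and synapses

Recurrent neurons follow adaptive exponential integrate-and-fire (AdEx)
dynamics, written per membrane capacitance so every current has units
mV/ms and no capacitance constant appears:

    dV/dt = [-(V - E_L) + Delta_T exp((V - V_T)/Delta_T)] / tau_m
            + X(t) + R(t) - w,
    tau_w dw/dt = -w.

A spike is recorded when V crosses V_th; V is then held for tau_ref and
reset to V_re, and w jumps by B.  V is clamped below at V_lb.  Defaults
(tau_m = 15 ms, E_L = V_re = -72 mV, V_T = -60 mV, V_th = -15 mV,
Delta_T = 1.5 mV, tau_ref = 1 ms, tau_w = 150 ms, B = 0.267 mV/ms,
V_lb = -100 mV) are the reference parameter set of the study conditions the
package reproduces; they are not meant to be tuned.

Synaptic input is a sum of exponentially filtered presynaptic spike trains.
Each kinetics class b in {E, I, X} has kernel eta_b(t) = exp(-t/tau_b)/tau_b
with unit integral (tau_E = 8, tau_I = 4, tau_X = 10 ms), so time-averaged
currents are independent of the time constants.  Inhibition is faster than
excitation to avoid synchrony artifacts at strong coupling.

### Connectivity

Each presynaptic neuron in population b draws exactly round(p_ab N_a)
postsynaptic targets in population a, uniformly with replacement; repeated
draws accumulate multiplicity, giving weights (#contacts) x J_ab.  Defaults:
p_EE = p_IE = p_IX = 0.1, p_EI = p_II = p_EX = 0.2; J_EE = 0.4,
J_IE = 0.83, J_EI = J_II = -1.67, J_EX = J_IX = 0.47 mV; N_E = 4000,
N_I = 1000, N_X = 4000.  Spatially structured graphs draw targets with
probability proportional to a wrapped-Gaussian kernel of the periodic
displacement in physical space (unit square) and orientation space (unit
circle, fractions of 180 degrees); the fixed out-degree keeps the realized
mean connection probability exactly at p_ab.

Network rescaling multiplies all p_ab and J_ab by (5000/N)^(1/4) and scales
population counts proportionally, which leaves the coupling table unchanged
at N = 5000 and makes the balance parameter scale like N^(-1/2).

## Mean-field theory

### Units

Rates are in Hz (1/s) while currents are quoted in mV/ms, so the mean-field
combination K_ab J_ab r_b carries mV/s.  The package keeps one explicit
constant, MV_MS_TO_MV_S = 1000: a raw injected current S (mV/ms) enters the
rescaled drive as s = eps * S * 1000, the inverse-gain matrix is
D = diag(1000/g) for a gain g in Hz per (mV/ms), and all reported
mean-input fields are converted back to mV/ms.  With these conventions the
amplified rate response g*s/eps reduces to the physical g*S.

eps = 1/(K_EX J_EX) itself is stored as a pure number (its reciprocal
carries mV); at the reference parameters eps = 1/376 = 0.00266.

### Discrete populations

The balanced limit solves W r + X = 0.  The solver treats W as singular
when its smallest singular value is below 1e-8 of the largest — this
separates the exactly structured cases (e.g. the three-population partial
stimulation matrix, singular by construction) from generic ones — and then
raises rather than returning garbage, since no finite mean input exists in
that limit.  The linear correction r = (eps D - W)^{-1} X assumes a
rectified-linear population transfer r = g [I - I0]_+ and is exact for the
model only in the positive orthant; negative entries are reported, never
clipped, and flag the regime where the linear theory is invalid.

Nullspace quantities come from the singular triplet of the smallest
singular value; v0 and v2 use the sign convention that their first nonzero
entry is positive, which reproduces the conventional orientation
[1-q, -q, 0] / [1, -1, 0] for the partial-stimulation geometry.
Multi-dimensional nullspaces return orthonormal bases and disable the
scalar amplified-component formula.

### Continuously indexed networks

Fields live on a periodic grid over [0,1)^2 x [0,1).  The transform
convention is the forward integral u~(n,k) = \int u e^{-2 pi i (x.n + k
theta)}, realized as an FFT divided by the number of grid points.  Gaussian
kernels have analytic coefficients w~_ab = wbar_ab exp[-2 pi^2 (\|n\|^2
alpha_b^2 + k^2 alpha_{b,theta}^2)]; the corrected solver inverts the 2x2
per-mode matrices in closed form.

Two numerical choices matter for the balanced solver:

- **Factored inversion.**  W~ factors as W0 diag(decay_E, decay_I) per
  mode, so -W~^{-1} X~ is computed by solving with the well-conditioned
  zero-mode matrix W0 and applying the exponent *differences* analytically.
  This avoids spurious overflow/underflow at high modes where the raw
  Gaussian factors leave double-precision range.
- **Spectrum floor and divergence test.**  Stimulus modes below 1e-13 of
  the spectral maximum are dropped (they are FFT noise that the analytic
  growth factors would otherwise amplify).  The solver then refuses to run
  — "balance cannot be realized" — when the summed mode power in the top
  octave of retained frequencies is not smaller than in the previous
  octave, an operational version of the square-summability requirement.
  Feasibility agrees with the width calculus: a Gaussian stimulus needs
  alpha_E, alpha_I < beta_X = sqrt(sigma_X^2 + alpha_X^2).

Default spatial conditions (the visual-cortex example): alpha_E = 0.15,
alpha_I = alpha_X = 0.04, alpha_{E,theta} = alpha_{I,theta} = 0.1,
alpha_{X,theta} = 0.125, strengths scaled by 1.2 at N = 2e5 / N_X = 1.6e5,
giving eps = 5.54e-5.  The orientation-width assignment reads the two
recurrent populations as sharing alpha_theta = 0.1, the only consistent
reading of the source listing.  Stimuli are calibrated so the spatial rate
factor spans 10–20 Hz.  The default grid is 64x64 spatial x 32 orientation
points (solvers accept any shape; scans that average over orientation use
ntheta = 1).

## Simulator numerics

- Forward Euler with dt = 0.1 ms; the exponential term's argument is capped
  at (V_th - V_T)/Delta_T before evaluation (overflow safety that cannot
  affect sub-threshold dynamics).
- Synaptic filter states decay by the exact factor exp(-dt/tau) between
  events and jump by weight/tau on arrival; spikes are delivered with a
  one-step delay so the update is independent of neuron ordering.
- Initial V is uniform on [V_re, V_T] from the run seed; w and filter
  states start at zero; a 500 ms burn-in is excluded from all statistics.
  Both choices are free parameters of the protocol and are configurable.
- Per-neuron, per-epoch mean currents are accumulated online (no full
  traces needed for the gain fit); full traces are recorded only for a
  requested subset, subsampled every trace_stride steps.
- "Rheobase units" for displayed currents divide by the constant
  10.5 mV/ms.  Note this display constant does not equal the analytic EIF
  rheobase (V_T - E_L - Delta_T)/tau_m = 0.7 mV/ms for these parameters; it
  is retained as an opaque presentation divisor and affects no computation.

## Estimators

The gain fit scans candidate active sets (the m points of largest current),
fits slope and intercept jointly on each active set, scores the rectified
prediction on all points, and returns the best positive-slope fit; for more
than 1024 points the active-set sizes are subsampled.  The fit is exactly
scale-equivariant and recovers noiseless rectified-linear data to machine
precision.  Pooling E and I neurons into one scalar g matches the common-D
form of the corrected theory.  Fitted values at the reference scale come
out near 12 Hz per (mV/ms), which is also the default gain of the spatial
runners (the source conditions do not pin this value; it is exposed
everywhere).

Profile widths are estimated by fitting baseline + amplitude x
wrapped-Gaussian to the axis marginal by nonlinear least squares, seeded
from the half-maximum width.

## What the generator does and does not emulate

The simulator *is* the data generator: Poisson external drive, sparse
multi-contact connectivity and AdEx dynamics reproduce the study
conditions.  It does not emulate conductance-based synapses, synaptic
delays or depression, heterogeneous per-neuron parameters, non-periodic
boundaries, or structured (non-salt-and-pepper) orientation maps — so
passing tests support the theory under the stated idealizations, not for
arbitrary cortical data.  The linear rate correction is only trustworthy
where predicted rates stay positive; for very sharp stimuli at the full
spatial-network eps its amplified peaks leave the physical range, which is
the expected breakdown of linearity, not a solver defect.

## Problem sizes used by the test suite

The acceptance tests run the reference network (N = 5000, N_X = 4000) for
5 s with stimulation at 2.5 s — long enough that epoch rate estimates have
standard errors well under the 20% comparison band — and mean-field scans
on 48–64 point grids.  The dense real-space oracle for the Fourier solver
uses a 16x16x8 grid, the largest size at which explicit circular-
convolution matrices stay cheap.  All seeds are fixed in the tests.

## Known limitations

- No stability analysis of the balanced fixed point; the solvers report
  fixed points whether or not the spiking network would realize them.
- The balanced spatial solver requires kernels whose mode-wise determinant
  factorizes (equal column decay), which holds for the wrapped-Gaussian
  family used here but not for arbitrary anisotropic kernels.
- The divergence test is a heuristic on retained modes; stimuli engineered
  to be marginally summable near the Nyquist limit may be misclassified on
  coarse grids.
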