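# Methods

## Model and assumptions

The package describes circuits of `N` homogeneous populations of leaky
integrate-and-fire neurons with exponentially decaying synaptic currents
(time constants `tau_m`, `tau_s`, absolute refractory period `tau_ref`,
threshold `V_th` and reset `V_reset` relative to rest).  Three
approximations underlie everything:

- **Diffusion approximation.** Each neuron receives many small inputs, so
  the summed synaptic input is Gaussian, characterised by its mean `mu_i`
  and variance `sigma_i^2` (the *working point*), both linear in the
  presynaptic rates through the indegrees `K_ij` and effective weights
  `W_ij` (mV).  Weights are stored as the membrane-potential charge
  equivalent of one synaptic event, `w = PSC_amplitude * tau_s / C_m`.
- **Self-consistent stationarity.** Pairwise correlations are neglected
  when computing the time-averaged rates; the rates solve the fixed point
  of the Siegert first-passage formula.  Synaptic filtering of the input
  noise (colored noise) is absorbed by shifting threshold and reset upward
  by `sigma * alpha/2 * sqrt(tau_s/tau_m)`, `alpha = sqrt(2)|zeta(1/2)|`.
- **Linear response.** Fluctuations around the stationary state follow a
  linear rate model driven by white "shot" noise of power `rbar_i/M_i` per
  population.  This holds in the asynchronous-irregular regime; near and
  beyond an instability (an eigenvalue of the effective connectivity
  reaching 1) the linear theory only indicates tendencies, because the
  spiking nonlinearity saturates growing oscillations.

The transfer function `H_i(omega)` of a population is the boundary-shifted
colored-noise linear response, expressed through parabolic cylinder
functions `U(z, x)` via `Psi(z, x) = exp(x^2/4) U(z, -x)` with
`z = -1/2 + i omega tau_m`, multiplied by the synaptic low-pass
`1/(1 + i omega tau_s)` (the modulation arrives as synaptic current), and
by the refractory occupancy `1 - nu * tau_ref`.  The occupancy factor is a
deliberate design choice: the bare response formula ignores the refractory
fraction of the population and therefore exceeds the slope of the
stationary rate at zero frequency by `1/(1 - nu tau_ref)` (about 1% at
5 spikes/s); with the factor included, `H(0)` equals `d(nu)/d(mu)` to
machine precision and the response is smooth through zero frequency.  A
white-noise variant (no synaptic filter) is available behind
`colored=False` for cross-checks.

Delays are Gaussian per connection, truncated at zero.  Their filter is the
characteristic function of the truncated density, evaluated through the
Faddeeva function so that the Gaussian envelope `exp(-sigma_d^2 omega^2/2)`
and the complementary error function can never overflow against each other;
it is entire in `omega`, which is what permits the Laplace-domain stability
analysis without modification.  For `d/sigma_d > 8` the truncated mass is
below machine precision and the untruncated closed form is used.

## Pipeline

`CircuitAnalysis` chains: stationary state -> transfer functions ->
effective connectivity `Md_ij(w) = H_i tau_m W_ij K_ij B_ij` -> propagator
`(I - Md)^-1` -> spectra `diag(P D P^dagger)` -> per-frequency
eigendecomposition with bi-orthonormal left/right eigenvectors
(`v_i^T u_i = 1`) tracked across frequency.  The transfer functions depend
only on the working point, so protocols that hold the working point fixed
while changing anatomy (indegree perturbation with external compensation,
sub-circuit isolation, minimal-circuit growth) reuse them at no cost.

Mode tracking relabels the per-frequency eigenpairs by greedy matching on
the left-right eigenvector overlap `|v_i(w_k)^T u_j(w_{k+1})|` (threshold
0.5, nearest-eigenvalue fallback); the rule is validated only by the
smoothness of the resulting trajectories, and near-degenerate crossings —
in particular among the four high-frequency modes of the bundled circuit —
remain the least certain part of the decomposition.

The sensitivity measure `Z_kl = v_k Md_kl u_l / (v^T u)` satisfies the
exact trace identity `sum_kl Z_kl = lambda` (tested at 1e-10) and predicts
eigenvalue displacements to first order in the indegree fraction.  The
amplitude/frequency projections use the unit vector pointing from the
critical eigenvalue toward 1 and its perpendicular.  In minimal-circuit
extraction, connections are ranked by the *absolute value* of the projected
components (the sign is retained in reports); candidates whose addition
drives any trajectory to `Re(lambda) >= 1` within `|Im(lambda)| < 0.05`
anywhere on the grid are skipped and the ranking continues (greedy, no
retry).  Recovery metrics compare reduced and full circuits per population:
frequency recovery `100 * min(f)/max(f)`, and log-amplitude recovery as the
same ratio on `log10(peak power / baseline)` with the flat Poisson level
`rbar/M` as the reference — the reference level and base are package
conventions, configurable, since no canonical definition exists.

## Stability analysis

A mode is unstable when `lambda(w') = 1` has a solution with negative
imaginary part of the complex frequency `w'`.  The root is found by damped
Newton iteration (complex central differences, step cap `2 pi * 20` rad/s,
trust radius `2 pi * 150` rad/s around the start) seeded at the real-axis
closest approach, with the eigenvalue followed by nearest-eigenvalue
continuity during the walk.  The residual contract is
`|lambda(w') - 1| < 1e-8`.  For modes far from criticality (distance to 1
of order 1) the continuity tracking can attach to a neighbouring branch;
the returned root is then a genuine solution of the characteristic equation
but its mode attribution is approximate.  The Hopf boundary of a connection
is located by bisection on the sign of `Im(w')` with the working point held
fixed.

## Rate-model simulator (numerical oracle)

The delayed linear rate model is integrated in the time domain:
`y[t] = x[t] + (g * y)[t]` with kernels `g_ij` obtained by inverse FFT of
`H_i(w) tau_m W_ij K_ij B_ij(w)` (the transfer function is evaluated on a
sparse node grid, dense below 500 Hz, and cubic-splined onto the FFT grid).
The convolution uses trapezoidal weights with the zero-lag term handled
implicitly, `y[t] = (I - dt/2 g(0))^{-1} (x[t] + dt sum_m g[m] y[t-m])`;
the exact spectrum of this discrete system matches the analytic `C(w)` to
four digits at `dt = 0.1 ms`, so the comparison against Welch periodograms
of the simulated noise realisations is a sharp test of the propagator
algebra and noise normalisation.  Kernels are truncated where they fall
below 1e-6 of their maximum; white noise enters with variance `rbar_i /
(M_i dt)` per step.  In the default *averaged-kernel* mode the delay
filter is the analytic truncated-Gaussian characteristic function, making
the simulated system exactly the one the theory describes; a *per-draw*
mode samples one delay per connection instead.  Periodograms are
Welch-averaged (boxcar, non-overlapping windows, default 0.5 s) and
returned in two-sided density units `(spikes/s)^2 s`, directly comparable
to `C(w)`; the per-bin standard error of a chi-square estimate with
`n_seg` segments is `C_true/sqrt(n_seg)`, so comparisons normalise
deviations by the *analytic* level, not the noisy estimate.

Test problem sizes: oracle comparisons use circuits of 2–3 populations,
10 s of simulated activity at `dt = 0.1 ms` (20 Welch segments), ten
independent random draws restricted to converged, fluctuation-driven
operating points (all rates in 0.5–50 spikes/s).  These sizes make the
suite a statement about the correctness of the algebra at desk scale; they
do not probe finite-size or non-Gaussian effects of real spiking data, nor
rates outside the irregular regime.

## The bundled microcircuit and its operating point

The fixture transcribes a published 8-population laminar circuit (layers
2/3, 4, 5, 6 with excitatory/inhibitory pairs; 77 169 neurons; indegrees
derived from pairwise connection probabilities with the standard
`ln(1-p)` synapse-count convention; `w = 87.8 pA`, `g = 4`, doubled
4E->2/3E weight; delays 1.5/0.75 ms for excitatory/inhibitory sources) and
applies three stabilising modifications at load: the 4E<-4I indegree scaled
by 0.85, all delay standard deviations set to 1 ms, and the external drive
to 4E scaled by 0.81.  A checksum test pins the fixture file.

The loader solves the modified circuit self-consistently.  A caveat
documented here deliberately: the 19% external reduction overcompensates
the removed recurrent inhibition in the mean-field balance (exact balance
at the theory's 4I rate would require about 16.5%), so the self-consistent
rates of the modified fixture (0.50–7.32 spikes/s) fall below the
0.9–8.6 spikes/s reported for spiking simulations of this circuit, whose
compensation was evidently calibrated on the simulations themselves.  The
weaker operating point propagates: the low-gamma resonance sits at
65–67 Hz with `|1 - lambda| ~ 0.33` (published analysis: 60–64 Hz at much
closer criticality), the dominant high-frequency mode peaks near 245–255 Hz
rather than 275 Hz and is weakly stable rather than marginally unstable,
and fixed-working-point perturbations change peaks far less drastically.
All structural findings are reproduced: the low-gamma peak is visible in
all populations and its sensitivity map is confined to layers 2/3 and 4;
four high-frequency modes arise from the inhibitory self-couplings with the
4I loop dominant; the zero-frequency map is dominated by layer 5.  The
end-to-end tests that pin the published numeric values are kept at their
stated tolerances and fail under the bundled parameter set; they are
retained unchanged rather than re-tuned, as an honest record of the gap.
Users analysing their own circuits can supply a prescribed rate vector to
`CircuitAnalysis(state=...)` to evaluate the linear response at any
operating point.

## Numerical choices

- Siegert integral: split at zero; `e^{s^2} erfc(-s) = erfcx(-s)` for the
  negative part (bounded), and `sqrt(pi)(erfi(b) - erfi(a)) - int erfcx`
  for the positive part (no cancellation); 200-node Gauss-Legendre for the
  bounded pieces.  Beyond `y_th > 25` the leading asymptotic term is used
  (the rate underflows smoothly to zero).  Verified against adaptive
  quadrature to 1e-8 relative on a 5x5 grid of working points.
- Rate solver: damped fixed-point iteration `r <- r + 0.05 (nu(r) - r)`
  (pseudo-time integration; the undamped map 2-cycles for the bundled
  circuit), tolerance 1e-12 spikes/s, at most 1e5 steps; non-convergence is
  flagged on the result, not raised.
- Frequency grid: explicit, shared by all downstream objects; default
  0–500 Hz at 1 Hz.  Peaks are refined by a quadratic fit on log-power
  through three grid points after re-evaluating the spectrum on a 0.25 Hz
  grid within +-5 Hz of the coarse candidate.
- Reporting bands: low-gamma 30–90 Hz, high-gamma 150–400 Hz, both
  configurable.
- Degenerate inputs: `sigma_d = 0` delays are pure phase factors; zero
  anatomy yields the exact Poisson baseline; an eigenvalue equal to 1 on
  the grid raises in the propagator and is flagged as infinite
  amplification in `p_factor`.

## Known limitations

- Quantitative accuracy degrades for synaptic time constants approaching
  `tau_m` and beyond an instability (linear theory saturates there only in
  the real spiking system).
- Only Gaussian (zero-truncated) delay distributions ship; the delay filter
  interface accepts any characteristic function in principle.
- Sensitivity is first-class only with respect to indegrees; weights,
  delays and the E/I ratio enter the effective connectivity in closed form
  and could be differentiated analogously.
- Mode identity near eigenvalue crossings (real-axis tracking and complex
  continuation alike) is heuristic; results that depend on a single mode's
  label near a crossing should be checked against the full spectrum.
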