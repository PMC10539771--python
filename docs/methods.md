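# Methods

## Model and conventions

One spin-1/2 in the rotating frame evolves during each waveform slice under
`H = wz*Iz + w1*(cos(phi)*Ix + sin(phi)*Iy)` (offsets `wz` and rf field
`w1 = 2*pi*nu1` in rad/s, I = sigma/2), and a shaped pulse is the ordered
product `Ueff = Un ... U1` of the closed-form slice exponentials.
Propagators act as `exp(-i*beta*I_phi)`; conjugation by `exp(-i*beta*Ix)`
maps `Iz -> Iz*cos(beta) - Iy*sin(beta)`, so a hard 90x takes +z to -y.
Internally all angular frequencies are rad/s and phases radians; user-facing
amplitudes are Hz, shape files store percent amplitude and degrees.  SU(2)
elements are carried as Cayley-Klein pairs `(a, b)` so ensemble propagation
is elementwise array arithmetic; unitarity is then structural, and drift
through 10^4 slices stays below 1e-12 (tested).

## Design target and quality factor

The target is a uniform rotation by `beta` about a transverse axis with
quadratic offset-dependent phase `alpha(wz) = Q*tp/(2*Omega)*wz^2 + alpha0`.
`Omega` is read as the *full* optimised bandwidth; offsets span
`[-Omega/2, +Omega/2]`.  Performance is the real propagator overlap
`Phi = Re tr(UT^dag Ueff)/2`, averaged over the offset x B1 grid.  The
normalisation by the Hilbert-space dimension makes `Phi = 1` the exact
optimum, the scale on which quality factors like 0.9999 are meaningful; the
real part (rather than the modulus) is kept deliberately so both members of
a 90/180 pair are forced onto one global sign convention — the modulus
variant exists as an option.  `alpha0` is a pure gauge (tested as the
phase-shift covariance of `Phi`) and defaults to 0.

Ensemble grids default to 101 uniform offsets across the band (51 at desk
scale) and, when B1 robustness is requested, 5 rf-amplitude multipliers
spanning the +/- range with Gaussian weights of sigma = half the range,
renormalised.  The grid density and sigma are package choices; results are
insensitive to doubling either.

## Exact gradients

Phase controls enter each slice by z-conjugation,
`U_k(phi) = exp(-i phi Iz) U_k(0) exp(+i phi Iz)`, so
`dU_k/dphi = -i[Iz, U_k]` exactly.  With cached forward and backward
cumulative products the full gradient of the ensemble overlap reduces to
first differences of one scalar stream per grid point and costs O(n) per
point — no finite-difference step enters anywhere.  For x/y-controls the
slice derivative is the closed-form Frechet derivative of the 2x2
exponential (the upper-right block of the augmented block-triangular
exponential, evaluated analytically for a traceless generator).  Both
routes are verified in the tests against central finite differences
(relative error < 1e-6) and against a brute-force 4x4 `expm` oracle
(1e-12).

Ascent is SciPy's L-BFGS-B (history 20, strong-Wolfe line search) on
`-Phi`; stopping at gradient infinity-norm 1e-8, relative stagnation
1e-12, or the node's iteration cap.  Runs are deterministic given the
initial pulse; the initial phase waveform is a seeded low-order random
Fourier series (8 orders, coefficient scale 1/m) so cold starts are smooth.

## Morphic staging

Cold starts at wide bandwidth find poor 90s, so design parameters move in
small warm-started increments: bandwidth ramps (e.g. 10 -> 50 kHz in 5 kHz
steps), duration expansions (slices appended with edge-value
initialisation, 30 us default steps), and finally B1 robustification over
the Gaussian ensemble, itself ramped over the +/- range in quarter steps
before full-budget polishing at +/-5 %.  Every node records its warm-start
provenance; pair selection maximises `min(Phi90, Phi180)` over the shared
`(Q, tp, Omega)` grid, which guarantees both members are scored against the
identical `alpha(wz)`.

The bootstrap seed (smooth random phases at a narrow band, then ramping)
replaces the unspecified precursor shapes a production workflow might reuse;
it reproduces the easy-to-hard morphing idea without importing external
waveforms.

## Reference families

* Hard pulses: single-slice rectangles, duration `beta/(2*pi*nu1)`.
* Chirps: linear or constant-adiabaticity frequency sweeps with
  sine-squared edge smoothing.  The CA law rescales the sweep rate by the
  squared envelope (renormalised to the full excursion), the standard
  offset-independent-adiabaticity reading; with the default 40 % smoothing
  this is a WURST-like envelope, and a 450 us / 50 kHz / 10 kHz-peak CA
  chirp inverts to Mz < -0.95 over the central 80 % of its band (tested by
  Bloch simulation).  A plain linear sweep of that length shows strong
  edge ripple — visible in the tests as the motivation for the CA law.
* BURBOP baselines: the same optimiser with Q = 0 (constant-axis target).
* Scaled refocusing 180: re-optimised at twice the rf amplitude and half
  the duration at fixed Q and Omega, halving the quadratic coefficient —
  the flat-phase echo condition `2*alpha180 - alpha90 = const`.  Naive 2x
  time compression of the existing 180 provably quarters the coefficient
  (the kappa-scaling identity) and fails the condition, which is why a
  re-optimisation, not a rescaling, is implemented.

## Sequence simulation

Up to three homonuclear spins-1/2 (Hilbert dimension <= 8) evolve as
density matrices from `sum Iz`.  Shaped pulses apply the full Hamiltonian
(offsets + J + common rf) piecewise with cached per-(pulse, phase)
propagators; scalar coupling defaults to the full strong-coupling `I.I`
form (weak `IzIz` is available for closed-form checks).  Detection is
`sum I-`; a spin at offset +nu appears at +nu after the FFT.  Transverse
relaxation is an optional per-spin dephasing applied during delays and
acquisition only: the coherence between two product states decays with the
summed `1/T2` of the spins whose state differs.  Gradient coherence
selection is emulated by projecting onto the -1 coherence after the
excitation pulse; for the single-spin echo element this makes the
delay-evolution cancellation exact and the detected signal equal to
`-c * b180^2` in Cayley-Klein components, which is also how the
`2*alpha180 - alpha90` phase law is verified.

Spectra are FFTs with optional zero-fill and exponential apodisation
(half-weighted first point); polynomial phase correction multiplies by
`exp(-i*(p0 + p1*dnu + p2*dnu^2))` about a pivot (default: the carrier,
matching `alpha(0) = alpha0`).  Decay times come from a log-linear seeded
nonlinear mono-exponential fit; non-decaying inputs return an infinite
time constant with a warning flag rather than an error.

## Problem sizes and numerical choices

* Slice duration defaults to 0.5 us (1440 slices at 720 us) — at least 20
  slices per rf period across the band.  The test suite and the acceptance
  script use 1 us slices and 51-101 offsets: evaluating a fixed shape at
  either resolution agrees to many digits, and optimisation outcomes differ
  between the two resolutions only at the level of ordinary run-to-run
  (seed) variation.
* Rotation decomposition fixes the SU(2) global sign by `sin(theta/2) >= 0`
  (angle in [0, pi]); below 1e-9 rad the axis is flagged undefined.
* The paired objective `min(Phi90, Phi180)` and the 30 us duration step are
  package choices where a range of reasonable alternatives exists.
* Degenerate inputs: empty grids, non-monotone morph schedules, >3-spin
  systems, and sequences without a trailing acquire raise immediately.

## Synthetic fixtures and what passing tests show

The fixture generator provides seeded random smooth shapes, a three-spin
fluorine-like system (shifts spread over a 153 ppm window at a chosen
field, couplings up to 100 Hz), and planted morph records for selection
logic.  Simulations model ideal hardware: no probe ringdown, amplifier
droop, gradient imperfections, radiation damping, or chemical exchange.
Passing tests therefore demonstrate the control-theoretic properties of
the waveforms and sequences, not their behaviour on a real probe; B1
inhomogeneity is the one hardware imperfection explicitly in the model.

## Known limitations

* Phase-only constant-amplitude control is the production path; the
  x/y-control mode is exact but loop-based and intended for baselines.
* Robustifying a 720 us / 50 kHz pair against the ±5 % Gaussian B1
  ensemble at constant 10 kHz amplitude is a genuine trade: the optimiser
  improves the ±5 % grid points substantially (e.g. 0.966 → 0.988) but
  gives up some nominal-B1 quality (≈0.9998 → ≈0.9989), and the ensemble
  overlap converges to ≈0.996–0.997 from the bootstrap schedule — direct
  ascent, staged B1 ramps, perturbation restarts, and 10k-iteration budgets
  all reach the same plateau.  Designs seeded from a larger morph search
  may do better; the bootstrap used here starts from seeded smooth-random
  phases only.
* No penalty terms for waveform smoothness or adiabaticity.
* Heteronuclear alignment conventions and >3-spin systems are out of scope.
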