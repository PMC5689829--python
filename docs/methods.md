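# Methods

## The model

`sparkfiber` simulates the chain of scales by which random single-channel
events become whole-tissue arrhythmia precursors:

1. **Release sites.** A ventricular myocyte is a 3D rectangular lattice of
   Ca²⁺ release sites (full scale 25×20×50 = 25,000; reduced lattices are
   used routinely, see *Problem sizes*), spaced 1 µm transversally and
   2 µm longitudinally. Each site holds a junctional-SR (JSR) store, a
   dyadic subspace (SS), and a submembrane shell (SM) around the t-tubule
   (annulus, inner radius 100 nm, outer 180 nm, length 1 µm), plus a
   cluster of 48 two-state stochastic RyRs and 8 L-type channels (LCCs).
2. **RyR gating.** Opening rate r_o = opening_scale · φ(ca_JSR) · k⁺ ·
   ca_SS^η with k⁺ = 1.107×10⁻⁴ ms⁻¹µM⁻η, η = 2.1 and luminal regulation
   φ = 0.8025 + (ca_JSR/1.5 mM)⁴; closing is Ca-independent with 2 ms mean
   open time. Cluster occupancy advances by binomial sampling of the exact
   two-state propagator (see *Numerical scheme*).
3. **LCC gating.** A reduced 4-state chain (closed, open,
   voltage-inactivated, Ca-inactivated) with Boltzmann activation
   (midpoint +27 mV, slope 4.5 mV, max rate 8 ms⁻¹ — calibrated, see
   below) and a Ca-dependent inactivation rate saturating in dyadic Ca²⁺.
   25 % of channels gate at baseline (60 % under β-adrenergic stimulation,
   with 4 % in a 5.8 ms-mean-open high-activity mode); the rest are
   silent. The unitary flux is GHK-shaped but influx-only: a real L-type
   pore does not conduct outward Ca²⁺ current at physiological potentials,
   and the nominal GHK reversal against the single bulk-dyad Ca²⁺ during a
   spark is an artifact of the one-compartment dyad.
4. **Ca²⁺ transport.** JSR→SS release flux proportional to cluster open
   fraction and the JSR–SS gradient; SS↔SM exchange; SM↔SM
   nearest-neighbour exchange with the longitudinal time constant twice
   the transverse one; SM→cytosol drain; SERCA (Hill 2) fills a global
   network SR that refills each JSR over ~60 ms — slow refill is what lets
   sparks *terminate* by local JSR depletion, without which the wave
   threshold collapses. Buffering: calsequestrin in the JSR, calmodulin +
   sarcolemmal sites in the SM, calmodulin + troponin in the cytosol. The
   SM buffer capacity is a first-order control of wave propagation: it
   sets how much released Ca²⁺ survives diffusion to the neighbouring
   shell.
5. **Membrane.** Fast I_Na (m³hj), Boltzmann-rectified I_K1, two-gate
   I_Kr/I_Ks, saturating Na/K-ATPase, small background and pump terms, and
   the electrogenic 3:1 Na/Ca exchanger evaluated twice — one half sensing
   the SM shells (site-summed), the other the bulk cytosol. Inward NCX
   current during spontaneous release carries the DAD. Na⁺ is
   protocol-controlled (fixed or ramped), not mass-conserving.
6. **Fiber.** Cells are single voltage nodes joined by gap-junction
   currents I_gap = g_gap(V_i − V_{i+1}); the cable voltage advances by
   Crank–Nicolson at the 50 µs macro step with sealed ends (operator
   splitting: cell interiors advance inside the step). The outer 24 cells
   per end (fewer at reduced scale) start at normal SR load, stay
   quiescent, and are excluded from statistics while still loading their
   neighbours electrotonically.
7. **Rare events.** The spatial-filter + shuffle estimator summarized in
   the README: uniform filter of odd width W over J_RyR(x,t), per-cell
   temporal maxima, W chosen to maximize r² against simulated V_max,
   z-score mapping to predicted V_max, and position-shuffling of interior
   cells to resample arbitrarily many surrogate fibers.

## Numerical scheme

Fixed macro step dt = 0.05 ms, operator-split:

- **Channels.** RyR clusters use the exact two-state propagator: with
  R = r_o + r_c and π = r_o/R, each closed channel is open after dt with
  probability π(1 − e^{−R·dt}), each open channel has closed with
  probability (1 − π)(1 − e^{−R·dt}); counts are binomial draws. This is
  unbiased at any step size. (A substepped first-order scheme was used
  initially and rejected: it carries an O(rate·dt_sub) occupancy bias that
  the stationarity test resolves.) The 4-state LCC chain has no such
  closed form and uses substepped binomial sampling with
  rate·dt_sub ≤ 0.1, competing exits split binomially by relative rate.
- **Calcium.** The dyad is stiff (relaxation ≪ dt), so its
  frozen-coefficient linear ODE — the GHK LCC term is exactly linear in
  ca_d and joins the solve — is integrated analytically, and the time
  integral of ca_d moves exact *amounts* between JSR, dyad and SM. All
  buffered pools (JSR/CSQ, SM, cytosol) use the rapid-buffering limit:
  total-pool bookkeeping, then inversion to free Ca²⁺ (quadratic for one
  buffer, Newton for two). A closed cell therefore conserves total Ca²⁺
  essentially to round-off (tested: < 0.1 % over 1 s with release active).
  An explicit SM-buffer ODE is unstable at this step — the sarcolemmal
  buffer's free-Ca coupling rate k_on(B_T − b) ≈ 30–100 ms⁻¹ is far above
  1/dt, which equally means the rapid limit is accurate to ~10 µs.
- **Membrane.** Rush–Larsen exponential gate updates; explicit Euler for V
  on an adaptive sub-step (one sub-step at rest, dt/4 whenever |dV/dt|·dt
  would exceed 0.5 mV). An embedded adaptive Runge–Kutta pair was
  considered and rejected: every compartment update is linear in its own
  state (making the exponential updates unconditionally stable) and
  channel shot noise dominates the error budget at this dt.

Randomness: one seeded PCG64 generator per simulation; the fixed
vectorized update order makes (config, state, seed) → trace bit-exact.

## Calibrated parameter set

The release-site transport values are not published in the source text;
the shipped defaults were calibrated against the printed whole-cell
constraints and then frozen:

- resting potential ≈ −90.5 mV, diastolic ca_i ≈ 0.1 µM;
- spontaneous-wave threshold ≈ 120–140 µmol/(L cytosol) (SR content, free
  + CSQ-bound, per litre cytosol; the detected onset sits at ~125–135 at
  desk scale);
- seeded-front wave velocity ≈ 50–70 µm/s just above threshold;
- fiber conduction velocity 55 cm/s after g_gap calibration (root search,
  mirroring how the coupling conductance is defined);
- ECC gain declining from 0 to +20 mV (see *Limitations*: neither the
  printed magnitude nor the full decline to +40 mV is reached).

Key sensitivities found during calibration: `tau_refill` (spark
termination; fast refill destroys the threshold), `bt_sl_sm` (SM buffer
capacity; high capacity absorbs the inter-site signal and kills true
propagation, low capacity collapses the threshold), `tau_sm_trans`
(propagation speed and threshold jointly), `k_rel` with `tau_ds` (spark
duration ~4–6 ms and dyadic spark Ca²⁺ ~200–300 µM).

## Protocols and measurements

- **ECC gain**: hold −80 mV, 160–200 ms steps to −20…+40 mV. Whole-cell
  LCC and RyR fluxes are averaged across repetitions *as traces*
  (time-locked clamp) and smoothed with a short boxcar (default 20 ms)
  before peak-taking, because at reduced lattice scale the instantaneous
  fluxes carry channel shot noise whose maximum-statistic biases
  low-open-probability potentials upward (the full-scale cell
  self-averages over ~2×10⁵ channels). Both peak-flux curves are
  normalized to their own maxima; gain is their ratio.
- **Leak–load**: [Ca²⁺]_NSR clamped at ascending values; cell-wide RyR
  leak from the second half of each run; wave flag from the detector
  below.
- **Wave detection** (`wave_metrics`): onset = first snapshot with ca_SM
  above a quarter of the peak (floor 2 µM; tracks the regenerative front,
  not isolated sparks). A wave requires the largest *connected* activated
  component to grow monotonically to ≥ 20 µm longitudinal extent with
  ≥ 25 % of sites activated — connectivity matters, since dense
  independent spark patches otherwise masquerade as waves. Velocity is
  the Theil–Sen slope of front distance vs median plane-onset along
  monotone runs from the earliest plane; nucleation sites are connected
  components of the earliest-onset seed region (within 40 ms).
- **Threshold**: lowest initial load whose 600 ms window shows a wave.
  The short window is deliberate: over longer windows, Ca²⁺ released by
  sub-threshold spark activity redistributes to the cytosol, re-sensitizes
  RyRs, and drifts the apparent threshold downward.
- **Velocity**: measured on a seeded front — a small ignition region
  (elevated ca_SM over the first three lattice planes) launches one
  unidirectional wave into quiescent tissue held just above threshold.
  At desk lattice scale spontaneous nucleation near threshold is dense
  relative to front traversal, so free-running waves form a patchwork
  with no measurable macroscopic front; the seeded protocol recovers the
  clean front the velocity constraint refers to.
- **DAD ensembles**: identical initial conditions, independent seeds;
  V_max, delay-to-peak, peak ca_i, peak J_RyR per realization; triggered
  APs classified by an upstroke crossing of −20 mV with dV/dt > 5 mV/ms.
- **Fiber condition comparisons** (baseline, 50 % I_K1, +50 % g_gap) use
  identical sub-threshold initial states so remodeling effects appear
  purely through membrane and coupling; at the elevated loads used for single cells the
  half-I_K1 desk fibers fire propagating APs and leave the sub-threshold
  DAD regime entirely.

## What the synthetic generator does and does not emulate

`synth.generate_profiles` draws per-cell double-exponential release pulses
(rise 20 ms, decay 100 ms) with independent Gaussian onsets (SD 178 ms —
the observed single-cell delay variability at the lowest load) and
amplitudes, on a baseline leak; boundary-buffer cells stay at baseline.
It reproduces exactly the statistical structure the estimator relies on —
per-cell independence, onset/amplitude spread, quiescent buffers — and
none of the biophysics: no intra-cell wave substructure, no load
dependence, no release-voltage coupling. Tests passing on synthetic
fibers validate the *estimator* (filter algebra, W recovery, resampling
validity, tail convergence); the reduced-scale simulated fibers validate
that the biophysical model feeds it data with the assumed structure
(independence diagnostics, r² ≥ 0.9 fits).

## Problem sizes

Routine work uses reduced lattices: 1,000 sites (5×5×40) for single-cell
wave studies, 96–160 sites per cell in fibers of 50–96 cells, and a
2,500-site validation scale. The full 25,000-site lattice is configurable
but not exercised by the test suite. Cell length for CV conversion is the
full-scale lattice extent (100 µm) regardless of the reduced lattice used
(a reduced lattice subsamples release sites of the same physical cell);
overridable in `FiberConfig`.

## Known limitations

- **ECC gain magnitude.** The computed gain at 0 mV is ~1.5–3 rather than
  ~14. In this architecture the same LCC opening rate α(0) controls both
  the synchrony of release at 0 mV (the numerator's peak) and the
  whole-cell LCC trickle flux (the denominator), so their normalized
  ratio is nearly α-independent; the single consolidated dyadic
  compartment — which the source model also adopted, noting that it
  attenuates low-potential gain — couples trigger and release Ca²⁺ and
  caps the ratio, and the effect is stronger at desk scale with ~2 gating
  LCCs per site. The gain declines from 0 to +20 mV, but the +30…+40 mV
  values are flattened by the spark-driven loss of LCC driving force, so
  neither the magnitude nor a clean monotone decline over the whole
  0…+40 mV range is resolved at desk scale.
- AP duration and its rate/load dependence are only loosely calibrated
  (not targets of this package).
- β-adrenergic stimulation is a static parameter mode (no PKA/CaMKII
  dynamics), as in the source model.
- Global cytosol/NSR compartments over-estimate how quickly distant sites
  feel a local release; spatially resolved bulk pools are out of scope.
- No intercellular Ca²⁺ diffusion through gap junctions, no 2D/3D tissue,
  no cell-to-cell parameter heterogeneity.
- The two-cell cable agreement with a reference ODE solution is first
  order in dt (operator splitting); the test asserts the observed error
  and its decay rather than machine agreement.
- The wave threshold and velocity at desk scale carry definitional
  dependence on the observation window and front detector documented
  above; both are implemented once, used uniformly, and not tuned per
  measurement.
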