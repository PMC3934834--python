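# Methods

## The three-state occupancy model

A filament barbed end growing from profilin-actin (PA) is modelled as a
continuous-time Markov chain over three occupancy states: free (B),
Nt-Spire-capped (BS), and formin-bound (BF). All transitions are
memoryless; association steps are pseudo-first order in the free ligand
concentration, which is assumed constant (ligand excess over ends, as in
microfluidics-assisted single-filament assays where the solution is
continuously replenished).

**Collapsed ternary states.** The mutual displacement reactions (Spire
entering a formin-bound end and vice versa) proceed physically through
short-lived ternary complexes in which both proteins contact the terminal
subunits. Their lifetimes are unresolved experimentally; only the
second-order entry rates (k′₊S, k′₊F) are measured, and the exit rates of
each protein are unchanged by the other's transient presence. We therefore
collapse the ternary intermediates into instantaneous BS→BF and BF→BS
transitions. An explicit-ternary variant would only be identifiable given a
measured complex lifetime.

**Driven cycle.** With the default constants, the product of rates around
B→BS→BF→B differs from the reverse product, so detailed balance is broken
and the stationary flux is positive (≈1.1×10⁻³ s⁻¹ at 10 nM Spire, 20 nM
formin). This is the model-level expression of the ping-pong alternation;
thermodynamically it must be paid for by actin-coupled ATP turnover, which
we do not model explicitly.

**Elongation.** Growth velocities are linear in [PA] through the origin:
8.8 subunits·s⁻¹·µM⁻¹ for free ends (measured at 1 µM PA; linearity through
the origin is an assumption for other concentrations), 63 for formin-bound
ends (measured as a titration slope), 0 for capped ends. One subunit adds
2.7 nm. Only the growth regime (ATP-actin) is modelled; nucleotide variants
in which formin-stimulated assembly is absent can be emulated by setting
`v_formin_slope = v_free_slope` and zeroing the on-rate advantages, but this
configuration is documented, not tested.

**Median vs. mean dwell.** The reported "average dwell time of 3 to 4 min"
and the 37 µm processive run length are both consistent with the *median*
of the exponential dwell at k₋F = 3.17×10⁻³ s⁻¹ (ln2/k₋F = 3.6 min;
3.6 min × 63 sub/s × 2.7 nm = 37.2 µm), not the mean (5.3 min, 53.7 µm).
The package computes both and uses the median for the headline run-length
and dwell figures.

## Simulator

Standard Gillespie: exponential sojourns at the state's total exit rate,
destinations proportional to outgoing rates. Subunit addition within a
sojourn of duration d at velocity v is Poisson(v·d) with sorted-uniform
event times (exact for a homogeneous Poisson process); stochastic rather
than deterministic addition gives short fast phases realistic count noise,
matching the filament-to-filament velocity scatter reported as mean ± sd.

Seeding: per-filament generators are `SeedSequence([master_seed, index])`
substreams, so populations are reproducible and independent of simulation
order. Depolymerization is excluded from the growth simulator (net assembly
dominates in the growth regime); the dilution regime is handled by the bulk
models.

The observation model samples true length on a uniform frame grid (default
10 s, the acquisition interval of the time-lapse data) and adds i.i.d.
Gaussian position noise. The default noise sd of 0.05 µm is a package
choice — sub-pixel at typical TIRF magnification (~0.27 µm/pixel); the
experimental tracking noise is not reported.

## Trace segmentation

Per-frame velocities are centred finite differences of subunit-converted
length (one-sided at the ends). Frames are classified by two thresholds,
paused ≤ 2·[PA] < slow < 25·[PA] ≤ fast (subunits/s), chosen between the
three velocity regimes and scaled with [PA] so classification tracks the
physical rates; the original analysis classified by eye, so the thresholds
are an explicit, configurable package decision. Runs shorter than
`min_frames = 2` are merged, shortest first, into the neighbour with the
closer mean velocity: a state must persist two frames to be called, which
is also the identifiability resolution of the underlying experiment. Phase
boundaries sit midway between adjacent frames (one-frame ambiguity);
per-phase velocity is the least-squares slope over the phase's frames.
First/last phases are flagged left-/right-censored so downstream dwell fits
can treat them properly. Local classification + merging was preferred over
global changepoint optimisation for transparency and because the
three-class semantics map directly onto the states.

## Inference

* **Censored exponential MLE**: k = (#events)/(Σ all times), the exact
  closed form; lognormal CI k·exp(±z/√d). A least-squares survival-curve
  mode mirrors single-exponential curve fitting of fraction-vs-time data.
* **Association constants**: per-concentration observed rates regressed on
  concentration through the origin (slopes are what is reported). When
  per-point SEs are available the slope SE is the fixed-effects
  inverse-variance form 1/√Σwᵢcᵢ², not residual-based (3–4 concentrations
  give residual variance estimates far too unstable for CIs).
* **Displacement fits**: switch experiments record the first exit of an
  occupied end and its destination. With the spontaneous off-rate known,
  the competing-risks MLE of the displacement hazard is
  (#displaced)/(Σ times); per-concentration estimates are then regressed
  through the origin, mirroring the two-step procedure used experimentally.
  Zero displaced events yield a zero estimate with a Poisson upper bound
  rather than an error, so a true null rate is reported as such.
* **Composite arrest rate**: when the transient free state between formin
  release and recapping is too short to resolve, the observed arrest rate
  of formin-bound ends is k_obs = k₊S[S](k′app + k₋F)/(k₊S[S] + k₋F);
  both the forward formula and its exact inverse are provided.
* **Isotherms**: hyperbolic occupancy by default; the exact two-component
  tight-binding quadratic is recommended when Kd is within ~10× of the ends
  concentration (sub-nanomolar affinities). Kd and plateau are fitted by
  least squares with the zero-concentration rate fixed at 1.

## Bulk models

**Depolymerization.** Dilution-induced disassembly is normalized to 1 for
free ends, of which f_barbed = 0.833 is the barbed-end share —
back-calculated from the paired observation that a saturating formin halves
the total rate while blocking "about 60%" of barbed-end disassembly
(0.5 = f_barbed × 0.6). Occupancy is equilibrium (initial rates read as
pre-equilibrated snapshots): formin-type species (Kd 6 nM) inhibit 60%;
Spire occupies free ends at Kd 9 nM (70% inhibition) and formin-bound ends
at the ~10-fold enhanced affinity (0.75 nM, midpoint of the reported
0.5–1 nM) with joint full blockage; KIND (Kd 20 nM) completes the cap on
FH1D-FH2-bound ends but strips FH2 and restores free-end disassembly.
Profilin variants shift the formin affinities (FH1D-FH2 → 1.5 nM,
FH2 → 20 nM). A single formin-type species plus either Spire or KIND is
supported; Spire and KIND together with a formin are not modelled jointly
(the assays add them separately). Profilin's own saturable acceleration of
barbed-end disassembly is not parameterised — no constants are reported for
it — so rates are relative to the buffer in use.

**Steady state.** With all barbed ends capped, only pointed ends exchange:
G_free = A_cP and PA_ss = P_total·A_cP/(K_P + A_cP) (profilin as a
sequestering protein); with active barbed ends, A_cB replaces A_cP.
F-actin is the mass-balance remainder; if the closed form exceeds the
available actin, F = 0 and PA is recomputed by exact two-component mass
action (flagged `depleted`). Default parameters (K_P = 0.1 µM,
A_cP = 0.6 µM, A_cB = 0.1 µM) are literature-typical placeholders, not
fitted values.

**Seeded growth.** Initial rate = [ends] × Σ π(state)·v(state) with π the
stationary occupancy. This reproduces the hyperbolic suppression by Spire
alone with half-effect at K_S and the formin-driven rescue of capped ends.

## Synthetic-data designs and what passing them shows

The generators emulate the experiment shapes, with defaults at the
experimental conditions: Spire 5–40 nM, formin 10–40 nM, 1 µM PA, horizons
600–1800 s, 10 s frames, 0.05 µm noise, 5% multiplicative noise on
dose-response rates. The recovery suite's problem sizes were set once from
identifiability arithmetic: capping 100 filaments/concentration (600 s);
dissociations 500 dwells (300 s horizon for Spire, leaving ~5–10%
right-censored to exercise the censored MLE; 1800 s for formin); formin
association 400 filaments/concentration over 1800 s (k₊F is so slow that
most observations are censored — the censored MLE handles ~75–95%
censoring); displacement switches 150 filaments/concentration (900 s); the
elongation-slope pipeline 30 filaments per PA concentration in
{0.3, 0.5, 1, 2} µM over 600 s.

Synthetic data are exactly exponential/Markovian with known noise; real
traces add tracking artefacts, drift, photobleaching-limited observation
spans, and possible non-exponential dwell mixtures. Passing recovery
therefore demonstrates correctness and statistical efficiency of the
pipeline under the model, not robustness to model misspecification.

## Numerical choices

* Stationary laws are solved from the 3×4 linear system [Qᵀ; 1]π = e₄ by
  least squares (handles the rank-1 deficiency; reducible chains resolve to
  the closed class, detectable by exact zeros in π); residual |πQ| is
  checked against 1e-9·max|Q|.
* Cycle flux is computed on the B↔BS edge; stationarity makes it identical
  on all three edges (asserted to 1e-12 in the tests).
* The exponential-rate CI is lognormal-based, exact in shape for this
  likelihood; the all-censored case reports an identifiable upper bound in
  the error message.
* Degenerate inputs: zero off-rates flag infinite dwells/unbounded runs;
  zero total exit rate yields a single sojourn to t_max; zero-concentration
  capping tables are all-censored but valid.

## Limitations

* No spatial/mechanical filament model, no image synthesis, no
  photobleaching; traces are length-vs-time tables.
* No nucleation rate law: spontaneous-assembly time courses are out of
  scope, and the low apparent half-effect of formin on Spire-capped ends in
  bulk seeded growth (~2 nM) is not reconciled with the single-filament
  constants — the bulk isotherm is treated as empirical.
* Bulk occupancies are equilibrium snapshots; no time-resolved pyrene
  kinetics.
* Filament-level labels ("alternating" vs "fast") are left to the user;
  the package reports phase sequences.
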