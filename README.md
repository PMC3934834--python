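# spireformin

Kinetic modelling and inference for the **ping-pong regulation of actin
filament barbed ends by Nt-Spire and formin 2 (Fmn2)** in the presence of
profilin-actin (PA).

During mouse meiosis, Spire and Fmn2 cooperate to build the dynamic
cytoplasmic actin network that positions the spindle. At the single-filament
level this cooperation is kinetic: Spire caps barbed ends and arrests growth,
but a capped end recruits formin ~30-fold faster than a bare end; the formin
displaces Spire and drives fast processive elongation until Spire in turn
displaces it. Filaments therefore alternate between paused and fast-growing
phases — a driven "ping-pong" cycle, visible as staircase-like kymographs in
TIRF movies.

This package is for quantitative cytoskeleton researchers who want to
simulate, analyse, or re-fit such single-filament and bulk kinetics.

## The model

Barbed-end occupancy is a three-state continuous-time Markov chain over
B (free), BS (Spire-capped) and BF (formin-bound), with generator entries

| transition | rate |
|---|---|
| B → BS | k₊S·[S] = 2.7 µM⁻¹s⁻¹ · [S] |
| BS → B | k₋S = 0.0101 s⁻¹ |
| B → BF | k₊F·[F] = 7.4×10⁻³ µM⁻¹s⁻¹ · [F] |
| BF → B | k₋F = 3.17×10⁻³ s⁻¹ |
| BS → BF | k′₊F·[F] = 0.29 µM⁻¹s⁻¹ · [F] (displacement) |
| BF → BS | k′₊S·[S] = 0.396 µM⁻¹s⁻¹ · [S] (displacement) |

Elongation is state-dependent: 8.8·[PA] subunits/s for free ends, 63·[PA]
subunits/s for formin-bound ends, 0 when capped (2.7 nm per subunit). The
displacement reactions make the stationary cycle flux strictly positive —
the alternation is driven, not an equilibrium.

On top of the chain the package provides:

* a Gillespie single-filament simulator with Poisson subunit addition and a
  TIRF-style observation model (10 s frames, Gaussian position noise);
* trace segmentation into paused/slow/fast phases with censoring-aware
  dwell-time extraction;
* inference: censored exponential MLE, pseudo-first-order regressions,
  competing-risks displacement fits, composite observed-rate corrections,
  and binding-isotherm (Kd) fits;
* closed-form bulk models: dilution-induced depolymerization with
  multi-species end occupancy, the steady-state profilin/actin partition,
  and seeded-growth initial rates;
* synthetic-data generators for every experiment shape, plus a full-circle
  parameter-recovery suite.

## Worked example

```python
from spireformin import (Conditions, default_rate_constants, derived_constants,
                         generator_matrix, stationary_distribution, cycle_flux)

rc = default_rate_constants()
cond = Conditions(spire_uM=0.010, formin_uM=0.020, pa_uM=1.0)

dc = derived_constants(rc, pa_uM=1.0)
print(f"K_S = {dc.K_S_nM:.2f} nM")                      # K_S = 3.74 nM
print(f"median formin dwell = {dc.median_dwell_BF_s/60:.2f} min")   # 3.64 min
print(f"median run length = {dc.median_run_length_um:.1f} um")      # 37.2 um

pi = stationary_distribution(generator_matrix(rc, cond))
print(f"pi = {pi.round(3)}")                  # pi = [0.204 0.436 0.359]
print(f"fast share of occupied ends = {100*pi[2]/(pi[1]+pi[2]):.1f}%")  # 45.2%
print(f"cycle flux = {cycle_flux(rc, cond):.2e} s^-1")  # 1.11e-03 s^-1
```

The Spire affinity for barbed ends (3.74 nM), the ~3.6 min median processive
dwell sustaining a ~37 µm run at 1 µM PA, and the 45% formin-bound share of
occupied ends at 10 nM Spire / 20 nM formin all follow directly from the six
measured rate constants; the positive cycle flux quantifies the ping-pong
drive.

## Analysis scripts

Numbered drivers under `analysis/` run the full study and write tables to
`results/`:

1. `01_model_constants.py` — derived constants, stationary occupancy, flux;
2. `02_simulate_filaments.py` — capping kinetics and ping-pong movies;
3. `03_segment_traces.py` — phase segmentation and elongation-slope recovery;
4. `04_recover_rates.py` — full-circle recovery of all six rate constants
   and the two bulk affinities;
5. `05_bulk_assays.py` — depolymerization occupancy scenarios, steady-state
   partition, seeded-growth saturation.

## Documentation

`docs/methods.md` describes the model assumptions, the synthetic-data
designs, numerical choices and known limitations.
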