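# Methods

## Model

The package simulates a well-mixed co-culture of a bacterial host and one
or more lytic phage genotypes. State variables are uninfected hosts `B`
(cells/ml), infected hosts `B_I` (cells/ml) and free phage `P_i`
(particles/ml) per genotype. Each genotype carries four traits:

| trait | symbol | units | default | meaning |
|---|---|---|---|---|
| adsorption constant | phi | ml⁻¹ min⁻¹ | 4e-9 (ancestor) | second-order rate of irreversible attachment |
| burst size | beta | particles/cell | 200 | progeny released per lysed cell |
| lysis time | tau | min | 17 | fixed delay from adsorption to lysis |
| decay rate | delta | min⁻¹ | 1.7e-2 (ancestor) | first-order loss of infectivity |

The reference genotypes shipped as defaults are the ancestor
(phi = 4e-9, delta = 1.7e-2), a slow-adsorbing variant
(phi = 2e-9, delta = 1.4e-2) and a fast-adsorbing, persistent variant
(phi = 6e-9, delta = 6e-3). Where a shared-decay comparison needs an
ancestral decay value, 1.7e-2 min⁻¹ is used; the 1.4e-2 min⁻¹ value enters
only the decay-differentiated comparisons, paired with 6e-3 min⁻¹ for the
persistent type.

Model assumptions, all deliberate simplifications of the in-vitro system:

* lysis time is a fixed delay, not a distribution — the within-transfer
  burst structure is therefore sharper than real one-step growth curves;
* infected cells disappear at lysis and never act as adsorption sinks
  (no debris binding);
* decay is constant first-order (no biphasic decay);
* host growth within a transfer is neglected — transfers are short
  relative to host doubling under the densities simulated;
* adsorption to an infected cell removes the phage with no progeny
  (superinfection contributes only the loss term).

The delayed lysis term uses the product `B(t-tau) * P_i(t-tau)`; delayed
densities are defined as zero before the start of available history, so a
freshly seeded culture releases nothing until `t = tau`.

## Transfer protocols

`pfu_reset` models harvest-and-reseed passaging: at each transfer end the
phage composition is kept, total free phage is rescaled to a fixed
inoculum (default 1e7 PFU/ml on 1e8 cells/ml, input MOI 0.1), infected
cells are discarded and the lysis history is cleared.

`fractional_carryover` models whole-culture dilution (default 2%, i.e.
50-fold): free phage and infected cells are both carried at the fraction
`f`. Cells infected before the reset must still lyse on schedule but at
diluted density, which the integrator implements by multiplying the stored
phage history by `f` (the stored host history is left untouched, so each
delayed product scales by exactly `f`). Carrying free phage along with the
infected cells is the only reading consistent with the settled three-burst
pattern: with no free phage at the transfer start there is nothing to
produce the dominant burst one latent period in, and leaving the history
unscaled makes the carried-cohort burst fifty-fold too large (and drives
`B_I` negative). The first transfer is always seeded with free phage only.

A genotype whose density falls below 1e-12 particles/ml is set to zero —
far below one particle per culture and purely a denormal guard.

## Numerical scheme

Classical fixed-step 4th-order Runge–Kutta, default step 0.01 min, with
the history stored on the same uniform grid. The step is required to
divide every lysis time, so the delayed lookups of whole-step stages land
exactly on stored nodes; the midpoint stages interpolate `B` and `P`
linearly between the two bracketing nodes before forming the product. This
makes delay handling exact, reproducible and cheap, lets a reset rescale
history by a scalar, and needs no event detection at the `t = tau` kink.
The inner loop is JIT-compiled with numba when available; a pure-Python
fallback with identical numerics is used otherwise.

Step-size rationale: the fastest rate in the system is phage loss to
adsorption, `phi * (B + B_I)` for hosts and `phi * P_total` for hosts'
loss when phage are at their peak. At the default densities the latter can
reach ~130 min⁻¹, and explicit RK4 is stable for rate × step below ~2.8,
so 0.01 min keeps the whole parameter range of interest comfortably inside
the stability region (0.05 min and coarser visibly fails at low dilution
factors). `refine_check` provides a step-halving self-convergence
diagnostic; an independent explicit-Euler oracle at step 1e-3 min agrees
with the production integrator within 0.5% sup-norm on the default
scenario (asserted in the test suite).

Degenerate negatives: because the lysis outflux is read from the delayed
history rather than from `B_I` itself, the infected pool can numerically
undershoot zero by O(step × flux) at the instant a cohort empties. The
integrator clamps negatives within `1e-6 × max density` plus twice the
step times the current cell-flux bound, and raises a numerical error for
anything larger (which in practice signals an unstable step).

## Experiments

* **Competition sweep** — two genotypes differing only in phi start 1:1 at
  total input MOI 0.1 on fresh hosts for one 30-min transfer; the ratio of
  free-phage titres at the end is the fitness readout. The optimum over a
  60-point log grid spanning 1000-fold below the baseline is refined by
  bounded golden-section search to 1% in phi. A boundary maximum is
  flagged unresolved instead of refined.
* **Stable pattern** — a transfer run converges at the first `n` whose
  transfer `n+1` total free-phage trajectory matches transfer `n` within a
  sup-norm relative tolerance (default 1%). Under the default 2% carryover
  protocol the transfer-to-transfer map approaches its fixed point through
  a damped two-transfer oscillation: the three-burst *shape* is in place
  by transfer 3, but the strict 1% criterion is first met around transfers
  8–9. Six-transfer analyses therefore use the final transfer as the
  settled pattern; its burst timings agree with the fully converged ones
  to well under a minute.
* **Burst detection** — strict local maxima of the total release flux
  `sum_i phi_i beta_i B_tau P_{i,tau}` above a configurable fraction
  (default 1%) of the transfer's peak flux. A plateau of equal values
  strictly above both neighbours yields one event at its midpoint node —
  deterministic and resolution-independent.
* **Dilution decomposition** — productive (`phi B P`) versus unproductive
  (`phi B_I P`) adsorption rates over the settled transfer, per dilution
  factor; the integral of the productive rate over a transfer equals the
  host drop exactly (asserted in tests).
* **Fitness landscape** — three genotypes with high/intermediate/low
  adsorption constants (6, 4, 2 × 10⁻⁹; all other traits shared, decay
  1.7e-2) compete from equal frequencies under fractional carryover for
  100 transfers per (transfer time, dilution) cell. The winner is the
  most frequent genotype at the end; "fixed" means frequency ≥ 0.99 —
  chosen as a conventional near-fixation cut since no sharper criterion is
  implied by a deterministic model. Cells stop early once a genotype
  passes 0.9999. Default grids span 20–240 min and 10–5000-fold,
  log-spaced, as representative laboratory-accessible ranges.
* **Robustness sweep** — repeats the optimum search across burst sizes and
  lysis times, reporting the fold reduction and whether fewer than two
  infection cycles fit in the transfer (`2 tau >` duration), the condition
  under which the single-transfer optimum is meaningful. When the lysis
  time exceeds the transfer, adsorption is pure loss and the optimum
  collapses to the slowest mutant on the grid.

## Estimators

Both estimators fit ordinary least squares on natural-log titres;
`k = -slope / B` (standard error `SE(slope)/B`) for the adsorption assay,
`delta = -slope` over samples at and after the raw maximum for the decay
fit. Natural logs make the slope directly interpretable; both quantities
are base-invariant. The raw-maximum peak rule matches half-hour sampling
granularity; a smoothed peak would shift the window by less than one
sampling interval. Log-scale OLS was chosen over nonlinear least squares
on the linear scale because plaque-count noise is closer to multiplicative
than additive; with three-point assays the reported per-fit standard
errors have only one residual degree of freedom and are accordingly noisy
(their RMS, not any single value, tracks the empirical scatter).
Zero-titre samples are excluded from log fits with a warning rather than
pseudo-counted. Replicates are combined by inverse-variance pooling;
mixed-model machinery is intentionally out of scope.

## Synthetic data

The generator emulates two assay designs: early-timepoint adsorption
assays (default samples at 2, 4 and 6 min, input MOI 0.05, expected titre
`P0 exp(-k B t)`; sampling is refused at or beyond the lysis time) and 5-h
persistence co-cultures (input MOI 0.1, samples every 30 min, produced by
the full delay model). Observation noise emulates plaque counting: the
expected titre is diluted by the smallest power of ten that brings the
expected count under 300 on a 100-µl plate (aiming at the conventional
30–300 countable window), a Poisson count is drawn and converted back to
PFU/ml. A log-normal mode is available as a lighter alternative for
property tests. All generators are pure functions of parameters and an
explicit seed.

What passing the round-trip tests does and does not show: the generators
share the package's own model of the assays, so recovery tests validate
the estimation pipeline's correctness and calibration under the stated
noise model — not robustness to real-data features such as distributed
lysis times, debris adsorption, biphasic decay, pipetting error or
plate-to-plate overdispersion, none of which are simulated.

## Known limitations

* The deterministic model cannot address fixation probabilities or drift
  at the transfer bottleneck; "fixation" means deterministic frequency
  convergence.
* The sharp productive/unproductive phase boundary is an artefact of the
  fixed lysis time; distributed latent periods would smooth it.
* The strict transfer-to-transfer convergence of the carryover protocol is
  slower (transfers ~8–9 at 1%) than visual log-scale inspection suggests
  (~2–3 transfers); analyses that quote "the settled pattern" at transfer
  6 rely on the burst structure, which is stable much earlier.
* Estimators assume constant host density over the assay window and a
  single-exponential decline; they will be biased if the fit window
  overlaps the productive phase (mitigated by starting the window at the
  observed peak, and diagnosable by moving the window start later).
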