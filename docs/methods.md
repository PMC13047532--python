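# Methods

## The kinetic model

Autoxidation of an unsaturated lipid LH proceeds by a radical chain
carried by lipid peroxyl radicals LOO•. With a thermal azo-initiator
supplying radicals at a constant rate *R*ᵢ, carbon-radical oxygenation
fast (k\_O₂ ≫ k\_p, so O₂ addition is never rate limiting), and
propagation (LOO• + LH, rate constant *k*\_p) rate-determining, the
minimal mechanism closes by peroxyl self-termination (2*k*\_t) and,
when a chain-breaking antioxidant AoxH is present, by peroxyl
trapping (*k*\_inh). `simulate_trace` integrates

    d[LOO•]/dt = Ri − 2·kt·[LOO•]² − n·kinh·[LOO•]·[AoxH]
    d[AoxH]/dt = −kinh·[LOO•]·[AoxH]
    d[LH]/dt   = −kp·[LH]·[LOO•]
    d[O₂]/dt   = −(kp·[LH]·[LOO•] + Ri)

with LSODA (rtol 1e-10; atol 1e-16 on the radical and antioxidant
pools, 1e-12 M on LH and O₂; [LOO•]₀ = 0).

Stoichiometry for non-integer *n*: the antioxidant is consumed at the
trapping rate *k*\_inh[LOO•][AoxH] while the radical pool loses
*n* radicals per trapping event. This is the net-bookkeeping form of
the usual phenolic mechanism (the phenoxyl radical either quenches a
second peroxyl, *n* = 2, or is lost to back reactions / stable
adducts, *n* < 1); it reproduces the induction-period relation
τ = *n*[AoxH]₀/*R*ᵢ in the strong-inhibition limit for any *n*. An
explicit Aox• species and cross-termination are not modelled.

Quasi-steady-state limits of the same mechanism give the closed forms
in `chain_kinetics` used as oracles throughout:

* uninhibited rate R\_ox = kp·[LH]·√(Ri/2kt)
* inhibited rate R\_inh = kp·[LH]·Ri/(n·kinh·[AoxH]₀) (instantaneous,
  antioxidant-dominated termination)
* integrated inhibited rate law
  U(t) = [O₂]₀ − [O₂]ₜ = (kp·[LH]/kinh)·(−ln(1 − t/τ)), 0 ≤ t < τ.
  The law is written so both sides are positive: U is cumulative O₂
  *consumption*, regressed against −ln(1 − t/τ) with a positive slope.

## Default parameters (the simulated bench system)

| parameter | default | why |
|---|---|---|
| kp | 41 M⁻¹s⁻¹ | propagation constant for linoleate esters in liposomes (literature range 15–100) |
| [LH]₀ | 2.74 mM | methyl linoleate dose; the DMPC matrix (20.2 mM) is treated as non-oxidizable |
| Ri | 4.9 nM s⁻¹ | initiation rate of 10 mM AAPH at 37 °C, pH 7.4, as calibrated from the reference antioxidant |
| kt | ≈2.51 × 10³ M⁻¹s⁻¹ | never tabulated for this microheterogeneous system; fixed by `calibrate_kt` so the uninhibited slope is the observed 111 nM/s. Overridable. |
| [O₂]₀ | 217 μM | air-saturated aqueous buffer at 37 °C (not reported; configurable) |
| baseline | 120 s | pre-initiation electrode settling |
| injection trigger | 0.85·[O₂]₀ | the bench protocol adds antioxidant when O₂ has fallen to 90–80% of initial |
| sampling | 1 s | Clark-electrode-like |
| noise σ | 0.2 μM | plausible electrode noise; replicate counts/noise for the oximetry runs are not reported, so these are stated defaults, not inferences |
| initiation uptake | on | each initiation event consumes O₂ (+Ri term); ≤5% of the control rate |

Reference compound set for `generate_experiment_set`: PMHC
(α-tocopherol analogue; 1 μM, kinh = 4.6 × 10⁴, n = 2), TBG (10 μM,
kinh = 7 × 10³, n = 0.3), IBG and DM506 (10 μM, kinh = 5 × 10², n = 1
— retarders). Ri is constant over a run (initiator half-life ≫ run
length); the initiator efficiency f is carried as metadata only.

## A structural property worth knowing: the μM radical pool

The pair (kp = 41, R\_ox = 111 nM/s) forces the steady-state peroxyl
concentration to [LOO•] = R\_ox/(kp[LH]) ≈ 1 μM, and hence a pool
relaxation time θ ≈ [LOO•]/Ri ≈ 200 s, regardless of kt. Two
consequences follow for any simulation faithful to these effective
constants, and they shape both the defaults and the tests:

1. **Mid-run injection taxes the dose.** Injecting AoxH into a
   running oxidation lets the pre-existing pool consume ≈[LOO•]/n of
   it immediately (≈0.5 μM of a 1 μM PMHC dose). `SimConfig` therefore
   offers `aox_at_initiation=True` (antioxidant present before the
   initiator) for clean Eq-1 conditions; parameter-recovery tests use
   it, while the demo keeps the bench trigger protocol. This is also
   why the demo's calibrated Ri (≈4.3 nM/s) sits below the generating
   4.9 nM/s.
2. **Transitions are smeared.** After the antioxidant is exhausted
   the pool regrows over ~θ, so the slope break at τ is soft, and as
   [AoxH] → 0 self-termination takes over radical removal, stretching
   the tail: at reference dosing (1 μM, n = 2, τ ≈ 2θ) the trace's own
   inflection sits 15–40% beyond n[AoxH]₀/Ri. Recovery accuracy is
   therefore quoted at doses where τ ≫ θ (n·c = 4 × 10⁻⁵ M,
   τ ≈ 8200 s): there detect_tau + fit_eq2 recover τ within 5% and
   kinh within 10% noiseless, and within 10%/15% per-realization at
   1% full-scale noise.

## Induction-period detection

`detect_tau` (per-step results recorded in provenance):

1. Slope-break screen: steep-phase slope (last quarter of the
   post-injection record, O₂-exhaustion truncated) over
   inhibited-phase slope (3–18% of the record). Ratio below
   `tau_slope_ratio_min` (default 2.0) ⇒ retardation, τ absent. The
   threshold sits between the ~2.6 of a weak antioxidant with a
   "slight inflection" and the ~1.1 of true retarders/controls.
2. Provisional breakpoint: last upward crossing of the smoothed
   uptake rate through the midpoint of the two slopes. (A curvature
   maximum is not used here: it latches onto the injection/start-up
   radical transient for weak traps.) Smoothing for this scan scales
   with record length; slope and rate-law fits always use raw samples.
3. τ estimate: intersection of the inhibited and steep tangent lines
   (`tangent_intersection`, default) or the maximum-curvature point
   (`second_derivative`).
4. Refinement: τ maximizing the linearity (r²) of uptake against
   −ln(1 − t/τ) over 0.2–0.92 τ, golden-section polished, capped to
   [0.7, 1.4]× the step-3 value and rejected when the r² landscape is
   monotone (no logarithmic curvature, e.g. piecewise-linear data).
   Line intersections alone carry the ~θ·ln 2 regrowth bias; the
   near-divergence samples pin τ much more sharply.

`fit_eq2` then regresses U(t) on −ln(1−t/τ) over 0.10–0.80 τ (chosen
to dodge the injection transient and the divergence; configurable) and
reports kinh = kp[LH]/slope with r²; fits with r² < 0.99 are flagged
unreliable. When the trace metadata says initiation uptake was
recorded, Ri·t is subtracted first — otherwise kinh is biased low
whenever the inhibited chain rate is comparable to Ri.

Rates: R\_ox1 is the least-squares slope over the central 30–80% of
the pre-injection (or whole control) record; R\_inh over 0.10–0.80 τ
when τ exists, else over the first half of the post-injection record
(retarded process); R\_ox2 from 1.15 τ to the end. ν values are exact
ratios R/Ri; display rounds ν to integers at ≥10 and one decimal
below, rates to 0.001 nM/s, τ to 0.01 min.

Classification: `reference` for the designated calibration standard;
`antioxidant` when τ is present and kinh ≥ 100·kp (the usual
"active antioxidant" criterion kinh ≫ 10² kp); `retarder` when τ is
absent but R\_inh ≤ 0.9·R\_ox1(control); `inactive` otherwise.
Boundary equalities resolve toward the stronger class.

## Endpoint statistics

Published endpoint summaries are mean ± SEM with n = 3; this reading
(rather than ±SD) is what reproduces the printed Cohen's d = 24.31
for the K⁺-efflux stressor-vs-control comparison (an SD reading gives
14.0). Cohen's d uses sd = sem·√n per group and the equal-n pooled
form √((sd₁²+sd₂²)/2), which equals the df-weighted pooled SD when
n₁ = n₂. CIs are t-based (df = n − 1), matching the printed intervals
to within one unit in the last digit (printed bounds were computed
from unrounded means; e.g. 7.02 vs our 7.03). The same input-rounding
effect shifts two published percent reductions by 0.1 point (43.4 vs
recomputed 43.3; 13.3 vs 13.2); tests compare at ±0.15 point.
`generate_endpoint_groups` draws replicates and affinely rescales them
so sample mean and SEM match the targets exactly — the statistics
stage therefore reproduces summary-derived effects to machine
precision, by construction. ANOVA/Tukey p-values are out of scope;
the module stops at descriptive effect measures.

## What the synthetic data does and does not emulate

The simulator reproduces the observable structure of inhibited
oximetry: baseline, injection timeline, induction/retardation/
uninhibited phases, O₂-exhaustion roll-off, Gaussian electrode noise
and linear drift, and summary-matched endpoint groups. It does not
emulate bilayer partitioning of the antioxidant, oxygen diffusion
limitation, co-antioxidant regeneration, tocopherol-mediated
propagation, pH/temperature dependence of rate constants, or the
sharp phase transitions of the real microheterogeneous system (see
the radical-pool discussion above — the homogeneous model with these
effective constants cannot show both a 111 nM/s chain at kp = 41 and
second-scale transitions). Passing round-trip tests therefore
demonstrate correctness of the analysis pipeline under the stated
mechanism, not instrument-grade fidelity to any particular bench
trace.

## Numerical and interface choices

* SI units (M, s) internally; μM/minutes/nM·s⁻¹ at file and report
  boundaries. Trace CSVs carry `time_s,o2_um` with a YAML sidecar for
  injection times and system parameters; readers reject exactly the
  inputs that violate trace invariants (header, monotone time,
  non-negative O₂, t\_aox ≥ t\_init), naming the offending line.
* Runs are truncated when O₂ < 5% of initial; noise is clipped at 0.
* Simulations and noise are seeded; identical config + seed gives
  byte-identical outputs, and every CLI output embeds the seed and a
  config digest.
* Test and demo problem sizes (dt 1–4 s, runs ≤ ~21000 simulated
  seconds, 20 noise realizations) keep the full suite under ~10 s
  while leaving every regime — strong/weak trap, retarder, noisy —
  represented.
* The CLI maps validation errors to exit 2 and computation errors to
  exit 1; unknown flags follow click's usage-error convention
  (exit 2).
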