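# Methods

This note documents the models implemented in `tubuvolt`, the conventions
and reconstructed constants they depend on, the design choices made where
the source formulas were ambiguous, and what the synthetic-data tests do and
do not demonstrate.

## Butler–Volmer energetics chain (`cv_energetics`)

From the baseline-corrected adsorption peak current i_p of a voltammogram,
the chain computes the exchange current density i_0 = i_p/A, the adsorption
free-energy magnitude

    ΔG = | RT ln( i_p h / (n F k_B T C) ) |  →  eV  (divide J/mol by F),

the charge-transfer resistance R_ct = RT/(nF i_0), resistivity
ρ = R_ct·A/l, conductivity σ = 1/ρ, and the Eyring-type rate
k_het = (k_B T/h) exp(−ΔG e/(k_B T)).

Conventions, fixed deliberately and verified against the reference tables:

- **Concentration units.** The free-energy logarithm takes C as its numeric
  value in mol/L (1 mM → 10⁻³). The alternative mol/cm³ reading shifts every
  ΔG by RT·ln(1000)/F ≈ 0.18 eV and does not reproduce the tabulated column;
  the mol/L numeric convention reproduces all six rows at the printed two
  decimals.
- **Signs.** Cathodic peak currents are negative in the reference table; all
  estimators use |i_p|, and ΔG is reported as a magnitude (the logarithm's
  argument is ≪ 1, so the raw value is negative).
- **R_ct as a bare number.** i_0 is in A/m² with A in m², and R_ct = RT/(nF i_0)
  is reported as the tabulated numeric value. Dimensionally this quantity is
  Ω·m², not Ω; the package reproduces the published numbers rather than
  repairing the dimension, and documents the fact here.
- **Path length l.** The conduction path length in ρ = R_ct·A/l is not part of
  the published setup. l = 1.0 µm is a reconstruction: it reproduces the
  resistivity and conductivity columns to ≤ 0.1%. It is configurable
  (`ElectrodeConfig.l`), and the reproduction report (`tubuvolt reproduce`)
  labels it as a reconstruction.
- **Temperature** defaults to 298.15 K.
- **Constants** are CODATA 2018 exact values, which satisfy R = F·k_B/e
  identically (an enforced invariant). One visible consequence: zF/M with
  M = 300 g/mol gives 89.34 mAh/g where the reference value 89.35 was
  computed with F rounded to 96 500 C/mol.
- **Known rounding boundary.** The recomputed conductivity at 50 mV/s is
  2.024 mS/m, which prints as 2.02 against the published 2.03; the cell is
  reported as "boundary" rather than pass/fail because the original rounding
  path is unknowable. All other σ cells match at printed precision.

Peak detection is intentionally simple: within each configured potential
window, on the sweep direction the feature belongs to, a straight baseline
through the window-edge samples is subtracted and the extremum of the
corrected current is taken; features below a prominence threshold (default
0.1 µA) are omitted. Default windows: adsorption [0.2, 0.4] V (forward),
desorption [−0.4, −0.2] V and hydrogen evolution [0.0, 0.1] V (reverse).
No double-layer or uncompensated-resistance correction is attempted.

The exchange-current expression
i_0 = (nFC·k_het/A)·exp(β n F E/(k_B T)) is implemented with its symbol
placement taken literally, including the molar/molecular mixing in the
exponent. No downstream tabulated value constrains β or E, so the formula
is exercised only by limit and factorization tests (E = 0 reduction,
exponential doubling at representable magnitudes).

## Monte Carlo box model (`mc_engine`)

### Model

A cubic box of half-length d_total = 690 Å represents the electrolyte: its
centre is the bulk, its walls the gold electrode. One α-tubulin and one
β-tubulin walker start at the centre with energies

    E_i1 = E_amt + d2/d1 + (d_α + ephiapp)/d_total
    E_i2 = E_bmt + d2/d1 + (d_β + ephiapp)/d_total

where d2 = d1 + Δd is the per-step covered distance, d1 = 2.39 Å the Au–S
bond distance (the critical contact length), Δd = x·(t/t_eq) with x = 3 Å
the solvation radius, and E_amt = 0.286 eV / E_bmt = 0.293 eV the
species–gold interaction energies. Chemical potentials are µ = E_i − ephiapp.
These expressions mix a distance ratio, angstroms and volts as plain
numbers; the package treats them as eV-equivalent bookkeeping, exactly as
defined, with no dimensional repair.

Each proposal draws a uniform variate per walker and accepts through the
Boltzmann gate exp(−F(µ₂−µ₁)/RT). Both comparison conventions are
implemented:

- `paper_ge` (default): accept when draw ≥ threshold, the model's printed
  criterion;
- `metropolis_le`: accept when draw ≤ min(1, threshold), the standard rule
  (provided because the printed direction accepts nothing when µ₂ = µ₁).

### Design choices where the model was underdetermined

- **Gate evaluation point.** The gate compares the two species at the
  *walker's own position*, so the chemical-potential gap is the constant
  species gap E_bmt − E_amt = 0.007 eV and the threshold is
  exp(−F·0.007/RT) ≈ 0.7615 (acceptance ≈ 0.2385 under `paper_ge`).
  Evaluating the gap on the separated pair instead makes the printed ≥
  criterion absorbing: once the α walker leads by more than
  0.007·d_total ≈ 4.8 Å the threshold exceeds one and both walkers freeze
  permanently. The co-located evaluation keeps the two walkers statistically
  independent, which is also what makes E_ad non-degenerate.
- **Independent walkers, first-contact termination.** The two walkers follow
  independent draw streams (a `symmetric_paths` flag shares one stream for
  the degenerate limit). The trajectory ends when the *first* walker crosses
  within d1 of the wall; E_ad = E_i1 − E_i2 is evaluated there (default
  `terminal` reduction; a `mean`-over-steps reduction is also exposed since
  the original reduction is unstated). Ending instead when *both* walkers
  arrive would pin both at the same quantized terminal distance and make
  E_ad identically E_amt − E_bmt = −0.007 eV, collapsing every stochastic
  property. With first-contact termination the laggard's deficit makes E_ad
  a random variable while the forced-symmetric case remains exactly
  −0.007 eV.
- **Load coupling.** Load enters only through the time fraction:
  t/t_eq = L/L_max (linear, normalized to 1 at the maximum load of the
  schedule, configurable). Physically: higher load means faster potential
  pulses, less relaxation between steps, larger effective step.
- **Load response is assessed with one per-load sd of slack.** Because the
  per-walk spread of E_ad scales like sqrt(Δd) ∝ sqrt(load) (a diffusive
  difference accumulated over a fixed 690 Å traverse in load-sized steps),
  the raw mean |E_ad| drifts mildly upward with load — by ≈ 0.2–0.4 of the
  per-load sd per step of the schedule. The monotonicity check therefore
  asserts mean_{i+1} ≤ mean_i + sd_i, which the default configuration passes
  comfortably; it is a qualitative, spread-aware verdict, not a claim that
  the means decrease pointwise. The published per-load curves exist only as
  figures and are not reproduced numerically; the cubic load response is
  honored at its zero-load limit (3.0 eV) and refit on simulated sweeps with
  load in MΩ.
- **ephiapp** defaults to 1.0 V, the vertex of the CV potential window.
- **RNG.** One master seed; replicate r of a sweep uses seed
  `rng_seed + r` (NumPy PCG64). Identical (config, seed) gives bit-identical
  trajectories, sweeps and fits.
- Walkers do not interact (no interaction potential is defined by the
  model); `n_units` is bookkeeping for the electrolyte model, and replicates
  play the role of independent units. The "fixed number of solvent
  molecules" enters no equation and is not implemented.

### Computational notes

A walk is simulated vectorized: with a constant gate threshold the accepted
steps are Bernoulli draws, so positions are Δd times a cumulative sum of
acceptance flags, truncated at the first contact. Default problem sizes (the
package's own choice of study conditions): 10³ replicate walks per load for
sweeps, with convergence checks at 10² and 10⁴ replicates at a single load;
a sweep over the six reference loads at 10³ replicates takes a few seconds
on one core. A `step_cap` (default 2·10⁶ proposals) turns a non-advancing
configuration (Δd = 0, or a zero-acceptance gate) into a convergence-failure
error instead of a hang.

## K⁺ transport (`transport`)

D inverts i_p = 0.446·nF(A·C)·sqrt(nFDv/RT) with every length in cm. The
stated electrode area with C = 1 mM does **not** reproduce the published
diffusion column; a single effective A·C = 4.90·10⁻⁷ mol/cm (obtainable by
least squares of the relation against the table before any other choice)
fits all six rows within 0.01·10⁻⁷ cm²/s and is the documented default.
Mobility µ = |z|FD/RT is evaluated at 293 K — the published mobility column
follows from the *printed, rounded* D values at that temperature (298 K does
not reproduce it); the diffusion inversion itself uses 298.15 K. Both
reconstructions are surfaced in the reproduction report. `transport_table`
computes µ from the unrounded recomputed D; comparisons against the printed
µ column therefore feed the printed D values through `ionic_mobility`,
mirroring how that column was evidently produced. The recomputed D at
50 mV/s (1.953·10⁻⁷) sits on the rounding boundary of the printed 1.96·10⁻⁷
and is flagged as such.

## Electrolyte conductance (`electrolyte`)

G = Λ⁰·C·A/l with Λ⁰(K⁺) = 73.5 S·cm²/mol and C converted mol/L → mol/cm³.
How the microtubule count enters is not defined by any published equation;
the package exposes an explicitly phenomenological saturation rule — below
`critical_n` (default 1500 units, the maximum simulated count) the MT
content leaves G unchanged, at and above it G is multiplied by `drop_factor`
(default 0.5) and held constant — reproducing the described
step-then-plateau shape for every KCl level. Both knobs are labelled
non-physical defaults. The published absolute conductance for 1 mM tubulin
(5.53·10⁻⁴ µS) implies an unexplained geometry and is not a package target;
likewise the two mutually inconsistent ionic-conductivity figures quoted in
the source are not derivable from Λ⁰·C and are not asserted anywhere.

## Battery metrics (`battery`)

Discharge segment = the maximal run of negative current within a cycle;
Δt is the time between the run's endpoints and ΔV the voltage span across
it. Conversions are fixed at 1 mAh = 3.6 C and mAh/g × V = Wh/kg. The
published initial capacity (63.2 mAh/g) and capacitance (173.65 F/g) do not
follow from the published Δt = 90 s, I = 1 A, m = 0.5 g, ΔV = 0.214 V
(the formulas give 50 mAh/g and 841 F/g); the package always computes from
the formulas and the reproduction report keeps the published figures as
labelled references only. The quantity published as "42.48% capacity
retention" is numerically the capacity *fade*, 100·(63.2 − 36.35)/63.2;
the package reports fade and retention separately with explicit labels.
M = 300 g/mol behind the zF/M capacity is a reconstruction by inversion
(tubulin's actual molar mass is ~50 kDa) and is labelled as such. C-rate
bookkeeping is not re-derived.

## Synthetic generators (`synthetic`)

Voltammograms are triangular sweeps at a fixed potential step with a
sign-following capacitive baseline, Gaussian peaks assigned to a sweep
direction, and optional Gaussian noise — peak shapes in the source exist
only as figures, so Gaussian is a modelling choice and the detector
tolerance (2%) is set accordingly. The six reference traces carry the
published peak currents at +0.30 V with width 0.02 V, narrow enough that the
window-edge baseline bias is < 10⁻⁵ relative. GCD trains are ideal linear
ramps (no IR step, since the published ΔV is taken as the full discharge
span) with segment endpoints always on the sample grid, so recovered
durations are exact; the `exponential-to-floor` fade model decays capacity
geometrically so the final cycle lands exactly on `Q_floor`. Passing
generator/analyzer closure tests shows the estimator chain is
self-consistent at the published operating point — it does not validate peak
shapes, double-layer physics or real instrument noise.

`paper_fixture_tables()` is the single in-package source of published
reference values; tests and the reproduction report draw from it rather than
re-hardcoding numbers.

## Reproduction pipeline (`report`, CLI `tubuvolt reproduce`)

Closed-form quantities are compared at half-ULP of their printed precision
(0.005 on two-decimal cells, 0.01·10⁻⁷ on diffusion mantissas, 0.1% relative
on resistivity); the two known boundary cells are reported as "boundary",
not pass/fail. Stochastic verdicts (monotonicity with one sd of slack, sem
shrinkage between replicate counts) run at fixed seeds. Reports are JSON
with the timestamp isolated to one header field so reruns are otherwise
byte-identical.

## Known limitations

- The box model has no explicit solvent, electrostatics, lattice geometry,
  GTP hydrolysis or walker interactions; its energies are bookkeeping in
  eV-equivalents and should be read as a phenomenological reproduction, not
  a physical free-energy calculation.
- Published figure-only curves (per-load E_ad values, CV/GCD traces) are not
  digitized; properties replace pointwise reproduction for those.
- The acceptance gate's printed comparison direction is kept as the default
  even though it is the reverse of Metropolis; both conventions are tested
  against their analytic acceptance probabilities.
- No impedance fitting, no Nyquist analysis, no equivalent-circuit or
  coulombic-efficiency modelling; the EC-anode cell variant is reported text
  only.
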