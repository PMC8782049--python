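# Methods

## Scope and model

`heteropka` implements a linear free-energy (QSAR) protocol for estimating
acid dissociation constants of pyrimidines and related nitrogen
heterocycles. The inputs are electronic energies of protonation microstates
— one energy per (compound, charge state, tautomer, phase) — computed
elsewhere (e.g. DFT with a continuum aqueous solvent model) and supplied as
CSV. The pipeline is:

1. **Consolidation** — collapse multiple literature pKa reports per
   compound/step to one experimental value.
2. **Tautomer resolution** — represent each charge state by its most stable
   tautomer.
3. **Descriptor** — ΔE, the energy of the deprotonated species minus the
   energy of its parent, in the same phase.
4. **Calibration** — OLS of experimental pKa on ΔE, per step.
5. **Prediction & report** — apply the line to every compound's ΔE,
   including compounds without measurements.

Two dissociation steps are supported: pKa1 (cation → neutral,
ΔE = E(AH) − E(AH₂⁺)) and pKa2 (neutral → anion, ΔE = E(A⁻) − E(AH)).

### Assumptions

* A single tautomer dominates each charge state. This is checked, not
  assumed blindly: ensembles whose two lowest tautomers lie within
  25 kJ/mol of each other raise a `SmallGapWarning` (the warning threshold
  is configurable), and a Boltzmann-weighted effective energy
  −RT·ln Σ exp(−Eᵢ/RT) is available as an alternative policy for
  sensitivity analysis. At a 25 kJ/mol gap the two policies differ by
  ≈ 1×10⁻⁴ kJ/mol per state — negligible against every other error source.
* The pKa–ΔE relation is linear over the calibration range. A perfect
  free-energy relationship would have |slope| = 1/(RT·ln 10) ≈ 0.175 per
  kJ/mol at 298.15 K; fitted slopes are validated against this bound.
* Raw electronic-energy differences (no ZPE/thermal corrections) suffice in
  solution; the regression absorbs systematic offsets. Gas-phase energies
  flow through the same machinery via a phase flag.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| temperature | 298.15 | K | standard state for the calibrations |
| R | 8.31446×10⁻³ | kJ/(mol·K) | gas constant |
| hartree → kJ/mol | 2625.5 | — | unit conversion on load |
| gap warning threshold | 25 | kJ/mol | typical inter-tautomer gap in this family |
| qualitative cut | −7 | pKa | separates the reference tables' `<0` (≈ −5.5) from `<<0` (≈ −9.5 and below) cases; no finer information is recoverable from negative-range data |
| G°(H⁺), gas | −26.3 | kJ/mol | standard proton free energy at 298.15 K |
| consolidation | mean of distinct values, half-up to 2 decimals | — | how the reference experimental columns were assembled |
| tautomer policy | most stable | — | the protocol's default; Boltzmann opt-in |

Reported precision follows the reference tables: coefficients to 3 decimals,
predictions and residuals to 2. Full floating-point precision is carried
internally everywhere; rounding is applied only at reporting boundaries. In
particular, `calibrate()` consolidates literature replicates at full
precision (`ndigits=None`) — a noiseless synthetic dataset is recovered to
1×10⁻⁹ — while direct `consolidate()` calls default to the 2-decimal
display rule. An optional `round_de_for_fit` switch reproduces fits made
from display-rounded (integer kJ/mol) descriptor tables.

### Calibration subset

Compounds enter a fit only when they have both a numeric experimental value
and an estimate in the calibrated (non-negative) range. In the packaged
reference tables this is encoded by the qualitative marks: the pKa1 table
has 22 rows of which 17 calibrate, the pKa2 table 21 rows of which 12
calibrate. Negative-range measurements (e.g. isoxazole, −2.0) are reported
with predictions but excluded from fitting, since such measurements carry
large uncertainties.

### Residuals and outliers

Residual = experimental − predicted, absent (never zero) when either side is
missing. No outliers are removed, ever; optionally rows whose internally
studentized residual exceeds 2.5 in magnitude are flagged in reports —
digressions from a calibration can signal genuinely different chemistry and
deserve attention, not deletion.

## Gas-phase validation

Computed free energies are validated against experimental gas-phase
deprotonation data via ΔrG° = |G°(A⁻) + G°(H⁺) − G°(AH)|. The magnitude is
used because tabulated gas-phase acidities are positive ~1400–1600 kJ/mol
regardless of the direction the reaction is written in; the quantity is
invariant to any common shift of the two free energies. On the packaged
six-compound validation table the experimental/calculated squared
correlation is 0.998 and succinimide is the only compound deviating by more
than 5 kJ/mol (13 kJ/mol).

## Synthetic data generator

`simulate_dataset` emulates the statistical structure the analysis assumes:
true ΔE uniform over (−1254, −872) kJ/mol (the span of the reference
descriptor tables); true pKa = slope·ΔE + intercept with defaults
(−0.131, −151.54); Gaussian observation noise (default sd 1.25, the pKa1
calibration's residual scatter); 1–3 replicate "literature" values per
compound scattered with sd 0.1 (the spread of repeated reports in the
reference literature table); tautomer ensembles of 1–4 states per charge
state whose non-representative members are offset upward by exponential
gaps of mean 30 kJ/mol. Energy baselines are drawn in an arbitrary window
because only differences enter the analysis — the pipeline is
translation-invariant, and a test asserts it.

What the generator does **not** emulate: systematic quantum-chemistry error
(basis-set or solvent-model bias), correlation between a compound's pKa1 and
pKa2 errors, non-Gaussian literature disagreement, and selection effects in
which compounds get measured. Passing recovery tests therefore demonstrate
the statistical machinery (unbiased slope recovery, nominal CI coverage,
correct s estimation) — not that any particular level of theory is accurate
for new chemistry.

The "bias → 0 with n" property is tested as: |mean fitted slope − truth|
within a 3·MC-SE envelope at n = 17, 50, 200, with the envelope and the
sampling sd both strictly decreasing. A literal comparison of |bias| values
between sample sizes would be a coin flip for an unbiased estimator.

## Numerical choices

* OLS is computed from centered sums; diagnostics from the standard
  n−2-degrees-of-freedom formulas. statsmodels reproduces every diagnostic
  to 1×10⁻⁹ in the tests but is not a runtime dependency.
* Boltzmann ensemble energies are computed with the minimum-energy shift, so
  no overflow occurs for any gap, including the +∞ perturbation limit.
* Exact energy ties in tautomer selection break on the lexicographically
  smallest tautomer id — arbitrary, but deterministic and
  permutation-invariant.
* Consolidation deduplicates exact repeats (the same number cited by two
  sources counts once) and averages in exact decimal arithmetic, so .5 ties
  are genuine decimal ties, then rounds half-up. Policies `median` and
  `first` are available.
* Rounding helper: half-up on the shortest decimal representation of the
  float, matching how a reader rounds the printed number.
* Empty pipeline inputs produce an empty report and a success exit, with a
  warning, rather than a fit error.

## Known limitations and data inconsistencies

The packaged reference tables are transcribed exactly as printed (guarded by
checksums), including their internal inconsistencies, and two acceptance
checks fail *by design* against them:

* **pKa2 refit vs published slope.** OLS on the printed pKa2 table (12
  pairs) gives slope −0.1505 (SE 0.012); the published calibration is
  −0.141 ± 0.008. The printed residuals of that table sum to +5.71, whereas
  genuine least-squares residuals sum to zero — the published line was
  evidently fitted to unrounded (unpublished) data. The test asserting
  one-published-SE agreement is kept failing for pKa2 rather than widened;
  the independent-oracle agreement (1×10⁻⁹) and the pKa1 check (−0.1354,
  within 0.008 of −0.131) pass.
* **Aziridine consolidation.** The literature values {7.98, 8.05} average
  to the exact tie 8.015, printed as 8.01 (rounded down), while piperazine's
  {9.78, 9.73} → 9.755 is printed as 9.76 (rounded up). No single tie-break
  reproduces both; the package's half-up rule yields 8.02 and the
  corresponding worked-case test is left failing. At printed precision the
  consolidation rule reproduces 15/17 pKa1 and 11/12 pKa2 experimental
  entries (remaining exceptions: a 7.95-vs-6.95 disagreement between two
  reference tables for 1-methylimidazole, and cytosine's 12.575 tie).
* The external-predictor comparison uses **all** complete
  (external, experimental) pairs — 21 for pKa1, 14 for pKa2 — although the
  published regressions quote n = 19 and n = 13 without identifying the
  excluded compounds.
* Formulas are stored as printed, including two evident typos (flagged in
  the data tests); identifiers, not formulas, key all joins.
* Microstates are supplied as records: the package neither enumerates
  tautomer structures nor perceives molecular graphs, and aqueous ΔE uses
  raw electronic energies by construction (no ZPE/thermal corrections).
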