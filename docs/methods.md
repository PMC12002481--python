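# Methods

## Model

`hrmtm` predicts the melting temperature observed in high-resolution
melting (HRM) of a PCR amplicon from the sequence alone, in two stages.

**Nearest-neighbor summation.** The duplex formed by a strand and its
reverse complement is decomposed into its n = L − 1 overlapping
dinucleotide stacks. Total enthalpy and entropy are

ΔH = Σ stacks ΔH°(stack) + ΔH°init(5′ terminus) + ΔH°init(3′ terminus) [+ ΔH°sym]
ΔS = Σ stacks ΔS°(stack) + ΔS°init(5′ terminus) + ΔS°init(3′ terminus) [+ ΔS°sym]

with the unified parameters of Allawi & SantaLucia (1997/1998): ten
canonical stack classes (the 16 dinucleotides reduce to 10 by
reverse-complement equivalence, e.g. TG ≡ CA/GT), an initiation term per
terminus depending on whether the terminal pair is G·C (0.1 kcal/mol,
−2.8 cal/(K·mol)) or A·T (2.3, +4.1), and an entropy-only symmetry
correction (0, −1.4) for self-complementary strands. Units are fixed:
ΔH in kcal/mol, ΔS in cal/(K·mol).

**Empirical Tm formula.** With GC% the G+C percentage over the full length
and n the stack count,

Tm(°C) = 1000·ΔH/ΔS − g(GC%) − (150 + 2n)/n − 273.15

where g = 0.27·GC% for 40 ≤ GC% ≤ 60 (boundaries inclusive) and
g = GC%/3 for GC% < 40. The factor 1000 converts ΔH to cal so that the
ratio term is a temperature in Kelvin; this bridge is forced numerically
(e.g. 932000/2507 ≈ 371.8 K → 82.4 °C, the scale of real amplicon melts).
GC% enters as percentage points, not a fraction, for the same reason.

### Model assumptions

- Two-state melting of a perfect-match duplex: no mismatches, dangling
  ends, loops, or salt/Mg²⁺ dependence. The underlying measurements were
  made at 1.5–2 mM Mg²⁺; outside that window the empirical constants
  absorb a different offset.
- Amplicon regime: the constants were fitted on 60–155 nt sequences with
  GC between roughly 34% and 55%. The length term (150 + 2n)/n decays
  monotonically toward 2 °C, so length sensitivity fades for long
  amplicons; behaviour above ~300 bp is unvalidated.
- The two GC branches do **not** join continuously at GC% = 40
  (0.27·40 = 10.8 vs 40/3 ≈ 13.33): the branch assignment (mid-GC branch
  at exactly 40) is part of the model, and the tests assert the assignment
  rather than continuity.
- GC% > 60 has no defined branch. `select_branch` refuses by default;
  an explicit `extrapolate` flag forces the mid-GC branch with a warning,
  because silently extrapolating would misrepresent the method.

### Symmetry-correction policy

The standard nearest-neighbor convention applies the −1.4 cal/(K·mol)
entropy correction only to self-complementary strands, and that is the
default (`symmetry_policy="auto"`). The published worked example for the
(non-self-complementary) hexamer GTGCAT/ATGCAC nevertheless includes the
term, so the worked-example regression values (ΔH = −40, ΔS = −112.7) are
checked under `symmetry_policy="always"`, and the auto-policy value
(−111.3) is checked alongside. For amplicon-length sequences the term
changes Tm by well under 0.01 °C, so the discrepancy is cosmetic.

## Parameters and defaults

| parameter | default | units | meaning |
|---|---|---|---|
| `gc_coeff_mid` | 0.27 | °C per GC point | GC correction, 40–60% branch |
| `gc_divisor_low` | 3 | – | GC%/3 correction, <40% branch |
| `length_const`, `length_slope` | 150, 2 | – | the (150 + 2n)/n length term |
| `branch_low_edge`, `branch_high_edge` | 40, 60 | GC points | branch boundaries |
| nearest-neighbor table | unified Allawi–SantaLucia values | kcal/mol, cal/(K·mol) | 10 stacks + 2 initiation + symmetry |

An alternative nearest-neighbor table can be loaded from TSV but must be
complete (all 13 entries); partial overrides are rejected so a run is
always attributable to exactly one parameter set. Formula constants are
overridable individually (`TmCoefficients`, or `--coeff key=value` on the
CLI) because they are independent empirical knobs.

## Bundled data and its inconsistencies

The package ships the study dataset verbatim as text fixtures: 28 amplicon
sequences (five diatom species × six primer systems; one primer amplifies
only three species, and those two absent rows are represented as missing,
not zero), the 20 training Tm measurements, the published per-amplicon
(GC%, n, ΔH, ΔS) summary, and the published validation table (predicted,
measured, |difference| for 8 amplicons; mean 0.67 °C). Loading verifies a
sha256 checksum per file and recomputes GC% and n from each sequence.

Printed values are never corrected. Disagreements between the printed
summary and the printed sequences are surfaced as per-row consistency
flags: the UPA99/*Navicula* row (printed GC 42.19%, n = 63 vs 41.27%,
n = 62 recomputed from its 63-nt sequence) plus two smaller GC
discrepancies (UPA99/*Odontella*, Primer1/*Skeletonema*). A GC tolerance
of 0.005 points keeps pure rounding-rule ties (half-up vs half-even, e.g.
40.625) from being flagged. The printed per-amplicon ΔH/ΔS totals are
likewise treated as inputs, not as recomputation targets: they are not
exactly reproducible from the printed sequences (the handling of the
symmetry term and possible sequence revisions behind them are unrecorded),
so `thermo_recomputation_deltas` reports the printed-minus-recomputed
differences for inspection and nothing asserts them.

One column-level anomaly is documented rather than resolved: in the
published validation table it is the *measured* column that the formula
reproduces from the published per-amplicon parameters (six of eight rows
exact at 2 decimals; the remaining two land 0.01 and 0.03 °C away, which
is what the 1-decimal rounding of the printed ΔH/ΔS propagates), while the
*predicted* column is not reproducible from the printed inputs. The
regression tests therefore assert the formula's output against the
reproducible column for the six exact rows and report the other two.

## Synthetic data

`generate_sequence(length, gc_target, seed)` builds sequences with a
**count-exact** GC composition: round(gc_target·L/100) positions are G or
C (each with probability ½), the rest A or T, uniformly shuffled. Exact
counts (rather than i.i.d. bases) make GC-dependent properties testable
without composition sampling noise. `generate_benchmark` draws lengths
uniformly over 60–155 nt and GC over 34–56% — the regime of the study's
amplicons — and labels each sequence with the model prediction plus
Gaussian noise (default sd 0.3 °C, the scale of the study's validation
errors). The generator emulates composition and ideal instrument noise
only: no primer structure, no biological sequence correlation, no
systematic salt/dye/ramp effects. Passing recovery tests therefore shows
the fitting machinery is correct and well-conditioned at study-like sample
sizes, not that the model generalizes to real melts.

## Coefficient refitting (a reconstruction)

How the published constants (0.27, /3, 150, 2) were derived is not stated.
`fit_coefficients` reconstructs the step as ordinary linear least squares,
which is the natural choice because the model is linear in the constants
once the thermodynamic ratio moves to the left-hand side:

y_i = Tm_i − 1000·ΔH_i/ΔS_i + 273.15 = −c·GC%_i − a/n_i − b

Free parameters are any subset of {c (optionally per branch), a, b}; fixed
ones keep their defaults. No regularization; rank deficiency (e.g. all
GC% equal with c free) is reported as an error rather than silently
pseudo-inverted. On data generated by the model with zero noise the fit
returns the generating constants to ≤1e−9 (an exact inverse); at noise
sd 0.3 °C with 50 training rows, a 300-replicate Monte-Carlo run of the
full generate→sum→fit pipeline put the empirical sd of ĉ near 0.008 with
every replicate within ±0.05 of the truth, which is the tolerance the
noisy-recovery test uses. Outputs of refitting on the bundled training
rows are reported (rmse, residuals) but never asserted against the
published constants, since the original derivation may have differed.

## Numerical choices

- All arithmetic at full double precision; 2-decimal rounding is applied
  only at display/comparison boundaries, matching the precision of the
  published tables.
- Comparisons against published Tm values use ±0.01 °C after rounding to
  2 decimals; rows where the published inputs' own 1-decimal rounding
  propagates more than that are excluded from assertions (reported only).
- The ratio term requires ΔS ≠ 0; sequences shorter than 2 nt are rejected
  at validation (no stack exists).
- Sequence canonicalization: whitespace stripped, case folded, U→T with a
  logged warning; IUPAC ambiguity codes are rejected by default since the
  study's amplicons are unambiguous and averaging stack parameters over
  expansions would silently change the thermodynamics.
- Ties and edge cases: GC% exactly 40 → mid branch; GC% exactly 60 → mid
  branch; self-complementarity requires even length by construction.
- Randomness: a single seeded `numpy` generator per entry point; benchmark
  child sequences derive their seeds from the parent stream, so one seed
  fixes the whole dataset.

## Problem sizes used by the shipped checks

The property suite uses exhaustive dimers, 1000-sequence random sweeps
(lengths 2–300) for sign/oracle invariants, 50-row noisy fits (30 seeds)
for recovery dispersion, and a 10⁴-record benchmark for the noise-sd
convergence check; the end-to-end acceptance recomputation is
deterministic and runs in well under a second.

## Known limitations

- No salt/Mg²⁺ correction term exists in the model; validity outside
  1.5–2 mM Mg²⁺ is undemonstrated.
- The empirical constants come from 20 training amplicons of one
  instrument and chemistry; transfer to other dyes, ramp rates or
  platforms may shift the additive terms.
- No branch exists above 60% GC, and the low-GC branch is supported by
  training data only down to ~34% GC.
- Heteroduplexes, mixed templates and multi-domain melting (multiple
  peaks) are out of scope: the model predicts a single Tm per sequence.
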