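# Methods

## Biogenesis model

The kinetic core is a linear two-compartment model of CFTR maturation. The
immature, core-glycosylated ER form (B band) receives constant synthesis
flux `synthesis_rate` (arbitrary units/h) and exits by first-order
maturation to the complex-glycosylated form (C band, rate `k_mat`, 1/h) or
first-order degradation (`k_deg_b`); the mature pool degrades at `k_deg_c`.
Metabolic labeling splits synthesis between heavy and light isotopologs
according to a piecewise-constant schedule, yielding four pools with shared
rate constants. First-order kinetics is the minimal model consistent with
the immature pool's exponential disappearance during the chase; it ignores
translation time, ER export transit and any saturation of the folding or
degradation machinery.

Because the system is affine with piecewise-constant coefficients, it is
solved exactly by the matrix exponential of the augmented system, one
segment at a time — no numerical time stepping, and all degenerate rate
combinations (zero rates, equal rates) are handled uniformly. Cumulative
synthesis and cumulative degradation are propagated alongside the pools so
mass balance can be audited; tests verify agreement with an independent
step-size-controlled integrator to 1e-8 relative and mass balance to 1e-8.

The pre-pulse state defaults to the steady state of the light pools
(`B = s/(k_mat+k_deg_b)`, `C = k_mat·B/k_deg_c`); an empty start is
available for protocols with effective starvation. When `k_deg_c = 0` the
mature pool has no finite steady state and is started empty. Reported
chase timepoints are measured from the end of the pulse (t = 0 is
"directly after the pulse").

### Parameter presets

Presets encode the study regimes rather than fitted values:

| preset | k_mat+k_deg_b (1/h) | φ | k_deg_c (1/h) | rationale |
|---|---|---|---|---|
| WT | 0.713 | 0.19 | ln2/18 | 30-min pulse labels ~30% of B; ~19% conversion; 18-h mature half-life |
| F508del | ln2/0.5 ≈ 1.386 | 0.005 | ln2/5.5 | ~50% labeling (B pool gone within 2.5 h); <1% conversion |
| F508del+TEZ / +ELX / +TEZ+ELX | 1.386 | 0.024 / 0.067 / 0.14 | ln2/5.5 | corrected conversion regimes |
| F508del+IDOR-3 / +IDOR-4 | 1.386 | 0.24 / 0.31 | ln2/5.5 | type IV regimes, beyond WT |

`synthesis_rate = 100` and `pulse_duration = 0.5 h` throughout. The heavy
labeling fraction at pulse end from steady state is `1 − exp(−a·τ)` with
`a = k_mat+k_deg_b`, which reproduces the ~30%/~50% WT/F508del regimes.

## Synthetic transition tables

The generator emits one row per fragment ion with full experimental
coordinates (experiment, sample, treatment, chase time, band, isotopolog,
peptide, fragment, replicate). Eight proteotypic CFTR peptides carry fixed
ground-truth relative response factors (0.25–3.0, reference AVQPLLLGR = 1);
each peptide contributes a deterministic 4–6 fragments (3–5 in the
footprint design) whose expected intensities sum to pool abundance ×
response factor. Noise is multiplicative lognormal per fragment,
independent across fragments, mean-preserving, with configurable CV
(default 0.10) — the standard dispersion model for MS intensities. No
sample-level scale noise, no missingness, no retention-time or peak-shape
effects, and no interference between isotopologs are simulated; passing
tests therefore demonstrate estimator correctness under calibrated
multiplicative noise, not robustness to chromatographic artifacts or
peptide dropout. Optional QC rows emulate the band-comigration peptides
(CLTC/SMC4 in the C region, MED23/LRPPRC in the B region) with a
configurable bleed fraction into the wrong band.

On the reference-peptide spelling: the assay's peptide list contains
AVQPLLLGR while the response-factor protocol text spells it AVQPLLGR (one
L fewer). The package treats AVQPLLLGR as canonical — it is the form in
the peptide list and in the CFTR sequence — but the reference is a plain
parameter everywhere, so either spelling can be configured.

## Quantification chain

1. **Fragment summing** — intensities are summed per (experiment, sample,
   treatment, time, band, isotopolog, peptide, replicate); fragment counts
   outside the configured bounds (default 3–6) are logged, not dropped.
2. **Response-factor calibration** — per experiment, on the light
   isotopolog of the wild-type samples, each peptide's intensity ratio to
   the reference peptide is averaged across samples (arithmetic mean of
   per-sample ratios). The reference must be present and nonzero wherever
   another peptide is quantified; violations name the sample.
3. **Band roll-up** — the mean (not sum) of calibrated peptide values per
   band/isotopolog/sample. After calibration every peptide estimates the
   same protein abundance, and the mean is robust to peptide dropout; the
   two policies differ only by a constant factor, which cancels in the
   next step. Missing peptides are omitted, never imputed.
4. **Pulse-max normalization** — every value of a (treatment, replicate)
   series is divided by that series' heavy-B abundance at the anchor time
   (default 0 h). The anchor is per replicate series, so normalized time
   courses are invariant to rescaling all samples of one series by a
   common constant (per-series scale invariance); scaling a single
   destructively-sampled well necessarily moves its own point.

## Kinetic estimators

* **Folding efficiency** = normalized heavy-C value at the efficiency time
  (default 2.5 h), computed per replicate and averaged (mean ± SEM). On
  noiseless model data this equals `C_h(2.5+τ)/B_h(τ)`, which approaches
  the branching fraction φ only in the short-pulse limit
  (`a·τ ≪ 1`) with a chase long enough to drain the labeled cohort; with
  a pulse long relative to B turnover the ratio exceeds φ by the factor
  `a·τ/(1−e^{−a·τ})` because part of the cohort exits B during the pulse.
  The estimator is therefore reported as what it is — a conversion ratio
  under the protocol — and validated against noiseless runs of the same
  protocol, not against φ directly.
* **Half-life**: OLS of ln(value) against chase time over all replicate
  points above the signal floor (default 5% of the series maximum, which
  excises noise-dominated tail points); `t_1/2 = ln2/|slope|` for negative
  slopes, a non-decaying flag otherwise. The log base is immaterial to
  `t_1/2`; the natural log is used. At least 3 usable timepoints are
  required.
* **Labeling fraction** = heavy/(heavy+light) of the B pool at pulse end,
  per replicate then averaged.
* **Wash-out check** = ratio of new heavy-C formation (rise of the
  replicate-mean pool between the first and last common chase timepoints)
  in washed versus unwashed conditions; below 0.25 (configurable) the
  wash-out is considered confirmed, near-zero unwashed formation is "not
  evaluable". The generator models wash-out as a parameter switch at chase
  start (corrected kinetics during pre-labeling, uncorrected during the
  chase), superposing the exact decay of the pre-existing pools.

## Footprint statistics

Peptide values are normalized twice: by the summed protein signal of the
sample, then by the peptide's mean normalized value across all its
observations (grand mean; with the balanced designs the generator emits
this equals the mean of per-condition means, and it makes every peptide's
normalized grand mean exactly 1). Technical replicates are averaged within
experiment before testing, so the t-test's unit of evidence is the
independent experiment (default 4 per group).

The loss-of-signal test is a one-sided two-sample t-test. The
pooled-variance (Student) form is the default: at n = 4 per group the
Welch–Satterthwaite approximation is measurably conservative (simulated
type-I rate ≈ 0.044 at nominal 0.05), whereas the pooled test is exact
under the generator's homoscedastic groups (≈ 0.050 simulated); Welch
remains available (`equal_var=False`) for heteroscedastic real data.
Zero-variance degenerate cases follow a fixed rule: equal means → p = 1;
test mean below control with both variances zero → p = 0.

Benjamini–Hochberg adjustment is applied within each comparison's family
of testable peptides (family size taken from the data, ~80); separate
comparisons are separate families. Flags are `p_adj < α` (default 0.05).

**Localization.** Tryptic digestion cleaves after K/R, optionally
suppressed before proline; the default "both" mode is the union of the
rule-on and rule-off universes, since DIA data can contain both the
proline-spanning and the cleaved form of the same region (e.g. LFFSWTRPILR
and LFFSWTR). Coordinates are 1-based inclusive. Overlapping flagged spans
are intersected and the window is extended upstream to the immediately
preceding cleavage residue — a modification on that K/R would equally
abolish the observed peptides. Disjoint flagged groups yield separate
sites; chained overlaps without a common core fall back to the union span
with an explanatory note.

## Screening

z′ uses sample (n−1) standard deviations. Percent activity is an affine
rescaling between the plate's negative-control mean (0%) and the reference
corrector's maximal effect (100%); hit calling uses a strict `>` cutoff
(default 13%), and the hit rate is reported to two decimals with full
precision retained internally. The 4PL fit is parameterized in log10
concentration with the EC50 bounded to the tested range × [0.01, 100],
Hill slope in [0.05, 20]; flat or non-convergent responses are flagged,
never raised. Plate simulation draws control wells from the stated normal
distributions and gives ~0.15% of compounds a uniform 15–80% activity,
emulating a primary-screen hit rate of roughly one per thousand.

## Problem sizes and reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical (configuration, seed) pairs
reproduce every table byte for byte. The test suite validates the
simulator against an independent ODE integrator on 100 random parameter
draws, the discrete operations against literal brute-force oracles on
200+ random instances each, and the footprint stage's calibration and
power on 100 seeds of the 80-peptide × 4-experiment design (two-condition
reduction for the single probe-versus-parent comparison). These sizes keep
the full suite under a minute on a laptop core while leaving the binomial
and power margins comfortably wide.

## Known limitations

* The generator starts at transition-level intensities; nothing upstream
  (spectra, chromatograms, identification) is modeled, and no missingness
  or batch structure is simulated.
* The folding-efficiency ratio is protocol-bound (see above); comparing
  efficiencies across protocols with different pulse lengths requires the
  short-pulse correction factor.
* The kinetic stage estimates ratios and regression slopes only; full ODE
  parameter fitting of (k_mat, k_deg_b, k_deg_c) is intentionally out of
  scope — the simulator's ground truth serves for validation instead.
* Localization reports the tryptic window, not the modified atom or
  residue within it; resolving a pose requires orthogonal structural
  evidence.
* The bundled CFTR N-terminal constant covers the first 60 residues
  (lasso domain context) for digestion and localization demonstrations;
  full-protein analyses should supply a FASTA.
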