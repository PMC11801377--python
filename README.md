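# foldtrace

Quantitative analysis pipelines for CFTR corrector pharmacology: SILAC
pulse-chase estimation of ER folding efficiency and post-folding half-life,
photo-crosslink peptide footprinting for binding-site localization, and
high-throughput-screening quality control with hit calling. Every stage can
be exercised end to end on a seeded synthetic-data generator with known
ground truth, so the estimators are testable without access to instrument
data.

The package is aimed at proteomics and screening scientists who work with
transition-level (fragment-ion) quantification tables exported from tools
such as Skyline or Spectronaut, and who need reproducible, scripted versions
of the bespoke calculations these assays require.

## The models and estimators

**Biogenesis kinetics.** The immature ER form of CFTR (SDS-PAGE B band) is
synthesized at constant rate *s* and either matures into the
complex-glycosylated form (C band) or is degraded:

    dB/dt = s(t) − (k_mat + k_degB)·B
    dC/dt = k_mat·B − k_degC·C

A pulse of heavy amino acids splits synthesis between heavy and light
isotopologs, giving four pools with shared rates. The system is linear with
piecewise-constant input and is solved exactly (matrix exponential). The ER
**folding efficiency** φ = k_mat/(k_mat + k_degB) is estimated as the heavy
C-band signal after a 2.5-h chase divided by the heavy B-band signal
directly after the pulse, per replicate, after fragment summing,
response-factor calibration against a reference peptide (AVQPLLLGR by
default) and normalization to the post-pulse heavy-B maximum. The
**post-folding half-life** is ln 2/|slope| from ordinary least squares of
log abundance versus chase time.

**Footprinting.** A photo-activatable probe covalently captured on the
protein under UV abolishes the unmodified form of every tryptic peptide
overlapping the attachment site. Peptide signals are doubly normalized (to
the per-sample protein total, then to the peptide's average across
conditions), tested one-sidedly for loss of signal against no-UV and parent
compound controls, Benjamini–Hochberg corrected per comparison, and flagged
peptide spans are intersected and extended upstream to the preceding
tryptic cleavage residue to obtain the crosslink window.

**Screening.** Plate quality is summarized by
z′ = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋|; compound signals become percent activity of
a reference corrector's maximal effect; hits are compounds strictly above
the activity cutoff; 4-parameter-logistic fits extract EC50/Emax from
concentration–response curves.

## Worked example

```python
import foldtrace as ft
from foldtrace.footprint import FootprintModel
from foldtrace.proteolysis import CFTR_NTERM, digest

design = ft.PulseChaseDesign(
    treatments={
        "WT": ft.kinetic_preset("WT"),
        "F508del": ft.kinetic_preset("F508del"),
        "F508del+IDOR-3": ft.kinetic_preset("F508del+IDOR-3"),
    },
    n_replicates=3,
)
records, truth = ft.simulate_pulse_chase_dataset(design, noise_cv=0.10, seed=1)
print(ft.PulseChaseModel.from_records(records).fit().summary())
```

```
Pulse-chase folding efficiency (heavy C at 2.5 h / heavy B at pulse end)
treatment               efficiency       SEM   n
F508del                     0.0053    0.0000   3
F508del+IDOR-3              0.2539    0.0050   3
WT                          0.1809    0.0025   3

B-pool heavy labeling fraction at pulse end
F508del                     0.5025             3
F508del+IDOR-3              0.4978             3
WT                          0.3010             3
```

The 30-min pulse labels ~30% of the wild-type immature pool but ~50% of the
faster-turning-over F508del pool; ~18% of the labeled WT cohort matures
within 2.5 h, almost none of uncorrected F508del, and ~25% of F508del under
a type IV corrector preset — the corrector restores folding efficiency
beyond the wild-type level.

```python
fp_design = ft.FootprintDesign(depletion=ft.LASSO_DEPLETION)
fp_records, _ = ft.simulate_footprint_dataset(fp_design, seed=1)
fp = FootprintModel(fp_records).fit(alpha=0.05)
print(fp.summary())
for site in fp.localize(digest(CFTR_NTERM, proline_rule="both"),
                        "IDOR-6A+UV vs IDOR-6+UV"):
    print(f"window {site.start}-{site.end} supported by {', '.join(site.peptides)}")
```

```
Footprint depletion test: 640 testable peptide x comparison pairs, 4 flagged at alpha=0.05
  LFFSWTR              IDOR-6A+UV vs IDOR-6A            ratio=0.503 p_adj=4.52e-05
  LFFSWTRPILR          IDOR-6A+UV vs IDOR-6A            ratio=0.503 p_adj=7.92e-07
  LFFSWTR              IDOR-6A+UV vs IDOR-6+UV          ratio=0.505 p_adj=3.99e-07
  LFFSWTRPILR          IDOR-6A+UV vs IDOR-6+UV          ratio=0.501 p_adj=1.58e-07
window 14-21 supported by LFFSWTR, LFFSWTRPILR
```

Of 80 quantified peptides only the two overlapping N-terminal peptides lose
signal under the photoactive probe with UV; intersecting their spans
(15–21, 15–25) and extending upstream to the tryptic lysine K14 localizes
the crosslink to residues 14–21 in lasso helix 1.

## Command line

```
foldtrace simulate pulse-chase --config run.yaml --seed 1 --out pc.tsv
foldtrace quantify --in pc.tsv --out tc.tsv
foldtrace kinetics efficiency --in tc.tsv
foldtrace kinetics halflife --in tc.tsv --pool C --isotopolog light
foldtrace footprint test --in fp.tsv --alpha 0.05 --out res.tsv
foldtrace footprint localize --results res.tsv --fasta cftr_nterm.fa
foldtrace screen qc --in plate.tsv
foldtrace screen hits --in plate.tsv --cutoff 13 --n-screened 67772
foldtrace run --config run.yaml --out-dir out/
foldtrace validate-config run.yaml
```

`foldtrace run` executes configured stages end to end and writes a
`manifest.json` echoing the resolved configuration and seed; identical
config and seed reproduce output tables byte for byte.

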