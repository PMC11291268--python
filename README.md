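# gnao1kit

Quantitative analysis toolkit for GNAO1 encephalopathy variants: kinetic
fitting of fluorescent-nucleotide binding/hydrolysis curves, the GDP/GTP
cycling model of Gαo, onset-based clinical scoring, and the
genotype–phenotype rank-correlation machinery used to screen candidate
severity biomarkers.

Missense mutations in *GNAO1*, encoding the major neuronal G-protein α
subunit Gαo, cause two related disorders: DEE17 (developmental and
epileptic encephalopathy, early onset) and NEDIM (a milder movement
disorder, late onset).  Characterising a variant biochemically means
estimating two rate constants from BODIPY fluorescence time courses —
`k_bind` (GTP uptake) and `k_hydr` (hydrolysis) — and translating them
into an equilibrium nucleotide state via the two-state cycle

    d[Gαo·GDP]/dt = k_hydr[Gαo·GTP] − k_bind[Gαo·GDP]
    d[Gαo·GTP]/dt = k_bind[Gαo·GDP] − k_hydr[Gαo·GTP]

whose steady-state ratio is `[Gαo·GTP]/[Gαo·GDP] = k_bind/k_hydr`.
Clinically, disease onset (in postnatal days, binned into very-early /
early / late / very-late classes) serves as the severity score, and
molecular phenotypes (expression, membrane localization, Gβγ/RGS19/
Ric8A/Ric8B interactions, ΔBRET) are ranked as biomarkers by the absolute
Spearman rank correlation `|r_s|` against onset — with exact small-sample
p-values, because these cohorts have 5–17 variants.

The package ships a synthetic-data module that generates every input with
known ground truth (traces, patient cohorts with configurable group
medians, phenotype tables with controllable association structure), so the
entire pipeline is testable end to end.  See `docs/methods.md` for models,
assumptions and limitations.

## Worked example

Run the demo pipeline (synthetic traces for WT, L199P, C215Y, Y231C and
the GTPase-dead control Q205L; a 60-patient synthetic cohort; a phenotype
table):

```sh
gnao1kit pipeline --seed 1 --out-dir demo_out
```

or equivalently from Python:

```python
from gnao1kit.config import load_config
from gnao1kit.pipeline import run_pipeline

artifacts = run_pipeline(load_config(), "demo_out", seed=1)
print(artifacts["report"])
```

which prints (abridged):

```
Group onset medians (days):
  by_disorder  DEE17      n=   29 median=40.0
  by_disorder  NEDIM      n=   31 median=555.0
  by_activity  inactive   n=   13 median=32.0
  DEE17 vs NEDIM onset: Mann-Whitney U=0.0 p=3.09e-11 (normal_approximation)

Steady-state GTP/GDP ratios (from fitted constants):
  C215Y    ratio=1.25 (2.06-fold decrease vs WT)
  L199P    ratio=24.9 (9.67-fold increase vs WT)
  Q205L    ratio=562 (218-fold increase vs WT)
  WT       ratio=2.58 (1-fold none vs WT)
  Y231C    ratio=35.9 (13.9-fold increase vs WT)

Biomarker ranking (|Spearman r_s| vs onset, descending):
  expression           r_s=+0.991 p=1.72e-15 (t_approximation)
  gbg_coip             r_s=+0.977 p=3.97e-12 (t_approximation)
  ric8b_coip           r_s=-0.961 p=2.25e-10 (t_approximation)
  ...
```

Reading this: the synthetic cohort reproduces the expected severity split
(DEE17 onsets cluster around ~6 weeks, NEDIM around ~1.5 years, and the
biochemically inactive variants are among the earliest); the rate
constants fitted back from noisy traces recover the configured variant
biochemistry (the wild-type ratio ≈ 2.56, L199P's ~9.7-fold GTP/GDP
increase, C215Y's ~2-fold decrease, Q205L's ~200-fold hydrolysis loss);
and the biomarker ranking recovers the association structure built into
the synthetic phenotype table, with strongly associated metrics at the
top and the unassociated ones (rgs19_coip, ric8a_coip, delta_bret) at the
bottom with non-significant p-values.

Each stage is also exposed individually (`gnao1kit simulate | fit |
cycle | classify | correlate | report`), reading and writing plain CSV
with provenance headers, so measured data in the same schemas can be
substituted for any synthetic input.

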