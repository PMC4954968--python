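# renofib

Noninvasive assessment of renal interstitial fibrosis (IF) from quantitative
MRI, with histological validation. The package implements the full analysis
chain used to evaluate the cortico-medullary ΔADC index in kidney allograft
recipients:

1. **Parametric mapping** — pixel-wise apparent diffusion coefficient (ADC)
   maps from multi-b-value DWI via the mono-exponential model
   `S(b) = S0·exp(−b·ADC)`, and T1 maps from inversion-recovery (MOLLI-style)
   magnitude data via the 3-parameter model `|S(TI)| = |A − B·exp(−TI/T1*)|`
   with polarity restoration and the Look-Locker correction
   `T1 = T1*·(B/A − 1)`.
2. **ROI indices** — cortical and medullary means pooled over multiple
   manually-placed ROIs, and the indices
   `ΔADC = ⟨ADC_cortex⟩ − ⟨ADC_medulla⟩` (×10⁻⁶ mm²/s) and
   `ΔT1 = ⟨T1_cortex⟩ − ⟨T1_medulla⟩` (ms). In fibrotic allografts ΔADC
   turns negative.
3. **Histology** — automated Sirius-red percent-area quantification:
   optical-density colour deconvolution, channel thresholds (human preset
   0.15 hematoxylin / 0.11 red; rat preset 0.07 / 0.45), and a 10 µm²
   minimum component area at 0.232 µm/pixel calibration.
4. **Cohort statistics** — Pearson correlations, Fisher-z comparison of two
   correlations, exact/approximate Wilcoxon rank-sum, ICC(1,1) inter-reader
   agreement, one-way ANOVA with Bonferroni post-hoc.
5. **Classification** — a sweep of IF cut-offs (10–70% step 10) selecting
   the most significant High-IF/Low-IF ΔADC split, a 1-D Gaussian linear
   discriminant giving resubstitution sensitivity/specificity, and a
   1000-replicate bootstrap of the accuracy with a percentile 95% CI.
6. **Synthetic data** — seeded generators for every input: two-compartment
   kidney phantoms with Rician noise, stained sections with known collagen
   fraction, and cohorts whose ΔADC–IF link crosses zero at 40% IF.

It is aimed at researchers developing quantitative-MRI biomarkers of kidney
fibrosis who need a tested, reproducible reference implementation of this
analysis — no clinical data ship with the package; everything runs on the
synthetic generators or on the user's own NIfTI/TIFF/CSV inputs.

## Worked example

```python
import renofib as rf

# noiseless two-compartment phantom: cortex ADC 1800, medulla 2000
spec = rf.PhantomSpec(rician_sigma=0.0)
series, labels, truth = rf.gen_dwi_phantom(spec)
adc_map, s0_map = rf.fit_adc_map(series, labels > 0, method="nonlinear")

rois = rf.gen_roi_set(labels, rng=0)
cortex = rf.summarize_compartment(adc_map, rois, "cortex")
medulla = rf.summarize_compartment(adc_map, rois, "medulla")
delta = rf.delta_index(cortex, medulla)
print(f"ΔADC = {delta.delta:.1f} {delta.units}")
# ΔADC = -200.0 1e-6 mm^2/s        (cortex < medulla: the healthy pattern)

cohort = rf.gen_cohort(rf.CohortSpec(seed=5))
sweep = rf.threshold_sweep(cohort["if_masson_pct"], cohort["delta_adc"])
high = cohort["if_masson_pct"].to_numpy() > sweep.selected_threshold
lda = rf.lda_fit_evaluate(cohort["delta_adc"], high)
boot = rf.bootstrap_accuracy(cohort["delta_adc"], high, n_boot=1000, seed=5)
print(f"threshold {sweep.selected_threshold:.0f}% IF, "
      f"sensitivity {lda.sensitivity:.0f}%, specificity {lda.specificity:.0f}%, "
      f"accuracy {boot.accuracy_mean:.2f} CI {boot.ci95}")
# threshold 20% IF, sensitivity 100%, specificity 100%, accuracy 0.97 CI (0.896551724137931, 1.0)
```

On this particular 29-subject draw the sweep finds its minimum p at 20% IF —
with n = 29 the selected cut-off fluctuates around the planted 40%
zero-crossing from seed to seed; the recovery-rate check in
`scripts/acceptance.py` quantifies how often 40% is recovered when the
separation is planted cleanly.

The selected threshold is the IF cut-off whose High/Low split of ΔADC is
most significant under the rank-sum test; sensitivity/specificity are
resubstitution recalls of the discriminant on the High-IF and Low-IF classes,
and the bootstrap CI is the 2.5–97.5 percentile interval of the refitted
accuracy over resampled cohorts.

The same pipeline is scriptable from the shell:

```sh
renofib simulate --seed 3 --out sim/           # NIfTI/TIFF/CSV bundle
renofib fit-adc sim/dwi.nii.gz --out adc.nii.gz
renofib classify --cohort sim/cohort.csv --seed 3
renofib run-all --seed 3 --out report/
```

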