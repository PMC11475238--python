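# fidmrsi

Quantification and inter-subject stability analysis for 7 T FID-MRSI of the
human brain, as a tested, reusable Python pipeline.

Whole-brain free-induction-decay MR spectroscopic imaging (FID-MRSI) at 7 T
yields a short-TR spectrum in every ~3.4 mm voxel, from which maps of brain
metabolites — N-acetylaspartate (NAA), total creatine (tCr), total choline
(tCho), glutamate (Glu), myo-inositol (mIns) — can be derived. Turning fitted
signal amplitudes into molar concentrations, and knowing how stable those
estimates are across subjects and brain regions, is the hard part. This
package implements that analysis end to end for researchers working on MRSI
methodology:

* a **synthetic phantom cohort** with known ground truth (smooth GM/WM/CSF
  tissue fractions, log-normal inter-subject concentration variability,
  Lorentzian metabolite resonances with the first-order phase of a 1.3 ms
  acquisition delay, macromolecular background, scalp lipid bleed, complex
  Gaussian noise, and the two acquisition parameter sets of the protocol:
  metabolite scan TR 450 ms / 39° / 2778 Hz / 345 ms, water reference
  TR 200 ms / 27° / 606 Hz / 158 ms);
* **L2-regularized lipid removal**, `x̂ = (I + β·L·Lᴴ)⁻¹·s`, with the lipid
  basis `L` taken from scalp-voxel spectra and β chosen by bisection;
* a **linear-combination spectral fitter** (non-negative amplitudes with
  global frequency-shift/damping/phase nuisances, solved by variable
  projection with an analytic Golub–Pereyra Jacobian) over the evaluation
  ranges 0.2–1.2 and 1.8–3.88 ppm, with per-metabolite Cramér–Rao lower
  bounds, tCr SNR and linewidth maps;
* **water-referenced quantification** with partial-volume and T1 saturation
  correction:

  `C_m = (A_m / A_w) · W(f) · E_w,eff / E_m,eff / (1 − f_CSF)`

  where `W(f) = f_GM·36.1 + f_WM·43.3 + f_CSF·53.8 mol/L` is the voxel water
  content and `E = sinθ·(1−E1)/(1−cosθ·E1)`, `E1 = exp(−TR/T1)`, are Ernst
  saturation factors per compartment;
* the **spectral quality mask** (tCr SNR ≥ 5, tCr FWHM ≤ 0.15 ppm, CRLB ≤
  40 %, fit value within 13 raw median absolute deviations) and the
  **ROI machinery**: joint-CRLB pass fractions, good/acceptable/rejected
  classification, metabolite qualification, ratios to tCr, and inter-subject
  coefficients of variation (CV = 100·SD/mean over per-subject ROI means).

## Worked example

```python
from fidmrsi.phantom import ROISpec
from fidmrsi.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    grid_shape=(16, 16, 8), n_subjects=4, inter_subject_cv=10.0,
    noise_sd=0.9, seed=42,
    roi_spec=[ROISpec("deep-WM", 0.30, 0.60, tissue="WM"),
              ROISpec("cortical-GM", 0.72, 0.90, tissue="GM")],
)
report = run_pipeline(cfg)
print(report.roi_classification)
print(report.cv_table[["NAA", "tCr", "tCho", "Glu", "mIns"]].round(1))
```

prints

```
{'deep-WM': 'good', 'cortical-GM': 'good'}
              NAA   tCr  tCho  Glu  mIns
deep-WM      12.3  10.9  13.7  8.0  10.0
cortical-GM  12.2  10.9  13.8  7.9  10.0
Mean         12.3  10.9  13.8  8.0  10.0
Min          12.2  10.9  13.7  7.9  10.0
Max          12.3  10.9  13.8  8.0  10.0
```

Both phantom ROIs classify as "good" (more than 80 % of voxels fit all of
NAA/tCr/tCho/mIns with CRLB < 40 %), and the estimated inter-subject CVs
scatter around the 10 % the cohort was generated with — the per-metabolite
spread (8–14 %) is the sampling error of a 4-subject draw, which shrinks
toward the true value at realistic cohort sizes (the n = 20 recovery study
in the acceptance suite lands within [7, 13] %). Per-subject ROI means in mM
are in `report.roi_subject_means`; for subject 0, deep WM gives NAA 10.45,
tCr 6.38, tCho 1.85, Glu 7.94, mIns 5.19 mM — inside the per-region ranges
reported for this kind of acquisition.

The same stages are exposed on the command line:

```bash
fidmrsi simulate-cohort --subjects 4 --seed 42 --grid 16 16 8 --out sim/
fidmrsi fit --input sim/subject_00.h5 --basis sim/basis.h5 --out fits0/
fidmrsi quantify --input sim/subject_00.h5 --fits fits0/fits.h5 --maps sim/maps --out quant0/
fidmrsi cohort-stats --quant quant0/ --quant quant1/ --roi-labels sim/maps/roi_labels.nii --out stats/
fidmrsi run-all --subjects 4 --seed 42 --out report/
fidmrsi reproduce-tables --out tables/
```

`reproduce-tables` recomputes the summary rows of the published per-ROI
cohort tables from the transcribed per-ROI columns shipped with the package
(clearly labeled as transcriptions under `fidmrsi/data/`); it prints

```
44 retained ROIs; qualified metabolites: tCho, tCr, Glu, mIns, NAA
```

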