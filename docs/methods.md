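# Methods

This note documents the models, parameter choices and numerical decisions
behind `fidmrsi`, in the spirit of a methods appendix: what is simulated,
how it is fitted and quantified, which defaults matter, and what the
synthetic studies do and do not demonstrate.

## Signal model and basis simulation

Every compound is a sum of Lorentzian resonances. A resonance at chemical
shift δ (ppm), proton weighting a, and effective transverse decay T2*
contributes

    s(t) = a · exp(i·2π·f·(t + τ)) · exp(−(t + τ)/T2*),
    f = (δ − δ_carrier) · f0,

sampled at t = n/BW for n = 0…N−1, with carrier δ_carrier = 4.7 ppm (water),
reference frequency f0 = 297.2 MHz (proton at 7 T) and acquisition delay
τ = 1.3 ms. The delay is applied inside the model — the first stored sample
sits at t = τ — which produces the characteristic first-order phase
2π·f·τ that the fitter's basis shares with the data. Sample counts follow
N = round(BW × readout): 958 points for the metabolite scan (2778 Hz,
345 ms), 96 for the water reference (606 Hz, 158 ms).

The resonance table is a singlet/simple-multiplet approximation (positions
from standard proton shift compilations; metabolite T2* 90 ms). No
J-coupling evolution or density-matrix simulation is attempted: the basis
exists to make generator and fitter share an exactly known line model, not
to reproduce coupled spin systems. The macromolecular background is eight
broad Lorentzians between 0.9 and 3.9 ppm with T2* = 10 ms, co-fitted as a
single "MM" compound; scalp lipid is a four-line profile dominated by the
1.2–1.8 ppm band with T2* = 25 ms.

Spectra are orthonormal DFTs (1/√N), so energy and — importantly — the
per-component noise SD carry over unchanged from time to frequency domain.

## Phantom cohort

The head is an ellipsoid parameterized by a normalized radius ρ: ventricular
CSF core (ρ < 0.25, with the innermost part hard-set to pure CSF), WM shell,
cortical GM shell, a thin CSF rim, and a detached scalp ring (1.10 ≤ ρ ≤
1.30) that carries lipid. Indicator maps are Gaussian-smoothed (σ = 0.7
voxels) and renormalized so f_GM + f_WM + f_CSF = 1 inside the brain.
Default grid 32×32×16 at 3.4 mm nominal voxel size; tests and validation
studies use 16×16×8, since every threshold in the pipeline is
resolution-independent and the smaller grid keeps a full cohort study in
minutes on one CPU.

Ground-truth tissue concentrations default to (GM, WM) pairs in mM of
NAA (10.0, 9.6), tCr (7.8, 7.0), tCho (1.7, 2.1), Glu (8.8, 7.0),
mIns (5.5, 5.0) — chosen to sit inside the per-ROI ranges reported for this
kind of acquisition, with a GM > WM glutamate contrast; they are documented
approximations, since per-tissue contrasts are not published per metabolite.
Inter-subject variability is log-normal and mean-preserving with a
configurable CV (default 10 %). One multiplier per (subject, metabolite) is
applied to both tissue means; fully correlated GM/WM variation keeps the
true ROI-level CV equal to the nominal CV regardless of an ROI's tissue mix
(independent draws would dilute it in mixed ROIs). Draws are independent
across metabolites. CSF carries water but no metabolites.

Voxel amplitudes follow the forward model

    A_m(v) = Σ_t f_t(v) · C_t,m · E(θ_met, TR_met, T1_m,t),      t ∈ {GM, WM}
    A_w(v) = Σ_c f_c(v) · W_c · E(θ_w, TR_w, T1_w,c) · 1000,     c ∈ {GM, WM, CSF}

with W = (36.1, 43.3, 53.8) mol/L and the T1 table below. Scalp lipid is an
amplitude map on the scalp ring convolved with a 5-tap Hamming kernel, so it
bleeds into peripheral brain voxels the way ringing does in practice without
simulating k-space. Complex Gaussian noise of equal SD per component is
added to both scans; the default SD of 0.9 puts the tCr SNR of a GM voxel
near 11, the cohort-median spectral quality this pipeline is designed
around. "Motion" subjects get all lines collapsed to an effective T2* of
5 ms plus a ±10 Hz in-plane frequency ramp; their linewidths then exceed the
0.15 ppm mask threshold and the subject drops out of cohort statistics, as
a motion-corrupted dataset should.

Water T1 in CSF defaults to 4300 ms; the literature table used for the
other values reports none for CSF, and the water compartment model needs a
long-T1 entry. It is configurable like every other table value.

## Lipid removal

Cleaning applies `(I + β·L·Lᴴ)⁻¹` per voxel in the frequency domain, where
L collects scalp-voxel spectra (optionally SVD-compressed; singular values
below 1e−8 of the largest are dropped as numerically null). The operator
shrinks the component along each left singular vector by 1/(1 + β·σ²) and
leaves the orthogonal complement untouched — it is linear, self-adjoint,
and contractive for β ≥ 0.

β is not a published constant. `auto_beta` bisects on log β until the
lipid-band (1.2–1.8 ppm) energy of brain voxels falls to 5 % of its
*removable* part: with E0 the band energy before cleaning and E_floor the
energy after complete suppression of the lipid subspace, the target is
E_floor + 0.05·(E0 − E_floor). The floor term matters because genuine MM
and metabolite signal in that band is orthogonal to the lipid subspace and
no β can remove it; a target expressed on the raw band energy would be
unattainable and push β to infinity.

## Spectral fitting

Each voxel spectrum is modeled as a non-negative linear combination of
basis spectra under three global nuisance parameters: frequency shift
(|Δf| ≤ 20 Hz), extra Lorentzian damping (0 ≤ γ ≤ 500 s⁻¹), and zero-order
phase (|φ| ≤ π). Only points inside the evaluation ranges 0.2–1.2 and
1.8–3.88 ppm enter the objective (closed intervals; the 1.2–1.8 ppm lipid
band is excluded, and the upper bound reflects water-suppression effects).
There is no spline baseline: the MM compound plus the lipid-removal stage
absorb the background.

The solver is separable least squares: for a candidate (Δf, γ, φ) the
amplitudes come from NNLS on the real-stacked masked points (the phase is
applied to the data rather than the model, keeping the design matrix
real-stackable); the nuisance parameters are optimized by a bounded
trust-region method with an analytic variable-projection (Golub–Pereyra)
Jacobian, multi-started over shift initializations (0, −5, +5 Hz) with
early exit once the residual reaches the noise floor, ties broken by lowest
residual then smallest |Δf|. A fixed four-step damped Gauss–Newton polish
(active bounds frozen, near-zero damping snapped to the bound) then pins the
stationary point to machine precision. The polish is what makes the fit a
smooth deterministic function of the data: receiver-gain changes propagate
through the whole pipeline at the 1e−15 relative level, and the spectrum is
norm-normalized before fitting for the same reason. A spectrum that is
exactly zero on the evaluation ranges (e.g. a pure-CSF voxel in a noiseless
phantom) returns a flagged `no-signal` result instead of an error.

Uncertainty: CRLB%_m = 100·sqrt([F⁻¹]_mm)/A_m with F = Re(Jᴴ·J)/σ² over all
parameters (active amplitudes + shift + damping + phase) at the optimum;
zero-amplitude compounds are excluded from F and reported as ∞. The
Monte-Carlo calibration study (200 noise replicates) shows SD/CRLB ratios
of 0.88–1.06 for the five main metabolites.

SNR is the phased-real peak height of the fitted tCr 3.02 ppm component
divided by the spectral noise SD; the noise SD comes from the known
generator value in synthetic mode, from the signal-free high-ppm end of the
axis (the usable part of the 9–10 ppm window) otherwise, or from the
pseudo-replica route (noise level measured on first differences of the FID
tail, propagated through the same FID→spectrum transform over 100 synthetic
replicas) — the two estimators agree within 10 % on fixtures. FWHM in ppm
is (1/T2*_basis + γ)/π/f0, i.e. the basis linewidth of the tCr reference
line plus the fitted extra damping.

The water reference is fitted with the same machinery and a one-compound
basis over its full (narrow) axis; voxels whose peak magnitude stays within
the noise are flagged `no-signal` rather than passed downstream.

## Quantification and quality masking

    C_m = (A_m / A_w) · W(f)·1000 · E_w,eff / E_m,eff / (1 − f_CSF)   [mM]

with W(f) the voxel water content in mol/L, E_w,eff the water-content-
weighted mean of per-compartment water Ernst factors, and E_m,eff the
GM/WM-fraction-weighted metabolite Ernst factor. Metabolite signal is
normalized to tissue volume by 1/(1 − f_CSF) (CSF contributes water but no
metabolites); only the amplitude *ratio* enters, so the estimate is exactly
invariant to receiver gain. No T2 correction is applied — at a 1.3 ms
acquisition delay T2 weighting is negligible. The metabolite-scan flip
angle is taken as configured (39°), not recomputed from the T1 table: the
averaging that yields a 39° "average Ernst angle" is not reproducible from
the published T1 values (they imply ≈ 42° at TR 450 ms), so the protocol
value is treated as an input.

T1 table [ms], (GM, WM): Asp 1000/1000, tCho 1510/1320, tCr 1780/1740,
GABA 1100/1200, Glu 1610/1750, Gln 1540/1740, Gly 1400/1400, GSH 1140/1060,
mIns 1280/1190, NAA 1535/1545, NAAG 1210/940, Ser 1400/1400, Tau 2150/2090,
water 2000/1550 (+ 4300 CSF). Water contents: 36.1/43.3/53.8 mol/L.

The quality mask passes a voxel iff tCr SNR ≥ 5 AND tCr FWHM ≤ 0.15 ppm AND
the metabolite's CRLB ≤ 40 % AND the fit value lies within 13 median
absolute deviations of the in-domain median. The MAD is raw (unscaled, no
1.4826 factor) and computed per compound per subject over the fitted brain
voxels; both choices are configurable since neither population nor scaling
is published. A zero MAD with unequal values falls back to excluding any
value off the median beyond a relative tolerance, with a logged warning.
Per-rule exclusion counts are reported and verified against a brute-force
per-voxel recount in the tests.

A subject whose tCr pass fraction falls below 25 % of fitted voxels is
excluded from cohort statistics (the motion phenotype); the threshold is
configurable.

## ROI statistics

Pass fraction per ROI = percentage of voxels with CRLB < 40 % for all of
NAA, tCr, tCho and mIns; classification: good ≥ 80 %, acceptable ≥ 66 %,
rejected below. The published wording leaves a 60–66 % gap between
"acceptable" and "rejected"; the cut is resolved at 66 % (consistent with
the reported 18 + 26 = 44 retained regions) and both thresholds are
configurable. Metabolites are discarded when fit in < 10 % of brain voxels
and qualify when their mean pass percentage over all ROIs is strictly
above 66 %.

Ratios to tCr are computed per subject as (ROI mean of metabolite)/(ROI
mean of tCr), then averaged over subjects; whether the original analysis
averaged per voxel or per ROI first is not stated, and ratio-of-ROI-means
matches the reported thalamus ratio arithmetic. Inter-subject CV =
100 × sample SD / mean of per-subject ROI means (≥ 2 subjects). Report
tables round CVs to integers and concentrations to two decimals. The
transcribed per-ROI tables shipped under `fidmrsi/data/` feed the summary
machinery; their header comments mark them as transcriptions of published
cohort results, not outputs of this code.

## Validation studies and their scope

`fidmrsi.validation` (used by both `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs: noiseless end-to-end recovery (one 16×16×8
subject; worst voxel error ≈ 0.3 %, bounded by the GM/WM Ernst-weighting
approximation in E_m,eff, well under the 2 % criterion); CRLB calibration
(200 replicates); CV recovery (n = 20 subjects at 10 % true CV, two ROIs;
estimate within [7, 13] %); lipid-removal efficacy (fitted NAA within 5 %
of the lipid-free fit in the most contaminated voxel; measured ≈ 0.8 %);
receiver-gain invariance (≈ 1e−15); and quality-mask bookkeeping against a
brute-force oracle on a 32×32×16 fixture.

What passing these studies shows: the estimator chain is unbiased where its
model holds, its uncertainty reporting is calibrated, and the cohort
statistics recover designed-in variability. What it does not show: the
phantom has no B0/B1 inhomogeneity, no k-space trajectory or coil effects,
no baseline mismatch beyond the shared MM model, no J-coupled multiplet
structure, and its lipid contamination lives exactly in the subspace the
remover sees. Real-data performance therefore degrades in ways these tests
cannot measure; the published per-ROI cohort tables are the external
reference for that.

## Known limitations

* Singlet-level basis: coupled spin systems (Glu/Gln/mIns multiplet
  patterns) are approximated by a few Lorentzians.
* One global shift/damping/phase per voxel; no per-compound frequency or
  lineshape freedom, no spline baseline.
* The phantom's inter-subject variability is log-normal and independent
  across metabolites; real cohorts correlate metabolites within subject.
* Real-data mode expects maps already reconstructed to NIfTI; no raw-data
  (k-space, coil) processing is included.
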