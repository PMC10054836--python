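# Methods

## Barrier impedance model

The epithelial monolayer on a permeable Transwell insert is represented by
a lumped equivalent circuit: the culture-medium resistance R_media in
series with two parallel RC elements, one per membrane face of the
polarized layer,

    Z(ω) = R_media + R₁/(1 + jωτ₁) + R₂/(1 + jωτ₂),   τᵢ = RᵢCᵢ.

Assumptions: the layer is laterally homogeneous over the electrode area;
electrode polarization and the insert membrane are absorbed into R_media;
no constant-phase or diffusion (Warburg) elements — the model is exactly
this topology. All quantities are area-normalized (Ω·cm², µF/cm²); raw-ohm
instrument files are converted at ingest with the membrane area
(default 4.67 cm², the nominal growth area of a 6-well insert). Since
capacitances are stored in µF/cm², time constants carry an explicit 1e-6
factor.

Sign convention: capacitive impedances have negative imaginary part;
Nyquist export emits (Re Z, −Im Z), so model spectra plot in the upper
half-plane.

The two elements enter symmetrically, so their labels are a gauge freedom.
The package fixes the gauge by ordering τ₁ ≤ τ₂ in every constructor and
in fit output. Barrier summaries: TEER = R₁ + R₂ (the DC resistance of the
cell layer, equal to the Re-axis span of the spectrum) and the series cell
capacitance 1/C = 1/C₁ + 1/C₂, the physically consistent combination of
two membrane capacitances in series along the current path.

## CNLS fitting

`EpithelialImpedanceModel.fit()` minimizes

    Σ_k w_k² |Z_obs(f_k) − Z_model(f_k; θ)|²

jointly over real and imaginary parts with `scipy.optimize.least_squares`
(trust-region reflective). Numerical choices:

- **Weighting** (default `modulus`): each residual divided by |Z_obs|.
  A spectrum spans decades of magnitude; unweighted CNLS would let the
  low-frequency plateau dominate. `unit` and `proportional` (per-part)
  weighting are available.
- **Log-parameterization**: optimization over log θ enforces positivity
  and equalizes parameter scales; the analytic Jacobian is propagated by
  the chain rule, and `x_scale='jac'` conditions the trust region.
- **Tolerances**: xtol = ftol = gtol = 1e-10, at most 1000 function
  evaluations.
- **Convergence acceptance**: when the evaluation cap is hit but the
  weighted relative RMS residual is below 1e-5, the fit is accepted as
  numerically converged. This happens only in the near-degenerate regime
  τ₁ ≈ τ₂, where the split direction is flat and the step tolerance is
  unreachable although TEER and C_cell are already recovered to ~1e-6
  relative; with realistic measurement noise the residual sits orders of
  magnitude above the threshold, so genuine non-convergence still raises
  (carrying the best-so-far parameters).
- **Initial guess**: R_media ← |Z| at the top of the band; R₁+R₂ ← DC-end
  Re(Z) minus R_media, split evenly; time constants bracketed ×0.3/×3
  around the −Im(Z) apex (ωτ = 1). Falls back to fixed defaults, with a
  warning, for spectra that are too short (< 8 points), narrower than two
  decades, or non-monotone in Re(Z) beyond 5 % of their span.
- **Identifiability**: fitted τ₂/τ₁ < 3 sets `identifiable_split=False`;
  the symmetric model collapses to one RC at equality, leaving the split
  arbitrary while the sum (TEER) and series capacitance stay identifiable.
- **Standard errors** come from the linearized covariance (pseudo-inverse
  of JᵀJ scaled by χ²/dof), mapped back from log scale by the delta
  method. They describe the single-spectrum fit; spread across replicate
  inserts is a separate aggregation (`aggregate_replicates`, sample SD
  with n−1).

## SWASV trace model and peak extraction

The stripping physics (deposition, ionophore binding, diffusion) is out of
scope; a trace is modelled phenomenologically as a Gaussian oxidation peak
on a linear baseline. Scan protocols are carried in full (deposition
potential/time, scan limits, step, pulse amplitude, frequency, cleaning
step) with built-in presets — Cu: −1.0 V/30 s deposition, scan −0.2→+0.5 V
in 4 mV steps, 20 mV amplitude, 25 Hz (176-point grid); Zn: −1.2 V/30 s,
−1.0→−0.2 V in 8 mV steps, 50 mV, 50 Hz (101 points); cleaning +0.3 V/90 s.
Deposition and cleaning are metadata only.

Peak height is measured after subtracting a straight line fitted to the
outer 15 % of points at each scan end (the flanks), the simplest baseline
consistent with the observed trace shapes; whether reported peak currents
should be baseline-subtracted is a declared convention of this package. A
peak is accepted only if its corrected height exceeds 3× the robust flank
noise (scaled MAD of flank residuals) plus a 1e-9-relative floor that
keeps line-fit roundoff from registering on blank traces. Default search
windows: Cu [0.0, 0.2] V, Zn [−0.55, −0.35] V, around each ion's stripping
potential.

Consequences checked by the property tests: the height estimate is
invariant (to < 1 %) under adding any straight line of slope up to
1 µA/V, linear in peak amplitude to < 0.5 %, and locates the peak within
one potential step. On an 8 mV grid a peak centred between samples is
underestimated by up to ~0.2 % (cos-like sampling loss), which is why
trace-pipeline slope recovery is asserted at 1 %, not machine precision.

## Calibration and detection limit

Mean replicate peak current is regressed on log₁₀ of molar concentration
by OLS (decadic log matches the sensing convention for these calibration
plots). Replicates are averaged before the regression; per-point
SD/mean·100 gives the RSD, and the worst point is reported (`rsd_max`).
Degenerate inputs: fewer than 3 distinct concentrations is an error; all
currents equal yields slope 0 and r reported as 0 with a warning.
Inversion 10^((i−b)/m) flags, rather than refuses, estimates outside the
calibrated range (default 10⁻¹¹–10⁻⁶ M).

LOD = 3σ_blank/m is computed literally. With m in A per decade the
quotient is dimensionally a decade count, yet the sensing literature
quotes the result on the molar scale; the result records this ambiguity
(`lod_note`) instead of resolving it, and no blank σ ships with the
package — it is an input.

## Synthetic data generator

Generators are pure functions of (arguments, seed) — bit-identical reruns
— and their defaults are the study conditions the analysis targets:

- **Barrier presets**: pre-disruption (R_media 20, R₁ 300, C₁ 2.4, R₂ 446,
  C₂ 7.2), post-EGTA (R₁ 116, R₂ 172, same capacitances), chosen so the
  sums give TEER 746 → 288 Ω·cm² and C_cell 1.8 µF/cm² while keeping
  τ₂/τ₁ ≈ 3–4.5 (both semicircle features resolvable, split identifiable).
  Only the sums are observationally anchored; the split itself is a
  synthetic choice. Corner frequencies (~221 Hz and ~50 Hz) lie inside the
  10 Hz–100 kHz band.
- **Frequency grid**: 50 log-spaced points over 10 Hz–100 kHz.
- **Noise**: proportional Gaussian (CV 0.02 default) applied independently
  to Re and Im of spectra, or per-sample to traces; additive Gaussian
  available. Proportional noise mirrors the replicate RSDs such sensors
  report (≈ 5–10 %).
- **Traces**: Gaussian peak (default width 30 mV, centres Cu +0.1 V,
  Zn −0.45 V) on a linear baseline (default zero).
- **Calibration sets**: heights on the characterized response lines
  (Cu: 1.64e-7·log₁₀C + 1.97e-6; Zn: 5.36e-7·log₁₀C + 6.07e-6 A) at the
  standard panel 10⁻¹¹–10⁻⁶ M, 3 replicates by default; optionally as
  full voltammograms so the peaks→regression pipeline is exercised.
- **EGTA schedules**: apical fractions (1, 0.60, 0.30) for Cu and
  (1, 0.55, 0.46) for Zn at (0, 1, 2) h encode the observed apical
  percent decreases; basolateral fractions are their mass-conserving
  complements, a synthetic choice — the basolateral rise is only known
  qualitatively — that also furnishes the apical/basolateral
  anti-correlation property.

What the generator does *not* emulate: electrode drift and fouling,
peak-shape asymmetry and inter-metal interference, frequency-dependent
instrument error correlations, the insert membrane's own impedance, or
biological variability between inserts. Passing tests therefore
demonstrate correctness of the analysis chain under the assumed signal
structure, not robustness to every artefact of real recordings.

## Problem sizes

Statistical checks use 50-point spectra; 100 seeds for noise-robustness
medians (spectrum refits, calibration linearity), 200 random circuits for
noiseless recovery, 50 seeds for the transport anti-correlation property.
These sizes give stable medians for the asserted tolerances while keeping
the whole suite fast.

## Known limitations

- Exactly the two-RC topology: no constant-phase elements, so real spectra
  with depressed semicircles will fit with biased capacitances.
- Single-spectrum fits; no global multi-spectrum fitting or
  Kramers–Kronig validity screening.
- Single-peak extraction; overlapping stripping peaks are not
  deconvolved.
- No mechanistic permeability coefficient: the transport readout stays at
  the level of percent decrease and qualitative basolateral appearance.
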