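# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `nanorheo`, and the limits of what its synthetic
benchmarks establish.

## 1. The diffusion-coefficient inversion

The central quantity is the local lipid diffusion coefficient obtained
from a calibrated shear-spectroscopy data point:

    D = k_B·T · (2π·R_tip·Δh / A_lipid) · (f_S·A_S / (√2·F_S))        (SI units)

Assumptions: the membrane is fluid and supported; the patch of lipids
trapped under the spherical tip apex behaves as a disk-like inclusion
whose mobility scales inversely with its contact area
A = 2π·R_tip·Δh (Evans–Sackmann); the measured drag force is linear in
the shear velocity (low Reynolds number), so the Einstein relation links
drag to diffusivity. `pipeline.diffusion_coefficient` evaluates the
expression exactly as written; the `f_S·A_S/√2` factor is kept verbatim
as the velocity term, and any bookkeeping between that term and the
kinematic RMS velocity `2π·f_S·A_S/√2` of a sinusoidal drive lives solely
in the forward model, whose lipid-branch drag is defined so that the
inversion is an algebraic identity. Known caveats: the apex is never
exactly spherical, so R_tip is an effective radius and errors are
systematic per tip — relative variations across a sample are the robust
observable; over protein-rich regions A_lipid must be replaced by the
inclusion's actual area (exposed as the `a_lipid` parameter).

## 2. Forward model (synthetic measurement)

`forward_model` generates approach curves, velocity sweeps and force-map
grids with known ground truth. It is a quasistatic, single-bilayer
idealization designed so that every downstream stage is testable by
recovery.

**Normal response.** Linear spring compression F_N = k_mem·Δh up to the
rupture force F_rup, then breakthrough: the tip advances by the remaining
membrane thickness and is pinned on a hard substrate. The cantilever
(stiffness k_flex) and membrane springs are solved in series along the
ramp, so deflection, indentation and base position are mutually
consistent; the jump in tip–sample separation at rupture equals
t_mem − F_rup/k_mem. The linear law is the simplest form reproducing the
observed phenomenology (flat baseline, monotone compression, breakthrough,
substrate pinning); it is a stand-in, isolated behind `normal_response`.

**Shear response.** F_S = ζ(Δh)·v_S with v_S = 2π·f_S·A_S/√2 (RMS). The
drag coefficient has two regimes:

* lipid branch (Δh ≥ h_hyd): ζ_lip = k_B·T·R_tip·Δh/(A_lipid·D), exactly
  the inverse of the expression in §1;
* hydration branch (Δh → 0): Couette-like film drag
  ζ_hyd = s·η_w·A(Δh)/h_hyd with dimensionless enhancement `s`
  (`hyd_drag_scale`), independent of the lipid D.

The two are blended with the weight w(Δh) = (1 − Δh/h_hyd)² over
[0, h_hyd]: ζ is continuous, hydration-dominated at shallow indentation,
and *identically* the lipid drag beyond the hydration layer, preserving
the exact round trip. A fully D-independent hydration branch cannot also
join the lipid branch continuously for arbitrary D; the smooth crossover
is this package's resolution and mimics the gradual expulsion of
interfacial water under load.

**Phase.** θ_S(Δh) = θ_∞·(1 − e^(−Δh/λ_θ)) — an empirical saturating form
consistent with the elastic-to-viscous transition seen with increasing
load; no measured functional form exists, so both parameters are
explicit model inputs. The phase is undefined (NaN) wherever there is no
shear force above the noise floor to carry it.

**Noise.** Additive Gaussian per channel: absolute F_N noise, absolute and
relative F_S noise, phase noise (inflated 5× where F_S < 3× the absolute
floor), and deflection-distance noise. Seeded `numpy` Generators make all
outputs bit-reproducible.

**Default parameters** (chosen once, from the physics of
DOPC-on-mica-type systems):

| parameter | default | why |
|---|---|---|
| D | 5.8 µm²/s | fluid-phase DOPC scale |
| t_mem | 4.5 nm | bilayer + headgroup water |
| h_hyd | 1.5 nm | overlap region of spectroscopy curves before phase-specific behaviour emerges |
| k_mem | 0.3 N/m | gives breakthrough at ~3.3 nm indentation under 1 nN |
| F_rup | 1 nN | typical bilayer breakthrough force |
| A_lipid | 0.70 nm² | mean area per lipid, fluid phase |
| R_tip | 5 nm | sharp apex |
| k_flex | 0.6 N/m | small fast lever |
| hyd_drag_scale | 1000 | bound interfacial water is orders of magnitude more viscous than bulk; 10³ makes the apparent D rise from ≈0.2·D to the plateau, matching the observed shape |
| θ_∞, λ_θ | 75°, 1 nm | saturating elastic→viscous transition |
| approach | 30 nm/s at 2 kHz (curves), 120 nm/s at 6.25 kHz (maps) | static-mode and mapping ramp settings |

**Maps.** The diffusivity field is a unit-variance Gaussian random field
with squared-exponential correlation C(r) = exp(−r²/2ℓ²), synthesized by
circulant spectral embedding on a doubled torus (exact covariance up to
eigenvalue clipping, which is negligible for this kernel). Per phase,
D = mean·(1 + sd_rel·g) truncated below at 5% of the phase mean (a warning
reports truncation). Phase geometry comes from thresholding a second,
longer-range GRF at the target liquid-ordered area fraction (default
0.35), or from an explicit mask. Topography is the phase offset (1.0 nm,
L_O higher) plus Gaussian roughness (0.15 nm). Defaults: 32×32 pixels at
5 nm, ℓ = 20 nm, sd_rel = 0.2 (the ~20% within-phase spread of plateau
diffusivities), D_LD = 5.8, D_LO = 2.0 µm²/s.

## 3. Lock-in demodulation

I/Q mixing against sin/cos references followed by `filter_order` (default
4) identical first-order exponential low-pass stages with time constant τ.
Presets: τ = 199.8 µs (shear frequencies ≥ 25 kHz) and τ = 1.973 ms
(1 kHz). Conventions: amplitude is the *peak* sinusoid amplitude (the
drive amplitude it calibrates is a displacement amplitude, not RMS); phase
is relative to the sine reference, wrapped to (−180°, 180°]; the settled
tail is averaged as phasors, not as wrapped angles. The default settling
window is 10τ per stage (40τ at order 4): a 4-stage cascade's step
response still carries ~1% transient at 10τ total, and the longer window
makes the <0.1% amplitude spec hold with margin. The filter order of the
real instrument is not known; only noise-bandwidth properties depend on
it, and the closed-form discrete transfer function and the numerically
integrated equivalent noise bandwidth are exposed for exactly those
checks.

## 4. Calibration

**SHO PSD fit.** P(f) = P_DC·f₀⁴/((f₀²−f²)² + (f·f₀/Q)²) + white, so
P_DC is the zero-frequency plateau of the resonance line. Peak candidates
need prominence ≥ 3× the median PSD (flat spectra fail loudly).  The fit
minimizes relative residuals (averaged-periodogram noise is multiplicative
χ²), over dimensionless multipliers of the initial guess — the raw
parameters span ~16 orders of magnitude and defeat the optimizer's step
control otherwise — with bounds keeping f₀ inside the window and
Q ≤ 10·f₀/Δf (a resonance narrower than a tenth of a frequency bin is a
noise spike, a spurious minimum of the relative-residual cost).
Standard errors come from the Jacobian at the solution scaled by the
residual variance.

**Sensitivities and forces.** γ_tors = h_tip·√(2k_BT/(π·k_φ·f₀·P_DC·Q))
is evaluated verbatim. With the lateral stiffness
k_L = k_φ·L/((L−ΔL)·h_tip²) this gives F_L = k_L·γ_tors·ΔV_L in newtons
when γ_tors is read in m/V — which is what the h_tip prefactor produces
from a voltage PSD. (Annotating γ_tors in rad/V would make F_L come out
in N·m/rad·... — dimensionally inconsistent with k_L in N/m; the m/V
reading is adopted and used consistently.) invOLS is the inverted OLS
slope of deflection volts vs z extension over the hard-contact branch
(≥10 points, positive slope enforced). Stiffness-from-thermal-noise is
provided as equipartition on the fitted SHO line,
k = k_B·T/⟨x²⟩ with ⟨x²⟩ = π·f₀·Q·P_DC/2 — a deliberate, documented
methodological simplification of the full air+liquid cross-medium scheme
(calibrate k_φ in air by equipartition, γ_tors in liquid from Eq. above).

## 5. Curve pipeline

Order: baseline → contact → indentation → rupture → noise floor → D(Δh) →
plateau → moduli.

* **Baseline**: median of the first 20% of the approach subtracted from
  both force channels (optional linear detrend of F_N for drift).
* **Contact**: first excursion of F_N above 3σ of the baseline sustained
  for 5 samples, refined by intersecting an OLS fit of the rising flank
  (extended until F_N clears 10× the threshold) with zero force. The long
  flank matters: with 10 pN noise on a 0.6 N/m lever a short fit biases
  the contact point by ~0.2 nm, which propagates to ~10% in D at 2 nm
  indentation.
* **Indentation**: Δh = (z − z_c) − F_N/k_flex (deflection-corrected
  tip–sample separation), clipped at 0, optionally capped at t_mem. The
  alternative reading of Δh as raw tip displacement past contact is not
  used; the deflection-corrected convention is the one under which the
  generator round-trips exactly.
* **Rupture**: largest jump between half-window (5-sample) medians of the
  separation exceeding 1 nm while the local load exceeds 100 pN, refined
  to the largest single-sample step nearby. Median differencing makes a
  single noisy sample unable to fake a breakthrough (zero false positives
  at 0.2 nm separation noise).
* **Noise floor**: 3× the baseline F_S standard deviation, per curve.
* **Masking**: D is only reported where F_S exceeds the floor, Δh > 0 and
  the membrane is intact — no infinities, no negative D, no D where the
  phase is undefined.
* **Plateau**: sliding window of 1 nm of indentation over the valid
  points sorted by Δh; the window minimizing the absolute least-squares
  slope of the lightly smoothed (≤5-point moving average) profile wins;
  ties break toward the deepest indentation (the plateau follows the
  hydration crossover, it does not precede it). The windowed LS slope *is*
  the window-mean of the local derivative, but stays finite when
  deflection noise locally scrambles the Δh ordering — raw central
  differences divide by near-zero spacings there and diverge. Mean and sd
  of the raw D values in the window are reported.
* **Moduli**: stress over the cylindrical contact band
  σ = F_S/(2π·R_tip·Δh), strain γ = A_S/Δh, G′ = (σ/γ)·cos θ_S,
  G″ = (σ/γ)·sin θ_S. These stress/strain conventions are this package's
  stated choice, isolated in one function so alternatives can be swapped.
* **Aggregation**: interpolation onto a common Δh grid spanning the
  intersection of supports; pointwise mean, sd and count; permutation
  invariant by construction.

Tip-radius robustness: at a *fixed applied load*, the contact-area factor
2π·R_tip·Δh that the inversion divides by is the same factor the measured
drag is proportional to, so the recovered D is insensitive to R_tip
(±20% perturbations move D by well under 5% in the synthetic world). Note
what this does and does not mean: an error in the *assumed* R_tip with
everything else measured still scales D linearly — the robustness is of
load-referenced comparisons, which is how maps and profiles are read.

## 6. Spatial statistics

Maps take per-pixel D either as the mean of D(Δh) over the indentation
band 2.0 ± 0.5 nm (default — past the hydration layer, before rupture) or
as the plateau estimate. Phase labels come from Otsu's threshold on the
height histogram (L_O is the higher mode); if the two classes are
separated by less than 2 pooled within-class standard deviations the map
is declared single-phase with a warning, and a manual threshold can
override.

Weights: rook or queen (default) contiguity on the pixel grid, optionally
restricted to within-phase edges; rows standardized to sum to 1; pixels
without neighbours are flagged isolated and excluded. The spatial lag is
Y_SL,i = Σ_j w_ij·v_j. Moran's I uses the standard cross-product form
with E[I] = −1/(n−1); inference is by random permutation of the values
over the non-isolated locations, p = (#{I_perm ≥ I_obs}+1)/(N+1),
one-sided for positive correlation by default (two-sided available),
default 9999 permutations with the seed recorded in the result.
Permutations are vectorized through one sparse mat-mat product per batch;
a brute-force O(n²) double loop serves as the test oracle, never the
implementation. Diffusivities are z-scored *within phase* before lag and
Moran analysis so the between-phase mean difference cannot masquerade as
short-range correlation; the whole-map statistic keeps all edges between
valid pixels, per-phase statistics drop cross-boundary edges. Both
neighbourhood schemes and both sidedness choices are configuration, since
neither is uniquely dictated by the method.

Sigmoid transects: four-parameter logistic
D(x) = a + (b−a)/(1+exp(−(x−x₀)/w)) fitted in normalized coordinates
(nm-scale x and 1e−12-scale D otherwise defeat the optimizer's step
control), optionally weighted by per-point uncertainties (then the
covariance is taken at face value); a step smaller than twice the residual
sd flags the fit degenerate.

## 7. What the benchmarks show — and what they do not

All validation is against the package's own forward model, whose lipid
branch inverts the diffusion expression exactly. Passing tests therefore
establish the *correctness and statistical calibration of the analysis
chain* (exact inversion, unbiased event detection, honest p-values, power
at 20 nm correlation lengths), not the physical accuracy of the
Evans–Sackmann picture on any real membrane. Features of real data the
generator does not emulate: piezo creep and hysteresis, 1/f and drift
noise (only white noise and an optional linear drift), photodiode
cross-talk, tip wear and non-spherical apexes, multiple bilayers,
adhesion on retract (the retract branch is out of scope entirely), and
thermal drift of the contact point during mapping.

Monte-Carlo problem sizes (500-seed recovery batches on ~1 s ramps at
2 kHz; 100-seed map batches at 32×32) are the package's chosen benchmark
scale: large enough for the rate estimates' binomial error to be a few
percent, small enough that the full suite runs in well under a minute per
module.
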