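# Methods

`aortakit` reimplements, as a tested pipeline, a complete analysis of aortic
shape and central haemodynamics in adults with surgically repaired aortic
coarctation: statistical shape modelling of centrelines with curvature and
calibre treated as separate descriptors, non-invasive central haemodynamics
from paired flow/area waveforms, association statistics, and a 1D pulse-wave
model used to corroborate the link between calibre patterns and wave
reflection.  This note records the models, the defaults and why they were
chosen, and what the synthetic validation does and does not demonstrate.

## Shape analysis

A centreline is an ordered 3D polyline with the maximal-inscribed-sphere
radius at every point.  The normalisation sequence is: resample to 100
points equally spaced in arc length (index correspondence across subjects);
scale every subject to the population mean arc length; build a reference by
generalised Procrustes alignment (GPA) and rigidly register every subject to
it (rotation + translation only, reflections forbidden — anatomy has fixed
chirality).  Radius profiles are scaled separately so every subject has the
same mean radius; the coordinates are untouched by that step.

PCA is run twice, on the registered coordinates ("curvature", a 300-vector
per subject) and on the mean-scaled radius profiles (a 100-vector), by SVD
of the mean-centred subject × feature matrix with no per-feature variance
scaling, so components live in millimetres and a reconstruction is directly
a shape.  The first five components are retained.  Subject weights are
reported in SD units; the display convention maps weight ±1 to ±2 SD, so a
"proto-aorta" at weight +1 is the shape two standard deviations along that
component.  Component signs are fixed by making the largest-magnitude
loading positive — PCA signs are otherwise arbitrary and deterministic signs
make results reproducible.

GPA converges to an RMS mean-shape change below 1e-10 mm by default
(stricter than needed, but cheap at these sizes; it makes the reference
independent of subject order to ~1e-8).  The converged mean is put in a
canonical pose — principal axes of the mean curve mapped to x/y/z with signs
fixed by the start-to-end chord and the curve's circulation — which removes
the rotational indeterminacy the alignment leaves behind.

Two clinical indices are read from the landmarked centreline radii
(diameter = 2 × inscribed-sphere radius): coarctation index = isthmus
diameter / descending (diaphragm) diameter, and arch index = transverse-arch
diameter / descending diameter.  Reading diameters from the centreline
radius rather than from image reformats is a deliberate substitution: images
are out of scope, and on synthetic data the two definitions coincide.
Subjects with coarctation index < 0.7 are excluded (residual
re-coarctation), as in the clinical study design.

## Synthetic cohorts

No per-subject data for this population is publicly deposited, so the
package carries a generator whose outputs have known ground truth at every
stage.

**Shapes.** The base geometry is an analytic "candy-cane": a straight
ascending limb (55 mm), a half-elliptical arch (60 mm wide, 30 mm high) and
a gently bowed descending limb (130 mm), about 280 mm in total, with a base
radius tapering from 12.5 mm (ascending) to 9.0 mm (diaphragm) — matching
the cohort means reported for this population (ascending diameter
2.5 ± 0.48 cm, descending 1.8 ± 0.24 cm).  Variation modes are unit-norm
spatial profiles added with Normal(0, SD²) weights:

| mode | kind | default SD | emulates |
|---|---|---|---|
| ascending_length | curvature | 6.0 mm | relative ascending length (dominant mode) |
| arch_angulation | curvature | 2.5 mm | tall, narrow "gothic" arch peaking |
| descending_bow | curvature | 1.5 mm | out-of-plane descending bow |
| ascending_dilation | radius | 3.5 mm | root/ascending dilation |
| transverse_arch | radius | 2.0 mm | transverse-arch calibre (− = hypoplasia) |
| isthmus | radius | 1.5 mm | isthmus calibre (− = residual narrowing) |

The radius SDs look large against the 0.27–0.38 peak values of the
unit-norm profiles; the products give point-wise radius SDs of ~0.9–1.3 mm,
i.e. the ±15% relative calibre variation reported for these patients.
Gaussian point jitter (default 0.15 mm) models segmentation noise; subjects
whose perturbed radius would go non-positive are rejected and redrawn
(clipping would corrupt the orthogonality of the realised modes), with the
redraw count logged.

Two projections make the generator consistent with the analysis it feeds:
curvature modes are projected out of the base shape's similarity space
(translations, infinitesimal rotations, uniform scale, and the arc-length
gradient), and radius modes are made zero-mean.  Pose, length and overall
calibre are exactly the quantities the normalisation pipeline removes; a
mode with a component along them would have that component silently deleted
(or, worse, folded into other modes through the per-subject scaling
factors), making "recover the generating modes" an ill-posed target.  With
the projections, fitted components recover the generating subspaces to a
couple of degrees and variance shares to fractions of a point.

The gothic-arch label is drawn from a Bernoulli with logistic link on the
arch-angulation weight (slope 0.8/mm, intercept −1.4, prevalence ≈ 23%), so
the logistic-regression stage has a known effect to find.

**Waveforms.** Flow/area pairs are built from linear wave theory: a forward
area pulse `A_f(t) = a sin^p(pi (t-t0)/w)` plus a delayed scaled reflection
`A_b(t) = G A_f(t - tau)`, with flow components fixed by the incremental
relations `dQ_f = c dA_f`, `dQ_b = -c dA_b`.  The component-wise
wave-intensity areas (FCW from the forward component, BCW from the backward
one) are computed exactly and stored as truth; for non-overlapping pulses
BCW/FCW = G² by superposition algebra.  Defaults: period 0.96 s sampled at
9.6 ms (the acquisition's temporal resolution, 100 samples), pulse width
0.5 s with exponent p = 1 (a broad, rounded systolic pulse: the peakier
sin² shape with realistic cuff pressures would force the exponential
calibration to implausible central pressures), amplitude 0.55 cm² on a
5.2 cm² baseline (≈13% distension), wave speed 400 cm/s, reflection
coefficient 0.2 arriving 0.16 s after onset.  In full cohorts the
reflection coefficient is tied to the radius-mode weights (larger root,
arch hypoplasia and isthmus narrowing each add reflection) plus noise, so
the association stage has a known signal in the radius columns and a null
in the curvature columns.

Cuff pressures, BSA, LVMi and LVEF are drawn around the cohort's reported
means (p-SBP 123 ± 14, DBP 70 ± 8 mmHg, BSA 1.9 m², LVMi 72 g/m²,
LVEF 66%); LV metrics are independent of everything else by construction,
mirroring the null associations reported for them.

**What the generator does not emulate:** imaging physics and segmentation
bias; within-beat variability and breathing; spatially correlated
segmentation error (jitter is iid); any nonlinear wall behaviour in the
waveform composition (it is exactly linear, which is why the recovery tests
can demand exactness).  Passing the recovery tests therefore shows the
analysis chain is correct and well-conditioned, not that it is robust to
every artefact of real CMR data.

## Central haemodynamics

**Central SBP.** The area waveform is mapped to pressure through the
single-stiffness-parameter exponential wall model
`P = P_d exp(alpha (A/A_d − 1))`, anchored at the diastolic pair
(`A_d = min A`, `P_d = DBP`) because diastolic and mean pressure are
conserved along the arterial tree while systolic is amplified.  The mean of
the synthesised pressure is strictly increasing in alpha, so the alpha that
matches the measured MBP is found by Brent root-finding on [1e-3, 1e3]
(tolerance 1e-6 mmHg).  c-SBP is the peak of the synthesised curve and
c-PP = c-SBP − DBP.  The generator implements the exact inverse of the same
model, and the round trip recovers alpha to ~1e-14 relative.

**Total arterial compliance.** The measured flow drives a two-element
windkessel `dP/dt = Q/C − P/(RC)` with R = MBP/CO; C is tuned by Brent
root-finding so the model pulse pressure equals the measured c-PP (PP is
strictly decreasing in C; the resistive limit `PP(C→0) = R (max Q − min Q)`
bounds attainable targets).  The periodic steady state is computed exactly
in the frequency domain — each flow harmonic attenuated by
`R/(1 + i w R C)` — which removes any dependence on an initial condition
and reproduces the closed-form sinusoidal solution to machine precision.
TACi = TAC/BSA.

**Wave intensity (flow–area).** The wave speed is the slope of the QA loop
over the early-systolic window: from upstroke onset (5% of the flow pulse
height) to 60% of peak flow, the window in which the wave is assumed
reflection-free.  Separation uses per-sample circular increments:
`dI± = ±(dQ ± c dA)²/(4c)`, whose sum telescopes exactly to the net
intensity `dQ·dA`.  Wave areas are sums over the dominant contiguous run of
the one-signed separated series, bounded where the signal falls below 1e-3
of the run's peak — a deterministic stand-in for reading the wave windows
off a plot.  FCW is the dominant positive (forward-compression) run, BCW
the dominant negative (backward-compression) run, reported as magnitudes.

Intensities are reported in the per-sample increment convention (units
labelled cm⁵ for a flow–area analysis), matching how the cohort magnitudes
were tabulated; the time-derivative convention (`dQ/dt · dA/dt`) is
available via a flag.  The two differ by a fixed factor `1/dt²` on a
uniform grid, so ratios and associations are unaffected by the choice.

## 1D pulse-wave model

The solver integrates the cross-sectionally averaged mass and momentum
equations with the tube law `P = beta (sqrt(A) − sqrt(A0))/A0` on every
segment of an arterial tree, using the two-step Lax–Wendroff (Richtmyer)
scheme, CFL-limited time step (default safety 0.5).  The pressure-gradient
term is recast as a conservative flux `beta A^{3/2}/(3 rho A0)` plus
geometric sources in dA0/dx and dbeta/dx derived so that the undisturbed
state of a tapered vessel is an exact steady solution.  Friction uses
`K_f = 22 pi nu` (polynomial velocity-profile approximation; nu =
0.035 cm²/s, rho = 1.06 g/cm³).  Units are CGS internally, mmHg at the API.

Boundaries close on the characteristic invariants `W± = u ± 4c` of the tube
law, interpolated at the foot of the respective characteristic.  Junctions
enforce flow conservation and static-pressure continuity by a small Newton
solve on the connecting end areas (static rather than total pressure: the
difference is O(u²/c²), second order at arterial Mach numbers).  Leaves
close with RCR windkessels (CGS), a non-reflecting matched condition, or a
closed end.  After each boundary solve the boundary node's area is
corrected from the half-cell continuity budget, which makes the discrete
total volume change exactly equal the net boundary inflow — per-beat mass
imbalance is ~1e-5 % of stroke volume, and without this correction the
characteristic closure leaks several percent per beat.

The inlet couples a time-varying elastance ventricle
`P_v = E(t)(V_v − V0)` with a double-Hill normalised elastance shape
(m1 = 1.32, m2 = 27.4, peak fractions 0.269/0.452 of the period), filled
from a constant-pressure atrium through a linear mitral resistance and
ejecting through an ideal diode valve with a quadratic Bernoulli loss.
Defaults (E_max 2.5, E_min 0.08 mmHg/ml, V0 10 ml, filling 10 mmHg, period
0.8 s) give ~120/80 mmHg root pressure at ~5.7 L/min in the default tree.

The default tree is a reduced systemic model: the aorta from sinotubular
junction to diaphragm as ten tapered segments (boundaries at the three arch
ostia and at the informative profile stations, so a 100-point proto-aorta
radius profile is faithfully resolved), plus innominate, left carotid and
left subclavian branches, every leaf closed by an RCR terminal sized to give
a mean pressure near 90 mmHg at 5 L/min with ~70% of flow to the lower
body.  Reference wave speed 470 cm/s in the aorta (post-repair aortas are
stiff), 580 cm/s in branches.  The published systemic-tree model this
emulates is not tabulated in the source, so these values are documented
substitutes and the solver's validation surface is analytic: tube-law wave
speed (within 3%), step-radius reflection against the transmission-line
coefficient `(Z2−Z1)/(Z2+Z1)` (within 2%), closed-end reflection, matched
terminals, and mass conservation.

**Proto-aorta experiment.** Radius profiles reconstructed at ±2SD along
chosen radius components are mapped onto the aortic segments (branch and
terminal parameters fixed), simulated to cycle-periodicity, and analysed at
a mid-ascending probe with conventional P–U wave intensity
(`dI± = ±(dP ± rho c dU)²/(4 rho c)`), using the model's exact local wave
speed — a probe a few centimetres from an interface receives its reflection
within the upstroke, and a loop-estimated wave speed would silently absorb
it into the forward wave.  Variants are compared on the BCW/FCW area
ratio: conventional wave intensity is per unit lumen area, so when a
variant changes the probe vessel's own calibre the raw areas scale
inversely with the lumen (measured: FCW ~ 1/A across ascending-dilation
variants) and the ratio is the calibre-fair reflection measure.

Direction of the effect: raising the proximal-to-distal calibre ratio —
dilating the root, enlarging the arch relative to the descending aorta, or
narrowing the isthmus — increases the backward-compression fraction
returned to the root, and every such adverse morphology also raises BCW
against the mean-shape baseline (ratios ~0.06–0.11 vs 0.017).  One nuance
is worth recording: a short, recovering constriction (classic focal arch
hypoplasia) produces entry and exit reflections of opposite sign that
partially cancel at pulse wavelengths (~0.5 m, much longer than the
constriction), so in the vs-opposite comparison the arch mode's adverse
direction is the one that enlarges the arch relative to the fixed
descending aorta; the hypoplastic variant still reflects clearly more than
the mean shape.

## Statistics

Pearson correlations (two-sided p from the t distribution with n−2 df),
multivariable OLS with intercept (F-test and Wald t; rank-deficient designs
rejected with the collinear columns named), and maximum-likelihood logistic
regression (IRLS; perfect separation reported as a non-converged fit with a
warning).  Variables are screened with Shapiro–Wilk at alpha = 0.05 and
natural-log transformed when rejected and strictly positive; the screen is
skipped for zero-mean score columns, which are outside the log model's
domain.  The correlation table (12 shape rows × 7 haemodynamic columns)
marks significance at p < 0.05 with *no* multiple-testing adjustment — the
deliberate trade of false-discovery risk for sensitivity, recorded in the
table metadata, and the reason the in-silico stage exists as independent
corroboration.  These routines delegate to scipy/statsmodels; the tests
check them against hand-rolled covariance/least-squares formulas and null
calibration (type-I error 0.036 at nominal 0.05 over 500 replicates).

## Pipeline and problem sizes

`pipeline.run_all` executes generate → filter (coarctation index ≥ 0.7) →
shape (100 points, 5 components) → haemodynamics → associations → 1D
proto-aorta experiment → report, with all randomness funnelled through one
seed; identical config + seed reproduces every output byte-for-byte.  The
default study replica uses 60 subjects, matching the clinical cohort.  The
shipped configuration runs the 1D stage at dx = 0.8 cm with convergence at
0.2% pulse-pressure change; a full three-component proto experiment is ~9
heart-driven simulations of ~15–20 s each, and the acceptance runs use one
component (three simulations) — the solver's physics checks are separate
and grid-independence was verified at dx = 0.25 cm.

## Known limitations

- Curvature is operationalised as registered coordinates, not differential
  curvature κ(s); the two describe the same variation but loadings are not
  comparable across conventions.
- The radius PCA uses mean-radius-scaled profiles on the resampled grid;
  whether to use length-normalised geometry's radii instead is ambiguous in
  the source description, and the choice changes weights at the percent
  level.
- The 1D model's topology, terminals and elastance constants are defaults,
  not a published parameter set; only analytic properties are claimed.
- Wave-area windows are detected deterministically (dominant run with a
  1e-3 relative floor); waves separated by shallower notches than that
  merge, which matters for late-systolic decompression waves that this
  analysis deliberately does not quantify.
- The generator's linear waveform model cannot probe the calibration's
  behaviour under nonlinear wall mechanics or measurement noise.
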