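# Methods

`forcespec` analyses three kinds of AFM force-distance experiments — cell
indentation, single-cell adhesion, and single-molecule polyprotein
unfolding — and ships a synthetic instrument that generates all three curve
classes with recorded ground truth. This note documents the models, the
tunable parameters and their defaults, the numerical choices, and what the
synthetic data do and do not emulate.

Units are fixed repository-wide: nm, pN, s, K; Young's moduli in kPa
(1 kPa = 10⁻³ pN/nm²), mechanical work in fJ (1 pN·nm = 10⁻⁶ fJ);
k_B = 0.0138065 pN·nm/K.

## Cell elasticity (Hertz–Sneddon)

Indentation curves are fitted with the pyramidal-indenter contact model

    F = E/(1−ν²) · (tan α/√2) · δ²,

with ν = 0.5 (cells as incompressible), α the pyramid face angle
(default 18°, configurable — probe geometry is instrument-specific), and
δ the indentation. E is the single free parameter, so the least-squares
fit over δ ∈ [0, 500 nm] is the closed-form regression of F on δ² through
the origin; an exhaustive 1-D search over E is kept in the test suite as
an oracle. The indentation at a load of 1 nN is read off the corrected
curve by linear interpolation at the first crossing.

Processing chain per curve:

1. **Baseline.** Linear least squares over the leading non-contact fraction
   (default 50%) with one round of 3σ residual clipping. (Theil–Sen was
   rejected on cost grounds: O(n²) pairwise slopes at ~5000-sample curves.)
2. **Contact point.** Candidate = start of the final run of samples whose
   corrected force stays above `threshold·noise_sd` (default 3σ, floor
   0.05 pN for noise-free data). Refinement minimises the RSS of a
   piecewise model — zero force before z₀, quadratic in the
   deflection-corrected indentation after — scanned over a ±250 nm window.
   All candidates are scored on the *same* fixed sample range (otherwise a
   candidate far on the zero side trivially wins by fitting almost no
   data), with prefix-sum algebra making the scan O(n), and a parabolic
   interpolation of the RSS minimum giving sub-sample resolution.
3. **Zero-slope refinement.** Once z₀ is known the baseline is refit over
   the entire pre-contact region and z₀ re-refined; this removes the
   extrapolation error a fixed-fraction baseline leaves behind.
4. **Indentation axis.** δ = (z₀ − z) − F/k on post-contact approach
   samples (piezo travel past contact minus cantilever deflection).
5. **QC.** Automated flags with explicit thresholds replace manual outlier
   screening: excessive noise (> 25 pN), no contact, non-monotone
   post-contact force (on a smoothed scale, with 4σ slack), saturation
   (≥ 5 nN), baseline drift (> 0.5 pN/nm). Thresholds were set on
   simulator output and are all configurable. QC failure is a result, not
   an error.

## Work of adhesion

For retract curves the work of adhesion is the trapezoidal integral of the
adhesive force over piezo distance between the retract zero-force point
and the detachment point. Sign handling is a documented choice: only
negative-force samples contribute (positive excursions between ruptures
add zero work); a signed-integration option exists. The constant-height
pause segment is never integrated.

The baseline comes from the farthest 20% of the retract — the only
guaranteed force-free region, since there is no pre-contact segment on a
retract. Detachment detection works on a 51-sample boxcar-smoothed trace
at 5× its (reduced) noise SD: a 100 µm force-free tail offers thousands of
chances for a spurious 3σ excursion, which would otherwise drag the
integration bound tens of µm past the true detachment and bias the work by
~15%. A sharp final rupture (single-sample step back to zero, > max(6σ,
~5σ-floor)) is taken at the step; a gradual return is refined with a
piecewise-linear kink fit (ramp meeting zero at z_d, zero after).
Discrete ruptures are counted as single-sample upward force steps larger
than max(6σ, 30 pN) starting from an adhesive level — steps shallower than
that threshold are genuinely indistinguishable from noise and are not
counted.

## Polyprotein unfolding (WLC + Bell–Evans)

Sawtooth retract traces of a 3×I27 – FLNA-repeat-22 – 4×I27 construct are
analysed as follows.

**WLC model.** Each rising edge is fitted with the interpolated worm-like
chain, F(x) = (k_BT/p)[¼(1−x/L_c)⁻² − ¼ + x/L_c], with the persistence
length fixed at p = 0.4 nm (the single-amino-acid scale); L_c is the only
fitted parameter, found by bounded 1-D least squares on
(x_max, 10·x_max) with `xatol` 10⁻⁴ nm. The extension axis is tip–sample
separation, x = z − z_start − F/k: deflection-corrected, which is the
physically correct axis for an entropic-chain model. A diagnostic free-p
mode is deliberately not offered in the pipeline path.

**Peak detection.** Local maxima of a lightly smoothed trace (5-sample
boxcar) above max(20 pN, 4σ_smoothed), at least 5 nm apart, qualifying
only if the force then falls by max(30% of the peak, 6σ) before the next
candidate. The 30% relative drop reflects late ruptures: an I27 unfolding
releases ~27 nm against ~250 nm of already-released contour and drops the
force by only ~45–50%. The per-event peak force is read from the raw
sample immediately before the rupture step (largest single-sample force
drop near the smoothed maximum): the smoothed maximum is biased several pN
low by post-drop samples inside the boxcar, and a raw maximum is biased
~+1σ by noise selection; the pre-rupture sample is unbiased up to noise.

**Event bookkeeping and classification.** The contour length attributed
to an unfolding peak is the fitted L_c of the *following* rising edge (the
length that rupture released), so the increment of event i is
L_c(edge i+1) − L_c(edge i); the first event's increment is measured
against the first edge's fitted L_c, which is the folded-backbone offset
read from the data itself. The final peak — tip–surface detachment — has
no following edge and is excluded from domain counting. Increments are
classified into FLNA (30.4 ± 1.5 nm) and I27 (27.3 ± 1.5 nm) windows
(configurable, non-overlap enforced); anything else is `unclassified`.
Using increments between successive events rather than absolute contour
lengths makes the classification immune to the unknown backbone offset.

**Trace acceptance.** A trace is accepted iff (each rule individually
switchable): ≥ 4 I27-classified events; at most one FLNA event; and if an
FLNA event is present, no stronger I27 event precedes it
(weak-before-strong ordering). Rejection is a result carrying its reason.
Summary tables are produced both for accepted traces and unfiltered.

**Bell–Evans.** The analytic most probable rupture force at constant
loading rate r is F* = (k_BT/Δx)·ln(rΔx/(k₀k_BT)); below the threshold
rate (argument ≤ 1) the most probable force is zero and the function
raises. For pulling through a compliant WLC the loading rate is local,
r(F) = k_eff(F)·v with k_eff the series stiffness of cantilever and chain;
`bell_evans_wlc_force` iterates the fixed point and serves as the
simulator's analytic oracle in the stiff-spring limit.

## The synthetic instrument

All generators are seeded (`numpy.random.default_rng`); identical config +
seed gives byte-identical curves. Noise is additive white Gaussian on
force only — no 1/f drift, no hydrodynamic drag, no cantilever resonance,
no refolding. Passing recovery tests on these data therefore demonstrates
correctness of the analysis chain under the stated noise model, not
robustness to every instrumental artefact of real data.

**Indentation** (per curve): 5 µm/s approach sampled at 4096 Hz over a
7.5 µm ramp, k = 120 pN/nm, 310 K, truncated at 1 nN; contact point drawn
uniformly in a 2.8–3.8 µm window (so that soft 0.5 kPa cells still reach
1 nN within the ramp and ≥ 50% of the curve is non-contact); baseline tilt
uniform in ±0.02 pN/nm; noise 5 pN SD. Populations: one modulus per cell
from a lognormal parameterized by its *mode* (the "most probable value"),
µ = ln(mode) + σ², defaults mode 1.88/2.72 kPa, σ = 0.5, 50 cells × 10
curves per group. Two-group studies reuse one RNG stream for both groups
(common random numbers): the same normal draws scale to either group's
lognormal, so recovered deltas isolate measurement error from
finite-sample drawing error.

**Adhesion** (per curve): 2 nN contact, 1 s pause, 100 µm retract at
5 µm/s and 2048 Hz. The adhesive dip is triangular (or a multi-rupture
sawtooth of equal-area dips ending in steps back to zero) between the
zero-force point and a detachment drawn in 20–40 µm, scaled so the
noise-free negative-force area equals the work target exactly. Per-curve
work is drawn from a lognormal with configurable median (default 1 fJ,
σ = 0.5; the edited-group median is 2.5× in the demo study). The 1 fJ
scale is a choice — the study this emulates reports works in fJ without a
deposited table.

**Unfolding**: constant-velocity pulling of the 8-domain construct
(initial folded-backbone contour 30 nm ≈ 8 folded domains plus linkers),
800 nm ramp, k = 10 pN/nm, 298 K, 400 or 1600 nm/s. The deterministic
force-vs-distance trajectory at each contour length is precomputed on a
uniform 0.25 pN force grid by inverting the WLC (vectorised bisection), so
force increments per integration step are bounded by construction; each
folded domain accrues Bell–Evans hazard ∫k₀e^{FΔx/k_BT}dt along the
trajectory against an Exp(1) threshold (kinetic Monte Carlo), and the
earliest crossing unfolds, adding its contour increment. The tip–surface
bond is modelled as a fixed 500 pN detachment threshold (covalent thiol
tether; it must exceed the I27 force tail). Trajectories are cached per
contour length, so a 400-trace ensemble simulates in under a second.

**Bell–Evans calibration defaults.** k₀ and Δx are not identifiable from
two mean forces and are not reported by the emulated study; the defaults
are calibration choices. They were iterated so that the *measured* most
probable unfolding force — the KDE peak of detected, accepted peak forces
at 5 pN noise, the same kind of quantity the experiments report — lands
near the published pairs at both speeds: I27 (3.09×10⁻³ s⁻¹, 0.172 nm) →
~215/250 pN; FLNA-Q (5.0 s⁻¹, 0.33 nm) → ~35/61 pN; FLNA-R (7.0 s⁻¹,
0.215 nm) → ~47/81 pN against 43.7/82.0. The R pair is a compromise: its
printed speed dependence implies a force-vs-log(rate) slope at the edge of
what the serial-WLC loading geometry supports, part of its 400 nm/s
population falls below the ~20 pN detection floor (invisible to detector
and instrument alike), and the surviving distribution is flat-topped, so
its peak estimate scatters by ~±15% between seeds. The rupture-force
distribution itself is left-skewed and non-lognormal, which is why
unfolding forces are summarised by the KDE peak, while moduli and works —
lognormal by construction — are summarised by the analytic lognormal mode.

## Statistics

`summarize` reports n, mean, median, SD, SE; 10/25/75/90th percentiles
with the type-7 (linear interpolation) quantile convention; a lognormal
fit by maximum likelihood on log values (mode = exp(µ−σ²), the "most
probable value"; the KDE peak is also reported as a cross-check); an R² of
the fitted density against a density-normalised Freedman–Diaconis
histogram; and a Gaussian KDE with Silverman bandwidth (checked to
integrate to 1 within 1%). Non-positive values are excluded from the
lognormal fit with the count reported. A normality screen (Shapiro–Wilk
up to n = 5000, D'Agostino beyond) routes the recommended description
(`normal` vs `lognormal`); the routing is reported, never silent.

Two-group comparison is the two-sided Mann–Whitney U test, U reported as
min(U_a, U_b). For n_a+n_b ≤ 20 (or on request) the p-value is exact:
full enumeration of all C(n_a+n_b, n_a) labelings using midranks (ties
handled), with the null U distribution cached by (n_a, midrank multiset) —
tie-free data at fixed sizes enumerate once. Larger samples use the
tie-corrected normal approximation (scipy). Significance stars follow
*P < 0.05, **P < 0.01, ***P < 0.001 with strict inequalities, so
p = 0.05 is `ns`. Per-curve values are compared by default; repeated
measurements per cell mean the test's n overstates the number of
independent units (no mixed-effects correction is attempted — a
limitation shared with the design this emulates).

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the studies at the design
sizes — 50 cells × 10 curves per group (stiffness; the acceptance script
uses 300 cells per group so the population-mode sampling error, ~3%, is
small against the recovery tolerances), 90 adhesion curves per group, and
200–600 unfolding traces per condition — sizes at which every recovery
check has comfortable Monte-Carlo margin while the whole suite completes
in well under a minute of compute.

## Known limitations

- The contact-point and detachment detectors are documented choices; the
  emulated study names these steps but not its algorithms.
- QC thresholds substitute explicit rules for expert visual screening.
- No viscoelasticity: the elastic contact model is exact for the
  simulator, whereas real cells show rate-dependent moduli.
- Adhesion rupture counting misses steps below max(6σ, 30 pN).
- FLNA events below the ~20 pN detection floor leave accepted traces with
  no labelled FLNA event (their increment then appears as an unclassified
  ~57 nm double step in ~1% of events).
- Mann–Whitney on per-curve values ignores cell-level clustering.
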