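# Methods

## The synthetic world

The generator (`columnscope.synthetic`) emulates a flattened cortical slab
from a column-scale 7 T experiment:

- **Geometry.** A lateral grid (default 128 × 128 vertices at dx = 0.5 mm)
  with gray-matter thickness 2.37 mm (the mean of the parietal region being
  emulated). Depth is in mm from the pia; the default depth axis spans
  2.4 mm above the pia through the gray/white interface in 12 samples.
  Fractional depth = mm / local thickness.
- **Columns.** Disjoint quasi-round patches of four families — P columns
  preferring approaching (PA) or withdrawing (PW) faces, D columns
  preferring near (DN) or far (DF) binocular disparity — planted by dart
  throwing with jittered centers, radii 1.2–2.0 mm, and a 0.5-mm minimum
  gap, assigned round-robin so the families interleave laterally. Labels
  are constant across depth (radial uniformity is the ground truth the
  columnarity statistics should detect). Default densities
  (PA 0.8, PW 0.5, DN 0.8, DF 0.6 per cm²) keep the observed asymmetries
  (more approach- than withdrawal-biased patches, more near- than
  far-biased) while staying well inside the feasible packing regime for
  sequential placement.
- **Vessel layer.** A smooth random surface-parallel pattern with support
  strictly above the pia, orthogonalized against the column contrast so its
  sample correlation with the columnar map is exactly zero. It stands in
  for pial-vessel hemodynamics that a depth-resolved analysis must not
  mistake for columns.
- **BOLD runs.** TR = 3 s. Three designs: 15-s alternating blocks (16
  stimulus blocks + 2 blanks = 90 TRs; the emulated study's stated block
  count and TR count are mutually inconsistent, and 16 + 2 is the only
  composition that fills 90 TRs exactly), 24-s disparity blocks (8 blocks +
  2 × 12-s blanks = 216 s, padded to the nominal 80 TRs with a longer final
  blank, logged), and a 3-s event-related design with ITIs drawn uniformly
  from TR-aligned values in 3–12 s. A run is baseline + Σ amplitude ·
  (boxcar ⊗ HRF) + Legendre drift + i.i.d. Gaussian noise + optional
  additive spikes. Signal units are % of a 100-unit baseline; the default
  preferred/non-preferred amplitudes (2.0 / 0.5) with noise SD 1.0 give
  single-run contrast maps qualitatively like the published single-subject
  maps (clear patches at −log₁₀ p ≥ 1.3 with noisy fringes).
- **Behavior.** Stop distances are truncated-normal draws (positive
  support) around a subject mean; subject means are drawn with
  between-subject SD 11.3 cm about 57 cm, matching the emulated behavioral
  summary, with a within-subject SD of 6 cm (~10% of the mean, the
  stability the stop-distance literature reports). The first trial of each
  subject is a flagged warm-up and is excluded from all statistics.

What the generator does *not* emulate: spatial noise correlations and BOLD
point-spread (noise is i.i.d. per voxel-timepoint, no AR(1)), partial-volume
mixing across depths, cortical curvature (offsets are grid shifts, not
geodesics), vascular physiology, and between-depth signal leakage. Passing
tests therefore show that the statistics behave correctly on data satisfying
their own assumptions — not that real laminar data meet those assumptions.

## Analysis choices

- **HRF.** Double-gamma, response peak 6 s, undershoot peak 16 s,
  response:undershoot ratio 6, length 32 s, unit peak. The designs in this
  package are TR-aligned, so condition regressors are built on the TR grid
  by default; an oversampling path exists for non-aligned onsets.
- **Drift.** Legendre polynomials up to order 2 per run (order 0 is the
  intercept).
- **Scrubbing.** DVARS_t = RMS over voxels of the frame difference; frames
  above Q3 + 1.5·IQR get spike-indicator regressors, which remove their
  influence on the betas exactly (verified against timepoint deletion). The
  first frame has no DVARS and is never flagged.
- **Contrast maps.** Signed −log₁₀(p) with the sign of the contrast
  estimate; p floored at 1e-300. Maps are reported uncorrected; threshold
  sweeps (default −log₁₀ p in [1.3, 10]) handle stringency.
- **Axis correlations.** Within-column r correlates depth fractions 0.1 and
  0.9. "Across columns" is operationalized as lateral-shift autocorrelation
  at the mean radial separation (1.9 mm), averaged over the four axis
  directions, with edge vertices dropped pairwise — the emulated analysis
  does not state its pairing rule for surface-parallel vertices, and shift
  autocorrelation is the assumption-light choice. Fisher z precedes the
  paired t for the axis table; the vessel-control table tests raw r values
  (that is the mode which reproduces its printed statistics exactly — both
  modes are exposed via `use_fisher_z`).
- **Spatial shuffling.** Random 2-D circular shifts within the ROI bounding
  frame (area- and autocorrelation-preserving); a vertex-permutation mode is
  provided for sensitivity analysis. The randomization of the emulated
  analysis is unspecified; shifts are the default because they preserve the
  mask's spatial statistics. Non-rectangular ROIs can clip shifted masks at
  the ROI edge; a warning is emitted. Tail p values are the plain fraction
  of shuffles at or beyond the aligned overlap.
- **Patch counting.** 8-neighbor connected components, minimum size 5
  vertices (neither is specified in the emulated analysis; 8-connectivity
  and a small-speck filter are the conventional defaults).
- **Repeated-measures ANOVA.** F from a one-way within-subject ANOVA
  (trial as factor, via pingouin); the Greenhouse–Geisser epsilon is
  computed from the double-centered trial covariance matrix,
  ε = tr(C)² / ((k−1)·tr(C²)), clipped to [1/(k−1), 1], and applied to both
  degrees of freedom. This in-package ε avoids the sphericity-test edge
  cases of very small samples.
- **Tuning.** "Peak amplitude" is operationalized as the per-condition GLM
  beta (equivalent up to HRF scaling). The generator's approach profile is
  amp(d) = 2·max(0, 100/d − 1) in % units — zero at and beyond the PS
  boundary, steep and monotone inside it; the withdrawal profile is its
  negation at half scale ("less dramatic", as observed). Classification
  requires outside-boundary amplitudes consistent with zero (per-distance t
  tests at α = 0.05) and a signed Spearman monotonicity test inside the
  boundary; it is equivariant under curve negation. The boundary estimator
  fits amp(d) = c·max(0, b/d − 1) for each candidate grid point b and picks
  the least-squares winner (nearest-grid accuracy by construction).

## The rate model

Two populations with leak −r, sigmoid coupling, baseline inputs θ_E, θ_I,
and a common external drive I weighted by W_E, W_I. The published presets
are approach: (W_EE, W_EI, W_IE, W_II, θ_E, θ_I, W_E, W_I) =
(5, −0.1, 0.1, −1, 10, 10, 1, 10) and withdrawal:
(0.1, −10, 10, −0.1, 10, 1, 0.1, 1), both with θ = 20.

Two printing ambiguities required decisions. The ODEs' trailing terms are
read as W_E·I and W_I·I (the only reading that uses the tabulated input
weights). The sigmoid is printed as f(x) = 1/(1+exp(−(x+θ))), but with
θ = 20 that form is saturated at rest and makes the withdrawal profile
monotonically *increasing* — contradicting the described
decrease-then-plateau regime and the meaning of a "soft threshold". The
package therefore defaults to the threshold-subtracting form f(x − θ),
which reproduces both described regimes, and keeps the printed form
available (`RateParams.threshold_convention = "add"`). `f_sigmoid` itself
implements the printed formula exactly.

Steady states integrate dr/dt with an adaptive RK45 (rtol 1e-10) from
r_E = r_I = 0 in 50-time-unit chunks; once the residual falls below 1e-3
a Newton polish with the analytic Jacobian finishes to tolerance 1e-8
(integration error alone bounds the residual near ~1e-7 at large rates).
Non-convergence by t_max = 1000 is returned flagged, never silently.
Response profiles warm-start each input level from the previous fixed point
(continuation); an independent damped fixed-point iteration
(`steady_state_fixed_point`, damping 0.2) serves as a cross-check, and the
two agree to ~1e-8 on both presets over I ∈ [0, 100]. The approach preset
has a genuine fold (5·max f′ > 1), so cold starts can land on a different
branch in a narrow bistable window; discrepancies between continuation and
cold starts are surfaced by the tests, not hidden. The distance→input link
is I = scale / distance (closer faces are larger, hence drive stronger
input); the inverse shape is an explicit assumption and the scale is
configurable.

## Pipeline and problem sizes

`run_pipeline` derives one child seed per stage from the master seed, so
identical configurations give byte-identical bundles. Per synthetic subject
the columnarity stage simulates and maps one run per depth plane (4
within-gray fractions and 3 above-pia planes); the default demo uses the
128 × 128 grid, 12-sample depth axis, 7 subjects and 1000 shuffles and
completes in well under a minute on one CPU. Tests and the acceptance
script use 32–96-vertex grids and 2–5 subjects — sizes chosen so the full
validation cycle stays fast while every statistic operates far from its
small-sample edge cases. The empirical quantities quoted anywhere in the
documentation are produced by the examples, the tests, or
`scripts/acceptance.py`; none are hand-entered results.

## Known limitations

- The above-pia planes in the pipeline carry *only* vessel-patterned
  signal, so the synthetic gray-vs-above correlations sit near zero rather
  than at the weakly positive values real pial spread produces; the
  separation property, not the absolute level, is the validated claim.
- The interdigitated families are disjoint by construction; the overlap
  machinery therefore validates detection, not any biological claim about
  partial overlap.
- Real per-depth maps (TSV/HDF5 flattened scalar maps plus an ROI mask) can
  be fed to the columnarity and interdigitation modules directly, but no
  surface reconstruction, registration, or depth sampling from volumetric
  data is provided.
- Group-level inference is limited to fixed-effects summaries (per-subject
  rows plus paired t tests); no weighted-least-squares group stage is
  implemented.
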