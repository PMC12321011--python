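# Methods

`mesosaxs` analyses reduced 1D small-angle X-ray scattering (SAXS) curves
of lyotropic lipid mesophases: it fits Bragg peaks, identifies which
mesophases (possibly coexisting) produced them, estimates lattice
parameters with uncertainties, and follows light-driven phase transitions
through time-resolved frame series. A seeded synthetic generator produces
patterns and kinetic series with known ground truth, so every stage of the
chain is testable without beamline data.

## Lattice model and reflection tables

A mesophase diffracts at

    q_hkl = 2π · m / a

with `a` the lattice parameter (for a lamellar stack, the repeat distance
*d*) and `m` the dimensionless spacing ratio: `m = n` for lamellar order
*n*, `m = √(h²+k²+l²)` for a cubic *hkl*, `m = √(h²+hk+k²)` for 2D
hexagonal. The allowed ratio sequences are generated from the reflection
conditions rather than hard-coded:

* lamellar — 1, 2, 3, 4, …
* Pn3m (double-diamond bicontinuous cubic) — √2, √3, √4, √6, √8, √9, …
  The n-glide condition is implemented as: a reflection with a zero index
  requires an even index sum; general hkl are allowed. An m² class counts
  as allowed if any representative passes (m² = 9 survives through 221
  although 300 is extinct).
* Im3m (primitive bicontinuous cubic) — √2, √4, √6, √8, √10, √12, …
  (body centring, h+k+l even).
* hexagonal (optional candidate) — 1, √3, 2, √7, …

The test suite cross-checks these tables against gemmi's space-group
systematic-absence machinery and against brute-force enumeration. Tables
are truncated at six reflections by default — for the analysis window
q = 0.5–4.5 nm⁻¹ and lattices of 6–13 nm no higher orders are reachable —
and the truncation depth is an argument for larger cells.

### Lattice regression

Given peaks assigned to reflections, `a` comes from weighted least squares
of `q_i = (2π/a)·m_i` through the origin (weights `1/σ_q²` when every peak
carries a position uncertainty, else uniform). With ≥ 2 peaks, σ_a is the
**larger** of the residual-scatter estimate and the propagated WLS slope
error: the residual estimate alone has roughly one degree of freedom for
the typical 2–4 assigned orders and badly underestimates (3σ coverage in
simulation rose from ~86% to ~97% with the floor). With a single peak,
σ_a is propagated from that peak's position uncertainty.

## Synthetic data generator

One pattern is

    I(q) = A·q^(−p) + C + Σ_phases Σ_reflections amp_j · exp(−(q−q_j)²/(2σ_q²)) + noise

* Background default `A = 50, p = 2, C = 5` (counts): a generic diffuse
  bilayer-scattering falloff; the exact experimental background shape is
  not modelled.
* Gaussian peaks, width default σ_q = 0.02 nm⁻¹ — sharp powder rings at
  typical beamline resolution. Widths are shared within a phase.
* Relative per-reflection intensities default to a geometric decay with
  ratio 0.5. They are free parameters, not structure factors; the analysis
  only consumes positions and per-peak intensities.
* Noise: `poisson` (counting statistics, σ = √I) or
  `gaussian-fractional` (σ = f·I, default f = 0.02), both seeded and
  bit-reproducible. The uncertainty column always matches the noise model.
* Default grid: 512 uniform points over q = 0.5–4.5 nm⁻¹.

Kinetic series emulate a light-induced lamellar → Pn3m transition:
lamellar amplitudes ramp from full to zero between a decay onset (default
30 s) and a completion time (default 120 s); Pn3m amplitudes grow from a
delayed growth onset (default 50 s) — the delay mimics a threshold
fraction of photoswitched molecules needed before the cubic phase
nucleates; any phase present in both end states (here Im3m) is a constant
spectator, which is what makes reference-peak normalization meaningful.
Frames default to 10 s spacing over 0–180 s. Transition shapes are
piecewise-linear or logistic; the logistic is renormalized so its inner
25–75% spans the onset-to-end window — with a gentler sigmoid the first
post-onset frame rises by only a few percent of the total change, which no
threshold detector can see above realistic noise. An optional
intensity-transfer mode slaves the growing phase's ramp to the decaying
one and rescales its amplitudes so total Bragg area is conserved exactly
in the noiseless case.

What the generator does **not** emulate: instrument smearing, structure
factors and form factors, detector artefacts, q-dependent resolution,
sample absorption. Passing tests therefore demonstrate correctness of the
analysis logic under the stated statistical model, not robustness to every
real-beamline systematic.

## Peak detection and fitting

Detection: 5-point moving-average smoothing, local maxima via
`scipy.signal.find_peaks`, prominence threshold = 3 × robust noise (1.4826
× MAD of the median-filter-detrended curve), minimum separation 0.06 nm⁻¹
(≈ 3 peak widths). Maxima closer than the separation merge; the higher
apex survives.

Fitting: each candidate is a Gaussian on a local **quadratic** background
over ±5σ windows; overlapping windows are fitted jointly (lmfit,
trust-region-reflective backend — the MINPACK bounds transform freezes a
parameter started exactly mid-bounds, which our center initialisations
always are). A quadratic rather than linear background is used because
chained windows over blended reflection groups span wide ranges where the
q⁻² diffuse falloff leaves curvature. Blended reflections that detection
merged are recovered by residual augmentation: an extra Gaussian is seeded
at the largest interior residual (in σ units when uncertainties exist,
else above 1% of the group apex) and kept only if χ² improves, up to 8
additions per group; such peaks are flagged `residual-added`. Peaks whose
apex falls below 3 × noise are flagged non-significant and excluded from
indexing. Parameter uncertainties come from the fit covariance.

## Phase indexing

Combination search over candidate phase subsets (default candidates:
lamellar, Pn3m, Im3m; hexagonal optional; subsets up to 3 phases):

1. For every permutation of every subset, each phase is anchored on the
   lowest-q still-unclaimed peak interpreted as each of its first three
   reflections (permutations matter because phases interleave in q).
2. Peaks within a relative tolerance (default 1%) of predicted positions
   are claimed best-first, each reflection claiming at most one peak and
   each peak claimed at most once; lattices are refined by the regression
   above and claim/refine iterates to a fixed point (≤ 10 rounds).
3. In a multi-phase assignment, a phase left holding a single peak is
   collapsed out and its peak reverts to unexplained — any stray peak can
   anchor *some* lattice, so one peak is no evidence of a phase. A lone
   single-phase/single-peak assignment survives but is flagged
   `underdetermined`.
4. Ranking is lexicographic: total defects (unexplained peaks + predicted
   reflections inside the measured window with no matching peak), then
   fewest phases, then relative position RMS, then the 1/m²-weighted
   missing count (a missing strong low-order prediction is worse than a
   missing weak high order), then phase-name order for determinism.

The missing-prediction term is essential: Pn3m and Im3m share the ratio
classes m² = 2, 4, 6, 8 and alias onto each other whenever only shared
reflections are visible; what separates them is the *absence* of √3 and
√9 (Pn3m-only) or √10 and √12 (Im3m-only) where they are predicted.
Passing the instrument q-window (`q_range`) extends that check below the
lowest observed peak, which catches wrong lattices that push their 110
into measured-but-empty territory. All assignments within a reporting
margin of the best are returned ahead of the remainder, so near-degenerate
alternatives (common for dilute cubic patterns) stay visible rather than
being silently resolved.

`compare_states` classifies a trans/cis pair of assignments as a mesophase
transition (phase sets differ), a d-spacing shift (a persisting lattice
moved by more than 1.5 combined σ), or no change. The 1.5σ default is
chosen so that a 0.04 nm lamellar shift with per-state errors of
0.01/0.02 nm — the magnitude photoswitching induces in dilute mixtures —
classifies as real.

## Time-resolved analysis

Tracking exploits that a seed assignment (from the first frame or
user-supplied lattices) fixes every reflection's position and width, so
the per-frame problem is **linear**: apex amplitudes of the target and of
all co-modelled neighbouring reflections, plus a local quadratic
background, are solved by weighted least squares with the Gaussian shapes
frozen. The target position may then shift by ≤ 2% via a bounded 1-D
search with the linear solve nested inside; the shift is kept only on a
decisive χ² gain (Δχ² > 9 with known uncertainties), because for blended
reflections a shift mostly trades amplitude between near-collinear
components. Fixed shapes make the tracker immune to component wandering
and orders of magnitude faster than free nonlinear fits. In d(t) tracking
the gate is dropped (any χ² improvement moves the position): there the
position is the measurand and the lamellar orders are well separated.

Intensities are divided per frame by the reference peak's fitted apex
(default Im3m 211 — a spectator of the transition), cancelling arbitrary
per-frame scale factors exactly; without a reference, by total integrated
intensity. Apex amplitude rather than area is tracked: area couples to
width drift. A vanished peak is recorded as amplitude 0 with the fit's
amplitude uncertainty, keeping traces defined over the whole series; a
vanished *reference* raises an error naming the frame.

### Onset and completion detectors

Onset: first frame deviating from the baseline mean by more than
`threshold × sd × √(1+1/k)` (default threshold 3, baseline k = 3 frames),
with 3 consecutive same-sign deviating frames required (debounce). The
√(1+1/k) factor accounts for the baseline mean's own noise. The noise
scale `sd` is the baseline standard deviation floored by the per-point
measurement uncertainty when available (and capped at 1.5× it — a
few-dof empirical sd exceeding a known noise level is an upward fluke);
without uncertainties it is pooled with a trend-immune estimate from the
whole trace (1.4826·MAD of second differences / √6 — second differences
vanish on linear/flat segments of a genuine transition). These choices
jointly deliver ≤ 1% false onsets on constant noisy traces and ≥ 90%
one-frame-accurate recovery over onset/completion grids at 2% noise; a
plain 3σ rule on a 3-frame baseline achieves neither. Note the detector
flags the first frame that has *already* deviated; for a sampled ramp the
change began up to one frame spacing earlier, and the acceptance script
reports that lower interval bound as the change-start estimate.

Completion: first frame after onset from which all values stay within a
tolerance of the final plateau (mean of the last 3 frames) — tolerance 5%
of the total change, floored at 3× the per-point uncertainty so plateau
noise does not postpone completion; a trace still moving in its final step
reports "not reached".

## Problem sizes and runtime choices

Simulation-based tests use 512-point patterns, 19-frame series, 20-seed
Monte-Carlo repetitions and a 100-instance indexing recovery study; the
acceptance script uses the same sizes with 5-seed kinetic medians. These
sizes give standard errors comfortably below the tolerances being checked
while keeping the whole suite under a minute of compute.

## Known limitations

* Gaussian peaks only; Lorentzian/Voigt shapes and resolution
  deconvolution are out of scope.
* A blended pair closer than ~1 width is fitted as one peak; the indexer
  then sees one position and counts the other reflection as missing.
  Heavily overlapped three-phase patterns are recovered noiselessly, but
  under strong noise individual cubic lattices from blends carry larger
  errors than isolated-peak cases.
* Candidate phases are limited to the built-in list (lamellar, Pn3m,
  Im3m, hexagonal); other cubic aspects (e.g. Ia3d) are not searched.
* The intensity model carries no structure-factor physics, so relative
  intensities cannot validate an assignment; only positions and
  presence/absence are used.
* HDF5 output is NXcanSAS-inspired (canonical q/I/Idev naming, group
  layout) but validated only against the package's own reader.
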