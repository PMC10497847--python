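# Methods

This note documents the models, measurement procedures and numerical
choices behind spinepipe, in the order data flow through the pipeline.

## 1. Synthetic image model

A scene is a dendrite tube of constant radius (default 0.5 μm) around a
polyline core, plus spines attached to the core. Each spine is a straight
or constant-curvature axis from the dendrite surface to the tip at
curvilinear distance *L*; geometry is a tapered neck (width interpolating
linearly from `neck_width` at the surface to `head_width` at the head
centre) ending in a circular head of diameter *W* centred at arc position
*L* − *W*/2. The indicator image of this geometry (evaluated analytically
at pixel centres, origin top-left, centres at (index + ½)·pixel size) is
blurred with an isotropic Gaussian PSF, scaled to an expected photon count,
and corrupted with Poisson photon noise plus additive Gaussian read noise
and a constant background. Defaults emulate the acquisition geometry of a
63× confocal with digital zoom: 0.07 μm pixels, 1024×1024 frames
(512×512 in the test scenes, purely a field-of-view choice), PSF σ =
0.1 μm, ~500 expected photons at the structure peak, background 10 counts,
read noise 2 counts.

Ground truth (lengths, head widths, ratios, label masks, base/tip points,
core length) is exact by construction; in particular the true ratio is
*L*/*W* to machine precision, which anchors all recovery tests.

The five morphological classes occupy consecutive ratio bins — stubby
[0, 1), mushroom [1, 2), thin [2, 3), long-thin [3, 4), filopodia
[4, ∞) — consistent with the 2.0 mature/immature boundary used in the
stratified statistics. The shape sampler draws the ratio uniformly inside
a class sub-range (stubby from [0.6, 1) and filopodia capped at 6 so every
generated spine is physically renderable and measurable), a class-typical
head width, and the length as ratio × width.

What the generator does **not** emulate: 3-D structure and z-projection
artifacts, dye labelling variability, spine overlap/occlusion along the
optical axis, spatially varying background, and non-Gaussian PSF tails.
Recovery results on these images therefore demonstrate the correctness and
calibration of the measurement chain, not its performance on real
micrographs.

## 2. Morphometry

**Dendrite core.** The maximal-intensity 8-connected path between user
anchors is found on a σ = 2 px smoothed image (cost = inverted intensity,
geometric path length). Each path point is then refined to the intensity
centroid of its perpendicular profile (background-subtracted, ±1 μm), the
polyline is lightly box-smoothed to remove the pixel staircase, and the arc
length is reported in μm. On noisy synthetic tubes (straight and a
quarter-circle of radius 5 μm) the recovered length is within 0.2% of
truth; the test tolerance is 2%. Anchors whose local smoothed intensity
falls below the Otsu threshold are rejected as background.

**Skeleton fit.** Within a spine ROI the skeleton is a curve of 7 control
points from the given base point to a tip candidate, optimised (Powell,
bounded perpendicular offsets of the interior points, deterministic
initialisation from the in-mask geodesic) to maximise the mean sampled
fluorescence normalised by the ROI peak, minus a curvature penalty
λ·Σ(Δ²x)²/Δs² with λ = 1. Mean (not integrated) intensity is used because
total intensity rewards arbitrarily long curves. Tip candidates are the
geodesically farthest mask pixels from the base (within 2 px of the
maximum); among candidates whose optimised objective is within 5% of the
best, the farthest wins — on a round head all rim pixels are equally
bright and near-equidistant, and the farthest is the tip by definition.
Two sub-pixel refinements follow: interior points are pulled to the local
perpendicular intensity centroid (the geodesic initialisation otherwise
hugs the inner edge of curved spines), and the end point is moved along
the end tangent to the half-maximum intensity edge (the mask tip pixel
centre sits ~half a pixel inside the blurred edge). The curvilinear length
is the arc length of the final curve.

**Head width.** Perpendicular intensity profiles are sampled along the
skeleton at arc positions s ∈ (L/3, L] — the basal third adjacent to the
dendrite is excluded by arc length, not Euclidean distance. Each profile
contributes its full width at half maximum above background; the
width-versus-arc sequence is median-smoothed (window 5) so one noisy
profile cannot inflate the maximum, and the maximum is reported. FWHM was
chosen over a thresholded mask width because it is robust to PSF
broadening and needs no binarisation threshold. When the acquisition PSF σ
is known (it is, for synthetic scenes; on a real microscope it is a
calibration input) the residual broadening is inverted through a
top-hat ⊗ Gaussian model of the observed FWHM; below the resolution floor
(~2.355 σ) the measurement is returned uncorrected.

Measured operating characteristics at the default imaging conditions
(200 spines spanning all classes, PSF 0.1 μm, 500 photons): median
relative error ≈ 3% in length and ≈ 5% in head width, ≈ 93% correct
mature/immature compartment assignment away from bin boundaries (the
acceptance bounds are 10%, 15% and 80%).

**Background** is estimated as the median of below-Otsu pixels unless
supplied. Region fluorescence for immunofluorescence-style quantification
averages in-mask pixels inside an over/under threshold window (default
640–4095, the 12-bit convention) minus the mean of background regions, and
group means are normalised to a reference group.

## 3. Behavioral scoring

A sample counts toward an object iff (i) the nose is within 2 cm of the
object footprint boundary, (ii) the nose-heading vector (nose − body)
points within a 45° half-angle cone at the object centre, and (iii) the
climbing flag is off. Time accumulates per counted sample (1/rate s);
scoring stops once the summed total reaches the 20-s criterion; latency is
the time of the first counted sample; sessions that never reach the
criterion are flagged excluded. When several objects qualify
simultaneously the nearest wins. The protocol phrase "at least 2 cm from
the object" is implemented as *within* 2 cm — the standard proximity
reading and the only one consistent with requiring the nose to face the
object. The heading half-angle (45°) is unstated in the protocol and is
configurable.

The trajectory generator renders bout plans into sampled positions (rest
corner between bouts, nose parked 1 cm off the footprint facing the centre
during bouts, nose on the object with the paws flag during climbing
bouts) and computes its ground-truth summary by applying the same counting
rules directly to the plan, so noise-free sessions round-trip through the
scorer exactly and jittered ones within one sample interval. Cohort plans
carry the novelty preference in the bout *durations* (the novel object
receives a `novel_bias` share of each visit pair's time), matching the
dwell-time character of the real effect and giving a detectable
group-level preference at n = 9 with bias 0.6.

## 4. Proteomic quantification

The Total Protein Approach converts raw intensities to absolute
concentrations, conc(i, s) = I(i, s) / (MW_i · Σ_j I(j, s)) with MW in
g/mol; mass conservation Σ_i conc·MW = 1 g/g per sample holds to machine
precision and is asserted to 10⁻¹². Missing intensities are NaN
throughout — never zero — so the presence filter is well defined.

Filters: ≥ 2 unique peptides, and presence in ≥ 60% of samples of **at
least one** group (retaining group-specific proteins fits a comparative
design; an "every group" mode is available). The two filters commute.

Differential abundance between two groups, per protein with ≥ 2 present
samples in both: fold change = ratio of (uncentered) group mean
concentrations; a two-sided t-test on log concentrations with

- per-sample median-centering of the log concentrations across tested
  proteins, which removes the correlated sample-level offset injected by
  the noisy TPA total (disabled below 50 tested proteins);
- residual variance pooled over *all* study groups (the one-way-model
  residual, df = 16 in a 4×5 design) rather than only the two compared
  groups;
- empirical-Bayes variance moderation: a scaled inverse-χ² prior (d₀,
  s₀²) fitted by the log-variance moments method, posterior variance
  (d₀s₀² + df·s²)/(d₀ + df), test df = df + d₀. With n = 5 per group the
  raw 8-df variance estimates are so noisy that an unmoderated
  t-test + BH screen retains only ~12% of genuine 1.5-fold changes; the
  moderated test operates within ~1% of a known-variance oracle. The
  classical per-protein test remains available.
- multiplicity control by the adaptive two-stage Benjamini–Hochberg
  procedure at α = 0.05 (deterministic, FDR ≤ α; single-stage BH
  available), then direction calls up/down only when the fold change also
  passes the 1.2 cutoff.

Measured at the design conditions (10% planted DAPs at fold 1.5, n = 5,
CV 20%, 50 simulations): sensitivity ≈ 0.61, realized FDR ≈ 0.04, and a
clean null (0 false calls over 30 null tables). Note that TPA is
compositional: a fold planted on raw intensities appears on concentrations
divided by the total-intensity shift, so large planted fractions or very
abundance-skewed tables bias recovered ratios — visible in the group
ratio matrix, which deliberately reports uncentered concentration-mean
ratios.

The synthetic tables draw per-protein baselines log-normally (log₁₀ sd
0.8), multiply mean-one log-normal sample noise at the configured CV,
plant a deterministic count (round(fraction·n)) of fold changes (up or
down) in one designated group, and draw unique-peptide counts with a 10%
singleton fraction. Group-structured missingness is Bernoulli per cell.

## 5. Group statistics

The two-sample KS statistic D is the maximal ECDF deviation over pooled
points; the reported scaled statistic is ks = D·√(n₁n₂/(n₁+n₂)). The
asymptotic p is the Kolmogorov series Q(λ) = 2Σ(−1)^{k−1}e^{−2k²λ²},
truncated when a term drops below 10⁻¹², without small-sample continuity
correction. The exact p is the full permutation tail probability of D,
computed by lattice-path counting over blocks of tied values — identical
to brute-force enumeration (verified against all 70 splits at n₁ = n₂ = 4,
including ties) but polynomial in n; it is limited to n₁·n₂ ≤ 10⁴. Reported
p-values are floored at 10⁻⁶ with the raw value retained. Stratified KS
applies the same test to the sub-samples below/above a ratio threshold
(default 2.0); values exactly at the threshold join the below stratum
(configurable), a convention chosen because the boundary's side is not
fixed by the shape-class definitions.

The t-test is Student's pooled-variance (df = n₁+n₂−2) as in the
underlying protocol; CV is 100·sd/mean with the n−1 denominator.

## 6. Study orchestration

`pipeline.run_study` derives one sub-seed per stage from the global seed
via `numpy.random.SeedSequence.spawn` (reduced mod 2³¹), so stages are
independently re-runnable and the whole report is bit-reproducible — the
determinism check hashes every report file except the timing-bearing run
log. The default four-group study uses class mixtures that make the old
groups stubby/mushroom-enriched and the treated old group more
filopodia-like in its immature compartment, behavioral programs in which
improved groups halve and impaired groups extend their Day-14 latency, and
a protein table with effects planted in the treated old group. Default
problem sizes (2 scenes × 8 spines per group, 9 animals, 1200 proteins)
keep a full run under ten seconds while leaving every statistic
computable; all sizes are configuration fields.

## 7. Known limitations

- The skeleton fit assumes the ROI contains one spine reachable from its
  base point; touching spines must be separated upstream (ROIs are taken
  as given, matching a semi-automatic workflow).
- Head-width PSF deconvolution assumes a top-hat cross-section; very
  small heads near the resolution floor remain biased high.
- The exploration scorer assumes the nose/body points and the climbing
  flag are already extracted; no pose estimation is included.
- The DA test assumes log-scale homoscedasticity within protein across
  groups; strong mean–variance trends would call for trend-fitted priors,
  which are not implemented.
- Printed study-level counts (DAP totals, densities) from any particular
  real dataset depend on its raw data and are not reproduced here; the
  pipeline reproduces *procedures* and verifies them on planted truth.
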