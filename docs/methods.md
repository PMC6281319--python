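# Methods

This note documents the models, parameter choices and numerical decisions
behind `nichedyn`, in the spirit of a methods supplement: what is being
simulated, what each measurement assumes, and what passing tests do and do
not establish about real microscopy data.

## The synthetic niche scene

The generator (`nichedyn.simulate`) produces a minimal but fully
ground-truthed stand-in for a live-imaged nephrogenic niche.

**Tip geometry.** The ureteric branch tip is a hemispherical dome — the
equal-axes case of a hemiellipsoid cap — of radius R(f) = R₀ + g·f whose
centre translates at the drift velocity v.  A dome keeps the "foot"
direction (radially inward) well defined and makes point-to-surface
distances exact, | |p − c| − R |, for any cell restricted to the cap solid
angle (default ≤ 75° polar).  Default R₀ = 20 µm, growth g = 0.05 µm/frame
and drift (0.2, 0, 0) µm/frame give tissue motion of the same order as
cell-intrinsic movement, which is the regime that makes drift correction
necessary.

**Attachment kinetics.** Each cell's state follows a two-state Markov
chain: attached → unattached with per-frame probability p_detach,
back with p_attach.  Two event types interrupt the chain: a division
(probability p_divide/frame) occupies one frame, after which the cell
re-enters the detached state and a daughter track spawns nearby — this
makes division a transient, countable category, consistent with cells that
detach briefly to divide and quickly reattach; and a field exit
(p_exit/frame), which censors the track (absorbing code 5).  No death
process is parameterised — code 4 is honoured throughout the analysis but
the simulator never emits it.  Event precedence within a frame is exit,
then division, then switching.  Defaults p_divide = p_exit = 0.001/frame
correspond to roughly one division and one exit per ten cells over a
~15 h movie, the frequency suggested by published representative track
panels of this preparation.

**Cell motion and observation noise.** Attached cells hold their membrane
overlapped with the tip shell by `attach_depth` and walk tangentially
(angular sd 0.02 rad/frame); detached cells random-walk radially and
tangentially in a shell 2–6 µm above the tip surface (the 2 µm floor
separates the detached population cleanly from the 1 µm attachment
threshold).  Observed positions add isotropic Gaussian jitter
(sd 0.5 µm) to the true centres — the simplest model of membrane-reporter
noise, which is precisely what triangulation is meant to remove.  Initial
placement enforces a minimum spacing (default 3 µm) by rejection
sampling.

**Markers.** At a snapshot frame (default 10) each cell gets: a foot
(nearest point on the tip), a Golgi displaced `golgi_offset` µm along the
radial cell axis (positive = away from the tip; control preset +2 µm,
mutant preset 0), a length/width pair drawn around the preset axis ratio
(0.45 control, 0.565 mutant), desmin-like foci of which
`desmin_near_fraction` lie within 5 µm of the tip surface, and a second,
interstitial-like cell population with a configurable near-tip fraction.

**Presets.** `control_like()` (p_detach = 0.005, p_attach = 0.2, all
cells initially attached, attach_depth 1.0 µm) and `mutant_like()`
(p_detach = 0.05, p_attach = 0.2, half initially attached, attach_depth
0.55 µm, rounder cells, unpolarised Golgi, 4× near-tip interstitial
fraction).  The detachment rates place the two cohorts in the ≥4-fold
transition-count regime; the attach-depth pair puts the mutant contact
area ≈30% below control.  These are the package's study conditions and
are not adjusted per analysis.

**What the generator does not emulate.** Photon noise and PSF blur,
mesenchymal shape dynamics (cells are spheres/ellipsoids), crowding and
cell–cell mechanical interactions, a moving niche boundary, or
spatially-correlated tissue deformation (drift is rigid translation).
Consequently, passing tests demonstrate that the measurement chain is
correct and well calibrated on data satisfying its assumptions — not that
those assumptions hold for any particular microscope or reporter.

## Track processing

Drift correction subtracts the cumulative displacement of a per-frame
reference from every track; the tip centroid is the default reference
(a mean-of-all-tracks fallback exists for data without a segmented tip).
The correction is translation-only and exactly invertible.  On rendered
stacks the dome's base plane aliases on the voxel grid as the tip crosses
z-voxel boundaries, so centroid-based recovery is validated for in-plane
drift (the axial component of explant drift usually means the movie is
discarded, not corrected).

Triangulation maps positions to consecutive-pair midpoints, assigned to
the earlier frame index so downstream status alignment keeps integer
frames; one pass is the default, `passes` iterates it.  By the triangle
inequality the construction can only shorten the path, and on a jittered
straight line it reduces both the path length and the RMS error to the
true line.  The analysis window (frames 10–97, i.e. 870 min at 10-min
intervals) is applied after drift correction and before smoothing; the
first ten frames are discarded as setup artefacts.

## Attachment classification and scoring

A frame is *attached* when the membrane-to-surface distance —
centre-to-surface minus the cell radius, floored at zero — is at most
`attach_distance` (default 1.0 µm, a membrane-apposition scale standing in
for the visual "clear membrane protrusion" criterion).  Division and
censoring frames are annotations (they are observable events in real
movies); frames with no surface available censor the cell rather than
being interpolated.  Eligibility drops any cell with a death/exit event at
or before the window end.  The transition count is the number of adjacent
unequal code pairs with both codes in {1, 2, 3}; transitions into and out
of division count, so 1→3→1 contributes 2.  Group summaries stratify by
the state at the first analysed frame (frame 10).

At the default jitter (0.5 µm) a small fraction of detached frames near
the 2 µm floor are misread as attached (the attached side is essentially
never misread); this inflates both cohorts' transition counts slightly
and is part of the measured, rather than true, phenotype contrast.

## Contact geometry

`build_surface` meshes a label volume by: optional Gaussian blur (µm,
converted to voxels per axis), linear resampling to the isotropic
`detail` pitch (1.0 µm for the tip, 0.3 µm for cells, following the
surface-detail settings of commercial reconstruction tools), a fixed
half-voxel anti-alias on the resampled grid, and marching cubes at the
0.5 level.  The anti-alias suppresses the staircase bias of meshing a
binary indicator (a 10 µm-radius sphere otherwise meshes ~6% over its
analytic area).  Meshes are watertight; areas converge to analytic values
as the source voxels and detail pitch refine.

Contacts are connected components (edge adjacency) of cell-surface
triangles whose centroids lie within `contact_distance` (default 0.5 µm)
of the tip surface or inside the tip solid — apposed segmentations may
interpenetrate, and membrane deeper than the contact distance is still in
contact.  Components below `min_area` (default 0.5 µm², applied per
patch) are discarded as noise.  Point-to-mesh distances use a two-stage
query (k-d tree over face centroids, then exact point–triangle distance
over the k = 8 nearest candidates), with inside/outside decided by the
nearest face normal; this is exact whenever the true nearest face is
among the candidates, which holds for the smooth, well-shaped meshes
produced here.

The closed-form sphere-cap area — the cell-membrane sphere's intersection
with the ball of radius R + contact_distance, area 2πr·h — is both the
independent oracle for the mesh route (they agree within mesh resolution)
and the per-cell estimator used in large replicate studies, where it is
applied to observed positions and averaged over a cell's attached frames.
Re-meshing every cohort of every replicate would measure the same
quantity through a slower route; the mesh and analytic routes are kept in
agreement by the geometry tests.

Spot counting smooths the marker field at 0.5 µm and counts local maxima
inside the region with a minimum separation (default one voxel); with
point-list input it is a plain inside-region count.

## Motility, polarity, niche metrics

Motility records displacement, path length, duration, velocity
(path/duration — total traversed distance per time, not net speed) and
the meandering index, defined here as displacement/path length (the
field also uses displacement/duration under this name; the ratio
definition is dimensionless and bounded by 1, and is stated prominently
for that reason).  Metrics are invariant to rigid transforms.

Roundness is the minor/major axis ratio (width/length): elongated
wild-type-like cells score ~0.45, rounder cells score higher.  When
extracted from masks, axes come from the principal components of the
voxel cloud (semi-axis = √(5λ) for a solid ellipsoid).  The Golgi ratio
a/b is oriented so that smaller values mean the Golgi lies farther from
the tip than the cell centre.  Neighbour composition reports per focal
cell the ratio of heterotypic to homotypic neighbours within a touch
distance; per-cell ratios are Jensen-biased upward in sparse
neighbourhoods, so population-level statements should use pooled counts.
Niche summaries count cells by spot detection or point membership,
measure volumes as labelled-voxel counts × voxel volume, and accept
nephron stages as categorical input only (staging is a visual call, never
inferred from morphology here).  Fold changes are reported at one decimal
place and percent reductions at the nearest integer, with full precision
alongside.

## Statistics

Group comparisons use Welch's unequal-variance two-sided t-test (a
pooled-variance option exists); SEM is sd/√n; significance tiers are
ns (p > 0.05), * (< 0.05), ** (< 0.01), *** (< 0.001); no
multiple-testing correction is applied.  Zero-variance identical groups
are reported as p = 1.  The Welch p-value is cross-checked against a
permutation test in the suite.

## Problem sizes and determinism

Simulated cohorts use 30 cells × 98 frames (88 analysed) per group —
matching the scale of a tracked live-imaging cohort; replicate studies
use 100 seeded replicate pairs; rendered-geometry checks use small
isotropic-voxel scenes (tips of 12–40 µm radius at 0.4–1 µm voxels).
Every stochastic entry point takes a seed, identical (parameters, seed)
reproduce byte-identical outputs, and the pipeline records the config
hash and seed in its summary.

## Known limitations

- The tip is a rigid dome: no branching events, no lumen, no epithelial
  cell resolution (tip-cell counts use rendered nuclei impulses).
- Attachment is binarised by a distance threshold; protrusion morphology
  (length, angle) is not modelled, so threshold sensitivity near the
  detached floor is the main classification error mode.
- The sphere-cap contact estimator assumes spherical membranes; strongly
  elongated attached cells would need the mesh route.
- Drift recovery from rendered centroids is validated in-plane only (see
  above).
- Daughter cells inherit no lineage-specific behaviour beyond starting
  detached.
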