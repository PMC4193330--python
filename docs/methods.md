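# Model and methods

This package implements a recurrent network model of figure-ground
segregation in the primate ventral stream.  The computational claim it
embodies is that *interior enhancement* — the elevated response of visual
neurons whose receptive field (RF) lies inside a figure — is a code for the
figure's **medial axis** (skeleton), computed by a population of cells with
*jittered* RF sizes and centres, and stabilized by feedback that measures
the Gestalt **closure** of the figure's boundary.

## Architecture

The model is a stack of retinotopic layers on a 64×64 pixel canvas.

1. **Edge map (lumped retina/LGN/V1).**  Input displays are reduced to a
   polarity-insensitive oriented boundary-energy field `E(y, x, o)` with 8
   orientation channels spanning 180°.  Each boundary pixel carries unit
   energy, soft-assigned to channels by the local boundary tangent.  For
   texture-defined figures the energy sits on the orientation-contrast
   outline of the figure, not on individual texture strokes.

2. **Curved-contour cells (model V4).**  Cells tuned to one of 8 arcs
   (45° each) of a circle at one of 7 radii.  The seven radii are linearly
   spaced, 3–24 px.  An arc template is a set of ~1 px-spaced samples along
   the arc, each requiring edge energy near the circle tangent
   (Gaussian orientation tuning, 22.5° half-width) and within ~1.2 px of the
   ring radially.  Template mass is normalized per (arc, scale), so
   responses are comparable across scales; the match is multiplied by a
   fixed gain (so a clean tangent contact scores near 1) and rectified
   against a threshold θ_c.

3. **Convex cells (model PIT).**  A convex cell at position p and scale s
   pools the 8 arc-sector responses of scale s around p (sector maps are
   blurred by a "jitter" Gaussian, σ = max(1.8, r/6) px, standing in for
   RF-centre scatter).  Two structural factors shape the drive:

   * **Opposing-sector gate** — the cell receives drive only if two active
     sectors lie ≥ 90° apart on the ring.  This admits both bar-like
     contacts (opposite walls) and corner contacts (perpendicular walls)
     while rejecting contours confined to one side of the RF.
   * **Closure coverage** — the drive is the sector mean multiplied by
     (mean sector saturation)^3.  A cell whose annulus is contacted all
     around (a closed contour at the matching radius) therefore out-drives
     a cell touching contours on two sides only, by far more than the raw
     energy ratio.  This realizes the convexity/closure preference of
     annular RFs and is what makes the equilibrium peak for a square sit at
     the centre (all four walls tangent) rather than along the midlines
     (two walls tangent).

   Convex cells interact through (a) quadratic cross-scale competition
   among scales sharing an RF centre (contrast-enhancing: a 60/40 scale
   profile sharpens toward the winner), and (b) the **coarse-to-fine
   recurrent circuit**: each cell receives inhibition collected from active
   larger-scale cells whose annulus covers it, *cancelled* in proportion to
   the fraction of its own ring input that those larger cells also see.
   Cells on a true medial axis share their boundary contours with the
   large-RF cells that respond to the figure's outer closure, so their
   inhibition cancels; cells inside a concavity see contours the outer
   closure cells do not, and keep their inhibition.

4. **Teardrop cells (model AIT).**  A teardrop cell at p with integration
   direction d (8 directions at 45°) reads an ordered ramp of convex cells:
   the largest RF at p itself and progressively smaller RFs at equally
   spaced offsets (5.25 px) along −d — the geometry of a medial-axis
   segment tapering into a corner.  Ramps of every top size τ = 2..7 are
   evaluated and the best one wins, so small figures drive teardrops
   through short ramps.  Ramp scoring is deliberately conjunctive: convex
   samples are contrast-normalized, passed through a saturating transform,
   and combined by a geometric mean, so one strong sample cannot carry a
   ramp.  Teardrop input is normalized to the convex field's maximum —
   teardrops judge the spatial *pattern* of activity, not its absolute
   level, which keeps the closure verdict stable while feedback rescales
   the convex layer.

5. **Closure feedback.**  At each position, direction agreement
   `Σ_d g(T_d) − θ_F` (g a steep Hill function) splits into an excitatory
   and an inhibitory half, both spread over a small neighbourhood (σ = 1.5
   px).  The excitatory half is modulatory: it multiplies the feedforward
   drive (feedback cannot create activity at scales with no bottom-up
   support).  The inhibitory half is subtracted from the drive, **down to a
   residual floor of 5 %** of the drive — suppression is strong but never
   abolishes a cell's response outright.  Suppression is gated by a global,
   latched "maturity" factor that saturates once any teardrop cell is
   decisively active: early in a run nothing is suppressed and the
   feedforward sweep establishes candidate medial responses; once closure
   evidence exists anywhere, absence of agreement counts against a figure.
   This gives the model its late-component character, and the latch
   prevents a slow relaxation oscillation through the global factor.

6. **Dynamics.**  Convex and teardrop layers obey shunting membrane
   equations dx/dt = −A·x + (B − x)·E − (D + x)·I with A = B = 1, D = 0.
   Each step applies the exact (exponential-Euler) solution with drives
   frozen, so activities provably stay in [0, B] for any gains and step
   size; updates are synchronous.  Runs integrate until the largest convex
   change falls below `convergence_tol` (default 1e-4) or `n_steps`.

## Lesion conditions

`LesionConfig` enables/disables the two feedback pathways independently:
Feedback-Intact, Convex-Only Feedback (recurrent circuit only),
Teardrop-Only Feedback (closure feedback only), No-Feedback.  Lesioned
pathways contribute exactly zero drive.

## Stimuli

The stimulus module generates the parametric display families used to
characterize the model — 64 rectangles (8×8 side grid, aspect 1/8..8), 96
C-shapes (16 aspects × 6 thicknesses), 36 crosses, 36 square-texture
arrays, and seeded random-block figures of low/medium/high complexity
(4/16/32 blocks added to a base rectangle, each edge-adjacent to the shape
grown so far) — plus named exemplars sized relative to the seven RF radii:
a 27 px square (half-width = radius 4), a C-shape with 13 px arms and an
equally wide concavity, a 12×40 cross, a 2×2 array of 13 px texture
elements with a 9 px gap, a 3 px bar thinner than the smallest ring, a
crescent, a triangle, and a texture-defined square paired with a
background-only control whose pixels are identical inside any interior
probe window.

Ground-truth skeletons are exact discrete medial axes (distance-transform
ridge, thinned preserving topology, seeded tie-breaks).  Note that the
exact skeleton of a rasterized disk includes thin axis spokes — the
discrete disk is a polygon — and that a square's skeleton is its diagonals
only.

## Figure-ground indices

IOI, MAI and BI are normalized contrasts of mean activity over
complementary regions (figure/ground; 1 px medial band / rest of interior;
1 px boundary band / everything else).  The medial band is clipped to the
figure so that corner spurs of the skeleton cannot claim ground pixels.
The activity map for the indices is the per-position maximum over scales;
the per-RF-size MAI (`mai_dominant`) is also reported, computed on the
maximally active scale's own map — this is the quantity quoted for the
exemplars.  The kurtosis diagnostic is the Pearson (non-excess) kurtosis
μ4/μ2² of the unit-sum 7-vector of per-scale maxima; uniform mass over 7
scales gives 1.75, an even split over the two extreme scales gives 1.

## Parameters

All constants live in `SimParams` with these defaults (units: activity is
dimensionless in [0, 1], space in pixels, time in integration steps of
dt = 0.15 membrane time constants):

| group | constant | default | role |
|---|---|---|---|
| shunting | decay A / ceiling B / floor D | 1 / 1 / 0 | membrane constants |
| integration | dt, n_steps, convergence_tol | 0.15, 400, 1e-4 | exponential-Euler loop |
| feedforward | ff_gain | 18 | annulus drive → convex excitation |
| feedforward | cover_pow | 3 | closure-coverage exponent |
| feedforward | jitter_floor | 1.8 | minimum sector-pooling σ |
| competition | comp_gain | 16 | quadratic cross-scale inhibition |
| recurrent | rec_gain, rec_kappa | 5, 1.5 | coarse-to-fine inhibition, cancellation |
| teardrop | td_gain, theta_t, td_blur, td_leak | 6, 0.25, 0.8, 0.25 | ramp drive, threshold, jitter |
| feedback | fb_exc_gain, fb_inh_gain | 2, 1.5 | boost / suppression strength |
| feedback | theta_f, g_half, g_pow | 2.6, 0.4, 4 | closure threshold and agreement shape |
| feedback | fb_spread_sigma, fb_residual | 1.5, 0.05 | spread and suppression floor |

The published account of this model family reports its simulations without
printing the governing equations or constants, so the values above are this
implementation's own operating point: the stimulus geometry was fixed first
from the stated RF-to-figure proportions, and the dynamical constants were
then chosen so the four exemplar simulations reproduce the published
medial-axis indices (0.91, 0.67, 0.74, 0.83) within the stated engineering
tolerance while keeping every field alive and every qualitative ordering
intact.  The defaults are deliberately exposed: substituting a different
operating point is a one-line change.

## What the synthetic displays do and do not show

The generators emulate the displays used in the electrophysiology this
model addresses: high-contrast, axis-aligned, mostly right-angled figures
on clean backgrounds, rendered at 64×64 with RF radii 3–24 px.  Passing
tests on them shows the circuits perform figure-ground segregation under
those conditions; it does not show robustness to natural images (supported
only as a demo through `io.load_image` + `compute_edge_map`), to curved or
oblique boundaries beyond the crescent/triangle exemplars, to clutter, or
to occlusion.  The isotropy artifact the model family acknowledges is
reproduced here too: elongated figures yield broader, less punctate
teardrop activity than squares of equal area.

## Numerical choices and degenerate inputs

* Exponential-Euler integration (unconditionally stable, bound-preserving);
  synchronous updates, so results are independent of within-step ordering.
* Arc kernels are built by bilinear splatting plus an isotropic Gaussian
  (σ 1.2 px) and the eight direction vectors share one √½ constant, so a
  90° rotation of the input rotates every layer's activity exactly (up to
  float tolerance) with arc/direction channels permuted by 2.
* Skeleton thinning tie-breaks are seeded; every generator is a
  deterministic function of its parameters and seed.
* Empty index regions (e.g. a bar so thin the medial band covers the whole
  interior) contribute mean 0 with a warning instead of aborting sweeps;
  an all-zero scale profile makes the kurtosis undefined and raises.
* Ties in the dominant-scale readout break toward the smaller scale.
* Boundary-clipped teardrop ramps renormalize over the in-grid sample
  count (minimum two samples).

## Known limitations

* At matched single-cell probes in the C-shape's arm and concavity
  midpoints, the intact-feedback equilibrium leaves both cells near the
  suppression floor, where their ordering follows the feedforward drive
  (which favours the three-walled concavity).  The medial-over-concavity
  preference under intact feedback holds at the population level (region
  maxima and means) but not at those matched midpoint cells.
* The recurrent coarse-to-fine circuit contributes little on small figures
  whose large-scale closure cells are weak; lesioning it alone is often
  numerically indistinguishable from no feedback on low-complexity block
  displays.
* No conduction delays, no border-ownership pathway, no concave-template
  cells, no depth or occlusion cues — consistent with the scope of the
  model family this package implements.
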