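# Methods

`clawtrack` turns video of claw-waving fiddler crabs into per-individual
wave phases and group-synchrony measures. This note describes the model
behind each stage, the parameters that matter, what the synthetic scenes do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## Pipeline model

The method assumes a fixed camera looking at many small, near-stationary
individuals whose only conspicuous motion is a brief periodic claw wave.
Under that assumption, *motion itself* is the detection signal — no
appearance model, background model, or training data is needed, which is
what makes the approach robust to cluttered field scenes where
blob-detection and learned trackers struggle.

Per consecutive frame pair:

1. **Dense optical flow.** A coarse-to-fine pyramidal iterative
   Lucas–Kanade estimator (`skimage.registration.optical_flow_ilk`) returns
   a per-pixel displacement field. The pyramid recovers displacements of
   several pixels; the iterative warping refines to well below 0.1 px on
   rigid translations (the test suite verifies < 0.5 px median error for
   shifts up to 5 px, and in practice the error is ~1e-5 px on clean
   texture). The estimator window (`flow.window`, default 15 px) trades
   locality against noise; the number of warp iterations
   (`flow.iterations`, default 3) is enough for sub-pixel convergence at
   claw-motion speeds. `flow.levels` is accepted for compatibility but the
   backend sizes its pyramid from the image.
2. **Grid averaging.** The field is reduced to a uniform grid
   (`grid.cell_size`, default 8 px) by the arithmetic mean of each cell's
   vectors; partial edge cells average the pixels actually present, so
   border motion is kept. Averaging suppresses single-pixel flow noise at
   the cost of diluting motion smaller than a cell.
3. **Magnitude threshold.** Cells with mean speed below
   `grid.speed_cutoff` (default 0.28 px/frame) are set to exactly zero.
   The default was calibrated once on synthetic scenes: it is the smallest
   round value above the maximum cell speed the flow estimator produces on
   a static textured background under the generator's default pixel noise
   (measured ceiling ≈ 0.21 px/frame), so background noise yields zero
   cells while claw motion (≥ 0.3 px/frame per cell on the slowest part of
   a wave) always survives. On other footage this cutoff is the single
   most important knob and must be re-tuned.
4. **DBSCAN clustering.** Surviving cells' centers are clustered with
   DBSCAN (`dbscan.epsilon` = 30 px, `dbscan.minpts` = 2, the point itself
   counted). Density clustering needs no preset number of crabs and
   tolerates arbitrary cluster shape. minpts = 2 errs on the side of
   inclusivity; spurious clusters are removed later by wave filtering.
   DBSCAN is implemented in-repo with classic semantics (kd-tree neighbor
   search, index-order seeding, border points claimed by the
   earliest-seeded cluster that reaches them) so that its behavior is fully
   specified and testable against a brute-force reference; point order is
   fixed to row-major grid order.
5. **Centroid ID tracking.** Each frame's cluster centroids are matched to
   live tracks greedily in order of globally smallest Euclidean distance,
   one-to-one, rejecting pairs beyond `track.max_distance` (default 30 px,
   the same spatial scale as epsilon). Greedy-global matching is
   deterministic, order-independent, and cannot double-assign, which plain
   per-cluster nearest-neighbor matching can. Unmatched clusters open new
   IDs; a track unmatched for `track.patience` consecutive frames (default
   10 ≈ 0.33 s at 30 fps) closes. Ten frames covers the brief intervals
   where a slowing claw dips under the speed cutoff around stroke
   reversals, while staying far below a wave period so distinct crabs are
   not bridged. A crab that leaves and returns gets a new ID;
   re-identification is out of scope.

The per-frame speed recorded on a track is the mean cell speed of its
matched cluster. Positions are pixel centroids; a single scalar
meters-per-pixel calibration (`io.metric_scale`) converts to metric space
when supplied. Parallax and lens distortion are not corrected.

## Wave extraction and synchrony

Each track's speed trace is one burst per claw wave. The chain is:

- **Smoothing**: centered moving average, `wave.smooth_window` = 9 frames
  (0.3 s at 30 fps), edges shrinking to the samples present. Nine frames
  matches the peak-separation scale; shorter windows leave frame-scale
  jitter on the burst top, longer ones start merging adjacent waves.
- **Peak detection**: local maxima with prominence ≥
  `wave.min_prominence` and spacing ≥ `wave.min_separation_s` (0.3 s). The
  prominence default is *half* the grid cutoff: the cell-averaged cluster
  speed is amplitude-compressed roughly twofold relative to the true claw
  speed, because slow periphery cells enter the average as the claw speeds
  up; a prominence equal to the full cutoff can therefore reject genuine
  waves, while half of it still sits well above smoothed background
  fluctuations (bounded by the cutoff calibration before smoothing).
- **Sub-frame localization**: the same membership compression flattens the
  burst top, so the literal argmax can wander several frames along a
  plateau. Each detected peak is relocated to the center of mass of the
  burst (samples above the half-height of a window of about a third of the
  peak spacing, never crossing the midpoint to a neighbor). On the
  reference scene this cuts the per-individual systematic peak-time error
  from ≈ 0.08 s to ≈ 0.04 s.
- **Phase**: the moment of maximum claw speed is phase zero; between
  successive peaks phase grows linearly to 2π. Phase is undefined before
  an individual's first and after its last peak — only actively waving
  crabs carry phase. Fewer than two peaks means no completed wave and no
  phase at all.
- **Synchrony**: at each instant, the Kuramoto order parameter
  R = |mean over active individuals of exp(iθ)|, undefined below two
  active phases. The headline scalar `mean_R` is the time average of R
  over its defined instants. The chance baseline is the Monte-Carlo mean
  of R for the typical (median) active count with i.i.d. uniform phases
  (`sync.chance_reps`, seeded); for n = 2 it equals 2/π and for large n
  approaches √π/(2√n).

A "full claw wave" for track filtering is one complete cycle — two
successive detected peaks — the smallest unit on which phase is definable;
IDs without one (transient noise blobs, crabs clipped at the boundary) are
discarded before analysis.

## Synthetic scenes

Field footage is not distributable, so the generator renders the regime the
tracker targets: 30 fps clips of `n_wavers` (default 10) individuals with
pairwise separation ≥ 110 px, each a static body blob plus a bright claw
patch about 15 px across, on a static low-contrast random texture, with
optional per-frame Gaussian pixel noise (default σ = 2 on a 0–255 scale).
All randomness derives from one seed; identical config + seed gives
bit-identical frames.

The claw orbits its rest point (orbit diameter = `claw_size`) with angular
speed ω(s) ∝ 1 − m·cos 2πs, m = `speed_modulation` (0.45). This gives
exactly one speed maximum per cycle — the planted wave event — and, unlike
any 1-D out-and-back stroke (which necessarily stalls and produces two
speed peaks per cycle), never stops while waving, so the planted "time of
maximum speed" is unambiguous. `duty_cycle` < 1 inserts a motionless pause
into each period, exercising detection gaps and active-waving masking.
Claw contrast (amplitude 90 over a texture of σ 12) was set so the slowest
part of a wave stays measurable above the noise-calibrated cutoff; the
default period is 1.5 s, within the natural one-to-a-few-seconds waving
rhythm.

Planted ground truth — per-waver peak times, phases (same
phase-zero-at-peak convention), and group R over time — lets every stage be
checked end to end: on the reference noise-free scene the pipeline recovers
the exact individual count with zero ID switches, wave periods to well
under 1 %, ≥ 95 % of interior wave events (a wave peaking within one period
of a clip boundary is not fully observed and is excluded from that
denominator), and mean R within 0.05 of planted.

The reference recovery scene plants *equal* phase offsets (a fully
synchronized lek, R = 1). Near R = 1 the residual per-individual phase
error (≈ 0.2 rad, from deterministic flow-estimation distortion of each
waver's speed trace) depresses R one-sidedly and quadratically, so the
0.05 recovery band is a meaningful test of the phase chain. Near R ≈ 0 the
same band would be dominated by sign-random fluctuation of R itself rather
than by pipeline quality. Incoherent and partially synchronized
configurations are covered by the planted-synchrony identity tests
(R = 1, 0, 1/3) and the phase-correlation checks.

What the scenes deliberately do **not** emulate: moving vegetation, water
ripples, shadows, camera shake, parallax, appearance variation, and
occlusion. Passing on synthetic scenes therefore demonstrates the
correctness of the measurement chain under the stated assumptions, not
robustness to every field nuisance; on real footage the cutoff, epsilon,
and the wave parameters must be tuned to the scene, and spurious IDs may
need manual review.

## Count and wave accuracy statistics

Against a human count N_hum (ground truth) and an algorithm count N_alg:
net error = N_alg − N_hum (signed); relative error =
|N_alg − N_hum|/N_hum × 100 %; agreement accuracy = 100 % − relative
error. Percentages are exact internally and displayed to two significant
figures. Wave-level accuracy matches annotated to detected events per ID,
one-to-one, greedily in time order within a tolerance (default 0.5 s), and
reports the matched fraction of annotated events; spurious detections are
not penalized there (count-level statistics cover them).

## Numerical and degenerate-input choices

- Constant (textureless) frame pairs return an exact zero flow field.
- Thresholding is idempotent; zeroed cells have both components exactly 0.
- Empty point sets cluster to an empty result; single isolated points are
  noise at minpts = 2.
- Matching ties (equal distances) break by track then cluster index.
- Scene placement tries rejection sampling for natural layouts and falls
  back to a jittered lattice; feasibility is judged by square-lattice
  capacity up front (slightly conservative for packings only a hexagonal
  arrangement could hold).
- Monte-Carlo chance levels and the scene generator consume seeds
  explicitly; nothing reads global random state.

## Problem sizes

Default test and acceptance runs use the reference scene (10 wavers,
480×360 px, 600 frames) plus smaller 2–3 waver clips for unit-level
checks; these sizes exercise every code path, including multi-cluster
contention, while a full run of the suite stays in the minutes range on a
single CPU.

## Known limitations

- Dense flow underestimates the speed of small patches over textured
  static backgrounds (the static texture inside the estimator window
  anchors the fit); the cell-averaged speed trace is therefore compressed
  and individual peak times carry a deterministic error of a frame or two.
  Phase relations are preserved to ≈ 0.2 rad, which is ample for
  population-level synchrony but not for, say, precise pairwise
  phase-lag estimation.
- IDs are not preserved through departures/re-entries or through
  cluster merges when crabs come within epsilon of each other.
- The pipeline measures synchrony; it does not fit coupled-oscillator
  dynamics or infer interaction networks.
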