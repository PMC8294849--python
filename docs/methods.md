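# Methods

This note records the models behind each module, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the underlying assay protocol left the design
open.

## Trafficking

Tracks are ordered (t, x, y) sequences at a uniform frame interval
(tolerance 10⁻⁶ s); the reference movies run 500 s at one frame per 5 s.

* **Mobility rule.** A track is mobile iff its cumulative path length in
  some contiguous 300-s window exceeds 2 μm. "Distance covered" is path
  length, not net displacement: organelles reverse direction and tracking
  software reports path statistics. Tracks shorter than the window use a
  pro-rated threshold `2 μm · duration/300 s` (disable with
  `prorate_short=False`, which then treats short tracks as errors).
* **Pause-excluded velocity.** A frame interval is *stationary* when its
  step is below 0.1 μm — a configurable surrogate for localisation jitter,
  which the protocol does not quantify. A *pause* is a maximal stationary
  run strictly longer than 10 s; velocity is (path outside pauses)/(time
  outside pauses). A track that is one long pause raises
  `UndefinedResultError` rather than returning 0: zero velocity and
  undefined velocity are different statements.
* The group statistic for velocity is the median across tracks, matching
  the way such distributions are summarised.

## Synthetic data

Every generator is a pure function of its parameters and seed (NumPy
`SeedSequence`-derived generators; bit-identical reruns), and returns its
ground truth. Target counts — mobile tracks, mito-containing boutons,
frames per zone — use round-half-away-from-zero with the remainder assigned
to the lowest-index items, so constructed fractions are exactly
reproducible regardless of parity.

* **Tracks.** Mobile tracks move at constant true speed with a persistent
  direction random walk (heading SD 0.3 rad/frame) and optional pauses
  (default 15–60 s, i.e. all longer than the 10-s exclusion); immobile
  tracks jitter with steps uniform in [0, 0.03] μm/frame, which caps every
  300-s window at 1.8 μm — strictly under the 2-μm rule by construction.
  Requesting a mobile track whose speed and pauses cannot exceed the
  windowed threshold is a parameter error, not a silently immobile track.
* **Morphologies.** A soma root sprouts one axon and one dendrite; each
  compartment grows by repeatedly extending a random open tip by a segment
  (mean 20 μm, 5 nodes) and bifurcating there, so the branch-point count
  per compartment equals the request exactly. Radii: soma 5 μm, neurites
  0.5 μm.
* **Mito stacks.** Isotropic Gaussian blobs (σ = PSF) with peak 10× the
  mean background so default binarisation keeps them deterministically;
  placements are uniform-on-tree (length-weighted), soma-biased
  (exp(−d/30 μm) weighting) or at given points. A voxel size beyond the
  PSF support triggers a warning (blobs may vanish after binarisation).
* **Soma/bouton images.** The soma mask is the N pixels nearest the image
  centre — an exact-area disk, so area fractions are exact pixel counts.
  Scattered mitochondria fill ten blobs grown from two staggered seed
  rings whose separation keeps the blobs disjoint up to fractions ≈ 0.5;
  clustered mitochondria grow from one perinuclear seed. Boutons are
  ~0.95 μm² disks (inside the 0.2–3 μm² detection bounds) on a dim shaft,
  jitter-spaced so components never merge; overcrowding is a parameter
  error.
* **Traces.** LFP = sinusoid + white Gaussian noise. PSCs are
  difference-of-exponentials transients normalised to stated peak
  amplitude, inward polarity; events closer than the rise time are flagged
  overlapping in the returned truth. Current-clamp sweeps follow an ideal
  RC membrane with piecewise-linear stereotyped spikes (5 V/s approach to
  threshold, 200 V/s upstroke) so a dV/dt criterion recovers the designed
  threshold. fEPSPs are negative alpha functions with 2-ms latency.
* **What is not emulated:** photon/shot noise statistics, PSF anisotropy,
  z-drift, bleaching, overlapping organelles, electrode drift, seizure-like
  events, real animal movement statistics. Passing tests therefore show
  the estimators are correct on data satisfying their stated assumptions,
  not that those assumptions hold for any particular microscope or rig.

## Morphometry

SWC world coordinates in μm; voxel indices 0-based; a voxel's position is
its center; shells are half-open [kΔ, (k+1)Δ); the Sholl/shell center is
the soma *root node* coordinate (the one well-defined point in an SWC).

* **Sholl crossings** are computed analytically per edge as roots of the
  quadratic ‖p(t)‖² − R² with a strict interior sign change; tangencies and
  nodes landing exactly on a sphere count zero, which is what a dense
  resampling of the edge converges to. An edge crossing a sphere twice
  contributes two. Nodes with more than two children count once as branch
  points (the object counted is the branch point, not the bifurcation).
* **Volume mask**: capsule union over edges with linearly interpolated
  radii, rasterised by stamping spheres at half-voxel steps; zero radii
  are clamped to voxel/2 so thin neurites stay connected. The mask can be
  rasterised onto the grid of an existing stack (`origin`/`shape`) for
  voxelwise AND with the mitochondrial channel.
* **MitoSholl** counts binarised voxels (not raw intensity): per-slice
  rolling-ball background subtraction, median filter (3×3 in-plane),
  global threshold, AND with the volume mask, shell binning. The default
  threshold is Otsu, with `isodata` (the closer analogue of the common
  "Default" auto-threshold) and fixed values as options.
* **Proximity**: per branch point, minimum distance to a positive voxel
  center, anisotropic voxel sizes respected, computed with a k-d tree and
  tested against an exhaustive all-pairs scan. Ties cannot change the
  minimum value; no positive voxels raises an undefined-distance error.
  Normalisation divides every group's distances by the reference group's
  mean, making the reference mean exactly 1.

## Image quantification

* Rolling-ball background subtraction wraps the standard restoration
  routine, clipped at zero; radii default to 50 px (mitochondrial
  channels) and 7 px (synaptic markers), per the source protocol.
* The interactive wand-tool soma selection is replaced by a deterministic
  analogue: threshold, then keep the connected component containing a seed
  point.
* **Cluster criterion** (not formalised in the source protocol): a soma is
  "clustered" when the largest connected mitochondrial component holds
  ≥ 50 % of the in-soma mitochondrial area. The dominance fraction is a
  parameter.
* **Puncta**: connected components of the thresholded image within
  0.2–3.0 μm² (typical PV bouton sizes; configurable). Merged blobs above
  the maximum are rejected rather than split.
* **Bouton mitochondrial content** (scored by eye in the source): a
  punctum contains mitochondria when its mean mito-channel intensity
  exceeds the shaft background mean + 2 SD, estimated over non-punctum
  pixels (or a supplied background mask).
* **Colocalization**: per channel rolling-ball(7) → 3×3 maximum filter →
  Otsu → label; a pre/post pair colocalises when overlap / min(areas) lies
  in [0.33, 1.0]; many-to-many candidates are reduced to one-to-one by
  greedy best-overlap assignment, so pair counts never exceed
  min(pre, post).

## Electrophysiology

* **Spectral estimator**: Welch with 2-s Hann segments and 50 % overlap
  (0.5 Hz resolution) rather than one long FFT — identical band metrics
  with stabler peak statistics; `single_fft=True` restores the plain
  periodogram. Normalisation: per-bin power sums to the signal variance
  (Parseval), a testable conservation law. Mains exclusion is a 49–51 Hz
  notch applied to band *statistics* (the bins are kept in the spectrum,
  flagged excluded).
* **50 % width**: four-parameter (amplitude, center, σ, baseline)
  least-squares Gaussian fit to the in-band power; FWHM = 2√(2 ln 2)·σ
  ≈ 2.355 σ, reported in Hz. Non-convergence or a non-physical optimum
  raises `FitError`; no default number is substituted.
* **sPSC detection**: zero-phase 4th-order Butterworth low-pass at 1 kHz,
  median baseline subtraction, peak finding above the 3 pA initial
  threshold. Events on the decay shoulder of a predecessor are measured by
  prominence (rise from the inter-event valley); isolated events by height
  above a 5-ms pre-event median baseline. Noise SD = 1.4826·MAD of the
  filtered trace with supra-threshold regions masked; events below
  5×SD are excluded. Note the SD refers to the *filtered* trace — white
  generator noise of SD s leaves ≈ 0.45 s after a 1-kHz filter at 10 kHz
  sampling.
* **Train recovery**: probe response amplitude normalised to the first
  train peak, per train, averaged across trains (default 10); trains with
  an undetectable first peak (< 3 pA) are excluded with a warning.
* **Intrinsic properties**: Rin from the slope of steady-state ΔV–ΔI over
  hyperpolarising steps; τm from a single-exponential fit of the largest
  hyperpolarising onset; spike threshold at dV/dt ≥ 20 V/s (configurable;
  the criterion is not stated in the source protocol); AP amplitude
  threshold→peak; half-width at half that height; rheobase = smallest step
  with ≥ 1 spike; rate read from the sweep nearest rheobase + 40 pA.
* **fEPSP slope**: artifact blanked 2 ms, extremum located within 50 ms, a
  line fitted over the 20–80 % span of the initial phase, in mV/ms
  (native scale; no arbitrary-unit normalisation is attempted).
  Deflections below 0.02 mV return (0, invalid).

## Behavior

Zone membership is point-in-polygon with the boundary counted inside, so
frames at arm junctions are never lost; occupancies may sum below 100 %
when the animal is outside every zone. The built-in EPM template has four
30×5 cm arms around a 5×5 cm center square (the center size is not given
in the source protocol and is a template parameter), the open-field
template a configurable center fraction. The rotarod formula is evaluated
exactly and pinned to the start/end speeds at 0 and 300 s. T-maze NO-GO
trials are dropped from the choice sequence and more than 3 of them flags
the animal excluded; fewer than two valid choices leaves the score
undefined (None), not zero.

## Pipeline

`run_pipeline(RunConfig)` executes every stage on synthetic inputs with a
single seed, writes per-module CSVs and a JSON report echoing every
effective parameter (schema-checked before any computation; unknown keys
are errors). Group-level hypothesis testing is deliberately left to
standard statistical routines; a transparent IQR-fence outlier *flagger*
(`iqr_fence_outliers`) is provided instead of regression-based outlier
removal, and it only flags — nothing is dropped silently.

## Problem sizes

Tests and the acceptance script use desk-scale inputs chosen to exercise
every code path with comfortable margins: 100-track movies, reconstructions
with ≤ 10 branch points per compartment, stacks of ~10⁵–10⁶ voxels,
300-s LFP at 5 kHz, 5–60 s voltage-clamp traces at 10 kHz, and 1000-frame
trajectories.

## Known limitations

* The MitoSholl profile counts voxels, not intensity mass; sub-voxel
  mitochondria near shell boundaries bin by their voxel center.
* PSC amplitudes for strongly overlapping events (closer than the rise
  time) are prominence-based lower bounds; the generator flags such events
  in its truth so tests can treat them separately.
* The proximity estimator measures to the nearest *binarised voxel*, which
  sits up to one blob radius closer than the true mitochondrial center;
  group normalisation cancels this bias when blob sizes are comparable
  across groups.
* The wand-tool, visual bouton scoring and interactive event curation of
  the original workflow are replaced by the deterministic criteria above;
  agreement with a human scorer on real images is untested here.
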