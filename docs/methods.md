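# Methods

## Signal model

A reconstructed complex OCT B-scan is treated as a band-pass signal in
depth: a scatterer at optical path length (OPL) `z` contributes a Gaussian
amplitude envelope centred at `z` carrying the double-pass interferometric
phase `4πz/λc`. Along the sampled depth axis the field therefore oscillates
at a carrier of `2·pitch/λc` cycles/pixel (negative sign in our convention:
content moving deeper gains phase). At the default pitch (1.05 µm in air,
i.e. 1.07 mm image depth over 1024 pixels) and λc = 840 nm this carrier is
2.5 cycles/px — aliased exactly to the Nyquist frequency. Two consequences
run through the whole package:

* **Shifts must unalias the carrier.** All sub-pixel translations (both the
  simulator's layer kinetics and the motion correction) apply linear phase
  ramps at the *true* axial frequencies, reconstructed from the known
  carrier by congruence. This is what makes the correction phase-restoring:
  a corrected reflector recovers both its envelope position and its phase
  (verified to < 10 mrad for sub-pixel moves).
* **Derived quantities must respect the alias.** Cross-correlation for
  shift estimation runs on carrier-demodulated complex frames (the
  upsampled correlation magnitude is otherwise ill-conditioned at the band
  wrap), and the complex mean over reference-layer rows is demodulated
  before averaging (adjacent rows are otherwise π out of phase and cancel).

Shift estimation itself is the standard single-step upsampled-DFT
cross-correlation (scikit-image, plain — unnormalized — correlation),
refined on a 1/100-px grid around the coarse peak, with an optional 5%
raised-cosine taper against wrap-around on non-circular data.

## Synthetic data: what it emulates

The generator freezes one speckle realisation per layer (circular-complex
scatterer fields convolved with the complex system PSF) and displaces each
slab sub-pixel over time, so the stimulus-evoked signal lives purely in
phase, as in real repeated B-scans. It reproduces:

* a layered outer retina — ELM, IS/OS, dim OS interior, OS tips, a dim
  interdigitation zone, a thin RPE monolayer, BrM — with fully developed
  speckle (unit intensity contrast, verified against Rayleigh statistics);
* stimulus-locked kinetics anchored at BrM: a fast OS elongation (gamma
  pulse peaking at 0.5 s with a slow undershoot peaking near 10 s and
  recovery by 30 s), a slow RPE-referenced rise, a delayed (1.5 s) SRS
  expansion rising at ~15 nm/s to ~250 nm around 20 s, a ~10 nm transient
  inner-segment compression, and a ~20 nm RPE contraction peaking near 3 s.
  Layer displacements are assembled so the pairwise distances equal these
  programmed signals exactly, which makes the SRS telescoping identity
  (SRS = Type-II + IS/OS-rel-ELM) exact on ground truth;
* rigid in-plane bulk motion: a slow drift (default 1.5 px over the
  recording) plus heartbeat (5 Hz, 0.3 px) and respiration (1 Hz, 0.2 px)
  oscillations — rat-physiology stand-ins, configurable because only the
  artifact sources, not their frequencies, are fixed by the acquisition
  context;
* SNR-dependent phase noise via additive circular-complex noise against
  per-layer linear amplitude SNRs (IS/OS 60, OS tips 45, BrM 45, RPE 35,
  ELM 30, OS interior 6). These defaults put the bright bands comfortably
  inside the 60 mrad pre-stimulus QC threshold and the dim interior outside
  it, matching the regime in which QC exclusions are a minority confined to
  low-SNR pixels;
* the three acquisition protocols: 200 B-scans/s × 5 s, 25 B-scans/s
  (prolonged), and 8 volumes/s × 5 s with 25 B-scans/volume (40 volumes),
  with 1 s (or configurable) pre-stimulus baseline.

Labelled phase traces for the classifier are generated directly from the
kinetics templates: Type-I and Type-II curves, intermediate traces as convex
mixtures `α·TypeI + (1−α)·TypeII` with `α ∈ [0.35, 0.65]` (the transition
band), and outliers as post-stimulus shape-shuffled copies. Shuffling is
done in 0.25 s blocks: a per-sample shuffle makes every outlier a
white-noise-like trace whose PCA scores collapse into one ultra-dense blob
near the origin, whereas block shuffling keeps low-frequency content so each
permutation projects to a different, peripheral feature-space point —
outliers are supposed to populate low-density regions. Trace depths draw
from two Gaussians (σ = 1 px) centred 7 px (Type-I) and 2 px (Type-II)
anterior of BrM — a 5 px separation mirroring the distinct depth histograms
of the two signal types; outlier depths are uniform.

What the simulator does **not** emulate: out-of-plane drift, non-rigid or
depth-dependent motion, vessel shadows and pulsatile choroid, absorption
and roll-off, speckle decorrelation from flow, inter-subject variability,
and photoreceptor disc ultrastructure. Passing tests therefore demonstrate
the correctness of the algorithms under the stated signal model, not
robustness to every in-vivo artifact.

## Analysis pipeline choices

* **Registration reference** = the highest-mean-intensity frame among the
  first ten (the choice is not fixed by the method; config knob).
* **Segmentation** finds each boundary as the minimum-cost lateral path
  with node cost `2 − normalized dark-to-light gradient + ε` and a 2 px
  step limit, sequentially (BrM as the most posterior prominent band of the
  lateral-mean profile, then IS/OS as the brightest band sufficiently
  anterior — near-ties resolved posteriorly — then ELM), each search
  restricted by the previous boundary. Boundaries are the anterior slab
  edges, where the dark-to-light transition is unbiased under a symmetric
  PSF. The mixed IS/OS→BrM layer splits into 5 equal-depth sub-bands by
  default (largest-remainder rule); the count is configuration.
* **Self-referencing**: target-pixel phase against the demodulated complex
  mean of the reference band (boundary row ± 1). Pixels within ~3.5 axial
  PSF sigmas (4 px) of the reference are excluded from the classification
  band: they share the reference's speckle, so their self-referenced phase
  is biased toward zero, and they otherwise seed a spurious anterior
  cluster that breaks depth-ordered cluster naming.
* **Filtering**: zero-phase (forward-backward) Butterworth. Band-stops are
  narrow notches (±0.05 Hz around 1 Hz and 5 Hz by default): the 0.5 s OS
  pulse loses ~17% of its peak through a ±0.2 Hz notch at 1 Hz but only ~4%
  through ±0.05 Hz. The 10 Hz low-pass is order 4 (≥ 20 dB at 15 Hz after
  the double pass) and is applied exclusively on the classification branch;
  reported signals see band-stops only. 0.2 s is trimmed from each end
  where filtfilt edge transients concentrate.
* **QC**: traces with pre-stimulus SD > 60 mrad are excluded — strictly, so
  exactly 60 mrad is retained.
* **Feature space**: window −1.0…+3.5 s, 5 ms grid (low-rate traces
  linearly interpolated and Gaussian-smoothed with σ = half the native
  interval); per-trace standardization; top-2 PCA (on the default synthetic
  population they capture ~72% of variance); min-max axis normalization
  with constants persisted in the model bundle — new points may leave
  [0, 1] and are flaggable. Outlier rule: k = ⌈0.02·(N−1)⌉-th-neighbour
  radius, linear-interpolation quartiles, fence `Q3 + (Q3−Q1)/5`; both the
  k rounding and quartile convention are configuration since several
  conventions exist. Note the fence is tight: on a homogeneous random
  cloud it legitimately flags roughly the top decile of radii; it is
  designed for clustered data where radii are strongly right-skewed.
* **Clustering and naming**: Ward linkage cut by cluster count (3) — Ward's
  merge heights are monotone, so a count cut equals a dendrogram threshold,
  and a fixed count is reproducible where a figure-specific height is not.
  The deepest cluster (smallest distance-to-BrM) is Type-II, the most
  anterior Type-I, the middle intermediate; depth ties break by cluster-mean
  peak latency, and a latency-order violation emits a warning.
* **SVM**: standardized features, Gaussian kernel, hyperparameters chosen
  by 10-fold stratified cross-validated grid search over
  C ∈ {1, 10, 100} × γ ∈ {scale, 1, 3, 10}; the fold assignment seed is
  recorded in the model bundle. On the default synthetic population the
  10-fold CV accuracy is ~98%. It sits below the ~99% reachable on in-vivo
  feature clouds for a structural reason: with equal class sizes a quarter
  of all traces are shape-shuffled outliers, so the density-rule decision
  surface threads regions whose point density matches the point spacing,
  and points whose coverage radius lies within a few percent of the
  quartile fence are irreducibly ambiguous to any held-out classifier
  (k-NN and boosted trees plateau at the same level).
* **Quantification**: peak metrics search a post-onset window (peaks below
  3× the pre-stimulus noise are flagged low-confidence); the SRS slope is a
  least-squares line over 2–10 s post-onset (the expansion begins ~1.5 s
  after the stimulus); expansion-rate curves use a Savitzky–Golay first
  derivative (0.25 s window, order 2 by default); depth distributions are
  Gaussian-fitted per subject and compared by a paired two-tailed t-test
  gated by Shapiro–Wilk, with identical pairs reported as a degenerate,
  non-significant comparison. En-face maps average classified traces per
  1.2° × 0.48° cell over a 12° field (10 × 25 grid); empty or under-QC'd
  cells are flagged. Physical deformation = ΔOPL / 1.41 is reported only
  where requested. The bleach model `F = 1 − exp(−Φ·t·P)` neglects pigment
  regeneration; `P = 1.26 × 10⁻⁸ µm²` (in-situ rhodopsin photosensitivity)
  is a named constant, and `Φ = power·λ/(hc)/area` with the 6.75 mm²
  Maxwellian illumination area as default.

## Problem sizes

Tests and the benchmark script run on scaled-down geometries chosen as the
package's own defaults for desk validation: 160 × 64 px B-scans (64 px
volumes at 96 px depth with an 8 µm synthetic lateral pitch, coarser than
the instrument's so a cell holds a workable number of speckles), 25 Hz × 30 s
prolonged series, and 2000-trace classification runs. All pipeline
parameters are resolution-independent (the carrier, PSF widths and windows
derive from the optics/protocol records), so the same code runs unchanged on
full-size 1000-A-scan recordings.

## Known limitations

* Rigid in-plane motion only; out-of-plane drift is unmodelled and
  uncorrected.
* The mixed-layer OS amplitude is biased low by ~10% through PSF cross-talk
  with neighbouring static/slow bands (plus ~4% notch loss) — inherent to
  NIR-resolution speckle mixing rather than to the estimator; the
  SRS/Type-II quantities are unbiased within ~1%.
* Cluster naming assumes the three-cluster depth ordering; populations
  without a genuine transition band can split one physical cluster instead
  (the latency warning flags this).
* Temporal unwrapping assumes |Δφ| < π between frames; faster dynamics
  require a higher frame rate.
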