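# Methods

## Data model and units

All positions are in micrometres and times in minutes. A *track* is one
cell's time-ordered 3D trajectory; the frame interval defaults to 3.0 min
(so an 8-point window spans 21 min) and is configurable, since acquisition
intervals vary between experiments. The anatomical axis convention is
likewise configuration: by default column `x` is medial-lateral, `y`
anterior-posterior, `z` dorsal-ventral. Readers of TrackMate/Imaris exports
remap their column names on ingest; units are converted before ingest, never
inside the package.

Sliding windows cover only gap-free runs of consecutive frames — no
interpolation across tracking gaps, because interpolated positions would
fabricate motion statistics. Tracks shorter than the window length are
skipped with a logged count.

## Window features

Each window yields the pairwise-displacement matrix `D[i,j] = ‖x_i − x_j‖`
and four scalars: net displacement, path length, speed (path length per
elapsed minute) and straightness (displacement / path length, defined as 0
for a stationary window). Displacement is the default segmentation feature;
speed + straightness are selectable. The matrix, not the scalars, feeds the
embedding: it retains the within-window temporal structure (sub-window
accelerations, loops) that a single summary number discards.

## VAE pseudotime

The generative model assumes windows arise from a single latent degree of
freedom `z ~ N(0,1)` with Gaussian decoder `P(D|z)` and amortized Gaussian
posterior `q(z|D)`; training maximizes the ELBO (reconstruction minus KL).
Implementation choices:

- **Networks.** Dense encoder 64 → 32 (tanh) → (μ_φ, log σ²_φ) and mirrored
  decoder 1 → 32 (tanh) → per-entry (μ_θ, log σ²_θ), written directly in
  numpy with analytic gradients and a hand-rolled Adam. At 8×8 inputs this
  capacity is ample, and a pure-numpy training loop is bit-reproducible
  from a single seed across platforms and thread counts.
- **Decoder variance** is per-entry (`σ²_θ : R → R^{8×8}`) and floored at
  1e-6 so exactly-reconstructable entries cannot blow up the likelihood.
- **Normalization.** Matrix entries are standardized by the training set's
  global mean/SD; the constants are stored with the model and the
  pseudotime sequence so queries are normalized identically.
- **Optimization.** Adam, lr 1e-3, batch 256 (clamped down for small
  datasets), at most 500 epochs, one reparametrized sample per datum per
  step, 10% validation split, early stopping with patience 30; the
  best-validation parameters are kept. Training requires ≥ 32 matrices.
- **Pseudotime** is the rank of the posterior mean μ_φ(D) (not a sample),
  with ties broken by (track id, start frame) so runs are deterministic.
  The latent axis has an arbitrary sign, so when per-window displacements
  are available the axis is oriented to make displacement decrease with
  rank — rank 0 is always the fast (DM-like) end.
- **Reference mapping.** New windows receive the pseudotime of their
  nearest reference window by Frobenius distance on the raw matrices (ties
  to the lowest reference rank). The distance metric is isolated behind a
  single function should a derived-space metric ever be preferable.

## Change-point segmentation

Items ordered by rank are discretized into 30 equal-count bins (the first
`n mod 30` bins take the extra items); per-bin count, vector sum and
sum-of-squared-norms are exact sufficient statistics, so any segment's SSE
is `sumsq − ‖sum‖²/count`. Break points live on bin boundaries; segment k
covers bins `(b_{k−1}, b_k]` (half-open, guaranteeing a partition). The
dynamic program is O(K·n_bins²) and returns the exact global minimizer —
a deterministic optimum was preferred over posterior sampling because the
objective is a deterministic minimum; an exhaustive-enumeration oracle with
the same contract guards it in the tests.

**Elbow selection.** The optimal error for K = 0..K_max (default 8 for
motion, 10 for expression) is min-max normalized on both axes and K is
chosen at the maximum perpendicular distance to the chord joining the
endpoints; ties go to the smallest K, and the curve must be non-increasing
within 1e-9 relative tolerance (a violation signals a broken optimizer).
Two caveats:

- A *flatness guard*: if the whole curve drops by less than 5% of the K=0
  error, the data carry no segmentation signal and K = 0 is returned.
  Without it, min-max normalization amplifies a nearly flat noise curve and
  the elbow hallucinates a change point in structureless data.
- A known limitation: when the feature varies *smoothly* along pseudotime
  (a continuum rather than discrete states), the error curve decays
  gradually and the elbow will still report a small number of change
  points — it cannot distinguish "no discrete states" from "a few states"
  on sorted continuous data. Interpreting the selected K as discrete states
  presupposes plateau-like structure; the abundance and ROI statistics
  downstream are robust to this because they only use relative labels.

## State calling and downstream statistics

The motion pipeline is windows → distance matrices → VAE ranks → z-scored
features (pooled across the embryos being segmented together by default;
per-embryo standardization is available for individual-embryo analyses) →
binned segmentation → labels joined back to window start positions. Labels
are renumbered by descending segment mean displacement (idempotent), so
state 0 is always the highest-displacement state; when exactly three states
are found the middle one is the PZ type, and for any other K states are
referenced by index only.

ROI membership uses the window's start position only, inside a closed
axis-aligned box. Signed medial-lateral displacement is
`|start − midline| − |end − midline|` per window — positive toward the
midline on either side, which makes left/right series directly comparable
and mirror-symmetric by construction. Frames with no member windows are
absent from the series, never reported as zero. ROI boxes are user-supplied
geometry (a helper derives defaults from the anterior-most 125 μm of
PSM-labeled windows per side); whether to use full-window or per-frame
displacement was open — full-window was chosen to match the windowed data
model.

## In situ quantification

Profiles run posterior (tail tip, index 0) → anterior; ingest reverses
arrays as needed. The PZ/PSM boundary is the *first* point strictly above
20% of the profile maximum, the anterior PSM end the *last* point strictly
above 85%; both thresholds are relative to the maximum, so the rules are
invariant to intensity rescaling. Scaled PZ length = boundary index /
anterior-end index. Defaults that the pipeline fixes but the original
procedure leaves open, all configurable: Gaussian smoothing σ = 2 px,
Savitzky-Golay axis window 21 / order 3, sliding-window profile width
10 px, per-side normalization by the post-smoothing maximum. For bent
axes, masked pixels are projected to their closest point on the smoothed
axis polyline (ties to the earlier arc-length position); region membership
by projected arc length is equivalent to dropping perpendiculars for a
straight axis and well behaved for curved ones. Channel-bleed subtraction
and adaxial-cell removal are upstream manual preprocessing and are assumed
done; midlines of bent embryos are user-supplied geometry.

## Synthetic data

The generators plant known structure so every stage is testable without
microscopy data; they are pure functions of (config, seed).

- **Tracks**: correlated random walks,
  `dir_t = normalize(p·dir_{t−1} + (1−p)·u)` with `u` a random unit vector
  and step lengths `N(μ, σ)` clipped at zero. The three default regimes use
  step means 5 : 2.5 : 1 μm/frame with persistence 0.8 / 0.6 / 0.2
  (window-scale straightness ≈ 0.98 / 0.84 / 0.40), 150 tracks per regime
  and 10 frames per track (≈ 1350 windows). The persistence values were
  chosen so the three regimes' net window displacements sit on distinct
  high/intermediate/low plateaus — an ordered fast regime, a slower but
  still processive disordered regime, and a confined slow regime — the
  structure the motion-state analysis is designed to resolve. There are no
  cell-cell interactions: collective effects in real tissue are an observed
  phenomenon, not part of this minimal model, so passing tests demonstrate
  correct state recovery on independently moving cells only. An optional
  spatial layout places regimes in boxes (e.g. left/right PSM) for
  end-to-end ROI exercises.
- **Expression**: six states by default, each expressing its own marker at
  amplitude 3 in a 6-dimensional feature space with unit isotropic noise
  (adjacent-state separation ≈ 3× noise SD), 600 cells in contiguous
  blocks along the planted ordering. Real single-cell data add dropout,
  correlated noise and imperfect orderings that this generator does not
  model.
- **Profiles**: rise → plateau → decay shapes with truncated Gaussian
  noise, returning the analytic 20%/85% crossings of the noiseless curve
  for comparison.
- **Speed gradient**: 400 single-window tracks with step means interpolated
  linearly over 1–5 μm/frame, for testing that the learned latent recovers
  a motion *continuum* and not only discrete regimes.

## Numerical and degenerate-input conventions

Zero-variance features are a hard error (they cannot be z-scored and
signal degenerate input). Duplicate (track, frame) rows, non-numeric
coordinates and missing columns fail fast with row-level messages. Empty
window sets, empty references, constant images and all-zero profiles raise
rather than returning sentinel values. DP ties break to the earliest break
point, elbow ties to the smallest K, nearest-reference ties to the lowest
rank, pixel-projection ties to the earlier arc-length position — every tie
rule is deterministic and tested.

## Problem sizes

Default test and reproduction runs use ~1350 windows for the three-regime
pipeline, 400 windows for the gradient check, 600 cells for expression and
100 random instances for the optimizer-exactness sweep — sizes at which the
full suite completes in well under a minute while keeping every planted
effect comfortably detectable at the stated noise levels.
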