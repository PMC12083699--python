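# Methods

## The mechanistic model

`pottsnet.cpm` implements a two-dimensional Cellular-Potts (Glazier–Graner–
Hogeweg) model of vasculogenesis on a periodic square lattice.  Each cell is
the set of lattice sites holding its index; index 0 is medium.  The effective
energy is

    H = Σ_neighbor-pairs J(τ(σi), τ(σj)) · [σi ≠ σj]
      + Σ_cells λ_vol (V − V_t)²  +  Σ_cells λ_surf (s·S − S_t)²

with a per-copy chemotaxis bias (below).  Dynamics are Metropolis pixel
copies: a uniform random site y and a uniform random neighbor y′ are drawn;
σ(y) overwrites σ(y′) with probability exp(−max(0, ΔH)/H′).  One Monte-Carlo
step (MCS) is `lattice_size²` attempts followed by the chemical-field update
for one time unit.  The default constants are λ_vol = 5, V_t = 50 px,
λ_surf = 1, S_t = 16.8, J_cell,medium = 8.2, J_cell,cell = 6,
λ_chem = 2000, saturation s_sat = 0.5, decay k = 0.6 /MCS, H′ = 8.

Conventions the model definition leaves open, and what this package does:

- **Neighborhood.** Copy-attempt pairs and the contact sum use the
  8-neighborhood (2nd order); this is the common CPM-framework default.
  A 4-neighborhood variant exists behind `neighbor_order=1` but produces a
  speckled, fragmented morphology at these energies.
- **Surface estimator.** A cell's surface S is its count of heterotypic
  (site, neighbor) contacts under the 4-neighborhood.  Because the minimal
  4-neighbor boundary of a 50-pixel cell is 30 contacts while S_t = 16.8,
  the raw count is multiplied by `surface_scale = 0.56` inside the energy so
  a compact cell sits near its target instead of being permanently
  penalized.  Both the estimator's neighbor order and the scale are config
  entries.
- **Chemotaxis.** The saturating bias
  −λ_chem·[c(y′)/(s_sat·c(y′)+1) − c(y)/(s_sat·c(y)+1)] is added to ΔH when
  the *invading* index (the copy source) is a cell: an extending cell is
  pulled up-gradient.  Applying the same term to medium-source copies would
  equally reward medium invading high-concentration sites and dissolve the
  aggregates, so retraction carries no chemotaxis term.  Because the bias
  compares source and destination of a move, it exists only for copies and
  is not part of the static energy returned by `total_energy`; the
  incremental `delta_h` is tested against a global-recompute oracle plus
  exactly this term.

## The chemical field

The attractant obeys ∂c/∂t = D∇²c − k·c + a·1[cell], solved by forward
Euler with the periodic 5-point Laplacian in `pde_substeps_per_mcs`
substeps per MCS (dt = 1/substeps).  The enforced step bound is the
positivity-preserving dt ≤ 1/(4D + k): the weaker von Neumann bound
2/(8D + k) is marginal for the pure-diffusion checkerboard mode, and the
decay term pushes that mode unstable, at which point clipping negative
concentrations to zero would silently inject mass.  Inside the bound the
scheme never produces negatives, so the clip is a pure safeguard and the
k = 0 field is exactly conservative.

**Free constants.**  D and the secretion rate are not part of the published
parameter set.  The defaults are D = 3 px²/MCS and secretion = k = 0.6, i.e.
a decay length √(D/k) ≈ 2.2 px (a thin halo around the vessel surface) and a
steady-state plateau concentration secretion/k = 1.0.  The halo regime was
chosen by qualitative piloting: it reproduces the three canonical behaviors
(sprouting, sprout extension and anastomosis subdividing large lacunae,
contraction of small lacunae) and, critically, keeps the network morphology
fine-grained and slowly coarsening over the full 20,000-MCS data-generation
horizon (~78 lacunae at MCS 2000, ~53 at MCS 10,000 at full scale).  Longer
decay lengths of one to two cell diameters (D ≈ 30–120) make the long-range
aggregation so effective that the pattern collapses into a handful of large
aggregates within a few thousand MCS, which contradicts the phenomenology
the data-generation protocol requires.

**A caveat on drift magnitudes.**  At 76% vessel coverage (1000 cells × 50
px on 256²), two *uncorrelated* masks already overlap with Dice ≈ 0.76, so
the published single-step reference Dice of 0.77 implies an almost complete
decorrelation of the mask every 100 MCS.  Under the printed energy scales
this implementation's interfaces are far stiffer: across every convention
and free-constant combination piloted (both neighbor orders, surface
conventions, D spanning 0.1–100 px²/MCS, secretion amplitude over 2.5
decades), the 100-MCS Dice stays ≈ 0.97–1.00.  The remodeling magnitude
evidently depends on implementation details of the original simulation
environment that the model description does not pin down; the baseline-drift
quantities this package reports are its own measured values, not a
reproduction of the published ones, and the acceptance machinery reports
them as computed.

## Initialization

~1000 cells are seeded at uniform-random torus positions as non-overlapping
square patches and inflate to V_t under the volume constraint within a few
MCS.  Patches are ~V_t/2 pixels (5×5): at 76% final coverage, full-size
7×7 patches cannot be placed by random sequential adsorption (aligned-square
RSA jams near 56% coverage), while half-size seeds keep initial coverage at
~38% and preserve genuinely random placement.  Placement, attempt selection
and acceptance all draw from a single seeded generator, so trajectories are
bit-reproducible given (seed, parameters).

## Encoding and datasets

A frame is encoded as two channels: the binary cell mask (lossless) and the
field divided by a *fixed global* `norm_scale` and clipped to [0, 1].  The
default scale 1.0 equals the secretion/decay plateau, the largest value the
default field approaches, so clipping is confined to the deep-vessel
plateau.  A fixed scale (never per-frame min-max) keeps squared errors
comparable across frames and simulations.  Pairs link the frame at t to the
frame at t+100 MCS within one simulation and are stored as index views over
the trajectory store.  The 80/20 split defaults to pair granularity;
simulation granularity is the leakage-safe alternative and is what the
desk-scale experiment uses (whole simulations held out).

## The surrogate

A U-Net (`pottsnet.surrogate`) maps the 2-channel state at t to the state at
t+100.  All convolutions are circular, so the torus topology holds
everywhere and the network is exactly shift-equivariant for shifts that are
multiples of the total pooling stride 2^depth (pooling breaks equivariance
for finer shifts).  Blocks are conv–BN–PReLU ×2; downsampling is 2×2 mean
pooling, upsampling periodic factor-2 bilinear, skip connections by
concatenation; both output heads are sigmoids.  The loss is
BCE(cell) + 10·MSE(field).  Defaults: depth 4, base 64 channels, 3×3
kernels, Adam at 1e-3, batch 16, 100 epochs, threshold 0.5 — the published
description fixes the ingredients but not these hyperparameters, so all are
config entries.  Rollout feeds the *binarized* mask (threshold 0.5) and the
predicted field back as the next input, matching the binary training
targets.

The network and its training loop are implemented directly on NumPy (BLAS
matmuls for the im2col convolutions, `np.roll` for the periodic index
arithmetic, hand-derived backward passes, Adam).  The backward pass of every
layer is verified against central finite differences in the test suite, and
the periodic upsampler against an adjointness identity.

## Metrics

- **Dice** 2|A∩B|/(|A|+|B|); two empty masks score 1 (perfect agreement).
- **Field MSE** over all sites of the normalized channel.
- **Lacunae areas**: medium regions are labeled with 4-connectivity
  (complementary to the 8-connected cells).  The default method labels the
  plain mask and merges labels across the two periodic seams with a
  union-find, which is exact for every mask including period-spanning
  regions.  An alternative `method="tiled"` reproduces the image-space
  recipe — 3×3 tiling, labeling, inertia-tensor-eigenvalue de-duplication
  (area exact, sorted eigenvalues within rtol 1e-6) — with two corrections
  that make it agree with the exact method: partial copies cut by the canvas
  edge are discarded (unless the region spans a full period in that axis),
  and areas are counted on wrapped-unique coordinates.  Areas < 3 px are
  dropped as stochastic specks.  Both methods are tested against an
  independent flood-fill oracle.
- **EMD**: Wasserstein-1 between the raw area multisets (equal-weight
  empirical distributions).  If exactly one distribution is empty the value
  is recorded as missing and excluded pairwise from aggregates; both empty
  is an error.

## Evaluation protocol

`evaluate_rollout` freezes a reference frame (default MCS 2000), rolls the
surrogate for n iterations, and at iteration i scores both the prediction
and the unchanged reference against the true trajectory at
reference+100·i — the frozen reference being the "do nothing" baseline a
useful surrogate must beat.  Replicate series aggregate to per-iteration
mean/s.d. with the replicate count n as an explicit parameter (the source
protocol quotes both 20 and 25 evaluation simulations; the harness reports
whichever is used).  A timing harness compares wall-clock medians of a
100-MCS simulator advance against one surrogate evaluation; its numbers are
informational only.

## Problem sizes used by the shipped experiments

- Baseline drift (tests and `scripts/acceptance.py`): full scale — 256²,
  1000 cells, 5 replicates to MCS 2100 (the published evaluation averages
  25 replicates; 5 keeps the recomputation fast while the replicate s.d. of
  the three drift metrics stays small).
- Desk-scale end-to-end (tests): 64² lattice, 60 cells (the same area
  density), 4 training simulations plus one held-out simulation to MCS
  3000, frames recorded every 25 MCS, pairs at stride 50, U-Net depth 3 /
  base 16 trained 20 epochs.  The test asserts that single-step Dice of the
  trained surrogate beats the frozen reference on the held-out simulation
  and that rollout Dice decays with iteration.

## Known limitations

- The NumPy training loop is CPU-bound; full-scale training (20 × 19,700
  pairs, 256², 100 epochs) is out of desk reach and is not attempted by the
  shipped experiments.
- The drift-magnitude caveat above: the mechanistic model reproduces the
  qualitative network phenomenology but not the published per-100-MCS
  decorrelation rate, and the package makes no attempt to force it by
  unphysical parameter choices.
- Single cell type, 2-D lattice only, no growth or division; the surrogate
  is deterministic and cannot represent the stochasticity of the simulator
  it approximates (its predictions are smoother than real states, and
  recursive error compounds).
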