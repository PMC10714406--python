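# Methods

This note documents the models implemented in `dectunroll`, the numerical
choices behind them, and what the synthetic experiments do and do not show.

## Forward model and units

Attenuation follows the two-material basis vector model
μ(x,E) = μ₁(E)c₁(x) + μ₂(E)c₂(x) with basis 1 a 23% (by weight) aqueous
CaCl₂ solution and basis 2 polystyrene.  All LACs are in mm⁻¹, lengths in
mm, energies in keV.  The energy grid defaults to 20–150 keV in 1 keV bins
with hard cutoffs; spectra are stored as mean counts per bin (already
bin-width weighted).  The mean measurement for spectrum j ∈ {L, H} is

    g_j(y) = Σ_E I₀ⱼ(E) exp(−Σ_i μ_i(E) ℓ_i(y)) + ξ_j(y),

with ℓ_i = H c_i the component line integrals and ξ an additive scatter
floor that defaults to zero (the field exists so simulation studies can
inject a constant or smooth floor; no physical scatter model is claimed).

### Attenuation data

Element mass attenuation coefficients (H, C, N, O, Al, P, Cl, K, Ca) are an
approximate compilation of standard photon cross-section tables at 10
reference energies (15–200 keV), combined by the mixture rule and log-log
interpolated.  Accuracy is at the few-percent level, which suffices for
simulation: every quantitative test compares reconstructions against the
same tables that generated the data.  Compound tables (water, the basis
materials, acrylic, three alcohols, K₂HPO₄ solutions at 50–250 mg/ml) are
bundled as two-column CSVs under `dectunroll/data/`.

### Spectra

Vendor spectra being proprietary, the 90/140 kVp pair is synthesized with
Kramers' rule times an aluminium filter factor, cut off at the tube
voltage.  The default filtration is differential — 2 mm Al on the low-kVp
beam, 8 mm on the high — emulating clinical dual-kVp practice.  This
matters: with equal filtration the two fluence-weighted basis-attenuation
vectors are 0.998-correlated and the basis-separation mode of any
alternating scheme stalls; the differential pair keeps the effective
energies (≈42 and ≈66 keV) usefully apart.

## The statistical reconstructor (DEAM)

Minimizing the I-divergence I(d‖g(c)) by alternating minimization of a
separable surrogate gives the per-voxel, per-component update

    c_i(x) ← c_i(x) − (1/Z_i(x)) log( b̃_i(x) / b̂_i(x) ),

where q_j(y,E) is the modeled energy-resolved sinogram,
p_j(y,E) = q_j(y,E) d_j(y)/Σ_E' q_j(y,E') redistributes the measured counts
over energy (so Σ_E p = d exactly), and b̂/b̃ are the μ_i-weighted
backprojections of q/p summed over spectra and energies.  Consistent data
(p = q) are a fixed point by construction.

### Step normalizer Z

Two rules are provided, both of the form
Z_i(x) = m_i (Σ_i' m_i') · max_{y: h(x,y)>0} Σ_x' h(x',y):

* `classic`: m_i = max_E μ_i(E).  Dominated by the low-energy photoelectric
  tail, which carries almost no fluence; steps are very conservative.
* `spectral` (default): m_i is 3× the larger of the two fluence-weighted
  mean attenuations Σ_E ψ_j(E) μ_i(E).  Weighting by where the photons are
  matches the effective curvature of the objective.

Neither rule is a closed-form majorizer over the whole energy grid (the
worst-case convexity bound would force steps ~100× smaller than either rule
and is uselessly slow); their validity is established empirically by the
objective-descent suite: the full-data objective is non-increasing on every
tested phantom, noisy or noiseless, and a descent test over 50 iterations
on five seeded phantoms is part of the acceptance tests.  The factor 3 in
the spectral rule is the smallest integer-ish margin that kept every
monotonicity run descending in a scan (a factor of 2 diverges); an optional
backtracking safeguard (halve the step while the objective increases, ≤5
halvings, single-subset loops) covers edge cases.  Voxels touched by no ray
get Z = +∞ and are frozen.

### Ordered subsets, momentum, penalty

Views are split into interleaved subsets visited in bit-reversed order
(balanced angular coverage, reproducible).  `n_subsets = 1` reproduces the
plain algorithm bit-for-bit.  With `momentum=True` the iterate is
Nesterov-extrapolated once per full iteration with adaptive restart on
objective increase — the standard ordered-subsets + momentum acceleration
for tomographic reconstruction.  Momentum is off by default (the plain
loop keeps guaranteed monotone descent); the desk-scale recovery protocol
(200 iterations × 30 subsets, momentum on) reaches well below 1% masked
60 keV VMI error from a zero start on the noiseless insert phantom.

The optional penalty is Σ_x Σ_i Σ_{x'∈N(x)} w ψ(c_i(x) − c_i(x')) with the
Huber-like potential ψ(t) = δ²(|t|/δ − ln(1+|t|/δ)), inverse-distance
weights normalized over the 8- (thin-z) or 26-neighborhood, δ in component
units (default 0.01) and a global strength.  The penalized update minimizes
the per-voxel 1D surrogate (b̂/Z)e^{−Zs} + b̃(c+s) plus a separable
quadratic bound on ψ (convexity splitting around the iterate with curvature
ψ'(t)/t), solved by a few guarded Newton steps; zero strength reproduces
the unpenalized update exactly.  A practical strength for the desk noisy
protocol is ~2·10⁴ (the I-divergence is in counts, the penalty in component
units).

## The system operator

`build_system_operator` assembles a sparse matrix of ray–voxel interaction
lengths by interpolating line integration: each ray is sampled at half-
voxel steps, each sample scattered onto the 8 surrounding voxels with
trilinear weights, weighted by the step length.  Rays are clipped half a
voxel beyond the grid so boundary basis functions integrate over their full
support.  Backprojection is the exact sparse transpose, so the adjoint
identity holds to machine precision — a prerequisite for the gradient
oracles.  Fan-beam (equiangular curved detector) and helical cone-beam
(curved detector, rows quoted at isocenter) modes share the same code.
Counters instrument forward/back applications (one count per component
field), which is how the DC-layer cost contract is measured.

Desk-scale defaults: fan2d 64×64 image at 1 mm, 95 channels, 120 views;
helical 32×32×24 at 1 mm, 4 rows × 3 mm, 60 views/rotation, 8 mm feed
(8 slices per rotation), 3 rotations aligned so each rotation's feed spans
exactly one 8-slice stack.

## Margin effect and per-rotation stacks

The number of gantry steps contributing to a slice at distance z (mm) from
the first slice is piecewise linear with a flat top at n_vpr; the formula
is evaluated in mm exactly as printed (including the 1 mm unit offset in
the descending branch, kept because it reproduces the printed full-rotation
window).  At the clinical geometry (8.304 mm feed, 12 mm collimation,
1.034 mm slices) the full-rotation window in slice indices is [2.2, 4.8]
and a rotation advances 8 slices.

Per-rotation processing cuts one rotation's rays and its 8-slice stack;
the stack is z-padded by ceil((Z_d/2)/dz) slices (6 at both the clinical
and desk helical geometries).  In the dataset the padding uses the *real*
neighboring slices of the initializer volume (stored in the sample
metadata); at volume ends `pad_stack` replicates edge slices, which avoids
the artificial attenuation step a zero fill would create.  The test suite
shows the mechanism directly: with padding, the truth stack is a fixed
point of the DC layer; without it, the update direction shows a spurious
response concentrated on the peripheral slices, and a network trained
without padding + down-weighting inflates peripheral-slice MSE relative to
one trained with the strategy.  Peripheral slices get loss weight 0.2
(full-rotation slices 1.0); the value is a choice — only "down-weighted" is
specified by the underlying approach.

Because the feed equals one stack height, the padded stack operator is
identical for every interior rotation (verified to 1e-15), so one matrix
serves all training stacks.

## The unrolled network

Each update block computes the DC direction (one DEAM update, identical to
`deam_step` by construction), stacks (c₁, c₂, Δc₁, Δc₂) and applies a
shrunken attention U-Net: channel plan N, 2N, 4N, 8N (depth 4 by default),
two 3^d convolutions + group normalization + ReLU per level, average-pool
downsampling, nearest-neighbor upsampling, additive attention gates
(skip and coarser gate → ReLU → 1×1 conv → logistic) scaling each skip
before concatenation, and a zero-initialized 1×1 output head so an
untrained block is the identity.  Group counts are the largest divisor of
the channel count ≤ 8.  Blocks never share weights.  The same code runs 2D
(fan-beam slices) and 3D (thin-z stacks).

`resolve_parity` picks per-variant channel counts so 1/2/4-block networks
match learnable-parameter totals within 10% (counts are quantized in
N_chl, so variants are matched to their common mean).

### DC backward modes

* `approx`: transposed Jacobian–vector product of the rank-reduced
  Jacobian obtained by assuming g ≈ d and q ≈ p; uses the cached q and b̂
  and costs exactly 2 forward + 2 back projections.  The 1/Z and b̂
  factors are treated as constants (their derivatives are part of what the
  approximation discards), and no gradient is propagated to the sinogram
  input (it is data, not a learnable path).
* `exact`: the full analytic Jacobian, materialized densely and guarded
  above 10⁴ voxels.  It is derived from first principles and includes the
  cross-energy coupling terms Σ_E μ_i(E)q(y,E) that the approximate rule
  drops, so it matches central finite differences anywhere (verified to
  1e-8 on a 9-voxel instance).  Away from monochromatic consistency the
  approximate rule deliberately differs from it; at consistent
  single-energy-bin data all rules coincide (verified to 1e-16).
* `zero`: the gradient-free variant.  As a standalone function it passes
  the upstream gradient through unchanged; inside the network it detaches
  the DC path, which is the operational meaning of a zero DC gradient.

Empirically the DC Jacobian attenuates upstream gradients by ~10⁶, so
2-block trainings with approx vs zero gradients produce near-identical
loss curves; both plateau together and the approximate rule is never
slower.  A cache serial number detects stale-cache use (a backward against
an operator whose latest forward belongs to another cache); the unrolled
network relaxes the strict check because it pairs each backward with its
own block's cache by construction.

### Training

Stage 1 pretrains block 1 for up to 100 epochs (ADAM, lr 10⁻⁴, ×0.8 every
10 epochs); the block's inputs are fixed across epochs, so each sample's DC
output is computed once and cached.  Stage 2 copies block-1 weights to all
blocks and trains end-to-end (50 epochs, ×0.8 every 5), minimizing the
weighted sum of intermediate losses with the three-phase weight table
(final block always 1.0; earlier blocks fade from 0.3–0.5 to 0.01).  The
loss per block is the basis-model loss
Σ_i‖Δc_i‖² + Σ_E ψ_L(E)‖Σ_i μ_i(E)Δc_i‖², implemented through the 2×2
energy Gram matrix of the low-kVp spectrum weights (mathematically
identical, O(1) in the number of energy bins).  Gradient accumulation over
4 singleton samples equals a batch of 4 exactly because group normalization
has no cross-sample statistics (asserted to 1e-6).  Epoch selection uses
the best validation composite loss.

## Image-domain baseline (IDD)

The baseline decomposition log-normalizes each spectrum's counts to an
effective monoenergetic sinogram, reconstructs both with damped LSQR
through the same sparse operator (no filtered-backprojection step: LSQR is
geometry-exact for fan and helical alike), and decomposes per voxel with a
2×2 solve against the basis LACs at the spectra's fluence-weighted mean
energies.  Zero-count bins are floored at 1 count.  It is fast, noisy, and
biased by residual beam hardening — the expected character of image-domain
methods — and serves as initializer and comparison baseline.  It is a
simplified stand-in for published iterative image-domain schemes, not a
transcription of any of them.

## Synthetic data

`make_phantom` voxelizes a cylindrical acrylic-shell phantom (215 mm shell,
6 mm wall, water fill, eight 31 mm bottles on a 65 mm ring: ethanol,
propanol, butanol, water, and K₂HPO₄ at 50/100/150/200 mg/ml), or a
head-like ellipse (calcium-bearing shell, water interior, air pockets).
Each region carries the least-squares basis decomposition of its material
over 40–140 keV (residual < 2% for every bundled material; < 1% for
water), so simulated data are exactly representable by the reconstruction
model.  `make_dataset` jitters insert diameters (±10%), K₂HPO₄
concentrations (±15%) and centers (±1 voxel), simulates Poisson counts at
2·10⁵ photons per ray per spectrum, and attaches the IDD initializer; all
randomness flows from one seed.

What passing tests show — and what they do not: the simulator commits the
"inverse crime" (the same operator and attenuation tables generate and
reconstruct the data), which is intentional: it isolates algorithmic
properties (fixed points, descent, gradient correctness, margin effect,
initialization behavior) from modeling error.  Accuracy numbers obtained
here do not predict clinical accuracy, where spectrum miscalibration,
scatter, motion, detector effects and basis-model mismatch all enter.
The desk problem sizes (64×64 fan, 32×32×24 helical, 40-sample training
sets, 30-epoch pretrainings) are chosen so the full suite runs on one CPU
in minutes; they are study conditions, and all quantitative thresholds in
the tests are stated at these conditions.

## Known limitations

* No scatter model beyond an additive floor; no bowtie, cross-talk, or
  focal-spot blur.
* The exact DC Jacobian is dense and only for small verification
  instances.
* The spectral step-normalizer safety factor is validated empirically, not
  by a majorization proof; pathological spectra could require the classic
  rule or the safeguard.
* Edge rotations of a helical scan lack full padding support; per-rotation
  samples are cut from interior rotations only.
* HU conversion uses the bundled water tables; the displayed-window
  round-trip is reproduced to ±2 HU, not exactly (the reference water LAC
  at 60 keV is convention-dependent in its fourth digit).
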