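# dectunroll

Statistical dual-energy CT (DECT) reconstruction and model-based deep
unrolling, with a synthetic phantom and measurement simulator.

## The problem

Dual-energy CT acquires transmission data at two tube voltages (here 90 and
140 kVp) and reconstructs two *basis component* images c₁(x), c₂(x) such
that the linear attenuation coefficient at any energy is

    μ(x, E) = μ₁(E) c₁(x) + μ₂(E) c₂(x),

with basis materials a 23% aqueous CaCl₂ solution and polystyrene.  From
c₁, c₂ one can synthesize virtual monoenergetic images (VMIs) at any energy
— the quantitative inputs radiotherapy planning needs.  The statistical way
to estimate **c** = (c₁, c₂) is to minimize the I-divergence (the Poisson
log-likelihood up to constants) between measured counts d and the mean
polychromatic sinogram

    g_j(y) = Σ_E I₀ⱼ(E) exp(−Σ_i μ_i(E)[H c_i](y)),   j ∈ {L, H},

where H is the system operator.  Alternating minimization of a separable
surrogate (DEAM) gives the per-voxel update

    c_i(x) ← c_i(x) − (1/Z_i(x)) · log( b̃_i(x) / b̂_i(x) ),

with b̂, b̃ the μ-weighted backprojections of the modeled (q) and
count-matched (p) energy-resolved sinograms, and Z_i(x) a step normalizer.
This is accurate but converges slowly; the package therefore also
implements an *unrolled network*: a few update blocks

    cᵏ = cᵏ⁻¹ + Ψ_k( stack(cᵏ⁻¹, DC(cᵏ⁻¹, d)) ),

whose data-consistency (DC) layer is exactly one DEAM update direction and
whose image updater Ψ_k is a small attention-gated U-Net.  The DC layer has
a hand-derived backward rule (approximate transposed Jacobian, an exact
dense oracle for verification, and a zero/detached mode), so the whole
network trains end-to-end without a deep-learning framework: the package
ships its own minimal reverse-mode autodiff over numpy.

Helical scans add the *margin effect*: slices outside a per-rotation stack
still attenuate its rays.  The package models the per-slice view support,
z-pads stacks by half a collimation width, and down-weights peripheral
slices in the training loss.

Since clinical raw data are not distributable, a first-class synthetic
module generates insert phantoms (alcohols, K₂HPO₄ solutions, water in an
acrylic shell), decomposes every material onto the basis, and simulates
polychromatic Poisson measurements for fan-beam and helical geometries.

## Worked example

```python
import numpy as np
from dectunroll import (
    BasisImage, DEAMConfig, EnergyGrid, PenaltyConfig, PhantomSpec,
    build_material_basis, build_spectrum, build_system_operator,
    desk_fan_geometry, evaluate_metrics, make_dataset, run_deam,
)
from dectunroll.metrics import idd_initializer

geom = desk_fan_geometry()                  # 64x64 image, 95 ch, 120 views
op = build_system_operator(geom)
grid = EnergyGrid()                         # 20-150 keV, 1 keV bins
basis = build_material_basis(grid)          # CaCl2 solution + polystyrene
spec = build_spectrum(90.0, 140.0, grid)

sample = make_dataset(
    1, PhantomSpec(scale=0.25), geom, op, spec, basis, grid,
    seed=0, noise="poisson",
    initializer=lambda d: idd_initializer(d, op, spec, basis))[0]

state = run_deam(
    sample.d, BasisImage(np.zeros_like(sample.target.c)),
    DEAMConfig(n_iterations=60, n_subsets=12),
    PenaltyConfig(delta=0.01, strength=2e4), op, spec, basis)

for name, img in [("IDD", sample.init), ("DEAM", state.c)]:
    m = evaluate_metrics(img, sample.target, basis, spec, d=sample.d, op=op)
    print(f"{name:5s} bias60 {m.percent_bias_60:+.2f}%  mae60 "
          f"{m.percent_mae_60:.2f}%  psnr60 {m.psnr_60:.1f} dB  "
          f"objective {m.sinogram_objective:.3g}")
```

prints

```
IDD   bias60 +8.30%  mae60 8.43%  psnr60 24.3 dB  objective 5.97e+06
DEAM  bias60 -1.92%  mae60 2.81%  psnr60 29.3 dB  objective 5.76e+04
```

i.e. on one noisy simulated scan the image-domain decomposition baseline
(IDD) carries ~8% masked 60 keV VMI error, while 60 penalized DEAM
iterations with 12 ordered subsets reduce it to ~2.8% and drop the
sinogram-domain objective by two orders of magnitude.  The bias/MAE/PSNR
are evaluated on VMIs over the soft/bony-tissue mask
(μ_GT(60 keV) ∈ [0.01, 0.05] mm⁻¹).

A command-line pipeline wraps the same stages:

```sh
dectunroll write-geometry --out geom.yaml
dectunroll simulate --geom geom.yaml --out data/ --n-samples 8 --seed 0
dectunroll deam --sino data/sample_0000.h5 --iters 60 --subsets 12 --out rec.h5
dectunroll train --data data/ --stage pretrain --blocks 1 --out ckpt.npz
dectunroll infer --sino data/sample_0000.h5 --ckpt ckpt.npz --out net.h5
dectunroll evaluate --est rec.h5 --gt gt.h5 --sino data/sample_0000.h5
```

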