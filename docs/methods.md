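# Methods

This note records the physical model implemented by `dpsf`, the package's
default study conditions with their rationale, the main design decisions, and
known limitations.

## Physical model

### Scalar propagation

Free-space propagation between parallel planes uses the angular spectrum
method: the field is Fourier-decomposed into plane waves, each multiplied by
the transfer function

```
H(f_x, f_y; d) = exp( j (2*pi/lambda_eff) d sqrt(1 - (lambda_eff f_x)^2 - (lambda_eff f_y)^2) )
```

for propagating components, and **exactly zero** for evanescent components
(`(lambda_eff f_x)^2 + (lambda_eff f_y)^2 >= 1`). Inside an immersion medium
of index `eta_m(lambda)` the effective wavelength is
`lambda_eff = lambda / eta_m`, which both adds the medium's phase delay and
moves the evanescent cutoff. Fields are zero-padded (default `pad_factor=2`)
before the FFT so that the implicit cyclic convolution cannot wrap
diffracted light back into the aperture; padding uses corner placement,
which is exactly equivalent to centered placement for `pad_factor >= 2`.
With `pad_factor=1` the propagation is exactly periodic — the test suite
exploits this to get machine-precision composition and shift-equivariance
oracles.

### Surfaces

Each of the K surfaces is a thin phase element on an M x M grid of features
of pitch `delta`. The thickness of each feature is parametrized through a
latent variable,

```
t = (t_max / 2) * (sin(t_latent) + 1),
```

which confines `t` to `[0, t_max]` without constrained optimization. The
phase at wavelength `lambda` is `phi = (2*pi/lambda) (eta(lambda) - 1) t`;
with `t_max = lambda / (eta - 1)` the full thickness range spans exactly one
2*pi phase cycle (for multiwavelength designs, `t_max` is the largest such
value over the design wavelengths). Outside the W x W aperture of each
surface the field is blocked; in the implementation the simulation grid
equals the layer grid, so blocking is realized by cropping to the grid after
each propagation (an `open_aperture` switch disables it for validation
oracles).

Fabrication precision is modeled by quantizing to `2^b` levels at bit depth
`b`: the *phase* (wrapped to `[0, 2*pi)`, nearest level, with wrap-around)
for single-wavelength designs, and the *thickness* (levels `k*t_max/2^b`)
for multiwavelength designs, where one physical thickness must serve all
wavelengths simultaneously.

### Geometry

For N trainable features split over K layers, the layer width is
`W = sqrt(N/K) * delta` with feature pitch `delta = 0.53 lambda` by default.
The default layer separation follows the full-connectivity condition

```
d = (W delta / lambda) * sqrt(1 - (lambda / (2 delta))^2),
```

the axial distance at which light from one edge feature can reach the whole
next layer. The input (output) volume consists of C_i (C_o) voxel planes of
H x W voxels at pitch `delta`, spaced `d_pp = 2.67 lambda` apart; `d_i`
(`d_o`) is the distance of the *farthest* input (output) plane from the
first (last) surface. The input-side numerical aperture is
`NA = eta_m * sin(arctan((W/2)/d_i))` and the axial two-point resolution
limit is `2 lambda / NA^2`.

### Incoherent forward model

Mutually incoherent emitters make the system linear in intensity:
`o = A' i`, with the columns of `A'` the vectorized 3D PSFs (plane-major,
then row-major voxel ordering: `q = plane*(H*W) + row*W + col`). The package
computes `A'` two ways:

- **Impulse matrix** (exact, deterministic): propagate a unit impulse from
  every input voxel; a single emitter needs no phase averaging because its
  random phase is global.
- **Random-phase ensemble** (Monte-Carlo): per input plane, draw i.i.d.
  uniform(0, 2*pi) phase maps, propagate `sqrt(I) exp(j phi_r)`, average the
  output intensities over `N_phi` realizations (default 10^4), and sum the
  plane contributions. The estimate converges to the impulse-matrix product
  at the `1/sqrt(N_phi)` Monte-Carlo rate (verified: fitted log-log slope
  -0.52 in the test suite). Phase streams are spawned per plane from one
  master seed, so planes never share a realization and results are
  reproducible.

A passive design controls only the *shape* of `A'`, not its overall
throughput, so realizations are compared to targets through the optimally
scaled `A_hat = sigma_A A'` with the closed-form least-squares scale
`sigma_A = <A, A'> / <A', A'>`.

### Loss and gradients

Training minimizes the scale-invariant transformation error

```
L = || A - sigma_A A' ||_F^2 / || A ||_F^2,
```

summed with configurable weights over design wavelengths for multispectral
designs. No autodiff framework is used: gradients are hand-derived adjoint
(Wirtinger) gradients through the FFT cascade. The adjoint of a propagation
is the same propagation with the conjugated transfer function; the
intensity measurement `I = |u|^2` back-propagates as `(dL/dI) * u`; a phase
surface contributes `dL/dphi = 2 Re(conj(g_out) j t u_in)` and passes
`conj(t) g_out` upstream. `sigma_A` is held fixed during differentiation —
because it is the exact minimizer of the scale, the envelope theorem makes
the resulting gradient exact, not approximate. The full gradient is
validated against central finite differences (relative agreement ~1e-9,
far tighter than the 1e-4 test threshold). Optimization uses a hand-rolled
Adam (default learning rate 0.02, cosine decay) with optional
plateau-based early stopping.

### Quantized training and bit-depth generalization

At a bounded training bit depth `b_train`, the forward pass uses the
quantized profile while gradients flow through the continuous one
(straight-through estimator). After training, `snap_to_quantized` projects
the latents onto the quantized, fabricable thickness profile — the
deliverable *is* the quantized device, so the stored design should be the
snapped one. A useful exact consequence: the `2^b` level grids are nested,
so re-evaluating a snapped design at any finer test bit depth
`b_test >= b_train` is a bit-identical no-op, while coarser `b_test`
degrades it. Without the snap, the continuous latents drift freely inside
their quantization bins during training and the evaluation at finer bit
depths diverges from the trained operating point.

## Default study conditions

These are the package's own scaled-down defaults, sized for single-CPU
reproduction; they are study conditions, not tuning dials.

- **Feature pitch** `delta = 0.53 lambda`; **voxel plane spacing**
  `d_pp = 2.67 lambda`; surface index 1.6518 at the design wavelength
  (a THz-band polymer; visible-band polymer and water dispersion tables are
  also bundled).
- **Standoff distances**: by default `d_i = d_o = (21/57) W`, which keeps
  the input NA at 0.81 for any layer width (for the bundled defaults:
  axial limit `2 lambda / NA^2 = 3.05 lambda`, close to and above
  `d_pp = 2.67 lambda`).
- **Benchmark design task**: K = 4 surfaces, N = 4 * N_i * N_o = 1296
  features, N_i = N_o = 18 voxels as two 3 x 3 planes per side, seeded
  uniform-random target, trained and evaluated at bit depth 12 with plateau
  stopping (<= 5000 iterations). Reference outcome: transformation error
  5.7e-06 and `max |A - A_hat| = 0.0046` (seeds 1/2; the acceptance script
  reproduces ~0.007 for independently derived seeds), well inside the 0.02
  figure of merit.
- **Trend studies** (seeds frozen before thresholds; see
  `tests/test_acceptance.py`):
  - *Depth*: at a near-equal feature budget below the `2 N_i N_o` capacity
    threshold (N = 338 vs 324; exactly equal N across K is impossible since
    N/K must be a perfect square), the deeper design wins:
    L(K=2) = 0.047 > L(K=4) = 0.0078. In over-parameterized regimes the
    ordering can invert, so the under-capacity regime is part of the study
    condition.
  - *Capacity*: with N_i = N_o = 18, the error collapses once N approaches
    `2 N_i N_o = 648` (L = 0.37 at N = 64, 3e-6 at N = 676) and plateaus
    beyond (9e-9 at N = 1296). A fixed `d_i = 3.5 lambda` is used across
    points so all N are geometrically feasible.
  - *Axial resolution*: at fixed `d_i = 8 lambda` (NA 0.51, axial limit
    7.6 lambda), shrinking `d_pp` through {2, 1, 0.5} lambda monotonically
    raises the error (0.0017 → 0.0037 → 0.0046): planes closer than the
    axial limit are progressively harder to address independently. Larger
    spacings are excluded because the growing depth asymmetry of the input
    volume (near plane at `d_i - d_pp`) becomes a confound.
- **Synthetic emitter volumes** (`generate_emitter_volume`) emulate sparse
  incoherent point sources (e.g. fluorescent beads): a seeded choice of
  voxels without replacement, intensities i.i.d. uniform(0.5, 1), optional
  per-emitter wavelength-channel labels.

## Design decisions

- **Simulation grid = layer grid.** The M x M feature grid is also the field
  sampling grid; input/output voxel blocks are embedded/extracted centered
  on it. This couples aperture and grid (see Limitations) but keeps every
  FFT at the minimal size and makes the aperture model explicit.
- **Exact linear model for training.** The loss is always computed from the
  impulse-response forward model, never the Monte-Carlo ensemble, so
  gradients are exact and traces are deterministic; the ensemble exists to
  model physical image formation and to validate the linear model.
- **Explicit zero-target rows.** Unassigned detector pixels in superpixel
  layouts (and other-channel pixels in multispectral targets) carry explicit
  zero rows, so the optimizer actively suppresses stray light and spectral
  cross-talk instead of ignoring it.
- **Reproducibility.** All stochastic stages (targets, initializations,
  phase ensembles, emitter volumes) take explicit integer seeds;
  per-plane/per-point sub-seeds are spawned via `numpy.random.SeedSequence`.
  Single-threaded re-runs are bit-identical.

## Limitations

- **Scalar, thin-element, paraxial-free but polarization-free.** The model
  is scalar diffraction with thin phase elements; polarization, volumetric
  (thick-element) effects, inter-feature shadowing, material absorption and
  Fresnel reflections at interfaces are not modeled.
- **Grid-limited aperture model.** Because the simulation grid equals the
  layer grid, light that would diffract around a surface and re-enter
  downstream is discarded at the crop; the `pad_factor` controls only
  wrap-around, not the modeled surround.
- **Input voxel grids share the feature pitch.** Voxel planes are sampled on
  the same lateral grid as the surfaces; sub-pitch emitter positions require
  an external interpolation step.
- **Desk-scale capacity.** The shipped study conditions use tens of voxels
  and ~10^3 features. The model and optimizer scale to larger N (cost is
  O(iterations * K * C_i * H_i * W_i * (pad*M)^2 log M), but headline-scale
  designs (hundreds of thousands of features, 10^4+ voxels) need
  correspondingly long single-CPU runs.
- **Monochromatic channels.** Multispectral designs treat each wavelength as
  a discrete, mutually incoherent channel; finite spectral linewidth is not
  modeled.
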