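"""Gradient-based optimization of the diffractive surfaces.

The design objective is the normalized, scale-invariant transformation error

    L = sum_pq (A[p,q] - sigma_A * A'[p,q])**2 / sum_pq A[p,q]**2,

where ``A`` is the target intensity transformation, ``A'`` the realized one
(stacked impulse responses) and ``sigma_A`` its closed-form optimal rescaling.
For multiwavelength designs the loss is a weighted mean of per-wavelength
losses (unweighted by default).

Gradients
---------
The forward model is a chain of linear complex maps (angular-spectrum
propagations, diagonal phase modulations) followed by the elementwise modulus
squared and the quadratic loss; its gradient with respect to each surface
phase is computed by an adjoint (reverse) pass written against the same FFT
primitives:

* modulus squared: ``dL/du* = (dL/dI) * u``;
* a propagation step is backpropagated by the same step with the conjugate
  transfer function (the exact adjoint, since zero-padding and cropping are
  mutually adjoint);
* a phase modulation ``u_out = u_in * exp(j*phi)`` contributes
  ``dL/dphi = 2 * Re(conj(g_out) * j * exp(j*phi) * u_in)`` and passes
  ``g_in = conj(exp(j*phi)) * g_out`` upstream.

``sigma_A`` is held fixed during the backward pass; because it is the exact
minimizer of the quadratic in ``sigma``, the resulting gradient is exact
(envelope theorem), not an approximation.  Bounded training bit depths use a
straight-through estimator: the forward pass sees quantized modulation, the
backward pass treats the quantizer as the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .incoherent import TransformMatrix, impulse_matrix, optimal_scale
from .processor import (
    DiffractiveProcessor,
    _grid_embed,
    _grid_extract,
    run_cascade_batch,
    surface_transmissions,
)
from .surfaces import BitDepthPolicy
from .wave_optics import propagate_samples

__all__ = [
    "TrainConfig",
    "TrainResult",
    "SweepResult",
    "transformation_error",
    "loss_and_gradient",
    "evaluate_loss",
    "snap_to_quantized",
    "train",
    "bit_depth_eval",
    "sweep",
]


def transformation_error(
    target: TransformMatrix | np.ndarray, realized: TransformMatrix | np.ndarray
) -> float:
    """Scale-invariant normalized squared error between ``A`` and ``A'``.

    Returns ``||A - sigma_A * A'||_F**2 / ||A||_F**2``; invariant to positive
    rescaling of ``A'`` and equal to 1 when ``A`` and ``A'`` are orthogonal
    (``sigma_A = 0``).
    """
    a = target.entries if isinstance(target, TransformMatrix) else np.asarray(target, float)
    ap = realized.entries if isinstance(realized, TransformMatrix) else np.asarray(realized, float)
    if a.shape != ap.shape:
        raise ValueError("target and realized matrices must have the same shape")
    denom = float(np.sum(a * a))
    if denom == 0.0:
        raise ValueError("target transformation is identically zero")
    try:
        sigma = optimal_scale(a, ap)
    except ZeroDivisionError:
        sigma = 0.0
    return float(np.sum((a - sigma * ap) ** 2)) / denom


# ---------------------------------------------------------------------------
# adjoint engine
# ---------------------------------------------------------------------------


def _normalize_targets(
    proc: DiffractiveProcessor,
    targets,
    weights: list[float] | None,
) -> tuple[list[tuple[float, np.ndarray, float]], float]:
    """Pair each design wavelength with its target matrix and loss weight."""
    if isinstance(targets, (TransformMatrix, np.ndarray)):
        targets = [targets]
    if len(targets) != len(proc.wavelengths):
        raise ValueError(
            f"{len(targets)} target(s) for {len(proc.wavelengths)} design wavelength(s)"
        )
    if weights is None:
        weights = [1.0] * len(targets)
    total_w = float(np.sum(weights))
    out = []
    for lam, tgt, wgt in zip(proc.wavelengths, targets, weights):
        a = tgt.entries if isinstance(tgt, TransformMatrix) else np.asarray(tgt, float)
        geom = proc.geometry
        if a.shape != (geom.n_output_voxels, geom.n_input_voxels):
            raise ValueError(
                f"target shape {a.shape} does not match the voxel grids "
                f"({geom.n_output_voxels} x {geom.n_input_voxels})"
            )
        out.append((lam, a, float(wgt)))
    return out, total_w


def _forward_realized(
    proc: DiffractiveProcessor,
    lam: float,
    bit_depth: int | None,
    trans: list[np.ndarray],
    record: bool,
):
    """Impulse-response forward pass at one wavelength, keeping tapes."""
    geom = proc.geometry
    ci, hi, wi = geom.input_shape
    co, ho, wo = geom.output_shape
    g = geom.features_per_side
    per_plane = hi * wi
    n_i, n_o = geom.n_input_voxels, geom.n_output_voxels
    impulses = np.eye(per_plane, dtype=np.complex128).reshape(per_plane, hi, wi)
    batch0 = _grid_embed(impulses, g)
    realized = np.empty((n_o, n_i), dtype=np.float64)
    tapes = []
    out_fields = []
    for n_pl in range(ci):
        fields, tape = run_cascade_batch(
            batch0, proc, n_pl, lam, bit_depth, record=record, transmissions=trans
        )
        inten = np.abs(_grid_extract(fields, (ho, wo))) ** 2
        block = np.transpose(inten, (1, 0, 2, 3)).reshape(per_plane, n_o).T
        realized[:, n_pl * per_plane : (n_pl + 1) * per_plane] = block
        tapes.append(tape)
        out_fields.append(fields)
    return realized, tapes, out_fields


def _backward_phase_grads(
    proc: DiffractiveProcessor,
    lam: float,
    grad_intensity: np.ndarray,
    tapes,
    out_fields,
) -> list[np.ndarray]:
    """Adjoint pass: from dL/dA' to dL/dphi_k for every surface."""
    geom = proc.geometry
    ci, hi, wi = geom.input_shape
    co, ho, wo = geom.output_shape
    g = geom.features_per_side
    per_plane = hi * wi
    pitch, pf = geom.pitch, proc.pad_factor
    phase_grads = [np.zeros((g, g)) for _ in range(geom.n_surfaces)]

    for n_pl in range(ci):
        tape = tapes[n_pl]
        fields = out_fields[n_pl]  # (C_o, B, G, G)
        # dL/dI for this plane's impulse batch, per output plane
        cols = grad_intensity[:, n_pl * per_plane : (n_pl + 1) * per_plane]
        di = np.transpose(cols.T.reshape(per_plane, co, ho, wo), (1, 0, 2, 3))
        g_after = np.zeros_like(tape.after_last)
        for n in range(co):
            g_out = np.zeros((per_plane, g, g), dtype=np.complex128)
            oy, ox = (g - ho) // 2, (g - wo) // 2
            sampled = _grid_extract(fields[n], (ho, wo))
            g_out[:, oy : oy + ho, ox : ox + wo] = di[n] * sampled
            g_after += propagate_samples(
                g_out,
                pitch,
                geom.output_plane_distance(n),
                lam,
                pf,
                conjugate_transfer=True,
            )
        grad = g_after
        for k in range(geom.n_surfaces - 1, -1, -1):
            if k < geom.n_surfaces - 1:
                grad = propagate_samples(
                    grad, pitch, geom.layer_gap, lam, pf, conjugate_transfer=True
                )
            t_k = tape.transmissions[k]
            u_in = tape.surface_inputs[k]
            phase_grads[k] += 2.0 * np.real(
                np.conj(grad) * (1j * t_k) * u_in
            ).sum(axis=0)
            grad = np.conj(t_k) * grad
    return phase_grads


def loss_and_gradient(
    proc: DiffractiveProcessor,
    targets,
    bit_depth: int | None = None,
    weights: list[float] | None = None,
) -> tuple[float, list[np.ndarray], list[float]]:
    """Transformation loss and its gradient w.r.t. every surface latent.

    Returns ``(loss, latent_grads, per_wavelength_losses)``.  The forward pass
    uses the (possibly quantized) modulation at ``bit_depth``; quantization is
    straight-through in the backward pass.
    """
    pairs, total_w = _normalize_targets(proc, targets, weights)
    geom = proc.geometry
    n_k = geom.n_surfaces
    thickness_grads = [np.zeros_like(s.latent) for s in proc.surfaces]
    losses = []
    total_loss = 0.0
    for lam, a, wgt in pairs:
        trans = surface_transmissions(proc, lam, bit_depth)
        realized, tapes, out_fields = _forward_realized(proc, lam, bit_depth, trans, True)
        denom = float(np.sum(a * a))
        try:
            sigma = optimal_scale(a, realized)
        except ZeroDivisionError:
            sigma = 0.0
        resid = sigma * realized - a
        loss_lam = float(np.sum(resid**2)) / denom
        losses.append(loss_lam)
        total_loss += wgt * loss_lam / total_w
        # dL_lam/dA' with sigma held fixed (exact by the envelope theorem)
        grad_a = (2.0 * sigma / denom) * resid
        phase_grads = _backward_phase_grads(proc, lam, grad_a, tapes, out_fields)
        # chain: phi = (2*pi/lam) * (eta - 1) * t (straight-through quantizers)
        for k in range(n_k):
            surf = proc.surfaces[k]
            eta = surf.material.index_at(lam)
            c_lam = (2.0 * np.pi / lam) * (eta - 1.0)
            thickness_grads[k] += (wgt / total_w) * c_lam * phase_grads[k]
    latent_grads = []
    for k, surf in enumerate(proc.surfaces):
        dt_dlatent = (surf.t_max / 2.0) * np.cos(surf.latent)
        latent_grads.append(thickness_grads[k] * dt_dlatent)
    return total_loss, latent_grads, losses


def evaluate_loss(
    proc: DiffractiveProcessor,
    targets,
    bit_depth: int | None = None,
    weights: list[float] | None = None,
) -> float:
    """Transformation loss of a design at a given evaluation bit depth."""
    pairs, total_w = _normalize_targets(proc, targets, weights)
    total = 0.0
    for lam, a, wgt in pairs:
        realized = impulse_matrix(proc, wavelength=lam, bit_depth=bit_depth)
        total += wgt * transformation_error(a, realized.entries) / total_w
    return total


# ---------------------------------------------------------------------------
# optimizer and harnesses
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Optimization settings for surface training."""

    iterations: int = 2000
    learning_rate: float = 0.02
    optimizer: str = "adam"
    seed: int = 0
    policy: BitDepthPolicy = field(default_factory=BitDepthPolicy)
    loss_weights: list[float] | None = None
    eval_every: int = 0  # 0: never evaluate at b_test during training
    cosine_decay: bool = True
    plateau_patience: int = 0  # 0: no early stopping
    plateau_rtol: float = 1e-4

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (self.learning_rate > 0):
            raise ValueError("learning rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclass
class TrainResult:
    """Trained design, its loss trace and evaluation-bit-depth final loss."""

    processor: DiffractiveProcessor
    loss_trace: np.ndarray
    final_loss: float
    per_wavelength_losses: list[float]
    config: TrainConfig

    @property
    def iterations_run(self) -> int:
        return len(self.loss_trace)


class _Adam:
    def __init__(self, shapes, lr):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.lr = lr
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params, grads, lr_scale=1.0):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * lr_scale * mhat / (np.sqrt(vhat) + self.eps)


def snap_to_quantized(proc: DiffractiveProcessor, bit_depth: int | None) -> None:
    """Project the latents onto the fabricable quantized thickness profile.

    A design trained at a bounded bit depth is realized as the *quantized*
    thickness map, so the stored latents are snapped (in place) to reproduce
    it exactly.  Because the ``2**b`` level grids are nested, re-quantizing
    the snapped design at any finer test bit depth leaves it unchanged —
    matching the observation that the error stays constant for
    ``b_test >= b_train``.  No-op for unbounded bit depth.
    """
    if bit_depth is None:
        return
    from .surfaces import quantize_phase, quantize_thickness, thickness_from_latent

    for surf in proc.surfaces:
        t_s = thickness_from_latent(surf.latent, surf.t_max)
        if proc.multiwavelength:
            t_q = quantize_thickness(t_s, surf.t_max, bit_depth)
        else:
            lam = proc.wavelengths[0]
            eta = surf.material.index_at(lam)
            c = (2.0 * np.pi / lam) * (eta - 1.0)
            phi_q = quantize_phase(c * t_s, bit_depth)
            t_q = np.clip(phi_q / c, 0.0, surf.t_max)
        surf.latent = np.arcsin(np.clip(2.0 * t_q / surf.t_max - 1.0, -1.0, 1.0))


def train(
    proc: DiffractiveProcessor,
    targets,
    config: TrainConfig,
) -> TrainResult:
    """Optimize the surface latents to realize the target transformation(s).

    The loss is recomputed each iteration from the exact impulse-response
    forward model (never the Monte-Carlo ensemble) at the training bit depth;
    the returned ``final_loss`` is evaluated at the testing bit depth.
    Training diverging to a non-finite loss raises with the config echoed.
    """
    proc = proc.copy()
    b_tr = config.policy.b_train
    params = [s.latent for s in proc.surfaces]
    opt = _Adam([p.shape for p in params], config.learning_rate)
    trace = []
    best = np.inf
    stale = 0
    for it in range(config.iterations):
        loss, grads, _ = loss_and_gradient(
            proc, targets, bit_depth=b_tr, weights=config.loss_weights
        )
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at iteration {it}: loss={loss!r}; config={config!r}"
            )
        trace.append(loss)
        lr_scale = (
            0.5 * (1.0 + np.cos(np.pi * it / config.iterations))
            if config.cosine_decay
            else 1.0
        )
        if config.optimizer == "adam":
            opt.step(params, grads, lr_scale)
        else:
            for p, g in zip(params, grads):
                p -= config.learning_rate * lr_scale * g
        if config.plateau_patience:
            if loss < best * (1.0 - config.plateau_rtol):
                best, stale = loss, 0
            else:
                stale += 1
                if stale >= config.plateau_patience:
                    break
    snap_to_quantized(proc, b_tr)
    b_te = config.policy.b_test
    pairs, total_w = _normalize_targets(proc, targets, config.loss_weights)
    per_lam = []
    final = 0.0
    for lam, a, wgt in pairs:
        realized = impulse_matrix(proc, wavelength=lam, bit_depth=b_te)
        loss_lam = transformation_error(a, realized.entries)
        per_lam.append(loss_lam)
        final += wgt * loss_lam / total_w
    return TrainResult(
        processor=proc,
        loss_trace=np.asarray(trace),
        final_loss=final,
        per_wavelength_losses=per_lam,
        config=config,
    )


def bit_depth_eval(
    proc: DiffractiveProcessor,
    targets,
    b_test: int | None,
    weights: list[float] | None = None,
) -> float:
    """Re-quantize a trained design at ``b_test`` and recompute the loss."""
    return evaluate_loss(proc, targets, bit_depth=b_test, weights=weights)


@dataclass
class SweepResult:
    """One trained design per axis value, with per-point seeds and errors."""

    axis: str
    values: list[float]
    errors: list[float]
    seeds: list[int]
    skipped: list[float] = field(default_factory=list)

    def as_rows(self):
        return list(zip(self.values, self.errors, self.seeds))


def sweep(
    axis: str,
    values,
    base_geometry_kwargs: dict,
    target: TransformMatrix,
    material,
    wavelengths: list[float],
    config: TrainConfig,
) -> SweepResult:
    """Architecture/precision trend study: one freshly trained design per value.

    ``axis`` is one of ``"N"``, ``"K"``, ``"b"``, ``"d_pp"``, ``"d_i"``
    (the latter sets ``d_i = d_o`` jointly).  The *same* target is shared by
    all points, isolating the architecture effect; each point gets a fresh,
    logged initialization seed derived from ``config.seed``.  For the ``N``
    sweep, layer width and separation follow the connectivity formulas.
    Infeasible points (non-square per-layer grids) are skipped with a warning.
    """
    import warnings

    from .processor import ProcessorGeometry

    valid_axes = ("N", "K", "b", "d_pp", "d_i")
    if axis not in valid_axes:
        raise ValueError(f"axis must be one of {valid_axes}")
    values = list(values)
    if values != sorted(values):
        raise ValueError("sweep values must be sorted ascending")
    seeds = [config.seed + 1000 * (i + 1) for i in range(len(values))]
    errors: list[float] = []
    kept_values: list[float] = []
    kept_seeds: list[int] = []
    skipped: list[float] = []
    for val, point_seed in zip(values, seeds):
        kwargs = dict(base_geometry_kwargs)
        policy = config.policy
        if axis == "N":
            kwargs["n_features"] = int(val)
        elif axis == "K":
            kwargs["n_surfaces"] = int(val)
        elif axis == "d_pp":
            kwargs["d_pp"] = float(val)
        elif axis == "d_i":
            kwargs["d_i"] = float(val)
            kwargs["d_o"] = float(val)
        elif axis == "b":
            policy = BitDepthPolicy(b_train=int(val), b_test=int(val))
        try:
            geom = ProcessorGeometry.from_feature_count(**kwargs)
        except ValueError as exc:
            warnings.warn(f"skipping {axis}={val}: {exc}", stacklevel=2)
            skipped.append(val)
            continue
        proc = DiffractiveProcessor.initialize(
            geom, material, wavelengths, seed=point_seed, policy=policy
        )
        point_config = TrainConfig(
            iterations=config.iterations,
            learning_rate=config.learning_rate,
            optimizer=config.optimizer,
            seed=point_seed,
            policy=policy,
            loss_weights=config.loss_weights,
            cosine_decay=config.cosine_decay,
            plateau_patience=config.plateau_patience,
            plateau_rtol=config.plateau_rtol,
        )
        result = train(proc, target, point_config)
        errors.append(result.final_loss)
        kept_values.append(val)
        kept_seeds.append(point_seed)
    return SweepResult(axis=axis, values=kept_values, errors=errors, seeds=kept_seeds, skipped=skipped)
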