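"""Spatially incoherent intensity forward model.

For mutually incoherent emitters the time-averaged cross-terms between any two
voxels vanish, so the system is linear in *intensity*: the output intensity
vector is ``o' = A' i`` where the columns of the nonnegative matrix ``A'`` are
the vectorized 3D PSFs of the individual input voxels.

Two equivalent routes compute the forward model:

* :func:`impulse_matrix` — exact and deterministic: propagate a unit impulse
  from every input voxel and stack the vectorized output intensities.
* :func:`ensemble_output` — Monte-Carlo: per input plane, draw random uniform
  phase maps, propagate the coherent fields ``sqrt(I) * exp(j*phi_r)``, and
  average the output intensities over realizations; contributions of the
  planes add (cross-plane incoherence).  The ensemble estimate converges to
  the exact matrix product at the usual ``1/sqrt(N_phi)`` Monte-Carlo rate.

A realized transformation ``A'`` approximates a target ``A`` only up to the
overall optical throughput; the scalar ``sigma_A`` minimizing
``||A - sigma * A'||_F**2`` (closed form, :func:`optimal_scale`) absorbs that
global scale, giving the scaled transformation ``A_hat = sigma_A * A'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .processor import (
    DiffractiveProcessor,
    EmitterVolume,
    OutputVolume,
    _grid_embed,
    _grid_extract,
    run_cascade_batch,
    surface_transmissions,
)

__all__ = [
    "TransformMatrix",
    "PhaseEnsembleSpec",
    "impulse_matrix",
    "ensemble_output",
    "multispectral_output",
    "apply_transform",
    "optimal_scale",
    "spectral_crosstalk",
]


@dataclass
class TransformMatrix:
    """A nonnegative ``N_o x N_i`` intensity transformation.

    ``role`` tags whether the matrix is a design target (``"target"``), the
    raw realized transformation (``"realized"``) or the optimally scaled
    realized transformation (``"scaled"``).  Columns follow the plane-major,
    row-major voxel vectorization ``q = n*(H*W) + l*W + m``.
    """

    entries: np.ndarray
    role: str = "target"
    input_shape: tuple[int, int, int] | None = None
    output_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.float64)
        if self.entries.ndim != 2:
            raise ValueError("transformation matrix must be 2D")
        if self.role not in ("target", "realized", "scaled"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role in ("realized", "scaled") and np.any(self.entries < 0):
            raise ValueError("realized intensity transformations must be nonnegative")
        for shape, n in (
            (self.input_shape, self.entries.shape[1]),
            (self.output_shape, self.entries.shape[0]),
        ):
            if shape is not None and int(np.prod(shape)) != n:
                raise ValueError("matrix shape inconsistent with voxel grid shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


@dataclass(frozen=True)
class PhaseEnsembleSpec:
    """Monte-Carlo settings: number of random-phase realizations and seed."""

    n_phase: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phase < 1:
            raise ValueError("n_phase must be >= 1")


def impulse_matrix(
    proc: DiffractiveProcessor,
    wavelength: float | None = None,
    bit_depth: int | None = None,
) -> TransformMatrix:
    """Exact realized transformation ``A'`` from unit-impulse responses.

    Column ``q`` is the vectorized incoherent PSF of input voxel ``q``: all
    impulses of one input plane are propagated as a batch, their squared
    moduli sampled at the output voxel grid and stacked.  Deterministic — a
    single emitter needs no phase averaging.
    """
    geom = proc.geometry
    lam = proc.wavelengths[0] if wavelength is None else wavelength
    ci, hi, wi = geom.input_shape
    co, ho, wo = geom.output_shape
    g = geom.features_per_side
    n_i, n_o = geom.n_input_voxels, geom.n_output_voxels
    trans = surface_transmissions(proc, lam, bit_depth)
    cols = np.empty((n_o, n_i), dtype=np.float64)
    per_plane = hi * wi
    impulses = np.eye(per_plane, dtype=np.complex128).reshape(per_plane, hi, wi)
    batch = _grid_embed(impulses, g)
    for n_pl in range(ci):
        fields, _ = run_cascade_batch(
            batch, proc, n_pl, lam, bit_depth, transmissions=trans
        )
        inten = np.abs(_grid_extract(fields, (ho, wo))) ** 2  # (C_o, B, ho, wo)
        block = np.transpose(inten, (1, 0, 2, 3)).reshape(per_plane, n_o).T
        cols[:, n_pl * per_plane : (n_pl + 1) * per_plane] = block
    return TransformMatrix(
        cols,
        role="realized",
        input_shape=geom.input_shape,
        output_shape=geom.output_shape,
    )


def ensemble_output(
    proc: DiffractiveProcessor,
    volume: EmitterVolume,
    spec: PhaseEnsembleSpec,
    wavelength: float | None = None,
    bit_depth: int | None = None,
    batch_size: int = 256,
) -> OutputVolume:
    """Monte-Carlo incoherent output intensity for an emitter volume.

    Each input plane is treated independently (cross-plane incoherence): per
    realization, i.i.d. uniform(0, 2*pi) phases are drawn for every voxel of
    the plane, the coherent field ``sqrt(I) * exp(j*phi_r)`` is cascaded, and
    the output intensities are averaged over ``spec.n_phase`` realizations.
    Plane contributions are then summed.  Phase streams are spawned from the
    master seed per plane, so results are reproducible and planes never share
    a realization.
    """
    geom = proc.geometry
    lam = proc.wavelengths[0] if wavelength is None else wavelength
    ci, hi, wi = geom.input_shape
    co, ho, wo = geom.output_shape
    if volume.shape != (ci, hi, wi):
        raise ValueError("emitter volume does not match the processor input grid")
    g = geom.features_per_side
    trans = surface_transmissions(proc, lam, bit_depth)
    streams = np.random.SeedSequence(spec.seed).spawn(ci)
    total = np.zeros((co, ho, wo), dtype=np.float64)
    for n_pl in range(ci):
        amp = np.sqrt(volume.intensity[n_pl])
        if not np.any(amp > 0):
            continue
        rng = np.random.default_rng(streams[n_pl])
        acc = np.zeros((co, ho, wo), dtype=np.float64)
        remaining = spec.n_phase
        while remaining > 0:
            b = min(batch_size, remaining)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=(b, hi, wi))
            batch = _grid_embed(amp * np.exp(1j * phases), g)
            fields, _ = run_cascade_batch(
                batch, proc, n_pl, lam, bit_depth, transmissions=trans
            )
            inten = np.abs(_grid_extract(fields, (ho, wo))) ** 2
            acc += inten.sum(axis=1)
            remaining -= b
        total += acc / spec.n_phase
    return OutputVolume(total, geom.pitch, geom.d_pp)


def multispectral_output(
    proc: DiffractiveProcessor,
    volume: EmitterVolume,
    spec: PhaseEnsembleSpec | None = None,
    bit_depth: int | None = None,
) -> OutputVolume:
    """Detector intensity for a multispectral emitter volume.

    Spectral channels are mutually incoherent, so per-wavelength outputs are
    computed independently (exactly, via the impulse matrix, or by Monte-Carlo
    when ``spec`` is given) and summed at the detector.
    """
    geom = proc.geometry
    total = np.zeros(geom.output_shape, dtype=np.float64)
    for ch, lam in enumerate(proc.wavelengths):
        inten = (
            volume.channel_intensity(ch)
            if volume.wavelength_labels is not None
            else volume.intensity
        )
        chan_vol = EmitterVolume(inten, volume.pitch, volume.d_pp)
        if spec is None:
            mat = impulse_matrix(proc, wavelength=lam, bit_depth=bit_depth)
            out = apply_transform(mat, chan_vol.vectorized())
            total += out.reshape(geom.output_shape)
        else:
            total += ensemble_output(
                proc, chan_vol, spec, wavelength=lam, bit_depth=bit_depth
            ).intensity
    return OutputVolume(total, geom.pitch, geom.d_pp)


def apply_transform(matrix: TransformMatrix, intensities: np.ndarray) -> np.ndarray:
    """Matrix-vector product ``o = A i`` on vectorized intensities."""
    i = np.asarray(intensities, dtype=np.float64).reshape(-1)
    if i.shape[0] != matrix.shape[1]:
        raise ValueError(
            f"input vector length {i.shape[0]} does not match matrix width "
            f"{matrix.shape[1]}"
        )
    if np.any(i < 0):
        raise ValueError("input intensities must be nonnegative")
    return matrix.entries @ i


def optimal_scale(target: np.ndarray, realized: np.ndarray) -> float:
    """Closed-form scalar minimizing ``||A - sigma * A'||_F**2``.

    ``sigma_A = <A, A'> / <A', A'>`` (Frobenius inner products).
    """
    a = np.asarray(target, dtype=np.float64)
    ap = np.asarray(realized, dtype=np.float64)
    if a.shape != ap.shape:
        raise ValueError("target and realized matrices must have the same shape")
    denom = float(np.sum(ap * ap))
    if denom == 0.0:
        raise ZeroDivisionError("realized transformation is identically zero")
    return float(np.sum(a * ap)) / denom


def spectral_crosstalk(
    frame: np.ndarray, channel_masks: list[np.ndarray], channel: int
) -> float:
    """Fraction of detector energy landing on pixels of *other* channels.

    ``channel_masks[w]`` is a boolean mask of the detector pixels assigned to
    wavelength channel ``w``; ``frame`` is the raw detector intensity produced
    by emitters of channel ``channel`` only.
    """
    total = float(np.sum(frame))
    if total == 0.0:
        return 0.0
    other = np.zeros_like(channel_masks[0], dtype=bool)
    for w, mask in enumerate(channel_masks):
        if w != channel:
            other |= np.asarray(mask, dtype=bool)
    return float(np.sum(frame[other])) / total
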