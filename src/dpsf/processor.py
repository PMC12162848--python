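"""Geometry and coherent end-to-end propagation of the cascaded processor.

The processor is a stack of ``K`` phase-only surfaces of lateral extent
``W = sqrt(N / K) * pitch`` (``N`` features in total), separated by free-space
gaps ``d``.  The default gap preserves full optical connectivity between the
feature grids of successive layers,

    d = (W * pitch / lam) * sqrt(1 - (lam / (2 * pitch))**2),

i.e. light diffracting at the maximum grating angle of the feature pitch just
reaches the edge of the next layer.

The input volume holds ``C_i`` planes of ``H_i x W_i`` voxels; plane 1 is the
*farthest* from the first surface, at distance ``d_i``, and successive planes
step closer by the plane spacing ``d_pp``.  The output volume mirrors this:
plane ``C_o`` is farthest from the last surface, at ``d_o``.  The distances of
the farthest planes set the input/output numerical apertures,

    NA = eta_m * sin(arctan((W / 2) / d_i)),

which in turn bound the axial resolution ``2 * lam / NA**2``.

The emitters may be immersed in a dispersive medium (e.g. water); by default
the medium fills the axial segment from each input plane up to the first
surface, while all other segments are free space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .materials import VACUUM, Dispersion, max_full_cycle_thickness
from .surfaces import BitDepthPolicy, DiffractiveSurface, modulate
from .wave_optics import (
    DEFAULT_PITCH_OVER_WAVELENGTH,
    ComplexField,
    PropagationSpec,
    propagate,
)

__all__ = [
    "ProcessorGeometry",
    "EmitterVolume",
    "OutputVolume",
    "DiffractiveProcessor",
    "coherent_cascade",
    "point_psf",
    "numerical_aperture",
    "axial_diffraction_limit",
    "connectivity_layer_separation",
]

#: default axial plane-to-plane spacing, in units of the wavelength
DEFAULT_DPP_OVER_WAVELENGTH = 2.67

#: default ratio d_i / W, chosen to reproduce an input NA of ~0.81
DEFAULT_STANDOFF_OVER_WIDTH = 21.0 / 57.0


def numerical_aperture(layer_width: float, standoff: float, medium_index: float = 1.0) -> float:
    """NA of the farthest plane: ``eta_m * sin(arctan((W/2) / standoff))``."""
    if standoff <= 0:
        raise ValueError("standoff distance must be positive")
    return medium_index * np.sin(np.arctan((layer_width / 2.0) / standoff))


def axial_diffraction_limit(wavelength: float, na: float) -> float:
    """Axial two-point resolution limit ``2 * lam / NA**2``."""
    if not (0 < na <= 1.5):
        raise ValueError("numerical aperture out of range")
    return 2.0 * wavelength / na**2


def connectivity_layer_separation(layer_width: float, pitch: float, wavelength: float) -> float:
    """Layer gap at which the feature-pitch diffraction cone spans the next layer."""
    s = 1.0 - (wavelength / (2.0 * pitch)) ** 2
    if s <= 0:
        raise ValueError("pitch must exceed lam/2 for a propagating diffraction cone")
    return (layer_width * pitch / wavelength) * np.sqrt(s)


@dataclass
class ProcessorGeometry:
    """Axial and lateral layout of the cascaded diffractive processor."""

    n_surfaces: int
    features_per_side: int
    pitch: float
    layer_gap: float
    d_i: float
    d_o: float
    d_pp: float
    input_shape: tuple[int, int, int]  # (C_i, H_i, W_i)
    output_shape: tuple[int, int, int]  # (C_o, H_o, W_o)

    def __post_init__(self) -> None:
        if self.n_surfaces < 1:
            raise ValueError("need at least one surface")
        if self.features_per_side < 1:
            raise ValueError("features_per_side must be >= 1")
        for name in ("pitch", "layer_gap", "d_i", "d_o", "d_pp"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        ci, hi, wi = self.input_shape
        co, ho, wo = self.output_shape
        m = self.features_per_side
        if max(hi, wi, ho, wo) > m:
            raise ValueError("voxel plane does not fit within the layer grid")
        if self.d_i < (ci - 1) * self.d_pp:
            raise ValueError("d_i too small: nearest input plane behind surface 1")
        if self.d_o < (co - 1) * self.d_pp:
            raise ValueError("d_o too small: nearest output plane behind surface K")

    # -- derived quantities -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.n_surfaces * self.features_per_side**2

    @property
    def layer_width(self) -> float:
        return self.features_per_side * self.pitch

    @property
    def n_input_voxels(self) -> int:
        c, h, w = self.input_shape
        return c * h * w

    @property
    def n_output_voxels(self) -> int:
        c, h, w = self.output_shape
        return c * h * w

    def input_plane_distance(self, plane: int) -> float:
        """Distance from input plane ``plane`` (0-based) to the first surface.

        Plane 0 is farthest, at ``d_i``; successive planes are closer by
        ``d_pp``.
        """
        ci = self.input_shape[0]
        if not (0 <= plane < ci):
            raise IndexError(f"input plane {plane} out of range [0, {ci})")
        return self.d_i - plane * self.d_pp

    def output_plane_distance(self, plane: int) -> float:
        """Distance from the last surface to output plane ``plane`` (0-based).

        The last plane (index ``C_o - 1``) is farthest, at ``d_o``.
        """
        co = self.output_shape[0]
        if not (0 <= plane < co):
            raise IndexError(f"output plane {plane} out of range [0, {co})")
        return self.d_o - (co - 1 - plane) * self.d_pp

    def input_numerical_aperture(self, medium_index: float = 1.0) -> float:
        return numerical_aperture(self.layer_width, self.d_i, medium_index)

    def output_numerical_aperture(self) -> float:
        return numerical_aperture(self.layer_width, self.d_o)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_feature_count(
        cls,
        n_features: int,
        n_surfaces: int,
        wavelength: float,
        input_shape: tuple[int, int, int],
        output_shape: tuple[int, int, int],
        pitch: float | None = None,
        d_pp: float | None = None,
        d_i: float | None = None,
        d_o: float | None = None,
        layer_gap: float | None = None,
    ) -> "ProcessorGeometry":
        """Standard layout for ``N`` features over ``K`` surfaces.

        ``sqrt(N / K)`` must be an integer.  Defaults: pitch ``0.53 * lam``,
        plane spacing ``2.67 * lam``, layer gap from the connectivity formula,
        and farthest-plane standoffs ``d_i = d_o = (21/57) * W`` which give an
        input/output NA of about 0.81 independent of scale.
        """
        m = round(np.sqrt(n_features / n_surfaces))
        if m * m * n_surfaces != n_features:
            raise ValueError(
                f"N={n_features} features over K={n_surfaces} surfaces is not a "
                "square per-layer grid (sqrt(N/K) must be an integer)"
            )
        pitch = DEFAULT_PITCH_OVER_WAVELENGTH * wavelength if pitch is None else pitch
        d_pp = DEFAULT_DPP_OVER_WAVELENGTH * wavelength if d_pp is None else d_pp
        width = m * pitch
        if layer_gap is None:
            layer_gap = connectivity_layer_separation(width, pitch, wavelength)
        if d_i is None:
            d_i = DEFAULT_STANDOFF_OVER_WIDTH * width
        if d_o is None:
            d_o = DEFAULT_STANDOFF_OVER_WIDTH * width
        return cls(
            n_surfaces=n_surfaces,
            features_per_side=m,
            pitch=pitch,
            layer_gap=layer_gap,
            d_i=d_i,
            d_o=d_o,
            d_pp=d_pp,
            input_shape=tuple(input_shape),
            output_shape=tuple(output_shape),
        )


@dataclass
class EmitterVolume:
    """Nonnegative voxelized 3D emission intensity ``I[plane, row, col]``.

    ``wavelength_labels`` optionally assigns each voxel an index into a list
    of emission wavelengths (-1 for "no emitter"), for multispectral scenes.
    """

    intensity: np.ndarray
    pitch: float
    d_pp: float
    wavelength_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3D (planes, rows, cols) grid")
        if np.any(self.intensity < 0):
            raise ValueError("emission intensities must be nonnegative")
        if self.wavelength_labels is not None:
            self.wavelength_labels = np.asarray(self.wavelength_labels, dtype=np.int64)
            if self.wavelength_labels.shape != self.intensity.shape:
                raise ValueError("wavelength_labels must match the intensity grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    def vectorized(self) -> np.ndarray:
        """Plane-major, then row-major flattening: ``q = n*(H*W) + l*W + m``."""
        return self.intensity.reshape(-1)

    def channel_intensity(self, channel: int) -> np.ndarray:
        """Intensity of the voxels emitting at wavelength channel ``channel``."""
        if self.wavelength_labels is None:
            raise ValueError("volume carries no wavelength labels")
        return np.where(self.wavelength_labels == channel, self.intensity, 0.0)


@dataclass
class OutputVolume:
    """Nonnegative voxelized 3D output intensity with the same conventions."""

    intensity: np.ndarray
    pitch: float
    d_pp: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3D (planes, rows, cols) grid")
        if np.any(self.intensity < -1e-12):
            raise ValueError("output intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    def vectorized(self) -> np.ndarray:
        return self.intensity.reshape(-1)


@dataclass
class DiffractiveProcessor:
    """A full design: geometry, surfaces, design wavelengths and media."""

    geometry: ProcessorGeometry
    surfaces: list[DiffractiveSurface]
    wavelengths: list[float]
    input_medium: Dispersion = VACUUM
    policy: BitDepthPolicy = field(default_factory=BitDepthPolicy)
    pad_factor: int = 2
    open_aperture: bool = False

    def __post_init__(self) -> None:
        if len(self.surfaces) != self.geometry.n_surfaces:
            raise ValueError("number of surfaces does not match the geometry")
        m = self.geometry.features_per_side
        for s in self.surfaces:
            if s.latent.shape != (m, m):
                raise ValueError("surface feature grid does not match the geometry")
        if not self.wavelengths:
            raise ValueError("at least one design wavelength required")

    @property
    def multiwavelength(self) -> bool:
        return len(self.wavelengths) > 1

    @classmethod
    def initialize(
        cls,
        geometry: ProcessorGeometry,
        material: Dispersion,
        wavelengths: list[float],
        seed: int,
        t_max: float | None = None,
        input_medium: Dispersion = VACUUM,
        policy: BitDepthPolicy | None = None,
        pad_factor: int = 2,
    ) -> "DiffractiveProcessor":
        """Random initialization: latents i.i.d. uniform(-pi, pi)."""
        rng = np.random.default_rng(seed)
        if t_max is None:
            t_max = max_full_cycle_thickness(material, wavelengths)
        m = geometry.features_per_side
        surfaces = [
            DiffractiveSurface(
                latent=rng.uniform(-np.pi, np.pi, size=(m, m)),
                t_max=t_max,
                material=material,
                feature_pitch=geometry.pitch,
            )
            for _ in range(geometry.n_surfaces)
        ]
        return cls(
            geometry=geometry,
            surfaces=surfaces,
            wavelengths=list(wavelengths),
            input_medium=input_medium,
            policy=policy if policy is not None else BitDepthPolicy(),
            pad_factor=pad_factor,
        )

    def copy(self) -> "DiffractiveProcessor":
        return replace(
            self,
            surfaces=[replace(s, latent=s.latent.copy()) for s in self.surfaces],
            wavelengths=list(self.wavelengths),
        )


def _grid_embed(plane_values: np.ndarray, grid_side: int) -> np.ndarray:
    """Place an ``H x W`` voxel-plane array centred on the field grid."""
    h, w = plane_values.shape[-2:]
    out = np.zeros(plane_values.shape[:-2] + (grid_side, grid_side), dtype=np.complex128)
    oy, ox = (grid_side - h) // 2, (grid_side - w) // 2
    out[..., oy : oy + h, ox : ox + w] = plane_values
    return out


def _grid_extract(grid_values: np.ndarray, shape_hw: tuple[int, int]) -> np.ndarray:
    """Sample the centred ``H x W`` voxel block from the field grid."""
    h, w = shape_hw
    g = grid_values.shape[-1]
    oy, ox = (g - h) // 2, (g - w) // 2
    return grid_values[..., oy : oy + h, ox : ox + w]


def coherent_cascade(
    fld: ComplexField,
    proc: DiffractiveProcessor,
    input_plane: int,
    output_plane: int,
    bit_depth: int | None = None,
) -> ComplexField:
    """Propagate a coherent field from an input plane to an output plane.

    The path is: medium segment from the input plane to surface 1, then for
    each surface a modulation followed by the layer gap (no gap after the last
    surface), then free space to the requested output plane.  ``bit_depth``
    controls phase quantization at every surface (``None`` = continuous).
    """
    geom = proc.geometry
    d_first = geom.input_plane_distance(input_plane)
    medium_index = proc.input_medium.index_at(fld.wavelength)
    current = replace(fld, medium_index=medium_index)
    current = propagate(current, PropagationSpec(d_first, proc.pad_factor))
    current = replace(current, medium_index=1.0)
    for k, surf in enumerate(proc.surfaces):
        current = modulate(
            current,
            surf,
            bit_depth=bit_depth,
            multiwavelength=proc.multiwavelength,
            open_aperture=proc.open_aperture,
        )
        if k < len(proc.surfaces) - 1:
            current = propagate(current, PropagationSpec(geom.layer_gap, proc.pad_factor))
    d_last = geom.output_plane_distance(output_plane)
    return propagate(current, PropagationSpec(d_last, proc.pad_factor))


def surface_transmissions(
    proc: DiffractiveProcessor, wavelength: float, bit_depth: int | None
) -> list[np.ndarray]:
    """Complex transmission grids ``exp(j*phi_k)`` of all surfaces at one wavelength.

    On the simulation grid (which coincides with the layer feature grid) the
    blocking aperture is the full grid, so the transmissions are pure phase.
    """
    return [
        np.exp(
            1j
            * s.phase(wavelength, bit_depth=bit_depth, multiwavelength=proc.multiwavelength)
        )
        for s in proc.surfaces
    ]


class CascadeTape:
    """Intermediates of a batched coherent cascade, for the adjoint pass."""

    def __init__(self) -> None:
        self.surface_inputs: list[np.ndarray] = []  # field incident on surface k
        self.after_last: np.ndarray | None = None  # field leaving surface K
        self.transmissions: list[np.ndarray] = []


def run_cascade_batch(
    samples: np.ndarray,
    proc: DiffractiveProcessor,
    input_plane: int,
    wavelength: float,
    bit_depth: int | None,
    record: bool = False,
    transmissions: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, CascadeTape | None]:
    """Cascade a batch of fields from one input plane to all output planes.

    ``samples`` has shape ``(..., G, G)`` on the simulation grid.  Returns the
    complex fields at every output plane, shape ``(C_o, ..., G, G)``, and, when
    ``record`` is set, the tape of intermediates needed by backpropagation.
    """
    from .wave_optics import propagate_samples

    geom = proc.geometry
    pitch, pf = geom.pitch, proc.pad_factor
    lam_in = wavelength / proc.input_medium.index_at(wavelength)
    if transmissions is None:
        transmissions = surface_transmissions(proc, wavelength, bit_depth)
    tape = CascadeTape() if record else None
    if tape is not None:
        tape.transmissions = transmissions

    u = propagate_samples(
        samples, pitch, geom.input_plane_distance(input_plane), lam_in, pf
    )
    for k, trans in enumerate(transmissions):
        if tape is not None:
            tape.surface_inputs.append(u)
        u = u * trans
        if k < geom.n_surfaces - 1:
            u = propagate_samples(u, pitch, geom.layer_gap, wavelength, pf)
    if tape is not None:
        tape.after_last = u
    co = geom.output_shape[0]
    outs = np.empty((co,) + u.shape, dtype=np.complex128)
    for n in range(co):
        outs[n] = propagate_samples(
            u, pitch, geom.output_plane_distance(n), wavelength, pf
        )
    return outs, tape


def point_psf(
    proc: DiffractiveProcessor,
    voxel: tuple[int, int, int],
    wavelength: float | None = None,
    bit_depth: int | None = None,
) -> OutputVolume:
    """Incoherent 3D PSF of one input voxel: ``|h|**2`` over the output grid.

    A unit-amplitude impulse at the voxel is cascaded coherently to every
    output plane; the squared moduli sampled at the output voxel grid form the
    PSF.  A single emitter needs no phase averaging: its global phase cancels
    in the modulus.
    """
    geom = proc.geometry
    ci, hi, wi = geom.input_shape
    n_pl, row, col = voxel
    if not (0 <= n_pl < ci and 0 <= row < hi and 0 <= col < wi):
        raise IndexError(f"voxel {voxel} outside the input grid {geom.input_shape}")
    lam = proc.wavelengths[0] if wavelength is None else wavelength
    g = geom.features_per_side
    plane = np.zeros((hi, wi), dtype=np.complex128)
    plane[row, col] = 1.0
    fields, _ = run_cascade_batch(
        _grid_embed(plane, g), proc, n_pl, lam, bit_depth
    )
    _, ho, wo = geom.output_shape
    out = np.abs(_grid_extract(fields, (ho, wo))) ** 2
    return OutputVolume(out, geom.pitch, geom.d_pp)
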