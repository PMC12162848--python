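"""Phase-only diffractive surfaces.

Each surface is a thin transmissive element whose local phase delay at
wavelength ``lam`` is set by its physical thickness profile ``t_S``:

    phi_S(x, y) = (2*pi / lam) * (eta(lam) - 1) * t_S(x, y)

with ``eta(lam)`` the material's refractive index.  During optimization the
thickness is parametrized through an unconstrained latent variable,

    t_S = (t_max / 2) * (sin(t_latent) + 1),

which confines it smoothly to ``[0, t_max]``.  Finite fabrication precision is
modelled by quantizing the modulation to ``2**b`` uniform levels ("bit depth"
``b``); an unbounded bit depth means continuous modulation.

Quantization domain
-------------------
For a single design wavelength the phase itself is wrapped to ``[0, 2*pi)``
and snapped to the nearest of the ``2**b`` levels (with wrap-around, so values
closer to ``2*pi`` than to the top level map to level 0).  For multiwavelength
designs one physical thickness must serve every channel, so the *thickness* is
quantized to ``2**b`` uniform levels in ``[0, t_max]``; at the wavelength whose
full-cycle thickness equals ``t_max`` this coincides with phase quantization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import Dispersion

__all__ = [
    "BitDepthPolicy",
    "DiffractiveSurface",
    "thickness_from_latent",
    "phase_from_thickness",
    "quantize_phase",
    "quantize_thickness",
    "modulate",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class BitDepthPolicy:
    """Bit depths used while training and while evaluating a design.

    ``None`` denotes unbounded precision (continuous modulation).  A bounded
    bit depth ``b`` gives ``2**b`` discrete modulation levels.
    """

    b_train: int | None = None
    b_test: int | None = None

    def __post_init__(self) -> None:
        for b in (self.b_train, self.b_test):
            if b is not None and b < 1:
                raise ValueError("bit depth must be >= 1 or None (unbounded)")


def thickness_from_latent(latent: np.ndarray, t_max: float) -> np.ndarray:
    """Map unconstrained latents to thicknesses in ``[0, t_max]``."""
    return (t_max / 2.0) * (np.sin(np.asarray(latent, dtype=np.float64)) + 1.0)


def phase_from_thickness(
    thickness: np.ndarray, wavelength: float, material: Dispersion
) -> np.ndarray:
    """Unwrapped phase delay (radians) of a thickness profile at ``wavelength``."""
    eta = material.index_at(wavelength)
    if eta <= 1.0:
        raise ValueError("material refractive index must exceed 1")
    return (TWO_PI / wavelength) * (eta - 1.0) * np.asarray(thickness, dtype=np.float64)


def quantize_phase(phase: np.ndarray, bit_depth: int | None) -> np.ndarray:
    """Snap a phase map to ``2**b`` uniform levels in ``[0, 2*pi)``.

    The phase is first wrapped into ``[0, 2*pi)``; nearest-level rounding is
    performed on the phase circle, so a value nearer to ``2*pi`` than to the
    top level wraps to level 0.  Unbounded ``bit_depth`` returns the input
    unchanged (continuous modulation).
    """
    phase = np.asarray(phase, dtype=np.float64)
    if bit_depth is None:
        return phase
    if bit_depth < 1:
        raise ValueError("bit depth must be >= 1")
    levels = 2**bit_depth
    step = TWO_PI / levels
    wrapped = np.mod(phase, TWO_PI)
    return np.mod(np.round(wrapped / step), levels) * step


def quantize_thickness(
    thickness: np.ndarray, t_max: float, bit_depth: int | None
) -> np.ndarray:
    """Snap thicknesses to ``2**b`` uniform levels spanning ``[0, t_max]``.

    Levels are ``k * t_max / 2**b`` for ``k = 0..2**b - 1`` so that, at the
    wavelength whose full-cycle thickness is ``t_max``, the induced phases are
    exactly the ``2**b`` phase levels in ``[0, 2*pi)``.
    """
    thickness = np.asarray(thickness, dtype=np.float64)
    if bit_depth is None:
        return thickness
    if bit_depth < 1:
        raise ValueError("bit depth must be >= 1")
    step = t_max / 2**bit_depth
    return np.clip(np.round(thickness / step), 0, 2**bit_depth - 1) * step


@dataclass
class DiffractiveSurface:
    """One phase-only modulation layer of the processor.

    Parameters
    ----------
    latent:
        ``M x M`` grid of unconstrained latent values, one per feature.
    t_max:
        Maximum physical thickness (same length unit as wavelengths).
    material:
        Dispersion of the surface material.
    feature_pitch:
        Lateral feature size; equals the field sampling interval.
    """

    latent: np.ndarray
    t_max: float
    material: Dispersion
    feature_pitch: float

    def __post_init__(self) -> None:
        self.latent = np.asarray(self.latent, dtype=np.float64)
        if self.latent.ndim != 2 or self.latent.shape[0] != self.latent.shape[1]:
            raise ValueError("latent grid must be square (M x M)")
        if not (self.t_max > 0):
            raise ValueError("t_max must be positive")

    @property
    def n_features(self) -> int:
        return self.latent.size

    def thickness(self, bit_depth: int | None = None, multiwavelength: bool = False) -> np.ndarray:
        """Physical thickness map, optionally quantized (multiwavelength mode)."""
        t = thickness_from_latent(self.latent, self.t_max)
        if multiwavelength:
            t = quantize_thickness(t, self.t_max, bit_depth)
        return t

    def phase(
        self,
        wavelength: float,
        bit_depth: int | None = None,
        multiwavelength: bool = False,
    ) -> np.ndarray:
        """Phase map at ``wavelength`` under the given bit depth.

        Monochrome designs quantize the phase directly; multiwavelength
        designs quantize the shared thickness (see module docstring).
        """
        if multiwavelength:
            t = self.thickness(bit_depth=bit_depth, multiwavelength=True)
            return phase_from_thickness(t, wavelength, self.material)
        phi = phase_from_thickness(self.thickness(), wavelength, self.material)
        return quantize_phase(phi, bit_depth)


def aperture_mask(grid_shape: tuple[int, int], aperture_shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of a centred rectangular aperture on the field grid."""
    gy, gx = grid_shape
    ay, ax = aperture_shape
    if ay > gy or ax > gx:
        raise ValueError("aperture larger than field grid")
    mask = np.zeros(grid_shape, dtype=np.float64)
    oy, ox = (gy - ay) // 2, (gx - ax) // 2
    mask[oy : oy + ay, ox : ox + ax] = 1.0
    return mask


def modulate(
    fld,
    surface: DiffractiveSurface,
    bit_depth: int | None = None,
    multiwavelength: bool = False,
    open_aperture: bool = False,
):
    """Apply a surface's phase modulation to a field.

    Inside the ``W x W`` layer extent the field is multiplied by
    ``exp(j * phi)`` (amplitude unchanged); outside it the field is blocked
    (set to 0) unless ``open_aperture`` is set.  The field grid must match the
    surface's feature grid in pitch; the feature grid is centred on the field
    grid.
    """
    if not np.isclose(fld.pitch, surface.feature_pitch):
        raise ValueError("field pitch must equal the surface feature pitch")
    m = surface.latent.shape[0]
    gy, gx = fld.shape
    if m > gy or m > gx:
        raise ValueError("surface feature grid exceeds the field grid")
    phi = surface.phase(fld.wavelength, bit_depth=bit_depth, multiwavelength=multiwavelength)
    trans = np.ones(fld.shape, dtype=np.complex128)
    oy, ox = (gy - m) // 2, (gx - m) // 2
    trans[oy : oy + m, ox : ox + m] = np.exp(1j * phi)
    if not open_aperture:
        trans *= aperture_mask(fld.shape, (m, m))
    return fld.copy_with(fld.samples * trans)
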