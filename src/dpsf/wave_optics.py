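"""Scalar free-space propagation by the angular spectrum method.

A sampled complex field is decomposed into plane waves with the 2D FFT,
each plane wave is advanced by the free-space transfer function

    H(fx, fy; d) = exp(j * (2*pi/lam) * d * sqrt(1 - (lam*fx)**2 - (lam*fy)**2))

for propagating frequencies (``fx**2 + fy**2 < 1/lam**2``) and set to zero in
the evanescent band, and the field is re-synthesized with the inverse FFT.
Fields are zero-padded before the transforms so that the circular convolution
implied by the DFT does not wrap energy around the grid; the spatial-frequency
spacing of the padded grid is ``1/(n_pad * pitch)`` along each axis.

Propagation inside a homogeneous medium of refractive index ``eta_m`` uses the
effective wavelength ``lam / eta_m``.  Negative distances apply the conjugate
transfer function (back-propagation), which makes round-trip identities exact
on the propagating band.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ComplexField",
    "PropagationSpec",
    "transfer_function",
    "propagate",
]

#: default lateral sampling interval, in units of the wavelength
DEFAULT_PITCH_OVER_WAVELENGTH = 0.53


@dataclass
class ComplexField:
    """A sampled 2D complex optical field at a single axial plane.

    Parameters
    ----------
    samples:
        2D complex array of field amplitudes, ``samples[row, col]``.
    pitch:
        Lateral sampling interval (same length unit as ``wavelength``).
    wavelength:
        Vacuum wavelength of the monochromatic field.
    medium_index:
        Refractive index of the surrounding homogeneous medium (>= 1).
    """

    samples: np.ndarray
    pitch: float
    wavelength: float
    medium_index: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 2 or min(self.samples.shape) < 1:
            raise ValueError("field samples must form a non-empty 2D grid")
        if not (self.pitch > 0):
            raise ValueError("pitch must be positive")
        if not (self.wavelength > 0):
            raise ValueError("wavelength must be positive")
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.samples.shape

    @property
    def effective_wavelength(self) -> float:
        """Wavelength inside the medium, ``wavelength / medium_index``."""
        return self.wavelength / self.medium_index

    def power(self) -> float:
        """Total power ``sum |u|**2`` over the grid."""
        return float(np.sum(np.abs(self.samples) ** 2))

    def copy_with(self, samples: np.ndarray) -> "ComplexField":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class PropagationSpec:
    """Axial propagation step: signed distance and FFT padding factor."""

    distance: float
    pad_factor: int = 2

    def __post_init__(self) -> None:
        if not np.isfinite(self.distance):
            raise ValueError("distance must be finite")
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")


def transfer_function(
    fx: np.ndarray | float,
    fy: np.ndarray | float,
    distance: float,
    wavelength: float,
) -> np.ndarray:
    """Free-space angular-spectrum transfer function with evanescent cutoff.

    ``wavelength`` is the *effective* wavelength ``lam / eta_m`` when the
    segment lies inside a medium of index ``eta_m``.  Returns a unit-modulus
    phase factor on the propagating band and exactly 0 where
    ``fx**2 + fy**2 >= 1/wavelength**2``.
    """
    fx = np.asarray(fx, dtype=np.float64)
    fy = np.asarray(fy, dtype=np.float64)
    if not (wavelength > 0):
        raise ValueError("wavelength must be positive")
    if not np.isfinite(distance):
        raise ValueError("distance must be finite")
    if not (np.all(np.isfinite(fx)) and np.all(np.isfinite(fy))):
        raise ValueError("spatial frequencies must be finite")

    arg = 1.0 - (wavelength * fx) ** 2 - (wavelength * fy) ** 2
    propagating = arg > 0.0
    kz = np.sqrt(np.where(propagating, arg, 0.0))
    h = np.exp(1j * (2.0 * np.pi / wavelength) * distance * kz)
    return np.where(propagating, h, 0.0 + 0.0j)


def _padded_transfer(
    shape: tuple[int, int],
    pitch: float,
    distance: float,
    wavelength: float,
    pad_factor: int,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Transfer function sampled on the padded DFT frequency grid."""
    ny, nx = shape
    pny, pnx = ny * pad_factor, nx * pad_factor
    fy = np.fft.fftfreq(pny, d=pitch)[:, None]
    fx = np.fft.fftfreq(pnx, d=pitch)[None, :]
    return transfer_function(fx, fy, distance, wavelength), (pny, pnx)


def propagate_samples(
    samples: np.ndarray,
    pitch: float,
    distance: float,
    wavelength: float,
    pad_factor: int = 2,
    conjugate_transfer: bool = False,
) -> np.ndarray:
    """Angular-spectrum propagation of raw samples (supports leading batch axes).

    ``conjugate_transfer=True`` applies ``conj(H)`` instead of ``H``; because
    zero-padding is self-adjoint with cropping, this is exactly the adjoint of
    the forward step and is used by the training backward pass.
    """
    samples = np.asarray(samples, dtype=np.complex128)
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    ny, nx = samples.shape[-2:]
    h, (pny, pnx) = _padded_transfer((ny, nx), pitch, distance, wavelength, pad_factor)
    if conjugate_transfer:
        h = np.conj(h)
    padded = np.zeros(samples.shape[:-2] + (pny, pnx), dtype=np.complex128)
    padded[..., :ny, :nx] = samples
    spectrum = np.fft.fft2(padded)
    out = np.fft.ifft2(spectrum * h)
    # centering of the pad is immaterial: the DFT convolution kernel is
    # applied circularly, so the leading corner block is the original window
    return out[..., :ny, :nx]


def propagate(fld: ComplexField, spec: PropagationSpec) -> ComplexField:
    """Propagate a field by ``spec.distance`` along the optical axis.

    The output grid, pitch and wavelength are identical to the input's; the
    effective wavelength of the field's medium is used in the transfer
    function.  ``distance`` may be zero or negative.
    """
    out = propagate_samples(
        fld.samples,
        fld.pitch,
        spec.distance,
        fld.effective_wavelength,
        pad_factor=spec.pad_factor,
    )
    return fld.copy_with(out)
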