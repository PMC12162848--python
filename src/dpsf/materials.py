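"""Refractive-index dispersion tables for diffractive materials and media.

A :class:`Dispersion` is an explicit table of vacuum wavelength -> refractive
index.  Lookups require an entry for the requested wavelength (within a tiny
relative tolerance); no interpolation is performed, so a design can only be
evaluated at wavelengths for which the material is characterized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Dispersion",
    "VACUUM",
    "THZ_POLYMER",
    "VISIBLE_POLYMER",
    "WATER_VISIBLE",
]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class Dispersion:
    """Wavelength -> refractive index table for one material."""

    name: str
    table: dict[float, float] = field(default_factory=dict)
    constant_index: float | None = None

    @classmethod
    def constant(cls, index: float, name: str = "constant") -> "Dispersion":
        """Dispersionless material with the same index at every wavelength."""
        return cls(name=name, constant_index=float(index))

    def index_at(self, wavelength: float) -> float:
        if self.constant_index is not None:
            return self.constant_index
        for lam, eta in self.table.items():
            if abs(lam - wavelength) <= _REL_TOL * max(abs(lam), abs(wavelength)):
                return eta
        raise KeyError(
            f"no dispersion entry for wavelength {wavelength!r} in material "
            f"{self.name!r}; known wavelengths: {sorted(self.table)}"
        )

    def wavelengths(self) -> list[float]:
        return sorted(self.table)


#: free space / non-dispersive surround
VACUUM = Dispersion.constant(1.0, name="vacuum")

#: 3D-printable polymer at THz wavelengths (lengths in micrometres)
THZ_POLYMER = Dispersion(
    name="thz-polymer",
    table={725.0: 1.6515, 750.0: 1.6518, 775.0: 1.6521},
)

#: photopolymer in the visible (lengths in micrometres)
VISIBLE_POLYMER = Dispersion(
    name="visible-polymer",
    table={0.580: 1.4587, 0.600: 1.4580, 0.620: 1.4574},
)

#: water as an immersion medium in the visible (lengths in micrometres)
WATER_VISIBLE = Dispersion(
    name="water",
    table={0.580: 1.3328, 0.600: 1.3320, 0.620: 1.3320},
)


def max_full_cycle_thickness(material: Dispersion, wavelengths: list[float]) -> float:
    """Default thickness ceiling: the largest lam/(eta(lam)-1) over channels.

    For a single wavelength this gives a phase modulation depth of exactly
    2*pi; for multiwavelength designs every channel reaches at least 2*pi.
    """
    if not wavelengths:
        raise ValueError("at least one wavelength required")
    vals = []
    for lam in wavelengths:
        eta = material.index_at(lam)
        if eta <= 1.0:
            raise ValueError("material index must exceed 1 for phase modulation")
        vals.append(lam / (eta - 1.0))
    return float(np.max(vals))
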