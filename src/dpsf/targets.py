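"""Target intensity transformations and detector-pixel multiplexing layouts.

Two families of design targets are provided:

* **Random-uniform targets** — every entry of ``A`` i.i.d. uniform(0, 1),
  standing in for an arbitrary set of spatially varying 3D PSFs.  Used for
  capacity and precision studies.
* **Kronecker imaging targets** — ``A[p, q] = 1`` iff input voxel ``q`` is
  assigned to output pixel ``p`` (and 0 elsewhere), realizing snapshot 3D
  (and multispectral 3D) imaging onto a single detector plane.

For the imaging targets, detector pixels are grouped into *superpixels*: one
superpixel per lateral input pixel, whose constituent pixels are assigned to
the (input plane, wavelength channel) pairs.  Imaging then requires no
reconstruction: demultiplexing is a pure rearrangement of detector pixel
values.  Detector pixels left unassigned inside a superpixel (when
``C_i * n_channels`` is not a perfect square) carry an explicit all-zero
target row, so optimization suppresses any light routed there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .incoherent import TransformMatrix

__all__ = [
    "SuperpixelLayout",
    "random_uniform_target",
    "snapshot3d_target",
    "multispectral_target",
    "multiplex",
    "demultiplex",
]


@dataclass(frozen=True)
class SuperpixelLayout:
    """Assignment of (input plane, wavelength) pairs to superpixel offsets.

    The detector plane holds one superpixel of ``block_side x block_side``
    pixels per lateral input pixel.  Constituent ``(plane, channel)`` pairs
    are packed row-major into the block: pair index ``j = plane * n_channels
    + channel`` sits at offset ``(j // block_side, j % block_side)``.
    """

    input_planes: int
    lateral_shape: tuple[int, int]  # (H_i, W_i)
    n_channels: int = 1

    def __post_init__(self) -> None:
        if self.input_planes < 1 or self.n_channels < 1:
            raise ValueError("need at least one input plane and one channel")
        if min(self.lateral_shape) < 1:
            raise ValueError("lateral shape must be positive")

    @property
    def block_side(self) -> int:
        return int(np.ceil(np.sqrt(self.input_planes * self.n_channels)))

    @property
    def detector_shape(self) -> tuple[int, int]:
        h, w = self.lateral_shape
        s = self.block_side
        return (h * s, w * s)

    @property
    def output_shape(self) -> tuple[int, int, int]:
        """Output voxel grid: a single detector plane."""
        return (1,) + self.detector_shape

    @property
    def n_output_pixels(self) -> int:
        h, w = self.detector_shape
        return h * w

    def constituent_offset(self, plane: int, channel: int = 0) -> tuple[int, int]:
        """Offset of the (plane, channel) constituent within its superpixel."""
        if not (0 <= plane < self.input_planes):
            raise IndexError(f"plane {plane} out of range")
        if not (0 <= channel < self.n_channels):
            raise IndexError(f"channel {channel} out of range")
        j = plane * self.n_channels + channel
        s = self.block_side
        return (j // s, j % s)

    def pixel_of_voxel(self, voxel: tuple[int, int, int], channel: int = 0) -> tuple[int, int]:
        """Detector (row, col) assigned to an input voxel at a channel."""
        n, l, m = voxel
        h, w = self.lateral_shape
        if not (0 <= l < h and 0 <= m < w):
            raise IndexError(f"lateral voxel index {(l, m)} out of range")
        dy, dx = self.constituent_offset(n, channel)
        s = self.block_side
        return (l * s + dy, m * s + dx)

    def pixel_index(self, voxel: tuple[int, int, int], channel: int = 0) -> int:
        row, col = self.pixel_of_voxel(voxel, channel)
        return row * self.detector_shape[1] + col

    def channel_mask(self, channel: int) -> np.ndarray:
        """Boolean detector mask of all pixels assigned to one channel."""
        mask = np.zeros(self.detector_shape, dtype=bool)
        h, w = self.lateral_shape
        for n in range(self.input_planes):
            for l in range(h):
                for m in range(w):
                    mask[self.pixel_of_voxel((n, l, m), channel)] = True
        return mask

    def plane_channel_mask(self, plane: int, channel: int = 0) -> np.ndarray:
        mask = np.zeros(self.detector_shape, dtype=bool)
        h, w = self.lateral_shape
        for l in range(h):
            for m in range(w):
                mask[self.pixel_of_voxel((plane, l, m), channel)] = True
        return mask


def random_uniform_target(
    n_out: int,
    n_in: int,
    seed: int,
    input_shape: tuple[int, int, int] | None = None,
    output_shape: tuple[int, int, int] | None = None,
) -> TransformMatrix:
    """Arbitrary nonnegative target: entries i.i.d. uniform(0, 1)."""
    if n_out < 1 or n_in < 1:
        raise ValueError("matrix dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    return TransformMatrix(
        rng.uniform(0.0, 1.0, size=(n_out, n_in)),
        role="target",
        input_shape=input_shape,
        output_shape=output_shape,
    )


def snapshot3d_target(layout: SuperpixelLayout) -> TransformMatrix:
    """Kronecker imaging target for single-wavelength snapshot 3D imaging.

    One unit entry per column (each voxel maps to exactly one detector
    pixel); rows of unassigned pixels are all-zero.  When every superpixel
    cell is used (``C_i`` a perfect square) the matrix is a permutation.
    """
    if layout.n_channels != 1:
        raise ValueError("snapshot3d_target is single-wavelength; use multispectral_target")
    ci = layout.input_planes
    h, w = layout.lateral_shape
    n_i = ci * h * w
    a = np.zeros((layout.n_output_pixels, n_i), dtype=np.float64)
    for n in range(ci):
        for l in range(h):
            for m in range(w):
                q = n * (h * w) + l * w + m
                a[layout.pixel_index((n, l, m)), q] = 1.0
    return TransformMatrix(
        a,
        role="target",
        input_shape=(ci, h, w),
        output_shape=layout.output_shape,
    )


def multispectral_target(layout: SuperpixelLayout) -> list[TransformMatrix]:
    """Per-wavelength Kronecker targets ``{A_w}`` for multispectral imaging.

    ``A_w[p, q] = 1`` iff voxel ``q`` emitting at channel ``w`` maps to pixel
    ``p``; all pixels assigned to *other* channels (and unassigned pixels)
    have explicit zero rows in ``A_w``, so the optimization actively
    suppresses spectral cross-talk rather than assuming it away.
    """
    if layout.n_channels < 2:
        raise ValueError("multispectral_target needs >= 2 wavelength channels")
    ci = layout.input_planes
    h, w = layout.lateral_shape
    n_i = ci * h * w
    out = []
    for ch in range(layout.n_channels):
        a = np.zeros((layout.n_output_pixels, n_i), dtype=np.float64)
        for n in range(ci):
            for l in range(h):
                for m in range(w):
                    q = n * (h * w) + l * w + m
                    a[layout.pixel_index((n, l, m), ch), q] = 1.0
        out.append(
            TransformMatrix(
                a,
                role="target",
                input_shape=(ci, h, w),
                output_shape=layout.output_shape,
            )
        )
    return out


def multiplex(
    images: np.ndarray, layout: SuperpixelLayout
) -> np.ndarray:
    """Assemble per-(plane, channel) images into one raw detector frame.

    ``images`` has shape ``(C_i, n_channels, H_i, W_i)`` (the channel axis
    may be omitted when ``n_channels == 1``).  Unassigned detector pixels are
    set to 0.
    """
    imgs = np.asarray(images, dtype=np.float64)
    if imgs.ndim == 3:
        imgs = imgs[:, None]
    ci, nch, h, w = imgs.shape
    if (ci, nch) != (layout.input_planes, layout.n_channels) or (h, w) != layout.lateral_shape:
        raise ValueError("image stack does not match the layout")
    frame = np.zeros(layout.detector_shape, dtype=np.float64)
    s = layout.block_side
    for n in range(ci):
        for ch in range(nch):
            dy, dx = layout.constituent_offset(n, ch)
            frame[dy::s, dx::s] = imgs[n, ch]
    return frame


def demultiplex(frame: np.ndarray, layout: SuperpixelLayout) -> np.ndarray:
    """Rearrange a raw detector frame into per-(plane, channel) images.

    The exact inverse of :func:`multiplex` on assigned pixels — a pure index
    rearrangement that preserves pixel values.  Returns shape
    ``(C_i, n_channels, H_i, W_i)``.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != layout.detector_shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match detector {layout.detector_shape}"
        )
    s = layout.block_side
    out = np.empty(
        (layout.input_planes, layout.n_channels) + layout.lateral_shape, dtype=np.float64
    )
    for n in range(layout.input_planes):
        for ch in range(layout.n_channels):
            dy, dx = layout.constituent_offset(n, ch)
            out[n, ch] = frame[dy::s, dx::s]
    return out
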