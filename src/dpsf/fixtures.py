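"""Seeded synthetic inputs: sparse emitter volumes for simulation and tests.

The generator emulates sparsely labelled fluorescent scenes: a handful of
independent point emitters scattered over the voxel grid, each with an
emission intensity drawn uniformly from [0.5, 1.0] and, for multispectral
scenes, a randomly assigned emission-wavelength channel.
"""

from __future__ import annotations

import numpy as np

from .processor import EmitterVolume

__all__ = ["generate_emitter_volume"]


def generate_emitter_volume(
    input_shape: tuple[int, int, int],
    n_emitters: int,
    seed: int,
    pitch: float = 0.53,
    d_pp: float = 2.67,
    n_channels: int = 1,
) -> EmitterVolume:
    """Sparse nonnegative emitter volume with ``n_emitters`` occupied voxels.

    Emitter voxels are sampled without replacement over the whole grid;
    intensities are i.i.d. uniform(0.5, 1.0).  With ``n_channels > 1`` each
    emitter is labelled with a wavelength-channel index (unoccupied voxels
    carry the label -1).  Fully reproducible under ``seed``.
    """
    ci, h, w = input_shape
    n_vox = ci * h * w
    if not (0 <= n_emitters <= n_vox):
        raise ValueError(f"n_emitters={n_emitters} exceeds the {n_vox}-voxel grid")
    rng = np.random.default_rng(seed)
    intensity = np.zeros(n_vox, dtype=np.float64)
    labels = None
    if n_emitters > 0:
        idx = rng.choice(n_vox, size=n_emitters, replace=False)
        intensity[idx] = rng.uniform(0.5, 1.0, size=n_emitters)
        if n_channels > 1:
            labels = np.full(n_vox, -1, dtype=np.int64)
            labels[idx] = rng.integers(0, n_channels, size=n_emitters)
    elif n_channels > 1:
        labels = np.full(n_vox, -1, dtype=np.int64)
    return EmitterVolume(
        intensity.reshape(input_shape),
        pitch=pitch,
        d_pp=d_pp,
        wavelength_labels=None if labels is None else labels.reshape(input_shape),
    )
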