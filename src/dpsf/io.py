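"""Persistence: designs and matrices in HDF5, maps in float TIFF, traces in CSV.

All float data round-trips losslessly (float64 in HDF5; thickness/phase maps
and detector frames as 32-bit float TIFF as fabrication/preview exports).
Transformation matrices record the voxel vectorization convention
(plane-major, then row-major) as an HDF5 attribute.  Run manifests are JSON
documents carrying the full configuration echo, seeds, package version,
per-stage timings and final metrics — enough to re-execute a run
bit-identically in a single-threaded session.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

from . import __version__
from .materials import Dispersion
from .incoherent import TransformMatrix
from .processor import DiffractiveProcessor, ProcessorGeometry
from .surfaces import BitDepthPolicy, DiffractiveSurface

__all__ = [
    "RunManifest",
    "save_design",
    "load_design",
    "save_matrix",
    "load_matrix",
    "write_thickness_tiff",
    "read_thickness_tiff",
    "write_trace_csv",
    "read_trace_csv",
    "save_png_preview",
]

VECTORIZATION_NOTE = "plane-major then row-major: q = plane*(H*W) + row*W + col"


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Reproducibility record for one CLI or library run."""

    command: str
    config: dict
    seeds: dict
    version: str = __version__
    timings_s: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    _t0: float = field(default_factory=time.perf_counter, repr=False)

    def time_stage(self, name: str) -> None:
        now = time.perf_counter()
        self.timings_s[name] = round(now - self._t0, 6)
        self._t0 = now

    def save(self, path: str | Path) -> None:
        doc = {
            "command": self.command,
            "version": self.version,
            "config": self.config,
            "seeds": self.seeds,
            "timings_s": self.timings_s,
            "metrics": self.metrics,
        }
        Path(path).write_text(json.dumps(doc, indent=2, default=_jsonify) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        doc = json.loads(Path(path).read_text())
        return cls(
            command=doc["command"],
            config=doc["config"],
            seeds=doc["seeds"],
            version=doc.get("version", "unknown"),
            timings_s=doc.get("timings_s", {}),
            metrics=doc.get("metrics", {}),
        )


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def _write_dispersion(grp: h5py.Group, disp: Dispersion) -> None:
    grp.attrs["name"] = disp.name
    if disp.constant_index is not None:
        grp.attrs["constant_index"] = disp.constant_index
    else:
        lams = sorted(disp.table)
        grp.create_dataset("wavelengths", data=np.asarray(lams))
        grp.create_dataset("indices", data=np.asarray([disp.table[l] for l in lams]))


def _read_dispersion(grp: h5py.Group) -> Dispersion:
    name = str(grp.attrs["name"])
    if "constant_index" in grp.attrs:
        return Dispersion.constant(float(grp.attrs["constant_index"]), name=name)
    lams = grp["wavelengths"][()]
    etas = grp["indices"][()]
    return Dispersion(name=name, table={float(l): float(e) for l, e in zip(lams, etas)})


def save_design(proc: DiffractiveProcessor, path: str | Path) -> None:
    """Persist a full design (geometry, latents, materials, policy) to HDF5."""
    geom = proc.geometry
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["package_version"] = __version__
        g = f.create_group("geometry")
        for name in (
            "n_surfaces",
            "features_per_side",
            "pitch",
            "layer_gap",
            "d_i",
            "d_o",
            "d_pp",
        ):
            g.attrs[name] = getattr(geom, name)
        g.attrs["input_shape"] = geom.input_shape
        g.attrs["output_shape"] = geom.output_shape
        f.attrs["wavelengths"] = np.asarray(proc.wavelengths)
        f.attrs["pad_factor"] = proc.pad_factor
        f.attrs["open_aperture"] = proc.open_aperture
        pol = f.create_group("policy")
        pol.attrs["b_train"] = -1 if proc.policy.b_train is None else proc.policy.b_train
        pol.attrs["b_test"] = -1 if proc.policy.b_test is None else proc.policy.b_test
        _write_dispersion(f.create_group("input_medium"), proc.input_medium)
        surfs = f.create_group("surfaces")
        for k, s in enumerate(proc.surfaces):
            sg = surfs.create_group(f"{k:03d}")
            sg.create_dataset("latent", data=s.latent)
            sg.attrs["t_max"] = s.t_max
            sg.attrs["feature_pitch"] = s.feature_pitch
            _write_dispersion(sg.create_group("material"), s.material)


def load_design(path: str | Path) -> DiffractiveProcessor:
    with h5py.File(path, "r") as f:
        if int(f.attrs["format_version"]) != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported design format version {f.attrs['format_version']}"
            )
        g = f["geometry"]
        geom = ProcessorGeometry(
            n_surfaces=int(g.attrs["n_surfaces"]),
            features_per_side=int(g.attrs["features_per_side"]),
            pitch=float(g.attrs["pitch"]),
            layer_gap=float(g.attrs["layer_gap"]),
            d_i=float(g.attrs["d_i"]),
            d_o=float(g.attrs["d_o"]),
            d_pp=float(g.attrs["d_pp"]),
            input_shape=tuple(int(v) for v in g.attrs["input_shape"]),
            output_shape=tuple(int(v) for v in g.attrs["output_shape"]),
        )
        b_tr = int(f["policy"].attrs["b_train"])
        b_te = int(f["policy"].attrs["b_test"])
        policy = BitDepthPolicy(
            b_train=None if b_tr < 0 else b_tr, b_test=None if b_te < 0 else b_te
        )
        surfaces = []
        for key in sorted(f["surfaces"]):
            sg = f["surfaces"][key]
            surfaces.append(
                DiffractiveSurface(
                    latent=sg["latent"][()],
                    t_max=float(sg.attrs["t_max"]),
                    material=_read_dispersion(sg["material"]),
                    feature_pitch=float(sg.attrs["feature_pitch"]),
                )
            )
        return DiffractiveProcessor(
            geometry=geom,
            surfaces=surfaces,
            wavelengths=[float(l) for l in f.attrs["wavelengths"]],
            input_medium=_read_dispersion(f["input_medium"]),
            policy=policy,
            pad_factor=int(f.attrs["pad_factor"]),
            open_aperture=bool(f.attrs["open_aperture"]),
        )


# ---------------------------------------------------------------------------
# matrices, maps, traces
# ---------------------------------------------------------------------------


def save_matrix(matrix: TransformMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("entries", data=matrix.entries)
        d.attrs["role"] = matrix.role
        d.attrs["vectorization"] = VECTORIZATION_NOTE
        if matrix.input_shape is not None:
            d.attrs["input_shape"] = matrix.input_shape
        if matrix.output_shape is not None:
            d.attrs["output_shape"] = matrix.output_shape


def load_matrix(path: str | Path) -> TransformMatrix:
    with h5py.File(path, "r") as f:
        d = f["entries"]
        return TransformMatrix(
            d[()],
            role=str(d.attrs["role"]),
            input_shape=(
                tuple(int(v) for v in d.attrs["input_shape"])
                if "input_shape" in d.attrs
                else None
            ),
            output_shape=(
                tuple(int(v) for v in d.attrs["output_shape"])
                if "output_shape" in d.attrs
                else None
            ),
        )


def write_thickness_tiff(maps: np.ndarray, path: str | Path) -> None:
    """Export thickness/phase maps (or a detector frame) as 32-bit float TIFF."""
    tifffile.imwrite(
        str(path), np.asarray(maps, dtype=np.float32), photometric="minisblack"
    )


def read_thickness_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_trace_csv(path: str | Path, trace, header: tuple[str, ...] = ("iteration", "loss")) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i, row in enumerate(np.atleast_1d(trace)):
            if np.ndim(row) == 0:
                writer.writerow([i, repr(float(row))])
            else:
                writer.writerow(list(row))


def read_trace_csv(path: str | Path) -> np.ndarray:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        return np.asarray([float(row[-1]) for row in reader])


def save_png_preview(image: np.ndarray, path: str | Path, title: str = "") -> None:
    """Quick-look PNG of a 2D map (thickness, phase or detector frame)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(np.asarray(image), cmap="viridis")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(str(path), dpi=120, bbox_inches="tight")
    plt.close(fig)
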