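"""NIfTI volume I/O, run configuration and provenance.

Conventions: NIfTI-1 (.nii/.nii.gz) for volumes; geometry (affine, voxel
dims) is carried solely by the volume header and preserved bit-exactly on
round trip.  4-D echo volumes are stored spatial-first (X, Y, Z, echo) on
disk — the NIfTI convention — and transposed to echo-first in memory.
CSV: UTF-8, comma, header row, '.' decimal, missing = empty cell.
Every pipeline run writes its resolved configuration and a provenance JSON
(seed, package version) beside the outputs so reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from ._errors import ValidationError

__all__ = [
    "RunConfig",
    "read_volume",
    "write_volume",
    "write_provenance",
    "echo_train_to_csv",
]


def echo_train_to_csv(train, path) -> None:
    """Export an echo train as CSV with columns echo_index, TE_ms, amplitude."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["echo_index", "TE_ms", "amplitude"])
        for i, (te, amp) in enumerate(zip(train.echo_times, train.amplitudes), start=1):
            w.writerow([i, repr(float(te)), repr(float(amp))])


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns ``(data, affine)``.

    3-D volumes come back as-is; 4-D volumes keep the on-disk axis order
    (X, Y, Z, echo) — use :func:`to_echo_first` for the fitting layout.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValidationError(f"cannot read NIfTI volume {path}: {exc}") from exc
    return np.asarray(img.dataobj), img.affine.copy()


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write an array as NIfTI-1 with the given affine."""
    data = np.asarray(data)
    img = nib.Nifti1Image(data, affine)
    nib.save(img, str(path))


def to_echo_first(data: np.ndarray) -> np.ndarray:
    """(X, Y, Z, E) on-disk layout -> (E, X, Y, Z) fitting layout."""
    if data.ndim != 4:
        raise ValidationError(f"expected a 4-D echo volume, got shape {data.shape}")
    return np.moveaxis(data, -1, 0)


def to_echo_last(data: np.ndarray) -> np.ndarray:
    """(E, X, Y, Z) -> (X, Y, Z, E)."""
    return np.moveaxis(data, 0, -1)


def affine_from_voxel_dims(voxel_dims) -> np.ndarray:
    dx, dy, dz = voxel_dims
    return np.diag([dx, dy, dz, 1.0])


def voxel_dims_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    # NIfTI-1 headers carry the affine in float32; round at header precision
    # so e.g. 1.8 survives the round trip as 1.8, not 1.79999995
    a = np.asarray(affine, dtype=float)
    return tuple(float(np.round(np.linalg.norm(a[:3, i]), 6)) for i in range(3))


@dataclasses.dataclass
class RunConfig:
    """Fully serialisable pipeline configuration.

    Groups the sequence parameters, fit tolerances, CSF/normalisation
    settings, conventions and seeds used by a run; written beside every
    output directory so the run can be reproduced byte-identically.
    """

    n_echoes: int = 10
    echo_spacing: float = 15.0
    repetition_time: float = 4.8
    nominal_flip: float = 180.0
    assumed_T1: float = 1000.0
    fit_tol: float = 1e-4
    max_iter: int = 25
    noise_floor: float = 0.0
    csf_t2_min: float = 400.0
    csf_min_component: int = 10
    min_csf_voxels: int = 20
    csf_percentile: float = 98.0
    percentile_convention: str = "linear"
    aggregation_convention: str = "pooled_voxel_median"
    slice_axis: int = -1
    voxel_dims: tuple[float, float, float] = (1.5, 1.5, 1.8)
    seed: int = 0

    def sequence_params(self):
        from .epg import SequenceParams

        return SequenceParams(
            n_echoes=self.n_echoes,
            echo_spacing=self.echo_spacing,
            repetition_time=self.repetition_time,
            nominal_flip=self.nominal_flip,
            assumed_T1=self.assumed_T1,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["voxel_dims"] = list(d["voxel_dims"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "voxel_dims" in d:
            d = {**d, "voxel_dims": tuple(d["voxel_dims"])}
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d or {})


def write_provenance(out_dir, config: RunConfig, extra: dict | None = None) -> None:
    """Write resolved config (YAML) and provenance (JSON) into ``out_dir``.

    Deliberately timestamp-free: identical config + seed must rerun to
    byte-identical outputs.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    prov = {"package": "drgpd", "version": __version__, "seed": config.seed}
    if extra:
        prov.update(extra)
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
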