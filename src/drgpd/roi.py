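"""ROI metrics: CSF-normalised DRG proton density, DRG T2 and DRG volume.

The subject-level imaging metrics are computed from the quantitative maps
plus an integer label volume:

* ``DRG-PD`` — median corrected M0 over DRG voxels, normalised slice-wise by
  the 98th percentile of CSF M0 (CSF proton density defines unity);
* ``DRG-T2`` — median corrected T2 over DRG voxels (ms);
* ``DRG-Vol`` — labelled voxel count times voxel volume (mm^3).

Label code book: 0 background, 1 CSF, 10/11 L5 left/right, 20/21 S1
left/right.  The slice axis is the last array axis (paracoronal
acquisition); per-slice CSF normalisers guard against residual B1/coil
shading along the slice direction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from ._errors import ValidationError
from .relaxometry import QuantMaps

__all__ = [
    "LABEL_CODES",
    "DRG_LABELS",
    "CSF_LABEL",
    "LabelVolume",
    "DRGMetrics",
    "csf_mask_auto",
    "normalize_slicewise",
    "drg_metrics",
]

LABEL_CODES = {
    0: "background",
    1: "csf",
    10: "L5_left",
    11: "L5_right",
    20: "S1_left",
    21: "S1_right",
}
CSF_LABEL = 1
DRG_LABELS = (10, 11, 20, 21)


@dataclasses.dataclass
class LabelVolume:
    """Integer ROI masks aligned to the quantitative maps."""

    labels: np.ndarray
    voxel_dims: tuple[float, float, float] = (1.5, 1.5, 1.8)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValidationError("labels must be an integer array")
        if np.any(lab < 0):
            raise ValidationError("labels must be non-negative")
        self.labels = lab

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def drg_mask(self) -> np.ndarray:
        return np.isin(self.labels, DRG_LABELS)

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz


@dataclasses.dataclass
class DRGMetrics:
    """Per-subject DRG metrics with the per-ganglion breakdown."""

    drg_pd: float
    drg_t2: float
    drg_vol: float
    per_ganglion: pd.DataFrame
    n_voxels: dict[int, int]
    slices_used: list[int]


def csf_mask_auto(
    maps: QuantMaps,
    t2_min: float = 400.0,
    pd_min: float | None = None,
    min_component: int = 10,
    labels: LabelVolume | None = None,
) -> tuple[np.ndarray, bool]:
    """Automatic CSF mask from the corrected maps, returning ``(mask, found)``.

    CSF is long-T2, high-M0 fluid: voxels with ``T2 > t2_min`` and
    ``M0 > pd_min`` (default: the volume's 90th M0 percentile) are kept and
    connected components smaller than ``min_component`` voxels discarded.
    A user-supplied CSF label (code 1) overrides the automatic mask — the
    study's CSF ROIs were expert-curated, so explicit labels always win.
    """
    if labels is not None and np.any(labels.labels == CSF_LABEL):
        return labels.mask(CSF_LABEL), True
    t2 = maps.T2_map
    m0 = maps.M0_map
    if pd_min is None:
        finite = m0[np.isfinite(m0)]
        if finite.size == 0:
            return np.zeros(m0.shape, dtype=bool), False
        pd_min = float(np.percentile(finite, 90))
    with np.errstate(invalid="ignore"):
        mask = (t2 > t2_min) & (m0 > pd_min)
    if not np.any(mask):
        return mask, False
    comp, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_component) + 1
        mask = np.isin(comp, keep)
    return mask, bool(np.any(mask))


def normalize_slicewise(
    M0_map: np.ndarray,
    csf_mask: np.ndarray,
    min_csf_voxels: int = 20,
    percentile: float = 98.0,
) -> tuple[np.ndarray, bool]:
    """Normalise an M0 map by the per-slice 98th percentile of CSF M0.

    For every slice (last axis) containing at least ``min_csf_voxels`` CSF
    voxels with finite M0, the divisor is the ``percentile``-th percentile
    (linear interpolation between order statistics) of CSF M0 in that slice
    and the slice of the returned PD map is ``M0 / divisor``.  Slices
    without a valid divisor are NaN.  Returns ``(PD_map, any_valid)``.
    """
    m0 = np.asarray(M0_map, dtype=float)
    csf = np.asarray(csf_mask, dtype=bool)
    if csf.shape != m0.shape:
        raise ValidationError(f"csf_mask shape {csf.shape} != M0 shape {m0.shape}")
    pd_map = np.full(m0.shape, np.nan)
    any_valid = False
    for z in range(m0.shape[-1]):
        vals = m0[..., z][csf[..., z]]
        vals = vals[np.isfinite(vals)]
        if vals.size < min_csf_voxels:
            continue
        divisor = np.percentile(vals, percentile)  # linear-interpolation convention
        if divisor > 0:
            pd_map[..., z] = m0[..., z] / divisor
            any_valid = True
    return pd_map, any_valid


def _masked_median(arr: np.ndarray, mask: np.ndarray) -> float:
    vals = arr[mask]
    vals = vals[np.isfinite(vals)]
    return float(np.median(vals)) if vals.size else float("nan")


def drg_metrics(
    maps: QuantMaps,
    PD_map: np.ndarray,
    labels: LabelVolume,
) -> DRGMetrics:
    """Aggregate maps over the DRG labels into the three subject metrics.

    Per ganglion: median T2, median PD (over voxels in slices with a valid
    CSF normaliser) and voxel-count volume.  The subject-level PD and T2 are
    medians over the pooled DRG voxels; volume is the sum.
    """
    lab = labels.labels
    if lab.shape != maps.M0_map.shape:
        raise ValidationError(f"label shape {lab.shape} != map shape {maps.M0_map.shape}")
    present = [c for c in DRG_LABELS if np.any(lab == c)]
    if not present:
        raise ValidationError("no DRG label voxels present (codes 10, 11, 20, 21)")

    vox_vol = labels.voxel_volume
    rows = []
    n_voxels: dict[int, int] = {}
    for code in present:
        m = lab == code
        n = int(m.sum())
        n_voxels[code] = n
        rows.append(
            {
                "label": code,
                "name": LABEL_CODES.get(code, str(code)),
                "drg_pd": _masked_median(PD_map, m),
                "drg_t2_ms": _masked_median(maps.T2_map, m),
                "drg_vol_mm3": n * vox_vol,
                "n_voxels": n,
            }
        )
    per_ganglion = pd.DataFrame(rows)

    pooled = labels.drg_mask()
    slices_used = sorted(
        int(z)
        for z in np.unique(np.nonzero(pooled)[-1])
        if np.any(np.isfinite(PD_map[..., z]))
    )
    return DRGMetrics(
        drg_pd=_masked_median(PD_map, pooled),
        drg_t2=_masked_median(maps.T2_map, pooled),
        drg_vol=float(pooled.sum()) * vox_vol,
        per_ganglion=per_ganglion,
        n_voxels=n_voxels,
        slices_used=slices_used,
    )
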