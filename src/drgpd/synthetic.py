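"""Synthetic phantoms and cohorts with known ground truth.

Two generators make the whole pipeline testable without patient data:

* :func:`make_phantom` builds a 4-D multi-echo spin-echo volume from
  ellipsoidal compartments (tissue background, a CSF tube spanning all
  slices, four DRG ellipsoids at L5/S1 left/right) under a spatially smooth
  effective refocusing flip-angle field, with Rician magnitude noise.  The
  forward model is the same EPG recursion the fitting pipeline inverts, so
  truth maps are exact by construction.
* :func:`cohort_generate` samples subject tables with the covariate and
  group structure the analysis layer expects: sex-dependent enzyme activity
  and lyso-Gb3, phenotype strata, SFN assigned through a logistic link, and
  imaging metrics drawn per (phenotype-group x SFN) stratum — DRG-PD from a
  logit-normal bounded to (0, 1.2) parameterised directly by median and
  IQR, so published stratum summaries translate into spec entries.

Everything is deterministic under the spec seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from ._errors import ValidationError
from .epg import SequenceParams, epg_cpmg_batch
from .relaxometry import QuantMaps
from .roi import CSF_LABEL, LabelVolume

__all__ = [
    "Compartment",
    "PhantomSpec",
    "CohortSpec",
    "b1_field",
    "make_phantom",
    "cohort_generate",
]


@dataclasses.dataclass(frozen=True)
class Compartment:
    """Ellipsoidal tissue compartment: label code, centre/semi-axes in voxels,
    and tissue parameters (M0 a.u., T2 ms, T1 ms)."""

    label: int
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    M0: float
    T2: float
    T1: float = 1000.0


def _default_compartments(drg_M0: float) -> tuple[Compartment, ...]:
    # CSF tube along the slice axis plus four DRG ellipsoids (L5/S1, L/R).
    return (
        Compartment(CSF_LABEL, (32, 14, 6), (5, 5, 20), M0=1.00, T2=2000.0, T1=4000.0),
        Compartment(10, (18, 34, 3.5), (5, 4, 2.6), M0=drg_M0, T2=95.0),
        Compartment(11, (46, 34, 3.5), (5, 4, 2.6), M0=drg_M0, T2=95.0),
        Compartment(20, (18, 48, 8.5), (5, 4, 2.6), M0=drg_M0, T2=95.0),
        Compartment(21, (46, 48, 8.5), (5, 4, 2.6), M0=drg_M0, T2=95.0),
    )


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Specification of a DRG phantom volume.

    The default DRG M0 of 0.765 a.u. corresponds to the SFN-positive
    classical-phenotype scenario; 0.701 a.u. is the matching SFN-negative
    value.  ``b1_range`` bounds the effective refocusing flip-angle field;
    ``noise_sigma`` is the per-channel Gaussian sigma of the Rician noise
    (0 = noiseless).  Background tissue is M0 0.5 / T2 60 ms inside an
    elliptical "body"; voxels outside it are signal-free air.
    """

    shape: tuple[int, int, int] = (64, 64, 12)
    voxel_dims: tuple[float, float, float] = (1.5, 1.5, 1.8)
    drg_M0: float = 0.765
    compartments: tuple[Compartment, ...] | None = None
    background_M0: float = 0.5
    background_T2: float = 60.0
    background_T1: float = 1000.0
    body_semi_axes: tuple[float, float] = (30.0, 30.0)
    b1_range: tuple[float, float] = (115.0, 180.0)
    noise_sigma: float = 0.0
    seed: int = 0
    supersample: int = 3
    boundary_policy: str = "pure"  # 'pure' | 'majority'

    def resolved_compartments(self) -> tuple[Compartment, ...]:
        return self.compartments or _default_compartments(self.drg_M0)

    def __post_init__(self) -> None:
        lo, hi = self.b1_range
        if not (60.0 < lo <= hi <= 180.0):
            raise ValidationError(f"b1_range must lie within (60, 180], got {self.b1_range}")
        if self.boundary_policy not in ("pure", "majority"):
            raise ValidationError("boundary_policy must be 'pure' or 'majority'")


def b1_field(
    shape: tuple[int, int, int],
    b1_range: tuple[float, float] = (115.0, 180.0),
    seed: int = 0,
) -> np.ndarray:
    """Smooth effective refocusing flip-angle field (deg), highest at centre.

    A radial (distance-proportional) falloff from the volume centre plus a
    heavily smoothed seeded perturbation, min-max mapped into ``b1_range``.
    Deterministic under ``seed``; at default settings the voxel-to-voxel
    change stays below 2 deg.
    """
    lo, hi = b1_range
    if not lo <= hi:
        raise ValidationError("b1_range must be (low, high) with low <= high")
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.arange(nx) - (nx - 1) / 2,
        np.arange(ny) - (ny - 1) / 2,
        np.arange(nz) - (nz - 1) / 2,
        indexing="ij",
    )
    r = np.sqrt(x**2 + y**2 + z**2)
    base = r / max(r.max(), 1.0)  # 0 at centre, 1 at the far corner
    rng = np.random.default_rng(seed)
    pert = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=8.0, mode="nearest")
    ptp = np.ptp(pert)
    if ptp > 0:
        pert = (pert - pert.min()) / ptp - 0.5
    field = base + 0.12 * pert
    if hi == lo:
        return np.full(shape, float(hi))
    field = (field - field.min()) / (field.max() - field.min())
    return hi - (hi - lo) * field


def _fraction_maps(spec: PhantomSpec) -> dict[int, np.ndarray]:
    """Sub-voxel occupancy fraction of every compartment via supersampling."""
    s = spec.supersample
    nx, ny, nz = spec.shape
    offs = (np.arange(s) + 0.5) / s  # sub-voxel centres in [0, 1)
    fracs: dict[int, np.ndarray] = {}
    # evaluate occupancy on the supersampled lattice, then box-average
    gx = (np.arange(nx * s) // s) + offs[np.arange(nx * s) % s]
    gy = (np.arange(ny * s) // s) + offs[np.arange(ny * s) % s]
    gz = (np.arange(nz * s) // s) + offs[np.arange(nz * s) % s]
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij", sparse=True)
    for comp in spec.resolved_compartments():
        cx, cy, cz = comp.center
        ax, ay, az = comp.semi_axes
        inside = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0
        f = inside.reshape(nx, s, ny, s, nz, s).mean(axis=(1, 3, 5))
        fracs[comp.label] = f
    total = sum(fracs.values())
    if np.any(total > 1.0 + 1e-9):
        raise ValidationError("compartments overlap")
    return fracs


def make_phantom(
    spec: PhantomSpec | None = None,
    seq: SequenceParams | None = None,
) -> tuple[np.ndarray, LabelVolume, QuantMaps]:
    """Simulate ``(echo_data, labels, truth)`` for a phantom specification.

    Every voxel's signal is the occupancy-weighted sum of the EPG trains of
    the compartments it intersects, evaluated at the voxel's local flip
    angle; Rician noise is applied as the magnitude of a complex Gaussian
    perturbation.  ``truth`` holds the exact parameter maps of the dominant
    compartment; labels follow ``spec.boundary_policy`` ('pure' labels only
    voxels fully inside a compartment, mirroring boundary-voxel exclusion in
    careful manual segmentation).
    """
    spec = spec or PhantomSpec()
    seq = seq or SequenceParams()
    fracs = _fraction_maps(spec)
    alpha = b1_field(spec.shape, spec.b1_range, spec.seed)

    nx, ny, nz = spec.shape
    x, y = np.meshgrid(
        np.arange(nx) - (nx - 1) / 2, np.arange(ny) - (ny - 1) / 2, indexing="ij"
    )
    bx, by = spec.body_semi_axes
    body = ((x / bx) ** 2 + (y / by) ** 2 <= 1.0)[..., None] & np.ones(nz, bool)
    bg_frac = np.clip(np.where(body, 1.0, 0.0) - sum(fracs.values()), 0.0, 1.0)

    flat_alpha = alpha.ravel()
    echo = np.zeros((seq.n_echoes, flat_alpha.size))
    pieces = [(bg_frac, spec.background_M0, spec.background_T2, spec.background_T1)]
    comp_by_label = {c.label: c for c in spec.resolved_compartments()}
    for label, frac in fracs.items():
        c = comp_by_label[label]
        pieces.append((frac, c.M0, c.T2, c.T1))
    for frac, M0, T2, T1 in pieces:
        f = frac.ravel()
        sel = f > 0
        if not np.any(sel):
            continue
        train = epg_cpmg_batch(M0, T2, T1, flat_alpha[sel], seq)
        echo[:, sel] += f[sel] * train
    echo_data = echo.reshape((seq.n_echoes, nx, ny, nz))

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        re = echo_data + rng.normal(0.0, spec.noise_sigma, echo_data.shape)
        im = rng.normal(0.0, spec.noise_sigma, echo_data.shape)
        echo_data = np.sqrt(re**2 + im**2)

    # labels and truth maps from compartment occupancy
    thresh = 1.0 - 1e-9 if spec.boundary_policy == "pure" else 0.5
    labels = np.zeros(spec.shape, dtype=np.int16)
    M0_t = np.where(body, spec.background_M0, 0.0)
    T2_t = np.full(spec.shape, spec.background_T2)
    for label, frac in fracs.items():
        c = comp_by_label[label]
        dominant = frac >= 0.5
        M0_t = np.where(dominant, c.M0, M0_t)
        T2_t = np.where(dominant, c.T2, T2_t)
        labels[frac >= thresh] = label

    truth = QuantMaps(
        M0_map=M0_t,
        T2_map=T2_t,
        alpha_map=alpha,
        rmse_map=np.zeros(spec.shape),
        fit_mask=body,
        voxel_dims=spec.voxel_dims,
    )
    return echo_data, LabelVolume(labels, spec.voxel_dims), truth


# ---------------------------------------------------------------------------
# cohorts


def _logit(p):
    return np.log(p / (1.0 - p))


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


#: Per-(phenotype-group, SFN) DRG-PD median and IQR (a.u.), matching the
#: published stratified summaries for the classical and benign/late-onset
#: phenotype groups.
DEFAULT_PD_STRATA = {
    ("classical", 1): (0.765, (0.761, 0.784)),
    ("classical", 0): (0.701, (0.687, 0.720)),
    ("other", 1): (0.674, (0.641, 0.736)),
    ("other", 0): (0.664, (0.619, 0.719)),
}

DEFAULT_T2_STRATA = {  # median ms, IQR
    ("classical", 1): (104.4, (93.5, 113.9)),
    ("classical", 0): (102.1, (92.0, 117.9)),
    ("other", 1): (92.3, (89.7, 99.8)),
    ("other", 0): (94.1, (83.8, 101.4)),
}

DEFAULT_VOL_SEX = {"m": (1342.1, (1012.6, 1610.7)), "f": (987.8, (769.1, 1187.5))}


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic Fabry cohort.

    Defaults reproduce the study-condition marginals: n = 80 with 38 m /
    42 f, phenotype proportions 18 classical / 54 late-onset-benign / 8 VUS,
    SFN prevalence ~25/80 assigned through a logistic link on phenotype, and
    imaging metrics drawn per stratum (``pd_strata`` maps (phenotype-group,
    sfn) to (median, (q1, q3))).  ``null_effect=True`` collapses the SFN+
    and SFN- metric distributions onto the SFN- one, giving a
    zero-group-difference generator for calibration checks.
    """

    n_subjects: int = 80
    p_male: float = 38 / 80
    phenotype_probs: tuple[float, float, float] = (18 / 80, 54 / 80, 8 / 80)
    sfn_link: tuple[float, float] = (-0.87, 0.42)  # intercept, classical coefficient
    pd_strata: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_PD_STRATA))
    t2_strata: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_T2_STRATA))
    vol_by_sex: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_VOL_SEX))
    pd_bound: float = 1.2
    null_effect: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.phenotype_probs) - 1.0) > 1e-9:
            raise ValidationError("phenotype proportions must sum to 1")
        if not 0 <= self.p_male <= 1:
            raise ValidationError("p_male must be a probability")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")


def _strata_to_yaml(strata: dict) -> dict:
    return {f"{g}|{s}": [med, list(iqr)] for (g, s), (med, iqr) in strata.items()}


def _strata_from_yaml(d: dict) -> dict:
    out = {}
    for key, (med, iqr) in d.items():
        g, s = key.rsplit("|", 1)
        out[(g, int(s))] = (float(med), tuple(float(v) for v in iqr))
    return out


def phantom_spec_to_yaml(spec: PhantomSpec, path) -> None:
    """Serialise a phantom specification to YAML."""
    import yaml

    d = dataclasses.asdict(spec)
    d["compartments"] = [dataclasses.asdict(c) for c in spec.resolved_compartments()]
    for k in ("shape", "voxel_dims", "body_semi_axes", "b1_range"):
        d[k] = list(d[k])
    from pathlib import Path

    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def phantom_spec_from_yaml(path) -> PhantomSpec:
    """Load a phantom specification from YAML."""
    import yaml
    from pathlib import Path

    d = yaml.safe_load(Path(path).read_text())
    comps = d.pop("compartments", None)
    if comps is not None:
        d["compartments"] = tuple(
            Compartment(
                label=int(c["label"]),
                center=tuple(c["center"]),
                semi_axes=tuple(c["semi_axes"]),
                M0=float(c["M0"]),
                T2=float(c["T2"]),
                T1=float(c.get("T1", 1000.0)),
            )
            for c in comps
        )
    for k in ("shape", "voxel_dims", "body_semi_axes", "b1_range"):
        if k in d:
            d[k] = tuple(d[k])
    return PhantomSpec(**d)


def cohort_spec_to_yaml(spec: "CohortSpec", path) -> None:
    """Serialise a cohort specification to YAML."""
    import yaml
    from pathlib import Path

    d = dataclasses.asdict(spec)
    d["phenotype_probs"] = list(d["phenotype_probs"])
    d["sfn_link"] = list(d["sfn_link"])
    d["pd_strata"] = _strata_to_yaml(spec.pd_strata)
    d["t2_strata"] = _strata_to_yaml(spec.t2_strata)
    d["vol_by_sex"] = {k: [m, list(iqr)] for k, (m, iqr) in spec.vol_by_sex.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def cohort_spec_from_yaml(path) -> "CohortSpec":
    """Load a cohort specification from YAML."""
    import yaml
    from pathlib import Path

    d = yaml.safe_load(Path(path).read_text())
    if "phenotype_probs" in d:
        d["phenotype_probs"] = tuple(d["phenotype_probs"])
    if "sfn_link" in d:
        d["sfn_link"] = tuple(d["sfn_link"])
    for key in ("pd_strata", "t2_strata"):
        if key in d:
            d[key] = _strata_from_yaml(d[key])
    if "vol_by_sex" in d:
        d["vol_by_sex"] = {
            k: (float(m), tuple(float(v) for v in iqr)) for k, (m, iqr) in d["vol_by_sex"].items()
        }
    return CohortSpec(**d)


def _lognormal_from_median_iqr(rng, median, iqr, size):
    q1, q3 = iqr
    mu = np.log(median)
    sigma = (np.log(q3) - np.log(q1)) / 1.349
    return rng.lognormal(mu, max(sigma, 1e-6), size)


def _normal_from_median_iqr(rng, median, iqr, size):
    q1, q3 = iqr
    return rng.normal(median, max((q3 - q1) / 1.349, 1e-9), size)


def _logitnormal_from_median_iqr(rng, median, iqr, bound, size):
    q1, q3 = iqr
    mu = _logit(median / bound)
    sigma = (_logit(q3 / bound) - _logit(q1 / bound)) / 1.349
    return bound * _sigmoid(rng.normal(mu, max(sigma, 1e-6), size))


def cohort_generate(spec: CohortSpec | None = None) -> tuple[pd.DataFrame, dict]:
    """Sample a synthetic cohort table; returns ``(table, truth)``.

    ``truth`` records the generating parameters (link coefficients and the
    per-stratum metric distributions actually used) for oracle use in tests.
    Deterministic under ``spec.seed``.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    sex = np.where(rng.random(n) < spec.p_male, "m", "f")
    phenotype = rng.choice(
        ["classical", "late_onset_benign", "VUS"], size=n, p=spec.phenotype_probs
    )
    is_m = sex == "m"
    is_classical = phenotype == "classical"

    age = np.clip(np.where(is_m, rng.normal(37, 11, n), rng.normal(50, 15, n)), 18, 82)
    bmi = np.clip(rng.normal(24.8, 4.0, n), 16, 42)
    alpha_gal = np.where(
        is_m,
        _lognormal_from_median_iqr(rng, 0.045, (0.04, 0.06), n),
        _lognormal_from_median_iqr(rng, 0.28, (0.23, 0.39), n),
    )
    lyso = np.where(
        is_m,
        _lognormal_from_median_iqr(rng, 20.1, (6.9, 60.8), n),
        _lognormal_from_median_iqr(rng, 4.2, (1.1, 13.8), n),
    )
    therapy = (rng.random(n) < np.where(is_m, 0.737, 0.452)).astype(int)

    b0, b1 = spec.sfn_link
    sfn = (rng.random(n) < _sigmoid(b0 + b1 * is_classical)).astype(int)

    group = np.where(is_classical, "classical", "other")
    drg_pd = np.empty(n)
    drg_t2 = np.empty(n)
    for (g, s), (med, iqr) in spec.pd_strata.items():
        if spec.null_effect:
            med, iqr = spec.pd_strata[(g, 0)]
        sel = (group == g) & (sfn == s)
        drg_pd[sel] = _logitnormal_from_median_iqr(rng, med, iqr, spec.pd_bound, sel.sum())
    for (g, s), (med, iqr) in spec.t2_strata.items():
        if spec.null_effect:
            med, iqr = spec.t2_strata[(g, 0)]
        sel = (group == g) & (sfn == s)
        drg_t2[sel] = _normal_from_median_iqr(rng, med, iqr, sel.sum())
    drg_vol = np.where(
        is_m,
        _lognormal_from_median_iqr(rng, *spec.vol_by_sex["m"], n),
        _lognormal_from_median_iqr(rng, *spec.vol_by_sex["f"], n),
    )

    # pain loads on SFN status; IENFD (biopsied subset) loads weakly against it
    pain_avg = np.clip(np.round(rng.normal(1.8 + 1.8 * sfn, 1.8, n)), 0, 10)
    pain_max = np.clip(pain_avg + np.round(rng.exponential(1.5, n)), 0, 10)
    ienfd_leg = _lognormal_from_median_iqr(rng, 4.2, (2.4, 7.0), n) * (1 - 0.25 * sfn)
    ienfd_thigh = _lognormal_from_median_iqr(rng, 18.3, (13.5, 26.2), n) * (1 - 0.15 * sfn)
    biopsy = rng.random(n) < 61 / 80
    ienfd_leg[~biopsy] = np.nan
    ienfd_thigh[~biopsy] = np.nan

    table = pd.DataFrame(
        {
            "id": [f"S{i:03d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": sex,
            "bmi": np.round(bmi, 1),
            "phenotype": phenotype,
            "alpha_gal": alpha_gal,
            "lyso_gb3": lyso,
            "ienfd_leg": ienfd_leg,
            "ienfd_thigh": ienfd_thigh,
            "prior_fd_therapy": therapy,
            "sfn": sfn,
            "pain_avg": pain_avg.astype(int),
            "pain_max": pain_max.astype(int),
            "drg_pd": drg_pd,
            "drg_t2": drg_t2,
            "drg_vol": drg_vol,
        }
    )
    truth = {
        "sfn_link": spec.sfn_link,
        "pd_strata": dict(spec.pd_strata),
        "t2_strata": dict(spec.t2_strata),
        "vol_by_sex": dict(spec.vol_by_sex),
        "null_effect": spec.null_effect,
        "seed": spec.seed,
    }
    return table, truth
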