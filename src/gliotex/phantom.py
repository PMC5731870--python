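"""Synthetic two-modality tumor phantoms with a known texture-to-CD3 link.

Each phantom is a pair of 3D volumes (T1-post-contrast and T2-FLAIR styled)
on a common, deliberately anisotropic grid, with an ellipsoidal tumor mask
and a disjoint spherical normal-appearing-white-matter (NAWM) reference
mask.  Voxel intensities are

    1 (background) + tumor contrast + amplitude * GRF + rim term + noise,

where the GRF is a unit-variance Gaussian random field (white noise
convolved with a Gaussian kernel whose width is the stated correlation
length in mm) and the rim term is a Gaussian ridge on the ellipsoid
boundary emulating contrast-enhancing rims.  The correlation length gives
continuous, seedable control over texture coarseness: longer correlation
lengths produce larger uniform zones after quantization, which is exactly
what the size-zone features downstream measure.

A cohort draws per-patient texture parameters from stated ranges and
generates a continuous CD3 z-score as a linear function of (population-
standardized) true texture parameters plus Gaussian noise; the binary
infiltration label is z > 0.  Clinical covariates (age, sex, KPS) are drawn
independently of CD3 so covariate-adjustment analyses have a known null.
Everything is reproducible from integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import MODALITIES, ROIMask, VolumeImage

#: Features most directly driven by the default CD3 link (which acts on the
#: T1-post fine-scale heterogeneity): speckle fragments the gray-level zone
#: partition, so the zone-count statistics — zone percentage (zones per
#: voxel) and zone-size non-uniformity — respond monotonically.
DEFAULT_CAUSAL_FEATURES: Tuple[str, ...] = (
    "t1post_glszm_zone_percentage",
    "t1post_glszm_zone_size_nonuniformity",
)


@dataclass(frozen=True)
class TextureParams:
    """Per-modality texture controls for one phantom.

    base_intensity is the tumor plateau relative to the unit background;
    corr_length_mm controls GRF coarseness; field_amplitude scales the GRF;
    rim_amplitude / rim_width_mm shape the boundary enhancement ridge;
    noise_sd is additive white noise.
    """

    base_intensity: float = 1.5
    corr_length_mm: float = 3.0
    field_amplitude: float = 0.35
    rim_amplitude: float = 0.4
    rim_width_mm: float = 2.0
    noise_sd: float = 0.05


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, texture and seed of a single synthetic patient."""

    grid_shape: Tuple[int, int, int] = (64, 56, 18)
    spacing_mm: Tuple[float, float, float] = (0.9, 0.9, 3.0)
    tumor_center_voxel: Tuple[float, float, float] = (22.0, 28.0, 9.0)
    tumor_semiaxes_mm: Tuple[float, float, float] = (16.0, 14.0, 12.0)
    flair_margin_mm: float = 3.0
    nawm_center_voxel: Tuple[float, float, float] = (57.0, 28.0, 9.0)
    nawm_radius_mm: float = 5.0
    texture_params: Mapping[str, TextureParams] = field(
        default_factory=lambda: {m: TextureParams() for m in MODALITIES}
    )
    seed: int = 0

    def validate(self) -> None:
        if any(a <= 0 for a in self.tumor_semiaxes_mm):
            raise ValueError("tumor semi-axes must be positive")
        if self.nawm_radius_mm <= 0:
            raise ValueError("NAWM radius must be positive")
        for m in MODALITIES:
            if m not in self.texture_params:
                raise ValueError(f"texture params missing modality '{m}'")


def _grid_coords_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_radius(
    spec: PhantomSpec, semiaxes: Tuple[float, float, float]
) -> np.ndarray:
    """Dimensionless ellipsoid radius r (r<=1 inside the tumor)."""
    X, Y, Z = _grid_coords_mm(spec.grid_shape, spec.spacing_mm)
    cx, cy, cz = (c * s for c, s in zip(spec.tumor_center_voxel, spec.spacing_mm))
    ax, ay, az = semiaxes
    return np.sqrt(((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2)


def _sphere_mask(spec: PhantomSpec) -> np.ndarray:
    X, Y, Z = _grid_coords_mm(spec.grid_shape, spec.spacing_mm)
    cx, cy, cz = (c * s for c, s in zip(spec.nawm_center_voxel, spec.spacing_mm))
    d2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
    return d2 <= spec.nawm_radius_mm ** 2


def gaussian_random_field(
    shape: Tuple[int, int, int],
    spacing_mm: Tuple[float, float, float],
    corr_length_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance smooth random field with the given correlation length.

    White Gaussian noise convolved with an isotropic (in mm) Gaussian
    kernel, then standardized to zero mean / unit variance over the grid.
    """
    white = rng.standard_normal(shape)
    sigma_vox = [corr_length_mm / s for s in spacing_mm]
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = f.std()
    if sd == 0:  # corr length >> grid: field is flat
        return np.zeros(shape)
    return (f - f.mean()) / sd


def generate_phantom(
    spec: PhantomSpec,
) -> Tuple[Dict[str, VolumeImage], Dict[str, ROIMask], ROIMask, Dict[str, float]]:
    """Render one synthetic patient.

    Returns (volumes by modality, tumor masks by modality, NAWM mask, true
    parameter dict with keys ``{modality}.{param}``).  The FLAIR tumor mask
    is the T1 ellipsoid inflated by ``flair_margin_mm`` on every semi-axis,
    mimicking the larger hyperintense (tumor + edema) region contoured on
    FLAIR.  Output is a deterministic function of the spec, its seed
    included.
    """
    spec.validate()
    semi = {
        "t1post": spec.tumor_semiaxes_mm,
        "flair": tuple(a + spec.flair_margin_mm for a in spec.tumor_semiaxes_mm),
    }
    radius = {m: _ellipsoid_radius(spec, semi[m]) for m in MODALITIES}
    tumors_np = {m: radius[m] <= 1.0 for m in MODALITIES}
    nawm = _sphere_mask(spec)
    if not nawm.any():
        raise ValueError("NAWM sphere contains no voxels")
    for m in MODALITIES:
        if not tumors_np[m].any():
            raise ValueError("tumor ellipsoid contains no voxels")
        if (tumors_np[m] & nawm).any():
            raise ValueError(
                "tumor and NAWM regions overlap; move the NAWM sphere or shrink the tumor"
            )

    seeds = np.random.SeedSequence(spec.seed).spawn(len(MODALITIES))
    volumes: Dict[str, VolumeImage] = {}
    true_params: Dict[str, float] = {}
    for mod, child in zip(MODALITIES, seeds):
        tp = spec.texture_params[mod]
        rng = np.random.default_rng(child)
        vals = np.ones(spec.grid_shape, dtype=np.float64)
        vals[tumors_np[mod]] += tp.base_intensity - 1.0
        grf = gaussian_random_field(
            spec.grid_shape, spec.spacing_mm, tp.corr_length_mm, rng
        )
        if tp.field_amplitude != 0:
            vals += tp.field_amplitude * grf
        if tp.rim_amplitude != 0:
            # effective radius converts dimensionless boundary distance to mm
            r_eff = float(np.cbrt(np.prod(semi[mod])))
            dist_mm = (radius[mod] - 1.0) * r_eff
            vals += tp.rim_amplitude * np.exp(-((dist_mm / tp.rim_width_mm) ** 2))
        if tp.noise_sd > 0:
            vals += tp.noise_sd * rng.standard_normal(spec.grid_shape)
        volumes[mod] = VolumeImage(vals, spec.spacing_mm, modality=mod)
        for name, v in vars(tp).items():
            true_params[f"{mod}.{name}"] = float(v)
    for i, ax in enumerate("xyz"):
        true_params[f"tumor_semiaxis_{ax}_mm"] = float(spec.tumor_semiaxes_mm[i])

    tumor_masks = {
        m: ROIMask(tumors_np[m], spec.spacing_mm, role="tumor") for m in MODALITIES
    }
    nawm_mask = ROIMask(nawm, spec.spacing_mm, role="nawm")
    return volumes, tumor_masks, nawm_mask, true_params


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Per-patient parameter ranges (uniform draws), keyed ``{modality}.{param}``.
#: Parameters not listed are held at the TextureParams defaults.
DEFAULT_PARAM_RANGES: Dict[str, Tuple[float, float]] = {
    "t1post.base_intensity": (1.4, 1.6),
    "t1post.corr_length_mm": (2.5, 3.5),
    "t1post.field_amplitude": (0.30, 0.40),
    "t1post.rim_amplitude": (0.20, 0.30),
    "t1post.noise_sd": (0.03, 0.25),
    "flair.base_intensity": (1.5, 1.7),
    "flair.corr_length_mm": (2.5, 3.5),
    "flair.field_amplitude": (0.30, 0.40),
    "flair.rim_amplitude": (0.0, 0.0),
    "flair.noise_sd": (0.03, 0.25),
}

#: Default CD3 link: the z-score tracks T1-post fine-scale heterogeneity
#: (higher immune infiltration emulated as higher speckle heterogeneity).
DEFAULT_CD3_LINK: Dict[str, float] = {"t1post.noise_sd": 1.0}


@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of a synthetic cohort.

    ``cd3_link`` maps true-parameter names to linear coefficients applied
    to population-standardized parameter values; the continuous CD3
    z-score is that linear combination plus N(0, cd3_noise_sd) noise, and
    the binary label is z > 0.
    """

    n_patients: int = 50
    param_ranges: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_RANGES)
    )
    semiaxes_ranges: Tuple[Tuple[float, float], ...] = (
        (13.0, 18.0), (11.0, 16.0), (9.0, 14.0),
    )
    cd3_link: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CD3_LINK)
    )
    cd3_noise_sd: float = 0.25
    age_mean: float = 57.0
    age_sd: float = 14.0
    kps_levels: Tuple[int, ...] = (60, 70, 80, 90, 100)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least 2 patients")
        if self.cd3_noise_sd < 0:
            raise ValueError("cd3 noise sd must be >= 0")
        for k in self.cd3_link:
            if k not in self.param_ranges:
                raise ValueError(f"cd3_link refers to undrawn parameter '{k}'")


def _standardize(value: float, lo: float, hi: float) -> float:
    """Standardize a U(lo, hi) draw by its population mean and sd."""
    if hi == lo:
        return 0.0
    return (value - (lo + hi) / 2.0) / ((hi - lo) / math.sqrt(12.0))


@dataclass
class CohortPatient:
    patient_id: str
    spec: PhantomSpec
    age: float
    sex: str
    kps: int
    cd3_z: float
    cd3_label: int
    true_params: Dict[str, float]

    def render(self):
        """Generate this patient's volumes and masks (deterministic)."""
        return generate_phantom(self.spec)


def generate_cohort(cspec: CohortSpec) -> List[CohortPatient]:
    """Draw the per-patient specs, covariates and CD3 outcomes of a cohort.

    Volumes are not rendered here; call :meth:`CohortPatient.render` (or
    :func:`iter_cohort_images`) to materialize them, which keeps large
    cohorts streamable.
    """
    cspec.validate()
    rng = np.random.default_rng(cspec.seed)
    patients: List[CohortPatient] = []
    for i in range(cspec.n_patients):
        draws: Dict[str, float] = {}
        for key, (lo, hi) in cspec.param_ranges.items():
            draws[key] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        tex = {}
        for mod in MODALITIES:
            base = TextureParams()
            overrides = {
                k.split(".", 1)[1]: v for k, v in draws.items()
                if k.startswith(mod + ".")
            }
            tex[mod] = replace(base, **overrides)
        semiaxes = tuple(float(rng.uniform(lo, hi)) for lo, hi in cspec.semiaxes_ranges)
        pspec = replace(
            cspec.phantom,
            texture_params=tex,
            tumor_semiaxes_mm=semiaxes,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        z = sum(
            coef * _standardize(draws[k], *cspec.param_ranges[k])
            for k, coef in cspec.cd3_link.items()
        )
        z += float(rng.normal(0.0, cspec.cd3_noise_sd)) if cspec.cd3_noise_sd else 0.0
        age = float(np.clip(rng.normal(cspec.age_mean, cspec.age_sd), 18, 90))
        sex = "F" if rng.random() < 0.5 else "M"
        kps = int(rng.choice(cspec.kps_levels))
        true_params = dict(draws)
        patients.append(
            CohortPatient(
                patient_id=f"P{i:04d}",
                spec=pspec,
                age=age,
                sex=sex,
                kps=kps,
                cd3_z=float(z),
                cd3_label=int(z > 0),
                true_params=true_params,
            )
        )
    return patients


def cohort_table(patients: List[CohortPatient]) -> pd.DataFrame:
    """Covariate/outcome table: patient_id, age, sex, kps, cd3_z, cd3_label."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "age": [p.age for p in patients],
            "sex": [p.sex for p in patients],
            "kps": [p.kps for p in patients],
            "cd3_z": [p.cd3_z for p in patients],
            "cd3_label": [p.cd3_label for p in patients],
        }
    ).set_index("patient_id")


def iter_cohort_images(
    patients: List[CohortPatient],
) -> Iterator[
    Tuple[CohortPatient, Dict[str, VolumeImage], Dict[str, ROIMask], ROIMask]
]:
    for p in patients:
        volumes, tumors, nawm, _ = p.render()
        yield p, volumes, tumors, nawm


def write_cohort(cspec: CohortSpec, outdir: str | Path) -> Path:
    """Materialize a cohort on disk as NIfTI files plus a manifest CSV.

    The manifest has one row per patient with columns patient_id, the file
    paths (volume and tumor mask per modality, shared NAWM mask), age,
    sex, kps, cd3_z, cd3_label.  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p, volumes, tumors, nawm in iter_cohort_images(generate_cohort(cspec)):
        paths = {}
        for mod in MODALITIES:
            f = outdir / f"{p.patient_id}_{mod}.nii.gz"
            volumes[mod].to_nifti(f)
            paths[f"{mod}_path"] = f.name
            ft = outdir / f"{p.patient_id}_{mod}_tumor.nii.gz"
            tumors[mod].to_nifti(ft)
            paths[f"{mod}_tumor_path"] = ft.name
        fn = outdir / f"{p.patient_id}_nawm.nii.gz"
        nawm.to_nifti(fn)
        rows.append(
            {
                "patient_id": p.patient_id,
                **paths,
                "nawm_path": fn.name,
                "age": p.age,
                "sex": p.sex,
                "kps": p.kps,
                "cd3_z": p.cd3_z,
                "cd3_label": p.cd3_label,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
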