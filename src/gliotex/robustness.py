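"""Feature robustness screening under geometric ROI perturbations.

Eight canonical perturbations of the (resliced, isotropic) tumor mask are
applied per patient; features are re-extracted from each perturbed mask and
a one-way random-effects intraclass correlation coefficient, ICC(1,1), is
computed per feature across the 9 versions (original + 8 perturbed).
Features with ICC >= 0.6 are retained.

Perturbation kinds (pixels = in-plane voxels on the 1 mm resliced grid):

* ``translate_h`` / ``translate_hv`` — rigid shift by 2 voxels along x /
  along x and y;
* ``rotate_1deg`` / ``rotate_5deg`` — in-plane (axial) rotation about the
  mask centroid, nearest-neighbor resampled;
* ``jitter_sd0.1`` / ``jitter_sd0.5`` — each point of every per-slice
  boundary contour displaced along its outward normal by zero-mean
  Gaussian noise (sd in voxels), then re-rasterized;
* ``dilate_1`` / ``erode_1`` — morphological dilation/erosion by a
  1-voxel spherical (6-connected) structuring element.

Robustness is assessed per modality: a feature passes on the strength of
its own modality's perturbed re-measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw, measure

from .image import ROIMask

PERTURBATION_KINDS: Tuple[str, ...] = (
    "translate_h",
    "translate_hv",
    "rotate_1deg",
    "rotate_5deg",
    "jitter_sd0.1",
    "jitter_sd0.5",
    "dilate_1",
    "erode_1",
)

ICC_THRESHOLD_DEFAULT = 0.6

# 6-connected ball of radius 1 voxel
_BALL_1 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class PerturbationSpec:
    """One of the 8 canonical geometric perturbations.

    ``seed`` is required (and only used) by the two jitter kinds.
    """

    kind: str
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(
                f"unknown perturbation kind '{self.kind}'; "
                f"expected one of {PERTURBATION_KINDS}"
            )
        if self.kind.startswith("jitter") and self.seed is None:
            raise ValueError(f"perturbation '{self.kind}' requires a seed")


def canonical_perturbations(seed: int = 0) -> List[PerturbationSpec]:
    """The 8 canonical specs; jitter kinds get seeds derived from ``seed``."""
    out = []
    for i, kind in enumerate(PERTURBATION_KINDS):
        s = seed * 16 + i if kind.startswith("jitter") else None
        out.append(PerturbationSpec(kind=kind, seed=s))
    return out


def _translate(mask: np.ndarray, shift: Tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(mask)
    src = []
    dst = []
    for d, n in zip(shift, mask.shape):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _rotate_axial(mask: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate in the x-y plane about the mask centroid, nearest neighbor."""
    idx = np.argwhere(mask)
    cx, cy = idx[:, 0].mean(), idx[:, 1].mean()
    th = np.deg2rad(degrees)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    # affine_transform maps output coords through the matrix: pull transform
    mat3 = np.eye(3)
    mat3[:2, :2] = rot
    offset = np.array([cx, cy, 0.0]) - mat3 @ np.array([cx, cy, 0.0])
    return ndimage.affine_transform(
        mask.astype(np.uint8), mat3, offset=offset, order=0, mode="constant", cval=0
    ).astype(bool)


def _jitter_contours(
    mask: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Displace each per-slice contour vertex along its outward normal."""
    out = np.zeros_like(mask)
    for k in range(mask.shape[2]):
        sl = mask[:, :, k]
        if not sl.any():
            continue
        filled = np.zeros_like(sl)
        for contour in measure.find_contours(sl.astype(float), 0.5):
            # tangent by central differences along the closed path; the
            # outward normal is the tangent rotated by -90 degrees (contours
            # from find_contours wind counterclockwise around high values)
            t = np.roll(contour, -1, axis=0) - np.roll(contour, 1, axis=0)
            norm = np.hypot(t[:, 0], t[:, 1])
            norm[norm == 0] = 1.0
            normal = np.column_stack([t[:, 1], -t[:, 0]]) / norm[:, None]
            disp = rng.normal(0.0, sd, size=len(contour))
            pts = contour + normal * disp[:, None]
            rr, cc = draw.polygon(pts[:, 0], pts[:, 1], shape=sl.shape)
            filled[rr, cc] = True
        out[:, :, k] = filled
    return out


def perturb_mask(mask: ROIMask, spec: PerturbationSpec) -> ROIMask:
    """Apply one canonical geometric perturbation to a tumor mask.

    Raises if the input is empty or if the perturbation (erosion) empties
    the mask.
    """
    if mask.is_empty():
        raise ValueError("cannot perturb an empty mask")
    m = mask.values
    if spec.kind == "translate_h":
        out = _translate(m, (2, 0, 0))
    elif spec.kind == "translate_hv":
        out = _translate(m, (2, 2, 0))
    elif spec.kind == "rotate_1deg":
        out = _rotate_axial(m, 1.0)
    elif spec.kind == "rotate_5deg":
        out = _rotate_axial(m, 5.0)
    elif spec.kind == "jitter_sd0.1":
        out = _jitter_contours(m, 0.1, np.random.default_rng(spec.seed))
    elif spec.kind == "jitter_sd0.5":
        out = _jitter_contours(m, 0.5, np.random.default_rng(spec.seed))
    elif spec.kind == "dilate_1":
        out = ndimage.binary_dilation(m, structure=_BALL_1)
    elif spec.kind == "erode_1":
        out = ndimage.binary_erosion(m, structure=_BALL_1)
    else:  # pragma: no cover - guarded by PerturbationSpec
        raise ValueError(spec.kind)
    if not out.any():
        raise ValueError(f"perturbation '{spec.kind}' emptied the mask")
    return ROIMask(values=out, spacing_mm=mask.spacing_mm, role=mask.role)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

@dataclass
class ICCRecord:
    feature_name: str
    icc: float
    n_subjects: int
    n_versions: int
    flagged: bool = False

    @property
    def icc_reported(self) -> float:
        """Report-time value, clamped to >= 0 (negative ICCs flagged)."""
        return max(self.icc, 0.0)


def icc(values: np.ndarray, form: str = "icc1") -> float:
    """Intraclass correlation of a subjects x versions measurement matrix.

    ``form='icc1'`` is the one-way random-effects ICC(1,1):
    ``(MSB - MSW) / (MSB + (k-1) MSW)`` with k versions.  ``form='icc3'``
    is the two-way mixed consistency ICC(3,1).  A matrix with zero total
    variance (identical measurements) is defined to have ICC 1.
    """
    a = np.asarray(values, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("ICC needs >= 2 subjects and >= 2 versions")
    if not np.all(np.isfinite(a)):
        raise ValueError("ICC input contains non-finite values")
    n, k = a.shape
    grand = a.mean()
    if np.allclose(a, grand):
        return 1.0
    row_means = a.mean(axis=1)
    ss_between = k * ((row_means - grand) ** 2).sum()
    ss_within = ((a - row_means[:, None]) ** 2).sum()
    msb = ss_between / (n - 1)
    if form == "icc1":
        msw = ss_within / (n * (k - 1))
        denom = msb + (k - 1) * msw
        return float((msb - msw) / denom) if denom > 0 else 1.0
    if form == "icc3":
        col_means = a.mean(axis=0)
        ss_cols = n * ((col_means - grand) ** 2).sum()
        ss_err = ss_within - ss_cols
        mse = ss_err / ((n - 1) * (k - 1))
        denom = msb + (k - 1) * mse
        return float((msb - mse) / denom) if denom > 0 else 1.0
    raise ValueError(f"unknown ICC form '{form}'")


def icc_records(
    tables: Sequence[pd.DataFrame], form: str = "icc1"
) -> List[ICCRecord]:
    """Per-feature ICC across feature tables (one table per ROI version).

    Each table is patients x features; all tables must share index and
    columns.  The first table is the original, the rest the perturbed
    versions.
    """
    if len(tables) < 2:
        raise ValueError("need the original plus at least one perturbed table")
    base = tables[0]
    for t in tables[1:]:
        if not (t.index.equals(base.index) and t.columns.equals(base.columns)):
            raise ValueError("feature tables are not aligned")
    records = []
    stack = np.stack([t.to_numpy(dtype=float) for t in tables], axis=2)
    for j, name in enumerate(base.columns):
        mat = stack[:, j, :]
        val = icc(mat, form=form)
        records.append(
            ICCRecord(
                feature_name=str(name),
                icc=val,
                n_subjects=mat.shape[0],
                n_versions=mat.shape[1],
                flagged=val < 0,
            )
        )
    return records


def robust_features(
    tables: Sequence[pd.DataFrame],
    threshold: float = ICC_THRESHOLD_DEFAULT,
    form: str = "icc1",
) -> Tuple[List[str], pd.DataFrame]:
    """Retain features whose ICC across ROI versions is >= threshold.

    ``tables`` holds the original feature table first, then one table per
    perturbation (9 in the canonical protocol).  Returns the retained
    feature names (original column order) and the per-feature report with
    columns feature_name, icc, passed, threshold, n_subjects, n_versions.
    """
    records = icc_records(tables, form=form)
    report = pd.DataFrame(
        {
            "feature_name": [r.feature_name for r in records],
            "icc": [r.icc_reported for r in records],
            "passed": [r.icc_reported >= threshold for r in records],
            "threshold": threshold,
            "n_subjects": [r.n_subjects for r in records],
            "n_versions": [r.n_versions for r in records],
        }
    )
    retained = report.loc[report["passed"], "feature_name"].tolist()
    return retained, report
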