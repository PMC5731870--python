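"""The 86-feature tumor texture panel.

Per modality (T1 post-contrast and T2-FLAIR) the panel comprises 43
features computed on the quantized tumor ROI:

* 6 histogram statistics of the gray-level distribution,
* 19 gray-tone spatial-dependence (GLCM / GTSDM) features,
* 5 neighborhood gray-tone difference (NGTDM) features
  (Amadasun-King coarseness, contrast, busyness, complexity, strength),
* 11 gray-level size-zone (GLSZM) features over 26-connected 3D zones,
* 2 regional features (tumor volume in mm^3 and the sum of NAWM-normalized
  tumor intensities).

Conventions, fixed throughout the package:

* GLCM: distance 1, the 13 unique 3D directions, symmetric accumulation,
  pooled (summed) over directions before normalization; logs are base 2.
* NGTDM neighborhoods and GLSZM zones use 26-connectivity.
* Kurtosis is the Pearson (non-excess) fourth standardized moment
  ``m4 / m2**2`` (normal distribution -> 3).
* Degenerate inputs (constant ROI, zero variance) yield documented
  sentinel values and set a per-feature quality flag instead of NaN/inf.

Feature names follow ``{modality}_{family}_{feature}``; the canonical
ordering of all 86 names ships as a JSON registry resource.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as _resources
from typing import Dict, List, Mapping, Tuple

import numpy as np
from scipy import ndimage

from .image import MODALITIES, QuantizedROI, ROIMask, VolumeImage
from .preprocess import normalize_to_nawm, quantize, reslice_isotropic

# Sentinel used where a ratio degenerates to x/0 (e.g. NGTDM coarseness of a
# constant ROI).  Declared once so tests and reports can refer to it.
COARSENESS_CAP = 1.0e6

#: The 13 unique unit-offset directions of the 3D 26-neighborhood (one per
#: antipodal pair); symmetric accumulation supplies the opposite direction.
GLCM_OFFSETS: Tuple[Tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

HISTOGRAM_FEATURES = ("mean", "variance", "skewness", "kurtosis", "entropy", "uniformity")
GTSDM_FEATURES = (
    "energy", "contrast", "correlation", "sum_of_squares_variance", "homogeneity",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
    "autocorrelation", "cluster_shade", "cluster_prominence", "cluster_tendency",
    "dissimilarity", "maximum_probability",
)
NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")
GLSZM_FEATURES = (
    "small_zone_emphasis", "large_zone_emphasis",
    "gray_level_nonuniformity", "zone_size_nonuniformity", "zone_percentage",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "small_zone_low_gray_level_emphasis", "small_zone_high_gray_level_emphasis",
    "large_zone_low_gray_level_emphasis", "large_zone_high_gray_level_emphasis",
)
REGIONAL_FEATURES = ("tumor_volume_mm3", "total_intensity")

FAMILIES: Tuple[Tuple[str, Tuple[str, ...]], ...] = (
    ("hist", HISTOGRAM_FEATURES),
    ("gtsdm", GTSDM_FEATURES),
    ("ngtdm", NGTDM_FEATURES),
    ("glszm", GLSZM_FEATURES),
    ("regional", REGIONAL_FEATURES),
)


def modality_feature_names(modality: str) -> List[str]:
    """The 43 ordered feature names for one modality."""
    return [f"{modality}_{fam}_{feat}" for fam, feats in FAMILIES for feat in feats]


def all_feature_names() -> List[str]:
    """The canonical ordering of all 86 feature names (T1-post then FLAIR)."""
    names: List[str] = []
    for mod in MODALITIES:
        names.extend(modality_feature_names(mod))
    return names


def load_feature_registry() -> List[str]:
    """Load the packaged feature-name registry (stable across versions)."""
    with _resources.files("gliotex.resources").joinpath("feature_registry.json").open() as fh:
        return json.load(fh)["features"]


@dataclass
class FeatureBlock:
    """Named feature values plus quality flags for degenerate guards."""

    values: Dict[str, float] = field(default_factory=dict)
    flags: Dict[str, str] = field(default_factory=dict)

    def update(self, other: "FeatureBlock") -> None:
        self.values.update(other.values)
        self.flags.update(other.flags)


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

def histogram_features(q: QuantizedROI) -> FeatureBlock:
    """First-order statistics of the quantized in-mask gray levels.

    Variance is the population second central moment; entropy is base-2
    over the level probabilities; uniformity is the sum of squared level
    probabilities (energy of the histogram).
    """
    x = q.in_mask_levels.astype(np.float64)
    if x.size == 0:
        raise ValueError("empty ROI")
    out = FeatureBlock()
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    out.values["mean"] = mean
    out.values["variance"] = m2
    if m2 > 0:
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        out.values["skewness"] = m3 / m2 ** 1.5
        out.values["kurtosis"] = m4 / m2 ** 2
    else:
        out.values["skewness"] = 0.0
        out.values["kurtosis"] = 0.0
        out.flags["skewness"] = "zero-variance ROI; sentinel 0"
        out.flags["kurtosis"] = "zero-variance ROI; sentinel 0"
    counts = np.bincount(q.in_mask_levels, minlength=q.n_levels + 1)[1:]
    p = counts[counts > 0] / x.size
    out.values["entropy"] = float(-(p * np.log2(p)).sum())
    out.values["uniformity"] = float((p ** 2).sum())
    return out


# ---------------------------------------------------------------------------
# GLCM / GTSDM
# ---------------------------------------------------------------------------

def glcm_matrix(q: QuantizedROI) -> np.ndarray:
    """Symmetric, direction-pooled, normalized co-occurrence matrix.

    Pairs are counted only when both voxels lie inside the mask; each of
    the 13 unit offsets is accumulated together with its opposite
    (symmetrization), pooled, and the pooled counts normalized to sum 1.
    """
    G = q.n_levels
    L = q.levels
    counts = np.zeros((G, G), dtype=np.float64)
    for off in GLCM_OFFSETS:
        a_sl, b_sl = [], []
        for d in off:
            if d == 0:
                a_sl.append(slice(None)); b_sl.append(slice(None))
            elif d > 0:
                a_sl.append(slice(None, -d)); b_sl.append(slice(d, None))
            else:
                a_sl.append(slice(-d, None)); b_sl.append(slice(None, d))
        a = L[tuple(a_sl)]
        b = L[tuple(b_sl)]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        codes = (a[valid] - 1) * G + (b[valid] - 1)
        counts += np.bincount(codes, minlength=G * G).reshape(G, G)
    counts = counts + counts.T  # symmetric accumulation
    total = counts.sum()
    if total == 0:
        raise ValueError("ROI has no valid voxel pairs at distance 1")
    return counts / total


def gtsdm_features(q: QuantizedROI) -> FeatureBlock:
    """The 19 co-occurrence features (Haralick set plus cluster/autocorrelation)."""
    P = glcm_matrix(q)
    G = P.shape[0]
    out = FeatureBlock()
    i = np.arange(1, G + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)  # == py by symmetry
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    eps_log = lambda v: np.log2(v, out=np.zeros_like(v), where=v > 0)

    out.values["energy"] = float((P ** 2).sum())
    out.values["contrast"] = float(((I - J) ** 2 * P).sum())
    if sigma2 > 0:
        out.values["correlation"] = float(((I - mu) * (J - mu) * P).sum() / sigma2)
    else:
        out.values["correlation"] = 0.0
        out.flags["correlation"] = "zero marginal variance; sentinel 0"
    out.values["sum_of_squares_variance"] = float(((I - mu) ** 2 * P).sum())
    out.values["homogeneity"] = float((P / (1.0 + (I - J) ** 2)).sum())

    # diagonal sums: p_{x+y}(k), k = 2..2G, and p_{x-y}(k), k = 0..G-1
    ksum = np.arange(2, 2 * G + 1, dtype=np.float64)
    p_sum = np.zeros(2 * G - 1)
    kdiff = np.arange(0, G, dtype=np.float64)
    p_diff = np.zeros(G)
    codes_sum = (I + J).astype(int) - 2
    codes_diff = np.abs(I - J).astype(int)
    np.add.at(p_sum, codes_sum.ravel(), P.ravel())
    np.add.at(p_diff, codes_diff.ravel(), P.ravel())

    sum_avg = float((ksum * p_sum).sum())
    out.values["sum_average"] = sum_avg
    out.values["sum_variance"] = float(((ksum - sum_avg) ** 2 * p_sum).sum())
    out.values["sum_entropy"] = float(-(p_sum * eps_log(p_sum)).sum())
    entropy = float(-(P * eps_log(P)).sum())
    out.values["entropy"] = entropy
    diff_avg = float((kdiff * p_diff).sum())
    out.values["difference_variance"] = float(((kdiff - diff_avg) ** 2 * p_diff).sum())
    out.values["difference_entropy"] = float(-(p_diff * eps_log(p_diff)).sum())

    # information measures of correlation
    pxpy = np.outer(px, px)
    hxy1 = float(-(P * eps_log(pxpy)).sum())
    hxy2 = float(-(pxpy * eps_log(pxpy)).sum())
    hx = float(-(px * eps_log(px)).sum())
    if hx > 0:
        out.values["imc1"] = (entropy - hxy1) / hx
    else:
        out.values["imc1"] = 0.0
        out.flags["imc1"] = "zero marginal entropy; sentinel 0"
    arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy) * np.log(2.0))
    out.values["imc2"] = float(np.sqrt(max(arg, 0.0)))

    out.values["autocorrelation"] = float((I * J * P).sum())
    c = I + J - 2.0 * mu
    out.values["cluster_shade"] = float((c ** 3 * P).sum())
    out.values["cluster_prominence"] = float((c ** 4 * P).sum())
    out.values["cluster_tendency"] = float((c ** 2 * P).sum())
    out.values["dissimilarity"] = float((np.abs(I - J) * P).sum())
    out.values["maximum_probability"] = float(P.max())
    return out


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(q: QuantizedROI) -> Tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence counts n_i and summed deviations s_i.

    The neighborhood is the 26-neighborhood restricted to in-mask voxels;
    voxels with no in-mask neighbor are excluded from the table.
    Returns ``(n, s)`` arrays indexed by level 1..G at positions 1..G.
    """
    G = q.n_levels
    mask = q.mask.values
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve(q.levels.astype(np.float64), kernel, mode="constant")
    nb_cnt = ndimage.convolve(mask.astype(np.float64), kernel, mode="constant")
    valid = mask & (nb_cnt > 0.5)
    if not valid.any():
        raise ValueError("all ROI voxels are isolated; NGTDM undefined")
    lev = q.levels[valid]
    dev = np.abs(lev - nb_sum[valid] / nb_cnt[valid])
    n = np.bincount(lev, minlength=G + 1).astype(np.float64)
    s = np.bincount(lev, weights=dev, minlength=G + 1)
    return n, s


def ngtdm_features(q: QuantizedROI) -> FeatureBlock:
    """Amadasun-King coarseness, contrast, busyness, complexity, strength."""
    n, s = ngtdm_table(q)
    N = n.sum()
    p = n / N
    present = np.flatnonzero(n > 0)  # gray levels occurring in the ROI
    Ngp = present.size
    out = FeatureBlock()

    ps = float((p * s).sum())
    if ps > 0:
        out.values["coarseness"] = min(1.0 / ps, COARSENESS_CAP)
    else:
        out.values["coarseness"] = COARSENESS_CAP
        out.flags["coarseness"] = "zero summed deviation; capped sentinel"

    ii = present.astype(np.float64)
    pi = p[present]
    si = s[present]
    D = ii[:, None] - ii[None, :]
    if Ngp > 1:
        pij = pi[:, None] * pi[None, :]
        out.values["contrast"] = float((pij * D ** 2).sum()) / (Ngp * (Ngp - 1)) * float(s.sum()) / N
    else:
        out.values["contrast"] = 0.0
        out.flags["contrast"] = "single gray level; sentinel 0"

    ipi = ii * pi
    denom_busy = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    if denom_busy > 0:
        out.values["busyness"] = ps / denom_busy
    else:
        out.values["busyness"] = 0.0
        out.flags["busyness"] = "zero busyness denominator; sentinel 0"

    psum = pi[:, None] + pi[None, :]
    num_cx = np.abs(D) * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
    out.values["complexity"] = float((num_cx / (N * psum)).sum())

    ssum = float(s.sum())
    if ssum > 0:
        out.values["strength"] = float((psum * D ** 2).sum()) / ssum
    else:
        out.values["strength"] = 0.0
        out.flags["strength"] = "zero summed deviation; sentinel 0"
    return out


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(q: QuantizedROI) -> np.ndarray:
    """Size-zone matrix: entry (i-1, j-1) = number of 26-connected zones of
    gray level i and size j voxels.  Columns run from size 1 to the largest
    observed zone; voxel conservation holds: sum_ij j * Z[i, j] = N."""
    G = q.n_levels
    zones: List[Tuple[int, int]] = []
    max_size = 1
    for g in range(1, G + 1):
        comp, n_comp = ndimage.label(q.levels == g, structure=_STRUCT_26)
        if n_comp == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        for sz in sizes:
            zones.append((g, int(sz)))
            max_size = max(max_size, int(sz))
    Z = np.zeros((G, max_size), dtype=np.float64)
    for g, sz in zones:
        Z[g - 1, sz - 1] += 1
    return Z


def glszm_features(q: QuantizedROI) -> FeatureBlock:
    """The 11 size-zone features (zone-size and gray-level emphases)."""
    Z = q if isinstance(q, np.ndarray) else glszm_matrix(q)
    n_voxels = q.n_voxels if isinstance(q, QuantizedROI) else None
    return _glszm_from_matrix(Z, n_voxels)


def _glszm_from_matrix(Z: np.ndarray, n_voxels: int | None = None) -> FeatureBlock:
    G, S = Z.shape
    i = np.arange(1, G + 1, dtype=np.float64)[:, None]
    j = np.arange(1, S + 1, dtype=np.float64)[None, :]
    Nz = Z.sum()
    if Nz == 0:
        raise ValueError("empty size-zone matrix")
    if n_voxels is None:
        n_voxels = int((Z * j).sum())
    out = FeatureBlock()
    out.values["small_zone_emphasis"] = float((Z / j ** 2).sum() / Nz)
    out.values["large_zone_emphasis"] = float((Z * j ** 2).sum() / Nz)
    out.values["gray_level_nonuniformity"] = float((Z.sum(axis=1) ** 2).sum() / Nz)
    out.values["zone_size_nonuniformity"] = float((Z.sum(axis=0) ** 2).sum() / Nz)
    out.values["zone_percentage"] = float(Nz / n_voxels)
    out.values["low_gray_level_zone_emphasis"] = float((Z / i ** 2).sum() / Nz)
    out.values["high_gray_level_zone_emphasis"] = float((Z * i ** 2).sum() / Nz)
    out.values["small_zone_low_gray_level_emphasis"] = float((Z / (i ** 2 * j ** 2)).sum() / Nz)
    out.values["small_zone_high_gray_level_emphasis"] = float((Z * i ** 2 / j ** 2).sum() / Nz)
    out.values["large_zone_low_gray_level_emphasis"] = float((Z * j ** 2 / i ** 2).sum() / Nz)
    out.values["large_zone_high_gray_level_emphasis"] = float((Z * i ** 2 * j ** 2).sum() / Nz)
    return out


# ---------------------------------------------------------------------------
# regional + assembly
# ---------------------------------------------------------------------------

def regional_features(vol_normalized: VolumeImage, tumor: ROIMask) -> FeatureBlock:
    """Tumor volume (mm^3) and total NAWM-normalized intensity over the mask."""
    if tumor.is_empty():
        raise ValueError("empty tumor mask")
    if tumor.shape != vol_normalized.shape:
        raise ValueError("mask grid does not match volume grid")
    out = FeatureBlock()
    out.values["tumor_volume_mm3"] = tumor.n_voxels * vol_normalized.voxel_volume_mm3
    out.values["total_intensity"] = float(vol_normalized.values[tumor.values].sum())
    return out


def modality_features_from_resliced(
    resliced: VolumeImage,
    tumor_r: ROIMask,
    n_levels: int = 8,
) -> FeatureBlock:
    """The 43 features from an already normalized + resliced volume/mask.

    Quantization happens here (it depends on the mask, so perturbed-ROI
    re-measurements re-quantize).  Names are prefixed
    ``{modality}_{family}_``.
    """
    q = quantize(resliced, tumor_r, n_levels=n_levels)
    blocks = {
        "hist": histogram_features(q),
        "gtsdm": gtsdm_features(q),
        "ngtdm": ngtdm_features(q),
        "glszm": glszm_features(q),
        "regional": regional_features(resliced, tumor_r),
    }
    out = FeatureBlock()
    for fam, feats in FAMILIES:
        blk = blocks[fam]
        for feat in feats:
            out.values[f"{resliced.modality}_{fam}_{feat}"] = blk.values[feat]
            if feat in blk.flags:
                out.flags[f"{resliced.modality}_{fam}_{feat}"] = blk.flags[feat]
    return out


def extract_modality_features(
    vol: VolumeImage,
    tumor: ROIMask,
    nawm: ROIMask,
    n_levels: int = 8,
    target_mm: float = 1.0,
) -> FeatureBlock:
    """Run the preprocessing chain and compute the 43 features of one modality.

    Names are prefixed ``{modality}_{family}_``.
    """
    normed = normalize_to_nawm(vol, tumor, nawm)
    resliced, (tumor_r, _) = reslice_isotropic(normed, (tumor, nawm), target_mm)
    return modality_features_from_resliced(resliced, tumor_r, n_levels=n_levels)


def extract_all(
    volumes: Mapping[str, VolumeImage],
    tumors: Mapping[str, ROIMask],
    nawms: Mapping[str, ROIMask],
    n_levels: int = 8,
    target_mm: float = 1.0,
) -> FeatureBlock:
    """Full 86-feature vector for one patient (both modalities).

    ``volumes``, ``tumors`` and ``nawms`` map modality name to the
    corresponding object; both ``"t1post"`` and ``"flair"`` must be present.
    Output ordering follows the packaged feature registry.
    """
    for mod in MODALITIES:
        if mod not in volumes or mod not in tumors or mod not in nawms:
            raise ValueError(f"missing modality '{mod}' in patient record")
    out = FeatureBlock()
    for mod in MODALITIES:
        vol = volumes[mod]
        if vol.modality != mod:
            raise ValueError(f"volume under key '{mod}' is tagged '{vol.modality}'")
        out.update(
            extract_modality_features(
                vol, tumors[mod], nawms[mod], n_levels=n_levels, target_mm=target_mm
            )
        )
    expected = all_feature_names()
    missing = [n for n in expected if n not in out.values]
    if missing:
        raise RuntimeError(f"feature assembly incomplete: {missing[:3]}...")
    out.values = {n: out.values[n] for n in expected}
    return out
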