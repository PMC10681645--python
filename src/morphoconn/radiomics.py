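"""Per-region radiomics feature extraction from a 3D image plus parcellation.

Each atlas region yields a fixed-length feature vector drawn from three
families:

* first-order intensity statistics over the in-region voxels,
* shape descriptors of the binary region mask (in physical mm units),
* Haralick-style texture features from a 3D gray-level co-occurrence
  matrix (GLCM), quantized per region and averaged over the 13 unique
  distance-1 offsets.

The default catalog has 47 features (14 intensity + 8 shape + 25 GLCM) and
is configuration-driven: any subset or reordering of the implemented
features can be requested by name, so the catalog can be swapped for an
alternative enumeration without code changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:  # nibabel is only needed when reading NIfTI from disk
    import nibabel as nib
except ImportError:  # pragma: no cover
    nib = None

__all__ = [
    "FeatureDescriptor",
    "FeatureCatalog",
    "RegionFeatureTable",
    "default_catalog",
    "extract_region_features",
    "load_feature_table",
    "write_feature_table",
]

# 13 unique 3D offsets at Chebyshev distance 1 (one representative per
# +/- direction pair; the symmetric accumulation supplies the other half).
_GLCM_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(_GLCM_OFFSETS) == 13

INTENSITY_FEATURES = (
    "int_mean", "int_median", "int_variance", "int_skewness", "int_kurtosis",
    "int_energy", "int_entropy", "int_minimum", "int_maximum", "int_range",
    "int_mad", "int_rms", "int_uniformity", "int_p90",
)
SHAPE_FEATURES = (
    "shp_voxel_count", "shp_volume_mm3", "shp_surface_area",
    "shp_surface_to_volume", "shp_sphericity", "shp_compactness",
    "shp_max_diameter", "shp_elongation",
)
GLCM_FEATURES = (
    "glcm_autocorrelation", "glcm_cluster_prominence", "glcm_cluster_shade",
    "glcm_cluster_tendency", "glcm_contrast", "glcm_correlation",
    "glcm_difference_average", "glcm_difference_entropy",
    "glcm_difference_variance", "glcm_dissimilarity", "glcm_id", "glcm_idm",
    "glcm_idmn", "glcm_idn", "glcm_imc1", "glcm_imc2",
    "glcm_inverse_variance", "glcm_joint_average", "glcm_joint_energy",
    "glcm_joint_entropy", "glcm_maximum_probability", "glcm_mcc",
    "glcm_sum_average", "glcm_sum_entropy", "glcm_sum_squares",
)


@dataclass(frozen=True)
class FeatureDescriptor:
    """One catalog entry: a feature name, its family and its parameters."""

    name: str
    family: str  # "intensity-first-order" | "shape" | "texture-GLCM"
    params: dict = field(default_factory=dict)


@dataclass
class FeatureCatalog:
    """Ordered, named collection of feature descriptors.

    ``n_gray`` (gray-level bin count for quantized features) is shared by the
    intensity histogram features and the GLCM, matching the fixed-bin-count
    convention that makes texture invariant to affine intensity rescaling.
    """

    entries: list[FeatureDescriptor]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names in a catalog must be unique")
        implemented = set(INTENSITY_FEATURES) | set(SHAPE_FEATURES) | set(GLCM_FEATURES)
        unknown = [n for n in names if n not in implemented]
        if unknown:
            raise ValueError(f"unknown feature names: {unknown}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def default_catalog(n_gray: int = 32) -> FeatureCatalog:
    """The default 47-feature catalog (14 intensity, 8 shape, 25 GLCM)."""
    entries = (
        [FeatureDescriptor(n, "intensity-first-order", {"n_bins": n_gray})
         for n in INTENSITY_FEATURES]
        + [FeatureDescriptor(n, "shape") for n in SHAPE_FEATURES]
        + [FeatureDescriptor(n, "texture-GLCM", {"n_gray": n_gray, "distance": 1})
           for n in GLCM_FEATURES]
    )
    return FeatureCatalog(entries)


@dataclass
class RegionFeatureTable:
    """Regions-by-features matrix for one subject.

    ``data`` is indexed by ``region_id``; ``flagged`` lists region ids whose
    masks were degenerate (fewer than 2 voxels) and whose rows should be
    excluded from normalization extremes downstream.
    """

    subject_id: str
    data: pd.DataFrame
    flagged: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate region_id in feature table")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def region_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# first-order intensity


def _intensity_features(v: np.ndarray, n_bins: int) -> dict[str, float]:
    v = np.asarray(v, dtype=float)
    n = v.size
    if n == 0:
        return {k: 0.0 for k in INTENSITY_FEATURES}
    mean = float(v.mean())
    var = float(v.var())
    sd = np.sqrt(var)
    if sd > 0:
        z = (v - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    else:
        skew = kurt = 0.0
    vmin, vmax = float(v.min()), float(v.max())
    rng = vmax - vmin
    if rng > 0:
        hist, _ = np.histogram(v, bins=n_bins, range=(vmin, vmax))
        p = hist / n
        pz = p[p > 0]
        entropy = float(-np.sum(pz * np.log2(pz)))
        uniformity = float(np.sum(p**2))
    else:
        entropy, uniformity = 0.0, 1.0
    return {
        "int_mean": mean,
        "int_median": float(np.median(v)),
        "int_variance": var,
        "int_skewness": skew,
        "int_kurtosis": kurt,
        "int_energy": float(np.sum(v**2)),
        "int_entropy": entropy,
        "int_minimum": vmin,
        "int_maximum": vmax,
        "int_range": rng,
        "int_mad": float(np.mean(np.abs(v - mean))),
        "int_rms": float(np.sqrt(np.mean(v**2))),
        "int_uniformity": uniformity,
        "int_p90": float(np.percentile(v, 90)),
    }


# ---------------------------------------------------------------------------
# shape


def _surface_area(mask: np.ndarray, spacing: np.ndarray) -> float:
    """Exposed-voxel-face surface estimate in mm^2."""
    area = 0.0
    face = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    padded = np.pad(mask, 1)
    for ax in range(3):
        d = np.diff(padded.astype(np.int8), axis=ax)
        area += float(np.count_nonzero(d)) * face[ax]
    return area


def _max_diameter(coords: np.ndarray) -> float:
    """Largest pairwise Euclidean distance between voxel centers (mm)."""
    if len(coords) < 2:
        return 0.0
    pts = coords
    if len(pts) > 512:  # restrict to the axis-extreme shell to stay cheap
        keep = np.zeros(len(pts), dtype=bool)
        for ax in range(3):
            lo, hi = pts[:, ax].min(), pts[:, ax].max()
            keep |= (pts[:, ax] == lo) | (pts[:, ax] == hi)
        pts = pts[keep]
    from scipy.spatial.distance import pdist

    return float(pdist(pts).max())


def _shape_features(mask: np.ndarray, spacing: np.ndarray) -> dict[str, float]:
    n_vox = int(np.count_nonzero(mask))
    out = {k: 0.0 for k in SHAPE_FEATURES}
    out["shp_voxel_count"] = float(n_vox)
    if n_vox == 0:
        return out
    vol = n_vox * float(np.prod(spacing))
    area = _surface_area(mask, spacing)
    coords = np.argwhere(mask) * spacing  # physical coordinates
    out["shp_volume_mm3"] = vol
    out["shp_surface_area"] = area
    out["shp_surface_to_volume"] = area / vol
    out["shp_sphericity"] = float(np.pi ** (1 / 3) * (6 * vol) ** (2 / 3) / area)
    out["shp_compactness"] = float(vol / (np.sqrt(np.pi) * area**1.5))
    out["shp_max_diameter"] = _max_diameter(coords)
    if n_vox > 1:
        eigvals = np.linalg.eigvalsh(np.cov(coords.T))
        eigvals = np.sort(np.clip(eigvals, 0, None))[::-1]
        out["shp_elongation"] = float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else 1.0
    else:
        out["shp_elongation"] = 1.0
    return out


# ---------------------------------------------------------------------------
# GLCM texture


def _quantize(v: np.ndarray, n_gray: int) -> np.ndarray:
    """Fixed-bin-count quantization over the region's own intensity range."""
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return np.zeros(v.shape, dtype=np.int64)
    q = np.floor((v - vmin) / (vmax - vmin) * n_gray).astype(np.int64)
    return np.clip(q, 0, n_gray - 1)


def _glcm_matrix(q: np.ndarray, mask: np.ndarray, n_gray: int) -> np.ndarray:
    """Symmetric GLCM averaged over the 13 distance-1 offsets.

    Each offset's count matrix is symmetrized and normalized before
    averaging; offsets with no valid voxel pair are skipped.
    """
    mats = []
    for off in _GLCM_OFFSETS:
        src = tuple(slice(max(0, -o), q.shape[i] - max(0, o)) for i, o in enumerate(off))
        dst = tuple(slice(max(0, o), q.shape[i] + min(0, o)) for i, o in enumerate(off))
        pair_ok = mask[src] & mask[dst]
        if not pair_ok.any():
            continue
        a = q[src][pair_ok]
        b = q[dst][pair_ok]
        counts = np.bincount(a * n_gray + b, minlength=n_gray * n_gray).reshape(n_gray, n_gray)
        counts = counts + counts.T
        mats.append(counts / counts.sum())
    if not mats:  # degenerate mask: put all mass on level (0, 0)
        P = np.zeros((n_gray, n_gray))
        P[0, 0] = 1.0
        return P
    return np.mean(mats, axis=0)


def _glcm_features(P: np.ndarray) -> dict[str, float]:
    n_gray = P.shape[0]
    i = np.arange(n_gray, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)  # == py by symmetry
    mu = float(np.sum(px * i))
    sigma2 = float(np.sum(px * (i - mu) ** 2))

    # p_{x+y} over k = 0..2(Ng-1); p_{x-y} over k = 0..Ng-1
    ksum = (ii + jj).astype(int)
    kdiff = np.abs(ii - jj).astype(int)
    p_sum = np.bincount(ksum.ravel(), weights=P.ravel(), minlength=2 * n_gray - 1)
    p_diff = np.bincount(kdiff.ravel(), weights=P.ravel(), minlength=n_gray)
    ks = np.arange(2 * n_gray - 1, dtype=float)
    kd = np.arange(n_gray, dtype=float)

    def _ent(p: np.ndarray) -> float:
        pz = p[p > 0]
        return float(-np.sum(pz * np.log2(pz)))

    diff_avg = float(np.sum(kd * p_diff))
    sum_avg = float(np.sum(ks * p_sum))
    contrast = float(np.sum(P * (ii - jj) ** 2))

    out: dict[str, float] = {}
    out["glcm_autocorrelation"] = float(np.sum(P * ii * jj))
    out["glcm_cluster_prominence"] = float(np.sum(P * (ii + jj - 2 * mu) ** 4))
    out["glcm_cluster_shade"] = float(np.sum(P * (ii + jj - 2 * mu) ** 3))
    out["glcm_cluster_tendency"] = float(np.sum(P * (ii + jj - 2 * mu) ** 2))
    out["glcm_contrast"] = contrast
    out["glcm_correlation"] = (
        float(np.sum(P * (ii - mu) * (jj - mu)) / sigma2) if sigma2 > 0 else 0.0
    )
    out["glcm_difference_average"] = diff_avg
    out["glcm_difference_entropy"] = _ent(p_diff)
    out["glcm_difference_variance"] = float(np.sum(p_diff * (kd - diff_avg) ** 2))
    out["glcm_dissimilarity"] = float(np.sum(P * np.abs(ii - jj)))
    out["glcm_id"] = float(np.sum(P / (1.0 + np.abs(ii - jj))))
    out["glcm_idm"] = float(np.sum(P / (1.0 + (ii - jj) ** 2)))
    out["glcm_idmn"] = float(np.sum(P / (1.0 + ((ii - jj) / n_gray) ** 2)))
    out["glcm_idn"] = float(np.sum(P / (1.0 + np.abs(ii - jj) / n_gray)))

    hxy = _ent(P.ravel())
    pxpy = np.outer(px, px)
    lg = np.zeros_like(pxpy)
    np.log2(pxpy, out=lg, where=pxpy > 0)
    hxy1 = float(-np.sum(P * lg))
    hxy2 = float(-np.sum(pxpy * lg))
    hx = _ent(px)
    # HX == HY by symmetry, so max(HX, HY) reduces to hx
    out["glcm_imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * max(hxy2 - hxy, 0.0))
    out["glcm_imc2"] = float(np.sqrt(max(arg, 0.0)))

    off_diag = np.abs(ii - jj) > 0
    out["glcm_inverse_variance"] = float(
        np.sum(P[off_diag] / (ii - jj)[off_diag] ** 2)
    )
    out["glcm_joint_average"] = float(np.sum(P * ii))
    out["glcm_joint_energy"] = float(np.sum(P**2))
    out["glcm_joint_entropy"] = hxy
    out["glcm_maximum_probability"] = float(P.max())
    out["glcm_mcc"] = _glcm_mcc(P, px)
    out["glcm_sum_average"] = sum_avg
    out["glcm_sum_entropy"] = _ent(p_sum)
    out["glcm_sum_squares"] = float(np.sum(P * (ii - mu) ** 2))
    return out


def _glcm_mcc(P: np.ndarray, px: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the 2nd eigenvalue of Q."""
    nz = px > 0
    if nz.sum() < 2:
        return 0.0
    Psub = P[np.ix_(nz, nz)]
    pxs = px[nz]
    Q = (Psub / pxs[:, None]) @ (Psub / pxs[None, :]).T
    ev = np.sort(np.abs(np.linalg.eigvals(Q)))
    return float(np.sqrt(max(ev[-2].real if len(ev) >= 2 else 0.0, 0.0)))


# ---------------------------------------------------------------------------
# extraction driver


def _as_array_and_spacing(obj, spacing):
    if nib is not None and isinstance(obj, nib.spatialimages.SpatialImage):
        return np.asarray(obj.get_fdata()), np.asarray(obj.header.get_zooms()[:3], dtype=float)
    arr = np.asarray(obj)
    sp = np.ones(3) if spacing is None else np.asarray(spacing, dtype=float)
    return arr, sp


def extract_region_features(
    image,
    parcellation,
    catalog: FeatureCatalog | None = None,
    spacing=None,
    region_ids=None,
    subject_id: str = "subject",
) -> RegionFeatureTable:
    """Compute the per-region feature table for one image/parcellation pair.

    Parameters
    ----------
    image, parcellation
        3D arrays or nibabel images sharing the same voxel grid.  The
        parcellation holds non-negative integer labels; 0 is background.
    catalog
        Which features to compute (default: the 47-feature catalog).
    spacing
        Voxel dimensions in mm for plain arrays (ignored for nibabel input).
    region_ids
        Atlas region ids defining the output rows.  Labels absent from the
        parcellation, or regions with fewer than 2 voxels, produce flagged
        rows with features set where defined and 0 elsewhere.
    """
    catalog = catalog or default_catalog()
    img, sp = _as_array_and_spacing(image, spacing)
    parc, sp2 = _as_array_and_spacing(parcellation, spacing)
    if img.shape != parc.shape:
        raise ValueError(
            f"image shape {img.shape} != parcellation shape {parc.shape}"
        )
    parc = parc.astype(np.int64)
    if region_ids is None:
        region_ids = np.unique(parc)
        region_ids = region_ids[region_ids > 0]
    region_ids = np.asarray(region_ids)

    n_gray = next(
        (e.params.get("n_gray", 32) for e in catalog.entries if e.family == "texture-GLCM"),
        32,
    )
    n_bins = next(
        (e.params.get("n_bins", 32) for e in catalog.entries if e.family == "intensity-first-order"),
        32,
    )

    rows = []
    flagged = set()
    for rid in region_ids:
        mask = parc == rid
        n_vox = int(np.count_nonzero(mask))
        if n_vox < 2:
            flagged.add(int(rid))
        feats: dict[str, float] = {}
        if n_vox == 0:
            feats.update({k: 0.0 for k in INTENSITY_FEATURES})
            feats.update(_shape_features(mask, sp))
            feats.update({k: 0.0 for k in GLCM_FEATURES})
        else:
            # crop to the bounding box before texture work
            idx = np.argwhere(mask)
            lo = idx.min(axis=0)
            hi = idx.max(axis=0) + 1
            box = tuple(slice(a, b) for a, b in zip(lo, hi))
            m_box = mask[box]
            v = img[mask]
            feats.update(_intensity_features(v, n_bins))
            feats.update(_shape_features(mask, sp))
            q = _quantize(img[box], n_gray)
            feats.update(_glcm_features(_glcm_matrix(q, m_box, n_gray)))
        rows.append([feats[name] for name in catalog.names])

    data = pd.DataFrame(rows, index=pd.Index(region_ids, name="region_id"),
                        columns=catalog.names)
    return RegionFeatureTable(subject_id=subject_id, data=data,
                              flagged=frozenset(flagged))


# ---------------------------------------------------------------------------
# table I/O


def write_feature_table(table: RegionFeatureTable, path) -> None:
    table.data.to_csv(path, sep="\t")


def load_feature_table(path, catalog: FeatureCatalog | None = None,
                       subject_id: str | None = None) -> RegionFeatureTable:
    """Read a TSV feature table (region_id index, numeric feature columns)."""
    df = pd.read_csv(path, sep="\t", index_col="region_id")
    if df.index.has_duplicates:
        raise ValueError(f"duplicate region_id entries in {path}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric feature columns in {path}: {non_numeric}")
    if df.isna().any().any():
        raise ValueError(f"missing values in feature table {path}")
    if catalog is not None and list(df.columns) != catalog.names:
        raise ValueError("feature columns do not match the supplied catalog")
    sid = subject_id if subject_id is not None else str(path)
    return RegionFeatureTable(subject_id=sid, data=df)
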