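"""Seeded generators for every input the pipeline consumes.

The generators emulate a three-group (NC / MCI / AD) structural-imaging
cohort analysed through radiomics similarity networks:

* an atlas of region centroids in a brain-sized volume (default 246
  regions),
* per-subject regions-by-features tables drawn from a latent-factor model
  whose shared pattern gives inter-regional feature correlations realistic
  non-zero structure, with a planted latent shift in chosen effect regions
  for AD (and half of it for MCI) that lowers those regions' RMCS,
* covariate/clinical tables with an age confound and clinical scores tied
  to each subject's latent disease burden,
* spatially autocorrelated regional expression maps (Gaussian random
  fields over centroid distance) with a fraction of genes loaded on the
  planted effect map and a ledger of regions without expression,
* cell-class gene sets plus the 28-symbol AD-risk list.

Every generator is deterministic given its seed; seeds are recorded in the
output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .radiomics import RegionFeatureTable, default_catalog
from .resources import AD_RISK_GENES, CELL_CLASSES, CLINICAL_CALIBRATION
from .transcriptomics import ExpressionMatrix

__all__ = [
    "AtlasGeometry",
    "CohortSpec",
    "ExpressionSpec",
    "generate_atlas",
    "generate_cohort",
    "generate_expression",
    "generate_gene_sets",
    "generate_toy_volume",
    "write_atlas",
    "load_atlas",
]

# Latent-factor model constants (see docs/methods.md for rationale).
N_LATENT = 12           # dimensionality of the region archetype space
ARCHETYPE_LENGTH = 180.0  # mm; spatial correlation length of archetypes, so
                        # nearby regions have similar feature profiles and
                        # the network has positive local edge structure
BASELINE_INTEGRITY = 0.7  # logit offset: healthy regions carry ~80% archetype
                        # signal, the rest idiosyncratic morphology
SUBJECT_SD = 1.6        # between-subject sd tau of the latent integrity
                        # score; the planted shift is effect_size * tau
                        # (Cohen's d on the subject latent)
AGE_SLOPE = -0.01       # latent integrity decline per year of age (confound)
BURDEN_NOISE = 0.35     # subject-level spread of clinical burden


@dataclass
class AtlasGeometry:
    """Region ids, names, and centroids (mm) of the parcellation."""

    table: pd.DataFrame  # columns: region_id, name, x, y, z
    seed: int | None = None

    def __post_init__(self) -> None:
        t = self.table
        required = {"region_id", "name", "x", "y", "z"}
        if not required.issubset(t.columns):
            raise ValueError(f"atlas table needs columns {sorted(required)}")
        ids = t["region_id"].to_numpy()
        if len(np.unique(ids)) != len(ids) or (ids <= 0).any():
            raise ValueError("region_ids must be unique and positive")
        if not np.isfinite(t[["x", "y", "z"]].to_numpy()).all():
            raise ValueError("centroids must be finite")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)


@dataclass
class CohortSpec:
    """Synthetic three-group cohort design.

    ``effect_size`` is the standardized latent shift (Cohen's d on the
    subject-level latent factor) applied to AD in ``effect_regions``; MCI
    receives half of it.  ``age_shift_ad`` moves the AD group's mean age,
    reproducing the age confound of real memory-clinic cohorts.
    """

    n_per_group: tuple[int, int, int] = (605, 766, 283)  # NC, MCI, AD
    n_regions: int = 246
    n_features: int = 47
    effect_regions: frozenset = frozenset()
    effect_size: float = 1.0
    age_shift_ad: float = 1.4
    seed: int = 0

    def validate(self, atlas: AtlasGeometry) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("need at least 2 subjects per group")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.n_regions != atlas.n_regions:
            raise ValueError("spec n_regions does not match the atlas")
        extra = set(self.effect_regions) - set(atlas.region_ids.tolist())
        if extra:
            raise ValueError(f"effect_regions not in atlas: {sorted(extra)}")


@dataclass
class ExpressionSpec:
    """Synthetic regional-expression design (Gaussian random fields)."""

    n_genes: int = 15633
    corr_length: float = 40.0      # mm; spatial autocorrelation scale
    n_missing_regions: int = 10
    planted_gene_fraction: float = 0.2
    planted_loading: float = 0.5   # correlation of a planted gene with the effect map
    seed: int = 0

    def validate(self, n_regions: int) -> None:
        if self.corr_length <= 0:
            raise ValueError("corr_length must be positive")
        if not 0 <= self.n_missing_regions < n_regions:
            raise ValueError("n_missing_regions out of range")
        if not 0 <= self.planted_gene_fraction <= 1:
            raise ValueError("planted_gene_fraction must be in [0, 1]")


def generate_atlas(n_regions: int = 246, seed: int = 0,
                   extent: tuple[float, float, float] = (140.0, 170.0, 130.0)
                   ) -> AtlasGeometry:
    """Sample region centroids uniformly in a brain-sized box (mm)."""
    if n_regions < 3:
        raise ValueError("an atlas needs at least 3 regions")
    rng = np.random.default_rng(seed)
    half = np.asarray(extent) / 2.0
    xyz = rng.uniform(-half, half, size=(n_regions, 3))
    table = pd.DataFrame({
        "region_id": np.arange(1, n_regions + 1),
        "name": [f"region_{i:03d}" for i in range(1, n_regions + 1)],
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
    })
    return AtlasGeometry(table=table, seed=seed)


def default_effect_regions(atlas: AtlasGeometry, n_effect: int = 25,
                           seed: int = 0) -> frozenset:
    """A reproducible planted-effect region set (default ~10% of regions)."""
    rng = np.random.default_rng(seed)
    pick = rng.choice(atlas.region_ids, size=min(n_effect, atlas.n_regions),
                      replace=False)
    return frozenset(int(r) for r in pick)


def generate_cohort(
    atlas: AtlasGeometry, spec: CohortSpec
) -> tuple[list[RegionFeatureTable], pd.DataFrame]:
    """Per-subject feature tables plus the covariate/clinical table.

    Feature model for subject s, region i, feature f:

        x[s,i,f]  = mu_f + s[s,i] * G[i,f] + sqrt(1 - s[s,i]^2) * eps[s,i,f]
        s[s,i]^2  = logistic( 2 * ell[s,i] )
        ell[s,i]  = BASELINE_INTEGRITY
                    + tau * (eta[s,i] - d_s * [i planted])
                    + AGE_SLOPE * (age_s - 73.5)

    with d_s = 0 / effect_size/2 / effect_size for NC / MCI / AD.  G holds
    fixed region archetype profiles built from a spatially smooth latent
    field, so nearby regions' feature vectors correlate (positive local
    network edges survive the per-subject min-max normalization, which
    cancels any purely additive shared component).  The latent integrity
    score ell controls how much of a region's unit-variance profile is
    archetype versus idiosyncratic morphological noise; the planted shift
    replaces archetype signal with noise at constant total variance, which
    decorrelates the region from its neighbours and lowers its RMCS — the
    disconnection signature the statistic is designed to detect.
    """
    spec.validate(atlas)
    rng = np.random.default_rng(spec.seed)
    n_nc, n_mci, n_ad = spec.n_per_group
    n_sub = n_nc + n_mci + n_ad
    R, F = atlas.n_regions, spec.n_features

    groups = np.array(["NC"] * n_nc + ["MCI"] * n_mci + ["AD"] * n_ad)
    d_s = np.where(groups == "AD", spec.effect_size,
                   np.where(groups == "MCI", spec.effect_size / 2.0, 0.0))

    # cohort-level fixed structure: smooth region archetypes
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(atlas.centroids))
    K = np.exp(-D / ARCHETYPE_LENGTH)
    L = np.linalg.cholesky(K + 1e-8 * np.eye(R))
    zeta = L @ rng.standard_normal((R, N_LATENT))   # smooth latent positions
    B = rng.standard_normal((N_LATENT, F))
    G = zeta @ B
    G /= G.std(axis=1, keepdims=True)               # unit signal sd per region
    mu_f = rng.normal(0.0, 1.0, size=F)
    planted = np.isin(atlas.region_ids, list(spec.effect_regions))

    # demographics
    age_mean = np.where(groups == "AD", 73.5 + spec.age_shift_ad,
                        np.where(groups == "MCI", 73.0, 73.5))
    age_sd = np.where(groups == "NC", 6.2, 7.7)
    ages = np.clip(rng.normal(age_mean, age_sd), 55.0, 95.0)
    sexes = rng.integers(0, 2, size=n_sub)

    eta = rng.normal(0.0, 1.0, size=(n_sub, R))
    ell = (
        BASELINE_INTEGRITY
        + SUBJECT_SD * (eta - d_s[:, None] * planted[None, :])
        + AGE_SLOPE * (ages[:, None] - 73.5)
    )
    s = np.sqrt(1.0 / (1.0 + np.exp(-2.0 * ell)))   # signal fraction in (0,1)
    eps = rng.normal(0.0, 1.0, size=(n_sub, R, F))
    X = (mu_f[None, None, :]
         + s[:, :, None] * G[None, :, :]
         + np.sqrt(1.0 - s[:, :, None] ** 2) * eps)

    catalog = default_catalog()
    feat_names = (catalog.names if F == len(catalog) else
                  [f"feature_{j:03d}" for j in range(1, F + 1)])
    region_index = pd.Index(atlas.region_ids, name="region_id")
    subject_ids = [f"sub-{i:04d}" for i in range(1, n_sub + 1)]
    tables = [
        RegionFeatureTable(subject_id=sid,
                           data=pd.DataFrame(X[s], index=region_index,
                                             columns=feat_names))
        for s, sid in enumerate(subject_ids)
    ]

    # clinical scores tied to the realized latent burden in planted regions
    if planted.any():
        realized = d_s - eta[:, planted].mean(axis=1)
    else:
        realized = np.zeros(n_sub)
    burden = realized + rng.normal(0.0, BURDEN_NOISE, size=n_sub)
    cov = pd.DataFrame({
        "subject_id": subject_ids,
        "group": groups,
        "age": ages,
        "sex": sexes,
    })
    for name, (base, slope, sd) in CLINICAL_CALIBRATION.items():
        cov[name] = base + slope * burden + rng.normal(0.0, sd, size=n_sub)
    # sprinkle a little realistic missingness into the clinical columns
    for name in CLINICAL_CALIBRATION:
        miss = rng.random(n_sub) < 0.002
        cov.loc[miss, name] = np.nan
    cov.attrs["seed"] = spec.seed
    cov.attrs["effect_regions"] = sorted(spec.effect_regions)
    return tables, cov


def generate_expression(
    atlas: AtlasGeometry, expr_spec: ExpressionSpec, effect_map
) -> ExpressionMatrix:
    """Spatially autocorrelated regional expression with planted genes.

    Each gene's regional profile is a Gaussian random field over centroid
    distances with an exponential kernel exp(-d / corr_length).  A seeded
    random subset of genes (``planted_gene_fraction``) is additionally
    loaded on the standardized effect map with correlation
    ``planted_loading`` and a random sign.  ``n_missing_regions`` region
    rows are removed entirely and recorded in the ledger.
    """
    expr_spec.validate(atlas.n_regions)
    effect_map = np.asarray(effect_map, dtype=float)
    if len(effect_map) != atlas.n_regions:
        raise ValueError("effect_map length must equal n_regions")
    rng = np.random.default_rng(expr_spec.seed)
    n, G = atlas.n_regions, expr_spec.n_genes

    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(atlas.centroids))
    K = np.exp(-D / expr_spec.corr_length)
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    Z = rng.standard_normal((n, G))
    maps = L @ Z  # one GRF column per gene

    n_planted = int(round(expr_spec.planted_gene_fraction * G))
    planted_idx = rng.choice(G, size=n_planted, replace=False)
    if n_planted and np.std(effect_map) > 0:
        e = (effect_map - effect_map.mean()) / effect_map.std()
        signs = rng.choice([-1.0, 1.0], size=n_planted)
        alpha = expr_spec.planted_loading
        maps[:, planted_idx] = (
            np.sqrt(1 - alpha**2) * maps[:, planted_idx]
            + alpha * np.outer(e, signs)
        )

    gene_names = list(AD_RISK_GENES[: min(len(AD_RISK_GENES), G)])
    gene_names += [f"GENE{j:05d}" for j in range(1, G - len(gene_names) + 1)]

    missing = rng.choice(atlas.region_ids, size=expr_spec.n_missing_regions,
                         replace=False)
    df = pd.DataFrame(maps, index=pd.Index(atlas.region_ids, name="region_id"),
                      columns=gene_names)
    df = df.drop(index=missing)
    return ExpressionMatrix(
        data=df,
        missing_regions=tuple(int(r) for r in np.sort(missing)),
        meta={
            "seed": expr_spec.seed,
            "corr_length": expr_spec.corr_length,
            "planted_genes": [gene_names[j] for j in np.sort(planted_idx)],
        },
    )


def generate_gene_sets(
    gene_names,
    n_classes: int = 7,
    sizes=None,
    seed: int = 0,
) -> tuple[dict[str, list[str]], list[str]]:
    """Cell-class gene sets (overlap allowed) plus the AD-risk list.

    Classes are named after the seven canonical brain cell classes when
    ``n_classes`` is 7, otherwise ``class_01`` ...  The AD-risk list is the
    fixed 28-symbol compilation, returned verbatim.
    """
    gene_names = list(gene_names)
    rng = np.random.default_rng(seed)
    if sizes is None:
        sizes = [max(10, len(gene_names) // 20)] * n_classes
    if len(sizes) != n_classes:
        raise ValueError("one size per class required")
    if any(s > len(gene_names) for s in sizes):
        raise ValueError("requested class size exceeds the gene pool")
    names = (list(CELL_CLASSES) if n_classes == 7
             else [f"class_{i:02d}" for i in range(1, n_classes + 1)])
    sets = {
        name: sorted(rng.choice(gene_names, size=size, replace=False).tolist())
        for name, size in zip(names, sizes)
    }
    return sets, list(AD_RISK_GENES)


def generate_toy_volume(
    atlas_or_n=8, shape=(24, 24, 24), seed: int = 0, spacing=(1.0, 1.0, 1.0)
):
    """A toy image + integer parcellation pair for the feature extractor.

    The parcellation is a Voronoi tessellation of random seed points (every
    label gets at least one voxel); the image is a smooth random field with
    per-region intensity offsets so regions differ in all three feature
    families.  Returns (image, parcellation) as nibabel Nifti1Image.
    """
    import nibabel as nib
    from scipy.ndimage import gaussian_filter

    n_regions = atlas_or_n.n_regions if hasattr(atlas_or_n, "n_regions") else int(atlas_or_n)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, np.array(shape) - 1, size=(n_regions, 3))
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    d2 = ((grid[..., None, :] - pts[None, None, None, :, :]) ** 2).sum(axis=-1)
    parc = np.argmin(d2, axis=-1) + 1
    offsets = rng.normal(0, 2.0, size=n_regions + 1)
    img = gaussian_filter(rng.normal(0, 1.0, size=shape), sigma=1.2)
    img = img + offsets[parc]
    affine = np.diag(list(spacing) + [1.0])
    return (
        nib.Nifti1Image(img.astype(np.float32), affine),
        nib.Nifti1Image(parc.astype(np.int16), affine),
    )


# ---------------------------------------------------------------------------
# I/O helpers


def write_atlas(atlas: AtlasGeometry, path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)


def load_atlas(path) -> AtlasGeometry:
    return AtlasGeometry(table=pd.read_csv(path, sep="\t"))


def write_gene_sets(sets: dict[str, list[str]], risk: list[str], out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, genes in sets.items():
        (out / f"{name}.txt").write_text("\n".join(genes) + "\n")
    (out / "ad_risk.txt").write_text("\n".join(risk) + "\n")
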