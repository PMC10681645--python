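"""PLS association between a regional statistic map and gene expression,
with variogram-matched spatial surrogate null models.

The spatial phenotype (a region-wise t-statistic map) serves as the
univariate predictor and the regions-by-genes expression matrix as the
response.  For a univariate predictor the first PLS component is available
in closed form: the response weight vector is proportional to the vector of
per-gene covariances with the predictor, the regional score is the
projection of the (standardized) expression onto that unit weight vector,
and explained variance is the Frobenius fraction captured by the rank-1
reconstruction.

Significance of map-map correlations is assessed against surrogate maps
that preserve the empirical variogram (spatial autocorrelation) of the
source map: permute, smooth over nearest neighbours with a distance-decay
kernel, and rescale smoothed + noise components so the surrogate variogram
matches the source variogram in a least-squares sense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

__all__ = [
    "ExpressionMatrix",
    "PLSResult",
    "SurrogateEnsemble",
    "align_regions",
    "pls_fit",
    "rank_genes",
    "empirical_variogram",
    "variogram_surrogates",
    "ensemble_correlations",
    "surrogate_pvalue",
    "adrisk_gene_correlations",
    "replicate_association",
]


@dataclass
class ExpressionMatrix:
    """Regions-by-genes expression with a ledger of absent regions.

    ``data`` holds only the retained regions (no missing values allowed);
    ``missing_regions`` lists atlas region ids for which no expression is
    available.
    """

    data: pd.DataFrame
    missing_regions: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("retained expression rows must be complete")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate region ids in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def region_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()


@dataclass
class PLSResult:
    """First PLS component of map -> expression."""

    weights: pd.Series          # per-gene response weights, unit norm
    scores: pd.Series           # PLS1 regional score, indexed by region_id
    explained_variance: float   # fraction of (standardized) expression variance
    r: float                    # Pearson(score, map)
    region_ids: np.ndarray


@dataclass
class SurrogateEnsemble:
    """Variogram-matched surrogate maps built on one source map."""

    maps: np.ndarray            # (n_surrogates, n_regions)
    region_ids: np.ndarray
    bin_edges: np.ndarray
    source_variogram: np.ndarray
    kernel: str = "exponential"
    seed: int | None = None
    fit_residuals: np.ndarray | None = None

    @property
    def n_surrogates(self) -> int:
        return self.maps.shape[0]


def _zscore(a: np.ndarray, axis: int = 0, ddof: int = 1) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    mu = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, ddof=ddof, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - mu) / sd


def align_regions(
    tmap: pd.Series, expression: ExpressionMatrix
) -> tuple[pd.Series, pd.DataFrame]:
    """Restrict the map and expression to their common regions, ordered.

    Regions in the expression ledger (and any id absent from either side)
    are removed from both; fewer than 10 common regions is an error because
    the spatial statistics downstream are meaningless below that.
    """
    common = tmap.index.intersection(expression.data.index).sort_values()
    if len(common) < 10:
        raise ValueError(
            f"only {len(common)} regions shared between map and expression"
        )
    return tmap.loc[common], expression.data.loc[common]


def pls_fit(tmap: pd.Series, expression: pd.DataFrame) -> PLSResult:
    """Closed-form first PLS component for a univariate predictor.

    Both the map and every gene column are z-scored across regions first.
    The response weight vector is the per-gene covariance with the map,
    normalized to unit length; the score is the projection of the
    standardized expression onto it.
    """
    if len(tmap) != len(expression):
        raise ValueError("map and expression must be aligned")
    if len(tmap) < 3:
        raise ValueError("need at least 3 regions")
    x = np.asarray(tmap, dtype=float)
    if np.std(x) == 0:
        raise ValueError("constant map has zero predictor variance")
    xz = _zscore(x)
    Y = _zscore(expression.to_numpy(dtype=float))
    n = len(xz)

    cov = Y.T @ xz / (n - 1)            # per-gene covariance with the map
    norm = np.linalg.norm(cov)
    if norm == 0:
        raise ValueError("expression is uncorrelated with the map everywhere")
    w = cov / norm
    t = Y @ w                            # PLS1 regional score
    tt = float(t @ t)
    p = Y.T @ t / tt                     # response loadings
    explained = tt * float(p @ p) / float(np.sum(Y**2))
    r = float(pearsonr(t, xz)[0])
    return PLSResult(
        weights=pd.Series(w, index=expression.columns, name="pls1_weight"),
        scores=pd.Series(t, index=expression.index, name="pls1_score"),
        explained_variance=float(explained),
        r=r,
        region_ids=expression.index.to_numpy(),
    )


def rank_genes(result: PLSResult, k: int = 500) -> pd.DataFrame:
    """Genes ordered by |PLS1 weight| descending, ties broken by symbol.

    Returns the full ranking with a ``rank`` column; the top-``k`` slice is
    ``rank_genes(res, k).head(k)`` — the frame carries a ``top_k`` attr so
    exports can write both the full list and the top slice.
    """
    if k > len(result.weights):
        raise ValueError(f"k={k} exceeds gene count {len(result.weights)}")
    df = pd.DataFrame({
        "gene": result.weights.index,
        "weight": result.weights.to_numpy(),
    })
    df["abs_weight"] = df["weight"].abs()
    df = df.sort_values(["abs_weight", "gene"],
                        ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df = df.set_index("rank")[["gene", "weight", "abs_weight"]]
    df.attrs["top_k"] = k
    return df


# ---------------------------------------------------------------------------
# variograms and surrogate maps


def _pair_arrays(coords: np.ndarray, n_bins: int, max_frac: float):
    """Upper-triangle pair indices, distances, and variogram bin labels."""
    n = len(coords)
    iu, ju = np.triu_indices(n, k=1)
    d = pdist(coords)
    dmax = np.quantile(d, max_frac)
    edges = np.linspace(0.0, dmax, n_bins + 1)
    inside = d <= dmax
    binned = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    return iu[inside], ju[inside], d[inside], binned[inside], edges


def _binned_variogram(values: np.ndarray, iu, ju, bins, n_bins) -> np.ndarray:
    """gamma(h) = half the mean squared difference per distance bin.

    ``values`` may be (n,) or (B, n); returns (n_bins,) or (B, n_bins).
    Bins with no pairs come back as NaN.
    """
    v = np.atleast_2d(values)
    d2 = (v[:, iu] - v[:, ju]) ** 2
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    sums = np.vstack([
        np.bincount(bins, weights=row, minlength=n_bins) for row in d2
    ])
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = 0.5 * sums / counts
    return gamma[0] if np.ndim(values) == 1 else gamma


def empirical_variogram(
    values, coords, n_bins: int = 25, max_frac: float = 0.7
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical variogram of a regional map over centroid distances.

    Returns (bin centers, gamma).  Pairs beyond the ``max_frac`` quantile of
    pairwise distance are excluded, the usual guard against the noisy
    long-range tail.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    iu, ju, _, bins, edges = _pair_arrays(coords, n_bins, max_frac)
    gamma = _binned_variogram(values, iu, ju, bins, n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, gamma


def variogram_surrogates(
    values,
    coords,
    n_surrogates: int = 1000,
    n_bins: int = 25,
    max_frac: float = 0.7,
    knn_frac: float = 0.7,
    kernel: str = "exponential",
    seed: int | None = None,
    batch: int = 200,
) -> SurrogateEnsemble:
    """Generate spatial-autocorrelation-preserving surrogate maps.

    Per surrogate: (1) randomly permute the map; (2) smooth the permuted
    map over each region's k nearest neighbours (k = ``knn_frac`` * n) with
    a distance-decay kernel at several candidate length scales; (3) fit
    non-negative factors (a, b) so the variogram of
    sqrt(a)*smoothed + sqrt(b)*noise matches the source variogram over the
    distance bins, where the noise term is an independent permutation of
    the map; (4) keep the candidate scale with the smallest residual.
    The surrogate inherits the source map's mean.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 regions for surrogate maps")
    D = squareform(pdist(coords))
    pos = D[np.triu_indices(n, k=1)]
    if pos.max() == 0:
        raise ValueError("degenerate geometry: all centroids identical")

    iu, ju, _, bins, edges = _pair_arrays(coords, n_bins, max_frac)
    # drop empty bins from the matching objective
    counts = np.bincount(bins, minlength=n_bins)
    good = counts > 0
    gamma_src = _binned_variogram(x, iu, ju, bins, n_bins)[good]
    # weight the fit by inverse source magnitude (so the short-range bins,
    # where the variogram is smallest, are matched in relative terms) and by
    # sqrt(pair count) (so sparsely populated, noisy bins cannot dominate)
    fit_w = (np.sqrt(counts[good] / counts[good].mean())
             / np.clip(gamma_src, 0.2 * np.median(gamma_src), None))

    k = max(3, int(np.ceil(knn_frac * n)))
    order = np.argsort(D, axis=1)[:, :k]  # self included: weight 1 at d=0
    nd = np.take_along_axis(D, order, axis=1)
    scales = np.quantile(pos, [0.02, 0.05, 0.10, 0.20, 0.35, 0.50, 0.70])
    scales = np.unique(scales[scales > 0])
    smoothers = []
    for s in scales:
        if kernel == "exponential":
            wk = np.exp(-nd / s)
        elif kernel == "gaussian":
            wk = np.exp(-0.5 * (nd / s) ** 2)
        else:
            raise ValueError(f"unknown kernel {kernel!r}")
        wk /= wk.sum(axis=1, keepdims=True)
        W = np.zeros((n, n))
        np.put_along_axis(W, order, wk, axis=1)
        smoothers.append(W)

    mu = x.mean()
    xc = x - mu
    out = np.empty((n_surrogates, n))
    residuals = np.empty(n_surrogates)
    for start in range(0, n_surrogates, batch):
        b = min(batch, n_surrogates - start)
        perm = np.array([rng.permutation(xc) for _ in range(b)])
        noise = np.array([rng.permutation(xc) for _ in range(b)])
        gamma_noise = _binned_variogram(noise, iu, ju, bins, n_bins)[:, good]
        best_res = np.full(b, np.inf)
        best_map = np.zeros((b, n))
        for W in smoothers:
            sm = perm @ W.T
            gamma_sm = _binned_variogram(sm, iu, ju, bins, n_bins)[:, good]
            a, bb, res = _nnls2(gamma_sm * fit_w, gamma_noise * fit_w,
                                gamma_src * fit_w)
            cand = (np.sqrt(a)[:, None] * sm + np.sqrt(bb)[:, None] * noise)
            better = res < best_res
            best_res = np.where(better, res, best_res)
            best_map[better] = cand[better]
        out[start:start + b] = best_map + mu
        residuals[start:start + b] = best_res

    return SurrogateEnsemble(
        maps=out,
        region_ids=np.arange(n),
        bin_edges=edges,
        source_variogram=_binned_variogram(x, iu, ju, bins, n_bins),
        kernel=kernel,
        seed=seed,
        fit_residuals=residuals,
    )


def _nnls2(G1: np.ndarray, G2: np.ndarray, y: np.ndarray):
    """Row-wise non-negative least squares with two regressors.

    Solves min_{a,b >= 0} ||y - a*G1_row - b*G2_row||^2 for every row,
    via the closed-form 2x2 solution with clamping to the axis solutions.
    Returns (a, b, residual_norm) arrays.
    """
    s11 = np.einsum("ij,ij->i", G1, G1)
    s22 = np.einsum("ij,ij->i", G2, G2)
    s12 = np.einsum("ij,ij->i", G1, G2)
    t1 = G1 @ y
    t2 = G2 @ y
    det = s11 * s22 - s12**2
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (s22 * t1 - s12 * t2) / det
        b = (s11 * t2 - s12 * t1) / det
        a1 = np.where(s11 > 0, t1 / s11, 0.0)  # b = 0 branch
        b1 = np.where(s22 > 0, t2 / s22, 0.0)  # a = 0 branch
    bad = ~np.isfinite(a) | ~np.isfinite(b) | (a < 0) | (b < 0)
    a1 = np.clip(a1, 0, None)
    b1 = np.clip(b1, 0, None)
    res_a = _res2(G1, G2, y, a1, np.zeros_like(a1))
    res_b = _res2(G1, G2, y, np.zeros_like(b1), b1)
    use_a = res_a <= res_b
    a = np.where(bad, np.where(use_a, a1, 0.0), a)
    b = np.where(bad, np.where(use_a, 0.0, b1), b)
    res = _res2(G1, G2, y, a, b)
    return a, b, res


def _res2(G1, G2, y, a, b):
    r = y[None, :] - a[:, None] * G1 - b[:, None] * G2
    return np.sqrt(np.einsum("ij,ij->i", r, r))


def ensemble_correlations(ensemble: SurrogateEnsemble, other: np.ndarray) -> np.ndarray:
    """Pearson r between each surrogate map and a fixed second map."""
    other = np.asarray(other, dtype=float)
    M = ensemble.maps - ensemble.maps.mean(axis=1, keepdims=True)
    o = other - other.mean()
    denom = np.linalg.norm(M, axis=1) * np.linalg.norm(o)
    denom = np.where(denom == 0, np.inf, denom)
    return (M @ o) / denom


def surrogate_pvalue(
    observed_r: float, ensemble: SurrogateEnsemble, other_map
) -> float:
    """Two-sided surrogate p-value with the add-one permutation estimator.

    p = (1 + #{|r_surr| >= |r_obs|}) / (1 + n_surrogates), where r_surr is
    the correlation of each surrogate (built on one map) with the other.
    """
    r_surr = ensemble_correlations(ensemble, other_map)
    n = ensemble.n_surrogates
    return float((1 + np.sum(np.abs(r_surr) >= abs(observed_r))) / (1 + n))


def adrisk_gene_correlations(
    tmap: pd.Series,
    expression: pd.DataFrame,
    risk_list,
    ensemble: SurrogateEnsemble | None = None,
) -> pd.DataFrame:
    """Pearson r (and surrogate p) of each available risk gene vs the map.

    Risk genes absent from the expression pool are recorded in the frame's
    ``attrs["missing_genes"]`` rather than raised.
    """
    risk_list = list(risk_list)
    present = [g for g in risk_list if g in expression.columns]
    missing = [g for g in risk_list if g not in expression.columns]
    if not present:
        raise ValueError("no risk gene present in the expression matrix")
    x = np.asarray(tmap, dtype=float)
    rows = []
    for g in present:
        prof = expression[g].to_numpy(dtype=float)
        if np.std(prof) == 0 or np.std(x) == 0:
            r, p_par = np.nan, np.nan
        else:
            r, p_par = pearsonr(prof, x)
        p_surr = (
            surrogate_pvalue(r, ensemble, prof)
            if ensemble is not None and np.isfinite(r)
            else np.nan
        )
        rows.append((g, float(r), p_surr, "AD-risk"))
    out = pd.DataFrame(rows, columns=["gene", "r", "surrogate_p", "flag"])
    out.attrs["missing_genes"] = missing
    return out


def replicate_association(
    result: PLSResult,
    other_map: pd.Series,
    expression: pd.DataFrame,
    ensemble: SurrogateEnsemble | None = None,
) -> dict:
    """Re-fit PLS on a second map over the same regions and compare.

    Reports the Pearson correlation between the two gene-weight vectors,
    plus the second fit's score-map correlation (and its surrogate p when
    an ensemble on the second map is supplied).
    """
    other = other_map.loc[pd.Index(result.region_ids)]
    refit = pls_fit(other, expression)
    w_r = float(pearsonr(result.weights.to_numpy(), refit.weights.to_numpy())[0])
    p = (
        surrogate_pvalue(refit.r, ensemble, refit.scores.to_numpy())
        if ensemble is not None
        else None
    )
    return {
        "weight_correlation": w_r,
        "r": refit.r,
        "surrogate_p": p,
        "refit": refit,
    }


# ---------------------------------------------------------------------------
# expression I/O


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = expr.data.copy()
    df.index.name = "region_id"
    df.to_csv(path, sep="\t")


def load_expression(path, missing_regions=()) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="region_id")
    return ExpressionMatrix(data=df, missing_regions=tuple(missing_regions))
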