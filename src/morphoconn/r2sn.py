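"""Regional radiomics similarity network (R2SN) construction and the RMCS
statistic.

Per subject: min-max normalize each feature across regions, drop features
that are redundant across the cohort (|r| above a threshold with an already
retained feature), correlate every pair of regions' retained-feature
vectors (Pearson) to obtain the network adjacency, and reduce each region
to its regional mean connectivity strength (RMCS) — the mean of its edge
weights excluding the diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .radiomics import RegionFeatureTable

__all__ = [
    "NormalizedFeatureTable",
    "RedundancyMask",
    "ConnectivityMatrix",
    "RMCSVector",
    "minmax_normalize",
    "find_redundant_features",
    "build_r2sn",
    "compute_rmcs",
    "cohort_rmcs",
]


@dataclass
class NormalizedFeatureTable:
    """Feature table after per-subject, per-feature min-max scaling."""

    subject_id: str
    data: pd.DataFrame
    flagged: frozenset = frozenset()


@dataclass
class RedundancyMask:
    """Which features survive the cohort-level redundancy filter.

    ``partner`` records, for each dropped feature, the retained feature it
    was correlated with beyond the threshold.
    """

    keep: pd.Series  # bool per feature, catalog order
    threshold: float
    partner: dict[str, str] = field(default_factory=dict)

    @property
    def retained(self) -> list[str]:
        return list(self.keep.index[self.keep])


@dataclass
class ConnectivityMatrix:
    """Symmetric region-by-region Pearson adjacency for one subject."""

    subject_id: str
    matrix: pd.DataFrame
    flagged_regions: frozenset = frozenset()
    diagonal: float = 1.0

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")


@dataclass
class RMCSVector:
    """Per-region mean connectivity strength for one subject."""

    subject_id: str
    values: pd.Series
    edge_sign: str = "signed"  # "signed" | "absolute"


def minmax_normalize(table: RegionFeatureTable | NormalizedFeatureTable) -> NormalizedFeatureTable:
    """Scale each feature to [0, 1] across regions within one subject.

    Constant feature columns map to 0.  Flagged (degenerate) regions are
    excluded when locating each column's min/max but are still rescaled, so
    a pathological region cannot distort the normalization of the rest.
    """
    df = table.data
    if len(df) < 2:
        raise ValueError("min-max normalization needs at least 2 regions")
    flagged = table.flagged
    ref = df.drop(index=[r for r in flagged if r in df.index]) if flagged else df
    if len(ref) < 2:
        ref = df
    lo = ref.min(axis=0)
    hi = ref.max(axis=0)
    span = hi - lo
    out = (df - lo) / span.replace(0.0, np.nan)
    out = out.fillna(0.0)
    return NormalizedFeatureTable(subject_id=table.subject_id, data=out,
                                  flagged=frozenset(flagged))


def find_redundant_features(
    tables: Sequence[NormalizedFeatureTable], threshold: float = 0.9
) -> RedundancyMask:
    """Cohort-level greedy redundancy filter on feature-feature Pearson |r|.

    Observations are region rows pooled across all subjects.  Scanning in
    catalog order, a feature is dropped iff its |r| with any already
    retained feature exceeds ``threshold`` (strictly).  One shared mask for
    the whole cohort keeps every subject's network on the same feature set.
    """
    if not tables:
        raise ValueError("cohort of normalized tables must be non-empty")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cols = list(tables[0].data.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 features")
    pooled = np.vstack([t.data.to_numpy() for t in tables])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(pooled, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # constant columns correlate with nothing

    keep = np.zeros(len(cols), dtype=bool)
    partner: dict[str, str] = {}
    retained_idx: list[int] = []
    # strict |r| > threshold; at threshold 1.0 exact duplicates still drop
    limit = min(threshold, 1.0 - 1e-12)
    for j in range(len(cols)):
        hits = [k for k in retained_idx if abs(corr[j, k]) > limit]
        if hits:
            partner[cols[j]] = cols[hits[0]]
        else:
            keep[j] = True
            retained_idx.append(j)
    n_keep = int(keep.sum())
    if n_keep < 2:
        raise ValueError("fewer than 2 features retained by redundancy filter")
    if n_keep == 2:
        warnings.warn(
            f"redundancy filter dropped all but {n_keep} features", stacklevel=2
        )
    return RedundancyMask(keep=pd.Series(keep, index=cols),
                          threshold=threshold, partner=partner)


def build_r2sn(
    table: NormalizedFeatureTable, mask: RedundancyMask | None = None
) -> ConnectivityMatrix:
    """Pearson-correlate every pair of regions' retained-feature vectors.

    A region whose retained features have zero variance cannot be
    correlated; its row/column are set to 0 and the region is flagged.
    """
    df = table.data if mask is None else table.data[mask.retained]
    if df.shape[1] < 3:
        raise ValueError("need at least 3 retained features for region Pearson edges")
    X = df.to_numpy(dtype=float)
    sd = X.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C = np.clip(np.nan_to_num(C, nan=0.0), -1.0, 1.0)
    C[degenerate, :] = 0.0
    C[:, degenerate] = 0.0
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0  # exact symmetry
    flagged = frozenset(int(r) for r in df.index[degenerate]) | table.flagged
    mat = pd.DataFrame(C, index=df.index, columns=df.index)
    return ConnectivityMatrix(subject_id=table.subject_id, matrix=mat,
                              flagged_regions=flagged)


def compute_rmcs(conn: ConnectivityMatrix, edge_sign: str = "signed") -> RMCSVector:
    """Mean connectivity strength per region, diagonal excluded.

    ``edge_sign="signed"`` averages raw edge weights (default);
    ``"absolute"`` averages their magnitudes.
    """
    if edge_sign not in ("signed", "absolute"):
        raise ValueError("edge_sign must be 'signed' or 'absolute'")
    W = conn.matrix.to_numpy(dtype=float).copy()
    if edge_sign == "absolute":
        W = np.abs(W)
    np.fill_diagonal(W, 0.0)
    n = W.shape[0]
    vals = W.sum(axis=1) / (n - 1)
    return RMCSVector(subject_id=conn.subject_id,
                      values=pd.Series(vals, index=conn.matrix.index),
                      edge_sign=edge_sign)


def cohort_rmcs(
    tables: Iterable[RegionFeatureTable],
    threshold: float = 0.9,
    edge_sign: str = "signed",
    mask: RedundancyMask | None = None,
) -> tuple[pd.DataFrame, RedundancyMask]:
    """Full per-subject pipeline: normalize, filter, correlate, reduce.

    Returns a subjects-by-regions RMCS table plus the shared redundancy
    mask (computed on the cohort unless supplied).
    """
    normalized = [minmax_normalize(t) for t in tables]
    if not normalized:
        raise ValueError("empty cohort")
    if mask is None:
        mask = find_redundant_features(normalized, threshold=threshold)
    rows = {}
    for t in normalized:
        rmcs = compute_rmcs(build_r2sn(t, mask), edge_sign=edge_sign)
        rows[t.subject_id] = rmcs.values
    out = pd.DataFrame(rows).T
    out.index.name = "subject_id"
    return out, mask
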