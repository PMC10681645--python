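"""Cell-class expression signatures and their spatial association with a
regional statistic map.

Each of the seven canonical brain cell classes (microglia, endothelial
cells, oligodendrocyte precursors, oligodendrocytes, astrocytes,
inhibitory neurons, excitatory neurons) is summarized as the mean regional
expression of its gene set, z-scored across regions, yielding a
retained-regions-by-7 matrix.  Associations with the map are Pearson
correlations tested against the shared variogram-matched surrogate
ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .transcriptomics import SurrogateEnsemble, surrogate_pvalue

__all__ = [
    "CellTypeSets",
    "restrict_sets",
    "celltype_matrix",
    "celltype_association",
    "load_gene_sets",
]


@dataclass
class CellTypeSets:
    """Named cell-class gene lists after restriction to a gene pool."""

    sets: dict[str, list[str]]
    empty_classes: tuple = ()
    provenance: str = ""


def load_gene_sets(directory) -> dict[str, list[str]]:
    """Read ``<class>.txt`` files (one gene symbol per line)."""
    from pathlib import Path

    out = {}
    for path in sorted(Path(directory).glob("*.txt")):
        genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        out[path.stem] = genes
    if not out:
        raise ValueError(f"no .txt gene-set files found in {directory}")
    return out


def restrict_sets(
    cell_sets: dict[str, list[str]],
    gene_pool,
    relevance_list=None,
    provenance: str = "",
) -> CellTypeSets:
    """Intersect every class with the expression pool (and a relevance list).

    The relevance list — by default the top-ranked PLS genes — narrows each
    class to the genes implicated by the map-expression analysis.  Classes
    that end up empty are flagged, not dropped silently; all classes empty
    is an error.  Within-class duplicates are removed (set semantics) while
    genes shared between classes are kept in each.
    """
    pool = set(gene_pool)
    if not pool:
        raise ValueError("gene pool is empty")
    allowed = pool if relevance_list is None else pool & set(relevance_list)
    restricted: dict[str, list[str]] = {}
    empty = []
    for name, genes in cell_sets.items():
        kept = sorted(set(genes) & allowed)
        restricted[name] = kept
        if not kept:
            empty.append(name)
    if len(empty) == len(cell_sets):
        raise ValueError("every cell class is empty after restriction")
    return CellTypeSets(sets=restricted, empty_classes=tuple(empty),
                        provenance=provenance)


def _zscore_cols(a: np.ndarray, ddof: int = 1) -> np.ndarray:
    mu = a.mean(axis=0, keepdims=True)
    sd = a.std(axis=0, ddof=ddof, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - mu) / sd


def celltype_matrix(
    expression: pd.DataFrame,
    cell_sets: CellTypeSets,
    gene_scaling: str = "zscore",
) -> pd.DataFrame:
    """Regions-by-classes signature matrix, each column z-scored.

    Per class: average the member genes' regional profiles (z-scored per
    gene first under the default ``gene_scaling="zscore"``, raw under
    ``"raw"``), then z-score the class column across regions.  Empty
    classes are omitted with a warning.
    """
    if gene_scaling not in ("zscore", "raw"):
        raise ValueError("gene_scaling must be 'zscore' or 'raw'")
    import warnings

    X = expression.to_numpy(dtype=float)
    if gene_scaling == "zscore":
        X = _zscore_cols(X)
    col_of = {g: j for j, g in enumerate(expression.columns)}
    cols = {}
    for name, genes in cell_sets.sets.items():
        idx = [col_of[g] for g in genes if g in col_of]
        if not idx:
            warnings.warn(f"cell class {name!r} has no genes in the "
                          "expression matrix; column omitted", stacklevel=2)
            continue
        cols[name] = X[:, idx].mean(axis=1)
    out = pd.DataFrame(cols, index=expression.index)
    out[:] = _zscore_cols(out.to_numpy())
    return out


def celltype_association(
    matrix: pd.DataFrame,
    tmap: pd.Series,
    ensemble: SurrogateEnsemble | None = None,
) -> pd.DataFrame:
    """Pearson r (and surrogate p) of each class signature vs the map."""
    if len(matrix) != len(tmap):
        raise ValueError("signature matrix and map must be aligned")
    x = np.asarray(tmap, dtype=float)
    rows = []
    for name in matrix.columns:
        prof = matrix[name].to_numpy(dtype=float)
        r, p_par = pearsonr(prof, x)
        p_surr = (
            surrogate_pvalue(float(r), ensemble, prof)
            if ensemble is not None else np.nan
        )
        rows.append((name, float(r), p_surr, float(p_par)))
    return pd.DataFrame(rows, columns=["cell_class", "r", "surrogate_p",
                                       "parametric_p"])
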