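"""Covariate-adjusted region-wise group statistics on RMCS.

Age and sex are removed by ordinary least squares fitted on all subjects
pooled; the residualized RMCS then feeds a one-way ANOVA across the three
diagnostic groups, pairwise two-sided t-tests per contrast, Bonferroni
control over regions, an age-matched subsampling robustness check, and
within-group clinical correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .resources import CLINICAL_MEASURES, GROUPS

__all__ = [
    "BootstrapReport",
    "residualize",
    "anova_by_region",
    "pairwise_t",
    "bonferroni_mask",
    "bootstrap_agematched",
    "clinical_correlation",
]


@dataclass
class BootstrapReport:
    """Outcome of the age-matched subsample robustness analysis."""

    n_iterations: int
    correlations: np.ndarray        # per-iteration Pearson r with the full map
    r_threshold: float
    fraction_above: float           # fraction of iterations with r > threshold
    n_failed: int                   # iterations whose redraw cap was exhausted
    age_match_attempts: np.ndarray  # redraws needed per iteration
    seed: int | None = None
    subsample_fraction: float = 0.8

    @property
    def acceptance_rate(self) -> float:
        """Fraction of candidate draws that passed the age-matching check."""
        return float(len(self.age_match_attempts) /
                     max(self.age_match_attempts.sum(), 1))


def _check_aligned(rmcs: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    cov = covariates.set_index("subject_id") if "subject_id" in covariates.columns else covariates
    if not rmcs.index.equals(cov.index):
        cov = cov.loc[rmcs.index]
    return cov


def residualize(rmcs: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Remove age and sex from every region's RMCS by pooled OLS.

    The design is [intercept, age, sex] over all subjects; residuals are
    returned with the same shape and labels.  A rank-deficient design
    (constant age and sex) is an error.
    """
    cov = _check_aligned(rmcs, covariates)
    if cov[["age", "sex"]].isna().any().any():
        raise ValueError("age/sex must be complete for residualization")
    X = np.column_stack([
        np.ones(len(cov)),
        cov["age"].to_numpy(dtype=float),
        cov["sex"].to_numpy(dtype=float),
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design (constant age and sex)")
    Y = rmcs.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid, index=rmcs.index, columns=rmcs.columns)


def _group_arrays(rmcs: pd.DataFrame, groups: pd.Series,
                  labels=GROUPS) -> list[np.ndarray]:
    g = groups.loc[rmcs.index] if not groups.index.equals(rmcs.index) else groups
    out = []
    for lab in labels:
        sel = rmcs.loc[(g == lab).to_numpy()]
        if sel.empty:
            raise ValueError(f"group {lab!r} is empty")
        out.append(sel.to_numpy(dtype=float))
    return out


def anova_by_region(rmcs: pd.DataFrame, groups: pd.Series,
                    labels=GROUPS) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per region across the given groups."""
    arrays = _group_arrays(rmcs, groups, labels)
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 subjects")
    F, p = stats.f_oneway(*arrays, axis=0)
    F = np.where(np.isfinite(F), F, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    out = pd.DataFrame({"F": F, "p": p}, index=rmcs.columns)
    out.index.name = "region_id"
    return out


def pairwise_t(
    rmcs: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str] = ("AD", "NC"),
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sided two-sample t per region; positive t = first group higher.

    Pooled-variance Student's t by default; ``equal_var=False`` switches to
    Welch.  Regions where both groups are constant with equal means are
    reported as t = 0, p = 1.
    """
    a, b = _group_arrays(rmcs, groups, contrast)
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=0), b.mean(axis=0))
        t = np.where(degenerate & equal_means, 0.0, t)
        p = np.where(degenerate & equal_means, 1.0, p)
    out = pd.DataFrame({"t": t, "p": p}, index=rmcs.columns)
    out.index.name = "region_id"
    out.attrs["contrast"] = f"{contrast[0]}-{contrast[1]}"
    return out


def bonferroni_mask(p, alpha: float = 0.05, n: int | None = None) -> np.ndarray:
    """Strict Bonferroni significance mask: p < alpha / n."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p) if n is None else n
    return p < alpha / n


def bootstrap_agematched(
    rmcs: pd.DataFrame,
    covariates: pd.DataFrame,
    n_iter: int = 1000,
    frac: float = 0.8,
    alpha_age: float = 0.05,
    r_threshold: float = 0.5,
    seed: int | None = None,
    redraw_cap: int = 100,
    labels=GROUPS,
) -> BootstrapReport:
    """Age-matched subsample robustness of the regional ANOVA map.

    Each iteration draws ``frac`` of every group without replacement and
    redraws (up to ``redraw_cap`` times) until a one-way ANOVA on age
    across the subgroups is non-significant (p > ``alpha_age``).  The
    regional significance map, -log10 p of the group ANOVA on the
    subsample, is then correlated (Pearson) with the full-sample map; the
    report gives the fraction of iterations whose correlation exceeds
    ``r_threshold``.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    cov = _check_aligned(rmcs, covariates)
    rng = np.random.default_rng(seed)
    g = cov["group"]
    idx_by_group = {lab: np.flatnonzero((g == lab).to_numpy()) for lab in labels}
    for lab, idx in idx_by_group.items():
        if len(idx) == 0:
            raise ValueError(f"group {lab!r} is empty")
    ages = cov["age"].to_numpy(dtype=float)
    Y = rmcs.to_numpy(dtype=float)
    grp_codes = g.to_numpy()

    def neglog_map(rows: np.ndarray) -> np.ndarray:
        sub = pd.DataFrame(Y[rows], columns=rmcs.columns)
        res = anova_by_region(sub, pd.Series(grp_codes[rows]), labels)
        return -np.log10(np.clip(res["p"].to_numpy(), 1e-300, None))

    full_map = neglog_map(np.arange(len(cov)))

    corrs, attempts = [], []
    n_failed = 0
    for _ in range(n_iter):
        if frac == 1.0:  # the subsample is the full sample; nothing to match
            sub_map = full_map
            corrs.append(float(np.corrcoef(sub_map, full_map)[0, 1])
                         if np.std(full_map) > 0 else 0.0)
            attempts.append(1)
            continue
        ok = False
        for attempt in range(1, redraw_cap + 1):
            rows = np.concatenate([
                rng.choice(idx, size=max(2, int(round(frac * len(idx)))),
                           replace=False)
                for idx in idx_by_group.values()
            ])
            age_groups = [ages[rows[grp_codes[rows] == lab]] for lab in labels]
            p_age = stats.f_oneway(*age_groups)[1]
            if not np.isfinite(p_age) or p_age > alpha_age:
                ok = True
                break
        attempts.append(attempt)
        if not ok:
            n_failed += 1
            continue
        sub_map = neglog_map(rows)
        if np.std(sub_map) == 0 or np.std(full_map) == 0:
            corrs.append(0.0)
        else:
            corrs.append(float(np.corrcoef(sub_map, full_map)[0, 1]))
    corrs = np.asarray(corrs)
    frac_above = float(np.mean(corrs > r_threshold)) if len(corrs) else 0.0
    return BootstrapReport(
        n_iterations=n_iter,
        correlations=corrs,
        r_threshold=r_threshold,
        fraction_above=frac_above,
        n_failed=n_failed,
        age_match_attempts=np.asarray(attempts),
        seed=seed,
        subsample_fraction=frac,
    )


def clinical_correlation(
    rmcs: pd.DataFrame,
    covariates: pd.DataFrame,
    regions=None,
    group: str = "AD",
    measures=CLINICAL_MEASURES,
) -> pd.DataFrame:
    """Pearson r of RMCS vs each clinical measure within one group.

    Computed per region of ``regions`` (default: all) with pairwise
    deletion of missing clinical values; intentionally uncorrected for
    multiple comparisons.  Entries with fewer than 3 complete pairs, or a
    constant score, are flagged undefined (NaN).
    """
    cov = _check_aligned(rmcs, covariates)
    if group not in set(cov["group"]):
        raise ValueError(f"group {group!r} not present")
    in_group = (cov["group"] == group).to_numpy()
    sub_rmcs = rmcs.loc[in_group]
    sub_cov = cov.loc[in_group]
    regions = list(rmcs.columns) if regions is None else list(regions)

    rows = []
    for measure in measures:
        if measure not in sub_cov.columns:
            raise ValueError(f"clinical column {measure!r} missing")
        score = sub_cov[measure].to_numpy(dtype=float)
        valid = np.isfinite(score)
        for region in regions:
            v = sub_rmcs[region].to_numpy(dtype=float)
            m = valid & np.isfinite(v)
            if m.sum() < 3 or np.std(score[m]) == 0 or np.std(v[m]) == 0:
                rows.append((region, measure, np.nan, np.nan, True))
                continue
            r, p = stats.pearsonr(v[m], score[m])
            rows.append((region, measure, float(r), float(p), False))
    out = pd.DataFrame(rows, columns=["region_id", "measure", "r", "p", "undefined"])
    out.attrs["group"] = group
    return out
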