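"""End-to-end orchestration of the analysis with one config and manifest.

Stages: simulate (optional) -> network -> groupdiff -> transcriptomics ->
celltypes.  Every stage writes plain-text outputs (TSV/JSON) under the run
directory and the manifest records the config hash, seeds, package
versions and a checksum per output, so a rerun of a downstream stage from
on-disk intermediates is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_types import celltype_association, celltype_matrix, restrict_sets
from .group_stats import (anova_by_region, bonferroni_mask,
                          bootstrap_agematched, clinical_correlation,
                          pairwise_t, residualize)
from .r2sn import cohort_rmcs
from .synthetic_cohort import (CohortSpec, ExpressionSpec, default_effect_regions,
                               generate_atlas, generate_cohort,
                               generate_expression, generate_gene_sets,
                               write_atlas, write_gene_sets)
from .transcriptomics import (adrisk_gene_correlations, align_regions, pls_fit,
                              rank_genes, replicate_association,
                              surrogate_pvalue, variogram_surrogates)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Run-wide settings; every fixed constant of the analysis is a key.

    The shipped desk-scale defaults (30 subjects/group, 60 regions, 800
    genes, 200 surrogates) complete quickly on one CPU; the full-scale
    values used by the original study design (246 regions, 47 features,
    605/766/283 subjects, up to 10,000 surrogates, 1000 bootstrap
    iterations) are plain config overrides.
    """

    out_dir: str = "morphoconn_run"
    seed: int = 0

    # synthetic cohort
    simulate: bool = True
    n_per_group: tuple[int, int, int] = (30, 30, 30)
    n_regions: int = 60
    n_features: int = 47
    n_effect_regions: int = 8
    effect_size: float = 1.0
    age_shift_ad: float = 1.4
    n_genes: int = 800
    corr_length: float = 40.0
    n_missing_regions: int = 4
    planted_gene_fraction: float = 0.2

    # network
    redundancy_threshold: float = 0.9
    edge_sign: str = "signed"

    # group statistics
    alpha: float = 0.05
    bonferroni_n: int | None = None       # default: number of regions
    t_test: str = "student"               # "student" | "welch"
    bootstrap_n_iter: int = 200
    bootstrap_frac: float = 0.8
    r_threshold: float = 0.5

    # transcriptomics / cell types
    n_surrogates: int = 200
    top_k: int = 500
    top_k_export: int = 1000
    celltype_relevance: str = "top_pls"   # "top_pls" | "ad_risk" | "all"

    # pre-computed inputs when simulate is False
    rmcs_path: str | None = None
    covariates_path: str | None = None
    atlas_path: str | None = None
    expression_path: str | None = None
    gene_sets_dir: str | None = None

    def validate(self) -> None:
        if not 0 < self.redundancy_threshold <= 1:
            raise ValueError("redundancy_threshold must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.bootstrap_frac <= 1:
            raise ValueError("bootstrap_frac must lie in (0, 1]")
        if self.edge_sign not in ("signed", "absolute"):
            raise ValueError("edge_sign must be 'signed' or 'absolute'")
        if self.t_test not in ("student", "welch"):
            raise ValueError("t_test must be 'student' or 'welch'")
        if self.celltype_relevance not in ("top_pls", "ad_risk", "all"):
            raise ValueError("celltype_relevance must be top_pls|ad_risk|all")
        if self.top_k > self.n_genes and self.simulate:
            raise ValueError("top_k exceeds the simulated gene count")
        if not self.simulate:
            missing = [k for k in ("rmcs_path", "covariates_path", "atlas_path",
                                   "expression_path", "gene_sets_dir")
                       if getattr(self, k) is None]
            if missing:
                raise ValueError(
                    f"simulate=false requires input paths: {missing}"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "n_per_group" in raw:
            raw["n_per_group"] = tuple(raw["n_per_group"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["n_per_group"] = list(d["n_per_group"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute all stages and return the manifest dict (also written)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)

    def record(stage: str, t0: float, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    try:
        # ------------------------------------------------------- simulate
        t0 = time.perf_counter()
        if config.simulate:
            atlas = generate_atlas(config.n_regions, seed=int(rng_seeds[0]))
            effect_regions = default_effect_regions(
                atlas, config.n_effect_regions, seed=int(rng_seeds[1]))
            cohort_spec = CohortSpec(
                n_per_group=config.n_per_group, n_regions=config.n_regions,
                n_features=config.n_features, effect_regions=effect_regions,
                effect_size=config.effect_size,
                age_shift_ad=config.age_shift_ad, seed=int(rng_seeds[2]),
            )
            tables, covariates = generate_cohort(atlas, cohort_spec)
            planted = np.isin(atlas.region_ids, sorted(effect_regions)).astype(float)
            expr_spec = ExpressionSpec(
                n_genes=config.n_genes, corr_length=config.corr_length,
                n_missing_regions=config.n_missing_regions,
                planted_gene_fraction=config.planted_gene_fraction,
                seed=int(rng_seeds[3]),
            )
            expression = generate_expression(atlas, expr_spec, planted)
            cell_sets, risk_list = generate_gene_sets(
                expression.genes, seed=int(rng_seeds[4]))
            sim_dir = out / "sim"
            sim_dir.mkdir(exist_ok=True)
            write_atlas(atlas, sim_dir / "atlas.tsv")
            covariates.to_csv(sim_dir / "covariates.csv", index=False)
            expression.data.to_csv(sim_dir / "expression.tsv", sep="\t")
            write_gene_sets(cell_sets, risk_list, sim_dir / "gene_sets")
            (sim_dir / "effect_regions.json").write_text(
                json.dumps(sorted(effect_regions)))
            record("simulate", t0, [sim_dir / "atlas.tsv",
                                    sim_dir / "covariates.csv",
                                    sim_dir / "expression.tsv"])
        else:
            from .cell_types import load_gene_sets
            from .resources import AD_RISK_GENES
            from .synthetic_cohort import load_atlas
            from .transcriptomics import load_expression

            atlas = load_atlas(config.atlas_path)
            covariates = pd.read_csv(config.covariates_path)
            expression = load_expression(config.expression_path)
            all_sets = load_gene_sets(config.gene_sets_dir)
            risk_list = all_sets.pop("ad_risk", None) or list(AD_RISK_GENES)
            cell_sets = all_sets
            tables = None
            record("load", t0, [])

        # -------------------------------------------------------- network
        t0 = time.perf_counter()
        if tables is not None:
            rmcs, mask = cohort_rmcs(tables,
                                     threshold=config.redundancy_threshold,
                                     edge_sign=config.edge_sign)
        else:
            rmcs = pd.read_csv(config.rmcs_path, sep="\t", index_col="subject_id")
            rmcs.columns = rmcs.columns.astype(int)
            mask = None
        rmcs_path = out / "rmcs.tsv"
        rmcs.to_csv(rmcs_path, sep="\t")
        if mask is not None:
            (out / "redundancy_mask.json").write_text(json.dumps({
                "threshold": mask.threshold,
                "retained": mask.retained,
                "dropped": mask.partner,
            }, indent=1))
        record("network", t0, [rmcs_path])

        # ------------------------------------------------------ groupdiff
        t0 = time.perf_counter()
        cov_idx = covariates.set_index("subject_id")
        adjusted = residualize(rmcs, covariates)
        groups = cov_idx.loc[rmcs.index, "group"]
        fmap = anova_by_region(adjusted, groups)
        n_bonf = config.bonferroni_n or rmcs.shape[1]
        tmaps = {}
        for contrast in (("AD", "NC"), ("MCI", "NC"), ("AD", "MCI")):
            tm = pairwise_t(adjusted, groups, contrast,
                            equal_var=config.t_test == "student")
            tm["significant"] = bonferroni_mask(tm["p"], config.alpha, n_bonf)
            tmaps["-".join(contrast)] = tm
            tm.to_csv(out / f"tmap_{contrast[0]}_vs_{contrast[1]}.tsv", sep="\t")
        fmap["significant"] = bonferroni_mask(fmap["p"], config.alpha, n_bonf)
        fmap.to_csv(out / "fmap.tsv", sep="\t")
        boot = bootstrap_agematched(
            rmcs, covariates, n_iter=config.bootstrap_n_iter,
            frac=config.bootstrap_frac, r_threshold=config.r_threshold,
            seed=int(rng_seeds[5]))
        (out / "bootstrap_report.json").write_text(json.dumps({
            "n_iterations": boot.n_iterations,
            "fraction_above": boot.fraction_above,
            "r_threshold": boot.r_threshold,
            "n_failed": boot.n_failed,
            "subsample_fraction": boot.subsample_fraction,
        }, indent=1))
        sig_regions = fmap.index[fmap["significant"]].tolist()
        clin_frames = []
        for grp in ("MCI", "AD"):
            cc = clinical_correlation(adjusted, covariates,
                                      regions=sig_regions or None, group=grp)
            cc.insert(0, "group", grp)
            clin_frames.append(cc)
        pd.concat(clin_frames).to_csv(out / "clinical_correlations.tsv",
                                      sep="\t", index=False)
        record("groupdiff", t0, [out / "fmap.tsv",
                                 out / "tmap_AD_vs_NC.tsv",
                                 out / "bootstrap_report.json"])

        # ------------------------------------------------- transcriptomics
        t0 = time.perf_counter()
        tmap_ad = tmaps["AD-NC"]["t"]
        tmap_aligned, expr_aligned = align_regions(tmap_ad, expression)
        centroids = atlas.table.set_index("region_id").loc[
            tmap_aligned.index, ["x", "y", "z"]].to_numpy()
        pls = pls_fit(tmap_aligned, expr_aligned)
        ensemble = variogram_surrogates(
            tmap_aligned.to_numpy(), centroids,
            n_surrogates=config.n_surrogates, seed=int(rng_seeds[6]))
        pls_p = surrogate_pvalue(pls.r, ensemble, pls.scores.to_numpy())
        ranking = rank_genes(pls, k=config.top_k)
        ranking.head(config.top_k_export).to_csv(out / "gene_ranking.tsv", sep="\t")
        ranking.head(config.top_k)["gene"].to_csv(
            out / "top_genes.txt", index=False, header=False)
        risk_table = adrisk_gene_correlations(tmap_aligned, expr_aligned,
                                              risk_list, ensemble)
        risk_table.to_csv(out / "adrisk_correlations.tsv", sep="\t", index=False)

        tmap_mci = tmaps["MCI-NC"]["t"].loc[tmap_aligned.index]
        rep_mci = replicate_association(pls, tmap_mci, expr_aligned, ensemble)
        sig_ad = tmaps["AD-NC"].loc[tmap_aligned.index]
        sig_map = tmap_aligned * sig_ad["significant"].to_numpy()
        rep_sig = (replicate_association(pls, sig_map, expr_aligned, ensemble)
                   if sig_map.std() > 0 else None)
        (out / "pls_report.json").write_text(json.dumps({
            "explained_variance": pls.explained_variance,
            "r": pls.r,
            "surrogate_p": pls_p,
            "n_regions": int(len(tmap_aligned)),
            "n_genes": int(expr_aligned.shape[1]),
            "replication_mci": {"weight_correlation": rep_mci["weight_correlation"],
                                "r": rep_mci["r"],
                                "surrogate_p": rep_mci["surrogate_p"]},
            "replication_significant_map": (
                None if rep_sig is None else
                {"weight_correlation": rep_sig["weight_correlation"],
                 "r": rep_sig["r"], "surrogate_p": rep_sig["surrogate_p"]}),
        }, indent=1))
        record("transcriptomics", t0, [out / "pls_report.json",
                                       out / "gene_ranking.tsv",
                                       out / "adrisk_correlations.tsv"])

        # ------------------------------------------------------ celltypes
        t0 = time.perf_counter()
        relevance = {
            "top_pls": ranking.head(config.top_k)["gene"].tolist(),
            "ad_risk": risk_list,
            "all": None,
        }[config.celltype_relevance]
        restricted = restrict_sets(cell_sets, expr_aligned.columns, relevance)
        signatures = celltype_matrix(expr_aligned, restricted)
        assoc = celltype_association(signatures, tmap_aligned, ensemble)
        signatures.to_csv(out / "celltype_matrix.tsv", sep="\t")
        assoc.to_csv(out / "celltype_associations.tsv", sep="\t", index=False)
        record("celltypes", t0, [out / "celltype_matrix.tsv",
                                 out / "celltype_associations.tsv"])
        manifest["status"] = "complete"
    except Exception as exc:  # record partial completion, then re-raise
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
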