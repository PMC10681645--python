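# Default desk-scale run configuration for `morphoconn run-all`.
# Every fixed constant of the analysis is a named key here; the full-scale
# study design is a matter of overriding the synthetic-cohort sizes
# (n_per_group: [605, 766, 283], n_regions: 246, n_genes: 15633,
# n_missing_regions: 10, n_surrogates: 10000, bootstrap_n_iter: 1000).

out_dir: morphoconn_run
seed: 0

# --- synthetic cohort -------------------------------------------------------
simulate: true
n_per_group: [30, 30, 30]     # NC, MCI, AD
n_regions: 60
n_features: 47                # radiomics features per region
n_effect_regions: 8           # planted disease regions (~10-15%)
effect_size: 1.0              # latent Cohen's d applied to AD (MCI gets half)
age_shift_ad: 1.4             # years; AD group mean age confound
n_genes: 800
corr_length: 40.0             # mm; expression spatial autocorrelation scale
n_missing_regions: 4          # regions without expression
planted_gene_fraction: 0.2

# --- network ----------------------------------------------------------------
redundancy_threshold: 0.9     # drop features with |r| > 0.9 to a kept one
edge_sign: signed             # signed | absolute RMCS averaging

# --- group statistics -------------------------------------------------------
alpha: 0.05
bonferroni_n: null            # null = number of regions
t_test: student               # student | welch
bootstrap_n_iter: 200
bootstrap_frac: 0.8
r_threshold: 0.5              # bootstrap map-correlation threshold

# --- transcriptomics / cell types -------------------------------------------
n_surrogates: 200             # variogram-matched surrogate maps
top_k: 500                    # genes selected by |PLS1 weight|
top_k_export: 1000            # length of the exported ranking
celltype_relevance: top_pls   # top_pls | ad_risk | all
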