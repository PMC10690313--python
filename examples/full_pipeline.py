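"""Run the complete prioritization pipeline on a synthetic cohort.

Screens variants, binarizes the trait at three thresholds, fits a signed
iterative random forest per threshold (with a prediction gate), and prints
the cross-threshold stability report.
"""

from losirf import (
    PipelineConfig,
    block_locus_map,
    planted_pair_study,
    run_pipeline,
    simulate_genotypes,
    simulate_phenotype,
)

cfg = planted_pair_study(seed=1)  # truth: interaction between L30 and L40
genotypes = simulate_genotypes(cfg)
phenotype, _ = simulate_phenotype(genotypes, cfg)
locus_map = block_locus_map(genotypes, cfg.block_size)

config = PipelineConfig(
    k=100, n_trees=100, n_iter=3, min_node=5, n_bootstrap=10, n_perm=10_000,
    covariates=("sex", "age"), split_sizes=(2400, 1000, 600), seed=1,
)
result = run_pipeline(genotypes, phenotype, locus_map, config)

print(f"screen kept {len(result.screen.selected)} variants")
for x, tr in result.per_threshold.items():
    print(
        f"threshold {x:.2f}: sirf balanced accuracy "
        f"{tr.metrics.loc['sirf', 'balanced_accuracy']:.3f} (gate passed)"
    )
print("\nsign-collapsed interactions, ranked by mean permutation p:")
sc = result.report.sign_collapsed
print(sc[sc["order"] >= 2].head(5).to_string(index=False))
# The planted pair L30;L40 should rank first: its signed version L30+_L40+
# (carriers of both loci) differentiates high- from low-trait individuals at
# every binarization threshold.
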