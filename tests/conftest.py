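"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from losirf import (
    GenotypeMatrix,
    LocusMap,
    PhenotypeTable,
    SimConfig,
    VariantInfo,
    simulate_genotypes,
    simulate_phenotype,
)
from losirf.forest import Forest, Tree


@pytest.fixture(scope="session")
def small_cohort():
    """2,000 individuals x 100 variants in 10-variant LD blocks, one planted
    additive effect and one planted threshold interaction across blocks."""
    cfg = SimConfig(
        n_individuals=2000,
        n_variants=100,
        block_size=10,
        within_block_rho=0.6,
        maf_range=(0.2, 0.45),
        additive_effects=[(5, 0.4)],
        epistatic_pairs=[(25, 35, 0.6)],
        sex_effect=0.4,
        covariate_effects=[("age", 0.2)],
        noise_sd=1.0,
        seed=11,
    )
    genotypes = simulate_genotypes(cfg)
    phenotype, truth = simulate_phenotype(genotypes, cfg)
    return cfg, genotypes, phenotype, truth


@pytest.fixture(scope="session")
def block_locus_map(small_cohort):
    _, genotypes, _, _ = small_cohort
    return LocusMap(
        {v.variant_id: f"L{j // 10:02d}" for j, v in enumerate(genotypes.variants)}
    )


def make_tree(feature, threshold, left, right, count0, count1):
    """Hand-build a Tree from parallel node lists."""
    return Tree(
        feature=np.asarray(feature, dtype=np.int32),
        threshold=np.asarray(threshold, dtype=np.float32),
        left=np.asarray(left, dtype=np.int32),
        right=np.asarray(right, dtype=np.int32),
        count0=np.asarray(count0, dtype=np.int64),
        count1=np.asarray(count1, dtype=np.int64),
        row_leaf=np.zeros(0, dtype=np.int32),
    )


@pytest.fixture
def stump_forest():
    """One stump splitting feature 'a' at 0.5; right leaf is pure class 1."""
    tree = make_tree(
        feature=[0, -1, -1],
        threshold=[0.5, 0.0, 0.0],
        left=[1, -1, -1],
        right=[2, -1, -1],
        count0=[10, 10, 0],
        count1=[10, 0, 10],
    )
    return Forest([tree], feature_names=["a", "b"])


def random_genotypes(n, p, seed, maf=(0.2, 0.5)) -> GenotypeMatrix:
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(*maf, size=p)
    dosages = rng.binomial(2, mafs, size=(n, p)).astype(np.int8)
    variants = [VariantInfo(variant_id=f"v{j:03d}", maf=float(mafs[j])) for j in range(p)]
    return GenotypeMatrix(
        individual_ids=[f"i{i:04d}" for i in range(n)],
        variants=variants,
        dosages=dosages,
    )


def make_phenotype(traits, sexes, **covariates) -> PhenotypeTable:
    n = len(traits)
    df = pd.DataFrame(
        {"trait": traits, "sex": sexes, **covariates},
        index=pd.Index([f"i{i:04d}" for i in range(n)], name="iid"),
    )
    return PhenotypeTable(df)
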