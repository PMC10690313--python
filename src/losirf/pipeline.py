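"""End-to-end orchestration: screen -> binarize -> fit -> gate -> prioritize.

The pipeline reduces the variant space with an association scan, binarizes the
trait at several per-sex tail thresholds, fits a signed iterative random
forest per threshold, refuses to interpret any forest that cannot beat random
guessing on held-out data, mines and stability-filters signed locus-level
interactions, permutation-tests their local stability importance on
validation individuals, and reports only candidates stable across all
thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .binarize import DEFAULT_THRESHOLDS, BinarizedLabels, binarize_phenotype
from .forest import (
    DEFAULT_N_ITER,
    DEFAULT_N_TREES,
    Forest,
    extract_signed_paths,
    iterate_sirf,
)
from .interactions import PathUniverse, RITCandidate, SignedInteraction, run_rit
from .io import DataSplit, GenotypeMatrix, LocusMap, PhenotypeTable, make_split
from .prioritize import (
    DEFAULT_N_PERM,
    DEFAULT_P_CUTOFF,
    DEFAULT_TOP_LOCI,
    PermutationTestResult,
    PrioritizationReport,
    aggregate_across_thresholds,
    local_stability_importance,
    locus_usage,
    make_permutation_indices,
    permutation_test,
    prediction_screen,
    rank_loci_setaside,
    select_candidates,
)
from .screen import DEFAULT_TOP_K, ScreenResult, assoc_scan, select_union_topk
from .stability import DEFAULT_B, InteractionStability, bootstrap_stability

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ThresholdResult", "PipelineResult", "PredictionGateError", "run_pipeline"]


class PredictionGateError(RuntimeError):
    """The forest did not beat random guessing; interpretation is refused."""


@dataclass
class PipelineConfig:
    """Tunable parameters of one pipeline run (full-scale defaults)."""

    k: int = DEFAULT_TOP_K
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    covariates: tuple[str, ...] = ()
    n_trees: int = DEFAULT_N_TREES
    n_iter: int = DEFAULT_N_ITER
    min_node: int = 1
    rit_params: dict = field(
        default_factory=lambda: {"depth": 3, "n_rit": 500, "n_child": 5, "min_node": 1}
    )
    n_bootstrap: int = DEFAULT_B
    n_perm: int = DEFAULT_N_PERM
    top_loci: int = DEFAULT_TOP_LOCI
    p_cutoff: float = DEFAULT_P_CUTOFF
    target_class: int = 1
    split_sizes: tuple[int, int, int] | None = None
    seed: int = 0


@dataclass
class ThresholdResult:
    """Everything the pipeline computed at one binarization threshold."""

    threshold: float
    labels: BinarizedLabels
    forest: Forest
    metrics: pd.DataFrame
    gate_passed: bool
    rit_candidates: list[RITCandidate]
    stability: dict[SignedInteraction, InteractionStability]
    locus_ranking: pd.DataFrame
    tested: dict[SignedInteraction, PermutationTestResult]


@dataclass
class PipelineResult:
    screen: ScreenResult
    split: DataSplit
    per_threshold: dict[float, ThresholdResult]
    report: PrioritizationReport


def _default_split(phenotype: PhenotypeTable, seed: int) -> DataSplit:
    # proportions mirror a 15,000 / 5,000 / 9,661 train/validation/test design
    n = len(phenotype)
    n_train = int(round(0.505 * n))
    n_val = int(round(0.17 * n))
    n_test = n - n_train - n_val
    return make_split(phenotype.individual_ids, (n_train, n_val, n_test), seed=seed)


def run_pipeline(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeTable,
    locus_map: LocusMap,
    config: PipelineConfig | None = None,
    split: DataSplit | None = None,
    extra_sumstats: Sequence[pd.DataFrame] = (),
) -> PipelineResult:
    """Run the full prioritization pipeline.

    Raises :class:`PredictionGateError` if, at any binarization threshold, the
    fitted forest's balanced accuracy on validation individuals does not
    exceed 0.5 — in that case the fit is deemed to carry no phenotypic signal
    and interpreting it would be meaningless.
    """
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(4 + 4 * len(config.thresholds)).astype(np.int64)

    if split is None:
        split = (
            _default_split(phenotype, int(seeds[0]))
            if config.split_sizes is None
            else make_split(phenotype.individual_ids, config.split_sizes, seed=int(seeds[0]))
        )

    # --- step 1: dimension reduction on training individuals
    pheno_train = phenotype.subset(split.train)
    geno_train = genotypes.subset_individuals(split.train)
    scan = assoc_scan(geno_train, pheno_train, config.covariates)
    screen_result = select_union_topk([scan, *extra_sumstats], k=config.k)
    X_sel = genotypes.subset_variants(
        [v for v in screen_result.selected if v in set(genotypes.variant_ids)]
    )
    logger.info("screen selected %d variants", X_sel.n_variants)

    fit_ids = set(split.train_fit)
    val_ids = set(split.validation)
    X_fit_all = X_sel.subset_individuals(split.train_fit)
    X_val_all = X_sel.subset_individuals(split.validation)
    X_aside = X_sel.subset_individuals(split.train_setaside)

    per_threshold: dict[float, ThresholdResult] = {}
    results: dict[float, dict[SignedInteraction, PermutationTestResult]] = {}
    for i, x in enumerate(config.thresholds):
        s_fit, s_boot, s_rit, s_perm = (int(v) for v in seeds[4 + 4 * i : 8 + 4 * i])
        labels = binarize_phenotype(phenotype, x)

        # --- step 3: fit + prediction gate
        fit_labeled = [j for j in split.train_fit if j in labels.labels]
        val_labeled = [j for j in split.validation if j in labels.labels]
        X_fit = X_fit_all.subset_individuals(fit_labeled)
        y_fit = labels.y(fit_labeled).to_numpy()
        X_val = X_val_all.subset_individuals(val_labeled)
        y_val = labels.y(val_labeled).to_numpy()
        forest = iterate_sirf(
            X_fit, y_fit,
            n_iter=config.n_iter, n_trees=config.n_trees,
            min_node=config.min_node, seed=s_fit,
        )
        metrics, gate = prediction_screen(
            forest, X_fit.dosages, y_fit, X_val.dosages, y_val, seed=s_fit
        )
        if not gate:
            raise PredictionGateError(
                f"at threshold {x:g} the forest's balanced accuracy "
                f"({metrics.loc['sirf', 'balanced_accuracy']:.3f}) does not exceed 0.5; "
                "the fit carries no detectable phenotypic signal and will not be "
                "interpreted"
            )

        # --- step 4: locus-level interactions + stability
        universe = PathUniverse(
            extract_signed_paths(forest), config.target_class, locus_map
        )
        rit_candidates = run_rit(universe, seed=s_rit, **config.rit_params)
        to_check = [c.interaction for c in rit_candidates if c.interaction.order >= 2]
        stability = bootstrap_stability(
            X_fit, y_fit, to_check,
            B=config.n_bootstrap, seed=s_boot, locus_map=locus_map,
            target_class=config.target_class, n_iter=config.n_iter,
            n_trees=config.n_trees, min_node=config.min_node,
            rit_params=config.rit_params,
        )
        cache_aside = locus_usage(forest, X_aside, locus_map)
        shortlist, locus_ranking = rank_loci_setaside(
            cache_aside, None, None, top_n=config.top_loci
        )
        candidates = select_candidates(shortlist, stability)

        # --- permutation tests on validation individuals
        cache_val = locus_usage(forest, X_val, locus_map)
        n1 = int(y_val.sum())
        perm_idx = make_permutation_indices(len(y_val), n1, config.n_perm, s_perm)
        tested: dict[SignedInteraction, PermutationTestResult] = {}
        for cand in candidates:
            scores = local_stability_importance(cache_val, None, cand)
            tested[cand] = permutation_test(
                scores.scores, y_val, n_perm=config.n_perm, seed=s_perm,
                perm_indices=perm_idx,
            )
        per_threshold[x] = ThresholdResult(
            threshold=x, labels=labels, forest=forest, metrics=metrics,
            gate_passed=gate, rit_candidates=rit_candidates, stability=stability,
            locus_ranking=locus_ranking, tested=tested,
        )
        results[x] = tested

    report = aggregate_across_thresholds(results, p_cutoff=config.p_cutoff)
    return PipelineResult(
        screen=screen_result, split=split, per_threshold=per_threshold, report=report
    )
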