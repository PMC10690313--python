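"""Bootstrap stability metrics for candidate signed interactions.

An interaction is only trusted if it is re-discovered when the whole fit is
repeated on bootstrap resamples of the individuals. Three scores are computed
per candidate over B replicates:

* ``stability`` — fraction of replicates whose intersection-tree output
  contains the candidate;
* ``smip_stability`` — fraction of replicates with a positive mean increase in
  precision: the candidate's precision minus the mean precision of its
  order-(K-1) sub-interactions;
* ``sfsd_stability`` — fraction of replicates with positive feature-selection
  dependence: the candidate's joint path prevalence minus the product of its
  components' marginal prevalences (zero when components are selected
  independently).

The downstream selection rule keeps interactions with stability > 0.5 and both
other scores > 0. For order-1 candidates the last two are undefined and
reported as ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .binarize import BinarizedLabels
from .forest import SignedPath, extract_signed_paths, iterate_sirf, _resolve_xy
from .interactions import (
    RIT_DEFAULTS,
    PathUniverse,
    SignedInteraction,
    run_rit,
)
from .io import GenotypeMatrix, LocusMap

__all__ = ["InteractionStability", "bootstrap_stability", "smip", "sfsd", "DEFAULT_B"]

#: full-scale number of bootstrap replicates
DEFAULT_B = 50


@dataclass
class InteractionStability:
    interaction: SignedInteraction
    stability: float
    smip_stability: float | None
    sfsd_stability: float | None


def smip(
    paths: Sequence[SignedPath] | PathUniverse,
    interaction: SignedInteraction,
    target_class: int = 1,
    locus_map: LocusMap | None = None,
) -> float:
    """Mean increase in precision over the order-(K-1) sub-interactions."""
    if interaction.order < 2:
        raise ValueError("smip is undefined for order-1 interactions")
    u = paths if isinstance(paths, PathUniverse) else PathUniverse(
        paths, target_class, locus_map
    )
    full = u.precision(interaction)
    subs = [u.precision(interaction.drop(comp)) for comp in interaction.components]
    return full - float(np.mean(subs))


def sfsd(
    paths: Sequence[SignedPath] | PathUniverse,
    interaction: SignedInteraction,
    target_class: int = 1,
    locus_map: LocusMap | None = None,
) -> float:
    """Feature-selection dependence: joint minus product-of-marginal prevalence."""
    if interaction.order < 2:
        raise ValueError("sfsd is undefined for order-1 interactions")
    u = paths if isinstance(paths, PathUniverse) else PathUniverse(
        paths, target_class, locus_map
    )
    joint = u.prevalence(interaction)
    product = 1.0
    for comp in interaction.components:
        product *= u.prevalence(SignedInteraction([comp]))
    return joint - product


def bootstrap_stability(
    X: GenotypeMatrix | np.ndarray,
    y: BinarizedLabels | Sequence[int],
    candidates: Sequence[SignedInteraction],
    B: int = DEFAULT_B,
    seed: int = 0,
    locus_map: LocusMap | None = None,
    target_class: int = 1,
    n_iter: int = 3,
    n_trees: int = 100,
    min_node: int = 1,
    rit_params: dict | None = None,
) -> dict[SignedInteraction, InteractionStability]:
    """Refit the iterated forest + intersection-tree search on B bootstraps.

    Each replicate resamples the labeled individuals with replacement, refits
    the full pipeline, and evaluates every candidate on the replicate's signed
    paths. Bootstrap draws that land on a single class are redrawn.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rit_kwargs = dict(RIT_DEFAULTS)
    if rit_params:
        rit_kwargs.update(rit_params)
    Xd, yv, names, _ = _resolve_xy(X, y)
    if yv is None:
        raise ValueError("labels are required")
    n = Xd.shape[0]
    ss = np.random.SeedSequence((seed, 0xB00))
    rng = np.random.default_rng(ss.spawn(1)[0])
    rep_seeds = ss.generate_state(2 * B)

    recovered = {c: 0 for c in candidates}
    smip_pos = {c: 0 for c in candidates}
    sfsd_pos = {c: 0 for c in candidates}
    # every interaction whose prevalence/precision a replicate needs, deduped
    needed: dict[SignedInteraction, None] = {}
    for cand in candidates:
        if cand.order >= 2:
            needed.setdefault(cand)
            for comp in cand.components:
                needed.setdefault(cand.drop(comp))
                needed.setdefault(SignedInteraction([comp]))
    needed_list = list(needed)
    for b in range(B):
        for _attempt in range(100):
            rows = rng.integers(0, n, size=n)
            yb = yv[rows]
            if yb.min() != yb.max():
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap")
        Xb = np.ascontiguousarray(Xd[rows])
        forest = iterate_sirf(
            Xb, yb, n_iter=n_iter, n_trees=n_trees, min_node=min_node,
            seed=int(rep_seeds[2 * b]),
        )
        forest.feature_names = list(names)
        universe = PathUniverse(extract_signed_paths(forest), target_class, locus_map)
        found = {
            c.interaction
            for c in run_rit(universe, seed=int(rep_seeds[2 * b + 1]), **rit_kwargs)
        }
        masks = [universe.mask_of(i) for i in needed_list]
        valid = [m for m in masks if m >= 0]
        prev_valid, prec_valid = universe.stats_many(valid)
        prev: dict[SignedInteraction, float] = {}
        prec: dict[SignedInteraction, float] = {}
        j = 0
        for interaction, m in zip(needed_list, masks):
            if m < 0:
                prev[interaction] = 0.0
                prec[interaction] = 0.0
            else:
                prev[interaction] = float(prev_valid[j])
                prec[interaction] = float(prec_valid[j])
                j += 1
        for cand in candidates:
            if cand in found:
                recovered[cand] += 1
            if cand.order >= 2:
                subs = [prec[cand.drop(comp)] for comp in cand.components]
                if prec[cand] - float(np.mean(subs)) > 0:
                    smip_pos[cand] += 1
                product = 1.0
                for comp in cand.components:
                    product *= prev[SignedInteraction([comp])]
                if prev[cand] - product > 0:
                    sfsd_pos[cand] += 1

    out: dict[SignedInteraction, InteractionStability] = {}
    for cand in candidates:
        order1 = cand.order < 2
        out[cand] = InteractionStability(
            interaction=cand,
            stability=recovered[cand] / B,
            smip_stability=None if order1 else smip_pos[cand] / B,
            sfsd_stability=None if order1 else sfsd_pos[cand] / B,
        )
    return out
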