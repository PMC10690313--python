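"""Random intersection trees over signed decision paths.

Sets of signed features (or signed loci, when a variant-to-locus map is given)
that co-occur on many target-class decision paths are candidate interactions.
Random intersection trees (RIT) find them without enumerating subsets: a
randomly drawn path is repeatedly intersected with further random paths, and
the sets that survive are frequent-enough intersections. Candidate prevalence
is always recomputed exactly as the weighted fraction of target-class paths
containing the set, so the randomized search only affects which sets are
found, not their scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .forest import SignedPath
from .io import LocusMap

__all__ = [
    "SignedInteraction",
    "RITCandidate",
    "PathUniverse",
    "run_rit",
    "path_prevalence",
    "interaction_precision",
    "RIT_DEFAULTS",
]

#: full-scale RIT defaults: depth, number of intersection trees, children per
#: node, and minimum surviving set size
RIT_DEFAULTS = {"depth": 3, "n_rit": 500, "n_child": 5, "min_node": 1}


@dataclass(frozen=True, order=True)
class SignedInteraction:
    """An order-K set of distinct signed components (locus or variant labels)."""

    components: tuple[tuple[str, str], ...]  # sorted ((label, '+'|'-'), ...)

    def __init__(self, components: Iterable[tuple[str, str]]):
        comps = tuple(sorted(set((str(l), str(s)) for l, s in components)))
        if not comps:
            raise ValueError("empty interaction")
        for _, s in comps:
            if s not in ("+", "-"):
                raise ValueError(f"sign must be '+' or '-', got {s!r}")
        object.__setattr__(self, "components", comps)

    @property
    def order(self) -> int:
        return len(self.components)

    def drop(self, component: tuple[str, str]) -> "SignedInteraction":
        return SignedInteraction(c for c in self.components if c != component)

    def __str__(self) -> str:
        return "_".join(f"{l}{s}" for l, s in self.components)


@dataclass(frozen=True)
class RITCandidate:
    """A surviving signed interaction with its exact path prevalence."""

    interaction: SignedInteraction
    prevalence: float


class PathUniverse:
    """Deduplicated signed paths of one class, encoded as bitmasks.

    Paths with identical signed-feature sets are merged, keeping their summed
    target-class (``weights``) and total (``totals``) training counts, so
    prevalence and precision queries are exact and vectorized.
    """

    def __init__(
        self,
        paths: Sequence[SignedPath],
        target_class: int = 1,
        locus_map: LocusMap | None = None,
    ):
        if target_class not in (0, 1):
            raise ValueError("target_class must be 0 or 1")
        vocab: dict[tuple[str, str], int] = {}
        weight_by_mask: dict[int, float] = {}
        target_by_mask: dict[int, float] = {}
        total_by_mask: dict[int, float] = {}
        for path in paths:
            weight = path.count1 if target_class == 1 else path.count0
            mask = 0
            for label, sign in path.signed_features:
                if locus_map is not None:
                    if label not in locus_map:
                        raise KeyError(f"variant {label!r} missing from locus map")
                    label = locus_map[label]
                key = (label, sign)
                bit = vocab.setdefault(key, len(vocab))
                mask |= 1 << bit
            # prevalence weights use target-class paths only; precision counts
            # samples from every leaf containing the set, both classes
            if weight > 0:
                weight_by_mask[mask] = weight_by_mask.get(mask, 0.0) + weight
            target_by_mask[mask] = target_by_mask.get(mask, 0.0) + weight
            total_by_mask[mask] = total_by_mask.get(mask, 0.0) + path.count0 + path.count1
        if not weight_by_mask:
            raise ValueError(f"no paths with target-class {target_class} samples")
        self.target_class = target_class
        self.vocab = vocab
        self.labels: list[tuple[str, str]] = [("", "")] * len(vocab)
        for key, bit in vocab.items():
            self.labels[bit] = key
        self.masks = list(weight_by_mask.keys())
        self.weights = np.array([weight_by_mask[m] for m in self.masks], dtype=float)
        self.total_weight = float(self.weights.sum())
        self.all_masks_list = list(total_by_mask.keys())
        self.all_targets = np.array(
            [target_by_mask[m] for m in self.all_masks_list], dtype=float
        )
        self.all_totals = np.array(
            [total_by_mask[m] for m in self.all_masks_list], dtype=float
        )
        self.all_weights = np.maximum(self.all_targets, 0.0)
        # word-packed copies for vectorized containment tests
        self.n_words = max(1, (len(vocab) + 63) // 64)
        self._words = np.zeros((len(self.masks), self.n_words), dtype=np.uint64)
        for i, m in enumerate(self.masks):
            self._words[i] = self._to_words(m)
        self._all_words = np.zeros((len(self.all_masks_list), self.n_words), dtype=np.uint64)
        for i, m in enumerate(self.all_masks_list):
            self._all_words[i] = self._to_words(m)

    @property
    def n_paths(self) -> int:
        return len(self.masks)

    def _to_words(self, mask: int) -> np.ndarray:
        out = np.zeros(self.n_words, dtype=np.uint64)
        for w in range(self.n_words):
            out[w] = (mask >> (64 * w)) & 0xFFFFFFFFFFFFFFFF
        return out

    def _containing(self, mask: int, words: np.ndarray | None = None) -> np.ndarray:
        mw = self._to_words(mask)
        w = self._words if words is None else words
        return ((w & mw) == mw).all(axis=1)

    def to_interaction(self, mask: int) -> SignedInteraction:
        comps = [self.labels[b] for b in range(len(self.labels)) if mask >> b & 1]
        return SignedInteraction(comps)

    def mask_of(self, interaction: SignedInteraction) -> int:
        mask = 0
        for comp in interaction.components:
            if comp not in self.vocab:
                return -1  # component never appears on any path
            mask |= 1 << self.vocab[comp]
        return mask

    def _contains_matrix(self, masks: Sequence[int], words: np.ndarray) -> np.ndarray:
        cand = np.zeros((len(masks), self.n_words), dtype=np.uint64)
        for i, m in enumerate(masks):
            cand[i] = self._to_words(m)
        contains = np.ones((len(masks), words.shape[0]), dtype=bool)
        for w in range(self.n_words):
            cw = cand[:, w][:, None]
            contains &= (words[:, w][None, :] & cw) == cw
        return contains

    def prevalence_many(self, masks: Sequence[int]) -> np.ndarray:
        """Prevalence of many sets at once (one containment matrix pass)."""
        if not len(masks):
            return np.zeros(0)
        contains = self._contains_matrix(masks, self._words)
        return contains @ self.weights / self.total_weight

    def precision_many(self, masks: Sequence[int]) -> np.ndarray:
        """Precision of many sets at once (over leaves of both classes)."""
        return self.stats_many(masks)[1]

    def stats_many(self, masks: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
        """(prevalence, precision) for many sets from one containment pass."""
        if not len(masks):
            return np.zeros(0), np.zeros(0)
        contains = self._contains_matrix(masks, self._all_words).astype(np.float64)
        prev = contains @ self.all_weights / self.total_weight
        totals = contains @ self.all_totals
        hits = contains @ self.all_targets
        prec = np.divide(hits, totals, out=np.zeros(len(masks)), where=totals > 0)
        return prev, prec

    def prevalence(self, target: SignedInteraction | int) -> float:
        """Weighted fraction of target-class paths containing the set."""
        mask = self.mask_of(target) if isinstance(target, SignedInteraction) else target
        if mask < 0:
            return 0.0
        return float(self.weights[self._containing(mask)].sum()) / self.total_weight

    def precision(self, target: SignedInteraction | int) -> float:
        """Fraction of target-class samples among samples in leaves whose
        paths contain the set, over leaves of both classes (0 if no leaf does)."""
        mask = self.mask_of(target) if isinstance(target, SignedInteraction) else target
        if mask < 0:
            return 0.0
        contains = self._containing(mask, self._all_words)
        total = float(self.all_totals[contains].sum())
        if total == 0:
            return 0.0
        return float(self.all_targets[contains].sum()) / total


def run_rit(
    paths: Sequence[SignedPath] | PathUniverse,
    target_class: int = 1,
    depth: int = RIT_DEFAULTS["depth"],
    n_rit: int = RIT_DEFAULTS["n_rit"],
    n_child: int = RIT_DEFAULTS["n_child"],
    min_node: int = RIT_DEFAULTS["min_node"],
    locus_map: LocusMap | None = None,
    seed: int = 0,
) -> list[RITCandidate]:
    """Random intersection trees over the target-class signed paths.

    Paths (deduplicated signed-feature sets) are sampled with probability
    proportional to their target-class training count. Each intersection tree
    starts from a sampled root path and recursively intersects with
    ``n_child`` further sampled paths down to ``depth`` levels; every nonempty
    set of size >= ``min_node`` seen at any node survives. When ``n_child``
    reaches the number of distinct paths, children become the full path set,
    making the search exhaustive over intersections reachable within ``depth``
    steps. If a locus map is given, signed variants are first replaced by
    signed locus labels (set-deduplicated) so the search runs at locus
    granularity. Prevalence of every survivor is recomputed exactly.
    """
    if isinstance(paths, PathUniverse):
        universe = paths
    else:
        universe = PathUniverse(paths, target_class, locus_map)
    rng = np.random.default_rng(seed)
    n_paths = universe.n_paths
    prob = universe.weights / universe.total_weight
    saturating = n_child >= n_paths
    all_masks = universe.masks

    survivors: set[int] = set()
    roots = rng.choice(n_paths, size=n_rit, p=prob)
    processed_roots: set[int] = set()
    for root_i in roots:
        root = all_masks[root_i]
        if saturating:
            # children are the full path set, so the search from one root is a
            # deterministic breadth-first closure; explore each discovered set
            # once and each distinct root once
            if root in processed_roots:
                continue
            processed_roots.add(root)
        frontier = {root}
        survivors.add(root)
        for _level in range(depth):
            nxt: set[int] = set()
            for node_mask in frontier:
                if saturating:
                    children = all_masks
                else:
                    children = [
                        all_masks[k] for k in rng.choice(n_paths, size=n_child, p=prob)
                    ]
                for child in children:
                    inter = node_mask & child
                    if inter:
                        nxt.add(inter)
            if saturating:
                frontier = nxt - survivors
            else:
                frontier = nxt
            survivors.update(nxt)
            if not frontier:
                break

    kept = [m for m in survivors if bin(m).count("1") >= max(min_node, 1)]
    prevs = universe.prevalence_many(kept)
    candidates = [
        RITCandidate(interaction=universe.to_interaction(m), prevalence=float(pv))
        for m, pv in zip(kept, prevs)
    ]
    candidates.sort(key=lambda c: (-c.prevalence, c.interaction.components))
    # anti-monotonicity: a set can never be more prevalent than any subset
    prev_by_mask = dict(zip(kept, prevs))
    sub_masks = []
    sub_of = []
    for mask, pv in prev_by_mask.items():
        if bin(mask).count("1") >= 2:
            b = 0
            rest = mask
            while rest:
                if rest & 1:
                    sub = mask & ~(1 << b)
                    if sub not in prev_by_mask:
                        sub_masks.append(sub)
                    sub_of.append((mask, sub))
                rest >>= 1
                b += 1
    prev_by_mask.update(zip(sub_masks, universe.prevalence_many(sub_masks)))
    for mask, sub in sub_of:
        if prev_by_mask[mask] > prev_by_mask[sub] + 1e-12:
            raise AssertionError("prevalence anti-monotonicity violated")
    return candidates


def path_prevalence(
    paths: Sequence[SignedPath] | PathUniverse,
    interaction: SignedInteraction,
    target_class: int = 1,
    locus_map: LocusMap | None = None,
) -> float:
    """Weighted fraction of target-class paths containing the interaction."""
    universe = paths if isinstance(paths, PathUniverse) else PathUniverse(
        paths, target_class, locus_map
    )
    return universe.prevalence(interaction)


def interaction_precision(
    paths: Sequence[SignedPath] | PathUniverse,
    interaction: SignedInteraction,
    target_class: int = 1,
    locus_map: LocusMap | None = None,
) -> float:
    """Precision of the interaction over the paths containing it."""
    universe = paths if isinstance(paths, PathUniverse) else PathUniverse(
        paths, target_class, locus_map
    )
    return universe.precision(interaction)
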