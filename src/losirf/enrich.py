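"""Downstream co-association, enrichment, TF rank-integration and network statistics.

These operate on gene-set and annotation inputs (GMT libraries, per-library
Fisher-test tables, annotation count tables, co-expression edge lists) and are
independent of the forest pipeline: they quantify whether the prioritized
genes hang together functionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TermGeneLibrary",
    "read_gmt",
    "co_association_scores",
    "annotation_enrichment",
    "fisher_exact_2x2",
    "tf_integrated_rank",
    "edge_connectivity_p",
]


@dataclass
class TermGeneLibrary:
    """A named term -> gene-set library."""

    name: str
    terms: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")

    def gene_terms(self, universe: Sequence[str] | None = None) -> dict[str, frozenset[str]]:
        """Invert: gene -> set of terms annotating it."""
        inv: dict[str, set[str]] = {}
        for term, genes in self.terms.items():
            for g in genes:
                inv.setdefault(g, set()).add(term)
        if universe is not None:
            return {g: frozenset(inv.get(_norm_gene(g), ())) for g in universe}
        return {g: frozenset(t) for g, t in inv.items()}


def _norm_gene(symbol: str) -> str:
    return symbol.strip().upper()


def read_gmt(path: str | Path, name: str | None = None) -> TermGeneLibrary:
    """Read a GMT file (term <tab> description <tab> gene...)."""
    terms: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        term = fields[0]
        if term in terms:
            raise ValueError(f"duplicate term {term!r}")
        genes = frozenset(_norm_gene(g) for g in fields[2:] if g.strip())
        terms[term] = genes
    return TermGeneLibrary(name=name or Path(path).stem, terms=terms)


def co_association_scores(
    gene_terms: Mapping[str, frozenset[str] | set[str]],
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Co-association R = N(A∩B)/N(A∪B) for every unordered gene pair.

    ``gene_terms`` maps each gene to the set of terms enriched for it. When
    the union is empty R = 0 by convention. The two-sided empirical p for a
    pair is the proportion of all pairs whose score is at least as extreme,
    relative to the overall mean score, as that pair's score — an exhaustive
    permutation over all pairs, no resampling.
    """
    genes = sorted({_norm_gene(g) for g in (universe or gene_terms)})
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    norm_lookup = {_norm_gene(g): frozenset(ts) for g, ts in gene_terms.items()}
    term_sets = {g: norm_lookup.get(g, frozenset()) for g in genes}

    rows = []
    for a, b in combinations(genes, 2):
        sa, sb = term_sets[a], term_sets[b]
        inter = len(sa & sb)
        union = len(sa | sb)
        r = inter / union if union else 0.0
        rows.append((a, b, r, inter, union))
    table = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "R", "n_intersection", "n_union"]
    )
    scores = table["R"].to_numpy()
    center = scores.mean()
    dev = np.abs(scores - center)
    # proportion of all pairs at least as extreme (includes the pair itself)
    order = np.sort(dev)
    counts = len(dev) - np.searchsorted(order, dev - 1e-12, side="left")
    table["p_empirical"] = counts / len(dev)
    return table


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test p for the table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def annotation_enrichment(
    locus_counts: Mapping[str, Mapping[str, int]],
    reference_counts: Mapping[str, int],
    printed_table: bool = False,
) -> pd.DataFrame:
    """Annotation enrichment of each locus against a reference panel.

    ``locus_counts[locus][annotation]`` = number of that locus's SNVs carrying
    the annotation; ``reference_counts[annotation]`` = number in the whole
    reference panel. The enrichment score is

        E = (n_j(i) / sum_t n_j(t)) / (N(i) / sum_t N(t)),

    the proportion of the locus's SNVs with the annotation over the proportion
    in the reference. The two-sided Fisher p uses the standard 2x2 partition
    (locus vs rest-of-reference) x (annotation vs other annotations):
    [[n_j(i), sum_t n_j(t) - n_j(i)], [N(i) - n_j(i),
    (sum_t N(t) - sum_t n_j(t)) - (N(i) - n_j(i))]]. ``printed_table=True``
    switches the fourth cell to sum_t N(t) - sum_t n_j(t) - n_j(i), a
    compatibility variant that does not partition the panel.
    """
    ref_total = sum(reference_counts.values())
    if ref_total == 0:
        raise ValueError("reference panel has zero total annotation count")
    rows = []
    for locus, counts in locus_counts.items():
        locus_total = sum(counts.values())
        for annotation, n_ji in counts.items():
            if annotation not in reference_counts:
                raise KeyError(f"annotation {annotation!r} missing from reference")
            n_i = reference_counts[annotation]
            if n_ji > n_i:
                raise ValueError(
                    f"locus count {n_ji} exceeds reference count {n_i} for {annotation!r}"
                )
            prop_locus = n_ji / locus_total if locus_total else 0.0
            prop_ref = n_i / ref_total
            e_score = prop_locus / prop_ref if prop_ref else 0.0
            a = n_ji
            b = locus_total - n_ji
            c = n_i - n_ji
            if printed_table:
                d = ref_total - locus_total - n_ji
            else:
                d = (ref_total - locus_total) - (n_i - n_ji)
            p = fisher_exact_2x2(a, b, c, max(d, 0))
            rows.append(
                {
                    "locus": locus,
                    "annotation": annotation,
                    "n_locus_annot": a,
                    "n_locus_total": locus_total,
                    "n_ref_annot": n_i,
                    "n_ref_total": ref_total,
                    "enrichment": e_score,
                    "p_fisher": p,
                }
            )
    return pd.DataFrame(rows)


def tf_integrated_rank(library_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Integrate per-library transcription-factor Fisher-test p tables.

    Each table has columns ``tf`` and ``p_value``. Within a library, TFs with
    identical p share an integer rank (dense ranking by ascending p); the
    scaled rank divides by the library's maximum integer rank. TFs are then
    ordered by (1) descending number of libraries with significant overlap
    (p < 0.05) and (2) ascending mean scaled rank over the libraries that
    contain the TF. Remaining ties are broken alphabetically (logged).
    """
    if not library_tables:
        raise ValueError("need at least one library table")
    per_tf: dict[str, dict] = {}
    for lib, table in library_tables.items():
        if not {"tf", "p_value"}.issubset(table.columns):
            raise ValueError(f"library {lib!r} needs tf and p_value columns")
        if not len(table):
            raise ValueError(f"library {lib!r} is empty")
        t = table.copy()
        t["int_rank"] = t["p_value"].rank(method="min").astype(int)
        max_rank = int(t["int_rank"].max())
        t["scaled_rank"] = t["int_rank"] / max_rank
        for row in t.itertuples():
            entry = per_tf.setdefault(
                row.tf, {"n_significant": 0, "scaled_ranks": [], "libraries": []}
            )
            entry["scaled_ranks"].append(row.scaled_rank)
            entry["libraries"].append(lib)
            if row.p_value < 0.05:
                entry["n_significant"] += 1
    rows = [
        {
            "tf": tf,
            "n_significant": e["n_significant"],
            "n_libraries": len(e["libraries"]),
            "mean_scaled_rank": float(np.mean(e["scaled_ranks"])),
        }
        for tf, e in per_tf.items()
    ]
    table = pd.DataFrame(rows).sort_values(
        ["n_significant", "mean_scaled_rank", "tf"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    dup = table.duplicated(["n_significant", "mean_scaled_rank"], keep=False)
    if dup.any():
        logger.info("%d TFs tied on both criteria; alphabetical order", int(dup.sum()))
    table["final_rank"] = np.arange(1, len(table) + 1)
    return table


def edge_connectivity_p(
    edges: pd.DataFrame | Sequence[pd.DataFrame],
    gene_pair: tuple[str, str],
    mode: str = "single",
) -> float:
    """Empirical p for a gene pair's co-expression edge weight(s).

    ``single`` mode takes one edge table (gene_a, gene_b, weight) and returns
    the one-sided empirical p: the proportion of all edges with weight at
    least the pair's weight. ``difference`` mode takes two tables (e.g.
    control and disease networks), z-normalizes each network's weights, and
    returns the two-tailed p: the proportion of pairs whose absolute
    z-difference is at least the pair's absolute difference.
    """
    def _key(a: str, b: str) -> tuple[str, str]:
        return tuple(sorted((_norm_gene(a), _norm_gene(b))))

    target = _key(*gene_pair)

    def _weights(table: pd.DataFrame) -> pd.Series:
        keys = [_key(a, b) for a, b in zip(table["gene_a"], table["gene_b"])]
        return pd.Series(table["weight"].to_numpy(dtype=float), index=keys)

    if mode == "single":
        if isinstance(edges, Sequence) and not isinstance(edges, pd.DataFrame):
            raise ValueError("single mode takes one edge table")
        w = _weights(edges)
        if target not in w.index:
            raise KeyError(f"pair {target} absent from network")
        value = float(w.loc[[target]].iloc[0])
        return float((w.to_numpy() >= value - 1e-12).mean())
    if mode == "difference":
        if isinstance(edges, pd.DataFrame) or len(edges) != 2:
            raise ValueError("difference mode takes exactly two edge tables")
        w1, w2 = (_weights(t) for t in edges)
        shared = w1.index.intersection(w2.index)
        if target not in shared:
            raise KeyError(f"pair {target} absent from one of the networks")
        z1 = (w1.loc[shared] - w1.loc[shared].mean()) / w1.loc[shared].std(ddof=0)
        z2 = (w2.loc[shared] - w2.loc[shared].mean()) / w2.loc[shared].std(ddof=0)
        diff = (z1 - z2).to_numpy()
        keys = list(shared)
        value = abs(diff[keys.index(target)])
        return float((np.abs(diff) >= value - 1e-12).mean())
    raise ValueError(f"unknown mode {mode!r}")
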