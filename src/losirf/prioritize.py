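"""Locus aggregation, local stability importance, permutation testing, ranking.

The forest's variant-level importances are weak and unstable under linkage
disequilibrium, so importance is assessed at the locus level. For a signed
interaction G = (g1..gK) between signed loci and an individual i, the local
stability importance LSI(G, i) is the proportion of trees whose decision path
for i used at least one signed variant from every signed locus of G. A
two-sample permutation test (difference in means, add-one empirical p) then
asks whether LSI scores differ between the low- and high-trait classes, and
only candidates with p below a cutoff at *every* binarization threshold are
reported, ranked by mean p with signed versions collapsed by the smaller p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._trees import _signed_group_usage
from .binarize import BinarizedLabels
from .forest import Forest
from .interactions import SignedInteraction
from .io import GenotypeMatrix, LocusMap
from .stability import InteractionStability

logger = logging.getLogger(__name__)

__all__ = [
    "LSIScores",
    "PermutationTestResult",
    "PrioritizationReport",
    "aggregate_snvs_to_loci",
    "locus_usage",
    "local_stability_importance",
    "rank_loci_setaside",
    "permutation_test",
    "select_candidates",
    "aggregate_across_thresholds",
    "prediction_screen",
    "DEFAULT_N_PERM",
    "DEFAULT_TOP_LOCI",
    "DEFAULT_P_CUTOFF",
]

#: full-scale defaults: permutations, shortlist size, per-run p cutoff
DEFAULT_N_PERM = 10_000
DEFAULT_TOP_LOCI = 25
DEFAULT_P_CUTOFF = 0.1


def aggregate_snvs_to_loci(
    selected_variants: Sequence[str], locus_map: LocusMap
) -> dict[str, list[str]]:
    """Partition the selected variants by locus (intergenic ``A;B`` labels kept
    verbatim). Every variant must be mapped; unmapped variants are an error."""
    unmapped = [v for v in selected_variants if v not in locus_map]
    if unmapped:
        raise KeyError(f"variants missing from locus map: {sorted(unmapped)[:10]}")
    table: dict[str, list[str]] = {}
    for v in dict.fromkeys(selected_variants):  # dedup, keep order
        table.setdefault(locus_map[v], []).append(v)
    return table


@dataclass
class LSIScores:
    """Per-individual local stability importance for one candidate."""

    interaction: SignedInteraction
    individual_ids: list[str]
    scores: np.ndarray  # in [0, 1], one per individual


@dataclass
class PermutationTestResult:
    interaction: SignedInteraction
    observed: float  # mean LSI in high minus mean in low
    p_value: float
    n_perm: int


@dataclass
class PrioritizationReport:
    """Cross-threshold stability report.

    ``table`` has one row per signed candidate with per-threshold p-values,
    mean p, the stability flag and the rank among stable candidates;
    ``sign_collapsed`` ranks each locus/interaction by the smaller of its
    signed versions' mean p-values.
    """

    table: pd.DataFrame
    sign_collapsed: pd.DataFrame
    thresholds: tuple[float, ...]
    p_cutoff: float


class _UsageCache:
    """Per-(forest, X) usage tensor: trees x individuals x signed loci."""

    def __init__(self, forest: Forest, X: GenotypeMatrix, locus_map: LocusMap):
        missing = [v for v in forest.feature_names if v not in locus_map]
        if missing:
            raise KeyError(f"forest features missing from locus map: {missing[:5]}")
        self.loci = sorted({locus_map[v] for v in forest.feature_names})
        locus_index = {l: g for g, l in enumerate(self.loci)}
        group = np.array(
            [locus_index[locus_map[v]] for v in forest.feature_names], dtype=np.int64
        )
        Xd = np.ascontiguousarray(
            X.subset_variants(forest.feature_names).dosages, dtype=np.int8
        )
        n = Xd.shape[0]
        g2 = 2 * len(self.loci)
        usage = np.zeros((forest.n_trees, n, g2), dtype=np.uint8)
        for t, tree in enumerate(forest.trees):
            _signed_group_usage(
                tree.feature, tree.threshold, tree.left, tree.right, Xd, group, usage[t]
            )
        self.usage = usage
        self.individual_ids = list(X.individual_ids)

    def column(self, locus: str, sign: str) -> int:
        g = self.loci.index(locus)
        return 2 * g + (1 if sign == "+" else 0)

    def lsi(self, interaction: SignedInteraction) -> np.ndarray:
        cols = []
        for label, sign in interaction.components:
            if label not in self.loci:
                # locus never among forest features: score 0 everywhere
                return np.zeros(self.usage.shape[1])
            cols.append(self.column(label, sign))
        present = self.usage[:, :, cols].all(axis=2)  # (trees, n)
        return present.mean(axis=0)


def locus_usage(
    forest: Forest, X: GenotypeMatrix, locus_map: LocusMap
) -> _UsageCache:
    """Precompute which signed loci each individual's paths use, per tree."""
    return _UsageCache(forest, X, locus_map)


def local_stability_importance(
    forest: Forest | _UsageCache,
    X: GenotypeMatrix | None,
    candidate: SignedInteraction,
    locus_map: LocusMap | None = None,
) -> LSIScores:
    """LSI(G, i) = (# trees whose path for i uses >= 1 signed variant from
    every signed locus of G) / (# trees)."""
    if isinstance(forest, _UsageCache):
        cache = forest
    else:
        if X is None or locus_map is None:
            raise ValueError("X and locus_map are required without a usage cache")
        cache = _UsageCache(forest, X, locus_map)
    return LSIScores(
        interaction=candidate,
        individual_ids=cache.individual_ids,
        scores=cache.lsi(candidate),
    )


def rank_loci_setaside(
    forest: Forest | _UsageCache,
    X_setaside: GenotypeMatrix | None,
    locus_map: LocusMap | None = None,
    top_n: int = DEFAULT_TOP_LOCI,
) -> tuple[list[SignedInteraction], pd.DataFrame]:
    """Rank signed loci by mean LSI over set-aside individuals.

    The set-aside samples were held out of the forest fit, so the ranking is
    not biased by training-leaf membership. Ties are broken by signed-locus
    label order (logged). Returns the top-n shortlist (as order-1
    interactions) and the full ranking table.
    """
    if isinstance(forest, _UsageCache):
        cache = forest
    else:
        if X_setaside is None or locus_map is None:
            raise ValueError("X_setaside and locus_map are required")
        cache = _UsageCache(forest, X_setaside, locus_map)
    if cache.usage.shape[1] == 0:
        raise ValueError("empty set-aside sample")
    rows = []
    for g, locus in enumerate(cache.loci):
        for sign, col in (("-", 2 * g), ("+", 2 * g + 1)):
            mean_lsi = float(cache.usage[:, :, col].mean())
            rows.append((locus, sign, mean_lsi))
    table = pd.DataFrame(rows, columns=["locus", "sign", "mean_lsi"])
    table = table.sort_values(
        ["mean_lsi", "locus", "sign"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    if table["mean_lsi"].duplicated().any():
        logger.info("ties in mean LSI broken by signed-locus label order")
    shortlist = [
        SignedInteraction([(r.locus, r.sign)])
        for r in table.head(top_n).itertuples()
        if r.mean_lsi > 0
    ]
    return shortlist, table


def make_permutation_indices(
    n: int, n1: int, n_perm: int, seed: int
) -> np.ndarray:
    """Pre-draw n_perm random n1-subsets of range(n) (one row each).

    Sharing one set of label permutations across every candidate tested at a
    threshold keeps the test seeded and fast."""
    rng = np.random.default_rng(seed)
    out = np.empty((n_perm, n1), dtype=np.int64)
    for k in range(n_perm):
        out[k] = rng.permutation(n)[:n1]
    return out


def permutation_test(
    scores: LSIScores | np.ndarray,
    labels: BinarizedLabels | Sequence[int],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    perm_indices: np.ndarray | None = None,
) -> PermutationTestResult:
    """Two-sided permutation test of mean LSI difference between classes.

    The statistic is mean(high) - mean(low); labels are shuffled among the
    scored individuals only and the empirical p uses the add-one rule
    p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1), so p > 0 always.
    """
    if isinstance(scores, LSIScores):
        interaction = scores.interaction
        if isinstance(labels, BinarizedLabels):
            ids = [i for i in scores.individual_ids if i in labels.labels]
            pos = {i: k for k, i in enumerate(scores.individual_ids)}
            values = scores.scores[[pos[i] for i in ids]]
            y = np.array([1 if labels.labels[i] == "high" else 0 for i in ids])
        else:
            values = scores.scores
            y = np.asarray(labels, dtype=int)
    else:
        interaction = None
        values = np.asarray(scores, dtype=float)
        y = (
            np.array([1 if labels.labels[i] == "high" else 0 for i in labels.labels])
            if isinstance(labels, BinarizedLabels)
            else np.asarray(labels, dtype=int)
        )
    if len(values) != len(y):
        raise ValueError("scores and labels misaligned")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present among scored individuals")

    obs = float(values[y == 1].mean() - values[y == 0].mean())
    if perm_indices is None:
        perm_indices = make_permutation_indices(len(y), n1, n_perm, seed)
    elif perm_indices.shape != (n_perm, n1):
        raise ValueError("perm_indices shape does not match (n_perm, n_high)")
    total = values.sum()
    # diff-in-means is affine in the sum over the permuted high class
    scale = 1.0 / n1 + 1.0 / n0
    s_high = values[perm_indices].sum(axis=1)
    stat = s_high * scale - total / n0
    exceed = int((np.abs(stat) >= abs(obs) - 1e-12).sum())
    p = (1 + exceed) / (n_perm + 1)
    return PermutationTestResult(
        interaction=interaction, observed=obs, p_value=p, n_perm=n_perm
    )


def select_candidates(
    shortlist: Sequence[SignedInteraction],
    stability: Mapping[SignedInteraction, InteractionStability],
    stability_cutoff: float = 0.5,
) -> list[SignedInteraction]:
    """Conservative candidate set for permutation testing.

    Union of the signed-locus shortlist (order-1 candidates) and the
    interactions passing the stability filter: stability > 0.5 (strict) and
    positive smip- and sfsd-stability.
    """
    stable = [
        s.interaction
        for s in stability.values()
        if s.interaction.order >= 2
        and s.stability > stability_cutoff
        and (s.smip_stability or 0) > 0
        and (s.sfsd_stability or 0) > 0
    ]
    if not stable:
        logger.warning("no stable interactions; candidates are loci only")
    seen: dict[SignedInteraction, None] = dict.fromkeys(list(shortlist) + stable)
    return list(seen)


def aggregate_across_thresholds(
    results: Mapping[float, Mapping[SignedInteraction, PermutationTestResult]],
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> PrioritizationReport:
    """Cross-threshold stability filter and final ranking.

    A candidate is stable if it was tested in every binarization run with
    p < p_cutoff each time; candidates missing from a run are unstable by
    definition (logged), not imputed. Stable candidates are ranked by the
    arithmetic mean p across runs. The sign-collapsed view ranks each
    locus/interaction by the smaller of its signed versions' mean p.
    Benjamini-Hochberg q-values are annotated for transparency but play no
    role in the ranking.
    """
    thresholds = tuple(sorted(results))
    candidates: dict[SignedInteraction, None] = {}
    for x in thresholds:
        candidates.update(dict.fromkeys(results[x]))

    rows = []
    for cand in candidates:
        ps = {x: results[x][cand].p_value if cand in results[x] else np.nan for x in thresholds}
        obs = [abs(results[x][cand].observed) for x in thresholds if cand in results[x]]
        present = [v for v in ps.values() if not np.isnan(v)]
        missing = len(present) < len(thresholds)
        if missing:
            logger.info("%s missing from %d run(s): unstable by definition",
                        cand, len(thresholds) - len(present))
        stable = (not missing) and all(v < p_cutoff for v in present)
        rows.append(
            {
                "candidate": str(cand),
                "order": cand.order,
                **{f"p_{x:g}": ps[x] for x in thresholds},
                "mean_p": float(np.mean(present)) if present else np.nan,
                "mean_abs_obs": float(np.mean(obs)) if obs else 0.0,
                "stable": stable,
                "_interaction": cand,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        complete = table[[f"p_{x:g}" for x in thresholds]].notna().all(axis=1)
        table["q_value"] = np.nan
        if complete.any():
            table.loc[complete, "q_value"] = sps.false_discovery_control(
                table.loc[complete, "mean_p"].to_numpy()
            )
        # candidates tied at the empirical-p floor are ordered by effect
        # size (mean |LSI difference|), then label
        table = table.sort_values(
            ["stable", "mean_p", "mean_abs_obs", "candidate"],
            ascending=[False, True, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
        table["rank"] = np.nan
        n_stable = int(table["stable"].sum())
        table.loc[: n_stable - 1, "rank"] = np.arange(1, n_stable + 1)

    # sign-collapsed: group by the unsigned component labels; the + and -
    # versions of a locus/interaction are reported at the smaller p
    collapsed_rows: dict[tuple[str, ...], dict] = {}
    for _, row in table.iterrows():
        cand: SignedInteraction = row["_interaction"]
        key = tuple(l for l, _ in cand.components)
        entry = collapsed_rows.setdefault(
            key,
            {"components": ";".join(key), "order": len(key),
             "mean_p": np.inf, "mean_abs_obs": 0.0, "stable": False,
             "best_signed": None},
        )
        better = row["mean_p"] < entry["mean_p"] or (
            row["mean_p"] == entry["mean_p"]
            and row["mean_abs_obs"] > entry["mean_abs_obs"]
        )
        if row["stable"] and better:
            entry["mean_p"] = row["mean_p"]
            entry["mean_abs_obs"] = row["mean_abs_obs"]
            entry["stable"] = True
            entry["best_signed"] = row["candidate"]
    collapsed = pd.DataFrame(
        [e for e in collapsed_rows.values() if e["stable"]]
    )
    if len(collapsed):
        collapsed = collapsed.sort_values(
            ["mean_p", "mean_abs_obs", "components"],
            ascending=[True, False, True], kind="mergesort",
        ).reset_index(drop=True)
        collapsed["rank"] = np.arange(1, len(collapsed) + 1)
    table = table.drop(columns=["_interaction"])
    return PrioritizationReport(
        table=table, sign_collapsed=collapsed, thresholds=thresholds, p_cutoff=p_cutoff
    )


def prediction_screen(
    forest: Forest,
    X_fit: np.ndarray,
    y_fit: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    seed: int = 0,
) -> tuple[pd.DataFrame, bool]:
    """Validation prediction check against standard baselines.

    Computes balanced accuracy, AUROC and AUPRC on the validation set for the
    signed iterated forest and for L1- and L2-penalized logistic regression, a
    standard random forest and a support-vector classifier (library fits,
    treated as plumbing). The gate passes only if the forest's balanced
    accuracy exceeds 0.5 (better than random guessing); downstream
    interpretation must not proceed otherwise.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import (
        average_precision_score,
        balanced_accuracy_score,
        roc_auc_score,
    )
    from sklearn.svm import SVC

    y_val = np.asarray(y_val, dtype=int)
    y_fit = np.asarray(y_fit, dtype=int)
    if len(np.unique(y_val)) < 2:
        raise ValueError("degenerate validation set: single class")

    def _metrics(scores: np.ndarray) -> dict:
        pred = (scores > 0.5).astype(int) if scores.min() >= 0 and scores.max() <= 1 \
            else (scores > 0).astype(int)
        return {
            "balanced_accuracy": balanced_accuracy_score(y_val, pred),
            "auroc": roc_auc_score(y_val, scores),
            "auprc": average_precision_score(y_val, scores),
        }

    rows = {"sirf": _metrics(forest.predict_proba(np.ascontiguousarray(X_val, dtype=np.int8)))}
    baselines = {
        "lasso_logistic": LogisticRegression(
            l1_ratio=1.0, solver="liblinear", max_iter=2000, random_state=seed
        ),
        "ridge_logistic": LogisticRegression(l1_ratio=0.0, max_iter=2000),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "svc": SVC(kernel="rbf", random_state=seed),
    }
    Xf = np.asarray(X_fit, dtype=float)
    Xv = np.asarray(X_val, dtype=float)
    for name, model in baselines.items():
        model.fit(Xf, y_fit)
        if hasattr(model, "predict_proba"):
            scores = model.predict_proba(Xv)[:, 1]
        else:
            scores = model.decision_function(Xv)
        rows[name] = _metrics(scores)
    metrics = pd.DataFrame(rows).T
    gate = bool(metrics.loc["sirf", "balanced_accuracy"] > 0.5)
    return metrics, gate
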