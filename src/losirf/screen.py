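"""Association scan and union-of-top-k dimension reduction.

The interaction search space is reduced by ranking variants with single-variant
ordinary least squares on the rank-based inverse-normal-transformed trait
(adjusted for covariates) and taking the union of the top-k variants across one
or more ranking tables. External summary statistics (e.g. from a mixed-model
GWAS) can be supplied as additional ranking tables; only ``variant_id`` and
``p`` columns are required of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenResult",
    "inverse_normal_transform",
    "assoc_scan",
    "select_union_topk",
    "read_sumstats_tsv",
    "DEFAULT_TOP_K",
]

#: per-method top-k used at full scale
DEFAULT_TOP_K = 1000


@dataclass
class ScreenResult:
    """Union of per-method top-k variants plus the per-method tables."""

    selected: list[str]
    tables: list[pd.DataFrame]
    k: int


def inverse_normal_transform(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Returns ``Phi^{-1}((r - 3/8) / (n + 1/4))`` where ``r`` is the average rank
    (ties share ranks). The result has mean approximately zero and is monotone
    in the input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector with at least 2 values")
    if not np.isfinite(x).all():
        raise ValueError("non-finite trait values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate trait: all values identical")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


def _covariate_design(
    phenotype: PhenotypeTable, covariate_names: Sequence[str]
) -> np.ndarray:
    """Intercept + covariates design; sex is encoded 0/1 if requested."""
    n = len(phenotype)
    cols = [np.ones(n)]
    for name in covariate_names:
        if name == "sex":
            cols.append((phenotype.sex.to_numpy() == "M").astype(float))
        else:
            cols.append(phenotype.df[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def assoc_scan(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeTable,
    covariate_names: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-variant OLS of the inverse-normal-transformed trait on dosage.

    Each variant is tested in its own model ``INT(trait) ~ dosage + covariates
    + intercept`` with a two-sided t-test on the dosage coefficient. All
    variants share the covariate projection, so the scan is computed by
    residualizing trait and dosages on the covariates once
    (Frisch-Waugh-Lovell) — numerically identical to p separate OLS fits.

    Returns a DataFrame with columns variant_id, beta, se, t_stat, p_value,
    rank (1-based by ascending p).
    """
    order = phenotype.individual_ids
    if order != genotypes.individual_ids:
        genotypes = genotypes.subset_individuals(order)
    y = inverse_normal_transform(phenotype.trait.to_numpy(dtype=float))
    Z = _covariate_design(phenotype, covariate_names)
    n, q = Z.shape
    rank_z = np.linalg.matrix_rank(Z)
    if rank_z < q:
        names = ["(intercept)"] + list(covariate_names)
        for j in range(1, q):
            sub = np.delete(Z, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank_z:
                raise ValueError(f"collinear covariate set: column {names[j]!r} is redundant")
        raise ValueError("collinear covariate set")

    Q, _ = np.linalg.qr(Z)
    X = genotypes.dosages.astype(np.float64)
    ry = y - Q @ (Q.T @ y)
    rX = X - Q @ (Q.T @ X)

    sxx = np.einsum("ij,ij->j", rX, rX)
    sxy = rX.T @ ry
    syy = float(ry @ ry)
    dof = n - q - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        rss = syy - beta**2 * sxx
        sigma2 = np.maximum(rss, 0.0) / dof
        se = np.sqrt(np.where(sxx > 0, sigma2 / np.where(sxx > 0, sxx, 1.0), np.inf))
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    monomorphic = sxx <= 0
    if monomorphic.any():
        logger.warning("%d monomorphic variants scored p=1", int(monomorphic.sum()))
        p[monomorphic] = 1.0
        se[monomorphic] = np.inf

    table = pd.DataFrame(
        {
            "variant_id": genotypes.variant_ids,
            "beta": beta,
            "se": se,
            "t_stat": t,
            "p_value": p,
        }
    )
    table["rank"] = (
        table[["p_value", "variant_id"]]
        .sort_values(["p_value", "variant_id"])
        .assign(r=np.arange(1, len(table) + 1))
        .sort_index()["r"]
    )
    return table


def read_sumstats_tsv(path: str | Path) -> pd.DataFrame:
    """Read an external summary-statistics TSV (variant_id, p[, beta, se])."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    if "p" in df.columns and "p_value" not in df.columns:
        df = df.rename(columns={"p": "p_value"})
    if not {"variant_id", "p_value"}.issubset(df.columns):
        raise ValueError("summary statistics need variant_id and p columns")
    return df


def select_union_topk(tables: Sequence[pd.DataFrame], k: int = DEFAULT_TOP_K) -> ScreenResult:
    """Union of per-table top-k variants by ascending p.

    Ties at the k-th p-value are broken lexicographically by variant id
    (logged). If k exceeds a table's size, all its variants are taken with a
    warning.
    """
    if not tables:
        raise ValueError("need at least one association table")
    if k < 1:
        raise ValueError("k must be >= 1")
    selected: set[str] = set()
    for t, table in enumerate(tables):
        if k > len(table):
            logger.warning("k=%d exceeds table %d size %d; taking all", k, t, len(table))
        ordered = table.sort_values(["p_value", "variant_id"], kind="mergesort")
        top = ordered["variant_id"].head(k).tolist()
        kth_p = ordered["p_value"].iloc[min(k, len(ordered)) - 1]
        n_tied = int((table["p_value"] == kth_p).sum())
        if n_tied > 1:
            logger.info(
                "table %d: %d variants tied at the k-th p; lexicographic tie-break", t, n_tied
            )
        selected.update(top)
    return ScreenResult(selected=sorted(selected), tables=list(tables), k=k)
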