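"""Core data model and readers/writers for genotypes, phenotypes, locus maps and splits.

Genotypes are additive dosages in {0, 1, 2} (copies of the alternate allele).
Missing entries are imputed at load time to the per-variant rounded mean, so that
downstream tree code always sees complete data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantInfo",
    "GenotypeMatrix",
    "PhenotypeTable",
    "LocusMap",
    "DataSplit",
    "read_plink_raw",
    "write_plink_raw",
    "read_vcf_minimal",
    "read_phenotype_table",
    "read_locus_map",
    "make_split",
]


@dataclass(frozen=True)
class VariantInfo:
    """Metadata for one biallelic variant.

    ``maf`` is the minor allele frequency; inputs are assumed post-QC
    (the source cohort filtered at MAF < 1e-4), so it is metadata here,
    not a filter.
    """

    variant_id: str
    chromosome: str = "0"
    position: int = 1
    ref_allele: str = "A"
    alt_allele: str = "G"
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass
class GenotypeMatrix:
    """Individuals x variants additive dosage matrix with variant metadata."""

    individual_ids: list[str]
    variants: list[VariantInfo]
    dosages: np.ndarray  # (n, p) int8, values in {0, 1, 2}

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, p = self.dosages.shape
        if n != len(self.individual_ids):
            raise ValueError("dosage rows do not match individual ids")
        if p != len(self.variants):
            raise ValueError("dosage columns do not match variant list")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids are not unique")
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} after imputation")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        """Column subset preserving the requested order."""
        index = {v: j for j, v in enumerate(self.variant_ids)}
        missing = [v for v in variant_ids if v not in index]
        if missing:
            raise KeyError(f"variants not in matrix: {missing[:5]}")
        cols = [index[v] for v in variant_ids]
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            variants=[self.variants[j] for j in cols],
            dosages=self.dosages[:, cols].copy(),
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {i: r for r, i in enumerate(self.individual_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"individuals not in matrix: {missing[:5]}")
        rows = [index[i] for i in ids]
        return GenotypeMatrix(
            individual_ids=list(ids),
            variants=list(self.variants),
            dosages=self.dosages[rows, :].copy(),
        )


class PhenotypeTable:
    """One row per individual: continuous trait, sex in {F, M}, named covariates.

    Backed by a pandas DataFrame indexed by individual id with columns
    ``trait``, ``sex`` and one column per covariate.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"trait", "sex"}
        if not required.issubset(df.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        if df.index.has_duplicates:
            raise ValueError("duplicate individual ids in phenotype table")
        if not np.isfinite(df["trait"].to_numpy(dtype=float)).all():
            raise ValueError("trait contains non-finite values")
        bad_sex = set(df["sex"].unique()) - {"F", "M"}
        if bad_sex:
            raise ValueError(f"sex must be F or M, found {sorted(bad_sex)}")
        self.df = df

    @property
    def individual_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def trait(self) -> pd.Series:
        return self.df["trait"]

    @property
    def sex(self) -> pd.Series:
        return self.df["sex"]

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("trait", "sex")]

    def covariates(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        return self.df[list(names) if names is not None else self.covariate_names]

    def subset(self, ids: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.df.loc[list(ids)].copy())

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="iid")

    def __len__(self) -> int:
        return len(self.df)


class LocusMap:
    """Variant id -> locus label (gene or intergenic ``A;B`` label).

    Every mapped variant has exactly one locus; conflicting rows are an error.
    """

    def __init__(self, mapping: dict[str, str]):
        self.mapping = dict(mapping)

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "LocusMap":
        mapping: dict[str, str] = {}
        for variant, locus in pairs:
            if variant in mapping and mapping[variant] != locus:
                raise ValueError(
                    f"conflicting locus assignment for {variant}: "
                    f"{mapping[variant]!r} vs {locus!r}"
                )
            mapping[variant] = locus
        return cls(mapping)

    def __getitem__(self, variant_id: str) -> str:
        return self.mapping[variant_id]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    @property
    def loci(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"variant_id": list(self.mapping), "locus": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class DataSplit:
    """Pairwise-disjoint id sets: training (fit + set-aside), validation, test.

    The training set is sub-split so that interaction-importance ranking can use
    samples never seen by the forest fit, mirroring a 2:1 fit/set-aside design.
    """

    train_fit: list[str]
    train_setaside: list[str]
    validation: list[str]
    test: list[str]

    def __post_init__(self) -> None:
        groups = [self.train_fit, self.train_setaside, self.validation, self.test]
        flat = [i for g in groups for i in g]
        if len(set(flat)) != len(flat):
            raise ValueError("split groups are not pairwise disjoint")

    @property
    def train(self) -> list[str]:
        return self.train_fit + self.train_setaside

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_fit": self.train_fit,
                    "train_setaside": self.train_setaside,
                    "validation": self.validation,
                    "test": self.test,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DataSplit":
        d = json.loads(Path(path).read_text())
        return cls(d["train_fit"], d["train_setaside"], d["validation"], d["test"])


def _impute_rounded_mean(column: np.ndarray, missing: np.ndarray) -> tuple[np.ndarray, int]:
    """Fill missing dosages with the round-half-up mean of observed entries."""
    n_missing = int(missing.sum())
    if n_missing:
        observed = column[~missing]
        if observed.size == 0:
            fill = 0
        else:
            fill = int(np.floor(observed.mean() + 0.5))
        column = column.copy()
        column[missing] = fill
    return column, n_missing


def read_plink_raw(
    path: str | Path, variant_info: pd.DataFrame | None = None
) -> GenotypeMatrix:
    """Read a PLINK ``--recode A`` (.raw) dosage export.

    The header is ``FID IID PAT MAT SEX PHENOTYPE`` followed by ``<SNP>_<allele>``
    columns; entries are 0/1/2 counts of ``<allele>`` with ``NA`` for missing.
    Missing entries are imputed to the per-variant rounded mean (logged).
    ``variant_info`` is an optional sidecar table (columns ``variant_id``,
    ``chromosome``, ``position``, ``ref_allele``, ``alt_allele``) since .raw
    files carry no positions.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    expected = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != expected:
        raise ValueError(f"malformed .raw header: expected {expected}, got {list(df.columns[:6])}")
    snp_cols = list(df.columns[6:])
    if not snp_cols:
        raise ValueError("no variants in .raw file")

    info_index = None
    if variant_info is not None:
        info_index = variant_info.set_index("variant_id")

    ids = df["IID"].tolist()
    n, p = len(ids), len(snp_cols)
    dosages = np.zeros((n, p), dtype=np.int8)
    variants: list[VariantInfo] = []
    total_imputed = 0
    for j, col in enumerate(snp_cols):
        if "_" not in col:
            raise ValueError(f"dosage column {col!r} lacks the <SNP>_<allele> suffix")
        vid, allele = col.rsplit("_", 1)
        raw = df[col].to_numpy()
        missing = (raw == "NA") | pd.isna(raw)
        values = np.zeros(n, dtype=np.int8)
        ok = ~missing
        try:
            parsed = raw[ok].astype(np.int8)
        except ValueError as exc:
            raise ValueError(f"non-{{0,1,2,NA}} token in column {col!r}") from exc
        if not np.isin(parsed, (0, 1, 2)).all():
            raise ValueError(f"non-{{0,1,2,NA}} token in column {col!r}")
        values[ok] = parsed
        values[missing] = -1
        values, n_imp = _impute_rounded_mean(values, np.asarray(missing))
        total_imputed += n_imp
        dosages[:, j] = values
        if info_index is not None and vid in info_index.index:
            row = info_index.loc[vid]
            variants.append(
                VariantInfo(
                    variant_id=vid,
                    chromosome=str(row.get("chromosome", "0")),
                    position=int(row.get("position", 1)),
                    ref_allele=str(row.get("ref_allele", "N")),
                    alt_allele=allele,
                )
            )
        else:
            variants.append(VariantInfo(variant_id=vid, alt_allele=allele))
    if total_imputed:
        logger.info("imputed %d missing dosage entries in %s", total_imputed, path.name)
    return GenotypeMatrix(individual_ids=ids, variants=variants, dosages=dosages)


def write_plink_raw(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK .raw file (space-delimited)."""
    path = Path(path)
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + [
        f"{v.variant_id}_{v.alt_allele}" for v in genotypes.variants
    ]
    with open(path, "w") as fh:
        fh.write(" ".join(header) + "\n")
        for i, iid in enumerate(genotypes.individual_ids):
            row = [iid, iid, "0", "0", "0", "-9"]
            row.extend(str(int(d)) for d in genotypes.dosages[i])
            fh.write(" ".join(row) + "\n")


def read_vcf_minimal(path: str | Path) -> GenotypeMatrix:
    """Read a minimal VCF (v4.x) with per-sample GT fields into dosages.

    ``0/0``, ``0/1``, ``1/1`` (phased or unphased) map to 0, 1, 2. Multiallelic
    records are rejected; missing GTs are imputed to the per-variant rounded mean.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    variants: list[VariantInfo] = []
    total_imputed = 0
    for record in vcf:
        if len(record.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {record.CHROM}:{record.POS} (ALT={record.ALT})"
            )
        values = np.empty(len(ids), dtype=np.int8)
        missing = np.zeros(len(ids), dtype=bool)
        for s, gt in enumerate(record.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) < 2:
                missing[s] = True
                values[s] = -1
            else:
                values[s] = sum(alleles)
        values, n_imp = _impute_rounded_mean(values, missing)
        total_imputed += n_imp
        vid = record.ID if record.ID not in (None, ".") else f"{record.CHROM}:{record.POS}"
        variants.append(
            VariantInfo(
                variant_id=vid,
                chromosome=str(record.CHROM),
                position=int(record.POS),
                ref_allele=record.REF,
                alt_allele=record.ALT[0],
            )
        )
        columns.append(values)
    if not variants:
        raise ValueError("no variants in VCF")
    if total_imputed:
        logger.info("imputed %d missing genotypes from %s", total_imputed, path)
    return GenotypeMatrix(
        individual_ids=ids, variants=variants, dosages=np.column_stack(columns)
    )


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    """Read a TSV with columns iid, trait, sex and any number of covariates."""
    df = pd.read_csv(path, sep="\t", dtype={"iid": str}).set_index("iid")
    return PhenotypeTable(df)


def read_locus_map(path: str | Path) -> LocusMap:
    """Read a two-column TSV (variant_id, locus)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return LocusMap.from_pairs(list(zip(df["variant_id"], df["locus"])))


def make_split(
    ids: Sequence[str],
    sizes: tuple[int, int, int],
    seed: int,
    fit_fraction: float = 2.0 / 3.0,
) -> DataSplit:
    """Seeded uniform partition into train/validation/test of the given sizes.

    The training portion is further sub-split into fit and set-aside parts with
    ``fit_fraction`` of the training ids in the fit part (default 2:1).
    """
    n_train, n_val, n_test = sizes
    if n_train + n_val + n_test > len(ids):
        raise ValueError(
            f"split sizes {sizes} exceed available {len(ids)} individuals"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    train = shuffled[:n_train]
    val = shuffled[n_train : n_train + n_val]
    test = shuffled[n_train + n_val : n_train + n_val + n_test]
    n_fit = int(round(n_train * fit_fraction))
    return DataSplit(
        train_fit=train[:n_fit],
        train_setaside=train[n_fit:],
        validation=val,
        test=test,
    )
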