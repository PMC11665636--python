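"""Core domain types and tabular IO.

All on-disk tables are TSV with a header row, UTF-8, samples as rows and
features (variants or genes) as columns.  Identifiers are opaque strings and
matched exactly.  Loaders fail loudly: missing or non-numeric cells are
errors, never silently imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataValidationError",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "EqtlCatalog",
    "SampleSplit",
    "PipelineConfig",
    "read_matrix_table",
    "write_matrix_table",
    "read_eqtl_catalog",
    "write_eqtl_catalog",
    "align_samples",
]


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Sample-by-variant dosage matrix.

    Dosages are integers in ``{0, .., ploidy}``: ``{0, 1}`` for haploid
    organisms (e.g. yeast segregants) and ``{0, 1, 2}`` for diploids.
    """

    data: pd.DataFrame
    ploidy: int = 2

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            raise DataValidationError("genotype dosages must be integers")
        allowed = set(range(self.ploidy + 1))
        bad = set(np.unique(values)) - allowed if values.size else set()
        if bad:
            raise DataValidationError(
                f"dosages {sorted(bad)} outside allowed set {sorted(allowed)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def dosages(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def column(self, variant_id: str) -> np.ndarray:
        return self.data[variant_id].to_numpy()

    def monomorphic_variants(self) -> list[str]:
        """Variant ids whose column has fewer than two distinct dosages."""
        nun = self.data.nunique(axis=0)
        return list(nun.index[nun < 2])

    def is_monomorphic(self, variant_id: str) -> bool:
        return self.data[variant_id].nunique() < 2

    def restrict_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.data.loc[list(sample_ids)], ploidy=self.ploidy)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Sample-by-gene matrix of real-valued expression levels."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataValidationError(
                "non-finite expression value at sample "
                f"{self.data.index[bad[0]]!r}, gene {self.data.columns[bad[1]]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def column(self, gene_id: str) -> np.ndarray:
        return self.data[gene_id].to_numpy()

    def restrict_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(sample_ids)])


@dataclass(frozen=True)
class EqtlCatalog:
    """Mapping gene -> ordered cis-eQTL variant ids, strongest first.

    Only genes present in the catalog take part in network reconstruction and
    trans modelling; the catalog is taken as given (cis-window definition and
    eQTL mapping happen upstream).
    """

    entries: Mapping[str, tuple[str, ...]]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def variants(self, gene_id: str) -> tuple[str, ...]:
        return self.entries[gene_id]

    def top_variant(self, gene_id: str) -> str:
        return self.entries[gene_id][0]

    def validate_against(
        self, geno: GenotypeMatrix, expr: ExpressionMatrix
    ) -> None:
        """Check every referenced id exists in the paired matrices."""
        variant_set = set(geno.variant_ids)
        gene_set = set(expr.gene_ids)
        for gene, variants in self.entries.items():
            if gene not in gene_set:
                raise DataValidationError(
                    f"catalog gene {gene!r} absent from expression matrix"
                )
            for v in variants:
                if v not in variant_set:
                    raise DataValidationError(
                        f"catalog variant {v!r} (gene {gene!r}) absent from "
                        "genotype matrix"
                    )


@dataclass(frozen=True)
class SampleSplit:
    """Disjoint train/test partition of the sample ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise DataValidationError("train and test sets overlap")


#: regression backends understood by :func:`grnimpute.regression.make_regressor`
BACKENDS = ("lasso", "ridge", "bayesian_ridge", "elastic_net")

#: edge-score recipes understood by :func:`grnimpute.pairtests.combine_posteriors`
RECIPES = ("P0", "P2P3", "P2P5", "HALF_P2P5_PLUS_P4")


def _default_alpha_grid() -> tuple[float, ...]:
    # 50 log-spaced penalty values spanning 0.001-10
    return tuple(np.logspace(np.log10(0.001), np.log10(10.0), 50))


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs shared across the pipeline.

    Parameters
    ----------
    backend
        Regression backend: ``lasso``, ``ridge``, ``bayesian_ridge`` or
        ``elastic_net``.
    alpha_grid
        Penalty-strength candidates for the cross-validated backends.
    l1_ratios
        Mixing ratios for the elastic net.
    recipe
        How pairwise posteriors are combined into edge scores.
    edge_threshold
        Minimum edge probability kept in the final network (strict ``>``).
    predictability_threshold
        Per-gene test R^2 (combined cis + observed-parent model) required for
        a gene to count as predictable; inclusive boundary.
    train_fraction, split_seed
        Train/test partitioning of samples.
    ploidy
        Dosage alphabet: 1 -> {0,1}, 2 -> {0,1,2}.
    n_random_networks
        Number of topology-preserving randomizations used as the null
        reference in network comparisons.
    cv_folds, seed
        Cross-validation folds and the master seed for every stochastic step.
    threshold_before_dag
        If True, drop sub-threshold scores before greedy DAG construction
        instead of thresholding the built DAG.
    """

    backend: str = "ridge"
    alpha_grid: tuple[float, ...] = field(default_factory=_default_alpha_grid)
    l1_ratios: tuple[float, ...] = (0.01, 0.5, 1.0)
    recipe: str = "HALF_P2P5_PLUS_P4"
    edge_threshold: float = 0.5
    predictability_threshold: float = 0.05
    train_fraction: float = 0.8
    ploidy: int = 2
    n_random_networks: int = 5
    cv_folds: int = 5
    max_iter: int = 10_000
    seed: int = 0
    threshold_before_dag: bool = False
    all_eqtls: bool = False

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise DataValidationError(
                f"unknown backend {self.backend!r}; expected one of {BACKENDS}"
            )
        if self.recipe not in RECIPES:
            raise DataValidationError(
                f"unknown recipe {self.recipe!r}; expected one of {RECIPES}"
            )
        for name in ("edge_threshold", "predictability_threshold"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise DataValidationError(f"{name}={value} outside [0, 1]")
        if not 0.0 < self.train_fraction < 1.0:
            raise DataValidationError("train_fraction must be in (0, 1)")
        if len(self.alpha_grid) == 0 or len(self.l1_ratios) == 0:
            raise DataValidationError("hyper-parameter grids must be non-empty")

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def to_json(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        return json.dumps(d, sort_keys=True)


# ---------------------------------------------------------------------------
# IO


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df


def read_matrix_table(
    path: str | Path, kind: str, ploidy: int = 2
) -> GenotypeMatrix | ExpressionMatrix:
    """Read a sample-by-feature TSV as a genotype or expression matrix.

    The first column holds sample ids, the header row feature ids.  Missing
    or non-numeric cells raise :class:`DataValidationError` naming the cell.
    """
    if kind not in ("genotype", "expression"):
        raise ValueError(f"kind must be 'genotype' or 'expression', got {kind!r}")
    df = _read_tsv(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataValidationError(
            f"non-numeric cell at sample {df.index[r]!r}, "
            f"feature {df.columns[c]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataValidationError(
            f"missing value at sample {df.index[r]!r}, "
            f"feature {df.columns[c]!r} in {path}"
        )
    if kind == "genotype":
        values = numeric.to_numpy()
        if not np.allclose(values, np.round(values)):
            r, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise DataValidationError(
                f"non-integer dosage at sample {df.index[r]!r}, "
                f"variant {df.columns[c]!r} in {path}"
            )
        return GenotypeMatrix(numeric.astype(np.int64), ploidy=ploidy)
    return ExpressionMatrix(numeric.astype(float))


def write_matrix_table(
    matrix: GenotypeMatrix | ExpressionMatrix, path: str | Path
) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="sample_id")


def read_eqtl_catalog(path: str | Path) -> EqtlCatalog:
    """Read a gene/variant/rank TSV into a catalog (rank 1 = strongest)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "variant_id": str, "rank": int}
    )
    expected = {"gene_id", "variant_id", "rank"}
    if not expected.issubset(df.columns):
        raise DataValidationError(
            f"catalog must have columns {sorted(expected)}, got {list(df.columns)}"
        )
    dup = df.duplicated(subset=["gene_id", "rank"])
    if dup.any():
        row = df[dup].iloc[0]
        raise DataValidationError(
            f"duplicate (gene, rank) pair ({row.gene_id!r}, {row['rank']})"
        )
    entries: dict[str, tuple[str, ...]] = {}
    for gene, group in df.groupby("gene_id", sort=False):
        ordered = group.sort_values("rank")
        entries[str(gene)] = tuple(ordered["variant_id"])
    return EqtlCatalog(entries)


def write_eqtl_catalog(catalog: EqtlCatalog, path: str | Path) -> None:
    rows = [
        {"gene_id": gene, "variant_id": v, "rank": i + 1}
        for gene, variants in catalog.entries.items()
        for i, v in enumerate(variants)
    ]
    pd.DataFrame(rows, columns=["gene_id", "variant_id", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def align_samples(
    geno: GenotypeMatrix, expr: ExpressionMatrix
) -> tuple[GenotypeMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common samples, in matching order.

    The order follows the genotype matrix.  Raises on an empty intersection.
    """
    common = [s for s in geno.sample_ids if s in set(expr.sample_ids)]
    if not common:
        raise DataValidationError("genotype and expression share no samples")
    return geno.restrict_samples(common), expr.restrict_samples(common)
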