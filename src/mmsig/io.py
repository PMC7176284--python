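"""Readers and writers for expression matrices and gene-set databases.

Expression matrices are tab-separated text with genes as rows and samples as
columns (the convention of the large RNA-seq compendia); values are either
raw TPM or log2(TPM+1). Gene sets use the MSigDB GMT interchange format:
one set per line as ``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALE_TPM = "tpm"
SCALE_LOG = "log2tpm1"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix with a scale tag."""

    values: pd.DataFrame
    scale: str = SCALE_LOG

    def __post_init__(self):
        if self.scale not in (SCALE_TPM, SCALE_LOG):
            raise ValueError(f"unknown scale tag: {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample identifiers: {list(dups)[:5]}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite values")
        if self.scale == SCALE_LOG and arr.size and arr.min() < 0:
            raise ValueError("log2(TPM+1) values must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.scale)

    def samples_by_genes(self, genes: Sequence[str] | None = None) -> pd.DataFrame:
        """Transpose to the samples-by-features layout the models expect."""
        df = self.values if genes is None else self.subset_genes(genes).values
        return df.T

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


def read_expression(path, orientation: str = "genes_rows",
                    scale: str = SCALE_LOG) -> ExpressionMatrix:
    """Load a tab-separated expression matrix.

    Duplicate gene rows are collapsed by their mean (with a logged warning);
    duplicate sample identifiers, missing values and unparsable numeric cells
    are errors.
    """
    if orientation not in ("genes_rows", "samples_rows"):
        raise ValueError("orientation must be 'genes_rows' or 'samples_rows'")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty expression file: {path}") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"expression file has no data: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) == df.shape[1]:
        df.columns = header           # undo pandas' dedup-mangling
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"unparsable numeric cell at row {df.index[row]!r}, "
            f"column {df.columns[col]!r}: {df.iat[row, col]!r}")
    if num.isna().to_numpy().any():
        row, col = np.argwhere(num.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at row {df.index[row]!r}, "
            f"column {df.columns[col]!r}")
    if orientation == "samples_rows":
        num = num.T
    if num.columns.duplicated().any():
        dups = num.columns[num.columns.duplicated()].unique()
        raise ValueError(f"duplicate sample identifiers: {list(dups)[:5]}")
    if num.index.duplicated().any():
        dups = list(num.index[num.index.duplicated()].unique())
        logger.warning("collapsing %d duplicated gene identifiers by mean: %s",
                       len(dups), dups[:5])
        num = num.groupby(level=0, sort=False).mean()
    num.index = pd.Index([str(i) for i in num.index])
    num.columns = pd.Index([str(c) for c in num.columns])
    return ExpressionMatrix(num.astype(float), scale)


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Transform raw TPM values to log2(TPM+1)."""
    if expr.scale == SCALE_LOG:
        raise ValueError("matrix is already on the log2(TPM+1) scale")
    arr = expr.values.to_numpy()
    if arr.size and arr.min() < 0:
        raise ValueError("TPM values must be nonnegative")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(arr + 1.0), index=expr.values.index,
                     columns=expr.values.columns),
        SCALE_LOG)


@dataclass
class GeneSetDB:
    """Named gene sets with descriptions, as parsed from a GMT file."""

    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def subset(self, names: Sequence[str]) -> "GeneSetDB":
        return GeneSetDB({n: self.sets[n] for n in names},
                         {n: self.descriptions.get(n, "") for n in names})

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[str]]) -> "GeneSetDB":
        sets = {}
        for name, genes in mapping.items():
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(str(g))
            sets[name] = tuple(seen)
        return cls(sets, {n: "" for n in sets})

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *genes]) + "\n")


def parse_gmt(path) -> GeneSetDB:
    """Parse a GMT gene-set file.

    Genes are kept verbatim (case preserved) and de-duplicated within a set;
    duplicate set names or lines with fewer than three fields are errors.
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected name, description and at "
                    f"least one gene, got {len(fields)} field(s)")
            name, desc, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(g)
            sets[name] = tuple(seen)
            descriptions[name] = desc
    return GeneSetDB(sets, descriptions)
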