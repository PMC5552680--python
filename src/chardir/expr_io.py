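"""Expression matrices, sample annotations and gene sets.

The whole pipeline operates on normalized expression values — log2
intensities for microarray-like data, linear RPKM for RNA-seq — carried in a
single genes × samples container.  Readers accept delimited text (TSV or
CSV, sniffed by extension) with gene identifiers in the first column and
sample identifiers in the header; gene sets use the standard GMT format.
Normalization itself (e.g. RMA of raw array data) happens upstream: inputs
are declared pre-normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("chardir")

CASE = "case"
CONTROL = "control"

_SCALE_TAGS = ("log", "linear")


class ExpressionIOError(ValueError):
    """Malformed expression table, annotation file or gene-set file."""


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of normalized expression values.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as index and sample identifiers as
        columns.  Values are log2 intensities (``scale_tag="log"``) or
        linear RPKM (``scale_tag="linear"``).
    scale_tag
        Either ``"log"`` or ``"linear"``.  Linear matrices must be
        non-negative.
    """

    data: pd.DataFrame
    scale_tag: str = "log"

    def __post_init__(self) -> None:
        if self.scale_tag not in _SCALE_TAGS:
            raise ValueError(f"scale_tag must be one of {_SCALE_TAGS}, got {self.scale_tag!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate gene identifiers: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate sample identifiers: {dups[:5]}")
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ExpressionIOError("expression values must be finite")
        if self.scale_tag == "linear" and (vals < 0).any():
            raise ExpressionIOError("linear-scale (RPKM) values must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given genes, preserving the given order."""
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)], self.scale_tag)


@dataclass
class SampleAnnotation:
    """Per-sample class labels (case = tumorigenic, control = healthy dividing)."""

    table: pd.DataFrame  # index: sample_id; columns: class_label, cell_type, origin

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ExpressionIOError("duplicate sample_id in annotation")
        labels = self.table["class_label"]
        bad = labels[~labels.isin([CASE, CONTROL])]
        if len(bad):
            raise ExpressionIOError(
                f"class_label must be '{CASE}' or '{CONTROL}'; offending samples: "
                f"{bad.index.tolist()[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_with_label(self, label: str) -> list[str]:
        return list(self.table.index[self.table["class_label"] == label])

    def class_mask(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Boolean mask over *sample_ids*: True for case samples."""
        labels = self.table["class_label"].reindex(sample_ids)
        if labels.isna().any():
            missing = [s for s, v in labels.items() if pd.isna(v)]
            raise KeyError(f"samples missing from annotation: {missing[:5]}")
        return (labels == CASE).to_numpy()


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene identifiers, e.g. a transcription-factor regulon."""

    name: str
    genes: frozenset[str]
    direction_tag: Optional[str] = None  # {"up", "down", None}

    def __post_init__(self) -> None:
        if self.direction_tag not in (None, "up", "down", "none"):
            raise ValueError(f"bad direction_tag {self.direction_tag!r}")

    def __len__(self) -> int:
        return len(self.genes)

    @staticmethod
    def from_iterable(name: str, genes: Iterable[str], direction_tag: Optional[str] = None) -> "GeneSet":
        return GeneSet(name, frozenset(genes), direction_tag)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_table(path, mode: str = "log") -> ExpressionMatrix:
    """Read a delimited genes × samples table.

    First column holds gene identifiers, header row holds sample
    identifiers.  Duplicate gene rows are collapsed by the arithmetic mean
    on the stored scale (logged).  Duplicate sample headers and non-numeric
    cells are errors.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    samples = header[1:]
    seen = set()
    for s in samples:
        if s in seen:
            raise ExpressionIOError(f"duplicate sample header {s!r} in {path.name}")
        seen.add(s)

    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.columns = samples
    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ExpressionIOError(
            f"non-numeric value {raw.iat[i, j]!r} at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} in {path.name}"
        )
    if num.isna().to_numpy().any():
        i, j = np.argwhere(num.isna().to_numpy())[0]
        raise ExpressionIOError(
            f"missing value at gene {num.index[i]!r}, sample {num.columns[j]!r} in {path.name}"
        )
    if num.index.has_duplicates:
        n_dup = int(num.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean in %s", n_dup, path.name)
        num = num.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(num.astype(float), scale_tag=mode)


def write_expression_table(em: ExpressionMatrix, path) -> None:
    """Write a matrix as delimited text (round-trips to full float precision)."""
    sep = _sep_for(path)
    em.data.to_csv(path, sep=sep, index_label="gene_id", float_format="%.17g")


def read_sample_annotation(path) -> SampleAnnotation:
    """Read a TSV with columns sample_id, class_label, cell_type, origin."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "class_label"}
    if not required.issubset(tab.columns):
        raise ExpressionIOError(f"annotation must have columns {sorted(required)}")
    for col in ("cell_type", "origin"):
        if col not in tab.columns:
            tab[col] = ""
    tab = tab.set_index("sample_id")
    return SampleAnnotation(tab[["class_label", "cell_type", "origin"]])


def write_sample_annotation(ann: SampleAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_sets(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...; tab-separated)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ExpressionIOError(
                    f"GMT line {lineno} has {len(fields)} fields; need name, "
                    "description and at least one gene"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            sets.append(GeneSet.from_iterable(name, genes))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.direction_tag or "na", *sorted(s.genes)]) + "\n")


def align_matrices(m1: ExpressionMatrix, m2: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to their shared genes, in a common order.

    Needed whenever independently normalized datasets must be compared in a
    single gene space (e.g. projecting a validation cohort onto a direction
    fitted on a discovery cohort).  Gene order follows *m1*; sample sets are
    untouched.
    """
    shared = [g for g in m1.gene_ids if g in set(m2.gene_ids)]
    if not shared:
        raise ExpressionIOError("no shared genes between matrices")
    return m1.subset_genes(shared), m2.subset_genes(shared)
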