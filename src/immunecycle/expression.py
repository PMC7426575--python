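"""Expression matrices and the normalization chain.

The pipeline consumes a dense genes × samples expression matrix and tracks
its normalization state through three stages: ``raw`` (linear, nonnegative),
``log`` (log2(x + offset)) and ``zscore`` (per-gene z-score across samples).
Downstream stages check the state they require: mixture clustering and
phenotype labeling run on z-scores, while cytolytic activity and the
TIC/IRP geometric means run on the linear scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._aliases import canonical_symbol

logger = logging.getLogger(__name__)

VALID_STATES = ("raw", "log", "zscore")


@dataclass
class ExpressionMatrix:
    """Dense genes × samples expression with tracked normalization state.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix; index = gene symbols, columns = sample ids, both
        unique.
    state : {"raw", "log", "zscore"}
        Normalization state of ``values``.
    provenance : list of str
        Ordered record of the transforms applied so far.
    """

    values: pd.DataFrame
    state: str = "raw"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.size == 0:
            raise ValueError("empty expression matrix")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("non-numeric expression values")
        if np.isnan(arr).any():
            raise ValueError("missing values in expression matrix")
        if self.state == "raw" and (arr < 0).any():
            raise ValueError("negative values in a raw-state matrix")

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

    def copy(self) -> "ExpressionMatrix":
        return replace(self, values=self.values.copy(),
                       provenance=list(self.provenance))


def read_expression(path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix (genes × samples).

    First column holds gene ids, the header row sample ids. Duplicate gene
    rows are collapsed by mean (logged); blank cells are imputed to 0
    (logged count); gene symbols are canonicalized (uppercase + alias
    table). The result is in ``raw`` state.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dupes = sorted({s for s in header if header.count(s) > 1})
    if dupes:
        raise ValueError(f"duplicate sample ids: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {path}")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("imputed %d missing expression cells to 0", n_missing)
        df = df.fillna(0.0)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc
    df.index = [canonical_symbol(g) for g in df.index]
    if pd.Index(df.index).has_duplicates:
        dupes = sorted(set(pd.Index(df.index)[pd.Index(df.index).duplicated()]))
        logger.warning("collapsing %d duplicated gene rows by mean: %s",
                       len(dupes), dupes[:10])
        df = df.groupby(level=0, sort=False).mean()
    prov = [f"read_expression({path})"]
    if n_missing:
        prov.append(f"impute_missing(n={n_missing})")
    return ExpressionMatrix(values=df, state="raw", provenance=prov)


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write ``expr`` in the same TSV dialect :func:`read_expression` reads.

    Floats are written with 17 significant digits so that a read-back
    round-trips bit-identically.
    """
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def log_transform(expr: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(x + offset) transform of a raw-state matrix."""
    if expr.state != "raw":
        raise ValueError(f"log_transform requires raw state, got {expr.state!r}")
    if offset <= 0:
        raise ValueError("offset must be positive")
    values = np.log2(expr.values + offset)
    return ExpressionMatrix(
        values=values, state="log",
        provenance=expr.provenance + [f"log2(x+{offset:g})"])


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Population z-score of each row across columns; constant rows -> 0."""
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    centered = arr - mean
    z = np.where(sd > 0, centered / np.where(sd == 0, 1.0, sd), 0.0)
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def zscore_vector(x: np.ndarray) -> np.ndarray:
    """Population z-score of a 1-D vector; constant vectors -> all zeros."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def zscore_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score across samples (population standard deviation).

    Constant gene rows become all-zero (their list is logged). Expects a
    log-state matrix; a raw-state input is accepted with a logged warning.
    """
    if expr.state == "zscore":
        raise ValueError("matrix is already z-scored")
    if expr.state == "raw":
        logger.warning("z-scoring a raw-state matrix (no log transform applied)")
    if expr.n_samples < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    arr = expr.values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=0)
    constant = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
    if constant:
        logger.info("%d constant gene rows set to zero: %s",
                    len(constant), constant[:10])
    z = zscore_rows(expr.values)
    return ExpressionMatrix(
        values=z, state="zscore",
        provenance=expr.provenance + ["zscore_genes(population)"])
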