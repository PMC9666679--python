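"""Expression/clinical I-O, gene-symbol mapping, cohort filters, encoder input transform.

Expression files are delimited text with one header row and one identifier
column, either genes-in-rows (the common FPKM export: first column = gene id,
header = sample ids) or samples-in-rows. Internally everything is samples x
genes. Clinical tables carry mandatory ``sample_id``, ``time_days``, ``event``
columns plus optional covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

#: clinical covariates recognised by the Table-1 style comparison
CATEGORICAL_COVARIATES = ("gender", "hsct")
CONTINUOUS_COVARIATES = ("age", "wbc", "ldh", "wt1", "blasts")


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values.

    ``values`` is an (n_samples, n_genes) float array; ``log_scale`` records
    whether values are on a log (True) or linear FPKM (False) scale. Linear
    FPKM values must be non-negative.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.gene_ids, "gene id")
        if not self.log_scale and np.any(self.values < 0):
            raise ValueError("negative FPKM values in linear-scale matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in expression matrix: {missing[:5]}")
        rows = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(sample_ids), list(self.gene_ids), self.values[rows], self.log_scale)


@dataclass
class ClinicalTable:
    """Per-sample survival time (days), event indicator, optional covariates."""

    frame: pd.DataFrame  # index: sample_id; columns: time_days, event, covariates

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("time_days", "event"):
            if col not in df.columns:
                raise ValueError(f"clinical table missing mandatory column {col!r}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in clinical table: {dups[:5]}")
        ev = df["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (death)")
        t = df["time_days"].dropna()
        if (t <= 0).any():
            raise ValueError("survival times must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def time(self) -> np.ndarray:
        return self.frame["time_days"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.frame["event"].to_numpy(dtype=float)

    def subset_samples(self, sample_ids: list[str]) -> "ClinicalTable":
        return ClinicalTable(self.frame.loc[list(sample_ids)].copy())


@dataclass
class GeneIdMap:
    """Source gene id -> official symbol pairs (e.g. a Gencode mapping)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if any(not sym for sym in self.mapping.values()):
            raise ValueError("gene symbols must be non-empty")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneIdMap":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: gene map needs two columns (source_id, symbol)")
        if df[0].duplicated().any():
            dups = df[0][df[0].duplicated()].tolist()
            raise ValueError(f"duplicate source ids in gene map: {dups[:5]}")
        return cls(dict(zip(df[0], df[1])))


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(
    path: str | Path,
    orientation: Literal["genes-in-rows", "samples-in-rows"] = "genes-in-rows",
    log_scale: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression matrix into samples x genes orientation.

    Raises ``ValueError`` naming the offending identifier or cell for
    duplicate ids, non-numeric cells and negative FPKM values.
    """
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]  # pandas mangles duplicates, so check raw
    dup_cols = sorted({h for h in header if header.count(h) > 1})
    if dup_cols:
        raise ValueError(f"{path}: duplicate column identifiers {dup_cols[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row identifiers {dups[:5]}")
    bad = df.columns[df.columns.str.startswith("Unnamed:")]
    if len(bad):
        raise ValueError(f"{path}: malformed header (unnamed columns {list(bad)})")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            rows = df.index[coerced.isna() & df[col].notna()].tolist()
            raise ValueError(f"{path}: non-numeric value in column {col!r}, rows {rows[:5]}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in expression matrix")
    if orientation == "genes-in-rows":
        df = df.T  # now samples x genes
    elif orientation != "samples-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        values=df.to_numpy(dtype=float),
        log_scale=log_scale,
    )


def write_expression_matrix(
    m: ExpressionMatrix,
    path: str | Path,
    orientation: Literal["genes-in-rows", "samples-in-rows"] = "genes-in-rows",
) -> None:
    df = m.to_frame()
    if orientation == "genes-in-rows":
        df = df.T
        df.index.name = "gene_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path))


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical table missing 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups[:5]}")
    return ClinicalTable(df.set_index("sample_id"))


def write_clinical_table(c: ClinicalTable, path: str | Path) -> None:
    df = c.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path))


def map_gene_ids(
    m: ExpressionMatrix,
    gene_map: GeneIdMap,
    collapse: Literal["max-mean", "sum", "first"] = "max-mean",
) -> ExpressionMatrix:
    """Rename source gene ids to official symbols.

    Genes absent from the map are dropped. Several source ids mapping to the
    same symbol are collapsed: ``max-mean`` keeps the source row with the
    highest mean expression, ``sum`` adds the rows, ``first`` keeps the first
    occurrence in file order.
    """
    kept = [(j, gene_map.mapping[g]) for j, g in enumerate(m.gene_ids) if g in gene_map.mapping]
    if not kept:
        raise ValueError("no gene ids overlap the gene-id map")
    by_symbol: dict[str, list[int]] = {}
    for j, sym in kept:
        by_symbol.setdefault(sym, []).append(j)
    symbols: list[str] = []
    cols: list[np.ndarray] = []
    for sym, js in by_symbol.items():
        symbols.append(sym)
        if len(js) == 1:
            cols.append(m.values[:, js[0]])
        elif collapse == "max-mean":
            means = m.values[:, js].mean(axis=0)
            cols.append(m.values[:, js[int(np.argmax(means))]])
        elif collapse == "sum":
            cols.append(m.values[:, js].sum(axis=1))
        elif collapse == "first":
            cols.append(m.values[:, js[0]])
        else:
            raise ValueError(f"unknown collapse rule {collapse!r}")
    return ExpressionMatrix(list(m.sample_ids), symbols, np.column_stack(cols), m.log_scale)


def filter_cohort(c: ClinicalTable, m: ExpressionMatrix) -> tuple[ClinicalTable, ExpressionMatrix]:
    """Drop samples with unknown event status or missing/zero survival time.

    Returns the clinical table and expression matrix restricted to the
    retained samples, in identical order.
    """
    df = c.frame
    ok = df["event"].notna() & df["time_days"].notna() & (df["time_days"] > 0)
    kept = [s for s, keep in zip(df.index, ok) if keep and s in set(m.sample_ids)]
    if not kept:
        raise ValueError("no samples remain after cohort filtering")
    return ClinicalTable(df.loc[kept].copy()), m.subset_samples(kept)


@dataclass
class EncoderInputTransform:
    """Fitted log2(x + pseudocount) + per-gene min-max parameters.

    Stores the training per-gene min and max (on the log scale) so the same
    transform can be applied to new cohorts; a gene missing from a new cohort
    is imputed at its training minimum (transforms to 0), and genes not seen
    in training are dropped because the encoder input dimension is fixed.
    """

    gene_ids: list[str]
    pseudocount: float
    log_min: np.ndarray
    log_max: np.ndarray

    def apply(self, m: ExpressionMatrix) -> ExpressionMatrix:
        if m.log_scale:
            raise ValueError("transform expects a linear-scale FPKM matrix")
        pos = {g: j for j, g in enumerate(m.gene_ids)}
        out = np.zeros((m.n_samples, len(self.gene_ids)))
        denom = np.where(self.log_max > self.log_min, self.log_max - self.log_min, 1.0)
        for k, g in enumerate(self.gene_ids):
            if g in pos:
                logged = np.log2(m.values[:, pos[g]] + self.pseudocount)
            else:
                logged = np.full(m.n_samples, self.log_min[k])
            out[:, k] = (logged - self.log_min[k]) / denom[k]
        return ExpressionMatrix(list(m.sample_ids), list(self.gene_ids), out, log_scale=True)

    def missing_genes(self, m: ExpressionMatrix) -> list[str]:
        have = set(m.gene_ids)
        return [g for g in self.gene_ids if g not in have]


def prepare_encoder_input(
    m: ExpressionMatrix, pseudocount: float = 1.0
) -> tuple[ExpressionMatrix, EncoderInputTransform]:
    """log2(FPKM + pseudocount) then per-gene min-max rescale to [0, 1].

    Parameters are fit on the supplied (training) matrix and returned so the
    identical transform can be applied to external cohorts. Constant genes
    rescale to 0 rather than NaN.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if m.log_scale:
        raise ValueError("prepare_encoder_input expects linear FPKM values")
    logged = np.log2(m.values + pseudocount)
    tr = EncoderInputTransform(
        gene_ids=list(m.gene_ids),
        pseudocount=pseudocount,
        log_min=logged.min(axis=0),
        log_max=logged.max(axis=0),
    )
    return tr.apply(m), tr
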