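"""Expression-matrix containers, I/O, and normalisation for 3' tag count data.

The pipeline operates on gene-by-sample matrices passing through a fixed
sequence of units: raw ``counts`` -> ``CPM`` (counts per million) ->
``logCPM`` (log2(CPM + 1)) -> ``zscore``.  Each transformation is explicit
and tags the result, so downstream stages can assert the unit they expect
instead of silently consuming the wrong scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "CPM", "logCPM", "zscore")


def _check_unique(index: pd.Index, what: str) -> None:
    dup = index[index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate {what} id(s): {', '.join(map(str, dup[:5]))}")


@dataclass(frozen=True)
class CountMatrix:
    """Raw integer counts, genes in rows and samples in columns.

    ``dup_pct``, when available, carries the per-gene percentage of
    duplicated reads reported by the quantification pipeline and is used by
    the QC filter.
    """

    counts: pd.DataFrame
    dup_pct: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        bad = ~(np.isfinite(arr) & (arr >= 0) & (arr == np.floor(arr)))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid count {arr[g, s]!r} at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}: counts must be nonnegative integers"
            )
        if self.dup_pct is not None:
            missing = self.counts.index.difference(self.dup_pct.index)
            if len(missing):
                raise ValueError(
                    f"dup_pct missing for gene(s): {', '.join(map(str, missing[:5]))}"
                )
            vals = self.dup_pct.loc[self.counts.index].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 100)):
                raise ValueError("dup_pct values must lie in [0, 100]")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued gene-by-sample matrix with an explicit unit tag."""

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _infer_sep(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_count_matrix(
    path: str | Path, dup_col: str = "dup_pct", sep: str | None = None
) -> CountMatrix:
    """Read a delimited gene-by-sample count table.

    First column holds gene identifiers, header row holds sample
    identifiers.  A column named ``dup_col`` (if present) is split off as
    the per-gene duplicated-read percentage.
    """
    sep = sep or _infer_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ValueError(f"duplicate sample id(s): {s}")
        seen.add(s)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.columns = samples
    dup = None
    if dup_col in df.columns:
        dup = df.pop(dup_col).astype(float)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric count entry in {path}: {exc}") from exc
    return CountMatrix(df, dup)


def write_count_matrix(m: CountMatrix, path: str | Path, sep: str | None = None) -> None:
    sep = sep or _infer_sep(path)
    out = m.counts.copy()
    if m.dup_pct is not None:
        out["dup_pct"] = m.dup_pct.loc[out.index]
    out.to_csv(path, sep=sep, index_label="gene_id")


def read_expression_matrix(
    path: str | Path, unit: str, sep: str | None = None
) -> ExpressionMatrix:
    sep = sep or _infer_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(df.astype(float), unit)


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, sep: str | None = None
) -> None:
    m.values.to_csv(path, sep=sep or _infer_sep(path), index_label="gene_id")


def cpm_normalize(m: CountMatrix | ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to counts per million (column sums of 1e6).

    Applying it to an already-CPM matrix is a no-op up to floating point,
    since each column is rescaled by its own total.
    """
    values = m.counts if isinstance(m, CountMatrix) else m.values
    totals = values.sum(axis=0)
    zero = totals.index[totals.to_numpy() == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, zero[:5]))}")
    return ExpressionMatrix(values / totals * 1e6, "CPM")


def filter_genes_qc(
    m: ExpressionMatrix,
    dup_pct: pd.Series | None = None,
    cpm_min: float = 5.0,
    dup_max: float = 20.0,
) -> ExpressionMatrix:
    """Drop low-abundance and duplication-heavy genes.

    Genes with mean CPM strictly below ``cpm_min`` are removed, as are genes
    whose duplicated-read percentage strictly exceeds ``dup_max``.  When no
    duplication percentages are available the second criterion is skipped
    with a warning.  Survivor order is preserved.
    """
    if m.unit != "CPM":
        raise ValueError(f"filter_genes_qc expects CPM input, got {m.unit!r}")
    keep = m.values.mean(axis=1) >= cpm_min
    if dup_pct is None:
        warnings.warn(
            "duplicated-read percentages unavailable; skipping the dup_pct filter",
            stacklevel=2,
        )
    else:
        missing = m.values.index.difference(dup_pct.index)
        if len(missing):
            raise ValueError(
                f"dup_pct missing for gene(s): {', '.join(map(str, missing[:5]))}"
            )
        keep &= dup_pct.loc[m.values.index] <= dup_max
    if not keep.any():
        raise ValueError("empty matrix after QC")
    return ExpressionMatrix(m.values.loc[keep], m.unit)


def filter_low_expression(m: ExpressionMatrix, cpm_min: float = 1.0) -> ExpressionMatrix:
    """Remove genes with mean CPM strictly below ``cpm_min`` across samples."""
    if m.unit != "CPM":
        raise ValueError(f"filter_low_expression expects CPM input, got {m.unit!r}")
    keep = m.values.mean(axis=1) >= cpm_min
    if not keep.any():
        raise ValueError("empty matrix after low-expression filtering")
    return ExpressionMatrix(m.values.loc[keep], m.unit)


def read_sample_annotation(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a sample annotation table (columns: sample_id, group, replicate_of)."""
    sep = sep or _infer_sep(path)
    ann = pd.read_csv(path, sep=sep, dtype=str)
    if "sample_id" not in ann.columns:
        raise ValueError("annotation must have a 'sample_id' column")
    _check_unique(pd.Index(ann["sample_id"]), "annotation sample")
    return ann


def average_replicates(m: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Average columns belonging to the same replicate group.

    A sample's group is its ``replicate_of`` key, falling back to its own id
    when blank; output columns appear in order of first appearance.
    """
    ann = annotation.set_index("sample_id")
    missing = m.sample_ids.difference(ann.index)
    if len(missing):
        raise ValueError(
            f"sample(s) without annotation: {', '.join(map(str, missing[:5]))}"
        )
    key = {}
    for s in m.sample_ids:
        rep = ann.at[s, "replicate_of"] if "replicate_of" in ann.columns else None
        key[s] = s if rep is None or (isinstance(rep, float) and np.isnan(rep)) or rep == "" else rep
    groups: dict[str, list[str]] = {}
    for s in m.sample_ids:
        groups.setdefault(key[s], []).append(s)
    out = pd.DataFrame(
        {g: m.values[cols].mean(axis=1) for g, cols in groups.items()},
        index=m.gene_ids,
    )
    return ExpressionMatrix(out, m.unit)


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(CPM + 1), the variance-stabilising transform used before z-scoring."""
    if m.unit != "CPM":
        raise ValueError(f"log2_transform expects CPM input, got {m.unit!r}")
    return ExpressionMatrix(np.log2(m.values + 1.0), "logCPM")


def zscore(m: ExpressionMatrix, axis: str = "gene", ddof: int = 1) -> ExpressionMatrix:
    """Standardise to mean 0 / unit variance along the chosen axis.

    ``axis='gene'`` standardises each gene across samples (the default used
    before GSEA ranking, so that ranks reflect relative rather than absolute
    abundance); ``axis='sample'`` standardises each profile across genes.
    Uses the sample variance (``ddof=1``).  Zero-variance genes are dropped
    with a warning; a zero-variance sample is an error.
    """
    if axis not in ("gene", "sample"):
        raise ValueError("axis must be 'gene' or 'sample'")
    v = m.values
    if axis == "gene":
        if v.shape[1] < 2:
            raise ValueError("z-scoring per gene requires at least 2 samples")
        sd = v.std(axis=1, ddof=ddof)
        flat = sd.index[sd.to_numpy() == 0]
        if len(flat):
            warnings.warn(
                f"dropping {len(flat)} zero-variance gene(s) before z-scoring",
                stacklevel=2,
            )
            v = v.loc[sd > 0]
            sd = sd.loc[sd > 0]
        if v.empty:
            raise ValueError("no genes left after dropping zero-variance rows")
        z = v.sub(v.mean(axis=1), axis=0).div(sd, axis=0)
    else:
        if v.shape[0] < 2:
            raise ValueError("z-scoring per sample requires at least 2 genes")
        sd = v.std(axis=0, ddof=ddof)
        if (sd.to_numpy() == 0).any():
            bad = sd.index[sd.to_numpy() == 0][0]
            raise ValueError(f"sample {bad!r} has zero variance across genes")
        z = v.sub(v.mean(axis=0), axis=1).div(sd, axis=1)
    return ExpressionMatrix(z, "zscore")
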