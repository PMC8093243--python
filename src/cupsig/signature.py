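"""Build a drug-resistance marker signature from a cell-line panel.

The workflow correlates per-gene expression with a continuous drug-response
readout (AUC of the dose-response curve; lower = more sensitive) across a
panel of cancer cell lines, keeps the genes most positively correlated with
AUC (putative resistance markers), labels the response extremes of the
panel, and refines the marker list with recursive feature elimination
driven by linear-SVM weights until the target signature size is reached.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .genesets import GeneSet
from .matrices import ExpressionMatrix, _infer_sep

__all__ = [
    "DrugResponseTable",
    "read_response_table",
    "join_panel",
    "correlate_expression_response",
    "select_top_markers",
    "label_extremes",
    "rfe_svm_select",
    "Signature",
    "build_signature",
]


@dataclass(frozen=True)
class DrugResponseTable:
    """Per-cell-line response: AUC (lower = more sensitive) or IC50 in uM."""

    values: pd.Series
    kind: str  # "auc" | "ic50"

    def __post_init__(self) -> None:
        if self.kind not in ("auc", "ic50"):
            raise ValueError("response kind must be 'auc' or 'ic50'")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate cell line id(s): {', '.join(map(str, dup[:5]))}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("response values must be finite")

    @property
    def lines(self) -> pd.Index:
        return self.values.index


def read_response_table(path: str | Path, sep: str | None = None) -> DrugResponseTable:
    """Read a response CSV with columns ``cell_line`` and ``auc`` or ``ic50_um``."""
    df = pd.read_csv(path, sep=sep or _infer_sep(path))
    if "cell_line" not in df.columns:
        raise ValueError("response table must have a 'cell_line' column")
    has_auc, has_ic50 = "auc" in df.columns, "ic50_um" in df.columns
    if has_auc == has_ic50:
        raise ValueError("response table must have exactly one of 'auc' or 'ic50_um'")
    col, kind = ("auc", "auc") if has_auc else ("ic50_um", "ic50")
    return DrugResponseTable(df.set_index("cell_line")[col].astype(float), kind)


def join_panel(
    expr: ExpressionMatrix, resp: DrugResponseTable, min_shared: int = 10
) -> tuple[ExpressionMatrix, DrugResponseTable]:
    """Restrict both objects to cell lines with expression AND response data."""
    shared = [s for s in expr.sample_ids if s in resp.values.index]
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} cell line(s) shared between expression and response "
            f"(need >= {min_shared})"
        )
    return (
        ExpressionMatrix(expr.values[shared], expr.unit),
        DrugResponseTable(resp.values.loc[shared], resp.kind),
    )


def correlate_expression_response(
    expr: ExpressionMatrix, resp: DrugResponseTable
) -> pd.DataFrame:
    """Pearson correlation of each gene's expression with AUC across lines.

    Returns a frame indexed by gene with columns ``pcc`` and ``n``.
    Zero-variance genes are excluded with a warning.
    """
    if resp.kind != "auc":
        raise ValueError("marker screening requires AUC response values")
    if expr.unit not in ("CPM", "logCPM"):
        raise ValueError(f"expected CPM or logCPM expression, got {expr.unit!r}")
    if not expr.sample_ids.equals(resp.values.index):
        raise ValueError("expression and response must be joined first (join_panel)")
    n = expr.shape[1]
    if n < 3:
        raise ValueError("need at least 3 cell lines to correlate")
    y = resp.values.to_numpy(dtype=float)
    yc = y - y.mean()
    ysd = math.sqrt((yc**2).sum())
    if ysd == 0:
        raise ValueError("degenerate response distribution (constant AUC)")
    X = expr.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    xsd = np.sqrt((Xc**2).sum(axis=1))
    flat = xsd == 0
    if flat.any():
        warnings.warn(
            f"excluding {int(flat.sum())} zero-variance gene(s) from the correlation screen",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = (Xc @ yc) / (xsd * ysd)
    out = pd.DataFrame({"pcc": pcc, "n": n}, index=expr.gene_ids)
    return out.loc[~flat]


def select_top_markers(corr: pd.DataFrame, k: int = 1000) -> list[str]:
    """The k genes with largest PCC, descending; ties broken by gene id."""
    if k > len(corr):
        raise ValueError(f"requested top {k} of only {len(corr)} genes")
    ids = corr.index.to_numpy()
    order = np.lexsort((ids, -corr["pcc"].to_numpy()))
    return list(ids[order][:k])


def label_extremes(
    resp: DrugResponseTable, low_q: float = 0.05, high_q: float = 0.95
) -> pd.Series:
    """Label the response tails: AUC <= 5th percentile -> sensitive,
    AUC >= 95th percentile -> resistant (linear-interpolation quantiles).

    Returns a Series over the tail lines only, values in
    {'sensitive', 'resistant'}.
    """
    if low_q >= high_q:
        raise ValueError("low_q must be below high_q")
    if resp.kind != "auc":
        raise ValueError("extreme labelling requires AUC response values")
    vals = resp.values.astype(float)
    if len(vals) < 20:
        raise ValueError("need at least 20 cell lines to label extremes")
    qlo = float(np.quantile(vals, low_q, method="linear"))
    qhi = float(np.quantile(vals, high_q, method="linear"))
    sens = vals.index[vals <= qlo]
    res = vals.index[vals >= qhi]
    if len(sens.intersection(res)):
        raise ValueError("degenerate response distribution: tails overlap")
    labels = pd.concat(
        [pd.Series("sensitive", index=sens), pd.Series("resistant", index=res)]
    )
    return labels


def _fit_weights(X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    """|weights| of a linear SVM on per-feature standardised data."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant features get weight ~0 and drop out first
    Xs = (X - mu) / sd
    svm = SVC(kernel="linear", C=C, class_weight="balanced")
    svm.fit(Xs, y)
    return np.abs(svm.coef_[0])


@dataclass(frozen=True)
class Signature:
    """Ordered resistance-marker gene list with build provenance."""

    genes: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def as_gene_set(self, name: str = "trametinib_resistance") -> GeneSet:
        return GeneSet(name, self.genes, "drug-resistance marker signature")


def rfe_svm_select(
    expr: ExpressionMatrix,
    labels: pd.Series,
    target: int = 500,
    step_frac: float = 0.10,
    C: float = 1.0,
    seed: int | None = None,
) -> Signature:
    """Recursive feature elimination with a linear SVM.

    Starting from the genes of ``expr`` restricted to the labelled extreme
    lines, repeatedly: standardise features, fit a linear SVM (sensitive vs
    resistant, balanced class weights), rank features by |weight|, and drop
    the lowest ``ceil(step_frac * current)`` (never past ``target``) until
    exactly ``target`` genes remain.  When ``target`` equals the starting
    size the input gene order is returned unchanged.  Ties in |weight| are
    broken by gene id (the lexicographically larger id is eliminated
    first), so the result is invariant to feature order permutations.
    The procedure is deterministic; ``seed`` is recorded as provenance.
    """
    classes = set(labels.unique())
    if classes != {"sensitive", "resistant"}:
        raise ValueError("labels must contain both 'sensitive' and 'resistant' lines")
    missing = labels.index.difference(expr.sample_ids)
    if len(missing):
        raise ValueError(f"labelled line(s) missing from expression: {list(missing[:5])}")
    genes = list(expr.gene_ids)
    if target > len(genes):
        raise ValueError(f"target {target} exceeds {len(genes)} starting features")
    prov = {
        "n_start": len(genes), "target": target, "step_frac": step_frac,
        "C": C, "seed": seed, "n_lines": int(len(labels)),
    }
    if target == len(genes):
        return Signature(tuple(genes), prov)
    Xfull = expr.values[labels.index].T.to_numpy(dtype=float)
    y = (labels == "resistant").astype(int).to_numpy()
    cols = np.arange(len(genes))
    while len(cols) > target:
        w = _fit_weights(Xfull[:, cols], y, C)
        ids = np.array([genes[c] for c in cols])
        # eliminate smallest |w|; among ties the larger gene id goes first
        order = np.lexsort((ids, w))
        n_drop = min(math.ceil(step_frac * len(cols)), len(cols) - target)
        drop_local = set(order[:n_drop])
        # ties spanning the drop boundary: prefer eliminating larger ids
        boundary_w = w[order[n_drop - 1]]
        tied = [i for i in range(len(cols)) if w[i] == boundary_w]
        if len(tied) > 1:
            tied_sorted = sorted(tied, key=lambda i: ids[i], reverse=True)
            n_tied_to_drop = sum(1 for i in order[:n_drop] if w[i] == boundary_w)
            drop_local -= {i for i in tied}
            drop_local |= set(tied_sorted[:n_tied_to_drop])
        keep = np.array([i for i in range(len(cols)) if i not in drop_local])
        cols = cols[keep]
    w = _fit_weights(Xfull[:, cols], y, C)
    ids = np.array([genes[c] for c in cols])
    final_order = np.lexsort((ids, -w))
    return Signature(tuple(ids[final_order]), prov)


def build_signature(
    expr: ExpressionMatrix,
    resp: DrugResponseTable,
    top_k: int = 1000,
    target: int = 500,
    low_q: float = 0.05,
    high_q: float = 0.95,
    step_frac: float = 0.10,
    C: float = 1.0,
    seed: int | None = None,
) -> tuple[Signature, pd.DataFrame, pd.Series]:
    """End-to-end signature construction on a joined (logCPM, AUC) panel.

    Returns the signature, the full correlation table, and the extreme-tail
    labels actually used for RFE.
    """
    expr, resp = join_panel(expr, resp)
    corr = correlate_expression_response(expr, resp)
    top = select_top_markers(corr, k=top_k)
    labels = label_extremes(resp, low_q=low_q, high_q=high_q)
    sub = ExpressionMatrix(expr.values.loc[top, labels.index], expr.unit)
    sig = rfe_svm_select(sub, labels, target=target, step_frac=step_frac, C=C, seed=seed)
    sig.provenance.update({"panel_size": int(expr.shape[1]), "top_k": top_k})
    return sig, corr, labels
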