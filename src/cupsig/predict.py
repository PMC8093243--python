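"""Classify transcriptional profiles as drug-sensitive or -resistant.

A profile is ranked from most to least expressed (z-scores) and the
resistance-marker signature is scored by GSEA: a positive enrichment score
means the resistance markers sit among the most expressed genes (predicted
resistant); a negative score predicts sensitivity.  Calls below the FDR
significance threshold are 'indeterminate'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import gsea
from .genesets import GeneSet
from .matrices import (
    ExpressionMatrix,
    average_replicates,
    filter_low_expression,
    log2_transform,
    zscore,
)
from .signature import DrugResponseTable, Signature

__all__ = [
    "ResponseCall",
    "predict_response",
    "prepare_cohort",
    "predict_cohort",
    "calls_frame",
    "score_calls",
    "validate_panel",
    "ValidationReport",
]


@dataclass(frozen=True)
class ResponseCall:
    sample: str
    call: str  # "sensitive" | "resistant" | "indeterminate"
    es: float
    nes: float
    p: float
    fdr: float
    error: str | None = None


def _as_gene_set(sig) -> GeneSet:
    if isinstance(sig, Signature):
        return sig.as_gene_set()
    if isinstance(sig, GeneSet):
        return sig
    return GeneSet("signature", tuple(sig))


def _call(es: float, fdr: float, threshold: float) -> str:
    if fdr < threshold:
        if es > 0:
            return "resistant"
        if es < 0:
            return "sensitive"
    return "indeterminate"


def predict_response(
    profile: pd.Series,
    signature,
    nperm: int = 1000,
    seed: int | None = None,
    fdr_threshold: float = 0.10,
    weight: float = 1.0,
    sample: str = "sample",
) -> ResponseCall:
    """Call one profile (gene -> z-score) against the resistance signature.

    With a single test the FDR equals the permutation p-value.
    """
    pt = gsea.permutation_null(
        profile, _as_gene_set(signature), nperm=nperm, seed=seed, weight=weight
    )
    return ResponseCall(
        sample, _call(pt.es, pt.p, fdr_threshold), pt.es, pt.nes, pt.p, pt.p
    )


def prepare_cohort(
    m: ExpressionMatrix,
    annotation: pd.DataFrame | None = None,
    cpm_min: float = 1.0,
    log2: bool = True,
) -> ExpressionMatrix:
    """Standard pre-ranking pipeline: average replicates, drop genes with
    mean CPM < ``cpm_min``, log2(CPM+1), then z-score each gene across the
    cohort."""
    if m.unit != "CPM":
        raise ValueError(f"prepare_cohort expects CPM input, got {m.unit!r}")
    if annotation is not None:
        m = average_replicates(m, annotation)
    m = filter_low_expression(m, cpm_min=cpm_min)
    if log2:
        m = log2_transform(m)
    return zscore(m, axis="gene")


def predict_cohort(
    m: ExpressionMatrix,
    signature,
    nperm: int = 1000,
    seed: int | None = None,
    fdr_threshold: float = 0.10,
    weight: float = 1.0,
) -> list[ResponseCall]:
    """Call every sample of a jointly z-scored cohort.

    CPM input is passed through :func:`prepare_cohort` first.  Every sample
    is scored against the same permutation-seed stream, so duplicated
    profiles receive identical calls; FDR is Benjamini-Hochberg across the
    cohort's per-sample p-values (one test per sample for one signature).
    Per-sample failures are returned as flagged rows.
    """
    if m.unit == "CPM":
        m = prepare_cohort(m)
    elif m.unit != "zscore":
        raise ValueError(f"predict_cohort expects CPM or zscore input, got {m.unit!r}")
    gs = _as_gene_set(signature)
    child = np.random.SeedSequence(seed).spawn(1)[0]
    rows: list[tuple[str, gsea.PermutationTest | None, str | None]] = []
    for s in m.sample_ids:
        try:
            pt = gsea.permutation_null(
                m.values[s], gs, nperm=nperm,
                seed=np.random.default_rng(child), weight=weight,
            )
            rows.append((s, pt, None))
        except ValueError as exc:
            rows.append((s, None, str(exc)))
    pvals = [pt.p for _, pt, _ in rows if pt is not None]
    fdrs = iter(multipletests(pvals, method="fdr_bh")[1]) if pvals else iter([])
    calls = []
    for s, pt, err in rows:
        if pt is None:
            calls.append(
                ResponseCall(s, "indeterminate", float("nan"), float("nan"),
                             float("nan"), float("nan"), err)
            )
        else:
            fdr = float(next(fdrs))
            calls.append(
                ResponseCall(s, _call(pt.es, fdr, fdr_threshold), pt.es, pt.nes, pt.p, fdr)
            )
    return calls


def calls_frame(calls: list[ResponseCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "ES": [c.es for c in calls],
            "NES": [c.nes for c in calls],
            "p": [c.p for c in calls],
            "FDR": [c.fdr for c in calls],
            "call": [c.call for c in calls],
            "error": [c.error or "" for c in calls],
        }
    ).set_index("sample")


@dataclass(frozen=True)
class ValidationReport:
    """Confusion counts and per-class accuracies of predicted vs true labels."""

    confusion: pd.DataFrame  # predicted call x truth class
    class_accuracy_pct: dict
    macro_accuracy_pct: float
    ic50_threshold_um: float | None = None


def score_calls(calls: list[ResponseCall], truth: pd.Series) -> ValidationReport:
    """Score calls against truth labels in {'sensitive', 'resistant'}.

    Indeterminate predictions count as incorrect for both classes
    (a conservative, documented choice).  Per-class accuracy is
    correct/total within each truth class; the macro accuracy is the mean
    of the two, in percent.
    """
    truth_classes = ("sensitive", "resistant")
    if not set(truth.unique()) <= set(truth_classes):
        raise ValueError("truth labels must be 'sensitive' or 'resistant'")
    by_sample = {c.sample: c.call for c in calls}
    missing = [s for s in truth.index if s not in by_sample]
    if missing:
        raise ValueError(f"no prediction for line(s): {missing[:5]}")
    pred = pd.Series({s: by_sample[s] for s in truth.index})
    conf = pd.crosstab(pred, truth.loc[pred.index]).reindex(
        index=["sensitive", "resistant", "indeterminate"],
        columns=list(truth_classes), fill_value=0,
    )
    acc = {}
    for cls in truth_classes:
        total = int(conf[cls].sum())
        if total == 0:
            raise ValueError(f"truth class {cls!r} is empty")
        acc[cls] = 100.0 * int(conf.at[cls, cls]) / total
    macro = float(np.mean([acc[c] for c in truth_classes]))
    return ValidationReport(conf, acc, macro)


def validate_panel(
    m: ExpressionMatrix,
    signature,
    resp: DrugResponseTable,
    threshold_um: float = 1.0,
    nperm: int = 1000,
    seed: int | None = None,
    fdr_threshold: float = 0.10,
    weight: float = 1.0,
) -> ValidationReport:
    """Validate the signature on a labelled panel.

    Truth: a line is sensitive if its IC50 is strictly below
    ``threshold_um`` (in uM), resistant otherwise.  Predictions come from
    :func:`predict_cohort` on the panel.
    """
    if resp.kind != "ic50":
        raise ValueError("validation truth labels require IC50 response values")
    lines = [s for s in m.sample_ids if s in resp.values.index]
    miss = resp.values.index.difference(m.sample_ids)
    if len(miss):
        raise ValueError(f"line(s) without expression profile: {list(miss[:5])}")
    truth = pd.Series(
        np.where(resp.values.loc[lines] < threshold_um, "sensitive", "resistant"),
        index=pd.Index(lines, name="cell_line"),
    )
    calls = predict_cohort(
        m, signature, nperm=nperm, seed=seed, fdr_threshold=fdr_threshold, weight=weight
    )
    report = score_calls([c for c in calls if c.sample in set(lines)], truth)
    return ValidationReport(
        report.confusion, report.class_accuracy_pct, report.macro_accuracy_pct,
        ic50_threshold_um=threshold_um,
    )
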