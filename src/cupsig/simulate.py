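"""Synthetic data generators for every pipeline stage.

The generators are pure functions of their parameters and seed, and emulate
the statistical structure each stage assumes:

* a cell-line panel in which a latent per-line resistance score drives both
  the expression of planted marker genes (on the log2 scale) and the drug
  AUC readout;
* cohort profiles with a signature shifted up or down on the z-score scale;
* limiting-dilution well outcomes under the single-hit Poisson model.

They make no attempt to mimic real gene-gene correlation structure, batch
effects, negative-binomial dispersion, or FFPE degradation; they exist so
the marker-discovery, enrichment-calling, and frequency-estimation
machinery can be exercised against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genesets import GeneSet
from .matrices import CountMatrix, ExpressionMatrix
from .assays import LimitingDilutionExperiment
from .signature import DrugResponseTable

__all__ = [
    "PanelTruth",
    "simulate_ccl_panel",
    "simulate_cohort",
    "simulate_lda",
]


@dataclass(frozen=True)
class PanelTruth:
    """Ground truth of a simulated panel: planted markers, latent scores,
    and the generative parameters, recorded verbatim."""

    markers: tuple[str, ...]
    latent: pd.Series
    params: dict


def simulate_ccl_panel(
    n_lines: int = 300,
    n_genes: int = 2000,
    n_markers: int = 100,
    beta: float = 1.0,
    gamma: float = 1.0,
    noise_sd: float = 0.5,
    auc_baseline: float = 10.0,
    library_size: int = 1_000_000,
    seed: int | None = None,
    markers: tuple[str, ...] | None = None,
) -> tuple[CountMatrix, DrugResponseTable, PanelTruth]:
    """Simulate a cell-line expression/response panel with planted markers.

    Per line i, a latent resistance score r_i ~ N(0,1) raises the log2
    expression of marker genes by ``beta * r_i`` and the response AUC by
    ``gamma * r_i`` (higher AUC = more resistant); both get independent
    Gaussian noise of sd ``noise_sd``.  Baseline log2 abundances are
    mu_g ~ N(5, 2).  Counts are multinomial draws of ``library_size`` reads
    per line over the 2^(log2 expression) abundance profile.

    ``markers`` fixes the planted marker gene ids (so an independent
    held-out panel can share the generative process of a training panel);
    by default a random subset of ``n_markers`` genes is drawn.
    """
    if not 0 < n_markers < n_genes:
        raise ValueError("need 0 < n_markers < n_genes")
    if n_lines < 2:
        raise ValueError("need at least 2 cell lines")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    lines = [f"CL{i:04d}" for i in range(1, n_lines + 1)]
    if markers is None:
        markers = tuple(sorted(rng.choice(genes, size=n_markers, replace=False)))
    else:
        markers = tuple(markers)
        if not set(markers) <= set(genes):
            raise ValueError("specified markers must be a subset of the gene universe")
        if len(markers) != n_markers:
            n_markers = len(markers)
    marker_mask = np.isin(genes, markers)
    mu = rng.normal(5.0, 2.0, size=n_genes)
    r = rng.normal(0.0, 1.0, size=n_lines)
    log2_expr = (
        mu[:, None]
        + beta * marker_mask[:, None] * r[None, :]
        + rng.normal(0.0, noise_sd, size=(n_genes, n_lines))
    )
    abundance = 2.0 ** log2_expr
    counts = np.empty((n_genes, n_lines), dtype=np.int64)
    for i in range(n_lines):
        p = abundance[:, i] / abundance[:, i].sum()
        counts[:, i] = rng.multinomial(library_size, p)
    auc = auc_baseline + gamma * r + rng.normal(0.0, noise_sd, size=n_lines)
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=lines))
    resp = DrugResponseTable(pd.Series(auc, index=pd.Index(lines, name="cell_line")), "auc")
    truth = PanelTruth(
        markers,
        pd.Series(r, index=lines),
        {
            "n_lines": n_lines, "n_genes": n_genes, "n_markers": n_markers,
            "beta": beta, "gamma": gamma, "noise_sd": noise_sd,
            "auc_baseline": auc_baseline, "library_size": library_size, "seed": seed,
        },
    )
    return cm, resp, truth


def simulate_cohort(
    directions: dict[str, str] | list[str],
    signature: GeneSet,
    gene_ids: list[str],
    effect: float = 2.0,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Simulate z-scored cohort profiles with a planted signature shift.

    ``directions`` maps sample id -> 'up' | 'down' | 'null' (a list gets
    auto-named samples S001..).  Baseline values are standard normal;
    signature genes are shifted by +effect ('up'), -effect ('down'), or
    left untouched ('null').
    """
    if isinstance(directions, list):
        directions = {f"S{i:03d}": d for i, d in enumerate(directions, start=1)}
    bad = {d for d in directions.values() if d not in ("up", "down", "null")}
    if bad:
        raise ValueError(f"unknown direction(s): {sorted(bad)}")
    missing = set(signature.members) - set(gene_ids)
    if missing:
        raise ValueError(
            f"signature gene(s) outside the gene universe: {sorted(missing)[:5]}"
        )
    rng = np.random.default_rng(seed)
    samples = list(directions)
    values = rng.normal(0.0, 1.0, size=(len(gene_ids), len(samples)))
    sig_mask = np.isin(gene_ids, list(signature.members))
    for j, s in enumerate(samples):
        if directions[s] == "up":
            values[sig_mask, j] += effect
        elif directions[s] == "down":
            values[sig_mask, j] -= effect
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=samples), "zscore"
    )


def simulate_lda(
    f: float,
    doses: list[int],
    wells_per_dose: int = 24,
    seed: int | None = None,
) -> LimitingDilutionExperiment:
    """Simulate limiting-dilution outcomes under the single-hit model:
    positive wells ~ Binomial(wells, 1 - exp(-f * dose)) per dose."""
    if not 0 <= f <= 1:
        raise ValueError("frequency f must lie in [0, 1]")
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    p = 1.0 - np.exp(-f * np.asarray(doses, dtype=float))
    positive = rng.binomial(wells_per_dose, p)
    return LimitingDilutionExperiment(
        pd.DataFrame(
            {"dose": doses, "tested": wells_per_dose, "positive": positive}
        )
    )
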