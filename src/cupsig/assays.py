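"""Quantitative assay statistics: limiting dilution, qPCR copy number,
tumor growth, and viability normalisation.

The limiting-dilution model is the single-hit Poisson model: a well seeded
with n cells is positive (grows a sphere / a tumor) with probability
1 - exp(-f n), where f is the frequency of clonogenic (or tumor-initiating)
cells.  The maximum-likelihood fit is an intercept-only binomial GLM with a
complementary log-log link and offset log n; the Wald 95% interval is
formed on the log-frequency scale and exponentiated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LimitingDilutionExperiment",
    "FrequencyEstimate",
    "lda_frequency",
    "compare_frequencies",
    "tumor_volume",
    "fold_change_series",
    "viability_fold_change",
    "cnv_ratio",
    "cnv_call_from_ratio",
    "cnv_call",
    "CnvResult",
]


@dataclass(frozen=True)
class LimitingDilutionExperiment:
    """Plate rows: cells per well (dose), wells tested, wells positive."""

    rows: pd.DataFrame  # columns: dose, tested, positive

    def __post_init__(self) -> None:
        need = {"dose", "tested", "positive"}
        if not need <= set(self.rows.columns):
            raise ValueError(f"plate table needs columns {sorted(need)}")
        if len(self.rows) == 0:
            raise ValueError("plate table is empty")
        r = self.rows
        if (r["dose"] <= 0).any():
            raise ValueError("doses must be positive")
        if (r["tested"] <= 0).any():
            raise ValueError("tested well counts must be positive")
        if ((r["positive"] < 0) | (r["positive"] > r["tested"])).any():
            raise ValueError("positive wells must satisfy 0 <= positive <= tested")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LimitingDilutionExperiment":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class FrequencyEstimate:
    """Clonogenic / tumor-initiating cell frequency with a 95% CI."""

    frequency: float
    ci_low: float
    ci_high: float
    flags: tuple[str, ...] = ()

    @property
    def percent(self) -> float:
        return 100.0 * self.frequency

    @property
    def one_in(self) -> float:
        return math.inf if self.frequency == 0 else 1.0 / self.frequency


def _loglik(f: float, dose, tested, positive) -> float:
    """Binomial log-likelihood of the single-hit model (constants dropped)."""
    dose = np.asarray(dose, dtype=float)
    tested = np.asarray(tested, dtype=float)
    positive = np.asarray(positive, dtype=float)
    q = -f * dose  # log P(well negative)
    p = -np.expm1(q)
    p = np.clip(p, 1e-300, 1.0)
    return float(np.sum(positive * np.log(p) + (tested - positive) * q))


def _fit_glm(rows: pd.DataFrame) -> tuple[float, float]:
    """Intercept and its standard error from the cloglog binomial GLM."""
    endog = rows[["positive"]].assign(neg=rows["tested"] - rows["positive"]).to_numpy()
    exog = np.ones((len(rows), 1))
    offset = np.log(rows["dose"].to_numpy(dtype=float))
    model = sm.GLM(
        endog, exog,
        family=sm.families.Binomial(link=sm.families.links.CLogLog()),
        offset=offset,
    )
    # intercept-only fits on one dose have zero residual df; the IRLS scale
    # bookkeeping then divides by zero, which is irrelevant to the MLE
    with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit()
    return float(res.params[0]), float(res.bse[0])


def lda_frequency(x: LimitingDilutionExperiment, alpha: float = 0.05) -> FrequencyEstimate:
    """Estimate the single-hit frequency from limiting-dilution outcomes.

    All-negative plates return a zero point estimate with a one-sided upper
    bound (flagged); all-positive plates leave the frequency unbounded and
    raise.
    """
    r = x.rows
    if (r["positive"] == r["tested"]).all():
        raise ValueError(
            "frequency unbounded: every well positive at every dose"
        )
    if (r["positive"] == 0).all():
        total_cells = float((r["tested"] * r["dose"]).sum())
        upper = -math.log(alpha) / total_cells
        return FrequencyEstimate(0.0, 0.0, upper, flags=("all_negative",))
    b, se = _fit_glm(r)
    z = stats.norm.ppf(1 - alpha / 2)
    f = math.exp(b)
    return FrequencyEstimate(f, math.exp(b - z * se), math.exp(b + z * se))


def compare_frequencies(
    a: LimitingDilutionExperiment, b: LimitingDilutionExperiment
) -> tuple[float, float]:
    """Likelihood-ratio test (1 df) of equal vs separate frequencies.

    Returns (chi-square statistic, p-value); symmetric in its arguments.
    """
    for x in (a, b):
        r = x.rows
        if (r["positive"] == r["tested"]).all() or (r["positive"] == 0).all():
            raise ValueError("cannot compare boundary fits (all wells positive or negative)")
    fa = lda_frequency(a).frequency
    fb = lda_frequency(b).frequency
    pooled = LimitingDilutionExperiment(
        pd.concat([a.rows, b.rows], ignore_index=True)
    )
    fp = lda_frequency(pooled).frequency
    ll_sep = (
        _loglik(fa, a.rows["dose"], a.rows["tested"], a.rows["positive"])
        + _loglik(fb, b.rows["dose"], b.rows["tested"], b.rows["positive"])
    )
    ll_pool = _loglik(fp, pooled.rows["dose"], pooled.rows["tested"], pooled.rows["positive"])
    stat = max(0.0, 2.0 * (ll_sep - ll_pool))
    return stat, float(stats.chi2.sf(stat, df=1))


def tumor_volume(d: float, D: float) -> float:
    """Caliper volume in mm^3 from minor axis d and major axis D: d^2 * D / 2."""
    if d <= 0 or D <= 0:
        raise ValueError("tumor axes must be positive")
    if d > D:
        warnings.warn("minor axis exceeds major axis; swapping", stacklevel=2)
        d, D = D, d
    return d * d * D / 2.0


def fold_change_series(volumes: Sequence[float], baseline_index: int = 0) -> np.ndarray:
    """Per-animal growth expressed as fold change vs the baseline timepoint."""
    v = np.asarray(volumes, dtype=float)
    baseline = v[baseline_index]
    if baseline <= 0:
        raise ValueError("baseline volume must be positive")
    return v / baseline


def viability_fold_change(
    treated: Sequence[float],
    control: Sequence[float],
    min_replicates: int = 6,
) -> float:
    """Mean treated luminescence normalised to the untreated control mean."""
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if len(t) < min_replicates or len(c) < min_replicates:
        warnings.warn(
            f"fewer than {min_replicates} technical replicates", stacklevel=2
        )
    if c.mean() <= 0:
        raise ValueError("control mean must be positive")
    return float(t.mean() / c.mean())


def cnv_ratio(
    ct_target_sample: float,
    ct_norm_sample: float,
    ct_target_calibrator: float,
    ct_norm_calibrator: float,
) -> tuple[float, float]:
    """2^-ddCt relative copy number of a target gene vs a normaliser gene.

    ddCt = (Ct_target,sample - Ct_norm,sample)
         - (Ct_target,calibrator - Ct_norm,calibrator).
    Returns (ddCt, ratio); ratio 1 indicates biallelic content.
    """
    cts = (ct_target_sample, ct_norm_sample, ct_target_calibrator, ct_norm_calibrator)
    for ct in cts:
        if ct is None or not math.isfinite(ct) or ct <= 0:
            raise ValueError("all four Ct values must be finite and positive")
    ddct = (ct_target_sample - ct_norm_sample) - (ct_target_calibrator - ct_norm_calibrator)
    return ddct, 2.0 ** (-ddct)


def cnv_call_from_ratio(ratio: float, loss_threshold: float = 0.7) -> str:
    """'loss' iff the copy-number ratio is strictly below the threshold."""
    return "loss" if ratio < loss_threshold else "neutral"


@dataclass(frozen=True)
class CnvResult:
    ddct: float
    ratio: float
    call: str


def cnv_call(
    ct_target_sample: float,
    ct_norm_sample: float,
    ct_target_calibrator: float,
    ct_norm_calibrator: float,
    loss_threshold: float = 0.7,
) -> CnvResult:
    """Copy-number call from four Ct values via the 2^-ddCt method."""
    ddct, ratio = cnv_ratio(
        ct_target_sample, ct_norm_sample, ct_target_calibrator, ct_norm_calibrator
    )
    return CnvResult(ddct, ratio, cnv_call_from_ratio(ratio, loss_threshold))
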