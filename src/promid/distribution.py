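"""Distribution-based MID comparators: 0.3 SD, 0.5 SD and SEM at baseline.

All three are computed on the scale-score distribution at t1 (the first
assessment, before or on the first day of treatment).  The SEM needs a
reliability coefficient; Cronbach's alpha at t1 is used for multi-item scales
when item responses are available, and a t1-to-t2 stability correlation among
anchor-stable patients otherwise (the proxy choice is recorded per scale).
Distribution-based values are comparators only and never gate anchor-based
retention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import AnchorDefinition, LongTable, ScaleDefinition
from .exceptions import EstimationError


@dataclass(frozen=True)
class DistributionEstimates:
    scale_code: str
    sd_baseline: float
    est_03sd: float
    est_05sd: float
    sem: float
    reliability: float
    reliability_source: str  # "cronbach_alpha" | "stability_proxy"
    n_baseline: int


def _baseline_rows(table: LongTable) -> pd.DataFrame:
    df = table.data
    first = df.groupby("patient_id")["time_rank"].transform("min")
    return df[df["time_rank"] == first]


def baseline_sd(table: LongTable, scale: str) -> float:
    """Sample SD (n-1 denominator) of the scale score at each patient's t1."""
    scores = _baseline_rows(table)[scale].dropna()
    if len(scores) < 2:
        raise EstimationError(
            f"baseline SD for {scale!r} needs >= 2 observations, got {len(scores)}"
        )
    return float(scores.std(ddof=1))


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha over complete-case rows of an items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the item sum).
    Undefined for single-item scales (callers fall back to the stability
    proxy).
    """
    items = items.dropna()
    k = items.shape[1]
    if k < 2:
        raise EstimationError("alpha undefined for a single-item scale")
    if len(items) < 2:
        raise EstimationError("alpha needs >= 2 complete-case patients")
    item_vars = items.var(ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise EstimationError("alpha undefined: zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def stability_reliability(
    table: LongTable, scale: str, anchor: AnchorDefinition
) -> float:
    """t1-to-t2 score correlation among patients whose anchor is stable.

    A test-retest stand-in for single-item scales: restricting to anchor-stable
    patients over the first pair of assessments approximates measuring an
    unchanged construct twice.  Clipped into [0, 1].
    """
    df = table.data
    t1 = df[df["time_rank"] == 1][["patient_id", scale, anchor.code]]
    t2 = df[df["time_rank"] == 2][["patient_id", scale, anchor.code]]
    merged = t1.merge(t2, on="patient_id", suffixes=("_1", "_2")).dropna()
    stable = merged[merged[f"{anchor.code}_1"] == merged[f"{anchor.code}_2"]]
    if len(stable) < 3:
        raise EstimationError(
            f"stability proxy for {scale!r} needs >= 3 anchor-stable patients"
        )
    r = np.corrcoef(stable[f"{scale}_1"], stable[f"{scale}_2"])[0, 1]
    if not np.isfinite(r):
        raise EstimationError(f"stability proxy for {scale!r} is undefined (zero variance)")
    return float(np.clip(r, 0.0, 1.0))


def sem(sd_baseline: float, reliability: float) -> float:
    """Standard error of measurement: SD * sqrt(1 - reliability)."""
    if not 0.0 <= reliability <= 1.0:
        raise EstimationError(f"reliability {reliability!r} outside [0, 1]")
    return float(sd_baseline * np.sqrt(1.0 - reliability))


def distribution_estimates(
    table: LongTable,
    scale: str,
    sdef: ScaleDefinition | None = None,
    anchor: AnchorDefinition | None = None,
) -> DistributionEstimates:
    """0.3 SD / 0.5 SD / SEM triple for one scale at baseline.

    Reliability comes from Cronbach's alpha when ``sdef`` names >= 2 items all
    present in the table; otherwise from the stability proxy, which needs an
    ``anchor``.
    """
    base = _baseline_rows(table)
    scores = base[scale].dropna()
    sd = baseline_sd(table, scale)
    reliability = None
    source = ""
    if sdef is not None and sdef.n_items >= 2 and all(
        c in table.data.columns for c in sdef.item_codes
    ):
        try:
            reliability = cronbach_alpha(base[list(sdef.item_codes)])
            reliability = float(np.clip(reliability, 0.0, 1.0))
            source = "cronbach_alpha"
        except EstimationError:
            reliability = None
    if reliability is None:
        if anchor is None:
            raise EstimationError(
                f"no reliability source for {scale!r}: items unavailable and no anchor "
                "given for the stability proxy"
            )
        reliability = stability_reliability(table, scale, anchor)
        source = "stability_proxy"
    return DistributionEstimates(
        scale_code=scale,
        sd_baseline=sd,
        est_03sd=0.3 * sd,
        est_05sd=0.5 * sd,
        sem=sem(sd, reliability),
        reliability=reliability,
        reliability_source=source,
        n_baseline=int(len(scores)),
    )
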