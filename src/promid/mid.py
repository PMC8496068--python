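"""Anchor-based MID estimation.

Within-group MIDs use the mean-change method: the mean HRQOL change score of
the records in the improved (or deteriorated) CCG.  Between-group MIDs are the
CCG-indicator coefficient of a linear model of change score on improved-vs-
stable (or deteriorated-vs-stable), estimated by GEE with patient-level
clusters and robust sandwich standard errors, since patients contribute
multiple change records.  The effect size (mean change divided by the SD of
all change scores) gates retention: only 0.2 <= |ES| < 0.8 is considered an
appropriate MID.  Excluded records (|anchor change| >= 2) never enter any
estimate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Exchangeable, Independence
from statsmodels.genmod.generalized_estimating_equations import GEE

from .changes import CCG_DETERIORATED, CCG_EXCLUDED, CCG_IMPROVED, CCG_STABLE
from .exceptions import EstimationError

ES_LOWER = 0.2   # inclusive: the footnote convention excludes only ES < 0.2
ES_UPPER = 0.8   # exclusive: ES >= 0.8 counts as large, outside the MID band
INTERACTION_ALPHA = 0.01  # 1% level for the trial-heterogeneity test

_DIRECTION_TO_CCG = {"improvement": CCG_IMPROVED, "deterioration": CCG_DETERIORATED}


@dataclass(frozen=True)
class MIDEstimate:
    scale_code: str
    anchor_code: str
    direction: str  # "improvement" | "deterioration"
    kind: str  # "within_group" | "between_group"
    mid: float
    se: float
    n_records: int
    n_patients: int
    es: float
    retained: bool
    trial_interaction_p: float | None = None
    reason: str = ""


@dataclass(frozen=True)
class InteractionTest:
    """Robust Wald test of CCG-indicator x trial interaction."""

    p_value: float | None
    flagged: bool
    n_trials: int
    reason: str = ""


def _nonexcluded(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["ccg"] != CCG_EXCLUDED]


def _target_label(direction: str) -> str:
    try:
        return _DIRECTION_TO_CCG[direction]
    except KeyError:
        raise ValueError(f"direction must be 'improvement' or 'deterioration', got {direction!r}")


def _codes(records: pd.DataFrame) -> tuple[str, str]:
    scale = records["scale_code"].iloc[0] if len(records) else ""
    anchor = records["anchor_code"].iloc[0] if len(records) else ""
    return str(scale), str(anchor)


def _cluster_se_of_mean(y: np.ndarray, clusters: np.ndarray) -> float:
    """Cluster-robust (patient-level) standard error of a plain mean."""
    resid = pd.Series(y - y.mean()).groupby(pd.Series(clusters)).sum()
    return float(np.sqrt((resid.to_numpy() ** 2).sum()) / y.size)


def effect_size(records: pd.DataFrame, direction: str) -> float:
    """Mean change in the target CCG divided by the SD of all change scores.

    "All" change scores means every non-excluded record of the (scale, anchor)
    pair across all timepoint pairs, not just the target CCG's.
    """
    label = _target_label(direction)
    usable = _nonexcluded(records)
    target = usable[usable["ccg"] == label]
    if target.empty:
        raise EstimationError(f"no MID: absence of records in the {label} group")
    sd_all = usable["hrqol_change"].std(ddof=1)
    if not np.isfinite(sd_all) or sd_all == 0:
        raise EstimationError("no MID: change scores have zero variance")
    return float(target["hrqol_change"].mean() / sd_all)


def within_group_mid(records: pd.DataFrame, direction: str) -> MIDEstimate:
    """Mean-change within-group MID for one (scale, anchor, direction)."""
    label = _target_label(direction)
    usable = _nonexcluded(records)
    sub = usable[usable["ccg"] == label]
    if len(sub) < 2:
        raise EstimationError(
            f"no MID: absence of records in the {label} group (n={len(sub)})"
        )
    y = sub["hrqol_change"].to_numpy(dtype=float)
    mid = float(y.mean())
    es = effect_size(records, direction)
    est = MIDEstimate(
        scale_code=_codes(records)[0],
        anchor_code=_codes(records)[1],
        direction=direction,
        kind="within_group",
        mid=mid,
        se=_cluster_se_of_mean(y, sub["patient_id"].to_numpy()),
        n_records=len(sub),
        n_patients=int(sub["patient_id"].nunique()),
        es=es,
        retained=False,
    )
    return apply_es_filter(est)


def _fit_gee(endog, exog, groups, working_correlation: str):
    cov = Exchangeable() if working_correlation == "exchangeable" else Independence()
    model = GEE(endog, exog, groups=groups, cov_struct=cov, family=sm.families.Gaussian())
    return model.fit(maxiter=100)


def between_group_mid(
    records: pd.DataFrame,
    direction: str,
    *,
    working_correlation: str = "exchangeable",
    within_es: float | None = None,
) -> MIDEstimate:
    """GEE-corrected between-group MID: target CCG vs stable contrast.

    The model is hrqol_change ~ intercept + 1{target CCG} over the records of
    the two CCGs, with patient-level clusters and robust SEs; the MID is the
    indicator coefficient.  The estimate inherits the within-group ES gate
    (pass ``within_es``); with independence working correlation and one record
    per patient it reduces exactly to the two-sample mean difference.
    """
    label = _target_label(direction)
    usable = _nonexcluded(records)
    sub = usable[usable["ccg"].isin([label, CCG_STABLE])].copy()
    n_target = int((sub["ccg"] == label).sum())
    n_stable = int((sub["ccg"] == CCG_STABLE).sum())
    if n_target == 0 or n_stable == 0:
        raise EstimationError(
            f"no MID: absence of records ({label}: {n_target}, stable: {n_stable})"
        )
    indicator = (sub["ccg"] == label).to_numpy(dtype=float)
    exog = np.column_stack([np.ones(len(sub)), indicator])
    res = _fit_gee(
        sub["hrqol_change"].to_numpy(dtype=float),
        exog,
        sub["patient_id"].to_numpy(),
        working_correlation,
    )
    es = within_es if within_es is not None else effect_size(records, direction)
    est = MIDEstimate(
        scale_code=_codes(records)[0],
        anchor_code=_codes(records)[1],
        direction=direction,
        kind="between_group",
        mid=float(res.params[1]),
        se=float(res.bse[1]),
        n_records=len(sub),
        n_patients=int(sub["patient_id"].nunique()),
        es=float(es),
        retained=False,
    )
    return apply_es_filter(est)


def trial_interaction_test(
    records: pd.DataFrame,
    direction: str,
    *,
    working_correlation: str = "exchangeable",
    alpha: float = INTERACTION_ALPHA,
) -> InteractionTest:
    """Test whether the between-group MID differs by trial.

    Extends the between-group GEE model with trial main effects and
    (CCG-indicator x trial) interactions and returns the robust Wald p-value
    of the interaction block; heterogeneity is flagged at the 1% level (the
    stringent level compensates for testing across many scales).
    """
    label = _target_label(direction)
    usable = _nonexcluded(records)
    sub = usable[usable["ccg"].isin([label, CCG_STABLE])].copy()
    trials = sorted(sub["trial_id"].unique())
    if len(trials) < 2:
        return InteractionTest(None, False, len(trials), reason="single-trial data")
    if (sub["ccg"] == label).sum() == 0 or (sub["ccg"] == CCG_STABLE).sum() == 0:
        return InteractionTest(None, False, len(trials), reason="empty change group")
    indicator = (sub["ccg"] == label).to_numpy(dtype=float)
    cols = [np.ones(len(sub)), indicator]
    for t in trials[1:]:
        d = (sub["trial_id"] == t).to_numpy(dtype=float)
        cols.append(d)
        cols.append(indicator * d)
    exog = np.column_stack(cols)
    res = _fit_gee(
        sub["hrqol_change"].to_numpy(dtype=float),
        exog,
        sub["patient_id"].to_numpy(),
        working_correlation,
    )
    p = exog.shape[1]
    inter_idx = list(range(3, p, 2))  # every interaction column
    r_matrix = np.eye(p)[inter_idx]
    wt = res.wald_test(r_matrix, scalar=True)
    p_value = float(np.squeeze(wt.pvalue))
    return InteractionTest(p_value=p_value, flagged=p_value < alpha, n_trials=len(trials))


def apply_es_filter(
    estimate: MIDEstimate,
    lower: float = ES_LOWER,
    upper: float = ES_UPPER,
) -> MIDEstimate:
    """Set the retention flag: retained iff lower <= |ES| < upper.

    The lower bound is inclusive (only ES < 0.2 is dismissed as trivial) and
    the upper bound exclusive (|ES| >= 0.8 marks more-than-minimal change).
    """
    ok = np.isfinite(estimate.es) and lower <= abs(estimate.es) < upper
    reason = estimate.reason
    if not ok and np.isfinite(estimate.es):
        cmp = "<" if abs(estimate.es) < lower else ">="
        bound = lower if abs(estimate.es) < lower else upper
        reason = f"no MID: |ES| = {abs(estimate.es):.2f} {cmp} {bound}"
    return dataclasses.replace(estimate, retained=bool(ok), reason=reason)
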