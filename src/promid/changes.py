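"""Pairwise change records and clinical change groups (CCGs).

Each record is one (patient, timepoint-pair) observation of an HRQOL change
score together with the anchor grade change over the same pair.  The anchor
change is sign-adjusted so that +1 always means health improved by one
category.  CCG labels: improved (+1), stable (0), deteriorated (-1); pairs
changing by two or more categories changed more than minimally and are
excluded from MID estimation.

Records, not patients, are the analysis unit: a patient legitimately
contributes records to several CCGs and several records to one CCG, which is
why GEE with patient-level clustering is used downstream.  Intermittent
missing assessments are handled by treating each pair independently: a pair
enters iff both ends carry a score and a grade.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import AnchorDefinition, LongTable

CCG_IMPROVED = "improved"
CCG_STABLE = "stable"
CCG_DETERIORATED = "deteriorated"
CCG_EXCLUDED = "excluded"
CCG_LABELS = (CCG_IMPROVED, CCG_STABLE, CCG_DETERIORATED, CCG_EXCLUDED)

RECORD_COLUMNS = (
    "patient_id",
    "trial_id",
    "scale_code",
    "anchor_code",
    "time_from",
    "time_to",
    "score_from",
    "score_to",
    "hrqol_change",
    "anchor_change",
    "ccg",
)


def classify_anchor_change(anchor_change: np.ndarray) -> np.ndarray:
    """Map sign-adjusted anchor changes onto CCG labels."""
    ac = np.asarray(anchor_change)
    return np.select(
        [ac == 1, ac == 0, ac == -1],
        [CCG_IMPROVED, CCG_STABLE, CCG_DETERIORATED],
        default=CCG_EXCLUDED,
    )


def make_change_records(
    table: LongTable,
    scale: str,
    anchor: AnchorDefinition,
    pairing: str = "all_pairs",
) -> pd.DataFrame:
    """Build change records for one (scale, anchor) pair.

    Parameters
    ----------
    pairing : {"all_pairs", "consecutive"}
        ``all_pairs`` (default) forms every ordered pair i < j of a patient's
        complete assessments; ``consecutive`` keeps only adjacent complete
        assessments, offered for sensitivity analysis.

    Returns
    -------
    DataFrame with :data:`RECORD_COLUMNS`;  ``.attrs["n_pairs_skipped"]``
    counts the pairs lost to missing scores or grades.
    """
    if pairing not in ("all_pairs", "consecutive"):
        raise ValueError(f"unknown pairing {pairing!r}")
    cols = ["patient_id", "trial_id", "timepoint", "time_rank", scale, anchor.code]
    df = table.data[cols]
    complete = df.dropna(subset=[scale, anchor.code]).copy()
    complete = complete.sort_values(["patient_id", "time_rank"], kind="mergesort")
    complete["obs_idx"] = complete.groupby("patient_id").cumcount()

    left = complete.rename(
        columns={
            "timepoint": "time_from",
            "time_rank": "rank_from",
            scale: "score_from",
            anchor.code: "grade_from",
            "obs_idx": "obs_from",
        }
    )
    right = complete.drop(columns="trial_id").rename(
        columns={
            "timepoint": "time_to",
            "time_rank": "rank_to",
            scale: "score_to",
            anchor.code: "grade_to",
            "obs_idx": "obs_to",
        }
    )
    pairs = left.merge(right, on="patient_id")
    pairs = pairs[pairs["rank_from"] < pairs["rank_to"]]
    if pairing == "consecutive":
        pairs = pairs[pairs["obs_to"] == pairs["obs_from"] + 1]

    records = pd.DataFrame(
        {
            "patient_id": pairs["patient_id"].to_numpy(),
            "trial_id": pairs["trial_id"].to_numpy(),
            "scale_code": scale,
            "anchor_code": anchor.code,
            "time_from": pairs["time_from"].to_numpy(),
            "time_to": pairs["time_to"].to_numpy(),
            "score_from": pairs["score_from"].to_numpy(),
            "score_to": pairs["score_to"].to_numpy(),
            "hrqol_change": (pairs["score_to"] - pairs["score_from"]).to_numpy(),
            "anchor_change": (
                anchor.worse_direction * (pairs["grade_from"] - pairs["grade_to"])
            ).to_numpy(),
        }
    )
    records["anchor_change"] = records["anchor_change"].astype(int)
    records["ccg"] = classify_anchor_change(records["anchor_change"])
    records = records.reset_index(drop=True)

    # pairs lost to missingness: all ordered pairs of assessments minus emitted
    n_per_patient = df.groupby("patient_id")["time_rank"].nunique()
    if pairing == "all_pairs":
        total = int((n_per_patient * (n_per_patient - 1) // 2).sum())
    else:
        total = int((n_per_patient - 1).clip(lower=0).sum())
    records.attrs["n_pairs_skipped"] = total - len(records)
    return records


def ccg_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Counts of records and of distinct patients per CCG per (scale, anchor).

    A patient contributing to several CCGs is counted once in each CCG's
    patient tally.  All four CCG labels always appear (zero-filled).
    """
    if records.empty:
        keys = [("", "", ccg) for ccg in CCG_LABELS]
        return pd.DataFrame(
            [
                {"scale_code": s, "anchor_code": a, "ccg": c, "n_records": 0, "n_patients": 0}
                for s, a, c in keys
            ]
        )
    rows = []
    for (scale, anchor), grp in records.groupby(["scale_code", "anchor_code"]):
        by_ccg = grp.groupby("ccg").agg(
            n_records=("patient_id", "size"), n_patients=("patient_id", "nunique")
        )
        for ccg in CCG_LABELS:
            n_rec = int(by_ccg["n_records"].get(ccg, 0))
            n_pat = int(by_ccg["n_patients"].get(ccg, 0))
            rows.append(
                {
                    "scale_code": scale,
                    "anchor_code": anchor,
                    "ccg": ccg,
                    "n_records": n_rec,
                    "n_patients": n_pat,
                }
            )
    return pd.DataFrame(rows)
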