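"""Shared data model and long-format table I/O.

The central container is :class:`LongTable`: a tidy pandas DataFrame with one
row per patient x assessment, carrying raw questionnaire item responses and/or
0-100 scale scores plus ordinal clinical anchor grades (e.g. WHO performance
status 0-4, CTCAE toxicity grade 0-4).  Validation is total: a file either
yields a fully valid table or a :class:`~promid.exceptions.ValidationError`
listing every offending row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError

CORE_COLUMNS = ("patient_id", "trial_id", "timepoint")


@dataclass(frozen=True)
class AnchorDefinition:
    """An ordinal clinical anchor.

    Parameters
    ----------
    code : str
        Short anchor code, e.g. ``"PS"`` or ``"CTCAE_DIARRHOEA"``.
    categories : tuple of int
        The ordered set of admissible grades.
    worse_direction : {+1, -1}
        +1 if a *higher* grade means *worse* health (true for performance
        status and CTCAE toxicity grades), -1 otherwise.
    """

    code: str
    categories: tuple[int, ...]
    worse_direction: int = 1

    def __post_init__(self):
        if len(self.categories) < 2:
            raise ValidationError(f"anchor {self.code!r}: needs >= 2 categories")
        if tuple(sorted(self.categories)) != tuple(self.categories):
            raise ValidationError(f"anchor {self.code!r}: categories must be sorted")
        if self.worse_direction not in (1, -1):
            raise ValidationError(f"anchor {self.code!r}: worse_direction must be +1 or -1")


@dataclass(frozen=True)
class ScaleDefinition:
    """One questionnaire scale: its items, kind and response range.

    ``item_range`` is the span of the response set (3 for 4-point items,
    1 for yes/no items, 6 for the 7-point global QoL items).
    ``reverse_for_consistency`` applies to symptom scales only: when True the
    symptom score is reversed at scoring time so that, for every scale,
    0 is the worst and 100 the best possible score.
    """

    code: str
    item_codes: tuple[str, ...]
    kind: str  # "functioning" | "symptom" | "global"
    version: int = 3
    item_range: int = 3
    reverse_for_consistency: bool = True

    def __post_init__(self):
        if not self.item_codes:
            raise ValidationError(f"scale {self.code!r}: item_codes must be non-empty")
        if self.item_range < 1:
            raise ValidationError(f"scale {self.code!r}: item_range must be >= 1")
        if self.kind not in ("functioning", "symptom", "global"):
            raise ValidationError(f"scale {self.code!r}: unknown kind {self.kind!r}")

    @property
    def n_items(self) -> int:
        return len(self.item_codes)

    @property
    def score_step(self) -> float:
        """Spacing of the achievable 0-100 score lattice."""
        return 100.0 / (self.n_items * self.item_range)


@dataclass
class LongTable:
    """Validated long-format trial table.

    ``data`` holds canonical columns: ``patient_id``, ``trial_id``,
    ``timepoint``, a derived per-patient ``time_rank`` (1 = first assessment),
    one column per item code, scale code and anchor code.
    """

    data: pd.DataFrame
    item_columns: tuple[str, ...] = ()
    score_columns: tuple[str, ...] = ()
    anchor_defs: dict[str, AnchorDefinition] = field(default_factory=dict)

    @property
    def anchor_columns(self) -> tuple[str, ...]:
        return tuple(self.anchor_defs)

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        item_columns: Sequence[str] = (),
        score_columns: Sequence[str] = (),
        anchor_defs: Mapping[str, AnchorDefinition] | None = None,
    ) -> "LongTable":
        """Validate a canonical frame and attach assessment ranks.

        Raises
        ------
        ValidationError
            On missing core columns, duplicate (patient, timepoint) rows,
            non-integer anchor tokens, or anchor grades outside the declared
            category set.  All problems are collected and reported together.
        """
        anchor_defs = dict(anchor_defs or {})
        problems: list[str] = []
        for col in CORE_COLUMNS:
            if col not in df.columns:
                problems.append(f"missing required column {col!r}")
        if problems:
            raise ValidationError(problems)

        df = df.copy()
        dup = df.duplicated(subset=["patient_id", "timepoint"], keep=False)
        if dup.any():
            pairs = df.loc[dup, ["patient_id", "timepoint"]].drop_duplicates()
            for pid, tp in pairs.itertuples(index=False):
                problems.append(f"duplicate assessment for (patient={pid!r}, timepoint={tp!r})")

        for code, adef in anchor_defs.items():
            if code not in df.columns:
                problems.append(f"missing anchor column {code!r}")
                continue
            raw = df[code]
            num = pd.to_numeric(raw, errors="coerce")
            bad_token = raw.notna() & num.isna()
            # non-integral numeric values are also errors, not missing (fail loud)
            non_int = num.notna() & (num != np.floor(num))
            allowed = set(adef.categories)
            out_of_range = num.notna() & ~non_int & ~num.isin(list(allowed))
            for idx in df.index[bad_token | non_int]:
                problems.append(
                    f"anchor {code!r}: non-integer value {raw[idx]!r} at "
                    f"(patient={df.at[idx, 'patient_id']!r}, timepoint={df.at[idx, 'timepoint']!r})"
                )
            for idx in df.index[out_of_range]:
                problems.append(
                    f"anchor {code!r}: grade {raw[idx]!r} outside allowed set "
                    f"{sorted(allowed)} at (patient={df.at[idx, 'patient_id']!r}, "
                    f"timepoint={df.at[idx, 'timepoint']!r})"
                )
            df[code] = num

        for col in list(item_columns) + list(score_columns):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="coerce")

        for col in score_columns:
            if col in df.columns:
                vals = df[col]
                bad = vals.notna() & ((vals < 0) | (vals > 100))
                for idx in df.index[bad]:
                    problems.append(
                        f"score {col!r}: value {vals[idx]!r} outside [0, 100] at "
                        f"(patient={df.at[idx, 'patient_id']!r}, "
                        f"timepoint={df.at[idx, 'timepoint']!r})"
                    )

        if problems:
            raise ValidationError(problems)

        df = df.sort_values(["trial_id", "patient_id", "timepoint"], kind="mergesort")
        df["time_rank"] = (
            df.groupby("patient_id")["timepoint"].rank(method="dense").astype(int)
        )
        df = df.reset_index(drop=True)
        return cls(
            data=df,
            item_columns=tuple(c for c in item_columns if c in df.columns),
            score_columns=tuple(c for c in score_columns if c in df.columns),
            anchor_defs=anchor_defs,
        )


@dataclass
class Schema:
    """Column mapping from an arbitrary CSV layout onto the canonical model."""

    patient_id: str = "patient_id"
    trial_id: str = "trial_id"
    timepoint: str = "timepoint"
    items: dict[str, str] = field(default_factory=dict)  # item code -> column
    scores: dict[str, str] = field(default_factory=dict)  # scale code -> column
    anchors: dict[str, str] = field(default_factory=dict)  # anchor code -> column
    anchor_defs: dict[str, AnchorDefinition] = field(default_factory=dict)

    @classmethod
    def canonical(
        cls,
        item_codes: Sequence[str] = (),
        score_codes: Sequence[str] = (),
        anchor_defs: Mapping[str, AnchorDefinition] | None = None,
    ) -> "Schema":
        """Identity mapping: the file already uses canonical column names."""
        anchor_defs = dict(anchor_defs or {})
        return cls(
            items={c: c for c in item_codes},
            scores={c: c for c in score_codes},
            anchors={c: c for c in anchor_defs},
            anchor_defs=anchor_defs,
        )

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "Schema":
        cols = cfg.get("columns", {})
        anchors = {}
        anchor_defs = {}
        for code, spec in cfg.get("anchors", {}).items():
            anchors[code] = spec["column"]
            anchor_defs[code] = AnchorDefinition(
                code=code,
                categories=tuple(int(c) for c in spec["categories"]),
                worse_direction=int(spec.get("worse_direction", 1)),
            )
        return cls(
            patient_id=cols.get("patient_id", "patient_id"),
            trial_id=cols.get("trial_id", "trial_id"),
            timepoint=cols.get("timepoint", "timepoint"),
            items=dict(cfg.get("items", {})),
            scores=dict(cfg.get("scores", {})),
            anchors=anchors,
            anchor_defs=anchor_defs,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Schema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def read_long_table(path: str | Path, schema: Schema) -> LongTable:
    """Read and validate a long-format CSV through a :class:`Schema`.

    Every schema-mapped column must exist; rows violating the data-model
    invariants raise a :class:`ValidationError` naming each offending row.
    """
    df = pd.read_csv(path)
    rename = {
        schema.patient_id: "patient_id",
        schema.trial_id: "trial_id",
        schema.timepoint: "timepoint",
    }
    rename.update({col: code for code, col in schema.items.items()})
    rename.update({col: code for code, col in schema.scores.items()})
    rename.update({col: code for code, col in schema.anchors.items()})
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise ValidationError([f"missing column {c!r} in {path}" for c in missing])
    df = df.rename(columns=rename)
    keep = list(CORE_COLUMNS) + list(schema.items) + list(schema.scores) + list(schema.anchors)
    df = df[[c for c in keep if c in df.columns]]
    df["patient_id"] = df["patient_id"].astype(str)
    df["trial_id"] = df["trial_id"].astype(str)
    return LongTable.from_frame(
        df,
        item_columns=list(schema.items),
        score_columns=list(schema.scores),
        anchor_defs=schema.anchor_defs,
    )


def write_long_table(table: LongTable, path: str | Path) -> None:
    """Write a LongTable to canonical CSV (round-trips through read_long_table)."""
    out = table.data.drop(columns=["time_rank"], errors="ignore")
    out.to_csv(path, index=False)


NO_MID = "no MID"


def _mid_cell(estimate) -> str:
    if estimate is None or not estimate.retained or not np.isfinite(estimate.mid):
        return NO_MID
    return f"{estimate.mid:.1f}"


def write_results(mids, dists, path: str | Path) -> pd.DataFrame:
    """Write the summary result table: one row per scale.

    Cells hold the within-/between-group improvement and deterioration MIDs,
    with the literal token ``"no MID"`` wherever an estimate is unavailable or
    failed the effect-size retention filter, followed by the distribution-based
    comparators (0.3 SD, 0.5 SD, 1 SEM).  Symptom scores are reversed upstream,
    so 0 is the worst and 100 the best score for every scale.
    """
    by_scale: dict[str, dict] = {}
    for est in mids:
        cell = by_scale.setdefault(est.scale_code, {})
        key = (est.kind, est.direction)
        if key not in cell:  # first (preferred) anchor wins; callers pre-select
            cell[key] = est
    dist_by_scale = {d.scale_code: d for d in dists}

    rows = []
    for scale in sorted(set(by_scale) | set(dist_by_scale)):
        cell = by_scale.get(scale, {})
        d = dist_by_scale.get(scale)
        rows.append(
            {
                "scale": scale,
                "within_improvement": _mid_cell(cell.get(("within_group", "improvement"))),
                "within_deterioration": _mid_cell(cell.get(("within_group", "deterioration"))),
                "between_improvement": _mid_cell(cell.get(("between_group", "improvement"))),
                "between_deterioration": _mid_cell(cell.get(("between_group", "deterioration"))),
                "sd_0_3": f"{d.est_03sd:.1f}" if d is not None else "",
                "sd_0_5": f"{d.est_05sd:.1f}" if d is not None else "",
                "sem_1": f"{d.sem:.1f}" if d is not None else "",
            }
        )
    cols = [
        "scale",
        "within_improvement",
        "within_deterioration",
        "between_improvement",
        "between_deterioration",
        "sd_0_3",
        "sd_0_5",
        "sem_1",
    ]
    frame = pd.DataFrame(rows, columns=cols)
    frame.to_csv(path, index=False)
    return frame
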