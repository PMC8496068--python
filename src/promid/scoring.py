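"""QLQ-C30 scale scoring.

Raw item responses (version 2 or 3) are averaged per scale (the half-rule:
the mean of answered items stands in for the scale mean whenever at least half
the items are answered) and linearly transformed to 0-100.  One unified sign
convention is applied at scoring time: symptom scores are reversed so that for
*every* scale 0 is the worst and 100 the best possible score, which gives all
downstream change scores and MIDs a single interpretable sign.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datamodel import LongTable, ScaleDefinition
from .exceptions import ScoringError

# (code, kind, item codes); items q29/q30 are the 7-point global QoL pair
_SCALE_STRUCTURE: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("PF", "functioning", ("q1", "q2", "q3", "q4", "q5")),
    ("RF", "functioning", ("q6", "q7")),
    ("EF", "functioning", ("q21", "q22", "q23", "q24")),
    ("CF", "functioning", ("q20", "q25")),
    ("SF", "functioning", ("q26", "q27")),
    ("QL", "global", ("q29", "q30")),
    ("FA", "symptom", ("q10", "q12", "q18")),
    ("NV", "symptom", ("q14", "q15")),
    ("PA", "symptom", ("q9", "q19")),
    ("DY", "symptom", ("q8",)),
    ("SL", "symptom", ("q11",)),
    ("AP", "symptom", ("q13",)),
    ("CO", "symptom", ("q16",)),
    ("DI", "symptom", ("q17",)),
    ("FI", "symptom", ("q28",)),
)

#: The financial-difficulties scale is scored but omitted from MID analysis.
EXCLUDED_FROM_ANALYSIS = ("FI",)

#: The 14 scales carried into the analysis.
ANALYSIS_SCALES = tuple(c for c, _, _ in _SCALE_STRUCTURE if c not in EXCLUDED_FROM_ANALYSIS)

ALL_ITEM_CODES = tuple(f"q{i}" for i in range(1, 31))


def scale_registry(version: int = 3) -> dict[str, ScaleDefinition]:
    """Built-in QLQ-C30 scale definitions.

    Versions 2 and 3 differ only in items q1-q5, which are yes/no
    (coded 1/2, item_range 1) in version 2 and 4-point in version 3.
    The global QoL items are 7-point (item_range 6) in both.
    """
    if version not in (2, 3):
        raise ScoringError(f"unsupported QLQ-C30 version {version!r}")
    defs = {}
    for code, kind, items in _SCALE_STRUCTURE:
        if kind == "global":
            rng = 6
        elif version == 2 and code == "PF":
            rng = 1
        else:
            rng = 3
        defs[code] = ScaleDefinition(
            code=code,
            item_codes=items,
            kind=kind,
            version=version,
            item_range=rng,
            reverse_for_consistency=(kind == "symptom"),
        )
    return defs


def raw_score(responses: Sequence[float], sdef: ScaleDefinition) -> float:
    """Mean of the answered raw item responses, or NaN under the half-rule.

    Responses must lie in the declared set {1, ..., 1 + item_range}; NaN marks
    a missing answer.  The scale raw score is defined when at least half of
    the scale's items are answered.
    """
    arr = np.asarray(responses, dtype=float)
    if arr.shape != (sdef.n_items,):
        raise ScoringError(
            f"scale {sdef.code!r}: expected {sdef.n_items} responses, got {arr.shape}"
        )
    answered = ~np.isnan(arr)
    lo, hi = 1, 1 + sdef.item_range
    bad = answered & ((arr < lo) | (arr > hi) | (arr != np.floor(arr)))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ScoringError(
            f"scale {sdef.code!r}, item {sdef.item_codes[i]!r}: response "
            f"{arr[i]!r} outside {{{lo}..{hi}}}"
        )
    if answered.sum() * 2 < sdef.n_items:
        return math.nan
    return float(arr[answered].mean())


def transform_score(raw: float, sdef: ScaleDefinition) -> float:
    """Linear 0-100 transformation with the unified best-is-100 convention.

    functioning: 100 * (1 - (raw - 1) / range)
    symptom:     100 * (raw - 1) / range, then reversed to 100 - that value
                 when ``reverse_for_consistency`` is set
    global QoL:  100 * (raw - 1) / range   (already best-high)
    """
    if isinstance(raw, float) and math.isnan(raw):
        return math.nan
    lo, hi = 1.0, 1.0 + sdef.item_range
    if not lo <= raw <= hi:
        raise ScoringError(f"scale {sdef.code!r}: raw score {raw!r} outside [{lo}, {hi}]")
    frac = (raw - 1.0) / sdef.item_range
    if sdef.kind == "functioning":
        return 100.0 * (1.0 - frac)
    if sdef.kind == "global":
        return 100.0 * frac
    score = 100.0 * frac
    return 100.0 - score if sdef.reverse_for_consistency else score


def score_items(responses: Sequence[float], sdef: ScaleDefinition) -> float:
    """Convenience composition of :func:`raw_score` and :func:`transform_score`."""
    return transform_score(raw_score(responses, sdef), sdef)


def score_table(
    table: LongTable,
    defs: Mapping[str, ScaleDefinition] | None = None,
    scales: Iterable[str] | None = None,
) -> LongTable:
    """Populate scale-score columns from item responses.

    Tables without item columns pass through unchanged (they already carry
    scores).  The financial-difficulties scale is omitted from the analysis
    set by default.
    """
    if not table.item_columns:
        return table
    defs = dict(defs) if defs is not None else scale_registry(3)
    wanted = tuple(scales) if scales is not None else ANALYSIS_SCALES
    df = table.data.copy()
    scored: list[str] = []
    for code in wanted:
        sdef = defs[code]
        present = [c for c in sdef.item_codes if c in df.columns]
        if len(present) != sdef.n_items:
            continue
        block = df[list(sdef.item_codes)].to_numpy(dtype=float)
        answered = ~np.isnan(block)
        lo, hi = 1, 1 + sdef.item_range
        bad = answered & ((block < lo) | (block > hi) | (block != np.floor(block)))
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise ScoringError(
                f"scale {code!r}, item {sdef.item_codes[c]!r}: response "
                f"{block[r, c]!r} outside {{{lo}..{hi}}} at row {r}"
            )
        n_answered = answered.sum(axis=1)
        with np.errstate(invalid="ignore"):
            raw = np.nanmean(np.where(answered, block, np.nan), axis=1)
        raw[n_answered * 2 < sdef.n_items] = np.nan
        frac = (raw - 1.0) / sdef.item_range
        if sdef.kind == "global":
            score = 100.0 * frac
        else:
            # functioning directly, symptom after reversal: identical formula
            score = 100.0 * (1.0 - frac)
            if sdef.kind == "symptom" and not sdef.reverse_for_consistency:
                score = 100.0 - score
        df[code] = score
        scored.append(code)
    score_cols = tuple(dict.fromkeys(list(table.score_columns) + scored))
    return LongTable(
        data=df,
        item_columns=table.item_columns,
        score_columns=score_cols,
        anchor_defs=table.anchor_defs,
    )
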