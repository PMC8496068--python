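"""Polyserial and polychoric correlations for anchor screening.

Both estimators use the standard two-step approach: the latent thresholds of
each ordinal variable are fixed at inverse-normal transforms of the observed
cumulative marginal proportions, then the latent correlation rho is obtained
by bounded 1-D maximum likelihood.  Screening pools all timepoints; anchors
are retained for a scale when the cross-sectional |rho| >= 0.3 (change-score
correlations are reported alongside but do not gate retention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import AnchorDefinition, LongTable
from .exceptions import DegenerateDataError

RHO_BOUND = 0.999
_RETENTION_THRESHOLD = 0.3


@dataclass(frozen=True)
class CorrelationResult:
    scale_code: str
    anchor_code: str
    basis: str  # "cross_sectional" | "change_score"
    rho: float
    thresholds: tuple[float, ...]
    n_patients: int
    n_observations: int
    method: str  # "polyserial" | "polychoric"


@dataclass
class CorrelationScreen:
    """All correlations from one screening pass plus skipped pairs."""

    results: list[CorrelationResult] = field(default_factory=list)
    skipped: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (scale, anchor, basis, reason)


def ordinal_thresholds(counts: Sequence[float]) -> np.ndarray:
    """Latent normal cutpoints from category frequencies.

    tau_k = Phi^-1(cumulative proportion up to category k) for the observed
    (nonzero-count) categories; zero-count categories collapse into their
    neighbours.  Raises if fewer than two categories carry mass.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or (counts < 0).any():
        raise DegenerateDataError("counts must be a nonnegative vector")
    nz = counts[counts > 0]
    if nz.size < 2:
        raise DegenerateDataError("degenerate ordinal variable: all mass in one category")
    cum = np.cumsum(nz)[:-1] / nz.sum()
    return stats.norm.ppf(cum)


def _recode(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map ordinal values onto dense 0..K-1 codes over observed categories."""
    _, codes = np.unique(y, return_inverse=True)
    counts = np.bincount(codes)
    return codes, counts


def _optimise(nll) -> float:
    res = optimize.minimize_scalar(
        nll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded", options={"xatol": 1e-6}
    )
    if not res.success:
        raise DegenerateDataError(f"latent correlation did not converge (last rho={res.x:.4f})")
    return float(res.x)


def polyserial_rho(
    x: Sequence[float],
    y: Sequence[int],
    *,
    scale_code: str = "x",
    anchor_code: str = "y",
    basis: str = "cross_sectional",
    n_patients: int | None = None,
    min_n: int = 30,
) -> CorrelationResult:
    """Two-step ML polyserial correlation between continuous x and ordinal y.

    The log-likelihood for each observation i with standardised x_i = z_i is
    log phi(z_i) + log[Phi((tau_{y_i} - rho z_i)/s) - Phi((tau_{y_i - 1} - rho z_i)/s)]
    with s = sqrt(1 - rho^2); thresholds are fixed from the marginals of y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    mask = ~np.isnan(x) & ~pd.isna(y)
    x, y = x[mask], np.asarray(y[mask], dtype=float)
    n = x.size
    if n < min_n:
        raise DegenerateDataError(f"too few complete observations (n={n} < {min_n})")
    sd = x.std(ddof=0)
    if sd == 0:
        raise DegenerateDataError("continuous variable has zero variance")
    z = (x - x.mean()) / sd
    codes, counts = _recode(y)
    tau = ordinal_thresholds(counts)
    lo = np.concatenate(([-np.inf], tau))[codes]
    hi = np.concatenate((tau, [np.inf]))[codes]

    def nll(rho: float) -> float:
        s = np.sqrt(1.0 - rho * rho)
        p = stats.norm.cdf((hi - rho * z) / s) - stats.norm.cdf((lo - rho * z) / s)
        return -np.log(np.clip(p, 1e-300, None)).sum()

    rho = _optimise(nll)
    return CorrelationResult(
        scale_code=scale_code,
        anchor_code=anchor_code,
        basis=basis,
        rho=rho,
        thresholds=tuple(tau),
        n_patients=int(n_patients) if n_patients is not None else n,
        n_observations=n,
        method="polyserial",
    )


def _bvn_cdf_grid(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """Bivariate standard normal CDF on the grid a x b (with +-inf handled)."""
    a = np.clip(a, -8.5, 8.5)
    b = np.clip(b, -8.5, 8.5)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    out = np.empty((a.size, b.size))
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            out[i, j] = stats.multivariate_normal.cdf([ai, bj], mean=[0.0, 0.0], cov=cov)
    return out


def polychoric_rho(
    x: Sequence[int],
    y: Sequence[int],
    *,
    scale_code: str = "x",
    anchor_code: str = "y",
    basis: str = "cross_sectional",
    n_patients: int | None = None,
    min_n: int = 30,
) -> CorrelationResult:
    """Two-step ML polychoric correlation between two ordinal variables.

    Both threshold vectors come from the marginals; rho maximises the
    multinomial likelihood of the contingency table under a latent bivariate
    normal whose cell probabilities are second differences of the joint CDF.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    mask = ~pd.isna(x) & ~pd.isna(y)
    x, y = np.asarray(x[mask], dtype=float), np.asarray(y[mask], dtype=float)
    n = x.size
    if n < min_n:
        raise DegenerateDataError(f"too few complete observations (n={n} < {min_n})")
    cx, countsx = _recode(x)
    cy, countsy = _recode(y)
    taux = ordinal_thresholds(countsx)
    tauy = ordinal_thresholds(countsy)
    K, L = countsx.size, countsy.size
    table = np.zeros((K, L))
    np.add.at(table, (cx, cy), 1.0)
    ax = np.concatenate((taux, [np.inf]))
    by = np.concatenate((tauy, [np.inf]))

    def nll(rho: float) -> float:
        cdf = _bvn_cdf_grid(ax, by, rho)
        # pad a leading zero row/col so second differences give cell probs
        padded = np.zeros((K + 1, L + 1))
        padded[1:, 1:] = cdf
        p = padded[1:, 1:] - padded[:-1, 1:] - padded[1:, :-1] + padded[:-1, :-1]
        return -(table * np.log(np.clip(p, 1e-300, None))).sum()

    rho = _optimise(nll)
    return CorrelationResult(
        scale_code=scale_code,
        anchor_code=anchor_code,
        basis=basis,
        rho=rho,
        thresholds=tuple(taux) + tuple(tauy),
        n_patients=int(n_patients) if n_patients is not None else n,
        n_observations=n,
        method="polychoric",
    )


#: More than this many distinct observed score values selects the polyserial
#: path; at or below it the score is treated as ordinal (single-item scales
#: have at most 4 observed levels).
POLYSERIAL_DISTINCT_CUTOFF = 7


def correlate_all(
    table: LongTable,
    scales: Iterable[str],
    anchors: Mapping[str, AnchorDefinition] | None = None,
    basis: str = "cross_sectional",
    *,
    pairing: str = "all_pairs",
    min_n: int = 30,
) -> CorrelationScreen:
    """Latent correlation for every (scale, anchor) pair with sufficient data.

    On the ``cross_sectional`` basis all timepoints are pooled (screening is a
    filter, not an inference, so within-patient clustering is ignored here).
    On the ``change_score`` basis the inputs are pairwise change records and
    the ordinal variable is the raw anchor grade change.
    """
    from .changes import make_change_records  # local import to avoid a cycle

    anchors = dict(anchors if anchors is not None else table.anchor_defs)
    screen = CorrelationScreen()
    for scale in scales:
        for code, adef in anchors.items():
            try:
                if basis == "cross_sectional":
                    df = table.data[["patient_id", scale, code]].dropna()
                    x = df[scale].to_numpy()
                    y = df[code].to_numpy()
                    n_pat = df["patient_id"].nunique()
                elif basis == "change_score":
                    rec = make_change_records(table, scale, adef, pairing=pairing)
                    x = rec["hrqol_change"].to_numpy()
                    # raw grade change keeps the anchor's own direction
                    y = -adef.worse_direction * rec["anchor_change"].to_numpy()
                    n_pat = rec["patient_id"].nunique()
                else:
                    raise ValueError(f"unknown basis {basis!r}")
                if x.size and np.unique(y).size < 2:
                    raise DegenerateDataError("anchor variable is constant")
                if np.unique(x).size > POLYSERIAL_DISTINCT_CUTOFF:
                    res = polyserial_rho(
                        x, y, scale_code=scale, anchor_code=code, basis=basis,
                        n_patients=n_pat, min_n=min_n,
                    )
                else:
                    res = polychoric_rho(
                        x, y, scale_code=scale, anchor_code=code, basis=basis,
                        n_patients=n_pat, min_n=min_n,
                    )
                screen.results.append(res)
            except DegenerateDataError as err:
                screen.skipped.append((scale, code, basis, str(err)))
    return screen


def select_anchors(
    results: Iterable[CorrelationResult],
    threshold: float = _RETENTION_THRESHOLD,
) -> list[tuple[str, str]]:
    """Retain (scale, anchor) pairs with cross-sectional |rho| >= threshold.

    Change-score correlations never gate retention (a pair with strong
    cross-sectional but weak change-score correlation stays retained).
    """
    retained = []
    for res in results:
        if res.basis != "cross_sectional":
            continue
        if abs(res.rho) >= threshold:
            retained.append((res.scale_code, res.anchor_code))
    return retained


def correlation_report(screen: CorrelationScreen, threshold: float = _RETENTION_THRESHOLD) -> pd.DataFrame:
    """Tabular report: one row per (scale, anchor) with both bases side by side."""
    rows: dict[tuple[str, str], dict] = {}
    for res in screen.results:
        row = rows.setdefault(
            (res.scale_code, res.anchor_code),
            {"scale": res.scale_code, "anchor": res.anchor_code},
        )
        if res.basis == "cross_sectional":
            row.update(
                n_patients=res.n_patients,
                n_observations=res.n_observations,
                cross_sectional_rho=res.rho,
                method=res.method,
            )
        else:
            row.update(
                n_patients_change=res.n_patients,
                n_observations_change=res.n_observations,
                change_score_rho=res.rho,
            )
    frame = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["scale"], r["anchor"])))
    if not frame.empty and "cross_sectional_rho" in frame:
        frame["retained"] = frame["cross_sectional_rho"].abs() >= threshold
    return frame
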