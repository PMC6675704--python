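"""Seropositivity cut-offs, case-control comparison and coverage.

For each panel peptide a seropositivity threshold on the SNR scale is chosen
data-driven: the cut-off is the SNR value that maximizes the difference in
positive response rate between the case (glioma) and control (healthy)
groups, where a serum is positive when its SNR is at or above the threshold
(boundary inclusive).  Candidate thresholds are the observed pooled SNR
values, which makes the search exact and checkable by exhaustive
enumeration; ties are broken toward the smallest maximizing candidate
(maximal sensitivity at equal discrimination).  A fixed-step grid mode is
available for sensitivity analysis.

Group differences per peptide are tested with Fisher's exact test on the
2x2 seropositive-by-group table, with Bonferroni correction across the
panel.  Coverage of a peptide in a serum set is the fraction of seropositive
sera, tracked per time point for longitudinal cohorts.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .array_signal import SampleReactivityProfile

logger = logging.getLogger(__name__)

__all__ = [
    "CutoffResult",
    "SerostatusCall",
    "CoverageSummary",
    "optimize_cutoff",
    "optimize_cutoffs",
    "classify",
    "classify_cohort",
    "fisher_exact_2x2",
    "bonferroni_adjust",
    "compare_groups",
    "render_comparison",
    "coverage",
    "longitudinal_coverage",
    "select_top_peptides",
    "percent",
]


@dataclass(frozen=True)
class CutoffResult:
    """A per-peptide seropositivity threshold and the objective it achieves."""

    peptide: str
    cutoff: float
    max_difference: float
    candidates_evaluated: int


@dataclass(frozen=True)
class SerostatusCall:
    serum_id: str
    peptide: str
    snr: float
    cutoff: float
    positive: bool


@dataclass(frozen=True)
class CoverageSummary:
    peptide: str
    label: str
    n_positive: int
    n_total: int

    @property
    def coverage(self) -> float:
        return self.n_positive / self.n_total


def optimize_cutoff(
    case_snr: Sequence[float] | np.ndarray,
    control_snr: Sequence[float] | np.ndarray,
    peptide: str = "",
    grid_step: float | None = None,
    min_cutoff: float | None = None,
) -> CutoffResult:
    """Choose the SNR threshold maximizing case rate minus control rate.

    The objective at candidate c is
    ``(#case >= c)/n_case - (#control >= c)/n_control``; candidates are the
    sorted unique pooled SNR values (or, with ``grid_step``, a fixed-step
    grid spanning the pooled range).  Ties are broken by the smallest
    maximizing candidate.

    ``min_cutoff`` floors the candidate set: only candidates at or above it
    (plus the floor itself) are searched.  For a peptide with no real group
    difference the unconstrained objective is maximized by sampling noise
    and can land inside the seronegative bulk; a floor at a conventional
    minimal positive SNR (the screening pipeline defaults to 2.0) keeps such
    peptides specific, and is consistent with published panel cut-offs never
    falling below 2.
    """
    case = np.asarray(case_snr, dtype=float)
    control = np.asarray(control_snr, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty to optimize a cut-off")
    if np.isnan(case).any() or np.isnan(control).any():
        case = case[~np.isnan(case)]
        control = control[~np.isnan(control)]
        if case.size == 0 or control.size == 0:
            raise ValueError("a group has no non-missing SNR values")
    pooled = np.concatenate([case, control])
    if grid_step is None:
        candidates = np.unique(pooled)
    else:
        lo = math.floor(pooled.min() / grid_step) * grid_step
        hi = math.ceil(pooled.max() / grid_step) * grid_step
        candidates = np.round(
            np.arange(lo, hi + grid_step / 2, grid_step), 12
        )
    if min_cutoff is not None:
        candidates = np.unique(
            np.concatenate([candidates[candidates >= min_cutoff], [min_cutoff]])
        )
    if np.unique(pooled).size == 1:
        warnings.warn(
            f"peptide {peptide or '<unnamed>'}: all SNR values identical; "
            "cut-off is degenerate",
            stacklevel=2,
        )
    # integer-exact objective: argmax over case_ge*n_ctrl - ctrl_ge*n_case so
    # mathematically tied candidates compare equal (no float-ulp tie breaks)
    case_sorted = np.sort(case)
    ctrl_sorted = np.sort(control)
    case_ge = case.size - np.searchsorted(case_sorted, candidates, side="left")
    ctrl_ge = control.size - np.searchsorted(ctrl_sorted, candidates, side="left")
    objective_int = case_ge * control.size - ctrl_ge * case.size
    best = int(np.argmax(objective_int))  # first (smallest) maximizer
    max_difference = case_ge[best] / case.size - ctrl_ge[best] / control.size
    return CutoffResult(
        peptide=peptide,
        cutoff=float(candidates[best]),
        max_difference=float(max_difference),
        candidates_evaluated=int(candidates.size),
    )


def optimize_cutoffs(
    long_snr: pd.DataFrame,
    case_group: str = "glioma",
    control_group: str = "healthy",
    grid_step: float | None = None,
    min_cutoff: float | None = 2.0,
) -> dict[str, CutoffResult]:
    """Per-peptide cut-offs from a long-format SNR table (serum_id, group,
    peptide, snr), using only the given case/control groups.  The default
    candidate floor of 2.0 (see :func:`optimize_cutoff`) keeps peptides with
    no group difference specific."""
    out: dict[str, CutoffResult] = {}
    for peptide, sub in long_snr.groupby("peptide", sort=True):
        case = sub.loc[sub["group"] == case_group, "snr"]
        control = sub.loc[sub["group"] == control_group, "snr"]
        out[str(peptide)] = optimize_cutoff(
            case,
            control,
            peptide=str(peptide),
            grid_step=grid_step,
            min_cutoff=min_cutoff,
        )
    return out


def classify(
    profile: SampleReactivityProfile,
    cutoffs: Mapping[str, CutoffResult | float],
) -> list[SerostatusCall]:
    """Call serostatus per peptide: positive iff SNR >= cut-off.

    A peptide with missing SNR produces no call; a profiled peptide without a
    cut-off raises ``KeyError`` naming it.
    """
    calls = []
    for peptide in sorted(profile.snr):
        snr = profile.snr[peptide]
        if peptide not in cutoffs:
            raise KeyError(f"no cut-off for peptide {peptide!r}")
        if snr is None or (isinstance(snr, float) and math.isnan(snr)):
            continue
        cut = cutoffs[peptide]
        cutoff = cut.cutoff if isinstance(cut, CutoffResult) else float(cut)
        calls.append(
            SerostatusCall(
                serum_id=profile.serum_id,
                peptide=peptide,
                snr=float(snr),
                cutoff=cutoff,
                positive=bool(snr >= cutoff),
            )
        )
    return calls


def classify_cohort(
    profiles: Iterable[SampleReactivityProfile],
    cutoffs: Mapping[str, CutoffResult | float],
) -> pd.DataFrame:
    """Calls for every non-missing profile, as a flat table."""
    rows = []
    for p in profiles:
        if p.missing:
            continue
        for c in classify(p, cutoffs):
            rows.append(
                {
                    "serum_id": c.serum_id,
                    "group": p.group,
                    "timepoint": p.timepoint,
                    "peptide": c.peptide,
                    "snr": c.snr,
                    "cutoff": c.cutoff,
                    "positive": c.positive,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["serum_id", "group", "timepoint", "peptide", "snr", "cutoff", "positive"],
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sided by the minimum-likelihood rule: the sum of hypergeometric
    probabilities (margins fixed) of all tables no more probable than the
    observed one.  A table with an empty row or column margin carries no
    information and returns p = 1 with a warning.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError(f"negative count in table {counts}")
    if (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
        warnings.warn(f"degenerate 2x2 margin in {counts}; p set to 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bonferroni_adjust(
    p_values: Sequence[float] | np.ndarray, m: int | None = None
) -> np.ndarray:
    """Bonferroni family-wise correction: min(1, m * p), order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"panel size m={m} smaller than number of tests {p.size}")
    return np.minimum(1.0, m * p)


def percent(x: float) -> int:
    """Whole-percent rendering with round-half-away-from-zero (0.448 -> 45)."""
    return int(math.copysign(math.floor(abs(x) * 100 + 0.5), x))


def compare_groups(
    calls: pd.DataFrame,
    case_group: str = "glioma",
    control_group: str = "healthy",
    m: int | None = None,
    cutoffs: Mapping[str, CutoffResult] | None = None,
) -> pd.DataFrame:
    """Per-peptide 2x2 counts, rates, rate difference, exact p and adjusted p.

    ``calls`` is a flat call table (from :func:`classify_cohort`); rows are
    restricted to the two named groups.  ``m`` defaults to the number of
    peptides compared.  The difference is case rate minus control rate, as a
    proportion.
    """
    sub = calls.loc[calls["group"].isin([case_group, control_group])]
    if sub.loc[sub["group"] == case_group].empty:
        raise ValueError(f"no calls for case group {case_group!r}")
    if sub.loc[sub["group"] == control_group].empty:
        raise ValueError(f"no calls for control group {control_group!r}")
    rows = []
    for peptide, pcalls in sub.groupby("peptide", sort=True):
        case = pcalls.loc[pcalls["group"] == case_group, "positive"]
        control = pcalls.loc[pcalls["group"] == control_group, "positive"]
        if case.empty or control.empty:
            raise ValueError(f"peptide {peptide!r}: a group has no calls")
        a = int(case.sum())
        b = int(case.size - a)
        c = int(control.sum())
        d = int(control.size - c)
        case_rate = a / (a + b)
        control_rate = c / (c + d)
        cutoff = float(pcalls["cutoff"].iloc[0]) if "cutoff" in pcalls else float("nan")
        if cutoffs is not None and peptide in cutoffs:
            cutoff = cutoffs[peptide].cutoff
        rows.append(
            {
                "peptide": peptide,
                "cutoff": cutoff,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "case_rate": case_rate,
                "control_rate": control_rate,
                "difference": case_rate - control_rate,
                "p_value": fisher_exact_2x2(a, b, c, d),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bonferroni_adjust(
        table["p_value"].to_numpy(), m=m if m is not None else len(table)
    )
    return table


def render_comparison(comparison: pd.DataFrame) -> pd.DataFrame:
    """Report-style rendering with whole-percent rates: peptide, cut-off,
    difference %, "n (rate%)" per group, raw p and Bonferroni-adjusted p."""
    out = pd.DataFrame(
        {
            "peptide": comparison["peptide"],
            "cutoff": comparison["cutoff"],
            "difference": [f"{percent(x)}%" for x in comparison["difference"]],
            "case": [
                f"{a} ({percent(r)}%)"
                for a, r in zip(comparison["a"], comparison["case_rate"])
            ],
            "control": [
                f"{c} ({percent(r)}%)"
                for c, r in zip(comparison["c"], comparison["control_rate"])
            ],
            "p_value": comparison["p_value"],
            "p_adjusted": comparison["p_adjusted"],
        }
    )
    return out


def coverage(
    calls: Iterable[SerostatusCall] | Sequence[bool] | pd.Series,
    peptide: str = "",
    label: str = "",
) -> CoverageSummary:
    """Fraction of seropositive sera in a set (one peptide, one cohort/time).

    Accepts serostatus calls or a boolean sequence; rejects an empty set.
    """
    flags = [
        bool(c.positive) if isinstance(c, SerostatusCall) else bool(c) for c in calls
    ]
    if not flags:
        raise ValueError("coverage undefined for an empty serum set")
    return CoverageSummary(
        peptide=peptide, label=label, n_positive=sum(flags), n_total=len(flags)
    )


def longitudinal_coverage(
    calls: pd.DataFrame,
    timepoints: Sequence[str] = ("preoperative", "postop_day30", "recurrence"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coverage per (peptide, timepoint) plus per-patient SNR trajectories.

    ``calls`` is a flat call table classified against fixed (preoperative
    case-control) cut-offs.  Unknown timepoint labels are rejected.  The
    trajectory table lists, for each patient with more than one timepoint,
    the SNR and serostatus at each sampled time and the transition string
    (e.g. "+/-/+" for seropositive, seroconverted negative at day 30,
    rebound at recurrence).
    """
    unknown = set(calls["timepoint"].unique()) - set(timepoints)
    if unknown:
        raise ValueError(f"unknown timepoint label(s): {sorted(unknown)}")
    cov_rows = []
    for (peptide, timepoint), sub in calls.groupby(["peptide", "timepoint"], sort=True):
        s = coverage(sub["positive"], peptide=str(peptide), label=str(timepoint))
        cov_rows.append(
            {
                "peptide": peptide,
                "timepoint": timepoint,
                "n_positive": s.n_positive,
                "n_total": s.n_total,
                "coverage": s.coverage,
            }
        )
    cov = pd.DataFrame(cov_rows)
    cov["timepoint"] = pd.Categorical(cov["timepoint"], categories=timepoints, ordered=True)
    cov = cov.sort_values(["peptide", "timepoint"]).reset_index(drop=True)

    traj_rows = []
    order = {t: i for i, t in enumerate(timepoints)}
    for (serum_id, peptide), sub in calls.groupby(["serum_id", "peptide"], sort=True):
        if sub["timepoint"].nunique() < 2:
            continue
        sub = sub.sort_values("timepoint", key=lambda s: s.map(order))
        transition = "/".join("+" if p else "-" for p in sub["positive"])
        for _, row in sub.iterrows():
            traj_rows.append(
                {
                    "serum_id": serum_id,
                    "peptide": peptide,
                    "timepoint": row["timepoint"],
                    "snr": row["snr"],
                    "cutoff": row["cutoff"],
                    "positive": row["positive"],
                    "transition": transition,
                }
            )
    traj = pd.DataFrame(
        traj_rows,
        columns=["serum_id", "peptide", "timepoint", "snr", "cutoff", "positive", "transition"],
    )
    return cov, traj


def select_top_peptides(
    comparison: pd.DataFrame, alpha: float = 0.05, k: int = 5
) -> list[str]:
    """Highly responsive peptides: Bonferroni-adjusted p < alpha, ranked by
    case-minus-control rate difference, top k."""
    sig = comparison.loc[comparison["p_adjusted"] < alpha]
    ranked = sig.sort_values(
        ["difference", "peptide"], ascending=[False, True], kind="mergesort"
    )
    return [str(p) for p in ranked["peptide"].head(k)]
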