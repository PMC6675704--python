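"""Recurrence-free survival: Kaplan-Meier, log-rank, Cox with forward selection.

Recurrence-free survival (RFS) is the interval in days from surgery to
observed tumor recurrence (event = 1) or to last follow-up (censored,
event = 0).  Group curves use the Kaplan-Meier product-limit estimator and
are compared with the two-group log-rank test.  Hazard ratios come from a
Cox proportional-hazards model whose partial likelihood is maximized by
Newton iteration; tied event times are handled by the Breslow approximation
by default (Efron available).  Multivariable models are built by forward
selection on the likelihood-ratio test with an entry threshold of p < 0.05
and no removal step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "CoxFit",
    "compute_rfs",
    "records_to_frame",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "forward_selection",
]

_DIVERGENCE_BOUND = 20.0  # |beta| beyond this signals monotone likelihood


@dataclass
class SurvivalRecord:
    """One patient's RFS time (days), event indicator and covariates."""

    subject_id: str
    time: float
    event: int
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.subject_id}: RFS time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"{self.subject_id}: event must be 0 or 1, got {self.event}")


@dataclass
class KMCurve:
    """Product-limit survival estimate with at-risk and event counts."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary."""

    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    null_loglik: float
    converged: bool
    n_iter: int
    n: int
    n_events: int
    tie_method: str
    warnings: list[str] = field(default_factory=list)

    @property
    def hazard_ratio(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.coef - 1.959963984540054 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.coef + 1.959963984540054 * self.se)

    @property
    def wald_p(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def lr_test_vs(self, null_loglik: float | None = None) -> tuple[float, float]:
        """Likelihood-ratio chi-square and p against a nested null."""
        ll0 = self.null_loglik if null_loglik is None else null_loglik
        chi2 = max(0.0, 2.0 * (self.loglik - ll0))
        return chi2, float(stats.chi2.sf(chi2, df=len(self.covariates)))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.coef,
                "HR": self.hazard_ratio,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p_value": self.wald_p,
            }
        )


def compute_rfs(
    surgery_date,
    recurrence_date=None,
    last_followup_date=None,
    subject_id: str = "",
    covariates: Mapping[str, float] | None = None,
) -> SurvivalRecord:
    """RFS from dates: recurrence observed -> event 1 at recurrence - surgery;
    otherwise censored at last follow-up.  Dates parse via pandas."""
    surgery = pd.Timestamp(surgery_date)
    if recurrence_date is not None and not pd.isna(pd.Timestamp(recurrence_date)):
        end = pd.Timestamp(recurrence_date)
        event = 1
        if end < surgery:
            raise ValueError(
                f"{subject_id}: recurrence {end.date()} precedes surgery {surgery.date()}"
            )
    else:
        if last_followup_date is None:
            raise ValueError(f"{subject_id}: need last_followup_date when no recurrence")
        end = pd.Timestamp(last_followup_date)
        event = 0
        if end < surgery:
            raise ValueError(
                f"{subject_id}: follow-up {end.date()} precedes surgery {surgery.date()}"
            )
    days = (end - surgery).days
    if days <= 0:
        raise ValueError(f"{subject_id}: zero-length RFS interval")
    return SurvivalRecord(
        subject_id=subject_id,
        time=float(days),
        event=event,
        covariates=dict(covariates or {}),
    )


def records_to_frame(
    records: Iterable[SurvivalRecord], covariates: Sequence[str] = ()
) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "time": r.time, "event": r.event}
        for name in covariates:
            if name not in r.covariates:
                raise KeyError(f"{r.subject_id}: missing covariate {name!r}")
            row[name] = r.covariates[name]
        rows.append(row)
    return pd.DataFrame(rows)


def _as_frame(records, covariates: Sequence[str] = ()) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records, covariates)


def km_estimate(records) -> KMCurve:
    """Kaplan-Meier product-limit estimate (subjects censored at an event
    time are counted at risk at that time)."""
    frame = _as_frame(records)
    if frame.empty:
        raise ValueError("cannot estimate a survival curve from zero records")
    fitter = KaplanMeierFitter()
    fitter.fit(frame["time"], frame["event"])
    table = fitter.event_table.iloc[1:] if 0.0 in fitter.event_table.index else fitter.event_table
    times = table.index.to_numpy(dtype=float)
    surv = fitter.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        times=times,
        survival=surv,
        n_at_risk=table["at_risk"].to_numpy(dtype=int),
        n_events=table["observed"].to_numpy(dtype=int),
    )


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank test (hypergeometric variance); returns the
    chi-square statistic and its two-sided p from 1 df."""
    fa = _as_frame(group_a)
    fb = _as_frame(group_b)
    if fa.empty or fb.empty:
        raise ValueError("both groups must be non-empty")
    if int(fa["event"].sum() + fb["event"].sum()) == 0:
        raise ValueError("no events in either group: log-rank test undefined")
    res = _lifelines_logrank(fa["time"], fb["time"], fa["event"], fb["event"])
    return float(res.test_statistic), float(res.p_value)


def _cox_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    tie_method: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Cox partial log-likelihood with gradient and Hessian.

    Processes unique times in decreasing order, accumulating risk-set sums
    S0 = sum exp(x'b), S1 = sum x exp(x'b), S2 = sum xx' exp(x'b); ties use
    the Breslow or Efron approximation.
    """
    n, p = X.shape
    raw_eta = X @ beta
    shift = float(raw_eta.max())  # constant offset for exp overflow safety
    w = np.exp(raw_eta - shift)
    order = np.argsort(-time, kind="mergesort")
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        t = time[order[i]]
        j = i
        while j < n and time[order[j]] == t:
            idx = order[j]
            S0 += w[idx]
            S1 += w[idx] * X[idx]
            S2 += w[idx] * np.outer(X[idx], X[idx])
            j += 1
        tied = [order[k] for k in range(i, j) if event[order[k]] == 1]
        d = len(tied)
        if d:
            xs = X[tied].sum(axis=0)
            ll += float(raw_eta[tied].sum())
            if tie_method == "breslow":
                # log of the true risk-set sum = log(S0) + shift
                ll -= d * (np.log(S0) + shift)
                grad += xs - d * S1 / S0
                hess -= d * (S2 / S0 - np.outer(S1, S1) / S0**2)
            elif tie_method == "efron":
                wD = w[tied].sum()
                s1D = (w[tied, None] * X[tied]).sum(axis=0)
                s2D = np.einsum("i,ij,ik->jk", w[tied], X[tied], X[tied])
                grad += xs
                for l in range(d):
                    f = l / d
                    S0l = S0 - f * wD
                    S1l = S1 - f * s1D
                    S2l = S2 - f * s2D
                    ll -= np.log(S0l) + shift
                    grad -= S1l / S0l
                    hess -= S2l / S0l - np.outer(S1l, S1l) / S0l**2
            else:
                raise ValueError(f"unknown tie_method {tie_method!r}")
        i = j
    return ll, grad, hess


def cox_fit(
    records,
    covariates: Sequence[str],
    tie_method: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton iteration.

    Requires at least one event and no constant covariate.  Monotone
    likelihood (perfect separation) is flagged: the fit is returned with
    ``converged=False`` and a diagnostic warning instead of an exception.
    """
    if tie_method not in ("breslow", "efron"):
        raise ValueError(f"unknown tie_method {tie_method!r}")
    frame = _as_frame(records, covariates)
    if not covariates:
        raise ValueError("at least one covariate required")
    missing = [c for c in covariates if c not in frame.columns]
    if missing:
        raise KeyError(f"covariates absent from records: {missing}")
    X = frame[list(covariates)].to_numpy(dtype=float)
    time = frame["time"].to_numpy(dtype=float)
    event = frame["event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events: Cox partial likelihood is flat")
    for k, name in enumerate(covariates):
        if np.ptp(X[:, k]) == 0:
            raise ValueError(f"covariate {name!r} is constant across all records")
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik(beta, X, time, event, tie_method)
    null_ll = ll
    converged = False
    notes: list[str] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            notes.append("singular Hessian; fit did not converge")
            break
        # step-halving to guarantee ascent
        factor = 1.0
        for _ in range(30):
            candidate = beta + factor * step
            ll_new, grad_new, hess_new = _cox_loglik(candidate, X, time, event, tie_method)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        delta = float(np.max(np.abs(candidate - beta)))
        beta, ll, grad, hess = candidate, ll_new, grad_new, hess_new
        if delta < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > _DIVERGENCE_BOUND:
        converged = False
        notes.append(
            "possible monotone likelihood (perfect separation): coefficient "
            f"magnitude exceeds {_DIVERGENCE_BOUND}"
        )
    if not converged and not notes:
        notes.append(f"Newton iteration did not converge in {max_iter} steps")
    for note in notes:
        warnings.warn(note, stacklevel=2)
    with np.errstate(invalid="ignore"):
        cov = np.linalg.pinv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return CoxFit(
        covariates=list(covariates),
        coef=beta,
        se=se,
        loglik=float(ll),
        null_loglik=float(null_ll),
        converged=converged,
        n_iter=n_iter,
        n=len(frame),
        n_events=int(event.sum()),
        tie_method=tie_method,
        warnings=notes,
    )


def forward_selection(
    records,
    candidates: Sequence[str],
    entry_p: float = 0.05,
    tie_method: str = "breslow",
) -> tuple[list[str], CoxFit | None]:
    """Forward selection on the likelihood-ratio test.

    At each step the remaining candidate with the smallest LR p-value below
    ``entry_p`` enters (ties resolved by candidate order); selection stops
    when no candidate qualifies.  Degenerate candidates (constant columns,
    failed fits) are skipped with a warning.  Returns the ordered selected
    covariates and the final fit (``None`` if nothing enters).
    """
    if not candidates:
        raise ValueError("no candidate covariates")
    frame = _as_frame(records, candidates)
    selected: list[str] = []
    current_fit: CoxFit | None = None
    current_ll: float | None = None
    while True:
        best_name, best_fit, best_p = None, None, entry_p
        for name in candidates:
            if name in selected:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = cox_fit(frame, selected + [name], tie_method=tie_method)
            except (ValueError, KeyError) as exc:
                logger.warning("forward selection: skipping %r (%s)", name, exc)
                continue
            ll0 = fit.null_loglik if current_ll is None else current_ll
            chi2 = max(0.0, 2.0 * (fit.loglik - ll0))
            p = float(stats.chi2.sf(chi2, df=1))
            if p < best_p:  # strict: ties keep the earlier candidate
                best_name, best_fit, best_p = name, fit, p
        if best_name is None:
            break
        selected.append(best_name)
        current_fit = best_fit
        current_ll = best_fit.loglik
        logger.info("forward selection: entered %r (LR p=%.4g)", best_name, best_p)
    return selected, current_fit
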