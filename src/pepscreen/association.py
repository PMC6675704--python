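"""Serology-IHC association.

Tumor MGMT expression is dichotomized from immunohistochemistry (IHC) as
positive when more than 10% of cell nuclei stain, and Ki-67 proliferation as
high when more than 20% stain (boundary values fall in the negative/low
class).  The association between autoantibody serostatus and protein
expression is quantified with the nonparametric Spearman rank correlation;
on binary-binary data the midrank Spearman coefficient equals the phi
coefficient of the 2x2 table,

    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)).

Two-sided p-values use the t-approximation by default; an exact permutation
p is available for small samples as a cross-check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IHC_THRESHOLDS",
    "AssociationResult",
    "ihc_call",
    "phi_coefficient",
    "spearman_association",
]

# marker -> (percent threshold, label if above, label if at-or-below)
IHC_THRESHOLDS = {
    "MGMT": (10.0, "positive", "negative"),
    "Ki67": (20.0, "high", "low"),
}


@dataclass(frozen=True)
class AssociationResult:
    r: float
    p_value: float
    n: int
    table: tuple[int, int, int, int] | None  # (a, b, c, d) when both inputs binary
    p_method: str


def ihc_call(percent: float, marker: str) -> str:
    """Dichotomize an IHC staining percentage (MGMT > 10 positive; Ki-67 > 20 high)."""
    if marker not in IHC_THRESHOLDS:
        raise ValueError(f"unknown IHC marker {marker!r}; expected one of {sorted(IHC_THRESHOLDS)}")
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"IHC percentage {percent} outside [0, 100]")
    threshold, above, at_or_below = IHC_THRESHOLDS[marker]
    return above if percent > threshold else at_or_below


def phi_coefficient(a: int, b: int, c: int, d: int) -> float:
    """Closed-form phi for a 2x2 table [[a, b], [c, d]]."""
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError(f"degenerate margin in table {(a, b, c, d)}")
    return (a * d - b * c) / math.sqrt(denom)


def _binary_table(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int] | None:
    if set(np.unique(x)) <= {0.0, 1.0} and set(np.unique(y)) <= {0.0, 1.0}:
        a = int(np.sum((x == 1) & (y == 1)))
        b = int(np.sum((x == 1) & (y == 0)))
        c = int(np.sum((x == 0) & (y == 1)))
        d = int(np.sum((x == 0) & (y == 0)))
        return a, b, c, d
    return None


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # midranks for ties
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Exact two-sided permutation p for Spearman r: P(|r_perm| >= |r_obs|).

    Binary vectors reduce to enumerating the 2x2 table count with
    hypergeometric weights; otherwise all n! permutations are enumerated
    (feasible for n <= 9).
    """
    n = x.size
    tab = _binary_table(x, y)
    tol = 1e-12
    if tab is not None:
        n1 = int(np.sum(x == 1))  # row margin
        m1 = int(np.sum(y == 1))  # column margin
        p = 0.0
        for a in range(max(0, n1 + m1 - n), min(n1, m1) + 1):
            b, c, d = n1 - a, m1 - a, n - n1 - (m1 - a)
            try:
                r_perm = phi_coefficient(a, b, c, d)
            except ValueError:
                r_perm = 0.0
            if abs(r_perm) >= abs(r_obs) - tol:
                p += stats.hypergeom.pmf(a, n, n1, m1)
        return float(min(1.0, p))
    if n > 9:
        raise ValueError(
            f"exact permutation p for non-binary data is limited to n <= 9 (got {n})"
        )
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    hits = 0
    total = 0
    for perm in itertools.permutations(ry):
        r_perm = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
        hits += abs(r_perm) >= abs(r_obs) - tol
        total += 1
    return hits / total


def spearman_association(
    x, y, p_method: str = "t-approx"
) -> AssociationResult:
    """Spearman rank correlation between two paired variables.

    ``p_method`` is ``"t-approx"`` (default; suited to the small-cohort
    sizes this assay produces) or ``"exact"`` (permutation; binary data of
    any moderate n, otherwise n <= 9).  Constant vectors are rejected since
    the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant vector: Spearman correlation undefined")
    r = _spearman_r(x, y)
    if p_method == "t-approx":
        # scipy's spearmanr p-value; identical r via midranks
        rho, p = stats.spearmanr(x, y)
        r = float(rho)
    elif p_method == "exact":
        p = _exact_permutation_p(x, y, r)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return AssociationResult(
        r=r, p_value=float(p), n=n, table=_binary_table(x, y), p_method=p_method
    )
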