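"""Correlation statistics relating plaque burden, freezing, and network dynamics.

Pearson's product-moment correlation is used for trajectory/locomotion-style
data; Spearman's rank correlation (with an exact permutation p-value at small
n) relates plaque burden to freezing; Steiger's Z-test compares two dependent
correlation coefficients that share a variable (e.g. freezing-vs-AI-burden
against freezing-vs-RSC-burden).

The Steiger test applies Fisher-z machinery to whatever coefficients it is
given; when those are rank correlations the normal approximation is the
conventional practice rather than an exact result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sstats

__all__ = [
    "CorrResult",
    "SteigerResult",
    "pearson",
    "spearman",
    "steiger_z",
    "linear_trend",
]

EXACT_PERM_MAX_N = 8


@dataclass(frozen=True)
class CorrResult:
    coefficient: float
    n: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (-1 - 1e-12 <= self.coefficient <= 1 + 1e-12):
            raise ValueError("|coefficient| must be <= 1")
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class SteigerResult:
    z: float
    p_value: float
    r12: float
    r13: float
    r23: float
    n: int
    method: str = "steiger-z1star"


def _check_xy(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return x, y


def pearson(x, y) -> CorrResult:
    """Product-moment correlation with two-sided p from the t-transform (n-2 df)."""
    x, y = _check_xy(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: Pearson correlation undefined")
    res = sstats.pearsonr(x, y)
    return CorrResult(
        coefficient=float(res.statistic),
        n=x.size,
        p_value=float(res.pvalue),
        method="pearson",
    )


def _midranks(v: np.ndarray) -> np.ndarray:
    return sstats.rankdata(v, method="average")


def spearman(x, y, p_mode: str = "auto") -> CorrResult:
    """Rank correlation: Pearson on midranks, with exact permutation p at small n.

    ``p_mode``:
      * ``"auto"`` — exact full-permutation p for n <= 8, t-approximation above;
      * ``"exact"`` — force exhaustive enumeration (n <= 8 only);
      * ``"approx"`` — force the t-approximation.

    The exact two-sided p is the proportion of the n! rank permutations whose
    |r_s| is at least the observed |r_s| (the observed ordering is included,
    so p >= 1/n!).
    """
    x, y = _check_xy(x, y)
    rx, ry = _midranks(x), _midranks(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("all-tied vector: Spearman correlation undefined")
    rs = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size

    if p_mode == "auto":
        p_mode = "exact" if n <= EXACT_PERM_MAX_N else "approx"
    if p_mode == "exact":
        if n > EXACT_PERM_MAX_N:
            raise ValueError(f"exact permutation p limited to n <= {EXACT_PERM_MAX_N}")
        rxc = rx - rx.mean()
        denom = np.sqrt((rxc @ rxc)) * np.sqrt(((ry - ry.mean()) ** 2).sum())
        obs = abs(rs)
        hits = 0
        total = 0
        ryc = ry - ry.mean()
        for perm in permutations(range(n)):
            r_perm = float(rxc @ ryc[list(perm)]) / denom
            if abs(r_perm) >= obs - 1e-12:
                hits += 1
            total += 1
        p = hits / total
        method = "spearman-exact"
    elif p_mode == "approx":
        if abs(rs) >= 1.0:
            p = 0.0
        else:
            t = rs * math.sqrt((n - 2) / (1 - rs * rs))
            p = 2 * sstats.t.sf(abs(t), df=n - 2)
        method = "spearman-t"
    else:
        raise ValueError(f"unknown p_mode {p_mode!r}")
    return CorrResult(coefficient=rs, n=n, p_value=float(min(p, 1.0)), method=method)


def _check_corr_triple(r12: float, r13: float, r23: float) -> None:
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not abs(r) < 1:
            raise ValueError(f"|{name}| must be < 1 for the Fisher transform")
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if det < -1e-12:
        raise ValueError(
            "correlation triple is not positive semi-definite "
            f"(|R| = {det:.3g} < 0); no data set can produce it"
        )


def steiger_z(r12: float, r13: float, r23: float, n: int, variant: str = "z1star") -> SteigerResult:
    """Compare two dependent correlations sharing variable 1.

    Tests H0: rho12 = rho13 given the correlation r23 between the two
    non-shared variables.  Default is the pooled-estimate Z1* variant: both
    coefficients are Fisher-z transformed, their covariance term is computed
    with the pooled mean r̄ = (r12 + r13)/2, and

        Z = (z12 - z13) * sqrt((n - 3) / (2 - 2*s)),
        s = psi / (1 - rbar^2)^2,
        psi = r23 (1 - 2 rbar^2) - (rbar^2 / 2) (1 - 2 rbar^2 - r23^2)

    with a two-sided normal p.  ``variant="williams-t2"`` gives Williams'
    T2 with a t reference distribution (n - 3 df) instead.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    _check_corr_triple(r12, r13, r23)

    if variant == "z1star":
        z12 = math.atanh(r12)
        z13 = math.atanh(r13)
        rbar = (r12 + r13) / 2
        psi = r23 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)
        s = psi / (1 - rbar**2) ** 2
        z = (z12 - z13) * math.sqrt((n - 3) / (2 - 2 * s))
        p = 2 * sstats.norm.sf(abs(z))
        return SteigerResult(z=float(z), p_value=float(min(p, 1.0)), r12=r12, r13=r13,
                             r23=r23, n=n, method="steiger-z1star")
    if variant == "williams-t2":
        detR = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
        rbar = (r12 + r13) / 2
        denom = 2 * detR * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3
        t2 = (r12 - r13) * math.sqrt((n - 1) * (1 + r23) / denom)
        p = 2 * sstats.t.sf(abs(t2), df=n - 3)
        return SteigerResult(z=float(t2), p_value=float(min(p, 1.0)), r12=r12, r13=r13,
                             r23=r23, n=n, method="williams-t2")
    raise ValueError(f"unknown variant {variant!r}")


def linear_trend(y: np.ndarray, x: np.ndarray | None = None) -> tuple[float, float]:
    """Ordinary least-squares line through (x, y); returns (slope, intercept).

    ``x`` defaults to the 0-based index, the convention used for
    quarter-trajectory trend lines.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 points for a trend line")
    x = np.arange(y.size, dtype=float) if x is None else np.asarray(x, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
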