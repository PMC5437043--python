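"""Self-contained statistical kernels used throughout the analysis.

Three procedures are needed: tie-corrected Spearman rank correlation
(p from the t approximation with n-2 df), the two-sided Mann-Whitney U
test (exact by enumeration for small samples, normal approximation with
tie and continuity corrections otherwise), and an ordinary least-squares
line with R^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import rankdata, t as t_dist


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    method: str
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


def spearman(x, y) -> StatResult:
    """Tie-corrected Spearman rank correlation with a t-approximation p.

    Midranks are assigned to ties and Pearson's r is computed on the
    ranks; p is two-sided from ``t = r * sqrt((n-2) / (1-r^2))`` with
    n-2 degrees of freedom.  Raises ``ValueError`` for constant input
    (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    r = float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t_stat = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * t_dist.sf(abs(t_stat), df=n - 2))
    return StatResult(statistic=r, p_value=min(p, 1.0), method="spearman", n=n)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: wins over b plus half ties (midrank formulation)."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    r_a = ranks[:n_a].sum()
    return float(r_a - n_a * (n_a + 1) / 2.0)


def mann_whitney_two_sided(a, b, exact_max_n: int = 12) -> StatResult:
    """Two-sided Mann-Whitney U test.

    The exact p is ``P(|U - mn/2| >= |u_obs - mn/2|)`` under the
    permutation null, computed by enumerating all C(m+n, m) group
    assignments of the pooled data when ``len(a)+len(b) <= exact_max_n``.
    Larger samples use the normal approximation with the tie-corrected
    variance and a 0.5 continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    u_obs = _u_statistic(a, b)
    mu = n_a * n_b / 2.0
    pooled = np.concatenate([a, b])
    n = n_a + n_b

    if n <= exact_max_n:
        dev = abs(u_obs - mu)
        hits = total = 0
        idx = np.arange(n)
        for subset in combinations(idx, n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(subset)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        p = hits / total
        method = "mann-whitney-exact"
    else:
        ranks = rankdata(pooled)
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
        sigma2 = n_a * n_b / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:  # all observations tied
            return StatResult(statistic=u_obs, p_value=1.0,
                              method="mann-whitney-normal", n=n)
        z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
        z = max(z, 0.0)
        p = float(min(1.0, math.erfc(z / math.sqrt(2.0))))
        method = "mann-whitney-normal"
    return StatResult(statistic=u_obs, p_value=p, method=method, n=n)


def ols_line(x, y) -> tuple[float, float, float]:
    """Least-squares line ``y = slope*x + intercept`` and R^2.

    R^2 = 1 - SSE/SST; for a constant y the fit is flat with R^2 = 0.
    Constant x raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors with >= 2 points")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    slope = float(xc @ yc / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    sst = float(yc @ yc)
    if sst == 0:
        return slope, intercept, 0.0 if slope == 0 else 1.0
    sse = float(((y - slope * x - intercept) ** 2).sum())
    return slope, intercept, 1.0 - sse / sst
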