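"""Summary statistics and Spearman rank correlation.

Used to relate a trial's per-criterion complexity scores to the word count
and reading grade level of the criterion texts: complexity captures the
computational burden of automated screening, readability the burden on a
human screener, and the rank correlation asks whether harder-to-read
criteria are also harder to compute.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["CorrelationResult", "median_iqr", "spearman", "StatsError"]


class StatsError(ValueError):
    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"{code}: {message}")


def median_iqr(
    values: Sequence[float], method: str = "linear"
) -> tuple[float, float, float]:
    """(median, q1, q3) with a selectable quantile interpolation method.

    ``method`` is any quantile method numpy accepts (``linear`` by default,
    the common interpolated-order-statistic rule).
    """
    if len(values) == 0:
        raise StatsError("EMPTY", "median_iqr of an empty list")
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method=method)
    return float(med), float(q1), float(q3)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str  # "t_approximation" | "exact_permutation"


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    # Pearson correlation of the two rank vectors
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t_approximation",
) -> CorrelationResult:
    """Spearman rank correlation with average-rank tie handling.

    rho is the Pearson correlation of the rank vectors.  The two-sided
    p-value uses the t approximation with n-2 degrees of freedom by default;
    ``method="exact_permutation"`` enumerates all n! permutations of one rank
    vector (n <= 10) and reports the exact two-sided tail probability.

    Constant inputs leave rho undefined and raise ``CONSTANT_INPUT``.
    """
    if len(x) != len(y):
        raise StatsError("LENGTH_MISMATCH", "x and y differ in length")
    n = len(x)
    if n < 3:
        raise StatsError("TOO_FEW", "need n >= 3 for a rank correlation")
    if method not in ("t_approximation", "exact_permutation"):
        raise StatsError("BAD_METHOD", f"unknown method {method!r}")
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise StatsError("CONSTANT_INPUT", "rho undefined for a constant vector")
    rx = sps.rankdata(xa, method="average")
    ry = sps.rankdata(ya, method="average")
    rho = _rank_rho(rx, ry)

    if method == "exact_permutation":
        if n > 10:
            raise StatsError("TOO_LARGE", "exact permutation limited to n <= 10")
        eps = 1e-12
        hits = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_rho(rx, np.asarray(perm))) >= abs(rho) - eps:
                hits += 1
        return CorrelationResult(rho, hits / total, n, method)

    if abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, p, n, method)
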