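"""Small deterministic 1-D maximizers shared by the calibration and HMM modules."""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0  # 1/phi


def golden_section_max(
    f: Callable[[float], float],
    lo: float,
    hi: float,
    rel_tol: float = 1e-3,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Golden-section maximization of ``f`` on [lo, hi].

    Deterministic; terminates when the bracket width falls below
    ``rel_tol * |mid|`` (relative) or after ``max_iter`` shrink steps.
    Returns ``(argmax, f(argmax))``.
    """
    if not (lo < hi):
        raise ValueError("need lo < hi")
    a, b = float(lo), float(hi)
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        if (b - a) <= rel_tol * max(abs(mid), 1e-300):
            break
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    x = c if fc >= fd else d
    return x, max(fc, fd)


def grid_then_golden_max(
    f: Callable[[float], float],
    grid: Sequence[float],
    rel_tol: float = 1e-3,
    log_domain: bool = True,
) -> tuple[float, float]:
    """Coarse-grid scan followed by golden-section refinement around the best point.

    With ``log_domain`` the golden search runs on log(x), appropriate for
    scale parameters such as mutation rates or pulse ages.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 3:
        raise ValueError("grid must be 1-D with at least 3 points")
    vals = np.array([f(x) for x in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    if lo == hi:  # degenerate single point
        return float(grid[i]), float(vals[i])
    if log_domain:
        x, fx = golden_section_max(
            lambda u: f(math.exp(u)), math.log(lo), math.log(hi), rel_tol=rel_tol
        )
        return math.exp(x), fx
    return golden_section_max(f, lo, hi, rel_tol=rel_tol)
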