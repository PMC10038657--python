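"""I/O and unit conversions for sequentially-Markovian-coalescent output.

This module consumes the tab-separated tables produced by MSMC2-style
cross-coalescence inference and MSMC-IM-style isolation-with-migration
post-processing.  Times in these files are *mutation-scaled*: a scaled time t
corresponds to t/mu generations, i.e. (t/mu)*g calendar years, where mu is the
per-site per-generation mutation rate and g the generation time in years.
Conversions here fix the following conventions, which differ between tools by
factors of two and are therefore stated explicitly:

* years before present  = (scaled_time / mu) * g
* diploid effective size Ne = 1 / (2 * lambda00 * mu), with lambda00 the
  within-population coalescence rate in scaled units
* relative cross-coalescence rCCR = 2*lambda01 / (lambda00 + lambda11)

The open right boundary of the last time segment is encoded as the string
``inf`` on disk and ``numpy.inf`` in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScalingFactor",
    "CoalRateTable",
    "MigrationTrajectory",
    "CoalParseError",
    "read_coal_rate_table",
    "write_coal_rate_table",
    "read_migration_trajectory",
    "write_migration_trajectory",
    "relative_cross_coalescence",
    "effective_size",
    "scale_to_years",
    "years_to_scaled",
]


class CoalParseError(ValueError):
    """Raised for malformed coalescent-output files; names the offending line."""


@dataclass(frozen=True)
class ScalingFactor:
    """Coalescent clock: mutation rate, generation time and calendar anchor.

    Parameters
    ----------
    mu : mutations per site per generation (> 0).
    g : years per generation (> 0).
    present_year : calendar year that "0 years before present" refers to.
    """

    mu: float
    g: float
    present_year: float = 2017.0

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if not self.g > 0:
            raise ValueError(f"g must be > 0, got {self.g}")

    @property
    def years_per_scaled_time(self) -> float:
        return self.g / self.mu


def _check_boundaries(left: np.ndarray, right: np.ndarray, where: str = "table"):
    if left.size == 0:
        raise CoalParseError(f"{where}: empty table")
    if left[0] != 0.0:
        raise CoalParseError(f"{where}: first left boundary must be 0, got {left[0]}")
    if np.any(right <= left):
        i = int(np.argmax(right <= left))
        raise CoalParseError(
            f"{where}: right boundary <= left boundary at segment {i} "
            f"(data line {i + 2})"
        )
    if np.any(np.diff(left) <= 0) or np.any(np.diff(right[:-1]) <= 0):
        raise CoalParseError(f"{where}: boundaries not strictly increasing")


@dataclass
class CoalRateTable:
    """Piecewise-constant coalescence rates over scaled-time segments.

    ``lambda01``/``lambda11`` are ``None`` for single-population files.
    """

    left: np.ndarray
    right: np.ndarray
    lambda00: np.ndarray
    lambda01: np.ndarray | None = None
    lambda11: np.ndarray | None = None

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.lambda00 = np.asarray(self.lambda00, dtype=float)
        if (self.lambda01 is None) != (self.lambda11 is None):
            raise ValueError("lambda01 and lambda11 must be given together")
        if self.lambda01 is not None:
            self.lambda01 = np.asarray(self.lambda01, dtype=float)
            self.lambda11 = np.asarray(self.lambda11, dtype=float)
        _check_boundaries(self.left, self.right)
        for name in ("lambda00", "lambda01", "lambda11"):
            lam = getattr(self, name)
            if lam is None:
                continue
            if lam.shape != self.left.shape:
                raise CoalParseError(f"{name}: wrong length")
            if np.any(lam < 0):
                i = int(np.argmax(lam < 0))
                raise CoalParseError(
                    f"negative rate in column {name} at segment {i} (data line {i + 2})"
                )

    @property
    def n_segments(self) -> int:
        return self.left.size

    @property
    def has_cross(self) -> bool:
        return self.lambda01 is not None

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "time_index": np.arange(self.n_segments),
            "left_time_boundary": self.left,
            "right_time_boundary": self.right,
            "lambda_00": self.lambda00,
        }
        if self.has_cross:
            cols["lambda_01"] = self.lambda01
            cols["lambda_11"] = self.lambda11
        return pd.DataFrame(cols)


@dataclass
class MigrationTrajectory:
    """Piecewise-constant migration density m(t) and cumulative migration M(t).

    ``M[i]`` is the cumulative migration probability at the *right* edge of
    segment i; it is non-decreasing, bounded by [0, 1] and is expected to
    plateau at 1 at the oldest boundary once the two populations have merged
    into a single ancestral population.
    """

    left: np.ndarray
    right: np.ndarray
    m: np.ndarray
    M: np.ndarray

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        _check_boundaries(self.left, self.right, where="trajectory")
        if self.m.shape != self.left.shape or self.M.shape != self.left.shape:
            raise CoalParseError("trajectory: m/M wrong length")
        if np.any(self.m < 0):
            raise CoalParseError("trajectory: negative migration density")
        if np.any(self.M < -1e-9) or np.any(self.M > 1 + 1e-9):
            raise CoalParseError("trajectory: M outside [0, 1]")
        if np.any(np.diff(self.M) < -1e-9):
            raise CoalParseError("trajectory: M not non-decreasing")
        # piecewise-constant density convention: M_right = M_left + m * width
        width = self.right - self.left
        finite = np.isfinite(width)
        if np.any(~finite & (self.m > 0)):
            raise CoalParseError("trajectory: positive m on an infinite segment")
        expected = np.concatenate([[0.0], self.M[:-1]]) + np.where(
            finite, self.m * np.where(finite, width, 0.0), 0.0
        )
        if np.any(np.abs(expected - self.M) > 1e-6 * max(1.0, float(self.M.max(initial=0)))):
            raise CoalParseError(
                "trajectory: M inconsistent with piecewise-constant m "
                "(M_right must equal M_left + m*width)"
            )

    @property
    def n_segments(self) -> int:
        return self.left.size

    @property
    def mass(self) -> np.ndarray:
        """Migration mass per segment (m * width; 0 on infinite segments)."""
        width = self.right - self.left
        return np.where(np.isfinite(width), self.m * np.where(np.isfinite(width), width, 0.0), 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "left_time_boundary": self.left,
                "right_time_boundary": self.right,
                "m": self.m,
                "M": self.M,
            }
        )


# ---------------------------------------------------------------------------
# file I/O


def read_coal_rate_table(path: str | Path) -> CoalRateTable:
    """Read an MSMC2-style combined rate table.

    Expects a tab-separated header line with columns ``time_index``,
    ``left_time_boundary``, ``right_time_boundary`` and either a single
    ``lambda`` (or ``lambda_00``) column or all of ``lambda_00``,
    ``lambda_01``, ``lambda_11``.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise CoalParseError(f"{path}: cannot parse: {exc}") from exc
    cols = set(df.columns)
    required = {"time_index", "left_time_boundary", "right_time_boundary"}
    if not required <= cols:
        raise CoalParseError(
            f"{path}: malformed header, missing {sorted(required - cols)} (line 1)"
        )
    if {"lambda_00", "lambda_01", "lambda_11"} <= cols:
        lam00, lam01, lam11 = df["lambda_00"], df["lambda_01"], df["lambda_11"]
    elif "lambda_00" in cols:
        lam00, lam01, lam11 = df["lambda_00"], None, None
    elif "lambda" in cols:
        lam00, lam01, lam11 = df["lambda"], None, None
    else:
        raise CoalParseError(f"{path}: malformed header, no lambda column (line 1)")
    return CoalRateTable(
        left=df["left_time_boundary"].to_numpy(float),
        right=df["right_time_boundary"].to_numpy(float),
        lambda00=np.asarray(lam00, dtype=float),
        lambda01=None if lam01 is None else np.asarray(lam01, dtype=float),
        lambda11=None if lam11 is None else np.asarray(lam11, dtype=float),
    )


def write_coal_rate_table(table: CoalRateTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_migration_trajectory(path: str | Path) -> MigrationTrajectory:
    """Read an MSMC-IM-style trajectory (columns left/right_time_boundary, m, M).

    Extra columns (e.g. per-population Ne estimates) are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"left_time_boundary", "right_time_boundary", "m", "M"}
    missing = required - set(df.columns)
    if missing:
        raise CoalParseError(f"{path}: malformed header, missing {sorted(missing)} (line 1)")
    return MigrationTrajectory(
        left=df["left_time_boundary"].to_numpy(float),
        right=df["right_time_boundary"].to_numpy(float),
        m=df["m"].to_numpy(float),
        M=df["M"].to_numpy(float),
    )


def write_migration_trajectory(traj: MigrationTrajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# conversions


def relative_cross_coalescence(table: CoalRateTable) -> np.ndarray:
    """Per-segment relative cross-coalescence rate 2*l01/(l00+l11).

    Near 0 for isolated populations, near 1 once they have merged.
    """
    if not table.has_cross:
        raise ValueError("table has no cross-coalescence (lambda_01) column")
    denom = table.lambda00 + table.lambda11
    if np.any(denom <= 0):
        i = int(np.argmax(denom <= 0))
        raise ValueError(f"lambda00 + lambda11 is zero at segment {i}")
    return 2.0 * table.lambda01 / denom


def effective_size(table: CoalRateTable, s: ScalingFactor) -> pd.DataFrame:
    """Per-segment diploid effective size with calendar-time boundaries.

    Ne = 1/(2*lambda00*mu); segment boundaries are returned in years before
    present via :func:`scale_to_years`.
    """
    if np.any(table.lambda00 <= 0):
        i = int(np.argmax(table.lambda00 <= 0))
        raise ValueError(f"lambda00 is zero at segment {i}; Ne undefined")
    return pd.DataFrame(
        {
            "left_years_bp": scale_to_years(table.left, s),
            "right_years_bp": scale_to_years(table.right, s),
            "Ne": 1.0 / (2.0 * table.lambda00 * s.mu),
        }
    )


def scale_to_years(scaled_times, s: ScalingFactor) -> np.ndarray:
    """Convert mutation-scaled times to years before present: (t/mu)*g."""
    t = np.asarray(scaled_times, dtype=float)
    if np.any(t[np.isfinite(t)] < 0):
        raise ValueError("scaled times must be non-negative")
    return t * (s.g / s.mu)


def years_to_scaled(years, s: ScalingFactor) -> np.ndarray:
    """Inverse of :func:`scale_to_years`: years before present -> scaled time."""
    y = np.asarray(years, dtype=float)
    if np.any(y[np.isfinite(y)] < 0):
        raise ValueError("years must be non-negative")
    return y * (s.mu / s.g)
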