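"""Half-open genomic-interval arithmetic shared by masking and power scoring."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 0-based half-open BED file (first three columns)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    if len(starts) == 0:
        return np.array([], dtype=float), np.array([], dtype=float)
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts, dtype=float)[order], np.asarray(ends, dtype=float)[order]
    ms, me = [s[0]], [e[0]]
    for i in range(1, s.size):
        if s[i] <= me[-1]:
            me[-1] = max(me[-1], e[i])
        else:
            ms.append(s[i])
            me.append(e[i])
    return np.asarray(ms), np.asarray(me)


def points_in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask: which points fall inside any merged half-open interval."""
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    ms, me = merge_intervals(starts, ends)
    idx = np.searchsorted(ms, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < me[idx[ok]]
    return out


def overlap_length(
    a_starts, a_ends, b_starts, b_ends
) -> float:
    """Total length of the intersection of two interval sets (same chromosome)."""
    a_s, a_e = merge_intervals(np.asarray(a_starts), np.asarray(a_ends))
    b_s, b_e = merge_intervals(np.asarray(b_starts), np.asarray(b_ends))
    total, i, j = 0.0, 0, 0
    while i < a_s.size and j < b_s.size:
        lo = max(a_s[i], b_s[j])
        hi = min(a_e[i], b_e[j])
        if hi > lo:
            total += hi - lo
        if a_e[i] < b_e[j]:
            i += 1
        else:
            j += 1
    return total


def total_length(starts, ends) -> float:
    s, e = merge_intervals(np.asarray(starts), np.asarray(ends))
    return float(np.sum(e - s))
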