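"""Peak-set comparisons across factors and treatment conditions.

Peak sets are DataFrames with ``chrom``, ``start``, ``end`` (0-based,
half-open) plus optional ``name``, ``tags``, ``factor`` and ``condition``
columns.  Two intervals overlap iff they share at least one base pair.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def normalize_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Validate and sort a peak table by (chrom, start, end)."""
    if np.any(peaks["start"].to_numpy() >= peaks["end"].to_numpy()):
        bad = peaks.index[peaks["start"] >= peaks["end"]].tolist()
        raise ValueError(f"intervals with start >= end at rows {bad}")
    return peaks.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def _overlap_flags(set_a: pd.DataFrame, set_b: pd.DataFrame) -> np.ndarray:
    """Per-peak flag: does this A interval intersect any B interval?"""
    flags = np.zeros(len(set_a), dtype=bool)
    for chrom, bsub in set_b.groupby("chrom"):
        asel = set_a["chrom"] == chrom
        if not asel.any():
            continue
        b = bsub.sort_values("start", kind="mergesort")
        b_starts = b["start"].to_numpy(dtype=np.int64)
        b_endmax = np.maximum.accumulate(b["end"].to_numpy(dtype=np.int64))
        a_start = set_a.loc[asel, "start"].to_numpy(dtype=np.int64)
        a_end = set_a.loc[asel, "end"].to_numpy(dtype=np.int64)
        # candidates: B intervals starting before a_end
        idx = np.searchsorted(b_starts, a_end, side="left")
        hit = (idx > 0) & (np.where(idx > 0, b_endmax[idx - 1], 0) > a_start)
        flags[np.flatnonzero(asel.to_numpy())] = hit
    return flags


def overlap_fraction(set_a: pd.DataFrame, set_b: pd.DataFrame) -> tuple[int, float]:
    """Number and fraction of A peaks overlapping any B peak (>= 1 bp)."""
    if len(set_a) == 0:
        raise ValueError("overlap fraction undefined for an empty peak set")
    n = int(_overlap_flags(set_a, set_b).sum())
    return n, n / len(set_a)


def subset_report(set_a: pd.DataFrame, set_b: pd.DataFrame) -> tuple[int, int]:
    """How many of A's peaks fall within B — reported as (x, y) for
    "x out of y"."""
    n = int(_overlap_flags(set_a, set_b).sum()) if len(set_a) else 0
    return n, len(set_a)


def tags_at_sites(
    sites: pd.DataFrame, signal_by_condition: dict
) -> pd.DataFrame:
    """Per-site tag counts per condition from overlapping signal regions.

    ``signal_by_condition`` maps a condition label to a peak table with a
    ``tags`` column; each site receives the summed tags of all
    overlapping signal regions (0 when none, logged).
    """
    out = pd.DataFrame(index=sites["name"] if "name" in sites else sites.index)
    for cond, signal in signal_by_condition.items():
        counts = np.zeros(len(sites), dtype=float)
        for chrom, ssub in signal.groupby("chrom"):
            sel = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
            if sel.size == 0:
                continue
            s_start = ssub["start"].to_numpy()
            s_end = ssub["end"].to_numpy()
            s_tags = ssub["tags"].to_numpy(dtype=float)
            a_start = sites.iloc[sel]["start"].to_numpy()
            a_end = sites.iloc[sel]["end"].to_numpy()
            ov = (s_start[None, :] < a_end[:, None]) & (s_end[None, :] > a_start[:, None])
            counts[sel] = ov @ s_tags
        n_zero = int((counts == 0).sum())
        if n_zero:
            logger.info("%d sites with no %s signal (count 0)", n_zero, cond)
        out[cond] = counts
    return out
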