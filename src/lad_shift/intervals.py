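"""Interval algebra on genomic (chrom, start, end) tables.

All coordinates are 0-based half-open (BED convention). Interval sets are
plain pandas DataFrames with at least ``chrom``, ``start``, ``end`` columns;
extra columns are carried through where the operation allows it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def empty_intervals(extra: list[str] | None = None) -> pd.DataFrame:
    cols = INTERVAL_COLUMNS + (extra or [])
    return pd.DataFrame({c: pd.Series(dtype=object if c == "chrom" else "int64" if c in ("start", "end") else float) for c in cols})


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def total_bp(df: pd.DataFrame) -> int:
    if len(df) == 0:
        return 0
    return int((df["end"] - df["start"]).sum())


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Union of intervals, additionally bridging gaps strictly smaller than `gap` bp.

    gap=0 merges only overlapping/abutting intervals (a zero-length gap is
    bridged because ``next_start - end < gap`` is then ``0 < 0`` == False;
    abutting intervals share a boundary and are merged via ``<=``).
    """
    if len(df) == 0:
        return empty_intervals()
    df = sort_intervals(df[INTERVAL_COLUMNS])
    out = []
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e < gap or s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLUMNS)


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Set difference a \\ b (both flattened first)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    if len(a) == 0:
        return empty_intervals()
    if len(b) == 0:
        return a
    out = []
    b_by_chrom = dict(tuple(b.groupby("chrom", sort=False)))
    for chrom, sub in a.groupby("chrom", sort=False):
        if chrom not in b_by_chrom:
            out.extend((chrom, s, e) for s, e in zip(sub["start"], sub["end"]))
            continue
        bs = b_by_chrom[chrom]["start"].to_numpy()
        be = b_by_chrom[chrom]["end"].to_numpy()
        for s, e in zip(sub["start"], sub["end"]):
            cur = s
            # b intervals overlapping [s, e)
            i0 = np.searchsorted(be, s, side="right")
            for j in range(i0, len(bs)):
                if bs[j] >= e:
                    break
                if bs[j] > cur:
                    out.append((chrom, cur, int(bs[j])))
                cur = max(cur, int(be[j]))
            if cur < e:
                out.append((chrom, cur, e))
    if not out:
        return empty_intervals()
    return pd.DataFrame(out, columns=INTERVAL_COLUMNS)


def intersect_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Total overlapping base pairs between the unions of a and b."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    bp = 0
    b_by_chrom = dict(tuple(b.groupby("chrom", sort=False)))
    for chrom, sub in a.groupby("chrom", sort=False):
        if chrom not in b_by_chrom:
            continue
        bs = b_by_chrom[chrom]["start"].to_numpy()
        be = b_by_chrom[chrom]["end"].to_numpy()
        for s, e in zip(sub["start"], sub["end"]):
            lo = np.maximum(bs, s)
            hi = np.minimum(be, e)
            ov = hi - lo
            bp += int(ov[ov > 0].sum())
    return bp


def jaccard(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Base-pair Jaccard index between two interval sets."""
    inter = intersect_bp(a, b)
    union = total_bp(merge_intervals(pd.concat([a[INTERVAL_COLUMNS], b[INTERVAL_COLUMNS]], ignore_index=True)))
    if union == 0:
        return float("nan")
    return inter / union


def overlaps_any(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: overlaps >=1 bp with any target interval."""
    result = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(targets) == 0:
        return result
    t = merge_intervals(targets)
    t_by_chrom = dict(tuple(t.groupby("chrom", sort=False)))
    query = query.reset_index(drop=True)
    for chrom, sub in query.groupby("chrom", sort=False):
        if chrom not in t_by_chrom:
            continue
        ts = t_by_chrom[chrom]["start"].to_numpy()
        te = t_by_chrom[chrom]["end"].to_numpy()
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        # overlap iff some target j with ts[j] < q.end and te[j] > q.start;
        # targets are disjoint+sorted, so check the running-max end among
        # all targets starting before q.end
        idx = np.searchsorted(ts, qe, side="left") - 1
        cummax_end = np.maximum.accumulate(te)
        hit = (idx >= 0) & (cummax_end[np.clip(idx, 0, None)] > qs)
        result[sub.index] = hit
    return result


def precision_recall_bp(called: pd.DataFrame, truth: pd.DataFrame) -> tuple[float, float]:
    """Base-pair precision/recall of a called interval set vs ground truth."""
    tp = intersect_bp(called, truth)
    called_bp = total_bp(merge_intervals(called))
    truth_bp = total_bp(merge_intervals(truth))
    precision = tp / called_bp if called_bp else float("nan")
    recall = tp / truth_bp if truth_bp else float("nan")
    return precision, recall
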