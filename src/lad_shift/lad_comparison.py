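"""Cross-condition LAD clustering, intersection classes and summary tables.

LAD boundaries rarely coincide exactly between conditions, so LADs are
grouped into clusters of overlapping intervals across all conditions
(single-linkage by >=1 bp overlap). Each cluster carries a membership
signature — the set of conditions contributing at least one LAD — from
which shared/unique counts and genomic coverages are tallied (the numbers
behind proportional Venn / Chow-Ruskey accounting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import merge_intervals, overlaps_any


@dataclass
class LADCluster:
    chrom: str
    start: int  # footprint = union of member LADs
    end: int
    signature: frozenset[str]
    members: pd.DataFrame = field(repr=False)  # chrom/start/end/condition


def cluster_lads(lad_sets: dict[str, pd.DataFrame]) -> list[LADCluster]:
    """Single-linkage clustering of LADs across conditions by interval overlap.

    Invariant to condition ordering and to interval ordering within a set.
    """
    if not lad_sets:
        return []
    frames = []
    for condition, lads in lad_sets.items():
        if len(lads) == 0:
            continue
        df = lads[["chrom", "start", "end"]].copy()
        df["condition"] = condition
        frames.append(df)
    if not frames:
        return []
    allads = pd.concat(frames, ignore_index=True)
    allads = allads.sort_values(["chrom", "start", "end", "condition"], kind="mergesort")
    clusters: list[LADCluster] = []
    for chrom, sub in allads.groupby("chrom", sort=True):
        sub = sub.reset_index(drop=True)
        cur_rows = [0]
        cur_end = int(sub.loc[0, "end"])
        cur_start = int(sub.loc[0, "start"])
        for i in range(1, len(sub)):
            s, e = int(sub.loc[i, "start"]), int(sub.loc[i, "end"])
            if s < cur_end:  # strict overlap (>=1 bp); abutting intervals do not chain
                cur_rows.append(i)
                cur_end = max(cur_end, e)
            else:
                clusters.append(_make_cluster(chrom, cur_start, cur_end, sub.loc[cur_rows]))
                cur_rows = [i]
                cur_start, cur_end = s, e
        clusters.append(_make_cluster(chrom, cur_start, cur_end, sub.loc[cur_rows]))
    return clusters


def _make_cluster(chrom, start, end, members: pd.DataFrame) -> LADCluster:
    return LADCluster(chrom=chrom, start=start, end=end,
                      signature=frozenset(members["condition"]),
                      members=members.reset_index(drop=True))


def intersection_counts(clusters: list[LADCluster]) -> pd.DataFrame:
    """Per exact membership signature: number of clusters and coverage in bp.

    Coverage is the union of the member LADs of the signature's clusters
    (for singleton signatures this equals the footprints).
    """
    by_sig: dict[frozenset, list[LADCluster]] = {}
    for cl in clusters:
        by_sig.setdefault(cl.signature, []).append(cl)
    rows = []
    for sig, cls in by_sig.items():
        members = pd.concat([c.members for c in cls], ignore_index=True)
        bp = int((lambda m: (m["end"] - m["start"]).sum())(merge_intervals(members)))
        rows.append(("+".join(sorted(sig)), len(cls), bp))
    out = pd.DataFrame(rows, columns=["signature", "n_clusters", "coverage_bp"])
    return out.sort_values("signature").reset_index(drop=True)


def summarize(intervals: pd.DataFrame, genes: pd.DataFrame | None, genome_size: int,
              label: str = "") -> dict:
    """One summary row: n, coverage (bp and % of genome), size range/mean/median,
    and the number of genes overlapping >=1 interval."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    n = len(intervals)
    if n == 0:
        return {"label": label, "n": 0, "coverage_bp": 0, "coverage_pct": 0.0,
                "min_size": None, "max_size": None, "mean_size": None, "median_size": None,
                "n_genes": 0}
    sizes = (intervals["end"] - intervals["start"]).to_numpy()
    coverage = int((lambda m: (m["end"] - m["start"]).sum())(merge_intervals(intervals)))
    n_genes = 0
    if genes is not None and len(genes):
        n_genes = int(overlaps_any(genes, intervals).sum())
    return {
        "label": label,
        "n": n,
        "coverage_bp": coverage,
        "coverage_pct": 100.0 * coverage / genome_size,
        "min_size": int(sizes.min()),
        "max_size": int(sizes.max()),
        "mean_size": float(sizes.mean()),
        "median_size": float(np.median(sizes)),
        "n_genes": n_genes,
    }


def summary_table(interval_sets: dict[str, pd.DataFrame], genes: pd.DataFrame | None,
                  genome_size: int) -> pd.DataFrame:
    return pd.DataFrame([summarize(df, genes, genome_size, label)
                         for label, df in interval_sets.items()])
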