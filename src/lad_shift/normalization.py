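"""From paired count tracks to smoothed, quantile-normalized log2 ratios.

The peripheral-association signal for each DpnI fragment is
log2(Dam-LaminB1 / Dam-alone). Counts are scaled by library size before the
ratio so conditions sequenced to different depths remain comparable, and a
small pseudocount keeps single-sample zeros finite; fragments with zero
counts in both samples carry no information and become missing (NaN).
Tracks from different conditions are then quantile normalized jointly and
smoothed along the fragment backbone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .fragment_map import CountTrack, FragmentMap

logger = logging.getLogger(__name__)


@dataclass
class SignalTrack:
    """Fragment-aligned real-valued signal (NaN = missing)."""

    values: np.ndarray
    stage: str = "raw_ratio"  # raw_ratio | normalized | smoothed
    condition: str = ""
    fragment_map: FragmentMap | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def log2_ratio(lamin: CountTrack, dam: CountTrack, pseudocount: float | None = None,
               condition: str = "") -> SignalTrack:
    """Per-fragment log2((lamin/N_lamin + p) / (dam/N_dam + p)).

    ``pseudocount=None`` uses p = 0.5 / min(library sizes), i.e. half a read
    in the shallower library. Fragments with zero counts in both samples are
    missing.
    """
    if lamin.fragment_map is not None and dam.fragment_map is not None:
        if lamin.fragment_map != dam.fragment_map:
            raise ValueError("lamin and dam tracks are on different fragment maps")
    if len(lamin.values) != len(dam.values):
        raise ValueError("count tracks differ in length")
    nl, nd = lamin.library_size, dam.library_size
    if pseudocount is None:
        m = min(nl, nd)
        pseudocount = 0.5 / m if m > 0 else 0.5
    lam_rate = lamin.values / nl if nl > 0 else np.zeros_like(lamin.values, dtype=float)
    dam_rate = dam.values / nd if nd > 0 else np.zeros_like(dam.values, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log2((lam_rate + pseudocount) / (dam_rate + pseudocount))
    vals[(lamin.values == 0) & (dam.values == 0)] = np.nan
    return SignalTrack(vals, stage="raw_ratio", condition=condition,
                       fragment_map=lamin.fragment_map or dam.fragment_map)


def quantile_normalize(tracks: list[SignalTrack]) -> list[SignalTrack]:
    """Force identical value distributions across tracks (rank -> cross-track mean).

    Within each track, the value of rank r is replaced by the mean across
    tracks of their rank-r values; ties receive the mean of the tied ranks'
    replacement values. Missing entries are left missing and excluded from
    ranking. With unequal missingness the per-track quantile grids are
    aligned by linear interpolation.
    """
    if len(tracks) < 2:
        warnings.warn("quantile_normalize called with a single track; returned unchanged")
        return list(tracks)
    n = len(tracks[0].values)
    if any(len(t.values) != n for t in tracks):
        raise ValueError("tracks differ in length")

    sorted_vals = []
    for t in tracks:
        v = t.values[~np.isnan(t.values)]
        if v.size == 0:
            raise ValueError(f"track {t.condition!r} is entirely missing")
        sorted_vals.append(np.sort(v))
    m_max = max(len(v) for v in sorted_vals)
    grid = (np.arange(m_max) + 0.5) / m_max
    ref = np.zeros(m_max)
    for v in sorted_vals:
        probs = (np.arange(len(v)) + 0.5) / len(v)
        ref += np.interp(grid, probs, v)
    ref /= len(tracks)

    out = []
    for t in tracks:
        vals = t.values.copy()
        mask = ~np.isnan(vals)
        v = vals[mask]
        ranks = rankdata(v, method="average")  # 1..m, ties averaged
        probs = (ranks - 0.5) / len(v)
        vals[mask] = np.interp(probs, grid, ref)
        out.append(SignalTrack(vals, stage="normalized", condition=t.condition,
                               fragment_map=t.fragment_map))
    return out


def smooth(track: SignalTrack, half_window: int = 50) -> SignalTrack:
    """Running mean over the +/- `half_window` nearest fragments per chromosome.

    Windows truncate at chromosome ends and never cross chromosomes; missing
    values are excluded from each window mean (a window of only-missing
    fragments stays missing).
    """
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    vals = track.values
    fmap = track.fragment_map
    out = np.empty_like(vals)
    if fmap is None:
        out[:] = _smooth_1d(vals, half_window)
    else:
        for chrom in fmap.chroms:
            sl = fmap.chrom_slice(chrom)
            out[sl] = _smooth_1d(vals[sl], half_window)
    return SignalTrack(out, stage="smoothed", condition=track.condition,
                       fragment_map=fmap)


def _smooth_1d(vals: np.ndarray, w: int) -> np.ndarray:
    n = len(vals)
    if n == 0:
        return vals.copy()
    finite = ~np.isnan(vals)
    filled = np.where(finite, vals, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
    i = np.arange(n)
    lo = np.maximum(i - w, 0)
    hi = np.minimum(i + w + 1, n)
    s = csum[hi] - csum[lo]
    c = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(c > 0, s / np.maximum(c, 1), np.nan)
    return out


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a fragment-resolution bedGraph (missing fragments omitted)."""
    fmap = track.fragment_map
    if fmap is None:
        raise ValueError("track has no fragment map attached")
    with open(path, "w") as fh:
        for chrom in fmap.chroms:
            sl = fmap.chrom_slice(chrom)
            v = track.values[sl]
            for s, e, x in zip(fmap.starts[chrom], fmap.ends[chrom], v):
                if np.isnan(x):
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{x:.6g}\n")
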