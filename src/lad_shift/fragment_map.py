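"""GATC (DpnI) fragment backbone and read-to-fragment counting.

DamID quantifies contact frequency per DpnI restriction fragment: the
genome is partitioned at every GA^TC cut site (DpnI cuts blunt between A
and T, i.e. 2 bp into the motif) and aligned reads are tallied per
fragment. GATC is its own reverse complement, so a single forward-strand
scan covers both strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MOTIF = "GATC"
_CUT_OFFSET = 2  # GA^TC


class FragmentMap:
    """Ordered DpnI-fragment partition of a genome.

    Fragments within each chromosome are adjacent, non-overlapping and tile
    [0, chrom_length). Fragments are globally indexed in chromosome insertion
    order so that fragment-aligned tracks are flat numpy vectors.
    """

    def __init__(self, boundaries: dict[str, np.ndarray], chrom_lengths: dict[str, int]):
        # boundaries[chrom]: sorted internal cut positions (excludes 0 and length)
        self.chrom_lengths = dict(chrom_lengths)
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        self.offsets: dict[str, int] = {}
        off = 0
        for chrom, length in self.chrom_lengths.items():
            cuts = np.asarray(boundaries.get(chrom, []), dtype=np.int64)
            edges = np.concatenate([[0], cuts, [length]])
            self.starts[chrom] = edges[:-1]
            self.ends[chrom] = edges[1:]
            self.offsets[chrom] = off
            off += len(edges) - 1
        self.n_fragments = off

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def n_fragments_chrom(self, chrom: str) -> int:
        return len(self.starts[chrom])

    def chrom_slice(self, chrom: str) -> slice:
        off = self.offsets[chrom]
        return slice(off, off + len(self.starts[chrom]))

    def fragment_lengths(self) -> np.ndarray:
        return np.concatenate([self.ends[c] - self.starts[c] for c in self.chroms])

    def midpoints(self) -> np.ndarray:
        return np.concatenate([(self.ends[c] + self.starts[c]) / 2.0 for c in self.chroms])

    def fragment_index(self, chrom: str, pos: float) -> int:
        """Global index of the fragment containing genomic position `pos`."""
        ends = self.ends[chrom]
        i = int(np.searchsorted(ends, pos, side="right"))
        i = min(i, len(ends) - 1)
        return self.offsets[chrom] + i

    def to_bed(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chroms:
            for s, e in zip(self.starts[chrom], self.ends[chrom]):
                rows.append((chrom, int(s), int(e)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def interval_to_fragments(self, chrom: str, start: int, end: int) -> slice:
        """Global slice of fragments whose midpoints fall inside [start, end)."""
        mids = (self.starts[chrom] + self.ends[chrom]) / 2.0
        lo = int(np.searchsorted(mids, start, side="left"))
        hi = int(np.searchsorted(mids, end, side="left"))
        off = self.offsets[chrom]
        return slice(off + lo, off + hi)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FragmentMap):
            return NotImplemented
        if self.chrom_lengths != other.chrom_lengths:
            return False
        return all(np.array_equal(self.starts[c], other.starts[c]) for c in self.chroms)


@dataclass
class CountTrack:
    """Per-fragment read counts for one sample on one FragmentMap."""

    values: np.ndarray
    label: str = ""
    n_skipped: int = 0
    fragment_map: FragmentMap | None = field(default=None, repr=False)

    @property
    def library_size(self) -> int:
        return int(self.values.sum())

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")


def find_gatc_sites(sequence: str) -> np.ndarray:
    """Start offsets of every GATC occurrence (uppercase comparison; N never matches)."""
    seq = sequence.upper()
    sites = []
    i = seq.find(_MOTIF)
    while i != -1:
        sites.append(i)
        i = seq.find(_MOTIF, i + 1)
    return np.asarray(sites, dtype=np.int64)


def digest_genome(sequences: dict[str, str]) -> FragmentMap:
    """In-silico DpnI digestion: cut every GATC at offset +2 (GA^TC).

    Parameters
    ----------
    sequences
        chromosome name -> sequence over {A,C,G,T,N} (case-insensitive).
    """
    if not sequences:
        raise ValueError("no sequences to digest")
    boundaries = {}
    lengths = {}
    for chrom, seq in sequences.items():
        if len(seq) == 0:
            raise ValueError(f"empty sequence for chromosome {chrom!r}")
        bad = set(seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"chromosome {chrom!r} contains invalid characters {sorted(bad)}")
        cuts = find_gatc_sites(seq) + _CUT_OFFSET
        # a motif at the very start/end yields a cut at 2 / len-2; those are
        # valid internal boundaries as long as 0 < cut < len
        cuts = cuts[(cuts > 0) & (cuts < len(seq))]
        boundaries[chrom] = cuts
        lengths[chrom] = len(seq)
    return FragmentMap(boundaries, lengths)


def count_reads(fmap: FragmentMap, reads: pd.DataFrame, label: str = "") -> CountTrack:
    """Assign each read to the fragment containing its midpoint.

    `reads` needs chrom/start/end columns. Reads on chromosomes absent from
    the map are skipped (counted and logged). Each assigned read increments
    exactly one fragment, so the library size equals reads in minus skipped.
    """
    values = np.zeros(fmap.n_fragments, dtype=np.int64)
    skipped = 0
    if len(reads):
        starts = reads["start"].to_numpy()
        ends = reads["end"].to_numpy()
        bad = np.nonzero(starts >= ends)[0]
        if len(bad):
            raise ValueError(f"malformed read interval at record {int(bad[0])}: start >= end")
        for chrom, sub in reads.groupby("chrom", sort=False):
            if chrom not in fmap.chrom_lengths:
                skipped += len(sub)
                continue
            mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
            idx = np.searchsorted(fmap.ends[chrom], mids, side="right")
            idx = np.clip(idx, 0, len(fmap.ends[chrom]) - 1)
            np.add.at(values, fmap.offsets[chrom] + idx, 1)
    if skipped:
        logger.warning("count_reads: skipped %d reads on chromosomes absent from the fragment map", skipped)
    logger.info("count_reads(%s): reads are counted as given (no deduplication applied)", label)
    return CountTrack(values=values, label=label, n_skipped=skipped, fragment_map=fmap)


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a chrom/start/end DataFrame (extra columns kept)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name", 4: "score", 5: "strand"})
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    cols = columns or [c for c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
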