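"""Footprint QC and the 3-nt periodicity test used to accept translated ORFs.

A footprint is reduced to a single P-site position per read.  Active
translation shows up as enrichment of P-sites in the reading frame of the
translated ORF; the test here is a one-sided binomial test of the frame-0
count against the uniform null p = 1/3, gated by a minimum frame-0 fraction
(f0 >= 0.6 by default) and a minimum number of P-sites.  Frames are always
computed relative to each ORF's own start codon, so nested or overlapping
ORFs are evaluated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import AnnotationSet, Interval, TranscriptSequence

DEFAULT_OFFSET = 12  # nt from the 5' end of a footprint to its P-site


@dataclass
class PSiteTrack:
    """Per-sample P-site counts keyed by (chrom, strand, position, read_length).

    ``read_length`` is -1 when footprint lengths were not recorded.
    """

    sample: str
    frame: pd.DataFrame  # columns: chrom, position, strand, read_length, count
    _index: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_frame(cls, sample: str, df: pd.DataFrame) -> "PSiteTrack":
        df = df[["chrom", "position", "strand", "read_length", "count"]].copy()
        df["count"] = df["count"].astype(int)
        if len(df) and (df["count"] < 0).any():
            raise ValueError("P-site counts must be non-negative")
        return cls(sample=sample, frame=df.reset_index(drop=True))

    @classmethod
    def empty(cls, sample: str) -> "PSiteTrack":
        return cls.from_frame(sample, pd.DataFrame(
            columns=["chrom", "position", "strand", "read_length", "count"]))

    @classmethod
    def pooled(cls, tracks: list["PSiteTrack"], sample: str = "pooled") -> "PSiteTrack":
        df = pd.concat([t.frame for t in tracks], ignore_index=True)
        df = (df.groupby(["chrom", "position", "strand", "read_length"],
                         as_index=False)["count"].sum())
        return cls.from_frame(sample, df)

    @property
    def total(self) -> int:
        return int(self.frame["count"].sum())

    def positions(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted position array and matching counts (summed over lengths)."""
        key = (chrom, strand)
        if key not in self._index:
            sub = self.frame[(self.frame["chrom"] == chrom)
                             & (self.frame["strand"] == strand)]
            agg = sub.groupby("position")["count"].sum().sort_index()
            self._index[key] = (agg.index.to_numpy(dtype=np.int64),
                                agg.to_numpy(dtype=np.int64))
        return self._index[key]

    def counts_at(self, chrom: str, strand: str, pos: np.ndarray) -> np.ndarray:
        """Counts at the given genome positions (0 where absent)."""
        xs, cs = self.positions(chrom, strand)
        if xs.size == 0:
            return np.zeros(len(pos), dtype=np.int64)
        idx = np.searchsorted(xs, pos)
        idx = np.clip(idx, 0, xs.size - 1)
        hit = xs[idx] == pos
        out = np.where(hit, cs[idx], 0)
        return out.astype(np.int64)

    def to_tsv(self, path: str) -> None:
        df = self.frame.copy()
        df["sample"] = self.sample
        df = df[["chrom", "position", "strand", "count", "sample", "read_length"]]
        df.sort_values(["chrom", "strand", "position", "read_length"]).to_csv(
            path, sep="\t", index=False)


@dataclass
class LengthHistogram:
    counts: dict[int, int]
    available: bool
    fraction_25_33: float | None
    fraction_25_30: float | None


@dataclass
class FrameStats:
    """Per-region frame tally for the periodicity test."""

    region_id: str
    n0: int
    n1: int
    n2: int
    pvalue: float | None

    @property
    def n(self) -> int:
        return self.n0 + self.n1 + self.n2

    @property
    def f0(self) -> float | None:
        return self.n0 / self.n if self.n else None


def binomial_frame_pvalue(n0, n):
    """One-sided binomial tail P[X >= n0] for X ~ Bin(n, 1/3); vectorized."""
    n0 = np.asarray(n0)
    n = np.asarray(n)
    return stats.binom.sf(n0 - 1, n, 1.0 / 3.0)


def length_histogram(track: PSiteTrack) -> LengthHistogram:
    """Footprint length histogram with the fractions in the expected QC bands."""
    df = track.frame
    if len(df) == 0:
        return LengthHistogram({}, available=True, fraction_25_33=None,
                               fraction_25_30=None)
    if (df["read_length"] < 0).all():
        return LengthHistogram({}, available=False, fraction_25_33=None,
                               fraction_25_30=None)
    sub = df[df["read_length"] >= 0]
    agg = sub.groupby("read_length")["count"].sum()
    total = agg.sum()
    in_25_33 = agg[(agg.index >= 25) & (agg.index <= 33)].sum()
    in_25_30 = agg[(agg.index >= 25) & (agg.index <= 30)].sum()
    return LengthHistogram(
        counts={int(k): int(v) for k, v in agg.items()},
        available=True,
        fraction_25_33=float(in_25_33 / total) if total else None,
        fraction_25_30=float(in_25_30 / total) if total else None,
    )


def _cds_start_positions(annot: AnnotationSet) -> list[tuple[str, str, int]]:
    """Genome coordinate of the first CDS base per coding transcript."""
    out = []
    for t in annot.transcripts.values():
        if not t.cds:
            continue
        if t.strand == "+":
            start = min(s for s, _ in t.cds)
        else:
            start = max(e for _, e in t.cds) - 1
        out.append((t.chrom, t.strand, start))
    return out


def assign_psites(placements: PSiteTrack, annot: AnnotationSet,
                  window: tuple[int, int] = (-40, 10),
                  default_offset: int = DEFAULT_OFFSET,
                  min_reads: int = 50,
                  min_coding: int = 20) -> tuple[PSiteTrack, pd.DataFrame]:
    """Calibrate per-read-length P-site offsets and apply them.

    ``placements`` carries 5'-end positions of footprints.  For each read
    length the offset is the modal distance from the 5' end to an annotated
    CDS start, pooled over a metagene window of 5' ends within
    ``window=[-40,+10]`` nt of the start (ties broken toward
    ``default_offset``).  Lengths with fewer than ``min_reads`` reads in the
    window fall back to the default offset of 12 nt and are flagged.

    Returns the offset-corrected track and the offset table
    (read_length, offset, n_reads, fallback).
    """
    starts = _cds_start_positions(annot)
    n_coding = len(starts)
    if n_coding < min_coding:
        raise ValueError(
            f"need >= {min_coding} coding transcripts for offset calibration, "
            f"got {n_coding}")
    lo, hi = window  # positions of 5' ends relative to the CDS start
    df = placements.frame
    lengths = sorted(int(x) for x in df["read_length"].unique())
    rows = []
    offsets: dict[int, int] = {}
    by_key: dict[tuple[str, str, int], np.ndarray] = {}
    counts_by_key: dict[tuple[str, str, int], np.ndarray] = {}
    for (chrom, strand, L), sub in df.groupby(["chrom", "strand", "read_length"]):
        agg = sub.groupby("position")["count"].sum().sort_index()
        by_key[(chrom, strand, int(L))] = agg.index.to_numpy(dtype=np.int64)
        counts_by_key[(chrom, strand, int(L))] = agg.to_numpy(dtype=np.int64)
    for L in lengths:
        # histogram of distance d = (CDS start - 5' end) in transcript direction
        hist: dict[int, int] = {}
        for chrom, strand, st in starts:
            key = (chrom, strand, L)
            if key not in by_key:
                continue
            xs, cs = by_key[key], counts_by_key[key]
            if strand == "+":
                w0, w1 = st + lo, st + hi
            else:
                w0, w1 = st - hi, st - lo
            i0, i1 = np.searchsorted(xs, [w0, w1 + 1])
            for x, c in zip(xs[i0:i1], cs[i0:i1]):
                d = (st - x) if strand == "+" else (x - st)
                hist[int(d)] = hist.get(int(d), 0) + int(c)
        n_reads = sum(hist.values())
        if n_reads < min_reads or not hist:
            offsets[L] = default_offset
            rows.append({"read_length": L, "offset": default_offset,
                         "n_reads": n_reads, "fallback": True})
            continue
        best = max(hist.values())
        modes = sorted(d for d, c in hist.items() if c == best)
        off = min(modes, key=lambda d: (abs(d - default_offset), d))
        offsets[L] = int(off)
        rows.append({"read_length": L, "offset": int(off),
                     "n_reads": n_reads, "fallback": False})
    shifted = df.copy()
    offs = shifted["read_length"].map(offsets).fillna(default_offset).astype(int)
    sign = np.where(shifted["strand"] == "+", 1, -1)
    shifted["position"] = shifted["position"] + sign * offs
    shifted = (shifted.groupby(["chrom", "position", "strand", "read_length"],
                               as_index=False)["count"].sum())
    table = pd.DataFrame(rows, columns=["read_length", "offset", "n_reads",
                                        "fallback"])
    return PSiteTrack.from_frame(placements.sample, shifted), table


def _masked_codons(span: Interval, mask: list[Interval]) -> np.ndarray:
    """Boolean keep-flag per codon of span; codons overlapping mask are dropped."""
    start, end = span
    n_codons = (end - start) // 3
    keep = np.ones(n_codons, dtype=bool)
    for ms, me in mask:
        if me <= start or ms >= end:
            continue
        c0 = max(0, (ms - start) // 3)
        c1 = min(n_codons, (me - start + 2) // 3)
        keep[c0:c1] = False
    return keep


def frame_stats(track: PSiteTrack, tseq: TranscriptSequence, span: Interval,
                chrom: str, strand: str,
                mask: list[Interval] | None = None,
                region_id: str = "") -> FrameStats:
    """Frame tally of P-sites over a transcript-space ORF span.

    ``span`` is [start, end) in transcript coordinates with length a multiple
    of 3; frame is (position - start) mod 3, i.e. relative to the region's own
    start codon.  ``mask`` lists transcript-space intervals (e.g. the annotated
    mORF CDS) whose overlapping codons are excluded entirely.
    """
    start, end = span
    if (end - start) % 3 != 0:
        raise ValueError(f"region length {end - start} not a multiple of 3")
    keep = _masked_codons(span, mask or [])
    if not keep.any():
        return FrameStats(region_id, 0, 0, 0, None)
    codon_idx = np.nonzero(keep)[0]
    tpos = (start + 3 * codon_idx[:, None] + np.arange(3)[None, :]).ravel()
    gpos = tseq.genome_positions[tpos]
    counts = track.counts_at(chrom, strand, gpos).reshape(-1, 3)
    n0, n1, n2 = (int(x) for x in counts.sum(axis=0))
    n = n0 + n1 + n2
    p = float(binomial_frame_pvalue(n0, n)) if n else None
    return FrameStats(region_id, n0, n1, n2, p)


def periodicity_pass(fs: FrameStats, min_n: int = 10, f0_min: float = 0.6,
                     alpha: float = 0.05) -> bool:
    """Accept a region as periodic: n >= min_n, f0 >= f0_min and p <= alpha."""
    if fs.n < min_n or fs.n == 0:
        return False
    return fs.f0 >= f0_min and fs.pvalue is not None and fs.pvalue <= alpha
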