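"""Candidate ORF enumeration, classification, Kozak scoring and acceptance.

An ORF is an AUG with an in-frame stop codon on the same transcript; spans
include the stop codon.  Candidates sharing a stop are collapsed to the one
with the most-upstream AUG.  Surviving candidates are classified by where
their AUG falls (5'UTR, 3'UTR, noncoding/intergenic transcript, or the
annotated CDS itself), and accepted as translated when the P-sites over their
codons *not* overlapping any annotated main-ORF CDS show 3-nt periodicity in
at least one stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation_io import (AnnotationSet, Interval, TranscriptSequence,
                            spliced_sequence, tx_span_to_genome_blocks)
from .periodicity import FrameStats, PSiteTrack, frame_stats, periodicity_pass

START = "ATG"
STOPS = ("TAA", "TAG", "TGA")

CATEGORIES = ("mORF", "five_prime_ORF", "three_prime_ORF", "ncORF", "internal")


@dataclass
class ORFCall:
    """One candidate/accepted ORF on a transcript."""

    id: str
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tx_start: int              # transcript-space, AUG first base
    tx_end: int                # past the stop codon
    genome_blocks: list[Interval]
    category: str
    peptide: str
    kozak_context: str
    kozak_strong: bool
    frame: FrameStats | None = None
    accepted: bool = False
    pass_stages: list[str] = field(default_factory=list)
    levels: dict[str, float] = field(default_factory=dict)  # stage -> ORF RPKM

    @property
    def n_codons(self) -> int:
        return (self.tx_end - self.tx_start) // 3


def enumerate_orfs(seq: str, min_codons: int = 3) -> list[Interval]:
    """All AUG-initiated ORF spans [start, end) with an in-frame stop.

    ``end`` includes the stop codon; ORFs shorter than ``min_codons`` total
    codons (start + body + stop) are dropped.  AUGs with no downstream
    in-frame stop are not emitted.
    """
    seq = seq.upper()
    n = len(seq)
    stops_by_frame: list[list[int]] = [[], [], []]
    starts: list[int] = []
    for i in range(n - 2):
        tri = seq[i:i + 3]
        if tri == START:
            starts.append(i)
        elif tri in STOPS:
            stops_by_frame[i % 3].append(i)
    spans = []
    for a in starts:
        stops = stops_by_frame[a % 3]
        j = np.searchsorted(stops, a + 3)
        if j == len(stops):
            continue
        end = stops[j] + 3
        if (end - a) // 3 >= min_codons:
            spans.append((a, end))
    return spans


def collapse_by_stop(candidates: list[Interval]) -> list[Interval]:
    """Among ORFs sharing a stop codon keep the most-upstream start; idempotent."""
    best: dict[int, int] = {}
    for s, e in candidates:
        if e not in best or s < best[e]:
            best[e] = s
    return sorted((s, e) for e, s in best.items())


def _tx_interval_len(ivs: list[Interval]) -> int:
    return sum(e - s for s, e in ivs)


def classify_orf(span: Interval, transcript) -> str:
    """Category by AUG location: 5'UTR, 3'UTR, noncoding host, CDS, or mORF."""
    a, end = span
    if transcript.noncoding or not transcript.cds:
        return "ncORF"
    utr5_len = _tx_interval_len(transcript.utr5)
    cds_len = transcript.cds_length
    if a == utr5_len and end == utr5_len + cds_len:
        return "mORF"
    if a < utr5_len:
        return "five_prime_ORF"
    if a >= utr5_len + cds_len:
        return "three_prime_ORF"
    return "internal"


def kozak_strong(seq: str, aug_position: int) -> tuple[str, bool]:
    """Kozak context around an AUG and whether it is 'strong'.

    Strong means A or G at the -3 position and G at +4, where the A of the
    AUG is +1 (so +4 is the base immediately after the AUG).  The returned
    context covers [-6, +5], padded with N at transcript edges; N never
    satisfies the rule.
    """
    a = aug_position
    window = []
    for i in range(a - 6, a + 5):
        window.append(seq[i] if 0 <= i < len(seq) else "N")
    ctx = "".join(window)
    minus3 = ctx[3]
    plus4 = ctx[9]
    return ctx, (minus3 in "AG") and (plus4 == "G")


def find_candidates(annot: AnnotationSet, genome: dict[str, str],
                    min_codons: int = 3,
                    tseqs: dict[str, TranscriptSequence] | None = None
                    ) -> list[ORFCall]:
    """Enumerate, collapse and classify candidate ORFs on every transcript."""
    calls: list[ORFCall] = []
    for tid, t in annot.transcripts.items():
        tseq = tseqs[tid] if tseqs else spliced_sequence(annot, genome, tid)
        for s, e in collapse_by_stop(enumerate_orfs(tseq.seq, min_codons)):
            cat = classify_orf((s, e), t)
            ctx, strong = kozak_strong(tseq.seq, s)
            pep = str(Seq(tseq.seq[s:e - 3]).translate())
            calls.append(ORFCall(
                id=f"{tid}:{s}-{e}", transcript_id=tid, gene_id=t.gene_id,
                chrom=t.chrom, strand=t.strand, tx_start=s, tx_end=e,
                genome_blocks=tx_span_to_genome_blocks(t.exons, t.strand, s, e),
                category=cat, peptide=pep, kozak_context=ctx,
                kozak_strong=strong))
    return calls


def accept_translated(orfs: list[ORFCall], stage_tracks: dict[str, PSiteTrack],
                      annot: AnnotationSet,
                      tseqs: dict[str, TranscriptSequence],
                      min_psites: int = 10, f0_min: float = 0.6,
                      alpha: float = 0.05) -> list[ORFCall]:
    """Periodicity-test candidate UTR/nc ORFs against per-stage P-site tracks.

    For each ORF, frame statistics are computed on codons that do not overlap
    the host transcript's annotated CDS (replicates pooled per stage
    upstream); the ORF is accepted if the test passes in at least one stage.
    Per-stage ORF RPKM over the full span is recorded for every candidate.
    mORF and internal candidates are carried through untested.

    Returns the accepted non-mORF ORFs.
    """
    totals_m = {stage: track.total / 1e6
                for stage, track in stage_tracks.items()}
    for orf in orfs:
        t = annot.transcripts[orf.transcript_id]
        tseq = tseqs[orf.transcript_id]
        orf_kb = (orf.tx_end - orf.tx_start) / 1000.0
        span_tpos = np.arange(orf.tx_start, orf.tx_end)
        span_gpos = tseq.genome_positions[span_tpos]
        for stage, track in stage_tracks.items():
            c = int(track.counts_at(orf.chrom, orf.strand, span_gpos).sum())
            orf.levels[stage] = (c / orf_kb / totals_m[stage]
                                 if totals_m[stage] > 0 else 0.0)
        if orf.category in ("mORF", "internal"):
            continue
        if t.cds:
            utr5_len = _tx_interval_len(t.utr5)
            mask = [(utr5_len, utr5_len + t.cds_length)]
        else:
            mask = []
        best: FrameStats | None = None
        for stage, track in stage_tracks.items():
            fs = frame_stats(track, tseq, (orf.tx_start, orf.tx_end),
                             orf.chrom, orf.strand, mask=mask, region_id=orf.id)
            if periodicity_pass(fs, min_n=min_psites, f0_min=f0_min,
                                alpha=alpha):
                orf.pass_stages.append(stage)
            if best is None or fs.n > best.n:
                best = fs
        orf.frame = best
        orf.accepted = bool(orf.pass_stages)
    return [o for o in orfs if o.accepted]


def orfs_to_frame(orfs: list[ORFCall]) -> pd.DataFrame:
    """Tabular view of ORF calls (one row per candidate)."""
    rows = []
    for o in orfs:
        row = {
            "orf_id": o.id, "transcript_id": o.transcript_id,
            "gene_id": o.gene_id, "chrom": o.chrom, "strand": o.strand,
            "tx_start": o.tx_start, "tx_end": o.tx_end,
            "n_codons": o.n_codons, "category": o.category,
            "kozak_context": o.kozak_context, "kozak_strong": o.kozak_strong,
            "accepted": o.accepted,
            "n_pass_stages": len(o.pass_stages),
            "f0": o.frame.f0 if o.frame and o.frame.n else np.nan,
            "n_psites": o.frame.n if o.frame else 0,
            "blocks": ",".join(f"{s}-{e}" for s, e in o.genome_blocks),
        }
        for stage, v in o.levels.items():
            row[f"rpkm_{stage}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("orf_id") if rows else pd.DataFrame()


def write_bed12(orfs: list[ORFCall], path: str) -> None:
    """Accepted-ORF genome blocks as BED12 (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for o in orfs:
            blocks = sorted(o.genome_blocks)
            chrom_start = blocks[0][0]
            chrom_end = blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - chrom_start) for s, e in blocks)
            fh.write("\t".join(map(str, [
                o.chrom, chrom_start, chrom_end, o.id, 0, o.strand,
                chrom_start, chrom_end, "0,0,0", len(blocks), sizes, starts,
            ])) + "\n")


def write_peptides_fasta(orfs: list[ORFCall], path: str) -> None:
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(f">{o.id} {o.category}\n{o.peptide}\n")
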