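"""Readers/writers for FASTA, GFF3 and P-site TSV tracks, and the coordinate model.

All coordinates are 0-based half-open internally.  On-disk formats keep their
native conventions: GFF3 is 1-based inclusive, BED-like TSVs are 0-based.
Transcript-level logic always operates in transcript orientation (index 0 is
the 5' end of the mature transcript, for either strand).
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq


class AnnotationError(ValueError):
    """Raised for structurally invalid annotation input."""


Interval = tuple[int, int]


def _interval_len(ivs: list[Interval]) -> int:
    return sum(e - s for s, e in ivs)


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass
class Transcript:
    """A transcript model with exon/CDS structure.

    ``exons`` and ``cds`` are genome-coordinate intervals ordered 5'->3' in
    transcript orientation (descending genomic start on the minus strand).
    ``utr5``/``utr3`` are inferred from the CDS and kept in the same order.
    """

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    noncoding: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    @property
    def spliced_length(self) -> int:
        return _interval_len(self.exons)

    @property
    def cds_length(self) -> int:
        return _interval_len(self.cds)


@dataclass
class AnnotationSet:
    """Genome annotation backbone: chromosomes, genes and transcript models."""

    chromosomes: dict[str, int]
    genes: dict[str, Gene]
    transcripts: dict[str, Transcript]
    source: str = ""
    checksum: str = ""

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    def gene_feature_intervals(self, gene_id: str, feature: str) -> list[Interval]:
        """Union of exon or CDS intervals over all transcripts of a gene."""
        ivs: list[Interval] = []
        for t in self.transcripts_of(gene_id):
            ivs.extend(t.exons if feature == "exon" else t.cds)
        return merge_intervals(ivs)


@dataclass
class TranscriptSequence:
    """Spliced transcript sequence plus the transcript<->genome position map."""

    transcript_id: str
    seq: str
    genome_positions: np.ndarray  # genome coordinate of each transcript position

    def __len__(self) -> int:
        return len(self.seq)

    def to_genome(self, tpos: int) -> int:
        return int(self.genome_positions[tpos])

    def to_transcript(self, gpos: int) -> int:
        hits = np.nonzero(self.genome_positions == gpos)[0]
        if hits.size == 0:
            raise KeyError(f"genome position {gpos} not exonic in {self.transcript_id}")
        return int(hits[0])


def merge_intervals(ivs: list[Interval]) -> list[Interval]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _tx_order(ivs: list[Interval], strand: str) -> list[Interval]:
    """Sort genome intervals 5'->3' in transcript orientation."""
    return sorted(ivs, key=lambda iv: iv[0], reverse=(strand == "-"))


def _infer_utrs(exons: list[Interval], cds: list[Interval], strand: str
                ) -> tuple[list[Interval], list[Interval]]:
    """Exonic sequence strictly upstream/downstream of the CDS, strand-aware."""
    if not cds:
        return [], []
    cds_lo = min(s for s, _ in cds)
    cds_hi = max(e for _, e in cds)
    left, right = [], []
    for s, e in exons:
        if s < cds_lo:
            left.append((s, min(e, cds_lo)))
        if e > cds_hi:
            right.append((max(s, cds_hi), e))
    if strand == "+":
        return _tx_order(left, strand), _tx_order(right, strand)
    return _tx_order(right, strand), _tx_order(left, strand)


def tx_span_to_genome_blocks(exons: list[Interval], strand: str,
                             tx_start: int, tx_end: int) -> list[Interval]:
    """Map a transcript-space interval to genome-space blocks via the exons.

    ``exons`` may be in either order; blocks are returned sorted genomically.
    """
    ordered = _tx_order(exons, strand)
    blocks = []
    tpos = 0
    for s, e in ordered:
        el = e - s
        lo = max(tx_start, tpos)
        hi = min(tx_end, tpos + el)
        if lo < hi:
            if strand == "+":
                blocks.append((s + (lo - tpos), s + (hi - tpos)))
            else:
                blocks.append((e - (hi - tpos), e - (lo - tpos)))
        tpos += el
    return sorted(blocks)


def _contained(inner: list[Interval], outer: list[Interval]) -> bool:
    outer = merge_intervals(outer)
    for s, e in inner:
        if not any(os_ <= s and e <= oe for os_, oe in outer):
            return False
    return True


_TRANSCRIPT_TYPES = {"mRNA", "transcript", "ncRNA", "lnc_RNA", "lncRNA"}
_NONCODING_TYPES = {"ncRNA", "lnc_RNA", "lncRNA"}


def read_gff3(path: str) -> AnnotationSet:
    """Parse a GFF3 file into an :class:`AnnotationSet`.

    Expects gene / mRNA (or transcript / ncRNA) / exon / CDS features with
    intact Parent links.  GFF3 1-based inclusive coordinates are converted to
    0-based half-open.  UTRs are inferred from exon/CDS structure; UTR features
    present in the file are ignored in favour of the inferred ones.
    """
    db = gffutils.create_db(path, dbfn=":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}

    for g in db.features_of_type("gene"):
        genes[g.id] = Gene(g.id, g.seqid, g.strand, g.start - 1, g.end)

    for ttype in sorted(_TRANSCRIPT_TYPES):
        for t in db.features_of_type(ttype):
            parents = t.attributes.get("Parent", [])
            gene_id = parents[0] if parents else t.id
            if parents and parents[0] not in genes:
                raise AnnotationError(
                    f"transcript {t.id}: Parent {parents[0]} is not a known gene")
            exons, cds = [], []
            for child in db.children(t.id, level=1):
                iv = (child.start - 1, child.end)
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "CDS":
                    cds.append(iv)
            if not exons:
                raise AnnotationError(f"transcript {t.id} has no exon children")
            if cds and not _contained(cds, exons):
                raise AnnotationError(f"transcript {t.id}: CDS outside exons")
            exons = _tx_order(merge_intervals(exons), t.strand)
            cds = _tx_order(merge_intervals(cds), t.strand)
            utr5, utr3 = _infer_utrs(exons, cds, t.strand)
            tx = Transcript(
                id=t.id, gene_id=gene_id, chrom=t.seqid, strand=t.strand,
                exons=exons, cds=cds, utr5=utr5, utr3=utr3,
                noncoding=(ttype in _NONCODING_TYPES or not cds),
            )
            if cds and tx.cds_length % 3 != 0:
                tx.flags.append("cds_length_not_multiple_of_3")
            transcripts[t.id] = tx
            if gene_id not in genes:  # orphan transcript: synthesize a gene record
                genes[gene_id] = Gene(gene_id, t.seqid, t.strand, t.start - 1, t.end)

    # orphan exon/CDS check: every exon/CDS parent must be a known transcript
    for ftype in ("exon", "CDS"):
        for f in db.features_of_type(ftype):
            for p in f.attributes.get("Parent", []):
                if p not in transcripts:
                    raise AnnotationError(
                        f"{ftype} feature at {f.seqid}:{f.start}-{f.end} has "
                        f"unknown Parent {p}")

    chrom_sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                chrom_sizes[parts[1]] = int(parts[3])
            elif not line.startswith("#"):
                break
    for g in genes.values():
        chrom_sizes.setdefault(g.chrom, 0)
        chrom_sizes[g.chrom] = max(chrom_sizes[g.chrom], g.end)

    with open(path, "rb") as fh:
        checksum = hashlib.sha256(fh.read()).hexdigest()
    return AnnotationSet(chromosomes=chrom_sizes, genes=genes,
                         transcripts=transcripts,
                         source=os.path.abspath(path), checksum=checksum)


def write_gff3(annot: AnnotationSet, path: str) -> None:
    """Write an AnnotationSet back to GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annot.chromosomes):
            fh.write(f"##sequence-region {chrom} 1 {annot.chromosomes[chrom]}\n")
        by_gene: dict[str, list[Transcript]] = {}
        for t in annot.transcripts.values():
            by_gene.setdefault(t.gene_id, []).append(t)
        for gid in annot.genes:
            g = annot.genes[gid]
            fh.write("\t".join([g.chrom, "riboutr", "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", f"ID={g.id}"]) + "\n")
            for t in sorted(by_gene.get(gid, []), key=lambda t: t.id):
                ttype = "ncRNA" if t.noncoding else "mRNA"
                s, e = t.span
                fh.write("\t".join([t.chrom, "riboutr", ttype, str(s + 1), str(e),
                                    ".", t.strand, ".",
                                    f"ID={t.id};Parent={gid}"]) + "\n")
                for i, (xs, xe) in enumerate(sorted(t.exons)):
                    fh.write("\t".join([t.chrom, "riboutr", "exon", str(xs + 1),
                                        str(xe), ".", t.strand, ".",
                                        f"ID={t.id}.exon{i};Parent={t.id}"]) + "\n")
                # CDS written in genomic order with running phase
                running = 0
                for cs, ce in (sorted(t.cds) if t.strand == "+"
                               else sorted(t.cds, reverse=True)):
                    phase = (3 - running % 3) % 3
                    fh.write("\t".join([t.chrom, "riboutr", "CDS", str(cs + 1),
                                        str(ce), ".", t.strand, str(phase),
                                        f"ID={t.id}.cds;Parent={t.id}"]) + "\n")
                    running += ce - cs


def read_fasta(path: str) -> dict[str, str]:
    """Load a genome FASTA into a name -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def spliced_sequence(annot: AnnotationSet, genome: dict[str, str],
                     transcript_id: str) -> TranscriptSequence:
    """Extract the spliced transcript sequence in transcript orientation.

    The returned position map gives, for each transcript index, the genome
    coordinate of that base; it is strictly descending for minus-strand
    transcripts and round-trips exactly with :meth:`TranscriptSequence.to_transcript`.
    """
    t = annot.transcripts[transcript_id]
    if t.chrom not in genome:
        raise AnnotationError(f"chromosome {t.chrom} absent from genome FASTA")
    chrom_seq = genome[t.chrom]
    for s, e in t.exons:
        if e > len(chrom_seq):
            raise AnnotationError(
                f"exon {s}-{e} of {transcript_id} exceeds length of {t.chrom}")
    parts, positions = [], []
    for s, e in sorted(t.exons):
        parts.append(chrom_seq[s:e])
        positions.append(np.arange(s, e))
    seq = "".join(parts)
    gpos = np.concatenate(positions) if positions else np.empty(0, dtype=int)
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        gpos = gpos[::-1].copy()
    return TranscriptSequence(transcript_id, seq, gpos)


PSITE_COLUMNS = ["chrom", "position", "strand", "count", "sample", "read_length"]


def read_psites(path: str, chrom_sizes: dict[str, int] | None = None):
    """Read a BED-like P-site TSV into a :class:`~riboutr.periodicity.PSiteTrack`.

    Columns: chrom, position (0-based), strand, count, sample, read_length
    (read_length optional).  Rows with identical keys are summed.
    """
    import pandas as pd

    from .periodicity import PSiteTrack

    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PSITE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise AnnotationError(f"P-site TSV missing columns: {missing}")
    if "read_length" not in df.columns:
        df["read_length"] = -1
    if len(df):
        if (df["count"] < 0).any() or (df["position"] < 0).any():
            raise AnnotationError("negative counts or positions in P-site TSV")
        if chrom_sizes is not None:
            for chrom, sub in df.groupby("chrom"):
                if chrom in chrom_sizes and (sub["position"] >= chrom_sizes[chrom]).any():
                    raise AnnotationError(
                        f"P-site position beyond length of chromosome {chrom}")
    sample = str(df["sample"].iloc[0]) if len(df) else os.path.basename(path)
    df = (df.groupby(["chrom", "position", "strand", "read_length"], as_index=False)
            ["count"].sum())
    return PSiteTrack.from_frame(sample, df)
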