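"""Cross-evidence for accepted ORFs: peptide matches and isoform support.

Mass-spectrometry peptides corroborate an ORF when they occur as an exact
substring of its predicted protein (optionally with I/L treated as
equivalent, since they are isobaric).  Transcript isoform models corroborate
an ORF when the ORF's genome blocks are fully contained in the isoform's
exon chain on the same strand with the AUG and stop intact in the isoform's
spliced sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation_io import AnnotationSet, merge_intervals

MIN_PEPTIDE_LEN = 7  # bounds the probability of chance substring matches


@dataclass
class PeptideMatch:
    peptide: str
    orf_id: str
    offsets: list[int]
    decoy: bool = False


@dataclass
class IsoformSupport:
    orf_id: str
    isoform_id: str
    contained: bool
    frame_consistent: bool

    @property
    def supported(self) -> bool:
        return self.contained and self.frame_consistent


def _collapse_il(s: str) -> str:
    return s.replace("I", "L")


def match_peptides(peptides: list[str], orf_peptides: dict[str, str],
                   min_len: int = MIN_PEPTIDE_LEN,
                   il_equivalent: bool = False,
                   decoys: list[str] | None = None
                   ) -> tuple[list[PeptideMatch], pd.DataFrame]:
    """Exact substring search of peptides against ORF protein sequences.

    All matching ORFs are reported per peptide.  Peptides shorter than
    ``min_len`` are skipped and recorded.  ``decoys`` (e.g. reversed
    peptides) are searched identically and flagged, giving an empirical
    chance-match rate.

    Returns the matches and a per-peptide summary table.
    """
    targets = {oid: (_collapse_il(seq) if il_equivalent else seq)
               for oid, seq in orf_peptides.items()}
    matches: list[PeptideMatch] = []
    rows = []
    for decoy, plist in ((False, peptides), (True, decoys or [])):
        for pep in plist:
            pep = pep.upper()
            if len(pep) < min_len:
                rows.append({"peptide": pep, "decoy": decoy, "skipped": True,
                             "n_orfs_matched": 0})
                continue
            query = _collapse_il(pep) if il_equivalent else pep
            hit_orfs = 0
            for oid, target in targets.items():
                offsets = []
                start = target.find(query)
                while start != -1:
                    offsets.append(start)
                    start = target.find(query, start + 1)
                if offsets:
                    matches.append(PeptideMatch(pep, oid, offsets, decoy))
                    hit_orfs += 1
            rows.append({"peptide": pep, "decoy": decoy, "skipped": False,
                         "n_orfs_matched": hit_orfs})
    return matches, pd.DataFrame(rows)


def _blocks_contained(blocks, exons) -> bool:
    exons = merge_intervals(list(exons))
    return all(any(s0 <= s and e <= e0 for s0, e0 in exons) for s, e in blocks)


def isoform_support(orfs, isoforms: AnnotationSet) -> list[IsoformSupport]:
    """Test accepted ORFs for containment in isoform transcript models.

    An ORF is supported by an isoform when (a) every ORF genome block lies
    within the isoform's exons, (b) strands match, and (c) the ORF sequence
    is contiguous in the isoform's spliced transcript (its AUG..stop reading
    frame is intact, i.e. the isoform splices no part of the ORF out).
    Only (ORF, isoform) pairs on a shared chromosome with matching strand and
    containment are reported.
    """
    known_chroms = set(isoforms.chromosomes) | {
        t.chrom for t in isoforms.transcripts.values()}
    out: list[IsoformSupport] = []
    for o in orfs:
        if o.chrom not in known_chroms:
            raise ValueError(f"ORF {o.id}: chromosome {o.chrom} absent from "
                             "isoform annotation (assembly mismatch?)")
        orf_len = sum(e - s for s, e in o.genome_blocks)
        for iso in isoforms.transcripts.values():
            if iso.chrom != o.chrom or iso.strand != o.strand:
                continue
            if not _blocks_contained(o.genome_blocks, iso.exons):
                continue
            # frame consistency: within the isoform's spliced sequence the
            # ORF bases must be consecutive, i.e. no isoform intron may fall
            # strictly inside the ORF's genomic extent over exonic sequence
            lo = min(s for s, _ in o.genome_blocks)
            hi = max(e for _, e in o.genome_blocks)
            iso_inside = [(max(s, lo), min(e, hi))
                          for s, e in iso.exons if s < hi and e > lo]
            covered = sum(e - s for s, e in merge_intervals(iso_inside))
            frame_ok = covered == orf_len
            out.append(IsoformSupport(o.id, iso.id, contained=True,
                                      frame_consistent=frame_ok))
    return out


def support_table(supports: list[IsoformSupport]) -> pd.DataFrame:
    rows = [{"orf_id": s.orf_id, "isoform_id": s.isoform_id,
             "contained": s.contained, "frame_consistent": s.frame_consistent,
             "supported": s.supported} for s in supports]
    return pd.DataFrame(rows, columns=["orf_id", "isoform_id", "contained",
                                       "frame_consistent", "supported"])
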