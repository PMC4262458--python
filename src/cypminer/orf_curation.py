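"""Sense-strand ORF extraction, domain coverage and full/partial curation.

Transcripts come from a strand-specific library, so only the given strand
is scanned.  Per reading frame the scanner reports every maximal
M-to-stop ORF plus terminal open fragments (start- and/or stop-missing);
the longest candidate per transcript is the representative that curation
judges against the domain model:

* ``full``    — starts with M, ends at an in-frame stop, and its local
  alignment to the domain consensus covers >= 85% of the model length;
* ``partial`` — missing the start or the stop, or covering < 80%;
* ``flagged`` — start and stop present but coverage in the 80–85% band,
  which is left to manual review rather than silently resolved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

from ._align import local_protein_alignment
from .io_utils import load_domain_consensus

logger = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
_CODON_MAP = {}


def _codon_map() -> dict[str, str]:
    if not _CODON_MAP:
        from Bio.Data.CodonTable import unambiguous_dna_by_id
        _CODON_MAP.update(unambiguous_dna_by_id[1].forward_table)
    return _CODON_MAP


def _translate_codon(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return _codon_map().get(codon, "X")  # N-containing codons -> X


@dataclass(frozen=True)
class OrfCandidate:
    """One ORF or open fragment on the sense strand (0-based half-open;
    the span includes the stop codon when has_stop)."""

    transcript_id: str
    frame: int
    start: int
    end: int
    protein: str
    has_start: bool
    has_stop: bool
    coverage: float | None = None

    def __post_init__(self):
        coding = (self.end - self.start) - (3 if self.has_stop else 0)
        if coding % 3 != 0:
            raise ValueError("ORF span not a whole number of codons")
        if len(self.protein) != coding // 3:
            raise ValueError("protein length inconsistent with span")


@dataclass(frozen=True)
class CurationThresholds:
    full_coverage_min: float = 0.85
    partial_coverage_max: float = 0.80
    domain_model_length: int = 463
    merge_identity_min: float = 0.97
    merge_overlap_min: int = 300

    def __post_init__(self):
        if self.partial_coverage_max > self.full_coverage_min:
            raise ValueError("partial_coverage_max must be <= full_coverage_min")


def find_orfs(sequence: str, transcript_id: str = "",
              min_fragment_aa: int = 1) -> list[OrfCandidate]:
    """Enumerate sense-strand ORF candidates in all three frames.

    Within each inter-stop segment the maximal M-initiated ORF is
    reported; segments without an M are reported as open fragments only
    when they touch a transcript edge (the only place an assembly
    truncation can have removed the start or the stop).
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGTN"):
        raise ValueError(f"sequence contains characters outside ACGTN")

    candidates: list[OrfCandidate] = []
    for frame in range(3):
        codon_starts = range(frame, len(seq) - 2, 3)
        codons = [seq[i:i + 3] for i in codon_starts]
        aa = [_translate_codon(c) for c in codons]
        segment_start = 0  # codon index
        for idx in range(len(aa) + 1):
            at_end = idx == len(aa)
            if not at_end and aa[idx] != "*":
                continue
            seg = aa[segment_start:idx]
            has_stop = not at_end
            if seg:
                cand = _segment_candidate(
                    transcript_id, frame, seg, segment_start, has_stop,
                    leading=segment_start == 0, min_fragment_aa=min_fragment_aa)
                if cand is not None:
                    candidates.append(cand)
            segment_start = idx + 1
    return candidates


def _segment_candidate(transcript_id: str, frame: int, seg: list[str],
                       seg_start_codon: int, has_stop: bool, leading: bool,
                       min_fragment_aa: int) -> OrfCandidate | None:
    trailing = not has_stop
    if "M" in seg:
        offset = seg.index("M")
        protein = "".join(seg[offset:])
        start_codon = seg_start_codon + offset
        has_start = True
    else:
        if not (leading or trailing) or len(seg) < min_fragment_aa:
            return None
        protein = "".join(seg)
        start_codon = seg_start_codon
        has_start = False
    start = frame + 3 * start_codon
    end = start + 3 * len(protein) + (3 if has_stop else 0)
    return OrfCandidate(transcript_id=transcript_id, frame=frame, start=start,
                        end=end, protein=protein, has_start=has_start,
                        has_stop=has_stop)


def representative_orf(candidates: list[OrfCandidate]) -> OrfCandidate:
    """Longest candidate; ties broken by lowest frame, then leftmost start."""
    if not candidates:
        raise ValueError("no ORF candidates")
    return max(candidates,
               key=lambda c: (len(c.protein), -c.frame, -c.start))


def domain_coverage(protein: str, domain_consensus: str | None = None) -> float:
    """Fraction of the domain model spanned by the best local alignment.

    The numerator is the consensus interval between the first and last
    aligned column (internal gaps count as covered, matching how profile
    hits are measured); the denominator is the model length.
    """
    if domain_consensus is None:
        domain_consensus = load_domain_consensus()
    if not protein:
        warnings.warn("empty protein has zero domain coverage")
        return 0.0
    aln = local_protein_alignment(protein.replace("*", ""), domain_consensus)
    if aln is None or aln.score <= 0:
        return 0.0
    ref_blocks = aln.aligned[1]
    if len(ref_blocks) == 0:
        return 0.0
    covered = int(ref_blocks[-1][1]) - int(ref_blocks[0][0])
    return covered / len(domain_consensus)


def curate(orf: OrfCandidate,
           thresholds: CurationThresholds | None = None) -> str:
    """Label an ORF candidate ``full``, ``partial`` or ``flagged``."""
    th = thresholds or CurationThresholds()
    if orf.coverage is None:
        raise ValueError("coverage must be computed before curation")
    if orf.has_start and orf.has_stop:
        if orf.coverage >= th.full_coverage_min:
            return "full"
        if orf.coverage >= th.partial_coverage_max:
            return "flagged"
        return "partial"
    return "partial"


def curate_transcript(transcript_id: str, sequence: str,
                      domain_consensus: str | None = None,
                      thresholds: CurationThresholds | None = None
                      ) -> tuple[OrfCandidate, str]:
    """find_orfs -> representative -> coverage -> status, in one step."""
    rep = representative_orf(find_orfs(sequence, transcript_id))
    rep = replace(rep, coverage=domain_coverage(rep.protein, domain_consensus))
    return rep, curate(rep, thresholds)


def merge_with_known(transcripts: dict[str, str], known: dict[str, str],
                     thresholds: CurationThresholds | None = None):
    """Unify transcripts with previously known nucleotide sequences.

    A transcript and a known sequence are the same gene when their best
    local alignment reaches both cutoffs (identity >= 0.97 over >= 300
    aligned nucleotides); the longer sequence is kept under the transcript
    id and every merge is logged and returned as provenance.
    """
    import pandas as pd

    from ._align import alignment_identity_stats, local_nucleotide_alignment

    if not transcripts or not known:
        raise ValueError("merge_with_known requires nonempty inputs")
    th = thresholds or CurationThresholds()
    merged = dict(transcripts)
    records = []
    for kid, kseq in known.items():
        kmers = {kseq[i:i + 16] for i in range(len(kseq) - 15)}
        for tid, tseq in transcripts.items():
            if not any(tseq[i:i + 16] in kmers
                       for i in range(0, max(len(tseq) - 15, 1), 8)):
                continue
            aln = local_nucleotide_alignment(tseq, kseq)
            if aln is None:
                continue
            matches, columns = alignment_identity_stats(aln)
            identity = matches / columns if columns else 0.0
            if columns >= th.merge_overlap_min and identity >= th.merge_identity_min:
                keep = tseq if len(tseq) >= len(kseq) else kseq
                merged[tid] = keep
                records.append(dict(transcript_id=tid, known_id=kid,
                                    identity=identity, overlap=columns,
                                    kept="transcript" if keep is tseq else "known"))
                logger.info("merged %s with known %s (identity %.3f over %d nt)",
                            tid, kid, identity, columns)
    return merged, pd.DataFrame(
        records, columns=["transcript_id", "known_id", "identity", "overlap",
                          "kept"])
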