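"""Antisense transcript detection by strand-aware local alignment.

With a strand-specific library the given strand of every transcript is
its sense strand, so an antisense relationship shows up as a local
alignment between a CDS and the *reverse complement* of another
transcript.  A reported pair must satisfy all four criteria: opposite
strand, alignment length >= 100 bp, E-value <= 1e-50 and identity >=
99%.  The initial scan uses the looser 1e-5 E-value of a standard
nucleotide search; the 1e-50 criterion is then applied as a filter (with
the scoring used here the length and identity criteria make the 1e-50
filter nearly redundant, which is noted rather than hidden).

E-values follow Karlin–Altschul, E = K * m * n * exp(-lambda * S), with
lambda solved from sum_ij p_i p_j exp(lambda * s_ij) = 1 at uniform base
composition and K fixed at the standard ungapped value for +1/-2
scoring, so results are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import pandas as pd
from scipy.optimize import brentq

from ._align import alignment_identity_stats, local_nucleotide_alignment
from .expression import pearson
from .synthetic_data import revcomp


@dataclass(frozen=True)
class AntisenseCriteria:
    min_align_len: int = 100
    evalue_max: float = 1e-50
    min_identity: float = 0.99
    scan_evalue_max: float = 1e-5
    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    karlin_k: float = 0.621  # standard ungapped K for +1/-2

    @property
    def karlin_lambda(self) -> float:
        return _solve_lambda(self.match, self.mismatch)


@lru_cache(maxsize=8)
def _solve_lambda(match: int, mismatch: int) -> float:
    """Positive root of (1/4) e^(lam*match) + (3/4) e^(lam*mismatch) = 1."""

    def f(lam):
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


@dataclass(frozen=True)
class AntisensePair:
    cds_id: str
    transcript_id: str
    align_len: int
    identity: float
    evalue: float
    score: float
    r: float | None = None
    correlation_class: str | None = None


def evalue(score: float, m: int, n: int,
           crit: AntisenseCriteria | None = None) -> float:
    crit = crit or AntisenseCriteria()
    return crit.karlin_k * m * n * math.exp(-crit.karlin_lambda * score)


def _shares_seed(a: str, b: str, k: int = 14) -> bool:
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
    return any(b[i:i + k] in kmers for i in range(len(b) - k + 1))


def antisense_scan(cds_set: dict[str, str], transcripts: dict[str, str],
                   crit: AntisenseCriteria | None = None
                   ) -> list[AntisensePair]:
    """Scan every CDS against the reverse complement of every other
    transcript and keep the pairs passing all four criteria.

    Self-pairs are excluded; same-strand duplicates never produce an
    opposite-strand alignment and therefore never pass.  A transcript may
    pair with several CDS and vice versa.
    """
    crit = crit or AntisenseCriteria()
    pairs: list[AntisensePair] = []
    for cds_id in sorted(cds_set):
        cds = cds_set[cds_id].upper()
        for tid in sorted(transcripts):
            if tid == cds_id:
                continue
            rc = revcomp(transcripts[tid].upper())
            if not _shares_seed(cds, rc):
                continue
            aln = local_nucleotide_alignment(
                cds, rc, match=crit.match, mismatch=crit.mismatch,
                gap_open=crit.gap_open, gap_extend=crit.gap_extend)
            if aln is None:
                continue
            matches, columns = alignment_identity_stats(aln)
            ev = evalue(aln.score, len(cds), len(rc), crit)
            if ev > crit.scan_evalue_max:
                continue
            identity = matches / columns if columns else 0.0
            if (columns >= crit.min_align_len
                    and identity >= crit.min_identity
                    and ev <= crit.evalue_max):
                pairs.append(AntisensePair(cds_id=cds_id, transcript_id=tid,
                                           align_len=columns,
                                           identity=identity, evalue=ev,
                                           score=float(aln.score)))
    return pairs


def antisense_correlation(pairs: list[AntisensePair],
                          expression: pd.DataFrame,
                          r_cut: float = 0.9) -> list[AntisensePair]:
    """Classify each sense-antisense pair by expression correlation.

    positive iff r >= r_cut, negative iff r <= -r_cut, otherwise neutral;
    pairs with a missing profile are classed 'unassessed'.
    """
    out = []
    for pair in pairs:
        if (pair.cds_id not in expression.index
                or pair.transcript_id not in expression.index):
            out.append(replace(pair, r=None, correlation_class="unassessed"))
            continue
        r = pearson(expression.loc[pair.cds_id],
                    expression.loc[pair.transcript_id])
        if r >= r_cut:
            cls = "positive"
        elif r <= -r_cut:
            cls = "negative"
        else:
            cls = "neutral"
        out.append(replace(pair, r=r, correlation_class=cls))
    return out


def pairs_frame(pairs: list[AntisensePair]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in pairs])
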