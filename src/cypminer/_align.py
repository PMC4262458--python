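"""Pairwise alignment primitives shared across the pipeline.

Two alignment flavours are needed:

* a *glocal* (end-gap-free global) protein alignment under BLOSUM62 with
  affine gaps, used for nomenclature identity — implemented here as a
  vectorised Gotoh DP that maximises ``(score, matches)`` lexicographically,
  so the reported identity is canonical even when co-optimal alignments
  disagree on match counts;
* plain local alignments (domain coverage, nucleotide antisense scan),
  delegated to :class:`Bio.Align.PairwiseAligner`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZX*"

# lexicographic encoding: combined = score * _SCALE + matches.  _SCALE must
# exceed any achievable match count (sequences here are < 2000 residues).
_SCALE = 1 << 12
_NEG = np.int64(-(1 << 40))


@lru_cache(maxsize=None)
def _blosum62() -> np.ndarray:
    """BLOSUM62 as an integer matrix over PROTEIN_ALPHABET."""
    m = substitution_matrices.load("BLOSUM62")
    n = len(PROTEIN_ALPHABET)
    out = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            out[i, j] = int(m[a, b])
    return out


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([PROTEIN_ALPHABET.index(c) for c in seq.upper()],
                        dtype=np.int64)
    except ValueError as e:  # pragma: no cover - defensive
        raise ValueError(f"non-protein character in sequence: {e}")


@dataclass(frozen=True)
class GlocalAlignment:
    """Result of an end-gap-free global alignment."""

    score: int
    matches: int
    columns: int          # aligned columns, terminal gaps excluded
    query_span: tuple[int, int]
    ref_span: tuple[int, int]

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def glocal_align(query: str, ref: str, gap_open: int = 11,
                 gap_extend: int = 1) -> GlocalAlignment:
    """Align two proteins globally with free end gaps (Gotoh, BLOSUM62).

    A gap of length ``k`` inside the alignment costs ``gap_open + k *
    gap_extend`` (BLAST convention); terminal gaps are free.  Among all
    optimal-score alignments the one with the maximum number of identical
    columns is chosen, which makes the identity fraction well defined.
    """
    if not query or not ref:
        raise ValueError("pairwise alignment requires nonempty sequences")
    a = _encode(query)
    b = _encode(ref)
    sub = _blosum62()
    n, m = len(a), len(b)
    open_cost = np.int64((gap_open + gap_extend) * _SCALE)  # first gap column
    open_only = np.int64(gap_open * _SCALE)
    ext_cost = np.int64(gap_extend * _SCALE)

    # H = best of all states, X = gap in ref (consumes query, vertical),
    # Y = gap in query (consumes ref, horizontal).  Full matrices kept for
    # traceback; sequences here are a few hundred residues.
    H = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    H[0, :] = 0   # free leading gaps
    H[:, 0] = 0

    for i in range(1, n + 1):
        svec = sub[a[i - 1], b] * _SCALE + (a[i - 1] == b)
        diag = H[i - 1, :-1] + svec
        X[i, 1:] = np.maximum(H[i - 1, 1:] - open_cost, X[i - 1, 1:] - ext_cost)
        # interior horizontal gaps: gap of length g costs open + g*extend,
        # computed as a running maximum along the row
        best_so_far = np.maximum(diag, X[i, 1:])
        run = np.maximum.accumulate(best_so_far + ext_cost * np.arange(1, m + 1))
        Y[i, 2:] = run[:-1] - open_only - ext_cost * np.arange(2, m + 1)
        H[i, 1:] = np.maximum(np.maximum(diag, X[i, 1:]), Y[i, 1:])

    # free trailing gaps: best cell on the last row or last column
    end_candidates = [(H[n, j], n, j) for j in range(m + 1)]
    end_candidates += [(H[i, m], i, m) for i in range(n + 1)]
    best, ei, ej = max(end_candidates, key=lambda t: (t[0], t[1] + t[2]))

    # traceback from (ei, ej) to the first touch of row 0 / column 0
    i, j = ei, ej
    matches = 0
    columns = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            svec = sub[a[i - 1], b[j - 1]] * _SCALE + (a[i - 1] == b[j - 1])
            if H[i, j] == H[i - 1, j - 1] + svec:
                matches += int(a[i - 1] == b[j - 1])
                columns += 1
                i, j = i - 1, j - 1
                continue
            if H[i, j] == X[i, j]:
                state = "X"
                continue
            state = "Y"
            continue
        if state == "X":
            columns += 1
            if X[i, j] == H[i - 1, j] - open_cost:
                state = "H"
            i -= 1
            continue
        # state == "Y"
        columns += 1
        prev_from_h = max(H[i, j - 1], _NEG) - open_cost
        if Y[i, j] == prev_from_h and H[i, j - 1] > _NEG:
            state = "H"
        j -= 1

    score, mcount = divmod(int(best), _SCALE)
    # divmod floors, which is exactly right: matches component is in [0, _SCALE)
    return GlocalAlignment(score=score, matches=mcount, columns=columns,
                           query_span=(i, ei), ref_span=(j, ej))


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the end-gap-free global alignment.

    Symmetric, in [0, 1]; 1.0 for identical sequences.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires nonempty sequences")
    return glocal_align(a, b).identity


@lru_cache(maxsize=8)
def _protein_local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def local_protein_alignment(query: str, ref: str):
    """Best local BLOSUM62 alignment (Smith–Waterman); None if score <= 0."""
    aligner = _protein_local_aligner()
    try:
        aln = aligner.align(query, ref)
    except ValueError:
        return None
    try:
        return aln[0]
    except IndexError:
        return None


@lru_cache(maxsize=8)
def _nucleotide_local_aligner(match: int, mismatch: int, gap_open: int,
                              gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_nucleotide_alignment(query: str, ref: str, match: int = 1,
                               mismatch: int = -2, gap_open: int = 5,
                               gap_extend: int = 2):
    """Best local nucleotide alignment under BLASTN-like +1/-2 scoring."""
    aligner = _nucleotide_local_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(query, ref)
    try:
        return aln[0]
    except IndexError:
        return None


def alignment_identity_stats(alignment) -> tuple[int, int]:
    """(identical columns, total aligned columns) of a Biopython alignment."""
    seq_a, seq_b = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(seq_a, seq_b)
                  if x == y and x != "-")
    return matches, len(seq_a)
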