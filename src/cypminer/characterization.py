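"""Physicochemical descriptors and conserved-motif detection.

Molecular weight uses average residue masses (the convention of the usual
pI/MW web calculators); the isoelectric point solves the
Henderson–Hasselbalch net-charge equation over the termini and the
ionisable side chains (D, E, C, Y, H, K, R) with the Bjellqvist pKa set
by bisection.  Motif detection is a targeted degenerate-pattern scan for
the four diagnostic CYP450 motifs (heme-binding signature, PERF, K-helix
EXXR, I-helix), with separate consensus variants for A-type and
non-A-type sequences.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

# average (not monoisotopic) residue masses, Da
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

# Bjellqvist pKa values
POSITIVE_PKS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
NEGATIVE_PKS = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}


def molecular_weight(protein: str) -> float:
    """Average molecular weight in kDa (one water added for the chain)."""
    if not protein:
        raise ValueError("empty protein")
    mass = WATER_MASS
    skipped = 0
    for aa in protein.upper():
        if aa in RESIDUE_MASS:
            mass += RESIDUE_MASS[aa]
        else:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} non-standard residue(s) excluded from MW")
    return mass / 1000.0


def net_charge(protein: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge at a given pH."""
    counts = {aa: protein.count(aa) for aa in "DECYHKR"}
    charge = 1.0 / (1.0 + 10 ** (ph - POSITIVE_PKS["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (NEGATIVE_PKS["Cterm"] - ph))
    for aa in "HKR":
        charge += counts[aa] / (1.0 + 10 ** (ph - POSITIVE_PKS[aa]))
    for aa in "DECY":
        charge -= counts[aa] / (1.0 + 10 ** (NEGATIVE_PKS[aa] - ph))
    return charge


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    if not protein:
        raise ValueError("empty protein")
    protein = protein.upper()
    lo, hi = 0.0, 14.0
    c_lo, c_hi = net_charge(protein, lo), net_charge(protein, hi)
    if c_lo < 0 or c_hi > 0:
        raise ValueError(
            f"no zero crossing in [0, 14]: charge(0)={c_lo:.3f}, "
            f"charge(14)={c_hi:.3f}")
    # bisect to interval convergence rather than stopping at the first
    # |charge| < tol point: on charge-poor sequences the curve plateaus
    # near zero and an early exit could sit far from the true crossing
    while hi - lo > 1e-7:
        mid = (lo + hi) / 2.0
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    mid = (lo + hi) / 2.0
    if abs(net_charge(protein, mid)) >= tol:
        raise ValueError("net charge did not converge to zero "
                         f"(|charge| = {abs(net_charge(protein, mid)):.2e})")
    return mid


# ---------------------------------------------------------------------------
# motifs

@dataclass(frozen=True)
class MotifDefinition:
    """Degenerate pattern pair for one conserved motif.

    Patterns use specific residues, X for any residue and bracketed
    alternatives such as [ED].
    """

    name: str
    pattern_a: str
    pattern_non_a: str
    flank: int = 5

    def pattern(self, cyp_type: str) -> str:
        return self.pattern_a if cyp_type == "A" else self.pattern_non_a


# The PERF motif is scanned with its extended consensus (conserved F at
# position -2); the classical 4-residue form is available via
# classic_perf=True.
DEFAULT_MOTIFS = (
    MotifDefinition("heme", "PFGXGRRXCXG", "XFXXGXRXCXG"),
    MotifDefinition("PERF", "FXPERF", "FXPXRX"),
    MotifDefinition("K-helix", "EXXR", "EXXR"),
    MotifDefinition("I-helix", "AGXDT", "AGX[ED]T"),
)
CLASSIC_PERF = MotifDefinition("PERF", "PERF", "PXRX")


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    position: int      # 0-based start of the core match
    core: str          # the residues matching the pattern
    matched: str       # core with up to `flank` residues of context each side


def _compile(pattern: str) -> re.Pattern:
    out, i = [], 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "X":
            out.append(".")
            i += 1
        elif ch == "[":
            j = pattern.index("]", i)
            out.append(pattern[i:j + 1])
            i = j + 1
        elif ch == "(":  # (E/D) alternative notation
            j = pattern.index(")", i)
            out.append("[" + pattern[i + 1:j].replace("/", "") + "]")
            i = j + 1
        else:
            out.append(re.escape(ch))
            i += 1
    return re.compile("".join(out))


def find_motifs(protein: str, cyp_type: str,
                defs: tuple[MotifDefinition, ...] = DEFAULT_MOTIFS,
                gene_id: str = "", classic_perf: bool = False
                ) -> list[MotifHit]:
    """All non-overlapping hits of each motif pattern, with flank context."""
    if cyp_type not in ("A", "non-A"):
        raise ValueError("cyp_type must be 'A' or 'non-A'")
    if classic_perf:
        defs = tuple(CLASSIC_PERF if d.name == "PERF" else d for d in defs)
    hits = []
    for d in defs:
        rx = _compile(d.pattern(cyp_type))
        for m in rx.finditer(protein):
            lo = max(0, m.start() - d.flank)
            hi = min(len(protein), m.end() + d.flank)
            hits.append(MotifHit(gene_id=gene_id, motif=d.name,
                                 position=m.start(), core=m.group(0),
                                 matched=protein[lo:hi]))
    return hits


def missing_motifs(hits: list[MotifHit],
                   defs: tuple[MotifDefinition, ...] = DEFAULT_MOTIFS
                   ) -> list[str]:
    """Motif names with no hit — the deviations report for one gene."""
    present = {h.motif for h in hits}
    return [d.name for d in defs if d.name not in present]


def motif_logo(sequences: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    """Position-frequency matrix and per-column information content (bits).

    All sequences must share one aligned width; columns of the frequency
    matrix sum to 1 and IC = log2(20) - H(column).
    """
    if not sequences:
        raise ValueError("at least one hit is required")
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise ValueError("motif hits have unequal aligned widths")
    alphabet = sorted(RESIDUE_MASS)
    counts = np.zeros((width, len(alphabet)))
    index = {aa: k for k, aa in enumerate(alphabet)}
    for s in sequences:
        for pos, aa in enumerate(s.upper()):
            if aa in index:
                counts[pos, index[aa]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freqs = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = math.log2(20) + plogp.sum(axis=1)
    return pd.DataFrame(freqs, columns=alphabet), ic


def characterize(gene_id: str, protein: str, cyp_type: str) -> dict:
    """One row of the characterisation table for a classified protein."""
    hits = find_motifs(protein, cyp_type, gene_id=gene_id)
    positions = {d.name: ";".join(str(h.position) for h in hits
                                  if h.motif == d.name)
                 for d in DEFAULT_MOTIFS}
    return dict(gene_id=gene_id, length=len(protein),
                pI=round(isoelectric_point(protein), 2),
                MW_kDa=round(molecular_weight(protein), 1),
                **{f"{k}_pos": v for k, v in positions.items()},
                missing=";".join(missing_motifs(hits)))
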