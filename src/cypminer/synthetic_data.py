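"""Seeded synthetic transcriptome bundles with recoverable planted truth.

The generator emulates the study design every downstream stage expects:

* a reference protein panel with the nomenclature tier structure
  (within-subfamily identity >= 0.55, within-family in [0.40, 0.55),
  across families < 0.40), derived from the packaged domain consensus so
  planted full-length genes clear the 85% domain-coverage bar;
* a strand-specific transcript set containing full-length ORFs at
  controlled identity to the panel, partial fragments (start- or
  stop-missing), antisense copies (>= 100 bp windows at >= 99% nucleotide
  identity on the opposite strand) and unrelated decoys;
* a 3-tissue FPKM matrix with genes planted co-expressed (Pearson r = 1
  before noise) or anti-correlated with a designated marker gene, plus a
  pathway annotation that makes the candidate set recoverable;
* a qPCR Ct table (3 biological x 3 technical replicates per tissue)
  whose relative expressions invert to the planted FPKM ratios.

Every planted claim is re-measured with the pipeline's own operations at
generation time; a violation that survives bounded re-drawing raises
instead of silently shipping a bad truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from ._align import pairwise_identity
from .io_utils import load_domain_consensus, write_fasta, write_tsv

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# columns of the packaged consensus occupied by the four conserved motifs;
# kept invariant under every mutation so motif-detection recall is 1 by
# construction (as in real CYPs, where these residues are near-invariant)
MOTIF_SPANS = {
    "I-helix": (300, 305),
    "K-helix": (355, 359),
    "PERF": (405, 411),
    "heme": (425, 436),
}
_MOTIF_COLUMNS = frozenset(
    i for start, end in MOTIF_SPANS.values() for i in range(start, end)
)

# additional short conserved blocks spaced along the domain.  Real CYP450s
# retain scattered near-invariant blocks besides the four named motifs;
# without them a distant member's local alignment to the domain model
# fragments and the full-length coverage criterion could not be met by any
# genuine family member, which would make the planted truth unrealisable.
_ANCHOR_SPANS = (
    (8, 14), (58, 64), (108, 114), (158, 164), (208, 214), (253, 259),
    (330, 336), (383, 389), (450, 456),
)
_CONSERVED_COLUMNS = _MOTIF_COLUMNS | frozenset(
    i for start, end in _ANCHOR_SPANS for i in range(start, end)
)


class GenerationError(RuntimeError):
    """Planted structure could not be realised within bounded attempts."""


@dataclass(frozen=True)
class PanelEntry:
    name: str
    protein: str
    family: str
    subfamily: str
    clan: str


@dataclass(frozen=True)
class ReferencePanel:
    entries: tuple[PanelEntry, ...]

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("panel names must be unique")
        fam_clan: dict[str, str] = {}
        for e in self.entries:
            if not e.subfamily.startswith(e.family):
                raise ValueError(f"subfamily {e.subfamily} does not extend {e.family}")
            if fam_clan.setdefault(e.family, e.clan) != e.clan:
                raise ValueError(f"family {e.family} maps to more than one clan")

    def proteins(self) -> dict[str, str]:
        return {e.name: e.protein for e in self.entries}

    def clan_map(self) -> dict[str, str]:
        return {e.family: e.clan for e in self.entries}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Defaults are the noise-free desk-scale conditions used throughout the
    test-suite: a 16-protein panel (4 families x 2 subfamilies x 2
    members), 20 full-length genes cycling through identity targets that
    exercise every nomenclature tier, partial fragments of both kinds,
    15 antisense copies planted 12 positively / 3 negatively correlated
    with their sense genes (mirroring the published sense-antisense
    counts), and 3 pathway-supported candidates among 10 co-expressed
    genes (mirroring the published dual-evidence candidate count).
    """

    n_families: int = 4
    n_subfamilies_per_family: int = 2
    n_members_per_subfamily: int = 2
    n_full: int = 20
    n_partial: int = 8
    n_antisense: int = 15
    n_decoys: int = 12
    identity_targets: tuple[float, ...] = (0.98, 0.85, 0.60, 0.45)
    tissues: tuple[str, str, str] = ("root", "leaf", "flower")
    r_target: float = 0.9
    noise_sd: float = 0.0
    seed: int = 0
    # expression-layer plantings
    n_coexpressed: int = 10
    n_anticorrelated: int = 3
    n_antisense_positive: int = 12
    n_antisense_negative: int = 3
    n_pathway_coexpressed: int = 3
    n_pathway_other: int = 2
    target_pathway: str = "diterpenoid biosynthesis"
    # qPCR layer
    n_qpcr_genes: int = 19
    control_gene: str = "ACTIN"
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    # previously-known sequences emitted for the merge stage
    n_known: int = 2

    def validate(self) -> None:
        counts = dict(n_families=self.n_families,
                      n_subfamilies_per_family=self.n_subfamilies_per_family,
                      n_members_per_subfamily=self.n_members_per_subfamily,
                      n_full=self.n_full, n_partial=self.n_partial,
                      n_antisense=self.n_antisense, n_decoys=self.n_decoys)
        for key, value in counts.items():
            if value < 0:
                raise ValueError(f"{key} must be nonnegative, got {value}")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for t in self.identity_targets:
            if not 0.0 < t <= 1.0:
                raise ValueError(f"identity target {t} outside (0, 1]")
        if len(self.tissues) != 3:
            raise ValueError("exactly 3 tissues are required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.r_target >= 1.0 and self.noise_sd > 0:
            raise ValueError("r_target >= 1 is unattainable with nonzero noise")
        if self.n_antisense_positive + self.n_antisense_negative > self.n_antisense:
            raise ValueError("planted antisense classes exceed n_antisense")
        if self.n_coexpressed + self.n_anticorrelated + 1 > self.n_full:
            raise ValueError("co-expression plantings exceed n_full (marker included)")
        if self.n_pathway_coexpressed > self.n_coexpressed:
            raise ValueError("pathway-supported candidates exceed n_coexpressed")
        if self.n_antisense > 0 and self.n_full == 0:
            raise ValueError("antisense copies require at least one full gene")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Deterministic child stream per generator stage."""
    root = np.random.SeedSequence(config.seed)
    streams = ["panel", "transcriptome", "expression", "qpcr"]
    return np.random.default_rng(root.spawn(len(streams))[streams.index(stream)])


# ---------------------------------------------------------------------------
# protein layer

def _mutate(protein: str, n_mut: int, rng: np.random.Generator,
            protect: frozenset[int] = _CONSERVED_COLUMNS) -> str:
    """Substitute n_mut positions (uniform over the 19 alternatives).

    Position 0 (the initiator M) and the conserved motif/anchor columns
    are never touched.
    """
    mutable = [i for i in range(1, len(protein)) if i not in protect]
    if n_mut > len(mutable):
        raise GenerationError("identity target requires more mutations than "
                              "there are mutable positions")
    sites = rng.choice(len(mutable), size=n_mut, replace=False)
    seq = list(protein)
    for s in sites:
        i = mutable[s]
        alternatives = AMINO_ACIDS.replace(seq[i], "")
        seq[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def _mutate_to_identity(protein: str, target: float, rng: np.random.Generator,
                        tol: float = 0.02, attempts: int = 12) -> str:
    """Mutate until the alignment-measured identity is within tol of target."""
    n_mut = round((1.0 - target) * len(protein))
    for _ in range(attempts):
        mutant = _mutate(protein, n_mut, rng)
        if abs(pairwise_identity(mutant, protein) - target) <= tol:
            return mutant
    raise GenerationError(f"could not realise identity target {target}")


_SUBFAMILY_LETTERS = [chr(ord("A") + i) for i in range(26)]


def make_reference_panel(config: SimulationConfig) -> ReferencePanel:
    """Generate a reference panel honouring the nomenclature tier structure.

    All panel proteins descend from the packaged domain consensus by point
    substitution only (no indels), which keeps the identity oracle exact
    and guarantees full-length domain coverage.  The realised tiers are
    re-measured with the pipeline's own identity operation; members that
    land outside their band are re-drawn a bounded number of times before
    an explicit failure is raised.
    """
    config.validate()
    rng = _rng(config, "panel")
    consensus = load_domain_consensus()
    L = len(consensus)
    clans = ["71", "85", "72", "86", "97", "74", "51", "711", "727"]

    fam_frac, sub_frac, member_frac = 0.55, 0.37, 0.05
    entries: list[PanelEntry] = []
    for f in range(config.n_families):
        family = f"CYP{801 + f}"
        clan = clans[f % len(clans)]
        # retries are hierarchical: a subfamily (or family) ancestor that
        # strands its descendants outside their identity band is re-drawn
        for fam_attempt in range(8):
            try:
                ancestor = _draw_with_coverage(consensus, round(fam_frac * L),
                                               rng, min_coverage=0.92)
                family_entries = list(entries)
                for s in range(config.n_subfamilies_per_family):
                    subfamily = family + _SUBFAMILY_LETTERS[s]
                    family_entries = _make_subfamily(
                        family_entries, family, subfamily, clan, ancestor,
                        config.n_members_per_subfamily,
                        round(sub_frac * L), round(member_frac * L), rng)
                entries = family_entries
                break
            except GenerationError:
                if fam_attempt == 7:
                    raise
    return ReferencePanel(tuple(entries))


def _make_subfamily(entries: list[PanelEntry], family: str, subfamily: str,
                    clan: str, ancestor: str, n_members: int,
                    n_mut_sub: int, n_mut_member: int,
                    rng: np.random.Generator) -> list[PanelEntry]:
    for attempt in range(8):
        try:
            sub_ancestor = _draw_with_coverage(ancestor, n_mut_sub, rng,
                                               min_coverage=0.91)
            out = list(entries)
            for m in range(n_members):
                name = f"{subfamily}{m + 1}"
                protein = _mutate(sub_ancestor, n_mut_member, rng)
                entry = PanelEntry(name, protein, family, subfamily, clan)
                out = _place_with_retries(out, entry, sub_ancestor,
                                          n_mut_member, rng)
            return out
        except GenerationError:
            if attempt == 7:
                raise
    raise GenerationError(f"subfamily {subfamily} infeasible")


def _draw_with_coverage(source: str, n_mut: int, rng: np.random.Generator,
                        min_coverage: float, attempts: int = 30) -> str:
    """Mutate, re-drawing until the domain model stays fully covered.

    Ancestors that lose domain coverage would doom every descendant, so
    coverage is enforced at each level of the panel hierarchy.
    """
    from .orf_curation import domain_coverage  # local import avoids a cycle

    for _ in range(attempts):
        mutant = _mutate(source, n_mut, rng)
        if domain_coverage(mutant) >= min_coverage:
            return mutant
    raise GenerationError(
        f"no mutant at {n_mut} substitutions kept domain coverage "
        f">= {min_coverage}")


def _tier_band(a: PanelEntry, b: PanelEntry) -> tuple[float, float]:
    if a.subfamily == b.subfamily:
        return (0.55, 1.0)
    if a.family == b.family:
        return (0.40, 0.55)
    return (0.0, 0.40)


def _place_with_retries(entries: list[PanelEntry], entry: PanelEntry,
                        source: str, n_mut: int, rng: np.random.Generator,
                        attempts: int = 20) -> list[PanelEntry]:
    """Append entry, re-drawing its protein until every pairwise tier holds
    and the member still covers the full domain model (panel references are
    full-length domain proteins by definition)."""
    from .orf_curation import domain_coverage  # local import avoids a cycle

    for _ in range(attempts):
        ok = domain_coverage(entry.protein) >= 0.90
        if ok:
            for other in entries:
                ident = pairwise_identity(entry.protein, other.protein)
                lo, hi = _tier_band(entry, other)
                if not (lo <= ident < hi or (hi == 1.0 and ident == 1.0)):
                    ok = False
                    break
        if ok:
            return entries + [entry]
        entry = replace(entry, protein=_mutate(source, n_mut, rng))
    raise GenerationError(
        f"tier structure infeasible for {entry.name} after {attempts} attempts")


# ---------------------------------------------------------------------------
# nucleotide layer

_CODON_TABLE = unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()
_STOP_CODONS = sorted(_CODON_TABLE.stop_codons)


def back_translate(protein: str, rng: np.random.Generator,
                   stop: bool = True) -> str:
    """Back-translate with uniform synonymous codon choice under the seed."""
    codons = [
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))] for aa in protein
    ]
    if stop:
        codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def _random_utr(rng: np.random.Generator, lo: int = 20, hi: int = 80) -> str:
    """Random UTR free of ATG triplets (keeps the planted ORF unambiguous)."""
    length = int(rng.integers(lo, hi + 1))
    bases = "ACGT"
    for _ in range(100):
        utr = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        if "ATG" not in utr:
            return utr
    raise GenerationError("could not draw an ATG-free UTR")  # pragma: no cover


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    panel: ReferencePanel
    transcripts: dict[str, str]
    truth: pd.DataFrame
    cds: dict[str, str] = field(default_factory=dict)       # full genes only
    proteins: dict[str, str] = field(default_factory=dict)  # planted proteins
    known: dict[str, str] = field(default_factory=dict)
    expression: pd.DataFrame | None = None
    expression_truth: dict | None = None
    pathway: pd.DataFrame | None = None
    qpcr: pd.DataFrame | None = None

    @property
    def marker(self) -> str:
        return self.expression_truth["marker"] if self.expression_truth else None

    def write(self, outdir) -> None:
        """Write the standard file bundle (FASTA wrapped at 60 cols, TSV)."""
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.transcripts, out / "transcripts.fasta")
        write_fasta(self.panel.proteins(), out / "panel.fasta")
        write_tsv(pd.DataFrame(
            [(e.name, e.family, e.subfamily, e.clan) for e in self.panel.entries],
            columns=["name", "family", "subfamily", "clan"]), out / "panel.tsv")
        write_tsv(self.truth, out / "truth.tsv")
        if self.known:
            write_fasta(self.known, out / "known.fasta")
        if self.expression is not None:
            self.expression.rename_axis("gene").reset_index().to_csv(
                out / "expression.tsv", sep="\t", index=False)
        if self.pathway is not None:
            write_tsv(self.pathway, out / "pathway.tsv")
        if self.qpcr is not None:
            write_tsv(self.qpcr, out / "qpcr.tsv")


def make_transcriptome(panel: ReferencePanel,
                       config: SimulationConfig) -> SyntheticBundle:
    """Plant full, partial, antisense and decoy transcripts with known truth."""
    config.validate()
    if not panel.entries:
        raise ValueError("panel must be nonempty")
    rng = _rng(config, "transcriptome")
    transcripts: dict[str, str] = {}
    cds: dict[str, str] = {}
    proteins: dict[str, str] = {}
    rows = []

    sources = panel.entries
    # --- full-length genes -------------------------------------------------
    for i in range(config.n_full):
        gid = f"TRN_F{i + 1:03d}"
        src = sources[i % len(sources)]
        target = config.identity_targets[i % len(config.identity_targets)]
        protein = _full_length_protein(src.protein, target, rng)
        coding = back_translate(protein, rng, stop=True)
        utr5, utr3 = _random_utr(rng), _random_utr(rng)
        transcripts[gid] = utr5 + coding + utr3
        cds[gid] = coding
        proteins[gid] = protein
        rows.append(dict(transcript_id=gid, truth_class="full_cyp",
                         source_ref=src.name,
                         planted_identity=pairwise_identity(protein, src.protein),
                         orf_start=len(utr5), orf_end=len(utr5) + len(coding),
                         sense_id=""))

    # --- partial fragments -------------------------------------------------
    for i in range(config.n_partial):
        gid = f"TRN_P{i + 1:03d}"
        src = sources[(i + 1) % len(sources)]
        target = config.identity_targets[i % len(config.identity_targets)]
        protein = _mutate_to_identity(src.protein, target, rng)
        if i % 2 == 0:
            # start-missing: 3'-anchored fragment, internal Ms removed so the
            # recovered candidate is the full open fragment from position 0
            keep = int(0.55 * len(protein))
            frag = protein[len(protein) - keep:].replace("M", "L")
            coding = back_translate(frag, rng, stop=True)
            transcripts[gid] = coding + _random_utr(rng)
            proteins[gid] = frag
            rows.append(dict(transcript_id=gid, truth_class="partial_cyp",
                             source_ref=src.name,
                             planted_identity=pairwise_identity(frag, src.protein),
                             orf_start=0, orf_end=len(coding), sense_id=""))
        else:
            # stop-missing: 5' end intact, transcript truncated mid-CDS
            keep = int(rng.integers(int(0.85 * len(protein)),
                                    int(0.95 * len(protein))))
            frag = protein[:keep]
            coding = back_translate(frag, rng, stop=False)
            utr5 = _random_utr(rng)
            transcripts[gid] = utr5 + coding
            proteins[gid] = frag
            rows.append(dict(transcript_id=gid, truth_class="partial_cyp",
                             source_ref=src.name,
                             planted_identity=pairwise_identity(frag, src.protein),
                             orf_start=len(utr5), orf_end=len(utr5) + len(coding),
                             sense_id=""))

    # --- antisense copies --------------------------------------------------
    full_ids = [f"TRN_F{i + 1:03d}" for i in range(config.n_full)]
    for i in range(config.n_antisense):
        gid = f"TRN_A{i + 1:03d}"
        sense = full_ids[i % len(full_ids)]
        seq, identity = _antisense_transcript(cds[sense], rng)
        transcripts[gid] = seq
        rows.append(dict(transcript_id=gid, truth_class="antisense",
                         source_ref="", planted_identity=identity,
                         orf_start=-1, orf_end=-1, sense_id=sense))

    # --- decoys ------------------------------------------------------------
    panel_proteins = list(panel.proteins().values())
    for i in range(config.n_decoys):
        gid = f"TRN_D{i + 1:03d}"
        transcripts[gid] = _draw_decoy(rng, panel_proteins)
        rows.append(dict(transcript_id=gid, truth_class="decoy", source_ref="",
                         planted_identity=float("nan"), orf_start=-1,
                         orf_end=-1, sense_id=""))

    # --- previously-known sequences for the merge stage --------------------
    known = {f"KNOWN_{i + 1:02d}": cds[full_ids[i]]
             for i in range(min(config.n_known, len(full_ids)))}

    truth = pd.DataFrame(rows)
    return SyntheticBundle(config=config, panel=panel, transcripts=transcripts,
                           truth=truth, cds=cds, proteins=proteins, known=known)


def _antisense_transcript(coding: str, rng: np.random.Generator,
                          attempts: int = 10) -> tuple[str, float]:
    """Reverse complement of a CDS window (>= 100 bp, >= 99% identity)
    embedded in random flanks.

    The claim is verified with the same local alignment the antisense
    scanner uses: chance matches in the flanks can extend the optimal
    alignment and dilute its identity below the planted value, so flanks
    are re-drawn until the *measured* identity stays above the filter.
    """
    from ._align import alignment_identity_stats, local_nucleotide_alignment

    for _ in range(attempts):
        wlen = int(rng.integers(120, min(351, len(coding))))
        start = int(rng.integers(0, len(coding) - wlen + 1))
        window = list(coding[start:start + wlen])
        n_mut = int(rng.integers(0, 2))  # 0 or 1 mismatch: identity >= 0.99
        for p in rng.choice(wlen, size=n_mut, replace=False):
            window[p] = "ACGT".replace(window[p], "")[rng.integers(3)]
        seq = (_random_utr(rng, 20, 60) + revcomp("".join(window))
               + _random_utr(rng, 20, 60))
        aln = local_nucleotide_alignment(coding, revcomp(seq))
        matches, columns = alignment_identity_stats(aln)
        if columns >= 100 and matches / columns >= 0.992:
            return seq, matches / columns
    raise GenerationError("could not plant a clean antisense window")


def _full_length_protein(source: str, target: float, rng: np.random.Generator,
                         attempts: int = 10) -> str:
    """A planted full-length protein: at `target` identity to its panel
    source AND clearing the full-length domain-coverage bar (with margin),
    re-drawn until both hold — truth-table claims must be realisable."""
    from .orf_curation import domain_coverage  # local import avoids a cycle

    if target == 1.0:
        return source
    for _ in range(attempts):
        protein = _mutate_to_identity(source, target, rng)
        if domain_coverage(protein) >= 0.87:
            return protein
    raise GenerationError(
        f"no mutant at identity {target} kept full domain coverage")


def _draw_decoy(rng: np.random.Generator, panel_proteins: list[str],
                attempts: int = 10) -> str:
    """Random transcript sharing no >= 40% identity ORF with the panel."""
    from .orf_curation import find_orfs  # local import to avoid a cycle

    bases = "ACGT"
    for _ in range(attempts):
        length = int(rng.integers(500, 1400))
        seq = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        candidates = find_orfs(seq)
        rep = max(candidates, key=lambda c: (len(c.protein), -c.frame))
        protein = rep.protein.replace("*", "").replace("X", "A")
        if len(protein) < 10:
            return seq
        worst = max(pairwise_identity(protein, p) for p in panel_proteins)
        if worst < 0.38:
            return seq
    raise GenerationError("could not draw a decoy below the identity ceiling")


# ---------------------------------------------------------------------------
# expression layer

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt((x ** 2).sum() * (y ** 2).sum())
    return float((x * y).sum() / denom) if denom else float("nan")


def make_expression(bundle: SyntheticBundle,
                    config: SimulationConfig | None = None) -> SyntheticBundle:
    """Attach a 3-tissue FPKM matrix with planted correlation structure."""
    config = config or bundle.config
    config.validate()
    rng = _rng(config, "expression")
    tissues = list(config.tissues)
    full_ids = sorted(t for t in bundle.transcripts if t.startswith("TRN_F"))
    if not full_ids:
        raise GenerationError("expression layer requires at least one full gene")

    marker = full_ids[0]
    marker_profile = np.array([120.0, 18.0, 6.0])  # root-dominant, marker-like
    profiles: dict[str, np.ndarray] = {marker: marker_profile}

    co = full_ids[1:1 + config.n_coexpressed]
    anti = full_ids[1 + config.n_coexpressed:
                    1 + config.n_coexpressed + config.n_anticorrelated]
    for gid in co:
        scale = float(rng.uniform(0.05, 3.0))
        offset = float(rng.uniform(0.0, 2.0))
        profiles[gid] = scale * marker_profile + offset       # r = +1 pre-noise
    hi, lo = marker_profile.max(), marker_profile.min()
    for gid in anti:
        scale = float(rng.uniform(0.2, 1.0))
        profiles[gid] = scale * (hi + lo - marker_profile)    # r = -1 pre-noise

    # antisense copies: planted positive / negative correlation with sense
    as_ids = sorted(t for t in bundle.transcripts if t.startswith("TRN_A"))
    sense_of = dict(zip(bundle.truth.transcript_id, bundle.truth.sense_id))
    as_pos = as_ids[:config.n_antisense_positive]
    as_neg = as_ids[config.n_antisense_positive:
                    config.n_antisense_positive + config.n_antisense_negative]

    # everything else: neutral profiles kept away from the screening cutoff
    neutral = [t for t in bundle.transcripts
               if t not in profiles and t not in as_pos and t not in as_neg]
    silent: dict[str, list[str]] = {}
    for k, gid in enumerate(neutral):
        profiles[gid] = _draw_neutral(rng, marker_profile)
        if gid.startswith("TRN_D") and k % 4 == 0:
            t = tissues[k % 3]
            profiles[gid] = profiles[gid].copy()
            profiles[gid][k % 3] = float(rng.uniform(0.0, 1.0))  # FPKM <= 1
            silent[gid] = [t]

    for gid in as_pos:
        sense_profile = profiles[sense_of[gid]]
        profiles[gid] = float(rng.uniform(0.1, 1.0)) * sense_profile
    for gid in as_neg:
        sense_profile = profiles[sense_of[gid]]
        shi, slo = sense_profile.max(), sense_profile.min()
        profiles[gid] = float(rng.uniform(0.2, 1.0)) * (shi + slo - sense_profile)

    order = list(bundle.transcripts)
    matrix = np.vstack([profiles[g] for g in order])
    if config.noise_sd > 0:
        matrix = matrix * np.exp(rng.normal(0.0, config.noise_sd, matrix.shape))
    expr = pd.DataFrame(matrix, index=order, columns=tissues)
    expr.index.name = "gene"

    pathway_members = co[:config.n_pathway_coexpressed]
    other_members = [g for g in full_ids
                     if g not in co and g != marker][:config.n_pathway_other]
    pathway = pd.DataFrame(
        [(g, config.target_pathway) for g in pathway_members + other_members]
        + [(g, "monoterpenoid biosynthesis") for g in anti],
        columns=["gene", "pathway"])

    bundle.expression = expr
    bundle.pathway = pathway
    bundle.expression_truth = dict(
        marker=marker, coexpressed=list(co), anticorrelated=list(anti),
        pathway_members=pathway_members + other_members,
        candidates=list(pathway_members),
        antisense_positive=list(as_pos), antisense_negative=list(as_neg),
        silent=silent,
    )
    return bundle


def _draw_neutral(rng: np.random.Generator, marker_profile: np.ndarray,
                  attempts: int = 200) -> np.ndarray:
    """Random positive profile with |r vs marker| < 0.85 (3-point r is
    degenerate, so rejection sampling is the honest way to stay neutral)."""
    for _ in range(attempts):
        profile = rng.uniform(0.5, 60.0, size=3)
        if abs(_pearson(profile, marker_profile)) < 0.85:
            return profile
    raise GenerationError("could not draw a neutral profile")  # pragma: no cover


# ---------------------------------------------------------------------------
# qPCR layer

def make_qpcr(bundle: SyntheticBundle,
              config: SimulationConfig | None = None) -> SyntheticBundle:
    """Ct table consistent with the planted expression under the 2^-ddCt model.

    Ct(gene, tissue) = offset - log2(FPKM) plus biological and technical
    noise; the endogenous control sits at a constant baseline, so relative
    expression computed by the ddCt stage inverts to the planted FPKM
    ratios exactly at noise 0.
    """
    config = config or bundle.config
    if bundle.expression is None:
        raise ValueError("make_expression must run before make_qpcr")
    rng = _rng(config, "qpcr")
    expr = bundle.expression
    full_ids = [g for g in expr.index if g.startswith("TRN_F")]
    measured = full_ids[:config.n_qpcr_genes]
    for gid in measured:
        if (expr.loc[gid] <= 0).any():
            raise ValueError(f"nonpositive expression for measured gene {gid}")

    bio_sd = config.noise_sd
    tech_sd = config.noise_sd / 2.0
    offset, control_ct = 28.0, 20.0
    rows = []
    for tissue in config.tissues:
        for bio in range(1, config.n_bio_reps + 1):
            bio_shift = rng.normal(0.0, bio_sd) if bio_sd else 0.0
            ctl_bio = rng.normal(0.0, bio_sd) if bio_sd else 0.0
            for tech in range(1, config.n_tech_reps + 1):
                rows.append((config.control_gene, tissue, bio, tech,
                             control_ct + ctl_bio
                             + (rng.normal(0.0, tech_sd) if tech_sd else 0.0)))
                for gid in measured:
                    ct = (offset - math.log2(float(expr.loc[gid, tissue]))
                          + bio_shift
                          + (rng.normal(0.0, tech_sd) if tech_sd else 0.0))
                    rows.append((gid, tissue, bio, tech, ct))
    bundle.qpcr = pd.DataFrame(
        rows, columns=["gene", "tissue", "bio_rep", "tech_rep", "Ct"])
    return bundle


def generate_bundle(config: SimulationConfig | None = None) -> SyntheticBundle:
    """Panel -> transcriptome -> expression -> qPCR, all from one seed."""
    config = config or SimulationConfig()
    panel = make_reference_panel(config)
    bundle = make_transcriptome(panel, config)
    bundle = make_expression(bundle, config)
    bundle = make_qpcr(bundle, config)
    return bundle
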