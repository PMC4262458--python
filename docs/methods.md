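# Methods

This note documents the models, parameter choices and numerical decisions
behind `cypminer`, and what the synthetic benchmarks do and do not show.

## Sequence identity for nomenclature

The tier cutoffs of CYP nomenclature (family 40%, subfamily 55%, allelic
variant 97%) presuppose a definition of "percent identity", which the
field rarely states. We use **identical columns / aligned columns of a
global alignment with free end gaps** (a "glocal" alignment), scored with
BLOSUM62 and affine gaps (opening 11, extension 1, a gap of length *k*
costing 11 + *k*). Free end gaps make the measure stable for fragment
queries: a partial protein contained in a reference scores by its overlap
rather than being punished for the reference's extra length. The flip
side, exercised deliberately in the tests, is that a query that is a
strict prefix of a reference is 100% identical to it — which is the
correct reading of the definition, not an artefact.

Co-optimal alignments can disagree on how many columns are identical, so
`pairwise_identity` is made canonical: the DP maximises the pair
(score, identical columns) lexicographically (implemented by scaling
integer scores by 2¹² and adding the match count, which is exact in
64-bit arithmetic). Tests verify the score against an independent
end-gap-free aligner on random pairs and the (score, matches) pair
against an exhaustive DP on short sequences.

Boundary semantics are **≥** at every cutoff (0.97/0.55/0.40), asserted
by unit tests. Queries below 40% to every reference are discarded as
contamination. Whether identity should be computed on the full sequence
or the domain region only is genuinely open; we compute it on the full
curated ORF protein, and since panel references here are full-domain
proteins the two coincide for full-length queries.

## ORF model and curation

Only the sense strand is scanned (strand-specific library). Per frame,
each inter-stop segment contributes one candidate: the maximal
M-initiated ORF if the segment contains an M, otherwise — only when the
segment touches a transcript edge — an open fragment (start- and/or
stop-missing). The representative is the longest candidate; equal
lengths break to the lowest frame index, then the leftmost start.
Spans are 0-based half-open and include the stop codon when present;
N-containing codons translate to X.

Domain coverage is the fraction of a packaged 463-residue domain
consensus spanned by the best local alignment (first to last aligned
consensus column; internal gaps count as covered, as in profile-hit
reporting). The consensus is a **synthetic stand-in** for a
profile-derived CYP domain consensus: a fixed random sequence with the
four conserved motifs and nine short anchor blocks embedded at realistic
offsets (see below). It is a data file and can be swapped for a real
profile consensus without code changes. A consensus-alignment proxy is
deterministic and dependency-free, but it is weaker than a true profile
HMM: hits to very distant homologues fragment sooner than `hmmscan`
hits would.

Curation: *full* ⟺ has_start ∧ has_stop ∧ coverage ≥ 0.85;
coverage in [0.80, 0.85) with start and stop present ⟹ *flagged*
(manual-review band — such cases were resolved by hand in the original
workflow); anything missing a start or stop, or below 0.80, is
*partial*. The pipeline forwards to classification only ORFs with
domain evidence (full status or coverage ≥ 0.30), mirroring the
profile-match gate that precedes nomenclature in the mining workflow;
without it, short junk fragments from antisense or decoy transcripts
reach the fragment-tolerant identity measure with spuriously high
scores.

Merging with previously known sequences requires local-alignment
identity ≥ 0.97 over ≥ 300 nt; the longer sequence is kept and every
merge is logged.

## Physicochemical descriptors and motifs

Molecular weight sums **average** residue masses plus one water,
reported in kDa (the convention of the standard pI/MW web calculators).
The isoelectric point solves the Henderson–Hasselbalch net-charge
equation over the termini and D, E, C, Y, H, K, R with the Bjellqvist
pKa set (N-term 7.5, K 10.0, R 12.0, H 5.98; C-term 3.55, D 4.05,
E 4.45, C 9.0, Y 10.0). Bisection runs to interval convergence (1e−7)
rather than stopping at the first |charge| < 1e−4 point: on charge-poor
sequences the charge curve plateaus near zero and an early exit can sit
visibly away from the true crossing. A dense-grid oracle (1e−4 steps)
agrees to < 1e−3 pH units.

Motifs are scanned as degenerate patterns with A-type / non-A-type
variants: heme `PFGXGRRXCXG` / `XFXXGXRXCXG`, PERF `FXPERF` / `FXPXRX`
(the extended consensus with the conserved F at −2; the classical
`PERF`/`PXRX` form is available via `classic_perf=True`), K-helix
`EXXR`, I-helix `AGXDT` / `AGX[ED]T`. Hits carry five residues of
context on each side — the flank is interpreted in residues (protein
logos have no meaningful "bp" unit). Logo matrices report per-column
frequencies and information content log₂(20) − H in bits.

## Phylogenetics

Distances are Poisson-corrected p-distances, d = −ln(1 − p), with
pairwise deletion of gap columns; ambiguous X residues are excluded from
shared columns as well (the treatment of ambiguity under pairwise
deletion is not standardised; excluding X is the conservative choice).
p = 1 is an explicit error, not an infinity. NJ follows Saitou–Nei with
the Q-criterion; negative branch lengths are floored at zero and logged;
additive matrices are recovered exactly (property-tested on random 4–10
taxon trees, and cross-checked against an independent NJ
implementation). Bootstrap resamples alignment columns with replacement
under a seed; support is the percentage of replicate trees containing
each internal bipartition (canonicalised leaf-set hashing); branches
with support ≤ 50 are collapsed in rendered Newick output, and
replicates with undefined distances are skipped with a log message.
The MSA is an input; the synthetic fixtures emit equal-length
(pre-aligned) families so the module is testable standalone.

## Expression analysis

FPKM = count / (length_kb × mapped_millions); FPKM ≤ 1 is "not
expressed" (so 1.0 is silent and 1.001 expressed — boundary tested).
The heat-map transform is log₂(FPKM + 1) centered by the row mean over
the three tissues; the log base is configurable and changes values but
not Euclidean/Ward topology. Ward clustering uses the squared-Euclidean
("Ward.D2"-equivalent) update via scipy, verified merge-by-merge
against a naive O(n³) Lance–Williams implementation; cut labels
C1…Ck are numbered in dendrogram leaf order.

Marker co-expression uses Pearson r on the three tissue means, exactly
as the screening design prescribes. **With n = 3 this statistic is
degenerate** — |r| = 1 occurs easily and no significance can be
attached; the generator documents this and the screen is therefore
always paired with a second, independent line of evidence:
candidate ⟺ co-expressed (r ≥ 0.9) ∧ annotated to the target pathway
(default "diterpenoid biosynthesis"). Both boundary conventions
(r ≥ 0.9 and r > 0.9) are supported; ≥ is the default. Zero-variance
profiles have undefined r and are recorded as not co-expressed with a
reason.

ΔΔCt: technical replicates are averaged first; ΔCt = Ct_target −
Ct_control per (tissue, biological replicate); ΔΔCt subtracts the same
replicate's calibrator-tissue ΔCt; relative expression 2^−ΔΔCt is
computed per biological replicate and then averaged, and both tables are
returned. Concordance between an RNA-seq profile and a qPCR profile
reports identical tissue ordering (stable sort, ties flagged) plus the
3-point Pearson r.

## Antisense detection

Each CDS is aligned locally against the reverse complement of every
other transcript (+1/−2, gap open 5 extend 2), after a shared 14-mer
prescreen. A reported pair must satisfy all four criteria: opposite
strand (by construction of the scan), alignment ≥ 100 bp, E ≤ 1e−50,
identity ≥ 99%. E-values follow Karlin–Altschul
E = K·m·n·e^(−λS) with λ solved from Σ pᵢpⱼe^(λsᵢⱼ) = 1 at uniform base
composition (λ ≈ 1.33 for +1/−2) and K = 0.621, the standard ungapped
value — fixed and reported so results are bit-reproducible. The scan
applies the conventional 1e−5 search cutoff first and 1e−50 as the
criterion filter; with this scoring the length and identity criteria
make the 1e−50 filter nearly redundant (a perfect 100 bp hit already
reaches ≈ 1e−52). Sense–antisense pairs are then classed positive
(r ≥ 0.9), negative (r ≤ −0.9) or neutral on their tissue profiles;
missing profiles give "unassessed". A transcript may pair with several
CDS and vice versa.

## The synthetic-data generator

The generator defines the study conditions; its defaults are the
noise-free desk-scale conditions the whole test-suite runs under:

* **Panel**: 4 families × 2 subfamilies × 2 members (16 proteins), all
  derived from the packaged 463-residue consensus by point substitution
  only (no indels — this keeps the identity oracle exact and every
  sequence pre-aligned). Mutation fractions 0.55 / 0.37 / 0.05 at the
  family / subfamily / member level put pairwise identities in their
  tiers (within-subfamily ≥ 0.55, within-family [0.40, 0.55), across
  families < 0.40); every pair is re-measured with the classifier's own
  identity operation and members, subfamily ancestors or family
  ancestors are re-drawn (bounded attempts) when a band is missed,
  failing loudly otherwise.
* **Conserved columns**: the four motif spans plus nine 6-residue anchor
  blocks spaced along the domain are never mutated. Real CYP450s retain
  scattered near-invariant blocks; without them no genuine low-identity
  family member could keep a contiguous local alignment to the
  consensus, and the 85% coverage criterion would be unrealisable for
  exactly the sequences it is meant to accept. Coverage is verified at
  every level of the hierarchy and for every planted full-length gene.
* **Transcripts**: 20 full-length genes cycling through identity targets
  (0.98, 0.85, 0.60, 0.45) — one per nomenclature tier — back-translated
  with uniform synonymous codon choice under the seed, flanked by
  ATG-free UTRs so the planted ORF is unambiguous; 8 partials
  alternating start-missing (3'-anchored fragment, ~55% retained,
  internal Ms removed so the recovered candidate is deterministic) and
  stop-missing (85–95% retained, transcript truncated mid-CDS); 15
  antisense copies (120–350 bp windows, 0–1 mismatches, measured
  identity re-verified against the scanner's own alignment because
  chance flank matches can dilute it); 12 random decoys verified to
  share no ≥ 40% identity ORF with the panel.
* **Expression**: three tissues, marker profile (120, 18, 6) FPKM
  (root-dominant, as for a root-specific biosynthesis marker), 10 genes
  planted co-expressed (positive-affine images of the marker, r = +1
  before noise), 3 anti-correlated (r = −1), everything else rejected-
  sampled to |r| < 0.85; 12 antisense copies positively and 3 negatively
  correlated with their sense genes, mirroring the published
  sense–antisense counts; 3 of the co-expressed genes annotated to the
  target pathway (the planted candidate set, mirroring the published
  dual-evidence count) plus 2 pathway members that are not co-expressed.
  Noise is multiplicative log-normal; the default is 0 because the
  recovery contracts (F1 = 1, sensitivity = specificity = 1, exact
  candidate set) are defined at zero noise. A 50-gene co-expression
  config at noise 0.05 exercises the ≥ 90% recovery bound.
* **qPCR**: Ct = 28 − log₂(FPKM) plus per-biological-replicate and
  per-technical-replicate Gaussian noise, control flat at Ct 20;
  3 × 3 replicates per tissue. At zero noise the ΔΔCt stage inverts the
  planted expression ratios exactly.

Determinism: one root seed; each stage draws from a deterministically
spawned child stream, so identical configurations produce byte-identical
bundles.

What passing these benchmarks does **not** show: robustness to
assembly artefacts (chimeras, fragmented isoforms), to indel divergence
(the no-indel mutation model makes identity exact but easy), to profile-
vs-consensus differences in domain detection, or to the sampling noise
of real FPKM estimates. The three-tissue Pearson screen in particular
should be read as a filter, not an inference.

## Problem sizes

The default bundle (16-panel, 55 transcripts) runs the full pipeline in
roughly 15 s on one core; the acceptance script (pipeline plus oracle
battery) in under half a minute. Bootstrap defaults to 1000 replicates
at the CLI but the pipeline demonstration uses 100, which is ample for
the well-separated synthetic clades.
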