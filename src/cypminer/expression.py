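"""FPKM handling, co-expression screening and qPCR concordance.

The expression surface follows the study design this pipeline targets:
three tissues, FPKM units with ``<= 1`` meaning not expressed, profiles
log-transformed and mean-centered per gene, Ward clustering of the
centered profiles, Pearson correlation against a designated marker gene,
dual-evidence candidate calling (co-expression AND pathway membership)
and qPCR validation via the 2^-ddCt method.

Correlations are computed on the three tissue means exactly as the
screening design prescribes; with n = 3 the Pearson coefficient is
highly degenerate (|r| = 1 occurs easily), which is documented rather
than papered over.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, leaves_list


# ---------------------------------------------------------------------------
# FPKM and flags

def fpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
         library_sizes: pd.Series) -> pd.DataFrame:
    """count / (length in kb x mapped fragments in millions)."""
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    libs = library_sizes.reindex(counts.columns)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)


def expressed_flags(matrix: pd.DataFrame, cutoff: float = 1.0
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Expressed means FPKM strictly above the cutoff (FPKM <= 1 is silent).

    Returns per-gene-per-tissue flags and the three-set Venn region
    counts, which partition the expressed gene set (genes silent
    everywhere are counted under 'none').
    """
    if matrix.shape[1] != 3:
        raise ValueError("the tissue Venn is defined for exactly 3 tissues")
    flags = matrix > cutoff
    tissues = list(matrix.columns)
    venn: dict[str, int] = {}
    sets = {t: set(flags.index[flags[t]]) for t in tissues}
    expressed_any = set().union(*sets.values())
    venn["none"] = len(set(flags.index) - expressed_any)
    for r in (1, 2, 3):
        for combo in combinations(tissues, r):
            inside = set.intersection(*(sets[t] for t in combo))
            outside = set().union(*(sets[t] for t in tissues
                                    if t not in combo), set())
            key = "&".join(combo) if r > 1 else f"{combo[0]}_only"
            if r == 3:
                key = "all"
            venn[key] = len(inside - outside)
    return flags, venn


def transform(matrix: pd.DataFrame, base: float = 2.0) -> pd.DataFrame:
    """log(FPKM + 1), then center each gene with its mean over the tissues.

    Log base 2 by default; the base changes heat-map values but not
    Euclidean/Ward clustering topology.
    """
    if (matrix < 0).any().any():
        raise ValueError("negative FPKM values")
    logged = np.log(matrix + 1.0) / np.log(base)
    return logged.sub(logged.mean(axis=1), axis=0)


# ---------------------------------------------------------------------------
# clustering

@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaf_order: list[str]
    labels: pd.Series  # gene -> "C1".."Ck", numbered by leaf order


def hier_cluster(transformed: pd.DataFrame, n_clusters: int = 6
                 ) -> ClusterResult:
    """Ward clustering (squared-Euclidean update) of centered profiles."""
    if len(transformed) < 2:
        raise ValueError("clustering requires at least 2 genes")
    Z = linkage(transformed.values, method="ward", metric="euclidean")
    order = [transformed.index[i] for i in leaves_list(Z)]
    k = min(n_clusters, len(transformed))
    raw = fcluster(Z, t=k, criterion="maxclust")
    raw = pd.Series(raw, index=transformed.index)
    seen: dict[int, str] = {}
    for gene in order:
        seen.setdefault(raw[gene], f"C{len(seen) + 1}")
    return ClusterResult(linkage=Z, leaf_order=order,
                         labels=raw.map(seen))


# ---------------------------------------------------------------------------
# marker co-expression

@dataclass(frozen=True)
class CorrelationRecord:
    gene_id: str
    r: float
    co_expressed: bool
    pathway_member: bool = False
    candidate: bool = False
    reason: str = ""


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def marker_correlation(matrix: pd.DataFrame, marker_id: str,
                       r_cut: float = 0.9,
                       strict_greater: bool = False) -> list[CorrelationRecord]:
    """Pearson r of every gene's tissue profile against the marker's.

    Zero-variance profiles have undefined r and are recorded as not
    co-expressed with a reason.  The cutoff is inclusive (r >= r_cut) by
    default; ``strict_greater`` switches to the strict convention.
    """
    if marker_id not in matrix.index:
        raise KeyError(f"marker {marker_id!r} not in matrix")
    marker = matrix.loc[marker_id].to_numpy(dtype=float)
    records = []
    for gene_id, row in matrix.iterrows():
        r = pearson(row.to_numpy(dtype=float), marker)
        if np.isnan(r):
            records.append(CorrelationRecord(gene_id, float("nan"), False,
                                             reason="zero-variance profile"))
            continue
        co = r > r_cut if strict_greater else r >= r_cut
        records.append(CorrelationRecord(gene_id, r, co))
    return records


def call_candidates(records: list[CorrelationRecord],
                    pathway_annotation: pd.DataFrame,
                    target_pathway: str = "diterpenoid biosynthesis",
                    ) -> list[CorrelationRecord]:
    """Dual-evidence calling: candidate iff co-expressed AND pathway member."""
    if pathway_annotation is None:
        raise ValueError("pathway annotation is required")
    members = set(pathway_annotation.loc[
        pathway_annotation["pathway"] == target_pathway, "gene"])
    out = []
    for rec in records:
        member = rec.gene_id in members
        out.append(CorrelationRecord(rec.gene_id, rec.r, rec.co_expressed,
                                     pathway_member=member,
                                     candidate=rec.co_expressed and member,
                                     reason=rec.reason))
    return out


def records_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# qPCR

def ddct(ct: pd.DataFrame, control: str, calibrator_tissue: str
         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative expression by the 2^-ddCt method.

    Technical replicates are averaged first; dCt = Ct_target - Ct_control
    within each (tissue, biological replicate); ddCt subtracts the same
    biological replicate's dCt in the calibrator tissue; relative
    expression 2^-ddCt is computed per biological replicate and then
    averaged.  Returns (per-biological-replicate table, per-tissue means).
    """
    required = {"gene", "tissue", "bio_rep", "tech_rep", "Ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    tech_avg = (ct.groupby(["gene", "tissue", "bio_rep"], as_index=False)["Ct"]
                .mean())
    ctrl = tech_avg[tech_avg.gene == control]
    samples = {(t, b) for t, b in zip(tech_avg.tissue, tech_avg.bio_rep)}
    have_ctrl = {(t, b) for t, b in zip(ctrl.tissue, ctrl.bio_rep)}
    missing = samples - have_ctrl
    if missing:
        raise ValueError(f"control {control!r} missing in samples {sorted(missing)}")
    ctrl_map = {(t, b): c for t, b, c in zip(ctrl.tissue, ctrl.bio_rep, ctrl.Ct)}
    rows = []
    targets = tech_avg[tech_avg.gene != control]
    dct = {
        (g, t, b): c - ctrl_map[(t, b)]
        for g, t, b, c in zip(targets.gene, targets.tissue, targets.bio_rep,
                              targets.Ct)
    }
    for (g, t, b), value in dct.items():
        cal_key = (g, calibrator_tissue, b)
        if cal_key not in dct:
            raise ValueError(f"calibrator tissue sample missing for {g!r}")
        ddct_value = value - dct[cal_key]
        rows.append(dict(gene=g, tissue=t, bio_rep=b, dCt=value,
                         ddCt=ddct_value, relative=2.0 ** (-ddct_value)))
    per_bio = pd.DataFrame(rows).sort_values(
        ["gene", "tissue", "bio_rep"]).reset_index(drop=True)
    means = (per_bio.groupby(["gene", "tissue"], as_index=False)["relative"]
             .mean())
    return per_bio, means


def concordance(rnaseq_profile: pd.Series, qpcr_profile: pd.Series
                ) -> tuple[bool, float, bool]:
    """(rank_match, Pearson r, had_ties) between two 3-tissue profiles.

    rank_match is True when both profiles order the tissues identically;
    ties are resolved by stable tissue order and flagged.
    """
    tissues = list(rnaseq_profile.index)
    q = qpcr_profile.reindex(tissues)
    a = rnaseq_profile.to_numpy(dtype=float)
    b = q.to_numpy(dtype=float)
    ties = (len(np.unique(a)) < len(a)) or (len(np.unique(b)) < len(b))
    order_a = np.argsort(a, kind="stable")
    order_b = np.argsort(b, kind="stable")
    return bool((order_a == order_b).all()), pearson(a, b), ties
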