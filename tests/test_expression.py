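"""FPKM, flags/Venn, transform, Ward clustering, screening and ddCt."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cypminer.expression import (call_candidates, concordance, ddct,
                                 expressed_flags, fpkm, hier_cluster,
                                 marker_correlation, pearson, records_frame,
                                 transform)

TISSUES = ["root", "leaf", "flower"]


def _matrix(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=TISSUES)


# ---------------------------------------------------------------------------
# FPKM

def test_fpkm_definition_and_scaling():
    counts = pd.DataFrame({"s1": [10, 0]}, index=["g1", "g2"])
    lengths = pd.Series({"g1": 1000, "g2": 500})
    libs = pd.Series({"s1": 1_000_000})
    out = fpkm(counts, lengths, libs)
    assert out.loc["g1", "s1"] == pytest.approx(10.0)
    assert out.loc["g2", "s1"] == 0.0
    doubled = fpkm(counts, lengths, libs * 2)
    assert np.allclose(doubled.values, out.values / 2)
    with pytest.raises(ValueError):
        fpkm(counts, lengths, pd.Series({"s1": 0}))


# ---------------------------------------------------------------------------
# expressed flags and Venn

def test_fpkm_cutoff_boundary():
    m = _matrix({"g1": [1.0, 1.001, 0.0]})
    flags, _ = expressed_flags(m)
    assert not flags.loc["g1", "root"]      # FPKM <= 1: silent
    assert flags.loc["g1", "leaf"]          # strictly above: expressed


def test_venn_regions_match_exhaustive_enumeration():
    rows = {f"g{i}": profile for i, profile in enumerate(
        itertools.product([0.0, 5.0], repeat=3))}
    m = _matrix(rows)
    flags, venn = expressed_flags(m)
    for combo_key, tissues_in in [
            ("root_only", {"root"}), ("leaf_only", {"leaf"}),
            ("flower_only", {"flower"}), ("root&leaf", {"root", "leaf"}),
            ("root&flower", {"root", "flower"}),
            ("leaf&flower", {"leaf", "flower"}),
            ("all", {"root", "leaf", "flower"})]:
        expected = sum(
            1 for g, profile in rows.items()
            if {t for t, v in zip(TISSUES, profile) if v > 1} == tissues_in)
        assert venn[combo_key] == expected, combo_key
    assert venn["none"] == 1
    assert sum(venn.values()) == len(rows)


# ---------------------------------------------------------------------------
# transform

def test_transform_rows_center_to_zero():
    m = _matrix({"g1": [4.0, 4.0, 4.0], "g2": [0.0, 0.0, 7.0]})
    t = transform(m)
    assert np.allclose(t.loc["g1"], 0.0)
    row = t.loc["g2"].to_numpy()
    assert row[0] == row[1] < 0 < row[2]
    assert abs(row.sum()) < 1e-12


def test_transform_hand_computed_example():
    m = _matrix({"g1": [0.0, 1.0, 3.0], "g2": [7.0, 0.0, 1.0]})
    t = transform(m)
    assert np.allclose(t.loc["g1"], [-1.0, 0.0, 1.0])
    assert np.allclose(t.loc["g2"], [5 / 3, -4 / 3, -1 / 3])
    with pytest.raises(ValueError):
        transform(_matrix({"g": [-1.0, 0.0, 0.0]}))


# ---------------------------------------------------------------------------
# Ward clustering

def _naive_ward(X):
    """O(n^3) Lance-Williams Ward agglomeration on squared distances."""
    clusters = {i: [i] for i in range(len(X))}
    S = {}
    for i in range(len(X)):
        for j in range(i + 1, len(X)):
            S[(i, j)] = float(((X[i] - X[j]) ** 2).sum())
    merges = []
    nxt = len(X)
    sizes = {i: 1 for i in range(len(X))}
    while len(clusters) > 1:
        (i, j), smin = min(S.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((frozenset(clusters[i]), frozenset(clusters[j]),
                       np.sqrt(smin)))
        clusters[nxt] = clusters.pop(i) + clusters.pop(j)
        ni, nj = sizes.pop(i), sizes.pop(j)
        sizes[nxt] = ni + nj
        newS = {}
        for (a, b), val in S.items():
            if i in (a, b) or j in (a, b):
                continue
            newS[(a, b)] = val
        for k in clusters:
            if k == nxt:
                continue
            nk = sizes[k]
            dki = S.get((min(i, k), max(i, k)))
            dkj = S.get((min(j, k), max(j, k)))
            merged = ((ni + nk) * dki + (nj + nk) * dkj - nk * smin) \
                / (ni + nj + nk)
            newS[(min(k, nxt), max(k, nxt))] = merged
        S = newS
        nxt += 1
    return merges


def test_identical_rows_merge_first_at_height_zero():
    m = _matrix({"g1": [1.0, 2.0, 3.0], "g2": [1.0, 2.0, 3.0],
                 "g3": [9.0, 1.0, 0.0]})
    res = hier_cluster(transform(m), n_clusters=2)
    first = res.linkage[0]
    assert {int(first[0]), int(first[1])} == {0, 1}
    assert first[2] == pytest.approx(0.0)


def test_ward_merge_sequence_matches_naive_oracle():
    rng = np.random.default_rng(0)
    for n in (5, 6, 8):
        X = rng.normal(size=(n, 3))
        m = pd.DataFrame(X, index=[f"g{i}" for i in range(n)],
                         columns=TISSUES)
        res = hier_cluster(m, n_clusters=2)
        oracle = _naive_ward(X)
        # replay scipy's merge list into member sets
        members = {i: frozenset([i]) for i in range(n)}
        for step, row in enumerate(res.linkage):
            a, b = int(row[0]), int(row[1])
            sa, sb = members[a], members[b]
            oa, ob, oh = oracle[step]
            assert {sa, sb} == {oa, ob}, f"step {step}"
            assert row[2] == pytest.approx(oh)
            members[n + step] = sa | sb
        del members


def test_dendrogram_invariant_to_input_order():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(7, 3))
    m = pd.DataFrame(X, index=[f"g{i}" for i in range(7)], columns=TISSUES)
    res1 = hier_cluster(m, n_clusters=3)
    perm = m.sample(frac=1.0, random_state=2)
    res2 = hier_cluster(perm, n_clusters=3)

    def merge_sets(frame, linkage):
        members = {i: frozenset([frame.index[i]]) for i in range(len(frame))}
        out = set()
        for step, row in enumerate(linkage):
            s = members[int(row[0])] | members[int(row[1])]
            members[len(frame) + step] = s
            out.add(s)
        return out

    assert merge_sets(m, res1.linkage) == merge_sets(perm, res2.linkage)


def test_cluster_labels_cover_requested_cut():
    rng = np.random.default_rng(3)
    m = pd.DataFrame(rng.normal(size=(20, 3)), columns=TISSUES,
                     index=[f"g{i}" for i in range(20)])
    res = hier_cluster(m, n_clusters=6)
    assert set(res.labels) == {f"C{i}" for i in range(1, 7)}
    with pytest.raises(ValueError):
        hier_cluster(m.iloc[:1])


# ---------------------------------------------------------------------------
# marker correlation and candidates

def test_marker_correlation_extremes_and_oracle():
    m = _matrix({"marker": [10.0, 5.0, 1.0],
                 "same": [20.0, 10.0, 2.0],
                 "anti": [1.0, 6.0, 10.0],
                 "flat": [3.0, 3.0, 3.0]})
    recs = {r.gene_id: r for r in marker_correlation(m, "marker")}
    assert recs["marker"].r == pytest.approx(1.0)
    assert recs["same"].r == pytest.approx(1.0)
    assert recs["anti"].r < 0
    assert np.isnan(recs["flat"].r) and recs["flat"].reason
    rng = np.random.default_rng(4)
    for _ in range(20):
        x, y = rng.normal(size=3), rng.normal(size=3)
        assert pearson(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1],
                                              abs=1e-12)


def test_candidate_is_exactly_coexpression_and_pathway():
    m = _matrix({"marker": [10.0, 5.0, 1.0],
                 "in_path": [20.0, 10.0, 2.0],
                 "no_path": [30.0, 15.0, 3.0],
                 "path_only": [1.0, 6.0, 10.0]})
    pathway = pd.DataFrame({"gene": ["in_path", "path_only"],
                            "pathway": ["diterpenoid biosynthesis"] * 2})
    recs = call_candidates(marker_correlation(m, "marker"), pathway)
    by_id = {r.gene_id: r for r in recs}
    assert by_id["in_path"].candidate
    assert not by_id["no_path"].candidate and by_id["no_path"].co_expressed
    assert not by_id["path_only"].candidate and by_id["path_only"].pathway_member
    for r in recs:
        assert r.candidate == (r.co_expressed and r.pathway_member)
    frame = records_frame(recs)
    assert set(frame.columns) >= {"gene_id", "r", "candidate"}


def test_r_cut_boundary_conventions():
    m = _matrix({"marker": [10.0, 5.0, 1.0], "g": [20.0, 10.0, 2.0]})
    inclusive = {r.gene_id: r for r in marker_correlation(m, "marker",
                                                          r_cut=1.0)}
    assert inclusive["g"].co_expressed        # r = 1.0 >= 1.0
    strict = {r.gene_id: r for r in marker_correlation(
        m, "marker", r_cut=1.0, strict_greater=True)}
    assert not strict["g"].co_expressed       # r = 1.0 not > 1.0


# ---------------------------------------------------------------------------
# ddCt and concordance

def _toy_ct():
    rows = []
    # control flat at 20; target: dCt 5 in root, 3 in leaf, 7 in flower
    for tissue, ct in [("root", 25.0), ("leaf", 23.0), ("flower", 27.0)]:
        for bio in (1, 2, 3):
            for tech in (1, 2, 3):
                rows.append(("ACTIN", tissue, bio, tech, 20.0))
                rows.append(("g1", tissue, bio, tech, ct))
    return pd.DataFrame(rows, columns=["gene", "tissue", "bio_rep",
                                       "tech_rep", "Ct"])


def test_ddct_hand_computation():
    per_bio, means = ddct(_toy_ct(), "ACTIN", "root")
    got = means.set_index("tissue")["relative"]
    assert got["root"] == pytest.approx(1.0)
    assert got["leaf"] == pytest.approx(4.0)     # ddCt = -2 -> 2^2
    assert got["flower"] == pytest.approx(0.25)  # ddCt = +2
    assert len(per_bio) == 9
    assert np.allclose(per_bio[per_bio.tissue == "leaf"].ddCt, -2.0)


def test_equal_expression_gives_unit_relatives():
    ct = _toy_ct()
    ct.loc[ct.gene == "g1", "Ct"] = 24.0
    _, means = ddct(ct, "ACTIN", "root")
    assert np.allclose(means.relative, 1.0)


def test_missing_control_is_an_error():
    ct = _toy_ct()
    with pytest.raises(ValueError):
        ddct(ct[ct.gene != "ACTIN"], "ACTIN", "root")


def test_concordance_orderings():
    rna = pd.Series([10.0, 5.0, 1.0], index=TISSUES)
    match, r, ties = concordance(rna, pd.Series([8.0, 4.0, 0.5],
                                                index=TISSUES))
    assert match and r == pytest.approx(1.0, abs=0.05) and not ties
    match, _, _ = concordance(rna, pd.Series([0.5, 4.0, 8.0], index=TISSUES))
    assert not match
    _, _, ties = concordance(rna, pd.Series([4.0, 4.0, 8.0], index=TISSUES))
    assert ties


# ---------------------------------------------------------------------------
# planted co-expression recovery (Monte-Carlo at a fixed seed)

def test_planted_coexpression_recovered_under_noise():
    """>= 90% of 50 planted co-expressed genes pass the r >= 0.9 screen
    at small generator noise."""
    from cypminer.synthetic_data import SimulationConfig, generate_bundle

    config = SimulationConfig(
        seed=17, n_families=1, n_subfamilies_per_family=1,
        n_members_per_subfamily=1, n_full=54, n_partial=0, n_antisense=0,
        n_decoys=0, identity_targets=(0.98,), n_coexpressed=50,
        n_anticorrelated=0, n_antisense_positive=0, n_antisense_negative=0,
        n_pathway_coexpressed=3, n_pathway_other=0, noise_sd=0.05,
        n_qpcr_genes=2)
    bundle = generate_bundle(config)
    records = {r.gene_id: r for r in marker_correlation(
        bundle.expression, bundle.marker)}
    planted = bundle.expression_truth["coexpressed"]
    recovered = sum(records[g].co_expressed for g in planted)
    assert recovered >= 0.9 * len(planted)
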