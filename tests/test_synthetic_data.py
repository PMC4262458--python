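"""Generator contracts: determinism, tier structure, planted truth."""

import itertools

import numpy as np
import pytest

from cypminer._align import pairwise_identity
from cypminer.orf_curation import find_orfs, representative_orf
from cypminer.synthetic_data import (GenerationError, SimulationConfig,
                                     generate_bundle, make_expression,
                                     make_reference_panel, make_transcriptome,
                                     revcomp)

SMALL = SimulationConfig(seed=33, n_families=1, n_subfamilies_per_family=1,
                         n_members_per_subfamily=1, n_full=4, n_partial=2,
                         n_antisense=2, n_decoys=2,
                         identity_targets=(1.0, 0.98), n_coexpressed=2,
                         n_anticorrelated=1, n_antisense_positive=1,
                         n_antisense_negative=1, n_pathway_coexpressed=1,
                         n_pathway_other=0, n_qpcr_genes=2)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_full=-1).validate()
    with pytest.raises(ValueError):
        SimulationConfig(identity_targets=(1.2,)).validate()
    with pytest.raises(ValueError):
        SimulationConfig(r_target=1.0, noise_sd=0.1).validate()
    with pytest.raises(ValueError):
        SimulationConfig(n_antisense=2, n_antisense_positive=2,
                         n_antisense_negative=1).validate()


def test_single_entry_panel():
    config = SimulationConfig(seed=1, n_families=1,
                              n_subfamilies_per_family=1,
                              n_members_per_subfamily=1)
    panel = make_reference_panel(config)
    assert len(panel.entries) == 1
    assert panel.entries[0].name == "CYP801A1"


def test_same_seed_gives_byte_identical_bundles():
    b1 = generate_bundle(SMALL)
    b2 = generate_bundle(SMALL)
    assert b1.transcripts == b2.transcripts
    assert b1.truth.equals(b2.truth)
    assert b1.expression.equals(b2.expression)
    assert b1.qpcr.equals(b2.qpcr)
    assert [e.protein for e in b1.panel.entries] == \
        [e.protein for e in b2.panel.entries]


def test_different_seeds_differ():
    from dataclasses import replace
    b1 = generate_bundle(SMALL)
    b2 = generate_bundle(replace(SMALL, seed=34))
    assert b1.transcripts != b2.transcripts


def test_panel_tier_structure_verified_by_alignment(panel):
    """All pairwise identities of the session panel sit in the tier their
    labels prescribe (checked with the DP identity the classifier uses)."""
    for a, b in itertools.combinations(panel.entries, 2):
        ident = pairwise_identity(a.protein, b.protein)
        if a.subfamily == b.subfamily:
            assert ident >= 0.55, (a.name, b.name, ident)
        elif a.family == b.family:
            assert 0.40 <= ident < 0.55, (a.name, b.name, ident)
        else:
            assert ident < 0.40, (a.name, b.name, ident)


def test_planted_identities_hit_their_targets(bundle):
    """Realised protein identities stay within +/-0.02 of the target."""
    truth = bundle.truth.set_index("transcript_id")
    sources = {e.name: e.protein for e in bundle.panel.entries}
    targets = itertools.cycle(bundle.config.identity_targets)
    n = 0
    for tid, protein in bundle.proteins.items():
        row = truth.loc[tid]
        if row.truth_class != "full_cyp":
            continue
        target = next(targets)
        measured = pairwise_identity(protein, sources[row.source_ref])
        assert measured == pytest.approx(target, abs=0.02)
        assert row.planted_identity == pytest.approx(measured)
        n += 1
    assert n == bundle.config.n_full


def test_identity_target_one_reproduces_the_source_exactly():
    bundle = generate_bundle(SMALL)
    truth = bundle.truth.set_index("transcript_id")
    sources = {e.name: e.protein for e in bundle.panel.entries}
    exact = [tid for tid, row in truth.iterrows()
             if row.truth_class == "full_cyp" and row.planted_identity == 1.0]
    assert exact
    for tid in exact:
        rep = representative_orf(find_orfs(bundle.transcripts[tid], tid))
        assert rep.protein == sources[truth.loc[tid, "source_ref"]]


def test_antisense_plants_are_reverse_complement_windows(bundle):
    truth = bundle.truth.set_index("transcript_id")
    for tid, row in truth[truth.truth_class == "antisense"].iterrows():
        seq = revcomp(bundle.transcripts[tid])
        cds = bundle.cds[row.sense_id]
        # a perfect window: some >= 100 nt substring occurs in the CDS
        if row.planted_identity == 1.0:
            found = any(seq[i:i + 100] in cds
                        for i in range(len(seq) - 99))
            assert found, tid


def test_truth_spans_point_at_real_orfs(bundle):
    truth = bundle.truth.set_index("transcript_id")
    for tid, row in truth.iterrows():
        if row.truth_class not in ("full_cyp", "partial_cyp"):
            assert row.orf_start == -1
            continue
        rep = representative_orf(find_orfs(bundle.transcripts[tid], tid))
        assert (rep.start, rep.end) == (row.orf_start, row.orf_end), tid


def test_expression_plants_are_exact_at_zero_noise(bundle):
    expr = bundle.expression
    et = bundle.expression_truth
    marker = expr.loc[et["marker"]].to_numpy()

    def r(profile):
        a = profile - profile.mean()
        b = marker - marker.mean()
        return float((a * b).sum() / np.sqrt((a ** 2).sum() * (b ** 2).sum()))

    for gid in et["coexpressed"]:
        assert r(expr.loc[gid].to_numpy()) == pytest.approx(1.0)
    for gid in et["anticorrelated"]:
        assert r(expr.loc[gid].to_numpy()) == pytest.approx(-1.0)
    for gid, tissues in et["silent"].items():
        for t in tissues:
            assert expr.loc[gid, t] <= 1.0


def test_qpcr_inverts_to_expression_ratios_at_zero_noise(bundle):
    from cypminer.expression import ddct
    _, means = ddct(bundle.qpcr, bundle.config.control_gene,
                    bundle.config.tissues[0])
    expr = bundle.expression
    for gid in means.gene.unique():
        rel = means[means.gene == gid].set_index("tissue")["relative"]
        expected = expr.loc[gid] / expr.loc[gid, bundle.config.tissues[0]]
        for t in bundle.config.tissues:
            assert rel[t] == pytest.approx(expected[t], rel=1e-9)


def test_noisy_qpcr_recovers_fold_changes_within_tolerance():
    from dataclasses import replace

    from cypminer.expression import ddct
    noisy = replace(SMALL, noise_sd=0.1, seed=55)
    bundle = generate_bundle(noisy)
    _, means = ddct(bundle.qpcr, noisy.control_gene, noisy.tissues[0])
    expr = bundle.expression
    for gid in means.gene.unique():
        rel = means[means.gene == gid].set_index("tissue")["relative"]
        expected = expr.loc[gid] / expr.loc[gid, noisy.tissues[0]]
        for t in noisy.tissues:
            assert np.log2(rel[t] / expected[t]) == pytest.approx(0.0,
                                                                  abs=0.75)


def test_decoys_share_no_high_identity_orf_with_the_panel(bundle):
    panel_proteins = [e.protein for e in bundle.panel.entries]
    truth = bundle.truth.set_index("transcript_id")
    for tid in truth.index[truth.truth_class == "decoy"]:
        rep = representative_orf(find_orfs(bundle.transcripts[tid], tid))
        protein = rep.protein.replace("*", "").replace("X", "A")
        if len(protein) < 10:
            continue
        assert max(pairwise_identity(protein, p)
                   for p in panel_proteins) < 0.40


def test_writer_emits_the_standard_bundle(tmp_path):
    bundle = generate_bundle(SMALL)
    bundle.write(tmp_path)
    for name in ("transcripts.fasta", "panel.fasta", "panel.tsv",
                 "truth.tsv", "expression.tsv", "qpcr.tsv", "pathway.tsv",
                 "known.fasta"):
        assert (tmp_path / name).exists(), name
    # FASTA wrapped at 60 columns
    lines = (tmp_path / "transcripts.fasta").read_text().splitlines()
    assert max(len(l) for l in lines if not l.startswith(">")) <= 60
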