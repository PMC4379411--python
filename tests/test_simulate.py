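from __future__ import annotations

import json

import numpy as np
import pytest

from splicevo.errors import ConfigurationError
from splicevo.gene_models import spliced_sequence, translate
from splicevo.intron_homology import anchor_sites, build_character_matrix, intron_sites
from splicevo.simulate import (
    SimulationConfig,
    emit_abundances,
    emit_ests,
    gene_tree_skeleton,
    read_truth,
    regime_config,
    simulate_family,
    write_family,
    write_truth,
)


def small_config(**over) -> SimulationConfig:
    """Four-species single-copy family for fast property checks."""
    base = dict(
        species_tree="((s1:0.4,s2:0.4)p12:0.4,(s3:0.4,s4:0.4)p34:0.4)root;",
        outgroup="s1",
        duplications=[],
        subfamily_labels={"g": "only"},
        protein_length=120,
        ancestral_introns=[(20, 0), (45, 1), (70, 0), (95, 2)],
        ancestral_poison_intron=2,
        n_ests=40,
        est_length=400,
    )
    base.update(over)
    return SimulationConfig.from_dict(base)


def test_zero_rates_preserve_ancestral_structure():
    cfg = small_config(
        substitution_rate=0.0, intron_gain_rate=0.0, intron_loss_rate=0.0, seed=5
    )
    fam = simulate_family(cfg)
    rows = {}
    sites_by_gene = {}
    for g in fam.genes:
        sites, _ = intron_sites(g)
        sites_by_gene[g.gene_id] = sites
    anchored, _ = anchor_sites(sites_by_gene, fam.msa)
    cm = build_character_matrix(anchored)
    values = {tuple(r) for _, r in cm.matrix.iterrows()}
    assert len(values) == 1  # all orthologs share every intron character
    assert len(cm.characters) == 4
    # and the sequences are identical too (no substitutions)
    assert len(set(fam.proteins.values())) == 1


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = small_config(seed=9)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_family(simulate_family(cfg), d1)
    write_family(simulate_family(cfg), d2)
    for p1 in sorted(d1.rglob("*")):
        if p1.is_file():
            p2 = d2 / p1.relative_to(d1)
            assert p1.read_bytes() == p2.read_bytes(), p1.name


def test_different_seeds_differ(tmp_path):
    f1 = simulate_family(small_config(seed=1))
    f2 = simulate_family(small_config(seed=2))
    assert f1.genomes != f2.genomes


def test_intron_gain_counts_follow_poisson_mean():
    """Mean gain count over replicates within 3 SE of rate * tree length."""
    rate = 0.8
    cfg = small_config(intron_gain_rate=rate, intron_loss_rate=0.0,
                       substitution_rate=0.0, n_ests=0)
    total_branch = 0.4 * 6  # six branches of 0.4 in the small tree
    lam = rate * total_branch
    n_rep = 200
    counts = []
    for r in range(n_rep):
        cfg_r = small_config(intron_gain_rate=rate, intron_loss_rate=0.0,
                             substitution_rate=0.0, n_ests=0, seed=10_000 + r)
        fam = simulate_family(cfg_r)
        counts.append(
            sum(1 for e in fam.truth.branch_log if e["type"] == "intron_gain")
        )
    mean = np.mean(counts)
    se = np.sqrt(lam / n_rep)
    assert abs(mean - lam) <= 3 * se


def test_productive_isoforms_translate_cleanly(scenario_family):
    for gene in scenario_family.genes:
        prod = scenario_family.isoforms[gene.gene_id][0]
        assert prod.kind == "productive"
        mrna = spliced_sequence(scenario_family.genomes, prod.isoform)
        protein = translate(mrna, prod.isoform.cds_offset)
        assert protein == scenario_family.proteins[gene.gene_id]


def test_truth_nmd_targets_satisfy_junction_rule(scenario_family):
    """Cross-module consistency: every truth NMD target is classified
    NMD_TARGET by the junction-rule classifier, and only those."""
    from splicevo.splice_events import classify_nmd

    genome = scenario_family.genomes
    gene_by_id = {g.gene_id: g for g in scenario_family.genes}
    for isos in scenario_family.isoforms.values():
        for s in isos:
            call = classify_nmd(
                s.isoform, genome, gene=gene_by_id[s.gene_id],
                threshold_nt=scenario_family.config.nmd_threshold,
            )
            assert call.verdict == s.nmd_verdict, s.isoform_id


def test_est_referential_integrity(scenario_family):
    iso_ids = {
        f"{s.gene_id}|{s.isoform_id.split(':', 1)[1]}"
        for isos in scenario_family.isoforms.values()
        for s in isos
    }
    for rec in emit_ests(scenario_family, "nmd_deficient"):
        gene, kind, _ = rec.name.split(";")[0].split("|")
        assert f"{gene}|{kind}" in iso_ids


def test_inclusion_rate_zero_emits_no_cassette_ests():
    cfg = small_config(inclusion_rate=0.0, seed=3)
    fam = simulate_family(cfg)
    for rec in emit_ests(fam, "nmd_deficient"):
        assert "|cassette" not in rec.name


def test_full_nmd_efficiency_suppresses_targets_in_wt_only():
    cfg = small_config(nmd_efficiency=1.0, seed=4, n_ests=150)
    fam = simulate_family(cfg)
    target_kinds = {
        (s.gene_id, s.isoform_id.split(":", 1)[1])
        for isos in fam.isoforms.values()
        for s in isos
        if s.nmd_verdict == "NMD_TARGET"
    }
    assert target_kinds
    wt_names = {
        tuple(r.name.split(";")[0].split("|")[:2]) for r in emit_ests(fam, "wt")
    }
    nd_names = {
        tuple(r.name.split(";")[0].split("|")[:2])
        for r in emit_ests(fam, "nmd_deficient")
    }
    assert not (wt_names & target_kinds)
    assert nd_names & target_kinds


def test_abundance_thinning_matches_expected_fold():
    """Deterministic mode reproduces the closed-form fold change of a target:
    fold = (1 - e * w_targets) / (1 - e) after renormalizing thinned mass."""
    e = 0.8
    cfg = small_config(seed=6, nmd_efficiency=e)
    fam = simulate_family(cfg)
    det = emit_abundances(fam, deterministic=True)
    sub = det[det["gene_id"] == "s1_g"].set_index("isoform_id")
    isos = fam.isoforms["s1_g"]
    target_mass = sum(s.weight for s in isos if s.nmd_verdict == "NMD_TARGET")
    target = next(s for s in isos if s.nmd_verdict == "NMD_TARGET")
    f_wt = sub.loc[target.isoform_id, "count_wt"] / sub["count_wt"].sum()
    f_nd = sub.loc[target.isoform_id, "count_nmd_deficient"] / sub[
        "count_nmd_deficient"
    ].sum()
    expected = (1 - e * target_mass) / (1 - e)
    assert f_nd / f_wt == pytest.approx(expected)
    assert expected >= 2.0  # comfortably above the stabilization min_fold


def test_truth_round_trip_and_regimes(tmp_path, scenario_family):
    write_truth(scenario_family.truth, tmp_path)
    back = read_truth(tmp_path)
    assert back == scenario_family.truth
    assert back.regime in {"SINGLE_ORIGIN", "INDEPENDENT", "REPLACEMENT"}


def test_replacement_coupling_one_logs_coupled_birth():
    cfg = small_config(
        seed=21, poison_death_rate=1.2, replacement_coupling=1.0,
        poison_birth_rate=0.0,
    )
    fam = simulate_family(cfg)
    births = [e for e in fam.truth.branch_log if e["type"] == "poison_birth"]
    deaths = [e for e in fam.truth.branch_log if e["type"] == "poison_death"]
    assert deaths, "seeded run should draw at least one death"
    assert any(b.get("coupled") for b in births)
    assert fam.truth.regime == "REPLACEMENT"
    for b in births:
        if b.get("coupled"):
            assert any(
                d["node"] == b["node"] and d["lineage"] == b["lineage"]
                for d in deaths
            )


def test_unknown_config_key_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig.from_dict({"nope": 1})


def test_gene_tree_skeleton_matches_duplication_spec():
    cfg = SimulationConfig()
    tree = gene_tree_skeleton(cfg)
    leaves = {t.name for t in tree.tips()}
    assert "neurospora_g" in leaves
    assert {"human_g.1", "human_g.2.1", "human_g.2.2"} <= leaves
    assert "lancelet_g.2" in leaves and "lancelet_g.2.1" not in leaves
    assert len(leaves) == 2 + 4 + 2 + 5 * 3


def test_regime_configs_record_their_regime():
    for regime in ("SINGLE_ORIGIN", "INDEPENDENT", "REPLACEMENT"):
        cfg = regime_config(regime, seed=5)
        fam = simulate_family(cfg)
        assert fam.truth.regime == regime
        groups = {
            s.group for isos in fam.isoforms.values() for s in isos if s.group
        }
        if regime == "SINGLE_ORIGIN":
            assert groups == {"P1"}
        elif regime == "INDEPENDENT":
            assert groups == {"PA", "PB"}
        else:
            assert "P2" in groups
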