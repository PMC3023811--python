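"""The generator must be reproducible and its planted signal recoverable."""

import numpy as np
import pandas as pd
import pytest

from chprofile import (MotifPattern, SyntheticConfig, generate_probe_alignments,
                       generate_promoters, generate_study, scan)
from chprofile.motifs import PromoterWindow, compile_pattern
from chprofile.synthetic import IUPAC_CHOICES, ConfigError, _revcomp


def test_same_seed_gives_identical_study():
    cfg = SyntheticConfig(n_genes=150, onset_fractions=(0.05, 0.02, 0.02), seed=9)
    s1, t1 = generate_study(cfg)
    s2, t2 = generate_study(cfg)
    pd.testing.assert_frame_equal(s1.matrix, s2.matrix)
    assert t1.de_genes_by_timepoint == t2.de_genes_by_timepoint
    assert t1.planted_set_members == t2.planted_set_members


def test_study_shape_and_design():
    cfg = SyntheticConfig(n_genes=120, n_replicates=3,
                          onset_fractions=(0.1, 0.05, 0.05), seed=2)
    study, _ = generate_study(cfg)
    assert study.matrix.shape == (120, 2 * 3 * 3)
    assert set(study.samples["timepoint"]) == {"t1", "t2", "t3"}
    assert set(study.samples["gfp"]) == {"+", "-"}


def test_mutant_genotype_doubles_columns(small_study):
    config, study, truth = small_study
    assert study.matrix.shape[1] == 2 * 2 * 3 * config.n_replicates
    assert truth.mutant_dependent_genes
    assert truth.mutant_dependent_genes <= set().union(*truth.de_genes_by_timepoint.values())


def test_planted_mean_difference_matches_effect_size():
    cfg = SyntheticConfig(n_genes=3000, onset_fractions=(0.1, 0.0, 0.0),
                          variance_heterogeneity=0.0, seed=4)
    study, truth = generate_study(cfg)
    planted = sorted(truth.de_genes_by_timepoint["t1"])
    pos = study.sample_ids(timepoint="t1", gfp="+")
    neg = study.sample_ids(timepoint="t1", gfp="-")
    diff = (study.matrix.loc[planted, pos].mean(axis=1)
            - study.matrix.loc[planted, neg].mean(axis=1))
    se = cfg.noise_sd * np.sqrt(2 / cfg.n_replicates) / np.sqrt(len(planted))
    assert abs(diff.mean() - cfg.effect_size) < 3 * se


def test_zero_effect_size_yields_null_differences():
    cfg = SyntheticConfig(n_genes=2000, onset_fractions=(0.1, 0.0, 0.0),
                          effect_size=0.0, seed=5)
    study, truth = generate_study(cfg)
    planted = sorted(truth.de_genes_by_timepoint["t1"])
    assert planted  # labels still honoured
    pos = study.sample_ids(timepoint="t1", gfp="+")
    neg = study.sample_ids(timepoint="t1", gfp="-")
    diff = (study.matrix.loc[planted, pos].mean(axis=1)
            - study.matrix.loc[planted, neg].mean(axis=1))
    se = diff.std() / np.sqrt(len(planted))
    assert abs(diff.mean()) < 3 * se


def test_cumulative_onset_is_nested():
    cfg = SyntheticConfig(n_genes=500, onset_fractions=(0.05, 0.05, 0.05), seed=6)
    _, truth = generate_study(cfg)
    t1, t2, t3 = (truth.de_genes_by_timepoint[tp] for tp in ("t1", "t2", "t3"))
    assert t1 <= t2 <= t3


def test_transient_onset_is_disjoint():
    cfg = SyntheticConfig(n_genes=500, onset_fractions=(0.05, 0.05, 0.05),
                          onset_model="transient", seed=6)
    _, truth = generate_study(cfg)
    t1, t2, t3 = (truth.de_genes_by_timepoint[tp] for tp in ("t1", "t2", "t3"))
    assert not (t1 & t2) and not (t2 & t3) and not (t1 & t3)


def test_ground_truth_labels_exist_in_matrix(small_study):
    _, study, truth = small_study
    genes = set(study.genes)
    for members in truth.de_genes_by_timepoint.values():
        assert members <= genes
    for members in truth.planted_set_members.values():
        assert members <= genes


@pytest.mark.parametrize("bad", [
    dict(n_genes=0),
    dict(onset_fractions=(0.6, 0.3, 0.3)),
    dict(onset_fractions=(-0.1, 0.0, 0.0)),
    dict(motif_plant_rate=1.5),
    dict(onset_model="sometimes"),
    dict(motif_iupac="CAXNTG"),
])
def test_invalid_config_rejected(bad):
    with pytest.raises(ConfigError):
        SyntheticConfig(n_genes=100, **bad).validate() if "n_genes" not in bad \
            else SyntheticConfig(**bad).validate()


# --- promoters -----------------------------------------------------------

def _promoter_setup(n=40, plant_rate=1.0, background=0.0, seed=3, length=200):
    cfg = SyntheticConfig(n_genes=n, promoter_length=length,
                          motif_plant_rate=plant_rate,
                          background_motif_rate=background, seed=seed)
    genes = [f"g{i:05d}" for i in range(n)]
    members = {"planted": genes[: n // 2]}
    return cfg, genes, members, generate_promoters(cfg, genes=genes, members=members)


def test_promoters_reproducible():
    _, _, _, p1 = _promoter_setup(seed=8)
    _, _, _, p2 = _promoter_setup(seed=8)
    assert p1.contigs == p2.contigs and p1.planted == p2.planted


def test_saturating_plant_rate_hits_every_member():
    cfg, genes, members, prom = _promoter_setup(n=20, plant_rate=1.0)
    windows = [PromoterWindow(g, cfg.promoter_length, "+", prom.windows[g])
               for g in genes]
    hits = scan(windows, MotifPattern("syn", cfg.motif_iupac))
    assert set(members["planted"]) <= hits.hit_genes()


def test_no_planting_no_background_means_zero_hits():
    cfg, genes, _, prom = _promoter_setup(plant_rate=0.0, background=0.0)
    windows = [PromoterWindow(g, cfg.promoter_length, "+", prom.windows[g])
               for g in genes]
    hits = scan(windows, MotifPattern("syn", cfg.motif_iupac))
    assert hits.counts["n_hits"].sum() == 0


def test_scan_recovers_exactly_the_planted_genes():
    cfg, genes, members, prom = _promoter_setup(n=100, plant_rate=0.8, seed=13)
    windows = [PromoterWindow(g, cfg.promoter_length, "+", prom.windows[g])
               for g in genes]
    hits = scan(windows, MotifPattern("syn", cfg.motif_iupac))
    assert hits.hit_genes() == set(prom.planted)
    for gene, planted_sites in prom.planted.items():
        offsets = {o for o, _ in hits.sites[gene]}
        assert all(o in offsets for o, _ in planted_sites)


def test_planted_positions_match_pattern_when_excised():
    cfg, genes, _, prom = _promoter_setup(n=60, plant_rate=1.0, seed=21)
    motif = compile_pattern(MotifPattern("syn", cfg.motif_iupac))
    L = len(cfg.motif_iupac)
    for gene, sites in prom.planted.items():
        for offset, strand in sites:
            piece = prom.windows[gene][offset:offset + L]
            if strand == "-":
                piece = _revcomp(piece)
            assert all(piece[i] in IUPAC_CHOICES[c]
                       for i, c in enumerate(cfg.motif_iupac))


def test_motif_longer_than_promoter_rejected():
    cfg = SyntheticConfig(n_genes=5, promoter_length=8, motif_iupac="CANNTGCANNTG",
                          seed=0)
    with pytest.raises(ConfigError):
        generate_promoters(cfg, genes=["a", "b"], members=None)


# --- probe alignments ----------------------------------------------------

def test_probe_alignment_truth_counts():
    aln, truth = generate_probe_alignments(
        50, 14, {"promiscuous": 4, "low_coverage": 6}, seed=1)
    assert (truth["expected_status"] == "promiscuous").sum() == 4
    assert (truth["expected_status"] == "unmapped").sum() == 6
    assert (truth["expected_status"] == "trusted").sum() == 40
    assert set(aln["total_oligos"]) == {14}


def test_probe_alignment_bad_spec():
    with pytest.raises(ConfigError):
        generate_probe_alignments(5, 14, {"promiscuous": 10})
    with pytest.raises(ConfigError):
        generate_probe_alignments(5, 14, {"weird": 1})
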