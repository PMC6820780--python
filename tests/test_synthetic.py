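"""The seeded synthetic study generator."""

import dataclasses

import numpy as np
import pytest

from netbeta import (
    GeneratorConfig,
    build_metaweb,
    generate_regional_pool,
    generate_site,
    generate_study,
    pairwise_matrices,
    write_study,
)
from netbeta.io_model import ValidationError
from netbeta.synthetic import GenerationError


def test_default_design_is_38_sites():
    cfg = GeneratorConfig(seed=3)
    study = generate_study(cfg)
    counts = {c: sum(1 for s in study.sites if s.category == c) for c in
              ("abandoned", "restored", "continuous")}
    assert counts == {"abandoned": 10, "restored": 18, "continuous": 10}
    study.validate()


def test_same_seed_reproduces_study(small_config):
    s1 = generate_study(small_config)
    s2 = generate_study(dataclasses.replace(small_config))
    assert s1.site_ids == s2.site_ids
    for a, b in zip(s1.sites, s2.sites):
        assert a.links == b.links
        assert a.plant_abundance == b.plant_abundance
        assert (a.x_km, a.y_km, a.area_ha) == (b.x_km, b.y_km, b.area_ha)


def test_written_csvs_byte_identical_across_runs(tmp_path, small_config):
    p1 = write_study(generate_study(small_config), tmp_path / "r1")
    p2 = write_study(generate_study(small_config), tmp_path / "r2")
    for k in p1:
        assert p1[k].read_bytes() == p2[k].read_bytes()


def test_full_connectance_gives_complete_metaweb():
    cfg = GeneratorConfig(n_regional_plants=6, n_regional_pollinators=5,
                          metaweb_connectance=1.0, seed=1)
    mw = generate_regional_pool(cfg)
    assert len(mw.links) == 30


def test_pool_link_count_tracks_connectance():
    """Mean link count over seeds stays near n_p*n_a*connectance."""
    counts = []
    for seed in range(40):
        cfg = GeneratorConfig(n_regional_plants=10, n_regional_pollinators=10,
                              metaweb_connectance=0.5, seed=seed)
        counts.append(len(generate_regional_pool(cfg).links))
    # conditioning on every species having >= 1 link biases slightly high,
    # but the mean must remain near 50 out of 100 possible links
    assert 40 < np.mean(counts) < 62


def test_impossible_connectance_raises():
    cfg = GeneratorConfig(n_regional_plants=200, n_regional_pollinators=200,
                          metaweb_connectance=0.0015, seed=0)
    with pytest.raises(GenerationError):
        generate_regional_pool(cfg)


def test_zero_rewiring_links_subset_of_metaweb(small_config):
    cfg = dataclasses.replace(small_config, rewiring_prob=0.0)
    mw = generate_regional_pool(cfg)
    study = generate_study(cfg)
    for s in study.sites:
        for link in s.links:
            assert link in mw.links


def test_rewiring_one_plant_marginal_uniform():
    """With full rewiring and flat flora, visits spread uniformly over plants."""
    scipy_stats = pytest.importorskip("scipy.stats")
    cfg = GeneratorConfig(
        n_sites_per_category={"abandoned": 0, "restored": 1, "continuous": 0},
        n_regional_plants=10, n_regional_pollinators=10,
        metaweb_connectance=0.5, core_fraction=1.0, category_turnover=0.0,
        richness_gradient={"abandoned": (5, 5), "restored": (5, 5), "continuous": (5, 5)},
        rewiring_prob=1.0, visits_per_site=10_000, visits_dispersion=0.0,
        visit_effort_by_category={"abandoned": 1.0, "restored": 1.0, "continuous": 1.0},
        abundance_dispersion=1.0, survey_miss_prob=0.0, seed=9,
    )
    mw = generate_regional_pool(cfg)
    site = generate_site(cfg, mw, "restored", 0)
    # rewired plant choice is uniform regardless of floral abundance
    plant_counts = {}
    for (p, _), w in site.links.items():
        plant_counts[p] = plant_counts.get(p, 0) + w
    obs = np.array(list(plant_counts.values()))
    chi = scipy_stats.chisquare(obs)
    assert chi.pvalue > 1e-4


def test_managed_taxon_injected():
    cfg = GeneratorConfig(
        n_sites_per_category={"abandoned": 1, "restored": 1, "continuous": 1},
        n_regional_plants=12, n_regional_pollinators=12,
        metaweb_connectance=0.4,
        richness_gradient={"abandoned": (6, 5), "restored": (6, 5), "continuous": (6, 5)},
        managed_taxon="Apis_mellifera", seed=2,
    )
    study = generate_study(cfg)
    assert any(a == "Apis_mellifera" for s in study.sites for (_, a) in s.links)


def test_category_turnover_raises_species_beta(small_config):
    """More category-specific species means higher compositional beta."""
    means = []
    for turn in (0.0, 0.8):
        tot = []
        for seed in range(3):
            cfg = dataclasses.replace(small_config, category_turnover=turn, seed=seed)
            mats = pairwise_matrices(generate_study(cfg), "quantitative")
            tot.append(np.nanmean(mats["L_total"].offdiag_values())
                       + np.nanmean(mats["U_total"].offdiag_values()))
        means.append(np.mean(tot))
    assert means[1] > means[0]


def test_config_validation():
    with pytest.raises(ValidationError):
        GeneratorConfig(metaweb_connectance=0.0).validate()
    with pytest.raises(ValidationError):
        GeneratorConfig(rewiring_prob=1.5).validate()
    with pytest.raises(ValidationError):
        GeneratorConfig(n_sites_per_category={"wild": 3}).validate()


def test_generated_study_passes_validation_and_metaweb_consistency(small_study):
    small_study.validate()
    mw = build_metaweb(small_study)
    for s in small_study.sites:
        for link in s.links:
            assert link in mw.links
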