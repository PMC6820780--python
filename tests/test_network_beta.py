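"""Pairwise four-component network comparison and its summaries."""

import itertools
import math

import numpy as np
import pytest

from netbeta import (
    PairwiseMatrix,
    StudyData,
    compare_networks,
    link_vectors,
    pairwise_matrices,
    partition_proportions,
    rewiring_fraction,
    shared_subwebs,
    species_vectors,
)
from netbeta.io_model import ValidationError
from tests.conftest import make_net


def test_species_vectors_aggregation():
    net = make_net(
        "s1", {("P1", "A1"): 2, ("P2", "A1"): 3},
        abundance={"P1": 5.0, "P2": 1.0, "P3": 4.0},
    )
    plants, polls = species_vectors(net)
    assert plants == {"P1": 5.0, "P2": 1.0, "P3": 4.0}
    assert polls == {"A1": 5.0}


def test_species_vectors_empty_web_keeps_floral_plants():
    net = make_net("s1", {}, abundance={"P1": 2.0})
    plants, polls = species_vectors(net)
    assert plants == {"P1": 2.0} and polls == {}


def test_link_vectors_union(toy_pair):
    v1, v2 = link_vectors(*toy_pair)
    assert v1 == {("P1", "A1"): 2.0, ("P1", "A2"): 1.0}
    assert v2 == {("P1", "A1"): 1.0, ("P2", "A1"): 3.0}


def test_shared_subwebs_restriction(toy_pair):
    sub1, sub2 = shared_subwebs(*toy_pair)
    assert sub1 == {("P1", "A1"): 2.0}
    assert sub2 == {("P1", "A1"): 1.0}


def test_shared_subwebs_marker_when_no_shared_pollinator():
    n1 = make_net("s1", {("P1", "A1"): 1})
    n2 = make_net("s2", {("P1", "A2"): 1})
    assert shared_subwebs(n1, n2) is None
    res = compare_networks(n1, n2, "quantitative")
    assert res.OS is None


def test_compare_networks_worked_example_quantitative(toy_pair):
    res = compare_networks(*toy_pair, mode="quantitative")
    assert (res.WN.total, res.WN.turnover, res.WN.richness) == pytest.approx(
        (5 / 6, 2 / 3, 1 / 6))
    assert (res.OS.total, res.OS.turnover, res.OS.richness) == pytest.approx(
        (0.5, 0.0, 0.5))
    assert res.n_shared_plants == 1 and res.n_shared_pollinators == 1


def test_compare_networks_worked_example_binary(toy_pair):
    res = compare_networks(*toy_pair, mode="binary")
    assert (res.WN.total, res.WN.turnover, res.WN.richness) == pytest.approx(
        (2 / 3, 2 / 3, 0.0))
    assert (res.OS.total, res.OS.turnover, res.OS.richness) == pytest.approx(
        (0.0, 0.0, 0.0))


@pytest.mark.parametrize("mode", ["binary", "quantitative"])
def test_compare_network_to_itself_is_zero(toy_pair, mode):
    net = toy_pair[0]
    res = compare_networks(net, net, mode)
    for comp in ("L", "U", "WN", "OS"):
        bc = res.component(comp)
        assert bc is not None
        assert (bc.total, bc.turnover, bc.richness) == (0.0, 0.0, 0.0)


def test_os_locality(toy_pair):
    """A link with an endpoint unknown to the partner changes WN, not OS."""
    net1, net2 = toy_pair
    grown = make_net(
        "s1b", {**net1.links, ("P9", "A9"): 5},
        abundance={**net1.plant_abundance, "P9": 5.0},
    )
    for mode in ("binary", "quantitative"):
        base = compare_networks(net1, net2, mode)
        more = compare_networks(grown, net2, mode)
        assert more.WN.total != pytest.approx(base.WN.total)
        assert more.OS.total == pytest.approx(base.OS.total)
        assert more.OS.turnover == pytest.approx(base.OS.turnover)


def test_binary_wn_zero_iff_identical_links(toy_pair):
    net1, net2 = toy_pair
    assert compare_networks(net1, net1, "binary").WN.total == 0.0
    assert compare_networks(net1, net2, "binary").WN.total > 0.0


def test_pairwise_matrices_match_compare_networks(toy_pair):
    study = StudyData(sites=list(toy_pair))
    mats = pairwise_matrices(study, "quantitative")
    res = compare_networks(*toy_pair, mode="quantitative")
    assert mats["WN_total"].values[0, 1] == pytest.approx(res.WN.total)
    assert mats["OS_richness"].values[1, 0] == pytest.approx(res.OS.richness)
    for m in mats.values():
        assert np.allclose(m.values, m.values.T, equal_nan=True)
        assert np.all(np.diag(m.values) == 0)


def test_pairwise_matrices_disjoint_sites():
    n1 = make_net("s1", {("P1", "A1"): 1})
    n2 = make_net("s2", {("P2", "A2"): 1})
    mats = pairwise_matrices(StudyData(sites=[n1, n2]), "binary")
    for comp in ("L", "U", "WN"):
        assert mats[f"{comp}_total"].values[0, 1] == 1.0
    assert math.isnan(mats["OS_total"].values[0, 1])


def test_pairwise_matrices_require_two_sites(toy_pair):
    with pytest.raises(ValidationError):
        pairwise_matrices(StudyData(sites=[toy_pair[0]]), "binary")


def _mat(vals):
    return PairwiseMatrix(site_ids=["a", "b", "c"], values=np.array(vals))


def test_partition_proportions_ratio_of_sums():
    tot = _mat([[0, 0.5, 2 / 3], [0.5, 0, 0], [2 / 3, 0, 0]])
    turn = _mat([[0, 0.5, 0], [0.5, 0, 0], [0, 0, 0]])
    rich = _mat([[0, 0, 2 / 3], [0, 0, 0], [2 / 3, 0, 0]])
    props = partition_proportions(tot, turn, rich)
    assert props["prop_turnover"] == pytest.approx(0.5 / (7 / 6))
    assert props["prop_richness"] == pytest.approx(1 - 0.5 / (7 / 6))


def test_partition_proportions_degenerate_and_full_turnover():
    zero = _mat(np.zeros((3, 3)))
    props = partition_proportions(zero, zero, zero)
    assert math.isnan(props["prop_turnover"])
    tot = _mat([[0, 0.4, 0.2], [0.4, 0, 0.1], [0.2, 0.1, 0]])
    props = partition_proportions(tot, tot, zero)
    assert props["prop_turnover"] == pytest.approx(1.0)


def test_partition_proportions_shape_mismatch():
    tot = _mat(np.zeros((3, 3)))
    other = PairwiseMatrix(site_ids=["a", "b"], values=np.zeros((2, 2)))
    with pytest.raises(ValidationError):
        partition_proportions(tot, other, other)


def test_rewiring_fraction_values():
    assert rewiring_fraction(0.66, 0.28) == pytest.approx(0.1848)
    assert rewiring_fraction(0.9, 0.0) == 0.0
    assert rewiring_fraction(1.0, 1.0) == 1.0
    with pytest.raises(ValidationError):
        rewiring_fraction(1.2, 0.5)


def test_mean_totals_invariant_to_relabelling_and_order(small_study):
    """Site order and species names must not affect study-mean betas."""
    mats = pairwise_matrices(small_study, "quantitative")
    base = {k: np.nanmean(m.offdiag_values()) for k, m in mats.items()}

    relabel = lambda s: f"x_{s}_y"
    sites = []
    for s in reversed(small_study.sites):
        links = {(relabel(p), relabel(a)): w for (p, a), w in s.links.items()}
        ab = {relabel(p): v for p, v in s.plant_abundance.items()}
        sites.append(make_net(s.site_id, links, abundance=ab, category=s.category))
    mats2 = pairwise_matrices(StudyData(sites=sites), "quantitative")
    for k in base:
        assert np.nanmean(mats2[k].offdiag_values()) == pytest.approx(base[k])


def test_pairwise_matrix_csv_round_trip(tmp_path, small_study):
    mats = pairwise_matrices(small_study, "binary")
    path = tmp_path / "m.csv"
    mats["OS_total"].write_csv(path)
    back = PairwiseMatrix.read_csv(path)
    assert back.site_ids == mats["OS_total"].site_ids
    assert np.allclose(back.values, mats["OS_total"].values, equal_nan=True)
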