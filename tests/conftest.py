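import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from netbeta import GeneratorConfig, SiteNetwork, StudyData, generate_study


def make_net(site_id, links, abundance=None, category="restored", **kw):
    """A SiteNetwork whose plant abundances default to per-plant link sums."""
    if abundance is None:
        abundance = {}
        for (p, _), w in links.items():
            abundance[p] = abundance.get(p, 0.0) + w
    return SiteNetwork(
        site_id=site_id, category=category, links=dict(links),
        plant_abundance=dict(abundance), **kw,
    )


@pytest.fixture
def toy_pair():
    """The two-network worked example used throughout the unit tests."""
    net1 = make_net("s1", {("P1", "A1"): 2, ("P1", "A2"): 1})
    net2 = make_net("s2", {("P1", "A1"): 1, ("P2", "A1"): 3})
    return net1, net2


@pytest.fixture
def small_config():
    return GeneratorConfig(
        n_sites_per_category={"abandoned": 2, "restored": 2, "continuous": 2},
        n_regional_plants=15,
        n_regional_pollinators=15,
        metaweb_connectance=0.4,
        richness_gradient={
            "abandoned": (8, 6), "restored": (8, 6), "continuous": (8, 6)
        },
        visits_per_site=60,
        seed=7,
    )


@pytest.fixture
def small_study(small_config):
    return generate_study(small_config)
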