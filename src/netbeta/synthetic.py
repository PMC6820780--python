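"""Seeded generator of synthetic multi-site plant-pollinator studies.

The generator emulates a space-for-time pasture study: three management
categories (10 abandoned / 18 restored / 10 continuously grazed sites by
default), a regional metaweb of possible links, category-structured
species turnover (a regional core shared by all categories plus
category-specific species pools), log-normal floral abundances, and
visitation sampled event by event.  Each visitation event picks a
pollinator proportional to its site abundance and then a plant
proportional to floral abundance among the pollinator's metaweb partners
present at the site — except with probability ``rewiring_prob`` the plant
is drawn uniformly among all plants present, producing a genuinely
rewired (non-metaweb-constrained) link.  Raising ``rewiring_prob``
therefore raises the true link turnover among shared species (the OS
turnover component) that the analysis is designed to detect.

Randomness is a hierarchical stream from a single seed (regional pool,
then each site, then its events), so adding sites does not perturb the
draws of earlier sites.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .io_model import (
    CATEGORIES,
    Metaweb,
    SiteNetwork,
    StudyData,
    ValidationError,
    complete_plant_abundances,
)


class GenerationError(RuntimeError):
    """The sampler could not satisfy a structural constraint."""


# mean pasture areas (ha) by category in the emulated study design
_AREA_MEANS = {"abandoned": 2.6, "restored": 3.8, "continuous": 2.8}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults emulate the study design.

    ``richness_gradient`` gives the mean site pool richness per category
    as (plants, pollinators).  ``core_fraction`` is the share of the
    regional pool common to all categories; ``category_turnover`` the
    share of each site's species drawn from its category-specific pool.
    """

    n_sites_per_category: dict[str, int] = field(
        default_factory=lambda: {"abandoned": 10, "restored": 18, "continuous": 10}
    )
    n_regional_plants: int = 80
    n_regional_pollinators: int = 90
    metaweb_connectance: float = 0.15
    generality_sigma: float = 0.75
    core_fraction: float = 0.35
    category_turnover: float = 0.4
    richness_gradient: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "abandoned": (22, 16),
            "restored": (26, 32),
            "continuous": (26, 20),
        }
    )
    rewiring_prob: float = 0.15
    visits_per_site: int = 85
    visit_effort_by_category: dict[str, float] = field(
        default_factory=lambda: {"abandoned": 0.45, "restored": 1.55, "continuous": 0.55}
    )
    visits_dispersion: float = 0.5
    abundance_dispersion: float = 1.0
    degree_abundance_coupling: float = 0.0
    survey_miss_prob: float = 0.1
    managed_taxon: Optional[str] = None
    managed_visit_fraction: float = 0.04
    extent_km: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("metaweb_connectance",):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        for name in ("core_fraction", "category_turnover", "rewiring_prob",
                     "survey_miss_prob", "managed_visit_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_regional_plants", "n_regional_pollinators", "visits_per_site"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.abundance_dispersion <= 0:
            raise ValidationError("abundance_dispersion must be positive")
        if self.generality_sigma < 0:
            raise ValidationError("generality_sigma must be non-negative")
        if self.visits_dispersion < 0:
            raise ValidationError("visits_dispersion must be non-negative")
        for cat, e in self.visit_effort_by_category.items():
            if cat not in CATEGORIES or e <= 0:
                raise ValidationError(f"bad visit_effort_by_category entry {cat!r}: {e}")
        for cat, n in self.n_sites_per_category.items():
            if cat not in CATEGORIES or n < 0:
                raise ValidationError(f"bad n_sites_per_category entry {cat!r}: {n}")
        for cat, rich in self.richness_gradient.items():
            if cat not in CATEGORIES or min(rich) < 1:
                raise ValidationError(f"bad richness_gradient entry {cat!r}: {rich}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["richness_gradient"] = {k: list(v) for k, v in d["richness_gradient"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "richness_gradient" in d:
            d["richness_gradient"] = {k: tuple(v) for k, v in d["richness_gradient"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _rng(config: GeneratorConfig, *key: int) -> np.random.Generator:
    # hierarchical stream: one child generator per (purpose, indices) key
    return np.random.default_rng(np.random.SeedSequence((int(config.seed),) + key))


def generate_regional_pool(config: GeneratorConfig) -> Metaweb:
    """Random bipartite metaweb over the regional species pool.

    Each plant-pollinator pair is a link independently with probability
    ``metaweb_connectance`` scaled by a log-normal per-pollinator
    generality weight (degree heterogeneity); every species must end up
    with at least one link, resampling a bounded number of times.
    """
    config.validate()
    rng = _rng(config, 0)
    n_p, n_a = config.n_regional_plants, config.n_regional_pollinators
    plants = [f"P{i:03d}" for i in range(n_p)]
    pollinators = [f"A{i:03d}" for i in range(n_a)]
    for _ in range(500):
        gen = rng.lognormal(mean=0.0, sigma=config.generality_sigma, size=n_a)
        gen /= gen.mean()
        # per-pollinator generality enters as an exponent so that
        # connectance 1 forces a complete web and probabilities stay valid
        prob = 1.0 - (1.0 - config.metaweb_connectance) ** gen
        adj = rng.random((n_p, n_a)) < prob[None, :]
        if adj.any(axis=1).all() and adj.any(axis=0).all():
            links = {
                (plants[i], pollinators[j]): 1
                for i, j in zip(*np.nonzero(adj))
            }
            return Metaweb(links=links, plants=set(plants), pollinators=set(pollinators))
    raise GenerationError(
        "could not build a metaweb with every species linked; "
        "raise metaweb_connectance or shrink the pool"
    )


def _species_pools(config: GeneratorConfig, species: list[str], *, stream: int):
    """Deterministic core / per-category partition of a species list."""
    rng = _rng(config, stream)
    order = list(rng.permutation(species))
    n_core = int(round(config.core_fraction * len(order)))
    core = order[:n_core]
    rest = order[n_core:]
    pools = {}
    k = len(CATEGORIES)
    for idx, cat in enumerate(CATEGORIES):
        pools[cat] = rest[idx::k]
    return core, pools


def _sample_pool(rng, core, specific, n_target, turnover):
    n_spec = min(int(round(turnover * n_target)), len(specific))
    n_core = min(n_target - n_spec, len(core))
    chosen = list(rng.choice(core, size=n_core, replace=False)) if n_core else []
    chosen += list(rng.choice(specific, size=n_spec, replace=False)) if n_spec else []
    return sorted(chosen)


def generate_site(
    config: GeneratorConfig,
    metaweb: Metaweb,
    category: str,
    site_index: int,
) -> SiteNetwork:
    """One site: species pools, floral survey and sampled visitation.

    Deterministic given (config.seed, site_index).  A random subset of
    visited plants is deleted from the floral survey (exercising the
    rare-plant abundance-1 rule) and immediately completed, so the
    returned network satisfies the abundance invariant.
    """
    if category not in CATEGORIES:
        raise ValidationError(f"unknown category {category!r}")
    rng = _rng(config, 3, site_index)
    plants_all = sorted(metaweb.plants)
    polls_all = sorted(metaweb.pollinators)
    core_p, pools_p = _species_pools(config, plants_all, stream=1)
    core_a, pools_a = _species_pools(config, polls_all, stream=2)
    n_plants, n_polls = config.richness_gradient[category]

    site_plants = _sample_pool(rng, core_p, pools_p[category], n_plants, config.category_turnover)
    site_polls = _sample_pool(rng, core_a, pools_a[category], n_polls, config.category_turnover)
    if not site_plants or not site_polls:
        raise GenerationError(f"empty species pool at site index {site_index}")

    # floral survey: log-normal flowering-unit totals, at least 1
    floral = {
        p: float(np.round(max(1.0, ab), 1))
        for p, ab in zip(
            site_plants,
            rng.lognormal(mean=3.0, sigma=config.abundance_dispersion, size=len(site_plants)),
        )
    }
    # pollinator local abundances (activity weights)
    poll_w = rng.lognormal(mean=0.0, sigma=config.abundance_dispersion, size=len(site_polls))

    # pollinators must have at least one metaweb partner present to forage
    plant_set = set(site_plants)
    partners = {
        a: [p for p in site_plants if (p, a) in metaweb.links] for a in site_polls
    }
    usable = [i for i, a in enumerate(site_polls) if partners[a]]
    if not usable:
        raise GenerationError(f"no pollinator with local metaweb partners at site {site_index}")
    site_polls = [site_polls[i] for i in usable]
    poll_w = poll_w[usable]
    if config.degree_abundance_coupling:
        # generalists tend to be more abundant; coupling exponent kappa
        # makes local activity scale with local partner count
        deg = np.array([len(partners[a]) for a in site_polls], float)
        poll_w = poll_w * deg ** config.degree_abundance_coupling
    poll_w = poll_w / poll_w.sum()

    floral_arr = np.array([floral[p] for p in site_plants], float)
    floral_prob = floral_arr / floral_arr.sum()

    # per-site sampling effort: category mean x mean-one log-normal noise
    effort = config.visit_effort_by_category.get(category, 1.0)
    sigma = config.visits_dispersion
    noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma) if sigma > 0 else 1.0
    n_events = max(1, int(round(config.visits_per_site * effort * noise)))
    rewired = rng.random(n_events) < config.rewiring_prob
    poll_idx = rng.choice(len(site_polls), size=n_events, p=poll_w)

    links: dict[tuple[str, str], int] = {}

    def add(p, a):
        links[(p, a)] = links.get((p, a), 0) + 1

    # rewired events: plant uniform among all present plants
    n_rw = int(rewired.sum())
    if n_rw:
        rw_plants = rng.choice(site_plants, size=n_rw)
        for p, ai in zip(rw_plants, poll_idx[rewired]):
            add(str(p), site_polls[ai])
    # faithful events: plant ~ floral abundance among the pollinator's partners
    faithful_idx = poll_idx[~rewired]
    for ai in np.unique(faithful_idx):
        a = site_polls[ai]
        part = partners[a]
        w = np.array([floral[p] for p in part], float)
        w /= w.sum()
        k = int((faithful_idx == ai).sum())
        for p in rng.choice(part, size=k, p=w):
            add(str(p), a)

    # managed taxon (e.g. honey bees): extra visits spread over the flora
    if config.managed_taxon:
        n_m = max(1, int(round(config.managed_visit_fraction * n_events)))
        for p in rng.choice(site_plants, size=n_m, p=floral_prob):
            add(str(p), config.managed_taxon)

    # drop some visited plants from the survey, then re-complete at 1
    visited = sorted({p for (p, _) in links})
    for p in visited:
        if rng.random() < config.survey_miss_prob:
            floral.pop(p, None)

    x, y = rng.uniform(0.0, config.extent_km, size=2)
    area = float(np.round(max(1.0, rng.lognormal(mean=np.log(_AREA_MEANS[category]), sigma=0.4)), 2))
    ysr = int(rng.integers(2, 17)) if category == "restored" else None

    net = SiteNetwork(
        site_id=f"s{site_index:02d}",
        category=category,
        links=links,
        plant_abundance=floral,
        x_km=float(np.round(x, 3)),
        y_km=float(np.round(y, 3)),
        area_ha=area,
        years_since_restoration=ysr,
    )
    return complete_plant_abundances(net)


def generate_study(config: GeneratorConfig) -> StudyData:
    """A full multi-site study; provenance records the config and seed."""
    config.validate()
    mw = generate_regional_pool(config)
    sites = []
    idx = 0
    for cat in CATEGORIES:
        for _ in range(config.n_sites_per_category.get(cat, 0)):
            sites.append(generate_site(config, mw, cat, idx))
            idx += 1
    study = StudyData(
        sites=sites,
        provenance={"generator": config.to_dict(), "seed": int(config.seed)},
    )
    study.validate()
    return study
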