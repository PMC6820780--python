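"""Domain types, CSV readers/writers and data-preparation filters.

The unit of observation is a semi-natural pasture ("site") holding a
quantitative bipartite flower-visitation web (plant x pollinator visit
counts summed over survey rounds) together with the site's full
flowering-plant abundance vector from the floral plots.  Plants recorded
in the floral plots but never visited stay in the abundance vector and
contribute to plant compositional beta diversity; plants visited but
missed by the plots are assumed rare and assigned abundance 1
(:func:`complete_plant_abundances`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

CATEGORIES = ("abandoned", "restored", "continuous")

Link = tuple[str, str]  # (plant_id, pollinator_id)


class FormatError(ValueError):
    """A required column or structural element is missing from an input table."""


class ReferentialError(ValueError):
    """A row references an entity (e.g. a site) that does not exist."""


class ValidationError(ValueError):
    """A value violates a domain invariant (negative count, bad category...)."""


@dataclass
class SiteNetwork:
    """One site's visitation web plus its floral abundance vector.

    Parameters
    ----------
    site_id : str
        Unique site identifier.
    category : str
        Management category, one of ``abandoned``, ``restored``,
        ``continuous``.
    links : dict[(plant, pollinator) -> int]
        Visit counts summed over survey rounds; zero-count links are not
        stored.
    plant_abundance : dict[plant -> float]
        Flowering-unit counts from the floral plots (surveyed plants) plus
        visited-but-unsurveyed plants once completed.
    x_km, y_km : float
        Site centre coordinates on a planar km grid.
    area_ha : float
        Pasture area in hectares.
    years_since_restoration : int or None
        Only meaningful for restored sites.
    """

    site_id: str
    category: str
    links: dict[Link, int] = field(default_factory=dict)
    plant_abundance: dict[str, float] = field(default_factory=dict)
    x_km: float = 0.0
    y_km: float = 0.0
    area_ha: float = 1.0
    years_since_restoration: Optional[int] = None

    # -- derived species sets ------------------------------------------
    @property
    def plants_in_web(self) -> set[str]:
        """Plants that appear as a link endpoint (visited plants)."""
        return {p for (p, _) in self.links}

    @property
    def pollinators_in_web(self) -> set[str]:
        return {a for (_, a) in self.links}

    def validate(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"site {self.site_id!r}: category {self.category!r} not in {CATEGORIES}"
            )
        if self.area_ha <= 0:
            raise ValidationError(f"site {self.site_id!r}: area_ha must be positive")
        for (p, a), w in self.links.items():
            if w < 1 or int(w) != w:
                raise ValidationError(
                    f"site {self.site_id!r}: link ({p},{a}) has count {w}; "
                    "stored visit counts must be integers >= 1"
                )
            if p not in self.plant_abundance or self.plant_abundance[p] < 1:
                raise ValidationError(
                    f"site {self.site_id!r}: visited plant {p!r} missing from "
                    "plant_abundance (run complete_plant_abundances) or abundance < 1"
                )
        for p, ab in self.plant_abundance.items():
            if ab < 0:
                raise ValidationError(
                    f"site {self.site_id!r}: negative abundance for {p!r}"
                )


@dataclass
class StudyData:
    """A collection of site networks plus provenance metadata."""

    sites: list[SiteNetwork] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate site ids: {dup}")
        for s in self.sites:
            s.validate()

    def site(self, site_id: str) -> SiteNetwork:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]


@dataclass
class Metaweb:
    """Aggregated network of all interactions observed across all sites."""

    links: dict[Link, int] = field(default_factory=dict)
    plants: set[str] = field(default_factory=set)
    pollinators: set[str] = field(default_factory=set)

    def validate(self) -> None:
        for p, a in self.links:
            if p not in self.plants or a not in self.pollinators:
                raise ValidationError(f"metaweb link ({p},{a}) endpoint not in species sets")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_INTERACTION_COLS = ["site_id", "plant", "pollinator", "visits"]
_FLORAL_COLS = ["site_id", "plant", "flowering_units"]
_SITE_COLS = ["site_id", "category", "x_km", "y_km", "area_ha", "years_since_restoration"]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_study(interactions_path, floral_path, metadata_path) -> StudyData:
    """Read a study from the three CSV tables.

    Duplicate (site, plant, pollinator) interaction rows are summed, as are
    duplicate (site, plant) floral rows.  Every interaction or floral row
    must reference a site present in the metadata table.
    """
    inter = pd.read_csv(interactions_path)
    floral = pd.read_csv(floral_path)
    meta = pd.read_csv(metadata_path)
    _require_columns(inter, _INTERACTION_COLS, interactions_path)
    _require_columns(floral, _FLORAL_COLS, floral_path)
    _require_columns(meta, _SITE_COLS, metadata_path)

    if len(inter) and (inter["visits"] < 0).any():
        raise ValidationError(f"{interactions_path}: negative visit counts")
    if len(floral) and (floral["flowering_units"] < 0).any():
        raise ValidationError(f"{floral_path}: negative flowering-unit counts")

    known = set(meta["site_id"].astype(str))
    for name, df in (("interaction", inter), ("floral", floral)):
        bad = set(df["site_id"].astype(str)) - known
        if bad:
            raise ReferentialError(
                f"{name} rows reference site(s) absent from metadata: {sorted(bad)}"
            )

    inter_g = (
        inter.groupby(["site_id", "plant", "pollinator"], sort=False)["visits"]
        .sum()
        .reset_index()
        if len(inter)
        else inter
    )
    floral_g = (
        floral.groupby(["site_id", "plant"], sort=False)["flowering_units"]
        .sum()
        .reset_index()
        if len(floral)
        else floral
    )

    sites = []
    for row in meta.itertuples(index=False):
        sid = str(row.site_id)
        links = {
            (str(r.plant), str(r.pollinator)): int(r.visits)
            for r in inter_g.itertuples(index=False)
            if str(r.site_id) == sid and r.visits > 0
        }
        abund = {
            str(r.plant): float(r.flowering_units)
            for r in floral_g.itertuples(index=False)
            if str(r.site_id) == sid
        }
        ysr = row.years_since_restoration
        ysr = None if pd.isna(ysr) else int(ysr)
        net = SiteNetwork(
            site_id=sid,
            category=str(row.category),
            links=links,
            plant_abundance=abund,
            x_km=float(row.x_km),
            y_km=float(row.y_km),
            area_ha=float(row.area_ha),
            years_since_restoration=ysr,
        )
        if net.category not in CATEGORIES:
            raise ValidationError(
                f"{metadata_path}: site {sid!r} category {net.category!r} not in {CATEGORIES}"
            )
        sites.append(net)
    return StudyData(
        sites=sites,
        provenance={
            "interactions": str(interactions_path),
            "floral": str(floral_path),
            "metadata": str(metadata_path),
        },
    )


def write_study(study: StudyData, outdir) -> dict[str, Path]:
    """Write the three study CSVs; returns the written paths.

    Rows are emitted in sorted order so identical studies produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    irows, frows, srows = [], [], []
    for s in study.sites:
        for (p, a), w in sorted(s.links.items()):
            irows.append((s.site_id, p, a, int(w)))
        for p, ab in sorted(s.plant_abundance.items()):
            frows.append((s.site_id, p, ab))
        srows.append(
            (
                s.site_id,
                s.category,
                s.x_km,
                s.y_km,
                s.area_ha,
                "" if s.years_since_restoration is None else s.years_since_restoration,
            )
        )
    paths = {
        "interactions": outdir / "interactions.csv",
        "floral": outdir / "floral.csv",
        "sites": outdir / "sites.csv",
    }
    pd.DataFrame(irows, columns=_INTERACTION_COLS).to_csv(paths["interactions"], index=False)
    pd.DataFrame(frows, columns=_FLORAL_COLS).to_csv(paths["floral"], index=False)
    pd.DataFrame(srows, columns=_SITE_COLS).to_csv(paths["sites"], index=False)
    return paths


# ---------------------------------------------------------------------------
# data-preparation filters
# ---------------------------------------------------------------------------

def exclude_taxa(study: StudyData, taxa: Iterable[str]) -> StudyData:
    """Drop every link whose pollinator is in ``taxa`` (e.g. managed honey
    bees); floral abundances are untouched.  Returns a new study."""
    taxa = set(taxa)
    sites = []
    for s in study.sites:
        links = {k: w for k, w in s.links.items() if k[1] not in taxa}
        sites.append(dataclasses.replace(s, links=links, plant_abundance=dict(s.plant_abundance)))
    prov = dict(study.provenance)
    if taxa:
        prov["excluded_taxa"] = sorted(taxa)
    return StudyData(sites=sites, provenance=prov)


def complete_plant_abundances(network: SiteNetwork) -> SiteNetwork:
    """Assign abundance 1 to visited plants absent from the floral plots.

    Such plants are assumed rare: they were visited by pollinators but did
    not fall in any 1 x 1 m plot.  Existing abundances are unchanged.
    """
    abund = dict(network.plant_abundance)
    for p in network.plants_in_web:
        if p not in abund:
            abund[p] = 1.0
    return dataclasses.replace(network, plant_abundance=abund)


def complete_study(study: StudyData) -> StudyData:
    """Apply :func:`complete_plant_abundances` to every site."""
    return StudyData(
        sites=[complete_plant_abundances(s) for s in study.sites],
        provenance=dict(study.provenance),
    )


def network_size_metrics(network: SiteNetwork) -> dict:
    """Web size summary: species counted from link endpoints only.

    ``links_per_species`` is n_links / (n_plants + n_pollinators), reported
    as NaN for an empty web.
    """
    np_, na = len(network.plants_in_web), len(network.pollinators_in_web)
    nl = len(network.links)
    lps = nl / (np_ + na) if (np_ + na) else float("nan")
    return {
        "n_plants_in_web": np_,
        "n_pollinators_in_web": na,
        "n_links": nl,
        "links_per_species": lps,
    }
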