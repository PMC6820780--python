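"""Pairwise network comparison: the L / U / WN / OS component family.

For each pair of site networks we compute:

* ``L`` — compositional beta diversity of the lower trophic level
  (plants, floral abundances; includes plants recorded only in the floral
  plots),
* ``U`` — compositional beta diversity of the higher trophic level
  (pollinators, per-species visit totals),
* ``WN`` — dissimilarity of the two whole link sets (visit counts),
* ``OS`` — link dissimilarity restricted to species present in both
  networks; its turnover part measures true rewiring, its richness part
  differences in the number of links among co-occurring species.

Each component carries the second decomposition (turnover + richness) in
both binary and quantitative (Ruzicka) modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .beta_core import (
    BINARY,
    MODES,
    QUANTITATIVE,
    BetaComponents,
    abc_binary,
    abc_quantitative,
    decompose,
)
from .io_model import Link, SiteNetwork, StudyData, ValidationError

COMPONENTS = ("L", "U", "WN", "OS")
PARTS = ("total", "turnover", "richness")


def species_vectors(network: SiteNetwork) -> tuple[dict[str, float], dict[str, float]]:
    """Plant and pollinator abundance vectors for compositional beta.

    Plants: the full floral abundance vector (surveyed plus completed
    visited plants).  Pollinators: total visit count per species, the only
    quantitative currency the webs record for the upper level.
    """
    plants = dict(network.plant_abundance)
    pollinators: dict[str, float] = {}
    for (p, a), w in network.links.items():
        pollinators[a] = pollinators.get(a, 0.0) + w
    return plants, pollinators


def link_vectors(net1: SiteNetwork, net2: SiteNetwork) -> tuple[dict[Link, float], dict[Link, float]]:
    """The two link-weight maps over the union of both link sets."""
    return {k: float(w) for k, w in net1.links.items()}, {
        k: float(w) for k, w in net2.links.items()
    }


def shared_subwebs(
    net1: SiteNetwork, net2: SiteNetwork
) -> Optional[tuple[dict[Link, float], dict[Link, float]]]:
    """Restrict both webs to links among species present in both networks.

    Shared plants and pollinators are intersections of the
    :func:`species_vectors` supports.  Returns ``None`` when either shared
    set is empty (OS is then undefined for the pair).
    """
    p1, a1 = species_vectors(net1)
    p2, a2 = species_vectors(net2)
    shared_p = {k for k, v in p1.items() if v > 0} & {k for k, v in p2.items() if v > 0}
    shared_a = set(a1) & set(a2)
    if not shared_p or not shared_a:
        return None
    sub1 = {k: float(w) for k, w in net1.links.items() if k[0] in shared_p and k[1] in shared_a}
    sub2 = {k: float(w) for k, w in net2.links.items() if k[0] in shared_p and k[1] in shared_a}
    return sub1, sub2


def _dissimilarity(x: dict, y: dict, mode: str) -> BetaComponents:
    if mode == BINARY:
        return decompose(abc_binary(x.keys(), y.keys()))
    return decompose(abc_quantitative(x, y))


@dataclass
class NetworkBetaResult:
    """The four-component comparison of two networks (OS may be missing)."""

    L: BetaComponents
    U: BetaComponents
    WN: BetaComponents
    OS: Optional[BetaComponents]
    mode: str
    n_shared_plants: int
    n_shared_pollinators: int

    def component(self, name: str) -> Optional[BetaComponents]:
        return getattr(self, name)


def compare_networks(net1: SiteNetwork, net2: SiteNetwork, mode: str = QUANTITATIVE) -> NetworkBetaResult:
    """All four beta-diversity components for one pair of networks."""
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    p1, a1 = species_vectors(net1)
    p2, a2 = species_vectors(net2)
    lv1, lv2 = link_vectors(net1, net2)
    shared = shared_subwebs(net1, net2)
    shared_p = {k for k, v in p1.items() if v > 0} & {k for k, v in p2.items() if v > 0}
    shared_a = set(a1) & set(a2)
    return NetworkBetaResult(
        L=_dissimilarity(p1, p2, mode),
        U=_dissimilarity(a1, a2, mode),
        WN=_dissimilarity(lv1, lv2, mode),
        OS=None if shared is None else _dissimilarity(shared[0], shared[1], mode),
        mode=mode,
        n_shared_plants=len(shared_p),
        n_shared_pollinators=len(shared_a),
    )


@dataclass
class PairwiseMatrix:
    """A symmetric site-by-site matrix of one dissimilarity component.

    ``values`` is a float array with zero diagonal; NaN marks pairs for
    which the component is undefined (possible only for OS).
    """

    site_ids: list[str]
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.site_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} site ids"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.site_ids)

    def write_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "site_id"
        df.to_csv(path)

    @classmethod
    def read_csv(cls, path, name: str = "") -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(site_ids=[str(s) for s in df.index], values=df.to_numpy(float), name=name)

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle (i < j) entries, NaN included."""
        iu = np.triu_indices(len(self.site_ids), k=1)
        return self.values[iu]


def pairwise_matrices(study: StudyData, mode: str = QUANTITATIVE) -> dict[str, PairwiseMatrix]:
    """Distance matrices for {L,U,WN,OS} x {total,turnover,richness}.

    Keys are ``"L_total"``, ``"L_turnover"``, ... OS entries are NaN where
    the pair shares no plant or no pollinator.
    """
    n = len(study.sites)
    if n < 2:
        raise ValidationError("pairwise matrices require at least 2 sites")
    ids = study.site_ids
    mats = {
        f"{comp}_{part}": np.zeros((n, n)) for comp in COMPONENTS for part in PARTS
    }
    for i in range(n):
        for j in range(i + 1, n):
            res = compare_networks(study.sites[i], study.sites[j], mode)
            for comp in COMPONENTS:
                bc = res.component(comp)
                for part in PARTS:
                    v = float("nan") if bc is None else getattr(bc, part)
                    mats[f"{comp}_{part}"][i, j] = v
                    mats[f"{comp}_{part}"][j, i] = v
    return {
        key: PairwiseMatrix(site_ids=list(ids), values=m, name=f"{key}_{mode}")
        for key, m in mats.items()
    }


def partition_proportions(
    matrix_total: PairwiseMatrix,
    matrix_turnover: PairwiseMatrix,
    matrix_richness: PairwiseMatrix,
) -> dict[str, float]:
    """Share of total beta diversity explained by turnover vs richness.

    Ratios of sums over the defined off-diagonal pairs (equivalently the
    ratio of means), which stays well defined when individual pair totals
    are 0.  NaN when the summed total is 0.
    """
    mats = (matrix_total, matrix_turnover, matrix_richness)
    ids = matrix_total.site_ids
    for m in mats[1:]:
        if m.site_ids != ids or m.values.shape != matrix_total.values.shape:
            raise ValidationError("partition matrices must share sites and shape")
    tot = matrix_total.offdiag_values()
    turn = matrix_turnover.offdiag_values()
    ok = ~np.isnan(tot)
    s_tot = float(np.sum(tot[ok]))
    if s_tot == 0:
        return {"prop_turnover": float("nan"), "prop_richness": float("nan")}
    prop_t = float(np.sum(turn[ok])) / s_tot
    return {"prop_turnover": prop_t, "prop_richness": 1.0 - prop_t}


def rewiring_fraction(mean_os_total: float, prop_os_turnover: float) -> float:
    """Fraction of interactions attributable to true rewiring.

    The product of the mean among-network dissimilarity of links between
    shared species (OS total) and the share of that dissimilarity due to
    link turnover rather than link-number differences.
    """
    for name, v in (("mean_os_total", mean_os_total), ("prop_os_turnover", prop_os_turnover)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1], got {v}")
    return mean_os_total * prop_os_turnover


def summary_table(matrices: dict[str, PairwiseMatrix], mode: str) -> pd.DataFrame:
    """Per-component summary: mean total, partition shares, pairs defined."""
    rows = []
    for comp in COMPONENTS:
        tot = matrices[f"{comp}_total"]
        vals = tot.offdiag_values()
        ok = ~np.isnan(vals)
        props = partition_proportions(
            tot, matrices[f"{comp}_turnover"], matrices[f"{comp}_richness"]
        )
        rows.append(
            {
                "component": comp,
                "mode": mode,
                "mean": float(np.mean(vals[ok])) if ok.any() else float("nan"),
                "prop_turnover": props["prop_turnover"],
                "prop_richness": props["prop_richness"],
                "n_pairs_defined": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)
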