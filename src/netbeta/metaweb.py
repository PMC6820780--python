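"""Regional metaweb construction and local-network realization (OS').

The metaweb aggregates every interaction observed across all sites and
stands for the regional pool of possible links.  Comparing a local web to
the metaweb restricted to the local species measures how much of the
regionally known link repertoire the site realizes: OS' near 0 means the
site expresses almost all links its species are known to engage in; OS'
near 1 means high local selectivity.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .beta_core import (
    BINARY,
    QUANTITATIVE,
    ABCTriple,
    BetaComponents,
    abc_binary,
    abc_quantitative,
    decompose,
)
from .io_model import Metaweb, SiteNetwork, StudyData, ValidationError
from .network_beta import species_vectors


class ConsistencyError(ValueError):
    """A local link is absent from the metaweb it is compared against."""


def build_metaweb(study: StudyData) -> Metaweb:
    """Sum link weights across all sites of a study."""
    if not study.sites:
        raise ValidationError("cannot build a metaweb from an empty study")
    links: dict = {}
    for s in study.sites:
        for k, w in s.links.items():
            links[k] = links.get(k, 0) + int(w)
    return Metaweb(
        links=links,
        plants={p for (p, _) in links},
        pollinators={a for (_, a) in links},
    )


def _restricted_pair(network: SiteNetwork, metaweb: Metaweb, strict: bool = True):
    """Local links and metaweb links restricted to the local species sets.

    With ``strict`` every local link must already be in the metaweb (the
    metaweb was built from a study containing the site); a leave-one-out
    metaweb legitimately misses links unique to the focal site.
    """
    plants, pollinators = species_vectors(network)
    local_p = {k for k, v in plants.items() if v > 0}
    local_a = set(pollinators)
    local = {k: float(w) for k, w in network.links.items()}
    if strict:
        for (p, a) in local:
            if (p, a) not in metaweb.links:
                raise ConsistencyError(
                    f"local link ({p},{a}) of site {network.site_id!r} is not in the "
                    "metaweb; the metaweb was not built from a study containing this site"
                )
    meta = {
        k: float(w)
        for k, w in metaweb.links.items()
        if k[0] in local_p and k[1] in local_a
    }
    return local, meta


def metaweb_abc(
    network: SiteNetwork, metaweb: Metaweb, mode: str = QUANTITATIVE, strict: bool = True
) -> ABCTriple:
    """The ABC triple of (local network, restricted metaweb).

    The local network is the first assemblage, so ``b_first`` counts local
    mass absent from the metaweb — structurally 0 in binary mode when the
    metaweb was built from a study containing the site.
    """
    local, meta = _restricted_pair(network, metaweb, strict=strict)
    if mode == BINARY:
        return abc_binary(local.keys(), meta.keys())
    return abc_quantitative(local, meta)


def compare_to_metaweb(
    network: SiteNetwork, metaweb: Metaweb, mode: str = QUANTITATIVE, strict: bool = True
) -> BetaComponents:
    """OS': dissimilarity of a local web to the metaweb among local species."""
    return decompose(metaweb_abc(network, metaweb, mode, strict=strict))


def metaweb_summary(
    study: StudyData,
    mode: str = QUANTITATIVE,
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Per-site OS' components plus the study mean (last row, site_id "mean").

    With ``leave_one_out`` the focal site's own links are removed from the
    aggregation before each comparison; the default keeps them in, i.e.
    the metaweb aggregates across all investigated sites.
    """
    if len(study.sites) < 2:
        raise ValidationError("metaweb summary requires at least 2 sites")
    full = build_metaweb(study)
    rows = []
    for s in study.sites:
        if leave_one_out:
            rest = StudyData(sites=[t for t in study.sites if t.site_id != s.site_id])
            if not any(t.links for t in rest.sites):
                rows.append((s.site_id, np.nan, np.nan, np.nan))
                continue
            mw = build_metaweb(rest)
            bc = compare_to_metaweb(s, mw, mode, strict=False)
        else:
            bc = compare_to_metaweb(s, full, mode)
        rows.append((s.site_id, bc.total, bc.turnover, bc.richness))
    df = pd.DataFrame(rows, columns=["site_id", "total", "turnover", "richness"])
    mean = df[["total", "turnover", "richness"]].mean()
    df.loc[len(df)] = ["mean", mean["total"], mean["turnover"], mean["richness"]]
    return df


def write_metaweb(metaweb: Metaweb, path) -> None:
    rows = [(p, a, int(w)) for (p, a), w in sorted(metaweb.links.items())]
    pd.DataFrame(rows, columns=["plant", "pollinator", "total_visits"]).to_csv(path, index=False)
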