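"""Permutation tests on distance matrices and regression-prep helpers.

:func:`permanova` is a one-way permutational multivariate analysis of
variance operating directly on a site-by-site dissimilarity matrix (the
classical adonis-style pseudo-F on squared distances, with an unrestricted
relabelling null).  :func:`epsilon_adjust` nudges exact 0/1 values into
the open unit interval so bounded responses can be fed to beta
regression.  :func:`category_summary` tabulates per-category means for
downstream model fitting with standard statistics tooling.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_model import StudyData, ValidationError
from .network_beta import PairwiseMatrix


class DesignError(ValueError):
    """The grouping design cannot support the requested test."""


def _as_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, PairwiseMatrix):
        return np.asarray(matrix.values, float), list(matrix.site_ids)
    m = np.asarray(matrix, float)
    return m, [str(i) for i in range(m.shape[0])]


def complete_case(matrix: PairwiseMatrix) -> tuple[PairwiseMatrix, list[str]]:
    """Drop whole sites until no NaN entry remains (listwise deletion).

    Sites are removed greedily by missing-entry count (ties broken by site
    order) so the retained matrix is complete.  Returns the reduced matrix
    and the dropped site ids.
    """
    vals, ids = _as_matrix(matrix)
    keep = list(range(len(ids)))
    dropped: list[str] = []
    while True:
        sub = vals[np.ix_(keep, keep)]
        nan_counts = np.isnan(sub).sum(axis=1)
        if not nan_counts.any():
            break
        worst = int(np.argmax(nan_counts))
        dropped.append(ids[keep[worst]])
        del keep[worst]
    return (
        PairwiseMatrix(
            site_ids=[ids[i] for i in keep],
            values=vals[np.ix_(keep, keep)],
            name=matrix.name if isinstance(matrix, PairwiseMatrix) else "",
        ),
        dropped,
    )


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(pseudo_F, R2) from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_among = ss_total - ss_within
    r2 = ss_among / ss_total if ss_total > 0 else float("nan")
    df_among = n_groups - 1
    df_within = n - n_groups
    if ss_within == 0.0:
        return float("inf"), r2
    f = (ss_among / df_among) / (ss_within / df_within)
    return f, r2


def permanova(
    matrix,
    labels: Sequence,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> dict:
    """One-way PERMANOVA of a distance matrix against a grouping factor.

    The matrix must be complete and symmetric (use :func:`complete_case`
    first if it has undefined entries); every group needs at least 2
    sites.  The p-value is ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``
    under unrestricted random relabelling.
    """
    vals, ids = _as_matrix(matrix)
    labels = list(labels)
    n = vals.shape[0]
    if len(labels) != n:
        raise ValidationError(f"{len(labels)} labels for a {n}-site matrix")
    if np.isnan(vals).any():
        raise ValidationError(
            "matrix contains undefined entries; drop incomplete sites first"
        )
    if not np.allclose(vals, vals.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    groups, codes = np.unique(np.asarray(labels, dtype=object), return_inverse=True)
    if len(groups) < 2:
        raise DesignError("PERMANOVA needs at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = [str(groups[g]) for g in np.flatnonzero(counts < 2)]
        raise DesignError(f"group(s) with fewer than 2 sites: {small}")

    d2 = vals ** 2
    k = len(groups)
    f_obs, r2 = _pseudo_f(d2, codes, k)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        f_p, _ = _pseudo_f(d2, perm, k)
        if f_p >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return {
        "pseudo_F": f_obs,
        "R2": float(r2),
        "p_value": p,
        "n_perm": n_perm,
        "n_sites_used": n,
        "n_groups": k,
    }


def permanova_exact(matrix, labels: Sequence) -> dict:
    """PERMANOVA p by exhaustive enumeration of all label arrangements.

    Feasible only for small n; used as an exact reference for the
    permutation approximation.
    """
    vals, _ = _as_matrix(matrix)
    groups, codes = np.unique(np.asarray(list(labels), dtype=object), return_inverse=True)
    d2 = vals ** 2
    k = len(groups)
    f_obs, r2 = _pseudo_f(d2, codes, k)
    n_arr = 0
    n_ge = 0
    for perm in set(itertools.permutations(codes)):
        n_arr += 1
        f_p, _ = _pseudo_f(d2, np.array(perm), k)
        if f_p >= f_obs:
            n_ge += 1
    return {"pseudo_F": f_obs, "R2": float(r2), "p_value": n_ge / n_arr, "n_arrangements": n_arr}


def epsilon_adjust(values: Sequence[float], eps: float = 1e-7) -> list[float]:
    """Map [0,1] responses into (0,1): 0 -> eps, 1 -> 1-eps.

    Beta regression requires strictly interior values; the shift is far
    below the resolution of the dissimilarities so relative differences
    between sites are preserved.
    """
    out = []
    for v in values:
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"value {v} outside [0, 1]")
        if v == 0.0:
            out.append(eps)
        elif v == 1.0:
            out.append(1.0 - eps)
        else:
            out.append(float(v))
    return out


def category_summary(
    study: StudyData,
    site_tables: Optional[dict[str, pd.DataFrame]] = None,
    matrices: Optional[dict[str, PairwiseMatrix]] = None,
) -> pd.DataFrame:
    """Long-format per-category means and standard errors.

    ``site_tables`` maps metric-group names to per-site data frames with a
    ``site_id`` column (e.g. network sizes, OS', CI); numeric columns
    become metrics.  ``matrices`` contributes the mean of within-category
    pairwise dissimilarities per component.  Output columns: category,
    metric, mean, se, n.
    """
    cat_of = {s.site_id: s.category for s in study.sites}
    records: list[tuple[str, str, float]] = []  # (category, metric, value)

    for name, df in (site_tables or {}).items():
        sub = df[df["site_id"].isin(cat_of)]
        for col in sub.columns:
            if col == "site_id" or not pd.api.types.is_numeric_dtype(sub[col]):
                continue
            for r in sub.itertuples(index=False):
                records.append((cat_of[str(r.site_id)], f"{name}.{col}", getattr(r, col)))

    for name, mat in (matrices or {}).items():
        ids = mat.site_ids
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                if cat_of.get(ids[i]) == cat_of.get(ids[j]):
                    v = mat.values[i, j]
                    if not math.isnan(v):
                        records.append((cat_of[ids[i]], f"within_pair.{name}", float(v)))

    if not records:
        return pd.DataFrame(columns=["category", "metric", "mean", "se", "n"])
    df = pd.DataFrame(records, columns=["category", "metric", "value"])
    out = (
        df.groupby(["category", "metric"])["value"]
        .agg(mean="mean", se=lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else float("nan"), n="count")
        .reset_index()
    )
    return out
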