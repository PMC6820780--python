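"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's code paths: they enumerate item
unions and apply the dissimilarity formulas literally.
"""

import itertools
import math


def literal_components(b_plus_c_parts):
    a, b, c = b_plus_c_parts
    d = a + b + c
    if d == 0:
        return (0.0, 0.0, 0.0)
    return ((b + c) / d, 2 * min(b, c) / d, abs(b - c) / d)


def abc_literal(x: dict, y: dict, binary: bool):
    keys = set(x) | set(y)
    if binary:
        a = sum(1 for k in keys if x.get(k, 0) > 0 and y.get(k, 0) > 0)
        b = sum(1 for k in keys if x.get(k, 0) > 0 and y.get(k, 0) == 0)
        c = sum(1 for k in keys if x.get(k, 0) == 0 and y.get(k, 0) > 0)
    else:
        a = sum(min(x.get(k, 0), y.get(k, 0)) for k in keys)
        b = sum(x.get(k, 0) for k in keys) - a
        c = sum(y.get(k, 0) for k in keys) - a
    return (a, b, c)


def brute_force_compare(links1: dict, links2: dict, abund1: dict, abund2: dict, binary: bool):
    """(L, U, WN, OS) component triples computed literally from two webs.

    ``links`` map (plant, pollinator) -> weight (weight 0 means absent);
    ``abund`` map plant -> floral abundance.  OS is None when the webs
    share no plant or no pollinator.
    """
    l1 = {k: w for k, w in links1.items() if w > 0}
    l2 = {k: w for k, w in links2.items() if w > 0}
    plants1 = dict(abund1)
    plants2 = dict(abund2)
    polls1, polls2 = {}, {}
    for (p, a), w in l1.items():
        polls1[a] = polls1.get(a, 0) + w
    for (p, a), w in l2.items():
        polls2[a] = polls2.get(a, 0) + w

    L = literal_components(abc_literal(plants1, plants2, binary))
    U = literal_components(abc_literal(polls1, polls2, binary))
    WN = literal_components(abc_literal(l1, l2, binary))

    shared_p = {p for p in plants1 if plants1[p] > 0} & {p for p in plants2 if plants2[p] > 0}
    shared_a = set(polls1) & set(polls2)
    if not shared_p or not shared_a:
        OS = None
    else:
        s1 = {k: w for k, w in l1.items() if k[0] in shared_p and k[1] in shared_a}
        s2 = {k: w for k, w in l2.items() if k[0] in shared_p and k[1] in shared_a}
        OS = literal_components(abc_literal(s1, s2, binary))
    return L, U, WN, OS


def enumerate_2x2_webs(weights=(0, 1, 2)):
    """Every 2-plant x 2-pollinator weighted web as a link dict."""
    cells = [("P1", "A1"), ("P1", "A2"), ("P2", "A1"), ("P2", "A2")]
    for ws in itertools.product(weights, repeat=4):
        yield {cell: w for cell, w in zip(cells, ws) if w > 0}
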