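"""Jaccard-family dissimilarity and its turnover / richness partition.

Every dissimilarity in the pipeline is built from a triple of shared and
unique "mass":

* binary data: ``a`` items common to both assemblages, ``b`` exclusive to
  the first, ``c`` exclusive to the second;
* quantitative data (Ruzicka, the abundance-weighted Jaccard):
  ``A = sum_i min(x_i, y_i)``, ``B = sum_i x_i - A``, ``C = sum_i y_i - A``.

The total dissimilarity ``(b+c)/(a+b+c)`` splits additively into a true
replacement (turnover) part ``2*min(b,c)/(a+b+c)`` and a richness- (or
link-number-) difference part ``|b-c|/(a+b+c)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .io_model import ValidationError

BINARY = "binary"
QUANTITATIVE = "quantitative"
MODES = (BINARY, QUANTITATIVE)


@dataclass(frozen=True)
class ABCTriple:
    """Shared / unique-to-first / unique-to-second mass of two assemblages."""

    a_shared: float
    b_first: float
    c_second: float
    mode: str

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if min(self.a_shared, self.b_first, self.c_second) < 0:
            raise ValidationError("ABC components must be non-negative")


@dataclass(frozen=True)
class BetaComponents:
    """A total dissimilarity with its additive partition.

    ``total = turnover + richness``; each lies in [0, 1].  A component may
    be NaN when the comparison is undefined (e.g. no shared species).
    """

    total: float
    turnover: float
    richness: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.total)


MISSING = BetaComponents(float("nan"), float("nan"), float("nan"))


def abc_binary(items_x: Iterable, items_y: Iterable) -> ABCTriple:
    """Presence/absence triple: a = |X∩Y|, b = |X\\Y|, c = |Y\\X|."""
    x, y = set(items_x), set(items_y)
    return ABCTriple(len(x & y), len(x - y), len(y - x), BINARY)


def abc_quantitative(x: Mapping, y: Mapping) -> ABCTriple:
    """Ruzicka triple from two abundance maps (absent key means 0)."""
    for m in (x, y):
        for k, v in m.items():
            if v < 0:
                raise ValidationError(f"negative abundance for {k!r}: {v}")
    a = sum(min(x.get(k, 0.0), y.get(k, 0.0)) for k in x.keys() & y.keys())
    b = sum(x.values()) - a
    c = sum(y.values()) - a
    # clamp tiny negative rounding residue from the subtractions
    return ABCTriple(a, max(b, 0.0), max(c, 0.0), QUANTITATIVE)


def decompose(abc: ABCTriple) -> BetaComponents:
    """Total dissimilarity plus its turnover and richness-difference parts.

    Two empty assemblages (a = b = c = 0) are treated as identical: all
    components are 0.
    """
    a, b, c = abc.a_shared, abc.b_first, abc.c_second
    d = a + b + c
    if d == 0:
        return BetaComponents(0.0, 0.0, 0.0)
    return BetaComponents(
        total=(b + c) / d,
        turnover=2.0 * min(b, c) / d,
        richness=abs(b - c) / d,
    )
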