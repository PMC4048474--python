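"""Chromosome telomere state and the replication rules acting on it.

A chromosome is reduced to the four telomere lengths at its ends: the two
antiparallel DNA strands each carry a telomere at the left and at the right
end.  We store them as a 2x2 "quartet"

    ( top_left     top_right  )
    ( bottom_left  bottom_right )

with the convention that when the *top* strand serves as template, its
newly synthesised complement is incomplete at the RIGHT end, and when the
*bottom* strand serves as template the complement is incomplete at the
LEFT end.  Under the canonical parent state (m, n / m, n-y) this
convention yields one daughter identical to the parent, (m, n / m, n-y),
and one shorter daughter, (m-y, n-y / m, n-y) — the end-replication
problem.

A chromosome has no intrinsic left/right handedness, so the shorter
daughter is returned re-oriented (both ends and both strands swapped)
into the same canonical presentation: (n-y, m / n-y, m-y').  The
re-orientation carries real dynamical content: it is what makes *both*
ends of a lineage erode under repeated replication.  Were the orientation
held fixed, the template strand of the shorter daughter would never be
eroded and a non-senescent chromosome could copy itself indefinitely,
which contradicts the approach of whole populations to senescence.

Werner's syndrome is modelled as an extra deletion of x basepairs at one
of the four strand/end positions, chosen uniformly: the deletion removes x
from both rows of one column (left or right) of one daughter.  A deletion
that would drive a telomere length negative is physically unrealistic; the
replication attempt then fails and the parent chromosome remains
undivided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .rate_models import LossModel, loss_y

__all__ = [
    "ChromosomeQuartet",
    "DaughterPair",
    "DivisionOutcome",
    "NORMAL_EVENT",
    "WERNER_VARIANTS",
    "chromosome_mean_length",
    "is_senescent",
    "replicate_normal",
    "replicate_werner",
    "sample_replication_event",
]

#: Event code for a normal (non-Werner) replication.
NORMAL_EVENT = 0
#: Werner deletion variants, labelled by the printed replication rules for
#: a canonical parent (m, n / m, n-y): 1 = extra deletion at the n-end of
#: the identical daughter, 2 = at its m-end, 3 = at the n-end of the
#: shorter daughter, 4 = at its m-end.
WERNER_VARIANTS = (1, 2, 3, 4)


@dataclass(frozen=True)
class ChromosomeQuartet:
    """The four telomere lengths of one chromosome, in basepairs."""

    top_left: float
    top_right: float
    bottom_left: float
    bottom_right: float

    def __post_init__(self) -> None:
        if min(self) < 0:
            raise ValueError(f"telomere lengths must be >= 0; got {self}")

    def __iter__(self):
        yield self.top_left
        yield self.top_right
        yield self.bottom_left
        yield self.bottom_right

    def as_array(self) -> np.ndarray:
        """Entries in (top_left, top_right, bottom_left, bottom_right) order."""
        return np.array(list(self), dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ChromosomeQuartet":
        tl, tr, bl, br = (float(v) for v in arr)
        return cls(tl, tr, bl, br)


class DaughterPair(NamedTuple):
    """The two products of a successful replication (order as written:
    shorter daughter first, identical daughter second)."""

    shorter: ChromosomeQuartet
    identical: ChromosomeQuartet


@dataclass(frozen=True)
class DivisionOutcome:
    """Result of a replication attempt: either two daughters, or no
    division (the parent retained unchanged)."""

    divided: bool
    daughters: DaughterPair | None = None

    def __post_init__(self) -> None:
        if self.divided and self.daughters is None:
            raise ValueError("a divided outcome must carry daughters")


def chromosome_mean_length(chrom: ChromosomeQuartet) -> float:
    """Arithmetic mean of the four telomere lengths."""
    return (
        chrom.top_left + chrom.top_right + chrom.bottom_left + chrom.bottom_right
    ) / 4.0


def is_senescent(chrom: ChromosomeQuartet, threshold: float) -> bool:
    """True iff any telomere has *reached* the critical length.

    A chromosome becomes permanently non-replicative as soon as its
    shortest telomere falls to or below ``threshold`` (min <= threshold).
    Reaching the critical length, not crossing strictly below it, is what
    stops division: with the canonical 200 bp loss and threshold, telomere
    lengths step through exact multiples of 200 and hit the threshold
    exactly.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return min(chrom) <= threshold


def replicate_normal(chrom: ChromosomeQuartet, loss: LossModel) -> DaughterPair:
    """Apply the normal-aging replication rule.

    Each parent strand templates one daughter.  The top strand's complement
    loses y at the right end, giving the identical daughter; the bottom
    strand's complement loses y at the left end, giving the shorter
    daughter, which is then re-oriented into the canonical presentation
    (see the module docstring).  The loss is evaluated at the current
    length of the telomere being eroded, and new entries are clamped at
    zero.  The caller is responsible for only replicating non-senescent
    chromosomes.
    """
    y_right = loss_y(chrom.top_right, loss)
    y_left = loss_y(chrom.bottom_left, loss)
    identical = ChromosomeQuartet(
        chrom.top_left,
        chrom.top_right,
        chrom.top_left,
        max(chrom.top_right - y_right, 0.0),
    )
    # raw form (bottom_left - y, bottom_right / bottom_left, bottom_right),
    # re-oriented by swapping both ends and both strands
    shorter = ChromosomeQuartet(
        chrom.bottom_right,
        chrom.bottom_left,
        chrom.bottom_right,
        max(chrom.bottom_left - y_left, 0.0),
    )
    return DaughterPair(shorter=shorter, identical=identical)


def sample_replication_event(rng: np.random.Generator, p_w: float) -> int:
    """Draw the replication event type for one chromosome.

    Returns ``NORMAL_EVENT`` (0) with probability 1 - p_w, otherwise one of
    the four Werner variants 1..4, each with conditional probability 1/4.
    The draw order (uniform r, then the variant index) is fixed so that
    simulations are reproducible for a given seed.
    """
    if not 0.0 <= p_w <= 1.0:
        raise ValueError(f"p_w must lie in [0, 1]; got {p_w}")
    r = rng.random()
    if r >= p_w:
        return NORMAL_EVENT
    return int(rng.integers(1, 5))


# Werner variant -> (daughter index in DaughterPair, entry indices of the
# deleted column).  Entry order: (top_left, top_right, bottom_left,
# bottom_right); left column = (0, 2), right column = (1, 3).  Variants 3
# and 4 delete at the shorter daughter's n- and m-ends respectively; after
# the canonical re-orientation of the shorter daughter the n-end sits in
# the left column and the m-end in the right column.
_VARIANT_TABLE: dict[int, tuple[int, tuple[int, int]]] = {
    1: (1, (1, 3)),  # n-end (right) of the identical daughter
    2: (1, (0, 2)),  # m-end (left) of the identical daughter
    3: (0, (0, 2)),  # n-end of the shorter daughter
    4: (0, (1, 3)),  # m-end of the shorter daughter
}


def replicate_werner(
    chrom: ChromosomeQuartet,
    loss: LossModel,
    x: float,
    variant: int,
    floor: float = 0.0,
) -> DivisionOutcome:
    """Attempt replication with a Werner deletion of ``x`` bp.

    The normal-aging daughters are formed first; the chosen variant then
    removes a further ``x`` basepairs from both strands of one end of one
    daughter.  A deletion that would leave the modified daughter with any
    telomere below ``floor`` is physically unrealistic: the outcome is
    infeasible, no division occurs and the parent is retained.  The
    population engine uses the senescence threshold as the floor; the
    default floor of 0 corresponds to working in threshold-subtracted
    lengths.  With x = 0 every variant reduces exactly to
    :func:`replicate_normal` (there is nothing to delete, so feasibility
    is not at issue).
    """
    if x < 0:
        raise ValueError(f"Werner deletion x must be >= 0; got {x}")
    if variant not in _VARIANT_TABLE:
        raise ValueError(f"variant must be one of {WERNER_VARIANTS}; got {variant}")
    pair = replicate_normal(chrom, loss)
    if x == 0:
        return DivisionOutcome(divided=True, daughters=pair)
    which, cols = _VARIANT_TABLE[variant]
    entries = list(pair[which])
    for c in cols:
        entries[c] -= x
    if min(entries) < floor:
        return DivisionOutcome(divided=False)
    modified = ChromosomeQuartet(*entries)
    daughters = (
        DaughterPair(shorter=modified, identical=pair.identical)
        if which == 0
        else DaughterPair(shorter=pair.shorter, identical=modified)
    )
    return DivisionOutcome(divided=True, daughters=daughters)
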