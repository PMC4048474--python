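"""Parametric loss and division-probability models, with the named presets.

The simulator distinguishes four families of replication rules for normal
aging.  Telomere loss per replication event is linear in the length of the
telomere being eroded,

    y(n) = y0 + y1 * n,

and the probability that a non-senescent chromosome (or cell) divides in a
given generation is a power law in telomere length,

    P_div(n) = (a + b * n) ** alpha,        0 <= alpha <= 1.

Case A (alpha = 0) divides whenever possible; Case B has a genuine
length-dependent division probability.  Cases A1/B1 use constant loss
(y1 = 0); A2/B2 use length-dependent loss.  All presets are calibrated so
that the expected loss per replication, P_div(n) * y(n), is roughly 200 bp
when the population is half-way to senescence (n ~ 3000 bp).

Werner's syndrome is parameterised by (p_w, x): with probability p_w a
replication event deletes an additional x basepairs from one chromosome
end.  The tabulated pairs keep the expected extra loss p_w * x at 200 bp so
that different deletion regimes are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LossModel",
    "DivisionModel",
    "WernerParams",
    "ModelSet",
    "loss_y",
    "p_div",
    "preset_case",
    "preset_werner",
    "PRESET_NAMES",
    "WERNER_TABLE",
]


@dataclass(frozen=True)
class LossModel:
    """Linear telomere loss y(n) = y0 + y1*n, in basepairs."""

    y0: float
    y1: float = 0.0

    def __post_init__(self) -> None:
        if self.y0 < 0 or self.y1 < 0:
            raise ValueError(f"loss model requires y0, y1 >= 0; got {self}")


@dataclass(frozen=True)
class DivisionModel:
    """Division probability P_div(n) = clamp(a + b*n)**alpha, in [0, 1]."""

    a: float
    b: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1]; got {self.alpha}")


@dataclass(frozen=True)
class WernerParams:
    """Probability p_w of an extra deletion of x basepairs per replication."""

    p_w: float = 0.0
    x: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_w <= 1.0:
            raise ValueError(f"p_w must lie in [0, 1]; got {self.p_w}")
        if self.x < 0:
            raise ValueError(f"x must be >= 0; got {self.x}")


@dataclass(frozen=True)
class ModelSet:
    """Bundle of loss, division and Werner parameters for one simulation."""

    loss: LossModel
    division: DivisionModel
    werner: WernerParams = field(default_factory=WernerParams)
    threshold: float = 200.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError(f"threshold must be >= 0; got {self.threshold}")


def loss_y(n, loss: LossModel):
    """Basepairs lost from a telomere of length ``n`` in one replication.

    Accepts a scalar or ndarray ``n`` (broadcasts).  Negative lengths are
    rejected: the loss law is only defined for physical telomere lengths.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("telomere length n must be >= 0")
    out = loss.y0 + loss.y1 * n
    return float(out) if out.ndim == 0 else out


def p_div(n, division: DivisionModel):
    """Division probability at telomere length ``n``, clamped to [0, 1].

    The base a + b*n is clamped at 0 before exponentiation so fractional
    exponents never see a negative base; the result is then clamped to
    [0, 1].  With alpha = 0 the probability is identically 1 (the Case A
    limit, including at the clamped base 0**0 == 1).
    """
    n = np.asarray(n, dtype=float)
    base = np.clip(division.a + division.b * n, 0.0, None)
    out = np.clip(base ** division.alpha, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


# (a, b) shared by every Case B preset: P_div = (n - 200) / 5750, which is 1
# at the initial mean length 5950 and 0 at the 200 bp senescence threshold.
_B_A = -200.0 / 5750.0
_B_B = 1.0 / 5750.0

# name -> (alpha, y0, y1)
_CASE_TABLE: dict[str, tuple[float, float, float]] = {
    "A1": (0.0, 200.0, 0.0),
    "A2": (0.0, 100.0, 1.0 / 30.0),
    "B1.1": (0.25, 240.0, 0.0),
    "B1.2": (0.5, 288.0, 0.0),
    "B1.3": (0.75, 345.0, 0.0),
    "B1.4": (1.0, 414.0, 0.0),
    "B2.1": (0.25, 120.0, 1.0 / 25.0),
    "B2.2": (0.5, 144.0, 1.0 / 21.0),
    "B2.3": (0.75, 172.5, 1.0 / 17.0),
    "B2.4": (1.0, 207.0, 1.0 / 14.0),
}

PRESET_NAMES: tuple[str, ...] = tuple(_CASE_TABLE) + ("zhang_fit",)

#: (p_w, x) pairs with p_w * x = 200 (to printed rounding); (0, 0) is
#: normal aging.
WERNER_TABLE: dict[float, float] = {
    0.0: 0.0,
    0.2: 1000.0,
    0.4: 500.0,
    0.6: 333.0,
    0.8: 250.0,
    1.0: 200.0,
}

#: Initial telomere length (bp) used with the ``zhang_fit`` preset.
ZHANG_INITIAL_LENGTH = 12200.0


def preset_case(name: str) -> ModelSet:
    """Return the ModelSet for a named case preset.

    Valid names are ``A1``, ``A2``, ``B1.1``..``B1.4``, ``B2.1``..``B2.4``
    and ``zhang_fit`` (the fit to cultured-fibroblast data, with loss
    Y(n) = 10 + 0.043 n and P_div(n) = (n/12200 - 0.03)**0.25, intended for
    an initial length of 12,200 bp).
    """
    if name == "zhang_fit":
        return ModelSet(
            loss=LossModel(10.0, 0.043),
            division=DivisionModel(-0.03, 1.0 / 12200.0, 0.25),
            name=name,
        )
    try:
        alpha, y0, y1 = _CASE_TABLE[name]
    except KeyError:
        raise ValueError(
            f"unknown case preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None
    return ModelSet(
        loss=LossModel(y0, y1),
        division=DivisionModel(_B_A, _B_B, alpha),
        name=name,
    )


def preset_werner(p_w: float) -> WernerParams:
    """Return the tabulated (p_w, x) pair for a listed p_w.

    Only the tabulated probabilities {0, 0.2, 0.4, 0.6, 0.8, 1} are
    accepted; arbitrary pairs can always be built directly as
    ``WernerParams(p_w, x)``.
    """
    try:
        x = WERNER_TABLE[float(p_w)]
    except (KeyError, TypeError):
        raise ValueError(
            f"p_w={p_w!r} is not tabulated; listed values: "
            f"{sorted(WERNER_TABLE)} (construct WernerParams directly for "
            "other pairs)"
        ) from None
    return WernerParams(float(p_w), x)
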