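"""Drift-barrier selection calculus for germline mutator alleles.

A mutator allele adding U extra mutations per genome per generation carries
an expected selection coefficient S(U) = U * E[s], where E[s] is the mean
fitness cost per extra mutation.  Selection purges alleles with
S > 1/(2 Ne), giving the near-neutrality threshold U* = 1/(2 Ne E[s]) for a
"nonclocklike" mutator whose load is fixed per generation.  A "clocklike"
mutator instead adds k mutations per genome per year of postpuberty
reproductive life, accumulating U = k * g * (1-p) per generation, so its
threshold is k* = 1/(2 g Ne (1-p) E[s]): the efficacy of selection against
clocklike mutators is governed by the product g*Ne rather than Ne alone.

With Ne declining as a power law Ne = C * g^gamma, the product g*Ne scales
as g^(1+gamma); for gamma > -1 it still increases with generation time, so
long-lived species feel stronger selection against clocklike mutators even
as their Ne shrinks.  Effective population size is obtained from nucleotide
diversity as Ne = pi / (4 mu).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "MutatorEffect",
    "PopulationContext",
    "selection_coefficient",
    "neutrality_threshold",
    "effective_size_from_diversity",
    "gNe_scaling_exponent",
    "per_year_rate",
]

Flavor = Literal["clocklike", "nonclocklike"]


@dataclass(frozen=True)
class MutatorEffect:
    """A mutator allele's per-genome effect and mean per-mutation cost.

    ``nonclocklike``: ``U_extra`` mutations per generation regardless of
    parental age.  ``clocklike``: ``k_extra`` mutations per year of
    postpuberty reproductive life.
    """

    Es: float
    flavor: Flavor
    U_extra: float | None = None
    k_extra: float | None = None

    def __post_init__(self) -> None:
        if self.flavor == "nonclocklike":
            if self.U_extra is None or self.k_extra is not None:
                raise ValueError("nonclocklike mutators set U_extra only")
        elif self.flavor == "clocklike":
            if self.k_extra is None or self.U_extra is not None:
                raise ValueError("clocklike mutators set k_extra only")
        else:
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if self.Es < 0:
            raise ValueError("E[s] must be nonnegative")


@dataclass(frozen=True)
class PopulationContext:
    """Population-level quantities entering the selection calculus."""

    Ne: float
    g: float = 1.0
    p: float = 0.0
    pi: float | None = None
    gamma: float | None = None
    C_const: float | None = None

    def __post_init__(self) -> None:
        if self.Ne <= 0:
            raise ValueError("Ne must be positive")
        if not 0.0 <= self.p < 1.0:
            raise ValueError("p must lie in [0, 1)")


def selection_coefficient(effect: MutatorEffect, ctx: PopulationContext) -> float:
    """Expected selection coefficient of the mutator in this population.

    Nonclocklike: U * E[s].  Clocklike: k * g * (1-p) * E[s] (the per-year
    increment integrated over the postpuberty reproductive span).
    """
    if effect.flavor == "nonclocklike":
        return effect.U_extra * effect.Es
    return effect.k_extra * ctx.g * (1.0 - ctx.p) * effect.Es


def neutrality_threshold(flavor: Flavor, ctx: PopulationContext, Es: float) -> float:
    """Smallest mutator effect that selection can purge, 1/(2 Ne) in S units.

    Nonclocklike: U* = 1/(2 Ne E[s]).
    Clocklike:    k* = 1/(2 g Ne (1-p) E[s]).
    """
    if Es <= 0:
        raise ZeroDivisionError("E[s] must be positive for a finite threshold")
    if flavor == "nonclocklike":
        return 1.0 / (2.0 * ctx.Ne * Es)
    if flavor == "clocklike":
        if ctx.g <= 0:
            raise ValueError("clocklike threshold needs g > 0")
        return 1.0 / (2.0 * ctx.g * ctx.Ne * (1.0 - ctx.p) * Es)
    raise ValueError(f"unknown flavor {flavor!r}")


def effective_size_from_diversity(pi: float, mu: float) -> float:
    """Effective population size Ne = pi / (4 mu) from nucleotide diversity."""
    if mu <= 0:
        raise ZeroDivisionError("mu must be positive")
    if pi < 0:
        raise ValueError("pi must be nonnegative")
    return pi / (4.0 * mu)


def gNe_scaling_exponent(gamma: float) -> float:
    """Exponent of g in g*Ne when Ne scales as g^gamma: returns 1 + gamma.

    Positive values mean g*Ne — and with it the strength of selection
    against clocklike mutators — grows with generation time.
    """
    return 1.0 + gamma


def per_year_rate(mu, g):
    """Per-year mutation rate mu_y = mu / g."""
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0):
        raise ValueError("generation time must be positive")
    out = np.asarray(mu, dtype=float) / g
    return out if out.ndim else float(out)
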