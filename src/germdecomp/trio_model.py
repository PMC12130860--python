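"""Germline mutation-rate decomposition algebra.

The per-site per-generation germline mutation rate is decomposed as

    mu = mu_E + (A_P - P) * mu_S + (A_M - P) * mu_O

where ``mu_E`` is the cumulative "early" (embryonic + prepuberty) load per
generation, ``mu_S`` and ``mu_O`` are the per-year rates in postpuberty
spermatogonia and oocytes, ``A_P``/``A_M`` are paternal/maternal ages at
conception and ``P`` the age of puberty.  With the sperm fraction
``rho = mu_S / (mu_O + mu_S)`` the two parental ages collapse into a single
weighted displacement ``A_bar = rho*A_P + (1-rho)*A_M - P`` and the expected
mutation count of a trio with callable haploid length L becomes
``2L * (mu_E + (mu_O + mu_S) * A_bar)`` — the identity-link Poisson mean used
throughout the regression module.

All rates in stored types are per-site; genome-length factors enter only
inside likelihood evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RateDecomposition",
    "InvalidMeanError",
    "weighted_parental_age",
    "expected_count",
    "per_generation_rate",
]


class InvalidMeanError(ValueError):
    """A nonpositive expected count: parameters incompatible with this trio."""


@dataclass(frozen=True)
class RateDecomposition:
    """The pair (mu_E per generation, mu_O+mu_S per year) for one species.

    ``sperm_fraction`` is rho = mu_S/(mu_O+mu_S); ``puberty_age`` the P used
    when forming weighted parental ages.
    """

    mu_E: float
    mu_OS: float
    sperm_fraction: float = 0.75
    puberty_age: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_E < 0 or self.mu_OS < 0:
            raise ValueError("rates must be nonnegative")
        if not 0.0 <= self.sperm_fraction <= 1.0:
            raise ValueError("sperm fraction must lie in [0, 1]")

    @property
    def mu_S(self) -> float:
        return self.sperm_fraction * self.mu_OS

    @property
    def mu_O(self) -> float:
        return (1.0 - self.sperm_fraction) * self.mu_OS


def weighted_parental_age(paternal_age, maternal_age, rho: float, puberty_age: float):
    """Sperm-fraction-weighted mean parental age, displaced from puberty.

    Returns ``rho*A_P + (1-rho)*A_M - P``.  A negative value (reproduction
    before the nominal species-level puberty age) is permitted with a
    warning, since P is an approximation, not a per-individual quantity.
    """
    paternal_age = np.asarray(paternal_age, dtype=float)
    maternal_age = np.asarray(maternal_age, dtype=float)
    if np.any(paternal_age <= 0) or np.any(maternal_age <= 0):
        raise ValueError("parental ages must be positive")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    a_bar = rho * paternal_age + (1.0 - rho) * maternal_age - puberty_age
    if np.any(a_bar < 0):
        logger.warning(
            "weighted parental age below puberty age P=%s for %d record(s)",
            puberty_age,
            int(np.sum(a_bar < 0)),
        )
    return a_bar if a_bar.ndim else float(a_bar)


def expected_count(mu_E: float, mu_OS: float, a_bar, callable_bp):
    """Expected corrected mutation count, ``2L*(mu_E + mu_OS*A_bar)``.

    Raises :class:`InvalidMeanError` if any resulting Poisson mean is
    nonpositive.
    """
    a_bar = np.asarray(a_bar, dtype=float)
    L = np.asarray(callable_bp, dtype=float)
    if np.any(L <= 0):
        raise ValueError("callable genome length must be positive")
    mean = 2.0 * L * (mu_E + mu_OS * a_bar)
    if np.any(mean <= 0):
        raise InvalidMeanError(
            "expected count is nonpositive; rate parameters are incompatible "
            "with this trio's weighted parental age"
        )
    return mean if mean.ndim else float(mean)


def per_generation_rate(decomposition: RateDecomposition, generation_time):
    """Per-site per-generation rate at parental ages equal to g.

    Evaluates ``mu_E + (g - P) * (mu_O + mu_S)``; requires g >= P.
    """
    g = np.asarray(generation_time, dtype=float)
    if np.any(g < decomposition.puberty_age):
        raise ValueError(
            f"generation time {generation_time} below puberty age "
            f"{decomposition.puberty_age}"
        )
    mu = decomposition.mu_E + (g - decomposition.puberty_age) * decomposition.mu_OS
    return mu if mu.ndim else float(mu)
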