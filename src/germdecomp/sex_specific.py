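"""Sex-specific mutation parameters from partially phased trio mutations.

A trio's de novo mutations split into maternally phased (U_M), paternally
phased (U_P) and unphased (U_X) counts.  With per-genome parameters mu_E,M
and mu_E,P (maternal/paternal halves of the prepuberty load) and per-year
per-genome rates mu_O (oocyte) and mu_S (spermatogonial), the expected
maternal and paternal loads of trio i are

    m_i = mu_E,M + mu_O * (A_M,i - P)      p_i = mu_E,P + mu_S * (A_P,i - P)

and, up to an additive constant, the log-likelihood of the observed counts is

    sum_i  U_M,i log m_i + U_P,i log p_i + U_X,i log(m_i + p_i) - (m_i + p_i).

The likelihood carries no genome-length factor, so parameters are estimated
per genome at a reference callable length and converted to per-site rates by
dividing by it; heterogeneous per-trio callable lengths enter by scaling each
trio's means by L_i / L_ref.  The maximized parameters give the sperm
fraction rho = mu_S / (mu_O + mu_S) that weights paternal age in the
downstream Poisson regression.

A grid-search alternative scans rho over [0, 1] and picks the value
maximizing McFadden's pseudo-R^2 of the identity-link Poisson regression —
useful when very few mutations are phased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .io import TrioRecord
from .rate_regression import RateRegression, SlopeUnidentifiableError

logger = logging.getLogger(__name__)

__all__ = [
    "SexSpecificParams",
    "PhaseFitResult",
    "RhoGridResult",
    "RhoUnidentifiableError",
    "phase_loglik",
    "SexSpecificMLE",
    "fit_sex_specific",
    "grid_search_rho",
    "filter_trios",
]

#: Default fallback sperm fraction for unphased-only datasets (large human
#: pedigree value).
DEFAULT_RHO = 0.75


class RhoUnidentifiableError(ValueError):
    """No phased mutations at all: the sperm fraction cannot be estimated."""


@dataclass(frozen=True)
class SexSpecificParams:
    """Per-genome sex-specific rate parameters at a reference callable length.

    ``muEM_genome``/``muEP_genome`` are expected maternal/paternal prepuberty
    mutations per genome per generation; ``muS_genome``/``muO_genome`` the
    paternal/maternal per-year increments.  Divide by ``reference_L`` for
    per-site rates.
    """

    muEM_genome: float
    muEP_genome: float
    muS_genome: float
    muO_genome: float
    reference_L: float

    def __post_init__(self) -> None:
        for name in ("muEM_genome", "muEP_genome", "muS_genome", "muO_genome"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def rho(self) -> float:
        denom = self.muS_genome + self.muO_genome
        return self.muS_genome / denom if denom > 0 else float("nan")


@dataclass(frozen=True)
class PhaseFitResult:
    params: SexSpecificParams
    loglik: float
    rho: float
    converged: bool
    boundary_flags: dict[str, bool]
    age_variation_warning: bool = False


@dataclass(frozen=True)
class RhoGridResult:
    rho_best: float
    grid: np.ndarray
    pseudo_R2: np.ndarray
    no_power: bool


def filter_trios(
    trios: Sequence[TrioRecord], predicate: Callable[[TrioRecord], bool]
) -> list[TrioRecord]:
    """Generic trio filter (e.g. restrict to mothers below a given age)."""
    return [t for t in trios if predicate(t)]


def _arrays(trios: Sequence[TrioRecord], puberty_age: float):
    UM = np.array([t.n_maternal_phased for t in trios], dtype=float)
    UP = np.array([t.n_paternal_phased for t in trios], dtype=float)
    UX = np.array([t.n_unphased for t in trios], dtype=float)
    AM = np.array([t.maternal_age for t in trios], dtype=float) - puberty_age
    AP = np.array([t.paternal_age for t in trios], dtype=float) - puberty_age
    L = np.array([t.callable_haploid_bp for t in trios], dtype=float)
    return UM, UP, UX, AM, AP, L


def phase_loglik(
    params: SexSpecificParams, trios: Sequence[TrioRecord], puberty_age: float
) -> float:
    """Log-likelihood of the phased/unphased counts (no factorial term).

    Returns -inf (rather than raising) when a nonpositive expected load
    meets a positive count, so optimizers can back away gracefully.
    """
    UM, UP, UX, AM, AP, L = _arrays(trios, puberty_age)
    s = L / params.reference_L
    m = s * (params.muEM_genome + params.muO_genome * AM)
    p = s * (params.muEP_genome + params.muS_genome * AP)
    tot = m + p
    if np.any((m <= 0) & (UM > 0)) or np.any((p <= 0) & (UP > 0)):
        return -np.inf
    if np.any(tot <= 0):
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (
            np.where(UM > 0, UM * np.log(m), 0.0)
            + np.where(UP > 0, UP * np.log(p), 0.0)
            + np.where(UX > 0, UX * np.log(tot), 0.0)
            - tot
        )
    return float(np.sum(terms))


class SexSpecificMLE(BaseEstimator):
    """Maximum-likelihood estimator of (mu_E,M, mu_E,P, mu_S, mu_O).

    Optimization is quasi-Newton on log-parameters (guaranteeing
    nonnegativity) with a floor of ``floor`` per-genome mutations and
    ``n_starts`` multi-starts seeded by ``random_state``.

    Attributes after ``fit``: ``params_`` (:class:`SexSpecificParams`),
    ``rho_``, ``loglik_``, ``converged_``, ``boundary_flags_``.
    """

    _names = ("muEM_genome", "muEP_genome", "muS_genome", "muO_genome")

    def __init__(
        self,
        puberty_age: float = 0.0,
        reference_L: float | None = None,
        n_starts: int = 5,
        random_state: int = 0,
        floor: float = 1e-12,
    ):
        self.puberty_age = puberty_age
        self.reference_L = reference_L
        self.n_starts = n_starts
        self.random_state = random_state
        self.floor = floor

    def _moment_start(self, trios: Sequence[TrioRecord]) -> np.ndarray:
        UM, UP, UX, AM, AP, L = _arrays(trios, self.puberty_age)
        U = UM + UP + UX
        fM = (np.sum(UM) + 1.0) / (np.sum(UM) + np.sum(UP) + 2.0)
        cM = max(fM * np.mean(U), 0.1)
        cP = max((1.0 - fM) * np.mean(U), 0.1)
        am = max(np.mean(AM), 0.5)
        ap = max(np.mean(AP), 0.5)
        return np.array([0.5 * cM, 0.5 * cP, 0.5 * cP / ap, 0.5 * cM / am])

    def fit(self, trios: Sequence[TrioRecord], y=None) -> "SexSpecificMLE":
        UM, UP, UX, AM, AP, L = _arrays(trios, self.puberty_age)
        if np.sum(UM) + np.sum(UP) == 0:
            raise RhoUnidentifiableError(
                "all mutations are unphased; rho is unidentifiable — "
                f"fall back to rho={DEFAULT_RHO}"
            )
        ref_L = self.reference_L if self.reference_L is not None else float(np.mean(L))
        age_flat = np.ptp(AM) < 1e-9 and np.ptp(AP) < 1e-9
        if age_flat:
            logger.warning("no parental-age variation: slopes weakly identified")

        def make(theta: np.ndarray) -> SexSpecificParams:
            vals = np.exp(theta)
            return SexSpecificParams(*vals, reference_L=ref_L)

        def neg(theta: np.ndarray) -> float:
            ll = phase_loglik(make(theta), trios, self.puberty_age)
            return 1e12 if not np.isfinite(ll) else -ll

        rng = np.random.default_rng(self.random_state)
        lo = np.log(self.floor)
        hi = np.log(1e6)
        x0 = np.clip(np.log(np.maximum(self._moment_start(trios), self.floor)), lo, hi)
        best = None
        for k in range(max(1, self.n_starts)):
            start = x0 if k == 0 else np.clip(x0 + rng.normal(0, 1.0, 4), lo, hi)
            res = optimize.minimize(
                neg, start, method="L-BFGS-B", bounds=[(lo, hi)] * 4
            )
            if best is None or res.fun < best.fun:
                best = res
        params = make(best.x)
        self.params_ = params
        self.loglik_ = -float(best.fun)
        self.rho_ = params.rho
        self.converged_ = bool(best.success)
        self.boundary_flags_ = {
            name: bool(val <= 10.0 * self.floor)
            for name, val in zip(
                self._names,
                (params.muEM_genome, params.muEP_genome, params.muS_genome, params.muO_genome),
            )
        }
        self.age_variation_warning_ = age_flat
        return self

    @property
    def result_(self) -> PhaseFitResult:
        return PhaseFitResult(
            params=self.params_,
            loglik=self.loglik_,
            rho=self.rho_,
            converged=self.converged_,
            boundary_flags=self.boundary_flags_,
            age_variation_warning=self.age_variation_warning_,
        )


def fit_sex_specific(
    trios: Sequence[TrioRecord],
    puberty_age: float = 0.0,
    seed: int = 0,
    reference_L: float | None = None,
    n_starts: int = 5,
) -> PhaseFitResult:
    """Functional wrapper around :class:`SexSpecificMLE`."""
    est = SexSpecificMLE(
        puberty_age=puberty_age,
        reference_L=reference_L,
        n_starts=n_starts,
        random_state=seed,
    ).fit(trios)
    return est.result_


def grid_search_rho(
    trios: Sequence[TrioRecord],
    puberty_age: float = 0.0,
    grid_step: float = 0.01,
) -> RhoGridResult:
    """Scan rho over [0, 1]; pick the pseudo-R^2-maximizing value.

    For each rho the weighted parental age is recomputed and the
    identity-link Poisson regression refitted; McFadden's pseudo-R^2
    (1 - loglik/loglik_null) measures how well that weighting explains the
    counts.  Ties resolve to the smallest rho; a flat curve (e.g. identical
    paternal and maternal ages in every trio) sets ``no_power``.
    """
    if len(trios) < 3:
        raise ValueError("need at least three trios for the rho grid search")
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2.0, grid_step), 10)
    curve = np.empty_like(grid)
    for i, rho in enumerate(grid):
        try:
            fit = RateRegression(rho=float(rho), puberty_age=puberty_age).fit(trios)
            curve[i] = fit.pseudo_R2_
        except SlopeUnidentifiableError:
            curve[i] = -np.inf
    finite = np.isfinite(curve)
    if not np.any(finite):
        raise SlopeUnidentifiableError("no rho value yields an identifiable regression")
    no_power = bool(np.ptp(curve[finite]) < 1e-10)
    best_idx = int(np.argmax(curve))  # first occurrence = smallest rho on ties
    return RhoGridResult(
        rho_best=float(grid[best_idx]), grid=grid, pseudo_R2=curve, no_power=no_power
    )
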