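"""Identity-link Poisson regression of mutation counts on weighted parental age.

For trio i with corrected count U_i, callable haploid length L_i and weighted
parental-age displacement A_i, the model is

    U_i ~ Poisson( 2 L_i * (mu_E + mu_OS * A_i) )

so the intercept is the prepuberty load mu_E and the slope the postpuberty
germ-cell rate mu_OS = mu_O + mu_S.  The additive mean rules out the
canonical log link, so the likelihood is maximized directly by a damped
Newton iteration constrained to keep every fitted mean positive and
mu_E >= 0.  Counts may be non-integer (multiplicative FP/FN corrections);
the log-likelihood uses the continuous extension lgamma(U+1) of the
factorial term, which shifts the likelihood by a constant and leaves the
maximizer unchanged.

Uncertainty comes from a nonparametric bootstrap over trios; batch effects
across source datasets are tested with a likelihood-ratio chi-square
comparing pooled and per-dataset parameter sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .io import TrioRecord
from .trio_model import RateDecomposition, weighted_parental_age

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionFit",
    "BootstrapResult",
    "RateRegression",
    "SlopeUnidentifiableError",
    "fit_rate_regression",
    "bootstrap_rates",
    "batch_effect_lrt",
]


class SlopeUnidentifiableError(ValueError):
    """No variation in weighted parental age: the slope cannot be estimated."""


@dataclass(frozen=True)
class RegressionFit:
    """Result of one identity-link Poisson fit."""

    decomposition: RateDecomposition
    loglik: float
    loglik_null: float
    pseudo_R2: float
    n_trios: int
    converged: bool = True
    boundary: bool = False


@dataclass(frozen=True)
class BootstrapResult:
    """Nonparametric bootstrap draws and percentile intervals."""

    draws: np.ndarray  # shape (B, 2): columns mu_E, mu_OS
    ci_muE: tuple[float, float]
    ci_muOS: tuple[float, float]
    seed: int
    B: int
    n_redrawn: int = 0


def _loglik(U: np.ndarray, mean: np.ndarray) -> float:
    """Poisson log-likelihood with continuous lgamma(U+1) normalizer."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(U > 0, U * np.log(mean), 0.0)
    return float(np.sum(terms - mean - gammaln(U + 1.0)))


def _fit_core(
    U: np.ndarray, A: np.ndarray, e: np.ndarray, tol: float = 1e-12, max_iter: int = 200
) -> tuple[float, float, bool, bool]:
    """Maximize sum U log(e*(a+b*A)) - e*(a+b*A) over a >= 0, means > 0.

    Damped Newton; Newton steps are affine-invariant so no rescaling of the
    tiny per-site rates is needed.  Returns (a, b, converged, boundary).
    """
    if np.all(U == 0):
        return 0.0, 0.0, True, True

    # Weighted least-squares start on the per-site scale, pulled inside the cone.
    y = U / e
    X = np.column_stack([np.ones_like(A), A])
    coef, *_ = np.linalg.lstsq(X * e[:, None], y * e, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    rate0 = float(np.sum(U) / np.sum(e))
    if a <= 0:
        a = 0.5 * rate0
    while np.min(a + b * A) <= 0:
        b *= 0.5
        if abs(b) < 1e-300:
            b = 0.0
            break

    def negfeas(a: float, b: float) -> bool:
        return a < 0 or np.min(a + b * A) <= 0

    ll = _loglik(U, e * (a + b * A))
    converged = False
    pin_a = False
    for _ in range(max_iter):
        m = e * (a + b * A)
        r = U / m - 1.0
        g = np.array([np.sum(r * e), np.sum(r * e * A)])
        w = U / m**2 * e**2
        H = np.array([[np.sum(w), np.sum(w * A)], [np.sum(w * A), np.sum(w * A**2)]])
        if pin_a:
            if abs(g[1]) < tol * max(1.0, abs(ll)) or H[1, 1] <= 0:
                converged = True
                break
            step = np.array([0.0, g[1] / H[1, 1]])
            decrement = g[1] * step[1]
        else:
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            decrement = float(g @ step)
        if decrement < tol * max(1.0, abs(ll)):
            converged = True
            break
        t = 1.0
        while t > 1e-14:
            a_new, b_new = a + t * step[0], b + t * step[1]
            if not negfeas(a_new, b_new):
                ll_new = _loglik(U, e * (a_new + b_new * A))
                if ll_new >= ll - 1e-12:
                    a, b, ll = a_new, b_new, ll_new
                    break
            t *= 0.5
        else:
            # Step blocked: the intercept wants the a = 0 boundary.
            if not pin_a and a < 1e-3 * rate0 and g[0] < 0:
                a, pin_a = 0.0, True
                if negfeas(a, b):
                    b = max(b, 0.0)
                ll = _loglik(U, e * (a + b * A)) if not negfeas(a, b) else ll
                continue
            break
        if not pin_a and a == 0.0 and g[0] < 0:
            pin_a = True
    boundary = pin_a or a == 0.0
    if not converged:
        logger.warning("identity-link Poisson fit did not fully converge")
    return a, b, converged, boundary


def _prepare(
    trios: Sequence[TrioRecord], rho: float, puberty_age: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    U = np.array([t.n_mut_total for t in trios], dtype=float)
    AP = np.array([t.paternal_age for t in trios], dtype=float)
    AM = np.array([t.maternal_age for t in trios], dtype=float)
    e = 2.0 * np.array([t.callable_haploid_bp for t in trios], dtype=float)
    A = np.asarray(weighted_parental_age(AP, AM, rho, puberty_age), dtype=float)
    return U, A, e


class RateRegression(BaseEstimator):
    """Estimator for the (mu_E, mu_O+mu_S) decomposition of one trio dataset.

    Parameters
    ----------
    rho:
        Sperm fraction mu_S/(mu_O+mu_S) used to weight paternal vs maternal
        age.  0.75 is the large-human-pedigree value used as the fallback
        when no species-specific estimate is available.
    puberty_age:
        Age of puberty / first reproduction P in years.

    Attributes (after ``fit``)
    --------------------------
    mu_E_, mu_OS_ : the per-site intercept (per generation) and slope (per
        year); ``decomposition_`` packages them with rho and P.
    loglik_, loglik_null_, pseudo_R2_ : fitted and intercept-only
        log-likelihoods and McFadden's pseudo-R^2 = 1 - loglik/loglik_null.
    """

    def __init__(self, rho: float = 0.75, puberty_age: float = 0.0):
        self.rho = rho
        self.puberty_age = puberty_age

    def fit(self, trios: Sequence[TrioRecord], y=None) -> "RateRegression":
        if len(trios) < 2:
            raise ValueError("need at least two trios")
        U, A, e = _prepare(trios, self.rho, self.puberty_age)
        if np.ptp(A) < 1e-12:
            raise SlopeUnidentifiableError(
                "all trios share one weighted parental age; mu_OS is unidentifiable"
            )
        a, b, converged, boundary = _fit_core(U, A, e)
        mean = e * (a + b * A)
        self.mu_E_ = a
        self.mu_OS_ = b
        self.loglik_ = _loglik(U, mean) if np.all(mean > 0) else 0.0
        a_null = float(np.sum(U) / np.sum(e))
        self.loglik_null_ = _loglik(U, e * a_null) if a_null > 0 else 0.0
        self.pseudo_R2_ = (
            1.0 - self.loglik_ / self.loglik_null_ if self.loglik_null_ < 0 else 0.0
        )
        self.n_trios_ = len(trios)
        self.converged_ = converged
        self.boundary_ = boundary
        self.decomposition_ = RateDecomposition(
            mu_E=max(a, 0.0),
            mu_OS=b if b >= 0 else b,  # slope may legitimately be negative
            sperm_fraction=self.rho,
            puberty_age=self.puberty_age,
        ) if b >= 0 else None
        if self.decomposition_ is None:
            # Negative slope: keep raw values, RateDecomposition enforces >= 0.
            logger.warning("fitted mu_OS is negative (%.3g)", b)
        return self

    def predict(self, trios: Sequence[TrioRecord]) -> np.ndarray:
        """Expected corrected mutation count per trio under the fitted rates."""
        U, A, e = _prepare(trios, self.rho, self.puberty_age)
        return e * (self.mu_E_ + self.mu_OS_ * A)

    @property
    def result_(self) -> RegressionFit:
        dec = self.decomposition_ or RateDecomposition(
            mu_E=max(self.mu_E_, 0.0),
            mu_OS=max(self.mu_OS_, 0.0),
            sperm_fraction=self.rho,
            puberty_age=self.puberty_age,
        )
        return RegressionFit(
            decomposition=dec,
            loglik=self.loglik_,
            loglik_null=self.loglik_null_,
            pseudo_R2=self.pseudo_R2_,
            n_trios=self.n_trios_,
            converged=self.converged_,
            boundary=self.boundary_,
        )


def fit_rate_regression(
    trios: Sequence[TrioRecord], rho: float = 0.75, puberty_age: float = 0.0
) -> RegressionFit:
    """Functional wrapper around :class:`RateRegression`."""
    est = RateRegression(rho=rho, puberty_age=puberty_age).fit(trios)
    return est.result_


def bootstrap_rates(
    trios: Sequence[TrioRecord],
    rho: float = 0.75,
    puberty_age: float = 0.0,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Nonparametric bootstrap over trios with percentile 95% intervals.

    Resamples that cannot be fitted (e.g. no age variation after resampling)
    are redrawn; the number of redraws is recorded.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(trios)
    draws = np.empty((B, 2))
    n_redrawn = 0
    for b_idx in range(B):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            sample = [trios[i] for i in idx]
            try:
                fit = RateRegression(rho=rho, puberty_age=puberty_age).fit(sample)
            except (SlopeUnidentifiableError, ValueError):
                n_redrawn += 1
                continue
            draws[b_idx] = (fit.mu_E_, fit.mu_OS_)
            break
        else:
            raise RuntimeError("bootstrap could not draw a fittable resample")
    lo_E, hi_E = np.percentile(draws[:, 0], [2.5, 97.5])
    lo_S, hi_S = np.percentile(draws[:, 1], [2.5, 97.5])
    if n_redrawn:
        logger.info("bootstrap redrew %d unfittable resamples", n_redrawn)
    return BootstrapResult(
        draws=draws,
        ci_muE=(float(lo_E), float(hi_E)),
        ci_muOS=(float(lo_S), float(hi_S)),
        seed=seed,
        B=B,
        n_redrawn=n_redrawn,
    )


def batch_effect_lrt(
    datasets: Sequence[tuple[str, Sequence[TrioRecord]]],
    rho: float = 0.75,
    puberty_age: float = 0.0,
) -> tuple[float, int, float]:
    """Likelihood-ratio test for dataset-specific (mu_E, mu_OS).

    Compares a pooled fit with shared parameters against a full model with a
    separate parameter pair per dataset (equivalent to a categorical source
    term interacting with both intercept and slope).  Returns
    (chi2, df, p-value) with df = 2*(K-1) for K datasets.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two labeled datasets")
    ll_full = 0.0
    for label, trios in datasets:
        try:
            ll_full += fit_rate_regression(trios, rho=rho, puberty_age=puberty_age).loglik
        except (ValueError, SlopeUnidentifiableError) as err:
            raise ValueError(f"dataset {label!r} cannot be fitted alone: {err}") from err
    pooled: list[TrioRecord] = [t for _, trios in datasets for t in trios]
    ll_pooled = fit_rate_regression(pooled, rho=rho, puberty_age=puberty_age).loglik
    chi2 = max(0.0, 2.0 * (ll_full - ll_pooled))
    df = 2 * (len(datasets) - 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
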