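"""Reproductive-longevity models of the per-generation mutation rate.

Two model families predict mu from generation time g alone:

* fixed-rate: reference-species rates are held constant and only the
  demographic parameters vary, ``mu(g) = mu_E,ref + g*(1-p) * mu_OS,ref``
  (or with an explicit reference puberty age, ``mu_E,ref + (g-P) * mu_OS,ref``);
* variable-rate: the rate components themselves scale as power laws of g,
  ``mu(g) = mu_E(1) * g^alpha + (1-p) * muOS(1) * g^(beta+1)``, with alpha
  and beta the log-log slopes of mu_E and mu_O+mu_S against g estimated by
  PGLS across species.

The puberty fraction p = P/g is treated as a cross-species constant
(default 0.42, the proportionality fitted across a large vertebrate
demographic panel); ``fit_puberty_fraction`` re-estimates it from any panel
via a through-origin regression of P on g.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import SpeciesRecord
from .pgls import PGLS, PGLSFit

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PUBERTY_FRACTION",
    "FixedRateModel",
    "ScalingModel",
    "PubertyFractionFit",
    "ScalingModelPGLS",
    "fit_puberty_fraction",
    "fixed_rate_mu",
    "variable_rate_mu",
    "fit_scaling_model",
    "mean_squared_log10_error",
]

#: Cross-vertebrate puberty fraction p = P/g.
DEFAULT_PUBERTY_FRACTION = 0.42


@dataclass(frozen=True)
class FixedRateModel:
    """Reference-species rates with variable demography.

    Exactly one of ``p`` (puberty fraction) or ``P_ref`` (explicit reference
    puberty age in years) drives the reproductive-span term.
    """

    muE_ref: float
    muOS_ref: float
    p: float | None = None
    P_ref: float | None = None

    def __post_init__(self) -> None:
        if (self.p is None) == (self.P_ref is None):
            raise ValueError("specify exactly one of p or P_ref")
        if self.p is not None and not 0.0 <= self.p < 1.0:
            raise ValueError("p must lie in [0, 1)")

    def predict(self, g):
        return fixed_rate_mu(g, self)


@dataclass(frozen=True)
class ScalingModel:
    """Power-law scaling of both rate components with generation time."""

    muE_at_1: float
    muOS_at_1: float
    alpha: float
    beta: float
    p: float = DEFAULT_PUBERTY_FRACTION

    def __post_init__(self) -> None:
        if self.muE_at_1 <= 0 or self.muOS_at_1 <= 0:
            raise ValueError("reference rates must be positive")
        if not 0.0 <= self.p < 1.0:
            raise ValueError("p must lie in [0, 1)")

    def predict(self, g):
        return variable_rate_mu(g, self)


@dataclass(frozen=True)
class PubertyFractionFit:
    p: float
    r: float
    slope_with_intercept: float
    intercept: float


def fit_puberty_fraction(
    species: Sequence[SpeciesRecord] | pd.DataFrame,
) -> PubertyFractionFit:
    """Through-origin slope of puberty age P on generation time g.

    Also reports the Pearson correlation of P and g and, as a diagnostic,
    the with-intercept least-squares fit.
    """
    if isinstance(species, pd.DataFrame):
        P = species["P"].to_numpy(dtype=float)
        g = species["g"].to_numpy(dtype=float)
    else:
        P = np.array([s.puberty_age for s in species], dtype=float)
        g = np.array([s.generation_time for s in species], dtype=float)
    if P.size < 3:
        raise ValueError("need at least three species")
    if np.any(g <= 0):
        raise ValueError("generation times must be positive")
    p = float(np.sum(P * g) / np.sum(g * g))
    r = float(stats.pearsonr(P, g).statistic)
    slope, intercept = np.polyfit(g, P, 1)
    return PubertyFractionFit(
        p=p, r=r, slope_with_intercept=float(slope), intercept=float(intercept)
    )


def fixed_rate_mu(g, model: FixedRateModel):
    """Fixed-rate prediction of mu at generation time g (either p or P form)."""
    g = np.asarray(g, dtype=float)
    if model.P_ref is not None:
        if np.any(g < model.P_ref):
            raise ValueError("generation time below the reference puberty age")
        span = g - model.P_ref
    else:
        span = g * (1.0 - model.p)
    mu = model.muE_ref + span * model.muOS_ref
    return mu if mu.ndim else float(mu)


def variable_rate_mu(g, model: ScalingModel):
    """Variable-rate prediction mu_E(1)*g^alpha + (1-p)*muOS(1)*g^(beta+1)."""
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0):
        raise ValueError("generation time must be positive")
    mu = model.muE_at_1 * g**model.alpha + (1.0 - model.p) * model.muOS_at_1 * g ** (
        model.beta + 1.0
    )
    return mu if mu.ndim else float(mu)


class ScalingModelPGLS(BaseEstimator):
    """Fit the power-law scaling model to a species panel by PGLS.

    ``fit`` takes a DataFrame with columns ``species, mu_E, mu_OS, g`` (and
    optionally ``P``) whose species match tips of ``tree``.  alpha and
    log10 mu_E(1) come from PGLS of log10 mu_E on log10 g; beta and
    log10 muOS(1) from PGLS of log10 mu_OS on log10 g (all logs base 10;
    slopes are base-invariant, intercepts are reported in base 10).

    Parameters: ``p`` fixes the puberty fraction (None derives it from the
    panel's P column when present, else 0.42); ``exclude`` drops species by
    name before fitting (e.g. the aye-aye outlier).
    """

    def __init__(
        self,
        tree: dendropy.Tree = None,
        p: float | None = DEFAULT_PUBERTY_FRACTION,
        exclude: Iterable[str] = (),
    ):
        self.tree = tree
        self.p = p
        self.exclude = exclude

    def fit(self, panel: pd.DataFrame, y=None) -> "ScalingModelPGLS":
        panel = panel[~panel["species"].isin(set(self.exclude))].reset_index(drop=True)
        if len(panel) < 4:
            raise ValueError("need at least four species after exclusions")
        if panel["species"].duplicated().any():
            raise ValueError(
                "panel has duplicate species rows; select one row per species first"
            )
        if (panel["mu_E"] <= 0).any() or (panel["mu_OS"] <= 0).any():
            raise ValueError("nonpositive rate estimates cannot be log-transformed")
        taxa = list(panel["species"])
        logg = np.log10(panel["g"].to_numpy(dtype=float))
        self.alpha_fit_ = (
            PGLS(tree=self.tree, taxa=taxa)
            .fit(logg, np.log10(panel["mu_E"].to_numpy(dtype=float)))
            .result_
        )
        self.beta_fit_ = (
            PGLS(tree=self.tree, taxa=taxa)
            .fit(logg, np.log10(panel["mu_OS"].to_numpy(dtype=float)))
            .result_
        )
        if self.p is not None:
            p_used = self.p
        elif "P" in panel.columns:
            p_used = fit_puberty_fraction(
                panel.rename(columns={"g": "g", "P": "P"})
            ).p
        else:
            p_used = DEFAULT_PUBERTY_FRACTION
        self.model_ = ScalingModel(
            muE_at_1=10.0 ** self.alpha_fit_.intercept,
            muOS_at_1=10.0 ** self.beta_fit_.intercept,
            alpha=self.alpha_fit_.slope,
            beta=self.beta_fit_.slope,
            p=p_used,
        )
        self.n_species_ = len(panel)
        return self

    def predict(self, g):
        return self.model_.predict(g)

    @property
    def alpha_(self) -> float:
        return self.model_.alpha

    @property
    def beta_(self) -> float:
        return self.model_.beta


def fit_scaling_model(
    panel: pd.DataFrame,
    tree: dendropy.Tree,
    p: float | None = DEFAULT_PUBERTY_FRACTION,
    exclude: Iterable[str] = (),
) -> tuple[ScalingModel, PGLSFit, PGLSFit]:
    """Functional wrapper: returns (model, alpha PGLS fit, beta PGLS fit)."""
    est = ScalingModelPGLS(tree=tree, p=p, exclude=exclude).fit(panel)
    return est.model_, est.alpha_fit_, est.beta_fit_


def mean_squared_log10_error(
    model: FixedRateModel | ScalingModel, panel: pd.DataFrame
) -> float:
    """Mean squared log10 error of predicted vs observed mu over a panel.

    The panel needs columns ``g`` and ``mu``; the model-family comparison of
    predictions across the vertebrate generation-time range uses this score.
    """
    g = panel["g"].to_numpy(dtype=float)
    mu_obs = panel["mu"].to_numpy(dtype=float)
    mu_pred = np.asarray(model.predict(g), dtype=float)
    return float(np.mean((np.log10(mu_pred) - np.log10(mu_obs)) ** 2))
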