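"""Synthetic data with the statistical structure the estimators assume.

Three generators:

* ``simulate_trios`` — trio datasets with sex-specific Poisson counts and
  Bernoulli partial phasing.  Maternal counts are Poisson with mean
  ``L * (muEM + muO * (A_M - P))`` and paternal counts analogous, where the
  rates are per site per *haploid* genome.  The total count therefore has
  the diploid ``2L`` form used by the regression module with intercept
  ``(muEM + muEP) / 2`` and slope ``(muS + muO) / 2``, exposed as the
  ``mu_E_regression`` / ``mu_OS_regression`` properties of the config.  Each mutation is
  phased to its true parent independently with probability ``phase_prob``.
* ``simulate_yule_tree`` — ultrametric pure-birth trees.
* ``simulate_trait_panel`` — per-species rate panels in which log10
  generation time and the log10 rate residuals evolve by Brownian motion on
  the tree (lambda-attenuated covariance), the rates follow exact power
  laws of g up to that noise, and diversity is assembled so that
  log Ne = gamma * log g + const.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .io import TrioRecord
from .pgls import pagel_transform, phylo_covariance

__all__ = [
    "TrioSimConfig",
    "PanelSimConfig",
    "simulate_trios",
    "simulate_yule_tree",
    "simulate_trait_panel",
]


@dataclass(frozen=True)
class TrioSimConfig:
    """Generating parameters for synthetic trio datasets.

    Defaults emulate a large human pedigree study: per-haploid-genome
    per-site rates summing to mu_E = 6.6e-9 per generation and
    mu_O + mu_S = 3.63e-10 per year on the diploid regression scale, sperm
    fraction 0.75, puberty at 13 y, parental ages spanning late teens to
    mid-forties, a 2.68 Gb callable haploid genome, and ~30% of mutations
    receiving parent-of-origin phase.
    """

    n_trios: int = 200
    true_muEM: float = 4.4e-9
    true_muEP: float = 8.8e-9
    true_muS: float = 5.445e-10
    true_muO: float = 1.815e-10
    puberty_age: float = 13.0
    paternal_age_range: tuple[float, float] = (18.0, 45.0)
    maternal_age_range: tuple[float, float] = (18.0, 42.0)
    L: float = 2.68289e9
    phase_prob: float = 0.3
    seed: int = 0
    dataset_label: str = "sim"
    allow_below_puberty: bool = False

    def __post_init__(self) -> None:
        for name in ("true_muEM", "true_muEP", "true_muS", "true_muO"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.phase_prob <= 1.0:
            raise ValueError("phase_prob must lie in [0, 1]")
        if self.L <= 0:
            raise ValueError("L must be positive")

    @property
    def mu_E_regression(self) -> float:
        """Regression-scale intercept truth, (muEM + muEP)/2 per diploid site."""
        return 0.5 * (self.true_muEM + self.true_muEP)

    @property
    def mu_OS_regression(self) -> float:
        """Regression-scale slope truth, (muS + muO)/2 per diploid site-year."""
        return 0.5 * (self.true_muS + self.true_muO)

    @property
    def rho(self) -> float:
        denom = self.true_muS + self.true_muO
        return self.true_muS / denom if denom > 0 else float("nan")


@dataclass(frozen=True)
class PanelSimConfig:
    """Generating parameters for synthetic multi-species trait panels."""

    n_taxa: int = 64
    birth_rate: float = 1.0
    true_alpha: float = 0.2
    true_beta: float = -0.6
    muE_at_1: float = 4e-9
    muOS_at_1: float = 6e-10
    p: float = 0.42
    bm_sigma: float = 0.15
    lam: float = 1.0
    gamma: float = -0.5
    seed: int = 0
    log10_g_mean: float = 0.8
    log10_g_sd: float = 0.45
    ne_const: float = 2e5
    ne_noise_sd: float = 0.0


def simulate_trios(cfg: TrioSimConfig) -> list[TrioRecord]:
    """Draw a trio dataset under the sex-specific Poisson model."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_trios
    AP = rng.uniform(*cfg.paternal_age_range, size=n)
    AM = rng.uniform(*cfg.maternal_age_range, size=n)
    dAM = AM - cfg.puberty_age
    dAP = AP - cfg.puberty_age
    mean_m = cfg.L * (cfg.true_muEM + cfg.true_muO * dAM)
    mean_p = cfg.L * (cfg.true_muEP + cfg.true_muS * dAP)
    if np.any(mean_m < 0) or np.any(mean_p < 0):
        if not cfg.allow_below_puberty:
            raise ValueError(
                "parental ages below puberty give negative Poisson means; "
                "set allow_below_puberty=True to clamp them to zero"
            )
        mean_m = np.maximum(mean_m, 0.0)
        mean_p = np.maximum(mean_p, 0.0)
    n_mat = rng.poisson(mean_m)
    n_pat = rng.poisson(mean_p)
    um = rng.binomial(n_mat, cfg.phase_prob)
    up = rng.binomial(n_pat, cfg.phase_prob)
    ux = (n_mat - um) + (n_pat - up)
    return [
        TrioRecord(
            trio_id=f"{cfg.dataset_label}-{i:04d}",
            dataset_label=cfg.dataset_label,
            paternal_age=float(AP[i]),
            maternal_age=float(AM[i]),
            n_mut_total=float(n_mat[i] + n_pat[i]),
            n_paternal_phased=float(up[i]),
            n_maternal_phased=float(um[i]),
            n_unphased=float(ux[i]),
            callable_haploid_bp=float(cfg.L),
        )
        for i in range(n)
    ]


def simulate_yule_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Ultrametric pure-birth tree on ``n_taxa`` tips, labelled t1..tn.

    Forward simulation: start from the root split (two lineages), wait
    Exp(k * birth_rate) between events while k lineages are active, split a
    uniformly chosen lineage at each event, and cut all lineages at one
    further Exp(n * birth_rate) beyond the final split so tip branches are
    nondegenerate.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    birth_time: dict = {}
    t = 0.0
    active = []
    for _ in range(2):
        child = dendropy.Node()
        tree.seed_node.add_child(child)
        birth_time[child] = 0.0
        active.append(child)
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(0, len(active))
        parent = active.pop(idx)
        parent.edge.length = t - birth_time[parent]
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            birth_time[child] = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for i, leaf in enumerate(active):
        leaf.edge.length = t - birth_time[leaf]
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(label=f"t{i + 1}")
    return tree


def simulate_trait_panel(tree: dendropy.Tree, cfg: PanelSimConfig) -> pd.DataFrame:
    """Draw a species panel with power-law rates and phylogenetic noise.

    Returns a DataFrame with columns species, g, P, mu_E, mu_OS, mu, pi, Ne.
    The covariance used for all Brownian draws is the tree covariance
    normalized to unit root-to-tip depth and attenuated by ``cfg.lam``, so
    ``bm_sigma`` and ``log10_g_sd`` are tip-level standard deviations.
    """
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    cov = phylo_covariance(tree, taxa)
    depth = float(np.max(np.diag(cov.C)))
    Cn = cov.C / depth if depth > 0 else np.eye(len(taxa))
    V = pagel_transform(Cn, cfg.lam)
    try:
        chol = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(V + 1e-10 * np.eye(len(taxa)))
    rng = np.random.default_rng(cfg.seed)
    n = len(taxa)

    def bm(sd: float) -> np.ndarray:
        return sd * (chol @ rng.standard_normal(n))

    log_g = cfg.log10_g_mean + bm(cfg.log10_g_sd)
    log_muE = np.log10(cfg.muE_at_1) + cfg.true_alpha * log_g + bm(cfg.bm_sigma)
    log_muOS = np.log10(cfg.muOS_at_1) + cfg.true_beta * log_g + bm(cfg.bm_sigma)
    g = 10.0**log_g
    mu_E = 10.0**log_muE
    mu_OS = 10.0**log_muOS
    P = cfg.p * g
    mu = mu_E + (g - P) * mu_OS
    log_Ne = np.log10(cfg.ne_const) + cfg.gamma * log_g
    if cfg.ne_noise_sd > 0:
        log_Ne = log_Ne + bm(cfg.ne_noise_sd)
    Ne = 10.0**log_Ne
    pi = 4.0 * mu * Ne
    return pd.DataFrame(
        {
            "species": taxa,
            "g": g,
            "P": P,
            "mu_E": mu_E,
            "mu_OS": mu_OS,
            "mu": mu,
            "pi": pi,
            "Ne": Ne,
        }
    )
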