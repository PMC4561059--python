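"""Monte-Carlo power analysis for the family-clustered GEE association test.

Each replicate draws a family sample (structures, Mendelian causal
genotypes, correlated liabilities), dichotomizes the liability, fits the
logistic GEE with exchangeable working correlation, and records the
sandwich-based Wald p-value of the causal locus.  Power is the fraction of
converged replicates significant at the chosen alpha, with an exact
(Clopper-Pearson) binomial confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gee import GEELogistic
from .simulate import (FamilyMixture, LiabilityParams, _config_groups,
                       _draw_causal_dosages, _draw_residuals,
                       sample_family_structures)

logger = logging.getLogger(__name__)


@dataclass
class PowerConfig:
    """Configuration of one Monte-Carlo power run."""

    n_replicates: int = 1000
    q2: float = 0.01
    alpha: float = 1e-8
    mixture: FamilyMixture = field(default_factory=FamilyMixture)
    liability: LiabilityParams = field(default_factory=LiabilityParams)
    seed: int = 0
    resample_structures: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        self.liability = LiabilityParams(
            r_spouse=self.liability.r_spouse, r_sib=self.liability.r_sib,
            r_po=self.liability.r_po, q2=self.q2,
            causal_maf=self.liability.causal_maf,
            z_threshold=self.liability.z_threshold)


@dataclass
class PowerResult:
    """Estimated power with its exact binomial confidence interval."""

    power_hat: float
    binomial_95ci: tuple[float, float]
    n_significant: int
    n_converged: int
    n_replicates: int
    mean_n_individuals: float
    alpha: float
    q2: float


def _replicate_pvalue(groups, n_rows, cluster_codes, params: LiabilityParams,
                      rng: np.random.Generator) -> float | None:
    """One replicate: genotypes -> liability -> dichotomize -> GEE Wald p."""
    g = _draw_causal_dosages(groups, n_rows, params.causal_maf, rng).astype(float)
    p = params.causal_maf
    beta = np.sqrt(params.q2 / (2 * p * (1 - p))) if params.q2 > 0 else 0.0
    liab = beta * (g - 2 * p) + _draw_residuals(groups, n_rows, params, rng)
    y = (liab > params.z_threshold).astype(float)
    if y.min() == y.max() or g.min() == g.max():
        return None
    X = np.column_stack([np.ones(n_rows), g])
    fit = GEELogistic().fit(X, y, clusters=cluster_codes)
    if not fit.converged_:
        return None
    return fit.wald_test(1)[1]


def single_replicate(config: PowerConfig, replicate_seed: int) -> float | None:
    """One full simulation-and-test replicate; returns the causal-SNP
    p-value, or None when the GEE fit does not converge."""
    ped = sample_family_structures(config.mixture, seed=replicate_seed
                                   if config.resample_structures else config.seed)
    groups = _config_groups(ped)
    rng = np.random.default_rng([config.seed, replicate_seed])
    return _replicate_pvalue(groups, len(ped.table), ped.cluster_codes(),
                             config.liability, rng)


def run_power_analysis(config: PowerConfig) -> PowerResult:
    """Estimate power at the configured effect size and alpha."""
    ped = sample_family_structures(config.mixture, seed=config.seed)
    groups = _config_groups(ped)
    n_rows = len(ped.table)
    clusters = ped.cluster_codes()

    n_sig = 0
    n_conv = 0
    total_n = 0
    for rep in range(config.n_replicates):
        if config.resample_structures:
            ped = sample_family_structures(config.mixture, seed=rep)
            groups = _config_groups(ped)
            n_rows = len(ped.table)
            clusters = ped.cluster_codes()
        rng = np.random.default_rng([config.seed, rep])
        pval = _replicate_pvalue(groups, n_rows, clusters, config.liability, rng)
        total_n += n_rows
        if pval is None:
            continue
        n_conv += 1
        if pval < config.alpha:
            n_sig += 1

    n_failed = config.n_replicates - n_conv
    if n_failed > 0.05 * config.n_replicates:
        logger.warning("%d of %d replicates failed to converge",
                       n_failed, config.n_replicates)
    if n_conv == 0:
        raise RuntimeError("no converged replicates")
    power = n_sig / n_conv
    ci = stats.binomtest(n_sig, n_conv).proportion_ci(confidence_level=0.95,
                                                     method="exact")
    return PowerResult(
        power_hat=power,
        binomial_95ci=(float(ci.low), float(ci.high)),
        n_significant=n_sig,
        n_converged=n_conv,
        n_replicates=config.n_replicates,
        mean_n_individuals=total_n / config.n_replicates,
        alpha=config.alpha,
        q2=config.q2,
    )
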