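"""Synthetic family data: structures, genotypes, liability, age at onset.

The generator emulates a population-register family design: a fixed number
of families drawn from a mixture of configurations (singletons, spouse
couples, sibships of size 1-6 with 0, 1 or 2 parents), a biallelic causal
locus in Hardy-Weinberg equilibrium transmitted Mendelianly within
families, a standard-normal liability with familial residual correlations
(spouse 0.39, sibling 0.35, parent-offspring 0.15) dichotomized at
z = 0.85 (~20% prevalence), and a right-censored age at first use drawn
from a Weibull proportional-hazards model with a liability-linked frailty.

All operations are deterministic given their ``seed`` argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING_PARENT, GenotypeDataset, Pedigree, SNPMETA_COLUMNS

logger = logging.getLogger(__name__)

CAUSAL_SNP_ID = "causal"


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

def _default_configurations() -> dict[tuple[int, int], float]:
    # (n_sibs, n_parents) -> probability.  (0,1) is a singleton, (0,2) a
    # childless couple.  Chosen so that 3690 families carry ~6,725
    # individuals in expectation, matching the analyzed-cohort scale.
    return {
        (0, 1): 0.52,
        (0, 2): 0.18,
        (2, 0): 0.08,
        (3, 0): 0.03,
        (1, 1): 0.03,
        (1, 2): 0.04,
        (2, 1): 0.02,
        (2, 2): 0.06,
        (3, 2): 0.03,
        (4, 2): 0.008,
        (5, 2): 0.0015,
        (6, 2): 0.0005,
    }


@dataclass
class FamilyMixture:
    """Mixture of family configurations.

    Keys of ``proportions`` are ``(n_sibs, n_parents)`` with n_parents in
    {0, 1, 2}; ``(0, 1)`` denotes a singleton and ``(0, 2)`` a childless
    couple.  Proportions must sum to 1.
    """

    n_families: int = 3690
    proportions: dict[tuple[int, int], float] = field(default_factory=_default_configurations)

    def __post_init__(self):
        total = sum(self.proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"configuration proportions sum to {total}, not 1")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("negative configuration proportion")
        if all(p == 0 for p in self.proportions.values()):
            raise ValueError("zero-probability mixture")
        for (k, j) in self.proportions:
            if k + j == 0 or j not in (0, 1, 2) or not (0 <= k <= 6):
                raise ValueError(f"unsupported configuration {(k, j)}")

    @property
    def expected_individuals(self) -> float:
        return self.n_families * sum((k + j) * p for (k, j), p in self.proportions.items())


@dataclass
class LiabilityParams:
    """Liability-threshold model parameters.

    The liability is L = beta * (g - 2p) + eps with beta chosen so that the
    causal locus explains ``q2`` of the (unit) liability variance; eps is
    multivariate normal within families with variance 1 - q2 and residual
    correlations ``r_spouse`` / ``r_sib`` / ``r_po``.  The binary trait is
    1{L > z_threshold}.
    """

    r_spouse: float = 0.39
    r_sib: float = 0.35
    r_po: float = 0.15
    q2: float = 0.0
    causal_maf: float = 0.5
    z_threshold: float = 0.85

    def __post_init__(self):
        for name in ("r_spouse", "r_sib", "r_po"):
            if not -1 < getattr(self, name) < 1:
                raise ValueError(f"{name} outside (-1, 1)")
        if not 0 <= self.q2 < 1:
            raise ValueError("q2 must be in [0, 1)")
        if not 0 < self.causal_maf <= 0.5:
            raise ValueError("causal_maf must be in (0, 0.5]")


@dataclass
class OnsetParams:
    """Weibull proportional-hazards onset model and censoring scheme.

    Latent onset age T satisfies S(t) = exp(-(t/scale)^shape * exp(eta))
    with eta = beta_g * (g - 2p) + frailty_scale * eps, eps the liability
    residual (so early onset co-segregates in families).  Ages are in
    years.  The observation (censoring) age is normal, truncated below.
    The default scale is calibrated so that ~16.6% of a default cohort has
    an observed event.
    """

    baseline_shape: float = 2.5
    baseline_scale: float = 104.0
    beta_g: float = 0.0
    frailty_scale: float = 0.5
    censor_mean: float = 47.0
    censor_sd: float = 17.5
    censor_min: float = 16.0
    min_onset_age: float = 10.0

    def __post_init__(self):
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if self.min_onset_age < 0 or self.censor_min < 0 or self.censor_sd <= 0:
            raise ValueError("ages must be non-negative and censor_sd positive")


def load_config(path) -> tuple[FamilyMixture, LiabilityParams, OnsetParams]:
    """Read generator parameters from a YAML key/value file.

    Recognized sections are ``mixture`` (n_families and optional
    ``proportions`` keyed as "<n_sibs>+<n_parents>"), ``liability`` and
    ``onset``; omitted entries keep their defaults.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    mix_cfg = dict(cfg.get("mixture", {}))
    if "proportions" in mix_cfg:
        mix_cfg["proportions"] = {
            tuple(int(t) for t in str(key).split("+")): float(v)
            for key, v in mix_cfg["proportions"].items()
        }
    mixture = FamilyMixture(**mix_cfg)
    liability = LiabilityParams(**cfg.get("liability", {}))
    onset = OnsetParams(**cfg.get("onset", {}))
    return mixture, liability, onset


# ---------------------------------------------------------------------------
# Family structures
# ---------------------------------------------------------------------------

def sample_family_structures(mixture: FamilyMixture | None = None, seed: int = 0) -> Pedigree:
    """Draw family configurations from the mixture and build a pedigree.

    Exactly ``mixture.n_families`` families are produced; per-configuration
    counts are multinomial around the mixture proportions.
    """
    if mixture is None:
        mixture = FamilyMixture()
    rng = np.random.default_rng(seed)
    configs = list(mixture.proportions)
    probs = np.array([mixture.proportions[c] for c in configs])
    counts = rng.multinomial(mixture.n_families, probs)

    rows = []
    fam = 0
    for (k, j), count in zip(configs, counts):
        for _ in range(count):
            fam += 1
            fid = f"F{fam:05d}"
            father = f"{fid}_P1"
            mother = f"{fid}_P2"
            if k == 0:
                role = "spouse" if j == 2 else "founder"
                if j >= 1:
                    rows.append((fid, father, MISSING_PARENT, MISSING_PARENT,
                                 int(rng.integers(1, 3)) if j == 1 else 1, "-9", role))
                if j == 2:
                    rows.append((fid, mother, MISSING_PARENT, MISSING_PARENT, 2, "-9", role))
            else:
                if j >= 1:
                    rows.append((fid, father, MISSING_PARENT, MISSING_PARENT, 1, "-9", "founder"))
                if j == 2:
                    rows.append((fid, mother, MISSING_PARENT, MISSING_PARENT, 2, "-9", "founder"))
                f_link = father if j >= 1 else MISSING_PARENT
                m_link = mother if j == 2 else MISSING_PARENT
                for s in range(1, k + 1):
                    rows.append((fid, f"{fid}_S{s}", f_link, m_link,
                                 int(rng.integers(1, 3)), "-9", "offspring"))
    table = pd.DataFrame(rows, columns=["family_id", "individual_id", "father_id",
                                        "mother_id", "sex", "phenotype", "role"])
    return Pedigree(table)


@dataclass
class _ConfigGroup:
    """Families of one configuration, with row indices for vectorized draws."""

    n_sibs: int
    n_parents: int
    parent_rows: np.ndarray  # (n_fam, n_parents) indices into the pedigree row order
    sib_rows: np.ndarray     # (n_fam, n_sibs)
    corr_chol: np.ndarray | None = None

    @property
    def size(self) -> int:
        return self.n_sibs + self.n_parents

    @property
    def n_fam(self) -> int:
        return self.parent_rows.shape[0] if self.n_parents else self.sib_rows.shape[0]

    def member_rows(self) -> np.ndarray:
        parts = []
        if self.n_parents:
            parts.append(self.parent_rows)
        if self.n_sibs:
            parts.append(self.sib_rows)
        return np.hstack(parts)


def _config_groups(pedigree: Pedigree) -> list[_ConfigGroup]:
    """Group families by (n_sibs, n_parents) configuration for batching."""
    t = pedigree.table
    is_off = (t["role"] == "offspring").to_numpy()
    fam_codes, _ = pd.factorize(t["family_id"])
    order = np.arange(len(t))
    buckets: dict[tuple[int, int], list[tuple[list[int], list[int]]]] = {}
    # iterate family blocks (pedigree rows are grouped by construction; group
    # generically via pandas to stay safe for externally built pedigrees)
    for _, idx in pd.Series(order).groupby(fam_codes, sort=False):
        idx = idx.to_numpy()
        sibs = [i for i in idx if is_off[i]]
        pars = [i for i in idx if not is_off[i]]
        if len(pars) > 2:
            raise ValueError("more than two non-offspring members in a family")
        buckets.setdefault((len(sibs), len(pars)), []).append((pars, sibs))
    groups = []
    for (k, j), fams in buckets.items():
        parent_rows = np.array([f[0] for f in fams], dtype=np.int64).reshape(len(fams), j)
        sib_rows = np.array([f[1] for f in fams], dtype=np.int64).reshape(len(fams), k)
        groups.append(_ConfigGroup(k, j, parent_rows, sib_rows))
    return groups


def _residual_correlation(group: _ConfigGroup, params: LiabilityParams) -> np.ndarray:
    """Within-family residual correlation matrix, parents first then sibs."""
    s = group.size
    corr = np.eye(s)
    j, k = group.n_parents, group.n_sibs
    if j == 2:
        corr[0, 1] = corr[1, 0] = params.r_spouse
    for a in range(j):
        for b in range(j, s):
            corr[a, b] = corr[b, a] = params.r_po
    for a in range(j, s):
        for b in range(a + 1, s):
            corr[a, b] = corr[b, a] = params.r_sib
    return corr


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _draw_causal_dosages(groups: list[_ConfigGroup], n_rows: int, maf: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Causal-locus dosages: founders from HWE, offspring by Mendelian
    transmission; parents of parentless sibships are synthesized internally
    and discarded."""
    g = np.zeros(n_rows, dtype=np.int8)
    for grp in groups:
        n = grp.n_fam
        # both parents always exist for transmission; only observed ones are kept
        par = rng.binomial(2, maf, size=(n, 2)).astype(np.int8)
        if grp.n_parents:
            g[grp.parent_rows] = par[:, : grp.n_parents]
        if grp.n_sibs:
            # each parent transmits one allele: Bernoulli(g/2) per child
            pa = rng.random((n, grp.n_sibs)) < par[:, [0]] / 2.0
            ma = rng.random((n, grp.n_sibs)) < par[:, [1]] / 2.0
            g[grp.sib_rows] = (pa.astype(np.int8) + ma.astype(np.int8))
    return g


def _draw_null_block(n_ind: int, mafs: np.ndarray, block_corr: float,
                     block_size: int, rng: np.random.Generator) -> np.ndarray:
    """Null SNPs via a Gaussian copula with AR(1) within-block correlation."""
    m = len(mafs)
    z = rng.standard_normal((n_ind, m))
    if block_corr != 0.0:
        w = np.sqrt(1.0 - block_corr**2)
        for s in range(0, m, block_size):
            blk = z[:, s:s + block_size]
            for c in range(1, blk.shape[1]):
                blk[:, c] = block_corr * blk[:, c - 1] + w * blk[:, c]
    u = stats.norm.cdf(z)
    # HWE genotype quantiles per SNP
    p0 = (1 - mafs) ** 2
    p01 = p0 + 2 * mafs * (1 - mafs)
    return ((u > p0[None, :]).astype(np.int8) + (u > p01[None, :]).astype(np.int8))


def simulate_genotypes(
    pedigree: Pedigree,
    causal_maf: float = 0.5,
    n_null_snps: int = 0,
    ld_block_corr: float = 0.0,
    ld_block_size: int = 10,
    null_maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypeDataset:
    """Simulate a causal locus plus optional null SNPs for a pedigree.

    The causal locus (snp_id ``"causal"``) is drawn in HWE among founders
    and transmitted Mendelianly to offspring.  Null SNPs are drawn from a
    Gaussian copula with AR(1) correlation ``ld_block_corr`` within blocks
    of ``ld_block_size`` adjacent SNPs, independently across individuals.
    """
    if not 0 < causal_maf <= 0.5:
        raise ValueError("causal_maf must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    groups = _config_groups(pedigree)
    n = len(pedigree.table)
    causal = _draw_causal_dosages(groups, n, causal_maf, rng)
    cols = [causal]
    meta = [(CAUSAL_SNP_ID, 1, 1_000_000, causal_maf, 1.0)]
    if n_null_snps:
        mafs = rng.uniform(*null_maf_range, size=n_null_snps)
        cols.append(_draw_null_block(n, mafs, ld_block_corr, ld_block_size, rng))
        pos = 2_000_000 + 1000 * np.arange(n_null_snps)
        meta += [(f"null{i+1}", 1, int(pos[i]), float(mafs[i]), 1.0)
                 for i in range(n_null_snps)]
    dosages = np.column_stack(cols) if len(cols) > 1 else causal[:, None]
    snps = pd.DataFrame(meta, columns=SNPMETA_COLUMNS)
    return GenotypeDataset(individuals=pedigree.individual_ids, snps=snps, dosages=dosages)


# ---------------------------------------------------------------------------
# Liability and binary trait
# ---------------------------------------------------------------------------

def _draw_residuals(groups: list[_ConfigGroup], n_rows: int, params: LiabilityParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Family-correlated residuals with variance 1 - q2."""
    eps = np.zeros(n_rows)
    sd = np.sqrt(1.0 - params.q2)
    for grp in groups:
        if grp.corr_chol is None:
            corr = _residual_correlation(grp, params)
            try:
                grp.corr_chol = np.linalg.cholesky(corr)
            except np.linalg.LinAlgError:
                raise ValueError(
                    f"residual correlation matrix for configuration "
                    f"{grp.n_sibs} sibs + {grp.n_parents} parents is not "
                    "positive definite"
                ) from None
        z = rng.standard_normal((grp.n_fam, grp.size))
        eps[grp.member_rows()] = sd * (z @ grp.corr_chol.T)
    return eps


def simulate_liability(
    pedigree: Pedigree,
    genotypes: GenotypeDataset | None = None,
    params: LiabilityParams | None = None,
    seed: int = 0,
    causal_snp: str = CAUSAL_SNP_ID,
    with_covariates: bool = True,
) -> pd.DataFrame:
    """Simulate the liability and the dichotomized initiation trait.

    Returns a phenotype table with columns ``individual_id``, ``family_id``,
    ``liability``, ``residual``, ``initiated`` and (by default) covariate
    columns sex, age, cohort2, cohort3, pc1-pc3 and batch.  The covariates
    are exchangeable noise; they exercise the covariate path of the scans
    without influencing the trait.
    """
    if params is None:
        params = LiabilityParams()
    rng = np.random.default_rng(seed)
    groups = _config_groups(pedigree)
    n = len(pedigree.table)

    if params.q2 > 0:
        if genotypes is None:
            raise ValueError("q2 > 0 requires a genotype dataset with the causal SNP")
        sel = genotypes.snps["snp_id"] == causal_snp
        if not sel.any():
            raise ValueError(f"causal SNP {causal_snp!r} not in dataset")
        g = genotypes.dosages[:, sel.to_numpy().argmax()].astype(float)
        p = params.causal_maf
        beta = np.sqrt(params.q2 / (2 * p * (1 - p)))
        genetic = beta * (g - 2 * p)
    else:
        genetic = np.zeros(n)
    eps = _draw_residuals(groups, n, params, rng)
    liability = genetic + eps
    initiated = (liability > params.z_threshold).astype(np.int8)

    table = pd.DataFrame({
        "individual_id": pedigree.individual_ids,
        "family_id": pedigree.family_ids,
        "liability": liability,
        "residual": eps,
        "initiated": initiated,
    })
    if with_covariates:
        table["sex"] = (pedigree.table["sex"].to_numpy() == 2).astype(int)
        age = rng.normal(39.0, 17.5, size=n).clip(min=10.5)
        table["age"] = age
        cohort = rng.choice([0, 1, 2], size=n, p=[0.3, 0.35, 0.35])
        table["cohort2"] = (cohort == 1).astype(int)
        table["cohort3"] = (cohort == 2).astype(int)
        for k in range(1, 4):
            table[f"pc{k}"] = rng.standard_normal(n)
        table["batch"] = rng.integers(0, 2, size=n)
    return table


# ---------------------------------------------------------------------------
# Age at onset
# ---------------------------------------------------------------------------

def simulate_onset(
    pedigree: Pedigree,
    genotypes: GenotypeDataset | None,
    phenotypes: pd.DataFrame,
    params: OnsetParams | None = None,
    seed: int = 0,
    causal_snp: str = CAUSAL_SNP_ID,
) -> pd.DataFrame:
    """Simulate censored age at onset for the survival cohort.

    A latent onset age is drawn from the Weibull proportional-hazards model
    with linear predictor beta_g * (g - 2p) + frailty_scale * residual; the
    event is observed when the latent onset does not exceed the observation
    age.  Latent onsets at or below ``min_onset_age`` are treated as
    unreliable reports and excluded from the returned cohort.  Within the
    cohort the initiation indicator equals the event indicator (initiation
    by the observation age is what defines an observed onset).
    """
    if params is None:
        params = OnsetParams()
    if "residual" not in phenotypes.columns:
        raise ValueError("phenotype table lacks the liability residual column")
    rng = np.random.default_rng(seed)
    n = len(phenotypes)

    sel = (genotypes.snps["snp_id"] == causal_snp) if genotypes is not None else \
        pd.Series([], dtype=bool)
    if genotypes is not None and sel.any() and params.beta_g != 0.0:
        g = genotypes.dosages[:, sel.to_numpy().argmax()].astype(float)
        p = float(genotypes.snps.loc[sel, "allele_freq"].iloc[0])
        eta = params.beta_g * (g - 2 * p)
    else:
        eta = np.zeros(n)
    eta = eta + params.frailty_scale * phenotypes["residual"].to_numpy()

    u = rng.uniform(size=n)
    latent = params.baseline_scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / params.baseline_shape)

    a = (params.censor_min - params.censor_mean) / params.censor_sd
    obs_age = stats.truncnorm.rvs(a, np.inf, loc=params.censor_mean,
                                  scale=params.censor_sd, size=n, random_state=rng)

    event = (latent <= obs_age).astype(np.int8)
    onset = np.where(event == 1, latent, np.nan)
    excluded = event.astype(bool) & (latent <= params.min_onset_age)
    if excluded.any():
        logger.info("excluding %d onsets at or below %.0f years", excluded.sum(),
                    params.min_onset_age)

    out = phenotypes.copy()
    out["onset_age"] = onset
    out["event"] = event
    out["observation_age"] = obs_age
    out["initiated"] = event
    return out.loc[~excluded].reset_index(drop=True)
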