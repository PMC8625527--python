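"""Synthetic cohorts and GWAS summary statistics with known ground truth.

Two families of generators:

* :func:`simulate_methylation_cohort` — a two-group (control / treated)
  methylation cohort shaped like a children's-blood 450k study: each
  gene owns a set of promoter probes and a set of body probes, beta
  values live in (0, 1), and a chosen subset of "effect" genes has its
  body-probe methylation shifted in the treated group only.  Noise is
  added on the logit scale and mapped back through the inverse logit,
  which keeps betas in range without clipping.  Default group sizes
  (179 control / 190 treated) match the cohort the pipeline is designed
  around.

* :func:`simulate_gwas_pair` / :func:`simulate_gwas_triplet` — two-
  sample MR inputs.  Instrument effects gamma_j on the exposure are
  drawn from a configurable distribution; outcome effects are
  theta * gamma_j + alpha_j + e_j where alpha_j is a per-SNP pleiotropy
  term (directional when its mean is nonzero) and e_j is estimation
  noise at the outcome's standard error.  SEs follow the usual
  1 / sqrt(2 N maf (1 - maf)) scaling, p-values the normal reference.
  The triplet version links two pairs through a mediator so a two-step
  analysis runs end to end, with ground-truth theta1 and theta2.

Every generator is a pure function of its config, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats
from scipy.special import expit

__all__ = [
    "MethylSimConfig",
    "GwasSimConfig",
    "GroundTruth",
    "simulate_methylation_cohort",
    "simulate_gwas_pair",
    "simulate_gwas_triplet",
]

_NON_PALINDROMIC = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


class MethylSimConfig(BaseModel):
    """Configuration for the two-group methylation cohort generator.

    ``effect_size`` is a logit-scale shift applied to the body-probe
    values of effect genes in treated samples; ``noise_sd`` is the
    logit-scale probe-by-sample noise SD.
    """

    n_genes: int = Field(default=1000, ge=1)
    probes_per_region: tuple[int, int] = (2, 8)
    n_control: int = Field(default=179, ge=2)
    n_treated: int = Field(default=190, ge=2)
    effect_genes: int = Field(default=10, ge=0)
    effect_size: float = 1.0
    noise_sd: float = Field(default=0.5, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.probes_per_region[0] < 2 or self.probes_per_region[1] < self.probes_per_region[0]:
            raise ValueError("probes_per_region must satisfy 2 <= min <= max")
        if self.effect_genes > self.n_genes:
            raise ValueError("effect_genes must not exceed n_genes")
        return self


class GwasSimConfig(BaseModel):
    """Configuration for one exposure/outcome GWAS summary-stat pair.

    ``instrument_strength`` is the (mean, sd) of true per-SNP exposure
    effects; ``n_exposure`` / ``n_outcome`` are effective GWAS sample
    sizes governing the SEs; ``theta`` the true causal effect;
    ``pleiotropy_mean`` / ``pleiotropy_sd`` parameterise the per-SNP
    direct (pleiotropic) effects on the outcome, applied to a
    ``frac_pleiotropic`` fraction of instruments;
    ``correlated_pleiotropy`` ties pleiotropy to instrument strength,
    breaking the InSIDE assumption.
    """

    n_snps: int = Field(default=50, ge=1)
    instrument_strength: tuple[float, float] = (0.15, 0.07)
    n_exposure: int = Field(default=500000, ge=10)
    n_outcome: int = Field(default=50000, ge=10)
    theta: float = 0.3
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = Field(default=0.0, ge=0)
    frac_pleiotropic: float = Field(default=1.0, ge=0, le=1)
    correlated_pleiotropy: bool = False
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_palindromic: float = Field(default=0.1, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < min <= max <= 0.5")
        if self.instrument_strength[1] < 0:
            raise ValueError("instrument_strength sd must be >= 0")
        return self


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery."""

    effect_gene_ids: list[str] = field(default_factory=list)
    theta: float | None = None
    theta1: float | None = None
    theta2: float | None = None
    pleiotropy: pd.Series | None = None  # per-SNP alpha_j
    gamma: pd.Series | None = None  # per-SNP true exposure effects


def simulate_methylation_cohort(
    cfg: MethylSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, GroundTruth]:
    """Generate (beta matrix, probe annotation, groups, ground truth).

    Per gene, promoter and body baseline logits are drawn to mimic the
    canonical pattern (hypomethylated promoters, methylated bodies);
    probe-by-sample noise is added on the logit scale; effect genes get
    ``effect_size`` added to body-probe logits of treated samples only.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_control + cfg.n_treated
    sample_ids = [f"ctrl_{i+1}" for i in range(cfg.n_control)] + [
        f"trt_{i+1}" for i in range(cfg.n_treated)
    ]
    groups = pd.Series(
        ["control"] * cfg.n_control + ["treated"] * cfg.n_treated,
        index=pd.Index(sample_ids, name="sample_id"),
        name="group",
    )
    treated_mask = (groups == "treated").to_numpy()

    gene_ids = [f"G{i+1:04d}" for i in range(cfg.n_genes)]
    effect_ids = set(gene_ids[: cfg.effect_genes])

    lo, hi = cfg.probes_per_region
    annot_rows = []
    blocks = []
    for gene in gene_ids:
        n_prom = int(rng.integers(lo, hi + 1))
        n_body = int(rng.integers(lo, hi + 1))
        mu_prom = rng.normal(-2.0, 0.5)
        mu_body = rng.normal(1.0, 0.5)

        logits = np.empty((n_prom + n_body, n_samples))
        logits[:n_prom] = mu_prom
        logits[n_prom:] = mu_body
        if gene in effect_ids:
            logits[n_prom:, treated_mask] += cfg.effect_size
        logits += rng.normal(0.0, cfg.noise_sd, size=logits.shape)
        blocks.append(expit(logits))

        for k in range(n_prom):
            annot_rows.append((f"{gene}_p{k+1}", gene, "promoter"))
        for k in range(n_body):
            annot_rows.append((f"{gene}_b{k+1}", gene, "body"))

    annot = pd.DataFrame(annot_rows, columns=["probe_id", "gene", "region"])
    beta = pd.DataFrame(
        np.vstack(blocks),
        index=pd.Index(annot["probe_id"].to_numpy(), name="probe_id"),
        columns=sample_ids,
    )
    truth = GroundTruth(effect_gene_ids=sorted(effect_ids))
    return beta, annot, groups, truth


def _gwas_table(
    rng: np.random.Generator,
    snps: list[str],
    true_beta: np.ndarray,
    maf: np.ndarray,
    n_eff: int,
    alleles: list[tuple[str, str]],
    eaf: np.ndarray,
    trait: str,
) -> pd.DataFrame:
    se = 1.0 / np.sqrt(2.0 * n_eff * maf * (1.0 - maf))
    beta_hat = rng.normal(true_beta, se)
    z = np.abs(beta_hat / se)
    pval = np.maximum(2.0 * stats.norm.sf(z), np.finfo(float).tiny)
    return pd.DataFrame(
        {
            "snp": snps,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "beta": beta_hat,
            "se": se,
            "pval": pval,
            "eaf": eaf,
            "trait": trait,
        }
    )


def _draw_alleles(rng: np.random.Generator, n: int, frac_palindromic: float):
    alleles = []
    for _ in range(n):
        if rng.random() < frac_palindromic:
            alleles.append(_PALINDROMIC[rng.integers(len(_PALINDROMIC))])
        else:
            alleles.append(_NON_PALINDROMIC[rng.integers(len(_NON_PALINDROMIC))])
    return alleles


def _draw_pleiotropy(rng: np.random.Generator, cfg: GwasSimConfig, gamma: np.ndarray) -> np.ndarray:
    alpha = np.zeros(cfg.n_snps)
    affected = rng.random(cfg.n_snps) < cfg.frac_pleiotropic
    if affected.any() and (cfg.pleiotropy_mean != 0 or cfg.pleiotropy_sd > 0):
        draws = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=int(affected.sum()))
        if cfg.correlated_pleiotropy:
            # tie pleiotropy to instrument strength: violates InSIDE
            g = gamma[affected]
            draws = draws * (g / np.mean(np.abs(gamma)))
        alpha[affected] = draws
    return alpha


def simulate_gwas_pair(
    cfg: GwasSimConfig, snp_prefix: str = "rs"
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (exposure table, outcome table, ground truth).

    Exposure and outcome tables share the full rsID universe; allele
    labels agree between tables (harmonization stress tests rearrange
    them explicitly).
    """
    rng = np.random.default_rng(cfg.seed)
    snps = [f"{snp_prefix}{i+1}" for i in range(cfg.n_snps)]
    gamma = rng.normal(*cfg.instrument_strength, size=cfg.n_snps)
    maf = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    alleles = _draw_alleles(rng, cfg.n_snps, cfg.frac_palindromic)
    alpha = _draw_pleiotropy(rng, cfg, gamma)
    # the effect allele is the same physical allele in both studies, so
    # its frequency side is a per-SNP property shared by both tables
    eaf = np.where(rng.random(cfg.n_snps) < 0.5, maf, 1.0 - maf)

    exposure = _gwas_table(rng, snps, gamma, maf, cfg.n_exposure, alleles, eaf, "exposure")
    outcome = _gwas_table(
        rng, snps, cfg.theta * gamma + alpha, maf, cfg.n_outcome, alleles, eaf, "outcome"
    )
    truth = GroundTruth(
        theta=cfg.theta,
        pleiotropy=pd.Series(alpha, index=snps, name="pleiotropy"),
        gamma=pd.Series(gamma, index=snps, name="gamma"),
    )
    return exposure, outcome, truth


def simulate_gwas_triplet(
    cfg1: GwasSimConfig,
    cfg2: GwasSimConfig,
    shared_snps: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (exposure, mediator, outcome) tables for two-step MR.

    ``cfg1`` governs the exposure -> mediator pair (theta1 =
    ``cfg1.theta``), ``cfg2`` the mediator -> outcome pair (theta2 =
    ``cfg2.theta``).  ``shared_snps`` limits how many of each step's
    instruments appear in the downstream table (default: all); with
    ``shared_snps=0`` the harmonization join is empty and the two-step
    runner raises.
    """
    if shared_snps is not None and shared_snps > min(cfg1.n_snps, cfg2.n_snps):
        raise ValueError("shared_snps must not exceed either n_snps")

    exp_tab, med_from_exp, truth1 = simulate_gwas_pair(cfg1, snp_prefix="rsA")
    cfg2b = cfg2.model_copy(update={"seed": cfg2.seed + 1})
    med_own, out_tab, truth2 = simulate_gwas_pair(cfg2b, snp_prefix="rsB")

    if shared_snps is not None:
        med_from_exp = med_from_exp.iloc[:shared_snps]
        out_tab = out_tab.iloc[:shared_snps]

    mediator = pd.concat([med_from_exp, med_own], ignore_index=True)
    mediator["trait"] = "mediator"
    exp_tab = exp_tab.assign(trait="exposure")
    out_tab = out_tab.assign(trait="outcome")

    truth = GroundTruth(
        theta1=cfg1.theta,
        theta2=cfg2.theta,
        pleiotropy=pd.concat([truth1.pleiotropy, truth2.pleiotropy]),
        gamma=pd.concat([truth1.gamma, truth2.gamma]),
    )
    return exp_tab, mediator, out_tab, truth
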