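"""Synthetic two-sample GWAS summary statistics with known ground truth.

Summary statistics are simulated directly on the summary scale rather than
via individual-level genotypes: for a variance-standardised trait the
sampling variance of a per-allele estimate at allele frequency p and sample
size n is approximately sigma² = 1/(2 n p (1 − p)). Exposure and outcome
effects receive *independent* noise draws, emulating two non-overlapping GWAS
samples.

The generative model per SNP j:

* allele frequency p_j ~ Uniform(maf_range);
* true SNP-exposure effect b_j ~ Normal(0, sigma_b²) (zero for reverse SNPs);
* horizontal pleiotropy alpha_j ~ Normal(mu_alpha, tau_alpha²) for an
  ``invalid_fraction`` share of SNPs, zero otherwise. Directional pleiotropy
  is defined on the *exposure-increasing allele orientation* (the convention
  under which an Egger intercept measures it), so in the coded-allele frame
  the contribution is sign(b_j)·alpha_j. Pleiotropy is drawn independently of
  b_j, i.e. the InSIDE condition holds;
* reverse-causal SNPs have b_j = 0 and a direct outcome effect
  d_j ~ Normal(0, reverse_effect_sd²);
* true SNP-outcome effect beta_Yj = theta·b_j + sign(b_j)·alpha_j + d_j.

An optional mediation block adds a covariate trait C with SNP effects g_j:
exposure effects become b_j = gamma·g_j + own component and outcome effects
theta·b_j + delta·g_j, mirroring a height/educational-attainment conditioning
design for multivariable MR. An optional LD block structure generates
correlated effect estimates plus the matching r² matrix for clumping tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from .exceptions import ValidationError
from .instruments import LDMatrix
from .summary_gwas import SummaryTable, table_from_arrays

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class MediationConfig:
    """Covariate-mediated structure: SNP → covariate → exposure/outcome."""

    gamma: float = 0.4  # covariate -> exposure
    delta: float = 0.3  # covariate -> outcome (direct, not via exposure)
    sigma_g: float = 0.05  # SD of SNP -> covariate effects
    n_cov: int = 353_315  # covariate GWAS sample size (UKBB scale)


@dataclass
class SimulationConfig:
    """Full generative specification. ``seed`` is mandatory."""

    seed: int
    J: int = 100
    n_x: int = 100_000
    n_y: int = 100_000
    theta: float = 0.2
    maf_range: tuple[float, float] = (0.05, 0.5)
    sigma_b: float = 0.05
    invalid_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_reverse: int = 0
    reverse_effect_sd: float = 0.05
    palindromic_fraction: float = 0.1
    mediation: MediationConfig | None = None
    ld_blocks: list[tuple[int, float]] | None = None
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    covariate_name: str = "covariate"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValidationError("invalid_fraction must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        if self.n_x <= 2 or self.n_y <= 2:
            raise ValidationError("sample sizes must exceed 2")
        if self.J < 1:
            raise ValidationError("J must be >= 1")
        if self.n_reverse < 0 or self.n_reverse > self.J:
            raise ValidationError("n_reverse must be in [0, J]")
        if self.ld_blocks:
            for size, r2 in self.ld_blocks:
                if size < 1:
                    raise ValidationError("LD block sizes must be >= 1")
                if not 0.0 <= r2 <= 1.0:
                    raise ValidationError("LD block r2 must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        med = raw.pop("mediation", None)
        if med is not None:
            med = MediationConfig(**med)
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        if raw.get("ld_blocks"):
            raw["ld_blocks"] = [tuple(b) for b in raw["ld_blocks"]]
        return cls(mediation=med, **raw)


@dataclass
class GroundTruth:
    """Per-dataset truth for estimator validation."""

    theta: float
    b: np.ndarray  # true SNP-exposure effects
    alpha: np.ndarray  # pleiotropy in the exposure-increasing orientation
    labels: list[str]  # valid | pleiotropic | reverse
    beta_y_true: np.ndarray
    reverse_effects: np.ndarray | None = None
    #: mediation bookkeeping: direct effect and implied univariable slope
    theta_direct: float | None = None
    univariable_slope: float | None = None
    g: np.ndarray | None = None
    tag_ids: list[str] | None = None

    def write(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame({"b_true": self.b, "alpha": self.alpha, "label": self.labels,
                           "beta_y_true": self.beta_y_true})
        df.to_csv(path, sep="\t", index=False)


def _se_std_trait(n: int | np.ndarray, p: np.ndarray) -> np.ndarray:
    """Sampling SD of a per-allele estimate, variance-standardised trait."""
    return 1.0 / np.sqrt(2.0 * np.asarray(n, dtype=float) * p * (1.0 - p))


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.maximum(p, np.finfo(float).tiny)


def _alleles(rng: np.random.Generator, J: int, palindromic_fraction: float):
    pal = rng.random(J) < palindromic_fraction
    ea, oa = [], []
    for is_pal in pal:
        pool = _PALINDROMIC_PAIRS if is_pal else _NONPALINDROMIC_PAIRS
        a, b = pool[rng.integers(len(pool))]
        ea.append(a)
        oa.append(b)
    return ea, oa


def _positions(J: int) -> tuple[list[str], list[int]]:
    # spread SNPs across 22 chromosomes, >10 Mb apart so the default clumping
    # window never removes independently simulated SNPs
    chrom = [str(j % 22 + 1) for j in range(J)]
    pos = [1_000_000 + (j // 22) * 20_000_000 for j in range(J)]
    return chrom, pos


def simulate_two_sample(
    cfg: SimulationConfig,
) -> tuple[SummaryTable, SummaryTable, GroundTruth]:
    """Generate one exposure/outcome summary-statistics pair with truth."""
    rng = np.random.default_rng(cfg.seed)
    J = cfg.J
    p = rng.uniform(*cfg.maf_range, size=J)

    labels = np.array(["valid"] * J, dtype=object)
    idx = rng.permutation(J)
    rev_idx = idx[: cfg.n_reverse]
    labels[rev_idx] = "reverse"
    remaining = idx[cfg.n_reverse:]
    n_invalid = int(round(cfg.invalid_fraction * (J - cfg.n_reverse)))
    plei_idx = remaining[:n_invalid]
    labels[plei_idx] = "pleiotropic"

    b = rng.normal(0.0, cfg.sigma_b, size=J)
    b[rev_idx] = 0.0
    alpha = np.zeros(J)
    if n_invalid:
        alpha[plei_idx] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_invalid)
    d = np.zeros(J)
    if cfg.n_reverse:
        d[rev_idx] = rng.normal(0.0, cfg.reverse_effect_sd, size=cfg.n_reverse)

    orient = np.where(b < 0, -1.0, 1.0)  # pleiotropy directional on the b>0 frame
    beta_y_true = cfg.theta * b + orient * alpha + d

    se_x = _se_std_trait(cfg.n_x, p)
    se_y = _se_std_trait(cfg.n_y, p)
    bx_obs = b + rng.normal(0.0, se_x)
    by_obs = beta_y_true + rng.normal(0.0, se_y)

    snp_ids = [f"rs{j + 1}" for j in range(J)]
    chrom, pos = _positions(J)
    ea, oa = _alleles(rng, J, cfg.palindromic_fraction)

    exposure = table_from_arrays(
        cfg.exposure_name, snp_ids, chrom, pos, ea, oa, p,
        bx_obs, se_x, _pvals(bx_obs, se_x), [cfg.n_x] * J,
    )
    outcome = table_from_arrays(
        cfg.outcome_name, snp_ids, chrom, pos, ea, oa, p,
        by_obs, se_y, _pvals(by_obs, se_y), [cfg.n_y] * J,
    )
    truth = GroundTruth(
        theta=cfg.theta, b=b, alpha=alpha, labels=list(labels),
        beta_y_true=beta_y_true, reverse_effects=d,
    )
    return exposure, outcome, truth


def simulate_mediated(
    cfg: SimulationConfig,
) -> tuple[SummaryTable, SummaryTable, SummaryTable, GroundTruth]:
    """Generate exposure, covariate and outcome tables with a mediation path.

    SNP → covariate effects g_j feed the exposure (gamma·g_j) and the outcome
    directly (delta·g_j); ``cfg.theta`` is the *direct* exposure → outcome
    effect. The truth records the implied univariable (confounded) slope
    (theta + delta·gamma·sigma_g² / var(b)).
    """
    if cfg.mediation is None:
        raise ValidationError("simulate_mediated requires cfg.mediation")
    med = cfg.mediation
    rng = np.random.default_rng(cfg.seed)
    J = cfg.J
    p = rng.uniform(*cfg.maf_range, size=J)

    g = rng.normal(0.0, med.sigma_g, size=J)
    b_own = rng.normal(0.0, cfg.sigma_b, size=J)
    b = med.gamma * g + b_own
    beta_y_true = cfg.theta * b + med.delta * g

    se_x = _se_std_trait(cfg.n_x, p)
    se_y = _se_std_trait(cfg.n_y, p)
    se_g = _se_std_trait(med.n_cov, p)
    bx_obs = b + rng.normal(0.0, se_x)
    by_obs = beta_y_true + rng.normal(0.0, se_y)
    bg_obs = g + rng.normal(0.0, se_g)

    snp_ids = [f"rs{j + 1}" for j in range(J)]
    chrom, pos = _positions(J)
    ea, oa = _alleles(rng, J, cfg.palindromic_fraction)

    def table(name: str, beta, se, n):
        return table_from_arrays(
            name, snp_ids, chrom, pos, ea, oa, p, beta, se, _pvals(beta, se), [n] * J
        )

    var_b = med.gamma**2 * med.sigma_g**2 + cfg.sigma_b**2
    truth = GroundTruth(
        theta=cfg.theta, b=b, alpha=np.zeros(J), labels=["valid"] * J,
        beta_y_true=beta_y_true, g=g,
        theta_direct=cfg.theta,
        univariable_slope=cfg.theta + med.delta * med.gamma * med.sigma_g**2 / var_b,
    )
    return (
        table(cfg.exposure_name, bx_obs, se_x, cfg.n_x),
        table(cfg.covariate_name, bg_obs, se_g, med.n_cov),
        table(cfg.outcome_name, by_obs, se_y, cfg.n_y),
        truth,
    )


def simulate_ld(
    cfg: SimulationConfig,
) -> tuple[SummaryTable, LDMatrix, GroundTruth]:
    """Generate an exposure table with block-correlated effect estimates plus
    the matching r² matrix (block-diagonal, zero off-block).

    Within a block the first SNP is the causal "tag"; other members' expected
    effects are attenuated by r = √r² (standard LD tagging) and their noise is
    correlated at r via a shared-component construction. Blocks are placed
    within the default clumping window on distinct chromosomes; any SNPs
    beyond the blocks (up to ``cfg.J``) are independent.
    """
    blocks = cfg.ld_blocks or []
    rng = np.random.default_rng(cfg.seed)
    n_block_snps = sum(size for size, _ in blocks)
    J = max(cfg.J, n_block_snps)
    n_free = J - n_block_snps

    p = rng.uniform(*cfg.maf_range, size=J)
    se_x = _se_std_trait(cfg.n_x, p)

    r2_mat = np.eye(J)
    beta_obs = np.empty(J)
    b_true = np.empty(J)
    chrom: list[str] = []
    pos: list[int] = []
    tag_ids: list[str] = []
    snp_ids = [f"rs{j + 1}" for j in range(J)]

    cursor = 0
    for k, (size, r2) in enumerate(blocks):
        r = float(np.sqrt(r2))
        sl = slice(cursor, cursor + size)
        b_tag = rng.normal(0.0, cfg.sigma_b)
        means = np.full(size, b_tag * r)
        means[0] = b_tag
        shared = rng.normal()
        indiv = rng.normal(size=size)
        noise = np.sqrt(r) * shared + np.sqrt(1.0 - r) * indiv  # corr(noise_i, noise_j) = r
        beta_obs[sl] = means + se_x[sl] * noise
        b_true[sl] = means
        r2_mat[sl, sl] = r2
        np.fill_diagonal(r2_mat[sl, sl], 1.0)
        # members 1 kb apart: well inside any sensible clumping window
        chrom.extend([str(k % 22 + 1)] * size)
        pos.extend(1_000_000 + 50_000_000 * (k // 22) + 1000 * i for i in range(size))
        tag_ids.append(snp_ids[cursor])
        cursor += size

    if n_free:
        b_free = rng.normal(0.0, cfg.sigma_b, size=n_free)
        beta_obs[cursor:] = b_free + rng.normal(0.0, se_x[cursor:])
        b_true[cursor:] = b_free
        fc, fp = _positions(n_free)
        # keep free SNPs clear of the block chromosomes' windows
        chrom.extend(fc)
        pos.extend(400_000_000 + x for x in fp)

    ea, oa = _alleles(rng, J, cfg.palindromic_fraction)
    table = table_from_arrays(
        cfg.exposure_name, snp_ids, chrom, pos, ea, oa, p,
        beta_obs, se_x, _pvals(beta_obs, se_x), [cfg.n_x] * J,
    )
    truth = GroundTruth(
        theta=cfg.theta, b=b_true, alpha=np.zeros(J), labels=["valid"] * J,
        beta_y_true=cfg.theta * b_true, tag_ids=tag_ids,
    )
    return table, LDMatrix(snp_ids, r2_mat), truth
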