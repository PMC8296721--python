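"""Multivariable Mendelian randomization (MVMR).

MVMR regresses the SNP-outcome effects jointly on the SNP effects for K ≥ 2
exposures (e.g. a lung-function measure plus a covariate such as height or
educational attainment), estimating each exposure's *direct* effect on the
outcome conditional on the others. This is the standard remedy when the
univariable instrument list may act through a covariate (mediation or
covariate-adjusted-GWAS collider structure).

The design is assembled as the union of SNPs reaching the significance
threshold for any exposure, jointly clumped (ranked by the best p-value
across exposures), with every SNP's association looked up against every
exposure and the outcome and harmonized to a common effect allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .exceptions import (
    CollinearityError,
    ConfigurationError,
    UnderIdentifiedError,
    ValidationError,
)
from .instruments import LDMatrix, greedy_clump, per_snp_f
from .summary_gwas import SummaryTable, harmonize

logger = logging.getLogger(__name__)


@dataclass
class MvmrDesign:
    """J×K design of SNP effects on K exposures plus SNP-outcome effects."""

    snp_ids: list[str]
    beta_x: np.ndarray  # J x K
    se_x: np.ndarray  # J x K
    beta_y: np.ndarray
    se_y: np.ndarray
    exposure_names: list[str]
    #: SNP counts attributed to each exposure's discovery list
    n_snp_per_source: dict[str, int] = field(default_factory=dict)
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, dtype=float))
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        J, K = self.beta_x.shape
        if K < 2:
            raise ValidationError("MVMR needs K >= 2 exposures")
        if J <= K:
            raise UnderIdentifiedError(f"MVMR needs J > K instruments, got J={J}, K={K}")
        if len(self.snp_ids) != J or len(self.beta_y) != J or len(self.se_y) != J:
            raise ValidationError("MVMR design vectors must share length J")
        if self.se_x.shape != (J, K):
            raise ValidationError("se_x must match beta_x shape")
        if np.any(~np.isfinite(self.beta_x)) or np.any(~np.isfinite(self.beta_y)):
            raise ValidationError("MVMR design contains missing associations")
        if np.any(self.se_y <= 0):
            raise ValidationError("all outcome SEs must be > 0")

    @property
    def J(self) -> int:
        return self.beta_x.shape[0]

    @property
    def K(self) -> int:
        return self.beta_x.shape[1]


@dataclass
class MvmrEstimate:
    """Per-exposure direct effects conditional on the other exposures."""

    exposure_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    n_snp_total: int
    n_snp_per_source: dict[str, int]
    q_mv: float
    q_df: int
    #: per-exposure mean marginal F — a crude strength summary, not a
    #: conditional F statistic
    mean_f_per_exposure: np.ndarray | None = None

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            name: {"beta": float(b), "se": float(s), "pval": float(p)}
            for name, b, s, p in zip(self.exposure_names, self.beta, self.se, self.pval)
        }


def build_design(
    primary: SummaryTable,
    covariate: SummaryTable,
    full_assoc: Mapping[str, SummaryTable],
    outcome_name: str,
    ld: LDMatrix | None = None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    intermediate_window: float = 0.08,
) -> MvmrDesign:
    """Assemble an MVMR design from two discovery lists and a full lookup.

    ``primary`` and ``covariate`` are the exposure discovery tables; the
    candidate set is the union of their SNPs passing ``p_threshold``. The
    union is jointly clumped (rank = best p across the two exposures), then
    every retained SNP's association with each exposure and with the outcome
    is pulled from ``full_assoc`` (a mapping trait name -> SummaryTable that
    must cover both exposures and ``outcome_name``) and harmonized to the
    primary exposure's effect allele. SNPs missing any association are
    dropped and logged.
    """
    for trait in (primary.trait_name, covariate.trait_name, outcome_name):
        if trait not in full_assoc:
            raise ConfigurationError(
                f"full association lookup missing trait {trait!r}"
            )
    sig_primary = {r.snp_id: r for r in primary.records if r.pval < p_threshold}
    sig_covar = {r.snp_id: r for r in covariate.records if r.pval < p_threshold}
    log: list[tuple[str, str, str]] = []

    # union candidate records ranked by the best discovery p across exposures
    union: dict[str, object] = {}
    best_p: dict[str, float] = {}
    source: dict[str, str] = {}
    for sid, rec in sig_primary.items():
        union[sid] = rec
        best_p[sid] = rec.pval
        source[sid] = primary.trait_name
    for sid, rec in sig_covar.items():
        if sid not in union:
            union[sid] = rec
            best_p[sid] = rec.pval
            source[sid] = covariate.trait_name
        elif rec.pval < best_p[sid]:
            # attribution follows the smaller discovery p; ties stay primary
            best_p[sid] = rec.pval
            source[sid] = covariate.trait_name
    if not union:
        raise ConfigurationError(
            f"no SNP passes p < {p_threshold} for either exposure"
        )

    ranked = [replace(union[sid], pval=best_p[sid]) for sid in union]
    rank_table = SummaryTable("mvmr_union", ranked)
    if ld is not None:
        clumped = greedy_clump(rank_table, ld, r2_threshold, window_kb)
        kept_ids = set(clumped.table.ids())
        log.extend(clumped.selection_log)
    else:
        kept_ids = set(rank_table.ids())

    exposures = [primary.trait_name, covariate.trait_name]
    assoc = {t: {r.snp_id: r for r in full_assoc[t].records} for t in exposures}
    # harmonize each exposure lookup against the outcome, aligned per exposure
    harmonized = {}
    for t in exposures:
        sub_ids = [s for s in kept_ids if s in assoc[t]]
        missing = kept_ids - set(sub_ids)
        for s in sorted(missing):
            log.append((s, "missing_assoc", t))
        sub = SummaryTable(t, [assoc[t][s] for s in sorted(sub_ids)])
        harmonized[t] = harmonize(
            sub, full_assoc[outcome_name], intermediate_window=intermediate_window
        )
    common = sorted(
        set(harmonized[exposures[0]].snp_ids) & set(harmonized[exposures[1]].snp_ids)
    )
    dropped_any = kept_ids - set(common)
    for s in sorted(dropped_any):
        if not any(entry[0] == s for entry in log):
            log.append((s, "harmonization", "dropped for at least one exposure"))
    if not common:
        raise ConfigurationError("no SNP survives harmonization for both exposures")

    h0 = harmonized[exposures[0]]
    h1 = harmonized[exposures[1]]
    i0 = {s: i for i, s in enumerate(h0.snp_ids)}
    i1 = {s: i for i, s in enumerate(h1.snp_ids)}
    # outcome vectors from the two pairwise harmonizations are aligned to each
    # exposure's effect allele; re-express exposure 2 on exposure 1's allele by
    # matching the sign of the shared outcome effect
    bx = np.empty((len(common), 2))
    sx = np.empty((len(common), 2))
    by = np.empty(len(common))
    sy = np.empty(len(common))
    for j, s in enumerate(common):
        a, b = i0[s], i1[s]
        by[j] = h0.beta_y[a]
        sy[j] = h0.se_y[a]
        bx[j, 0] = h0.beta_x[a]
        sx[j, 0] = h0.se_x[a]
        # both pairwise harmonizations aligned the *same* outcome record; if
        # they chose opposite effect alleles the outcome betas are negated
        flip = 1.0 if np.isclose(h1.beta_y[b], h0.beta_y[a]) else -1.0
        bx[j, 1] = flip * h1.beta_x[b]
        sx[j, 1] = h1.se_x[b]

    counts = {primary.trait_name: 0, covariate.trait_name: 0}
    for s in common:
        counts[source.get(s, primary.trait_name)] += 1

    design = MvmrDesign(
        snp_ids=list(common),
        beta_x=bx,
        se_x=sx,
        beta_y=by,
        se_y=sy,
        exposure_names=exposures,
        n_snp_per_source=counts,
        selection_log=log,
    )
    return design


def mvmr_ivw(d: MvmrDesign) -> MvmrEstimate:
    """Multivariable IVW: weighted least squares of β_Y on the K exposure
    columns with weights σ_Y⁻² and no intercept.

    SEs are inflated by max(1, √(Q_mv/(J−K))) where Q_mv is the weighted
    residual sum of squares; p-values use the t distribution with J−K df.
    """
    X, y = d.beta_x, d.beta_y
    w = d.se_y**-2.0
    A = X.T @ (w[:, None] * X)
    rank = np.linalg.matrix_rank(A, tol=1e-12 * np.abs(A).max())
    if rank < d.K:
        # find the most collinear pair to name in the error
        C = np.corrcoef(X.T)
        off = np.abs(C - np.eye(d.K))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise CollinearityError(
            f"exposure-effect columns {d.exposure_names[i]!r} and "
            f"{d.exposure_names[j]!r} are collinear (|r| = {off[i, j]:.4f})"
        )
    coef = np.linalg.solve(A, X.T @ (w * y))
    resid = y - X @ coef
    q_mv = float(np.sum(w * resid**2))
    df = d.J - d.K
    scale = max(1.0, np.sqrt(q_mv / df))
    se = np.sqrt(np.diag(np.linalg.inv(A))) * scale
    tstat = coef / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    mean_f = np.array(
        [float(np.mean(per_snp_f(d.beta_x[:, k], d.se_x[:, k]))) for k in range(d.K)]
    )
    return MvmrEstimate(
        exposure_names=list(d.exposure_names),
        beta=coef,
        se=se,
        pval=np.maximum(pval, np.finfo(float).tiny),
        n_snp_total=d.J,
        n_snp_per_source=dict(d.n_snp_per_source),
        q_mv=q_mv,
        q_df=df,
        mean_f_per_exposure=mean_f,
    )
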