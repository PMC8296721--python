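"""Univariable two-sample MR estimators and heterogeneity diagnostics.

All estimators consume a :class:`~mrkit.summary_gwas.HarmonizedSet` holding
aligned SNP-exposure effects (β_Xj, σ_Xj) and SNP-outcome effects
(β_Yj, σ_Yj) for J instruments.

* **Wald ratio** — β_Yj/β_Xj for a single SNP, first-order SE σ_Yj/|β_Xj|.
* **IVW** — inverse-variance-weighted meta-analysis of Wald ratios, i.e. a
  weighted regression of β_Y on β_X through the origin with weights σ_Yj⁻².
  The default multiplicative random-effects model scales the fixed-effect SE
  by max(1, √(Q/(J−1))) to absorb overdispersion.
* **MR-Egger** — the same weighted regression with a free intercept after
  orienting every SNP to a non-negative exposure effect; the intercept
  estimates average directional pleiotropy, the slope the causal effect under
  the InSIDE assumption. Inference uses the t distribution on J−2 df.
* **Weighted median / weighted mode** — quantile and kernel-mode estimators
  of the ratio distribution, consistent under partial instrument invalidity;
  SEs come from a seeded parametric bootstrap.
* **Cochran Q** and a **radial outlier scan** expose per-SNP heterogeneity
  contributions Q_j; the scan flags SNPs contributing more than a fraction
  (default 5%) of total Q, or exceeding a χ²(1) quantile, and re-estimates
  IVW without them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    AllOutliersError,
    DegenerateDesignError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
    ValidationError,
)
from .summary_gwas import HarmonizedSet

Method = Literal["Wald", "IVW", "Egger", "WeightedMedian", "WeightedMode"]


@dataclass
class MREstimate:
    """One method's causal estimate.

    ``beta`` is the causal effect per unit of the exposure (SD of a
    quantitative trait, log-odds for a binary one). Heterogeneity fields are
    populated where defined; Egger additionally carries its intercept
    (average directional pleiotropy) with SE and p-value.
    """

    method: Method
    beta: float
    se: float
    pval: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return self.beta - z * self.se, self.beta + z * self.se


def _norm_p(z: float) -> float:
    return float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MREstimate:
    """Single-SNP causal estimate β_Y/β_X with first-order delta-method SE."""
    if beta_x == 0:
        raise UndefinedRatioError("Wald ratio undefined for beta_x = 0")
    if se_y <= 0:
        raise ValidationError("se_y must be > 0")
    beta = beta_y / beta_x
    se = se_y / abs(beta_x)
    return MREstimate("Wald", beta, se, _norm_p(beta / se), n_snp=1)


def _check_h(h: HarmonizedSet, min_snps: int, method: str) -> None:
    if len(h) < min_snps:
        raise InsufficientInstrumentsError(
            f"{method} needs at least {min_snps} instruments, got {len(h)}"
        )


def ivw(h: HarmonizedSet, model: Literal["fixed", "random"] = "random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted regression of β_Y on β_X through the origin with weights σ_Y⁻²:
    β̂ = Σ wβ_Xβ_Y / Σ wβ_X². Fixed-effect SE is (Σ wβ_X²)^(-1/2); the default
    multiplicative random-effects model inflates it by max(1, √(Q/(J−1))).
    """
    _check_h(h, 1, "IVW")
    J = len(h)
    if J == 1:
        est = wald_ratio(h.beta_x[0], h.se_x[0], h.beta_y[0], h.se_y[0])
        est.method = "IVW"
        return est
    w = h.se_y**-2.0
    sxx = float(np.sum(w * h.beta_x**2))
    if sxx == 0.0:
        raise DegenerateDesignError("all SNP-exposure effects are zero")
    beta = float(np.sum(w * h.beta_x * h.beta_y)) / sxx
    se_fixed = sxx**-0.5
    q = float(np.sum(w * (h.beta_y - beta * h.beta_x) ** 2))
    q_df = J - 1
    scale = max(1.0, np.sqrt(q / q_df)) if model == "random" else 1.0
    se = se_fixed * scale
    return MREstimate(
        "IVW", beta, se, _norm_p(beta / se), n_snp=J,
        q=q, q_df=q_df, q_pval=float(stats.chi2.sf(q, q_df)),
    )


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted fit of β_Y on β_X with a free intercept.

    Each SNP is first oriented so its exposure effect is non-negative (both
    members of the pair negated together). The intercept estimates average
    directional pleiotropy; under InSIDE the slope remains a consistent causal
    estimate. SEs are inflated by max(1, √(Q/(J−2))) and p-values use the t
    distribution with J−2 df.
    """
    _check_h(h, 3, "MR-Egger")
    J = len(h)
    s = np.where(h.beta_x < 0, -1.0, 1.0)
    bx, by = s * h.beta_x, s * h.beta_y
    w = h.se_y**-2.0
    if np.allclose(bx, bx[0]):
        raise DegenerateDesignError("no variance in oriented SNP-exposure effects")
    X = np.column_stack([np.ones(J), bx])
    A = X.T @ (w[:, None] * X)
    c = X.T @ (w * by)
    coef = np.linalg.solve(A, c)
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    df = J - 2
    scale = max(1.0, np.sqrt(q / df))
    cov_unscaled = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_unscaled)) * scale
    p = [float(2.0 * stats.t.sf(abs(coef[i] / se[i]), df)) for i in range(2)]
    return MREstimate(
        "Egger", float(coef[1]), float(se[1]), max(p[1], np.finfo(float).tiny), n_snp=J,
        intercept=float(coef[0]), intercept_se=float(se[0]), intercept_pval=max(p[0], np.finfo(float).tiny),
        q=q, q_df=df, q_pval=float(stats.chi2.sf(q, df)),
    )


def _ratios_weights(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    zero = np.flatnonzero(h.beta_x == 0)
    if zero.size:
        raise UndefinedRatioError(
            f"zero SNP-exposure effect for {h.snp_ids[zero[0]]}; ratio undefined"
        )
    r = h.beta_y / h.beta_x
    w = h.beta_x**2 / h.se_y**2  # inverse variance of the ratio, first order
    return r, w


def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r)
    r, w = r[order], w[order] / w.sum()
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, r))


def _weighted_quantile(r: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(r)
    r, w = r[order], w[order] / w.sum()
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(q, p, r))


def _bootstrap_se(
    h: HarmonizedSet,
    point_fn,
    n_boot: int,
    seed: int | None,
) -> float:
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(h.beta_x, h.se_x)
        by = rng.normal(h.beta_y, h.se_y)
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        reps[b] = point_fn(by / bx, bx**2 / h.se_y**2)
    sd = float(np.std(reps, ddof=1)) if n_boot > 1 else float("nan")
    return sd


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted median of the per-SNP Wald ratios.

    Ratios are sorted and assigned cumulative-midpoint positions
    p_j = Σ_{k≤j} w_k − w_j/2 (weights w_j = β_Xj²/σ_Yj² normalised to 1);
    the estimate interpolates the ratio at p = 0.5. Consistent when valid
    instruments carry a majority of the weight. SE from a seeded parametric
    bootstrap (``n_boot`` replicates).
    """
    _check_h(h, 2, "weighted median")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    r, w = _ratios_weights(h)
    beta = _weighted_median(r, w)
    se = _bootstrap_se(h, _weighted_median, n_boot, seed)
    pval = _norm_p(beta / se) if np.isfinite(se) and se > 0 else 1.0
    return MREstimate("WeightedMedian", beta, se if se > 0 else np.finfo(float).tiny,
                      pval, n_snp=len(h))


def _mode_bandwidth(r: np.ndarray, w: np.ndarray, factor: float) -> float:
    wn = w / w.sum()
    mean = float(np.sum(wn * r))
    sd = float(np.sqrt(np.sum(wn * (r - mean) ** 2)))
    iqr = _weighted_quantile(r, w, 0.75) - _weighted_quantile(r, w, 0.25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return factor * 0.9 * spread * len(r) ** (-0.2)


def _weighted_mode(r: np.ndarray, w: np.ndarray, factor: float = 1.0) -> float:
    bw = _mode_bandwidth(r, w, factor)
    if bw <= 0 or not np.isfinite(bw):
        return float(r[0])  # degenerate: all ratios (effectively) identical
    wn = w / w.sum()

    def neg_density(x: float) -> float:
        return -float(np.sum(wn * np.exp(-0.5 * ((x - r) / bw) ** 2)))

    # the KDE argmax lies within one bandwidth of some data point: evaluate the
    # density at every ratio, then refine around the best one.  A fixed grid
    # would lose the spike when stray extreme ratios stretch the range.
    dens_at_points = (wn[None, :] * np.exp(-0.5 * ((r[:, None] - r[None, :]) / bw) ** 2)).sum(axis=1)
    x0 = r[int(np.argmax(dens_at_points))]
    res = optimize.minimize_scalar(
        neg_density, bounds=(x0 - bw, x0 + bw), method="bounded"
    )
    return float(res.x)


def weighted_mode(
    h: HarmonizedSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based estimate: argmax of a weighted normal-kernel density over
    the per-SNP ratios.

    Bandwidth follows the Silverman-type rule
    h = factor × 0.9 × min(sd, IQR/1.34) × J^(−1/5) with weighted sd/IQR
    analogues; weights are inverse ratio variances. Consistent when the
    largest weight-share of instruments is valid. SE from a seeded parametric
    bootstrap.
    """
    _check_h(h, 3, "weighted mode")
    r, w = _ratios_weights(h)
    beta = _weighted_mode(r, w, bandwidth_factor)
    se = _bootstrap_se(h, lambda rr, ww: _weighted_mode(rr, ww, bandwidth_factor), n_boot, seed)
    pval = _norm_p(beta / se) if np.isfinite(se) and se > 0 else 1.0
    return MREstimate("WeightedMode", beta, se if se > 0 else np.finfo(float).tiny,
                      pval, n_snp=len(h))


def cochran_q(h: HarmonizedSet, estimate: MREstimate) -> tuple[float, int, float]:
    """Cochran heterogeneity statistic about a fitted estimate.

    Q = Σ v_j (r_j − β̂)² with ratio estimates r_j and first-order weights
    v_j = (β_Xj/σ_Yj)²; equivalently the weighted residual sum of squares of
    the regression. For Egger the residuals are taken about the fitted line
    (intercept included) and df = J − 2; otherwise df = J − 1.
    """
    _check_h(h, 2, "Cochran Q")
    J = len(h)
    w = h.se_y**-2.0
    if estimate.method == "Egger":
        s = np.where(h.beta_x < 0, -1.0, 1.0)
        resid = s * h.beta_y - (estimate.intercept + estimate.beta * (s * h.beta_x))
        df = J - 2
    else:
        _ratios_weights(h)  # raises on zero beta_x, matching the ratio form
        resid = h.beta_y - estimate.beta * h.beta_x
        df = J - 1
    q = float(np.sum(w * resid**2))
    return q, df, float(stats.chi2.sf(q, df))


@dataclass
class RadialScan:
    """Outcome of a radial outlier scan.

    ``q_contributions`` are the per-SNP heterogeneity contributions
    Q_j = v_j (r_j − β̂_IVW)², which sum to the IVW Cochran Q.
    """

    outlier_ids: list[str]
    rule: Literal["chi2", "fraction"]
    q_contributions: np.ndarray
    snp_ids: list[str]
    reestimate: MREstimate
    original: MREstimate = field(repr=False, default=None)  # type: ignore[assignment]


def radial_scan(
    h: HarmonizedSet,
    rule: Literal["chi2", "fraction"] = "fraction",
    alpha: float = 0.05,
    fraction_threshold: float = 0.05,
) -> RadialScan:
    """Flag heterogeneity outliers and re-estimate IVW without them.

    The default ``fraction`` rule flags any SNP contributing more than
    ``fraction_threshold`` (5%) of total Q; the ``chi2`` rule flags SNPs whose
    contribution exceeds the upper-``alpha`` χ²(1) quantile. A single pass —
    no iterative re-fitting.
    """
    _check_h(h, 3, "radial scan")
    fit = ivw(h)
    r, v = _ratios_weights(h)
    qj = v * (r - fit.beta) ** 2
    total = float(qj.sum())
    if rule == "fraction":
        flagged = qj > fraction_threshold * total if total > 0 else np.zeros(len(h), bool)
    elif rule == "chi2":
        flagged = qj > stats.chi2.isf(alpha, 1)
    else:
        raise ValidationError(f"unknown radial rule {rule!r}")
    if flagged.all():
        raise AllOutliersError(
            "every instrument flagged as an outlier; refusing to re-estimate"
        )
    sub = h.subset(~flagged)
    re_fit = ivw(sub) if len(sub) > 1 else wald_ratio(
        sub.beta_x[0], sub.se_x[0], sub.beta_y[0], sub.se_y[0]
    )
    return RadialScan(
        outlier_ids=[s for s, f in zip(h.snp_ids, flagged) if f],
        rule=rule,
        q_contributions=qj,
        snp_ids=list(h.snp_ids),
        reestimate=re_fit,
        original=fit,
    )


def estimate_all(
    h: HarmonizedSet,
    methods: Sequence[str] = ("ivw", "egger", "wmedian", "wmode"),
    ivw_model: Literal["fixed", "random"] = "random",
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[MREstimate]:
    """Run a panel of estimators on one harmonized set."""
    dispatch = {
        "ivw": lambda: ivw(h, model=ivw_model),
        "egger": lambda: egger(h),
        "wmedian": lambda: weighted_median(h, n_boot=n_boot, seed=seed),
        "wmode": lambda: weighted_mode(h, bandwidth_factor=bandwidth_factor,
                                       n_boot=n_boot, seed=seed),
        "wald": lambda: wald_ratio(h.beta_x[0], h.se_x[0], h.beta_y[0], h.se_y[0]),
    }
    out = []
    for m in methods:
        key = m.lower()
        if key not in dispatch:
            raise ValidationError(f"unknown method {m!r}; choose from {sorted(dispatch)}")
        out.append(dispatch[key]())
    return out
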