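"""Repeatable validation studies: oracle checks and simulation calibrations.

Each function runs a self-contained study against the package's own
generator and estimators and returns a small dict of summary numbers. They
back both the validation test-suite and the ``scripts/acceptance.py``
reporting script. Problem sizes default to the study conditions documented
in ``docs/methods.md``; every function takes a seed and is deterministic
given it.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .estimators import egger, ivw, weighted_median
from .instruments import LDMatrix, combined_f, greedy_clump, per_snp_f, steiger_filter
from .mvmr import MvmrDesign, mvmr_ivw
from .summary_gwas import HarmonizedSet, SummaryTable, harmonize
from .synthetic import MediationConfig, SimulationConfig, simulate_ld, simulate_mediated, simulate_two_sample

GENOME_WIDE_P = 5e-8


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _harmonized(exposure: SummaryTable, outcome: SummaryTable) -> HarmonizedSet:
    return harmonize(exposure, outcome)


# ---------------------------------------------------------------------------
# oracle equivalence


def _ivw_oracle(bx, by, sy):
    """Fixed-effect IVW by explicit weighted normal equations (1x1 solve)."""
    w = sy**-2.0
    A = np.array([[np.sum(w * bx * bx)]])
    c = np.array([np.sum(w * bx * by)])
    return float(np.linalg.solve(A, c)[0])


def _egger_oracle(bx, by, sy):
    """Egger coefficients by explicit 2x2 weighted normal equations."""
    s = np.where(bx < 0, -1.0, 1.0)
    bx, by = s * bx, s * by
    w = sy**-2.0
    A = np.array(
        [
            [np.sum(w), np.sum(w * bx)],
            [np.sum(w * bx), np.sum(w * bx * bx)],
        ]
    )
    c = np.array([np.sum(w * by), np.sum(w * bx * by)])
    icpt, slope = np.linalg.solve(A, c)
    return float(icpt), float(slope)


def oracle_equivalence(seed: int, n_instances: int = 10_000) -> dict[str, float]:
    """IVW and Egger vs explicit normal-equations solutions on random 3-10
    SNP instances; returns the largest absolute discrepancies."""
    rng = np.random.default_rng(seed)
    worst_ivw = worst_slope = worst_icpt = 0.0
    for _ in range(n_instances):
        J = int(rng.integers(3, 11))
        bx = rng.normal(0.0, 0.3, J)
        bx[bx == 0] = 0.1
        by = rng.normal(0.0, 0.3, J)
        sy = rng.uniform(0.01, 0.5, J)
        h = HarmonizedSet(
            snp_ids=[f"s{i}" for i in range(J)],
            beta_x=bx, se_x=np.full(J, 0.05), beta_y=by, se_y=sy,
            eaf=np.full(J, 0.3), n_x=np.full(J, 1e5), n_y=np.full(J, 1e5),
        )
        worst_ivw = max(worst_ivw, abs(ivw(h, model="fixed").beta - _ivw_oracle(bx, by, sy)))
        e = egger(h)
        oi, osl = _egger_oracle(bx, by, sy)
        worst_slope = max(worst_slope, abs(e.beta - osl))
        worst_icpt = max(worst_icpt, abs(e.intercept - oi))
    return {
        "ivw_max_abs_diff": worst_ivw,
        "egger_slope_max_abs_diff": worst_slope,
        "egger_intercept_max_abs_diff": worst_icpt,
        "n_instances": n_instances,
    }


# ---------------------------------------------------------------------------
# IVW calibration


def ivw_recovery(
    seed: int,
    n_rep: int = 500,
    theta: float = 0.2,
    J: int = 100,
    n: int = 100_000,
) -> dict[str, float]:
    """Mean IVW estimate and 95% CI coverage under a clean causal model."""
    est = np.empty(n_rep)
    cover = np.empty(n_rep, bool)
    for i, s in enumerate(_child_seeds(seed, n_rep)):
        cfg = SimulationConfig(seed=s, J=J, n_x=n, n_y=n, theta=theta)
        exp, out, _ = simulate_two_sample(cfg)
        fit = ivw(_harmonized(exp, out))
        est[i] = fit.beta
        lo, hi = fit.ci()
        cover[i] = lo <= theta <= hi
    return {
        "theta": theta,
        "mean_estimate": float(est.mean()),
        "mc_se": float(est.std(ddof=1) / np.sqrt(n_rep)),
        "coverage": float(cover.mean()),
        "n_rep": n_rep,
    }


def null_calibration(seed: int, n_rep: int = 1000, J: int = 100, n: int = 100_000) -> dict[str, float]:
    """IVW type-I error rate at nominal 0.05 under theta = 0."""
    reject = np.empty(n_rep, bool)
    for i, s in enumerate(_child_seeds(seed, n_rep)):
        cfg = SimulationConfig(seed=s, J=J, n_x=n, n_y=n, theta=0.0)
        exp, out, _ = simulate_two_sample(cfg)
        reject[i] = ivw(_harmonized(exp, out)).pval < 0.05
    rate = float(reject.mean())
    return {
        "type1_rate": rate,
        "binomial_se": float(np.sqrt(0.05 * 0.95 / n_rep)),
        "n_rep": n_rep,
    }


def egger_pleiotropy_recovery(
    seed: int,
    n_rep: int = 500,
    J: int = 200,
    n: int = 100_000_000,
    sigma_b: float = 0.5,
    theta: float = 0.2,
    mu_alpha: float = 0.02,
    tau_alpha: float = 0.01,
) -> dict[str, float]:
    """Egger intercept/slope under directional pleiotropy with InSIDE holding.

    All instruments are pleiotropic with oriented mean ``mu_alpha``. The
    sample size and effect scale are set deep in the asymptotic regime
    (mean per-SNP F ~ 1e7): Egger carries O(sigma_X/sigma_b) finite-sample
    biases — regression dilution and sign misorientation of weak SNPs — so
    the consistency check needs those far below the Monte-Carlo resolution
    of the replicate mean. The intercept's sampling scale is invariant to
    the effect scale, so this isolates the bias term only."""
    icpt = np.empty(n_rep)
    slope = np.empty(n_rep)
    for i, s in enumerate(_child_seeds(seed, n_rep)):
        cfg = SimulationConfig(
            seed=s, J=J, n_x=n, n_y=n, theta=theta, sigma_b=sigma_b,
            invalid_fraction=1.0, pleiotropy_mean=mu_alpha, pleiotropy_sd=tau_alpha,
        )
        exp, out, _ = simulate_two_sample(cfg)
        fit = egger(_harmonized(exp, out))
        icpt[i] = fit.intercept
        slope[i] = fit.beta
    return {
        "mu_alpha": mu_alpha,
        "theta": theta,
        "mean_intercept": float(icpt.mean()),
        "intercept_mc_se": float(icpt.std(ddof=1) / np.sqrt(n_rep)),
        "mean_slope": float(slope.mean()),
        "slope_mc_se": float(slope.std(ddof=1) / np.sqrt(n_rep)),
        "n_rep": n_rep,
    }


def robustness_ordering(
    seed: int,
    n_rep: int = 500,
    J: int = 100,
    n: int = 500_000,
    theta: float = 0.2,
    mu_alpha: float = 0.01,
    tau_alpha: float = 0.005,
    invalid_fraction: float = 0.4,
) -> dict[str, float]:
    """Share of replicates where the weighted median beats fixed-effect IVW
    in absolute bias under 40% directionally pleiotropic instruments."""
    better = np.empty(n_rep, bool)
    bias_ivw = np.empty(n_rep)
    bias_med = np.empty(n_rep)
    for i, s in enumerate(_child_seeds(seed, n_rep)):
        cfg = SimulationConfig(
            seed=s, J=J, n_x=n, n_y=n, theta=theta,
            invalid_fraction=invalid_fraction,
            pleiotropy_mean=mu_alpha, pleiotropy_sd=tau_alpha,
        )
        exp, out, _ = simulate_two_sample(cfg)
        h = _harmonized(exp, out)
        b_ivw = ivw(h, model="fixed").beta
        b_med = weighted_median(h, n_boot=2, seed=s).beta
        bias_ivw[i] = b_ivw - theta
        bias_med[i] = b_med - theta
        better[i] = abs(bias_med[i]) < abs(bias_ivw[i])
    return {
        "fraction_median_better": float(better.mean()),
        "mean_abs_bias_ivw_fixed": float(np.abs(bias_ivw).mean()),
        "mean_abs_bias_wmedian": float(np.abs(bias_med).mean()),
        "n_rep": n_rep,
    }


# ---------------------------------------------------------------------------
# Steiger


def steiger_rates(
    seed: int,
    n_rep: int = 200,
    J: int = 60,
    n_reverse: int = 10,
    n: int = 1_000_000,
    theta: float = 0.2,
) -> dict[str, float]:
    """Steiger removal rates: reverse-causal SNPs (should be dropped) and
    genome-wide-significant valid instruments (should be retained).

    Reverse SNPs carry no exposure effect, so they can never enter a
    p-thresholded instrument list; the filter is assessed on them directly,
    emulating contamination of an instrument list, while the false-removal
    rate is assessed on valid SNPs that would actually be selected."""
    rev_removed = rev_total = 0
    val_removed = val_total = 0
    for s in _child_seeds(seed, n_rep):
        cfg = SimulationConfig(seed=s, J=J, n_x=n, n_y=n, theta=theta, n_reverse=n_reverse)
        exp, out, truth = simulate_two_sample(cfg)
        h = harmonize(exp, out)
        kept = set(steiger_filter(h).snp_ids)
        label = {f"rs{j + 1}": truth.labels[j] for j in range(J)}
        sig = {r.snp_id for r in exp.records if r.pval < GENOME_WIDE_P}
        for sid in h.snp_ids:
            if label[sid] == "reverse":
                rev_total += 1
                rev_removed += sid not in kept
            elif label[sid] == "valid" and sid in sig:
                val_total += 1
                val_removed += sid not in kept
    return {
        "reverse_removal_rate": rev_removed / rev_total,
        "valid_removal_rate": val_removed / max(val_total, 1),
        "n_reverse_snps": rev_total,
        "n_valid_snps": val_total,
    }


# ---------------------------------------------------------------------------
# clumping


def _clump_oracle(records, ld: LDMatrix, r2_threshold: float, window_kb: float) -> set[str]:
    """Independent re-derivation of the greedy rule, dictionary style."""
    ranked = sorted(records, key=lambda r: (r.pval, r.snp_id))
    kept: list = []
    for cand in ranked:
        ok = True
        for k in kept:
            near = k.chrom == cand.chrom and abs(k.pos - cand.pos) <= window_kb * 1000
            corr = ld.lookup(cand.snp_id, k.snp_id) > r2_threshold
            if near or corr:
                ok = False
                break
        if ok:
            kept.append(cand)
    return {r.snp_id for r in kept}


def clump_oracle(seed: int, n_instances: int = 300) -> dict[str, float]:
    """Greedy clumping vs an independent rule evaluation on random <=20-SNP
    instances, plus the {3,4,5}-LD-block fixture (3 index SNPs expected)."""
    import logging

    logging.getLogger("mrkit.instruments").setLevel(logging.ERROR)
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        J = int(rng.integers(2, 21))
        ids = [f"v{i}" for i in range(J)]
        r = rng.uniform(0, 1, (J, J))
        r2 = (r + r.T) / 2.0 * (rng.random((J, J)) < 0.5)
        r2 = np.triu(r2, 1)
        r2 = r2 + r2.T + np.eye(J)
        ld = LDMatrix(ids, np.clip(r2, 0, 1))
        from .summary_gwas import table_from_arrays

        table = table_from_arrays(
            "x", ids,
            chrom=rng.integers(1, 4, J).astype(str),
            pos=rng.integers(1, 30_000_000, J),
            effect_allele=["A"] * J, other_allele=["G"] * J,
            eaf=rng.uniform(0.1, 0.9, J),
            beta=rng.normal(0, 0.1, J), se=rng.uniform(0.01, 0.1, J),
            pval=rng.uniform(1e-12, 1, J), n=[10_000] * J,
        )
        got = set(greedy_clump(table, ld, 0.1, 5_000).table.ids())
        want = _clump_oracle(table.records, ld, 0.1, 5_000)
        agree += got == want
    block_cfg = SimulationConfig(seed=seed, J=12, ld_blocks=[(3, 0.9), (4, 0.9), (5, 0.9)])
    table, ld, _ = simulate_ld(block_cfg)
    n_block = len(greedy_clump(table, ld, 0.001, 10_000).table)
    return {
        "agreement_rate": agree / n_instances,
        "block_fixture_retained": float(n_block),
        "n_instances": n_instances,
    }


# ---------------------------------------------------------------------------
# MVMR


def mvmr_attenuation(
    seed: int,
    n_rep: int = 500,
    J: int = 300,
    theta_direct: float = 0.0,
) -> dict[str, float]:
    """Mediation scenario: zero direct effect, covariate drives both exposure
    and outcome. Univariable IVW should be materially non-zero, the MVMR
    direct effect near zero, and conditioning should attenuate."""
    uni = np.empty(n_rep)
    direct = np.empty(n_rep)
    attenuated = np.empty(n_rep, bool)
    expected_uni = None
    for i, s in enumerate(_child_seeds(seed, n_rep)):
        cfg = SimulationConfig(
            seed=s, J=J, n_x=353_315, n_y=132_452, theta=theta_direct,
            sigma_b=0.035, mediation=MediationConfig(),
        )
        exp, cov, out, truth = simulate_mediated(cfg)
        expected_uni = truth.univariable_slope
        h = harmonize(exp, out)
        uni[i] = ivw(h).beta
        hc = harmonize(cov, out)
        common = sorted(set(h.snp_ids) & set(hc.snp_ids))
        ih = {sid: k for k, sid in enumerate(h.snp_ids)}
        ic = {sid: k for k, sid in enumerate(hc.snp_ids)}
        rows_h = [ih[sid] for sid in common]
        rows_c = [ic[sid] for sid in common]
        # outcome effects from both harmonizations refer to the same records;
        # align the covariate column to the exposure's effect allele
        flip = np.where(
            np.isclose(hc.beta_y[rows_c], h.beta_y[rows_h]), 1.0, -1.0
        )
        design = MvmrDesign(
            snp_ids=common,
            beta_x=np.column_stack([h.beta_x[rows_h], flip * hc.beta_x[rows_c]]),
            se_x=np.column_stack([h.se_x[rows_h], hc.se_x[rows_c]]),
            beta_y=h.beta_y[rows_h],
            se_y=h.se_y[rows_h],
            exposure_names=[exp.trait_name, cov.trait_name],
        )
        direct[i] = mvmr_ivw(design).beta[0]
        attenuated[i] = abs(direct[i]) < abs(uni[i])
    return {
        "theta_direct": theta_direct,
        "expected_univariable_slope": float(expected_uni),
        "mean_univariable": float(uni.mean()),
        "mean_mvmr_direct": float(direct.mean()),
        "direct_mc_se": float(direct.std(ddof=1) / np.sqrt(n_rep)),
        "attenuation_fraction": float(attenuated.mean()),
        "n_rep": n_rep,
    }


# ---------------------------------------------------------------------------
# heterogeneity


def q_calibration(
    seed: int,
    n_rep: int = 1000,
    J: int = 50,
    n_x: int = 1_000_000,
    n_y: int = 100_000,
    theta: float = 0.2,
) -> dict[str, float]:
    """Mean Cochran Q under homogeneity; expectation J - 1.

    The exposure GWAS is much larger than the outcome GWAS so that the
    first-order weights' neglect of exposure-side noise is negligible."""
    qs = np.empty(n_rep)
    dfs = np.empty(n_rep)
    for i, s in enumerate(_child_seeds(seed, n_rep)):
        cfg = SimulationConfig(seed=s, J=J, n_x=n_x, n_y=n_y, theta=theta,
                               palindromic_fraction=0.0)
        exp, out, _ = simulate_two_sample(cfg)
        fit = ivw(_harmonized(exp, out))
        qs[i] = fit.q
        dfs[i] = fit.q_df
    return {
        "mean_q": float(qs.mean()),
        "mean_df": float(dfs.mean()),
        "mc_se": float(qs.std(ddof=1) / np.sqrt(n_rep)),
        "n_rep": n_rep,
    }


def combined_f_reference(seed: int, J: int = 100, n: int = 100_000) -> dict[str, float]:
    """Combined F of the genome-wide-significant instruments in the reference
    configuration (mean of per-SNP beta^2/SE^2)."""
    cfg = SimulationConfig(seed=seed, J=J, n_x=n, n_y=n)
    exp, _, _ = simulate_two_sample(cfg)
    sig = SummaryTable(exp.trait_name, [r for r in exp.records if r.pval < GENOME_WIDE_P])
    f = combined_f(
        per_snp_f(
            np.array([r.beta for r in sig.records]), np.array([r.se for r in sig.records])
        )
    )
    return {"combined_f": f.mean, "f_min": f.min, "f_median": f.median, "n_snp": f.n_snp}
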