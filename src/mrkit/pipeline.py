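"""End-to-end orchestration: univariable and multivariable runs with reports.

The univariable workflow mirrors a standard two-sample MR analysis:

    clump -> harmonize (duplicates, palindromes) -> Steiger filter ->
    IVW / weighted median / weighted mode / MR-Egger -> Cochran Q ->
    radial outlier scan and IVW re-estimate

Steiger filtering needs paired SNP-outcome associations, so it runs on the
harmonized set — after clumping, before estimation. Each stage logs every
exclusion with its SNP id and reason, and reports are deterministic given
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml

from . import __version__
from .estimators import MREstimate, cochran_q, estimate_all, radial_scan
from .exceptions import ConfigurationError, EmptyInputError
from .instruments import LDMatrix, combined_f, greedy_clump, per_snp_f, steiger_filter
from .mvmr import build_design, mvmr_ivw
from .summary_gwas import HarmonizedSet, SummaryTable, harmonize, read_summary_table

logger = logging.getLogger(__name__)

METHOD_LABELS = {
    "IVW": "IVW",
    "WeightedMedian": "Weighted median",
    "WeightedMode": "Weighted mode",
    "Egger": "MR Egger",
    "Wald": "Wald ratio",
}


@dataclass
class RunConfig:
    """Flat run configuration (YAML-subset on disk; every default echoed)."""

    exposure: str | None = None
    outcome: str | None = None
    covariate: str | None = None
    assoc: str | None = None
    ld: str | None = None
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    intermediate_window: float = 0.08
    methods: list[str] = field(default_factory=lambda: ["ivw", "wmedian", "wmode", "egger"])
    ivw_model: Literal["fixed", "random"] = "random"
    radial_rule: Literal["fraction", "chi2"] = "fraction"
    radial_threshold: float = 0.05
    radial_alpha: float = 0.05
    steiger: bool = True
    clump: bool = True
    flip_exposure: bool = False
    n_boot: int = 1000
    seed: int | None = None
    out_dir: str = "mr_out"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory in the run configuration")
        if not 0 < self.p_threshold <= 1:
            raise ConfigurationError("p_threshold must be in (0, 1]")
        if not 0 < self.clump_r2 < 1:
            raise ConfigurationError("clump_r2 must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def echo(self) -> str:
        lines = [f"mrkit {__version__} run configuration:"]
        for f in dataclasses.fields(self):
            lines.append(f"  {f.name}: {getattr(self, f.name)}")
        return "\n".join(lines)


@dataclass
class UnivariableResult:
    report: pd.DataFrame
    harmonized: HarmonizedSet
    estimates: list[MREstimate]
    radial: object
    f_combined: object
    log_lines: list[str]


def _significant(table: SummaryTable, p_threshold: float) -> SummaryTable:
    kept = [r for r in table.records if r.pval < p_threshold]
    return SummaryTable(table.trait_name, kept, table.trait_type)


def run_univariable(
    cfg: RunConfig,
    exposure: SummaryTable | None = None,
    outcome: SummaryTable | None = None,
    ld: LDMatrix | None = None,
    write: bool = True,
) -> UnivariableResult:
    """Execute the univariable workflow; tables may be passed in-memory or
    read from the paths in ``cfg``."""
    log: list[str] = [cfg.echo()]

    if exposure is None:
        if cfg.exposure is None:
            raise ConfigurationError("no exposure table supplied (path or object)")
        exposure = read_summary_table(cfg.exposure, trait_name=Path(cfg.exposure).stem)
    if outcome is None:
        if cfg.outcome is None:
            raise ConfigurationError("no outcome table supplied (path or object)")
        outcome = read_summary_table(cfg.outcome, trait_name=Path(cfg.outcome).stem)
    if ld is None and cfg.ld is not None:
        ld = LDMatrix.read(cfg.ld)

    dropped: list[tuple[str, str]] = []

    sig = _significant(exposure, cfg.p_threshold)
    log.append(f"stage p_threshold: {len(exposure)} -> {len(sig)} SNPs at p < {cfg.p_threshold}")
    if len(sig) == 0:
        raise EmptyInputError(
            f"stage p_threshold: no exposure SNP passes p < {cfg.p_threshold}"
        )

    if cfg.clump:
        if ld is None:
            raise ConfigurationError(
                "stage clump: no LD matrix supplied; pass one or disable clumping"
            )
        inst = greedy_clump(sig, ld, cfg.clump_r2, cfg.clump_kb)
        dropped += [(s, reason) for s, reason, _ in inst.selection_log]
        instruments = inst.table
        log.append(f"stage clump: {len(sig)} -> {len(instruments)} index SNPs "
                   f"(r2 {cfg.clump_r2}, window {cfg.clump_kb} kb)")
    else:
        instruments = sig
        log.append("stage clump: DISABLED by config")

    h = harmonize(instruments, outcome, intermediate_window=cfg.intermediate_window)
    log.append(f"stage harmonize: {len(h)} SNPs retained, {len(h.dropped)} dropped")
    dropped += h.dropped

    if cfg.steiger:
        before = len(h)
        h = steiger_filter(h)
        log.append(f"stage steiger: {before} -> {len(h)} SNPs")
        dropped = list(dict.fromkeys(dropped + h.dropped))
    else:
        log.append("stage steiger: DISABLED by config")

    if len(h) == 0:
        counts = pd.Series([r for _, r in dropped]).value_counts().to_dict()
        raise EmptyInputError(f"no instruments survive QC; exclusions: {counts}")

    if cfg.flip_exposure:
        h.beta_x = -h.beta_x
        log.append("stage flip_exposure: exposure effects negated "
                   "(estimates are per unit DECREASE of the exposure)")

    f = combined_f(per_snp_f(h.beta_x, h.se_x))
    log.append(f"combined F statistic: mean {f.mean:.1f} (min {f.min:.1f}, "
               f"median {f.median:.1f}) over {f.n_snp} SNPs")

    estimates = estimate_all(
        h, methods=cfg.methods, ivw_model=cfg.ivw_model, n_boot=cfg.n_boot, seed=cfg.seed
    )

    rows = []
    for est in estimates:
        q_p = None
        if est.method == "IVW":
            _, _, q_p = cochran_q(h, est)
        rows.append(
            {
                "exposure": h.exposure_name,
                "n_snp": est.n_snp,
                "method": METHOD_LABELS.get(est.method, est.method),
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "q_pval": q_p,
            }
        )
    report = pd.DataFrame(rows)

    radial = None
    if len(h) >= 3:
        try:
            radial = radial_scan(h, rule=cfg.radial_rule, alpha=cfg.radial_alpha,
                                 fraction_threshold=cfg.radial_threshold)
            log.append(
                f"radial scan ({cfg.radial_rule}): {len(radial.outlier_ids)} outliers "
                f"{radial.outlier_ids}; IVW re-estimate beta {radial.reestimate.beta:.4g} "
                f"(se {radial.reestimate.se:.4g})"
            )
        except Exception as exc:  # pragma: no cover - surfaced in the log
            log.append(f"radial scan failed: {exc}")

    if write:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.tsv", sep="\t", index=False)
        pd.DataFrame(dropped, columns=["SNP", "REASON"]).to_csv(
            out / "dropped.tsv", sep="\t", index=False
        )
        (out / "log.txt").write_text("\n".join(log) + "\n")
        (out / "config-echo.yaml").write_text(cfg.echo() + "\n")

    return UnivariableResult(report, h, estimates, radial, f, log)


@dataclass
class MvmrResult:
    report: pd.DataFrame
    log_lines: list[str]


def run_mvmr(
    cfg: RunConfig,
    primary: SummaryTable | None = None,
    covariate: SummaryTable | None = None,
    full_assoc: dict[str, SummaryTable] | None = None,
    outcome_name: str | None = None,
    ld: LDMatrix | None = None,
    write: bool = True,
) -> MvmrResult:
    """Paired unconditioned (univariable IVW) and conditioned (MVMR) report.

    ``full_assoc`` maps trait name -> SummaryTable and must cover the primary
    exposure, the covariate and the outcome. On disk it is a long table with
    a TRAIT column prepended to the canonical summary-statistic columns.
    """
    log: list[str] = [cfg.echo()]
    if primary is None:
        if cfg.exposure is None:
            raise ConfigurationError("no primary exposure supplied")
        primary = read_summary_table(cfg.exposure, trait_name=Path(cfg.exposure).stem)
    if covariate is None:
        if cfg.covariate is None:
            raise ConfigurationError("no covariate table supplied")
        covariate = read_summary_table(cfg.covariate, trait_name=Path(cfg.covariate).stem)
    if full_assoc is None:
        if cfg.assoc is None:
            raise ConfigurationError(
                "no full association lookup supplied (config key 'assoc')"
            )
        full_assoc = read_assoc_lookup(cfg.assoc)
    if outcome_name is None:
        if cfg.outcome is None:
            raise ConfigurationError("no outcome name/path supplied")
        outcome_name = Path(cfg.outcome).stem
    if ld is None and cfg.ld is not None:
        ld = LDMatrix.read(cfg.ld)

    # unconditioned: univariable IVW of the primary exposure on the outcome
    sig = _significant(primary, cfg.p_threshold)
    if cfg.clump and ld is not None:
        sig = greedy_clump(sig, ld, cfg.clump_r2, cfg.clump_kb).table
    h_uni = harmonize(sig, full_assoc[outcome_name],
                      intermediate_window=cfg.intermediate_window)
    if cfg.steiger:
        h_uni = steiger_filter(h_uni)
    uni = estimate_all(h_uni, methods=["ivw"], ivw_model=cfg.ivw_model, seed=cfg.seed)[0]
    log.append(f"univariable IVW: beta {uni.beta:.4g} (se {uni.se:.4g}) on {uni.n_snp} SNPs")

    design = build_design(
        primary, covariate, full_assoc, outcome_name, ld=ld,
        p_threshold=cfg.p_threshold, r2_threshold=cfg.clump_r2,
        window_kb=cfg.clump_kb, intermediate_window=cfg.intermediate_window,
    )
    est = mvmr_ivw(design)
    log.append(f"MVMR ({design.K} exposures, {design.J} SNPs): "
               + ", ".join(f"{n}={b:.4g}" for n, b in zip(est.exposure_names, est.beta)))

    counts = est.n_snp_per_source
    rows = [
        {
            "exposure": primary.trait_name,
            "condition": "None",
            "n_snp_trait": uni.n_snp,
            "n_snp_condition": 0,
            "beta": uni.beta,
            "se": uni.se,
            "pval": uni.pval,
        },
        {
            "exposure": primary.trait_name,
            "condition": covariate.trait_name,
            "n_snp_trait": counts.get(primary.trait_name, 0),
            "n_snp_condition": counts.get(covariate.trait_name, 0),
            "beta": float(est.beta[0]),
            "se": float(est.se[0]),
            "pval": float(est.pval[0]),
        },
    ]
    report = pd.DataFrame(rows)

    if write:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "mvmr_report.tsv", sep="\t", index=False)
        (out / "mvmr_log.txt").write_text("\n".join(log) + "\n")
    return MvmrResult(report, log)


def read_assoc_lookup(path: str | Path) -> dict[str, SummaryTable]:
    """Read a long-format association lookup (TRAIT + canonical columns)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"association lookup file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if "TRAIT" not in df.columns:
        raise ConfigurationError(f"{path}: association lookup needs a TRAIT column")
    out: dict[str, SummaryTable] = {}
    for trait, sub in df.groupby("TRAIT", sort=False):
        out[str(trait)] = SummaryTable.from_dataframe(
            sub.drop(columns=["TRAIT"]), trait_name=str(trait)
        )
    return out


def write_assoc_lookup(tables: dict[str, SummaryTable], path: str | Path) -> None:
    frames = []
    for trait, tab in tables.items():
        df = tab.to_dataframe()
        df.insert(0, "TRAIT", trait)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False)
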