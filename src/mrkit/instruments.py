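"""Instrument selection and quality control.

Three QC stages used before estimation:

* **LD clumping** — greedy pruning so that retained instruments are
  approximately independent: no pair more correlated than an r² threshold and
  no same-chromosome pair closer than a physical window (defaults r² = 0.001,
  10,000 kb). SNPs are ranked by association p-value, strongest first.
* **F statistics** — per-SNP instrument strength F = beta²/SE²; values above
  ~10 make weak-instrument bias unlikely. The "combined" F for an instrument
  list is summarised as the arithmetic mean (min and median also carried).
* **Steiger filtering** — directionality check: a valid instrument should
  explain more variance in the exposure than in the outcome. Variance
  explained is approximated from the t statistic as r² = t²/(t² + n − 2);
  SNPs with r²(outcome) > r²(exposure) are suspected of reverse causation and
  removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ValidationError
from .summary_gwas import HarmonizedSet, SummaryTable

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Symmetric matrix of squared correlations (r²) over candidate SNPs."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValidationError(f"LD matrix shape {self.r2.shape} != ({n}, {n})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-10):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-10):
            raise ValidationError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValidationError("LD r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float:
        """r² between two SNPs; SNPs absent from the matrix count as uncorrelated."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    @classmethod
    def identity(cls, snp_ids: Iterable[str]) -> "LDMatrix":
        ids = list(snp_ids)
        return cls(ids, np.eye(len(ids)))

    @classmethod
    def read(cls, path: str | Path) -> "LDMatrix":
        """Read either a square matrix (header row of ids, id column first) or
        a long 3-column table SNP_A, SNP_B, R2."""
        path = Path(path)
        df = pd.read_csv(path, sep=None, engine="python")
        if set(df.columns[:3]) >= {"SNP_A", "SNP_B", "R2"} or list(df.columns[:3]) == [
            "SNP_A",
            "SNP_B",
            "R2",
        ]:
            ids = sorted(set(df["SNP_A"]) | set(df["SNP_B"]))
            idx = {s: i for i, s in enumerate(ids)}
            m = np.eye(len(ids))
            for a, b, r2 in zip(df["SNP_A"], df["SNP_B"], df["R2"]):
                m[idx[a], idx[b]] = m[idx[b], idx[a]] = float(r2)
            return cls(ids, m)
        ids = [str(s) for s in df.iloc[:, 0]]
        return cls(ids, df.iloc[:, 1:].to_numpy(dtype=float))

    def write(self, path: str | Path) -> None:
        out = pd.DataFrame(self.r2, columns=self.snp_ids)
        out.insert(0, "SNP", self.snp_ids)
        out.to_csv(path, sep="\t", index=False)


def per_snp_f(beta: float | np.ndarray, se: float | np.ndarray) -> float | np.ndarray:
    """Instrument-strength F statistic, beta²/SE²."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValidationError("se must be > 0 for the F statistic")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CombinedF:
    """Combined instrument strength for a SNP list (mean, with min/median context)."""

    mean: float
    min: float
    median: float
    n_snp: int

    def __float__(self) -> float:
        return self.mean


def combined_f(f_values: Iterable[float]) -> CombinedF:
    """Aggregate per-SNP F statistics: arithmetic mean, with min and median."""
    f = np.asarray(list(f_values), dtype=float)
    if f.size == 0:
        raise ValidationError("combined_f needs at least one F value")
    return CombinedF(float(f.mean()), float(f.min()), float(np.median(f)), int(f.size))


@dataclass
class InstrumentSet:
    """Result of instrument QC: the retained table plus strength diagnostics."""

    table: SummaryTable
    f_per_snp: np.ndarray
    f_combined: CombinedF
    #: ordered (snp_id, reason, detail) exclusions
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)


def _clump_order(table: SummaryTable) -> list[int]:
    # ascending p, ties broken lexicographically on snp_id
    return sorted(range(len(table)), key=lambda i: (table.records[i].pval, table.records[i].snp_id))


def greedy_clump(
    table: SummaryTable,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> InstrumentSet:
    """Greedy LD clumping.

    SNPs are visited in ascending p-value order (ties broken on id). A SNP is
    retained iff no already-retained SNP on the same chromosome lies within
    ``window_kb`` kilobases of it and no already-retained SNP (any chromosome)
    has r² above ``r2_threshold`` with it. SNPs missing from the LD matrix are
    treated as uncorrelated with everything (with a warning), mirroring
    clumping against an incomplete reference panel.
    """
    if not 0.0 < r2_threshold < 1.0:
        raise ValidationError(f"r2_threshold must be in (0,1), got {r2_threshold}")
    if window_kb <= 0:
        raise ValidationError(f"window_kb must be > 0, got {window_kb}")
    missing = [r.snp_id for r in table.records if r.snp_id not in ld]
    if missing:
        logger.warning(
            "%d SNPs absent from LD matrix treated as uncorrelated (e.g. %s)",
            len(missing), missing[:3],
        )
    window_bp = window_kb * 1000.0
    retained_idx: list[int] = []
    log: list[tuple[str, str, str]] = []
    recs = table.records
    for i in _clump_order(table):
        cand = recs[i]
        verdict: tuple[str, str, str] | None = None
        for j in retained_idx:
            kept = recs[j]
            if kept.chrom == cand.chrom and abs(kept.pos - cand.pos) <= window_bp:
                verdict = (cand.snp_id, "clumped", f"within {window_kb}kb of {kept.snp_id}")
                break
            if ld.lookup(cand.snp_id, kept.snp_id) > r2_threshold:
                verdict = (cand.snp_id, "clumped", f"r2>{r2_threshold} with {kept.snp_id}")
                break
        if verdict is None:
            retained_idx.append(i)
        else:
            log.append(verdict)
    retained_idx.sort()  # preserve input row order in the output table
    kept_records = [recs[i] for i in retained_idx]
    out = SummaryTable(table.trait_name, kept_records, table.trait_type)
    f = per_snp_f(
        np.array([r.beta for r in kept_records]),
        np.array([r.se for r in kept_records]),
    )
    f = np.atleast_1d(f)
    weak = int(np.sum(f < 10))
    if weak:
        logger.warning("%d retained instruments have F < 10 (weak-instrument risk)", weak)
    return InstrumentSet(table=out, f_per_snp=f, f_combined=combined_f(f), selection_log=log)


SteigerMode = Literal["compare", "ztest"]


def steiger_variance_explained(t: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Variance-explained proxy r² = t²/(t² + n − 2) from a t statistic."""
    t2 = np.asarray(t, dtype=float) ** 2
    return t2 / (t2 + np.asarray(n, dtype=float) - 2.0)


def steiger_filter(
    h: HarmonizedSet,
    mode: SteigerMode = "compare",
    alpha: float = 0.05,
) -> HarmonizedSet:
    """Remove SNPs explaining more outcome than exposure variance.

    ``mode="compare"`` (default) drops a SNP whenever r²(outcome) >
    r²(exposure). ``mode="ztest"`` drops only when the difference is
    significant at ``alpha`` under a Fisher-z test of the two correlations.
    For binary outcomes the transform is applied on the log-odds scale and is
    approximate.
    """
    if len(h) == 0:
        return h
    if np.any(~np.isfinite(h.n_x)) or np.any(~np.isfinite(h.n_y)) or np.any(
        h.n_x <= 2
    ) or np.any(h.n_y <= 2):
        raise ConfigurationError(
            "Steiger filtering needs per-SNP sample sizes N > 2 for both GWAS; "
            "supply N columns in the summary tables"
        )
    t_x = h.beta_x / h.se_x
    t_y = h.beta_y / h.se_y
    r2_x = steiger_variance_explained(t_x, h.n_x)
    r2_y = steiger_variance_explained(t_y, h.n_y)
    if mode == "compare":
        drop = r2_y > r2_x
    elif mode == "ztest":
        rx, ry = np.sqrt(r2_x), np.sqrt(r2_y)
        z = (np.arctanh(np.clip(rx, 0, 1 - 1e-15)) - np.arctanh(np.clip(ry, 0, 1 - 1e-15))) / np.sqrt(
            1.0 / (h.n_x - 3) + 1.0 / (h.n_y - 3)
        )
        # one-sided: drop only when outcome r2 significantly exceeds exposure r2
        drop = (r2_y > r2_x) & (stats.norm.cdf(z) < alpha)
    else:
        raise ConfigurationError(f"unknown Steiger mode {mode!r}")
    kept = h.subset(~drop)
    kept.dropped = list(h.dropped) + [
        (s, "steiger") for s, d in zip(h.snp_ids, drop) if d
    ]
    return kept
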