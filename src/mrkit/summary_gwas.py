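"""GWAS summary statistics: data model, I/O and exposure-outcome harmonization.

A summary-statistics table holds one row per SNP: identifier, position, the
effect and other allele, effect-allele frequency (EAF), the per-allele effect
``beta`` with its standard error, the association p-value and the GWAS sample
size. Two-sample Mendelian randomization regresses SNP-outcome on SNP-exposure
effects, which is only meaningful after both tables are expressed on the same
effect allele — the job of :func:`harmonize`.

Harmonization handles four situations for a shared SNP:

* identical alleles — copy as is;
* swapped alleles (outcome effect allele equals the exposure other allele) —
  negate the outcome beta and complement its EAF;
* strand-complement alleles (the outcome was reported on the opposite strand)
  — complement, then fall into one of the two cases above;
* palindromic SNPs (A/T or C/G) — complementing maps the pair onto itself, so
  alleles alone cannot resolve the strand.  If the allele frequency is close
  to 0.5 the SNP is dropped; otherwise the frequency itself orients the SNP
  (or, if ``palindromic_action="drop"``, all palindromic SNPs are dropped).

Every input SNP is accounted for: it ends up either in the harmonized set or
in the ``dropped`` log with a reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptyInputError,
    NoOverlapError,
    ValidationError,
)

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: canonical column names of the on-disk format
CANONICAL_COLUMNS = ("SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N")

TraitType = Literal["quantitative", "binary"]


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association with one trait.

    ``beta`` is in SD units for a quantitative trait or log-odds for a binary
    one (e.g. COPD liability); ``eaf`` is the effect-allele frequency.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(f"{self.snp_id}: non-ACGT effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(f"{self.snp_id}: non-ACGT other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele identical")
        if not np.isfinite(self.se) or self.se <= 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not np.isfinite(self.eaf) or not 0.0 < self.eaf < 1.0:
            raise ValidationError(f"{self.snp_id}: eaf must be in (0,1), got {self.eaf}")
        if not np.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: non-finite beta")
        if not 0.0 < self.pval <= 1.0:
            raise ValidationError(f"{self.snp_id}: pval must be in (0,1], got {self.pval}")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if self.n <= 0:
            raise ValidationError(f"{self.snp_id}: n must be positive, got {self.n}")

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class SummaryTable:
    """An ordered collection of :class:`SummaryRecord` for one trait."""

    trait_name: str
    records: list[SummaryRecord]
    trait_type: TraitType = "quantitative"
    #: (line_number_or_index, reason) for rows rejected during reading
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SummaryRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def get(self, snp_id: str) -> SummaryRecord:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        raise KeyError(snp_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": [r.snp_id for r in self.records],
                "CHR": [r.chrom for r in self.records],
                "POS": [r.pos for r in self.records],
                "EA": [r.effect_allele for r in self.records],
                "OA": [r.other_allele for r in self.records],
                "EAF": [r.eaf for r in self.records],
                "BETA": [r.beta for r in self.records],
                "SE": [r.se for r in self.records],
                "P": [r.pval for r in self.records],
                "N": [r.n for r in self.records],
            }
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        trait_name: str,
        trait_type: TraitType = "quantitative",
        collect_rejects: bool = True,
    ) -> "SummaryTable":
        records: list[SummaryRecord] = []
        rejected: list[tuple[int, str]] = []
        for i, row in enumerate(df.itertuples(index=False)):
            rec = SummaryRecord(
                snp_id=str(row.SNP),
                chrom=str(row.CHR),
                pos=int(row.POS),
                effect_allele=str(row.EA).upper(),
                other_allele=str(row.OA).upper(),
                eaf=float(row.EAF),
                beta=float(row.BETA),
                se=float(row.SE),
                pval=float(row.P),
                n=int(row.N),
            )
            try:
                rec.validate()
            except ValidationError as exc:
                if not collect_rejects:
                    raise
                rejected.append((i, str(exc)))
                logger.warning("row %d rejected: %s", i, exc)
                continue
            records.append(rec)
        return cls(trait_name=trait_name, records=records, trait_type=trait_type, rejected=rejected)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)

    def deduplicate(self) -> tuple["SummaryTable", list[tuple[str, str]]]:
        """Drop duplicate snp_ids, keeping the smallest-p record per id.

        Returns the deduplicated table and a ``(snp_id, "duplicate")`` log for
        every removed row.
        """
        best: dict[str, SummaryRecord] = {}
        for r in self.records:
            prev = best.get(r.snp_id)
            if prev is None or r.pval < prev.pval:
                best[r.snp_id] = r
        dropped: list[tuple[str, str]] = []
        kept: list[SummaryRecord] = []
        seen: set[str] = set()
        for r in self.records:
            if r.snp_id in seen:
                dropped.append((r.snp_id, "duplicate"))
                continue
            seen.add(r.snp_id)
            kept.append(best[r.snp_id])
        return (
            SummaryTable(self.trait_name, kept, self.trait_type),
            dropped,
        )


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise ConfigurationError(
        f"{path}: cannot auto-detect delimiter (expected tab or comma in header); "
        "pass delimiter explicitly"
    )


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: TraitType = "quantitative",
    trait_name: str | None = None,
    delimiter: str | None = None,
) -> SummaryTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path:
        Tab- or comma-delimited text file with a header row.
    column_map:
        Mapping from canonical field names (``SNP, CHR, POS, EA, OA, EAF,
        BETA, SE, P, N``) to the headers actually present in the file.
        Omitted keys default to the canonical name itself.
    trait_type:
        ``"quantitative"`` (beta in SD units) or ``"binary"`` (log-odds).

    Rows violating record invariants (non-ACGT allele, se <= 0, eaf outside
    (0,1)...) are skipped and collected in ``table.rejected`` with their line
    numbers. A file with zero valid rows raises :class:`EmptyInputError`.
    """
    path = Path(path)
    sep = delimiter or _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    cmap = dict(column_map or {})
    rename: dict[str, str] = {}
    for canon in CANONICAL_COLUMNS:
        source = cmap.get(canon, canon)
        if source not in df.columns:
            raise ConfigurationError(
                f"{path}: required column {source!r} (field {canon}) not found; "
                f"available: {list(df.columns)}"
            )
        rename[source] = canon
    df = df.rename(columns=rename)[list(CANONICAL_COLUMNS)]
    table = SummaryTable.from_dataframe(
        df, trait_name=trait_name or path.stem, trait_type=trait_type
    )
    # report 1-based data line numbers (header is line 1)
    table.rejected = [(i + 2, msg) for i, msg in table.rejected]
    if len(table) == 0:
        raise EmptyInputError(f"{path}: no valid summary-statistic rows")
    return table


PalindromeStatus = Literal["keep", "drop", "keep_informative"]


def classify_palindromic(
    effect_allele: str,
    other_allele: str,
    eaf: float,
    intermediate_window: float = 0.08,
) -> PalindromeStatus:
    """Classify an allele pair for strand ambiguity.

    Returns ``"keep"`` for non-complementary pairs, ``"drop"`` for a
    palindromic pair (A/T or C/G) whose effect-allele frequency lies within
    ``intermediate_window`` of 0.5, and ``"keep_informative"`` for a
    palindromic pair whose frequency is extreme enough to orient the strand.
    """
    ea, oa = effect_allele.upper(), other_allele.upper()
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        raise ValidationError(f"non-ACGT allele pair {ea}/{oa}")
    if not 0.0 < eaf < 1.0:
        raise ValidationError(f"eaf must be in (0,1), got {eaf}")
    if COMPLEMENT[ea] != oa:
        return "keep"
    if abs(eaf - 0.5) <= intermediate_window:
        return "drop"
    return "keep_informative"


@dataclass
class HarmonizedSet:
    """Aligned exposure/outcome effect vectors over a common SNP set.

    All vectors are parallel, aligned to the exposure effect allele. ``dropped``
    lists every shared SNP excluded during harmonization with its reason
    (``palindromic_intermediate``, ``palindromic_no_eaf``, ``allele_mismatch``,
    ``duplicate``, or ``steiger`` once the directionality filter has run).
    """

    snp_ids: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    eaf: np.ndarray
    n_x: np.ndarray
    n_y: np.ndarray
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        self.eaf = np.asarray(self.eaf, dtype=float)
        self.n_x = np.asarray(self.n_x, dtype=float)
        self.n_y = np.asarray(self.n_y, dtype=float)
        J = len(self.snp_ids)
        for name in ("beta_x", "se_x", "beta_y", "se_y", "eaf", "n_x", "n_y"):
            if len(getattr(self, name)) != J:
                raise ValidationError(f"HarmonizedSet.{name} length != {J}")
        if J and (np.any(self.se_x <= 0) or np.any(self.se_y <= 0)):
            raise ValidationError("all standard errors must be > 0")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask: Sequence[bool] | np.ndarray) -> "HarmonizedSet":
        mask = np.asarray(mask, dtype=bool)
        ids = [s for s, m in zip(self.snp_ids, mask) if m]
        return replace(
            self,
            snp_ids=ids,
            beta_x=self.beta_x[mask],
            se_x=self.se_x[mask],
            beta_y=self.beta_y[mask],
            se_y=self.se_y[mask],
            eaf=self.eaf[mask],
            n_x=self.n_x[mask],
            n_y=self.n_y[mask],
            dropped=list(self.dropped),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.snp_ids,
                "BETA_X": self.beta_x,
                "SE_X": self.se_x,
                "BETA_Y": self.beta_y,
                "SE_Y": self.se_y,
                "EAF": self.eaf,
            }
        )

    def write(self, path: str | Path, dropped_path: str | Path | None = None) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)
        if dropped_path is not None:
            pd.DataFrame(self.dropped, columns=["SNP", "REASON"]).to_csv(
                dropped_path, sep="\t", index=False
            )


PalindromicAction = Literal["infer", "drop"]


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    intermediate_window: float = 0.08,
    palindromic_action: PalindromicAction = "infer",
) -> HarmonizedSet:
    """Align outcome effects to the exposure effect allele for shared SNPs.

    Duplicated ids within either table are resolved first (smallest p wins,
    extra copies logged as ``duplicate``). Palindromic SNPs with EAF within
    ``intermediate_window`` of 0.5 are dropped; other palindromic SNPs are
    oriented by allele frequency (``palindromic_action="infer"``, default) or
    dropped outright (``"drop"``).
    """
    exp_tab, exp_dups = exposure.deduplicate()
    out_tab, out_dups = outcome.deduplicate()
    dropped: list[tuple[str, str]] = exp_dups + out_dups

    out_by_id = {r.snp_id: r for r in out_tab.records}
    shared = [r for r in exp_tab.records if r.snp_id in out_by_id]
    if not shared:
        raise NoOverlapError(
            f"no shared SNPs between exposure {exposure.trait_name!r} "
            f"and outcome {outcome.trait_name!r}"
        )

    ids: list[str] = []
    bx, sx, by, sy, eaf, nx, ny = ([] for _ in range(7))

    for ex in shared:
        oy = out_by_id[ex.snp_id]
        e_pair = (ex.effect_allele, ex.other_allele)
        o_pair = (oy.effect_allele, oy.other_allele)
        beta_y, eaf_y = oy.beta, oy.eaf

        if ex.is_palindromic:
            # complement maps the pair onto itself: alleles cannot resolve strand
            if o_pair not in (e_pair, (e_pair[1], e_pair[0])):
                dropped.append((ex.snp_id, "allele_mismatch"))
                continue
            if np.isnan(ex.eaf) or np.isnan(oy.eaf):
                dropped.append((ex.snp_id, "palindromic_no_eaf"))
                continue
            intermediate = (
                abs(ex.eaf - 0.5) <= intermediate_window
                or abs(oy.eaf - 0.5) <= intermediate_window
            )
            if intermediate or palindromic_action == "drop":
                dropped.append((ex.snp_id, "palindromic_intermediate"))
                continue
            # orient by frequency: matching minor/major side means same allele
            if (ex.eaf < 0.5) != (oy.eaf < 0.5):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
        else:
            comp_pair = (COMPLEMENT[oy.effect_allele], COMPLEMENT[oy.other_allele])
            if o_pair == e_pair:
                pass
            elif o_pair == (e_pair[1], e_pair[0]):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            elif comp_pair == e_pair:
                pass  # strand flip only; effect and frequency unchanged
            elif comp_pair == (e_pair[1], e_pair[0]):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            else:
                dropped.append((ex.snp_id, "allele_mismatch"))
                continue

        ids.append(ex.snp_id)
        bx.append(ex.beta)
        sx.append(ex.se)
        by.append(beta_y)
        sy.append(oy.se)
        eaf.append(ex.eaf)
        nx.append(ex.n)
        ny.append(oy.n)

    return HarmonizedSet(
        snp_ids=ids,
        beta_x=np.array(bx),
        se_x=np.array(sx),
        beta_y=np.array(by),
        se_y=np.array(sy),
        eaf=np.array(eaf),
        n_x=np.array(nx),
        n_y=np.array(ny),
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        dropped=dropped,
    )


def table_from_arrays(
    trait_name: str,
    snp_ids: Iterable[str],
    chrom: Iterable[str],
    pos: Iterable[int],
    effect_allele: Iterable[str],
    other_allele: Iterable[str],
    eaf: Iterable[float],
    beta: Iterable[float],
    se: Iterable[float],
    pval: Iterable[float],
    n: Iterable[int],
    trait_type: TraitType = "quantitative",
) -> SummaryTable:
    """Assemble a validated SummaryTable from parallel sequences."""
    records = [
        SummaryRecord(str(s), str(c), int(p), str(ea).upper(), str(oa).upper(),
                      float(f), float(b), float(e), float(pv), int(nn))
        for s, c, p, ea, oa, f, b, e, pv, nn in zip(
            snp_ids, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval, n
        )
    ]
    for r in records:
        r.validate()
    return SummaryTable(trait_name=trait_name, records=records, trait_type=trait_type)
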