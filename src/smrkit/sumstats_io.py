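"""Reading and writing GWAS / eQTL summary-statistic tables.

Input files are delimited text (tab by default) with one header line and one
row per SNP (GWAS) or per SNP x expression-probe pair (eQTL).  Column names
vary between providers, so each file is read through a :class:`Dialect` that
maps the provider's header names onto the canonical fields; the defaults
follow the widely used ".ma"-style layout (SNP, A1, A2, freq, b, se, p, n).

Rows violating the numeric invariants (nonpositive SE, p outside (0, 1],
allele frequency outside [0, 1], no usable route to a Z score) are dropped
and counted per reason in a :class:`LoadReport`; a p-value of exactly 0 is
treated as malformed rather than clamped, because the normal-quantile Z
computation is undefined there.  Odds ratios are converted to ``ln(OR)`` at
read time when the dialect declares ``effect_scale="OR"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import RESULT_COLUMNS

__all__ = [
    "Dialect",
    "EQTL_DIALECT",
    "GWAS_DIALECT",
    "LoadReport",
    "read_gwas",
    "read_eqtl",
    "write_results",
    "read_results",
]

#: Canonical GWAS field names used throughout the package.
GWAS_FIELDS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]
EQTL_FIELDS = GWAS_FIELDS + ["probe_id", "gene_name", "probe_level"]


@dataclass(frozen=True)
class Dialect:
    """Column mapping and conventions for one summary-statistics file.

    ``effect_scale`` is ``"beta"`` (signed additive effect) or ``"OR"``
    (odds ratio, log-transformed on read).  ``probe_level`` declares whether
    the eQTL probes are gene-level or exon-level; it is a property of the
    dataset, not a column.  Optional columns (chrom/pos/eaf/n and one of
    se/p) may be absent from the header.
    """

    delimiter: str = "\t"
    snp_id: str = "SNP"
    effect_allele: str = "A1"
    other_allele: str = "A2"
    eaf: str = "freq"
    beta: str = "b"
    se: str = "se"
    pvalue: str = "p"
    n: str = "n"
    chrom: str = "chr"
    pos: str = "bp"
    effect_scale: str = "beta"
    probe_id: str = "probe"
    gene_name: str = "gene"
    probe_level: str = "gene"


GWAS_DIALECT = Dialect()
EQTL_DIALECT = Dialect()


@dataclass
class LoadReport:
    """Accounting of one file read: every data row is kept or counted dropped."""

    path: str
    n_rows: int = 0
    n_kept: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)
    n_duplicates: int = 0

    @property
    def n_dropped(self) -> int:
        return sum(self.drop_reasons.values())

    def _drop(self, reason: str, count: int) -> None:
        if count:
            self.drop_reasons[reason] = self.drop_reasons.get(reason, 0) + int(count)


class SumstatsError(ValueError):
    """Hard error while reading a summary-statistics file."""


def _numeric(df: pd.DataFrame, col: str | None) -> pd.Series:
    if col is None or col not in df.columns:
        return pd.Series(np.nan, index=df.index)
    return pd.to_numeric(df[col], errors="coerce")


def _read_table(path, dialect: Dialect, eqtl: bool) -> tuple[pd.DataFrame, LoadReport]:
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str, comment=None)
    except OSError as exc:
        raise SumstatsError(f"cannot read {path}: {exc}") from exc

    required = ["snp_id", "effect_allele", "other_allele", "beta"]
    if eqtl:
        required.append("probe_id")
    for fieldname in required:
        colname = getattr(dialect, fieldname)
        if colname not in raw.columns:
            raise SumstatsError(
                f"{path}: missing required column {colname!r} (maps to {fieldname})"
            )
    if dialect.se not in raw.columns and dialect.pvalue not in raw.columns:
        raise SumstatsError(
            f"{path}: need at least one of columns {dialect.se!r} (SE) or "
            f"{dialect.pvalue!r} (p-value) to standardize effects"
        )

    report = LoadReport(path=str(path), n_rows=len(raw))

    df = pd.DataFrame(index=raw.index)
    df["snp_id"] = raw[dialect.snp_id].astype(str)
    df["chrom"] = raw[dialect.chrom].astype(str) if dialect.chrom in raw.columns else pd.NA
    df["pos"] = _numeric(raw, dialect.pos)
    df["effect_allele"] = raw[dialect.effect_allele].astype(str).str.upper()
    df["other_allele"] = raw[dialect.other_allele].astype(str).str.upper()
    df["eaf"] = _numeric(raw, dialect.eaf)
    df["beta"] = _numeric(raw, dialect.beta)
    df["se"] = _numeric(raw, dialect.se)
    df["pvalue"] = _numeric(raw, dialect.pvalue)
    df["n"] = _numeric(raw, dialect.n)
    if eqtl:
        df["probe_id"] = raw[dialect.probe_id].astype(str)
        gn = dialect.gene_name
        df["gene_name"] = raw[gn].astype(str) if gn in raw.columns else df["probe_id"]
        df["probe_level"] = dialect.probe_level

    # Odds-ratio scale: beta column actually holds OR, convert to ln(OR).
    if dialect.effect_scale.upper() == "OR":
        bad_or = df["beta"].notna() & (df["beta"] <= 0)
        report._drop("nonpositive OR", bad_or.sum())
        df = df[~bad_or]
        df.loc[:, "beta"] = np.log(df["beta"])

    # Row-level invariants, counted with first-applicable reason.
    checks = [
        ("missing beta", df["beta"].isna()),
        ("nonpositive SE", _present_and(df["se"], lambda s: s <= 0)),
        ("p out of range", _present_and(df["pvalue"], lambda p: (p <= 0) | (p > 1))),
        ("eaf out of range", _present_and(df["eaf"], lambda f: (f < 0) | (f > 1))),
        ("unusable for Z", df["se"].isna() & df["pvalue"].isna()),
    ]
    dropped = pd.Series(False, index=df.index)
    for reason, mask in checks:
        newly = mask & ~dropped
        report._drop(reason, newly.sum())
        dropped |= newly
    df = df[~dropped].reset_index(drop=True)

    report.n_kept = len(df)
    if report.n_kept == 0:
        raise SumstatsError(f"{path}: zero usable rows after validation")
    return df, report


def _present_and(series: pd.Series, cond) -> pd.Series:
    return series.notna() & cond(series)


def read_gwas(path, dialect: Dialect = GWAS_DIALECT) -> tuple[pd.DataFrame, LoadReport]:
    """Read a GWAS summary file into the canonical frame, in file order.

    Returns ``(frame, report)``; the frame has columns :data:`GWAS_FIELDS`
    and the report accounts for every input row (kept + dropped = total).
    """
    df, report = _read_table(path, dialect, eqtl=False)
    return df[GWAS_FIELDS], report


def read_eqtl(path, dialect: Dialect | None = None) -> tuple[pd.DataFrame, LoadReport]:
    """Read an eQTL summary file (one row per SNP x probe), deduplicated.

    Duplicate (snp_id, probe_id) rows collapse to the first occurrence, with
    the number of discarded duplicates recorded in ``report.n_duplicates``.
    """
    dialect = dialect or EQTL_DIALECT
    df, report = _read_table(path, dialect, eqtl=True)
    before = len(df)
    df = df.drop_duplicates(subset=["snp_id", "probe_id"], keep="first").reset_index(drop=True)
    report.n_duplicates = before - len(df)
    report.n_kept = len(df)
    return df[EQTL_FIELDS], report


def exon_dialect(**overrides) -> Dialect:
    """Convenience: the default eQTL dialect marked as exon-level probes."""
    return replace(EQTL_DIALECT, probe_level="exon", **overrides)


def write_results(results: pd.DataFrame, path) -> None:
    """Write an SMR result table as TSV with the fixed column header.

    Floats are serialized with 12 significant digits, which round-trips
    through :func:`read_results` to within 1 ulp (scientific notation such
    as 9.17e-09 is preserved exactly).
    """
    out = results.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[RESULT_COLUMNS]
    try:
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")
    except OSError as exc:
        raise SumstatsError(f"cannot write {path}: {exc}") from exc


def read_results(path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != RESULT_COLUMNS:
        raise SumstatsError(f"{path}: unexpected result header {list(df.columns)}")
    df["significant"] = df["significant"].astype("boolean")
    return df
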