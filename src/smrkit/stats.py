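"""Core SMR test statistics.

The SMR (summary-data-based Mendelian randomization) test asks whether the
expression of a gene mediates a trait association, using only per-SNP summary
statistics from a GWAS and an eQTL study.  For one SNP with standardized
effects ``Z_GWAS`` and ``Z_eQTL`` the test statistic is

    T_SMR = (Z_GWAS^2 * Z_eQTL^2) / (Z_GWAS^2 + Z_eQTL^2)

which under the null of no mediated effect (and a strong eQTL instrument) is
approximately chi-square with one degree of freedom; the Delta method gives
this form as the variance-standardized square of the Wald ratio
``Z_GWAS / Z_eQTL`` times the instrument strength.

Z scores are obtained either directly as ``beta / se`` or, when no standard
error is published, from the two-sided p-value as the signed upper
``1 - p/2`` normal quantile with the sign taken from beta.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtri_exp
from scipy.stats import chi2

__all__ = [
    "z_from_beta_se",
    "z_from_p_beta",
    "choose_z",
    "t_smr",
    "p_from_t",
    "run_smr",
    "RESULT_COLUMNS",
]

_LN2 = float(np.log(2.0))

#: Fixed column order of an SMR result table.
RESULT_COLUMNS = [
    "smr_label",
    "probe_id",
    "gene_name",
    "snp_id",
    "z_gwas",
    "z_eqtl",
    "t_smr",
    "p_smr",
    "p_adj",
    "significant",
]


def z_from_beta_se(beta: float, se: float) -> float:
    """Z score as the effect estimate divided by its standard error."""
    if not se > 0:
        raise ValueError(f"nonpositive SE: {se!r}")
    return beta / se


def z_from_p_beta(p: float, beta_sign: float) -> float:
    """Signed Z score from a two-sided p-value and the sign of the effect.

    ``|Z|`` is the upper ``1 - p/2`` quantile of the standard normal.  The
    quantile is evaluated on the log scale (``ndtri_exp``) so that p-values
    far below double-precision epsilon (down to ~5e-324) yield a finite
    magnitude that remains strictly monotone in p.  ``beta_sign == 0`` is a
    degenerate case (the sign of Z is undefined); Z is set to 0 with a
    warning, which contributes nothing to T_SMR.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p out of range (0, 1]: {p!r}")
    if beta_sign == 0:
        warnings.warn("beta = 0 with p-only record: Z sign undefined, set to 0")
        return 0.0
    magnitude = -ndtri_exp(np.log(p) - _LN2)
    return float(magnitude if beta_sign > 0 else -magnitude)


def choose_z(
    beta: float, se: float | None, pvalue: float | None
) -> tuple[float, str]:
    """Standardize one record, preferring beta/se over the p-value route.

    Returns ``(z, rule)`` where ``rule`` is ``"beta_se"`` or ``"p_beta"``.
    beta/se takes precedence because published p-values are typically rounded
    while beta and se are printed in full.  Raises ``ValueError`` when
    neither rule applies (record unusable for Z computation).
    """
    se_ok = se is not None and np.isfinite(se) and se > 0
    beta_ok = beta is not None and np.isfinite(beta)
    p_ok = pvalue is not None and np.isfinite(pvalue) and 0.0 < pvalue <= 1.0
    if beta_ok and se_ok:
        return z_from_beta_se(beta, se), "beta_se"
    if beta_ok and p_ok:
        return z_from_p_beta(pvalue, np.sign(beta)), "p_beta"
    raise ValueError("record unusable for Z computation (need beta+se or beta+p)")


def z_scores(
    beta: np.ndarray, se: np.ndarray, pvalue: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`choose_z` over aligned arrays.

    Returns ``(z, usable)``; positions where neither rule applies get
    ``z = nan`` and ``usable = False``.  NaN marks missing se/p.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    pvalue = np.asarray(pvalue, dtype=float)

    se_ok = np.isfinite(se) & (se > 0)
    p_ok = np.isfinite(pvalue) & (pvalue > 0) & (pvalue <= 1)
    beta_ok = np.isfinite(beta)

    z = np.full(beta.shape, np.nan)
    use_ratio = beta_ok & se_ok
    with np.errstate(divide="ignore", invalid="ignore"):
        z[use_ratio] = beta[use_ratio] / se[use_ratio]

    use_p = beta_ok & ~se_ok & p_ok
    if use_p.any():
        mag = -ndtri_exp(np.log(pvalue[use_p]) - _LN2)
        z[use_p] = np.where(beta[use_p] >= 0, mag, -mag)
        # beta exactly 0 with p-only: sign undefined, Z conservatively 0
        z[use_p & (beta == 0)] = 0.0

    return z, use_ratio | use_p


def t_smr(z_gwas: float | np.ndarray, z_eqtl: float | np.ndarray):
    """The SMR statistic ``(a^2 b^2)/(a^2 + b^2)``, with 0 at a = b = 0.

    Total on finite inputs: symmetric in its arguments, invariant to either
    sign, bounded by ``min(a^2, b^2)`` and tending to ``a^2`` as ``|b|``
    grows (the statistic is limited by the weaker of the two associations).
    """
    a2 = np.square(np.asarray(z_gwas, dtype=float))
    b2 = np.square(np.asarray(z_eqtl, dtype=float))
    denom = a2 + b2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, a2 * b2 / np.where(denom > 0, denom, 1.0), 0.0)
    return float(t) if np.ndim(t) == 0 else t


def p_from_t(t: float | np.ndarray):
    """Upper-tail chi-square(1) p-value of the SMR statistic.

    Uses the survival function directly (never ``1 - cdf``), so the result
    stays accurate for arbitrarily large t instead of saturating at the
    double-precision epsilon of the CDF.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    p = chi2.sf(t, df=1)
    return float(p) if np.ndim(p) == 0 else p


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Map chromosome labels to sortable integers (1..22, X, Y, MT, other)."""
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}

    def one(c) -> int:
        if pd.isna(c):
            return 99
        s = str(c).removeprefix("chr")
        if s.isdigit():
            return int(s)
        return special.get(s.upper(), 90)

    return chrom.map(one)


def run_smr(pairs: pd.DataFrame, smr_label: str) -> pd.DataFrame:
    """Compute T_SMR and P_SMR for every harmonized SNP x probe pair.

    ``pairs`` is the output of :func:`smrkit.harmonize.overlap_and_harmonize`.
    Returns one row per pair with ``p_adj`` and ``significant`` left unset
    (filled later by :mod:`smrkit.multiple_testing`), ordered by
    (chrom, pos, probe_id) for reproducibility.  Internal extra columns of
    ``pairs`` (e.g. aligned betas) are carried through for downstream
    simulation scoring but are not part of the written result table.
    """
    out = pairs.copy()
    out["smr_label"] = smr_label
    out["t_smr"] = t_smr(out["z_gwas"].to_numpy(), out["z_eqtl"].to_numpy())
    out["p_smr"] = p_from_t(out["t_smr"].to_numpy())
    out["p_adj"] = np.nan
    out["significant"] = pd.array([pd.NA] * len(out), dtype="boolean")
    if len(out):
        order = np.lexsort(
            (
                out["probe_id"].astype(str).to_numpy(),
                out["pos"].fillna(-1).to_numpy() if "pos" in out else np.zeros(len(out)),
                _chrom_sort_key(out["chrom"]).to_numpy() if "chrom" in out else np.zeros(len(out)),
            )
        )
        out = out.iloc[order].reset_index(drop=True)
    extras = [c for c in out.columns if c not in RESULT_COLUMNS]
    return out[RESULT_COLUMNS + extras]
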