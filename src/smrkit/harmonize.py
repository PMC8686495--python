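"""Overlap a GWAS with an eQTL dataset and align effect alleles.

The SMR statistic compares signed Z scores from two studies, so both must
report their effects relative to the same allele of each SNP.  The eQTL
effect allele is taken as the reference orientation and the GWAS effect is
flipped onto it; since T_SMR depends only on squared Z scores this choice
cannot change any p-value, but it makes signed Wald ratios meaningful.

Alignment rules, applied per overlapping (SNP, probe) pair:

* identical allele pairs -> direct (+1);
* swapped effect/other alleles -> flipped (-1, GWAS beta negated once);
* with ``allow_strand_flip``, reverse-complement the GWAS alleles first
  and retry, so files reported on opposite strands still align;
* palindromic SNPs (A/T or C/G), whose strand cannot be inferred from the
  allele letters, are resolved by comparing effect-allele frequencies when
  these are informative, and dropped otherwise (policy configurable).

SNPs are matched on rsID, not chrom:pos, because the source datasets may
use different genome builds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .stats import z_scores

__all__ = [
    "HarmonizeOptions",
    "HarmonizeReport",
    "align_alleles",
    "overlap_and_harmonize",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_BASES = frozenset(_COMPLEMENT)


@dataclass(frozen=True)
class HarmonizeOptions:
    """Allele-alignment policy.

    palindromic_policy:
        ``drop_ambiguous`` (default) keeps a palindromic SNP only when both
        allele frequencies are present and outside the ambiguity window, in
        which case frequency agreement decides the orientation;
        ``drop_all`` discards every palindromic SNP;
        ``keep`` aligns palindromic SNPs by allele letters alone (no strand
        flip is attempted — it would be a no-op composed with a swap).
    """

    allow_strand_flip: bool = True
    palindromic_policy: str = "drop_ambiguous"
    eaf_ambiguity_window: tuple[float, float] = (0.40, 0.60)


@dataclass
class HarmonizeReport:
    """Counts describing one GWAS x eQTL overlap-and-harmonize run."""

    n_gwas_snps: int = 0
    n_eqtl_snps: int = 0
    n_overlap_snps: int = 0
    n_pairs: int = 0
    n_flipped: int = 0
    n_dropped_allele_mismatch: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_unusable_z: int = 0

    def to_dict(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.__dict__.items()}


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def align_alleles(
    g_effect: str,
    g_other: str,
    e_effect: str,
    e_other: str,
    g_eaf: Optional[float] = None,
    e_eaf: Optional[float] = None,
    options: HarmonizeOptions = HarmonizeOptions(),
) -> tuple[Optional[int], Optional[str]]:
    """Decide the GWAS sign multiplier relative to the eQTL orientation.

    Returns ``(+1, None)`` for a direct match, ``(-1, None)`` when the GWAS
    effect/other alleles are swapped relative to the eQTL record, and
    ``(None, reason)`` when the pair must be dropped (``"palindromic"`` or
    ``"allele mismatch"``).
    """
    g1, g2, e1, e2 = (x.upper() for x in (g_effect, g_other, e_effect, e_other))
    if not ({g1, g2} <= _BASES and {e1, e2} <= _BASES):
        return None, "allele mismatch"

    if _is_palindromic(e1, e2) or _is_palindromic(g1, g2):
        if {g1, g2} != {e1, e2}:
            return None, "allele mismatch"
        policy = options.palindromic_policy
        if policy == "drop_all":
            return None, "palindromic"
        if policy == "keep":
            return (1, None) if (g1, g2) == (e1, e2) else (-1, None)
        if policy != "drop_ambiguous":
            raise ValueError(f"unknown palindromic policy {policy!r}")
        lo, hi = options.eaf_ambiguity_window
        if g_eaf is None or e_eaf is None or np.isnan(g_eaf) or np.isnan(e_eaf):
            return None, "palindromic"
        if lo <= g_eaf <= hi or lo <= e_eaf <= hi:
            return None, "palindromic"
        # Frequencies are informative: minor/major status identifies the
        # shared physical allele regardless of strand or letter order.
        freqs_agree = (g_eaf < 0.5) == (e_eaf < 0.5)
        return (1, None) if freqs_agree else (-1, None)

    if (g1, g2) == (e1, e2):
        return 1, None
    if (g1, g2) == (e2, e1):
        return -1, None
    if options.allow_strand_flip:
        c1, c2 = _COMPLEMENT[g1], _COMPLEMENT[g2]
        if (c1, c2) == (e1, e2):
            return 1, None
        if (c1, c2) == (e2, e1):
            return -1, None
    return None, "allele mismatch"


def overlap_and_harmonize(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    options: HarmonizeOptions = HarmonizeOptions(),
) -> tuple[pd.DataFrame, HarmonizeReport]:
    """Build the harmonized SMR input for one GWAS x eQTL pairing.

    Intersects the two datasets on rsID, aligns alleles per
    :func:`align_alleles`, and computes standardized Z scores for both
    studies on the aligned effects.  Returns a frame with one row per kept
    (SNP, probe) pair — columns ``snp_id, probe_id, gene_name, chrom, pos,
    z_gwas, z_eqtl, alignment`` plus internal aligned-beta columns
    ``b_gwas, b_eqtl`` used by simulation scoring — and a
    :class:`HarmonizeReport` with overlap and drop counts.  An empty
    intersection yields an empty frame, not an error.
    """
    report = HarmonizeReport(
        n_gwas_snps=gwas["snp_id"].nunique(),
        n_eqtl_snps=eqtl["snp_id"].nunique(),
    )

    g = gwas.drop_duplicates(subset="snp_id", keep="first")
    merged = eqtl.merge(
        g, on="snp_id", how="inner", suffixes=("", "_gwas"), sort=False
    )
    report.n_overlap_snps = merged["snp_id"].nunique()
    if merged.empty:
        return _empty_pairs(), report

    signs = np.zeros(len(merged), dtype=float)
    reasons: list[Optional[str]] = [None] * len(merged)
    cols = merged[
        ["effect_allele_gwas", "other_allele_gwas", "effect_allele",
         "other_allele", "eaf_gwas", "eaf"]
    ].to_numpy(dtype=object)
    for i, (ga1, ga2, ea1, ea2, gf, ef) in enumerate(cols):
        sign, reason = align_alleles(
            ga1, ga2, ea1, ea2,
            None if pd.isna(gf) else float(gf),
            None if pd.isna(ef) else float(ef),
            options,
        )
        signs[i] = 0 if sign is None else sign
        reasons[i] = reason

    reasons_arr = np.array([r or "" for r in reasons])
    report.n_dropped_allele_mismatch = int((reasons_arr == "allele mismatch").sum())
    report.n_dropped_palindromic = int((reasons_arr == "palindromic").sum())

    keep = signs != 0
    merged = merged[keep].reset_index(drop=True)
    signs = signs[keep]

    b_gwas = signs * merged["beta_gwas"].to_numpy(dtype=float)
    z_g, ok_g = z_scores(b_gwas, merged["se_gwas"].to_numpy(), merged["pvalue_gwas"].to_numpy())
    z_e, ok_e = z_scores(
        merged["beta"].to_numpy(), merged["se"].to_numpy(), merged["pvalue"].to_numpy()
    )
    usable = ok_g & ok_e & np.isfinite(z_g) & np.isfinite(z_e)
    report.n_dropped_unusable_z = int((~usable).sum())

    pairs = pd.DataFrame(
        {
            "snp_id": merged["snp_id"],
            "probe_id": merged["probe_id"],
            "gene_name": merged["gene_name"],
            "chrom": merged["chrom"].where(merged["chrom"].notna(), merged.get("chrom_gwas")),
            "pos": merged["pos"].where(merged["pos"].notna(), merged.get("pos_gwas")),
            "z_gwas": z_g,
            "z_eqtl": z_e,
            "alignment": np.where(signs < 0, "flipped", "direct"),
            "b_gwas": b_gwas,
            "b_eqtl": merged["beta"].to_numpy(dtype=float),
        }
    )[usable].reset_index(drop=True)

    report.n_pairs = len(pairs)
    report.n_flipped = int((pairs["alignment"] == "flipped").sum())
    return pairs, report


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(
        {
            c: pd.Series(dtype=t)
            for c, t in [
                ("snp_id", str), ("probe_id", str), ("gene_name", str),
                ("chrom", object), ("pos", float),
                ("z_gwas", float), ("z_eqtl", float),
                ("alignment", str), ("b_gwas", float), ("b_eqtl", float),
            ]
        }
    )
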