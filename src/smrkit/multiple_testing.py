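"""FDR adjustment, significance filtering and cross-dataset summaries.

P_SMR values are adjusted with the Benjamini-Hochberg step-up procedure,
by default within each GWAS x eQTL dataset pairing separately (each pairing
tests its own family of SNP x probe hypotheses; pooled adjustment across
pairings is available via ``scope="pooled"``).  Significance is strict:
``p_adj < alpha`` with alpha defaulting to 0.05.

Summaries across pairings count *distinct* SNPs and genes: the same locus
recovered in several pairings, or several exon probes of one gene, counts
once.  Exon-level probes map to genes through ``gene_name``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "bh_adjust",
    "adjust_results",
    "filter_significant",
    "SignificanceSummary",
    "summarize_across",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, in the original input order.

    Step-up procedure: sort ascending, scale p_(i) by m/i, enforce monotone
    non-decreasing adjusted values from the top rank downward, cap at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def adjust_results(
    results: pd.DataFrame, alpha: float = 0.05, scope: str = "per_dataset"
) -> pd.DataFrame:
    """Fill ``p_adj`` and ``significant`` on an SMR result frame.

    ``scope="per_dataset"`` adjusts within each ``smr_label`` group;
    ``scope="pooled"`` treats all rows as one family.
    """
    out = results.copy()
    if out.empty:
        return out
    if scope == "pooled":
        out["p_adj"] = bh_adjust(out["p_smr"].to_numpy())
    elif scope == "per_dataset":
        out["p_adj"] = out.groupby("smr_label", sort=False)["p_smr"].transform(
            lambda s: bh_adjust(s.to_numpy())
        )
    else:
        raise ValueError(f"unknown FDR scope {scope!r}")
    out["significant"] = (out["p_adj"] < alpha).astype("boolean")
    return out


def filter_significant(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows with ``p_adj`` strictly below alpha, original order preserved.

    Also (re)sets the ``significant`` flag on the input frame.  Raises if
    any ``p_adj`` is unset.
    """
    if len(results) and results["p_adj"].isna().any():
        raise ValueError("p_adj unset; run adjust_results first")
    flags = (results["p_adj"] < alpha).astype("boolean")
    results["significant"] = flags
    return results[flags.fillna(False).to_numpy(dtype=bool)].copy()


@dataclass
class SignificanceSummary:
    """Distinct significant SNPs/genes across a chosen set of pairings."""

    per_dataset: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_distinct_snps: int = 0
    n_distinct_genes: int = 0
    gene_to_snps: dict[str, set[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_distinct_snps": self.n_distinct_snps,
            "n_distinct_genes": self.n_distinct_genes,
            "per_dataset_counts": {k: len(v) for k, v in sorted(self.per_dataset.items())},
            "gene_to_snps": {g: sorted(s) for g, s in sorted(self.gene_to_snps.items())},
        }


def summarize_across(
    results_by_dataset: Mapping[str, pd.DataFrame],
    selected_labels: Iterable[str] | None = None,
) -> SignificanceSummary:
    """Union significant SNPs and genes over the selected dataset pairings.

    ``results_by_dataset`` maps each pairing label to its *significant*
    result rows (as from :func:`filter_significant`).  Unknown labels in
    ``selected_labels`` raise; omitting it selects every available pairing.
    """
    labels = list(selected_labels) if selected_labels is not None else sorted(results_by_dataset)
    unknown = [l for l in labels if l not in results_by_dataset]
    if unknown:
        raise KeyError(f"unknown dataset label(s): {unknown}")

    summary = SignificanceSummary()
    snps: set[str] = set()
    genes: set[str] = set()
    for label in labels:
        rows = results_by_dataset[label]
        summary.per_dataset[label] = rows
        snps.update(rows["snp_id"].astype(str))
        genes.update(rows["gene_name"].astype(str))
        for gene, grp in rows.groupby("gene_name"):
            summary.gene_to_snps.setdefault(str(gene), set()).update(
                grp["snp_id"].astype(str)
            )
    summary.n_distinct_snps = len(snps)
    summary.n_distinct_genes = len(genes)
    return summary
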