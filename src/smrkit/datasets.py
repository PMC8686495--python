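"""Bundled reference tables.

``lung_smr_hits.tsv`` lists previously reported significant SMR
associations for lung cancer: two GWAS sources (a European-ancestry
biobank meta-analysis, labelled ``Meta_*``, and a Japanese biobank,
labelled ``BBJ_*``) each crossed with four eQTL panels (GTEx blood, GTEx
lung, and gene-level / exon-level blood panels).  Each row is one
significant SNP x gene test with its raw and FDR-adjusted SMR p-value.
The table is used as a worked example for cross-dataset summarization:
the four BBJ pairings yield 10 distinct SNPs regulating 7 distinct genes,
and the Meta pairings yield 2 distinct SNPs (both acting on PSMA4).
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

__all__ = ["load_lung_smr_hits", "META_LABELS", "BBJ_LABELS"]

META_LABELS = ["Meta_GTEx_Blood", "Meta_GTEx_Lung", "Meta_GENE_Blood", "Meta_EXON_Blood"]
BBJ_LABELS = ["BBJ_GTEx_Blood", "BBJ_GTEx_Lung", "BBJ_GENE_Blood", "BBJ_EXON_Blood"]


def load_lung_smr_hits() -> dict[str, pd.DataFrame]:
    """Published significant lung-cancer SMR hits, grouped by pairing label.

    Returns a mapping from SMR dataset label to its significant rows
    (columns: smr_label, snp_id, p_smr, p_adj, gene_name), in the shape
    :func:`smrkit.multiple_testing.summarize_across` consumes.  Pairings
    with no significant hit (the two lung-tissue pairings and
    Meta_GTEx_Blood/Meta_GTEx_Lung) are present with empty frames.
    """
    path = files("smrkit").joinpath("data/lung_smr_hits.tsv")
    with path.open("r") as fh:
        df = pd.read_csv(fh, sep="\t")
    out: dict[str, pd.DataFrame] = {}
    for label in META_LABELS + BBJ_LABELS:
        out[label] = df[df["smr_label"] == label].reset_index(drop=True)
    return out
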