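"""Synthetic GWAS / eQTL summary statistics with known causal architecture.

The generator emulates the two-sample summary-statistics setting the SMR
test operates in, without simulating individual genotypes.  For each gene a
set of instrument SNPs is drawn; SNP j with minor-allele frequency ``f_j``
has genotype variance ``2 f_j (1 - f_j)`` under Hardy-Weinberg, giving the
standardized-trait standard errors

    se_zx = 1 / sqrt(2 f (1-f) n_eqtl)     (SNP -> expression)
    se_zy = 1 / sqrt(2 f (1-f) n_gwas)     (SNP -> trait)

A fraction of genes is causal with gene-to-trait effect ``b_xy``; every SNP
of a causal gene has true trait effect ``b_zy = b_xy * b_zx`` while null
genes have ``b_zy = 0``.  Observed effects are drawn independently as
``Normal(truth, se^2)`` — the two studies share no samples and SNPs are in
linkage equilibrium (no LD).  Two-sided normal p-values are written along
with beta and se; a configurable fraction of GWAS rows is written in the
swapped allele orientation to exercise harmonization.

``evaluate`` scores pipeline output against the stored truth: per-gene
type-I error and power (a gene is rejected when any of its SNP x probe
tests is significant) and the median bias of the Wald ratio estimate
``b_xy_hat = beta_gwas / beta_eqtl`` taken at each causal gene's
strongest eQTL SNP.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "SimTruth", "EvalReport", "simulate", "simulate_frames", "evaluate"]

# Ordered non-palindromic allele pairs; swaps/strand flips stay resolvable.
_ALLELE_PAIRS = [
    ("A", "C"), ("C", "A"), ("A", "G"), ("G", "A"),
    ("T", "C"), ("C", "T"), ("T", "G"), ("G", "T"),
]

_SMALLEST_P = 5e-324  # underflow floor when writing p columns; see module docs


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic GWAS + eQTL dataset pair.

    Defaults give a minutes-scale dataset with uniformly strong instruments
    (smallest |b_zx|/se_zx ~ 9 at the lower maf bound), suitable for
    calibration studies with tight binomial error bars.
    """

    n_genes: int = 2000
    snps_per_gene: int = 1
    frac_causal: float = 0.05
    b_xy: float = 0.3
    b_zx_range: tuple[float, float] = (0.3, 0.5)
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_gwas: int = 100_000
    n_eqtl: int = 10_000
    overlap_frac: float = 1.0
    swap_frac: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.snps_per_gene, self.n_gwas, self.n_eqtl) <= 0:
            raise ValueError("counts must be positive")
        for name, frac in [("frac_causal", self.frac_causal),
                           ("overlap_frac", self.overlap_frac),
                           ("swap_frac", self.swap_frac)]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.overlap_frac > 0 and round(self.overlap_frac * self.n_genes * self.snps_per_gene) < 1:
            raise ValueError("overlap_frac leaves no shared SNPs")


@dataclass
class SimTruth:
    """Ground-truth causal architecture of a simulated dataset.

    ``genes``: gene_name, causal, b_xy.
    ``snps``: snp_id, gene_name, maf, b_zx, b_zy (= b_xy * b_zx, 0 for
    SNPs of non-causal genes).
    """

    genes: pd.DataFrame
    snps: pd.DataFrame
    config: SimConfig | None = None

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False, float_format="%.12g")
        self.snps.to_csv(out_dir / "truth_snps.tsv", sep="\t", index=False, float_format="%.12g")
        if self.config is not None:
            (out_dir / "sim_config.json").write_text(
                json.dumps(asdict(self.config), indent=1, sort_keys=True) + "\n"
            )

    @classmethod
    def load(cls, out_dir) -> "SimTruth":
        out_dir = Path(out_dir)
        cfg_path = out_dir / "sim_config.json"
        config = None
        if cfg_path.exists():
            raw = json.loads(cfg_path.read_text())
            for key in ("b_zx_range", "maf_range"):
                raw[key] = tuple(raw[key])
            config = SimConfig(**raw)
        return cls(
            genes=pd.read_csv(out_dir / "truth_genes.tsv", sep="\t"),
            snps=pd.read_csv(out_dir / "truth_snps.tsv", sep="\t"),
            config=config,
        )


def simulate_frames(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw one synthetic dataset; returns (gwas, eqtl, truth) frames.

    The gwas/eqtl frames use the default file dialect's column names and
    are exactly what :func:`simulate` writes to disk.  Fully reproducible
    from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_snps = config.n_genes * config.snps_per_gene
    gene_names = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    causal = np.zeros(config.n_genes, dtype=bool)
    n_causal = int(round(config.frac_causal * config.n_genes))
    causal[rng.permutation(config.n_genes)[:n_causal]] = True
    b_xy_gene = np.where(causal, config.b_xy, 0.0)

    gene_of_snp = np.repeat(np.arange(config.n_genes), config.snps_per_gene)
    snp_ids = np.array([f"rs{1_000_001 + i}" for i in range(n_snps)])
    chrom = (gene_of_snp % 22) + 1
    pos = 10_000 + 1_000 * np.arange(n_snps)

    maf = rng.uniform(*config.maf_range, size=n_snps)
    lo, hi = config.b_zx_range
    b_zx = rng.uniform(lo, hi, size=n_snps) * rng.choice([-1.0, 1.0], size=n_snps)
    b_zy = b_xy_gene[gene_of_snp] * b_zx

    var = 2.0 * maf * (1.0 - maf)
    se_zx = 1.0 / np.sqrt(var * config.n_eqtl)
    se_zy = 1.0 / np.sqrt(var * config.n_gwas)
    if not (np.isfinite(se_zx).all() and np.isfinite(se_zy).all()):
        raise ValueError("degenerate config: infinite standard errors")

    b_zx_hat = rng.normal(b_zx, se_zx)
    b_zy_hat = rng.normal(b_zy, se_zy)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    eqtl = pd.DataFrame(
        {
            "SNP": snp_ids, "chr": chrom, "bp": pos,
            "A1": a1, "A2": a2, "freq": maf,
            "b": b_zx_hat, "se": se_zx, "p": _two_sided_p(b_zx_hat / se_zx),
            "n": config.n_eqtl,
            "probe": gene_names[gene_of_snp], "gene": gene_names[gene_of_snp],
        }
    )

    keep = np.sort(
        rng.permutation(n_snps)[: max(1, int(round(config.overlap_frac * n_snps)))]
    )
    swap = rng.random(len(keep)) < config.swap_frac
    g_beta = np.where(swap, -b_zy_hat[keep], b_zy_hat[keep])
    gwas = pd.DataFrame(
        {
            "SNP": snp_ids[keep], "chr": chrom[keep], "bp": pos[keep],
            "A1": np.where(swap, a2[keep], a1[keep]),
            "A2": np.where(swap, a1[keep], a2[keep]),
            "freq": np.where(swap, 1.0 - maf[keep], maf[keep]),
            "b": g_beta, "se": se_zy[keep],
            "p": _two_sided_p(b_zy_hat[keep] / se_zy[keep]),
            "n": config.n_gwas,
        }
    )

    truth = SimTruth(
        genes=pd.DataFrame({"gene_name": gene_names, "causal": causal, "b_xy": b_xy_gene}),
        snps=pd.DataFrame(
            {
                "snp_id": snp_ids, "gene_name": gene_names[gene_of_snp],
                "maf": maf, "b_zx": b_zx, "b_zy": b_zy,
            }
        ),
        config=config,
    )
    return gwas, eqtl, truth


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    from scipy.special import ndtr

    p = 2.0 * ndtr(-np.abs(z))
    # strong instruments underflow double precision; the readers reject
    # p = 0 as malformed, and Z computation prefers beta/se regardless
    return np.maximum(p, _SMALLEST_P)


def simulate(config: SimConfig, out_dir) -> tuple[Path, Path, SimTruth]:
    """Write one synthetic dataset to ``out_dir``; returns the file paths.

    Emits ``gwas.tsv`` and ``eqtl.tsv`` in the default reader dialect plus
    the truth tables (``truth_genes.tsv``, ``truth_snps.tsv``,
    ``sim_config.json``).  Identical configs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gwas, eqtl, truth = simulate_frames(config)
    gwas_path = out_dir / "gwas.tsv"
    eqtl_path = out_dir / "eqtl.tsv"
    gwas.to_csv(gwas_path, sep="\t", index=False, float_format="%.12g")
    eqtl.to_csv(eqtl_path, sep="\t", index=False, float_format="%.12g")
    truth.save(out_dir)
    return gwas_path, eqtl_path, truth


@dataclass
class EvalReport:
    """Truth-scored pipeline performance on one simulated dataset."""

    alpha: float
    type1_rate: float
    power: float
    bias_bxy: float
    n_null: int
    n_causal: int

    def to_dict(self) -> dict:
        return {k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in self.__dict__.items()}


def evaluate(
    results: pd.DataFrame,
    truth: SimTruth,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> EvalReport:
    """Score SMR results against simulation truth.

    A gene counts as rejected when any of its SNP x probe tests has
    ``p_smr < alpha`` (calibration mode) or ``p_adj < alpha`` when
    ``use_adjusted`` (pipeline mode).  Ratio-estimate bias needs the
    internal aligned-beta columns (``b_gwas``, ``b_eqtl``) produced by
    harmonization; it is NaN when they are absent or no causal gene was
    tested.
    """
    known = set(truth.genes["gene_name"].astype(str))
    seen = set(results["gene_name"].astype(str))
    stray = seen - known
    if stray:
        raise ValueError(f"results contain genes absent from truth: {sorted(stray)[:5]}")

    pcol = "p_adj" if use_adjusted else "p_smr"
    rejected = set(results.loc[results[pcol] < alpha, "gene_name"].astype(str))

    gene_truth = truth.genes.set_index("gene_name")["causal"].astype(bool)
    null_genes = gene_truth.index[~gene_truth]
    causal_genes = gene_truth.index[gene_truth]

    type1 = float(np.mean([g in rejected for g in null_genes])) if len(null_genes) else np.nan
    power = float(np.mean([g in rejected for g in causal_genes])) if len(causal_genes) else np.nan

    bias = np.nan
    if {"b_gwas", "b_eqtl"} <= set(results.columns) and len(causal_genes):
        causal_res = results[results["gene_name"].isin(causal_genes)]
        if len(causal_res):
            top = causal_res.loc[
                causal_res.groupby("gene_name")["z_eqtl"]
                .transform(lambda s: s.abs().rank(method="first", ascending=False))
                == 1
            ]
            est = top["b_gwas"].to_numpy() / top["b_eqtl"].to_numpy()
            true_bxy = truth.genes.set_index("gene_name").loc[top["gene_name"], "b_xy"].to_numpy()
            bias = float(np.median(est - true_bxy))

    return EvalReport(
        alpha=alpha,
        type1_rate=type1,
        power=power,
        bias_bxy=bias,
        n_null=int(len(null_genes)),
        n_causal=int(len(causal_genes)),
    )
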