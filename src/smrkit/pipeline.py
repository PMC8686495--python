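"""Batch orchestration of GWAS x eQTL pairings and plot-data export.

A run is declared in a single YAML/JSON config listing the dataset pairings
(the typical study crosses a handful of GWAS with a handful of eQTL panels),
harmonization options, the significance level and the FDR scope.  For each
pairing the pipeline reads both files, harmonizes, computes the SMR test,
adjusts p-values and writes: the full result table, the harmonization
report, the significant hits, and Manhattan plot data; a combined summary
of distinct significant SNPs and genes across pairings is written once.

All outputs are deterministic: rerunning the same config yields
byte-identical files, and every number equals what the underlying library
calls produce directly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import multiple_testing as mt
from .harmonize import HarmonizeOptions, overlap_and_harmonize
from .stats import _chrom_sort_key, run_smr
from .sumstats_io import Dialect, read_eqtl, read_gwas, write_results

__all__ = [
    "PairingSpec",
    "RunConfig",
    "ConfigError",
    "load_run_config",
    "run_pairings",
    "export_manhattan",
    "plot_manhattan",
]

log = logging.getLogger("smrkit")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PairingSpec:
    label: str
    gwas_path: str
    eqtl_path: str
    gwas_dialect: Dialect = Dialect()
    eqtl_dialect: Dialect = Dialect()


@dataclass
class RunConfig:
    pairings: list[PairingSpec]
    out_dir: str
    options: HarmonizeOptions = field(default_factory=HarmonizeOptions)
    alpha: float = 0.05
    fdr_scope: str = "per_dataset"

    def validate(self) -> None:
        if not self.pairings:
            raise ConfigError("no pairings configured")
        labels = [p.label for p in self.pairings]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"duplicate pairing labels: {labels}")
        for p in self.pairings:
            for kind, path in [("GWAS", p.gwas_path), ("eQTL", p.eqtl_path)]:
                if not Path(path).exists():
                    raise ConfigError(
                        f"pairing {p.label!r}: {kind} file not found: {path}"
                    )
        if self.fdr_scope not in ("per_dataset", "pooled"):
            raise ConfigError(f"unknown fdr_scope {self.fdr_scope!r}")


def _dialect_from(d: dict | None) -> Dialect:
    if not d:
        return Dialect()
    unknown = set(d) - {f.name for f in dataclasses.fields(Dialect)}
    if unknown:
        raise ConfigError(f"unknown dialect keys: {sorted(unknown)}")
    return Dialect(**d)


def load_run_config(path, out_dir: str | None = None) -> RunConfig:
    """Parse a YAML (or JSON) run configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "pairings" not in raw:
        raise ConfigError(f"{path}: config must be a mapping with a 'pairings' list")
    pairings = [
        PairingSpec(
            label=p["label"],
            gwas_path=p["gwas"],
            eqtl_path=p["eqtl"],
            gwas_dialect=_dialect_from(p.get("gwas_dialect")),
            eqtl_dialect=_dialect_from(p.get("eqtl_dialect")),
        )
        for p in raw["pairings"]
    ]
    opts = raw.get("harmonize", {})
    if "eaf_ambiguity_window" in opts:
        opts["eaf_ambiguity_window"] = tuple(opts["eaf_ambiguity_window"])
    return RunConfig(
        pairings=pairings,
        out_dir=out_dir or raw.get("out_dir", "smr_out"),
        options=HarmonizeOptions(**opts),
        alpha=float(raw.get("alpha", 0.05)),
        fdr_scope=raw.get("fdr_scope", "per_dataset"),
    )


def run_pairings(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute every pairing and write all result files under ``out_dir``.

    Returns the adjusted result frame per label (with internal extra
    columns, for callers that go on to score against simulation truth).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    all_results: dict[str, pd.DataFrame] = {}
    significant: dict[str, pd.DataFrame] = {}
    for spec in config.pairings:
        log.info("pairing %s: reading inputs", spec.label)
        gwas, g_rep = read_gwas(spec.gwas_path, spec.gwas_dialect)
        eqtl, e_rep = read_eqtl(spec.eqtl_path, spec.eqtl_dialect)
        pairs, h_rep = overlap_and_harmonize(gwas, eqtl, config.options)
        log.info("pairing %s: %s", spec.label, h_rep.to_dict())
        results = run_smr(pairs, spec.label)
        if config.fdr_scope == "per_dataset":
            results = mt.adjust_results(results, config.alpha, scope="per_dataset")
        all_results[spec.label] = results

        report = {
            "gwas_load": {"n_rows": g_rep.n_rows, "n_kept": g_rep.n_kept,
                          "drop_reasons": g_rep.drop_reasons},
            "eqtl_load": {"n_rows": e_rep.n_rows, "n_kept": e_rep.n_kept,
                          "drop_reasons": e_rep.drop_reasons,
                          "n_duplicates": e_rep.n_duplicates},
            "harmonize": h_rep.to_dict(),
        }
        (out / f"{spec.label}.harmonize.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n"
        )

    if config.fdr_scope == "pooled":
        pooled = pd.concat(all_results.values(), ignore_index=True)
        pooled = mt.adjust_results(pooled, config.alpha, scope="pooled")
        all_results = {
            label: grp.reset_index(drop=True)
            for label, grp in pooled.groupby("smr_label", sort=False)
        }

    for label, results in all_results.items():
        write_results(results, out / f"{label}.results.tsv")
        hits = mt.filter_significant(results, config.alpha)
        significant[label] = hits
        write_results(hits, out / f"{label}.significant.tsv")
        export_manhattan(results, out / f"{label}.manhattan.tsv")

    summary = mt.summarize_across(significant)
    (out / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    return all_results


_TINY = 5e-324  # plotting floor for p = underflow; flagged in the output


def export_manhattan(results: pd.DataFrame, path) -> int:
    """Write Manhattan plot data: one row per test, sorted by genome position.

    Columns: chrom, pos, probe_id, snp_id, neg_log10_p, significant,
    floored.  ``neg_log10_p`` is always finite: p-values of exactly 0
    (possible only from upstream underflow) are floored to the smallest
    positive double for plotting and flagged.  Rows without coordinates are
    skipped; the count of skipped rows is returned.
    """
    has_coords = results["chrom"].notna() & results["pos"].notna()
    n_skipped = int((~has_coords).sum())
    df = results[has_coords].copy()

    p = df["p_smr"].to_numpy(dtype=float)
    floored = p < _TINY
    df["neg_log10_p"] = -np.log10(np.maximum(p, _TINY))
    df["floored"] = floored
    order = np.lexsort((df["pos"].to_numpy(), _chrom_sort_key(df["chrom"]).to_numpy()))
    df = df.iloc[order]
    cols = ["chrom", "pos", "probe_id", "snp_id", "neg_log10_p", "significant", "floored"]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.12g")
    return n_skipped


def plot_manhattan(results: pd.DataFrame, png_path, alpha_line: float | None = None) -> None:
    """Optional image rendering of the exported Manhattan data."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results[results["chrom"].notna() & results["pos"].notna()].copy()
    df["ckey"] = _chrom_sort_key(df["chrom"])
    df = df.sort_values(["ckey", "pos"])
    df["x"] = np.arange(len(df))
    fig, ax = plt.subplots(figsize=(9, 3))
    for i, (_, grp) in enumerate(df.groupby("ckey", sort=True)):
        ax.scatter(grp["x"], -np.log10(np.maximum(grp["p_smr"], _TINY)),
                   s=4, color=["#36648b", "#7ba7c9"][i % 2])
    if alpha_line:
        ax.axhline(-np.log10(alpha_line), color="red", lw=0.7, ls="--")
    ax.set_xlabel("genome position (ordered)")
    ax.set_ylabel(r"$-\log_{10} P_{SMR}$")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
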