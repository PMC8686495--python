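import numpy as np
import pandas as pd
import pytest

from smrkit.synthetic import SimConfig, simulate_frames


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared across read-only tests."""
    config = SimConfig(n_genes=300, snps_per_gene=3, frac_causal=0.1,
                       overlap_frac=0.8, swap_frac=0.3, seed=11)
    gwas, eqtl, truth = simulate_frames(config)
    return config, gwas, eqtl, truth


@pytest.fixture()
def gwas_file(tmp_path):
    """Write a tiny GWAS TSV in the default dialect and return its path."""

    def _write(rows, header="SNP\tchr\tbp\tA1\tA2\tfreq\tb\tse\tp\tn", name="gwas.tsv"):
        path = tmp_path / name
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return _write


def random_pairs(rng, n):
    """Random harmonized-pair frame for statistic-level tests."""
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "probe_id": [f"P{i % 7}" for i in range(n)],
            "gene_name": [f"G{i % 7}" for i in range(n)],
            "chrom": rng.integers(1, 23, n),
            "pos": rng.integers(1, 10**8, n),
            "z_gwas": rng.normal(0, 2, n),
            "z_eqtl": rng.normal(0, 4, n),
            "alignment": "direct",
        }
    )
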