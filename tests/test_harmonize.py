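"""Overlap construction and allele alignment, checked against brute force."""

import numpy as np
import pandas as pd
import pytest

from smrkit.harmonize import (
    HarmonizeOptions,
    align_alleles,
    overlap_and_harmonize,
)
from smrkit.stats import choose_z, t_smr
from smrkit.synthetic import SimConfig, simulate_frames
from smrkit.sumstats_io import GWAS_FIELDS


def _gwas(rows):
    return pd.DataFrame(rows, columns=GWAS_FIELDS)


def _eqtl(rows):
    cols = GWAS_FIELDS + ["probe_id", "gene_name", "probe_level"]
    return pd.DataFrame(rows, columns=cols)


def g_row(snp, a1="A", a2="G", beta=0.1, eaf=0.3):
    return (snp, "1", 100, a1, a2, eaf, beta, 0.05, 0.04, 1000)


def e_row(snp, probe, a1="A", a2="G", beta=0.2, eaf=0.3):
    return (snp, "1", 100, a1, a2, eaf, beta, 0.05, 0.04, 500, probe, probe, "gene")


class TestAlignAlleles:
    def test_identity(self):
        assert align_alleles("A", "G", "A", "G") == (1, None)

    def test_swap(self):
        assert align_alleles("A", "G", "G", "A") == (-1, None)

    def test_strand_flip_direct(self):
        # GWAS on the other strand: A/G complements to T/C
        assert align_alleles("T", "C", "A", "G") == (1, None)

    def test_strand_flip_swapped(self):
        assert align_alleles("C", "T", "A", "G") == (-1, None)

    def test_strand_flip_disabled(self):
        opts = HarmonizeOptions(allow_strand_flip=False)
        assert align_alleles("T", "C", "A", "G", options=opts) == (None, "allele mismatch")

    def test_palindromic_dropped_by_policy(self):
        opts = HarmonizeOptions(palindromic_policy="drop_all")
        assert align_alleles("A", "T", "A", "T", options=opts) == (None, "palindromic")

    def test_palindromic_ambiguous_frequency_dropped(self):
        assert align_alleles("A", "T", "A", "T", 0.5, 0.5) == (None, "palindromic")
        assert align_alleles("A", "T", "A", "T", None, 0.2) == (None, "palindromic")

    def test_palindromic_resolved_by_frequency(self):
        # both effect alleles minor -> same physical allele
        assert align_alleles("A", "T", "A", "T", 0.2, 0.25) == (1, None)
        # one minor, one major -> opposite alleles
        assert align_alleles("A", "T", "A", "T", 0.2, 0.8) == (-1, None)
        # swapped letters, frequencies agree: opposite strand, direct effect
        assert align_alleles("A", "T", "T", "A", 0.2, 0.25) == (1, None)

    def test_irreconcilable_alleles(self):
        assert align_alleles("A", "G", "A", "C") == (None, "allele mismatch")

    def test_non_acgt_rejected(self):
        assert align_alleles("A", "GT", "A", "G")[1] == "allele mismatch"


class TestOverlap:
    def test_intersection_example(self):
        gwas = _gwas([g_row("rs1"), g_row("rs2")])
        eqtl = _eqtl([e_row("rs2", "P1"), e_row("rs3", "P1")])
        pairs, report = overlap_and_harmonize(gwas, eqtl)
        assert list(pairs["snp_id"]) == ["rs2"]
        assert report.n_overlap_snps == 1
        assert report.n_pairs == 1

    def test_flip_negates_gwas_beta(self):
        gwas = _gwas([g_row("rs1", a1="A", a2="G", beta=0.1)])
        eqtl = _eqtl([e_row("rs1", "P1", a1="G", a2="A")])
        pairs, report = overlap_and_harmonize(gwas, eqtl)
        assert pairs.loc[0, "alignment"] == "flipped"
        assert pairs.loc[0, "b_gwas"] == pytest.approx(-0.1)
        assert pairs.loc[0, "z_gwas"] == pytest.approx(-0.1 / 0.05)
        assert report.n_flipped == 1

    def test_empty_intersection_not_an_error(self):
        pairs, report = overlap_and_harmonize(
            _gwas([g_row("rs1")]), _eqtl([e_row("rs2", "P1")])
        )
        assert len(pairs) == 0
        assert report.n_overlap_snps == 0

    def test_report_counts_additive(self, small_sim):
        _, gwas_f, eqtl_f, _ = small_sim
        gwas = _from_dialect(gwas_f)
        eqtl = _from_dialect(eqtl_f, eqtl=True)
        pairs, rep = overlap_and_harmonize(gwas, eqtl)
        merged_pairs = eqtl[eqtl["snp_id"].isin(set(gwas["snp_id"]))].shape[0]
        assert rep.n_pairs + rep.n_dropped_allele_mismatch + \
            rep.n_dropped_palindromic + rep.n_dropped_unusable_z == merged_pairs


def _from_dialect(frame, eqtl=False):
    """Map a simulator frame (file-dialect names) to canonical columns."""
    ren = {"SNP": "snp_id", "chr": "chrom", "bp": "pos", "A1": "effect_allele",
           "A2": "other_allele", "freq": "eaf", "b": "beta", "p": "pvalue"}
    out = frame.rename(columns=ren)
    if eqtl:
        out = out.rename(columns={"probe": "probe_id", "gene": "gene_name"})
        out["probe_level"] = "gene"
    return out


def brute_force_harmonize(gwas, eqtl, options=HarmonizeOptions()):
    """Independent oracle: per-pair Python loop over every eQTL record,
    with scalar allele alignment and scalar Z computation."""
    gwas_by_id = {}
    for rec in gwas.to_dict("records"):
        gwas_by_id.setdefault(rec["snp_id"], rec)
    kept = {}
    for rec in eqtl.to_dict("records"):
        g = gwas_by_id.get(rec["snp_id"])
        if g is None:
            continue
        sign, reason = align_alleles(
            g["effect_allele"], g["other_allele"],
            rec["effect_allele"], rec["other_allele"],
            g["eaf"], rec["eaf"], options,
        )
        if sign is None:
            continue
        zg, _ = choose_z(sign * g["beta"],
                         None if pd.isna(g["se"]) else g["se"],
                         None if pd.isna(g["pvalue"]) else g["pvalue"])
        ze, _ = choose_z(rec["beta"],
                         None if pd.isna(rec["se"]) else rec["se"],
                         None if pd.isna(rec["pvalue"]) else rec["pvalue"])
        kept[(rec["snp_id"], rec["probe_id"])] = (zg, ze)
    return kept


class TestBruteForceEquivalence:
    def test_matches_oracle_on_simulated_instance(self, small_sim):
        _, gwas_f, eqtl_f, _ = small_sim
        gwas = _from_dialect(gwas_f)
        eqtl = _from_dialect(eqtl_f, eqtl=True)
        pairs, _ = overlap_and_harmonize(gwas, eqtl)
        oracle = brute_force_harmonize(gwas, eqtl)
        got = {(r.snp_id, r.probe_id): (r.z_gwas, r.z_eqtl) for r in pairs.itertuples()}
        assert got.keys() == oracle.keys()
        for key, (zg, ze) in oracle.items():
            assert got[key][0] == pytest.approx(zg, rel=1e-12)
            assert got[key][1] == pytest.approx(ze, rel=1e-12)


class TestGlobalSwapInvariance:
    def test_eqtl_orientation_swap_flips_z_preserves_t(self, small_sim):
        """Rewriting the whole eQTL file in the opposite allele orientation
        (swap alleles, negate betas, eaf -> 1-eaf) must flip every z_eqtl
        sign, keep |z_eqtl|, and leave every T_SMR unchanged."""
        _, gwas_f, eqtl_f, _ = small_sim
        gwas = _from_dialect(gwas_f)
        eqtl = _from_dialect(eqtl_f, eqtl=True)
        swapped = eqtl.copy()
        swapped[["effect_allele", "other_allele"]] = eqtl[["other_allele", "effect_allele"]].to_numpy()
        swapped["beta"] = -eqtl["beta"]
        swapped["eaf"] = 1.0 - eqtl["eaf"]

        p1, _ = overlap_and_harmonize(gwas, eqtl)
        p2, _ = overlap_and_harmonize(gwas, swapped)
        k1 = p1.set_index(["snp_id", "probe_id"]).sort_index()
        k2 = p2.set_index(["snp_id", "probe_id"]).sort_index()
        assert k1.index.equals(k2.index)
        np.testing.assert_allclose(k2["z_eqtl"], -k1["z_eqtl"], rtol=1e-12)
        np.testing.assert_allclose(k2["z_gwas"], -k1["z_gwas"], rtol=1e-12)
        np.testing.assert_allclose(
            t_smr(k2["z_gwas"].to_numpy(), k2["z_eqtl"].to_numpy()),
            t_smr(k1["z_gwas"].to_numpy(), k1["z_eqtl"].to_numpy()),
            rtol=1e-12,
        )

    def test_determinism(self, small_sim):
        _, gwas_f, eqtl_f, _ = small_sim
        gwas = _from_dialect(gwas_f)
        eqtl = _from_dialect(eqtl_f, eqtl=True)
        p1, r1 = overlap_and_harmonize(gwas, eqtl)
        p2, r2 = overlap_and_harmonize(gwas, eqtl)
        pd.testing.assert_frame_equal(p1, p2)
        assert r1 == r2
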