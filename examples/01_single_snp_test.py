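"""One SNP, by hand: Z scores, the SMR statistic, and its p-value.

A SNP associated with both a trait (GWAS) and the expression of a gene
(eQTL) is a candidate instrument for a causal expression->trait effect.
The SMR test combines the two standardized associations into
T_SMR = (Z_g^2 Z_e^2)/(Z_g^2 + Z_e^2), compared against chi-square(1).
"""

from smrkit import p_from_t, t_smr, z_from_beta_se, z_from_p_beta

# GWAS reports beta and SE; the eQTL study only printed a p-value and the
# direction of effect, so its Z comes from the normal quantile instead.
z_gwas = z_from_beta_se(beta=0.052, se=0.009)
z_eqtl = z_from_p_beta(p=3.1e-12, beta_sign=-1)

t = t_smr(z_gwas, z_eqtl)
p = p_from_t(t)

print(f"Z_GWAS = {z_gwas:+.3f}   (beta/se route)")
print(f"Z_eQTL = {z_eqtl:+.3f}   (signed normal quantile of the p-value)")
print(f"T_SMR  = {t:.3f}")
print(f"P_SMR  = {p:.3g}")
print()
print("T_SMR is bounded by the weaker of the two associations squared:")
print("a large value needs BOTH a trait association and an eQTL signal,")
print("which is what makes it a (single-instrument) mediation test.")
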