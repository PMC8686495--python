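# Methods

## Model and test

The pipeline treats each overlapping SNP × expression-probe pair as one
single-instrument Mendelian randomization test. Writing $b_{zx}$ for the
SNP→expression effect, $b_{zy}$ for the SNP→trait effect and $b_{xy}$ for
the causal expression→trait effect, the instrumental-variable model implies
$b_{zy} = b_{xy} \, b_{zx}$; the Wald ratio $\hat b_{xy} = \hat b_{zy} /
\hat b_{zx}$ estimates the causal effect and the Delta method gives its
variance-standardized square as

$$T_{SMR} = \frac{Z_{GWAS}^2 Z_{eQTL}^2}{Z_{GWAS}^2 + Z_{eQTL}^2},
\qquad Z = \hat b / SE .$$

Under $H_0\!: b_{xy} = 0$ and a strong instrument
($|b_{zx}|/SE_{zx} \gg 0$), $T_{SMR}$ is asymptotically $\chi^2_1$ and
$P_{SMR}$ is its upper tail. With a *weak* instrument both $Z$'s are small
and $T_{SMR} \le \min(Z_{GWAS}^2, Z_{eQTL}^2)$ deflates the statistic, so
the test is conservative rather than anti-conservative — verified by the
weak-instrument simulation test. One degree of freedom and the upper tail
are the only choices consistent with the statistic's construction as a
squared standardized ratio.

Assumptions inherited from the single-instrument setting: no LD-aware
variance correction, no heterogeneity (HEIDI-type) test to distinguish
pleiotropy or linkage from causality, and two-sample independence of the
GWAS and eQTL cohorts. A significant pair is therefore evidence of an
association mediated *or tagged* by expression, not proof of causality.

## Z-score standardization

`beta/se` is used whenever a positive SE is present; otherwise the signed
normal quantile $\pm \Phi^{-1}(1 - p/2)$ with the sign of beta. The ratio
route takes precedence because public p-values are usually rounded while
beta and SE are printed in full. The quantile is evaluated in log space
(`scipy.special.ndtri_exp`), keeping it finite and strictly monotone for
p-values down to the smallest positive double (5e-324) instead of clamping.
Records with beta = 0 and only a p-value have an undefined sign; Z is set
to 0 with a warning (contributing $T_{SMR} = 0$, the conservative choice).
p = 0 exactly is rejected as malformed input rather than clamped: clamping
would silently fabricate a Z score. $P_{SMR}$ uses the chi-square survival
function directly, never $1 - \mathrm{CDF}$, so it is accurate for
arbitrarily large statistics.

## Harmonization

Datasets are intersected on rsID (not chrom:pos — source files may sit on
different genome builds). The eQTL effect allele is the reference
orientation and the GWAS beta is flipped onto it; since $T_{SMR}$ depends
only on squared Z's, the choice of reference cannot change any p-value
(asserted by test), but it makes signed Wald ratios meaningful. Alignment
per pair: direct letter match (+1), swapped effect/other alleles (−1),
reverse-complement matching first when strand flips are allowed (default
on). Palindromic SNPs (A/T, C/G) carry no strand information in their
letters; by default they are kept only when both allele frequencies are
present and outside [0.40, 0.60], in which case minor/major status
identifies the shared allele — otherwise dropped. Every overlapping
(SNP, probe) pair is tested, not just each probe's top eQTL, because one
gene can have several informative instruments. All drops are counted by
reason in a `HarmonizeReport` so the impact of the policy on any real run
is auditable from logs.

## Multiple testing

Benjamini–Hochberg step-up, implemented in-package (sort ascending, scale
$p_{(i)}$ by $m/i$, cumulative minimum from the largest rank, cap at 1,
return in input order) and cross-checked in the test suite against both a
brute-force reference and statsmodels. Adjustment is applied **within each
dataset pairing** over all of its SNP × probe tests: each pairing is its
own hypothesis family, and back-calculating the test count from a
published rank-1 adjusted p-value ($0.0004 / 9.17\times10^{-9} \approx
4\times10^4$) matches a single pairing's test count rather than a pooled
one. Pooled adjustment is available (`fdr_scope: pooled`). Significance is
strict, $P_{adj} < 0.05$. Cross-pairing summaries count *distinct* SNPs
and distinct genes (exon probes collapse to their gene via `gene_name`).

## Synthetic data generator

Emulates the two-sample summary-statistics setting without individual
genotypes. Per SNP with minor-allele frequency $f \sim
U(\text{maf\_range})$, the standardized-trait approximation gives
$SE = 1/\sqrt{2f(1-f)\,n}$ per study; observed effects are drawn
independently as $\mathcal N(b_{zx}, SE_{zx}^2)$ and
$\mathcal N(b_{xy} b_{zx}, SE_{zy}^2)$, with $b_{xy} = 0$ for the
non-causal genes. Alleles come from the eight non-palindromic ordered
pairs, and a configurable fraction of GWAS rows is written in the swapped
orientation (alleles exchanged, beta negated, eaf complemented) to
exercise harmonization. p-values are two-sided normal tails, floored at
5e-324 when they underflow double precision (readers reject p = 0, and Z
computation prefers beta/se regardless).

Defaults are sized for calibration studies with tight binomial error bars
at minutes-scale runtime: 2,000 genes × 1 SNP, 5% causal with
$b_{xy} = 0.3$, $|b_{zx}| \sim U(0.3, 0.5)$, maf ∈ [0.05, 0.5],
$n_{GWAS} = 10^5$, $n_{eQTL} = 10^4$ — instrument Z scores of ≈9 at the
weakest corner, comfortably in the strong-instrument regime where the
$\chi^2_1$ null holds. The evaluation harness reports per-gene type-I
error and power (a gene is rejected when any of its tests is significant,
mirroring how multi-SNP discoveries are reported per gene), and the median
bias of the Wald ratio at each causal gene's strongest instrument; the
bias check uses $n_{eQTL} = 10^5$, where the ratio estimator's
instrument-noise bias is negligible.

What the generator does **not** emulate — hence what passing tests do not
show about real data: LD between instruments (SNPs are independent),
pleiotropic or shared-confounder architectures, allele-frequency drift
between ancestries, sample overlap between the two studies, and
non-normal effect-size distributions. Calibration results transfer to real
data only insofar as those features are absent or handled upstream.

## Numerical and design choices

- Odds ratios are converted to $\ln(OR)$ at read time when the dialect
  declares `effect_scale: OR`; the test operates on signed additive
  effects throughout.
- Result tables serialize floats with 12 significant digits and round-trip
  to ≤1 ulp; rerunning any pipeline config is byte-identical.
- Result ordering is (chromosome, position, probe) with natural chromosome
  order (1–22, X, Y, MT); ties broken by probe id.
- Manhattan export floors p at 5e-324 *for plotting only* and flags
  floored rows; rows without coordinates are skipped and counted.
- Dialects are configurable per dataset because providers do not share a
  column layout; defaults follow the common ".ma"-style schema.
- Simulation problem sizes in tests (e.g. 10⁴ SNPs for the harmonization
  equivalence check, 2,000 null genes for calibration) were chosen as the
  package's own desk-scale study conditions.

## Known limitations

Per-SNP testing means several significant SNPs for one gene are *not*
independent discoveries when in LD in the source data; the distinct-gene
summary partially addresses this but no LD pruning is performed.
Multi-allelic variants are not handled (first record wins on duplicate
keys). The palindromic-SNP frequency heuristic can mis-orient variants
whose frequencies differ strongly between cohorts for ancestry reasons.
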