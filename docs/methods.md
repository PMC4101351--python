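# Methods

## Statistic and null model

For a binary disease status $Y$ and a $k$-SNP combination $X$, each SNP coded
as minor-allele dosage 0/1/2, the scan statistic is the information gain in
bits, $IG(Y|X) = H(Y) - H(Y|X)$, computed from the $|X| \times 2$
contingency table of observed joint-genotype categories against
control/case. $IG$ is the mutual information of the table and satisfies
$0 \le IG \le \min(H(X), H(Y))$; $0\log 0$ is taken as 0.

Significance uses the analytic null
$IG \sim \Gamma(\tfrac12(|Y|-1)(|X|-1),\ 1/(N\ln 2))$ for $N$ samples. This
is an identity with the likelihood-ratio (G) test: $2N\ln2\cdot IG$ is the
G statistic of the table, asymptotically $\chi^2$ with $(|X|-1)(|Y|-1)$
degrees of freedom; the gamma form is the same distribution expressed on the
bits scale. The unit test suite asserts the identity to 1e-10 over random
$(N, |X|, IG)$ triples. Entropies in natural log would rescale the statistic
and the scale parameter identically and leave every p-value unchanged.

P-values are computed as regularised upper incomplete gamma functions
(survival form), never as $1 - \text{CDF}$, so the far tail keeps relative
precision. Degenerate variables ($|X| = 1$ or $|Y| = 1$) carry no
information: $IG$ is reported as 0 and the p-value as 1. Information-gain
values in $[-10^{-12}, 0)$ arising from floating-point cancellation are
clamped to 0.

### Degrees of freedom for sparse tables

$|X|$ defaults to the number of *observed* nonempty joint-genotype
categories rather than the theoretical $3^k$ (`levels="theoretical"`
restores the latter). With rare alleles the theoretical count overstates the
dimension of tables whose rare cells are empty; observed-category counting
adapts the degrees of freedom the way practitioners reduce df for sparse
contingency tables. $N$ is the complete-case count of the combination
actually tabulated: samples missing any of the $k$ genotypes are excluded
per combination, and the null must describe the table that was tested.

## Search engines

**Exhaustive** (`ExhaustiveIGScan`): all $\binom{M}{k}$ combinations of a
fixed order; Bonferroni $m = \binom{M}{k}$ (overridable). Order 2 uses a
vectorised path — per-SNP one-hot indicators (missing encodes to the zero
vector) and two symmetric matrix products give every pair's 3×3 case and
control count blocks at once; this is an internal optimisation whose
contract is bit-identical agreement with the naive per-combination
tabulation, enforced in tests against an independent brute-force oracle.

**Stepwise** (`StepwiseIGScan`): forward selection. All $M$ single SNPs are
evaluated; those with **raw** p-value below the screen $t$ (default 0.05,
the conventional marginal-screen level) seed the search. Each passing
combination is extended by every SNP not already in it; the union of
extensions is deduplicated and evaluated once; the search advances an order
while any extension passes $t$, up to `max_order` (default 4). Because the
termination rule in forward-selection schemes is genuinely open —
"backtrack to the next-ranked combinations" can mean many things — this
implementation expands *all* combinations passing $t$, in rank order, before
stopping; rank order then only fixes reporting, not reachability, which
makes runs reproducible and the search's output independent of traversal
accidents. With $t = 1$ the engine degenerates to the exhaustive scan.

Bonferroni $m$ at each order is, by default, the number of IG evaluations
actually performed at that order (*adaptive*): claiming $\binom{M}{k}$ tests
when only a screened subset was evaluated would be anti-conservative about
the search's selection effect in the wrong direction — the subset was chosen
*because* it looked significant at lower order, so the honest family is the
set of tests run. `m_mode="fixed"` restores $\binom{M}{k}$ for
comparability with the exhaustive scan.

Ranking everywhere is (p ascending, IG descending, index tuple
lexicographic), a total order, so ties cannot reorder across runs.

## Simulator

A $k$-locus model is a $3^k$ penetrance table plus MAFs. Genotypes are HWE
draws (dosage $\sim$ Binomial(2, q)); status is Bernoulli(penetrance);
case/control quotas are filled by rejection sampling from this population
model — the standard mechanism when a generator is described only by its
penetrance table. Noise SNPs are independent HWE draws at MAFs from a
sampler, uniform on [0.05, 0.5] by default (matching the MAF ≥ 5% QC
convention; null-scan calibration is evaluated on the same range). Null
datasets assign the phenotype independently of all genotypes with an exact
balanced split by default.

Built-in two-locus fixtures (registry `builtin_model`): `xor`
(baseline 0.05, effect 0.3, MAFs 0.5/0.5 — penetrance elevated exactly where
dosage parity is odd; marginals are flat at MAF 0.5, the canonical
no-main-effect epistasis), `multiplicative` (baseline 0.05, odds factor 2
per allele, MAFs 0.3/0.3 — strong marginal footprint, used as the planted
model for stepwise-efficiency checks), `additive`, and `constant-null`.
These are representative parameterisations, not published tables; arbitrary
penetrance tables load from TSV so published models can be plugged in
verbatim. `marginal_penetrance` returns each locus's penetrance averaged
over the other loci's HWE distribution, the analytic check for main
effects.

What the generator emulates: independent biallelic SNPs in HWE, disease
driven only by the causal loci. What it does not: linkage disequilibrium,
genotyping error, population stratification, covariates. Passing tests
therefore demonstrate calibration and detection under clean independence
assumptions, not robustness to structured real data.

## Experiments and problem sizes

`type1_experiment` estimates family-wise error of the pairwise null scan:
fraction of replicates whose minimum Bonferroni-adjusted p-value falls below
each nominal level, with Monte-Carlo standard errors
$\sqrt{\hat p(1-\hat p)/R}$. "False positive rate" is interpreted family-
wise — per-test rates after Bonferroni would be orders of magnitude below
the nominal levels and could not track them. The family is pairs-only by
default (`include_first_order` adds the single-SNP tests).

`power_experiment` counts a replicate as a detection only when the exact
causal SNP set is reported significant (a lenient containment mode exists
but is off by default: a superset hit is not a discovery of the pair).

`stepwise_efficiency` runs both engines on shared replicates and reports
power(stepwise)/power(exhaustive) and the ratio of IG evaluations —
evaluation counts, not wall-clock, so the ratio is hardware-independent.
The default comparison is at order ≤ 2 (the planted models are two-locus
pairs); the exhaustive denominator uses the same order range, which makes
the reported computation ratio conservative relative to a deeper sweep.

The package's standing problem sizes: acceptance-scale calibration at 300
null replicates × 500 SNPs × 1000 balanced samples; stepwise efficiency at
100 replicates × 50 SNPs × 400 samples; unit-level calibration smoke tests
at 60 replicates × 100 SNPs. Replicate $r$ of base seed $s$ uses the RNG
stream seeded by $(s, r)$, making reports bit-identical across reruns and
replicates independent.

## Known limitations

* **Far-tail conservatism of the analytic null.** The gamma/χ² null is
  accurate at moderate significance (raw p-values are KS-uniform on null
  data down to p ≈ 1e-3), but the true tail of the discrete statistic is
  lighter than the approximation at genome-scan Bonferroni depths: in a
  12-million-pair null simulation at N = 1000, MAF ∈ [0.05, 0.5],
  P(p < t)/t ≈ 0.78 at t = 1e-5, ≈ 0.66 at t = 2.4e-6 and ≈ 0.4 at
  t = 4e-7. Family-wise error of the Bonferroni-corrected pairwise scan
  therefore runs somewhat *below* the nominal level at the upper levels
  (e.g. ≈ 0.21–0.25 at nominal 0.30 under the conditions above) — the scan
  is conservative, not inflated. This is a property of likelihood-ratio-type
  statistics on sparse 3×3×2 tables, not of the implementation, which is
  verified exactly against chi-square and brute-force oracles.
* The HWE QC filter uses the 1-df chi-square goodness-of-fit test in
  controls only; an exact-test upgrade is future work.
* The stepwise search cannot find interactions with no lower-order
  footprint; that trade-off is intrinsic to forward selection and is
  demonstrated (not worked around) in the tests.
* No linkage disequilibrium, imputation, sex-chromosome handling, VCF
  input, or gene–environment terms (an environment factor can only enter as
  a categorical pseudo-SNP column).
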