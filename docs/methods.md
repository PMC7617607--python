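# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic-data generator, the main parameters (units, defaults, and
rationale), and the numerical choices. It makes no empirical claims beyond
what the test suite and `scripts/acceptance.py` recompute.

## 1. Summary-statistic model

All inference operates on GWAS summary statistics: per variant *j*, a
marginal effect estimate β̂ⱼ, its standard error SEⱼ, the effect-allele
frequency fⱼ, a p-value, and the sample size. Under the standard
regression-with-summary-statistics (RSS) approximation, the vector of
z-scores in a region with LD correlation matrix **R** is distributed

z ~ MVN(**R** η, **R**),  ηⱼ = bⱼ / SEⱼ,

where bⱼ is the joint (causal) effect of variant *j* (zero for non-causal
variants). Standard errors use the asymptotic forms

- quantitative trait: SEⱼ = 1 / √(2 n fⱼ(1−fⱼ)) — β in phenotype SD units
  per allele;
- binary trait: SEⱼ = 1 / √(2 n φ(1−φ) fⱼ(1−fⱼ)) with case fraction φ —
  β in log-odds per allele.

## 2. Synthetic-data generator (`coagmr.simulate`)

The generator draws z from the MVN above and converts back to β̂ = z·SE.

What it emulates:

- block AR(1) LD (correlation ρ^|i−j| within a block, zero across blocks),
  which reproduces the local decay of LD without requiring a reference panel;
- one or more causal cis variants per protein with effects in SD units
  (λ, default region setups use 0.4–0.5 — strong cis-pQTLs);
- outcome effects induced through the causal chain: an outcome with causal
  effect θ on the protein scale receives joint variant effects θ·λ (plus any
  direct pleiotropic effects configured per variant);
- multiple cohorts per protein with different sample sizes, an optional
  assay sign-flip artifact per cohort, and sample-overlap correlation
  between traits (shared noise component with correlation equal to the
  overlap fraction);
- per-(seed, region, stream) counter-based seeding
  (`numpy.random.SeedSequence([seed, region_idx, stream])`) so that adding a
  trait or region never perturbs existing draws.

What it does not emulate: genotyping/imputation error, allele-frequency
mismatch between data sets, population stratification, non-additive effects,
winner's-curse selection, and realistic genome-wide polygenicity outside the
simulated regions. Positions are laid out uniformly (1 kb spacing); allele
pairs are drawn uniformly from the ordered non-identical pairs, so
palindromic variants occur at their natural 1/3 rate.

An auxiliary Gaussian-copula individual-level generator (genotypes with a
target LD, phenotype from joint effects plus Gaussian noise) serves as the
oracle for validating summary-statistic conditional analysis.

## 3. Instrument selection (`coagmr.proxies`)

Filter cascade, in order, each step logged with in/out counts:

| parameter | default | rationale |
|---|---|---|
| cis region | gene body ± flank (bp) | cis instruments minimize pleiotropy |
| `p_threshold` | 5×10⁻⁸ | genome-wide significance |
| `maf_floor` | 0.01 | excludes frequency range with unstable β̂ |
| `liability_alpha` | 0.05 (disable switch) | requires nominal VTE support, the pathway-specificity filter |
| `clump_r2` | 0.001 | near-independence so IVW's diagonal-weight assumption holds |

Clumping is greedy: order by (p-value, position, variant id), keep the best,
discard everything with r² ≥ threshold against it, repeat. A variant missing
from the LD matrix is a hard error, not a silent skip.

## 4. Harmonization (`coagmr.harmonize`)

Outcome records are aligned to the exposure's effect allele: direct match,
allele swap (negating β), or strand complement for non-palindromic variants.
Palindromic variants (A/T, C/G) are excluded when MAF > 0.42 in either data
set (`maf_ambiguity`; frequencies closer to 0.5 cannot resolve strand), and
otherwise oriented by effect-allele-frequency concordance. Exclusion is a
value (`action = "excluded:<reason>"`), never an exception, preserving a
complete audit trail.

## 5. MR estimation (`coagmr.mr`)

- Wald ratio: θ̂ = β̂_out / β̂_exp, SE = SE_out / |β̂_exp| (first-order delta
  method; exposure-side uncertainty neglected as usual for strong
  instruments).
- IVW: no-intercept weighted least squares of β̂_out on β̂_exp with weights
  1/SE_out²; heterogeneity Q; multiplicative random effects
  φ = max(1, Q/(J−1)) inflating the SE by √φ. The max(1, ·) floor never
  shrinks below the fixed-effect SE, making the test conservative rather
  than anticonservative under homogeneity. J = 1 reduces exactly to the
  Wald ratio.
- MVMR: joint no-intercept WLS on K exposures, SEs from the weighted
  information matrix, φ = max(1, Q/(J−K)); a rank-deficient exposure matrix
  is an error naming the collinear pair.
- Liability scale: when the VTE GWAS itself provides the exposure, θ̂ is per
  unit VTE log-odds; multiplying θ̂ and SE by ln 2 re-expresses it per
  doubling of liability odds (`exposure_scale = "per_doubling_liability"`).
- Multiple testing: Bonferroni plans; 30 proteins → α = 0.05/30 ≈ 1.7×10⁻³
  (|z| > 3.14), a 46-proxy × 30-protein library → α = 0.05/1380 ≈ 3.6×10⁻⁵.

## 6. Regional inference (`coagmr.regional`)

- Wakefield log approximate Bayes factor:
  log ABF = ½·log(1−r) + r·z²/2 with r = W/(V+W), V = SE², prior effect SD
  √W = 0.15 (quantitative) or 0.20 (binary log-odds) — conventional values
  for GWAS effect sizes.
- Colocalization: enumeration over single-causal configurations with priors
  p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ (one causal variant per ~10 kb, shared at a
  tenth of that rate); hypothesis sums computed with log-sum-exp, the H3
  cross-term via a stable log1p(−exp(·)) identity. Posteriors sum to 1.
- Conditional analysis: z_cond,j = (zⱼ − r_j,idx·z_idx)/√(1−r_j,idx²);
  variants in perfect LD with the index are inestimable (NaN) and excluded
  from residual-significance tests.
- Fine-mapping: single-causal posterior inclusion probabilities
  PIPⱼ = ABFⱼ/Σₖ ABFₖ (uniform prior); 95% credible set = smallest
  descending-PIP prefix reaching 0.95 (ties broken by position).
- Signal counting: stepwise — take the min-p variant, stop when
  p ≥ 0.05/m (regional Bonferroni), else condition and repeat.

## 7. Cross-trait report and prioritization (`coagmr.report`)

The cross-trait library looks up every selected proxy in every protein GWAS;
the Bonferroni family counts only cells with an available measurement. The
z-comparison classifies each pQTL proxy by |z| against the family cutoff in
the VTE and stroke GWAS (both / vte_only / outcome_only / neither). The final
verdict per protein is the conjunction: MR p < 0.05/n_proteins **and**
colocalization PP(H4) ≥ 0.7 (`pp_min`); proteins without a colocalization
result are "incomplete", never prioritized.

## 8. Numerical and calibration choices

- p-values are clipped to [10⁻³²⁰, 1] to stay within double precision;
  written files use repr-exact float formatting and are re-read with
  round-trip float parsing, so fixtures are byte-stable across runs.
- Type-I calibration is checked by the Clopper–Pearson (exact binomial) 95%
  interval of the empirical rejection rate containing the nominal α; the
  multiplicative random-effects floor makes the IVW test mildly conservative,
  which this criterion accepts.
- Estimator correctness is established against independent oracles:
  unweighted closed forms, `numpy.linalg.lstsq` weighted regressions,
  numerical quadrature for the Wakefield ABF, exhaustive greedy restatement
  for clumping, and individual-level joint regression for conditional
  analysis.
- Monte-Carlo study sizes (500 replicates for recovery, 10⁴ for type-I
  error, 200 regional seeds, 50 end-to-end seeds) balance statistical
  resolution against a laptop-scale runtime (the full acceptance script runs
  in seconds).

## 9. Limitations

- Single-causal assumptions: the colocalization and fine-mapping models
  enumerate one causal variant per trait per region; allelic heterogeneity
  is only addressed through stepwise conditioning.
- The conjunction rule controls the family-wise error rate per screen, but
  over many repeated screens occasional false positives at the
  PP(H4) ≥ 0.7 boundary remain possible by construction.
- The delta-method Wald SE ignores exposure-side sampling error (NOME
  approximation); weak instruments would require different methods than
  those implemented here.
- Synthetic LD is block AR(1); conclusions about performance under realistic
  LD (long-range, admixture-related) are out of scope.
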