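# Methods

## Model and estimation

The association model for a trait vector Y over n individuals is

    Y = Wv + SNPᵢ + Zu + e,   u ~ N(0, K_g Vg),   e ~ N(0, I Ve).

W is the fixed-effect design — an intercept plus the top k principal
components of the column-centered dosage matrix (k = 3 by default, the
usual choice for weakly structured panels).  Z is the n × n′ incidence of
individuals onto compression groups and K_g the n′ × n′ group kinship, so
the phenotypic covariance is V = Z K_g Zᵀ Vg + I Ve.  When every group is a
singleton, Z = I and K_g = K: the model is the ordinary MLM, and all three
strategies coincide (this equivalence is asserted bitwise in the tests).

Variance components are estimated by REML.  Writing λ = Vg/Ve and
eigen-decomposing G = Z K_g Zᵀ = U S Uᵀ once per fit, rotation by Uᵀ makes
V diagonal up to the scale Ve, so the restricted likelihood is a
one-dimensional function of λ with Ve profiled in closed form.  λ is
minimised over a 100-point log-spaced grid on [1e−5, 1e5] followed by
bounded scalar refinement (tolerance 1e−8) between the bracketing grid
points.  `neg2_restricted_loglik` evaluates the same objective by the dense
textbook formula

    (n−p)·log 2π + log|V| + log|WᵀV⁻¹W| − log|WᵀW| + yᵀPy,

and the two routes are required to agree to 1e−8 in the tests.  G's
eigenvalues below −1e−8 raise an error (non-PSD compressed covariance);
small negative round-off is clipped to zero.

## Marker tests

Scanning uses P3D by default: the null-model λ is fixed for every marker,
the marker column joins the fixed effects, and the test is a GLS F-test
with one numerator degree of freedom.  The residual *scale* is re-profiled
per marker from that marker's own weighted residual sum of squares with
n − p − 1 degrees of freedom.  This convention makes the statistic collapse
exactly to the ordinary least-squares F-test when Vg = 0, which the tests
assert; it also means the `full` mode (re-optimising λ per marker) differs
only through λ.  Markers collinear with W — including zero-variance
columns — are reported with missing p and counted, detected through the
final Cholesky pivot of the augmented normal equations (relative threshold
1e−10).  Samples missing the analysed trait are dropped listwise before
fitting.

## Compression

Group kinship summarises the individual kinship over label blocks
(operators mean/median/max/min; mean by default, the convention of the
compressed-model literature).  Diagonal blocks include the self-kinship
terms.  The CMLM search clusters individuals hierarchically on the
distance d = max(K) − K (a monotone kinship→distance conversion; the model
only needs relative closeness) with average linkage by default, cuts the
dendrogram at each gridded group count (a roughly geometric grid
{1, 2, 3, 5, 7, 10, …, n}), fits the null model for every combination, and
keeps the minimum −2LL.

Two −2LL values closer than 3.84 — the 5% χ²₁ quantile, i.e. a likelihood
gap that would not be significant even if compression level were a single
free parameter — are treated as equivalent, and equivalence resolves toward
*less* compression.  This is deliberate: on unstructured data the −2LL
profile across compression levels is flat apart from noise-level dips of
order one unit, and without an equivalence band the search would pick an
arbitrary intermediate grouping that the likelihood cannot actually
distinguish from no compression.  With the band, a flat profile collapses
the search to singleton groups (plain MLM) — the documented failure mode
that motivates supplying groups externally — while any grouping that
genuinely improves the restricted likelihood is still selected.

pCMLM bypasses the search: a `sample_id<TAB>group` file (the compress_z
vector; equal labels = one group) is validated against the analysis
samples — labels for absent samples are dropped with a warning, unlabelled
analysis samples are an error — and used as-is.  Principal components are
computed once and shared across strategies.

## Quality control and supporting statistics

Markers are retained when MAF ≥ 0.05, missing rate ≤ 0.05 and the
two-sided Hardy–Weinberg exact p ≥ 1e−6, all recomputed from the current
codes; the exact test enumerates the conditional heterozygote distribution
in log space with no mid-p correction, and is verified against exact
rational-arithmetic enumeration for all counts up to n = 30.  Genotypes are
coded as ALT-allele dosage (stable under subsetting; MAF is computed
separately), missing calls are mean-imputed per marker before kinship and
PCA, and kinship is VanRaden method 1, K = M Mᵀ / Σ 2p̂(1−p̂).  Bonferroni
significance is strict: p < α/m.  λ_GC is the median χ²₁ implied by the
observed p-values over the null median.  LD is the composite r² of unphased
dosages over pairwise-complete samples; decay curves bin intra-chromosomal
pairs into half-open [lo, hi) distance windows.  Candidate-gene lookup
intersects closed 1-based intervals ±20 kb around a lead SNP (the
characteristic LD-decay scale of the target genome) and widens to ±100 kb
when the primary window is empty.

## The simulator

`simulate_structured_genotypes` draws Balding–Nichols genotypes: ancestral
frequency uniform on [0.05, 0.5], per-population frequencies from
Beta(p(1−F)/F, (1−p)(1−F)/F), dosages binomial(2, p_pop), positions uniform
over 5 chromosomes.  Defaults emulate the study panel this package targets:
94 individuals in 7 populations of sizes 51/12/12/6/6/3/4, weak
differentiation (F = 0.05 by default; the structured experiments use 0.1),
and 31 breeds nested within the populations (17/4/4/2/2/1/1 per region).
`simulate_phenotype` adds an additive QTL term, a polygenic term drawn from
N(0, K) with K the *realized* kinship of the simulated markers (so
parameter-recovery tests are self-consistent), and Gaussian noise; each
realized component is rescaled to hit its target variance fraction exactly
in-sample, total variance 1.  `breed_mean_mode` replaces each value by its
breed mean — breed, not population: because breeds are finer than the
compression groups, breed-mean traits still vary within groups, which is
the regime in which a provided grouping is informative rather than
perfectly confounded with the trait.

What the simulator does not emulate: linkage disequilibrium between
markers (markers are exchangeable given structure), admixed individuals,
genotyping-error patterns, and selection.  Calibration and power results
on it therefore speak to the statistical machinery — structure correction,
variance-component estimation, test calibration — not to LD-driven
fine-mapping resolution on real data.

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately modest problem
sizes chosen to exercise every code path with stable statistics: dense
oracle comparisons at n = 12; null calibration at n = 300 with 5,000
markers; heritability recovery (true h² = 0.5) averaged over 20 seeds at
n = 400; FST recovery at 5 populations × 100 with 5,000 markers; and the
MLM-vs-pCMLM power comparison over 50 study-scale replicates (94 samples,
1,000 markers, one QTL at 20% of variance, polygenic h² = 0.3, breed-mean
phenotypes).  At those study conditions absolute power at the Bonferroni
level is low for every strategy — breed averaging removes most
within-breed QTL signal at n = 94 — so the meaningful comparison, and the
one asserted, is relative: the provided grouping costs nothing against
MLM (equal power and type-I within binomial error), while its −2LL differs
from the likelihood-searched CMLM fit by a few percent of their mean.

All randomness flows through `numpy.random.default_rng` seeds carried in
the configuration objects; re-running any generator with the same seed
reproduces its output bit for bit.

## Known limitations

- Exact breed-mean phenotypes with compression groups *equal* to the breed
  level are degenerate: the group effect can absorb the trait entirely and
  every marker p-value approaches 1.  The package does not guard against
  supplying a grouping identical to the phenotype-averaging level; the
  simulator avoids it by nesting breeds strictly inside populations.
- P3D standard errors ignore uncertainty in the variance components, as is
  standard.
- The hierarchical clustering follows SciPy's deterministic agglomeration
  order; exact tie handling among merge candidates is SciPy's.
- `full`-mode scans re-run the λ grid per marker and are intended for
  small marker panels, not genome scale.
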