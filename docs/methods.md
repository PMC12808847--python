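# Methods

## Analysis unit and preprocessing

The unit of analysis is a cohort: one cancer-type dataset whose mutation
matrix, omics layers and clinical table share a single ordered sample
list. Mutation status is gene-level and binary — any qualifying variant in
a gene makes the sample mutant for that gene; samples present in the omics
or clinical data but absent from the MAF are wild-type, matching standard
MAF semantics. The default variant filter keeps the non-silent classes
(missense, nonsense, frameshift, in-frame indel, splice site, start/stop
disruption); whether silent variants should count is exposed as
configuration rather than decided silently, since conventions differ
between consortia.

Mutations are retained when their within-cohort frequency is at least 5%
(`filter_mutations_by_frequency`, inclusive by default with a strict `>`
switch). Layers are Z-score normalized per feature — site-level for
phosphosites, gene-level for RNA and protein — using the sample standard
deviation (ddof = 1, the convention fixed package-wide for
reproducibility). Features with zero spread or fewer than two observed
values are set to zero and reported, not dropped, so layer shapes stay
stable. Missing values are handled by complete-case deletion per feature;
no imputation is performed.

## Group statistics

Each metric rests on a mutant-vs-WT comparison per feature: a pooled
two-sample Student's *t*-test (Welch available behind a flag), requiring at
least two observed values per group; features failing that rule carry
missing statistics and are excluded from the multiple-testing family. The
Benjamini–Hochberg family is exactly the testable features of one
mutation × one layer comparison — FDR is never pooled across layers or
mutations. The per-feature summary is the SignedFDR,
sign(Δz̄)·(−log10 FDR), with FDR floored at 1e−300 so scores stay finite;
a zero mean difference or FDR of 1 gives exactly 0. When a feature has
zero pooled spread the test degenerates: p = 1 for equal means, p = 0
(flagged) otherwise.

Survival uses the standard two-group log-rank test, implemented on
explicit risk tables because the direction statistic — observed minus
expected events in the mutant group — is part of the contract
(`worse_in_mutant`); the implementation is cross-checked against lifelines
in the test suite. Pairwise mutation co-occurrence uses two-sided Fisher's
exact tests with BH across pairs and Haldane–Anscombe-corrected odds
ratios; the co-occurring / mutually-exclusive labels use FDR < 0.05.

## ssGSEA

Pathway activity per sample is scored by single-sample gene-set
enrichment: features ranked by value descending (missing values excluded
from that sample's ranking; ties broken by feature id for determinism),
enrichment = Σ over rank positions of (weighted in-set ECDF − uniform
out-of-set ECDF), with in-set weights rank^α normalized to sum 1.
Defaults α = 0.25 and global max−min range normalization follow the
conventional single-sample GSEA settings. A set covering every ranked
feature has a vacuous complement; its score is defined as 0, the unique
symmetric choice. Because the score is rank-based it is invariant to any
strictly increasing per-sample transform, which the tests exploit.
Immune-deconvolution outputs (xCell / CIBERSORT / ESTIMATE style) are
accepted as precomputed matrices; a linear signature-weight scorer
(Σ weight × z over shared genes, missing → 0) covers coefficient-based
pathway tools. Neither deconvolution algorithm is re-implemented.

## The five metrics

* **PB** — log-rank per available endpoint (OS, DSS, DFS, PFS, RFS). The
  *flag* is directional: some endpoint with p < 0.05 and poorer outcome in
  mutants. The *score* feeding downstream comparison is −log10 of the
  minimum endpoint p, direction-agnostic: a strongly protective mutation
  is still a strong prognostic signal, and the sign requirement lives in
  the flag.
* **EP / IM / PE** — the fraction of testable terms with
  SignedFDR ≥ 1.301, computed over the RNA layer (EP; protein reported
  alongside, never silently substituted), the immune layer (IM) and each
  pathway layer (PE; per-layer values plus their mean as the combined
  score).
* **AD** — over the testable signed scores of the mutation's own phospho
  comparison, sites strictly above the upper box-plot fence
  Q3 + 1.5·IQR (linear-interpolation quantiles) are upper outliers; the
  score is their fraction. The fence operates on the comparison's own
  signed distribution, which reproduces the intended picture of one site
  towering over the rest; requiring outliers to also pass the 1.301
  cutoff is available as an optional extra filter. Outlier sites are
  annotated with the parent gene's RNA/protein SignedFDR when those
  layers cover it, missing otherwise.

A metric whose layer is absent is missing, never zero — zero means
"tested and null", absence means "not measurable", and the two are kept
distinct throughout.

## Pan-cancer rank points

Per metric, cohorts with a non-missing value are ranked descending (ties
broken by cohort name for determinism) and awarded 5,5,4,4,3,3,3,3,2,2,1,1
points for the canonical 12 cohorts; other counts generalize the same
proportions (1/6, 1/6, 1/3, 1/6, 1/6) with block boundaries by rounding
cumulative fractions. A cohort whose metric family contains no
significant term — no feature at SignedFDR ≥ 1.301, or for PB no
directional log-rank hit — is overridden to 1. Both raw values and points
are emitted, since either may feed a radar plot.

## AOS and driver grading

Within a cohort (≥3 mutations), each metric is Z-normalized across
mutations (ddof = 1; zero spread → all zeros, flagged) and the AOS is the
mean of the available normalized metrics — missing metrics are excluded
from the mean rather than imputed as zero, so cohorts lacking a layer are
not penalized. Outlier tests run on the cohort's AOS distribution
(≥4 values): the IQR fence (strict inequality) and |Z| > 2.5, a threshold
stricter than ±2 SD (~95% of a normal distribution) that captures roughly
the top 1%. The two-sided |Z| rule is implemented as stated, which lets a
strongly negative AOS carry a one-test grade; `z_mode="upper"` restricts
to the upper tail for the reading consistent with upper-outlier driver
dots. Grades: both tests + known driver → 1; both + novel → 2A; one +
known → 2B; one + novel → 3; neither → none.

## Synthetic cohorts

The generator emulates exactly the structure the statistics assume:
Gaussian i.i.d. baselines per layer with additive mean shifts planted in
mutant samples (heavier-tailed options deferred); deterministic mutant
counts round(frequency·n) so frequency-filter tests are exact;
exponential survival with per-sample hazard baseline·ΠHRᵍ over mutated
genes and uniform censoring on (0, horizon]; immune signature scores
generated directly with planted shifts; pathway activity derived by the
package's own ssGSEA over simulated gene sets, one of which contains each
mutation's upregulated genes so pathway scores respond to planted
expression effects. Each data component draws from its own RNG stream
derived from the master seed, so enabling a layer never perturbs another
and the full fixture is byte-deterministic. MCAR missingness is available
as a configured cell fraction.

The standard planted-driver study (`driver_fixture_config`) uses 200
samples, 1000 genes, 500 phosphosites, 10 mutations at frequency 0.2; the
driver carries δ = 1.5 on 5% of genes (RNA and protein), hazard ratio 3,
+5 shifts on 1% of phosphosites, and a shift of 1.0 on a quarter of the
20 immune signatures — the immune effect size is the package's own
choice of a clearly detectable but not dominant perturbation, keeping the
driver elevated on all five metrics. Test-suite variants scale the same
design down (e.g. 80–120 samples, 200–400 genes) to keep the default run
fast; the full 10-cohort × 20-seed recovery check runs at the standard
sizes.

What passing these tests shows — and does not. The generator matches the
t-test/Z-difference machinery by construction: real data have correlated
features, batch effects, non-Gaussian tails and informative missingness,
none of which are modelled, so the recovery rates measured here are
upper bounds on real-data behavior, and the FDR-control results confirm
internal consistency, not robustness to model violation.

## Numerical choices

Quantiles use linear interpolation between order statistics throughout
(fence computations, AOS outliers). Sample SD uses ddof = 1 everywhere.
Ranking ties in ssGSEA break by feature id; rank ties in point allocation
break by cohort name. FDR floor 1e−300 before −log10. Log-rank variance
terms with a single subject at risk are skipped; zero variance with equal
observed/expected events yields chi² = 0, p = 1. Degenerate Z-score
features are zeroed and flagged.

## Known limitations

Two-level inference on pre-normalization data is not implemented. Immune
deconvolution and purity tools are consumed as precomputed score
matrices, not re-implemented. No Cox regression or multivariate survival
adjustment (log-rank only). No imputation. The co-occurrence test
(Fisher/BH) is this package's choice of method for an output whose
procedure is otherwise unspecified. Driver evidence from mutation
recurrence or functional domains is out of scope; grading reflects
downstream molecular consequences only.
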