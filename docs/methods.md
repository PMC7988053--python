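# Methods

## The analysis chain

`methylstage` models a staged disease-progression methylation study: a
parental castration-sensitive line (LN), a castration-resistant
derivative (CRPC), and enzalutamide-resistant derivatives of both
adenocarcinoma (ADENO) and treatment-induced neuroendocrine (NE1/NE2)
phenotype, each profiled in triplicate on a CpG probe array. The chain
is: probe filtering → per-comparison DMP calling → set algebra across
comparisons → genomic annotation → gene-level scoring → differential
expression and scenario classification → cfDNA biomarker. Each stage is
a pure function over typed tables (pandas DataFrames with fixed column
orders), so stages can be used independently of the orchestrator.

## Differential methylation model

Beta values β = M/(U+M+100) are tested directly on the beta scale so
that the effect-size threshold (|Δβ| ≥ 0.2 by default) is interpretable
as a methylation-fraction change. For a case/reference contrast with
n₁, n₂ replicates the per-probe statistic is a moderated t:

* pooled per-probe variance s²_g with d = n₁+n₂−2 residual df;
* a scaled-F prior fitted across probes by method of moments on log s²
  (prior df d₀ from the inverse-trigamma of the excess variance of
  log s², prior variance s₀² from its mean) — the same estimator limma
  uses, and the test suite pins agreement with R limma to ~1e-8;
* posterior variance (d₀s₀² + d·s²_g)/(d₀+d), t with d+d₀ df
  (standard normal when d₀ is infinite);
* two-sided p, Benjamini–Hochberg q across all tested probes, and a DMP
  call when q < fdr_cut AND |Δβ| ≥ delta_cut.

With three replicates per group the raw per-probe variance has only
4 df; shrinkage is what makes the caller usable at that replication.
Zero-variance probes receive the prior variance through the posterior
(never NaN); when the prior df is forced to 0 the statistic reduces
exactly to the ordinary pooled t (a tested limit). A Welch t backend is
available for unequal-variance settings. Beta-scale testing (rather
than M-values) is this package's recorded choice; logit-scale noise in
real arrays makes mid-range probes the noisiest, which the moderated
prior absorbs.

Filtering removes probes flagged snp / cross_reactive / multi_hit and,
when a detection-p table is supplied, probes failing in any sample
(strict rule; a failing-fraction alternative is exposed). Normalisation
is an identity hook: probe-type bias correction belongs upstream and
synthetic data carry none.

## Comparison sets and gene scores

A probe is "common" to several comparisons only if it passed the
calling thresholds in each one — no p-value pooling — optionally with
the same direction everywhere. Direction-switch tables cross-tabulate
the directions of probes shared by two comparisons; the transposition
and marginal-sum identities are property-tested.

Gene summaries count unique probes per (gene, comparison) by region ×
direction; probes annotated to several genes count once per gene in
summaries but once in total in region-composition tables. The net
methylation score is log2((n_hyper+0.5)/(n_hypo+0.5)) over all DMPs in
or near a gene with at least `min_dmps` (default 6, i.e. "more than 5")
DMPs; the pseudocount keeps genes with a zero denominator finite, and
the hyper/hypo class label is decided on raw counts so it is exact.

## Expression and scenarios

Differential expression uses a per-gene 2×2 chi-squared test of gene
counts vs rest-of-library counts, case vs reference, replicates pooled
per group and expectations proportional to library size (BH FDR 0.05;
log2 fold change from group-mean CPM with a 0.5 pseudocount). This
count-based test assumes Poisson-like dispersion, appropriate for
technical-replicate cell-line libraries; a Welch t on log-CPM is the
backend for overdispersed data. Scenario classification then requires,
per differentially expressed gene, the stated promoter/body methylation
pattern with zero called DMPs of the same direction in the opposite
region: a = down + TSS-hyper, b = up + body-hyper, c = down +
body-hypo, d = up + TSS-hypo. a/b and c/d are mutually exclusive by
expression direction; a/c and b/d may co-occur and both letters are
reported.

## cfDNA biomarker

Two overlap granularities share one interval engine (0-based half-open
intervals; probe at 1-based position p hits [s,e) iff s ≤ p−1 < e):

* **ratio statistic** (DMR-level): a patient DMR is a hit if it
  contains ≥ 1 query DMP, counted once, tallied by the DMR's direction;
  the statistic is (n_hyper_hit+0.5)/(n_hypo_hit+0.5) (a strict mode
  drops zero-denominator patients instead). Spearman correlation with
  time to progression uses average ranks and the t approximation.
* **resampling null** (probe-level): p̂ = fraction of the k unique
  query probes inside any patient DMR; the null redraws k probes
  uniformly without replacement from the filtered manifest n_iter times
  (default 10,000) and p₀ is the mean in-DMR fraction. Because the
  in-DMR status of every manifest probe is precomputed, the in-DMR
  count of such a draw is exactly hypergeometric, and the implementation
  samples that distribution directly — an exact, vectorised form of the
  same resample. The one-proportion z-test
  z = (p̂−p₀)/√(p₀(1−p₀)/k) is reported two-sided; per-patient p values
  are unadjusted (a BH column is emitted alongside for transparency).

The interval engine itself is sorted-array binary search
(numpy.searchsorted over merged intervals), chosen over an interval
tree because the Monte-Carlo tests run thousands of queries; its
correctness is pinned to an O(n·m) brute-force oracle on hundreds of
random instances.

## Synthetic data: what it emulates, and what it does not

The generator provides the study conditions every test runs under.

* **Manifest** — three ~10 Mb chromosomes; genes laid left to right
  with occasional near-adjacent pairs so multi-gene probes exist;
  feature windows TSS (1500 bp upstream), 5'UTR, 1stExon, Body, 3'UTR;
  CpG islands at ~60% of TSSs plus random intergenic islands, with
  shores ±2 kb and shelves ±2–4 kb; ~3% of probes flagged
  snp/cross_reactive/multi_hit; per-gene probe counts skewed so roughly
  half of genes carry only 1–2 probes; default 50,000 probes /
  2,000 genes.
* **Beta values** — baselines drawn from context-dependent Beta
  distributions (islands low, open sea high, giving the familiar
  bimodal marginal); replicate noise N(0, 0.15) on the logit scale
  (beta-scale sd ≈ 0.02–0.04 at mid-range, matching replicate
  variability of cell-line arrays) mapped back through the logistic and
  clipped to [1e-6, 1−1e-6]. Planted effects are ±δ (default 0.3) on
  the beta scale, applied to the plant's case group; hyper shifts are
  planted only on probes with baseline ≤ 1−δ−0.05 and hypo shifts only
  on baselines ≥ δ+0.05, so a planted difference is never flattened
  against the [0,1] boundary. The recorded truth for every comparison
  is derived from the full probe-by-group shift matrix, so comparisons
  sharing a shifted group agree with what the data contain.
* **Expression** — near-Poisson negative-binomial counts
  (size 800) around log-normal gene means; scenario genes are drawn
  from genes whose already-planted DMPs realise the scenario's
  methylation pattern and are shifted 4-fold in the comparison's case
  group. The large size parameter reflects the chi-squared DE test's
  Poisson assumption: the generator emulates technical, not biological,
  dispersion.
* **Cohort** — per patient, an equal number of hyper- and
  hypomethylated DMRs (200–2000 total, widths 100–2000 bp); a fraction
  f (default graded 0→0.5 across patients) of the hypermethylated DMRs
  is seeded to contain a planted neuroendocrine-hyper DMP. Time to
  progression is TTP = 365 d × (expected ratio)^−1 × exp(0.25·ε), where
  the expected ratio is the deterministic function of f and the
  analytic background hit rate. Coupling TTP to the *expected* rather
  than the realised ratio is deliberate: with f = 0 the expected ratio
  is identical for all patients (balanced DMR directions), so TTP is
  exactly independent of the measured overlap and the biomarker's null
  size can be measured honestly; with noise 0, TTP is exactly monotone
  in the expected ratio (a tested identity). Tying TTP to the realised
  ratio instead would leak background Poisson noise into both variables
  and make even a signal-free cohort appear correlated. No censoring is
  modelled (the correlation is rank-based on observed TTP).

What passing these tests shows: the caller controls its error rates and
recovers effects of the planted size under the planted noise; the
downstream algebra, scores and biomarker recover planted structure
exactly or within stated Monte-Carlo bounds. What it does not show:
robustness to probe-type intensity bias, batch effects, biological
dispersion in expression, cell-type admixture in cfDNA, or censored
outcomes — none of which the generator emulates.

## Numerical choices and degenerate inputs

* BH adjustment delegates to statsmodels (`fdr_bh`); a four-value
  worked example is asserted exactly.
* Moderated-t prior: excess log-variance ≤ 0 → infinite prior df
  (common variance, normal reference); fewer than two positive sample
  variances → no moderation. Inverse trigamma by Newton iteration.
* Heatmap ranking ties: min q, then max |Δβ|, then probe id — output
  order is deterministic. DMP/DEG tables are sorted by (q, id).
* Degenerate probes (zero variance and zero Δβ) are reported
  non-significant, not NaN; all-zero genes are skipped and logged.
* Ratio statistic with pseudocount 0 and a zero denominator raises;
  the default pseudocount 0.5 maps an uninformative (0,0) patient to
  the neutral ratio 1.
* z-test with p₀ ∈ {0,1}: z is 0 when p̂ = p₀ and signed infinity
  otherwise (p value 1 or 0 respectively).
* All generator randomness flows from one root seed split per stage via
  CRC32-tagged `numpy.random.SeedSequence` children (< 2³¹), so runs
  are reproducible byte-for-byte across processes.

## Problem sizes used by the test and acceptance runs

The acceptance surface regenerates a 50,000-probe / 2,000-gene
manifest, the five-group triplicate design with 2,000 planted probes
per comparison, a 20-patient cohort, 100 replicate cohorts for the
power Monte Carlo (400 for the null-size estimate, where a ~5%
proportion needs the extra resolution), and 1,000 random query sets at
1,000 resampling iterations for calibration; unit tests use an
8,000-probe study. These sizes give every Monte-Carlo bound at least a
3-standard-error margin while keeping a full run in tens of seconds.

## Known limitations

* DMP calling is two-group only; no covariates, paired designs or
  continuous phenotypes.
* The chi-squared DE test is anticonservative under real biological
  overdispersion — use the Welch backend or an external DE tool for
  patient-derived libraries.
* Gene-set enrichment is a plain hypergeometric over user-supplied
  sets; it does not correct for per-gene probe-count bias (a weight
  hook is exposed, unused by default).
* The cfDNA stage consumes DMRs as given; calling DMRs from sequencing
  is out of scope, as are survival models beyond rank correlation.
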