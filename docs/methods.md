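# Methods

## The analysis

`dynsig` models treatment-induced transcriptional dynamics in matched
pre/post-treatment tumor pairs. Throughout, expression is log2-scale and
the per-tumor fold change is FC[g, t] = post[g, t] − pre[g, t], so 1.0
means a 2-fold change.

**Responsive genes and modules.** A gene is treatment-responsive when its
mean over tumors of |FC| is at least `fc_threshold` (default 1.0,
inclusive). The mean-of-absolute summary is deliberate: a gene moving +1
in some tumors and −1 in others is highly responsive even though its
signed mean is zero, and that bidirectional pattern is exactly the
phenomenon of interest; a signed-mean summary is available
(`fc_summary="signed_mean"`). Responsive genes are projected onto a
gene–gene interaction network; each surviving edge is weighted by the
expression correlation of its endpoints (Pearson by default, over pooled
pre+post samples; Spearman and pre-/post-only selectable). Edges below
`edge_weight_floor` (default 0) are removed — modularity on negative
weights is ill-defined, so anti-correlated pairs never count as
co-expression evidence. The weighted graph is partitioned by greedy
(CNM) modularity maximization; nodes are relabelled in sorted order
first, so tie-breaking — and therefore the whole pipeline — is
deterministic. Modules are annotated with the mean correlation over *all*
unordered member pairs (not only network-adjacent pairs) and kept when
they have ≥ `min_module_size` (10) genes and mean correlation strictly
above `min_avg_corr` (0.5).

The partitioner runs at modularity resolution 0.5 by default. At
resolution 1, greedy modularity splits even a single dense 40-node block
along random edge-density fluctuations, which is the wrong behaviour for
this application: a treatment-responsive module is a dense coherent
subgraph, and carving it into arbitrary halves destroys the downstream
signature. At resolution 0.5 dense blocks stay whole while disconnected
structures still separate (merging disconnected communities lowers
modularity at any positive resolution), so on graphs whose components are
uniform cliques the output is exactly the components. The resolution is a
`DiscoveryParams` field for users who want finer partitions.

**Module change profile.** A tumor's change score is the mean FC over
module genes; its sign classifies the tumor as up-/down-regulating the
module (zero is flagged explicitly). The accompanying Spearman check
correlates per-tumor mean *pre-treatment* module expression with the
change score: under the biology modelled here, baseline proliferation
does not determine the direction of the treatment response, so this
correlation should be null.

**Response Signature.** Tumors are ranked by change score; the
`k_extreme` (6) highest and lowest form the up- and down-groups. Per
gene, a Welch t statistic on pre-treatment expression (up minus down)
ranks genes; the `n_genes` (10) of largest |t| form the signature, each
weighted sign(t) (+1 = higher at baseline in up-regulating tumors). A
plain mean-difference statistic is selectable; ties at the cutoff resolve
by gene identifier, making derivation invariant to tumor and gene input
order. Scoring z-scores each signature gene across the cohort's samples
(so scores are invariant to per-gene affine rescaling, i.e. robust to
platform scale), then averages direction-weighted z-scores with the +1
weights negated, fixing the orientation contract used by every downstream
evaluation: **higher score ⇒ predicted module down-regulation ⇒ predicted
resistance**. Cohort-internal standardization is assumed; scores are not
comparable across cohorts without it.

**Nearest shrunken centroids.** For gene g and class k with class sizes
n_k, m_k = √(1/n_k − 1/n), pooled within-class SD s_g and fudge constant
s0 = median(s_g) (the method's customary choice), the standardized
difference d_gk = (x̄_gk − x̄_g)/(m_k (s_g + s0)) is soft-thresholded at Δ
and centroids rebuilt as x̄_g + m_k (s_g + s0) d′_gk. Classification
minimizes Σ_g (x_g − x̄′_gk)²/(s_g + s0)² − 2 log π_k with empirical
priors (uniform selectable); the two-class signature score is
δ(negative) − δ(positive), higher = more positive-class-like (mutant,
under the pipeline's labels). Δ is chosen by stratified, seeded 10-fold
cross-validation over an even grid from 0 to max|d_gk|: by default the
largest Δ whose CV misclassification is within one standard error of the
minimum (the sparsest competitive model — appropriate when the goal is a
small probe signature), with plain minimum-error selection available.
Zero-gene models (pure prior classifiers) are excluded from selection:
when CV error curves are flat — typical at very small training sizes —
the one-SE rule would otherwise collapse to the degenerate model even
though the continuous signature score still validates well.

**Evaluation.** AUC is computed by midrank pair-counting, identical to
the Mann–Whitney statistic. Significance against AUC = 0.5 uses exact
enumeration of the U distribution when n_pos·n_neg ≤ 400 and scores are
tie-free, otherwise the tie-corrected normal approximation; the 95% CI
uses the DeLong placement-variance estimator. (With 6 vs 6 and complete
separation the exact two-sided p is 2/C(12,6) ≈ 0.0022; published ROC
software sometimes prints other values for this case, so p-values are
method-dependent and no cross-software equality should be expected.)
Welch t-tests use Satterthwaite degrees of freedom, with zero-variance
degeneracies handled explicitly. Spearman correlation uses midranks with
the t-approximation p. Logistic models are maximum-likelihood (Newton
IRLS via statsmodels) with Wald intervals on the OR scale; perfect
separation is flagged as non-converged rather than reported as huge
coefficients, and singular designs raise naming the collinear terms.
Continuous scores enter regressions standardized to unit SD, so odds
ratios have declared per-SD units. All tests are two-sided.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: a 26-tumor
paired cohort, of which round(frac_up·n) = 8 tumors up-regulate one
planted 40-gene module after treatment and 18 down-regulate it.

* **Within-module correlation** comes from one shared latent factor per
  tumor: x_g = √ρ·f + √(1−ρ)·ε_g with unit-variance f, ε, giving expected
  pairwise correlation exactly ρ (default 0.7).
* **Treatment effect**: post = pre + s_t·module_effect on module genes
  (s_t = ±1 by direction class, default effect 1.5) plus N(0, noise_sd²)
  noise everywhere (default 0.5).
* **Response label** = 1 for up-class tumors, flipped with probability
  0.1 — the clinical label is an imperfect proxy of the transcriptional
  class. The flip probability imposes a ceiling on any classifier's
  response-label AUC (≈ 0.88 at these class proportions); evaluations
  against the direction class itself are ceiling-free.
* **RS-informative genes**: 10 genes (disjoint from the module) shifted
  between direction classes by rs_effect in both pre and post, so they
  carry baseline, not fold-change, information. Default rs_effect = 3.0
  (log2 units at unit residual SD), set by a power analysis of the
  derivation procedure: a 6-vs-6 Welch-t screen over 2000 genes only
  ranks planted genes above the null extreme order statistics (max |t| ≈
  4.6 across ~2000 genes at ~10 df) when their expected t ≈ 3/√(1/3) ≈ 5
  exceeds that extreme — the regime the analysis itself assumes, since
  the discriminating genes of a real cohort are the genome's most
  extreme.
* **Network**: the module is wired as a ring plus second-neighbour chords
  (connected, minimum degree 4) plus ER(0.3) within-module edges;
  the background is Erdős–Rényi with mean degree 3 over all 2000 genes.
* **p53 cohort**: single-timepoint Gaussian cohort, ~30% mutant class,
  exactly 18 informative probes shifted by 1.0 (mutant higher), all other
  probes null.
* **Covariates**: age and node status independent of response; ER
  positivity depleted and high grade enriched among responders, scaled by
  `covariate_assoc` (0 = fully independent) — the directions reported for
  neoadjuvant breast cohorts.

All randomness flows through numpy's PCG64 generator seeded from
`SimulationConfig.seed` (independent child streams per stage), so every
output is bit-reproducible across platforms; the algorithm name is
recorded in the config for provenance.

What the generator does **not** emulate: microarray probe saturation,
batch and platform effects, correlated null genes, non-Gaussian noise,
missing clinical annotations, or survival times. Passing tests therefore
demonstrate that the estimators and the pipeline logic are correct under
the declared statistical structure — not that the biological findings
replicate on any particular external cohort.

## Numerical and design choices

* Duplicate probe rows collapse to the highest-mean row (stable,
  identifier-ordered tie-break); cells missing in ≤ 50% of samples are
  imputed with the per-gene mean (logged), genes beyond that are dropped.
* Input is assumed log2; `log2_transform` applies log2(x+1) to
  linear-scale matrices.
* Signature files are GMT-like with one record per direction *run*, so
  interleaved gene order (the ranking) survives a write/read round-trip.
* Fold assignments, seeds and parameter echoes are written into every
  run manifest together with sha256 hashes of all artifacts; re-running
  with the same inputs and seed reproduces the hashes byte-for-byte
  (fixed float formatting, sorted JSON keys, no timestamps in hashed
  artifacts).
* Degenerate inputs are errors, not silent NaNs: constant vectors in
  correlation, one-class ROC labels, constant scores in standardization,
  classes below 2 samples in centroid fits, folds that lose a class.
* Problem sizes used by the test suite and acceptance script (26-tumor
  discovery cohorts, 100-tumor validation cohorts, 251-sample p53 cohorts
  with a 34/217 split, 20-seed recovery batches, 100-run null
  calibrations, 500-run CI coverage) are chosen to make the Monte-Carlo
  assertions stable while keeping a full run inside a few minutes on one
  CPU.

## Known limitations

* Greedy modularity is one of many defensible partitioners; the
  pipeline's contract is planted-structure recovery, and the resolution
  knob (plus the disjoint-partition invariant) is the supported way to
  swap behaviour. Very small or very sparse graphs degrade to
  singletons, which the size filter then removes.
* The Welch-t gene screen is unmoderated; at 6-vs-6 a near-constant null
  gene occasionally produces an extreme t and displaces a true signature
  gene. Variance-moderated screens would stabilise this but change the
  derivation contract.
* The one-SE rule is sensible only when CV error curves are informative;
  at very small training sizes the returned model can be much sparser or
  denser than the "true" probe set even though its continuous score
  validates well. The selected-probe count is therefore not a stable
  statistic at n ≈ 34.
* Logistic Wald intervals undercover under separation or tiny cell
  counts; separation is flagged, but profile-likelihood intervals are not
  implemented.
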