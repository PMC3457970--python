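# Methods

This note records the statistical procedures `metkinsig` implements, the
conventions it fixes where several were defensible, what the synthetic
generators do and do not emulate, and the package's known limitations.

## Kinetic response testing

For each gene and each post-baseline time point *t*, the response
statistic is the set of log-ratios
`expr(cell line, replicate, t) − baseline(cell line)` pooled over all
cell lines and replicates, tested against zero with a two-sided
one-sample t-test.

* **Baseline convention.** The baseline is the cell line's *mean* time-0
  value across its replicate arrays, not the same replicate's single
  baseline. Averaging the replicate baselines halves the reference's
  noise contribution and is the standard choice when the contrast of
  interest is "treatment effect within cell line". With the default
  replication (6 lines × 2 replicates) this raises per-gene detection
  power from ≈0.86 to ≈0.98 at effect 1.0 / noise sd 0.25 (noncentral-t
  calculation), which is what makes near-complete recovery of a planted
  signature possible at all.
* **Degenerate cases.** Fewer than two ratios, or zero variance across
  ratios, yields an undefined (NaN) p-value, flagged — never a silent 1.
* **Multiplicity.** Benjamini-Hochberg within each time point across
  genes (each time point is its own contrast family; joint correction
  across the three time points would be more conservative and couple the
  families). The default significance threshold is q ≤ 1e-4.
* **Initial response.** The earliest post-baseline time with q ≤ α;
  its direction is the sign of the mean log-ratio there. Genes whose
  earliest detection is late (noise at 10 min) are assigned to the later
  group — a deliberate, simple operationalization.

## Six-group partition and signature selection

With the default grid (0/10/30/1440 min) there are exactly
2 × 3 = 6 (direction, time) groups; every responder belongs to exactly
one; groups may be empty. Each non-empty group is evaluated by clustering
*all* samples on the group's genes (see below) and Fisher-exact testing
the two-cluster split against the high/low receptor-activity labels
(two-sided). The signature is the group with the smallest separation p;
ties break toward the larger group, then lexicographic key order, so
builds are deterministic. Perfect separation of 24-vs-24 samples has
p = 2/C(48,24) ≈ 6.2e-14; of 12-vs-12, p = 2/C(24,12) ≈ 7.4e-7.

## Expression scores and z-normalization

Gene rows are z-normalized with the *population* standard deviation
(divide by n); zero-variance rows become all-zero and are flagged.
Normalization is always within one dataset (cell model or single cohort);
cohorts are never pooled. A gene set's score per sample is the plain mean
of member-gene z-scores; genes missing from the matrix are dropped and
reported as coverage. For pathway coherency the cell-model matrix is
z-normalized per gene *per cell line*, so coherency measures shared
response shape rather than shared baseline.

## Clustering and stratification

Samples/patients are clustered on the relevant gene set with
1 − Pearson correlation between sample profiles and average linkage, cut
into exactly two clusters. Columns are sorted lexicographically before
linkage, and cluster 1 is the cluster containing the lexicographically
first sample, so the bipartition is invariant to input order. A sample
with zero variance across the gene set (correlation undefined) is
assigned to the nearer cluster centroid (Euclidean) and flagged. The
cluster with the higher mean canonical-pathway score is `HighSig`; an
exact tie breaks to cluster 1 with a loud flag. The canonical gene list
is user-supplied configuration — the package ships no claimed
reconstruction of any curated receptor-pathway list.

Discrete phenotype associations use the chi-square test without
continuity correction (a 2×2 table with any expected count < 5 falls back
to Fisher's exact test, flagged); continuous phenotypes use the two-sided
Welch t-test. Welch (unequal-variance) is the default wherever a
two-sample t-test appears in the pipeline.

## Survival

Kaplan-Meier, log-rank and Cox proportional hazards are delegated to
lifelines; censorings at an event time count as at-risk for that time's
events, and the Cox fit uses lifelines' Efron tie handling (simulated
times are continuous, so ties are a measure-zero concern). The
good/bad-prognosis rule is: *bad* = event (disease death or metastasis,
per the configured endpoint) at any time during follow-up; *good* =
event-free with follow-up ≥ 60 months, the five-year boundary applied
inclusively; all other patients are excluded. PPV = P(bad | HighSig) and
NPV = P(good | LowSig) are computed over non-excluded patients.

## Anchored pathway inference

The interaction graph is undirected with per-edge confidence in (0, 1];
manual curation enters as configuration: ordered pairs that may only be
traversed in the stated direction, and nodes removed before inference.
Each terminal's pathway is the minimum-weight simple path from the anchor
with edge weight −ln(confidence) — i.e. the maximum-confidence chain
under independence of edge evidence. The search is an explicit Dijkstra
whose priority is the tuple (weight, hop count, lexicographic node
sequence), making results deterministic under ties. This is a documented
shortest-path approximation of interactive anchored-network tools whose
inference internals (Steiner-style objectives over curated databases)
are not public; the module isolates it behind one function so a
Steiner-style variant could be substituted.

**Containment pruning.** If one pathway's node sequence occurs as a
contiguous run inside another's (either orientation), the *longer*
pathway is removed, applied pairwise to exhaustion. Removing the longer
chain is the stated curation rule this module reproduces, even though
removing the contained (shorter) one is the more common convention; with
single-source shortest paths the case is rare (nested chains arise only
through ties).

**Pathway statistics.** Differentiation: Welch t-test of the pathway
score between high and low samples. Prognosis: Welch t-test good vs bad
per cohort, excluded patients dropped. Prognosis ranking:
log10 of the *worst* (maximum) p across cohorts — a lower bound on
performance; more negative is better. Coherency: mean Pearson
correlation of consecutive gene pairs (pairs lacking expression are
skipped and counted). The coherency-prognosis relation is summarized by
Spearman rank correlation with mid-ranks for ties. Under these
conventions, pathways that are both co-regulated in the cell model and
outcome-linked in patients produce a *negative* rho (high coherency,
very negative ranking); the package reports rho under its own documented
conventions and does not assert any external sign.

**Edge-correlation specificity.** The distribution of expression
correlations over inferred-subnetwork edges is compared with that over
all expression-covered edges of the background graph; the primary
statistic is the one-sided (greater) Wilcoxon-Mann-Whitney p, with the
two-sided WMW and Welch t reported alongside.

## Null models

Random signatures are exactly size-matched ("similar size" read as equal
size — simplest faithful choice, configurable) and sampled uniformly
without replacement. The 95%-of-null rule calls an observed statistic
significant when its −log10(p) exceeds the 95th percentile of the null
−log10(p) values (one-sided on the −log10 scale; chosen and documented
since the alternative reading — raw significance levels — is equivalent
up to monotonicity here); empirical quantiles use (r+1)/(n+1) so no
replicate reports an exact zero. The signature-vs-random survival
comparison scores each signature by its worst log-rank p across cohorts
and reports the real signature's rank among the randoms. Annotation
enrichment is the upper-tail hypergeometric probability
P(X ≥ k) with BH across terms; no ontology-graph propagation is
attempted (the annotation table is caller-supplied).

## Synthetic data: what it emulates, and what it does not

The generators state one world and keep it fixed:

* **Cell model.** Log-expression = per-gene Gaussian baseline
  (mean 7, sd 1) + planted response steps (±`response_effect` from the
  onset time onward; default 1.0) + a planted high-vs-low contrast on the
  designated signature group (±`baseline_group_effect`, default 1.0,
  with a fixed ⅔-positive/⅓-negative per-gene sign pattern) + iid
  Gaussian noise (sd 0.25). The mixed contrast signs matter: a uniform
  offset across a gene set is invisible to correlation-based clustering
  and cancels in no useful way; varying the sign makes the groups differ
  in profile shape while the set's mean-z score keeps a net shift. The
  default planted signature has 131 genes down-regulated at 10 minutes —
  the size and group of the motivating study's derived signature. There
  is deliberately *no* per-cell-line random effect, so group comparisons
  across samples are exactly calibrated under the null; real arrays have
  correlated within-line measurements, batch and probe effects, none of
  which are modelled. Replicate count is exposed (`n_replicates`,
  default 2) since experimental designs vary on this point.
* **PPI.** Erdős–Rényi decoy background (400 nodes, 1600 edges by
  default) plus one planted anchor→terminal path of length 2–5 per
  terminal. Decoy confidences occupy the bottom 40% of
  `confidence_range` (default (0.2, 0.99)) and planted confidences the
  top decile, which makes a single decoy edge heavier than any five-edge
  planted path — each planted path is the unique optimum, giving a
  known-answer oracle for recovery. Planted intermediates are drawn
  without replacement across paths while the pool lasts, so planted
  skeletons cannot shortcut each other.
* **Cohorts.** Latent risk r ~ N(0,1) loads on signature genes (unit
  coefficients, the same ⅔/⅓ sign pattern; `loading="uniform"` for
  scenarios that only score sets), survival is exponential with hazard
  (ln 2 / 60 months) · exp(β·r) (β default 1.0), administrative
  censoring at 120 months plus uniform dropout for a `censor_rate`
  fraction (default 0.2). `censor_rate = 0` disables *all* censoring —
  the exact everyone-has-an-event regime used by null checks. Grade,
  nodal status and tumor size correlate with r; age does not.
* **Half-lives.** Normal(6.99, 3.3) hours for signature genes vs
  Normal(8.9, 6.1) for background, truncated at zero (defaults on the
  scale reported for mammalian mRNA turnover, with signature transcripts
  about two hours shorter-lived; truncation shifts realized means upward
  by ~0.15/0.9 h, which tests account for).
* **Coherent-pathway scenario.** Disjoint anchor-gene chains; the
  coherent half share one latent per-(cell line, time) profile in the
  cell model and load on patient risk in every cohort; the rest are
  independent in both. This is the stated world for the qualitative
  claim "coherent pathways carry the prognosis signal".

A green test on this world establishes that the *procedures* behave as
specified (calibration, recovery, determinism, oracle equivalence) — not
that any biological conclusion transfers to real cohorts.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` seeded from a
  single integer; identical (config, seed) reproduces outputs
  byte-for-byte, and the pipeline manifest records hashes to prove it.
* Null pathway-differentiation calibration is estimated by pooling over
  independent simulated worlds: within one dataset the pathway tests
  share samples and correlate strongly, so a single-world estimate has
  far more than binomial variance.
* BH-FDR is statsmodels' implementation with NaN-aware wrapping; KM,
  log-rank and Cox are lifelines; both are pinned against independent
  brute-force implementations in the test suite (product-limit
  enumeration, hand hypergeometric tables, exhaustive path enumeration,
  the step-up definition of BH).
* Fisher-exact is used for the separation test because the compared
  partition is a 2×2 table of small fixed margins; the chi-square
  approximation would be unreliable at 24–48 samples.

## Limitations

* The anchored inference is a per-terminal shortest path, not a global
  Steiner-style objective: shared intermediates are reused but not
  optimized jointly, and the 104-pathway output of the original
  interactive tool is not reproduced (nor is its interaction database).
* No probe-to-gene mapping, cross-platform normalization, batch
  correction, or moderated-variance (empirical-Bayes) testing.
* k = 2 clustering is fixed by design; no consensus clustering or
  optimal-k selection.
* Competing risks and time-varying covariates are out of scope for the
  survival layer.
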