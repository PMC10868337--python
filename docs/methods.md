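# Methods

## Model and procedure

`drcombo` treats chemical mimicry of transcription-factor (TF) driven direct
reprogramming (DR) as signature matching in a landmark-gene space. The
per-gene conversion effect is the log2 ratio `z = log2(target) − log2(source)`;
perturbation responses (TF overexpression, small molecules) are response
vectors over the same genes after one-to-one ortholog alignment across
species. The DR-characteristic signature `z'_DR` is `z` restricted to the
genes whose TF responses track their conversion ratios, and the search
problem is

    maximize over nonempty I ⊆ {1..n}:  f(I) = f_corr(I) + f_mole(I)

with `f_corr` the Pearson correlation between the columnwise **sum** of the
selected molecules' signatures and `z'_DR`, and `f_mole = 1` for `|I| ≤ T`,
`exp(−(|I|/t)²)` otherwise. Summing rather than averaging means adding an
uninformative molecule actively dilutes the match, which is what makes small
exact combinations optimal. `f_corr ≤ 1` (Cauchy–Schwarz) and `f_mole ≤ 1`
give `f ≤ 2`. Note `f_corr` can be negative, so `f` can drop below 0; values
are reported unclamped.

### Per-gene concordance

A single pair of vectors (TF profile, target profile) yields one correlation
number, not one per gene; to score genes individually the package correlates,
for each gene, its t panel columns against its m replicate log-ratio columns
paired **by index** (requiring t = m). This choice is exposed as the
`pairing` argument and Pearson vs Spearman as `method`, so alternative
operationalizations can be added without API change. Genes with zero variance
on either side are *undefined* (NaN) and are never selected at any threshold
above 0 — an uninformative gene cannot be "highly correlated".

The number of paired observations matters: the null distribution of a sample
Pearson correlation over q points is heavy-tailed for small q
(P(r ≥ 0.9) ≈ 0.14 at q = 3, ≈ 0.007 at q = 6 under independence), so
thresholding at 0.9 only separates signal from noise with roughly five or
more pairs. This is why the synthetic generator simulates two assay replicate
profiles per TF (3 TFs × 2 = 6 paired columns) — the real landmark assay
provides many replicate signatures per perturbagen — while the cardinality
penalty keeps `t = 3`, the number of reprogramming TFs.

### Threshold sweep

Signatures are extracted on the grid θ ∈ {0, 0.5, 0.55, …, 0.95}: θ = 0
keeps all r orthologs, larger θ gives nested, shrinking signatures
(monotonicity is asserted in tests). θ = 1 is typically empty and raises.
Each threshold gets an independently seeded annealing run; no warm-starting
across thresholds, so per-threshold results are comparable.

### Annealing variant

Moves flip a single molecule: with probability ½ add a uniformly chosen
unselected molecule, otherwise remove a uniformly chosen selected one; an
impossible draw (add at k = n, remove at k = 1 — the empty selection is
outside the state space because `f_corr` of a zero vector is undefined)
falls through to the other move. Strict improvements are always accepted;
a worsening by d is accepted with probability `exp(−d·iteration/n)` — an
effective temperature `n/iteration`, so the walk is nearly free for the
first ~n iterations and approximately greedy after ~10n. (Some descriptions
write the gap in this rule with the opposite sign, which would exceed 1
exactly when invoked; the implemented gap `f_current − f_proposed ≥ 0` is
the only reading that yields a valid probability.) The highest f visited and
its selection are the result ("prediction score"); with restarts, each
restart gets a seed spawned from the master seed and the best restart wins,
ties to the earlier restart.

Implementation notes: the summed signature and its moments are maintained
incrementally (O(s) per proposal) and refreshed every 4096 iterations to
cancel float drift; degenerate proposals (zero-variance sum) are rejected as
moves rather than given an invented objective value; initial k is uniform on
{1..min(T, n)} unless `initial_k` is set, biasing the start into the
feasible k ≤ T region; termination is `max_iterations` (default 10⁶) with an
optional wall-time budget. A single seeded PCG64 generator drives every
stochastic choice, so runs are exactly reproducible.

The exhaustive oracle enumerates all 2ⁿ − 1 nonempty subsets (refused above
n = 20) in vectorized chunks. Because float noise can split mathematically
tied subsets, the reported subset is the smallest bitmask (lexicographic on
index sets) among subsets within 1e-12 of the maximum; the reported score is
the true maximum.

### Enrichment evaluation

Predicted combinations are scored for over-representation of known
DR-inducing molecules: with K known among N candidates and x known among the
n_pred predicted, the one-sided p-value is the hypergeometric upper tail
P(X ≥ x), computed by direct summation of pmf terms (scipy's pmf; the test
suite cross-checks against an independent log-factorial summation to 1e-10).
The default tail is "greater" because the question is enrichment; a
two-sided small-sample-exact mode exists. The 2×2 construction is exactly
(x, n_pred − x, K − x, N − K − n_pred + x); published analyses sometimes
leave their table construction unstated, so externally reported p-values may
not be reproducible from counts alone.

## Synthetic-study generator

`simulate_study` emulates the pipeline's data shapes at the real study's
scale — defaults: 978 landmark genes, 594 common orthologs, 3 TFs × 2
replicate profiles, 1522-molecule library with 36 known actives — with two
planted truths:

* **Planted genes** (default fraction 0.2 of orthologs): their TF-response
  columns equal `response_scale` × the realized replicate log-ratio columns
  plus N(0, noise_sd²); all other genes get independent noise. Baseline
  expression is N(7, 1) on the log2 scale with replicate noise sd 0.3 and
  per-gene conversion effects N(0, 1) — magnitudes typical of log-scale
  expression data.
* **Planted combination** (default 5 molecules): each member carries the
  conversion effect masked to the planted genes plus a *centered*
  within-combination deviation (sd 1.0; the deviations cancel exactly in the
  sum) plus N(0, noise_sd²). The sum is therefore an affine image of the
  masked conversion profile up to noise, while every proper subset fits
  strictly worse — the combination, not any member, is the optimum.
  Non-planted molecules are strong uncorrelated responders (N(0, 2²));
  their larger scale means chance alignment with the signature is dominated
  by the dilution they cause, so the planted optimum is stable.

The ortholog map is a species-prefixed bijection plus ambiguous decoy pairs
that the one-to-one filter must drop. Known-active labels mark the planted
molecules plus random decoys up to 36. All outputs are written through the
package's own writers; a seed reproduces files byte-for-byte.

What the generator does **not** emulate: landmark-inference error for
non-landmark genes, plate/batch effects, dose–response structure,
correlated gene–gene noise, and molecules with partial or antagonistic
signature overlap. Passing recovery tests therefore shows the machinery is
correct and well-conditioned under Gaussian noise at realistic magnitudes,
not that real libraries contain recoverable combinations.

## Numerical and design choices

* Expression scale is explicit per matrix (`scale_tag`); linear inputs are
  log2-transformed before differencing, and non-positive linear values are
  an error, never silently masked. Missing values are NaN and genes carrying
  them are dropped where downstream math requires completeness.
* Replicate pairing in the paired log-ratio mode is by column order and
  recorded in output metadata; the unpaired mode averages in linear space
  before taking the ratio.
* Many-to-many orthologs are dropped entirely (no averaging), making
  alignment deterministic and order-independent.
* Pearson is the default correlation everywhere (the statistics of the
  pipeline are moment-based); Spearman is available for the concordance
  step.
* `f_mole`'s exponent is `(k/t)²`; an alternative reading `k/t²` is
  selectable via `ObjectiveConfig.mole_exponent`.
* Degenerate inputs fail loudly: an all-constant library, a zero-variance
  signature, or 100 consecutive degenerate initializations raise rather
  than return a value.

## Problem sizes used in the shipped checks

The test suite runs the annealer-vs-oracle comparison on 20 random
12-molecule, 50-gene instances (10⁵ iterations, 3 restarts), and
planted-combination recovery on 10 seeds of a 200-molecule, 300-gene study
(10⁵ iterations, 5 restarts) — sizes at which the exhaustive oracle is
cheap and the full sweep completes in about a minute, while preserving the
n ≫ k regime of the real search.

## Known limitations

* The per-gene concordance construction is one defensible operationalization
  of "correlate the TF profile with the target profile and select genes";
  results at a given threshold depend on it.
* The annealer is a heuristic: the oracle-equivalence guarantee is empirical
  and only verified at small n; at n in the thousands only restarts and the
  prediction-score trace indicate convergence.
* Cross-species alignment quality is inherited from the user-supplied
  ortholog table; the package neither infers orthologs nor resolves
  paralogs.
* Dose, duration and delivery of molecules are outside the model: two
  combinations with identical signatures are indistinguishable to `f`.
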