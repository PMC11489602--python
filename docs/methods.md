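# Methods

This note documents the statistical model behind `symptomnet`, the defaults
and why they were chosen, the synthetic-data model and its limits, and the
numerical conventions that make runs reproducible.

## Data model and pre-analysis filtering

The unit of analysis is a patients × symptoms matrix of binary lifetime
indicators.  Missing values are not supported: the MI estimator below
assumes complete 2×2 contingency tables, and an incomplete cell in the input
is a parse error rather than something to impute.

Before inference, variables whose minority class (the smaller of the
ones-count and zeros-count) falls below `min_minority_count` (default 2) are
excluded.  A constant indicator has zero entropy and therefore zero MI with
everything; an indicator discordant in a single patient is statistically
indistinguishable from constant at any realistic cohort size.  The default
of 2 is deliberately permissive: a symptom reported by only 3 of 529
patients is retained, which matches how sparse comorbidities are usually
kept in published symptom networks, while a 528-of-529 indicator is dropped.
Whether indicators other than the near-universal one should be screened is a
judgment call; the threshold is exposed for that reason.

Prevalence percentages are reported as 100·count/n rounded half-up to one
decimal, the convention of printed clinical tables (banker's rounding would
turn 47.45 into 47.4).

## Edge weights: plug-in mutual information

For binary X, Y the mutual information in bits is

I(X;Y) = H(X) − H(X|Y) = Σ p(x,y) log₂ [ p(x,y) / (p(x) p(y)) ],

estimated by plugging in empirical cell frequencies, with 0·log 0 = 0
applied cell-wise.  No bias correction (Miller–Madow, shrinkage) is applied.
The plug-in estimator is positively biased under independence, but the
surrogate null below is computed with the *same* estimator on the same
marginals, so the bias cancels out of the significance decision; correcting
the point estimate would only complicate the entropy-bound interpretation
(0 ≤ I ≤ min(H(X), H(Y))) that makes MI readable for skewed indicators.

Numerics: cell counts stay exact integers until the final log-sum, and the
four cell terms are summed in sorted order, which makes the result exactly
invariant to swapping X and Y (the swap exchanges the two off-diagonal
terms; IEEE addition is not associative, so a fixed summation order is
needed for bit-for-bit symmetry).  Rounding can leave the four-term sum at
−1e−17 for an exactly independent table; the value is clamped at 0.  The
conditional entropy reported alongside is computed independently as
H(X,Y) − H(Y), so the identity I = H(X) − H(X|Y) is an internal cross-check
(asserted to 1e−12 in the tests), not a restatement.

The pairwise MI matrix has a zero diagonal by convention: self-links are
never edges, and downstream code treats the matrix as an adjacency
candidate.

## Edge significance: surrogate permutation null and FDR

For each pair, one series is permuted uniformly across patients
`n_surrogates` times (default 5000) and MI recomputed.  Permutation rather
than Bernoulli resampling preserves both marginals exactly, so every
surrogate lives on the same entropy-bounded MI scale as the observed value.
The p-value uses the add-one rule p = (1 + #{MI_surr ≥ MI_obs}) /
(n_surrogates + 1): it is never zero, the test is valid at any n_surrogates,
and ties count toward the null (conservative).  Because observed and
surrogate MI come from the identical integer-count formula, tie detection by
exact float comparison is safe.

Edges are selected by Benjamini–Hochberg step-up FDR at q = 0.05 over the
C(k,2) upper-triangle p-values.  BH assumes independence/PRDS; the
Benjamini–Yekutieli variant (valid under arbitrary dependence) is available
via `fdr_method="by"`.  BH at 0.05 is the field default for network edge
selection and is what the global-null simulations in the test suite
calibrate against.  Note the attainable p-value floor is
1/(n_surrogates + 1); with 253 pairs, scaled-down runs below ~500 surrogates
coarsen the BH step and should be labeled accordingly.

Reproducibility: one master seed; each pair draws from an RNG substream
keyed by SHA-256 of its *sorted* variable-name pair mixed with the seed.
Results are therefore bit-identical across runs and invariant to column
order, and `surrogate_pvalue` canonicalizes its argument pair internally so
swapping x and y reproduces the identical realization.

## Network characterization

- **Degree / strength**: count, and MI-weight sum, of a node's significant
  edges.  Strength is reported to one decimal in tables.
- **Betweenness centrality**: default mode treats the significant-edge graph
  as unweighted — a path's length is its number of links — matching the
  usual verbal definition of shortest paths between symptoms.  An
  inverse-weight mode (edge length 1/MI, strong dependencies are "shorter")
  is exposed, and the mode used is recorded in output metadata; values are
  unnormalized pair counts (integers after rounding in reports), with equal
  splitting across tied geodesics.  Tests verify both against exhaustive
  path enumeration on all small graphs.
- **Core-periphery**: discrete two-block Borgatti–Everett decomposition.
  Quality of an assignment is the Pearson correlation between the
  off-diagonal weights and the ideal pattern (core-core = 1,
  core-periphery = 1, periphery-periphery = 0).  Optimization is single-flip
  hill climbing from `restarts` random starts (default 50), deterministic
  for a fixed seed, ties broken toward the lexicographically smallest
  assignment.  Tests verify the search attains the exhaustive-search optimum
  on networks up to 12 nodes.  Note the ideal pattern expects the periphery
  to be attached to the core: for a clique whose periphery hangs on single
  pendant edges, the mathematical optimum of this quality need not be the
  planted clique itself — an inherent property of the Borgatti–Everett
  correlation objective, not a search failure.  An edgeless network is all
  periphery with undefined (NaN) quality.
- **Modularity**: weighted Newman modularity at resolution γ (default 1.0),
  optimized by Louvain multi-level moves, best of `restarts` seeded runs
  (default 100), exact ties broken by the lexicographically smallest label
  vector.  Labels are renumbered 1..M by descending module size (the numbers
  carry no other semantics); isolated nodes are singleton modules; the
  reported quality is recomputed from the returned labels.

## Synthetic cohorts: dichotomized Gaussian

A cohort is drawn from a latent threshold model: Z ~ N(0, R) with unit
variances, and variable i is present iff Z_i > Φ⁻¹(1 − prevalence_i).  The
model scales to dozens of correlated variables with arbitrary marginals, and
positive semidefiniteness of R is its only consistency condition (smallest
eigenvalue below −1e−8 is rejected naming the eigenvalue; anything between
−1e−8 and 0 is treated as rounding and projected to zero).

Pairwise dependencies are planted on the MI scale: the population MI of a
thresholded pair is computed exactly from the bivariate-normal orthant
probability P(Z_x > t_x, Z_y > t_y; ρ) and inverted by bisection on
ρ ∈ [0, 1) (MI is strictly increasing in ρ there), to a default tolerance of
1e−4 bits.  Targets above min(H(X), H(Y)), or above what the comonotone
ρ → 1 limit can deliver for unequal marginals, are rejected with the bound
in the message.

Variables flagged *degenerate* (e.g. a 99.8%-prevalence indicator emulating
a near-universal symptom) are generated independently of the latent block
with an **exact** minority count — round(prevalence·n) ones at random
positions — so that degeneracy filtering behaves identically in every draw
instead of flickering with binomial noise.  Such variables must have zero
latent correlation with everything else, which also keeps them out of the
PSD bookkeeping.

`planted_structure_spec` provides the three canonical test structures:
global-null (identity R), two-block (within-block pairs at a target MI,
blocks independent), and core-periphery (core pairs at the target, each
periphery variable attached to one core variable at half the target).  For
the core-periphery kind, several pendants sharing a core variable can make
the requested attachment infeasible; the core-periphery block is then shrunk
to the largest PSD-feasible scale rather than failing, since the structure
(not the exact attachment strength) is what the construct exists to plant.

The bundled recipe `specs/clinic_young_cohort.yaml` (also available as
`presets.young_clinic_spec()`) emulates a 529-patient, 24-indicator young
clinic cohort with prevalences from 0.6% to 99.8% and an illustrative
single-factor-per-group dependency block (complex tics, OCD-like, ADHD-like,
urge/suppression groups; ρ_ij = loading_i·loading_j within a group, which is
PSD by construction).  What the generator emulates is the *marginals* and
*selected pairwise dependencies* of such data; it does not attempt
higher-order interaction structure, item-level measurement error, or
age/severity covariates.  Passing tests on synthetic cohorts therefore
demonstrate that the pipeline recovers planted pairwise structure at
realistic sizes — not that any particular clinical dataset has that
structure.

## Simulation sizes and defaults used in verification

The test suite and the acceptance script verify the pipeline at sizes chosen
to give stable Monte-Carlo answers at interactive runtimes: 10,000 random
2×2 tables for estimator identities; 1000 independent pairs (n = 500
patients, 500 surrogates) for type-I calibration against the 95% binomial
interval; 100 replicate 10-variable global-null cohorts for FDR control; 100
replicates of a planted 0.2-bit pair for power (detection in ≥95% expected);
20 replicate two-block cohorts for community recovery (mean adjusted Rand
≥ 0.9); n = 100,000 draws for generator fidelity (marginals and MI within
0.005).  Production-scale defaults (5000 surrogates) are used for the
bundled-cohort run in the acceptance script; scaled-down surrogate counts in
simulations are always a multiple of the p-value floor consideration above.

## Known limitations

- Plug-in MI is biased upward for weak dependencies at small n; only the
  *significance decision* is bias-corrected (via the surrogate null), not
  the reported weight.
- BH-FDR assumes positive dependence across the C(k,2) tests; overlapping
  pairs share variables, which is the standard situation in which BH is used
  for network edges, but a theoretically safe alternative (BY) is config
  only, not default.
- The core-periphery objective is the two-block correlation form; continuous
  coreness scores and multi-block generalizations are out of scope.
- The generator matches marginals and chosen pairwise dependencies only; it
  cannot reproduce a real cohort's full joint distribution, and no attempt
  is made to estimate one.
- Cohort comparisons are descriptive (set differences of core membership,
  side-by-side metrics); no formal network-difference test is provided.
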