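# Methods

This note documents the statistical model behind `cocomplex`, the choices
made where the design was genuinely open, and what the synthetic test bed
does and does not establish.

## Evidence model

The unit of evidence is the unordered gene pair.  Two channels are calibrated
independently and added:

**Expression channel.** Pearson's r is computed per pair on
pairwise-complete samples.  A pair needs at least `min_overlap = 10` jointly
observed samples for r to be defined (correlations over fewer samples are
noise-dominated; the cutoff is configurable).  Pairs with undefined r carry
zero expression LLR — neutral, not a penalty.

**Interaction channel.** Each PPI edge (a, b) receives the shared-partner
score `s = −log10 P(X ≥ k)` under a hypergeometric null: universe = all
network nodes except a and b, success states = deg(a), draws = deg(b), where
neighbor sets exclude a and b themselves (their mutual edge is already the
evidence gating which pairs are scored).  `p = 0` underflow is capped at
score 300.  Non-edges are not scored and carry zero interaction LLR.

**Calibration.** For each channel a logistic regression of co-complex
membership on the single feature is trained against a reference catalogue:
positives are pairs co-annotated in a reference complex of ≤ 30 members
(larger assemblies would dominate the pair counts), negatives are sampled
uniformly from measured, non-co-annotated gene pairs at 300 negatives per
positive.  The LLR follows from the Bayes identity
`LLR(x) = logit p̂(x) − logit π`, which equals the log density ratio
`log[P(x | co-complex)/P(x | background)]` when the logistic posterior is
correct.  This avoids estimating the background density by binning, is
numerically stable, and keeps the LLR monotone in the feature.  The stored
prior uses the *achieved* negative:positive ratio so the identity stays
exact when fewer negatives are available than requested.

Two calibration details matter in practice:

* The background population for the interaction channel is **all measured
  pairs**, with non-edges entering at feature 0 (the same value as an edge
  whose endpoints share no partners).  Restricting negatives to edges
  conditions the prior on interacting pairs and erases the evidence carried
  by the edge itself; under that conditioning, complexes small enough to
  share only one partner per edge score negatively and can never seed.
* The interaction feature is compressed with `log1p` before the linear
  logistic term.  The raw −log10 p feature spans 0–20+ and the discriminative
  transition happens almost entirely between 0 and ~2 (zero versus one shared
  partner); a linear logit fitted on the full range underestimates the LLR in
  exactly that region.  `log1p` is monotone, so the LLR remains monotone in
  the raw score, and the Bayes identity is unaffected.  The expression
  channel keeps the identity transform: r is already bounded.

If the two classes are linearly separable the unpenalized fit diverges; the
fitter detects this (|β₁| · feature spread > 200) and falls back to a
ridge-penalized fit, logged.  A constant feature yields β₁ = 0 and an LLR
identically zero.

## Set scoring and search

`LLR(S)` sums both channels over all |S|(|S|−1)/2 pairs; singletons score
zero.  The search is constrained to sets positive on *both* channels:

1. **Seeding.** All edges and all network triangles are scored; candidates
   with positive expression and interaction sums are kept, and the highest
   scoring candidate is repeatedly selected (overlapping candidates
   discarded) until none remain.  Remaining genes become singletons.
   Candidates are static during seeding; refinement compensates.
2. **Refinement.** Iterated best-move local search over merges of two
   clusters, removal of one protein to a singleton, and switching one
   protein between clusters.  The applied move is the one with the largest
   integrated gain among moves whose expression gain and interaction gain
   are both strictly positive (> 1e−12 to exclude float dust).  The total
   integrated score strictly increases every iteration, so the search
   terminates; an iteration cap (default 10,000) guards pathological inputs.
   Ties are broken by the lexicographically smallest sorted member-name
   tuple, making runs byte-reproducible.

Move proposals are restricted to cluster pairs joined by at least one
network edge, and switches to clusters containing an interaction partner of
the moving protein.  Any move whose *target-side* interaction gain is
positive requires such an edge, so the restriction is exact for the moves
the constraint is designed to admit; it can only miss moves whose entire
benefit is escaping a negative-scoring source cluster.  `refine_clusters(...,
exact=True)` enumerates all cluster pairs and all (protein, cluster)
switches instead, and is used in the test suite to verify constrained local
optimality on small instances.

Delta evaluation is incremental: a move changes at most two clusters, so
only cache entries touching changed clusters are recomputed.

## Empirical FDR

Spurious clusters arise when interacting proteins are correlated by chance.
The null reruns the full seeding + refinement on inputs in which the
assignment of expression profiles to gene identifiers is a uniform random
permutation of the measured genes; the network and the fitted LLR models are
left untouched.  Models are deliberately *not* refitted per randomization:
refitting on shuffled data degenerates the expression model and makes score
thresholds incomparable between real and null runs.  Because a permutation
of profiles permutes the correlation matrix, each null run reuses the real
correlation table, permuted — the randomization is exact, not approximate.

For each threshold t in the grid of observed real cluster scores,
`FDR(t) = mean genes clustered in null runs at score ≥ t / genes clustered
in the real run at score ≥ t`, counted over clusters with ≥ 2 members and
positive scores on both channels (gene counting follows the discovery's
gene-level yield; a cluster-level curve is available from the same arrays).
A running minimum makes the curve non-increasing in t, and the catalogue is
cut at the smallest t with FDR ≤ the target (default 10%).  If no threshold
qualifies the catalogue is empty.  The default is 100 randomizations;
the test suite and acceptance script use 25 (and 10 for supplementary
seeds), which stabilizes the mean count at the problem sizes used there.

This permutation null is mildly conservative on structured data: shuffling
occasionally relocates two genuinely correlated profiles onto adjacent
network nodes, so null runs can contain medium-score clusters that have no
counterpart mechanism in the real run.  The realized false-gene fraction on
synthetic ground truth therefore tends to sit at or below the estimate.

## Downstream statistics

**Mann–Whitney U.** Exact (distribution enumeration) when the combined
sample is ≤ 12 and untied; otherwise normal approximation with tie and
continuity corrections.  If every value is tied the test is uninformative
and p = 1.  Effect sizes are rank-biserial, `s = 2U/(n₁n₂) − 1 ∈ [−1, 1]`.

**Subtype-specific complex expression.** Per protein and subtype, the
difference between the median expression in the subtype and the median in
all other samples; per complex with ≥ 3 measured members, a two-sided
Mann–Whitney of member versus non-member median differences.  BH correction
is applied jointly across all complex × subtype tests.  The statistic is
invariant to positive affine transforms of the matrix but *not* to arbitrary
monotone transforms (median differences are compared across proteins), unlike
the purely rank-based collateral test.

**Alteration profiles and collateral loss.** A sample is altered for a gene
under four definitions: protein-affecting mutation only (missense, splice
site, insertion, deletion, nonsense — never synonymous/other), hemizygous
deletion (GISTIC −1), homozygous deletion (−2), or mutation-or-homozygous
deletion.  For the complex-level test, protein abundances are ranked within
each sample (ascending, average ties, missing excluded); the per-sample
statistic is the mean rank of the complex members after excluding the
altered gene itself and — in deletion-containing modes — every member on the
altered gene's chromosome, so co-deletion in cis cannot masquerade as a
trans effect.  Pure-mutation profiles exclude only the altered gene.
One-sided Mann–Whitney (altered lower), minimum 3 altered samples
(configurable), ≥ 2 members surviving the exclusions, BH across all
(gene, complex) tests of a run.

**Catalogue overlap.** Best hypergeometric upper-tail overlap per discovered
complex against a reference catalogue over a fixed background universe
(genes present in both expression data and network), with Jaccard and
coverage, BH-corrected across discovered complexes.

**Isogenic differential expression.** Technical replicates are averaged per
biological replicate; missing intensities are imputed with each sample's
minimum observed intensity (absent ≈ below detection); log2; two-sided Welch
t per protein; BH.  With 3 + 3 biological replicates, duplicate technical
measurements of SD 0.3 log2 units, and a 2-fold change, simulation gives
power ≈ 0.95 at p < 0.05 (and only ≈ 0.36 at p < 0.005); the test suite
asserts the former.

## Synthetic test bed

Each planted complex c draws a per-sample latent factor f_c ~ N(0,1); member
expression is `a·f_c + ε` with unit noise and loading `a = √(r/(1−r))`,
giving exchangeable within-complex correlation exactly r (default 0.7).
Background genes are independent N(0,1).  Within-complex edges appear with
probability 0.9 on top of uniformly sampled background edges; missingness is
completely at random per gene at a rate drawn from U(0, 0.3) (protein matrix
only).  Subtype shifts and collateral events act in units of the gene's
marginal SD so that power targets are portable.  A collateral event
depresses the altered gene in both the protein and mRNA matrices but its
partners in the protein matrix only, reproducing the post-transcriptional
signature; the mRNA matrix shares the latent factors with fresh noise.
Decoy sets are correlated-only (factor, no planted edges) or clique-only
(full clique, independent expression).  Reference catalogues for calibration
are the planted truth with 20% of members dropped and 20% random members
added, emulating imperfect curation.  Everything is deterministic given the
seed.

The default benchmark conditions are 1,000 genes, 60 samples, 25 complexes
of 3–12 subunits, 2,000 background edges, 10 decoys of each kind.  The
generator emulates the statistical structure the method relies on, not real
mass spectrometry: no intensity-dependent missingness, batch effects,
isoform interference or copy-number segments.  Passing tests therefore show
the machinery is correct and well calibrated under its stated model, not
that real tumor cohorts satisfy that model.

## Known limitations

* Complexes are disjoint by construction; shared subunits and complex
  isoform variants are out of scope.
* The greedy + local-search optimizer finds a constrained local optimum,
  not the global one; seeding is static.
* The permutation FDR inherits the conservativeness described above.
* Network assembly (publication-count thresholds, database merging) is the
  caller's responsibility; the package consumes a generic edge list.
* Size-3 planted complexes are the hardest case: their interaction evidence
  rests on single shared partners and a missing within-complex edge can make
  them undiscoverable; benchmark recall is driven almost entirely by this
  regime.
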