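# Methods

## The model

`codonsel` analyses selective pressure on duplicated protein-coding
genes through codon substitution models. The state space is the 61
sense codons of the standard genetic code; instantaneous change between
codons i and j is allowed only for single-nucleotide differences, with
rate

    q_ij = pi_j * kappa^[i->j is a transition] * omega^[i->j is non-synonymous],

the classic Goldman–Yang-style parameterisation. `kappa` is the
transition/transversion rate ratio, `pi` the equilibrium codon
frequencies, and `omega = dN/dS` the ratio of non-synonymous to
synonymous substitution rates: `omega < 1` indicates purifying
selection, `omega = 1` neutrality, `omega > 1` positive selection. Q is
rescaled so that one unit of branch length equals one expected
substitution per codon site, making branch lengths comparable across
models. Under detailed balance the symmetrised matrix
`diag(sqrt(pi)) Q diag(1/sqrt(pi))` is symmetric, so transition
probabilities `P(t) = exp(Qt)` come from a real eigendecomposition.

Three families of hypotheses about duplicated genes are expressed as
constraints on omega:

* **Branch models** (one omega class per site, omegas varying across
  branch labels): M0 — one ratio for everything except the outgroup
  branch; MP — one ratio per paralog clade ("paralog effect"); MA — one
  ratio for the two basal post-duplication branches ("early") and one
  for everything more recent ("late": the "age effect"); MPA — the full
  paralog × age factorial (five ratios including the outgroup's).
* **Site models** (one branch class, omega varying over sites): M8A —
  omega follows a Beta(p, q) discretized into 10 equal-weight
  categories, plus a neutral category fixed at omega = 1 with weight
  p_ad; M8 — identical except the additional category's omega_ad >= 1
  is free, which is the positive-selection alternative. The discrete
  M3(k) is also provided.
* **Clade models**: MD(k) takes M3(k) and lets one class's omega differ
  between the two paralog clades (omega_A vs omega_B), the
  clade-divergence alternative to M3(k).

Nested pairs are compared by likelihood-ratio tests, `2 * delta logL`
against a chi-square with df equal to the difference in free-parameter
counts, with no boundary mixture — the plain chi-square convention
standard for these model pairs (the M8-vs-M8A test is then mildly
conservative, which the calibration harness verifies empirically).
Sites in the positive-selection (or clade-divergent) class are
identified by naive empirical Bayes at the ML estimates:
`P(class c | site) ∝ weight_c * L_c(site)`. Sites are listed at
posterior > 0.50 and starred above 0.95. Full (parameter-uncertainty
averaging) empirical Bayes is a possible future refinement.

## Parameter accounting

Likelihoods are evaluated on unrooted trees (root placement is
irrelevant under a reversible model), so a tree with n tips contributes
2n−3 free branch lengths. Every model adds 1 for kappa plus its omega
structure: 2 (M0), 3 (MP, MA), 5 (MPA), 3 (M8A: p, q, p_ad), 4 (M8),
2k−1 (M3(k)), 2k (MD(k)). kappa is treated as a free, globally shared
parameter in every model; this is the convention under which the
standard published parameter counts for this battery (e.g. 58 for M0 on
a 29-tip tree, 20 for M8 on a 9-tip tree) are reproduced exactly.

Equilibrium frequencies are estimated from the data by counting, not by
ML: `equal` (uniform 1/61), `F1x4`/`F3x4` (products of overall or
positional nucleotide frequencies over sense codons, renormalized) and
`F61` (observed codon proportions). F3x4 is the default, as in standard
codon-model software. A pseudocount (0.5 per codon for F61, 0.5 per
nucleotide count for F1x4/F3x4) prevents zero equilibrium frequencies,
which would break reversibility. Frequency parameters are not counted
in np, again following the standard convention.

## Numerical choices

* **Beta discretization.** Category omega values are the conditional
  means of the beta over its equal-probability quantile intervals,
  computed from the regularized incomplete beta function (not the
  interval medians — the mean preserves the distribution's mass
  balance). Values are clipped to (1e-9, 1−1e-9) and nudged to remain
  strictly increasing for extreme shapes whose tail categories would
  otherwise collapse to 0 or 1.
* **Pruning.** Felsenstein pruning over unique site patterns, batched
  across site classes, with per-node rescaling of partial likelihoods
  and log-space accumulation, so alignments of arbitrary length cannot
  underflow. Gapped or ambiguous codons are MISSING states contributing
  all-ones partials (likelihood-neutral); IUPAC ambiguity codes are not
  expanded.
* **Optimization.** Bounded L-BFGS-B on log-transformed positive
  parameters, jointly over branch lengths and model parameters, with
  optional multi-start (seeded jitter; deterministic given the seed).
  Bounds: omega in [1e-4, 99], kappa in [0.01, 100], beta shapes in
  [0.005, 99], branch lengths in [1e-6, 25]; the 99 ceiling matches the
  conventional codeml-style bound, for comparability of boundary fits.
  Mixture weights for M3/MD are optimized through a softmax
  transform. In the batteries each richer model is warm-started from
  its best nested parent (MPA from the better of MA/MP; M8 from M8A at
  omega_ad = 1+1e-6; MD(k) from M3(k)), and since the null always lies
  inside the alternative's parameter space, an alternative that ends
  below its parent's likelihood (a failed local search) is floored at
  the parent's value, making LRT statistics non-negative by
  construction.
* **Ties.** All sites within 1e-9 of the maximal positive-class
  posterior are reported as maximal.

## The clade partition

Branch labels are derived from the two clade tip sets and the outgroup:
the OG label goes to every branch on the outgroup side of the
duplication node; "early" is the single branch descending into each
paralog clade (overridable by explicit branch lists, for analyses that
reassign an ancestral branch to the late set); everything distal is
"late". Under MP/MPA the basal branch inherits its clade's identity so
that labels partition all branches. In the outgroup-free CLADE scheme
used by MD, every branch belongs to the clade on whose side of the
central split it lies; the single inter-clade branch carries the label
of the clade opposite the (arbitrary) traversal root, a deterministic
convention with no likelihood consequence beyond which clade's omega
that one branch uses.

## The synthetic-data generator

The simulator draws root codons from pi, a site class per site from the
mixture weights, and evolves states branch-by-branch with the
(class, branch-label)-appropriate transition matrices, retaining the
true class vector. Trees are built by coalescent-style random pairwise
joining within each clade (exponential branch lengths, mean 0.06
substitutions/codon), two basal branches of 0.15 and an outgroup branch
of 0.5 — total tree lengths of order 1–3 for the default clade sizes,
in the range typical of ML trees for recently duplicated plant genes.
Scenario presets mirror the study conditions the package is designed
around: an age-effect truth (two clades of 17 and 11 tips plus
outgroup, early omega 0.14 vs late 0.05, 266 codons), a paralog-effect
truth (0.25 vs 0.41, 243 codons), a positive-selection truth
(Beta(0.01, 0.05) plus omega_ad = 4.45 at weight 0.10, 243 codons), a
clade-divergent truth (shared omega 0.12 at weight 0.79, divergent pair
1.54/3.13), and a single-ratio null (omega 0.2, kappa 2, 300 codons).
The default pi is a mildly AT-rich product-form vector typical of plant
nuclear coding sequence.

What the generator does **not** emulate: indels and alignment error,
recombination and gene conversion between paralogs, selection on codon
usage, non-stationary or non-reversible composition, and the
sequencing/pseudogenization process (pseudogene test fixtures are
written directly as edited sequences). Passing recovery and calibration
tests therefore demonstrates internal statistical correctness of the
estimator and tests under the model's own assumptions, not robustness
to these real-data complications.

## Validation harnesses and problem sizes

`parameter_recovery` simulates, refits the true family and tabulates
bias, RMSE and Monte-Carlo SE per parameter; fits use the scenario's
true equilibrium frequencies so that recovery measures the substitution
parameters rather than frequency-estimation noise. `lrt_calibration`
measures empirical rejection rates with exact (Clopper–Pearson)
binomial intervals; in type-I-error mode the scenario is generated
under the test's null family. For the M8-vs-M8A pair the alternative's
branch lengths are frozen at the null fit by default: the statistic is
then a lower bound on the fully optimized statistic, keeping the check
conservative at a fraction of the cost (a full joint refit is one flag
away). The default validation runs use reduced problem sizes — clades
of 3–4 tips, 150–300 codons, tens to low hundreds of replicates —
chosen as the package's own compromise between Monte-Carlo resolution
and turnaround; all sizes are arguments, and the reported binomial
intervals make the resolution explicit.

## Known limitations

* Naive (not Bayes) empirical Bayes posteriors ignore parameter
  uncertainty and are anticonservative for very short alignments.
* Mixture fits (M3/MD, and M8 under weak signal) have multimodal
  likelihood surfaces; multi-start and warm-starting mitigate but do
  not eliminate local optima — raise `restarts` for final analyses.
* The chi-square reference for boundary tests (M8 vs M8A) is
  conservative rather than exact.
* At the modest divergences the generator produces (total tree lengths
  around one substitution per codon), the M8-vs-M8A test has limited
  power even under a strong positive-selection effect — the neutral
  class of the null can absorb weakly informative elevated-omega sites.
  The validation harness therefore asserts the test's consistency
  (rejection and statistic above their null counterparts at matched
  conditions), not an absolute power level.
* No rate variation beyond the specified site classes, no covarion
  behaviour, no amino-acid or nucleotide-level models.
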