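# Methods

`kinopipe` reimplements, as a tested library, the analysis chain used to
profile kinase-signaling (kinome) responses on peptide microarrays: each
array spots short peptide substrates of known phosphosites in technical
replicate; lysate kinase activity phosphorylates them; spot intensities are
normalized, quality-filtered, tested for differential phosphorylation
between treatment cohorts, clustered and embedded, and the differential
proteins are tested for pathway over-representation.  A companion module
computes qPCR relative-expression fold changes (2^-ddCt).  Because no raw
scans are publicly deposited for the motivating adjuvant study, a
synthetic-array generator with planted ground truth stands in for raw data
in all recovery tests, and the study's printed differential-peptide tables
are packaged as fixtures.

## Array design and synthetic data

The emulated design is 282 unique peptides x 9 technical replicates per
array, one array per animal, with 3 treatments (PBS control, the
polyphosphazene adjuvant PCEP, alum) x 2 tissues (injection-site muscle,
draining lymph node) x 5 animals.

The generator (`kinopipe.simulate`) draws, per array k, peptide p,
replicate i:

    raw = B + exp(mu_p + alpha_k + delta_{p,g} + eps_pki) + eta_pki

with peptide baselines `mu_p ~ N(6.5, 1.4^2)` on the natural-log scale,
array effects `alpha_k ~ N(0, 0.2^2)`, replicate noise
`eps ~ N(0, 0.25^2)`, additive background noise `eta ~ N(0, 8^2)` around a
background offset `B = 50`, truncated at zero.  These defaults were
calibrated once so that raw intensities span roughly 2.5 decades and the
per-peptide replicate standard deviation rises strongly with the mean
(Spearman > 0.9) — the mean-variance coupling that motivates
variance-stabilizing normalization.  Treatment effects `delta` are planted
on the log scale with random sign (Rademacher) on a fraction
`frac_differential` (default 0.2) of peptides at magnitude
`effect_log_mean` (default 1.0); PBS groups carry zero effect by
construction.  A fraction `frac_inconsistent` (default 0.1) of peptides has
replicate variance inflated by `kappa` (default 25, i.e. 5x the sd) —
the targets of the consistency filter.  Generation is a pure function of
the seed.

What the generator does **not** emulate: spatial artefacts (print-tip and
gradient effects), cross-hybridization, subject-level biological variance
beyond the array effect, and non-Gaussian scanner noise.  Passing recovery
tests therefore demonstrate correctness of the statistical machinery under
the stated noise model, not performance on real scans.

Recovery scenarios plant only the structure they probe: the
consistency-filter scenario plants inconsistency without treatment effects,
and the differential scenario plants effects without inconsistency.  With
both planted at once, peptides that are simultaneously differential and
inconsistent are removed by the filter *by design*, which caps attainable
sensitivity near 0.85 and would measure the interaction of the two
mechanisms rather than either one.

## Variance-stabilizing normalization

The transform is the canonical two-parameter affine-arsinh (generalized
log) calibration `y = arsinh(a_k + b_k x)` fitted jointly across the arrays
of a tissue under a common-mean model `y_pki = mu_p + e`,
`e ~ N(0, sigma^2)`.  `mu_p` and `sigma^2` are profiled out in closed form;
the per-array `(a_k, log b_k)` maximize the profile likelihood (Jacobian
term included — without it the likelihood is unbounded as `b -> 0`) by
L-BFGS with an analytic gradient.

Two numerical points matter.  First, the likelihood is nearly flat along
the direction that scales all `(a_k, b_k)` by a common factor: in the
high-intensity regime `arsinh(u) ~ log u`, so a common scale change is
absorbed by the free peptide means; only the *variance compression* of
low-intensity spots (where the transform is locally linear rather than
logarithmic) identifies the overall scale.  Quasi-Newton steps barely move
along this ridge, so each solve is followed by an explicit one-dimensional
search along it.  Consequently, scale recovery to within 10% requires data
with substantial low-intensity mass; the parameter-recovery test generates
about half its peptide means in the curved region, which mirrors real
arrays where many substrates stay near background.  Second, robustness:
an optional least-trimmed-squares loop (default `trim_fraction` 0.1)
excludes the spots with the largest squared residuals and refits until the
excluded set stabilizes, preventing truly differential peptides — which
violate the common-mean assumption — from dragging the calibration.
Convergence is declared when the trim set is stable and the relative
parameter change falls below `tolerance` (default 1e-8, relative change
floored at unit magnitude); non-convergence flags the fit rather than
raising.  Initialization is scale-free: `a = 0`, `b = 1/mad(x)` per array.

Normalized values are left on the arsinh scale; no back-transform is
applied.

## Technical-replicate consistency filter

Per (array, peptide) the statistic is `chi2 = (R-1) s^2 / sigma_hat^2`
with `s^2` the replicate sample variance on the normalized scale and
`sigma_hat^2` a robust array-wide scale: the median of `s^2` over that
array's peptides divided by the median of the chi-square(R-1)/(R-1)
distribution, so the statistic is calibrated under homogeneous noise while
outlier peptides cannot inflate the denominator.  The p-value is the upper
chi-square tail with R-1 degrees of freedom.  The source procedure writes
the threshold ambiguously as "chi2 < 0.01"; a *statistic* below 0.01 would
flag the most consistent peptides, contradicting the stated intent of
removing peptides that "showed variation", so the threshold is read as the
test's p-value (remove when p <= 0.01).  A peptide failing on any array of
the dataset under comparison is removed from that whole comparison, since
fold changes, tests and clustering need a common peptide universe.  The
exact construction inside the original online pipeline (PIIKA) is cited,
not published; this statistic is an interpretation and is labelled as such.

Operating characteristics under the synthetic model (contrast scale, 10
arrays): planted inconsistent peptides (25x variance) are removed
essentially always; the dataset-wide false-removal rate is ~6% — the
family-wise accumulation `1-(1-r)^10` of a per-array rate `r ~ 0.6%` that
is itself conservative relative to the nominal 1% because contamination
inflates the median-based scale.  Filtering is monotone in alpha, and the
statistic is invariant to location shifts and scales linearly with a
single peptide's replicate variance.

## Differential phosphorylation

Technical replicates of kept peptides are averaged per array, giving one
value per biological subject; Welch's two-tailed unequal-variance t-test
(Welch-Satterthwaite degrees of freedom) compares treatment to the
tissue-matched PBS control at raw p < 0.05 per peptide.  No
multiple-testing correction is applied at the peptide level — this
reproduces the source procedure faithfully and is a property, not a bug to
fix; the null type-I error of the full chain (normalize -> filter -> test)
is verified to sit in [0.03, 0.07].  Degenerate inputs: two zero-variance
samples with equal means give p = 1; zero variance with unequal means gives
the p = 0 limit.

Fold change uses the signed-ratio convention of the printed tables (values
never in (-1, 1)): the treatment/control ratio `r` of mean intensities is
reported as `r` when `r >= 1` and `-1/r` otherwise.  Because arsinh values
can be non-positive, both group means are back-shifted by the same
dataset-wide constant `1 - min(profile values)` before the ratio; the
shared shift preserves the treatment/control antisymmetry `FC -> -FC`.
This convention is the largest interpretive choice in the package: the
source text delegates the formula to an earlier paper, and the convention
adopted here is the one consistent with the structure of the printed
values.

## Clustering and embedding

Array and peptide profiles are clustered agglomeratively with distance
`1 - Pearson r` and WPGMA (McQuitty) linkage: the distance from a merged
cluster to any other is the unweighted average of its two members'
distances.  Ties in the minimum-distance search break toward the
lexicographically smallest pair of cluster indices, making the merge
sequence deterministic; the naive O(n^3) implementation is cross-checked
against the reference `scipy` "weighted" linkage on tie-free matrices.
Dendrograms serialize to Newick with ultrametric branch lengths
(leaf-to-root path = merge height / 2), and the heatmap export permutes
the profile matrix to both leaf orders.

The 2-d embedding is exact t-SNE (per-point Gaussian bandwidths calibrated
by binary search to the target perplexity; Student-t low-dimensional
affinities; gradient descent with momentum and early exaggeration), run
`n_restarts` times (default 100) from random initializations with restart
seeds fixed at 1..n_restarts, keeping the restart with the lowest final KL
divergence.  Defaults: perplexity `min(30, floor((n-1)/3))`, 1000
iterations, learning rate 200, early exaggeration 12.  The exact method is
used deliberately instead of tree-based approximation: at a few dozen
arrays it is cheaper and removes the approximation hyperparameter while
optimizing the identical objective.

## Pathway over-representation

Differential peptides map to their proteins' UniProt accessions (multiple
phosphosites on one protein count once).  The universe is the accession set
of all consistently phosphorylated peptides — the testable background of
the measurement, a deliberately conservative choice against testing the
whole proteome.  Each gene set from a user-supplied GMT file, intersected
with the universe, is tested with the one-sided hypergeometric upper tail
(computed in log space); Benjamini-Hochberg adjustment runs across all
tested sets, with significance at adjusted p < 0.05.  Membership databases
version quickly, so the published pathway p-values are reproducible in
shape but not in value; the GMT input makes the structure reproducible
without a live database.

## qPCR fold change

CT tables are reduced technical duplicates -> biological samples -> group
means; `dCt = mean CT_target - mean CT_reference` per group,
`ddCt = dCt_treated - dCt_control`, fold change `2^-ddCt` with
amplification efficiency fixed at 2 (the method's defining assumption;
efficiency-corrected models are out of scope).  The reference gene is
selected as the candidate with minimum CT standard deviation across all
samples — the simplest defensible stability criterion; because the
reference cancels in ddCt, a constant CT shift of any sample leaves the
fold change unchanged.

## Problem sizes and tolerances in the test suite

Monte-Carlo checks run at the sizes the package documents as its standard
verification: null calibration over 3 simulated studies (about 3,000
peptide-tests), consistency-filter recovery over 10 contrast-scale
datasets, differential recovery over 20, transform-scale recovery over 5,
embedding recovery over 3 planted two-cluster datasets (one with the full
100 restarts), and ddCt recovery over 10 repeats at n = 6 with CT noise
sd 0.3.  Numerical comparisons: Welch p-values match the reference
implementation to 1e-10; hypergeometric tails match exhaustive draw
enumeration exactly for every instance with N <= 12; WPGMA merge traces
match a hand-executed table; transform identities hold to 1e-9.

## Known limitations

- The consistency-filter statistic and the fold-change formula are
  documented interpretations of procedures whose exact definitions live in
  unpublished or cited-only software.
- The generator's Gaussian additive tail leaves mild residual
  heteroscedasticity after normalization (post-transform sd/mean Spearman
  around -0.05), which nudges the filter's dataset-wide false-removal rate
  above its per-array nominal level.
- Printed-table fixtures are transcriptions, typos included; they are data,
  not corrections.  The source text's own counts disagree with its tables
  in places (87 vs 86 printed rows for the muscle table; 98 vs 100 for the
  node table across sections); the fixtures follow the printed tables.
- ORA reports accession-level counts; whether the original database counted
  genes or peptides per pathway is ambiguous, so both the accession overlap
  and the contributing peptide count are derivable from the outputs.
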