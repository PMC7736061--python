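# Methods

## Scope and data model

The package operates on biallelic SNP genotype matrices (loci × samples,
calls coded 0/1/2 as the count of the ALT allele, with a dedicated missing
sentinel). Which allele counts as "A" in the frequency formulas is the ALT
allele throughout; both FST and δ are invariant to this choice. The
canonical on-disk form is a loci-major CSV (missing written as empty,
`NA` accepted on read); VCF 4.x is supported as an interchange path (GT
field only, multiallelic records skipped with a warning, 1-based
coordinates preserved).

## Quality control

Two locus filters run sequentially: MAF < 0.01 strictly, then — among
survivors — missingness > 0.25 strictly. Running MAF first makes the two
removed sets disjoint and the accounting identity
`n_input = n_removed_maf + n_removed_missing + n_retained` exact, and
pins down the ambiguous boundary cases: a locus at exactly MAF 0.01 or
exactly 25% missing is kept. MAF is always computed over the samples
present in the matrix at call time; the caller controls the sample set
(e.g. core populations only) by subsetting first.

## Pairwise differentiation statistics

Per locus and population pair, FST = (HT − HS)/HT with HT the expected
heterozygosity 2p̄(1−p̄) at the unweighted mean frequency and HS the
unweighted mean of the two within-population heterozygosities; δ is the
absolute frequency difference. No small-sample bias correction is applied:
these are descriptive ranking inputs, not reported estimators. When both
populations are fixed for the same allele (HT = 0), FST is defined as 0 so
that rankings are total. Frequencies undefined in a population (zero calls
at a locus) propagate as undefined and the affected (pair, locus) rows are
omitted from the statistics table.

## Panel construction

The panel is the de-duplicated union of per-pair top-N lists (default
N = 75) under each requested metric. Ties in the metric are broken by locus
identifier ascending — the ranking needs a deterministic total order for
reproducible panel sizes, and identifier order is self-documenting. Because
both the ranking and the final ordering are deterministic, the panel is
invariant to the row order of the input table. Provenance (which pair,
metric and rank selected each locus) is retained; it is what makes the
deliberate ascertainment bias of such panels inspectable.

## DAPC

Preparation transposes to samples × loci, imputes missing calls with the
locus mean call, and centers each locus by that mean; loci are not scaled
(allele-count variance is already comparable across loci, and scaling
would up-weight rare variants). PCA is computed once by thin SVD; retaining
n_pca components is a column slice. The discriminant step solves the
generalized symmetric eigenproblem B v = λ W v on PC scores, with B/W the
between/within-group scatter (covariance scaling); eigenvectors are
W-orthonormal, so discriminant axes are orthogonal in the within-group
metric. At most min(n_groups − 1, n_pca) axes exist; requests beyond that
are capped. A within-scatter minimum eigenvalue below 1e−8 (tiny groups,
large n_pca) triggers a logged ridge of 1e−8 on the diagonal. n_pca
requests beyond matrix rank are reduced with a warning.

**Posterior model.** New samples are imputed/centered with the *training*
means, projected through loadings and axes, and given posterior
membership ∝ exp(−½d²) for the Euclidean distance d to each group centroid
in discriminant space, with uniform priors. This isotropic-Gaussian rule is
the package's documented choice; it makes argmax-posterior identical to
nearest-centroid, which the tests verify by brute force.

**Choosing n_pca.** Stratified cross-validation: per replicate, 75% of each
group trains the model and the holdout is predicted; replicate success is
the mean over groups of per-group correct fractions; the score is
RMSE = √(mean over replicates of (1 − success)²), minimized over the
candidate grid with ties going to the smaller candidate (fewer parameters).
The a-score alternative subtracts from the training reassignment success
its mean under random label permutations, penalizing overfit; the candidate
maximizing it is chosen.

**Unsupervised clustering.** k-means (scikit-learn, best of n_start
initializations) on retained PC scores, scored by
BIC(k) = n·ln(W_k/n) + k·ln(n) with W_k the total within-cluster sum of
squares. The argmin k is advisory: at realistic sample sizes the k·ln(n)
penalty is weak relative to n·ln(W_k), so curves flatten or decline —
matching the behaviour typically seen on admixed strain collections. The
tests therefore verify the two-cluster optimum in a small-sample regime
where it is decisive.

## Assignment rules

Individuals: argmax posterior strain; unassignable when missing more than
25% of the model's loci (the panel-missingness reading of "unassigned" —
the alternative, a posterior-probability floor, is not used) or on an exact
posterior tie. Hatcheries: modal strain over assignable individuals;
modal_fraction excludes unassignable fish from the denominator; status is
`assigned` only when modal_fraction ≥ threshold (default 0.75) and the mode
is unique — ties surface as `tie`, never silently broken. Agreement
statistics between hatchery-identified and DAPC-assigned strains are
computed only over cases whose identified strain is one of the model's
populations; unknown-strain hatcheries are reported separately. Group-level
assignment maps strains to the four ancestral groups (total map required;
unmapped labels are an error) and re-runs the same machinery; collapsing
posteriors by group-sum and re-mapping assigned labels preserves
per-hatchery counts, which the tests check as a commutation property.

Core-population validation masks a stratified 25% of each population,
fits on the remainder, predicts the masked fish, and averages tallies over
10 repeats into a row-percentage confusion matrix. With `n_pca="auto"` the
retained-PC count is chosen once per call by stratified cross-validation on
the full data and reused across repeats; re-running the selection inside
every repeat would multiply cost roughly forty-fold without changing the
statistic being validated.

## Synthetic data

The generator emulates the structure the pipeline assumes, not any real
dataset:

- **Divergence** follows the Balding–Nichols model — drifted frequency
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F), mean p, variance F·p(1−p). It is the
  standard single-parameter divergence model and matches the tool's
  FST-based logic; multi-generation binomial drift would add parameters
  without adding test power.
- **Composite strains** are convex combinations of parent frequency vectors
  (followed by their own drift), modelling hybrid strains at the
  allele-frequency level rather than by pedigree — enough to reproduce the
  multi-cluster behaviour of heterogeneous composite populations.
- **Genotypes** are Hardy–Weinberg draws, Binomial(2, p); missingness is
  uniform at random (platform-structured missingness is out of scope).
- **Default design**: ten core strains with the reference sample counts
  (99, 47, 47, 94, 172, 21, 122, 94, 120, 36 — total 852); divergence
  F = 0.15 per strain from a shared founder, with BEST, Nile × Moss and
  Molobicus as admixtures of GIFT-WF / FaST / O. mossambicus ancestry
  echoing their hybrid origins; founder frequencies uniform on
  [0.05, 0.95]; 2% missing calls; 200 hatcheries of ~10 broodstock each
  (mirroring the scale of a two-country hatchery survey and keeping
  binomial noise on hatchery-level rates small), each drifted at F = 0.02
  from its source strain, with a configurable probability that a hatchery's
  identified strain is wrong.
- **Scale**: the default fixture uses 1,000 loci — the desk scale at which
  the whole pipeline (QC → ranking → panel → DAPC → assignment) runs in
  seconds; genome-scale locus counts are one constructor argument away and
  change nothing structurally.

What passing tests show: the pipeline recovers truth under its own model
assumptions (independent loci, HWE, uniform missingness, drift-only
divergence). What they do not show: robustness to linkage, selection,
platform-biased missingness, or hatchery stocks mixed from several strains
— with real data, the confidence threshold is doing the work the tests
cannot.

## Numerical choices

- Rank tolerance: singular values below 1e−9 × s₁ are treated as zero.
- Ridge on within-group scatter: 1e−8, logged when applied.
- Posterior computation subtracts the row-max log-density before
  exponentiating (no overflow for distant samples).
- Argmin/argmax ties resolve toward the smaller candidate or
  lexicographically smaller label everywhere.
- All stochastic operations take an explicit seed; CLI defaults are fixed
  constants so runs are reproducible, and every CLI stage writes a manifest
  (input hashes, parameters, seed, version).

## Known limitations

- The two-population FST form is not a multi-population or genome-wide
  estimator and is not meant to be reported as one.
- Posterior probabilities are calibrated only under the isotropic-Gaussian
  assumption; they order candidates correctly but should not be read as
  frequentist assignment confidence.
- The BIC curve rarely has a sharp minimum at realistic n; treat chosen_k
  as advisory and inspect the curve.
- Unsupervised clustering with very large requested PC counts is capped at
  matrix rank (a warning is emitted); requesting more PCs than samples
  support is a no-op by construction.
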