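# Methods

## Expression profiles

Raw single-cell matrices enter as genes × cells with one label per cell and
a declared unit (count, UMI, CPM, RPKM, TPM).  Read counts are converted to
counts-per-million so that sequencing depth differences between cells do not
masquerade as expression differences; UMI counts, RPKM and TPM are used
as-is (they are already depth- or length-normalized in the sense their
producers intended).  Expression is then log₂(x+1)-transformed **per cell**
and averaged over the cells of each labelled type — log first, then
average, following the per-cell-type mean of log expression

    E_c = (1/n) Σᵢ log₂(eᵢ + 1)

and the dataset average A = (1/N) Σ_c E_c over the N cell types.  The
`Average` column is recomputed whenever cell types are subset
(`subset_profile`), because A defines what "specific" means: conditioning
on the average over brain cell types only asks a different question than
conditioning on a whole-body average, and both are legitimate.

Cell-level quality control is deliberately out of scope: it is
dataset-specific, so the package assumes QC-ed input and offers only a
minimum-cells-per-type filter (default 1).  One label column is consumed
per run; if a dataset carries multiple annotation levels, the caller picks
one per run and may build several profiles.

Gene identifiers are harmonized through user-supplied two-column tables
(ortholog or symbol/alias maps).  Unmapped genes are dropped; when two
source genes map to the same target, both are dropped — a duplicated target
row is uninterpretable in a gene-keyed regression, and dropping is the only
choice that cannot silently double-count.

Tissue-level TPM matrices pass through the same container: genes kept when
their per-tissue average TPM exceeds 1 somewhere, values winsorized at 50
(values above 50 set to exactly 50, an upper winsorization that tames the
heavy right tail of TPM before the log), then log₂(x+1).

## The gene-property regression

`GenePropertyModel` regresses gene-based Z-scores (probit transform of the
gene-based P, so smaller P means larger Z) on an intercept, the cell type's
expression E_c, the dataset average A, and technical covariates B (gene
length and log length when present in the statistics file).  The test of
interest is one-sided, β_E > 0: trait association increasing with
*specific* expression.  P-values come from the Student t distribution with
df = n − k rather than the normal — exact finite-sample behaviour at
desk-scale gene counts costs nothing.

Conditional variants reuse the same machinery:

* within-dataset joint model: intercept + E_a + E_b + A + B — the one-sided
  P of each cell type's coefficient is its conditional P given the other;
* cross-dataset (CD) marginal model: intercept + E_c₁ + A₁ + A₂ + B — the
  other dataset's average enters so that the two datasets' general
  expression levels are both controlled;
* CD conditional model: intercept + E_c₁ + E_c₂ + A₁ + A₂ + B.

All fits use the intersection of genes present in every input of that fit
and report `n_genes_used`, so proportional-significance comparisons across
fits can note differing gene sets.  A minimum of 50 intersecting genes is
enforced (configurable).

An optional gene–gene correlation matrix (LD-induced correlation of
gene-based statistics) turns the fit into generalized least squares: the
correlation is ridge-stabilized (ε = 1e-6 on the diagonal), Cholesky
factored, and both the response and every design column — intercept
included — are pre-multiplied by the inverse factor, after which ordinary
least squares on the whitened system equals GLS on the original.  This is
an approximation to a full LD-aware gene analysis, which is out of scope;
by default no correlation is supplied and the fit is OLS.

Collinearity is handled two ways.  Designs with a rank deficiency raise
`CollinearityError` naming the dependent columns (e.g. a one-cell-type
profile, where E_c equals A exactly).  For pairwise conditional fits the
two tested expression columns are first residualized on the remaining
covariates; if their correlation exceeds 0.999 the pair is flagged
`colinear` and its conditional P-values are withheld rather than reported
as meaningless near-zero-variance estimates.  The 0.999 level flags
duplicates without destroying analyses of merely similar cell types.

## The three-step workflow

**Step 1.**  Marginal fits for every cell type of every dataset; the
Bonferroni threshold is α divided by the total number of dataset–cell-type
combinations tested (all tests, not per dataset).

**Step 2.**  Per dataset, significant cell types are visited in order of
ascending marginal P.  The retained list starts with the top cell type;
each candidate is conditioned pairwise against every retained cell type
(the Methods-style pairwise rules, not a single joint model over all
retained — the joint alternative would conflate the pairwise PS thresholds)
and kept only when every comparison retains it.  Pair classification uses
proportional significance PS(a,b) = −log₁₀ p(a|b) / −log₁₀ p(a)
(P-values floored at 1e-300), with "a" the smaller marginal P:

| # | condition (after any flip)                      | outcome |
|---|--------------------------------------------------|---------|
| 1 | PS_ab ≥ 0.8 and PS_ba ≥ 0.8                      | independent — retain both |
| 2 | PS_ab ≥ 0.5 and PS_ba ≥ 0.5                      | partially joint — retain both |
| 3 | PS_ab < 0.2 and PS_ba < 0.2                      | jointly explained — retain a |
| 4 | PS_ab > 0.8, PS_ba < 0.5, p(b|a) < 0.05          | a drives b, residual signal in b — retain a |
| 5 | PS_ab ≥ 0.5 and p(b|a) ≥ 0.05                    | a fully drives b — retain a |
| 6–7 | mirrored 4–5 after the flip rule               | b drives a — retain b |
| 8 | anything else                                    | ambiguous — retain a |

The flip rule: when PS_ab < 0.2 while PS_ba ≥ 0.2, the nominally weaker
cell type is the driver and the roles are exchanged before classification.
Scenario 8 covers threshold gaps the rules leave open (e.g. PS 0.3/0.3);
retaining the stronger marginal there is the conservative default and the
pair log records every decision for audit.  When a flipped driver scenario
says the candidate drives an already-retained cell type, that cell type is
removed from the retained list — forward selection honours the flip.

**Step 3.**  All pairs of step-2 survivors are compared: cross-dataset
pairs through the CD marginal/conditional models (CD PS per entity),
within-dataset pairs through the step-2 joint model.  Forward selection by
step-1 marginal P: a cell type founds a new cluster only if its PS against
*every existing founder* exceeds 0.5 in both directions; otherwise it joins
the first founder that explains it.  Founders-only conditioning matches the
"mostly independent" semantics of the summary counts; conditioning on all
prior cell types is a stricter alternative not implemented.  Collinear
pairs are treated as dependent.  Each entity in a cross-dataset pair also
carries an `avg_explained` flag: true when the CD marginal −log₁₀ P is
below half the step-1 marginal −log₁₀ P, i.e. the other dataset's average
expression alone explains ≥ 50% of the association.

Multiple-testing correction applies at step 1 only; steps 2–3 use the
nominal thresholds embedded in the PS rules (0.05 for the reverse
conditional P).

Trait-similarity reporting correlates (Spearman) the −log₁₀ marginal-P
vectors of multiple traits over a common dataset:cell-type axis, orders
traits by average-linkage hierarchical clustering on 1 − ρ, and, given a
cell-type→category annotation, reports per-trait proportions of significant
cell types per category.

## Specificity representations and dataset comparison

The S score S[g,c] = E[g,c] / Σⱼ E[g,j] is the proportional-expression
specificity used by gene-set style approaches; rows that are all zero stay
all zero.  Equal-count binning ranks the m nonzero values ascending
(average ranks on ties — deterministic and permutation-invariant; the
original binning procedure does not specify tie handling) and assigns
bin = ⌈rank · n_bins / m⌉, so bin sizes differ by at most one and genes
with value 0 keep bin 0: 40 bins yield 41 distinct values, 100 bins 101.
Binning is invariant to strictly monotone transforms of the nonzero values,
which is the point — cross-dataset comparisons run on within-dataset ranks.

Dataset similarity is the Spearman correlation of two datasets' 100-bin
binned average expression over shared genes.  Cell-type similarity first
removes the dataset average (residuals of E[·,c] on intercept + A, the
"residual specificity"), then bins the residuals into 100 bins *without*
the zero carve-out — the zero rule is stated for expression values, and a
residual of zero has no special meaning — and correlates.  Group contrasts
(e.g. within- vs between-species correlations) use the two-sided
Mann–Whitney U test, exact for small groups, normal approximation with tie
correction otherwise.  The 2-D overview map is t-SNE (perplexity 30 by
default, reduced with a warning when there are fewer than 3× perplexity
entities) run `restarts` times with sub-seeds derived from one seed,
keeping the run with minimal Kullback–Leibler divergence.  Whether the
embedding should consume binned residual-specificity vectors or raw binned
averages is genuinely ambiguous; both are supported (`level` /
`--features`), neither asserted as canonical.

The top-decile gene-set constructor returns the ⌈0.10 · n⌉ highest-scoring
genes with boundary ties broken by gene ID, for handover to SNP-annotation
based tools; running those tools is out of scope.

## Synthetic data generator

`FixtureSpec` describes a study: per-gene baseline log₂ expression drawn
N(1, 1) (a log-normal on the natural scale), sparse expression programs
(default 5% of genes, log₂-scale additive shifts of scale 2 × U(0.5, 1.5))
planted into named (dataset, cell type) members, per-cell Gaussian log₂
noise (default sd 1), and uniform zero inflation (default 0.2 of entries —
a moderate dropout level; per-profile averages remain informative).  Cell
counts per type default to 30.  Gene-based Z-scores are generated in the
model's own causal direction: effect × standardized program loading summed
over causal programs, plus N(0, 1) noise — the unit normal is the exact
null scale of a Z-score, so null fixtures are null by construction and the
calibration tests are meaningful.  (The Z noise scale is a separate
parameter from the expression noise; coupling them would tie two unrelated
noise sources to one dial.)  A simulated gene-length confounder (log-normal
around 10 kb) exercises the B matrix, with optional leakage into Z.  All
generators are pure functions of the spec, including its seed; a truth
record of planted programs and effects accompanies every draw.

The generator reproduces the covariance structure the regression consumes —
rank structure across genes, shared programs across datasets, dropout — and
nothing else: no droplet chemistry, no batch-specific capture efficiency,
no cell-level heterogeneity within a type beyond Gaussian log noise.
Passing tests therefore demonstrate correctness of the statistical
machinery on data satisfying its assumptions, not robustness to every
artefact of real scRNA-seq.

The confounded fixture used for the model-comparison demonstration gives
each gene one favored cell type whose concentration weight is
rank-anticorrelated with the gene's mean expression at a chosen coupling —
the direction real data show: ubiquitously high-expressed housekeeping-like
genes spread evenly, specific genes sit lower.  For any single cell type
the S score of the non-favored majority then rises with mean expression,
so binned S scores correlate positively with average-expression bins while
the average-conditioned regression on the same profile stays calibrated
under the null.  Mean-independent dropout alone reproduces the same
confounding through the zeros (a dropped entry sends S to bin 0 and lowers
the recomputed average), most visibly with few cell types.

## Numerical choices and problem sizes

* Least squares via `numpy.linalg.lstsq`; standard errors from the
  pseudo-inverse of XᵀX; one-sided P from `scipy.stats.t.sf`.
* P-values floored at 1e-300 inside PS ratios; PS may exceed 1 (conditional
  signal stronger than marginal), which step 3 reports as-is.
* Forward-selection ties (equal marginal P) break by dataset ID then
  cell-type name, ascending; the workflow is deterministic given its
  inputs.
* Test-suite simulations use 800–2,000 genes, 3–10 datasets of 5–20 cell
  types and 10–60 cells per type, 200–2,000 replicates for calibration and
  20 seeds for recovery scoring — sizes at which every statistical check
  has comfortable power while the whole suite runs in well under a minute
  of regression fitting.

## Known limitations

* The GLS decorrelation approximates, not replicates, a full LD-aware
  gene-level analysis; computing gene-based statistics from SNP-level GWAS
  is out of scope.
* Step 2 conditions pairwise, not jointly over the full retained set;
  step 3 conditions on cluster founders only.  Both are documented choices
  with stricter alternatives.
* Whether additional shrinkage or weighting beyond the stated covariates
  belongs in the gene-property fit is left open; none is applied.
* The scenario table reconstructs the pairwise decision rules from their
  prose definitions; the `ambiguous` bucket and all thresholds are
  configurable (`Thresholds` / YAML) precisely because the gaps are real.
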