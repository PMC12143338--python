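# Methods

This note documents the statistical machinery implemented in `immunogate`,
the defaults it ships with and why, what the synthetic-data generator does
and does not emulate, and the numerical choices that affect results.

## Saturation and QC

Sequencing saturation is defined per cell as `1 − #UMIs/#reads`, where reads
are all transcriptomic reads assigned to the cell (the generator defines
"reads" this way too; whether intronic/unmapped reads should count is a
pipeline-dependent choice the statistic itself does not fix). Saturation is
the fraction of reads that re-sampled an already-seen molecule, so it
measures sampling completeness in a way that adapts across cell types with
very different RNA content. The QC contract: UMI and feature counts are
filtered with **inclusive** ranges (defaults 0–20,000 UMIs, 200–5,000
features), saturation with **strict** floors (RNA > 0.35, ADT > 0.1) — a
cell at exactly 0.35 is dropped. Cells without ADT data skip the ADT rule,
since not every lane carries antibody tags. Rules are evaluated in a fixed
order (UMI, features, RNA saturation, ADT saturation); the first failure is
the recorded primary reason and all failures are tallied, so relaxing any
threshold can only grow the kept set and re-filtering a filtered bundle is a
no-op.

## Normalization

Log normalization is `x′ = ln(1 + 10⁴·x/T)` with `T` the cell's total count;
it preserves the zero pattern and the within-cell ordering of genes.
Z-scaling uses the sample SD (n−1) and clips at ±10, the long-standing
defaults of the pipelines this mirrors. Variable genes are ranked by the
dispersion `ln(var/mean)` of the exp-normalized (linear per-10k) values,
standardized within 20 equal-occupancy bins of log-mean; quantile bins are
used rather than equal-width bins because a lone high-mean gene would
otherwise form a singleton bin with an undefined z-score. A gene is selected
at standardized dispersion ≥ 0.5 (or the top `n_top` after exclusion). The
exclusion list (glob patterns; packaged default covers class-I MHC symbols,
which are unreliable against a single reference in outbred primates, and
ribosomal genes, which batch-shift) affects selection only — excluded genes
stay in every matrix.

ADT counts are CLR-normalized independently per lane to absorb per-lane
staining/depth effects: for a vector x, `clr(x)ᵢ = ln(1 + xᵢ/g(x))` with
`g(x) = exp(Σ_{xⱼ>0} ln(1+xⱼ)/n)` and `n` the full vector length. The default
margin transforms each tag across the cells of a lane; the per-cell margin is
available because the field's implementations disagree about which margin the
conventional "margin = 1" denotes. Note the pseudo-counted geometric mean
makes `clr([e−1, e−1]) = ln(2 − 1/e) ≈ 0.4899`.

## Rank-based module scores

For a module of n genes in a matrix of G genes, each cell's genes are ranked
by decreasing expression with average ties; module ranks are capped at
`max_rank + 1` (default 1,500, the scoring convention this follows) and the
score is `max(0, 1 − U/(n·max_rank))` with `U = Σ r′ᵢ − n(n+1)/2`. Because
only within-cell ranks enter, the score is invariant to library size and to
any monotone transform, which is what makes module definitions portable.
Zero-expression genes share the average of the remaining ranks; provided the
matrix has substantially more than `max_rank` genes (the generator default is
5,000), an unexpressed module is capped to ≈ 0. Two caveats are documented
rather than hidden: module genes absent from a matrix are treated as
maximally lowly expressed (rank `max_rank+1`), and the intuitive rule
"adding the cell's weakest gene cannot raise the score" holds exactly only
while the score exceeds `n/max_rank`; below that, both scores sit in the
clamped near-zero tail.

Dot-plot summaries report, per group and gene, the mean of the linear
per-10k expression, the z-score of those group means across groups (sample
SD; zero with a single group), and the fraction of cells with count > 0. ADT
positivity is called per (tag, lane) by an exact deterministic 1-D two-means
split of the CLR values (sorted prefix sums; no random initialization);
lanes with < 10 cells or cluster separation < 0.5 CLR units are called
all-negative — a mixture fit was deliberately avoided to keep the call
deterministic and dependency-light.

## Coarse annotation

Gating: a cell passes a lineage gate when all its positive modules score
≥ threshold (default 0.2) and any negative modules score below theirs;
exactly one passing gate assigns the label, several give `ambiguous`, none
`unassigned`. Optional smoothing averages scores over 30 nearest neighbours
in 30-component PCA space (off by default). The confidently gated cells are
balanced by down-sampling without replacement (classes smaller than the cap
are taken whole; classes with fewer than 25 confident cells are excluded
from training entirely, because a handful of spuriously gated guard-lineage
cells would otherwise drag every class down to their size). The classifier
is an L2-regularized multinomial logistic model over all genes
(scikit-learn, fixed seed, deterministic); cells are labelled by the argmax
class when its probability reaches τ = 0.5, else `unassigned`.

Doublet filtering deliberately uses the raw module scores, not classifier
probabilities: a multinomial model normalizes co-occurring identities away,
while co-positivity of two mutually exclusive lineage modules is precisely
the doublet fingerprint. A cell is flagged when both members of any
incompatibility pair pass their gate thresholds; the shipped default pairs
are B × T/NK, T/NK × erythrocyte, B × myeloid and T/NK × myeloid, and the
rule file is editable.

## Effector-differentiation score

Derivation uses sorted reference populations (the packaged vocabulary:
CD4/CD8 naive, central/transitional memory, effector memory, and γδ).
Pairwise two-sided Wilcoxon rank-sum tests (exact when both groups have ≤ 8
cells and no ties, otherwise the normal approximation with midrank tie
correction) are BH-corrected within each pair; candidates need adjusted
p < 0.05, |log2FC| ≥ 0.25 (log2FC = difference of ln-normalized means / ln 2)
and detection in ≥ 10 % of either group. Robust markers are the candidates
expressed in ≥ 50 % of the population they mark (the "high fraction"
threshold is configurable; 0.5 is this package's choice). The marker genes
are z-scored over the derivation cells (constants dropped with a warning)
and the unit-norm first principal axis of that reduced space — computed by
SVD, i.e. correlation PCA on markers only, not projected to all genes — is
oriented so the effector-memory anchor population scores above the naive
anchor.

The signature stores genes, loadings, per-gene μ and σ, orientation anchors
and thresholds, so application elsewhere is the weighted sum
`Σ w_g (x_g − μ_g)/σ_g`: missing genes contribute 0 (equivalent to imputing
the derivation mean), reported coverage is the present fraction of |w| mass,
and cross-species use is supported by optional case-insensitive symbol
matching only (no orthology inference). Because the absolute scale of a PC1
is tied to its own derivation, thresholds live inside each signature: the
packaged signature carries the reference effector threshold 6.0 (strict >,
so a score of exactly 6 is intermediate), while freshly derived signatures
default to quantile-calibrated thresholds (25th percentile of the naive
anchor, 75th of the effector anchor). The packaged file
`eds_signature_synthetic.json` is a **synthetic** stand-in: 175 genes derived
from the bundled sorted-reference simulator at a fixed seed, mirroring the
size and structure of a sorted-reference signature without encoding any real
dataset.

## TCR rules

Contigs are dropped when the CDR3 is absent, the contig is not full length,
or any of V/J/C is uncalled; segment loci are parsed from the first three
characters plus the positional letter (TRAV/TRBJ/TRGC/...), anything else is
`unparseable`. V/J/C loci must agree, with two permitted chimeras — TRDV with
TRAC (kept as TRA) and TRAV with TRDC (kept as TRD) — whose chain is always
reassigned from the constant region; the J segment of an exception record
must come from one of the two loci involved. Productivity is recorded but
not required. Clonotypes are keyed by (locus, CDR3 amino-acid sequence) by
default (V/J-inclusive keying by flag); a cell contributes its highest-UMI
record per chain. Clonality: `public` if seen in ≥ 2 subjects, else
`expanded` if ≥ 2 cells in its single subject, else `singleton`
(public > expanded > singleton). Top-expanded lists sort by descending cell
count with lexicographic CDR3 tie-breaks. Cell categorization combines chain
presence (αβ, γδ, both) with CD3 (any of CD3D/E/G > 0) and CD16 (FCGR3 > 0)
RNA into six classes.

## Tissue enrichment

For a labels × tissues table, expected counts are `E = R·C/N`; Pearson
residuals `(O−E)/√E` (0 where E = 0) and adjusted residuals
`r/√((1−R/N)(1−C/N))` are both reported — "standardized" is ambiguous in the
field, and the adjusted (Haberman) variant is the one with unit variance
under independence, hence the one to read against N(0,1). The chi-square
statistic is Σ of squared Pearson residuals. "Linear scaling" divides the
adjusted residuals by max|s| for display parity and never replaces the
unscaled values. Composition fractions are column-normalized observed counts.

## Synthetic data generator

The generator emulates the structure the pipeline consumes, with ground
truth for every claim: log-normal baseline expression in three tiers
(filler: lognormal(0, 1.5); broadly expressed gradient-program genes:
lognormal(1.2, 0.4); near-off lineage markers: lognormal(−1, 0.4));
population markers multiply the baseline by a configured fold (lineage
markers use folds of 40–100 so that on-state markers sit at ~0.2 % of the
transcriptome, matching empirical abundances of genes like CD3D or MS4A1);
T-lineage cells carry a latent coordinate d ~ Uniform on a per-population
range, driving the program genes via five response laws (linear up for the
S100A/memory program, quadratic up for GZMB/GZMH, linear down for
CCR7/SELL and the naive program, quadratic down for GZMM, and a 4d(1−d)
peak for GZMK). Counts are negative binomial via gamma–Poisson mixing with
size θ = 10 around library-size-scaled relative expression (libraries
lognormal(ln 6000, 0.25)); reads are the UMI total plus a
negative-binomial(UMIs, p = 0.35) number of duplicates — the sum of
per-molecule shifted-geometric draws — so reads ≥ UMIs by construction and
saturation centres near 0.65. Doublets are a deterministic `round(rate·n)`
count (default 5 %) formed by adding the counts of a second parent from a
different population, so fixtures are exactly checkable. ADT tags are
negative binomial around background/positive means (5/60) with a
multiplicative lane factor. Clonotypes: 40 clones per subject across 4
subjects with power-law (exponent 1.5) sizes, each clone guaranteed one
cell; 10 % of clones draw their primary CDR3 from a pool shared across
subjects, producing public clones. All draws flow from one seeded Generator
in a fixed order, so identical configs give bit-identical outputs across
processes.

Two presets define the study conditions used in tests and in
`scripts/acceptance.py`: `coarse` (six populations × 500 cells — T stages at
d ∈ [0.02,0.25], [0.35,0.65], [0.75,0.98], CD16⁺ NK, B, myeloid — 5,000
genes) and `sorted` (seven sorted T populations × 500 cells with CD4/CD8/γδ
branch programs layered on the shared gradient, ~185 differential genes, so
selecting the top 175 markers is a genuine selection). These sizes keep the
whole suite under a few minutes on one CPU while leaving wide statistical
margins.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: ambient RNA and index hopping, empty droplets,
cell-cycle and stress programs, batch effects beyond a scalar ADT lane
factor, gene–gene correlation beyond the shared latent programs, isoform or
intronic structure, and hash-based multiplexing artifacts. Annotation
accuracy and doublet-detection rates on simulated data are upper bounds for
real tissues.

## Numerical choices and degenerate inputs

Sample SD (n−1) everywhere a z-score is formed; constant genes z to 0 (or
are dropped from PCA with a warning). Wilcoxon p-values of constant genes
are treated as 1. The exact 1-D two-means split breaks ties toward the
smaller split and is wholly deterministic. Zero-total cells are a hard error
naming the cell; empty groups, zero-count tissues, and single-row/column
tables degrade to warnings with zero-valued outputs. Serialization
round-trips (classifier JSON, signature JSON, count bundles) are
bit-faithful and covered by tests.

## Known limitations

The gating registry, incompatibility pairs and exclusion list are editable
defaults, not a curated atlas; the packaged EDS signature is synthetic (see
above) and should be replaced by one derived from real sorted reference
data for any biological use. The doublet filter only detects cross-lineage
doublets — within-lineage doublets need neighbourhood-simulation methods,
which are out of scope. Module scores depend on the total gene count through
`max_rank`; matrices much smaller than `max_rank` genes compress all scores
upward.
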