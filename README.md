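# immunogate

Reproducible, gating-style phenotyping for single-cell immune data.

Unsupervised clustering of scRNA-seq data groups cells by whatever dominates
transcriptional variance — which, inside T and NK cells especially, is often a
shared effector program rather than lineage or mode of antigen recognition.
`immunogate` implements the complementary strategy: score each cell directly
for small, curated diagnostic gene programs and for a portable
effector-differentiation axis, so the same definition of a phenotype can be
applied identically across datasets and laboratories. It is aimed at
immunologists and bioinformaticians analysing droplet scRNA-seq (optionally
CITE-seq and V(D)J) data from primates.

The package covers the full supporting pipeline:

* **QC** — per-cell sequencing saturation `1 − #UMIs/#reads`, with filters
  0–20,000 UMIs/cell, 200–5,000 features/cell, RNA saturation > 0.35 and ADT
  saturation > 0.1.
* **Normalization** — `ln(1 + 10⁴·x/T)` library-size log normalization,
  per-gene z-scaling, dispersion-based variable-gene selection with an
  editable exclusion list (class-I MHC, ribosomal genes), and per-lane
  centered log-ratio (CLR) normalization of antibody-derived tags.
* **Rank-based module scores** — for a module of *n* genes, rank all genes in
  a cell by decreasing expression (average ties), cap ranks at
  `max_rank + 1` (default 1,500), and map the rank-sum through the
  Mann–Whitney U statistic:
  `score = max(0, 1 − U/(n·max_rank))`, `U = Σ r′ᵢ − n(n+1)/2`.
  Ships with lineage modules, the S100A memory program, the granzyme K/M vs
  A/B/H programs and three mature-B-cell programs.
* **Coarse annotation** — threshold gating on the lineage module scores, a
  balanced training set from the confidently gated cells, an L2-regularized
  multinomial logistic classifier over the full transcriptome, and a doublet
  filter that flags cells co-positive for incompatible lineages (B × T/NK,
  T/NK × erythrocyte, ...).
* **Effector-differentiation score (EDS)** — pairwise Wilcoxon contrasts
  between sorted T cell populations → robust markers (expressed in ≥ 50 % of
  the population they mark) → correlation-PCA on the marker space; the
  oriented first principal axis is stored as a portable signature
  (`score = Σ w_g·(x_g − μ_g)/σ_g`) with per-gene centering/scaling and
  naive/effector thresholds (effector iff score > 6 for the packaged
  signature).
* **TCR analysis** — contig filtering (CDR3 present, full length, V/J/C
  called, loci concordant except the permitted TRDV/TRAC and TRAV/TRDC
  chimeras, which are classified by the constant region), cross-subject
  clonotype grouping, singleton/expanded/public clonality, top-expanded
  clonotypes, and TCR/CD3/CD16 cell categorization.
* **Tissue enrichment** — chi-squared Pearson and adjusted (Haberman)
  standardized residuals `s = (O−E)/√(E(1−R/N)(1−C/N))` with optional linear
  scaling, plus per-tissue composition fractions.
* **Synthetic data** — a seeded generator producing sparse count bundles with
  known lineages, a latent naive→effector coordinate driving the
  S100A/granzyme/naive programs, doublets, lanes, ADT tags and clonotype
  tables, so every claim above is testable against ground truth.

## Worked example

```python
from immunogate import (annotate_coarse, apply_eds, categorize_by_eds,
                        default_registry, load_packaged_signature,
                        lognormalize, score_modules)
from immunogate.simulate import coarse_default_config, simulate_immune_dataset

bundle, truth, contigs = simulate_immune_dataset(coarse_default_config(seed=1))
result = annotate_coarse(bundle)
print(result.report)

norm = lognormalize(bundle.rna_counts, cell_ids=bundle.cell_ids)
reg = default_registry()
scores = score_modules(norm, bundle.gene_ids, [reg["S100A_memory"]])
for pop in ("T_naive", "T_cm", "T_em"):
    mask = (truth.cells.population == pop).to_numpy()
    print(f"S100A memory score, {pop}: {scores['S100A_memory'][mask].mean():.3f}")

sig = load_packaged_signature()
eds, coverage = apply_eds(sig, norm, bundle.gene_ids)
print(f"EDS coverage {coverage:.1%}")
```

Output:

```
{'n_cells': 3000, 'n_gated': 2860, 'n_trained_on': 1377, 'n_confident': 2999,
 'n_incompatible': 118, 'per_class': {'T_NK': 1941, 'Myeloid': 473, 'B': 468,
 'doublet': 118}}
S100A memory score, T_naive: 0.365
S100A memory score, T_cm: 0.610
S100A memory score, T_em: 0.731
EDS coverage 94.5%
```

Of 3,000 simulated cells (150 of them injected doublets), 2,860 gate
confidently; the classifier labels essentially all cells, and 118 are removed
as incompatible-lineage doublets. The S100A memory score rises monotonically
across the naive → central-memory → effector-memory stages, and the packaged
EDS signature applies to this independent dataset with 94.5 % of its weight
mass present. The packaged signature (`immunogate/data/
eds_signature_synthetic.json`) is a synthetic stand-in derived from the
bundled sorted-reference simulator; derive one from your own sorted reference
populations with `immunogate eds derive`.

The same functionality is exposed on the command line:

```bash
immunogate simulate --preset coarse --seed 1 --out data/
immunogate qc --in data/ --out qcdata/
immunogate score --in qcdata/ --out scores.tsv
immunogate annotate --in qcdata/ --seed 0 --out annotated/
immunogate tcr clonality --contigs data/contigs.csv --subjects data/subject_map.tsv --out clones.tsv
immunogate enrich --labels labels.tsv --by tissue --out enrichment
```

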