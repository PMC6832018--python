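# Methods

`oralmgx` re-implements, as a tested and reusable pipeline, the analysis
chain used in shotgun-metagenomic studies of the childhood oral
microbiome: read quality control, species/gene abundance estimation with
multi-mapped read redistribution, community diversity and permutation
tests, differential abundance, metagenomic-species (MGS) clustering,
co-occurrence network inference, multivariate phenotype association, and
a marker-species disease classifier. Because the cohort data such studies
rest on is far beyond desk scale, every stage is validated on synthetic
communities with planted, known structure. This note records the models,
the defaults and why they were chosen, what the simulator does and does
not emulate, and the design decisions taken where the methodology was
genuinely open.

## Abundance estimation

Mapped read pairs are split into *unique* reads U (exactly one species)
and *multiple* reads M (two or more). For species S with average genome
length l:

    Ab(U) = U / l
    Co(S) = Ab(U, S) / Σ_{i ∈ {M}} Ab(U, i)        (per multi-read)
    Ab(M) = ( Σ_{multi reads containing S} Co(S) ) / l
    Ab(S) = Ab(U) + Ab(M)

The estimator is one-pass: coefficients derive from unique abundances
only. An iterate-to-convergence mode exists but is off by default, since
the defining equations describe no iteration. When no species in a
multi-read's set has unique support, Co is undefined; the default splits
the read uniformly (Co = 1/N), preserving read mass; a drop-the-read
alternative is available. Relative abundance is Ab(S) normalised over
species; both raw and relative values are reported. Higher taxa are
aggregated by summing species relative abundances.

With one reference genome per species, l is that genome's length; with
several, the arithmetic mean.

## Read quality control

Defaults: discard a pair when either mate has more than 5 ambiguous
(non-ACGT) bases **or** more than 50 bases below Phred 2 (the two clauses
are combined with OR — the stricter of the two readings); trim the
maximal all-low-quality suffix of each mate; drop pairs with a mate
shorter than 30 bases after trimming (the floor is ours — some floor is
needed to avoid zero-length reads). The pipeline runs trim → filter →
host-removal so the low-quality-count filter sees post-trim reads and
cannot discard a read whose only bad bases are in a trimmable tail; the
order is configurable. The Phred < 2 cutoff is unusually low but is the
documented default; it is exposed as a flag.

Host removal is a *contract*, not an aligner: the bundled matcher flags a
pair when either mate occurs verbatim in the (synthetic) host reference,
which is exact for error-free simulated reads; adapters for external
aligners can be substituted. Re-implementing a short-read aligner is out
of scope, as is adapter trimming and duplicate removal.

## Diversity, ordination and permutation tests

Alpha diversity per sample: richness (features > 0), Shannon H = −Σ p ln p
(natural log) and Gini–Simpson 1 − Σ p² — base-2 Shannon and inverse
Simpson variants were deliberately not defaulted; flags exist. Beta
diversity uses Bray-Curtis Σ|x−y| / Σ(x+y).

PCoA eigendecomposes the Gower-centred −d²/2 matrix. Negative
eigenvalues (expected: Bray-Curtis is non-Euclidean) are reported, not
dropped, and are excluded from the variance-explained denominator. Sign
convention: the first loading of each axis with magnitude above 1e-12 is
made positive, so ordinations are reproducible across platforms.

Three distance-based group tests are provided, all with label-permutation
inference and the add-one rule p = (1 + b)/(1 + m), so p ≥ 1/(m+1) and
never 0:

* **MRPP** — delta = Σ_g (n_g/N) · mean within-group distance (group-size
  weighting; other weightings exist, this is one of the standard choices);
  small delta is extreme.
* **ANOSIM** — R = (mean between-group rank − mean within-group rank) /
  (n(n−1)/4) on midranked distances.
* **Adonis / PERMANOVA** — pseudo-F from the McArdle–Anderson partition:
  with hat matrix H of the design and Gower matrix G,
  F = [tr(HG)/(m−1)] / [(tr G − tr(HG))/(n−m)]. The same hat-matrix path
  serves single-variable phenotype PERMANOVA, dummy-coding categorical
  variables and entering continuous ones directly.

Permutation counts default to 999 (scaled to 199 inside large calibration
sweeps). Calibration is verified empirically: on 500 structureless
communities each test's type-I error at α = 0.05 falls in [0.03, 0.07].

## Differential abundance and enrichment

Per-feature two-sided Wilcoxon rank-sum tests with midrank ties; the
exact null is used when both groups have ≤ 10 samples and the feature has
no ties, the normal approximation with continuity correction otherwise
(the switch point mirrors common practice). Benjamini–Hochberg adjustment
runs across all tested features; canonical thresholds are FDR < 0.1 for
taxa and FDR < 0.07 for genes (the unusual 0.07 is retained verbatim as
the gene default). Features nonzero in fewer than 2 samples are excluded
from testing to avoid degenerate ranks (configurable). Constant features
get p = 1 by convention and are flagged. Category enrichment uses the
upper-tail hypergeometric P(X ≥ overlap) with BH across categories; the
universe defaults to all annotated features and is configurable.

## MGS clustering

Marker genes (gene-level rank-sum, q < 0.07) are clustered in two stages.
Stage 1 is greedy canopy clustering: the unassigned gene with the highest
mean abundance seeds a cluster that absorbs every unassigned gene with
Spearman rho > 0.9 **to the seed profile** (not the running cluster mean
— the simplest reading of correlation-threshold clustering; stage 2
handles refinement). Seed ties break lexicographically on gene id, so
the algorithm is deterministic and seed-free. Stage 2 drops clusters
under 25 genes, then merges survivors by average-linkage hierarchical
clustering of cluster mean profiles on distance 1 − rho, cut at rho 0.8
(linkage choice ours; only "hierarchical clustering" is prescribed).
Each final MGS carries the majority enrichment direction of its member
genes and 25 tracer genes chosen by top mean abundance (the tracer rule
is ours; no selection rule is documented for the display subset).
Correlations are computed on relative abundances; because Spearman is
rank-based within genes this matters only through the per-sample
normalisation, and the raw-scale alternative is one flag away.

## Co-occurrence networks

Within each condition, species with mean relative abundance below 0.01%
are removed (mean-within-condition is our reading; a prevalence
alternative is exposed). All species pairs get Spearman rho with
two-sided p (t-approximation; exact permutation below 10 samples — note
the exact path enumerates n! rank permutations and is intended for small
n only), BH across pairs, and an edge when |rho| > 0.6 and q < 0.05 —
the magnitude rule, since negative edges are meaningful and signed.
Topology on the unweighted graph: degree; betweenness with fractional
credit over equal-length shortest paths, endpoints excluded; closeness
= 1 / (summed shortest-path distance to reachable nodes), computed within
the connected component, 0 for isolated nodes. The within-component
convention matches the common graph-library behaviour and is logged
because it affects cross-condition closeness comparisons on fragmented
networks. Network comparison reports shared-edge fractions relative to
each network, rank-sum p-values comparing the node-metric distributions,
and main clusters (components with > 10 nodes) summarised by their most
frequent genera.

## Association models

Features are restricted to mean relative abundance > 0.01% and presence
in ≥ 10 samples ("more than 10" and "at least 10" both circulate; ≥ 10
is the default, flag-controlled). Abundances are arcsine-square-root
transformed (y = arcsin √p) and each (feature, phenotype) pair is fitted
by OLS with age, gender and BMI as confounders; the phenotype coefficient
gets a two-sided t-test and BH runs globally across all pairs in the run
(per-variable families available). The original MaAsLin framework adds
boosting-based variable pre-selection; this package implements the
confounder-adjusted linear model directly, which is the documented
analysis. Ordinal diet/education/income variables enter numerically.
Collinear designs (constant phenotype, or phenotype aliased with
covariates) are skipped with a recorded reason. Matrices with a planted
linear phenotype link are left column-unnormalised in the recovery
experiments: re-scaling columns would distort the planted linear relation
that the exact-recovery check (coefficient to 1e-9 at zero noise)
verifies.

## Marker classifier

Candidates: species at raw rank-sum P < 0.01 (raw, not FDR — the
documented rule). Ranking: greedy mRMR with the MID (difference)
criterion on median-binarised features; ties break lexicographically.
Subsets: prefixes at 5-species intervals plus the full set, each scored
by leave-one-out cross-validated two-class LDA (pooled covariance with a
diagonal ridge of 1e-6 × mean diagonal — p can approach n inside LOO
folds) pooled into a single confusion matrix; the grid winner is the
smallest prefix attaining the maximum MCC.

The refinement step that produces off-grid panel sizes (such as 7 from a
5-interval grid) is under-specified in the source methodology, and the
choice matters: LOO MCC at n = 44 moves in steps of ~0.045, so exact ties
across subset sizes are the norm, and a shrink-on-tie rule collapses
panels below the number of genuinely informative markers. This package
therefore scans the interval-wide window around the grid winner and moves
off it only for a better MCC, resolving ties toward the **larger**
prefix: a tie never discards a candidate marker. Under this rule the
planted-marker experiment (7 informative species among 200, +2.5 log2
effects, 25+19 samples) recovers ≥ 6 of 7 markers in 92% of seeds with
mean LOO AUC 0.996; under shrink-on-tie the same experiment plateaus
near 50% for every effect size we examined, because panels collapse to
the first grid point.

The discriminant and the final classifier operate on log10 relative
abundances (pseudocount 1e-10): relative abundances are heavily
right-skewed and LDA assumes roughly Gaussian features — on the raw scale
LOO performance *decreases* with panel size as covariance estimation
noise accumulates, which is an artefact, not marker information. The
candidate tests and mRMR are rank/median-based and monotone-invariant, so
they see the raw relative matrix.

Final model: RBF-kernel SVM, cost 1, kernel scale 1/(number of
informative panel features) after per-feature standardisation (constant
features standardise to zero and are inert), matching the cited
implementation's defaults; probabilities come from a monotone logistic
(Platt-style) calibration of decision values fitted by Newton iteration.
ROC AUC uses the Mann–Whitney formulation with half-credit ties; the 95%
CI uses the DeLong structural-components variance (a bootstrap CI is
available by flag).

## Synthetic communities

The generator is a pure function of (spec, seed) and produces reference
genomes, paired reads, abundance matrices, metadata and a truth record.

* **Genomes** are uniform-random ACGT of configurable length; shared
  segments are copied verbatim into both members of a species pair,
  guaranteeing multi-mapping reads; genes tile each genome as
  non-overlapping intervals.
* **Reads** are drawn per-base-uniformly with species probabilities
  proportional to abundance × genome length, so U/l-style estimates are
  proportional to true abundance. Mates are stored in reference
  orientation. Qualities follow a two-level model (Phred 40, with a
  configurable per-base chance of Phred 1). A configurable fraction of
  pairs comes from a bundled synthetic host sequence and is recorded in
  the truth set. No sequencing-error, insert-size or GC models are
  attempted.
* **Abundance matrices** start from log-normal base abundances
  (meanlog 0, sdlog 1 across features — heavy-tailed like real
  profiles and easy to invert in tests). Two variance knobs are
  separated: `profile_sd` scales each feature's per-sample latent
  variation (the signal that correlations and clusterings act on) and
  `noise_sd` adds independent entry-level noise. With both at zero a
  feature is constant across samples, which makes planted group-effect
  ratios exact; with only `noise_sd` zero, planted co-abundant gene
  clusters and positively planted species edges have within-cluster and
  pairwise Spearman rho exactly 1 — both assertable directly in tests.
  Group effects multiply the unnormalised scale by 2^effect in the
  enriched group (optionally in only a penetrance-fraction of its
  samples, a polymicrobial-realism option that defaults off). Planted
  inter-species edges share a per-sample latent factor (negated for
  negative edges). Planted MGS are realised as scaled copies of the
  carrier species' profile; cluster genes are down-weighted
  (`mgs_gene_scale`, default 0.02) so that, as in real catalogues where
  differential genes are a small mass fraction, a cluster's group shift
  does not compositionally displace the background genes. Columns of the
  relative matrix sum to 1 ± 1e-9.
* **Metadata** mimics a two-group preschool cohort: age uniform over
  45–73 months; dmfs = 0 for every healthy child and ≥ 8 for every
  caries child (the severe-caries inclusion rule); gender, height, BMI,
  dmft, toothache history, diet frequency, parental education and income
  from plausible marginals, independent of the microbiome unless a link
  is planted. `plant_association` writes a linear link on the
  arcsine-sqrt scale so OLS recovery is exact at zero noise.

What passing tests therefore show: the estimators, tests and clusterings
recover exactly the kind of structure they assume, at realistic cohort
sizes, under heavy-tailed abundances and compositional normalisation.
What they do not show: robustness to sequencing error, mapping ambiguity
beyond exact repeats, batch effects, zero-inflation beyond what the
log-normal induces, or phylogenetic correlation among species.

## Problem sizes and orchestration

The full pipeline (`oralmgx run`, or `run_pipeline`) chains simulate →
qc → profile → diversity → diff → mgs → network → assoc → classify under
one config whose defaults are the canonical thresholds above, and writes
a manifest with the config hash and SHA-256 checksums of every output;
identical config + seed reproduces byte-identical trees. The default
synthetic study uses 22+22 samples, 200 species and 2,000 genes for the
statistical stages, and a 10-species read-level community (5 kb genomes,
2,000 pairs per sample, 20% host reads, one 600 bp shared segment) for
the QC and profiling stages — large enough to exercise every code path
while a complete run stays within a few seconds on one CPU. Validation
experiments use the cohort sizes stated alongside each stage above
(e.g. 25+19 samples for the classifier, 40 samples and 100 species for
networks, 50,000 read pairs for profiling recovery).

## Known limitations

* The exact-substring aligner and host matcher assume error-free reads;
  with real data, external aligner adapters must be used.
* The Spearman exact-permutation path enumerates n! permutations and is
  only meant for n < 10.
* Gene-level profiles are simulated directly rather than derived from a
  simulated gene catalogue; assembly, ORF prediction and catalogue
  deduplication are out of scope.
* Strain-level phylogenetics, functional (KEGG/eggNOG/MetaCyc)
  annotation and compositionality-aware correlation (SparCC-style) are
  out of scope.
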