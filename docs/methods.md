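# Methods

This note records the models and conventions `gofunc` implements, the
choices made where more than one convention exists, and what the synthetic
data does and does not emulate.

## Ontology model and propagation

The ontology is a directed acyclic graph over GO terms with edges typed
`is_a` or `part_of`, one root per namespace (MFO, BPO, CCO). Annotation
propagation (the true-path rule) closes each protein's term set under the
ancestor relation over both edge types — the convention of the DeepGO
family of predictors. Other relation types (`regulates`, cross-namespace
links) are dropped at parse time. Obsolete terms carry no edges;
annotations to them are discarded with a warning; `alt_id`s resolve to
their primary term. OBO parsing is delegated to `obonet`; the package only
re-types and filters the result.

## Information content

GO evaluation needs a term-specificity weight for S_min. We use
annotation-frequency IC in bits:

    IC(t) = -log2(count(t) / N)

with `count(t)` the number of *propagated training* proteins annotated
with t and N the training size. Terms never seen in training get the
smoothed ceiling `-log2(1/(N+1))`, which is finite, exceeds every observed
IC, and approaches the rarest-term IC as N grows. IC is a property of the
training split only; computing it on test data would leak label
frequencies into the metric.

## Dataset splits

Two split designs:

* **Similarity split.** All-vs-all alignment hits (BLAST/DIAMOND outfmt 6)
  with e-value ≤ 0.001 define an undirected similarity graph (both hit
  directions merged, best e-value per pair). Connected components are
  indivisible: after a seeded shuffle they are assigned largest-first to
  the train/valid/test bin whose fill is furthest below its 81/9/10 target
  protein count. This is deterministic given the seed, lands within one
  component of the targets, and guarantees zero similarity edges across
  split labels. A component larger than the largest bin goes to train with
  a warning. Targets are measured in proteins, not components.
* **Time-based split.** Given two annotation releases, the evaluation set
  contains proteins with zero experimental annotations in the namespace in
  the old release and at least one in the new — the per-namespace
  "no-knowledge" convention, so a protein already annotated in BPO can
  still enter the MFO evaluation set.

Ground truth is restricted to the 13 experimental/curated evidence codes
(EXP, IDA, IPI, IMP, IGI, IEP, TAS, IC, HTP, HDA, HMP, HGI, HEP);
computational codes such as IEA are excluded, and unknown codes are
dropped with a log message rather than an error.

## Baselines and the score-table interface

Every predictor emits scores in [0, 1] per (protein, term). The naive
baseline assigns each term its training frequency, identically for all
proteins — by construction its per-term ROC-AUC is 0.5. DiamondScore
transfers annotations from aligned training proteins weighted by bit
score: score(q, t) = Σ_{s : t ∈ ann(s)} bits(s) / Σ_s bits(s) over the
query's hits. The MLP baseline (one hidden layer on precomputed embedding
vectors, per-term sigmoid outputs, fixed seed) is a desk-scale reference
showing how a learned model slots into the same interface; constant output
columns are carried through as constants since a classifier cannot be fit
on a single class. External predictors load from TSV; duplicate rows keep
the maximum score. `hierarchy_normalize` (max over descendants-or-self,
computed in one topological pass) makes arbitrary plug-in scores
true-path-consistent and is applied by default before evaluation, with a
toggle.

## Evaluation metrics

Fmax and Smin sweep score thresholds τ. The reported numbers use the grid
τ = 0.01, 0.02, …, 1.00; an `exact=True` flag sweeps every distinct
positive score instead, which is what the oracle-equivalence tests use. At
each τ precision is averaged over proteins with ≥ 1 predicted term
(the CAFA m(τ) convention) while recall averages over all evaluated
proteins; Fmax ties resolve to the smallest τ. Smin uses
ru(τ) = mean summed IC of false negatives and mi(τ) = mean summed IC of
false positives. AUPR is micro-averaged over all (protein, term) pairs of
the evaluation universe — unpredicted pairs score 0 — with trapezoidal
integration over distinct cut points, anchored at recall 0 with the
highest-threshold precision (so uniform scores integrate exactly to the
positive prevalence). Mean AUC averages per-term ROC-AUC (computed by
scikit-learn) over terms with at least one positive and one negative
protein. The evaluation universe excludes namespace roots; proteins are
those with ≥ 1 truth term in the universe. An empty prediction table is
valid and yields Fmax 0 and Smin equal to the full remaining uncertainty.

## Functional profiles

16S route: an OTU table of per-sample relative abundances (rows
renormalized with a warning when they deviate from 1 by more than 1e-6)
is combined with a taxon→function map. The map is derived from per-taxon
protein prediction scores with a presence cutoff, default 0.3 — the paper
trail of which predictor and cutoff produced a map is stored in its
`provenance` field — and is ancestor-closed, which makes parent columns
dominate child columns in every profile. The binary profile marks f
present iff some taxon with R > 0 carries it; the abundance profile is
A(f) = Σᵢ R(tᵢ)·I(f, tᵢ), which is linear in the abundance vector and
bounded by 1. Taxa missing from the map contribute nothing (real 16S data
always has unmapped taxa). WGS route: per-sample protein annotations are
thresholded, unioned and optionally ancestor-closed into one function set
per sample; the WGS profile is binary only — weighting WGS functions is a
possible extension, not implemented.

## Clustering purity

Samples are PCA-reduced to the smallest number of components reaching 90%
explained variance by default (configurable, or a fixed component count);
component signs are fixed by a largest-loading-positive rule so the
reduction is deterministic. k-means uses k = number of phenotype
categories, k-means++ initialization and 10 seeded restarts. Purity is

    WACP = (1/N) * sum_i max_j w_j * n_ij

over clusters i and categories j. With the default uniform weights this is
classical size-weighted purity — the fraction of samples in their
cluster's majority category — equal to 1 iff every cluster is
single-category and bounded below by the largest category fraction.
Optional category weights (normalized to mean 1 so uniform weights
reproduce classical purity) let imbalanced phenotypes down-weight a
trivial majority cluster. Profiles enter unscaled; a standardization flag
is deliberately absent from the default path since binary and abundance
values are already commensurate within a matrix.

## Synthetic communities

`gen_community` draws per-sample taxon abundances from a Dirichlet with
concentration `noise × mean × n_taxa` (default noise 50, i.e. moderately
tight around the mean composition), zeroes abundances below a detection
floor of 0.02 and renormalizes. Default shape: 3 categories × 10 samples,
20 taxa, a 30-function pool, ~12 functions per taxon — the scale of a
small paired 16S/WGS benchmark, sized for test speed. Taxa are divided
into one guild per category. The two planted regimes:

* **function-driven** — each guild's taxa all carry that category's
  marker functions (4 per category, disjoint), and each sample multiplies
  the Dirichlet mean of exactly one *randomly chosen* guild taxon by
  (1 + 8·effect). The dominant taxon varies within a category, so OTU
  profiles are inconsistent, while the summed abundance of the marker
  functions — the guild total — is stable and high: the functional signal
  survives aggregation, the taxonomic one does not.
* **taxon-driven** — every sample of a category multiplies its whole
  guild's means by the same factor (consistent taxonomic signal), and the
  taxon→function map is guild-balanced: each function is carried by
  equally many taxa from every guild (functional redundancy), so shifting
  mass between guilds leaves expected function abundance flat and the
  functional profiles retain little phenotype signal.

At effect 0 both regimes reduce to identical label-independent generation.
The generator emulates compositional abundance noise, detection limits,
and the taxonomy-versus-function attribution question; it does not emulate
16S copy-number bias, chimeras, taxonomic misassignment, sparse real-world
function catalogs, or within-taxon genomic variation — so passing tests
demonstrate that the pipeline *can* separate the two regimes when they are
cleanly planted, not that real phenotypes decompose this cleanly.

## Numerical and degenerate-input conventions

Scores outside [0, 1] are rejected at construction and at load, naming the
offending row. Constant matrices are rejected by PCA (no variance).
Proteins with no predictions count as zero-recall, zero-coverage proteins
rather than being dropped. Fmax tie-breaks favor the smallest threshold;
k-means ties resolve by lowest inertia across restarts under the given
seed. All generators and the split assignment are exactly reproducible
from their integer seeds.

## Problem sizes

Tests and the acceptance script run at deliberately small scale — ≤ 50
proteins × 30 terms for metric-oracle checks, 150-protein benchmarks,
30-sample communities, 20 seeds per planted-signal comparison — chosen as
the smallest sizes at which the contrasts of interest are stable.
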