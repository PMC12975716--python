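# Methods

## The problem

Assigning a biological identity to each transcriptional cluster of a
single-cell RNA-seq experiment is usually either manual (slow,
irreproducible) or automated but opaque (a single label with no stated
reasons). cellscribe implements a fully transparent middle road: every
cluster receives exactly three ranked cell-type candidates, each with an
itemized point breakdown saying which evidence earned or cost it points, so
a reviewer can audit every number in the report.

## Pipeline

Annotation runs in three stages per cluster, mirroring step-back reasoning
(enumerate plausible answers first, then decide):

1. **Prospector** — filters the marker knowledge base (KB) down to cell
   types plausible in the declared tissue. An empty tissue admits all
   entries. If a declared tissue matches no entry the stage falls back to
   the full KB rather than hand the next stage an empty shortlist (logged);
   every shortlisted name carries a provenance note. Entries are ordered by
   name and truncated to `shortlist_limit` (default 10, which keeps the
   quadratic cross-candidate shared-marker checks small).
2. **Insightor** — scores every shortlisted candidate against the cluster's
   evidence through a pluggable backend. The reference backend is the
   deterministic rubric below. A completion backend adapts any text → text
   callable behind a strict JSON request/response schema; in tests it is
   driven only by a replay transport that answers from recorded fixtures
   and fails loudly on a cache miss, so the adapter contract is exercised
   without network access.
3. **Reviewer** — ranks candidates by total (ties broken by name), keeps
   exactly three slots (padding from the remaining KB entries when the
   shortlist was shorter, or marking slots explicitly absent when the KB
   itself has fewer than three types), assigns confidence tiers
   (high ≥ 70, medium ≥ 40, low otherwise — the rubric spans ±100 and 70
   requires strong positive marker evidence), and flags a cluster
   `low_agreement` when the top two totals differ by fewer than
   `low_agreement_margin` points (default 10 = one shared-marker deduction's
   worth of ambiguity).

Clusters are statistically independent, so they may be processed on a
thread pool; results are assembled in cluster-id order and per-cluster
failures are captured in the report rather than aborting the run. Serial
and concurrent runs serialize byte-identically (the thread count is
execution mechanics and is deliberately excluded from the echoed config).

## Evidence

**Differential expression.** One-vs-rest Wilcoxon rank-sum per gene on
log1p CP10K-normalized counts, one-sided for over-expression (the DEG list
feeds marker *matching*, so down-regulated genes must not enter it),
Benjamini–Hochberg adjusted across genes. Ranking key: adjusted p
ascending, then signed log2 fold-change descending, then symbol — the
signed tie-break matters because among non-significant BH-tied genes an
absolute-value tie-break would pull strongly suppressed genes into the top
list. The exact p-value path (both groups ≤ 8 untied observations) agrees
with brute-force permutation enumeration; larger groups use the normal
approximation with tie correction, the field default. Genes constant across
all cells get p = 1 and log2FC = 0; with everything tied the ranking
degenerates to symbol order. log2FC uses mean CP10K with a pseudocount
of 1.

**Pathway over-representation.** Hypergeometric upper-tail test of the
cluster's top `top_n` DEGs (default 20, a typical shortlist-prompt size)
against each GMT set, universe = all genes in the matrix (overridable),
BH across terms, terms significant at adjusted p < 0.05 feeding the rubric.
Sets with no gene in the universe are skipped and logged.

## Scoring rubric

Each candidate is scored per criterion; positive criteria award
*proportional* credit capped at the criterion maximum and rounded half-up
(2 of 4 broad markers matched → 45 × 2/4 = 22.5 → 23), deductions are fixed
one-shot penalties applied at most once however many items trigger them:

| stream  | criterion                                   | points |
|---------|---------------------------------------------|-------:|
| marker  | cell-type/state markers among top DEGs      | +45 max|
| marker  | narrow (high-specificity) markers detected  | +15 max|
| marker  | matched markers shared with another candidate | −10  |
| marker  | negative markers present                    | −30    |
| pathway | enriched pathways fit the cell state        | +15 max|
| pathway | enriched pathways fit the cell type         | +5 max |
| pathway | matched pathway shared with another candidate | −10  |
| pathway | conflicting pathways                        | −20    |
| context | cell type plausible in tissue/condition     | +10 max|
| context | cell state plausible in tissue/condition    | +10 max|
| context | type/state biologically implausible         | −30    |

Totals therefore lie in [−100, +100]. When no gene-set collection is
supplied the pathway criteria are *absent* from the breakdown (not zeroed):
this is the two-component (marker + context) score; the two-component
point values reuse the marker and context rows unchanged.

Design choices that were genuinely open:

- **Proportional credit.** Only caps are published; proportionality
  preserves ordering by evidence strength and keeps every number
  hand-checkable.
- **One-shot deductions.** The deduction rows carry single values without a
  "max" qualifier, so they are read as fixed penalties, not per-gene ones.
- **Shared vs conflicting pathways.** A *shared* pathway is one this
  candidate matched that a competitor also claims (−10, specificity loss);
  a *conflicting* pathway is a significant term claimed exclusively by a
  competitor (−20, functional mismatch). Requiring competitor-exclusivity
  keeps the two penalties disjoint.
- **Empty context is vacuously plausible.** Absence of context must not
  punish candidates: type points are awarded and the implausibility
  deduction can never fire. Context-*state* points, by contrast, require a
  non-empty context and a declared state whose tissue/condition tags are
  compatible with it (state items are `name[@tissue[/condition]]`; unset
  tags match anything), so an empty context yields 0 state points.
- **Declared-but-wrong tissue.** An entry that declares tissues not
  containing the context tissue takes the −30 deduction and no type points;
  an entry declaring *no* tissues is treated the same way under a non-empty
  context (plausibility must be claimed to be credited).
- **Monotonicity caveat.** Adding a matched broad marker can never lower
  the total in the absence of competitors; with a shortlist it can
  legitimately do so when the new marker triggers the shared-marker
  deduction. The property suite tests the competitor-free form.

Because every criterion is deterministic and ties break lexicographically,
scoring is a pure function: identical inputs give identical breakdowns.

## Agreement metric

Annotation quality against a reference is a three-level score per cluster:
**1.0** when predicted and reference labels resolve to the same canonical
KB name or the same Cell Ontology (CL) term; **0.5** when one term is an
is_a ancestor of the other at any distance, or both map to the same
configured broad-category label; **0.0** otherwise. Two terms sharing only
a remote common ancestor (siblings) score 0.0 unless a broad-category map
says otherwise — "shared ancestry" is read as lineage between the two
terms, and the category map (default empty) is the explicit mechanism for
coarser credit. Because each cluster carries three candidates, its score is
the maximum over them; a benchmark is the arithmetic mean of per-cluster
maxima plus full/partial/mismatch counts. The metric is symmetric; labels
resolving neither in the KB nor in the ontology are compared as normalized
strings only (logged), since ontology levels need a term.

## Synthetic data generator

The generator exists so every stage is testable without downloads: one
cluster per KB entry, counts drawn i.i.d. negative binomial with mean
`baseline_mean` and size `dispersion` (variance m + m²/r), the planted
type's positive markers multiplied by `marker_fold` in their own cluster
and its negative markers multiplied by `negative_suppression`. Defaults —
50 cells per cluster, 200 background genes (named `GBG0001…` to avoid
symbol collisions), baseline mean 2, dispersion 2, fold 8, suppression
0.1 — give a clearly separable but noisy signal: fold 8 on a mean-2
baseline is the magnitude of a canonical marker in its own lineage, and
dispersion 2 yields the strong overdispersion typical of UMI counts.
Marker overlap between planted types is allowed (and logged): it is the
mechanism for exercising the shared-marker deduction.

What the generator does *not* emulate: library-size variation, dropout
zero-inflation, batch effects, doublets, ambient RNA. Passing the recovery
suite therefore shows the pipeline recovers planted marker structure under
NB noise — it does not certify performance on real tissue atlases, where
DE quality, KB coverage and marker ambiguity dominate.

The recovery suite runs the full pipeline on 20 seeded datasets (the
built-in five-type blood KB: B cell, T cell, NK cell, monocyte, dendritic
cell, distinct canonical markers) and requires top-1 recovery ≥ 90% and
mean agreement ≥ 0.9. It runs the two-component path — the generator
plants marker signal only, so a pathway component would be constant zero.
These problem sizes (5 × 50 cells, ~230 genes, 20 seeds) run in seconds
and are the regime where the planted-recovery question is meaningful.

## Numerical and degenerate-input choices

- Rounding of proportional credit: half-up via `floor(x + 0.5)` (inputs are
  non-negative), so 22.5 → 23.
- All label comparisons lower-case, collapse whitespace and map `-`/`_` to
  a space; gene symbols are upper-cased on ingestion.
- Every ordering ends in a lexicographic key (gene, term, candidate name,
  cluster id), making all outputs reproducible bit-for-bit.
- A cluster with fewer than 2 cells on either side of its one-vs-rest split
  is a per-cluster error, isolated in the report.
- `top_n` beyond the gene count truncates with a warning; empty ORA query
  or universe is a hard error; a gene set disjoint from the universe is
  skipped, not an error.
- Cycles in the ontology and edges to undeclared terms are hard errors at
  load time.

## Known limitations

- The rubric's proportional-credit and one-shot-deduction readings are
  design interpretations of published caps; alternative readings (per-gene
  penalties, binary credit) would change absolute totals but rarely the
  ranking on well-separated clusters.
- KB quality bounds annotation quality: the engine cannot propose a type
  the KB does not contain, and the built-in five-type KB is a demonstration
  fixture, not a curated atlas resource.
- The completion backend validates structure, not content: a live language
  model's scores would need their own calibration before the confidence
  tiers mean the same thing they mean for the rubric backend.
- Broad-category partial credit is only as good as the supplied term →
  category map; none ships by default.
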