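# Methods

## Scope and data model

`orthofam` classifies query proteins of a gene family into
reference-anchored subfamilies and profiles their presence across
organisms. It consumes finished search and inference outputs — protein
FASTA, 12-column BLAST tabular hit tables, domain-annotation TSVs
(Pfam/SMART style), and Newick gene trees whose numeric internal labels
are interpreted as supports — and never invokes the external tools
itself. The 12-column tabular dialect is an interface choice; any search
engine emitting `qseqid sseqid ... evalue bitscore` columns works.

Supports carry an explicit scale: maximum-likelihood bootstrap
percentages on [0, 100] or Bayesian posteriors on [0, 1]. All thresholds
operate on the bootstrap-percent scale; posteriors are multiplied by 100
first. Internally a support belongs to a bipartition (edge), not a node:
rooting re-attaches every support to the node subtending the same
bipartition, so rooting never changes the support associated with a
split. When an outgroup is not monophyletic in the unrooted tree, the
root is placed on the edge maximizing the number of outgroup leaves on
the outgroup side, ties broken toward the smaller clade, with a warning —
published rooted figures rarely state the rule used, so a deterministic
one is fixed here.

## Classification procedure

Per query, evidence is sought in strict order — tree, E-value margin,
unclassified — never skipping forward:

1. **Tree rule.** The query's *first reference-containing ancestor* is
   the smallest clade above it holding at least one reference leaf. If
   the references in that clade belong to one subfamily and the clade's
   support strictly exceeds `min_support` (default 50), the query is
   assigned with the support as its statistic. A mixed-subfamily clade
   fails the rule rather than guessing ("clustering with a subfamily" is
   read as an exclusive grouping). A missing support compares as 0, so
   unsupported clades never pass. A query present in several trees takes
   the passing call with the highest support; two passing calls naming
   different subfamilies are flagged as a conflict and fall through to
   the margin rule. This keeps the outcome deterministic where a curator
   would otherwise adjudicate by eye.
2. **Five-orders margin.** The query's profile maps each subfamily to the
   minimum E-value over hits to its references (multiple HSPs collapse to
   the best per pair). With best E₁ and next-best E₂, assign iff
   E₁ ≤ `margin`·E₂, inclusive, with `margin` = 1e-5. The comparison is a
   pure ratio, hence invariant under global E-value rescaling. Zero or
   underflowed E-values are floored at `evalue_floor` = 1e-180 before the
   ratio, far below anything a search reports. A profile hitting only one
   subfamily has no ratio; it qualifies only below an absolute ceiling
   (`solo_hit_ceiling` = 1e-10), a conservative stand-in for a case the
   margin rule leaves undefined.
3. **Unclassified** queries keep family membership but no subfamily.

Within-subfamily clade calls re-run the tree rule restricted to one
subfamily's clade-level anchors. Because any clade-free stretch of the
path collapses identically, this equals evaluating on the subtree spanned
by the subfamily's references plus the query; a query attaching below the
clades' common stem stays subfamily-level-only.

Boundary conventions: the support comparison is strict (`> 50`), matching
the usual "greater than 50% bootstrap" phrasing; the margin and domain
E-value comparisons are inclusive (≤), chosen for floating-point
robustness — the difference is measure-zero.

## Curation filters

* **Longest isoform**: one record per `gene_id`, the longest sequence;
  length ties break to the lexicographically smallest accession so reruns
  are identical.
* **Domain requirement**: keep records with ≥ 1 annotation of the
  required domain at E ≤ `domain_max_evalue` (default 1e-4, the usual
  profile-search cutoff for diagnostic domains such as Cyclin_N). The
  filter is an exact partition of its input.
* **RBH exclusion**: a record is removed iff it forms a reciprocal best
  hit (mutual minimum-E-value partner, ties lexicographic) with a listed
  non-family reference (e.g. CABLES/CNTD homologs among Cyclin_N
  carriers). Both hit directions are required; RBH is undecidable from
  one.
* **Guide-tree screen**: a candidate whose first reference-containing
  ancestor holds only non-family anchors (e.g. MAP kinases among CDK
  candidates) is discarded; a mixed ancestor keeps the candidate with an
  ambiguity flag — inclusion errs toward the downstream classifier, which
  can still reject it.
* **Alignment trimming**: columns whose gap fraction exceeds
  `max_gap_fraction` (default 0.5) are dropped and a column map is
  emitted. Published pipelines often remove "poorly aligned positions"
  manually; the gap-fraction rule is a reproducible stand-in, not a
  reconstruction of any manual choice, and the threshold is recorded in
  output provenance. At threshold 1.0 it is the identity and the retained
  column count is monotone in the threshold.

## Synthetic benchmark generator

The generator produces families with known truth so every stage is
testable without downloads. K founder subfamilies (default 8, the size of
the CDK scheme) each evolve independently down a species tree under a
linear birth–death process: duplications (rate λ, default 0.2 per unit
branch length) bifurcate a gene lineage within a species branch, losses
(rate μ, default 0.1) terminate it, speciations copy it into both
descendant branches. Founder subtrees join the root through stem branches
(length 2.0), making subfamilies well-separated monophyletic groups — the
regime the classifier assumes. The shipped default species tree has 18
tips named for a representative metazoan/fungal/amoebozoan organism set;
its branch lengths are plausible rather than estimated, with a minimum
internal branch of 0.1. The expected surviving members per founder is
Σ_tips e^{(λ−μ)·depth}, the linear birth–death expectation, which the test
suite and acceptance script verify by Monte Carlo.

Observables are emulated, not inferred:

* **Supports**: an edge of length ℓ gets
  100·(1 − e^{−κℓ}) + ε, ε ~ N(0, `support_noise_sd`), rounded and
  clamped to [0, 100]. κ (default 25) makes branches ≥ 0.1 — every edge
  of the default species tree — exceed 90, so the no-duplication,
  noise-free configuration is "clean by construction".
* **E-values**: a (query, reference) pair at patristic distance d gets
  log₁₀E = −β·e^{−d/τ} + ε, floored at −180, with pairs above the
  reporting threshold (log₁₀E > −2) omitted. β = 50 and τ = 2 place
  within-subfamily hits for the most distant organisms near 1e-12–1e-15
  and nearest between-subfamily hits near 1e-5 — the magnitudes reported
  in comparative CDK/cyclin work, where distant within-subfamily
  orthologs still score ~1e-15 and related-but-distinct subfamilies
  remain clearly separated.
* One seed drives independent per-stage streams (tree, supports,
  E-values, sequences), so a stage regenerates in isolation and a bundle
  is byte-identical across reruns.

Reference anchors are one surviving member per subfamily from a
designated reference organism (default: the first species-tree tip,
mirroring the use of human proteins as anchors), falling back down the
tip order when the subfamily died out there. Optional toy sequences use a
Poisson substitution model over the 20-letter amino-acid alphabet —
enough to smoke-test sequence plumbing, with no claim to realism.

What the generator does **not** emulate: rate heterogeneity across sites
and lineages, alignment and inference error correlated across edges,
horizontal transfer, partial sequences and annotation artifacts, or
search-engine idiosyncrasies. Passing on synthetic data therefore shows
the decision logic is correct under the stated model, not that any
particular biological dataset will be classified correctly.

## Test and acceptance design

Unit tests fix small hand-computable trees and tables. Property tests
check the classifier against independent brute-force oracles: the
first-reference-ancestor walk and the tree rule against exhaustive clade
enumeration on random trees of ≤ 12 leaves; RBH against an all-pairs
scan; the margin rule against global rescaling. End-to-end tests require
100% truth recovery on clean bundles (no duplication/loss noise beyond
the model, supports > 90, noise-free E-values; 20 seeds) and a (weakly)
non-increasing recovery curve across E-value noise SDs {0, 0.5, 1, 2}
log₁₀ units. The degradation curve is measured with the tree signal
deliberately weakened (κ = 3, support noise 10) so the E-value pathway
carries the classification — under the defaults the tree rule alone
saturates recovery and the curve is flat. Common seeds across the noise
grid keep the comparison paired. Monte-Carlo problem sizes (1,000 random
trees/profiles/replicates, 20 seeds per condition) were chosen to keep
the full suite under a minute while leaving standard errors well below
the asserted margins.

One check in the acceptance suite — reproduction of the published
per-organism census for the curated 18-organism CDK (total 172) and
cyclin (total 226) sets — requires the third-party curated FASTA files,
which are not redistributable here; the test states the expected table
and fails with a clear message until those files are placed under
`data/supplementary/`.

## Known limitations

* The guide-tree screen and tree rule trust the input trees; no attempt
  is made to detect rogue taxa or conflicting signal beyond the
  multi-tree conflict flag.
* The five-orders solo-profile ceiling is a convention (1e-10); datasets
  whose searches report only one subfamily per query are sensitive to it.
* Clade-level calls inherit the subfamily-level support threshold; no
  separate calibration is attempted.
* The simulator's birth–death process is homogeneous in time and across
  subfamilies; empirical families violate both.
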