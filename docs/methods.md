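# Methods

This note documents the statistical procedures, the defaults and why they
are set where they are, what the synthetic-data generator does and does not
emulate, and the design choices made where more than one reasonable
definition existed.

## Analysis streams

### Essentiality

For a gene g, the dependent fraction is the number of cell lines with
dependency score strictly below the threshold divided by the number of
lines with a non-missing score for g. The threshold default is −0.5, the
recommended cutoff for CERES-style scores; the inequality is strict, so a
line at exactly −0.5 is not counted. Categories are assigned by the first
matching rule: **pan** (fraction ≥ 0.9), **strong** (≥ 0.30), **partial**
(n_dependent ≥ ⌈1% of tested lines⌉ — the ceiling makes "1% of 789 lines"
come out as 8), **rare** (n_dependent ≥ min_dependent_lines, default 3),
else **none**.

### Lineage-sensitivity scan

Each (gene, lineage) pair with at least `min_lineage_size` (default 5)
non-missing in-group scores is tested with a Welch unequal-variance
two-sided t-test of the lineage's scores against all other lines. Welch
rather than pooled Student is deliberate: the two groups (one lineage vs
the rest of a panel) have very unequal sizes and often unequal variances,
and Welch is the safe default in that regime. The reported effect is
`diff = mean_out − mean_in`, positive when the lineage is more sensitive.
BH correction is applied once across every pair tested in the run (a single
global family, the most literal reading of correcting "the p-values" of a
scan repeated over tumor types and genes); a pair is flagged when raw
p < 0.05 and q < 0.1. Pairs skipped for size reasons are returned in a
separate table with reason codes, never silently dropped.

### Co-dependency

Pairwise-complete Pearson correlation between the query gene's dependency
vector and every other gene's, requiring `min_codep_overlap` (default 10)
shared non-missing lines — the dependency matrix is dense in practice, so
this guard mostly protects degenerate inputs. Partners that are constant
over the shared support have undefined r and are omitted with a log entry
rather than assigned r = 0. Ranking is by descending |r| by default
("absolute" mode): negative co-dependents are genuine biology (e.g. a
negative regulator in the same pathway) and per-gene summaries display
both signs; "positive" mode (descending signed r) is available in the
configuration because the sign convention of published top-k lists is not
always stated. Ties break lexicographically by symbol so output is
deterministic. The top k = 7 partners feed the evidence integration; 5–10
give similar results and k is configurable. Co-dependency is only computed
for queries with at least `min_dependent_lines` dependent lines — a gene
whose knockout affects almost no line has a near-flat profile whose
correlations are noise.

### Proteomics co-expression

Pairwise-complete Pearson over jointly detected cell lines, restricted to
partners sharing at least `min_shared_lines` (default 100) detections with
the query; partners failing the rule are excluded *before* testing and do
not enter the FDR family. The family is per query gene across its eligible
partners, mirroring a per-DUB analysis. Significance requires BH q <
`coexpr_fdr` (default 0.01) **and** |z| > `coexpr_z` (default 2), where
z_i = (r_i − mean(r·)) / sd(r·) standardizes the query's vector of partner
correlations with the sample standard deviation. Standardizing within-query
is one of three defensible choices (within-partner and global are the
others); it is isolated in one place so an alternative (e.g. Fisher-
transform z) can be swapped without touching the scan.

### Interactions and perturbation similarity

Interaction edge lists are canonicalized (lexicographically ordered pairs,
self-edges dropped with a count) and compiled by union; provenance is the
union of source labels per edge, and compilation is idempotent. Tau
similarity scores are consumed, not computed: the flag is tau strictly
greater than `tau_threshold` (default 90), after resolving duplicate
(query, hit) rows to the maximum tau. A hit with any tau row is "tested";
absence of a row is recorded distinctly from "tested, not similar" in the
evidence table's `tau_tested` column. Any perturbation type qualifies for
the flag; the type column is carried through for users who want to
restrict it. `rank_similarity` — a Kendall-style concordance
(C − D) / (m(m−1)/2) over the genes common to two ranked lists — is an
auxiliary statistic for comparing ranked outputs; it is *not* a
reimplementation of compendium-percentile tau, which depends on a reference
signature compendium we do not model.

### Over-representation

Exact upper-tail hypergeometric probability, accumulated in log space
(log-gamma binomials, max-shifted log-sum-exp), stable for universes up to
~1e5 genes. Query and gene sets are intersected with the universe before
counting; sets empty within the universe are not tested; query genes
outside the universe are dropped with a warning (empty intersection is an
error naming the dropped genes). BH across tested sets; a term is
significant at q < 0.05. The universe default is the data source that
produced the query — panel columns for co-dependents — because published
ORA results are sensitive to the background and a per-source background is
the defensible default when none is stated. Ranked gene-set enrichment
(GSEA) is deliberately out of scope; ORA is the implemented test.

### Evidence integration

One row per (query, partner) pair flagged in ≥ 1 stream; `evidence_count`
is the sum of the four boolean flags and is re-derivable from them on every
row. The sparse enumeration (union of flagged partners) is the default
because all-pairs output is overwhelmingly zeros; an exhaustive mode emits
count-0 rows on request. Partners flagged by a non-panel stream but absent
from the dependency panel are retained and annotated (`in_panel = False`)
rather than dropped. The ligase network keeps pairs whose co-dependency
flag is true *and* whose partner is in the designated transferase gene set;
the other three flags annotate each edge. Per-gene summaries are pure
projections of the stream outputs (fraction and category, top enriched
term with q, top-k partners with r and flags); a gene with no term below
q < 0.05 carries an explicit null marker, and a gene with too few dependent
lines is marked not analyzed for co-dependency rather than omitted.

## Synthetic data generator

Dependency scores follow
`score(g,c) = base_mean + λ_g·f_{m(g),c} + shift·1[planted] + ε` with a
standard-normal factor f per complex per line, λ_g = factor_sd (0.6) for
complex members and 0 otherwise, and ε ~ N(0, noise_sd = 0.3). The implied
within-complex co-dependency is r = λ²/(λ²+σ²) = 0.8 — strong but
comparable to well-resolved complexes in real dependency data. The default
`base_mean = −0.2` with planted complexes shifted by the factor makes the
designated query genes "strong" dependencies, exercising the category
rules. Abundance uses the same module structure with per-gene mean offsets
and MCAR masking at rate 0.3. Real proteomics missingness is
abundance-dependent (censored at the detection limit), not MCAR; MCAR
suffices to exercise the ≥ 100-shared-lines rule, which is the behaviour
under test, but recovery results here say nothing about
missing-not-at-random bias. Edges are Bernoulli: 0.8 within complexes,
0.002 background, each edge attributed to one or both of two synthetic
sources so provenance merging is exercised. Tau is generated directly
(95 ± 2 for same-complex pairs, N(0, 30) truncated to [−100, 100]
otherwise) rather than derived from simulated expression, because the
pipeline consumes tau and computing compendium tau end-to-end is out of
scope.

Sizes: 200 genes × 300 lines × 8 lineages by default. 300 lines makes the
expected shared detection under 30% missingness ≈ 300·0.7² = 147, safely
above the 100-line rule (a 200-line panel would sit at ≈ 98 and starve the
co-expression stream), and is of the same order as real proteomics panels;
8 lineages of ~37 lines each comfortably clear the minimum lineage size.
Lineages are assigned by shuffled round-robin: membership is random but
sizes are balanced, so minimum-size eligibility is deterministic. The
first member of each planted complex is the designated query (the
DUB-analogue) and the second the designated E3-role gene; the gene-set
collection contains one set per complex plus a transferase set holding the
E3-role genes and a few background genes.

What passing tests show: the pipeline recovers planted structure of this
strength at these panel sizes with calibrated null behaviour. What they do
not show: performance under copy-number confounding, guide-level noise,
abundance-dependent missingness, symbol-alias mismatches across databases,
or complexes with much weaker latent factors — none of which the generator
models.

## Numerical choices and edge cases

- All symbol joins use uppercased, whitespace-stripped symbols; the
  Entrez suffix of dependency-matrix headers is parsed off and kept in a
  side map. No alias/ontology mapping is attempted; unmatched symbols
  surface in logs and in `in_panel`.
- Missing values are NaN internally, empty cells on disk; writers emit
  UTF-8 with LF endings and outputs are byte-reproducible given identical
  inputs and configuration (run manifests carry a config hash and no
  timestamps).
- Pearson r is clipped to [−1, 1] against floating-point overshoot; p uses
  the t transform on n−2 df.
- BH is the textbook step-up; it is not idempotent and is not asserted to
  be. q ≥ p elementwise and q follows the p-order by construction.
- Tie-breaks everywhere (co-dependency ranking, ORA ordering, evidence
  ordering) are lexicographic after the primary sort keys, so every output
  table has a single canonical order.
- Strictness of thresholds follows the source conventions: dependency
  score < −0.5, tau > 90, both strict; q-cutoffs are strict `<`.

## Known limitations

- Evidence counts treat the four streams as exchangeable votes; no
  weighting by stream reliability or effect size.
- The co-expression z definition is one convention among several; results
  near the |z| = 2 boundary can shift under a different standardization.
- The ORA universe choice materially affects p-values; it is logged and
  configurable but defaults are per-source, not a curated background.
- Lineage labels are compared as plain strings; hierarchical tumor-type
  relationships (e.g. a leukemia subtype inside a broader category) are
  not modelled.
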