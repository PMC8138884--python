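# Methods

## Model and objectives

An alteration matrix A ∈ {0,1}^(m×n) records whether sample s carries an
alteration in gene g.  For a gene subset G the two figures of merit are

* coverage γ(G) = |{s : ∃ g ∈ G, A(s,g) = 1}|, and
* overlap ω(G) = Σ_{g∈G} γ({g}) − γ(G),

where ω(G) equals the per-sample sum of max(0, k_s − 1) excess events
(k_s = number of altered G-genes in sample s).  This event-sum convention
is the standard one in the mutual-exclusivity literature; both the
"events beyond the first per sample" and the "co-occurrence count"
readings reduce to it, and the package asserts the equivalence by brute
force in its tests.  Multiple alteration types on one (sample, gene) cell
are collapsed to a single flag before objective computation; coverage is
kept as an integer count internally and formatted as a percentage with
one decimal only at the presentation layer.

Optimization is bi-objective: maximize γ and minimize either ω
(`coverage_overlap` mode) or |G| (`coverage_size` mode).  Subset a
dominates b iff γ(a) ≥ γ(b), second(a) ≤ second(b), strictly in at least
one coordinate.  The result of a run is the Pareto set: mutually
non-dominated (selection, objective-vector) pairs with pairwise distinct
vectors, sorted by coverage ascending.  When several selections share a
vector, the lexicographically smallest gene set (by sorted gene names) is
kept as the representative so output is deterministic.

## Evolutionary search

The search is a generational NSGA-II over binary membership vectors:

1. Initialize μ solutions, each gene included i.i.d. with probability
   p_sel.
2. Per iteration: rank the population by non-domination fronts and
   crowding distance; draw μ parents by size-τ tournaments (lower rank,
   then larger crowding, then a random tie-break); recombine consecutive
   pairs by uniform crossover with pair-level probability p_cx (each
   position swaps with probability 0.5 — membership bits are conserved
   position-wise); flip each offspring bit independently with probability
   p_mut; evaluate the μ offspring; truncate parents + offspring back to
   μ by rank then crowding.
3. Every evaluated solution feeds an external elitist archive holding
   the non-dominated set over the whole run; this archive, not the final
   population, is returned.  An archive is used because the crowding
   truncation of plain NSGA-II can drop extreme or thin regions of an
   integer-valued front; the archive is the safe superset and costs
   little since the objective space is small (coverage ≤ m).

Exactly μ objective evaluations are spent per iteration, so a run with k
iterations schedules μ·k evaluations (the μ initial evaluations are
accounted separately); with the default setup (μ = 100, k = 10^6) that
is 10^8 evaluations.  The evaluation counter is exposed on the returned
Pareto set and through the per-iteration progress callback.

Determinism: one seeded NumPy generator drives the entire run; identical
(matrix, parameters, seed) give identical Pareto sets.  Inside the loop
the tournament tie-break uses a fresh random permutation of the
population per generation as the final ordering key (a vectorization of
the per-draw uniform tie-break; the public `tournament_select` implements
the per-draw version literally).  Batch runs derive child seeds as
seed + run index.

### Parameter surface

Users configure runs through a "simple setup" in interpretable units,
mapped onto algorithm parameters for an n-gene candidate pool:

| simple setup                  | default | algorithm parameter            |
|-------------------------------|---------|--------------------------------|
| population size               | 100     | μ = 100                        |
| solution combination count    | 5       | p_cx = count / (μ/2) = 0.1     |
| initially selected genes      | 20      | p_sel = 20 / n                 |
| swapped genes (in expectation)| 2       | p_mut = 2 / n                  |
| selection pressure            | 10      | τ = 10 (tournament size)       |
| search steps                  | 10^6    | k = 10^6                       |

For n = 208 the defaults give p_sel ≈ 0.0962 and p_mut ≈ 0.0096.  The
p_cx mapping divides by μ/2 because crossover is decided once per
offspring pair, so μ/2 pairs at rate p_cx yield the configured expected
number of combinations.  "Swapped genes" is realized as independent
per-gene bit flips with matching expectation, not as an exchange of
exactly two genes.  Candidate-pool filters (e.g. the ≥ 5% frequency
filter) are applied *before* the mapping, so n is the filtered pool size.

### Exact oracle

`pareto_front_exact` enumerates all 2^n subsets (refusing n > max_genes,
default 20, rather than truncating silently) and applies the same
dedup/sort contract.  It is the independent correctness reference: on
small random instances (≤ 12 genes × ≤ 30 samples) the evolutionary
search at test scale (μ = 50, k = 500, tournament size 5, p_cx = 0.12,
p_sel = min(4, n)/n, p_mut = 2/n) reproduces the exact objective-vector
set in ≥ 95% of seeded runs; these test-scale sizes were chosen as the
smallest instances for which the check is still meaningful while the
whole suite stays fast on one CPU.

## Gene and sample ordering

Gene order is greedy set cover: starting from an empty partial cover (or
an optional forced prefix), repeatedly append the gene covering the most
currently uncovered samples; ties break by higher total alteration count,
then matrix column order; once no gene adds new samples the rest follow
by decreasing total count.  Consequently marginal gains are
non-increasing along the order and the first gene is a single-gene
coverage maximizer.  Sample order is the memo-sort convention: within
each group, samples sort by their binary pattern over the gene order read
as a binary number (first gene most significant), descending, ties by
sample id — the canonical oncoprint staircase.  Both orderings are pure
functions; covered-at-least-once semantics are used (overlap does not
influence ordering).

## Preprocessing

* **Binarization**: gene-wise overexpression calling at
  value > mean + c·SD with c = 1 by default; SD is the sample standard
  deviation (ddof = 1, configurable), missing values are excluded from
  the statistics and never called altered, the comparison is strict, and
  constant or < 2-finite-value genes yield no alterations.  The call is
  invariant under positive affine transforms of a gene's values.
* **Study merging**: gene-set union, primary study wins on duplicate
  samples, absent cells are 0; alteration kinds must match.
* **Clinical operations**: attribute regrouping via rename maps;
  attribute derivation via first-match-wins condition lists (with
  MISSING / PRESENT sentinels) that never overwrite existing values
  unless asked; sample filtering via ordered drop clauses that report
  per-clause deletion counts; gene filtering via whitelist plus an
  inclusive in-group frequency threshold.

All operations are pure and compose.  The packaged HNSCC-style pipeline
is: binarize → harmonize primary sites → derive HPV status from p16 and
site (p16 positivity counts only in the oropharynx; p16-negative means
HPV-negative; otherwise missing — the rule is data, not code, and can be
replaced) → drop lip, hypopharynx and missing-HPV samples → keep
CTA-listed genes at ≥ 5% in-cohort frequency.

## Synthetic data

The planted-module generator controls exactly what the optimizer must
recover: per module, a module_coverage fraction of samples (drawn without
replacement, so coverage is exact) receives one uniformly chosen module
gene; with probability module_overlap_rate a covered sample receives one
extra, distinct module gene (at most one — richer co-occurrence is out of
scope); noise genes are altered i.i.d.  Defaults — 200 samples, one
4-gene module at 90% coverage and zero planted overlap, 20 noise genes at
5% — define the reference recovery scenario: the size-4 Pareto entry
equals the planted module in ≥ 90% of seeded test-scale runs.  The
cohort size of 200 matches typical tumor-cohort scales.

The HNSCC-like fixture emulates cohort *counts*, not biology: 522
samples across eight raw site labels (including exactly 2 lip and 10
hypopharynx), exactly 19 samples from the retained sites left without a
derivable HPV status, a site split of roughly 63% oral cavity / 23%
oropharynx / 15% larynx among survivors with ~73% HPV-positivity in the
oropharynx, and 240 genes of which exactly 208 CTA-named genes carry
planted overexpression outliers (≥ 26 per gene among the 491 surviving
samples, placed at ~7 on a standard-normal background so they clear the
mean + 1 SD threshold with a wide margin and the 5% frequency filter).
Twelve CTA genes are constant (no overexpression) and 20 informative
genes fall outside the keep list, so the pipeline's gene count is pinned
from both sides.  What passing tests on this fixture shows: the pipeline
arithmetic (deletion counts, filter boundaries, derivation precedence) is
correct.  What it does not show: robustness to real expression
distributions, batch effects, or ambiguous clinical coding.

## Rendering

SVG is written by a small internal builder with fixed float formatting
and no timestamps, so identical inputs produce byte-identical files; the
test suite parses the output as XML and checks cell-count identities
(filled cells = Σ γ({g}), overlap-colored cells = ω(G)).  "First
alteration in sample" is resolved against the displayed gene order
(topmost row), the only context in which "first" is defined.  Defaults:
blue `#1f77b4` first-alteration cells, green `#2ca02c` overlap cells,
magenta `#cc00cc` highlights — all overridable via `PlotStyle`.  PDF and
PNG export render the same geometry through matplotlib.

## Interfaces and configuration

The CLI (`paretomut`) exposes `synth`, `import`, `preprocess`,
`optimize`, `batch`, `report` and `plot` subcommands; configuration files
are versioned YAML (a deliberately diffable, testable format), datasets
travel as TSV bundles with a small JSON manifest, and Pareto sets as TSV
tables.  Batch mode executes runs in worker processes, derives child
seeds deterministically, isolates per-run output directories, continues
past individual failures, and prints progress lines of the form
`Runs: r/R - Progress: p% - Estimated Duration: HH:MM:SS`, where the
percentage is completed scheduled evaluations over the total and the
estimate is elapsed · (1 − p)/p.

## Known limitations

* The overlap definition is the event-sum convention; weighted or
  per-type variants are not supported.
* Only bi-objective search is implemented (no three-objective mode, no
  alternative MOEAs such as SPEA2 or MOEA/D).
* The exact oracle is exponential and refuses pools beyond 20 genes.
* Sample ordering supports the memo-sort convention only.
* Readers accept delimited text (and MAF-dialect record lists); there is
  no live database import, VCF/CNA parsing, or GUI.
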