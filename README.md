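# paretomut

Pareto-optimal gene-subset selection from binary somatic alteration
matrices, with oncoprint-style visualization.

## The problem

Cancer cohorts are commonly summarized as a binary *alteration matrix*:
samples × genes, with a 1 wherever a sample carries an alteration
(mutation, overexpression, methylation) in a gene.  Many applications —
driver-module discovery, panel design, selection of shared vaccination
antigens — need a *small* gene subset G ⊆ 𝒢 that represents the cohort
well.  Two properties compete:

* **coverage** γ(G): the number of samples with ≥ 1 alteration in any
  gene of G (to be maximized), and
* **overlap** ω(G) = Σ_{g∈G} γ({g}) − γ(G): alteration events beyond the
  first per sample (to be minimized; ω(G) = 0 means the genes of G are
  perfectly mutually exclusive) — or alternatively the subset size |G|.

Rather than fixing an arbitrary weight between the objectives, `paretomut`
searches for the full **Pareto set** 𝒮\* ⊆ 𝒮 = {G ⊆ 𝒢}: all subsets not
dominated in (γ, ω) or (γ, |G|).  The search is an NSGA-II-style
generational evolutionary algorithm over binary gene-membership vectors
(tournament selection, uniform crossover, per-gene bit-flip mutation,
non-domination rank + crowding-distance truncation) with an external
elitist archive, so the returned front is the non-dominated set of *every*
solution evaluated during the run.  An exact enumeration oracle is
included for small instances, and a greedy set-cover gene ordering plus
memo-sort sample ordering produce reproducible waterfall alteration plots
(blue = first alteration in a sample, green = overlapping alterations).

The package also ships the preprocessing steps used for expression
cohorts (standard-deviation-threshold overexpression calling, study
merging, clinical attribute harmonization and derivation, sample/gene
filtering) and a synthetic-data generator that plants mutually exclusive
gene modules with known ground truth.

## Worked example

Plant a 4-gene mutually exclusive module covering 90% of 200 samples
among 20 noise genes, then recover the trade-off front:

```python
import paretomut as pm

matrix, modules = pm.generate_planted(pm.PlantedModuleConfig(seed=0))
setup = pm.SimpleSetup(population_size=50, solution_combination_count=3,
                       initially_selected_genes=4, swapped_genes=2,
                       selection_pressure=5, search_steps=500)
params = pm.simple_to_algorithm_params(setup, n_genes=matrix.n_genes, seed=0)
pareto = pm.evolve(matrix, matrix.gene_ids, pm.COVERAGE_SIZE, params)
for sel, vec in pareto.entries[:5]:
    print(vec.coverage, vec.second, ",".join(sel.members))
sel, vec = pareto.max_coverage_within_size(4)
print("best with <=4 genes:", vec.as_tuple(), sel.members)
```

prints

```
0 0
56 1 MOD1_G3
102 2 MOD1_G3,MOD1_G4
144 3 MOD1_G1,MOD1_G3,MOD1_G4
180 4 MOD1_G1,MOD1_G2,MOD1_G3,MOD1_G4
best with <=4 genes: (180, 4) ('MOD1_G1', 'MOD1_G2', 'MOD1_G3', 'MOD1_G4')
```

Each Pareto entry is one optimal trade-off: e.g. 180/200 samples (90.0%)
covered with 4 genes — exactly the planted module, recovered from 25 000
objective evaluations.  The coverage-maximal entry under a size budget
(here ≤ 4 genes) mirrors the "largest coverage with at most s genes"
selection rule used when composing a multi-antigen panel.

The same workflow is available from the shell:

```sh
paretomut synth planted -o data/planted --seed 0
paretomut optimize -f run.yaml -o results/run1
paretomut batch -f batch.yaml -o results/batch -t 6
paretomut plot alteration -d data/planted --genes MOD1_G1,MOD1_G2,MOD1_G3,MOD1_G4 -o module.svg
paretomut report -p results/run1/pareto.tsv -s 10
```

`paretomut synth hnsc` generates a 522-sample head-and-neck (HNSCC-like)
expression + clinical fixture; `paretomut preprocess` runs the full
pipeline on it — overexpression calling at mean + 1 SD, primary-site
harmonization, HPV-status derivation from p16 and site, deletion of the
lip / hypopharynx / missing-HPV samples, and the cancer-testis-antigen
keep-list with a 5% in-cohort frequency filter — yielding a 491-sample ×
208-gene analysis-ready dataset.

## Layout

```
src/paretomut/
  metrics.py    alteration matrix, gene selections, coverage & overlap
  moea.py       NSGA-II search, Pareto set, exact brute-force oracle
  ordering.py   greedy set-cover gene order, memo-sort sample order
  io.py         delimited/MAF readers, binarization, clinical preprocessing
  plotting.py   deterministic SVG (plus PDF/PNG) figure rendering
  synthetic.py  planted-module generator, HNSCC-like fixture
  config.py     run configs, batch driver with progress reporting
  cli.py        `paretomut` command-line interface
```

See `docs/methods.md` for the model, algorithmic choices and limitations.
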