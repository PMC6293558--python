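# sgcopt

Multi-objective optimality analysis of the standard genetic code (SGC).

The SGC maps 64 codons onto 20 amino acids and the stop signal. The adaptive
view of its evolution holds that similar amino acids got similar codons so
that point mutations and translational errors cause cheap replacements. This
package quantifies that claim by *searching* the space of theoretical codes
for the extremes — codes that minimize and codes that maximize replacement
costs — and locating the SGC between them, instead of comparing it to random
codes.

## The model

Two code spaces are searched, both with the stop codons UAA/UAG/UGA pinned:

* **BS (block structure)** — codes that keep the SGC's partition of the 61
  sense codons into 20 codon blocks and permute amino acids across blocks;
* **US (unrestricted)** — any surjective assignment of the 61 sense codons
  to the 20 amino acids (≈1.51·10⁸⁴ surjective assignments exist for the
  full 64→21 problem).

Replacement costs come from eight representative AAindex property scales
(BLAM930101, BIOV880101, MAXF760101, TSAJ990101, NAKH920108, CEDJ970104,
LIFS790101, MIYS990104), each turned into a max-normalized squared-difference
cost matrix. The objective for index *i* is

F_i(code) = Σ_{⟨c₁,c₂⟩∈C} [p_i(c₁) − p_i(c₂)]²,

summed over the set *C* of the 263 sense–sense codon pairs one point
mutation apart, with p_i the (normalized) property of the encoded amino
acid. Codes are evolved with a customized SPEA2 — strength/raw/density
fitness, a bounded elitist archive with k-nearest-neighbour truncation and
binary tournament selection — in both directions (cost-minimizing "best" and
cost-maximizing "worst" codes), with model-specific swap/point mutation and
structure-preserving crossover operators. A single-objective variant of the
same loop handles each index separately.

The SGC is then placed between the extremes with

* m_s = 100% · db/dbw (single objective; db = |F(SGC) − F(best)|,
  dbw = |F(worst) − F(best)|),
* m_min = 100% · db_min/(db_min + dw_min) and m_mean analogously
  (multi-objective; minimum/average Euclidean distances from the SGC's
  objective vector to the best and worst Pareto sets),

and structurally with d_str, the Hamming count of sense codons assigned
different amino acids (maximum 61 with fixed stops). Values below 50% mean
the SGC sits closer to the best codes than to the worst.

## Worked example

Locate the SGC between the best and worst block-structure codes for the
MIYS990104 partition-energy scale (desk scale: population 300, archive 50,
300 generations, 5 repeats per direction):

```python
import sgcopt as sg

mats = [sg.cost_matrix(i) for i in sg.load_builtin_indices(("MIYS990104",))]
sgc_cost = sg.evaluate_objectives(sg.standard_code(), mats).values[0]

runs = {}
for direction in ("minimize", "maximize"):
    cfg = sg.EngineConfig(population_size=300, archive_cap=50,
                          generations=300, model="BS", repeats=5,
                          seed=2018, direction=direction,
                          objectives=("MIYS990104",))
    runs[direction] = sg.run_repeats(cfg, mats)

best = min(m.objectives.values[0]
           for r in runs["minimize"] for m in r.archive.members)
worst = max(m.objectives.values[0]
            for r in runs["maximize"] for m in r.archive.members)
result = sg.m_s(sgc_cost, best, worst)
print(f"F(SGC)   = {sgc_cost:.3f}")
print(f"F(best)  = {best:.3f}")
print(f"F(worst) = {worst:.3f}")
print(f"m_s      = {result.value:.2f}%")
```

prints

```
F(SGC)   = 27.912
F(best)  = 20.317
F(worst) = 75.376
m_s      = 13.79%
```

The SGC's summed MIYS cost (27.9) sits 14% of the way along the range from
the best evolved code (20.3) to the worst (75.4): strongly biased toward
error minimization for this property, though clearly improvable.

The same experiment runs from the shell with a YAML config:

```
sgcopt run --config experiment.yaml --out results/
sgcopt tables --out results/          # deviation table + Spearman stats
sgcopt fixtures --out syn.txt --n 8   # synthetic indices for offline tests
```

`sgcopt run` writes per-direction archives (serialized codes + objective
columns), JSON-lines generation logs and a `measures.json` with
m_s or m_min/m_mean, the dominance-count histogram and the d_str summary.

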