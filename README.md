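# dmcminer

Drug-metabolite-cluster data mining for LC-MS^n metabolite
identification.

Comprehensive metabolite profiling of a drug candidate is hard because
metabolites of metabolites — products of sequential phase-I/phase-II
biotransformation — sit far from the parent mass and drown in
endogenous background.  `dmcminer` implements the *drug metabolite
cluster* (DMC) strategy for this problem: every confirmed metabolite
becomes a new cluster center around which the next generation of
candidates is predicted, so the search radiates outward through
primary, secondary and tertiary metabolism instead of stopping at
direct products of the parent drug.  It is aimed at mass-spectrometry
practitioners doing in-vivo metabolism studies on a hybrid
trap/orbitrap platform, and ships with a fully ground-truthed
synthetic-run generator so every stage is testable without instrument
data.

The toolkit covers, per stage:

* **Mass engine** — elemental-formula arithmetic on monoisotopic
  masses; [M+H]+/[M−H]− ion m/z; ppm errors; mass defects; RDB
  equivalents; molecular-formula decomposition of an accurate ion m/z
  under the constraints C[0–30] H[0–50] O[0–20] S[0–2] N[0–3],
  RDB [0–15], 5 ppm.
* **Network expansion** — a reaction-template library (oxidation,
  methylation/demethylation, methoxylation/demethoxylation, flavanone
  and chalcone formation, ring-cleavage losses, glucuronidation,
  sulfation) expanded breadth-first into a generation-ranked directed
  multigraph; confirmed nodes are promoted to centers and re-expanded.
* **MS^1 screening** — high-resolution extracted ion chromatograms
  (±5 ppm), polarity intensity thresholds (10,000 neg / 40,000 pos),
  and multiple mass-defect filtering (±50 mDa over ±50 Da windows
  around each center, its glucuronide and its sulfate).
* **MS^n confirmation** — neutral-loss rules (CH3·, H2O, CO, SO3 80 Da,
  glucuronyl 176 Da, ...), the n × 15 methyl-ladder screen, and
  retro-Diels-Alder diagnostic product ions (151+X flavone, 211
  flavanone base peak, 221/197 chalcone) combined into a skeleton
  classifier over precursor-linked MS^2→MS^3 trees.
* **Reporting** — identification tables (theoretical/experimental m/z,
  ppm error, reaction path, skeleton class, identified/potential
  status), GraphML/DOT cluster graphs, and summaries.

## Worked example

Simulate a run with the prototype drug C19H18O7 plus five planted
metabolites, then mine it end to end:

```python
from dmcminer import (parse_formula, build_manifest, generate_run,
                      run_pipeline, PipelineConfig, summarize)

htf = parse_formula("C19H18O7")                   # the prototype drug
manifest = build_manifest(htf, n_nodes=5, seed=17, sigma_ppm=1.0)
run = generate_run(manifest)                      # one positive-mode run
records, graph = run_pipeline([run], htf, PipelineConfig(random_seed=17))
print(summarize(records)["status"])
for r in records[:6]:
    obs = next(iter(r.observations.values()))
    print(r.label, r.neutral_formula.hill(), r.generation,
          f"{obs.theoretical_mz:.5f}", f"{obs.experimental_mz:.5f}",
          f"{obs.error_ppm:.1f}", r.status, r.reaction)
```

prints

```
{'identified': 6, 'potential': 4}
M0 C19H18O7 0 359.11253 359.11171 -2.3 identified Prototype
M1 C18H14O7 1 343.08123 343.08080 -1.3 identified Methane Loss
M2 C18H16O6 1 329.10196 329.10215 0.6 identified Demethoxylation
M3 C18H16O7 1 345.09688 345.09689 0.0 identified Demethylation
M4 C18H18O6 1 331.11761 331.11724 -1.1 identified Carbonyl Loss
M5 C19H18O10S 1 439.06934 439.06949 0.3 identified Sulfation
```

All six planted metabolites are recovered at their correct generations
with sub-2.5-ppm mass errors; the four *potential* records are
generation-2 predictions whose ion m/z collides with a planted isomer
in MS^1 but whose MS^n evidence contradicts them — they are kept,
flagged, and not promoted.  The same loop at the standard benchmark
size (20 planted metabolites over three generations, 2 ppm error)
gives recall 1.0 with zero false positives
(`dmcminer.recovery_experiment`).

A command-line interface wraps the same functions:

```
dmcminer simulate --plan-nodes 20 --seed 42 --out run.tsv
dmcminer run --runs run.tsv --out results/
dmcminer predict --max-generation 3 --out dmc.graphml
dmcminer pil --polarity pos            # parent-ion inclusion list
dmcminer benchmark --plan-nodes 20
```

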