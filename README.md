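# domainage

Age-stratified analysis of protein domain architectures: phylostratigraphic
dating of Pfam-style domains and proteins, classification of how young
(lineage-specific) domains combined with older ones, positional bias of
young-domain insertion, and per-domain-region dN/dS comparison between age
classes — with a seeded synthetic-data generator so every stage is testable
without external downloads.

It is aimed at molecular-evolution work of the kind done on human-mouse
orthologue panels: given per-species domain-hit tables, phyletic
presence/absence profiles across ranked clades, and pairwise codon
alignments of 1:1 orthologous coding sequences, it answers

* how old is each domain type (oldest occupied clade, tolerating secondary
  losses) and each protein (oldest domain; homology fallback for domainless
  proteins);
* did a young domain arise in a new gene or get gained by an existing older
  protein (gain-dependent / mutual / fusion / complex arrangement classes
  over domain configuration sets);
* where do young domains insert (N-terminal / internal / C-terminal,
  chi-square against a uniform-insertion null);
* do young domains evolve faster (NG86 dN/dS with Jukes-Cantor correction:
  dN = -3/4 ln(1 - 4 pN / 3), omega = dN/dS; Kolmogorov-Smirnov across age
  classes, paired Wilcoxon and an exact binomial test on substitution counts
  within proteins).

See `docs/methods.md` for the model, all defaults and known limitations.

## Worked example

The `analysis/` scripts run the whole study on a seeded synthetic bundle
whose ground truth is known:

```sh
python analysis/01_simulate_dataset.py   # writes results/synthetic_bundle/
python analysis/02_assign_ages.py
python analysis/03_classify_architectures.py
python analysis/04_estimate_rates.py
python analysis/05_report.py
```

Selected output (seed 42):

```
dated 207 domain types -> results/ages/domain_ages.tsv
recovery vs ledger: 207/207 (100.0%)
scenario classes: {'GAIN_DEPENDENT': 45, 'MUTUAL_DEPENDENCE': 3, 'FUSION': 7, 'COMPLEX': 9}
2-domain stratum: observed {'N_terminal': 31, 'C_terminal': 14}, chi2 = 6.42, p = 0.0113
rates estimated for 462 regions, 414 pass filters
     group   n   median
 Mammalian  25 0.361417
       Old 243 0.101410
Vertebrate 146 0.189144
paired Wilcoxon: W = 259.0, p = 2.93e-07
paired binomial verdicts: {'young_faster': 31, 'old_faster': 0, 'no_difference': 32}
```

Reading it: with the origin-clade guarantee on, the oldest-hit rule recovers
every simulated domain age; the arrangement classifier reproduces the
generator's regime counts exactly; the young domain sits N-terminally far
more often than the even null expects; and median omega falls with age
(0.36 mammalian-specific, 0.19 vertebrate-specific, 0.10 old), with the
young member evolving faster in every significant within-protein pair.

The same operations are available as a CLI (`domainage simulate | ages |
report | all`) and as plain library calls:

```python
from domainage import SimulationParams, generate_bundle, run_analysis
report = run_analysis(generate_bundle(SimulationParams(), seed=42))
print(report.group_comparison.group_stats)
```

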