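# lynxrescue

Genetic monitoring and genetic-rescue planning for small, inbred wildlife
populations, built around the case of a reintroduced Eurasian lynx
population: founded in 1973 by six partially related animals, monitored
with a 19-locus microsatellite panel, and reinforced with 12 translocated
animals in 2019–2023.

The package has two halves that feed each other:

* **Monitoring statistics** for multilocus genotype tables — observed and
  Nei's unbiased expected heterozygosity, alleles per locus,
  `F_is = 1 − H_o/H_e`, *effective inbreeding* against the source
  population `Fe = 1 − H_target/H_source`, a travelling-window Fe time
  series, allele-dosage PCA, and effective population size from linkage
  disequilibrium (bias-corrected Burrows r², MAF 0.02 exclusion,
  delete-one-locus jackknife CIs).
* An **individual-based genetic–demographic simulator** — overlapping
  generations, polygynous seasonal mating, Mendelian inheritance over the
  marker panel, exact pedigree identity-by-descent, inbreeding-load
  survival `exp(−B·F)` with B lethal equivalents, carrying capacity and
  translocation events — plus founder calibration of B, management
  scenarios (no action, the completed reinforcement, periodic
  translocation programmes, minimum group sizes against an inbreeding
  threshold of 0.15), and a random-forest sensitivity metamodel ranked by
  mean decrease in impurity.

A `synthetic` module generates a complete stand-in study system (source
populations, a drifted descendant, dated longitudinal samples), so every
stage is testable without the original supplementary tables. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
from lynxrescue import diversity_summary, travelling_window_fe, ld_ne
from lynxrescue.scenarios import ScenarioSpec, calibrate_founders, run_scenario
from lynxrescue.synthetic import generate_study_data

study = generate_study_data(seed=8)
dataset, sources = study["dataset"], study["sources"]

print(diversity_summary(dataset).round(3))
ske = sources["slovakia"].expected_heterozygosity()
din = dataset.subset(population="dinaric", include_translocated=False)
tw = travelling_window_fe(din, source_he=ske, window_width=60, basis="expected")
est = ld_ne(dataset, population="dinaric", min_year=2011, max_year=2019)

cal = calibrate_founders(sources["slovakia"],
                         b_grid=[0.1, 0.6, 0.85, 1.1, 1.35, 1.6, 2.1, 3.1, 4.6],
                         n_iterations=60, seed=2)
no_action = run_scenario(
    ScenarioSpec(label="no-action", interval=None, include_reinforcement=False,
                 horizon=60),
    sources, cal.snapshots, f_pool=cal.f_distribution, n_replicates=30, seed=3)
print(cal.selected_b, no_action.extinction_summary())
```

Printed by this exact pipeline (`python scripts/acceptance.py --seed 1 ...`):

```
              n     he  he_se     ho  ho_se      a   a_se
population
dinaric     152  0.520  0.039  0.503  0.041  4.684  0.242
romania      22  0.525  0.040  0.550  0.045  3.368  0.256
slovakia     48  0.589  0.037  0.582  0.043  4.526  0.280
travelling-window Fe: first 0.145 last 0.186
recent LD-Ne: 31.2 (95% CI 14.7-763.5)
selected B = 0.85; baseline mean IBD = 0.245
no action: 100% extinct, mean extinction year 22.9
```

Reading the numbers: the reintroduced ("dinaric") population is less
diverse than its source, its effective inbreeding rises through the
sampling record, and its recent effective population size is far below the
census — the classic signature of a bottlenecked, drifting population. The
calibration selects an inbreeding load near one haploid lethal equivalent,
and without intervention the simulated population collapses within a few
decades; the reinforcement scenario delays the relapse of inbreeding past
the warning threshold by decades.

## Command line

A thin CLI wraps the library:

```sh
lynxrescue stats diversity genotypes.csv
lynxrescue stats fe-window genotypes.csv --source-he 0.583 --width 60 --basis expected
lynxrescue stats ldne genotypes.csv --maf 0.02 --from-year 2011
lynxrescue stats pca genotypes.csv -o scores.csv
lynxrescue synth freqs --target-he 0.583 --seed 1 -o freqs.csv
lynxrescue calibrate --source-freqs freqs.csv --b-grid 0.1:6:0.5 --iterations 100
lynxrescue simulate --config scenario.yaml --replicates 50 --seed 1
```

Genotypes travel as a long CSV (`individual_id, population, date, sex,
translocated, locus, allele1, allele2`; missing = `0`) or GenePop files;
allele-frequency tables as CSV (`population, locus, allele, frequency`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the main computation from scratch — synthetic study generation,
monitoring statistics, founder calibration, and the no-action and
completed-reinforcement scenarios — printing a summary and writing the
JSON results file.
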