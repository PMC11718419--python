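# Methods

This note documents the models, estimators and design choices behind
`lynxrescue`, and what its synthetic test world does and does not
establish.

## The scientific setting

A small reintroduced carnivore population, founded in 1973 by six
partially related animals from a large Carpathian source population,
accumulated inbreeding for four and a half decades and was reinforced with
12 translocated animals in 2019–2023. The package implements both sides of
the assessment of such a genetic rescue: (i) monitoring statistics on
multilocus microsatellite genotypes, and (ii) a forward-time
individual-based genetic–demographic simulator used to calibrate the
inbreeding load, project population viability under management scenarios,
and rank the drivers of the projections with a random-forest metamodel.

## Monitoring statistics (`diversity`, `ldne`)

* **Heterozygosities.** Observed heterozygosity is the per-locus fraction
  of heterozygous scored individuals; expected heterozygosity is Nei's
  unbiased estimator `He = 2n/(2n−1) · (1 − Σ p_i²)`. Per-population
  values are reported as means ± SE **across loci**, matching the standard
  per-population presentation.
* **Effective inbreeding.** `Fe = 1 − H_target/H_source` measures the
  drift component of Wright's hierarchy for a reintroduced population
  against its source gene pool: under random mating within the derived
  population (F_is ≈ 0), Fe is the inbreeding a random mating carries
  relative to the source. Fe may be negative during admixture transients
  (a Wahlund-type heterozygosity excess after mixing).
* **Travelling window.** Records are date-ordered (year resolution; ties
  broken by individual id) and a fixed-width window (default 60
  individuals) advances one individual at a time; per window the mean
  multilocus heterozygosity on the chosen basis (observed or expected)
  enters the Fe formula with a *fixed* source-population heterozygosity in
  the denominator. Translocated animals and their descendants can be
  included or excluded to separate the realised from the
  without-intervention trend.
* **PCA.** Individuals are encoded as allele-dosage vectors (one column
  per allele per locus, value = fraction of copies ∈ {0, ½, 1}); missing
  calls are mean-imputed, columns centred but not scaled, and the
  covariance eigendecomposed via SVD. Percent variance is per-axis
  eigenvalue over the total.
* **LD-Ne.** Effective population size from the linkage disequilibrium a
  single sample of unlinked loci carries. Burrows' composite
  disequilibrium Δ is computed per allele pair of each locus pair and
  normalised to `r² = Δ²/(p(1−p)q(1−q))`; small-sample factors are chosen
  so that the null expectation of r̂² matches the published
  `E[r²|S] = 1/S + 3.19/S²` (S ≥ 30; the S < 30 variant otherwise), which
  is verified by simulation in the test suite. After subtracting the
  sampling expectation, Ne solves the quadratic drift relation of the
  bias-corrected method (random-mating variant). Alleles with frequency
  < 0.02 are excluded by default. Confidence intervals use a
  **delete-one-locus jackknife**: locus pairs sharing a locus are strongly
  correlated, and a pair-level jackknife understates the variance (≈60–70%
  realised coverage in calibration experiments, vs 93–97% for locus
  blocks). A corrected r̂² at or below zero is reported as an infinite
  estimate — the sample carries no measurable drift signal. Known
  limitation: two coexisting gene pools (right after translocations)
  inflate r² and bias Ne sharply downward; the simulator reproduces this
  transient.

## Pedigree inbreeding (`pedigree`)

Kinship follows the classic tabular recursion with founder self-kinship
`(1+f)/2` for a founder baseline f, and *declared founder kinships* for
known relationships among founders whose parents are outside the pedigree
(the 1973 founding is encoded as a mother–son pair and a sibling pair,
kinship ¼ each). An individual's inbreeding coefficient F is the kinship
of its parents. Correctness is checked against gene-dropping Monte Carlo
and textbook values.

## The individual-based simulator (`simulate`)

One time step = one year = one mating season; generations overlap.

| parameter | default | meaning |
|---|---|---|
| natural mortality | 0.13 / y | baseline yearly death probability, all ages |
| juvenile mortality | 0.5 | first-year mortality, applied right after mating |
| litter size | Normal(2.1, 0.9), rounded, ≥ 0 | kittens per mated female |
| lethal equivalents B | 1.1 | haploid load; survival factor `exp(−B·F)` |
| carrying capacity K | 240 adults | ceiling on adults |
| breeding age | > 2 years | both sexes |
| max age | 16 y | removal after this age |
| census ceiling | None (scenarios: start census) | recruitment-limited total-size target |

Females mate at most once per season with a uniformly chosen breeding-age
male (males may mate repeatedly); offspring inherit one uniformly chosen
allele per locus from each parent. Kinship among the living is maintained
incrementally (a newborn's kinship row is the mean of its parents' rows),
so per-individual F is exact pedigree identity-by-descent with no
recursion at simulation time.

**Inbreeding-load survival.** Survival probabilities `exp(−B·F)` are drawn
as independent Bernoulli events *for every individual, every year*
(`load_applies="all"`), separate from the baseline mortalities. A
newborn-only variant is available; with it the demographic feedback of
inbreeding depression disappears and the population is stable at the
observed inbreeding levels, which contradicts the documented decline —
this is why the annual variant is the default.

**Population regulation.** Two mechanisms: (i) the adult carrying
capacity (reproduction suppressed at K, random overflow adults removed —
a hard ceiling, so the adult count never exceeds K after the first step);
(ii) an optional recruitment-limited census ceiling: each season newborn
recruits only top the total population up to the target size, mortality
may push it below, and standing animals are never culled by this
mechanism. The second mirrors size-controlled mating schemes of classical
individual-based frameworks and is the constraint that actually binds in
management scenarios; the 240-adult cap binds only in unconstrained runs.

**Extinction** is zero census or the loss of one sex across all age
classes (functional extinction).

**Translocations** add animals drawn from a source allele-frequency table
(sources are treated as infinite, mortality- and drift-free gene pools);
they enter as unrelated pedigree founders with F = 0, aged uniformly 2–4,
and carry a heritable translocated-lineage flag.

## Founder calibration and scenarios (`scenarios`)

* **Calibration.** For each lethal-equivalents value B on a grid, the 1973
  founding (six animals sampled from the source gene pool, declared
  founder relationships as above, 3 females / 3 males) is replayed for 45
  years over many iterations. The replicate-mean trajectory is scored
  against the monitoring series: mean |ΔFe| at the three travelling-window
  epochs (years 12, 32, 45 ≙ mid-1980s, mid-2000s, 2018) plus the mean
  normalised |ΔNe| against the recent LD-Ne estimate (13.4) at years 32
  and 42, equally weighted. A B whose foundings essentially never survive
  the horizon (< 5% of runs) is excluded: the real population persisted,
  and a never-surviving parameterisation yields no baseline-IBD
  distribution to carry forward. The best B's surviving end states provide
  (i) snapshot populations and (ii) the pooled distribution of individual
  IBD values used to seed scenario starts.
* **Scenario starts.** Each replicate re-initialises a drawn calibration
  end state at the empirical census scale (default 110, backed out of the
  recent estimate of 156 after the documented > 40% growth during the
  reinforcement years): genotypes are sampled from the end state's allele
  frequencies, individual F values from the calibrated IBD distribution,
  and the between-individual background kinship is set to `(F_i + F_j)/2`
  so that the baseline inbreeding level propagates to offspring instead of
  collapsing to zero. Ages follow a truncated negative binomial (mean 4,
  dispersion 2).
* **Schedules.** The completed reinforcement is 12 animals over five
  annual events (3+2+3+2+2), sources alternating between the two
  Carpathian tables, sexes as even as possible. Periodic programmes start
  one generation (5 y) after the reinforcement ends and run for 50 years;
  totals per 50 years are reported under both floor and round conventions
  because the published table is internally inconsistent on this point.
* **Thresholds.** The warning (0.15) and critical (0.25, full-sib
  equivalent) inbreeding thresholds are judged on the **replicate-mean
  effective-inbreeding curve** by default. Pedigree-IBD judging is
  available, but Fe is what makes source populations distinguishable: all
  immigrants enter the pedigree as unrelated F = 0 founders, so IBD
  dynamics cannot prefer one source over another, whereas a more
  divergent source restores more heterozygosity per animal.
* **Minimum translocation sizes** search ascending group sizes per event
  until the mean curve stays below the warning threshold throughout the
  programme window (odd groups alternate the extra animal's sex). All
  translocated animals are assumed to survive and reproduce.

## Metamodel (`metamodel`)

Latin-hypercube designs over (a) demographic/genetic inputs — natural
mortality 0.05–0.30, lethal equivalents 0.1–6 (the calibration grid),
kitten survival 0.30–0.70, litter size 1.5–3.0, starting census 40–240 —
and (b) programme inputs — interval ∈ {3,5,10,15,20,25} y, males and
females per event 0–5 (≥ 1 animal), source population. Each design row
runs reduced-replicate simulations; outputs (mean IBD, LD-Ne, expected
heterozygosity) are taken at fixed evaluation years, with the last
observed state carried forward for runs that collapse earlier — dropping
those rows would discard precisely the informative, collapsing corner of
parameter space. One random forest (500 trees) is fitted per output ×
evaluation year on an 80/20 split; mean-decrease-in-impurity importances
(normalised to 1 per model) are averaged across models with a 95% CI, and
held-out MSE is reported per output.

## The synthetic world (`synthetic`)

Generators produce: source allele-frequency tables (Dirichlet draws per
locus, tuned by mixing toward/away from uniformity until the mean expected
heterozygosity hits a target — 0.583 and 0.545 for the two source
stand-ins); a drifted descendant population (six related founders, 45
years, mild load B = 0.3 with a census ceiling of 130 — parameters chosen
once so the end state matches the documented structure: He ≈ 0.46,
surviving census ≈ 100, Fe in the 0.2–0.35 band); and dated longitudinal
samples in which each individual is genotyped once (opportunistic
historical sampling, intensified recent seasons), plus a flagged
reinforcement cohort. Everything is seed-reproducible, and the drifted
generator conditions on lineage survival by deterministic retries — the
monitored population is, by construction, a surviving one.

A green test on this world establishes that the estimators and the
simulation machinery are correct and that the pipeline reproduces the
*structure* of the empirical analysis; it does not certify the published
per-locus table values, which require the original genotype table.

## Known limitations

* Mate choice is uniform among breeding-age males — no territoriality,
  dominance or reproductive skew beyond polygyny. This caps the model's
  Ne/census ratio near 0.4–0.6, whereas the monitored system shows ≈ 0.1
  (Ne 13.4 at a census of 110–130). Consequently, scenario projections at
  the empirical census scale lose diversity several-fold more slowly than
  drift-matched expectations; the calibration phase is unaffected because
  the founding bottleneck keeps the simulated census small.
* Sources are infinite and constant; no cost model, no failed
  integrations of translocated animals, no spatial structure.
* LD-Ne inside simulations is computed from samples of ≤ 50 individuals
  to mirror monitoring practice, inheriting that estimator's admixture
  bias (which is itself a documented phenomenon of interest).
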