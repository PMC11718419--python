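"""Forward-time, overlapping-generation individual-based simulator.

Models a small felid population with yearly time steps (one mating season
per year): polygynous mating among individuals older than the minimum
breeding age, Gaussian litter sizes, Mendelian inheritance over a
microsatellite panel, pedigree-exact identity-by-descent (IBD) inbreeding,
an inbreeding-load survival term exp(-B*F) with B haploid lethal
equivalents, baseline juvenile and natural mortality, a carrying capacity
expressed as a ceiling on adults, and translocations from source
populations of infinite size represented by allele-frequency tables.

Kinship between all living individuals is maintained incrementally: when a
child of (s, d) is born,

    f(child, x)      = (f(s, x) + f(d, x)) / 2
    f(child, child)  = (1 + f(s, d)) / 2
    F_child          = f(s, d)

so per-individual F is exact pedigree IBD without any recursion at
simulation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import (
    AlleleFrequencyTable,
    GenotypeDataset,
    GenotypeRecord,
    MarkerPanel,
)
from .ldne import ld_ne_from_calls

__all__ = [
    "DemographicParams",
    "TranslocationEvent",
    "Population",
    "Newborns",
    "TrajectorySet",
    "initialize_population",
    "population_from_founders",
    "mating_step",
    "survival_step",
    "translocate",
    "step_year",
    "run_simulation",
]

FEMALE, MALE = 0, 1


@dataclass
class DemographicParams:
    """Demographic and genetic parameters of the simulated population.

    Defaults are the study system's values: yearly natural mortality 0.13,
    first-year (juvenile) mortality 0.5, litter size 2.1 +/- 0.9 kittens,
    B = 1.1 haploid lethal equivalents, carrying capacity 240 adults,
    breeding restricted to animals older than 2 years.
    """

    natural_mortality: float = 0.13
    juvenile_mortality: float = 0.5
    litter_mean: float = 2.1
    litter_sd: float = 0.9
    lethal_equivalents: float = 1.1
    carrying_capacity: int = 240
    min_breeding_age: int = 2  # breeding requires age > min_breeding_age
    max_age: int = 16
    load_applies: str = "all"  # {"all", "newborns"}: who faces exp(-B*F)
    k_strategy: str = "suppress"  # {"suppress", "cull"}
    # recruitment-limited ceiling on TOTAL census (the mating season tops the
    # population up with newborn recruits only to this size, mirroring a
    # size-controlled mating scheme); None disables it.  Mortality can push
    # the census below the ceiling, and translocations may transiently
    # exceed it -- standing animals are never removed by this mechanism.
    census_ceiling: int | None = None

    def __post_init__(self):
        for name in ("natural_mortality", "juvenile_mortality"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying capacity must be positive")
        if self.load_applies not in ("all", "newborns"):
            raise ValueError("load_applies must be 'all' or 'newborns'")
        if self.k_strategy not in ("suppress", "cull"):
            raise ValueError("k_strategy must be 'suppress' or 'cull'")


@dataclass
class TranslocationEvent:
    year: int
    source: AlleleFrequencyTable
    n_males: int
    n_females: int

    def __post_init__(self):
        if self.n_males < 0 or self.n_females < 0:
            raise ValueError("translocation counts must be >= 0")


class Population:
    """Array-backed set of individuals with an incrementally maintained
    kinship matrix and a parent log (the realised pedigree)."""

    def __init__(self, loci, allele_labels):
        self.loci = list(loci)
        self.allele_labels = [list(a) for a in allele_labels]
        n0 = 0
        L = len(self.loci)
        self.ids = np.empty(0, dtype=np.int64)
        self.age = np.empty(0, dtype=np.int32)
        self.sex = np.empty(0, dtype=np.int8)
        self.F = np.empty(0, dtype=np.float64)
        self.lineage = np.empty(0, dtype=bool)
        self.genotypes = np.empty((n0, L, 2), dtype=np.int16)
        self.kinship = np.empty((0, 0), dtype=np.float64)
        self.pedigree_log: list[tuple[int, int, int]] = []
        self.next_id = 0
        self.year = 0

    # -- basic views ------------------------------------------------------

    @property
    def census(self) -> int:
        return len(self.ids)

    def adults(self, params: DemographicParams) -> np.ndarray:
        return self.age > params.min_breeding_age

    def n_adults(self, params: DemographicParams) -> int:
        return int(self.adults(params).sum())

    def copy(self) -> "Population":
        new = Population(self.loci, self.allele_labels)
        for name in ("ids", "age", "sex", "F", "lineage", "genotypes", "kinship"):
            setattr(new, name, getattr(self, name).copy())
        new.pedigree_log = list(self.pedigree_log)
        new.next_id = self.next_id
        new.year = self.year
        return new

    # -- genetic summaries ------------------------------------------------

    def expected_heterozygosity(self) -> float:
        """Mean over loci of 1 - sum p^2 from the current gene pool."""
        if self.census == 0:
            return np.nan
        vals = []
        for j in range(len(self.loci)):
            flat = self.genotypes[:, j, :].reshape(-1)
            counts = np.bincount(flat)
            p = counts / flat.size
            vals.append(1.0 - float(np.sum(p**2)))
        return float(np.mean(vals))

    def observed_heterozygosity(self) -> float:
        if self.census == 0:
            return np.nan
        het = self.genotypes[:, :, 0] != self.genotypes[:, :, 1]
        return float(het.mean())

    def allele_frequencies(self, population: str = "simulated") -> AlleleFrequencyTable:
        freqs: dict[str, dict[str, float]] = {}
        for j, locus in enumerate(self.loci):
            flat = self.genotypes[:, j, :].reshape(-1)
            counts = np.bincount(flat, minlength=len(self.allele_labels[j]))
            p = counts / flat.size
            freqs[locus] = {
                self.allele_labels[j][k]: float(p[k])
                for k in range(len(p))
                if p[k] > 0
            }
        return AlleleFrequencyTable(
            population=population, frequencies=freqs, n_source=self.census
        )

    def sample_calls(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Allele-call array of a random sample (for LD-Ne monitoring)."""
        idx = rng.choice(self.census, size=min(n, self.census), replace=False)
        return np.asarray(self.genotypes[idx], dtype=np.int32)

    def to_genotype_dataset(
        self,
        population: str,
        date: str | None = None,
        indices=None,
        id_prefix: str = "sim",
    ) -> GenotypeDataset:
        idx = np.arange(self.census) if indices is None else np.asarray(indices)
        records = []
        for i in idx:
            genotype = {
                locus: (
                    self.allele_labels[j][self.genotypes[i, j, 0]],
                    self.allele_labels[j][self.genotypes[i, j, 1]],
                )
                for j, locus in enumerate(self.loci)
            }
            records.append(
                GenotypeRecord(
                    individual_id=f"{id_prefix}{self.ids[i]}",
                    population=population,
                    date=date,
                    sex="F" if self.sex[i] == FEMALE else "M",
                    translocated=bool(self.lineage[i]),
                    genotype=genotype,
                )
            )
        return GenotypeDataset(MarkerPanel(tuple(self.loci)), records)

    # -- mutation of state ------------------------------------------------

    def _append(self, age, sex, F, lineage, genotypes, kin_rows, kin_diag, sires=None, dams=None):
        """Append m individuals; kin_rows is (m, n_old) kinship to residents,
        kin_diag the new diagonal block (m, m)."""
        m = len(age)
        new_ids = np.arange(self.next_id, self.next_id + m, dtype=np.int64)
        self.next_id += m
        n_old = self.census
        k = np.empty((n_old + m, n_old + m))
        k[:n_old, :n_old] = self.kinship
        k[n_old:, :n_old] = kin_rows
        k[:n_old, n_old:] = kin_rows.T
        k[n_old:, n_old:] = kin_diag
        self.kinship = k
        self.ids = np.concatenate([self.ids, new_ids])
        self.age = np.concatenate([self.age, np.asarray(age, dtype=np.int32)])
        self.sex = np.concatenate([self.sex, np.asarray(sex, dtype=np.int8)])
        self.F = np.concatenate([self.F, np.asarray(F, dtype=np.float64)])
        self.lineage = np.concatenate([self.lineage, np.asarray(lineage, dtype=bool)])
        self.genotypes = np.concatenate(
            [self.genotypes, np.asarray(genotypes, dtype=np.int16)], axis=0
        )
        if sires is None:
            sires = dams = np.full(m, -1, dtype=np.int64)
        for i in range(m):
            self.pedigree_log.append((int(new_ids[i]), int(sires[i]), int(dams[i])))
        return new_ids

    def keep(self, mask: np.ndarray) -> None:
        idx = np.nonzero(mask)[0]
        self.ids = self.ids[idx]
        self.age = self.age[idx]
        self.sex = self.sex[idx]
        self.F = self.F[idx]
        self.lineage = self.lineage[idx]
        self.genotypes = self.genotypes[idx]
        self.kinship = self.kinship[np.ix_(idx, idx)]


def _sample_genotypes_from_freqs(
    freqs: AlleleFrequencyTable, loci, allele_labels, n, rng
) -> np.ndarray:
    """Draw n diploid genotypes allele-wise from a frequency table, coding
    alleles against (and extending) allele_labels in place."""
    L = len(loci)
    out = np.empty((n, L, 2), dtype=np.int16)
    for j, locus in enumerate(loci):
        fmap = freqs.frequencies[locus]
        labels = allele_labels[j]
        for a in fmap:
            if a not in labels:
                labels.append(a)
        codes = np.array([labels.index(a) for a in fmap], dtype=np.int16)
        p = np.fromiter(fmap.values(), dtype=float)
        p = p / p.sum()
        draws = rng.choice(codes, size=(n, 2), p=p)
        out[:, j, :] = draws
    return out


def initialize_population(
    freqs: AlleleFrequencyTable,
    n: int,
    rng: np.random.Generator,
    params: DemographicParams | None = None,
    baseline_f=None,
    background_kinship: str = "mean_f",
    age_mean: float = 4.0,
    age_dispersion: float = 2.0,
    year: int = 0,
) -> Population:
    """Population of n individuals drawn from an allele-frequency table.

    Genotypes are sampled allele-wise from ``freqs``; sexes are
    Bernoulli(0.5); ages follow a negative binomial (mean ``age_mean``,
    dispersion ``age_dispersion``) truncated at max_age.  ``baseline_f`` is
    an empirical sample of IBD values (e.g. from founder calibration) drawn
    from with replacement; with ``background_kinship="mean_f"`` the pairwise
    kinship between starting individuals is set to (F_i + F_j)/2 so that the
    baseline inbreeding level carries forward to offspring instead of
    collapsing to zero.
    """
    if n <= 0:
        raise ValueError("initial population size must be positive")
    params = params or DemographicParams()
    if background_kinship not in ("mean_f", "zero"):
        raise ValueError("background_kinship must be 'mean_f' or 'zero'")
    pop = Population(list(freqs.loci), [[] for _ in freqs.loci])
    genotypes = _sample_genotypes_from_freqs(
        freqs, pop.loci, pop.allele_labels, n, rng
    )
    sex = rng.integers(0, 2, size=n).astype(np.int8)
    p_nb = age_dispersion / (age_dispersion + age_mean)
    age = np.minimum(rng.negative_binomial(age_dispersion, p_nb, size=n), params.max_age)
    if baseline_f is None:
        F = np.zeros(n)
    else:
        base = np.atleast_1d(np.asarray(baseline_f, dtype=float))
        F = base[rng.integers(0, base.size, size=n)]
    if background_kinship == "mean_f":
        rows = 0.5 * (F[:, None] + F[None, :])
    else:
        rows = np.zeros((n, n))
    diag = 0.5 * (1.0 + F)
    np.fill_diagonal(rows, diag)
    pop._append(age, sex, F, np.zeros(n, dtype=bool), genotypes, np.empty((n, 0)), rows)
    pop.year = year
    return pop


def population_from_founders(
    freqs: AlleleFrequencyTable,
    n_founders: int,
    rng: np.random.Generator,
    founder_kinships: dict[tuple[int, int], float] | None = None,
    sexes=None,
    ages=None,
    year: int = 0,
) -> Population:
    """A founding group sampled from a source gene pool.

    ``founder_kinships`` declares known relationships between founder
    indices (0-based), e.g. {(0, 1): 0.25, (2, 3): 0.25} for a mother-son
    pair and a sibling pair.
    """
    pop = Population(list(freqs.loci), [[] for _ in freqs.loci])
    genotypes = _sample_genotypes_from_freqs(
        freqs, pop.loci, pop.allele_labels, n_founders, rng
    )
    if sexes is None:
        sexes = np.array([FEMALE, MALE] * (n_founders // 2 + 1))[:n_founders]
    if ages is None:
        ages = rng.integers(2, 6, size=n_founders)
    kin = np.zeros((n_founders, n_founders))
    np.fill_diagonal(kin, 0.5)
    for (i, j), v in (founder_kinships or {}).items():
        kin[i, j] = kin[j, i] = v
    pop._append(
        np.asarray(ages),
        np.asarray(sexes, dtype=np.int8),
        np.zeros(n_founders),
        np.zeros(n_founders, dtype=bool),
        genotypes,
        np.empty((n_founders, 0)),
        kin,
    )
    pop.year = year
    return pop


@dataclass
class Newborns:
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    genotypes: np.ndarray
    F: np.ndarray
    lineage: np.ndarray

    @property
    def count(self) -> int:
        return len(self.F)

    @classmethod
    def empty(cls, L: int) -> "Newborns":
        z = np.empty(0, dtype=np.int64)
        return cls(z, z, np.empty((0, L, 2), dtype=np.int16), np.empty(0), np.empty(0, dtype=bool))


def mating_step(
    pop: Population, params: DemographicParams, rng: np.random.Generator
) -> Newborns:
    """One mating season.

    Every breeding-age female mates at most once with a uniformly chosen
    breeding-age male (males may mate repeatedly); litter sizes are
    Normal(litter_mean, litter_sd) rounded and clipped at zero; each
    offspring inherits one uniformly chosen allele per locus from each
    parent; offspring F is the pedigree kinship of its parents.
    """
    L = len(pop.loci)
    breeding = pop.adults(params)
    females = np.nonzero(breeding & (pop.sex == FEMALE))[0]
    males = np.nonzero(breeding & (pop.sex == MALE))[0]
    if len(females) == 0 or len(males) == 0:
        return Newborns.empty(L)
    litters = np.clip(np.rint(rng.normal(params.litter_mean, params.litter_sd, size=len(females))), 0, None).astype(int)
    mates = males[rng.integers(0, len(males), size=len(females))]
    dam_idx = np.repeat(females, litters)
    sire_idx = np.repeat(mates, litters)
    m = len(dam_idx)
    if m == 0:
        return Newborns.empty(L)
    pick_d = rng.integers(0, 2, size=(m, L))
    pick_s = rng.integers(0, 2, size=(m, L))
    gen = np.empty((m, L, 2), dtype=np.int16)
    ar = np.arange(L)
    gen[:, :, 0] = pop.genotypes[dam_idx][:, ar, :][np.arange(m)[:, None], ar, pick_d]
    gen[:, :, 1] = pop.genotypes[sire_idx][:, ar, :][np.arange(m)[:, None], ar, pick_s]
    F = pop.kinship[sire_idx, dam_idx]
    lineage = pop.lineage[sire_idx] | pop.lineage[dam_idx]
    return Newborns(sire_idx, dam_idx, gen, F, lineage)


def survival_step(
    pop: Population, newborns: Newborns, params: DemographicParams, rng: np.random.Generator
) -> None:
    """Apply mortality, recruit surviving newborns, advance ages by one year.

    Newborns survive their first year with probability
    (1 - juvenile_mortality); the inbreeding-load factor exp(-B*F) is a
    separate Bernoulli survival event applied to every individual
    (load_applies="all", default) or to newborns only ("newborns"); all
    survivors then face the yearly natural mortality, and animals beyond
    max_age are removed.
    """
    B = params.lethal_equivalents
    # newborn first-year survival
    p_new = np.full(newborns.count, 1.0 - params.juvenile_mortality)
    p_new *= np.exp(-B * newborns.F)
    p_new *= 1.0 - params.natural_mortality
    alive_new = rng.random(newborns.count) < p_new
    # residents
    n = pop.census
    p_res = np.full(n, 1.0 - params.natural_mortality)
    if params.load_applies == "all":
        p_res *= np.exp(-B * pop.F)
    alive_res = rng.random(n) < p_res
    alive_res &= pop.age + 1 <= params.max_age

    # kinship rows for surviving newborns, from the pre-survival matrix
    s_idx = newborns.sire_idx[alive_new]
    d_idx = newborns.dam_idx[alive_new]
    m = len(s_idx)
    if m:
        rows_full = 0.5 * (pop.kinship[s_idx, :] + pop.kinship[d_idx, :])  # m x n_old
        blk = 0.25 * (
            pop.kinship[np.ix_(s_idx, s_idx)]
            + pop.kinship[np.ix_(s_idx, d_idx)]
            + pop.kinship[np.ix_(d_idx, s_idx)]
            + pop.kinship[np.ix_(d_idx, d_idx)]
        )
        np.fill_diagonal(blk, 0.5 * (1.0 + newborns.F[alive_new]))
        sire_ids = pop.ids[s_idx]
        dam_ids = pop.ids[d_idx]
    pop.keep(alive_res)
    pop.age += 1
    if m and params.census_ceiling is not None:
        room = max(0, params.census_ceiling - pop.census)
        if m > room:  # drop random excess recruits, never standing animals
            sel = rng.permutation(m)[:room]
            sel.sort()
            s_idx, d_idx = s_idx[sel], d_idx[sel]
            sire_ids, dam_ids = sire_ids[sel], dam_ids[sel]
            rows_full = rows_full[sel]
            blk = blk[np.ix_(sel, sel)]
            alive_pos = np.nonzero(alive_new)[0][sel]
            alive_new = np.zeros_like(alive_new)
            alive_new[alive_pos] = True
            m = room
    if m:
        keep_cols = np.nonzero(alive_res)[0]
        pop._append(
            np.ones(m, dtype=np.int32),  # newborns turn 1 with the year advance
            rng.integers(0, 2, size=m).astype(np.int8),
            newborns.F[alive_new],
            newborns.lineage[alive_new],
            newborns.genotypes[alive_new],
            rows_full[:, keep_cols],
            blk,
            sires=sire_ids,
            dams=dam_ids,
        )


def translocate(
    pop: Population,
    event: TranslocationEvent,
    rng: np.random.Generator,
    age_range: tuple[int, int] = (2, 4),
) -> None:
    """Add translocated adults drawn from a source frequency table.

    They enter as pedigree founders: F = 0 and zero kinship to residents;
    their translocated-lineage flag is inherited by all descendants.
    """
    m = event.n_males + event.n_females
    if m == 0:
        return
    genotypes = _sample_genotypes_from_freqs(
        event.source, pop.loci, pop.allele_labels, m, rng
    )
    sex = np.array([MALE] * event.n_males + [FEMALE] * event.n_females, dtype=np.int8)
    age = rng.integers(age_range[0], age_range[1] + 1, size=m)
    rows = np.zeros((m, pop.census))
    diag = np.zeros((m, m))
    np.fill_diagonal(diag, 0.5)
    pop._append(age, sex, np.zeros(m), np.ones(m, dtype=bool), genotypes, rows, diag)


def step_year(
    pop: Population,
    params: DemographicParams,
    rng: np.random.Generator,
    events: list[TranslocationEvent] | None = None,
) -> None:
    """One full yearly cycle: translocations, mating (suppressed at the
    adult carrying capacity), survival/recruitment, K enforcement."""
    for ev in events or ():
        translocate(pop, ev, rng)
    at_capacity = pop.n_adults(params) >= params.carrying_capacity
    if at_capacity and params.k_strategy == "suppress":
        newborns = Newborns.empty(len(pop.loci))
    else:
        newborns = mating_step(pop, params, rng)
    survival_step(pop, newborns, params, rng)
    # hard ceiling on adults: remove random overflow
    excess = pop.n_adults(params) - params.carrying_capacity
    if excess > 0:
        adult_idx = np.nonzero(pop.adults(params))[0]
        drop = rng.choice(adult_idx, size=excess, replace=False)
        mask = np.ones(pop.census, dtype=bool)
        mask[drop] = False
        pop.keep(mask)
    pop.year += 1


def _is_extinct(pop: Population) -> bool:
    if pop.census == 0:
        return True
    return bool((pop.sex == FEMALE).sum() == 0 or (pop.sex == MALE).sum() == 0)


@dataclass
class TrajectorySet:
    """Tidy per-replicate, per-year trajectories of a simulation run."""

    frame: pd.DataFrame  # replicate, year, census, adults, ho, he, fe, mean_f, ne
    extinction_year: pd.Series  # per replicate; NaN = persisted

    METRICS = ("census", "adults", "ho", "he", "fe", "mean_f", "ne")

    def mean_by_year(self) -> pd.DataFrame:
        return self.frame.groupby("year")[list(self.METRICS)].mean()

    def std_by_year(self) -> pd.DataFrame:
        return self.frame.groupby("year")[list(self.METRICS)].std()

    def tidy(self) -> pd.DataFrame:
        return self.frame.melt(
            id_vars=["replicate", "year"], var_name="metric", value_name="value"
        )


def run_simulation(
    start,
    params: DemographicParams,
    n_years: int,
    n_replicates: int,
    seed: int,
    events: dict[int, list[TranslocationEvent]] | None = None,
    source_he: float | None = None,
    ne_years=None,
    ne_sample: int = 50,
    stop_at_extinction: bool = True,
) -> TrajectorySet:
    """Run replicate simulations and collect yearly trajectories.

    Parameters
    ----------
    start : Population or callable (replicate_index, rng) -> Population
        Starting state; a Population is copied per replicate.
    events : {year offset: [TranslocationEvent, ...]}
        Translocations applied at the start of the given year.
    source_he : float, optional
        Source-population expected heterozygosity for Fe = 1 - He/He_src.
    ne_years : iterable of ints, optional
        Years (offsets from start) at which to estimate LD-Ne from a random
        sample of min(ne_sample, census) individuals; None disables Ne
        estimation (it dominates runtime), "all" estimates every year.
    """
    events = events or {}
    for yr in events:
        if yr < 0 or yr > n_years:
            raise ValueError(f"translocation scheduled outside run horizon: year {yr}")
    if ne_years == "all":
        ne_years = range(n_years + 1)
    ne_set = set(ne_years) if ne_years is not None else set()
    rows = []
    ext = {}
    root = np.random.SeedSequence(seed)
    for rep, child in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        pop = start(rep, rng) if callable(start) else start.copy()
        for ev in events.get(0, ()):  # events in the starting year
            translocate(pop, ev, rng)
        extinct_year = np.nan
        for t in range(n_years + 1):
            extinct = _is_extinct(pop)
            if extinct and np.isnan(extinct_year):
                extinct_year = t
            if extinct:
                rows.append((rep, t, pop.census, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
                if stop_at_extinction:
                    break
            else:
                he = pop.expected_heterozygosity()
                ho = pop.observed_heterozygosity()
                fe = (
                    1.0 - he / source_he if source_he else np.nan
                )
                ne = np.nan
                if t in ne_set and pop.census >= 10:
                    try:
                        est = ld_ne_from_calls(pop.sample_calls(ne_sample, rng))
                        ne = est.ne if est.is_finite else np.nan
                    except ValueError:
                        ne = np.nan
                rows.append(
                    (
                        rep,
                        t,
                        pop.census,
                        pop.n_adults(params),
                        ho,
                        he,
                        fe,
                        float(pop.F.mean()),
                        ne,
                    )
                )
            if t < n_years and not extinct:
                step_year(pop, params, rng, events.get(t + 1))
        ext[rep] = extinct_year
    frame = pd.DataFrame(
        rows,
        columns=["replicate", "year", "census", "adults", "ho", "he", "fe", "mean_f", "ne"],
    )
    return TrajectorySet(frame=frame, extinction_year=pd.Series(ext, name="extinction_year"))
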