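"""Genetic diversity, inbreeding and structure statistics.

Implements the monitoring statistics used to track a reintroduced
population against its source: observed heterozygosity Ho, Nei's unbiased
expected heterozygosity He, alleles per locus A, the inbreeding
coefficients F_is = 1 - Ho/He and "effective inbreeding"
Fe = 1 - H_target/H_source (the drift component of Wright's hierarchy for a
population measured against its source gene pool), a travelling-window Fe
time series, and PCA of allele-dosage genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeDataset, dataset_to_arrays

__all__ = [
    "LocusStatistics",
    "DiversitySummary",
    "PcaResult",
    "observed_heterozygosity",
    "expected_heterozygosity_nei",
    "allelic_diversity",
    "diversity_summary",
    "effective_inbreeding",
    "fis",
    "travelling_window_fe",
    "pca_genotypes",
]


@dataclass
class LocusStatistics:
    """Per-locus values of one statistic with mean +/- SE over loci."""

    per_locus: pd.Series
    mean: float
    se: float
    n: int  # individuals used

    def __float__(self) -> float:
        return self.mean


def _summarise(values: pd.Series, n: int) -> LocusStatistics:
    vals = values.dropna()
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return LocusStatistics(per_locus=values, mean=mean, se=se, n=n)


def _select(dataset: GenotypeDataset, population, loci):
    sub = dataset.subset(population=population) if population else dataset
    if len(sub) == 0:
        raise ValueError(f"no records selected (population={population!r})")
    calls, loci, labels = dataset_to_arrays(sub, loci)
    return sub, calls, loci, labels


def observed_heterozygosity(
    dataset: GenotypeDataset, population: str | None = None, loci=None
) -> LocusStatistics:
    """Ho per locus = heterozygote count / scored individuals."""
    sub, calls, loci, _ = _select(dataset, population, loci)
    scored = calls[:, :, 0] >= 0
    het = scored & (calls[:, :, 0] != calls[:, :, 1])
    n_scored = scored.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_scored > 0, het.sum(axis=0) / n_scored, np.nan)
    return _summarise(pd.Series(ho, index=loci), n=len(sub))


def _locus_frequencies(calls: np.ndarray, j: int) -> tuple[np.ndarray, int]:
    """Allele frequency vector and scored-individual count at locus j."""
    col = calls[:, j, :]
    scored = col[col[:, 0] >= 0]
    if scored.size == 0:
        return np.array([]), 0
    flat = scored.reshape(-1)
    counts = np.bincount(flat)
    return counts / flat.size, scored.shape[0]


def expected_heterozygosity_nei(
    dataset: GenotypeDataset, population: str | None = None, loci=None
) -> LocusStatistics:
    """Nei's unbiased He = 2n/(2n-1) * (1 - sum p_i^2), n scored individuals.

    Loci with no scored genotype are skipped with a NaN; if every locus is
    skipped an error is raised.
    """
    sub, calls, loci, _ = _select(dataset, population, loci)
    he = []
    for j in range(len(loci)):
        p, n = _locus_frequencies(calls, j)
        if n == 0:
            he.append(np.nan)
            continue
        he.append((2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p**2))))
    series = pd.Series(he, index=loci)
    if series.isna().all():
        raise ValueError("no locus with scored genotypes in selection")
    return _summarise(series, n=len(sub))


def allelic_diversity(
    dataset: GenotypeDataset, population: str | None = None, loci=None
) -> LocusStatistics:
    """A = number of distinct observed alleles per locus."""
    sub, calls, loci, labels = _select(dataset, population, loci)
    a = pd.Series([float(len(lab)) if lab else np.nan for lab in labels], index=loci)
    return _summarise(a, n=len(sub))


def diversity_summary(
    dataset: GenotypeDataset, populations=None
) -> pd.DataFrame:
    """He/Ho/A summary table (one row per population, mean +/- SE over loci)."""
    pops = populations or dataset.populations
    rows = []
    for pop in pops:
        he = expected_heterozygosity_nei(dataset, pop)
        ho = observed_heterozygosity(dataset, pop)
        a = allelic_diversity(dataset, pop)
        rows.append((pop, he.n, he.mean, he.se, ho.mean, ho.se, a.mean, a.se))
    return pd.DataFrame(
        rows, columns=["population", "n", "he", "he_se", "ho", "ho_se", "a", "a_se"]
    ).set_index("population")


def effective_inbreeding(h_target: float, h_source: float) -> float:
    """Fe = 1 - H_target/H_source.

    The expected inbreeding of a random mating in the derived population
    relative to the source gene pool.  Negative when the target exceeds the
    source (e.g. transient Wahlund excess after admixture).
    """
    if h_source <= 0:
        raise ValueError("source heterozygosity must be positive")
    if not (0 <= h_target <= 1 and h_source <= 1):
        raise ValueError("heterozygosities must lie in [0, 1]")
    return 1.0 - h_target / h_source


def fis(dataset: GenotypeDataset, population: str | None = None) -> float:
    """Multilocus F_is = 1 - mean(Ho)/mean(He)."""
    he = expected_heterozygosity_nei(dataset, population).mean
    if he <= 0:
        raise ValueError("F_is undefined: expected heterozygosity is zero")
    ho = observed_heterozygosity(dataset, population).mean
    return 1.0 - ho / he


def travelling_window_fe(
    dataset: GenotypeDataset,
    source_he: float,
    window_width: int = 60,
    basis: str = "observed",
    include_translocated: bool = False,
    population: str | None = None,
) -> pd.DataFrame:
    """Sliding-window Fe through time.

    Records are date-ordered (ties broken by individual id) and a window of
    exactly ``window_width`` individuals advances one individual at a time;
    per window the mean multilocus heterozygosity on the chosen basis
    ({"observed", "expected"}) is compared with the fixed source value.

    Returns a frame with window start/centre/end years, the window
    heterozygosity and Fe.
    """
    if basis not in ("observed", "expected"):
        raise ValueError("basis must be 'observed' or 'expected'")
    sub = dataset.subset(population=population, include_translocated=include_translocated)
    sub = GenotypeDataset(sub.panel, [r for r in sub if r.year is not None])
    sub = sub.sorted_by_date()
    if len(sub) < window_width:
        raise ValueError(
            f"only {len(sub)} eligible records for window width {window_width}"
        )
    stat = observed_heterozygosity if basis == "observed" else expected_heterozygosity_nei
    rows = []
    for start in range(len(sub) - window_width + 1):
        window = GenotypeDataset(sub.panel, sub.records[start : start + window_width])
        years = [r.year for r in window]
        h = stat(window).mean
        rows.append(
            (
                years[0],
                float(np.median(years)),
                years[-1],
                h,
                effective_inbreeding(h, source_he),
            )
        )
    return pd.DataFrame(
        rows, columns=["start_year", "centre_year", "end_year", "h_window", "fe"]
    )


@dataclass
class PcaResult:
    """PCA of centred allele-dosage genotypes."""

    scores: pd.DataFrame  # individuals x axes
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    populations: pd.Series

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def dosage_matrix(
    dataset: GenotypeDataset,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Individuals x allele-dosage matrix (fraction of copies, 0/0.5/1).

    Missing calls are imputed to the column mean.  Returns (matrix,
    individual ids, column labels "locus:allele").
    """
    calls, loci, labels = dataset_to_arrays(dataset)
    n = calls.shape[0]
    cols = []
    names = []
    for j, locus in enumerate(loci):
        k = len(labels[j])
        if k == 0:
            continue
        scored = calls[:, j, 0] >= 0
        dose = np.zeros((n, k))
        for c in range(2):
            idx = calls[scored, j, c]
            dose[np.nonzero(scored)[0], idx] += 0.5
        if scored.any():
            mean = dose[scored].mean(axis=0)
        else:
            mean = np.zeros(k)
        dose[~scored] = mean
        cols.append(dose)
        names.extend(f"{locus}:{a}" for a in labels[j])
    X = np.hstack(cols)
    ids = [r.individual_id for r in dataset]
    return X, ids, names


def pca_genotypes(dataset: GenotypeDataset, n_axes: int | None = None) -> PcaResult:
    """PCA on the centred (unscaled) dosage covariance.

    Individuals with no scored locus at all are excluded.  Percent variance
    per axis is eigenvalue / total * 100 over all axes.
    """
    keep = [r for r in dataset if any(v is not None for v in r.genotype.values())]
    if len(keep) < 2:
        raise ValueError("PCA needs at least two genotyped individuals")
    ds = GenotypeDataset(dataset.panel, keep)
    X, ids, _ = dosage_matrix(ds)
    Xc = X - X.mean(axis=0)
    # SVD of the centred matrix == eigendecomposition of the covariance
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (Xc.shape[0] - 1)
    total = eig.sum()
    pct = 100 * eig / total if total > 0 else np.zeros_like(eig)
    scores = U * s
    if n_axes is not None:
        scores, eig, pct = scores[:, :n_axes], eig[:n_axes], pct[:n_axes]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=ids, columns=cols),
        eigenvalues=eig,
        percent_variance=pct,
        populations=pd.Series([r.population for r in ds], index=ids),
    )
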