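"""Containers and I/O for multilocus microsatellite genotype data.

The primary on-disk dialect is a long CSV with one row per (individual, locus):

    individual_id,population,date,sex,translocated,locus,allele1,allele2

Missing genotypes use the GenePop convention: allele "0" (or an empty cell)
on both columns.  A half-called genotype (one allele present, one missing)
is rejected.  GenePop files (4-digit allele coding) are supported for
interoperability with classic population-genetics software.

Allele identifiers are opaque strings; a genotype is an unordered pair, so
(A, B) and (B, A) are the same call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = "0"

__all__ = [
    "MISSING",
    "MarkerPanel",
    "GenotypeRecord",
    "GenotypeDataset",
    "AlleleFrequencyTable",
    "GenotypeValidationError",
    "read_genotypes",
    "write_genotypes",
    "read_allele_frequencies",
    "write_allele_frequencies",
    "compute_allele_frequencies",
    "dataset_to_arrays",
]


class GenotypeValidationError(ValueError):
    """Raised when a genotype table violates a structural invariant."""


def _norm_allele(value) -> str:
    if value is None:
        return MISSING
    s = str(value).strip()
    if s in ("", "nan", "NA", "na", "None"):
        return MISSING
    if s.endswith(".0") and s[:-2].isdigit():  # CSV round-trip through floats
        s = s[:-2]
    return s


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered, unique list of locus names."""

    loci: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "loci", tuple(str(l) for l in self.loci))
        if len(set(self.loci)) != len(self.loci):
            raise GenotypeValidationError("duplicate locus names in marker panel")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def index(self, locus: str) -> int:
        return self.loci.index(locus)


@dataclass
class GenotypeRecord:
    """One individual's diploid multilocus genotype plus sampling metadata."""

    individual_id: str
    population: str
    date: str | None = None  # ISO year "1998" or full date "1998-03-07"
    sex: str = "unknown"  # {"M", "F", "unknown"}
    translocated: bool = False  # translocated animal or its descendant
    genotype: dict[str, tuple[str, str] | None] = field(default_factory=dict)

    def __post_init__(self):
        if self.sex not in ("M", "F", "unknown"):
            raise GenotypeValidationError(
                f"individual {self.individual_id}: sex must be M/F/unknown, got {self.sex!r}"
            )
        clean: dict[str, tuple[str, str] | None] = {}
        for locus, call in self.genotype.items():
            if call is None:
                clean[locus] = None
                continue
            a1, a2 = (_norm_allele(call[0]), _norm_allele(call[1]))
            if (a1 == MISSING) != (a2 == MISSING):
                raise GenotypeValidationError(
                    f"individual {self.individual_id}, locus {locus}: half-called "
                    f"genotype ({a1!r}, {a2!r}); a locus needs 0 or 2 allele calls"
                )
            clean[locus] = None if a1 == MISSING else (a1, a2)
        self.genotype = clean

    @property
    def year(self) -> int | None:
        if self.date is None:
            return None
        return int(str(self.date)[:4])

    def call(self, locus: str) -> tuple[str, str] | None:
        return self.genotype.get(locus)

    def is_heterozygous(self, locus: str) -> bool | None:
        g = self.call(locus)
        if g is None:
            return None
        return g[0] != g[1]


class GenotypeDataset:
    """A marker panel plus a list of genotyped individuals."""

    def __init__(self, panel: MarkerPanel, records: Sequence[GenotypeRecord]):
        self.panel = panel
        self.records = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.individual_id in seen:
                raise GenotypeValidationError(
                    f"duplicate individual_id {rec.individual_id!r}"
                )
            seen.add(rec.individual_id)
            extra = set(rec.genotype) - set(panel.loci)
            if extra:
                raise GenotypeValidationError(
                    f"individual {rec.individual_id}: loci {sorted(extra)} "
                    "not in the marker panel"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def populations(self) -> list[str]:
        return sorted({r.population for r in self.records})

    def subset(
        self,
        population: str | None = None,
        include_translocated: bool = True,
        min_year: int | None = None,
        max_year: int | None = None,
    ) -> "GenotypeDataset":
        recs = self.records
        if population is not None:
            recs = [r for r in recs if r.population == population]
        if not include_translocated:
            recs = [r for r in recs if not r.translocated]
        if min_year is not None:
            recs = [r for r in recs if r.year is not None and r.year >= min_year]
        if max_year is not None:
            recs = [r for r in recs if r.year is not None and r.year <= max_year]
        return GenotypeDataset(self.panel, recs)

    def sorted_by_date(self) -> "GenotypeDataset":
        """Date order with individual_id as the deterministic tie-break."""
        keyed = sorted(
            self.records,
            key=lambda r: (r.year if r.year is not None else 10**9, r.individual_id),
        )
        return GenotypeDataset(self.panel, keyed)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            for locus in self.panel:
                call = rec.call(locus)
                a1, a2 = call if call is not None else (MISSING, MISSING)
                rows.append(
                    (
                        rec.individual_id,
                        rec.population,
                        rec.date if rec.date is not None else "",
                        rec.sex,
                        rec.translocated,
                        locus,
                        a1,
                        a2,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "individual_id",
                "population",
                "date",
                "sex",
                "translocated",
                "locus",
                "allele1",
                "allele2",
            ],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        if self.panel.loci != other.panel.loci or len(self) != len(other):
            return False
        for a, b in zip(self.records, other.records):
            ga = {l: (None if c is None else tuple(sorted(c))) for l, c in a.genotype.items() if c is not None}
            gb = {l: (None if c is None else tuple(sorted(c))) for l, c in b.genotype.items() if c is not None}
            if (
                a.individual_id != b.individual_id
                or a.population != b.population
                or a.year != b.year
                or a.sex != b.sex
                or a.translocated != b.translocated
                or ga != gb
            ):
                return False
        return True


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele -> frequency maps for one named population.

    ``n_source`` records how many individuals the frequencies were estimated
    from (0 when unknown or when the table is parametric/synthetic).
    """

    population: str
    frequencies: dict[str, dict[str, float]]
    n_source: int = 0

    def __post_init__(self):
        for locus, fmap in self.frequencies.items():
            total = float(sum(fmap.values()))
            if abs(total - 1.0) > 1e-6:
                raise GenotypeValidationError(
                    f"locus {locus}: allele frequencies sum to {total:.6f}, not 1"
                )
            for allele, f in fmap.items():
                if not (0.0 <= f <= 1.0 + 1e-12):
                    raise GenotypeValidationError(
                        f"locus {locus}, allele {allele}: frequency {f} outside [0,1]"
                    )
            # exact renormalisation so downstream samplers see sums of 1 - 1e-9
            self.frequencies[locus] = {a: f / total for a, f in fmap.items()}

    @property
    def loci(self) -> list[str]:
        return list(self.frequencies)

    def expected_heterozygosity(self) -> float:
        """Mean over loci of the plain gene diversity 1 - sum(p^2)."""
        vals = [
            1.0 - sum(f * f for f in fmap.values())
            for fmap in self.frequencies.values()
        ]
        return float(np.mean(vals))

    def per_locus_heterozygosity(self) -> pd.Series:
        return pd.Series(
            {
                locus: 1.0 - sum(f * f for f in fmap.values())
                for locus, fmap in self.frequencies.items()
            }
        )


# ---------------------------------------------------------------------------
# long-CSV dialect
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "individual_id": "individual_id",
    "population": "population",
    "date": "date",
    "sex": "sex",
    "translocated": "translocated",
    "locus": "locus",
    "allele1": "allele1",
    "allele2": "allele2",
}


def _read_long_csv(path, column_map: Mapping[str, str] | None) -> GenotypeDataset:
    cmap = dict(_DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in cmap.values() if c not in df.columns]
    if missing_cols:
        raise GenotypeValidationError(
            f"{path}: missing required columns {missing_cols}"
        )
    panel = MarkerPanel(tuple(dict.fromkeys(df[cmap["locus"]])))
    records: list[GenotypeRecord] = []
    for ind_id, grp in df.groupby(cmap["individual_id"], sort=False):
        meta = grp.iloc[0]
        translocated = str(meta[cmap["translocated"]]).strip().lower() in (
            "true", "1", "yes", "t",
        )
        genotype = {}
        for i, row in grp.iterrows():
            a1, a2 = _norm_allele(row[cmap["allele1"]]), _norm_allele(row[cmap["allele2"]])
            if (a1 == MISSING) != (a2 == MISSING):
                raise GenotypeValidationError(
                    f"{path} row {i}: half-called genotype for individual "
                    f"{ind_id!r}, locus {row[cmap['locus']]!r}"
                )
            genotype[str(row[cmap["locus"]])] = None if a1 == MISSING else (a1, a2)
        date = str(meta[cmap["date"]]).strip() or None
        sex = str(meta[cmap["sex"]]).strip() or "unknown"
        records.append(
            GenotypeRecord(
                individual_id=str(ind_id),
                population=str(meta[cmap["population"]]),
                date=date,
                sex=sex if sex in ("M", "F") else "unknown",
                translocated=translocated,
                genotype=genotype,
            )
        )
    return GenotypeDataset(panel, records)


# ---------------------------------------------------------------------------
# GenePop dialect
# ---------------------------------------------------------------------------


def _genepop_code(allele: str, width: int = 3) -> str:
    if allele == MISSING:
        return "0" * width
    if not allele.isdigit():
        raise GenotypeValidationError(
            f"GenePop export needs numeric allele identifiers, got {allele!r}"
        )
    if len(allele) > width:
        raise GenotypeValidationError(
            f"allele {allele!r} does not fit in {width}-digit GenePop coding"
        )
    return allele.zfill(width)


def _write_genepop(dataset: GenotypeDataset, path, title: str = "lynxrescue export"):
    lines = [title]
    lines.extend(dataset.panel.loci)
    for pop in dataset.populations:
        lines.append("POP")
        for rec in dataset.subset(population=pop):
            calls = []
            for locus in dataset.panel:
                g = rec.call(locus)
                if g is None:
                    calls.append("000000")
                else:
                    calls.append(_genepop_code(g[0]) + _genepop_code(g[1]))
            lines.append(f"{rec.individual_id}, " + " ".join(calls))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_genepop(path) -> GenotypeDataset:
    from Bio.PopGen import GenePop

    with open(path) as fh:
        rec = GenePop.read(fh)
    panel = MarkerPanel(tuple(rec.loci_list))
    width = 3 if rec.marker_len == 3 else rec.marker_len
    records = []
    for ip, pop in enumerate(rec.populations):
        pop_label = f"pop{ip + 1}"
        for name, genos in pop:
            genotype = {}
            for locus, alleles in zip(panel, genos):
                if alleles is None or any(a is None for a in alleles):
                    genotype[locus] = None
                else:
                    a1, a2 = (str(int(a)) for a in alleles)
                    genotype[locus] = None if a1 == "0" or a2 == "0" else (a1, a2)
            records.append(
                GenotypeRecord(
                    individual_id=str(name).strip(),
                    population=pop_label,
                    genotype=genotype,
                )
            )
    return GenotypeDataset(panel, records)


def read_genotypes(
    path, format: str = "long", column_map: Mapping[str, str] | None = None
) -> GenotypeDataset:
    """Read a genotype table.

    Parameters
    ----------
    path : file path
    format : {"long", "genepop"}
        "long" is the package's long-CSV dialect; "genepop" accepts classic
        GenePop files (population labels become pop1, pop2, ...).
    column_map : mapping, optional
        Overrides for the long-CSV column names, e.g. ``{"date": "year"}``.
    """
    if format == "long":
        return _read_long_csv(path, column_map)
    if format == "genepop":
        return _read_genepop(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(dataset: GenotypeDataset, path, format: str = "long") -> None:
    if format == "long":
        dataset.to_frame().to_csv(path, index=False)
    elif format == "genepop":
        _write_genepop(dataset, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def compute_allele_frequencies(
    dataset: GenotypeDataset, population: str | None = None
) -> AlleleFrequencyTable:
    """Empirical allele frequencies: count of allele / (2 x scored individuals).

    Raises an error naming the locus when a locus has no scored genotype in
    the selected population.
    """
    sub = dataset.subset(population=population) if population else dataset
    if len(sub) == 0:
        raise GenotypeValidationError(f"no records for population {population!r}")
    freqs: dict[str, dict[str, float]] = {}
    for locus in sub.panel:
        counts: dict[str, int] = {}
        n = 0
        for rec in sub:
            g = rec.call(locus)
            if g is None:
                continue
            n += 1
            for a in g:
                counts[a] = counts.get(a, 0) + 1
        if n == 0:
            raise GenotypeValidationError(
                f"locus {locus}: zero non-missing genotypes in "
                f"population {population!r}"
            )
        freqs[locus] = {a: c / (2 * n) for a, c in sorted(counts.items())}
    return AlleleFrequencyTable(
        population=population or "all", frequencies=freqs, n_source=len(sub)
    )


def write_allele_frequencies(table: AlleleFrequencyTable, path) -> None:
    rows = [
        (table.population, locus, allele, freq, table.n_source)
        for locus, fmap in table.frequencies.items()
        for allele, freq in fmap.items()
    ]
    pd.DataFrame(
        rows, columns=["population", "locus", "allele", "frequency", "n_source"]
    ).to_csv(path, index=False)


def read_allele_frequencies(path) -> AlleleFrequencyTable:
    df = pd.read_csv(path, dtype={"allele": str, "locus": str})
    required = {"population", "locus", "allele", "frequency"}
    if not required <= set(df.columns):
        raise GenotypeValidationError(
            f"{path}: allele-frequency table needs columns {sorted(required)}"
        )
    pops = df["population"].unique()
    if len(pops) != 1:
        raise GenotypeValidationError(
            f"{path}: expected one population per file, found {list(pops)}"
        )
    freqs: dict[str, dict[str, float]] = {}
    for locus, grp in df.groupby("locus", sort=False):
        freqs[str(locus)] = dict(zip(grp["allele"], grp["frequency"].astype(float)))
    n_source = int(df["n_source"].iloc[0]) if "n_source" in df.columns else 0
    return AlleleFrequencyTable(
        population=str(pops[0]), frequencies=freqs, n_source=n_source
    )


# ---------------------------------------------------------------------------
# numeric views
# ---------------------------------------------------------------------------


def dataset_to_arrays(
    dataset: GenotypeDataset, loci: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str], list[list[str]]]:
    """Encode a dataset as an integer allele-call array.

    Returns ``(calls, loci, allele_labels)`` where ``calls`` has shape
    (n_individuals, n_loci, 2) with allele indices per locus and -1 for
    missing, and ``allele_labels[l][k]`` is the allele identifier encoded as
    ``k`` at locus ``l``.
    """
    loci = list(loci) if loci is not None else list(dataset.panel)
    n, L = len(dataset), len(loci)
    calls = np.full((n, L, 2), -1, dtype=np.int32)
    labels: list[list[str]] = []
    for j, locus in enumerate(loci):
        seen: dict[str, int] = {}
        for i, rec in enumerate(dataset):
            g = rec.call(locus)
            if g is None:
                continue
            for k, a in enumerate(g):
                if a not in seen:
                    seen[a] = len(seen)
                calls[i, j, k] = seen[a]
        labels.append([a for a, _ in sorted(seen.items(), key=lambda kv: kv[1])])
    return calls, loci, labels
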