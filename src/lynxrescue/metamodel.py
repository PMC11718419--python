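"""Random-forest metamodel over simulator inputs and outputs.

A sensitivity analysis of the individual-based model: sample input
parameters (Latin hypercube), run reduced-replicate simulations, fit a
random-forest regression per simulation output and evaluation year, and
rank inputs by mean decrease in impurity (MDI).  Two designs mirror the
two questions asked of the model:

* baseline design — demographic/genetic inputs (natural mortality, lethal
  equivalents, kitten survival, litter size, starting census size) against
  IBD, Ne and expected heterozygosity;
* translocation design — programme inputs (translocation frequency,
  males and females per event, source population) against the same
  outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import qmc
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error
from sklearn.model_selection import train_test_split

from .genotypes import AlleleFrequencyTable
from .scenarios import ScenarioSpec, build_events
from .simulate import DemographicParams, initialize_population, run_simulation

__all__ = [
    "BASELINE_RANGES",
    "ImportanceReport",
    "baseline_design",
    "translocation_design",
    "fit_rf_metamodel",
]

BASELINE_RANGES = {
    "natural_mortality": (0.05, 0.30),
    "lethal_equivalents": (0.1, 6.0),
    "kitten_survival": (0.30, 0.70),
    "litter_size": (1.5, 3.0),
    "census_size": (40, 240),
}

TRANSLOCATION_INTERVALS = (3, 5, 10, 15, 20, 25)

OUTPUT_METRICS = {"ibd": "mean_f", "ne": "ne", "he": "he"}


def _lhs(n_runs: int, d: int, seed: int) -> np.ndarray:
    return qmc.LatinHypercube(d=d, seed=seed).random(n_runs)


def _output_columns(eval_years) -> list[str]:
    return [f"{k}_y{y}" for k in OUTPUT_METRICS for y in eval_years]


def _collect_outputs(traj, eval_years) -> dict[str, float]:
    """Outputs at the evaluation years, replicate-averaged.

    Extinct replicates stop reporting genetics; the last observed state is
    carried forward (the population's final genetic condition), so that
    parameter combinations driving early collapse still contribute rows.
    A run with no observable value at all for some output is skipped."""
    mean = traj.mean_by_year()
    out = {}
    for key, col in OUTPUT_METRICS.items():
        filled = mean[col].ffill()
        for y in eval_years:
            idx = filled.index[filled.index <= y]
            v = filled.loc[idx[-1]] if len(idx) else np.nan
            out[f"{key}_y{y}"] = float(v) if np.isfinite(v) else np.nan
    return out


def baseline_design(
    dinaric_freqs: AlleleFrequencyTable,
    baseline_f,
    n_runs: int = 200,
    seed: int = 0,
    eval_years=(10, 25, 45),
    n_replicates: int = 3,
    ranges: dict | None = None,
    params: DemographicParams | None = None,
    source_he: float | None = None,
    ne_sample: int = 50,
) -> pd.DataFrame:
    """Latin-hypercube design over demographic/genetic inputs.

    Each run initialises the population from the reintroduced population's
    allele frequencies at the sampled census size, with IBD values drawn
    from the calibrated baseline distribution, and simulates to the last
    evaluation year.  Runs whose outputs cannot be evaluated (e.g. all
    replicates extinct before an evaluation year, or no finite Ne) are
    dropped, with the count recorded in ``df.attrs["n_skipped"]``.
    """
    ranges = dict(BASELINE_RANGES, **(ranges or {}))
    names = list(ranges)
    base_params = params or DemographicParams()
    unit = _lhs(n_runs, len(names), seed)
    lo = np.array([ranges[k][0] for k in names])
    hi = np.array([ranges[k][1] for k in names])
    X = lo + unit * (hi - lo)
    horizon = max(eval_years)
    rows = []
    skipped = 0
    for r in range(n_runs):
        vals = dict(zip(names, X[r]))
        census = int(round(vals["census_size"]))
        run_params = replace(
            base_params,
            natural_mortality=vals["natural_mortality"],
            lethal_equivalents=vals["lethal_equivalents"],
            juvenile_mortality=1.0 - vals["kitten_survival"],
            litter_mean=vals["litter_size"],
        )

        def factory(rep, rng, _census=census, _p=run_params):
            return initialize_population(
                dinaric_freqs, _census, rng, params=_p, baseline_f=baseline_f
            )

        traj = run_simulation(
            factory,
            run_params,
            n_years=horizon,
            n_replicates=n_replicates,
            seed=seed * 100003 + r,
            source_he=source_he,
            # estimate Ne on a 5-year grid so early-collapsing runs still
            # leave a last-observed estimate to carry forward
            ne_years=sorted(set(range(0, horizon + 1, 5)) | set(eval_years)),
            ne_sample=ne_sample,
        )
        out = _collect_outputs(traj, eval_years)
        if any(not np.isfinite(v) for v in out.values()):
            skipped += 1
            continue
        rows.append({**{k: vals[k] for k in names}, **out})
    df = pd.DataFrame(rows)
    df.attrs["inputs"] = names
    df.attrs["outputs"] = _output_columns(eval_years)
    df.attrs["n_skipped"] = skipped
    return df


def translocation_design(
    sources: dict[str, AlleleFrequencyTable],
    snapshots,
    n_runs: int = 200,
    seed: int = 0,
    eval_years=(25, 50, 90),
    n_replicates: int = 3,
    max_per_sex: int = 5,
    params: DemographicParams | None = None,
    ne_sample: int = 50,
) -> pd.DataFrame:
    """Latin-hypercube design over translocation-programme inputs.

    Inputs: translocation interval (years, from the supported set), males
    and females per event (0..max_per_sex, at least one animal in total)
    and the source population (categorical, encoded 0/1).
    """
    base_params = params or DemographicParams()
    labels = sorted(sources)
    unit = _lhs(n_runs, 4, seed)
    horizon = max(eval_years)
    rows = []
    skipped = 0
    for r in range(n_runs):
        interval = TRANSLOCATION_INTERVALS[
            int(unit[r, 0] * len(TRANSLOCATION_INTERVALS)) % len(TRANSLOCATION_INTERVALS)
        ]
        n_m = int(unit[r, 1] * (max_per_sex + 1)) % (max_per_sex + 1)
        n_f = int(unit[r, 2] * (max_per_sex + 1)) % (max_per_sex + 1)
        if n_m + n_f == 0:
            n_f = 1
        src_idx = int(unit[r, 3] * len(labels)) % len(labels)
        spec = ScenarioSpec(
            label=f"design-{r}",
            interval=int(interval),
            n_per_event=n_m + n_f,
            source=labels[src_idx],
            horizon=horizon,
        )
        events = {
            yr: evs for yr, evs in build_events(spec, sources).items() if yr <= horizon
        }
        # impose the sampled sex composition exactly
        for evs in events.values():
            for ev in evs:
                if ev.year >= spec.program_start:
                    ev.n_males, ev.n_females = n_m, n_f
        traj = run_simulation(
            _snapshot_factory(snapshots),
            base_params,
            n_years=horizon,
            n_replicates=n_replicates,
            seed=seed * 99991 + r,
            events=events,
            source_he=sources[labels[0]].expected_heterozygosity(),
            ne_years=sorted(set(range(0, horizon + 1, 5)) | set(eval_years)),
            ne_sample=ne_sample,
        )
        out = _collect_outputs(traj, eval_years)
        if any(not np.isfinite(v) for v in out.values()):
            skipped += 1
            continue
        rows.append(
            {
                "translocation_frequency": float(interval),
                "n_males": float(n_m),
                "n_females": float(n_f),
                "source": float(src_idx),
                **out,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["inputs"] = ["translocation_frequency", "n_males", "n_females", "source"]
    df.attrs["outputs"] = _output_columns(eval_years)
    df.attrs["n_skipped"] = skipped
    return df


def _snapshot_factory(snapshots):
    def factory(rep, rng):
        pop = snapshots[rng.integers(0, len(snapshots))].copy()
        pop.year = 0
        return pop

    return factory


@dataclass
class ImportanceReport:
    """MDI feature importances averaged over per-output, per-year forests."""

    importances: pd.DataFrame  # feature x model (one column per output col)
    mean_importance: pd.Series  # feature -> mean MDI
    ci95: pd.Series  # feature -> 1.96 * SE over models
    validation_mse: pd.Series  # output column -> MSE on the held-out split
    output_variance: pd.Series  # output column -> variance of the response

    def top_feature(self) -> str:
        return str(self.mean_importance.idxmax())

    def bottom_feature(self) -> str:
        return str(self.mean_importance.idxmin())


def fit_rf_metamodel(
    design: pd.DataFrame,
    inputs=None,
    outputs=None,
    split_fraction: float = 0.8,
    seed: int = 0,
    n_trees: int = 500,
) -> ImportanceReport:
    """Fit one regression forest per output column and report MDI scores.

    MDI vectors are normalised (sum to 1 per model, sklearn's convention)
    and averaged across output models with a 95% CI; validation MSE uses a
    held-out (1 - split_fraction) fraction.  A constant output column makes
    the importance undefined and raises.
    """
    inputs = list(inputs) if inputs is not None else list(design.attrs["inputs"])
    outputs = list(outputs) if outputs is not None else [
        c for c in design.attrs["outputs"] if c in design.columns
    ]
    if len(design) < 50:
        raise ValueError(f"metamodel needs >= 50 design rows, got {len(design)}")
    X = design[inputs].to_numpy()
    imp = {}
    mse = {}
    var = {}
    for col in outputs:
        y = design[col].to_numpy()
        if np.std(y) == 0:
            raise ValueError(f"output {col!r} is constant; importance undefined")
        Xtr, Xva, ytr, yva = train_test_split(
            X, y, train_size=split_fraction, random_state=seed
        )
        rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
        rf.fit(Xtr, ytr)
        imp[col] = pd.Series(rf.feature_importances_, index=inputs)
        mse[col] = float(mean_squared_error(yva, rf.predict(Xva)))
        var[col] = float(np.var(y))
    importances = pd.DataFrame(imp)
    mean_imp = importances.mean(axis=1)
    se = importances.std(axis=1, ddof=1) / np.sqrt(importances.shape[1])
    return ImportanceReport(
        importances=importances,
        mean_importance=mean_imp,
        ci95=1.96 * se,
        validation_mse=pd.Series(mse),
        output_variance=pd.Series(var),
    )
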