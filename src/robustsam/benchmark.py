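"""Simulation benchmarks: scenario x sample-size grids and FDR accuracy.

`run_benchmark` reproduces the ranking-quality experiment layout: for each
(scenario, sample-size) cell and statistic, it averages RS, AUC and TRF(r)
over independently seeded replicate datasets and reports Monte-Carlo
standard errors.  `fdr_accuracy_experiment` reproduces the FDR-calibration
experiment: for each replicate and target (estimated) FDR, the smallest
delta whose median permutation-FDR estimate meets the target is found, the
genes are called, and the realized TRUE FDR and false/total call counts
are averaged per grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fdr as fdrmod
from . import metrics
from .containers import METHODS
from .simulate import SCENARIOS, ScenarioConfig, generate_dataset
from .statistics import compute_statistics

__all__ = [
    "ExperimentGrid",
    "run_benchmark",
    "fdr_accuracy_experiment",
    "false_calls_at_matched_totals",
]

#: the sample-size grid used throughout the simulation study
SIZE_PAIRS = ((5, 5), (5, 10), (10, 5), (10, 10), (10, 15), (15, 10), (15, 15))


@dataclass(frozen=True)
class ExperimentGrid:
    """One ranking-benchmark experiment definition.

    Each cell is averaged over ``n_reps`` replicate datasets seeded
    ``base_seed + rep`` so any cell is recomputable in isolation.
    """

    scenarios: tuple[str, ...] = ("beta_low", "beta_high")
    size_pairs: tuple[tuple[int, int], ...] = SIZE_PAIRS
    methods: tuple[str, ...] = ("sam", "msam1", "msam2")
    n_reps: int = 100
    trf_cutoffs: tuple[int, ...] = (100, 200)
    n_genes: int = 10_000
    msam1_p: float = 0.001
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios {sorted(unknown)!r}")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)!r}")


def _method_applicable(method: str, n1: int, n2: int) -> bool:
    if method == "sam_tbor":
        return n1 >= 4 and n2 >= 4
    return True


def run_benchmark(grid: ExperimentGrid) -> pd.DataFrame:
    """Average RS/AUC/TRF per (scenario, n1, n2, method) cell.

    Returns one row per cell with ``<metric>_mean`` and ``<metric>_se``
    columns (SE = sample SD across replicates / sqrt(n_reps)).  Cells where
    a method is inapplicable (trimming with fewer than 4 replicates per
    group) are marked ``applicable = False`` with NaN metrics.
    """
    metric_names = ["rs", "auc"] + [f"trf{r}" for r in grid.trf_cutoffs]
    rows = []
    for scenario in grid.scenarios:
        for n1, n2 in grid.size_pairs:
            per_method: dict[str, list[list[float]]] = {
                m: [] for m in grid.methods
            }
            for rep in range(grid.n_reps):
                config = ScenarioConfig(
                    scenario=scenario,
                    n_genes=grid.n_genes,
                    n1=n1,
                    n2=n2,
                    seed=grid.base_seed + rep,
                )
                expr, truth = generate_dataset(config)
                for method in grid.methods:
                    if not _method_applicable(method, n1, n2):
                        continue
                    stat = compute_statistics(
                        expr, method=method, p=grid.msam1_p
                    ).statistic
                    values = [
                        metrics.rank_sum(stat, truth),
                        metrics.ranking_auc(stat, truth),
                    ]
                    values += [
                        metrics.top_ranked_frequency(stat, truth, r)
                        for r in grid.trf_cutoffs
                    ]
                    per_method[method].append(values)
            for method in grid.methods:
                row = {
                    "scenario": scenario,
                    "n1": n1,
                    "n2": n2,
                    "method": method,
                    "n_reps": grid.n_reps,
                    "applicable": _method_applicable(method, n1, n2),
                }
                if row["applicable"]:
                    arr = np.asarray(per_method[method], dtype=float)
                    for k, name in enumerate(metric_names):
                        row[f"{name}_mean"] = arr[:, k].mean()
                        row[f"{name}_se"] = (
                            arr[:, k].std(ddof=1) / np.sqrt(arr.shape[0])
                            if arr.shape[0] > 1
                            else 0.0
                        )
                else:
                    for name in metric_names:
                        row[f"{name}_mean"] = np.nan
                        row[f"{name}_se"] = np.nan
                rows.append(row)
    return pd.DataFrame(rows)


def fdr_accuracy_experiment(
    scenario: str = "beta_low",
    n1: int = 5,
    n2: int = 10,
    methods: tuple[str, ...] = ("sam", "msam1", "msam2"),
    n_reps: int = 20,
    fdr_grid: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5),
    B: int = 100,
    n_genes: int = 10_000,
    max_deltas: int = 1000,
    msam1_p: float = 0.001,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Estimated-FDR calibration curves per method.

    For every replicate dataset and method, one permutation null (B label
    shuffles) is computed; every observed departure |d_(i) - d^E_(i)| in
    the top ``max_deltas`` is a candidate delta (so call counts step one
    gene at a time); and for each target FDR the smallest delta whose
    median-FDR estimate meets the target yields a call whose TRUE FDR and
    false/total counts are recorded.  Unreachable targets are dropped.
    Returns per (method, estimated_fdr): mean achieved estimate, mean true
    FDR, mean total/false call counts and the number of contributing
    replicates.
    """
    if any(f <= 0 or f > 0.5 for f in fdr_grid):
        raise ValueError("estimated-FDR grid must lie in (0, 0.5]")
    records = []
    for rep in range(n_reps):
        config = ScenarioConfig(
            scenario=scenario, n_genes=n_genes, n1=n1, n2=n2,
            seed=base_seed + rep,
        )
        expr, truth = generate_dataset(config)
        plan = fdrmod.build_permutations(n1, n2, B, seed=base_seed + rep)
        for method in methods:
            res = compute_statistics(expr, method=method, p=msam1_p)
            order = np.argsort(res.statistic, kind="stable")
            sorted_stats = res.statistic[order]
            null = fdrmod.permutation_null(
                expr, plan, method=method, p=msam1_p, s0=res.s0
            )
            diff = sorted_stats - null.d_e
            deltas = np.sort(np.abs(diff))[-max_deltas:]
            deltas = np.unique(deltas[deltas > 0])
            # cutoffs and observed call counts per candidate delta
            n = sorted_stats.size
            d_up = np.full(deltas.size, np.inf)
            d_down = np.full(deltas.size, -np.inf)
            n_called = np.zeros(deltas.size, dtype=int)
            for k, delta in enumerate(deltas):
                up = diff > delta
                down = diff < -delta
                n_called[k] = up.sum() + down.sum()
                if up.any():
                    d_up[k] = sorted_stats[up].min()
                if down.any():
                    d_down[k] = sorted_stats[down].max()
            # per-permutation exceedance counts, vectorized over deltas
            counts = np.zeros((plan.B, deltas.size), dtype=int)
            fin_up, fin_down = np.isfinite(d_up), np.isfinite(d_down)
            for b, row in enumerate(null.sorted_stats):
                counts[b, fin_up] += n - np.searchsorted(
                    row, d_up[fin_up], side="left"
                )
                counts[b, fin_down] += np.searchsorted(
                    row, d_down[fin_down], side="right"
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                fdr_median = np.where(
                    n_called > 0,
                    np.minimum(np.median(counts, axis=0) / n_called, 1.0),
                    np.nan,
                )
            for target in fdr_grid:
                ok = np.flatnonzero((n_called > 0) & (fdr_median <= target))
                if ok.size == 0:
                    continue
                k = ok[0]  # smallest qualifying delta
                call = fdrmod.call_significant(
                    sorted_stats, null.d_e, deltas[k], order=order
                )
                tfdr = metrics.true_fdr(call, truth)
                records.append(
                    {
                        "method": method,
                        "estimated_fdr": target,
                        "rep": rep,
                        "achieved_estimate": float(fdr_median[k]),
                        "true_fdr": tfdr,
                        "n_called": call.n_called,
                        "n_false": int(round(tfdr * call.n_called)),
                    }
                )
    df = pd.DataFrame.from_records(records)
    if df.empty:
        return df
    out = (
        df.groupby(["method", "estimated_fdr"], as_index=False)
        .agg(
            achieved_estimate_mean=("achieved_estimate", "mean"),
            true_fdr_mean=("true_fdr", "mean"),
            n_called_mean=("n_called", "mean"),
            n_false_mean=("n_false", "mean"),
            n_reps_used=("rep", "count"),
        )
        .sort_values(["method", "estimated_fdr"])
        .reset_index(drop=True)
    )
    return out


def false_calls_at_matched_totals(
    curves: pd.DataFrame, method_a: str, method_b: str
) -> pd.DataFrame:
    """Compare false-call counts of two methods at matched total counts.

    Interpolates method_b's mean false-call curve (false vs total called)
    at method_a's mean total-call counts, restricted to the overlapping
    range.  Returns rows (total_called, false_a, false_b_interp).
    """
    a = curves[curves["method"] == method_a].sort_values("n_called_mean")
    b = curves[curves["method"] == method_b].sort_values("n_called_mean")
    if a.empty or b.empty:
        raise ValueError("both methods need at least one curve point")
    lo, hi = b["n_called_mean"].min(), b["n_called_mean"].max()
    a = a[(a["n_called_mean"] >= lo) & (a["n_called_mean"] <= hi)]
    false_b = np.interp(
        a["n_called_mean"], b["n_called_mean"], b["n_false_mean"]
    )
    return pd.DataFrame(
        {
            "total_called": a["n_called_mean"].to_numpy(),
            f"false_{method_a}": a["n_false_mean"].to_numpy(),
            f"false_{method_b}": false_b,
        }
    )
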