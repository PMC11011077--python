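"""Bootstrap resampling study of tumour-size detectability.

The central experiment: from one cohort, draw bootstrap samples (rows
with replacement) at a grid of sample sizes, refit the chosen Cox model
in every resample, and record the p-value that judges the tumour-size
effect — the overall Wald p for univariable models, the Wald p of the
size coefficient for adjusted models.  The share of resamples below a
significance threshold estimates how likely a study of that size would
be to "find" the prognostic effect; Kolmogorov-Smirnov tests compare
p-value distributions across sample sizes.

Sampling uses common random numbers: repetition ``r`` at sample size
``n`` takes the first ``n`` entries of one shared index vector, and the
same indices are reused for every model spec on the same source rows.
Each cell's marginal bootstrap distribution is untouched (a prefix of
iid uniform indices is iid uniform), while differences across sample
sizes and transforms — the quantities of interest — are estimated with
far less Monte-Carlo noise.

Models adjusted for MGMT resample only the methylation-known subset, so
their maximum sample size is capped at that subset's size (the 258-of-
279 analogue).

A separate entry point, :func:`run_null_calibration`, checks type-I
error of the whole pipeline by fitting each repetition on a *freshly
generated* null cohort.  That distinction matters: bootstrap rejection
rates from a single fixed cohort concentrate around the realised sample
association of that cohort rather than the nominal level, so only
fresh-cohort simulation should be compared with the 5% target.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._engine import newton_cox
from .config import CohortConfig
from .cox import ModelSpec, design_matrix, wald_p

__all__ = [
    "ResamplingConfig",
    "CellResult",
    "ResamplingResult",
    "KSResult",
    "bootstrap_sample",
    "run_resampling",
    "run_null_calibration",
    "percent_significant",
    "ks_compare",
    "compare_extremes",
    "DEFAULT_SAMPLE_SIZES",
    "default_univariable_specs",
]

DEFAULT_SAMPLE_SIZES = (50, 100, 150, 200, 250, 258, 279)


def default_univariable_specs() -> tuple[ModelSpec, ...]:
    """The six univariable models: 3 size variables x identity/log."""
    return tuple(
        ModelSpec(size, transform)
        for size, transform in itertools.product(("diameter", "cv", "wv"), ("identity", "log"))
    )


@dataclass
class ResamplingConfig:
    """Parameters of one resampling experiment."""

    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    repetitions: int = 10_000
    thresholds: tuple[float, ...] = (0.05, 0.01, 0.001)
    model_specs: tuple[ModelSpec, ...] = field(default_factory=default_univariable_specs)
    master_seed: int = 0
    store_pvalues: bool = True

    def __post_init__(self):
        self.sample_sizes = tuple(int(n) for n in self.sample_sizes)
        self.thresholds = tuple(float(a) for a in self.thresholds)
        self.model_specs = tuple(self.model_specs)
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be positive")
        if any(b <= a for a, b in zip(self.sample_sizes, self.sample_sizes[1:])) or len(
            set(self.sample_sizes)
        ) != len(self.sample_sizes):
            raise ValueError("sample_sizes must be strictly increasing")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if any(not 0.0 < a < 1.0 for a in self.thresholds):
            raise ValueError("thresholds must lie strictly in (0, 1)")
        if not self.model_specs:
            raise ValueError("at least one model spec is required")


@dataclass
class CellResult:
    """Resampling outcome for one (sample size, model spec) cell."""

    spec: ModelSpec
    sample_size: int
    n_failed: int
    n_counted: int
    pvalues: np.ndarray | None = None
    threshold_counts: dict[float, int] | None = None

    def percent_significant(self, alpha: float) -> float:
        return percent_significant(self, alpha)


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison of p-value collections."""

    D: float
    p: float
    n1: int
    n2: int


@dataclass
class ResamplingResult:
    """All cells of a resampling experiment, keyed by (spec, sample size)."""

    config: ResamplingConfig
    cells: dict[tuple[ModelSpec, int], CellResult]
    grids: dict[ModelSpec, tuple[int, ...]]

    def cell(self, spec: ModelSpec, sample_size: int) -> CellResult:
        return self.cells[(spec, sample_size)]

    def percent_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Sample sizes x model specs table of percent-significant values."""
        sizes = sorted({n for _, n in self.cells})
        data = {}
        for spec in self.config.model_specs:
            col = {}
            for n in self.grids[spec]:
                col[n] = self.cells[(spec, n)].percent_significant(alpha)
            data[spec.label] = [col.get(n, np.nan) for n in sizes]
        return pd.DataFrame(data, index=pd.Index(sizes, name="sample_size"))

    def long_frame(self) -> pd.DataFrame:
        """Long-format p-value export (one row per counted repetition)."""
        rows = []
        for (spec, n), cell in self.cells.items():
            if cell.pvalues is None:
                raise ValueError("p-values were not stored; enable store_pvalues")
            rows.append(
                pd.DataFrame(
                    {
                        "sample_size": n,
                        "size_variable": spec.size_variable,
                        "transform": spec.transform,
                        "adjustment": "+".join(spec.adjustment),
                        "repetition": np.arange(len(cell.pvalues)),
                        "p": cell.pvalues,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def compare_extremes(self, spec: ModelSpec) -> KSResult:
        return compare_extremes(self, spec)


# ----------------------------------------------------------------------


def bootstrap_sample(table: pd.DataFrame, m: int, rng: np.random.Generator) -> pd.DataFrame:
    """m rows drawn iid uniformly with replacement (row identity kept)."""
    if len(table) == 0:
        raise ValueError("cannot resample an empty table")
    if m < 1:
        raise ValueError("m must be positive")
    idx = rng.integers(0, len(table), size=m)
    return table.iloc[idx].reset_index(drop=True)


def percent_significant(cell: CellResult, alpha: float) -> float:
    """100 * #{p < alpha} / n_counted (strict inequality)."""
    if cell.n_counted == 0:
        raise ValueError("no counted repetitions in this cell")
    if cell.pvalues is not None:
        return float(100.0 * np.mean(cell.pvalues < alpha))
    if cell.threshold_counts is None or alpha not in cell.threshold_counts:
        raise ValueError(
            f"alpha={alpha} was not tracked; enable store_pvalues or add it to thresholds"
        )
    return float(100.0 * cell.threshold_counts[alpha] / cell.n_counted)


def ks_compare(pvals_a, pvals_b) -> KSResult:
    """Two-sided two-sample KS test (asymptotic p) on p-value samples."""
    a = np.asarray(pvals_a, dtype=float)
    b = np.asarray(pvals_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both p-value samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return KSResult(D=float(res.statistic), p=float(min(res.pvalue, 1.0)), n1=a.size, n2=b.size)


def compare_extremes(result: ResamplingResult, spec: ModelSpec) -> KSResult:
    """KS comparison of the smallest vs largest sample-size cells."""
    grid = result.grids[spec]
    lo, hi = result.cells[(spec, grid[0])], result.cells[(spec, grid[-1])]
    if lo.pvalues is None or hi.pvalues is None:
        raise ValueError(
            "p-values were not stored for this run; re-run with store_pvalues=True"
        )
    return ks_compare(lo.pvalues, hi.pvalues)


# ----------------------------------------------------------------------


def _fit_pvalue(time, event, X, univariable: bool):
    """p-value for the size term (column 0) in one resample, or None on failure."""
    if event.sum() < 2:
        return None
    keep = np.ptp(X, axis=0) > 0
    if not keep[0]:  # size variable constant in this resample
        return None
    res = newton_cox(time, event, X[:, keep])
    if not res.converged:
        return None
    # univariable models have a single term, so the overall Wald p equals
    # the size coefficient's Wald p; adjusted models report the latter.
    return wald_p(res.beta[0], res.se[0])


def run_resampling(
    table: pd.DataFrame, config: ResamplingConfig, progress=None
) -> ResamplingResult:
    """Run the full bootstrap experiment on one cohort.

    Per-fit failures (no events, constant size, non-convergence or
    separation) are counted in ``n_failed`` and excluded from the
    percent-significant denominator; they never abort the run.
    """
    if len(table) == 0:
        raise ValueError("cohort table is empty")
    sources = {"all": table.reset_index(drop=True)}
    known = table[table["mgmt"] != "unknown"].reset_index(drop=True)
    needs_known = any("mgmt" in s.adjustment for s in config.model_specs)
    if needs_known:
        if len(known) == 0:
            raise ValueError("no rows with known MGMT status")
        sources["mgmt_known"] = known

    # one shared bootstrap index matrix per source (common random numbers)
    index_mats = {}
    for j, (name, src) in enumerate(sources.items()):
        grid_max = min(max(config.sample_sizes), len(src)) if name == "mgmt_known" else max(
            config.sample_sizes
        )
        rng = np.random.default_rng(
            np.random.SeedSequence(config.master_seed, spawn_key=(j,))
        )
        index_mats[name] = rng.integers(
            0, len(src), size=(config.repetitions, grid_max), dtype=np.int64
        )

    cells: dict[tuple[ModelSpec, int], CellResult] = {}
    grids: dict[ModelSpec, tuple[int, ...]] = {}
    for spec in config.model_specs:
        src_name = "mgmt_known" if "mgmt" in spec.adjustment else "all"
        src = sources[src_name]
        X_full, names, src_df = design_matrix(src, spec)
        time_full = src_df["time_months"].to_numpy(dtype=float)
        event_full = src_df["event"].to_numpy(dtype=np.int64)
        idx_mat = index_mats[src_name]

        # cap sizes above the source size (the 258-rule), deduplicated
        grid = []
        for n in config.sample_sizes:
            eff = min(n, len(src))
            if eff not in grid:
                grid.append(eff)
        grids[spec] = tuple(grid)

        for n in grid:
            pvals = np.empty(config.repetitions)
            n_fail = 0
            k = 0
            for r in range(config.repetitions):
                rows = idx_mat[r, :n]
                p = _fit_pvalue(
                    time_full[rows], event_full[rows], X_full[rows], spec.univariable
                )
                if p is None:
                    n_fail += 1
                else:
                    pvals[k] = p
                    k += 1
            pvals = pvals[:k]
            cell = CellResult(
                spec=spec,
                sample_size=n,
                n_failed=n_fail,
                n_counted=k,
            )
            if config.store_pvalues:
                cell.pvalues = pvals
            else:
                cell.threshold_counts = {
                    a: int(np.sum(pvals < a)) for a in config.thresholds
                }
            cells[(spec, n)] = cell
            if progress is not None:
                progress(spec, n)
    return ResamplingResult(config=config, cells=cells, grids=grids)


def run_unconditional_power(
    cohort_config: CohortConfig,
    config: ResamplingConfig,
) -> ResamplingResult:
    """Procedure-level power of the bootstrap study design.

    Where :func:`run_resampling` conditions on one observed cohort (its
    percentages then vary with the realised sample association of that
    cohort), this function draws a *fresh* cohort from the generator for
    every repetition, takes one bootstrap resample of each requested
    size from it, and fits every model spec on it.  The resulting
    percent-significant values estimate the unconditional probability
    that a bootstrap resample of size n detects the generative effect —
    the quantity that is guaranteed to grow with n — with the same
    common-random-numbers coupling across cells.
    """
    from .cohort import generate_cohort

    max_n = max(config.sample_sizes)
    seeds = np.random.SeedSequence(config.master_seed, spawn_key=(0,)).generate_state(
        config.repetitions
    )
    idx_rng = np.random.default_rng(
        np.random.SeedSequence(config.master_seed, spawn_key=(1,))
    )
    hits: dict[tuple[ModelSpec, int], list] = {
        (spec, n): [] for spec in config.model_specs for n in config.sample_sizes
    }
    fails = {key: 0 for key in hits}
    for r in range(config.repetitions):
        cohort = generate_cohort(
            cohort_config.replace(n_patients=max_n, seed=int(seeds[r] % (2**31)))
        )
        idx = idx_rng.integers(0, max_n, size=max_n)
        for spec in config.model_specs:
            X, _, df = design_matrix(cohort, spec)
            t = df["time_months"].to_numpy(dtype=float)
            e = df["event"].to_numpy(dtype=np.int64)
            m = len(df)
            for n in config.sample_sizes:
                rows = idx[:n] if m == max_n else idx_rng.integers(0, m, size=min(n, m))
                p = _fit_pvalue(t[rows], e[rows], X[rows], spec.univariable)
                if p is None:
                    fails[(spec, n)] += 1
                else:
                    hits[(spec, n)].append(p)
    cells = {}
    grids = {}
    for spec in config.model_specs:
        grids[spec] = tuple(config.sample_sizes)
        for n in config.sample_sizes:
            pv = np.asarray(hits[(spec, n)])
            cells[(spec, n)] = CellResult(
                spec=spec,
                sample_size=n,
                n_failed=fails[(spec, n)],
                n_counted=pv.size,
                pvalues=pv if config.store_pvalues else None,
                threshold_counts=None
                if config.store_pvalues
                else {a: int(np.sum(pv < a)) for a in config.thresholds},
            )
    return ResamplingResult(config=config, cells=cells, grids=grids)


def run_null_calibration(
    config: CohortConfig,
    spec: ModelSpec,
    sample_sizes=(50, 279),
    repetitions: int = 10_000,
    master_seed: int = 0,
) -> dict[int, CellResult]:
    """Type-I-error calibration with a fresh cohort per repetition.

    Generates ``repetitions`` independent cohorts of each requested size
    from ``config`` (which should carry no covariate effects), fits the
    given model in each, and collects the size-term p-values.  Under the
    null these are uniform, so percent-significant should sit at the
    nominal level — the property bootstrap-from-one-cohort rates do not
    have.
    """
    from .cohort import generate_cohort

    out: dict[int, CellResult] = {}
    for i, n in enumerate(sample_sizes):
        child_seeds = np.random.SeedSequence(master_seed, spawn_key=(i,)).generate_state(
            repetitions
        )
        pvals = np.empty(repetitions)
        n_fail = 0
        k = 0
        for r in range(repetitions):
            cohort = generate_cohort(config.replace(n_patients=int(n), seed=int(child_seeds[r] % (2**31))))
            X, names, df = design_matrix(cohort, spec)
            p = _fit_pvalue(
                df["time_months"].to_numpy(dtype=float),
                df["event"].to_numpy(dtype=np.int64),
                X,
                spec.univariable,
            )
            if p is None:
                n_fail += 1
            else:
                pvals[k] = p
                k += 1
        out[int(n)] = CellResult(
            spec=spec,
            sample_size=int(n),
            n_failed=n_fail,
            n_counted=k,
            pvalues=pvals[:k],
        )
    return out
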