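"""Intervention protocols as reproducible sweeps, plus session statistics.

Two protocols over a grid of parameter-reduction ratios:

``developmental``
    every (reduction, session) cell builds a network with the window attached,
    trains it fully, and evaluates — G grid points x S sessions trainings.
``disorganized``
    every session trains ONE conventional network, then evaluates it at every
    grid point after post-training masking — S trainings total.

Cell seeds are derived from (base_seed, protocol, family, grid index, session
index), so results are independent of execution order.  Mean session error is
reported per grid point; diverged sessions are excluded from means and listed
as failures.  Session samples are compared with the two-sided Wilcoxon
rank-sum (Mann-Whitney) test — exact for tie-free samples of at most 12 per
side, tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import derive_seed
from .data import ImageDataset
from .errors import ContractError, TrainingError
from .windows import NodeGeometry, solve_window
from .zoo import (
    NetworkConfig,
    TrainingSchedule,
    build_network,
    disorganize_model,
    evaluate,
    train,
)

__all__ = [
    "SweepResult",
    "ComparisonReport",
    "run_developmental_sweep",
    "run_disorganized_sweep",
    "wilcoxon_compare",
    "summarize",
    "write_summary",
]


@dataclass
class SweepResult:
    """Session errors across a reduction grid for one protocol/family."""

    protocol: str
    family: str
    reductions: list[float]  # requested grid, always includes 0.0
    errors: dict[float, list[float]] = field(default_factory=dict)
    achieved: dict[float, float] = field(default_factory=dict)  # snapped reductions
    failures: list[tuple[float, int, str]] = field(default_factory=list)
    base_seed: int = 0
    n_trainings: int = 0
    schedule: TrainingSchedule | None = None

    @property
    def mean_errors(self) -> dict[float, float]:
        return {
            r: float(np.mean(errs)) for r, errs in self.errors.items() if len(errs)
        }

    @property
    def baseline_mean(self) -> float:
        return self.mean_errors[0.0]

    def sessions_at(self, reduction: float) -> list[float]:
        return self.errors[reduction]


def _normalize_grid(reductions) -> list[float]:
    grid = sorted({float(r) for r in reductions} | {0.0})
    if any(not (0.0 <= r < 1.0) for r in grid):
        raise ContractError(f"reductions must lie in [0, 1): {grid}")
    return grid


def _sweep_family(family: str | None, config: NetworkConfig) -> str:
    """Explicit family, else the config's, else the diagonal (band) default."""
    if family is not None:
        return family
    if config.window.family != "full":
        return config.window.family
    return "diagonal"


def run_developmental_sweep(
    config: NetworkConfig,
    train_ds: ImageDataset,
    val_ds: ImageDataset,
    reductions,
    sessions: int,
    base_seed: int,
    schedule: TrainingSchedule,
    family: str | None = None,
) -> SweepResult:
    """Train with the window attached at every grid point and session.

    The reduction-0 cell is the full-window baseline and equals a conventional
    network trained at the same seed.
    """
    from dataclasses import replace

    family = _sweep_family(family, config)
    grid = _normalize_grid(reductions)
    result = SweepResult("developmental", family, grid, base_seed=base_seed, schedule=schedule)
    for ri, r in enumerate(grid):
        errs: list[float] = []
        for si in range(sessions):
            seed = derive_seed(base_seed, "developmental", family, ri, si)
            wspec = replace(config.window, family=family if r > 0 else "full", reduction=r)
            cfg = replace(config, window=wspec)
            model = build_network(cfg, seed=derive_seed(seed, "init"))
            sched = replace(schedule, seed=derive_seed(seed, "train"))
            try:
                train(model, train_ds, val_ds, sched, record_trace=False)
                result.n_trainings += 1
            except TrainingError as exc:
                result.failures.append((r, si, str(exc)))
                continue
            errs.append(evaluate(model, val_ds))
            if r > 0:
                sz = model.layers[model.sz_layer_index]
                if sz.window is not None:
                    result.achieved.setdefault(r, sz.window.reduction)
        result.errors[r] = errs
        result.achieved.setdefault(r, r)
    return result


def run_disorganized_sweep(
    config: NetworkConfig,
    train_ds: ImageDataset,
    val_ds: ImageDataset,
    reductions,
    sessions: int,
    base_seed: int,
    schedule: TrainingSchedule,
    family: str | None = None,
) -> SweepResult:
    """Train once per session, then mask at every grid point for evaluation."""
    from dataclasses import replace

    family = _sweep_family(family, config)
    grid = _normalize_grid(reductions)
    result = SweepResult("disorganized", family, grid, base_seed=base_seed, schedule=schedule)
    errs: dict[float, list[float]] = {r: [] for r in grid}
    for si in range(sessions):
        seed = derive_seed(base_seed, "disorganized", family, 0, si)
        model = build_network(config, seed=derive_seed(seed, "init"))
        sched = replace(schedule, seed=derive_seed(seed, "train"))
        try:
            train(model, train_ds, val_ds, sched, record_trace=False)
            result.n_trainings += 1
        except TrainingError as exc:
            result.failures.append((0.0, si, str(exc)))
            continue
        for ri, r in enumerate(grid):
            if r == 0.0:
                errs[r].append(evaluate(model, val_ds))
                result.achieved.setdefault(r, 0.0)
                continue
            layer = model.layers[model.sz_layer_index]
            window = solve_window(
                NodeGeometry(layer.n_in, layer.n_out),
                family,
                r,
                seed=derive_seed(base_seed, "disorganized", family, ri, si, "window"),
            )
            masked = disorganize_model(model, window)
            errs[r].append(evaluate(masked, val_ds))
            result.achieved.setdefault(r, window.reduction)
    result.errors = errs
    return result


# ---------------------------------------------------------------------------
# statistics


@dataclass(frozen=True)
class ComparisonReport:
    """Two-sided rank-sum comparison of two error samples."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    significant: bool  # p < 0.05
    method: str
    note: str = ""


def wilcoxon_compare(
    errors_a, errors_b, label_a: str = "a", label_b: str = "b"
) -> ComparisonReport:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test on independent sessions.

    Exact null distribution when both samples have at most 12 values and the
    pooled sample is tie-free; otherwise the normal approximation with tie and
    continuity corrections.  Identical constant samples degenerate to p = 1.
    """
    a = np.asarray(list(errors_a), dtype=float)
    b = np.asarray(list(errors_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ContractError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ComparisonReport(
            label_a, label_b, a.size, b.size,
            statistic=float(a.size * b.size / 2),
            p_value=1.0, significant=False, method="degenerate",
            note="all values identical across both samples",
        )
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and max(a.size, b.size) <= 12:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic (tie-corrected)"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p = min(float(res.pvalue), 1.0)
    return ComparisonReport(
        label_a, label_b, a.size, b.size,
        statistic=float(res.statistic), p_value=p,
        significant=p < 0.05, method=method,
    )


# ---------------------------------------------------------------------------
# reporting


def summarize(sweeps: list[SweepResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format session table and per-grid-point means table.

    All sweeps must share the same reduction grid.  Rows are deterministically
    ordered by (protocol, family, reduction, session).
    """
    if not sweeps:
        raise ContractError("no sweeps to summarize")
    grids = {tuple(s.reductions) for s in sweeps}
    if len(grids) > 1:
        raise ContractError(f"sweeps have mismatched reduction grids: {sorted(grids)}")
    rows = []
    for s in sweeps:
        for r in s.reductions:
            for si, err in enumerate(s.errors.get(r, [])):
                rows.append(
                    {
                        "protocol": s.protocol,
                        "family": s.family,
                        "reduction": r,
                        "achieved_reduction": s.achieved.get(r, r),
                        "session": si,
                        "error": err,
                    }
                )
    long_df = pd.DataFrame(rows).sort_values(
        ["protocol", "family", "reduction", "session"], ignore_index=True
    )
    means_df = (
        long_df.groupby(["protocol", "family", "reduction"], as_index=False)
        .agg(mean_error=("error", "mean"), sessions=("error", "size"))
        .sort_values(["protocol", "family", "reduction"], ignore_index=True)
    )
    return long_df, means_df


def write_summary(sweeps: list[SweepResult], outdir) -> tuple[str, str]:
    """Write ``sessions.csv`` and ``means.csv`` under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long_df, means_df = summarize(sweeps)
    long_path = outdir / "sessions.csv"
    means_path = outdir / "means.csv"
    long_df.to_csv(long_path, index=False)
    means_df.to_csv(means_path, index=False)
    return str(long_path), str(means_path)
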