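"""Learning-curve summaries, the effectiveness ratio, and the comparison protocol.

The area under the learning curve (AULC) is a unit-step sum of the accuracy
recorded after each query; effectiveness of the drop-out mechanism is the
gain it adds to a strategy, normalized by how much that strategy beats random
sampling:

    (AULC_with - AULC_without) / (AULC_without - AULC_random)

Per-cell AULC values from repeated runs feed paired one-sided t-tests across
(dataset, heuristic) cells, testing whether masking improves the curves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .active_learning import ALConfig, LearningCurve, run_al_cycle
from .datasets import TabularDataset
from .oracles import fit_fft, fit_ttb

__all__ = [
    "aulc",
    "effectiveness_increase",
    "paired_t_test",
    "TTestResult",
    "ExperimentResult",
    "run_experiment",
]

logger = logging.getLogger(__name__)

HEURISTICS = ("ttb", "fft")


def aulc(curve) -> float:
    """Area under a learning curve: unit-step sum of post-query accuracies.

    A :class:`~dropal.active_learning.LearningCurve` contributes one term per
    query (its pre-query point, index 0, is excluded); a bare sequence is
    taken as per-query accuracies and summed directly.
    """
    if isinstance(curve, LearningCurve):
        values = np.asarray(curve.accuracies, dtype=float)[1:]
    else:
        values = np.asarray(curve, dtype=float)
    if values.size == 0:
        raise ValueError("cannot integrate an empty learning curve")
    return float(values.sum())


def effectiveness_increase(auc_with: float, auc_without: float, auc_random: float) -> float:
    """Drop-out gain relative to the strategy's edge over random sampling.

    Returns NaN (flagged undefined) when the strategy is no better than
    random sampling, i.e. the denominator vanishes.  Multiply by 100 to quote
    a percentage.
    """
    denom = auc_without - auc_random
    if denom == 0:
        logger.warning(
            "effectiveness undefined: strategy AULC equals random-sampling AULC"
        )
        return math.nan
    return (auc_with - auc_without) / denom


class TTestResult(NamedTuple):
    t: float
    df: int
    p_one_sided: float


def paired_t_test(
    with_values: Sequence[float], without_values: Sequence[float]
) -> TTestResult:
    """Paired t-test, one-sided for the alternative "with > without".

    Degenerate difference spreads are handled explicitly: identical lists give
    t = 0, p = 0.5; a constant nonzero difference leaves t undefined (NaN).
    """
    w = np.asarray(with_values, dtype=float)
    wo = np.asarray(without_values, dtype=float)
    if w.shape != wo.shape or w.ndim != 1 or w.size < 2:
        raise ValueError("need two equal-length 1-d samples with n >= 2")
    diff = w - wo
    n = diff.size
    if diff.std(ddof=1) == 0.0:
        if diff.mean() == 0.0:
            return TTestResult(0.0, n - 1, 0.5)
        return TTestResult(math.nan, n - 1, math.nan)
    res = stats.ttest_rel(w, wo, alternative="greater")
    return TTestResult(float(res.statistic), n - 1, float(res.pvalue))


@dataclass
class ExperimentResult:
    """Per-cell AULC values for a full (dataset x heuristic x strategy x dropout) grid.

    Cells are keyed ``(dataset, heuristic, strategy, dropout_flag)``; the
    random-sampling baseline is stored with ``dropout_flag=False``.
    """

    aulc_values: dict[tuple[str, str, str, bool], np.ndarray]
    iterations: int
    base_seed: int
    datasets: list[str] = field(default_factory=list)
    heuristics: list[str] = field(default_factory=list)
    strategies: list[str] = field(default_factory=list)

    def cell_mean(self, dataset: str, heuristic: str, strategy: str, dropout: bool) -> float:
        return float(np.nanmean(self.aulc_values[(dataset, heuristic, strategy, dropout)]))

    def summary_frame(self) -> pd.DataFrame:
        """Per-(dataset, heuristic) mean AULC for every strategy/dropout cell."""
        rows = []
        for ds in self.datasets:
            for h in self.heuristics:
                row: dict[str, object] = {"dataset": ds, "heuristic": h}
                for strat in self.strategies:
                    if strat == "random":
                        row["random"] = self.cell_mean(ds, h, "random", False)
                    else:
                        row[f"{strat}_without"] = self.cell_mean(ds, h, strat, False)
                        row[f"{strat}_with"] = self.cell_mean(ds, h, strat, True)
                rows.append(row)
        return pd.DataFrame(rows)

    def aggregate_frame(self) -> pd.DataFrame:
        """Mean AULC across datasets, one row per heuristic."""
        summary = self.summary_frame()
        return summary.drop(columns="dataset").groupby("heuristic", sort=False).mean().reset_index()

    def effectiveness(self, strategy: str, heuristic: str | None = None) -> float:
        """Effectiveness increase for a strategy, AULC first averaged across
        datasets (and heuristics unless one is given) so the denominator is
        well separated from cell-wise noise."""
        if strategy == "random":
            raise ValueError("effectiveness is defined relative to random sampling")
        if "random" not in self.strategies:
            raise ValueError("experiment has no random-sampling baseline")
        summary = self.summary_frame()
        if heuristic is not None:
            summary = summary[summary["heuristic"] == heuristic]
        return effectiveness_increase(
            summary[f"{strategy}_with"].mean(),
            summary[f"{strategy}_without"].mean(),
            summary["random"].mean(),
        )

    def paired_tests(self) -> dict[str, TTestResult]:
        """One-sided paired t-tests (with vs without drop-out) per strategy,
        pairing the per-(dataset, heuristic) mean AULC values."""
        summary = self.summary_frame()
        out = {}
        for strat in self.strategies:
            if strat == "random":
                continue
            w = summary[f"{strat}_with"].to_numpy()
            wo = summary[f"{strat}_without"].to_numpy()
            if w.size < 2:  # a single cell cannot be paired-tested
                out[strat] = TTestResult(math.nan, w.size - 1, math.nan)
            else:
                out[strat] = paired_t_test(w, wo)
        return out


def _fit_oracle(dataset: TabularDataset, heuristic: str, fft_depth: int):
    if heuristic == "ttb":
        return fit_ttb(dataset)
    if heuristic == "fft":
        return fit_fft(dataset, depth=min(fft_depth, dataset.d))
    raise ValueError(f"unknown heuristic {heuristic!r}; expected one of {HEURISTICS}")


def run_experiment(
    datasets: Mapping[str, TabularDataset],
    heuristics: Sequence[str] = HEURISTICS,
    strategies: Sequence[str] = ("random", "entropy", "density"),
    iterations: int = 10,
    base_seed: int = 0,
    config: ALConfig | None = None,
    fft_depth: int = 3,
) -> ExperimentResult:
    """Run the full comparison grid.

    Every (dataset, heuristic, strategy, dropout) cell gets ``iterations``
    independent active-learning runs with seeds ``base_seed + iteration``; the
    same seed is shared across cells within an iteration, so initial labeled
    sets are matched and the with/without comparison is paired.  Random
    sampling is run without drop-out only (it is the baseline).  A failed run
    is logged and recorded as NaN for its cell.
    """
    config = config or ALConfig()
    values: dict[tuple[str, str, str, bool], np.ndarray] = {}
    for ds_name, dataset in datasets.items():
        for heuristic in heuristics:
            oracle = _fit_oracle(dataset, heuristic, fft_depth)
            cells = []
            for strat in strategies:
                flags = (False,) if strat == "random" else (False, True)
                cells.extend((strat, flag) for flag in flags)
            for strat, flag in cells:
                aulcs = np.full(iterations, np.nan)
                for it in range(iterations):
                    seed = base_seed + it
                    try:
                        curve = run_al_cycle(
                            dataset, strat, oracle,
                            dropout_enabled=flag, config=config, seed=seed,
                        )
                        aulcs[it] = aulc(curve)
                    except Exception:
                        logger.exception(
                            "run failed: dataset=%s heuristic=%s strategy=%s "
                            "dropout=%s seed=%d", ds_name, heuristic, strat, flag, seed,
                        )
                values[(ds_name, heuristic, strat, flag)] = aulcs
    return ExperimentResult(
        aulc_values=values,
        iterations=iterations,
        base_seed=base_seed,
        datasets=list(datasets.keys()),
        heuristics=list(heuristics),
        strategies=list(strategies),
    )
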