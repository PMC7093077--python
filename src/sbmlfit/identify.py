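"""Repeated-estimation identifiability analysis.

Many independent optimization runs on the same problem, keep the best
fraction by final fitness, divide each retained estimate by its reference
(true) value, and summarize the normalized distributions per parameter.  A
tight distribution (low coefficient of variation) marks the parameter as
practically identifiable; a wide one means the data do not constrain it.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .estimate import EstimationResult, OptimizerConfig, estimate

__all__ = [
    "RunEnsemble",
    "ParameterSummary",
    "IdentifiabilityReport",
    "run_repeated",
    "select_best_fraction",
    "normalize_and_summarize",
    "plot_distributions",
    "DEFAULT_CV_THRESHOLD",
]

DEFAULT_CV_THRESHOLD = 0.2


@dataclass
class RunEnsemble:
    results: list[EstimationResult]
    seeds: list[int]

    def __post_init__(self) -> None:
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("ensemble seeds must be distinct")

    def __len__(self) -> int:
        return len(self.results)

    @property
    def parameter_ids(self) -> list[str]:
        return self.results[0].parameter_ids if self.results else []


@dataclass
class ParameterSummary:
    parameter: str
    mean: float  # of estimate / reference
    sd: float
    cv: float
    identifiable: bool


@dataclass
class IdentifiabilityReport:
    summaries: list[ParameterSummary]
    retained: int
    total: int
    cv_threshold: float
    ratios: np.ndarray = field(default=None, repr=False)  # (retained, n_params)
    parameter_ids: list[str] = field(default_factory=list)

    def summary_for(self, pid: str) -> ParameterSummary:
        for s in self.summaries:
            if s.parameter == pid:
                return s
        raise KeyError(f"no summary for parameter {pid!r}")

    def write_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["parameter", "mean", "sd", "cv", "identifiable"])
            for s in self.summaries:
                w.writerow([s.parameter, repr(s.mean), repr(s.sd),
                            repr(s.cv), str(s.identifiable).lower()])


def run_repeated(problem, config: OptimizerConfig, n: int,
                 seed0: int = 0) -> RunEnsemble:
    """``n`` independent runs with seeds ``seed0 .. seed0 + n - 1``."""
    if n < 2:
        raise ValueError("repeated estimation needs at least 2 runs")
    results = []
    seeds = []
    for k in range(n):
        cfg = OptimizerConfig(**{**config.__dict__, "seed": seed0 + k})
        results.append(estimate(problem, cfg))
        seeds.append(seed0 + k)
    return RunEnsemble(results=results, seeds=seeds)


def select_best_fraction(ens: RunEnsemble, fraction: float) -> RunEnsemble:
    """Retain the ``ceil(fraction * n)`` runs with the best final fitness;
    ties broken by seed for determinism."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    order = sorted(range(len(ens)),
                   key=lambda i: (ens.results[i].best_fitness, ens.seeds[i]))
    keep = order[:math.ceil(fraction * len(ens))]
    return RunEnsemble(results=[ens.results[i] for i in keep],
                       seeds=[ens.seeds[i] for i in keep])


def normalize_and_summarize(
    ens: RunEnsemble,
    reference: Mapping[str, float],
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> IdentifiabilityReport:
    """Per-parameter statistics of estimate/reference over the ensemble.

    Sample standard deviation (ddof=1); ``cv = sd / mean``.  A zero
    reference value is an error naming the parameter.
    """
    pids = ens.parameter_ids
    for pid in pids:
        if pid not in reference:
            raise KeyError(f"no reference value for parameter {pid!r}")
        if reference[pid] == 0:
            raise ValueError(f"zero reference value for parameter {pid!r}")
    ratios = np.array([
        [res.best[pid] / reference[pid] for pid in pids]
        for res in ens.results
    ])
    summaries = []
    for j, pid in enumerate(pids):
        col = ratios[:, j]
        mean = float(np.mean(col))
        sd = float(np.std(col, ddof=1)) if len(col) > 1 else 0.0
        cv = abs(sd / mean) if mean != 0 else math.inf
        summaries.append(ParameterSummary(
            parameter=pid, mean=mean, sd=sd, cv=cv,
            identifiable=cv <= cv_threshold))
    return IdentifiabilityReport(
        summaries=summaries,
        retained=len(ens),
        total=len(ens),
        cv_threshold=cv_threshold,
        ratios=ratios,
        parameter_ids=list(pids),
    )


def plot_distributions(report: IdentifiabilityReport,
                       path: str | os.PathLike) -> None:
    """Box plot of the normalized estimates, one box per parameter, with a
    horizontal reference line at ratio 1."""
    if not report.summaries:
        raise ValueError("cannot plot an empty report")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(report.parameter_ids)), 4))
    ax.boxplot([report.ratios[:, j] for j in range(report.ratios.shape[1])],
               tick_labels=report.parameter_ids)
    ax.axhline(1.0, color="0.4", linestyle="--", linewidth=1)
    ax.set_ylabel("estimate / reference")
    ax.set_xlabel("parameter")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
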