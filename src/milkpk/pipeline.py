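"""End-to-end analysis pipeline: NCA → summaries → penetration → WT → tests.

One call takes a :class:`StudyDataset` (real or simulated) and a
:class:`RunConfig` and returns every stage's output keyed by dose, the
shape the CLI ``pipeline`` subcommand and the reproduction script both
consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .data import RunConfig, StudyDataset
from .dose_stats import TestResult, compare_doses
from .exceptions import (
    CappingError,
    InsufficientDataError,
    MilkPKError,
    NotEstimableError,
    WindowError,
)
from .nca import NCAResults, compute_nca, results_to_frame, summarize_all
from .penetration import penetration_ratios
from .withdrawal import WtResult, estimate_wt_from_dataset

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("milkpk")


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    nca_results: dict[tuple[float, str], list[NCAResults]]  # (dose, matrix) -> results
    nca_table: pd.DataFrame
    summaries: dict[tuple[float, str], pd.DataFrame]        # (dose, matrix) -> table
    penetration: pd.DataFrame                               # per subject x dose
    wt: dict[float, WtResult]                               # dose -> WT
    wt_errors: dict[float, str] = field(default_factory=dict)
    comparisons: dict[str, TestResult] = field(default_factory=dict)


def run_pipeline(dataset: StudyDataset, config: RunConfig | None = None,
                 compare_parameters: tuple[str, ...] = ("cmax", "auc_inf"),
                 wt_round_to: float = 1.0,
                 excluded_times_by_dose: dict[float, tuple[float, ...]] | None = None,
                 ) -> PipelineResult:
    """Run every analysis stage on a dataset.

    Per dose and matrix: per-profile NCA and geometric summaries; per
    dose: subject-wise milk/plasma AUC ratios and the tolerance-limit
    withdrawal time (exclusion times from the config are applied only if
    the uncapped time selection overflows the cap).  When the dataset is
    a two-dose crossover, the listed parameters are compared between arms
    on dose-normalized values (plasma) and milk Cmax.
    """
    config = config or RunConfig()
    doses = dataset.doses
    nca_results: dict[tuple[float, str], list[NCAResults]] = {}
    for dose in doses:
        for matrix in ("plasma", "milk"):
            out = []
            for prof in dataset.select(matrix=matrix, dose=dose):
                try:
                    out.append(compute_nca(prof, config))
                except InsufficientDataError as e:
                    log.warning("NCA skipped for %s: %s", prof.key, e)
            nca_results[(dose, matrix)] = out

    all_results = [r for group in nca_results.values() for r in group]
    nca_table = results_to_frame(all_results) if all_results else pd.DataFrame()
    summaries = {k: summarize_all(v) for k, v in nca_results.items() if v}

    pen_rows = []
    for dose in doses:
        plasma = {r.subject_id: r for r in nca_results.get((dose, "plasma"), [])}
        for milk in nca_results.get((dose, "milk"), []):
            if milk.subject_id in plasma:
                pen_rows.append(
                    penetration_ratios(milk, plasma[milk.subject_id]).to_dict()
                )
    penetration = pd.DataFrame(pen_rows)

    wt: dict[float, WtResult] = {}
    wt_errors: dict[float, str] = {}
    for dose in doses:
        excl = None
        if excluded_times_by_dose is not None:
            excl = excluded_times_by_dose.get(dose, ())
        try:
            wt[dose] = estimate_wt_from_dataset(
                dataset, dose, config, round_to=wt_round_to,
                excluded_times=excl,
            )
        except (MilkPKError,) as e:
            wt_errors[dose] = str(e)
            log.warning("WT not estimable at dose %s: %s", dose, e)

    comparisons: dict[str, TestResult] = {}
    if len(doses) == 2 and dataset.design == "crossover":
        low, high = doses
        for matrix in ("plasma", "milk"):
            for param in compare_parameters:
                try:
                    comparisons[f"{matrix}_{param}"] = compare_doses(
                        nca_results[(low, matrix)], nca_results[(high, matrix)],
                        param, normalize=True,
                    )
                except MilkPKError as e:
                    log.warning("comparison %s/%s failed: %s", matrix, param, e)

    log.info(
        "pipeline: %d profiles analyzed, %d WT estimates, %d comparisons",
        len(all_results), len(wt), len(comparisons),
    )
    return PipelineResult(
        nca_results=nca_results, nca_table=nca_table, summaries=summaries,
        penetration=penetration, wt=wt, wt_errors=wt_errors,
        comparisons=comparisons,
    )
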