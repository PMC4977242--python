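"""End-to-end analysis: read -> summarize -> fit -> split -> validate -> report.

The headline quantity is ``measurements_to_plateau``: the number of
individual measurements performed before within-subject variance
stabilised (measurements per subject x knot index in a balanced design).
The report also embeds enough provenance (input path, flags, seed) to
re-run bit-identically.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import io as plio
from .errors import InsufficientDataError
from .records import MeasurementRecord
from .regression import QuadraticPlateauFit, fit_quadratic_plateau, fitted_curve_table
from .summaries import DEFAULT_SCALE_FACTOR, summarize_subjects
from .validation import DEFAULT_STRATA, GroupComparison, validate_split

log = logging.getLogger("plateaulc")

REPORT_SCHEMA = "plateau-lc/1"


@dataclass(frozen=True)
class AnalysisOptions:
    """Every decision flag of the pipeline, echoed into the report."""

    scale_factor: float = DEFAULT_SCALE_FACTOR
    min_measurements: int = 2
    skip_insufficient: bool = False
    knot_grid: Optional[tuple[int, int]] = None
    refine: bool = True
    levene_center: str = "mean"
    strata: Sequence[str] = DEFAULT_STRATA
    seed: Optional[int] = None


@dataclass(frozen=True)
class AnalysisReport:
    fit: QuadraticPlateauFit
    comparisons: list[GroupComparison]
    n_subjects: int
    n_measurements_per_subject: Optional[int]  # None when unbalanced
    measurements_to_plateau: Optional[int]
    curve: pd.DataFrame
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "schema": REPORT_SCHEMA,
            "fit": asdict(self.fit),
            "comparisons": [asdict(c) for c in self.comparisons],
            "n_subjects": self.n_subjects,
            "n_measurements_per_subject": self.n_measurements_per_subject,
            "measurements_to_plateau": self.measurements_to_plateau,
            "provenance": self.provenance,
        }


def run_analysis(
    source: Union[str, Path, Sequence[MeasurementRecord]],
    options: AnalysisOptions = AnalysisOptions(),
) -> AnalysisReport:
    """Run the full pipeline on a measurement CSV path or record list."""
    if isinstance(source, (str, Path)):
        records = plio.read_measurements(source)
        input_name = str(source)
    else:
        records = list(source)
        input_name = "<in-memory records>"
    log.info(
        "analysis flags: scale_factor=%s levene_center=%s refine=%s knot_grid=%s seed=%s",
        options.scale_factor, options.levene_center, options.refine,
        options.knot_grid, options.seed,
    )

    summaries = summarize_subjects(
        records,
        scale_factor=options.scale_factor,
        min_measurements=options.min_measurements,
        skip_insufficient=options.skip_insufficient,
    )
    if len(summaries) < 4:
        raise InsufficientDataError(
            f"need at least 4 subjects for the plateau fit, got {len(summaries)}"
        )

    fit = fit_quadratic_plateau(
        summaries, knot_grid=options.knot_grid, refine=options.refine
    )
    if fit.degenerate:
        log.warning("degenerate fit: no decreasing variance limb in the data")
        comparisons: list[GroupComparison] = []
    else:
        comparisons = validate_split(
            summaries,
            fit.knot_index,
            strata=options.strata,
            scale_factor=options.scale_factor,
            levene_center=options.levene_center,
        )

    counts = {s.n_measurements for s in summaries}
    n_per = counts.pop() if len(counts) == 1 else None
    measurements_to_plateau = (
        n_per * fit.knot_index if (n_per is not None and not fit.degenerate) else None
    )
    log.info(
        "knot at subject %d; ~%s individual measurements to plateau",
        fit.knot_index, measurements_to_plateau,
    )

    return AnalysisReport(
        fit=fit,
        comparisons=comparisons,
        n_subjects=len(summaries),
        n_measurements_per_subject=n_per,
        measurements_to_plateau=measurements_to_plateau,
        curve=fitted_curve_table(fit, summaries),
        provenance={
            "input": input_name,
            "n_records": len(records),
            "scale_factor": options.scale_factor,
            "min_measurements": options.min_measurements,
            "knot_grid": list(options.knot_grid) if options.knot_grid else None,
            "refine": options.refine,
            "levene_center": options.levene_center,
            "strata": list(options.strata),
            "seed": options.seed,
        },
    )
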