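"""Collapse raw repeated measurements into per-subject summaries.

The working assumption is that every measurement taken on one subject
targets the same true quantity, so any spread among a subject's values is
measurement error.  The per-subject sample variance is therefore the
response of the learning-curve regression, and the per-subject mean is the
unit of analysis for the early/late group comparisons.

Units: means are always reported in mm.  Variances are computed after
multiplying each value by ``scale_factor``; the default of 10 puts them on
a tenths-of-mm scale, the scale on which sub-millimetre calipers read and
on which the variance magnitudes are of order 1-20 rather than 0.01-0.2.
Variance scales with the square of the factor.
"""
from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Sequence

import numpy as np

from .errors import InsufficientReplicatesError
from .records import MeasurementRecord, SubjectSummary

DEFAULT_SCALE_FACTOR = 10.0


def summarize_subjects(
    records: Sequence[MeasurementRecord],
    scale_factor: float = DEFAULT_SCALE_FACTOR,
    min_measurements: int = 2,
    skip_insufficient: bool = False,
) -> list[SubjectSummary]:
    """Compute per-subject mean (mm) and within-subject sample variance.

    Parameters
    ----------
    records : sequence of MeasurementRecord
    scale_factor : float
        Values are multiplied by this before the variance is taken
        (default 10: tenths-of-mm variance scale).  The mean is unscaled.
    min_measurements : int
        Minimum replicates per subject (default 2; a variance needs >= 2).
    skip_insufficient : bool
        If True, subjects below the minimum are dropped with a warning
        instead of raising.

    Returns
    -------
    list of SubjectSummary ordered by subject_index.
    """
    if scale_factor <= 0:
        raise ValueError(f"scale_factor must be positive, got {scale_factor}")
    if min_measurements < 2:
        raise ValueError("min_measurements must be at least 2")
    by_subject: dict[str, list[MeasurementRecord]] = defaultdict(list)
    for rec in records:
        by_subject[rec.subject_id].append(rec)

    summaries = []
    for sid, recs in by_subject.items():
        if len(recs) < min_measurements:
            msg = (
                f"subject {sid!r} has {len(recs)} measurement(s), "
                f"fewer than the required {min_measurements}"
            )
            if skip_insufficient:
                warnings.warn(msg + "; excluded", stacklevel=2)
                continue
            raise InsufficientReplicatesError(msg)
        values = np.array([r.value for r in recs], dtype=float)
        sexes = {r.sex for r in recs if r.sex is not None}
        summaries.append(
            SubjectSummary(
                subject_index=recs[0].subject_index,
                subject_id=sid,
                n_measurements=len(values),
                mean=float(values.mean()),
                within_variance=float(np.var(values * scale_factor, ddof=1)),
                sex=sexes.pop() if len(sexes) == 1 else None,
            )
        )
    summaries.sort(key=lambda s: (s.subject_index, s.subject_id))
    return summaries
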