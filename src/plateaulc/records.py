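"""Core domain types: raw measurements and per-subject summaries.

The unit of raw data is one measurement of a physical quantity (here,
optic nerve sheath diameter in mm) at a labelled site on a subject.
Subjects carry an explicit chronological index: the order in which the
operator examined them is the abscissa of the learning curve, so it must
be supplied, never guessed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

SEXES = ("male", "female", "unknown")

#: default site vocabulary: {left,right} eye x {horizontal,sagittal} plane
DEFAULT_SITES = tuple(
    f"{eye}_{plane}" for eye in ("left", "right") for plane in ("horizontal", "sagittal")
)


@dataclass(frozen=True, order=True)
class MeasurementRecord:
    """A single measurement on one subject.

    Attributes
    ----------
    subject_index : int
        1-based chronological order of the subject's examination.
    subject_id : str
        Opaque subject identifier; all records of one subject share one index.
    site : str
        Measurement-site label (e.g. ``left_horizontal``).
    value : float
        Measured length in mm; strictly positive and finite.
    sex : str, optional
        ``male``, ``female`` or ``unknown``.
    """

    subject_index: int
    subject_id: str
    site: str
    value: float
    sex: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        if self.subject_index < 1:
            raise ValueError(f"subject_index must be >= 1, got {self.subject_index}")
        if not (math.isfinite(self.value) and self.value > 0):
            raise ValueError(f"value must be a positive finite length, got {self.value}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject collapse of the repeated measurements.

    ``mean`` is in mm; ``within_variance`` is the sample variance of the
    subject's measurements on the configured measurement scale (see
    :func:`plateaulc.summaries.summarize_subjects`).  Under the identity
    assumption -- all sites on a subject share one true value -- the
    within-subject variance is pure measurement error, and its decay over
    ``subject_index`` is the operator's learning curve.
    """

    subject_index: int
    subject_id: str
    n_measurements: int
    mean: float
    within_variance: float
    sex: Optional[str] = None

    def __post_init__(self):
        if self.n_measurements < 2:
            raise ValueError("a summary needs at least 2 measurements")
        if self.within_variance < 0:
            raise ValueError("within_variance cannot be negative")
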