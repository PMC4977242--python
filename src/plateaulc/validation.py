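"""Early/late validation of the learning-curve split.

Locating a plateau in within-subject variance only certifies the *operator*;
the split is valid evidence that early measurements remain usable if the
subjects before and after the knot look alike otherwise.  Two checks, on
the per-subject means (one number per subject, never pooled measurements):

* Welch's two-sample t test for equality of group means -- no equal-variance
  assumption, Welch-Satterthwaite degrees of freedom;
* Levene's test for homogeneity of the between-subject variance -- a one-way
  ANOVA on absolute deviations from each group's centre (mean for classic
  Levene, median for the Brown-Forsythe variant).

Both are run overall and within sex strata, two-sided, unadjusted: each
stratum is reported on its own.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, SplitError
from .records import SubjectSummary

DEFAULT_STRATA = ("overall", "male", "female")


@dataclass(frozen=True)
class GroupComparison:
    """Early-vs-late comparison within one stratum.

    Means are in mm; ``var_early``/``var_late`` are between-subject sample
    variances of the group means on the configured variance scale.
    ``flagged`` marks conventional results on degenerate input (all values
    identical), where p = 1 is returned by definition rather than computed.
    """

    stratum: str
    n_early: int
    n_late: int
    mean_early: float
    mean_late: float
    welch_t: float
    welch_df: float
    welch_p: float
    var_early: float
    var_late: float
    levene_W: float
    levene_p: float
    flagged: bool = False


def split_early_late(
    summaries: Sequence[SubjectSummary], knot_index: int
) -> tuple[list[SubjectSummary], list[SubjectSummary]]:
    """Partition subjects at the knot: index <= knot is early, rest late.

    Raises :class:`SplitError` if either side would be empty.
    """
    early = [s for s in summaries if s.subject_index <= knot_index]
    late = [s for s in summaries if s.subject_index > knot_index]
    if not early:
        raise SplitError(f"knot index {knot_index} leaves the early group empty")
    if not late:
        raise SplitError(f"knot index {knot_index} leaves the late group empty")
    return early, late


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float, bool]:
    """Welch two-sample t test (two-sided).

    Returns ``(t, df, p, flagged)``.  ``flagged`` is True for the degenerate
    convention: both groups constant with equal means gives t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("Welch's t test needs >= 2 values per group")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0, True
        raise InsufficientDataError(
            "both groups are constant with different means; t is undefined"
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue), False


def levene_test(
    x: Sequence[float], y: Sequence[float], center: str = "mean"
) -> tuple[float, float, bool]:
    """Levene's test for homogeneity of variance across two groups.

    ``center='mean'`` is the classic Levene statistic; ``'median'`` gives
    the Brown-Forsythe variant.  Returns ``(W, p, flagged)`` with the
    degenerate convention W = 0, p = 1 when every absolute deviation is
    zero in both groups.
    """
    if center not in ("mean", "median"):
        raise ValueError(f"center must be 'mean' or 'median', got {center!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("Levene's test needs >= 2 values per group")
    centre = np.mean if center == "mean" else np.median
    if np.all(np.abs(x - centre(x)) == 0) and np.all(np.abs(y - centre(y)) == 0):
        return 0.0, 1.0, True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warnings handled above
        W, p = stats.levene(x, y, center=center)
    return float(W), float(p), False


def validate_split(
    summaries: Sequence[SubjectSummary],
    knot_index: int,
    strata: Sequence[str] = DEFAULT_STRATA,
    scale_factor: float = 10.0,
    levene_center: str = "mean",
) -> list[GroupComparison]:
    """Run the early/late validation in each stratum.

    Welch's test is run on the per-subject means in mm; Levene's test and
    the reported between-subject variances use the means multiplied by
    ``scale_factor``, matching the scale of the within-subject variances
    (the Levene statistic itself is scale-invariant, so only the reported
    variances depend on it).  Strata whose early or late side is empty are
    skipped with a warning.
    """
    out = []
    for stratum in strata:
        if stratum == "overall":
            subset = list(summaries)
        else:
            subset = [s for s in summaries if s.sex == stratum]
        early = [s for s in subset if s.subject_index <= knot_index]
        late = [s for s in subset if s.subject_index > knot_index]
        if len(early) < 2 or len(late) < 2:
            warnings.warn(
                f"stratum {stratum!r} skipped: early/late sizes "
                f"({len(early)}, {len(late)}) are too small",
                stacklevel=2,
            )
            continue
        mx = np.array([s.mean for s in early])
        my = np.array([s.mean for s in late])
        t, df, p_t, flag_t = welch_t_test(mx, my)
        W, p_w, flag_w = levene_test(mx * scale_factor, my * scale_factor, levene_center)
        out.append(
            GroupComparison(
                stratum=stratum,
                n_early=len(early),
                n_late=len(late),
                mean_early=float(mx.mean()),
                mean_late=float(my.mean()),
                welch_t=t,
                welch_df=df,
                welch_p=p_t,
                var_early=float(np.var(mx * scale_factor, ddof=1)),
                var_late=float(np.var(my * scale_factor, ddof=1)),
                levene_W=W,
                levene_p=p_w,
                flagged=flag_t or flag_w,
            )
        )
    return out
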