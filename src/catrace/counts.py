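"""Immunostaining count-ratio analyses and freezing summaries.

Count tables carry one row per imaged slice: total DAPI nuclei, two marker
counts (e.g. mCherry+ engram cells and cFOS+ activated cells) and their
overlap.  Ratios such as (mCherry+)/DAPI or overlap/cFOS+ are computed per
slice and then averaged per mouse — the per-mouse value is the mean of its
slices, not the ratio of pooled counts — matching how reactivation
proportions are quantified from sectioned tissue.  ``chance_overlap``
provides the independence baseline (m1/DAPI)*(m2/DAPI) for judging overlap
enrichment.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import FREEZING, BehaviorTrack, InvalidConfigError

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ("mouse_id", "slice_id", "region",
                 "n_dapi", "n_marker1", "n_marker2", "n_overlap")

#: ratio name -> (numerator column, denominator column)
RATIOS = {
    "marker1/dapi": ("n_marker1", "n_dapi"),
    "marker2/dapi": ("n_marker2", "n_dapi"),
    "overlap/dapi": ("n_overlap", "n_dapi"),
    "overlap/marker1": ("n_overlap", "n_marker1"),
    "overlap/marker2": ("n_overlap", "n_marker2"),
}


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidConfigError(f"count table missing columns {missing}")
    t = table.copy()
    num = ["n_dapi", "n_marker1", "n_marker2", "n_overlap"]
    if (t[num] < 0).any().any():
        raise InvalidConfigError("counts must be nonnegative")
    bad = (t["n_overlap"] > t[["n_marker1", "n_marker2"]].min(axis=1)) \
        | (t[["n_marker1", "n_marker2"]].max(axis=1) > t["n_dapi"])
    if bad.any():
        raise InvalidConfigError(
            f"count-closure violated in slices {list(t.loc[bad, 'slice_id'])}")
    return t


def overlap_ratios(table: pd.DataFrame, ratio_spec: list[str] | None = None
                   ) -> pd.DataFrame:
    """Per-mouse marker ratios: slice-level ratio, then mouse mean.

    ``ratio_spec`` lists keys of :data:`RATIOS` (default: all).  Slices
    whose denominator is zero are reported as missing with a warning and
    dropped from that mouse's average.
    """
    t = validate_count_table(table)
    spec = ratio_spec or list(RATIOS)
    unknown = [r for r in spec if r not in RATIOS]
    if unknown:
        raise InvalidConfigError(f"unknown ratios {unknown}; choose from {list(RATIOS)}")
    for name in spec:
        num, den = RATIOS[name]
        zero = t[den] == 0
        if zero.any():
            msg = (f"{name}: zero denominator in slices "
                   f"{list(t.loc[zero, 'slice_id'])}; excluded from mouse averages")
            logger.warning(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            t[name] = np.where(zero, np.nan, t[num] / t[den])
    return t.groupby("mouse_id", sort=True)[spec].mean()


def chance_overlap(table: pd.DataFrame) -> pd.Series:
    """Expected overlap/DAPI fraction under marker independence, per mouse.

    Per slice: (n_marker1/n_dapi) * (n_marker2/n_dapi); then averaged over
    each mouse's slices.
    """
    t = validate_count_table(table)
    if (t["n_dapi"] == 0).any():
        raise InvalidConfigError("zero DAPI count in a slice")
    t["chance"] = (t["n_marker1"] / t["n_dapi"]) * (t["n_marker2"] / t["n_dapi"])
    return t.groupby("mouse_id", sort=True)["chance"].mean()


def freezing_percentage(behavior: BehaviorTrack, bin_s: float | None = None
                        ) -> np.ndarray:
    """Percent time freezing, whole-session or in consecutive bins.

    With ``bin_s`` set, the session is tiled into ``floor(duration/bin_s)``
    full bins and the freezing percentage of each is returned; without it a
    single whole-session percentage is returned (as a 1-element array).
    """
    if bin_s is None:
        return np.array([100.0 * behavior.occupancy(FREEZING)])
    if bin_s <= 0 or bin_s > behavior.duration_s:
        raise InvalidConfigError("bin_s must be in (0, session duration]")
    n_bins = int(behavior.duration_s / bin_s + 1e-9)
    edges = np.arange(n_bins + 1) * bin_s
    out = np.zeros(n_bins)
    for state, s, e in behavior.bouts:
        if state != FREEZING:
            continue
        for b in range(n_bins):
            lo, hi = edges[b], edges[b + 1]
            out[b] += max(0.0, min(e, hi) - max(s, lo))
    return 100.0 * out / bin_s


def group_compare(values_a, values_b, design: str = "unpaired"
                  ) -> tuple[float, float]:
    """Two-group comparison with a named standard test.

    ``design`` is one of ``unpaired`` (two-sample two-tailed Student's t,
    pooled variance), ``paired`` (paired t), ``mannwhitney`` (two-sided
    Mann-Whitney U) or ``pearson`` (correlation of paired values).  Returns
    ``(statistic, p_value)``.  The test is always the caller's explicit
    choice; no normality-based dispatch happens here.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidConfigError("need at least 2 values per group")
    if design == "unpaired":
        res = stats.ttest_ind(a, b)
    elif design == "paired":
        if a.size != b.size:
            raise InvalidConfigError("paired design needs equal-length groups")
        res = stats.ttest_rel(a, b)
    elif design == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif design == "pearson":
        if a.size != b.size:
            raise InvalidConfigError("correlation needs equal-length groups")
        res = stats.pearsonr(a, b)
    else:
        raise InvalidConfigError(f"unknown design {design!r}")
    return float(res.statistic), float(res.pvalue)
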