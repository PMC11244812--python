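"""Activity ranking and engram-composition statistics.

Neurons are ranked by AUC/sec within a recording group; the top 10%
(configurable) are the "active" population and the lower 90% "inactive".
The engram composition of each class (mCherry+ vs mCherry-) is compared
between groups with a Pearson chi-squared test on the 2x2 counts.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .core import CatraceError, InvalidConfigError, NeuronRecord

ACTIVE = "active"
INACTIVE = "inactive"


def classify_activity(records: list[NeuronRecord], active_fraction: float = 0.10
                      ) -> list[NeuronRecord]:
    """Label the top ``active_fraction`` of neurons by AUC/sec as active.

    Neurons are sorted ascending by ``(auc_per_sec, neuron_id)``; the top
    ``ceil(active_fraction * n)`` are active, the rest inactive.  The
    neuron-id tie-break makes the split deterministic when scores tie.
    Records are updated in place and returned.
    """
    if not records:
        raise InvalidConfigError("empty population")
    if not 0.0 < active_fraction < 1.0:
        raise InvalidConfigError("active_fraction must be in (0, 1)")
    if any(math.isnan(r.auc_per_sec) for r in records):
        raise CatraceError("all records need auc_per_sec before classification")
    n_active = math.ceil(active_fraction * len(records))
    ranked = sorted(records, key=lambda r: (r.auc_per_sec, r.neuron_id))
    for r in ranked[:-n_active]:
        r.activity_class = INACTIVE
    for r in ranked[-n_active:]:
        r.activity_class = ACTIVE
    return records


def composition_table(records: list[NeuronRecord]) -> pd.DataFrame:
    """2x2 cross-tabulation: {active, inactive} x {engram, non-engram}."""
    if any(r.activity_class is None for r in records):
        raise CatraceError("activity classes must be assigned first")
    table = pd.DataFrame(0, index=[ACTIVE, INACTIVE], columns=["engram", "non_engram"])
    for r in records:
        table.loc[r.activity_class, "engram" if r.engram else "non_engram"] += 1
    return table


def chi2_proportion_test(table) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 count table, df = 1.

    No continuity correction (large-sample usage).  Returns
    ``(statistic, p_value)``.
    """
    counts = np.asarray(table, dtype=float)
    if counts.shape != (2, 2):
        raise InvalidConfigError("expected a 2x2 table")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise InvalidConfigError("counts must be nonnegative integers")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise InvalidConfigError("degenerate table: a margin is zero")
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    assert dof == 1
    return float(stat), float(p)


def records_from_session(auc: pd.Series, engram_labels: np.ndarray
                         ) -> list[NeuronRecord]:
    """Bundle AUC/sec scores and engram labels into NeuronRecords."""
    if len(auc) != len(engram_labels):
        raise InvalidConfigError("auc and engram label lengths differ")
    return [NeuronRecord(neuron_id=str(nid), engram=bool(lab), auc_per_sec=float(v))
            for (nid, v), lab in zip(auc.items(), engram_labels)]
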