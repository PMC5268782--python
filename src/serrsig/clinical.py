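"""Clinical marker rules, contingency tests, and survival statistics.

Marker classification follows the study's scoring conventions: IHC positivity
means strictly more than 10% of neoplastic cells stained; CIMP-high means more
than 3 of 5 marker promoters methylated (low = 0-2, a count of exactly 3 goes
high under the default, configurable); MSI means at least 2 of 5
mononucleotide markers unstable. Associations between binary marker calls are
tested with the two-sided Fisher exact test (probability-ordering rule);
survival uses the Kaplan-Meier product-limit estimator and the log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from serrsig.matrix import SerrsigError


# ---------------------------------------------------------------------------
# marker classification rules

def ihc_call(fraction: float, threshold: float = 0.10) -> str:
    """Positive iff strictly more than ``threshold`` of neoplastic cells stain."""
    if not 0.0 <= fraction <= 1.0:
        raise SerrsigError(f"stained fraction must be in [0, 1], got {fraction}")
    return "positive" if fraction > threshold else "negative"


def cimp_call(methylated_count: int, three_is_high: bool = True) -> str:
    """CIMP-high vs CIMP-low from the 5-promoter methylation count.

    0-2 is low and 4-5 high; a count of exactly 3 falls between the study's
    stated definitions and goes high by default (``three_is_high``).
    """
    if methylated_count not in range(6):
        raise SerrsigError(f"methylated promoter count must be 0..5, got {methylated_count}")
    if methylated_count <= 2:
        return "CIMP-low"
    if methylated_count >= 4:
        return "CIMP-high"
    return "CIMP-high" if three_is_high else "CIMP-low"


def msi_call(unstable_count: int) -> str:
    """MSI iff at least 2 of the 5 microsatellite markers are unstable."""
    if unstable_count not in range(6):
        raise SerrsigError(f"unstable marker count must be 0..5, got {unstable_count}")
    return "MSI" if unstable_count >= 2 else "MSS"


# ---------------------------------------------------------------------------
# contingency tables and Fisher tests

def crosstab(records: pd.DataFrame, row_marker: str, col_marker: str) -> pd.DataFrame:
    """Cross-tabulate two called markers; cases missing either call are excluded.

    Returns the counts table (rows = categories of ``row_marker``); the
    number of excluded cases is stored in ``table.attrs['n_excluded']``.
    """
    sub = records[[row_marker, col_marker]]
    complete = sub.dropna()
    table = pd.crosstab(complete[row_marker], complete[col_marker])
    if table.to_numpy().sum() == 0:
        raise SerrsigError(f"empty contingency table for {row_marker} x {col_marker}")
    table.attrs["n_excluded"] = len(sub) - len(complete)
    return table


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher exact p for a 2x2 table with fixed margins.

    Two-sided p sums the point probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's (with a
    small relative tolerance for ties); one-sided alternatives are
    hypergeometric tails.
    """
    arr = np.asarray(getattr(table, "values", table), dtype=np.int64)
    if arr.shape != (2, 2):
        raise SerrsigError(f"fisher_exact_2x2 needs a 2x2 table, got shape {arr.shape}")
    if arr.sum() < 1:
        raise SerrsigError("empty 2x2 table")
    return float(stats.fisher_exact(arr, alternative=alternative)[1])


# ---------------------------------------------------------------------------
# survival

@dataclass
class SurvivalCurve:
    """Product-limit estimate for one group.

    ``median`` is the smallest time at which S(t) <= 0.5, or ``inf`` when the
    curve never reaches 0.5 within follow-up (reported as "greater than" the
    last observed time).
    """

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float
    n: int

    @property
    def median_label(self) -> str:
        if np.isfinite(self.median):
            return f"{self.median:g}"
        return f">{self.times.max():g}"


def km_estimate(records: pd.DataFrame) -> dict[str, SurvivalCurve]:
    """Kaplan-Meier curve per group from (time_days, event, group) records."""
    if (records["time_days"] <= 0).any():
        raise SerrsigError("nonpositive survival time")
    curves = {}
    for group, sub in records.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_days"], event_observed=sub["event"].astype(bool))
        sf = kmf.survival_function_.iloc[:, 0]
        ev = kmf.event_table
        curves[group] = SurvivalCurve(
            group=group,
            times=sf.index.to_numpy(dtype=float),
            survival=sf.to_numpy(dtype=float),
            at_risk=ev["at_risk"].to_numpy(dtype=float),
            median=float(kmf.median_survival_time_),
            n=len(sub),
        )
    return curves


def logrank_test(records: pd.DataFrame, group_a: str, group_b: str) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its two-sided p."""
    a = records[records["group"] == group_a]
    b = records[records["group"] == group_b]
    if a["event"].astype(bool).sum() + b["event"].astype(bool).sum() < 1:
        raise SerrsigError("log-rank test needs at least one event")
    res = _ll_logrank(
        a["time_days"], b["time_days"],
        event_observed_A=a["event"].astype(bool),
        event_observed_B=b["event"].astype(bool),
    )
    return float(res.test_statistic), float(res.p_value)
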