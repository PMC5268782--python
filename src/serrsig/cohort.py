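"""Human-cohort case/control definition and the two-group expression signature.

Cases mirror the CDX2-low / BRAF V600E-mutant tumours; controls are
CDX2-high / BRAF wild-type. "Low CDX2" has no canonical cut, so the rule is a
configurable quantile of CDX2 expression across the cohort (default lowest
quartile) and is always recorded in the design's provenance note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from serrsig.matrix import DesignError, ExpressionMatrix, SerrsigError


@dataclass
class CohortDesign:
    case_ids: list[str]
    control_ids: list[str]
    provenance: str = ""
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if set(self.case_ids) & set(self.control_ids):
            raise DesignError("case and control sets overlap")
        if len(self.case_ids) < 2 or len(self.control_ids) < 2:
            raise DesignError("each cohort group needs at least 2 samples")


def assign_cohort_groups(
    cdx2_expression: pd.Series,
    braf_mutant: pd.Series,
    cdx2_low_quantile: float = 0.25,
) -> CohortDesign:
    """Split a cohort into CDX2-low/BRAF-mutant cases vs CDX2-high/wild-type controls.

    ``cdx2_expression`` maps sample id to the CDX2 log2 value;
    ``braf_mutant`` maps sample id to a boolean mutation status. Samples at
    or below the ``cdx2_low_quantile`` quantile of CDX2 are "low", the rest
    "high". Samples matching neither case nor control pattern are excluded
    and counted.
    """
    missing = cdx2_expression.index.difference(braf_mutant.index)
    if len(missing):
        raise SerrsigError(f"samples without mutation status: {list(missing[:5])}")
    braf_mutant = braf_mutant.loc[cdx2_expression.index].astype(bool)
    cut = cdx2_expression.quantile(cdx2_low_quantile)
    low = cdx2_expression <= cut
    cases = list(cdx2_expression.index[low & braf_mutant])
    controls = list(cdx2_expression.index[~low & ~braf_mutant])
    if not cases:
        raise DesignError("no samples are CDX2-low and BRAF-mutant (empty case set)")
    if not controls:
        raise DesignError("no samples are CDX2-high and BRAF-wild-type (empty control set)")
    n_excluded = len(cdx2_expression) - len(cases) - len(controls)
    prov = (
        f"cases = CDX2 <= {cdx2_low_quantile:g}-quantile ({cut:.4g}) and BRAF mutant; "
        f"controls = CDX2 above that quantile and BRAF wild-type; "
        f"{n_excluded} samples matched neither and were excluded"
    )
    return CohortDesign(cases, controls, provenance=prov, n_excluded=n_excluded)


def two_group_stats(
    X: ExpressionMatrix, design: CohortDesign, welch: bool = False
) -> pd.DataFrame:
    """Per-gene two-sample t statistics of cases vs controls.

    Returns columns ``diff_log2`` (case minus control mean), ``fold_change``
    (2**|diff|, direction in ``diff_log2``), ``t``, ``p`` (two-sided) and
    ``degenerate`` (zero pooled variance). The default test pools an equal
    variance across the two groups; ``welch=True`` switches to the unequal
    variance form.
    """
    a = X.values[design.case_ids].to_numpy(dtype=float)
    b = X.values[design.control_ids].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise DesignError("each group needs >=2 samples for a t-test")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    diff = m1 - m2
    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(diff, n1 + n2 - 2)
    # A zero pooled variance with a zero difference carries no information
    # (degenerate, excluded); with a nonzero difference it is an exact
    # separation of the groups and the two-sided p collapses to 0.
    degenerate = (se2 <= 0) & (diff == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame(
        {
            "diff_log2": diff,
            "fold_change": np.exp2(np.abs(diff)),
            "t": t,
            "p": p,
            "degenerate": degenerate,
        },
        index=X.gene_ids,
    )
    out.loc[degenerate, ["t", "p"]] = np.nan
    return out


def two_group_signature(
    X: ExpressionMatrix,
    design: CohortDesign,
    p_max: float = 0.01,
    fc_min: float = 1.3,
    welch: bool = False,
) -> pd.Series:
    """Call genes up/down/neither by t-test p and geometric fold-change.

    up: p < p_max and diff > log2(fc_min); down: p < p_max and
    diff < -log2(fc_min); both cuts strict. Degenerate genes are excluded.
    """
    st = two_group_stats(X, design, welch=welch)
    lfc = np.log2(fc_min)
    ok = st["p"].notna() & (st["p"] < p_max)
    calls = pd.Series("neither", index=st.index, name="call")
    calls[ok & (st["diff_log2"] > lfc)] = "up"
    calls[ok & (st["diff_log2"] < -lfc)] = "down"
    return calls
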