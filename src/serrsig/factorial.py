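"""Per-gene one-way ANOVA, the Cdx2-by-Braf interaction contrast, and PCA.

The central statistic is a factorial difference-of-differences on log2
expression over the genotype quartet (control, Cdx2KO, BrafVE,
Cdx2KO_BrafVE)::

    c = (mean_Cdx2KO_BrafVE - mean_BrafVE) - (mean_Cdx2KO - mean_control)

with anti-log ``rho = 2**c``, the *ratio of ratios*: the fold-change of the
double mutant over the BRAF single mutant divided by the fold-change of the
CDX2 single mutant over control. ``rho`` far from 1 with a small interaction
p-value marks genes whose response to BRAF V600E depends on CDX2 status.

Each gene is fitted by classical fixed-effects one-way ANOVA with a pooled
equal variance across all fitted groups; contrasts are t-tests on the fit's
residual degrees of freedom (no shrinkage or moderation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from serrsig.matrix import DesignError, ExpressionMatrix, SerrsigError

logger = logging.getLogger(__name__)

#: Default genotype labels of the five-group mouse design.
DEFAULT_GROUPS = ("control", "Cdx2KO", "BrafVE", "Cdx2KO_BrafVE", "ApcKO")
#: The factorial quartet, ordered (control, Cdx2KO, BrafVE, Cdx2KO_BrafVE).
DEFAULT_QUARTET = ("control", "Cdx2KO", "BrafVE", "Cdx2KO_BrafVE")


@dataclass
class GroupDesign:
    """Group labels and the interaction quartet of a factorial design.

    ``quartet`` is ordered (control, Cdx2KO, BrafVE, Cdx2KO_BrafVE); the
    interaction contrast is defined with respect to that order.
    """

    groups: tuple[str, ...] = DEFAULT_GROUPS
    quartet: tuple[str, str, str, str] | None = DEFAULT_QUARTET

    def __post_init__(self) -> None:
        if self.quartet is None:
            return
        if len(set(self.quartet)) != 4:
            raise DesignError("quartet groups must be four distinct labels")
        missing = [q for q in self.quartet if q not in self.groups]
        if missing:
            raise DesignError(f"quartet groups not in design: {missing}")


@dataclass
class AnovaFit:
    """Per-gene one-way ANOVA fit.

    Attributes
    ----------
    group_means :
        DataFrame genes x groups of arithmetic means of log2 values.
    s2 :
        Pooled within-group residual variance per gene (log2^2 units),
        ``SS_within / df``.
    df :
        Residual degrees of freedom, ``N_samples - N_groups`` (shared by all
        genes).
    n_per_group :
        Sample count per fitted group.
    """

    group_means: pd.DataFrame
    s2: pd.Series
    df: int
    n_per_group: dict[str, int] = field(default_factory=dict)


@dataclass
class SelectionThresholds:
    """Selection regime: strict on p, inclusive on the ratio of ratios.

    ``rho_min = 10`` is the heatmap regime; ``rho_min = 1.3`` the enrichment
    regime.
    """

    p_max: float = 0.01
    rho_min: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.p_max <= 1:
            raise SerrsigError(f"p_max must be in (0, 1], got {self.p_max}")
        if not self.rho_min > 1:
            raise SerrsigError(f"rho_min must exceed 1, got {self.rho_min}")


def fit_oneway_anova(X: ExpressionMatrix, design: GroupDesign | None = None) -> AnovaFit:
    """Fit a per-gene one-way ANOVA across the design's groups.

    Pools the within-group variance across *all* fitted groups with residual
    df ``N - G``. Raises :class:`DesignError` if a design group is absent and
    a df-0 error if every group has a single sample (no test is possible).
    """
    if design is None:
        design = GroupDesign(groups=tuple(X.groups()), quartet=DEFAULT_QUARTET)
    values = X.values
    means = {}
    n_per_group = {}
    ss_within = np.zeros(X.n_genes)
    for g in design.groups:
        cols = X.samples_in_group(g)
        if not cols:
            raise DesignError(f"design group {g!r} has no samples in the matrix")
        sub = values[cols].to_numpy()
        mu = sub.mean(axis=1)
        means[g] = mu
        n_per_group[g] = len(cols)
        ss_within += ((sub - mu[:, None]) ** 2).sum(axis=1)
    n_total = sum(n_per_group.values())
    df = n_total - len(design.groups)
    if df < 1:
        raise DesignError(
            "residual degrees of freedom is 0 (all groups have a single "
            "sample); group-comparison tests are unavailable"
        )
    group_means = pd.DataFrame(means, index=values.index)
    s2 = pd.Series(ss_within / df, index=values.index, name="s2")
    return AnovaFit(group_means=group_means, s2=s2, df=df, n_per_group=n_per_group)


def _contrast_frame(fit: AnovaFit, contrast: pd.Series, se_factor: float) -> pd.DataFrame:
    """t statistics and two-sided p for a per-gene contrast with common se factor."""
    se = np.sqrt(fit.s2 * se_factor)
    degenerate = fit.s2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = contrast / se
    p = 2.0 * stats.t.sf(np.abs(t), fit.df)
    out = pd.DataFrame(
        {
            "contrast_log2": contrast,
            "se": se,
            "t": t,
            "p": p,
            "degenerate": degenerate,
        }
    )
    out.loc[degenerate, ["t", "p"]] = np.nan
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning(
            "%d genes with zero residual variance: p flagged degenerate, "
            "excluded from selection",
            n_deg,
        )
    return out


def interaction_test(fit: AnovaFit, quartet: tuple[str, str, str, str] = DEFAULT_QUARTET) -> pd.DataFrame:
    """Difference-of-differences interaction statistic per gene.

    Returns a DataFrame with columns ``contrast_log2`` (c), ``se``, ``t``,
    ``p`` (two-sided, t distribution on the fit's residual df),
    ``ratio_of_ratios`` (2**c) and ``degenerate`` (zero residual variance;
    such genes carry NaN p and are excluded by selection).
    """
    ctrl, cdx2, braf, double = quartet
    for g in quartet:
        if g not in fit.group_means.columns:
            raise DesignError(f"quartet group {g!r} not in fit")
    m = fit.group_means
    c = (m[double] - m[braf]) - (m[cdx2] - m[ctrl])
    se_factor = sum(1.0 / fit.n_per_group[g] for g in quartet)
    out = _contrast_frame(fit, c, se_factor)
    out["ratio_of_ratios"] = np.exp2(out["contrast_log2"])
    return out


def pairwise_group_test(fit: AnovaFit, g1: str, g2: str) -> pd.DataFrame:
    """Contrast of two group means using the pooled ANOVA variance."""
    for g in (g1, g2):
        if g not in fit.group_means.columns:
            raise DesignError(f"group {g!r} not in fit")
    diff = fit.group_means[g1] - fit.group_means[g2]
    se_factor = 1.0 / fit.n_per_group[g1] + 1.0 / fit.n_per_group[g2]
    return _contrast_frame(fit, diff, se_factor)


def select_interaction_genes(
    stats_df: pd.DataFrame, thresholds: SelectionThresholds | None = None
) -> pd.Series:
    """Call each gene up / down / neither at the given threshold regime.

    up: p < p_max and rho >= rho_min; down: p < p_max and rho <= 1/rho_min.
    The p cut is strict, the rho cut inclusive. Degenerate genes (NaN p) are
    never selected.
    """
    thr = thresholds or SelectionThresholds()
    p = stats_df["p"]
    rho = stats_df["ratio_of_ratios"]
    ok = p.notna() & (p < thr.p_max)
    calls = pd.Series("neither", index=stats_df.index, name="call")
    calls[ok & (rho >= thr.rho_min)] = "up"
    calls[ok & (rho <= 1.0 / thr.rho_min)] = "down"
    return calls


def collapse_probesets(probe_calls: pd.Series, probe_to_gene: pd.Series) -> pd.Series:
    """Collapse probe-level calls to distinct genes.

    A gene is *up* if at least one of its probes is up and none is down
    (symmetrically for *down*); conflicting probes force *neither* (logged).
    Probes without a mapping are dropped with a logged count.
    """
    mapped = probe_calls.index.intersection(probe_to_gene.index)
    n_unmapped = len(probe_calls) - len(mapped)
    if n_unmapped:
        logger.info("dropped %d unmapped probes during collapsing", n_unmapped)
    df = pd.DataFrame(
        {"call": probe_calls.loc[mapped], "gene": probe_to_gene.loc[mapped]}
    )
    out = {}
    n_conflicts = 0
    for gene, sub in df.groupby("gene", sort=True):
        has_up = (sub["call"] == "up").any()
        has_down = (sub["call"] == "down").any()
        if has_up and has_down:
            out[gene] = "neither"
            n_conflicts += 1
        elif has_up:
            out[gene] = "up"
        elif has_down:
            out[gene] = "down"
        else:
            out[gene] = "neither"
    if n_conflicts:
        logger.warning("%d genes had conflicting probe calls; set to neither", n_conflicts)
    return pd.Series(out, name="call")


def principal_components(X: ExpressionMatrix, n_components: int = 2):
    """Sample-level principal component scores of gene-centered expression.

    Genes are centered (no scaling); components are those of the sample
    covariance, ordered by decreasing explained variance. The sign of each
    component is fixed so its largest-magnitude sample loading is positive.

    Returns ``(scores, explained_variance)`` where ``scores`` is a samples x
    components DataFrame and ``explained_variance`` the per-component
    variances (summing, over a full decomposition, to the total gene-centered
    variance).
    """
    if X.n_samples < 2:
        raise DesignError("principal components require at least 2 samples")
    if n_components > X.n_samples:
        raise DesignError(
            f"n_components={n_components} exceeds the number of samples {X.n_samples}"
        )
    A = X.values.to_numpy(dtype=float)
    A = A - A.mean(axis=1, keepdims=True)
    # SVD of the centered matrix: sample scores are V * S.
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    scores = vt.T * s
    for j in range(scores.shape[1]):
        k = np.argmax(np.abs(scores[:, j]))
        if scores[k, j] < 0:
            scores[:, j] = -scores[:, j]
    explained = s**2 / (X.n_samples - 1)
    scores = scores[:, :n_components]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=X.sample_ids, columns=cols),
        pd.Series(explained[:n_components], index=cols, name="explained_variance"),
    )
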