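"""Mouse-to-human homolog mapping and the Mantel-Haenszel concordance test.

Mouse interaction calls are carried to human genes through 1-to-1 best
homolog pairs (homology groups with exactly one gene per species). The
mouse-selected, human-measured genes populate a 3x2 table — rows = human
call {up, neither, down} scored {+1, 0, -1}, columns = mouse call {up, down}
scored {+1, -1} — and the association is tested with the Mantel-Haenszel
chi-square for singly ordered tables: Q_MH = (N - 1) r**2, where r is the
count-weighted Pearson correlation of the row and column scores, referred to
a chi-square distribution with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from serrsig.matrix import SerrsigError

MOUSE_TAXON = "10090"
HUMAN_TAXON = "9606"

ROW_CATEGORIES = ("up", "neither", "down")
ROW_SCORES = (1.0, 0.0, -1.0)
COL_CATEGORIES = ("up", "down")
COL_SCORES = (1.0, -1.0)


def map_homologs_one_to_one(
    records: pd.DataFrame,
    source_taxon: str = MOUSE_TAXON,
    target_taxon: str = HUMAN_TAXON,
) -> pd.DataFrame:
    """Retain only homology groups with exactly one gene of each species.

    ``records`` is the tidy Homologene-dialect table (columns ``group_id``,
    ``taxon_id``, ``gene_id``, optionally ``gene_symbol``). Returns a
    two-column frame ``source_gene`` / ``target_gene``, one row per retained
    group, sorted by group id.
    """
    recs = records[records["taxon_id"].isin([source_taxon, target_taxon])]
    pairs = []
    for gid, sub in recs.groupby("group_id", sort=True):
        src = sub.loc[sub["taxon_id"] == source_taxon, "gene_id"]
        tgt = sub.loc[sub["taxon_id"] == target_taxon, "gene_id"]
        if len(src) == 1 and len(tgt) == 1:
            pairs.append((gid, src.iloc[0], tgt.iloc[0]))
    return pd.DataFrame(pairs, columns=["group_id", "source_gene", "target_gene"])


@dataclass
class ConcordanceTable:
    """3x2 counts: rows = human {up, neither, down}, columns = mouse {up, down}."""

    counts: pd.DataFrame
    n_unmeasured: int = 0
    row_scores: tuple[float, ...] = ROW_SCORES
    col_scores: tuple[float, ...] = COL_SCORES

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise SerrsigError("negative counts in concordance table")
        if self.N == 0:
            raise SerrsigError("empty concordance table")

    @property
    def N(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class MHResult:
    r: float
    q_mh: float
    p: float
    log10_p: float
    N: int


def concordance_table(
    mouse_calls: pd.Series,
    human_calls: pd.Series,
    pairs: pd.DataFrame,
) -> ConcordanceTable:
    """Cross-tabulate mouse vs human calls over 1-to-1 mapped genes.

    The population is the mapped genes whose mouse call is up or down and
    that are measured (present) in the human call series; mapped genes
    missing from either series are excluded and counted in
    ``n_unmeasured``.
    """
    src = pairs["source_gene"]
    tgt = pairs["target_gene"]
    measured = src.isin(mouse_calls.index) & tgt.isin(human_calls.index)
    n_unmeasured = int((~measured).sum())
    src, tgt = src[measured], tgt[measured]
    mcall = mouse_calls.loc[src].to_numpy()
    hcall = human_calls.loc[tgt].to_numpy()
    keep = np.isin(mcall, COL_CATEGORIES)
    mcall, hcall = mcall[keep], hcall[keep]
    counts = pd.DataFrame(0, index=list(ROW_CATEGORIES), columns=list(COL_CATEGORIES))
    for h, m in zip(hcall, mcall):
        h = h if h in ROW_CATEGORIES else "neither"
        counts.loc[h, m] += 1
    return ConcordanceTable(counts, n_unmeasured=n_unmeasured)


def mantel_haenszel_association(table: ConcordanceTable) -> MHResult:
    """Mantel-Haenszel chi-square of linear association for a scored r x c table.

    ``Q_MH = (N - 1) * r**2`` with ``r`` the count-weighted Pearson
    correlation between row and column scores; p is the upper chi-square(1)
    tail. For p-values beyond float range ``log10_p`` carries the tail on the
    log10 scale. Raises on degenerate tables (all mass in one row or one
    column).
    """
    w = table.counts.to_numpy(dtype=float)
    N = w.sum()
    if N < 2:
        raise SerrsigError("Mantel-Haenszel test needs N >= 2")
    rs = np.asarray(table.row_scores, dtype=float)
    cs = np.asarray(table.col_scores, dtype=float)
    x = np.repeat(rs, len(cs)).reshape(w.shape)  # row score per cell
    y = np.tile(cs, (len(rs), 1))  # column score per cell
    mx = (w * x).sum() / N
    my = (w * y).sum() / N
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        raise SerrsigError("degenerate table: zero score variance in a margin")
    cov = (w * (x - mx) * (y - my)).sum()
    r = cov / np.sqrt(vx * vy)
    q = (N - 1.0) * r**2
    p = float(stats.chi2.sf(q, df=1))
    log10_p = float(stats.chi2.logsf(q, df=1) / np.log(10.0))
    return MHResult(r=float(r), q_mh=float(q), p=p, log10_p=log10_p, N=int(N))
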