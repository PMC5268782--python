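"""Gene-set over-representation with one-sided exact tests and permutation FDR.

For a selected list of K genes from a universe of N, each gene set of
in-universe size n overlapping the list in x genes receives the upper-tail
hypergeometric probability

    p = P(X >= x),  X ~ Hypergeometric(N, K, n)

(equal to the one-sided Fisher exact p of the 2x2 overlap table) and an
observed/expected ratio ``x / (n K / N)``. Sets are ranked by ascending p and
a permutation FDR (Q-value) is attached: selected identifiers are redrawn
uniformly at random ``n_perm`` times at fixed K — equivalent to permuting
gene identifiers — and Q at rank k is the mean number of permuted sets
reaching the observed rank-k p-value, divided by k, truncated at 1 and made
nondecreasing in rank.

Tail probabilities are accumulated in log space (logsumexp over the
hypergeometric point masses) so magnitudes of order 1e-28 keep full relative
accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from serrsig.matrix import SerrsigError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions; member and name uniqueness enforced."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise SerrsigError(f"duplicate members in gene set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then members.

    Duplicate members within a line are dropped with a warning; a line with
    fewer than three fields is a parse error naming the line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SerrsigError(
                    f"{path}:{lineno}: malformed GMT line (expected >=3 tab-separated fields)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r} deduplicated")
            if name in sets:
                raise SerrsigError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def _log_upper_tail(x: int, N: int, K: int, n: int) -> float:
    """log P(X >= x) by log-space summation of hypergeometric point masses."""
    hi = min(n, K)
    if x <= max(0, n + K - N):
        return 0.0
    if x > hi:
        return -np.inf
    support = np.arange(x, hi + 1)
    return float(logsumexp(hypergeom.logpmf(support, N, K, n)))


def hypergeom_enrichment(
    selected: list[str], universe: list[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """One row per set: overlap counts, one-sided exact p, observed/expected.

    Sets are intersected with the universe before sizing; ``selected`` must
    be a subset of ``universe`` (offenders are listed in the error).
    """
    uni = set(universe)
    sel = set(selected)
    stray = sorted(sel - uni)
    if stray:
        raise SerrsigError(f"selected genes outside the universe: {stray[:10]}")
    N, K = len(uni), len(sel)
    rows = []
    for name, members in collection.sets.items():
        in_uni = uni.intersection(members)
        n = len(in_uni)
        x = len(sel.intersection(in_uni))
        expected = n * K / N
        p = float(np.exp(_log_upper_tail(x, N, K, n))) if n else 1.0
        rows.append(
            {
                "set": name,
                "n": n,
                "x": x,
                "p": min(p, 1.0),
                "obs_exp": (x / expected) if expected > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("set")


def rank_sets(rows: pd.DataFrame) -> pd.DataFrame:
    """Rank by ascending p, ties by descending obs_exp then set name (1-based)."""
    out = rows.copy()
    out["_name"] = out.index
    out = out.sort_values(["p", "obs_exp", "_name"], ascending=[True, False, True])
    out = out.drop(columns="_name")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def permutation_fdr(
    ranked: pd.DataFrame,
    universe: list[str],
    K: int,
    collection: GeneSetCollection,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach permutation Q-values to a ranked enrichment table.

    For each permutation a uniform random K-subset of the universe stands in
    for the selected list and all set p-values are recomputed; Q at rank k is
    the mean count of permuted sets with p <= p_(k), divided by k, truncated
    at 1 and monotonized to be nondecreasing in rank. Deterministic given
    ``seed``.
    """
    if n_perm < 1:
        raise SerrsigError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    uni = sorted(set(universe))
    N = len(uni)
    if K > N:
        raise SerrsigError("K exceeds the universe size")
    # Boolean membership matrix over a fixed universe ordering.
    idx = {g: i for i, g in enumerate(uni)}
    names = ranked.index.to_list()
    member = np.zeros((len(names), N), dtype=bool)
    sizes = np.zeros(len(names), dtype=int)
    for i, name in enumerate(names):
        cols = [idx[g] for g in collection.sets[name] if g in idx]
        member[i, cols] = True
        sizes[i] = len(cols)
    obs_p = ranked["p"].to_numpy()
    exceed = np.zeros(len(names))  # permutation-mean count of sets with p <= p_(k)
    for _ in range(n_perm):
        draw = rng.choice(N, size=K, replace=False)
        mask = np.zeros(N, dtype=bool)
        mask[draw] = True
        overlap = member[:, mask].sum(axis=1)
        perm_p = hypergeom.sf(overlap - 1, N, sizes, K)
        # count permuted sets reaching each observed p-threshold
        exceed += (perm_p[None, :] <= obs_p[:, None] * (1 + 1e-12)).sum(axis=1)
    exceed /= n_perm
    q = np.minimum(exceed / ranked["rank"].to_numpy(), 1.0)
    q = np.maximum.accumulate(q)  # nondecreasing in rank
    out = ranked.copy()
    out["q"] = q
    return out


def enrich(
    selected: list[str],
    universe: list[str],
    collection: GeneSetCollection,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Full over-representation pipeline: test, rank, permutation FDR."""
    rows = hypergeom_enrichment(selected, universe, collection)
    ranked = rank_sets(rows)
    return permutation_fdr(ranked, universe, len(set(selected)), collection, n_perm, seed)
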