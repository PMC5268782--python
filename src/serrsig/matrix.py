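"""The log2 expression matrix container used by every expression stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SerrsigError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(SerrsigError):
    """Invalid configuration value; the message names the offending field."""


class DesignError(SerrsigError):
    """Sample/group design does not support the requested computation."""


@dataclass
class ExpressionMatrix:
    """Log2 abundance values for genes x samples with per-sample group labels.

    Parameters
    ----------
    values :
        DataFrame of log2 abundances, index = gene ids, columns = sample ids.
        Missing values are rejected (rows with NaN must be dropped upstream).
    sample_groups :
        Mapping (Series or dict) from sample id to group label; every sample
        column must be covered.
    """

    values: pd.DataFrame
    sample_groups: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if isinstance(self.sample_groups, dict):
            self.sample_groups = pd.Series(self.sample_groups)
        if self.sample_groups is None:
            raise DesignError("sample_groups is required")
        missing = [s for s in self.values.columns if s not in self.sample_groups.index]
        if missing:
            raise DesignError(f"samples without a group label: {missing[:5]}")
        self.sample_groups = self.sample_groups.loc[self.values.columns]
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)]
            raise SerrsigError(
                f"missing values in expression matrix for genes {list(bad[:5])}; "
                "drop incomplete rows before constructing the matrix"
            )
        if not np.issubdtype(self.values.dtypes.iloc[0], np.number):
            raise SerrsigError("expression values must be numeric")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> list[str]:
        """Distinct group labels in column order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.sample_groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.sample_groups.index[self.sample_groups == group])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(sample_ids)],
            self.sample_groups.loc[list(sample_ids)],
        )
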