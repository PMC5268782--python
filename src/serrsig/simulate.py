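"""Synthetic generators for every input the pipeline consumes.

The generators emulate the study conditions at desk scale: a five-genotype
mouse design with three animals per group and planted Cdx2-by-Braf
interaction effects; an 18-vs-104 human cohort with planted signature genes;
Homologene-like homology groups with a controllable 1-to-1 fraction;
gene-set collections over a universe; a 36-case marker cohort with latent
class structure; and per-group exponential survival with administrative
censoring at 480 days. Noise is i.i.d. Gaussian on the log2 scale; the same
seed and config always reproduce the same output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from serrsig.enrichment import GeneSetCollection
from serrsig.factorial import DEFAULT_GROUPS
from serrsig.matrix import ConfigError, ExpressionMatrix


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


# ---------------------------------------------------------------------------
# factorial mouse design

@dataclass
class SimFactorialConfig:
    """Five-genotype factorial expression simulation.

    ``interaction_effect`` is the signed log2 contrast planted on interaction
    genes: (mu_Cdx2KO_BrafVE - mu_BrafVE) - (mu_Cdx2KO - mu_control).
    ``frac_marginal`` genes receive a Cdx2 main effect only (it cancels in the
    interaction contrast).
    """

    n_genes: int = 1000
    n_per_group: int = 3
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    baseline_mean: float = 7.0
    noise_sd: float = 0.5
    frac_interaction: float = 0.05
    interaction_effect: float = 2.0
    frac_marginal: float = 0.10
    marginal_effect: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_genes > 0, "n_genes", "must be positive")
        _check(self.n_per_group > 0, "n_per_group", "must be positive")
        _check(len(self.group_labels) == 5, "group_labels", "exactly five labels required")
        _check(len(set(self.group_labels)) == 5, "group_labels", "labels must be distinct")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _check(0 <= self.frac_interaction <= 1, "frac_interaction", "must be in [0, 1]")
        _check(0 <= self.frac_marginal <= 1, "frac_marginal", "must be in [0, 1]")
        _check(
            self.frac_interaction + self.frac_marginal <= 1,
            "frac_interaction",
            "frac_interaction + frac_marginal must be <= 1",
        )
        _check(np.isfinite(self.interaction_effect), "interaction_effect", "must be finite")


def simulate_factorial_expression(cfg: SimFactorialConfig):
    """Generate the five-group mouse matrix and its truth table.

    Returns ``(ExpressionMatrix, TruthTable)``; the truth table is a
    DataFrame indexed by gene id with columns ``planted_class``
    (interaction-up / interaction-down / marginal-only / null) and
    ``planted_contrast`` (log2 units, 0 except for interaction genes).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ctrl, cdx2, braf, double, apc = cfg.group_labels
    genes = [f"mgene{i:05d}" for i in range(cfg.n_genes)]
    n_int = int(cfg.frac_interaction * cfg.n_genes)
    n_marg = int(cfg.frac_marginal * cfg.n_genes)

    means = pd.DataFrame(
        cfg.baseline_mean, index=genes, columns=list(cfg.group_labels), dtype=float
    )
    classes = pd.Series("null", index=genes, name="planted_class")
    contrast = pd.Series(0.0, index=genes, name="planted_contrast")

    int_genes = genes[:n_int]
    means.loc[int_genes, double] += cfg.interaction_effect
    contrast[int_genes] = cfg.interaction_effect
    classes[int_genes] = (
        "interaction-up" if cfg.interaction_effect > 0 else "interaction-down"
    )
    if cfg.interaction_effect == 0:
        classes[int_genes] = "null"

    marg_genes = genes[n_int : n_int + n_marg]
    # Cdx2 main effect: equal shift in both Cdx2-null groups, cancels in the contrast.
    means.loc[marg_genes, [cdx2, double]] += cfg.marginal_effect
    classes[marg_genes] = "marginal-only"

    sample_ids, groups_of = [], []
    for g in cfg.group_labels:
        for i in range(cfg.n_per_group):
            sample_ids.append(f"{g}_{i + 1}")
            groups_of.append(g)
    mu = means[groups_of].to_numpy()
    noise = rng.normal(0.0, cfg.noise_sd, size=mu.shape) if cfg.noise_sd > 0 else 0.0
    values = pd.DataFrame(mu + noise, index=genes, columns=sample_ids)
    X = ExpressionMatrix(values, pd.Series(groups_of, index=sample_ids))
    truth = pd.concat([classes, contrast], axis=1)
    return X, truth


# ---------------------------------------------------------------------------
# human cohort

@dataclass
class SimCohortConfig:
    """Two-group human cohort: 18 CDX2-low/BRAF-mutant cases vs 104 controls."""

    n_genes: int = 1000
    n_case: int = 18
    n_control: int = 104
    frac_signature: float = 0.05
    effect_log2: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_genes > 0, "n_genes", "must be positive")
        _check(self.n_case >= 2, "n_case", "must be >= 2")
        _check(self.n_control >= 2, "n_control", "must be >= 2")
        _check(0 <= self.frac_signature <= 1, "frac_signature", "must be in [0, 1]")
        _check(np.isfinite(self.effect_log2), "effect_log2", "must be finite")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")


def simulate_cohort(cfg: SimCohortConfig):
    """Two-group matrix with signature genes shifted by +/- effect_log2 in cases.

    Returns ``(ExpressionMatrix, labels, TruthTable)`` where ``labels`` maps
    sample id to "case"/"control" and the truth table records the planted
    class (signature-up / signature-down / null) and signed planted shift.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = [f"hgene{i:05d}" for i in range(cfg.n_genes)]
    n_sig = int(cfg.frac_signature * cfg.n_genes)
    signs = np.where(rng.random(n_sig) < 0.5, 1.0, -1.0)

    shift = pd.Series(0.0, index=genes, name="planted_shift")
    shift.iloc[:n_sig] = signs * cfg.effect_log2
    classes = pd.Series("null", index=genes, name="planted_class")
    classes.iloc[:n_sig] = np.where(shift.iloc[:n_sig] > 0, "signature-up", "signature-down")
    if cfg.effect_log2 == 0:
        classes.iloc[:n_sig] = "null"

    case_ids = [f"case_{i + 1}" for i in range(cfg.n_case)]
    control_ids = [f"ctrl_{i + 1}" for i in range(cfg.n_control)]
    sample_ids = case_ids + control_ids
    baseline = 7.0
    mu = np.full((cfg.n_genes, len(sample_ids)), baseline)
    mu[:, : cfg.n_case] += shift.to_numpy()[:, None]
    noise = rng.normal(0.0, cfg.noise_sd, size=mu.shape) if cfg.noise_sd > 0 else 0.0
    values = pd.DataFrame(mu + noise, index=genes, columns=sample_ids)
    labels = pd.Series(
        ["case"] * cfg.n_case + ["control"] * cfg.n_control, index=sample_ids, name="group"
    )
    X = ExpressionMatrix(values, labels)
    truth = pd.concat([classes, shift], axis=1)
    return X, labels, truth


# ---------------------------------------------------------------------------
# homolog map

def simulate_homolog_map(n_groups: int, frac_one_to_one: float, seed: int = 0) -> pd.DataFrame:
    """Homologene-dialect records with exactly floor(frac * n_groups) 1-to-1 groups.

    Non-1-to-1 groups get two or three genes on a randomly chosen side.
    Mouse gene ids follow the factorial generator's naming, human ids the
    cohort generator's, so simulated calls can be joined directly.
    """
    _check(n_groups > 0, "n_groups", "must be positive")
    _check(0 <= frac_one_to_one <= 1, "frac_one_to_one", "must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_one = int(frac_one_to_one * n_groups)
    records = []
    mouse_i = human_i = 0

    def mouse_gene():
        nonlocal mouse_i
        g = f"mgene{mouse_i:05d}"
        mouse_i += 1
        return g

    def human_gene():
        nonlocal human_i
        g = f"hgene{human_i:05d}"
        human_i += 1
        return g

    for gid in range(n_groups):
        group = f"HG{gid:05d}"
        if gid < n_one:
            n_mouse, n_human = 1, 1
        else:
            if rng.random() < 0.5:
                n_mouse, n_human = int(rng.integers(2, 4)), 1
            else:
                n_mouse, n_human = 1, int(rng.integers(2, 4))
        for _ in range(n_mouse):
            g = mouse_gene()
            records.append((group, "10090", g, g.upper()))
        for _ in range(n_human):
            g = human_gene()
            records.append((group, "9606", g, g.upper()))
    return pd.DataFrame(records, columns=["group_id", "taxon_id", "gene_id", "gene_symbol"])


# ---------------------------------------------------------------------------
# gene sets

def simulate_gene_sets(
    universe: list[str],
    n_sets: int = 50,
    size_min: int = 36,
    size_max: int = 194,
    seed: int = 0,
) -> GeneSetCollection:
    """Uniform random gene sets over a universe, sizes uniform in [size_min, size_max]."""
    _check(n_sets > 0, "n_sets", "must be positive")
    _check(0 < size_min <= size_max, "size_min", "need 0 < size_min <= size_max")
    _check(size_max <= len(universe), "size_max", "must not exceed the universe size")
    rng = np.random.default_rng(seed)
    uni = np.asarray(universe)
    sets = {}
    descriptions = {}
    for i in range(n_sets):
        size = int(rng.integers(size_min, size_max + 1))
        members = sorted(rng.choice(uni, size=size, replace=False).tolist())
        name = f"SIMSET_{i:03d}"
        sets[name] = members
        descriptions[name] = "synthetic gene set"
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# IHC marker cohort

@dataclass
class SimIHCConfig:
    """Binary marker-call cohort with a latent class driving associations.

    ``markers`` maps marker name to (baseline positive probability, odds
    multiplier applied when the case belongs to the latent class, e.g.
    CDX2-lost). ``latent_prevalence`` is the latent-class probability.
    """

    n_cases: int = 36
    markers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "CDX2_lost": (0.2, 8.0),
            "BRAF_mut": (0.2, 8.0),
            "MUC5AC": (0.3, 5.0),
            "ANXA10": (0.2, 6.0),
            "CIMP_high": (0.15, 5.0),
        }
    )
    latent_prevalence: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_cases > 0, "n_cases", "must be positive")
        _check(0 <= self.latent_prevalence <= 1, "latent_prevalence", "must be in [0, 1]")
        for name, (p, mult) in self.markers.items():
            _check(0 <= p <= 1, f"markers[{name}]", "baseline probability must be in [0, 1]")
            _check(mult > 0, f"markers[{name}]", "odds multiplier must be > 0")


def simulate_ihc_cohort(cfg: SimIHCConfig) -> pd.DataFrame:
    """Case-by-marker boolean call table; latent class in column ``latent_class``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    latent = rng.random(cfg.n_cases) < cfg.latent_prevalence
    data = {"latent_class": latent}
    for name, (p, mult) in cfg.markers.items():
        if p in (0.0, 1.0):
            prob = np.full(cfg.n_cases, p)
        else:
            odds = p / (1 - p) * np.where(latent, mult, 1.0)
            prob = odds / (1 + odds)
        data[name] = rng.random(cfg.n_cases) < prob
    index = [f"case{i + 1:02d}" for i in range(cfg.n_cases)]
    return pd.DataFrame(data, index=pd.Index(index, name="case_id"))


# ---------------------------------------------------------------------------
# survival

@dataclass
class SimSurvivalConfig:
    """Exponential event times per group with administrative censoring.

    ``hazards`` maps group label to a rate per day (0 means no events);
    ``n_per_group`` maps group label to cohort size; follow-up ends at
    ``censor_days``.
    """

    hazards: dict[str, float] = field(
        default_factory=lambda: {
            "Cdx2KO_BrafVE": np.log(2) / 103.0,
            "Apc_Cdx2KO_BrafVE": np.log(2) / 158.0,
            "Cdx2KO": 0.0,
            "BrafVE": 0.0,
        }
    )
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {
            "Cdx2KO_BrafVE": 7,
            "Apc_Cdx2KO_BrafVE": 5,
            "Cdx2KO": 6,
            "BrafVE": 5,
        }
    )
    censor_days: float = 480.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.censor_days > 0, "censor_days", "must be > 0")
        for g, h in self.hazards.items():
            _check(h >= 0, f"hazards[{g}]", "must be >= 0")
        for g, n in self.n_per_group.items():
            _check(n > 0, f"n_per_group[{g}]", "must be positive")
            _check(g in self.hazards, f"n_per_group[{g}]", "group lacks a hazard rate")


def simulate_survival(cfg: SimSurvivalConfig) -> pd.DataFrame:
    """(sample_id, time_days, event, group) records; times past follow-up censored."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for group in cfg.n_per_group:
        n = cfg.n_per_group[group]
        lam = cfg.hazards[group]
        times = rng.exponential(1.0 / lam, size=n) if lam > 0 else np.full(n, np.inf)
        for i, t in enumerate(times):
            event = t <= cfg.censor_days
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1}",
                    "time_days": float(min(t, cfg.censor_days)),
                    "event": int(event),
                    "group": group,
                }
            )
    return pd.DataFrame(rows)
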