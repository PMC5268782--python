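"""Generate every synthetic input the downstream stages consume.

Writes the five-genotype mouse expression matrix (3 mice/group), the
18-vs-104 human cohort, a Homologene-style homolog map, a 50-set gene-set
collection, the 36-case marker cohort, and group-wise survival records,
all under scratch/sim/ (regenerable inputs; summary tables land in results/).
"""

from pathlib import Path

from serrsig import enrichment, io
from serrsig.simulate import (
    SimCohortConfig,
    SimFactorialConfig,
    SimIHCConfig,
    SimSurvivalConfig,
    simulate_cohort,
    simulate_factorial_expression,
    simulate_gene_sets,
    simulate_homolog_map,
    simulate_ihc_cohort,
    simulate_survival,
)

SEED = 20331
OUT = Path(__file__).resolve().parent.parent / "scratch" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    n_genes = 4000
    X, truth = simulate_factorial_expression(
        SimFactorialConfig(n_genes=n_genes, frac_interaction=0.05, frac_marginal=0.10,
                           interaction_effect=3.5, noise_sd=0.5, seed=SEED)
    )
    io.write_expression(X, OUT / "mouse_expr.tsv", OUT / "mouse_groups.tsv")
    truth.to_csv(OUT / "mouse_truth.tsv", sep="\t")
    print(f"mouse matrix: {X.n_genes} genes x {X.n_samples} samples "
          f"({(truth.planted_class.str.startswith('interaction')).sum()} interaction genes planted)")

    Xh, labels, truth_h = simulate_cohort(
        SimCohortConfig(n_genes=n_genes, frac_signature=0.05, effect_log2=2.0,
                        noise_sd=0.5, seed=SEED + 1)
    )
    io.write_expression(Xh, OUT / "human_expr.tsv", OUT / "human_groups.tsv")
    truth_h.to_csv(OUT / "human_truth.tsv", sep="\t")
    print(f"human cohort: {(labels == 'case').sum()} cases vs {(labels == 'control').sum()} controls")

    homologs = simulate_homolog_map(n_groups=n_genes, frac_one_to_one=0.7, seed=SEED + 2)
    io.write_homolog_map(homologs, OUT / "homologene.tsv")
    print(f"homolog map: {homologs.group_id.nunique()} groups")

    universe = [f"hgene{i:05d}" for i in range(n_genes)]
    sets = simulate_gene_sets(universe, n_sets=50, size_min=36, size_max=194, seed=SEED + 3)
    enrichment.write_gmt(sets, OUT / "hallmark_like.gmt")
    print(f"gene sets: {len(sets)} sets over a {len(universe)}-gene universe")

    ihc = simulate_ihc_cohort(SimIHCConfig(seed=SEED + 4))
    io.write_marker_table(ihc, OUT / "markers.tsv")
    print(f"marker cohort: {len(ihc)} cases, {ihc.shape[1] - 1} markers")

    surv = simulate_survival(SimSurvivalConfig(seed=SEED + 5))
    io.write_survival(surv, OUT / "survival.tsv")
    print(f"survival records: {len(surv)} mice in {surv.group.nunique()} genotype groups")


if __name__ == "__main__":
    main()
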