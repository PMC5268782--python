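"""Per-gene interaction statistics on the simulated mouse design.

Fits the five-group one-way ANOVA, computes the Cdx2-by-Braf
difference-of-differences ("ratio of ratios") per gene, selects genes at
both threshold regimes (heatmap: p<0.01 & rho>=10; enrichment: p<0.01 &
rho>=1.3), and writes sample-level principal components.
"""

from pathlib import Path

import pandas as pd

from serrsig import io
from serrsig.factorial import (
    SelectionThresholds,
    fit_oneway_anova,
    interaction_test,
    principal_components,
    select_interaction_genes,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    X = io.read_expression(SCRATCH / "sim" / "mouse_expr.tsv", SCRATCH / "sim" / "mouse_groups.tsv")
    truth = pd.read_csv(SCRATCH / "sim" / "mouse_truth.tsv", sep="\t", index_col=0, keep_default_na=False)

    fit = fit_oneway_anova(X)
    st = interaction_test(fit)
    for regime, rho_min in (("heatmap", 10.0), ("enrichment", 1.3)):
        calls = select_interaction_genes(st, SelectionThresholds(p_max=0.01, rho_min=rho_min))
        st[f"call_{regime}"] = calls
        n_up, n_down = (calls == "up").sum(), (calls == "down").sum()
        planted = truth["planted_class"].str.startswith("interaction")
        recovered = (calls[planted] != "neither").mean() if planted.any() else float("nan")
        print(f"{regime} regime (rho>={rho_min}): {n_up} up, {n_down} down; "
              f"planted-gene recovery {recovered:.1%}")

    table = pd.concat([fit.group_means, st], axis=1)
    table.to_csv(RESULTS / "mouse_interaction_stats.tsv", sep="\t",
                 index_label="gene_id", float_format="%.6g")

    scores, ev = principal_components(X, n_components=2)
    scores.join(X.sample_groups.rename("group")).to_csv(
        RESULTS / "mouse_pca.tsv", sep="\t", index_label="sample_id", float_format="%.6g"
    )
    frac = ev / ((X.values.to_numpy() - X.values.to_numpy().mean(1, keepdims=True)) ** 2).sum() * (X.n_samples - 1)
    print(f"PCA: PC1 {frac.iloc[0]:.1%}, PC2 {frac.iloc[1]:.1%} of gene-centered variance; "
          "double mutants separate from single mutants on PC1 when interaction genes dominate")


if __name__ == "__main__":
    main()
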