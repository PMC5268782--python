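"""Published study inputs used by the reproduction drivers.

These are the count inputs the original analyses print and that the
recomputation stages consume: hallmark gene-set sizes and overlaps with the
mouse-derived up/down signatures (after 1-to-1 homolog mapping into a
15,735-gene human universe), and the 36-case marker contingency tables.
Statistics are always recomputed from these counts, never transcribed.
"""

from __future__ import annotations

#: Human universe size after 1-to-1 homolog mapping.
UNIVERSE_N = 15735
#: Size of the up- and down-regulated human signature lists.
UP_K = 1277
DOWN_K = 634

#: (direction, hallmark set, in-universe set size n, overlap x)
HALLMARK_OVERLAPS: list[tuple[str, str, int, int]] = [
    ("up", "HALLMARK_EPITHELIAL_MESENCHYMAL_TRANSITION", 186, 69),
    ("up", "HALLMARK_KRAS_SIGNALING_UP", 192, 41),
    ("up", "HALLMARK_HYPOXIA", 189, 36),
    ("up", "HALLMARK_COAGULATION", 126, 27),
    ("up", "HALLMARK_TNFA_SIGNALING_VIA_NFKB", 189, 35),
    ("up", "HALLMARK_UV_RESPONSE_DN", 141, 28),
    ("up", "HALLMARK_ANGIOGENESIS", 36, 12),
    ("up", "HALLMARK_INFLAMMATORY_RESPONSE", 189, 32),
    ("up", "HALLMARK_IL2_STAT5_SIGNALING", 193, 30),
    ("up", "HALLMARK_APICAL_JUNCTION", 191, 29),
    ("down", "HALLMARK_CHOLESTEROL_HOMEOSTASIS", 72, 17),
    ("down", "HALLMARK_ADIPOGENESIS", 191, 22),
    ("down", "HALLMARK_XENOBIOTIC_METABOLISM", 194, 22),
    ("down", "HALLMARK_ESTROGEN_RESPONSE_LATE", 189, 21),
    ("down", "HALLMARK_MTORC1_SIGNALING", 193, 21),
    ("down", "HALLMARK_BILE_ACID_METABOLISM", 109, 14),
    ("down", "HALLMARK_FATTY_ACID_METABOLISM", 149, 16),
    ("down", "HALLMARK_PEROXISOME", 101, 12),
    ("down", "HALLMARK_GLYCOLYSIS", 193, 18),
    ("down", "HALLMARK_ESTROGEN_RESPONSE_EARLY", 190, 17),
]

#: 2x2 marker-association tables from the 36-case serrated CRC cohort,
#: rows = first marker (positive, negative), columns = second marker.
MARKER_TABLES: dict[str, list[list[int]]] = {
    "MUC5AC_x_CDX2": [[2, 15], [13, 6]],
    "ANXA10_x_CDX2": [[6, 18], [9, 3]],
    "BCATENIN_MEMBRANOUS_x_BRAF": [[14, 3], [6, 13]],
    "CIMP_x_BRAF": [[11, 1], [9, 15]],
    "CIMP_x_CDX2": [[2, 10], [13, 11]],
    "P16_x_CDX2": [[11, 7], [4, 14]],
}

#: Margins of the CDX2-loss / BRAF-mutation concurrence test:
#: (total cases, CDX2-lost, BRAF-mutant, concurrent).
CONCURRENCE_MARGINS = (36, 21, 20, 15)


def concurrence_table() -> list[list[int]]:
    """Reconstruct the CDX2-loss x BRAF-mutation 2x2 table from its margins."""
    n, n_cdx2, n_braf, n_both = CONCURRENCE_MARGINS
    return [
        [n_both, n_cdx2 - n_both],
        [n_braf - n_both, n - n_cdx2 - n_braf + n_both],
    ]


def hallmark_selection_sizes(direction: str) -> int:
    return UP_K if direction == "up" else DOWN_K
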