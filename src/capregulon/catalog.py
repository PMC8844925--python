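"""Reference catalog of the M. xanthus DK 1622 c-di-GMP-associated gene set.

The focal gene set comprises every gene encoding a protein with a GGDEF, EAL,
HD-GYP, PilZ, or MshEN domain, plus the three named receptor/effector
proteins CdbA, CdbB, and Nla24. The per-family counts below describe that
catalog; the developmental cluster sizes are the study-scale reference split
of the catalog into the four expression clusters.
"""

from __future__ import annotations

FOCAL_GENE_FAMILIES: dict[str, int] = {
    "GGDEF": 18,
    "EAL": 2,
    "HD-GYP": 6,
    "PilZ": 24,
    "MshEN": 17,
    "named_receptors": 3,  # CdbA, CdbB, Nla24
}

EXPRESSION_CLUSTER_SIZES: dict[str, int] = {
    "strong_up": 10,
    "up": 18,
    "down": 10,
    "unchanged": 32,
}


def focal_gene_total() -> int:
    """Total number of c-di-GMP-associated genes in the catalog."""
    return sum(FOCAL_GENE_FAMILIES.values())


def upregulated_total() -> int:
    """Genes induced during development (both up clusters)."""
    return EXPRESSION_CLUSTER_SIZES["strong_up"] + EXPRESSION_CLUSTER_SIZES["up"]


def unchanged_total() -> int:
    """Genes not significantly regulated, by subtraction from the catalog."""
    return focal_gene_total() - (
        EXPRESSION_CLUSTER_SIZES["strong_up"]
        + EXPRESSION_CLUSTER_SIZES["up"]
        + EXPRESSION_CLUSTER_SIZES["down"]
    )
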