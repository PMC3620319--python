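"""Evidence layer: known-cancer-gene enrichment, PPI neighborhood, POG.

Three external lines of support for a driver-gene list: overlap with a
curated compendium of known cancer genes (hypergeometric), enrichment of
the novel drivers among the direct interaction neighbors of known cancer
genes on a protein-interaction network, and the percentage of
overlapping genes (POG) between driver lists derived from independent
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from ._stats import hypergeom_sf
from .data_model import ValidationError, neighbors_of_set


@dataclass
class EnrichmentResult:
    n_test: int
    n_target: int
    n_background: int
    overlap: int
    percentage: float
    p: float


def cancer_gene_enrichment(
    drivers: frozenset[str], cancer_genes: frozenset[str], background: frozenset[str]
) -> EnrichmentResult:
    """Overlap of a driver list with known cancer genes, with hypergeometric p.

    The percentage is 100 * overlap / |drivers|; the p-value is the upper
    tail of drawing |drivers| genes from the background containing the
    (background-restricted) cancer genes.
    """
    drivers = frozenset(drivers)
    if not drivers:
        raise ValidationError("driver list is empty")
    if not drivers <= frozenset(background):
        raise ValidationError("drivers must be a subset of the background")
    targets = frozenset(cancer_genes) & frozenset(background)
    k = len(drivers & targets)
    return EnrichmentResult(
        n_test=len(drivers),
        n_target=len(targets),
        n_background=len(background),
        overlap=k,
        percentage=100.0 * k / len(drivers),
        p=hypergeom_sf(k, len(background), len(targets), len(drivers)),
    )


def ppi_neighbor_enrichment(
    drivers: frozenset[str], cancer_genes: frozenset[str], network: nx.Graph
) -> EnrichmentResult | None:
    """Are novel drivers enriched among direct neighbors of cancer genes?

    Test set: drivers not already known cancer genes, restricted to
    network nodes. Target: direct neighbors of the cancer genes. The
    background is the network node set minus the cancer genes. Returns
    ``None`` when the test set is empty after restriction.
    """
    nodes = frozenset(network.nodes)
    cancer = frozenset(cancer_genes)
    test = (frozenset(drivers) - cancer) & nodes
    if not test:
        return None
    target = neighbors_of_set(network, cancer)
    background = nodes - cancer
    k = len(test & target)
    return EnrichmentResult(
        n_test=len(test),
        n_target=len(target),
        n_background=len(background),
        overlap=k,
        percentage=100.0 * k / len(test),
        p=hypergeom_sf(k, len(background), len(target), len(test)),
    )


@dataclass
class POGResult:
    overlap: int
    pct_a_in_b: float  # 100 * k / |A|
    pct_b_in_a: float  # 100 * k / |B|
    pog: float  # symmetrized mean of the two directional percentages


def pog(list_a: frozenset[str], list_b: frozenset[str]) -> POGResult:
    """Percentage of overlapping genes between two driver lists.

    Symmetrized as the mean of the two directional overlap percentages
    100*k/|A| and 100*k/|B|; both directions are reported as well.
    """
    A, B = frozenset(list_a), frozenset(list_b)
    if not A or not B:
        raise ValidationError("POG lists must be nonempty")
    k = len(A & B)
    pa = 100.0 * k / len(A)
    pb = 100.0 * k / len(B)
    return POGResult(overlap=k, pct_a_in_b=pa, pct_b_in_a=pb, pog=(pa + pb) / 2.0)


def pog_significance(
    list_a: frozenset[str], list_b: frozenset[str], background: frozenset[str]
) -> float:
    """Upper-tail hypergeometric p for the overlap of two gene lists."""
    A, B = frozenset(list_a), frozenset(list_b)
    bg = frozenset(background)
    if not A or not B:
        raise ValidationError("POG lists must be nonempty")
    if not (A <= bg and B <= bg):
        raise ValidationError("both lists must be subsets of the background")
    k = len(A & B)
    return hypergeom_sf(k, len(bg), len(A), len(B))
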