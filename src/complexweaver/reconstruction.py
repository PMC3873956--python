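"""Reconstruct the interaction network: reliable positives plus the
top-n predicted pairs from the ranking."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .core import canonical_pair
from .lpu import select_top

__all__ = ["ReconstructionRecipe", "reconstruct_network"]


@dataclass
class ReconstructionRecipe:
    """Reliable positive pairs + a ranking + how many predictions to add."""

    reliable: set[tuple[str, str]]
    ranked: Sequence[tuple[tuple[str, str], float]]
    top_n: int = 0
    copy_scores_as_weights: bool = False

    def __post_init__(self) -> None:
        if self.top_n < 0:
            raise ValueError("top_n must be >= 0")


def reconstruct_network(recipe: ReconstructionRecipe) -> nx.Graph:
    """Union of the reliable edges and the top-n predicted edges.

    Every edge carries a ``provenance`` attribute ('reliable' or
    'predicted').  Predicted edges overlapping the reliable set signal
    a pool-construction bug upstream (positives must have been excluded
    from the unlabeled pool) and raise.
    """
    g = nx.Graph()
    reliable = {canonical_pair(a, b) for a, b in recipe.reliable}
    for a, b in reliable:
        g.add_edge(a, b, provenance="reliable")
    predicted = select_top(recipe.ranked, recipe.top_n)
    overlap = predicted & reliable
    if overlap:
        raise ValueError(
            f"{len(overlap)} predicted pair(s) already in the reliable set; "
            "the unlabeled pool was not disjoint from the positives"
        )
    scores = dict(recipe.ranked)
    for a, b in predicted:
        attrs = {"provenance": "predicted"}
        if recipe.copy_scores_as_weights:
            attrs["weight"] = scores[(a, b)]
        g.add_edge(a, b, **attrs)
    return g
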