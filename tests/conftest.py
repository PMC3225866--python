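from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from corsignet.io import ExpressionMatrix, GeneSet, InteractionSet


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    """Five genes x five samples with known pairwise correlations.

    g1/g2 perfectly correlated, g1/g3 perfectly anti-correlated, g4 noisy,
    g5 constant (zero variance).
    """
    data = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 5.0, 2.0, 3.0],
            "s2": [2.0, 4.0, 4.0, 1.0, 3.0],
            "s3": [3.0, 6.0, 3.0, 5.0, 3.0],
            "s4": [4.0, 8.0, 2.0, 2.5, 3.0],
            "s5": [5.0, 10.0, 1.0, 4.0, 3.0],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def toy_interactions() -> InteractionSet:
    return InteractionSet(
        frozenset(
            {("g1", "g2"), ("g1", "g3"), ("g2", "g4"), ("g3", "g4"), ("g4", "g5")}
        )
    )


@pytest.fixture
def triangle_net() -> nx.Graph:
    """A weighted triangle A-B-C with a cheap detour A-B-C vs direct A-C."""
    g = nx.Graph()
    g.add_edge("A", "B", distance=0.1, rho=0.9)
    g.add_edge("B", "C", distance=0.1, rho=0.9)
    g.add_edge("A", "C", distance=0.3, rho=0.7)
    return g


def make_expression(genes: list[str], matrix: list[list[float]]) -> ExpressionMatrix:
    cols = [f"s{i}" for i in range(len(matrix[0]))]
    return ExpressionMatrix(pd.DataFrame(matrix, index=genes, columns=cols))


def gene_set(role, *symbols) -> GeneSet:
    return GeneSet(role=role, symbols=frozenset(symbols))
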