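"""Pearson link correlations, link distances and correlation categories.

Each protein-protein link (x, y) carries the signed Pearson correlation
rho_xy of the expression of its two genes across the cohort's samples, and
the link distance d_xy = 1 - |rho_xy|.  High co-regulation (in either
direction — induction and inhibition are treated alike via the absolute
value) therefore means a short link.  Absolute correlations are further
discretized into three categories used by the motif counters:

* ``none`` : |rho| in [0, 0.3)
* ``low``  : |rho| in [0.3, 0.5]
* ``high`` : |rho| in (0.5, 1]

Both boundaries are closed into ``low`` so ties are deterministic.
A zero-variance gene makes rho undefined (NaN sentinel); such links are
kept with distance 1.0 and category ``none`` — maximally unattractive to
the shortest-path search rather than silently deleted.
"""

from __future__ import annotations

import logging
import math
from typing import Literal

import networkx as nx
import numpy as np

from .io import ExpressionMatrix, InteractionSet

logger = logging.getLogger(__name__)

Category = Literal["none", "low", "high"]

#: Category bounds on |rho|: below the first -> none, above the second -> high.
DEFAULT_BOUNDS: tuple[float, float] = (0.3, 0.5)

_RHO_TOL = 1e-9


def pearson_correlation(x, y) -> float:
    """Signed Pearson correlation of two equal-length sample vectors.

    Returns NaN (the "undefined" sentinel) when either vector has zero
    variance.  Requires n >= 3 finite values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 samples, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in sample vectors")
    cx = x - x.mean()
    cy = y - y.mean()
    nx_ = math.sqrt(float(cx @ cx))
    ny_ = math.sqrt(float(cy @ cy))
    if nx_ == 0.0 or ny_ == 0.0:
        return math.nan
    rho = float(cx @ cy) / (nx_ * ny_)
    # guard against floating-point overshoot
    return max(-1.0, min(1.0, rho))


def link_distance(rho: float) -> float:
    """Link distance d = 1 - |rho|; an even function of rho.

    The NaN sentinel (undefined correlation) maps to the maximal distance 1.
    |rho| beyond 1 by more than 1e-9 is an error; within tolerance it clamps.
    """
    if math.isnan(rho):
        return 1.0
    a = abs(rho)
    if a > 1.0 + _RHO_TOL:
        raise ValueError(f"|rho| = {a} exceeds 1")
    return 1.0 - min(a, 1.0)


def correlation_category(
    rho: float, bounds: tuple[float, float] = DEFAULT_BOUNDS
) -> Category:
    """Discretize |rho| into none / low / high."""
    if math.isnan(rho):
        return "none"
    a = abs(rho)
    if a > 1.0 + _RHO_TOL:
        raise ValueError(f"|rho| = {a} exceeds 1")
    low, high = bounds
    if a < low:
        return "none"
    if a <= high:
        return "low"
    return "high"


def build_weighted_network(
    interactions: InteractionSet, expr: ExpressionMatrix
) -> nx.Graph:
    """Weight every interaction with the cohort's Pearson correlation.

    Links whose two genes are not both measured in the cohort are dropped
    (count reported via logging).  Each surviving link carries edge
    attributes ``rho`` (signed, NaN when undefined) and ``distance``.
    """
    genes = set(expr.gene_ids)
    kept = [(a, b) for a, b in interactions.links if a in genes and b in genes]
    dropped = len(interactions) - len(kept)
    if dropped:
        logger.info("dropped %d link(s) lacking expression for >= 1 gene", dropped)
    if not kept:
        raise ValueError("no interaction has expression for both genes")

    # vectorized per-edge correlation on the centered matrix
    used_genes = sorted({g for link in kept for g in link})
    mat = expr.data.loc[used_genes].to_numpy(dtype=float)
    mat = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(mat, axis=1)
    row = {g: i for i, g in enumerate(used_genes)}

    net = nx.Graph()
    for a, b in kept:
        ia, ib = row[a], row[b]
        if norms[ia] == 0.0 or norms[ib] == 0.0:
            rho = math.nan
        else:
            rho = float(mat[ia] @ mat[ib]) / float(norms[ia] * norms[ib])
            rho = max(-1.0, min(1.0, rho))
        net.add_edge(a, b, rho=rho, distance=link_distance(rho))
    return net
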