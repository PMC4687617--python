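"""Comparator methods: PIC, PIDC, and the corrected centroid geometry.

PIC (phylogenetically independent contrasts) follows Felsenstein's pruning
algorithm for a Brownian-motion trait on log-transformed data: each
internal node receives the inverse-adjusted-branch-length weighted mean of
its daughters (the local ML ancestral state), and the branch above it is
lengthened by the pruning correction b_L*b_R/(b_L+b_R).

PIDC (partially independent directional contrasts) reuses the PIC
ancestral states but emits one standardized directional contrast per
branch, (descendant - ancestor)/sqrt(branch length) — 2n-2 values, the
directional analogue IE's branch-specific changes are compared against.

``apollonius_centroid_distances`` is the corrected triangle geometry: the
distance from a vertex to the centroid is 2/3 of the median from that
vertex, which Apollonius' theorem gives in closed form from the three side
lengths.  It replaces the Wagner-tree formulas IE misuses for the same
quantity.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .trees import Phylogeny

__all__ = [
    "pic_ancestral_states",
    "pic_contrasts",
    "pidc_contrasts",
    "apollonius_centroid_distances",
    "branch_change_table",
]


def _tip_array(tree: Phylogeny, tips: Mapping[str, float]) -> np.ndarray:
    x = np.empty(tree.n_nodes)
    x.fill(np.nan)
    for t in tree.tips:
        lab = tree.labels[t]
        if lab not in tips:
            raise KeyError(f"missing trait value for tip {lab!r}")
        x[t] = tips[lab]
    return x


def _prune(tree: Phylogeny, tips: Mapping[str, float]):
    """One Felsenstein pruning pass on log-space tip values.

    Returns (node value array, adjusted branch length array, contrast
    variance per internal node).  Node values at internal entries are the
    local ML ancestral states.
    """
    value = _tip_array(tree, tips)
    adj = tree.lengths.copy()  # adjusted branch length above each node
    cvar = np.full(tree.n_nodes, np.nan)  # b1'+b2' per internal node
    # postorder ids are already a valid tipward->rootward order
    for v in range(tree.n_nodes):
        if tree.is_tip[v]:
            continue
        c1, c2 = tree.children[v]
        b1, b2 = adj[c1], adj[c2]
        value[v] = (value[c1] / b1 + value[c2] / b2) / (1.0 / b1 + 1.0 / b2)
        cvar[v] = b1 + b2
        if v != tree.root:
            adj[v] = tree.lengths[v] + b1 * b2 / (b1 + b2)
    return value, adj, cvar


def pic_ancestral_states(
    tree: Phylogeny, log_tips: Mapping[str, float]
) -> pd.Series:
    """Local ML ancestral states (pruning pass) for log-space tip values.

    Returns one value per internal node, indexed by node id.
    """
    value, _, _ = _prune(tree, log_tips)
    idx = tree.internal_nodes
    return pd.Series(value[idx], index=pd.Index(idx, name="node"), name="ancestral_state")


def pic_contrasts(
    tree: Phylogeny, log_tips: Mapping[str, float]
) -> pd.DataFrame:
    """Standardized independent contrasts, one per internal node (n-1 rows).

    Contrast = (daughter1 - daughter2)/sqrt(adjusted b1 + adjusted b2),
    daughters ordered by node id.  Under BM with rate sigma2 the contrasts
    are iid Normal(0, sigma2).
    """
    value, adj, cvar = _prune(tree, log_tips)
    rows = []
    for v in tree.internal_nodes:
        c1, c2 = tree.children[v]
        rows.append(
            {
                "branch": int(v),
                "parent": int(v),
                "child": int(c1),
                "child2": int(c2),
                "length": float(cvar[v]),
                "depth": float(tree.depths[v]),
                "contrast": float((value[c1] - value[c2]) / math.sqrt(cvar[v])),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["method"] = "PIC"
    return df


def pidc_contrasts(
    tree: Phylogeny, log_tips: Mapping[str, float]
) -> pd.DataFrame:
    """Standardized directional contrasts from PIC ancestral states.

    One row per branch (2n-2): (child value - parent value)/sqrt(branch
    length), mixing observed tips and internal estimates.
    """
    value, _, _ = _prune(tree, log_tips)
    return branch_change_table(tree, value, method="PIDC")


def branch_change_table(
    tree: Phylogeny, node_values: np.ndarray, method: str
) -> pd.DataFrame:
    """Per-branch standardized directional contrasts from full node values."""
    b = tree.branches
    parent = tree.parent[b]
    blen = tree.lengths[b]
    df = pd.DataFrame(
        {
            "branch": b,
            "parent": parent,
            "child": b,
            "length": blen,
            "depth": tree.depths[b],
            "contrast": (node_values[b] - node_values[parent]) / np.sqrt(blen),
        }
    )
    df.attrs["method"] = method
    return df


def apollonius_centroid_distances(
    a: float, b: float, c: float
) -> tuple[float, float, float]:
    """Vertex-to-centroid distances of a triangle with side lengths a, b, c.

    The centroid lies 2/3 of the way along each median, and Apollonius'
    theorem gives the median from vertex A (the vertex opposite side a) as
    m_a = sqrt(2b^2 + 2c^2 - a^2)/2, so T_A = sqrt(2b^2 + 2c^2 - a^2)/3.
    Returns (T_A, T_B, T_C) with each vertex labelled by its opposite side.
    Degenerate (collinear) triangles are allowed; a triangle-inequality
    violation makes a radicand negative and raises ValueError.
    """
    sides = (a, b, c)
    if any(s < 0 or not math.isfinite(s) for s in sides):
        raise ValueError(f"side lengths must be non-negative and finite: {sides}")
    out = []
    for opp, (u, v) in ((a, (b, c)), (b, (a, c)), (c, (a, b))):
        rad = 2.0 * u * u + 2.0 * v * v - opp * opp
        if rad < 0:
            raise ValueError(
                f"sides {sides} violate the triangle inequality "
                f"(negative radicand for the side-{opp} median)"
            )
        out.append(math.sqrt(rad) / 3.0)
    return tuple(out)
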