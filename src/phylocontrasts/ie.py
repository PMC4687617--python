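"""The Independent Evolution (IE) ancestral-state algorithm and variants.

IE reconstructs ancestral states by triangulation.  For every internal node
an "adaptive peak" (AP) is first computed as the inverse-path-distance
weighted mean of *all* tip values.  The tree is then traversed tipward to
rootward: each cherry's two values and the AP of their parent are treated
as triangle vertices; side lengths come from a proportional-distance
metric; Farris' Wagner-tree formulas give per-vertex "T-distances"; these
are scaled by relative branch length into R-values; and the ancestral state
is the inverse-R-weighted mean of the two descendant values.  The cherry is
then replaced by its parent carrying the reconstructed value.

Two side metrics are supported:

``"ie"``
    the original metric S = 2|x-y|/(x+y) applied to arithmetic values
    (asymptotes at 2, undefined when x+y=0);
``"log"``
    the corrected variant: values are log-transformed at entry and sides
    are absolute differences of logs (an unbiased proportional distance).
    With equal branch lengths and the peak between the two values this
    variant's ancestral state coincides exactly with the adaptive peak.

IE is an algorithm under audit here, not an endorsed method: the package
also emits its per-branch R-values and standardized directional contrasts
so their statistical behaviour can be compared against Brownian-motion
ground truth and against PIC/PIDC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .trees import Phylogeny

__all__ = [
    "TriangleSides",
    "IEResult",
    "UndefinedValueError",
    "ie_distance",
    "log_distance",
    "adaptive_peak",
    "adaptive_peaks",
    "farris_T",
    "r_values",
    "ancestral_state",
    "ie_reconstruct",
]


class UndefinedValueError(ArithmeticError):
    """An IE quantity is undefined for the given inputs (zero denominator)."""


@dataclass(frozen=True)
class TriangleSides:
    """Side lengths of one IE triangle (dimensionless proportional distances).

    ``s1`` joins the two descendant vertices; ``s2`` joins descendant 2 to
    the adaptive-peak vertex; ``s3`` joins descendant 1 to the peak vertex.
    """

    s1: float
    s2: float
    s3: float


def ie_distance(x: float, y: float) -> float:
    """Original IE proportional distance, S = 2|x-y|/(x+y).

    Bounded: for positive inputs S < 2, approaching 2 as the values diverge.
    Undefined when the two values average to zero.
    """
    denom = x + y
    if denom == 0:
        raise UndefinedValueError(
            f"IE distance undefined for ({x!r}, {y!r}): x+y = 0"
        )
    return 2.0 * abs(x - y) / denom


def log_distance(x: float, y: float) -> float:
    """Unbiased proportional distance |ln x - ln y| (= |ln(x/y)|)."""
    if x <= 0 or y <= 0:
        raise UndefinedValueError(
            f"log distance requires positive values, got ({x!r}, {y!r})"
        )
    return abs(math.log(x) - math.log(y))


def adaptive_peaks(
    tree: Phylogeny, tip_values: np.ndarray
) -> np.ndarray:
    """Adaptive peak for every node: inverse-tip-distance weighted mean.

    ``tip_values`` is ordered as ``tree.tips``.  Returns an array over all
    node ids (tips included; only internal entries are used by IE).
    AP(v) = sum_i(x_i/d_i) / sum_i(1/d_i) with d_i the path distance from
    tip i to v; a tip at zero distance (v itself a tip) contributes its own
    value exactly, by the limiting convention AP(tip) = x_tip.
    """
    d = tree.tip_path_distances()
    ap = np.empty(tree.n_nodes)
    for v in range(tree.n_nodes):
        dv = d[v]
        zero = dv == 0.0
        if zero.any():
            ap[v] = tip_values[zero][0]
            continue
        w = 1.0 / dv
        ap[v] = np.dot(w, tip_values) / w.sum()
    return ap


def adaptive_peak(
    tree: Phylogeny, tips: Mapping[str, float], node: int
) -> float:
    """Adaptive peak of one internal node from a tip-label→value map."""
    if tree.is_tip[node]:
        raise ValueError(f"node {node} is a tip; adaptive peaks are internal")
    num = den = 0.0
    for t in tree.tips:
        lab = tree.labels[t]
        if lab not in tips:
            raise KeyError(f"missing trait value for tip {lab!r}")
        dist = tree.path_distance(t, node)
        if dist == 0.0:
            raise UndefinedValueError(
                f"tip {lab!r} at zero distance from node {node}"
            )
        num += tips[lab] / dist
        den += 1.0 / dist
    return num / den


def farris_T(sides: TriangleSides) -> tuple[float, float, float]:
    """Farris' Wagner-tree 'vertex distances': (sum of incident - opposite)/2.

    ``T1`` belongs to descendant 1 (incident sides s1, s3), ``T2`` to
    descendant 2 (incident s1, s2), ``T3`` to the adaptive-peak vertex
    (incident s2, s3).  Negative values are arithmetically possible when the
    sides violate the triangle inequality and are returned as-is (callers
    flag them); both supported metrics are true metrics, so valid inputs
    give T >= 0.
    """
    t1 = (sides.s1 + sides.s3 - sides.s2) / 2.0
    t2 = (sides.s1 + sides.s2 - sides.s3) / 2.0
    t3 = (sides.s2 + sides.s3 - sides.s1) / 2.0
    return (t1, t2, t3)


def r_values(
    t1: float, t2: float, b1: float, b2: float
) -> tuple[float, float]:
    """Scale T-distances by relative branch length: R_i = T_i * 2*b_i/(b1+b2).

    Verbatim from the algorithm's step 8; with equal branch lengths the
    scale factor is 1 and R_i = T_i.
    """
    if b1 <= 0 or b2 <= 0:
        raise ValueError(f"branch lengths must be positive, got ({b1}, {b2})")
    s = b1 + b2
    return (t1 * 2.0 * b1 / s, t2 * 2.0 * b2 / s)


def ancestral_state(x1: float, x2: float, r1: float, r2: float) -> float:
    """Inverse-R-weighted mean of the two descendant values.

    A = (x1/R1 + x2/R2) / (1/R1 + 1/R2).  Equal R gives the plain mean.
    Undefined when either R is 0 (which happens whenever the two descendant
    values are equal, since then one triangle side collapses).
    """
    if r1 == 0 or r2 == 0:
        raise UndefinedValueError(
            f"ancestral state undefined: R-value is zero (R1={r1}, R2={r2})"
        )
    den = 1.0 / r1 + 1.0 / r2
    if den == 0:
        raise UndefinedValueError(
            f"ancestral state undefined: 1/R1 + 1/R2 = 0 (R1={r1}, R2={r2})"
        )
    return (x1 / r1 + x2 / r2) / den


@dataclass(frozen=True)
class IEResult:
    """Per-node and per-branch output of one IE reconstruction.

    ``nodes`` has one row per internal node: adaptive peak, ancestral
    state, and the triangle sides used.  ``branches`` has one row per
    branch (2n-2): T, R, signed R, and the log-space standardized
    directional contrast.  ``metric`` records which side metric produced
    the result; for ``"log"`` the node values are in log-trait units.
    """

    nodes: pd.DataFrame
    branches: pd.DataFrame
    metric: str
    n_undefined: int

    @property
    def ancestral_states(self) -> pd.Series:
        return self.nodes.set_index("node")["ancestral_state"]


def ie_reconstruct(
    tree: Phylogeny,
    tips: Mapping[str, float],
    metric: str = "ie",
    on_undefined: str = "raise",
) -> IEResult:
    """Run the full IE algorithm over a tree.

    Parameters
    ----------
    tree
        Validated binary rooted tree.
    tips
        Tip-label → strictly positive trait value (arithmetic scale).
    metric
        ``"ie"`` for the original algorithm on arithmetic values, ``"log"``
        for the corrected variant (values logged at entry, sides are
        absolute log differences; outputs in log space).
    on_undefined
        ``"raise"`` aborts with :class:`UndefinedValueError` naming the
        node; ``"nan"`` records NaN and continues (NaN then propagates to
        every enclosing ancestor), for bulk simulation runs.

    Notes
    -----
    Adaptive peaks are computed once from the original tip values and
    original path distances and are not updated as cherries collapse.
    Cherries are processed deepest-first (ties by node id); each collapsed
    cherry's parent keeps its own original branch length, so the order does
    not affect the values, only error reporting.  The per-branch signed R
    multiplies R by the sign of (descendant - reconstructed ancestor), and
    the standardized directional contrast is
    (ln descendant - ln ancestor)/sqrt(branch length).
    """
    if metric not in ("ie", "log"):
        raise ValueError(f"unknown metric {metric!r}")
    if on_undefined not in ("raise", "nan"):
        raise ValueError(f"unknown on_undefined policy {on_undefined!r}")

    tip_ids = tree.tips
    x_tip = np.empty(len(tip_ids))
    for j, t in enumerate(tip_ids):
        lab = tree.labels[t]
        if lab not in tips:
            raise KeyError(f"missing trait value for tip {lab!r}")
        x_tip[j] = tips[lab]
    if np.any(x_tip <= 0) or not np.all(np.isfinite(x_tip)):
        bad = tree.labels[tip_ids[np.flatnonzero(~((x_tip > 0) & np.isfinite(x_tip)))[0]]]
        raise ValueError(
            f"IE requires strictly positive finite trait values (tip {bad!r})"
        )

    work_tip = np.log(x_tip) if metric == "log" else x_tip
    dist = log_abs_diff if metric == "log" else ie_distance
    ap = adaptive_peaks(tree, work_tip)

    value = np.full(tree.n_nodes, np.nan)
    value[tip_ids] = work_tip

    n = tree.n_nodes
    T = np.full(n, np.nan)
    R = np.full(n, np.nan)
    s_used = np.full((n, 3), np.nan)  # per internal node: (s1, s2, s3)
    negative_T = np.zeros(n, dtype=bool)
    n_undef = 0

    # deepest-first: children always resolve before their parent
    internal = sorted(
        (int(v) for v in tree.internal_nodes),
        key=lambda v: (-tree.depths[v], v),
    )
    for v in internal:
        c1, c2 = tree.children[v]
        x1, x2 = value[c1], value[c2]
        b1, b2 = float(tree.lengths[c1]), float(tree.lengths[c2])
        try:
            if np.isnan(x1) or np.isnan(x2):
                raise UndefinedValueError("descendant value undefined")
            sides = TriangleSides(
                s1=dist(x1, x2), s2=dist(x2, ap[v]), s3=dist(x1, ap[v])
            )
            t1, t2, t3 = farris_T(sides)
            r1, r2 = r_values(t1, t2, b1, b2)
            a = ancestral_state(x1, x2, r1, r2)
        except UndefinedValueError as exc:
            if on_undefined == "raise":
                raise UndefinedValueError(f"node {v}: {exc}") from exc
            n_undef += 1
            sides = TriangleSides(np.nan, np.nan, np.nan)
            t1 = t2 = r1 = r2 = a = np.nan
        value[v] = a
        s_used[v] = (sides.s1, sides.s2, sides.s3)
        T[c1], T[c2] = t1, t2
        R[c1], R[c2] = r1, r2
        negative_T[c1] = t1 < 0
        negative_T[c2] = t2 < 0

    # log-space node values for contrasts (metric "log" already is log-space)
    with np.errstate(invalid="ignore"):
        logv = value.copy() if metric == "log" else np.log(value)

    branch_ids = tree.branches
    parent = tree.parent[branch_ids]
    blen = tree.lengths[branch_ids]
    with np.errstate(invalid="ignore"):
        signed_R = R[branch_ids] * np.sign(value[branch_ids] - value[parent])
        contrast = (logv[branch_ids] - logv[parent]) / np.sqrt(blen)

    internal_ids = np.array(internal)
    nodes = pd.DataFrame(
        {
            "node": internal_ids,
            "depth": tree.depths[internal_ids],
            "adaptive_peak": ap[internal_ids],
            "ancestral_state": value[internal_ids],
            "s1": s_used[internal_ids, 0],
            "s2": s_used[internal_ids, 1],
            "s3": s_used[internal_ids, 2],
        }
    ).sort_values("node", ignore_index=True)
    branches = pd.DataFrame(
        {
            "branch": branch_ids,
            "parent": parent,
            "child": branch_ids,
            "length": blen,
            "depth": tree.depths[branch_ids],
            "T": T[branch_ids],
            "R": R[branch_ids],
            "signed_R": signed_R,
            "contrast": contrast,
            "negative_T": negative_T[branch_ids],
        }
    )
    return IEResult(nodes=nodes, branches=branches, metric=metric, n_undefined=n_undef)


def log_abs_diff(u: float, v: float) -> float:
    """Side metric for already-logged values: plain absolute difference."""
    return abs(u - v)
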