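"""The two simulation experiments auditing IE against PIC/PIDC.

Single-trait experiment: many geometrically normal traits are simulated by
BM in log space (root 0, rate sigma2) on one fixed tree; IE runs on the
arithmetic values (its ancestral states are then log-transformed so all
comparisons are in log space) and PIDC runs on the logged values.  The
outputs are per-node and per-branch box-plot statistics of estimation
error, ordered by distance from the root, plus the per-branch pairing of
IE signed R-values with the true simulated changes.

Pair-trait experiment: pairs of traits are simulated under correlated BM
with the evolutionary regression coefficient beta swept evenly from 0 to
1.  For each pair the coefficient is re-estimated four ways — PIC
contrasts, PIDC directional contrasts, IE standardized contrasts, IE
signed R-values — by OLS through the origin, and each method's estimates
are meta-regressed (again through the origin) on the simulated betas.  An
unbiased method has meta-slope 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ie import ie_reconstruct
from .reference import pic_ancestral_states, pic_contrasts, pidc_contrasts
from .simulate import beta_grid, simulate_bm_trait, simulate_correlated_pair
from .trees import Phylogeny

__all__ = [
    "BiasSummary",
    "SingleTraitResult",
    "SlopeRecoveryResult",
    "origin_ols",
    "single_trait_experiment",
    "pair_trait_experiment",
    "rvalue_accuracy",
]


def origin_ols(x: np.ndarray, y: np.ndarray) -> float:
    """Ordinary least squares through the origin: slope = sum(xy)/sum(x^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 2:
        raise ValueError("need at least two points")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("all x are zero; slope undefined")
    return float(np.dot(x, y) / sxx)


@dataclass(frozen=True)
class BiasSummary:
    """Box-plot statistics of (estimate - truth), row-per-node-or-branch.

    ``table`` columns: id, depth, mean, sd, median, q1, q3, min, max, n,
    n_nan (plus ``mean_value``/``sd_value`` — statistics of the raw
    estimates — for branch tables, where the truth itself has mean 0).
    Rows are ordered by distance from the root.
    """

    table: pd.DataFrame
    method: str
    level: str  # "node" | "branch"
    n_replicates: int


def _summarize(
    ids: np.ndarray,
    depths: np.ndarray,
    errors: np.ndarray,  # (n_replicates, n_ids), may contain NaN
    values: np.ndarray | None,
    method: str,
    level: str,
) -> BiasSummary:
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # branches whose estimates were undefined in every replicate yield
        # all-NaN slices; the NaN row is the intended output
        warnings.simplefilter("ignore", RuntimeWarning)
        tab = pd.DataFrame(
            {
                "id": ids,
                "depth": depths,
                "mean": np.nanmean(errors, axis=0),
                "sd": np.nanstd(errors, axis=0, ddof=1),
                "median": np.nanmedian(errors, axis=0),
                "q1": np.nanpercentile(errors, 25, axis=0),
                "q3": np.nanpercentile(errors, 75, axis=0),
                "min": np.nanmin(errors, axis=0),
                "max": np.nanmax(errors, axis=0),
                "n": np.sum(~np.isnan(errors), axis=0),
                "n_nan": np.sum(np.isnan(errors), axis=0),
            }
        )
        if values is not None:
            tab["mean_value"] = np.nanmean(values, axis=0)
            tab["sd_value"] = np.nanstd(values, axis=0, ddof=1)
    tab = tab.sort_values(["depth", "id"], ignore_index=True)
    return BiasSummary(
        table=tab, method=method, level=level, n_replicates=errors.shape[0]
    )


@dataclass(frozen=True)
class SingleTraitResult:
    """All outputs of the single-trait bias experiment."""

    node_bias: dict[str, BiasSummary]      # method -> per-node summary
    branch_bias: dict[str, BiasSummary]    # method -> per-branch summary
    rvalue_pairs: pd.DataFrame             # replicate, branch, signed_R, true_change
    n_replicates: int
    n_undefined: int                       # IE undefined-value events, pooled
    seed: int


def single_trait_experiment(
    tree: Phylogeny,
    n_traits: int = 1000,
    sigma2: float = 1.0,
    seed: int = 0,
    methods: tuple[str, ...] = ("IE", "PIDC"),
) -> SingleTraitResult:
    """Bias audit of IE vs PIDC on replicated single-trait BM simulations.

    Per replicate: simulate a geometrically normal trait (BM in log space,
    root value 0, rate ``sigma2``, then exponentiated), reconstruct with IE
    on the arithmetic values (permissive mode: rare undefined draws record
    NaN) and with PIDC on the logged values, and score both against the
    simulated truth in log space.  ``methods`` restricts the methods run
    (PIDC alone is cheap enough for very high replicate counts).
    """
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    unknown = set(methods) - {"IE", "PIDC"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    internal = tree.internal_nodes
    branch_ids = tree.branches
    n_int, n_br = len(internal), len(branch_ids)

    node_err = {m: np.empty((n_traits, n_int)) for m in methods}
    br_val = {m: np.empty((n_traits, n_br)) for m in (*methods, "truth")}
    rv_rows = []
    n_undef = 0

    for r in range(n_traits):
        truth = simulate_bm_trait(tree, sigma2=sigma2, root_value=0.0, seed=[seed, r])
        true_nodes = truth.log_values[internal]
        true_changes = truth.branch_changes[branch_ids]
        br_val["truth"][r] = truth.standardized_changes[branch_ids]

        if "IE" in methods:
            ie = ie_reconstruct(
                tree, truth.tip_values("arithmetic"), metric="ie", on_undefined="nan"
            )
            n_undef += ie.n_undefined
            with np.errstate(invalid="ignore"):
                ie_nodes_log = np.log(ie.nodes.set_index("node")["ancestral_state"])
            node_err["IE"][r] = ie_nodes_log.loc[internal].to_numpy() - true_nodes
            ieb = ie.branches.set_index("branch")
            br_val["IE"][r] = ieb.loc[branch_ids, "contrast"].to_numpy()
            rv_rows.append(
                pd.DataFrame(
                    {
                        "replicate": r,
                        "branch": branch_ids,
                        "signed_R": ieb.loc[branch_ids, "signed_R"].to_numpy(),
                        "true_change": true_changes,
                    }
                )
            )

        if "PIDC" in methods:
            log_tips = truth.tip_values("log")
            pidcb = pidc_contrasts(tree, log_tips).set_index("branch")
            pa = pic_ancestral_states(tree, log_tips)
            node_err["PIDC"][r] = pa.loc[internal].to_numpy() - true_nodes
            br_val["PIDC"][r] = pidcb.loc[branch_ids, "contrast"].to_numpy()

    depths_n = tree.depths[internal]
    depths_b = tree.depths[branch_ids]
    truth_std = br_val["truth"]
    node_bias = {
        m: _summarize(internal, depths_n, node_err[m], None, m, "node")
        for m in methods
    }
    branch_bias = {
        m: _summarize(
            branch_ids, depths_b, br_val[m] - truth_std, br_val[m], m, "branch"
        )
        for m in methods
    }
    branch_bias["truth"] = _summarize(
        branch_ids, depths_b, truth_std - truth_std, truth_std, "truth", "branch"
    )
    empty = pd.DataFrame(columns=["replicate", "branch", "signed_R", "true_change"])
    return SingleTraitResult(
        node_bias=node_bias,
        branch_bias=branch_bias,
        rvalue_pairs=pd.concat(rv_rows, ignore_index=True) if rv_rows else empty,
        n_replicates=n_traits,
        n_undefined=n_undef,
        seed=seed,
    )


def rvalue_accuracy(rvalue_pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-branch agreement between IE signed R-values and true changes.

    Columns: branch, n, pearson_r, sign_agreement, mean_bias
    (mean of signed R minus true change).  Requires >= 10 replicates.
    """
    n_rep = rvalue_pairs["replicate"].nunique()
    if n_rep < 10:
        raise ValueError(f"need >= 10 replicates, got {n_rep}")
    rows = []
    for br, g in rvalue_pairs.groupby("branch"):
        ok = g.dropna(subset=["signed_R", "true_change"])
        r_arr = ok["signed_R"].to_numpy()
        t_arr = ok["true_change"].to_numpy()
        if len(ok) < 3 or np.std(r_arr) == 0 or np.std(t_arr) == 0:
            pear = np.nan
        else:
            pear = float(stats.pearsonr(r_arr, t_arr)[0])
        rows.append(
            {
                "branch": br,
                "n": len(ok),
                "pearson_r": pear,
                "sign_agreement": float(
                    np.mean(np.sign(r_arr) == np.sign(t_arr))
                ) if len(ok) else np.nan,
                "mean_bias": float(np.mean(r_arr - t_arr)) if len(ok) else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SlopeRecoveryResult:
    """Estimated vs simulated evolutionary regression coefficients.

    ``per_pair`` has one row per simulated pair (beta plus one estimated
    slope per method); ``meta_slopes`` maps method -> origin-OLS slope of
    estimated on simulated; ``n_dropped`` counts pairs excluded from the
    IE meta-regressions because IE produced undefined values.
    """

    per_pair: pd.DataFrame
    meta_slopes: dict[str, float]
    n_dropped: dict[str, int]
    seed: int

    METHODS = ("PIC", "PIDC", "IE", "IE-R")


def pair_trait_experiment(
    tree: Phylogeny,
    n_pairs: int = 500,
    seed: int = 0,
) -> SlopeRecoveryResult:
    """Slope-recovery audit on correlated trait pairs, beta swept 0 -> 1.

    PIC and PIDC consume the logged values; IE consumes the arithmetic
    (exponentiated) values, mirroring the single-trait protocol.  Pairs in
    which IE yields any undefined value are dropped from the IE
    meta-regressions only.
    """
    betas = beta_grid(n_pairs)
    rows = []
    for i, beta in enumerate(betas):
        pair = simulate_correlated_pair(tree, beta=float(beta), seed=[seed, i])
        row = {"beta": float(beta)}

        c1 = pic_contrasts(tree, pair.trait1.tip_values("log"))["contrast"].to_numpy()
        c2 = pic_contrasts(tree, pair.trait2.tip_values("log"))["contrast"].to_numpy()
        row["PIC"] = origin_ols(c1, c2)

        d1 = pidc_contrasts(tree, pair.trait1.tip_values("log"))["contrast"].to_numpy()
        d2 = pidc_contrasts(tree, pair.trait2.tip_values("log"))["contrast"].to_numpy()
        row["PIDC"] = origin_ols(d1, d2)

        ie1 = ie_reconstruct(
            tree, pair.trait1.tip_values("arithmetic"), metric="ie", on_undefined="nan"
        )
        ie2 = ie_reconstruct(
            tree, pair.trait2.tip_values("arithmetic"), metric="ie", on_undefined="nan"
        )
        for name, col in (("IE", "contrast"), ("IE-R", "signed_R")):
            u = ie1.branches[col].to_numpy()
            v = ie2.branches[col].to_numpy()
            if np.isnan(u).any() or np.isnan(v).any():
                row[name] = np.nan
            else:
                row[name] = origin_ols(u, v)
        rows.append(row)

    per_pair = pd.DataFrame(rows)
    meta, dropped = {}, {}
    for m in SlopeRecoveryResult.METHODS:
        ok = per_pair.dropna(subset=[m])
        dropped[m] = len(per_pair) - len(ok)
        meta[m] = origin_ols(ok["beta"].to_numpy(), ok[m].to_numpy())
    return SlopeRecoveryResult(
        per_pair=per_pair, meta_slopes=meta, n_dropped=dropped, seed=seed
    )
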