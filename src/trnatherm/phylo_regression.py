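"""Phylogenetic generalized least squares under BM and OU tip covariance.

Residual covariance across species follows a trait-evolution model on a
rooted, time-calibrated phylogeny: Brownian Motion (variance accumulates
with shared root-to-MRCA path length) or a fixed-root Ornstein–Uhlenbeck
process with selection strength α, whose tip covariance is

    V_ij = (1 / 2α) · exp(−α d_ij) · (1 − exp(−2α t_ij))

with d_ij the tip-to-tip path distance and t_ij the shared time (MRCA
depth).  As α → 0 the OU matrix converges to the BM matrix.  Coefficients
are estimated by GLS with the trait variance rate σ² profiled out by maximum
likelihood; for OU, α is optimized on a deterministic log-grid followed by
bounded refinement.  Models are compared by AIC with a parsimony rule: when
AICs differ by less than 2 units the model with fewer parameters wins.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

#: AIC difference under which the fewer-parameter model is preferred.
AIC_PARSIMONY_MARGIN = 2.0

#: Deterministic log10-α starting grid for the OU profile search (α in units
#: of 1/tree-depth for a unit-depth calibrated tree).
_OU_LOG_ALPHA_GRID = np.linspace(-6.0, 3.0, 19)


class PhyloRegressionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Trees


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths and validate it."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    validate_tree(tree)
    return tree


def validate_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise PhyloRegressionError("duplicate tip labels in tree")
    if len(labels) < 3:
        raise PhyloRegressionError(f"need ≥ 3 tips for fitting, got {len(labels)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
        if not math.isfinite(edge.length) or edge.length < 0:
            raise PhyloRegressionError(f"invalid branch length {edge.length}")


def prune_to_taxa(tree: dendropy.Tree, labels: Sequence[str]) -> dendropy.Tree:
    """Prune the tree to the given tip labels, reporting both unmatched sets."""
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    wanted = set(labels)
    keep = tip_labels & wanted
    if len(keep) < 3:
        raise PhyloRegressionError(
            f"fewer than 3 species shared between tree and data "
            f"(tree-only: {sorted(tip_labels - wanted)[:5]}…, "
            f"data-only: {sorted(wanted - tip_labels)[:5]}…)"
        )
    if tip_labels - wanted:
        logger.info("pruning %d tree tips absent from data", len(tip_labels - wanted))
    if wanted - tip_labels:
        logger.warning(
            "%d data species absent from tree are excluded from regression: %s",
            len(wanted - tip_labels), sorted(wanted - tip_labels)[:10],
        )
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    return pruned


def _tip_depths_and_mrca(tree: dendropy.Tree) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """Tip labels, per-tip root-to-tip depths, and the MRCA-depth matrix.

    Single postorder pass: every internal node contributes its depth as the
    shared time of all tip pairs split across its children.
    """
    depth: Dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    labels: List[str] = []
    index: Dict[int, List[int]] = {}
    for leaf in tree.leaf_node_iter():
        index[id(leaf)] = [len(labels)]
        labels.append(leaf.taxon.label)
    n = len(labels)
    t_mrca = np.zeros((n, n))
    tip_depth = np.zeros(n)
    for leaf in tree.leaf_node_iter():
        i = index[id(leaf)][0]
        tip_depth[i] = depth[id(leaf)]
        t_mrca[i, i] = depth[id(leaf)]

    for node in tree.postorder_internal_node_iter():
        children = [index.get(id(ch), []) for ch in node.child_nodes()]
        merged: List[int] = []
        for k, tips_k in enumerate(children):
            for tips_l in children[k + 1:]:
                for i in tips_k:
                    t_mrca[i, tips_l] = depth[id(node)]
                    t_mrca[tips_l, i] = depth[id(node)]
            merged.extend(tips_k)
        index[id(node)] = merged
    return labels, tip_depth, t_mrca


def vcv(
    tree: dendropy.Tree, model: str = "BM", alpha: Optional[float] = None
) -> Tuple[List[str], np.ndarray]:
    """Tip covariance-structure matrix under BM or fixed-root OU.

    Returns (tip labels, matrix).  BM: V_ij = shared root-to-MRCA path
    length, diagonal = root-to-tip depth.  OU: the fixed-root form above;
    requires ``alpha`` > 0.  Non-ultrametric trees are accepted with a
    warning (per-tip depths are used as-is).
    """
    validate_tree(tree)
    labels, tip_depth, t_mrca = _tip_depths_and_mrca(tree)
    if np.ptp(tip_depth) > 1e-6 * max(tip_depth.max(), 1.0):
        logger.warning("tree is not ultrametric; using per-tip depths in the covariance")
    model = model.upper()
    if model == "BM":
        return labels, t_mrca
    if model != "OU":
        raise ValueError(f"unknown covariance model {model!r}")
    if alpha is None or alpha <= 0:
        raise ValueError("OU covariance requires alpha > 0")
    d = tip_depth[:, None] + tip_depth[None, :] - 2.0 * t_mrca  # tip-to-tip distance
    v = (1.0 / (2.0 * alpha)) * np.exp(-alpha * d) * (1.0 - np.exp(-2.0 * alpha * t_mrca))
    return labels, v


# ---------------------------------------------------------------------------
# GLS / ML fitting


@dataclass
class FitResult:
    """A fitted phylogenetic regression.

    ``coefficients`` is a DataFrame indexed by term with columns estimate /
    se / t / p_value.  ``k`` counts regression coefficients plus σ² (plus α
    for OU); AIC = 2k − 2 lnL.
    """

    model: str
    coefficients: pd.DataFrame
    sigma2: float
    lnL: float
    aic: float
    n: int
    k: int
    alpha: Optional[float] = None
    data_fingerprint: str = ""

    @property
    def beta(self) -> np.ndarray:
        return self.coefficients["estimate"].to_numpy()


def _fingerprint(y: np.ndarray, X: np.ndarray) -> str:
    h = hashlib.sha256()
    order = np.lexsort(np.column_stack([X, y[:, None]]).T)
    h.update(np.ascontiguousarray(np.round(y[order], 10)).tobytes())
    h.update(np.ascontiguousarray(np.round(X[order], 10)).tobytes())
    return h.hexdigest()[:16]


def gls_fit(
    y: np.ndarray,
    X: np.ndarray,
    V: np.ndarray,
    term_names: Optional[Sequence[str]] = None,
    model: str = "GLS",
    extra_params: int = 0,
) -> FitResult:
    """Generalized least squares with the trait variance rate σ² profiled
    out by maximum likelihood.

    β̂ = (XᵀV⁻¹X)⁻¹ XᵀV⁻¹y, σ̂² = rᵀV⁻¹r / n, with the Gaussian
    log-likelihood evaluated at the optimum.  Standard errors come from
    σ̂²(XᵀV⁻¹X)⁻¹ and two-sided p-values from the t distribution with
    n − p degrees of freedom.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape[0] != n or V.shape != (n, n):
        raise ValueError("dimension mismatch between y, X and V")
    if np.linalg.matrix_rank(X) < p:
        raise PhyloRegressionError("design matrix is rank deficient")
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise PhyloRegressionError("covariance matrix is not positive definite") from exc

    # whiten: solve L z = · turns GLS into OLS
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    dof = n - p
    if rss <= 1e-12 * max(1.0, float(yw @ yw)):
        # exact linear fit: β̂ is exact, the Gaussian likelihood degenerates
        sigma2, lnL = 0.0, math.inf
        se = np.zeros(p)
        tval = np.full(p, np.nan)
        pval = np.full(p, np.nan)
    else:
        lnL = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet_v + n)
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        tval = beta / se
        pval = 2.0 * stats.t.sf(np.abs(tval), df=dof)

    k = p + 1 + extra_params  # coefficients + sigma^2 (+ alpha for OU)
    names = list(term_names) if term_names is not None else [f"x{j}" for j in range(p)]
    coef = pd.DataFrame(
        {"estimate": beta, "se": se, "t": tval, "p_value": pval}, index=names
    )
    return FitResult(
        model=model,
        coefficients=coef,
        sigma2=sigma2,
        lnL=lnL,
        aic=2.0 * k - 2.0 * lnL,
        n=n,
        k=k,
        data_fingerprint=_fingerprint(y, X),
    )


def ml_fit(
    y: np.ndarray,
    X: np.ndarray,
    tree: dendropy.Tree,
    model: str = "BM",
    term_names: Optional[Sequence[str]] = None,
    tip_order: Optional[Sequence[str]] = None,
) -> FitResult:
    """Maximum-likelihood phylogenetic regression under BM or OU covariance.

    ``tip_order`` gives the species order of the rows of y/X; defaults to the
    tree's leaf-iteration order.  For OU, α is profiled by a deterministic
    grid search over log α refined with bounded scalar optimization.
    """
    model = model.upper()
    y = np.asarray(y, dtype=float).ravel()
    if np.allclose(y, y[0]):
        raise PhyloRegressionError("response has zero variance; fit is degenerate")
    labels, tip_depth, t_mrca = _tip_depths_and_mrca(tree)
    perm = _alignment_permutation(labels, tip_order)
    t_mrca = t_mrca[np.ix_(perm, perm)]
    tip_depth = tip_depth[perm]

    if model == "BM":
        return gls_fit(y, X, t_mrca, term_names, model="BM")
    if model != "OU":
        raise ValueError(f"unknown model {model!r}")

    d = tip_depth[:, None] + tip_depth[None, :] - 2.0 * t_mrca

    def ou_v(alpha: float) -> np.ndarray:
        return (1.0 / (2.0 * alpha)) * np.exp(-alpha * d) * (
            1.0 - np.exp(-2.0 * alpha * t_mrca)
        )

    def neg_lnL(log_alpha: float) -> float:
        try:
            return -gls_fit(y, X, ou_v(math.exp(log_alpha)), model="OU").lnL
        except PhyloRegressionError:
            return math.inf

    grid = _OU_LOG_ALPHA_GRID * math.log(10.0)
    grid_vals = [neg_lnL(g) for g in grid]
    best = int(np.argmin(grid_vals))
    if not math.isfinite(grid_vals[best]):
        raise PhyloRegressionError("OU likelihood not computable on the α grid")
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        neg_lnL, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    if not res.success:
        raise PhyloRegressionError(f"OU α optimization failed: {res.message}")
    pick = res.x if res.fun <= grid_vals[best] else grid[best]
    alpha_hat = math.exp(pick)
    fit = gls_fit(y, X, ou_v(alpha_hat), term_names, model="OU", extra_params=1)
    fit.alpha = alpha_hat
    return fit


def _alignment_permutation(
    labels: Sequence[str], tip_order: Optional[Sequence[str]]
) -> np.ndarray:
    if tip_order is None:
        return np.arange(len(labels))
    pos = {lab: i for i, lab in enumerate(labels)}
    missing = [s for s in tip_order if s not in pos]
    if missing or len(tip_order) != len(labels):
        raise PhyloRegressionError(
            f"tip_order does not match tree tips (missing from tree: {missing[:5]})"
        )
    return np.array([pos[s] for s in tip_order])


def select_model(fits: Sequence[FitResult]) -> FitResult:
    """Pick a fit by minimum AIC with a parsimony rule.

    Fits whose AIC lies within 2 units of the minimum are interchangeable;
    among those the fewest-parameter fit wins, ties broken BM before OU,
    then alphabetical.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to select among")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were computed on different data; selection is meaningless")
    best_aic = min(f.aic for f in fits)
    candidates = [f for f in fits if f.aic - best_aic < AIC_PARSIMONY_MARGIN]
    model_rank = {"BM": 0, "OU": 1}
    return min(
        candidates,
        key=lambda f: (f.k, model_rank.get(f.model, 99), f.model, f.aic),
    )


# ---------------------------------------------------------------------------
# Design matrices


def design_matrix(
    df: pd.DataFrame,
    predictors: Sequence[str],
    class_column: str = "temp_class",
    reference: str = "mesophile",
) -> Tuple[np.ndarray, List[str]]:
    """Design matrix with intercept, 0/1 temperature-class indicators
    (reference class omitted) and continuous predictors.

    Indicator columns for classes absent from the data are dropped with a
    warning so the design stays full rank.
    """
    cols: List[np.ndarray] = [np.ones(len(df))]
    names: List[str] = ["intercept"]
    for pred in predictors:
        if pred == class_column:
            levels = [c for c in ("thermophile", "psychrophile") if c != reference]
            for level in levels:
                indicator = (df[class_column] == level).to_numpy(dtype=float)
                if indicator.sum() == 0:
                    logger.warning("no %s in data; dropping its indicator", level)
                    continue
                cols.append(indicator)
                names.append(level)
        else:
            cols.append(df[pred].to_numpy(dtype=float))
            names.append(pred)
    return np.column_stack(cols), names
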