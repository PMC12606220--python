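"""Maximum-likelihood optimization of branch lengths and model parameters.

Coordinate ascent: bounded Brent line searches per branch length, then
bounded scalar searches for p_inv and the free-rate parameters (w1, r1; r2
is solved from the mean-rate constraint).  Every accepted step increases the
log-likelihood; iteration stops when a full round improves it by less than
``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .likelihood import CompressedAlignment, pattern_log_likelihoods
from .substitution import PhyloModel, solve_r2
from .tree import Tree

BRANCH_MIN = 1e-8
BRANCH_MAX = 10.0
RATE_MIN = 1e-4
RATE_MAX = 100.0
PINV_MAX = 0.95


@dataclass
class OptimizeResult:
    tree: Tree
    model: PhyloModel
    loglik: float
    n_rounds: int
    converged: bool


def _total(tree: Tree, comp: CompressedAlignment, model: PhyloModel, lp, inv) -> float:
    return float(
        pattern_log_likelihoods(tree, comp, model, leaf_partials=lp, invariant=inv)
        @ comp.weights
    )


def optimize_branch_lengths(
    tree: Tree,
    comp: CompressedAlignment,
    model: PhyloModel,
    rounds: int = 2,
    tol: float = 1e-6,
) -> float:
    """In-place Brent optimization of every branch length; returns logL.

    Uses the standard two-pass scheme: conditional likelihoods below each
    node (postorder) and outside each edge (preorder) are cached per rate
    category, so a single-branch likelihood evaluation costs one transition
    matrix and one (patterns x 20) product instead of a full-tree pruning.
    Each per-edge line search is exact coordinate ascent given the other
    branches, so the total log-likelihood is non-decreasing.
    """
    lp = comp.leaf_partials()
    inv = comp.invariant_likelihood(model.pi) if model.p_inv > 0 else None
    n_pat = comp.n_patterns
    pat_w = comp.weights
    rates = [float(r) for r in model.rates]
    cat_logw = np.log((1.0 - model.p_inv) * model.rate_weights)
    inv_term = model.p_inv * inv if inv is not None else None
    current = -np.inf

    def mix_loglik(per_cat: list[np.ndarray]) -> float:
        """Combine per-category pattern log-likelihoods into total logL."""
        stacked = np.vstack([lw + v for lw, v in zip(cat_logw, per_cat)])
        mx = stacked.max(axis=0)
        mx = np.where(np.isfinite(mx), mx, 0.0)
        lik = np.exp(stacked - mx[None, :]).sum(axis=0)
        if inv_term is not None:
            lik = lik + inv_term * np.exp(-mx)
        return float(pat_w @ (mx + np.log(lik)))

    n_cat = len(rates)

    def _rescale(acc: list[np.ndarray], scale: np.ndarray) -> np.ndarray:
        mx = np.maximum.reduce([a.max(axis=1) for a in acc])
        safe = np.where(mx > 0, mx, 1.0)
        for k in range(n_cat):
            acc[k] /= safe[:, None]
        return scale + np.log(safe)

    down: dict[int, list[np.ndarray]] = {}
    down_scale: dict[int, np.ndarray] = {}

    def refresh_down(node) -> None:
        """Recompute down[node] from its children's current partials."""
        if node.is_leaf:
            if node.name not in lp:
                raise ValueError(f"taxon {node.name!r} absent from alignment")
            down[id(node)] = [lp[node.name]] * n_cat
            down_scale[id(node)] = np.zeros(n_pat)
            return
        acc = [np.ones((n_pat, 20)) for _ in range(n_cat)]
        scale = np.zeros(n_pat)
        for child in node.children:
            if child.length < 0:
                raise ValueError(f"negative branch length {child.length}")
            for k, r in enumerate(rates):
                P = model.transition_matrix(child.length * r)
                acc[k] = acc[k] * (down[id(child)][k] @ P.T)
            scale = scale + down_scale[id(child)]
        down[id(node)] = acc
        down_scale[id(node)] = _rescale(acc, scale)

    best_ll = [-np.inf]

    def visit(v, out_v: list[np.ndarray], out_scale_v: np.ndarray) -> None:
        """Optimize edge v given valid out/down caches, then recurse.

        On entry down[] is current for v's subtree and out_v holds the
        likelihood of all data outside v's subtree indexed by the state at
        v's parent.  On exit v's subtree edges are optimized and down[v]
        refreshed, so later siblings see current values — this makes every
        per-edge line search exact coordinate ascent.
        """
        dv = down[id(v)]
        total_scale = out_scale_v + down_scale[id(v)]

        def edge_loglik(t: float) -> float:
            per_cat = []
            for k, r in enumerate(rates):
                P = model.transition_matrix(t * r)
                lik = (out_v[k] * (dv[k] @ P.T)).sum(axis=1)
                with np.errstate(divide="ignore"):
                    per_cat.append(np.log(lik) + total_scale)
            return mix_loglik(per_cat)

        ll0 = edge_loglik(v.length)
        res = minimize_scalar(
            lambda x: -edge_loglik(x),
            bounds=(BRANCH_MIN, BRANCH_MAX),
            method="bounded",
            options={"xatol": 1e-7},
        )
        if -res.fun > ll0:
            v.length = float(res.x)
            ll0 = -res.fun
        best_ll[0] = ll0
        if not v.is_leaf:
            for w in v.children:
                base = [
                    (out_v[k] @ model.transition_matrix(v.length * r))
                    for k, r in enumerate(rates)
                ]
                scale = out_scale_v.copy()
                for sib in v.children:
                    if sib is w:
                        continue
                    for k, r in enumerate(rates):
                        P = model.transition_matrix(sib.length * r)
                        base[k] = base[k] * (down[id(sib)][k] @ P.T)
                    scale = scale + down_scale[id(sib)]
                scale = _rescale(base, scale)
                visit(w, base, scale)
            refresh_down(v)

    for _ in range(max(1, rounds)):
        for node in tree.postorder():
            refresh_down(node)
        prev = current
        root = tree.root
        for w in root.children:
            base = [np.tile(model.pi, (n_pat, 1)) for _ in range(n_cat)]
            scale = np.zeros(n_pat)
            for sib in root.children:
                if sib is w:
                    continue
                for k, r in enumerate(rates):
                    P = model.transition_matrix(sib.length * r)
                    base[k] = base[k] * (down[id(sib)][k] @ P.T)
                scale = scale + down_scale[id(sib)]
            scale = _rescale(base, scale)
            visit(w, base, scale)
        current = best_ll[0]
        if current - prev < tol:
            break
    return float(current)


def _optimize_scalar(setter, lo, hi, tree, comp, model, lp, current) -> float:
    inv_cache = {}

    def neg(x: float) -> float:
        setter(float(x))
        inv = None
        if model.p_inv > 0:
            inv = inv_cache.setdefault("v", comp.invariant_likelihood(model.pi))
        return -_total(tree, comp, model, lp, inv)

    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6})
    if -res.fun > current:
        setter(float(res.x))
        return -res.fun
    return current


def optimize(
    tree: Tree,
    aln,
    model: PhyloModel,
    free_branches: bool = True,
    free_pinv: bool = True,
    free_rates: bool = True,
    observed_frequencies: bool = False,
    tol: float = 1e-6,
    max_rounds: int = 25,
) -> OptimizeResult:
    """Joint coordinate-ascent fit of branch lengths and rate parameters.

    The tree is modified in place (branch lengths); the model object is
    modified in place (p_inv, rate categories, and frequencies when
    ``observed_frequencies``).  Rate-heterogeneity switches apply only when
    the model actually carries the corresponding component.
    """
    comp = aln if isinstance(aln, CompressedAlignment) else CompressedAlignment(aln)
    if observed_frequencies:
        model.pi = comp.observed_counts() + 0.5
    lp = comp.leaf_partials()

    def cur_inv():
        return comp.invariant_likelihood(model.pi) if model.p_inv > 0 else None

    current = _total(tree, comp, model, lp, cur_inv())
    if not np.isfinite(current):
        raise FloatingPointError("non-finite starting likelihood")
    n_rounds = 0
    converged = False
    has_r2 = model.n_free_rate_categories == 2
    for n_rounds in range(1, max_rounds + 1):
        before = current
        if free_branches:
            current = optimize_branch_lengths(tree, comp, model, rounds=1, tol=tol)
        # Convention: a model is "+I" iff it starts with p_inv > 0.
        if free_pinv and model.p_inv > 0:

            def set_pinv(x: float) -> None:
                w1 = float(model.rate_weights[0])
                if has_r2:
                    r1 = min(float(model.rates[0]), 1.0 / (1.0 - x) - RATE_MIN)
                    r1 = max(r1, RATE_MIN)
                    model.set_rate_params(x, [w1, 1 - w1], [r1, solve_r2(x, w1, r1)])
                else:
                    model.set_rate_params(x, [1.0], [1.0 / (1.0 - x)])

            current = _optimize_scalar(set_pinv, 0.0, PINV_MAX, tree, comp, model, lp, current)
        if free_rates and has_r2:
            # r1 (lower-rate category), bounded so r2 stays in range.
            def set_r1(x: float) -> None:
                w1 = float(model.rate_weights[0])
                model.set_rate_params(model.p_inv, [w1, 1 - w1], [x, solve_r2(model.p_inv, w1, x)])

            mean = 1.0 / (1.0 - model.p_inv)
            current = _optimize_scalar(
                set_r1, RATE_MIN, mean - RATE_MIN, tree, comp, model, lp, current
            )

            def set_w1(x: float) -> None:
                r1 = float(model.rates[0])
                model.set_rate_params(model.p_inv, [x, 1 - x], [r1, solve_r2(model.p_inv, x, r1)])

            current = _optimize_scalar(set_w1, 0.02, 0.98, tree, comp, model, lp, current)
        if current - before < tol:
            converged = True
            break
    return OptimizeResult(tree=tree, model=model, loglik=current, n_rounds=n_rounds, converged=converged)
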