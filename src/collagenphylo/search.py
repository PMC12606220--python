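"""Tree search (NNI hill climbing) and nonparametric bootstrap support."""

from __future__ import annotations

import numpy as np

from .assembly import AminoAcidAlignment
from .likelihood import CompressedAlignment
from .optimize import optimize, optimize_branch_lengths
from .substitution import PhyloModel
from .tree import Tree, nni_neighbors, random_topology


def nni_search(
    aln: AminoAcidAlignment | CompressedAlignment,
    model: PhyloModel,
    start: Tree | None = None,
    restarts: int = 1,
    seed: int = 0,
    tol: float = 1e-6,
    optimize_model: bool = True,
) -> tuple[Tree, float]:
    """Hill-climbing NNI search; returns (best unrooted tree, logL).

    Each restart perturbs the starting topology with random NNI moves
    (restart 0 starts unperturbed).  Deterministic for a given seed.
    """
    comp = aln if isinstance(aln, CompressedAlignment) else CompressedAlignment(aln)
    if len(comp.taxa) < 4:
        raise ValueError("tree search needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    if start is None:
        start = random_topology(sorted(comp.taxa), rng)
    start = start.copy()
    start.unroot()

    best_tree: Tree | None = None
    best_model = model
    best_ll = -np.inf
    for restart in range(max(1, restarts)):
        tree = start.copy()
        if restart > 0:
            for _ in range(1 + rng.integers(3)):
                nbs = nni_neighbors(tree)
                tree = nbs[rng.integers(len(nbs))]
        work_model = model.copy()
        if optimize_model:
            res = optimize(tree, comp, work_model)
            current = res.loglik
        else:
            current = optimize_branch_lengths(tree, comp, work_model)
        improved = True
        while improved:
            improved = False
            for nb in nni_neighbors(tree):
                ll = optimize_branch_lengths(nb, comp, work_model)
                if ll > current + tol:
                    tree, current = nb, ll
                    improved = True
                    break
            if not improved and optimize_model:
                res = optimize(tree, comp, work_model)
                if res.loglik > current + tol:
                    current = res.loglik
                    improved = True
        if current > best_ll:
            best_ll, best_tree, best_model = current, tree, work_model
    # Final polish of the winning tree's branch lengths.
    best_ll = optimize_branch_lengths(best_tree, comp, best_model, rounds=6, tol=tol)
    return best_tree, float(best_ll)


def bootstrap_support(
    aln: AminoAcidAlignment | CompressedAlignment,
    model: PhyloModel,
    best: Tree,
    replicates: int = 100,
    seed: int = 0,
    search: str = "nni",
) -> dict[frozenset[str], float]:
    """Nonparametric bootstrap support (%) for each bipartition of ``best``.

    Columns are resampled with replacement; each replicate re-optimizes
    branch lengths on the best topology and, with ``search="nni"``, takes
    greedy NNI improvements.  Support = percentage of replicate trees
    containing the bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    comp = aln if isinstance(aln, CompressedAlignment) else CompressedAlignment(aln)
    rng = np.random.default_rng(seed)
    best = best.copy()
    best.unroot()
    target = best.bipartitions()
    counts = {bp: 0 for bp in target}
    n = comp.n_sites
    pattern_of_site = comp.site_to_pattern
    for _ in range(replicates):
        sites = rng.integers(0, n, size=n)
        weights = np.bincount(pattern_of_site[sites], minlength=comp.n_patterns).astype(float)
        rcomp = _ReweightedAlignment(comp, weights)
        tree = best.copy()
        ll = optimize_branch_lengths(tree, rcomp, model)
        if search == "nni":
            improved = True
            while improved:
                improved = False
                for nb in nni_neighbors(tree):
                    nll = optimize_branch_lengths(nb, rcomp, model, rounds=1)
                    if nll > ll + 1e-4:
                        tree, ll = nb, nll
                        improved = True
                        break
        bps = tree.bipartitions()
        for bp in target:
            if bp in bps:
                counts[bp] += 1
    return {bp: 100.0 * c / replicates for bp, c in counts.items()}


class _ReweightedAlignment:
    """A CompressedAlignment view with bootstrap pattern weights."""

    def __init__(self, comp: CompressedAlignment, weights: np.ndarray):
        self._comp = comp
        self.weights = weights

    def __getattr__(self, item):
        return getattr(self._comp, item)


def annotate_support(tree: Tree, support: dict[frozenset[str], float]) -> str:
    """Newick string of ``tree`` with per-branch bootstrap support labels."""
    all_taxa = frozenset(tree.taxa)
    ref = min(all_taxa)

    def label(node) -> str | None:
        side = frozenset(n.name for n in Tree(node).leaves())
        if ref in side:
            side = all_taxa - side
        val = support.get(side)
        return None if val is None else f"{val:.0f}"

    return tree.to_newick(label=label)
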