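"""Felsenstein pruning likelihood for amino-acid alignments.

Sites are compressed to unique columns (patterns) before computation; 'X'
is treated as fully missing data (a conditional-likelihood vector of ones).
Rate heterogeneity follows the model's invariant-sites + free-rate mixture:

    L_site = p_inv * I_site + (1 - p_inv) * sum_k w_k L_site(r_k)

where I_site is pi[a] when every observed residue in the column equals a
(and 1 for an all-missing column), else 0.  Per-pattern scaling keeps the
recursion stable on larger trees.
"""

from __future__ import annotations

import numpy as np

from .assembly import AminoAcidAlignment
from .constants import AMINO_ACIDS, UNKNOWN
from .substitution import PhyloModel
from .tree import Tree

_STATE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_MISSING = 20


class CompressedAlignment:
    """Alignment columns collapsed to unique patterns with weights."""

    def __init__(self, aln: AminoAcidAlignment):
        self.taxa = list(aln.taxa)
        n = len(self.taxa)
        L = aln.n_columns
        states = np.empty((n, L), dtype=np.int8)
        for i, t in enumerate(self.taxa):
            row = aln.rows[t]
            states[i] = [_STATE.get(c, _MISSING) for c in row]
        cols = states.T
        uniq, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = uniq.T  # (n_taxa, n_patterns)
        self.weights = counts.astype(float)
        self.site_to_pattern = inverse
        self.n_sites = L
        self.n_patterns = uniq.shape[0]

    def observed_counts(self) -> np.ndarray:
        """Residue counts over all cells (for +F frequencies)."""
        counts = np.zeros(20)
        flat = self.patterns  # (n_taxa, n_patterns)
        for s in range(20):
            counts[s] = float(((flat == s) * self.weights[None, :]).sum())
        return counts

    def invariant_likelihood(self, pi: np.ndarray) -> np.ndarray:
        """Per-pattern likelihood under the invariant-sites class."""
        out = np.zeros(self.n_patterns)
        for p in range(self.n_patterns):
            col = self.patterns[:, p]
            obs = np.unique(col[col != _MISSING])
            if len(obs) == 0:
                out[p] = 1.0
            elif len(obs) == 1:
                out[p] = pi[obs[0]]
        return out

    def leaf_partials(self) -> dict[str, np.ndarray]:
        """(n_patterns, 20) tip conditional likelihoods per taxon."""
        out = {}
        eye = np.vstack([np.eye(20), np.ones(20)])
        for i, t in enumerate(self.taxa):
            out[t] = eye[self.patterns[i]]
        return out


def _category_pattern_loglik(
    tree: Tree,
    leaf_partials: dict[str, np.ndarray],
    model: PhyloModel,
    rate: float,
    n_patterns: int,
) -> np.ndarray:
    """log per-pattern likelihood for one rate category."""
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_patterns)
    for node in tree.postorder():
        if node.is_leaf:
            if node.name not in leaf_partials:
                raise ValueError(f"taxon {node.name!r} absent from alignment")
            partial[id(node)] = leaf_partials[node.name]
            continue
        acc = np.ones((n_patterns, 20))
        for child in node.children:
            if child.length < 0:
                raise ValueError(f"negative branch length {child.length}")
            P = model.transition_matrix(child.length * rate)
            acc *= partial[id(child)] @ P.T
            del partial[id(child)]
        # Rescale to avoid underflow.
        mx = acc.max(axis=1)
        safe = np.where(mx > 0, mx, 1.0)
        acc /= safe[:, None]
        logscale += np.log(safe, where=mx > 0, out=np.zeros_like(safe))
        # Patterns that underflowed to exactly 0 stay 0 (log -> -inf later).
        partial[id(node)] = acc
    root_l = partial[id(tree.root)] @ model.pi
    with np.errstate(divide="ignore"):
        return np.log(root_l) + logscale


def pattern_log_likelihoods(
    tree: Tree, comp: CompressedAlignment, model: PhyloModel,
    leaf_partials: dict[str, np.ndarray] | None = None,
    invariant: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pattern log-likelihood under the full I+R mixture."""
    if set(tree.taxa) != set(comp.taxa):
        raise ValueError(
            f"tree/alignment taxon mismatch: {sorted(set(tree.taxa) ^ set(comp.taxa))}"
        )
    if leaf_partials is None:
        leaf_partials = comp.leaf_partials()
    terms = []  # (log_weight, log_lik_vector)
    if model.p_inv > 0:
        if invariant is None:
            invariant = comp.invariant_likelihood(model.pi)
        with np.errstate(divide="ignore"):
            terms.append(np.log(model.p_inv) + np.log(invariant))
    logw = np.log((1.0 - model.p_inv) * model.rate_weights)
    for lw, rate in zip(logw, model.rates):
        ll = _category_pattern_loglik(tree, leaf_partials, model, float(rate), comp.n_patterns)
        terms.append(lw + ll)
    stacked = np.vstack(terms)
    mx = stacked.max(axis=0)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    out = mx + np.log(np.exp(stacked - mx[None, :]).sum(axis=0))
    if not np.all(np.isfinite(out)):
        bad = int(np.flatnonzero(~np.isfinite(out))[0])
        raise FloatingPointError(f"non-finite likelihood at pattern {bad}")
    return out


def site_log_likelihoods(
    tree: Tree, aln: AminoAcidAlignment | CompressedAlignment, model: PhyloModel
) -> np.ndarray:
    """Per-site log-likelihood vector in original column order."""
    comp = aln if isinstance(aln, CompressedAlignment) else CompressedAlignment(aln)
    per_pattern = pattern_log_likelihoods(tree, comp, model)
    return per_pattern[comp.site_to_pattern]


def log_likelihood(
    tree: Tree, aln: AminoAcidAlignment | CompressedAlignment, model: PhyloModel
) -> float:
    comp = aln if isinstance(aln, CompressedAlignment) else CompressedAlignment(aln)
    return float(pattern_log_likelihoods(tree, comp, model) @ comp.weights)


def brute_force_log_likelihood(
    tree: Tree, aln: AminoAcidAlignment, model: PhyloModel, rate: float = 1.0
) -> float:
    """Exhaustive-enumeration likelihood (oracle; exponential in tree size).

    Sums over every assignment of states to internal nodes; single rate
    category only.  Usable for <= 4 taxa and short alignments.
    """
    import itertools

    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    P = {
        id(n): model.transition_matrix(n.length * rate)
        for n in nodes
        if n.parent is not None
    }
    total = 0.0
    for j in range(aln.n_columns):
        col = {t: aln.rows[t][j] for t in aln.taxa}
        site_l = 0.0
        for assign in itertools.product(range(20), repeat=len(internals)):
            state = {id(n): s for n, s in zip(internals, assign)}
            for leaf in leaves:
                c = col[leaf.name]
                state[id(leaf)] = _STATE.get(c, _MISSING)
            prob = model.pi[state[id(tree.root)]]
            ok = True
            for n in nodes:
                if n.parent is None:
                    continue
                s_par = state[id(n.parent)]
                s_child = state[id(n)]
                if s_child == _MISSING:
                    continue  # marginalized below
                prob *= P[id(n)][s_par, s_child]
                if prob == 0.0:
                    ok = False
                    break
            if ok:
                # Leaves with X contribute sum over states = 1 (row sums 1).
                site_l += prob
        total += np.log(site_l)
    return float(total)
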