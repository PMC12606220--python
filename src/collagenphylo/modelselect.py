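"""Substitution-model selection by AIC/BIC over empirical-matrix variants."""

from __future__ import annotations

from dataclasses import dataclass

from .likelihood import CompressedAlignment
from .optimize import optimize
from .substitution import make_model
from .tree import Tree


@dataclass
class ModelFit:
    description: str
    loglik: float
    n_params: int
    aic: float
    bic: float


def _spec_to_model(matrix: str, plus_f: bool, plus_i: bool, plus_r2: bool, comp):
    model = make_model(
        matrix,
        p_inv=0.1 if plus_i else 0.0,
        r2=(0.5, 0.5) if plus_r2 else None,
    )
    if plus_f:
        model.pi = comp.observed_counts() + 0.5
    return model


def count_free_parameters(n_taxa: int, plus_f: bool, plus_i: bool, plus_r2: bool) -> int:
    """Branch lengths (2n-3 unrooted) + frequency, invariant-site and
    free-rate parameters.  +F counts 19 (frequencies estimated from data),
    +I counts 1, +R2 counts 2 (one weight, one free rate; the other rate is
    fixed by the mean-rate constraint)."""
    k = 2 * n_taxa - 3
    if plus_f:
        k += 19
    if plus_i:
        k += 1
    if plus_r2:
        k += 2
    return k


def model_select(
    aln,
    tree: Tree,
    matrices: tuple[str, ...] = ("mtMAM", "mtREV"),
    criterion: str = "AIC",
) -> list[ModelFit]:
    """Fit each candidate {matrix} x {+F} x {+I} x {+R2} combination on the
    given topology and rank by the chosen information criterion.

    Returns fits sorted best-first.  A single-column alignment still returns
    a ranking (the fits are just poorly informed).
    """
    import numpy as np

    comp = aln if isinstance(aln, CompressedAlignment) else CompressedAlignment(aln)
    n = comp.n_sites
    n_taxa = len(comp.taxa)
    fits: list[ModelFit] = []
    for matrix in matrices:
        for plus_f in (False, True):
            for plus_i in (False, True):
                for plus_r2 in (False, True):
                    model = _spec_to_model(matrix, plus_f, plus_i, plus_r2, comp)
                    work = tree.copy()
                    res = optimize(work, comp, model)
                    k = count_free_parameters(n_taxa, plus_f, plus_i, plus_r2)
                    desc = matrix + ("+F" if plus_f else "") + ("+I" if plus_i else "") + (
                        "+R2" if plus_r2 else ""
                    )
                    fits.append(
                        ModelFit(
                            description=desc,
                            loglik=res.loglik,
                            n_params=k,
                            aic=2 * k - 2 * res.loglik,
                            bic=k * np.log(max(n, 1)) - 2 * res.loglik,
                        )
                    )
    key = (lambda f: f.aic) if criterion.upper() == "AIC" else (lambda f: f.bic)
    return sorted(fits, key=key)
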