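"""Empirical amino-acid substitution models.

Implements time-reversible 20-state models built from a shipped empirical
exchangeability matrix (mtMAM or mtREV24) and equilibrium frequencies, with
two optional rate-heterogeneity components:

* +I — a proportion ``p_inv`` of invariant sites (rate 0);
* +R2 — a two-category free-rate mixture {(w_k, r_k)} with sum(w_k) = 1 and
  the mean-rate constraint (1 - p_inv) * sum(w_k r_k) = 1, so branch lengths
  stay in expected substitutions per variable-site-unit across models.

+F replaces the model's equilibrium frequencies with frequencies observed in
the alignment.  The rate matrix is Q[i,j] = S[i,j] * pi[j], rows summing to
zero, scaled so that -sum_i pi[i] Q[i,i] = 1 (one expected substitution per
unit branch length at rate 1).
"""

from __future__ import annotations

from importlib import resources
from typing import Sequence

import numpy as np

from .constants import AMINO_ACIDS

_MODEL_FILES = {"mtMAM": "mtmam.txt", "mtREV": "mtrev.txt"}
_TABLE_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def load_empirical_model(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (S, pi): 20x20 symmetric exchangeabilities and frequencies.

    Row/column order follows :data:`collagenphylo.constants.AMINO_ACIDS`.
    """
    if name not in _MODEL_FILES:
        raise ValueError(f"unknown empirical model {name!r}; available: {sorted(_MODEL_FILES)}")
    if name not in _TABLE_CACHE:
        text = (
            resources.files("collagenphylo").joinpath("data", _MODEL_FILES[name]).read_text()
        )
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        header = lines[0].split()
        if "".join(header) != AMINO_ACIDS:
            raise ValueError(f"{name}: unexpected residue order {header}")
        S = np.array([[float(x) for x in ln.split()] for ln in lines[1:21]])
        pi = np.array([float(x) for x in lines[21].split()])
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise ValueError(f"{name}: malformed exchangeability table")
        pi = pi / pi.sum()
        _TABLE_CACHE[name] = (S, pi)
    S, pi = _TABLE_CACHE[name]
    return S.copy(), pi.copy()


class PhyloModel:
    """A reversible amino-acid model with +F/+I/+R rate heterogeneity.

    Parameters
    ----------
    name:
        Empirical matrix name ("mtMAM" or "mtREV").
    frequencies:
        Equilibrium frequencies; defaults to the matrix's own.  Use
        :meth:`with_observed_frequencies` for +F.
    p_inv:
        Proportion of invariant sites in [0, 1).
    rate_weights, rates:
        Free-rate category weights and rates.  Defaults to a single
        category at rate satisfying the mean-rate constraint.
    """

    def __init__(
        self,
        name: str = "mtMAM",
        frequencies: Sequence[float] | None = None,
        p_inv: float = 0.0,
        rate_weights: Sequence[float] | None = None,
        rates: Sequence[float] | None = None,
    ) -> None:
        self.name = name
        self.S, self._base_pi = load_empirical_model(name)
        self._pi = np.asarray(frequencies, dtype=float) if frequencies is not None else self._base_pi
        if not (0 <= p_inv < 1):
            raise ValueError(f"p_inv must be in [0, 1), got {p_inv}")
        self.p_inv = float(p_inv)
        if rate_weights is None:
            rate_weights = [1.0]
        if rates is None:
            rates = [1.0 / (1.0 - self.p_inv)]
        self.rate_weights = np.asarray(rate_weights, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        self._validate_rates()
        self._eigen: tuple | None = None

    # -- parameters ---------------------------------------------------------

    def _validate_rates(self) -> None:
        if len(self.rate_weights) != len(self.rates):
            raise ValueError("rate_weights and rates must have equal length")
        if abs(self.rate_weights.sum() - 1.0) > 1e-8:
            raise ValueError("rate weights must sum to 1")
        if np.any(self.rates <= 0) or np.any(self.rate_weights <= 0):
            raise ValueError("rates and weights must be positive")
        mean = (1.0 - self.p_inv) * float(self.rate_weights @ self.rates)
        if abs(mean - 1.0) > 1e-6:
            raise ValueError(f"mean-rate constraint violated: (1-p_inv)*E[r] = {mean:.6f}")

    @property
    def pi(self) -> np.ndarray:
        return self._pi

    @pi.setter
    def pi(self, value: Sequence[float]) -> None:
        v = np.asarray(value, dtype=float)
        if v.shape != (20,) or np.any(v < 0):
            raise ValueError("frequencies must be a non-negative 20-vector")
        self._pi = v / v.sum()
        self._eigen = None

    def set_rate_params(self, p_inv: float, rate_weights: Sequence[float], rates: Sequence[float]) -> None:
        if not (0 <= p_inv < 1):
            raise ValueError(f"p_inv must be in [0, 1), got {p_inv}")
        self.p_inv = float(p_inv)
        self.rate_weights = np.asarray(rate_weights, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        self._validate_rates()

    def with_observed_frequencies(self, counts: Sequence[float], pseudocount: float = 0.5) -> "PhyloModel":
        """Return a copy with +F frequencies from observed residue counts."""
        counts = np.asarray(counts, dtype=float) + pseudocount
        m = self.copy()
        m.pi = counts / counts.sum()
        return m

    def copy(self) -> "PhyloModel":
        m = PhyloModel.__new__(PhyloModel)
        m.name = self.name
        m.S = self.S
        m._base_pi = self._base_pi
        m._pi = self._pi.copy()
        m.p_inv = self.p_inv
        m.rate_weights = self.rate_weights.copy()
        m.rates = self.rates.copy()
        m._eigen = None
        return m

    @property
    def n_free_rate_categories(self) -> int:
        return len(self.rates)

    # -- rate matrix --------------------------------------------------------

    def q_matrix(self) -> np.ndarray:
        """Normalized rate matrix: rows sum to 0, -sum(pi_i Q_ii) = 1."""
        Q = self.S * self._pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -float(self._pi @ np.diag(Q))
        return Q / scale

    def _decompose(self):
        if self._eigen is None:
            Q = self.q_matrix()
            sqrt_pi = np.sqrt(self._pi)
            # Reversibility: A = D^{1/2} Q D^{-1/2} is symmetric.
            A = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
            lam, V = np.linalg.eigh((A + A.T) / 2)
            U = V / sqrt_pi[:, None]
            Vinv = V.T * sqrt_pi[None, :]
            self._eigen = (lam, U, Vinv)
        return self._eigen

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) via the symmetric eigendecomposition."""
        if t < 0:
            raise ValueError(f"negative evolutionary time {t}")
        lam, U, Vinv = self._decompose()
        P = (U * np.exp(lam * t)[None, :]) @ Vinv
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    # -- description --------------------------------------------------------

    def describe(self) -> str:
        parts = [self.name]
        if not np.allclose(self._pi, self._base_pi):
            parts.append("F")
        if self.p_inv > 0:
            parts.append("I")
        if len(self.rates) > 1:
            parts.append(f"R{len(self.rates)}")
        return "+".join(parts)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PhyloModel({self.describe()}, p_inv={self.p_inv:.4f}, "
            f"weights={np.round(self.rate_weights, 4).tolist()}, "
            f"rates={np.round(self.rates, 4).tolist()})"
        )


def solve_r2(p_inv: float, w1: float, r1: float) -> float:
    """Second free-rate category rate from the mean-rate constraint."""
    target = 1.0 / (1.0 - p_inv)
    r2 = (target - w1 * r1) / (1.0 - w1)
    if r2 <= 0:
        raise ValueError(f"infeasible free-rate parameters: r2 = {r2:.6g}")
    return r2


def make_model(
    name: str = "mtMAM",
    plus_f_counts: Sequence[float] | None = None,
    p_inv: float = 0.0,
    r2: tuple[float, float] | None = None,
) -> PhyloModel:
    """Convenience constructor, e.g. mtMAM+F+I+R2.

    ``r2`` = (w1, r1) for the two-category free-rate mixture; the second
    rate is solved from the mean-rate constraint.
    """
    if r2 is not None:
        w1, r1 = r2
        weights = [w1, 1.0 - w1]
        rates = [r1, solve_r2(p_inv, w1, r1)]
    else:
        weights = [1.0]
        rates = [1.0 / (1.0 - p_inv)]
    model = PhyloModel(name=name, p_inv=p_inv, rate_weights=weights, rates=rates)
    if plus_f_counts is not None:
        model = model.with_observed_frequencies(plus_f_counts)
    return model
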