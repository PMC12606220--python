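"""Bayesian node dating on a fixed rooted topology.

Metropolis-Hastings sampling of internal-node ages under uniform fossil
calibrations, an optional birth-death node-age prior conditioned on the root
age, and either a strict clock or an uncorrelated lognormal relaxed clock
(per-branch rate multipliers with mean 1: log m ~ Normal(-sigma^2/2,
sigma^2)).  The sequence likelihood is the pruning likelihood with branch
lengths = clock_mean * multiplier * duration.

Node-age proposals draw uniformly inside the feasible window
[max(children ages, calibration min), min(parent age, calibration max)],
which is symmetric (the window does not depend on the node's own age) and,
in prior-only mode with no tree prior, samples uniform calibration
densities exactly.

Posterior summaries: shortest-interval HPD, effective sample size via the
initial-positive-sequence autocorrelation rule, and a maximum clade
credibility (MCC) tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .likelihood import CompressedAlignment, pattern_log_likelihoods
from .substitution import PhyloModel
from .tree import Node, Tree


@dataclass(frozen=True)
class Calibration:
    """Uniform age calibration on a clade's crown (MRCA) or stem node."""

    taxa: frozenset[str]
    min_age: float
    max_age: float
    node: str = "stem"  # "stem" (parent of the MRCA) or "crown"

    def __post_init__(self) -> None:
        if not self.min_age < self.max_age:
            raise ValueError(f"calibration needs min < max, got [{self.min_age}, {self.max_age}]")
        if self.node not in ("stem", "crown"):
            raise ValueError(f"calibration node must be 'stem' or 'crown', got {self.node!r}")


@dataclass
class PosteriorSample:
    step: int
    ages: np.ndarray  # per-node ages, problem node order
    clades: tuple[frozenset[str], ...]  # clade below each internal node
    clock_mean: float
    clock_sigma: float
    birth: float
    death: float
    log_likelihood: float
    log_prior: float


class DatingProblem:
    """Indexed view of a rooted binary topology for the dating MCMC."""

    def __init__(self, topology: Tree):
        root = topology.root
        if len(root.children) != 2:
            raise ValueError(
                "dating requires a rooted binary topology (root with 2 children); "
                f"root has {len(root.children)}"
            )
        self.nodes: list[Node] = list(topology.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = np.array(
            [self.index[id(n.parent)] if n.parent is not None else -1 for n in self.nodes]
        )
        self.children: list[list[int]] = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.is_leaf = np.array([n.is_leaf for n in self.nodes])
        self.root_index = self.index[id(root)]
        self.tree = topology
        # Clade (leaf set) below each node.
        self.clades: list[frozenset[str]] = []
        for i, n in enumerate(self.nodes):
            if self.is_leaf[i]:
                self.clades.append(frozenset([n.name]))
            else:
                s: set[str] = set()
                for c in self.children[i]:
                    s |= self.clades[c]
                self.clades.append(frozenset(s))

    def calibrated_node(self, cal: Calibration) -> int:
        matches = [
            i
            for i in range(len(self.nodes))
            if not self.is_leaf[i] and cal.taxa <= self.clades[i]
        ]
        if not matches:
            raise ValueError(f"clade {sorted(cal.taxa)} not found in topology")
        mrca = min(matches, key=lambda i: len(self.clades[i]))
        if cal.node == "crown":
            return mrca
        parent = self.parent[mrca]
        if parent == -1:
            return mrca  # stem of the root clade is the root itself
        return int(parent)


def _birth_death_log_density(ages: np.ndarray, problem: DatingProblem, birth: float, death: float) -> float:
    """Gernhard-style conditioned birth-death density of non-root internal
    node ages given the root age (each age iid on [0, t_root])."""
    root_age = ages[problem.root_index]
    if root_age <= 0:
        return -np.inf
    r = birth - death
    if r <= 0:
        return -np.inf
    a = death / birth

    def log_f(t: float) -> float:
        e = math.exp(-r * t)
        return math.log(r) + math.log1p(-a) - r * t - 2.0 * math.log(1.0 - a * e)

    def log_F(t: float) -> float:
        e = math.exp(-r * t)
        return math.log1p(-e) - math.log(1.0 - a * e)

    total = 0.0
    norm = log_F(root_age)
    for i in range(len(problem.nodes)):
        if problem.is_leaf[i] or i == problem.root_index:
            continue
        total += log_f(float(ages[i])) - norm
    return total


@dataclass
class _McmcSettings:
    age_weight: float = 0.4
    rate_weight: float = 0.3
    scalar_weight: float = 0.3
    log_step: float = 0.3
    clock_mean_prior_log_mean: float = math.log(1e-2)
    clock_mean_prior_log_sd: float = 2.0
    sigma_prior_mean: float = 0.5
    birth_prior_mean: float = 0.5
    death_prior_mean: float = 0.25
    root_max: float = 200.0


def mcmc_date(
    aln,
    topology: Tree,
    model: PhyloModel,
    calibrations: Sequence[Calibration],
    chain_length: int = 200_000,
    sample_every: int = 100,
    n_chains: int = 3,
    seeds: Sequence[int] | None = None,
    clock: str = "lognormal",
    use_likelihood: bool = True,
    use_tree_prior: bool = True,
    init: dict | None = None,
    settings: _McmcSettings | None = None,
) -> list[list[PosteriorSample]]:
    """Run independent MCMC chains; returns one sample list per chain.

    ``aln`` may be None when ``use_likelihood`` is False (prior-only run).
    ``clock`` is "strict" or "lognormal".  ``init`` may preset
    clock_mean/clock_sigma/birth/death.
    """
    if chain_length < sample_every or chain_length <= 0:
        raise ValueError("chain_length must be >= sample_every and > 0")
    if clock not in ("strict", "lognormal"):
        raise ValueError(f"unknown clock model {clock!r}")
    if seeds is None:
        seeds = list(range(1, n_chains + 1))
    if len(seeds) != n_chains:
        raise ValueError("need one seed per chain")
    settings = settings or _McmcSettings()

    problem = DatingProblem(topology.copy())
    n_nodes = len(problem.nodes)

    # Per-node calibration bounds.
    lo = np.zeros(n_nodes)
    hi = np.full(n_nodes, np.inf)
    for cal in calibrations:
        i = problem.calibrated_node(cal)
        lo[i] = max(lo[i], cal.min_age)
        hi[i] = min(hi[i], cal.max_age)
        if lo[i] >= hi[i]:
            raise ValueError(f"inconsistent calibrations at node for {sorted(cal.taxa)}")
    if not np.isfinite(hi[problem.root_index]):
        hi[problem.root_index] = settings.root_max

    # Structural feasibility: lower bounds propagate up, uppers propagate down.
    lower = lo.copy()
    for i in range(n_nodes):  # postorder
        for c in problem.children[i]:
            lower[i] = max(lower[i], lower[c])
    upper = hi.copy()
    for i in reversed(range(n_nodes)):  # preorder
        p = problem.parent[i]
        if p != -1:
            upper[i] = min(upper[i], upper[p])
    for i in range(n_nodes):
        if not problem.is_leaf[i] and lower[i] >= upper[i]:
            raise ValueError(
                f"inconsistent calibrations: node above {sorted(problem.clades[i])[:3]}... "
                f"has empty feasible age window [{lower[i]}, {upper[i]}]"
            )

    comp = None
    leaf_partials = invariant = None
    if use_likelihood:
        if aln is None:
            raise ValueError("alignment required when use_likelihood=True")
        comp = aln if isinstance(aln, CompressedAlignment) else CompressedAlignment(aln)
        leaf_partials = comp.leaf_partials()
        invariant = comp.invariant_likelihood(model.pi) if model.p_inv > 0 else None

    internal = [i for i in range(n_nodes) if not problem.is_leaf[i]]
    non_root = [i for i in range(n_nodes) if problem.parent[i] != -1]

    def age_window(i: int, ages: np.ndarray) -> tuple[float, float]:
        a_lo = lo[i]
        for c in problem.children[i]:
            a_lo = max(a_lo, ages[c])
        p = problem.parent[i]
        a_hi = hi[i] if p == -1 else min(hi[i], ages[p])
        return a_lo, a_hi

    def compute_loglik(ages: np.ndarray, mult: np.ndarray, clock_mean: float) -> float:
        if not use_likelihood:
            return 0.0
        for i in non_root:
            dur = ages[problem.parent[i]] - ages[i]
            problem.nodes[i].length = clock_mean * mult[i] * max(dur, 0.0)
        pat = pattern_log_likelihoods(
            problem.tree, comp, model, leaf_partials=leaf_partials, invariant=invariant
        )
        return float(pat @ comp.weights)

    def compute_logprior(ages, mult, clock_mean, sigma, birth, death) -> float:
        total = 0.0
        for i in internal:
            if not (lo[i] <= ages[i] <= hi[i]):
                return -np.inf
            if hi[i] < np.inf or lo[i] > 0:
                total -= math.log(hi[i] - lo[i]) if np.isfinite(hi[i]) else 0.0
        for i in non_root:
            if ages[problem.parent[i]] <= ages[i] and not problem.is_leaf[i]:
                return -np.inf
        if use_tree_prior:
            if birth <= 0 or death < 0 or death >= birth:
                return -np.inf
            total += _birth_death_log_density(ages, problem, birth, death)
            total += -birth / settings.birth_prior_mean - death / settings.death_prior_mean
        if clock == "lognormal":
            if sigma <= 0:
                return -np.inf
            lm = np.log(mult[non_root])
            total += float(
                np.sum(-0.5 * ((lm + sigma**2 / 2) / sigma) ** 2 - np.log(sigma) - lm)
            )
            total += -sigma / settings.sigma_prior_mean
        if use_likelihood:
            z = (math.log(clock_mean) - settings.clock_mean_prior_log_mean) / settings.clock_mean_prior_log_sd
            total += -0.5 * z * z - math.log(clock_mean)
        return total

    chains: list[list[PosteriorSample]] = []
    clade_tuple = tuple(problem.clades)
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        ages = np.zeros(n_nodes)
        for i in range(n_nodes):  # postorder: children before parents
            if problem.is_leaf[i]:
                continue
            floor = max([ages[c] for c in problem.children[i]] + [lower[i]])
            ceil = upper[i]
            ages[i] = floor + 0.5 * (ceil - floor) if np.isfinite(ceil) else floor + 1.0
        mult = np.ones(n_nodes)
        state = dict(
            clock_mean=(init or {}).get("clock_mean", 1e-2),
            sigma=(init or {}).get("clock_sigma", 0.3 if clock == "lognormal" else 0.0),
            birth=(init or {}).get("birth", settings.birth_prior_mean),
            death=(init or {}).get("death", settings.death_prior_mean / 2),
        )
        if clock == "lognormal":
            mult[non_root] = np.exp(
                rng.normal(-state["sigma"] ** 2 / 2, state["sigma"], size=len(non_root))
            )
        cur_ll = compute_loglik(ages, mult, state["clock_mean"])
        cur_lp = compute_logprior(
            ages, mult, state["clock_mean"], state["sigma"], state["birth"], state["death"]
        )
        if not np.isfinite(cur_lp):
            raise RuntimeError("infeasible initial state (check calibrations)")
        samples: list[PosteriorSample] = []
        w_age = settings.age_weight
        w_rate = settings.rate_weight if clock == "lognormal" else 0.0
        w_scalar = settings.scalar_weight
        wsum = w_age + w_rate + w_scalar
        for step in range(1, chain_length + 1):
            u = rng.random() * wsum
            if u < w_age:
                i = internal[rng.integers(len(internal))]
                a_lo, a_hi = age_window(i, ages)
                if a_hi <= a_lo:
                    continue
                old = ages[i]
                ages[i] = rng.uniform(a_lo, a_hi)
                new_ll = compute_loglik(ages, mult, state["clock_mean"])
                new_lp = compute_logprior(
                    ages, mult, state["clock_mean"], state["sigma"], state["birth"], state["death"]
                )
                if math.log(rng.random() + 1e-300) < (new_ll + new_lp) - (cur_ll + cur_lp):
                    cur_ll, cur_lp = new_ll, new_lp
                else:
                    ages[i] = old
            elif u < w_age + w_rate:
                i = non_root[rng.integers(len(non_root))]
                old = mult[i]
                mult[i] = old * math.exp(rng.normal(0, settings.log_step))
                new_ll = compute_loglik(ages, mult, state["clock_mean"])
                new_lp = compute_logprior(
                    ages, mult, state["clock_mean"], state["sigma"], state["birth"], state["death"]
                )
                log_hastings = math.log(mult[i] / old)
                if math.log(rng.random() + 1e-300) < (new_ll + new_lp) - (cur_ll + cur_lp) + log_hastings:
                    cur_ll, cur_lp = new_ll, new_lp
                else:
                    mult[i] = old
            else:
                names = ["clock_mean"] if use_likelihood else []
                if clock == "lognormal":
                    names.append("sigma")
                if use_tree_prior:
                    names += ["birth", "death"]
                if not names:
                    continue
                name = names[rng.integers(len(names))]
                old = state[name]
                state[name] = old * math.exp(rng.normal(0, settings.log_step))
                new_ll = (
                    compute_loglik(ages, mult, state["clock_mean"])
                    if name == "clock_mean"
                    else cur_ll
                )
                new_lp = compute_logprior(
                    ages, mult, state["clock_mean"], state["sigma"], state["birth"], state["death"]
                )
                log_hastings = math.log(state[name] / old)
                if math.log(rng.random() + 1e-300) < (new_ll + new_lp) - (cur_ll + cur_lp) + log_hastings:
                    cur_ll, cur_lp = new_ll, new_lp
                else:
                    state[name] = old
            if step % sample_every == 0:
                samples.append(
                    PosteriorSample(
                        step=step,
                        ages=ages.copy(),
                        clades=clade_tuple,
                        clock_mean=state["clock_mean"],
                        clock_sigma=state["sigma"],
                        birth=state["birth"],
                        death=state["death"],
                        log_likelihood=cur_ll,
                        log_prior=cur_lp,
                    )
                )
        chains.append(samples)
    return chains


# ---------------------------------------------------------------------------
# Posterior summaries

def hpd_interval(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ceil(mass * n) sorted samples."""
    if not 0 < mass < 1:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    m = int(np.ceil(mass * n))
    m = min(m, n)
    widths = x[m - 1 :] - x[: n - m + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + m - 1])


def ess(samples: Sequence[float]) -> tuple[float, bool]:
    """Effective sample size with the initial-positive-sequence truncation.

    Returns (ess, degenerate).  A constant chain is flagged degenerate with
    ESS defined as n; a negatively autocorrelated chain can report ESS > n
    (flagged).
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples")
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return float(n), True
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (n * var)
    # Geyer initial positive sequence: Gamma_m = rho_{2m} + rho_{2m+1},
    # summed while positive; tau = 2*sum(Gamma) - 1.
    gamma_sum = 0.0
    m = 0
    while 2 * m + 1 < n:
        pair = acf[2 * m] + acf[2 * m + 1]
        if pair <= 0:
            break
        gamma_sum += pair
        m += 1
    tau = 2.0 * gamma_sum - 1.0
    if tau <= 1e-12:
        # Pathologically anticorrelated chain; ESS unbounded above.
        return float(100 * n), True
    e = n / tau
    return float(e), e > n


@dataclass
class NodeSummary:
    clade: frozenset[str]
    mean_age: float
    hpd: tuple[float, float]
    posterior_support: float


@dataclass
class DatingSummary:
    mcc_clades: tuple[frozenset[str], ...]
    nodes: list[NodeSummary]
    ess: dict[str, float]
    ess_degenerate: dict[str, bool]
    n_samples: int

    def newick(self, n_taxa_total: int | None = None) -> str:
        """MCC tree as a Newick string with node ages as heights."""
        by_size = sorted(self.mcc_clades, key=lambda c: len(c))
        age = {ns.clade: ns.mean_age for ns in self.nodes}

        def build(clade: frozenset[str]) -> tuple[str, float]:
            if len(clade) == 1:
                return next(iter(clade)), 0.0
            kids: list[frozenset[str]] = []
            remaining = set(clade)
            for sub in by_size:
                if sub < clade and sub <= remaining:
                    kids.append(sub)
                    remaining -= sub
            for t in sorted(remaining):
                kids.append(frozenset([t]))
            parts = []
            for k in kids:
                s, h = build(k)
                parts.append(f"{s}:{age[clade] - h:.6g}")
            return "(" + ",".join(parts) + ")", age[clade]

        root = max(self.mcc_clades, key=lambda c: len(c))
        s, _ = build(root)
        return s + ";"


def summarize(
    chains: list[list[PosteriorSample]],
    burnin_fraction: float = 0.10,
    mass: float = 0.95,
) -> DatingSummary:
    """Discard burn-in, pool chains, and build the MCC summary.

    The MCC topology maximizes the product of clade posterior frequencies
    over the sampled topologies; each of its nodes is annotated with the
    mean age and HPD of the samples containing that clade.
    """
    if not chains or all(not c for c in chains):
        raise ValueError("no chains to summarize")
    pooled: list[PosteriorSample] = []
    for chain in chains:
        drop = int(len(chain) * burnin_fraction)
        pooled.extend(chain[drop:])
    if not pooled:
        raise ValueError("all samples discarded as burn-in")
    n = len(pooled)

    # Clade posterior frequencies.
    clade_count: dict[frozenset[str], int] = {}
    for s in pooled:
        for i, clade in enumerate(s.clades):
            if len(clade) > 1:
                clade_count[clade] = clade_count.get(clade, 0) + 1

    # MCC topology: the sampled topology with max product of clade freqs.
    def score(s: PosteriorSample) -> float:
        return sum(
            math.log(clade_count[c] / n) for c in s.clades if len(c) > 1
        )

    best = max(pooled, key=score)
    mcc_clades = tuple(c for c in best.clades if len(c) >= 1)

    nodes: list[NodeSummary] = []
    for clade in {c for c in best.clades if len(c) > 1}:
        ages = [
            s.ages[s.clades.index(clade)] for s in pooled if clade in s.clades
        ]
        nodes.append(
            NodeSummary(
                clade=clade,
                mean_age=float(np.mean(ages)),
                hpd=hpd_interval(ages, mass) if len(ages) > 1 else (ages[0], ages[0]),
                posterior_support=clade_count[clade] / n,
            )
        )
    nodes.sort(key=lambda ns: -len(ns.clade))

    ess_out: dict[str, float] = {}
    ess_flag: dict[str, bool] = {}
    scalars = {
        "clock_mean": [s.clock_mean for s in pooled],
        "clock_sigma": [s.clock_sigma for s in pooled],
        "birth": [s.birth for s in pooled],
        "death": [s.death for s in pooled],
        "root_age": [max(s.ages) for s in pooled],
    }
    for name, vals in scalars.items():
        if len(vals) >= 10:
            e, flag = ess(vals)
            ess_out[name], ess_flag[name] = e, flag
    return DatingSummary(
        mcc_clades=mcc_clades,
        nodes=nodes,
        ess=ess_out,
        ess_degenerate=ess_flag,
        n_samples=n,
    )


# ---------------------------------------------------------------------------
# Calibration table I/O (TSV: taxa comma-joined, min, max, [stem|crown])

def read_calibrations(path: str | Path) -> list[Calibration]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("taxa\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 'taxa<TAB>min<TAB>max[<TAB>node]'")
            node = parts[3] if len(parts) > 3 and parts[3] else "stem"
            out.append(
                Calibration(
                    taxa=frozenset(parts[0].split(",")),
                    min_age=float(parts[1]),
                    max_age=float(parts[2]),
                    node=node,
                )
            )
    return out


def write_posterior_log(chains: list[list[PosteriorSample]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tstep\tclock_mean\tclock_sigma\tbirth\tdeath\tlog_likelihood\tlog_prior\troot_age\n")
        for ci, chain in enumerate(chains):
            for s in chain:
                fh.write(
                    f"{ci}\t{s.step}\t{s.clock_mean:.6g}\t{s.clock_sigma:.6g}\t"
                    f"{s.birth:.6g}\t{s.death:.6g}\t{s.log_likelihood:.6f}\t"
                    f"{s.log_prior:.6f}\t{max(s.ages):.6f}\n"
                )
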