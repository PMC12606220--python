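"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a ZooMS + collagen-phylogenetics study end to end:

* a birth-death time tree over a small marsupial-like radiation;
* collagen chains evolving under the empirical amino-acid model, with an
  (optional) relaxed lognormal clock;
* per-taxon sequence coverage in the 74-84% range (peptide-shaped
  contiguous missing blocks, as LC-MS/MS recovery leaves them);
* tryptic MALDI spectra with m/z jitter, lognormal intensity noise, peak
  dropout, and a degradation-dependent 1105/1106 deamidation peak pair;
* "poor" samples whose high-m/z peptides fall below the detection floor.

All randomness flows from one master seed; the same seed reproduces the
bundle byte-for-byte.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .assembly import AminoAcidAlignment, RecoveredPeptideSet
from .collagen import CollagenSequence, theoretical_fingerprint, tryptic_digest
from .constants import AMINO_ACIDS, UNKNOWN
from .peaks import PeakList
from .pmf import DEAMIDATION_DEAM_MZ, DEAMIDATION_REF_MZ, MarkerPanel, build_marker_panel
from .substitution import PhyloModel, make_model
from .tree import Node, Tree


@dataclass
class SimulationConfig:
    n_taxa: int = 8
    birth_rate: float = 0.15  # per Ma
    death_rate: float = 0.05
    root_age: float = 50.0  # Ma
    sequence_length: int = 2000  # concatenated COL1A1+COL1A2 residues
    chain_split: float = 0.5  # fraction of columns assigned to COL1A1
    model_name: str = "mtMAM"
    p_inv: float = 0.0
    clock_mean: float = 0.002  # substitutions/site/Ma
    clock_sigma: float = 0.0  # 0 = strict clock
    coverage_range: tuple[float, float] = (0.74, 0.84)
    mask_block_length: float = 15.0  # geometric mean masked block (residues)
    mz_jitter_sd: float = 0.02  # Da
    intensity_sigma: float = 0.5  # lognormal sigma of peak heights
    dropout: float = 0.1  # per-peak dropout probability
    poor_high_mz_cutoff: float = 2400.0
    poor_high_mz_scale: float = 0.05  # high-m/z peaks shrink to 5% of base
    sample_age_range: tuple[float, float] = (10.0, 100.0)  # ka
    deamidation_ratio_range: tuple[float, float] = (0.58, 0.77)
    deamidation_half_age: float = 50.0  # ka, logistic midpoint
    deamidation_scale: float = 20.0  # ka, logistic width
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("rates must be positive (death >= 0)")
        lo, hi = self.coverage_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("coverage range must lie in (0, 1]")


def deamidation_ratio_for_age(config: SimulationConfig, age_ka: float) -> float:
    """Expected 1105:1106 intensity ratio for a sample of the given age.

    Logistic decay from the youngest-sample ratio to the oldest: older bone
    is more deamidated, so the ratio falls with age.
    """
    lo, hi = config.deamidation_ratio_range
    f = 1.0 / (1.0 + np.exp((age_ka - config.deamidation_half_age) / config.deamidation_scale))
    return lo + (hi - lo) * f


def simulate_tree(config: SimulationConfig, seed: int | None = None) -> Tree:
    """Birth-death time tree conditioned on n_taxa, rescaled to root_age.

    Returns a rooted ultrametric tree with branch lengths in Ma.
    """
    seed = config.seed if seed is None else seed
    rng = _random.Random(int(seed))
    last_err: Exception | None = None
    for _ in range(20):
        try:
            dt = dendropy.model.birthdeath.birth_death_tree(
                birth_rate=config.birth_rate,
                death_rate=config.death_rate,
                num_extant_tips=config.n_taxa,
                rng=rng,
            )
            break
        except Exception as err:  # infeasible draw; retry with advanced rng
            last_err = err
    else:
        raise RuntimeError(f"birth-death simulation failed after 20 tries: {last_err}")
    for i, leaf in enumerate(dt.leaf_node_iter()):
        leaf.taxon.label = f"T{i + 1}"
    tree = Tree.from_dendropy(dt)
    # The generator stops exactly at the n-th speciation, leaving a zero-age
    # cherry; extend all tip edges by the waiting time to the next event so
    # tip ages stay contemporaneous but the youngest node age is positive.
    extra = rng.expovariate(config.n_taxa * (config.birth_rate + config.death_rate))
    for leaf in tree.leaves():
        leaf.length += extra
    # Rescale to the requested root age.
    depth = 0.0
    node = tree.leaves()[0]
    while node.parent is not None:
        depth += node.length
        node = node.parent
    scale = config.root_age / depth
    for n in tree.postorder():
        n.length *= scale
    return tree


def node_ages(tree: Tree) -> dict[frozenset[str], float]:
    """Clade -> age (Ma) map for an ultrametric time tree."""
    ages: dict[frozenset[str], float] = {}
    height: dict[int, float] = {}
    clade: dict[int, frozenset[str]] = {}
    for n in tree.postorder():
        if n.is_leaf:
            height[id(n)] = 0.0
            clade[id(n)] = frozenset([n.name])
        else:
            c0 = n.children[0]
            height[id(n)] = height[id(c0)] + c0.length
            clade[id(n)] = frozenset().union(*(clade[id(c)] for c in n.children))
            ages[clade[id(n)]] = height[id(n)]
    return ages


def simulate_alignment(
    tree: Tree,
    model: PhyloModel,
    length: int,
    clock_mean: float = 1.0,
    clock_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[AminoAcidAlignment, dict[frozenset[str] | str, float]]:
    """Evolve sequences along a time tree; returns (alignment, true branch
    lengths in substitutions/site keyed by the leaf set below each branch).

    Branch substitution length = duration * clock_mean * multiplier, with
    lognormal mean-1 multipliers when clock_sigma > 0.  Site-to-site rate
    variation follows the model's invariant + free-rate mixture.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    # Site rates from the model mixture.
    cats = len(model.rates)
    probs = np.concatenate(([model.p_inv], (1 - model.p_inv) * model.rate_weights))
    rates = np.concatenate(([0.0], model.rates))
    site_rate = rates[rng.choice(cats + 1, size=length, p=probs)]

    states: dict[int, np.ndarray] = {}
    true_bl: dict[frozenset[str] | str, float] = {}
    root_state = rng.choice(20, size=length, p=model.pi)
    states[id(tree.root)] = root_state
    for n in tree.preorder():
        if n.parent is None:
            continue
        mult = 1.0
        if clock_sigma > 0:
            mult = float(np.exp(rng.normal(-clock_sigma**2 / 2, clock_sigma)))
        bl = n.length * clock_mean * mult
        leafset = frozenset(x.name for x in Tree(n).leaves())
        true_bl[leafset if len(leafset) > 1 else next(iter(leafset))] = bl
        parent_state = states[id(n.parent)]
        child = parent_state.copy()
        for r in np.unique(site_rate):
            if r == 0.0:
                continue
            idx = np.flatnonzero(site_rate == r)
            P = model.transition_matrix(bl * float(r))
            cum = P.cumsum(axis=1)
            u = rng.random(len(idx))
            child[idx] = (u[:, None] > cum[parent_state[idx]]).sum(axis=1)
        states[id(n)] = child
    rows = {
        n.name: "".join(aa[states[id(n)]]) for n in tree.leaves()
    }
    return AminoAcidAlignment(taxa=[n.name for n in tree.leaves()], rows=rows), true_bl


def mask_coverage(
    aln: AminoAcidAlignment,
    fraction: dict[str, float] | float,
    seed: int = 0,
    block_length: float = 15.0,
) -> AminoAcidAlignment:
    """Mask contiguous blocks with 'X' until each taxon reaches the target
    masked fraction (fraction = share of columns turned to X)."""
    rng = np.random.default_rng(seed)
    L = aln.n_columns
    rows = {}
    for t in aln.taxa:
        f = fraction[t] if isinstance(fraction, dict) else fraction
        if not 0 <= f <= 1:
            raise ValueError(f"mask fraction must be in [0, 1], got {f}")
        row = np.array(list(aln.rows[t]))
        target = int(round(f * L))
        masked = np.zeros(L, dtype=bool)
        guard = 0
        while masked.sum() < target and guard < 10_000:
            guard += 1
            start = rng.integers(L)
            blk = 1 + rng.geometric(1.0 / block_length)
            need = target - int(masked.sum())
            end = min(L, start + min(blk, need + blk))
            masked[start:end] = True
            if masked.sum() > target:
                # Trim overshoot from this block's end.
                excess = int(masked.sum()) - target
                masked[end - excess : end] = False
        row[masked] = UNKNOWN
        rows[t] = "".join(row)
    return AminoAcidAlignment(taxa=list(aln.taxa), rows=rows)


def recovered_peptides_for_coverage(
    seq: CollagenSequence, target_coverage: float, rng: np.random.Generator
) -> RecoveredPeptideSet:
    """Subset of tryptic peptides whose spans reach ~target_coverage of the
    concatenated sequence (emulating LC-MS/MS peptide recovery)."""
    peps = [p for p in tryptic_digest(seq, max_missed=0) if UNKNOWN not in p.sequence]
    order = rng.permutation(len(peps))
    L = len(seq.concatenated)
    covered = np.zeros(L, dtype=bool)
    chosen = []
    for k in order:
        p = peps[k]
        s, e = p.concatenated_span(seq)
        if covered.sum() / L >= target_coverage:
            break
        covered[s - 1 : e] = True
        chosen.append((p.sequence, p.chain, p.start, p.end))
    return RecoveredPeptideSet(taxon_id=seq.taxon_id, peptides=chosen)


def simulate_spectrum(
    seq: CollagenSequence,
    config: SimulationConfig,
    sample_age: float,
    seed: int = 0,
    poor: bool = False,
    sample_id: str | None = None,
) -> PeakList:
    """Tryptic MALDI fingerprint of a collagen sequence with noise.

    Peaks come from the theoretical fingerprint (one hydroxylation level per
    peptide to keep spectra sparse), with Gaussian m/z jitter, lognormal
    intensities and random dropout; the 1105.58/1106.56 deamidation pair is
    injected with the age-mapped height ratio.  ``poor`` samples have their
    high-m/z peaks scaled down to the detection floor.
    """
    rng = np.random.default_rng(seed)
    fp = theoretical_fingerprint(seq, max_missed=0, max_hydroxylations=1, max_deamidations=0)
    peaks: list[tuple[float, float]] = []
    base = 100.0
    for pep, mz in fp:
        if config.dropout > 0 and rng.random() < config.dropout:
            continue
        jmz = float(mz + rng.normal(0, config.mz_jitter_sd)) if config.mz_jitter_sd > 0 else float(mz)
        inten = base * float(np.exp(rng.normal(0, config.intensity_sigma))) if config.intensity_sigma > 0 else base
        peaks.append((jmz, inten))
    # Deamidation reference pair at the configured age-dependent ratio.
    ratio = deamidation_ratio_for_age(config, sample_age)
    deam_height = base
    peaks.append((DEAMIDATION_REF_MZ, deam_height * ratio))
    peaks.append((DEAMIDATION_DEAM_MZ, deam_height))
    if poor:
        bp = max(h for _, h in peaks)
        peaks = [
            (mz, h * config.poor_high_mz_scale if mz > config.poor_high_mz_cutoff else h)
            for mz, h in peaks
        ]
    return PeakList(
        sample_id=sample_id or f"{seq.taxon_id}_sample",
        peaks=peaks,
        metadata={"taxon": seq.taxon_id, "age_ka": sample_age, "poor": poor},
    )


@dataclass
class DatasetBundle:
    config: SimulationConfig
    tree: Tree  # time tree, branch lengths in Ma
    true_node_ages: dict[frozenset[str], float]
    sequences: list[CollagenSequence]  # full true collagen sequences
    alignment: AminoAcidAlignment  # masked to target coverage
    peptide_sets: list[RecoveredPeptideSet]
    spectra: list[PeakList]
    panel: MarkerPanel
    truth: dict = field(default_factory=dict)


def simulate_dataset(config: SimulationConfig) -> DatasetBundle:
    """End-to-end synthetic study bundle with a ground-truth manifest."""
    master = np.random.default_rng(config.seed)
    tree_seed, aln_seed, cov_seed, spec_seed = master.integers(2**31 - 1, size=4)
    tree = simulate_tree(config, seed=int(tree_seed))
    ages = node_ages(tree)
    model = make_model(config.model_name, p_inv=config.p_inv)
    full_aln, true_bl = simulate_alignment(
        tree,
        model,
        config.sequence_length,
        clock_mean=config.clock_mean,
        clock_sigma=config.clock_sigma,
        seed=int(aln_seed),
    )
    split = int(round(config.sequence_length * config.chain_split))
    sequences = [
        CollagenSequence(t, full_aln.rows[t][:split], full_aln.rows[t][split:])
        for t in full_aln.taxa
    ]
    cov_rng = np.random.default_rng(int(cov_seed))
    lo, hi = config.coverage_range
    coverage = {t: float(cov_rng.uniform(lo, hi)) for t in full_aln.taxa}
    peptide_sets = [
        recovered_peptides_for_coverage(s, coverage[s.taxon_id], cov_rng)
        for s in sequences
    ]
    masked = mask_coverage(
        full_aln,
        {t: 1.0 - coverage[t] for t in full_aln.taxa},
        seed=int(cov_seed),
        block_length=config.mask_block_length,
    )
    fingerprints = {
        s.taxon_id: [
            mz
            for _, mz in theoretical_fingerprint(
                s, max_missed=0, max_hydroxylations=1, max_deamidations=0
            )
        ]
        for s in sequences
    }
    panel = build_marker_panel(fingerprints)
    spec_rng = np.random.default_rng(int(spec_seed))
    spectra = []
    truth_samples = {}
    for s in sequences:
        age = float(spec_rng.uniform(*config.sample_age_range))
        poor = bool(spec_rng.random() < 0.1)
        pl = simulate_spectrum(
            s,
            config,
            sample_age=age,
            seed=int(spec_rng.integers(2**31 - 1)),
            poor=poor,
            sample_id=f"{s.taxon_id}_s1",
        )
        spectra.append(pl)
        truth_samples[pl.sample_id] = {
            "taxon": s.taxon_id,
            "age_ka": age,
            "poor": poor,
            "expected_deamidation_ratio": deamidation_ratio_for_age(config, age),
        }
    truth = {
        "seed": config.seed,
        "tree_newick": tree.to_newick(),
        "node_ages": {",".join(sorted(c)): a for c, a in ages.items()},
        "true_branch_lengths": {
            (",".join(sorted(k)) if isinstance(k, frozenset) else k): v
            for k, v in true_bl.items()
        },
        "coverage": coverage,
        "samples": truth_samples,
    }
    return DatasetBundle(
        config=config,
        tree=tree,
        true_node_ages=ages,
        sequences=sequences,
        alignment=masked,
        peptide_sets=peptide_sets,
        spectra=spectra,
        panel=panel,
        truth=truth,
    )


def write_bundle(bundle: DatasetBundle, outdir: str | Path) -> None:
    """Write a bundle to disk: FASTA, Newick, TSV spectra, JSON manifest."""
    from .assembly import write_alignment
    from .collagen import write_collagen_fasta
    from .peaks import write_peaklist_tsv
    from .pmf import write_marker_panel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_collagen_fasta(bundle.sequences, outdir / "collagen.fasta")
    write_alignment(bundle.alignment, outdir / "alignment.fasta", "fasta")
    (outdir / "tree.nwk").write_text(bundle.tree.to_newick() + "\n")
    write_marker_panel(bundle.panel, outdir / "panel.tsv")
    specdir = outdir / "spectra"
    specdir.mkdir(exist_ok=True)
    for pl in bundle.spectra:
        write_peaklist_tsv(pl, specdir / f"{pl.sample_id}.tsv")
    with open(outdir / "peptides.tsv", "w") as fh:
        fh.write("taxon\tpeptide\tchain\tstart\tend\n")
        for ps in bundle.peptide_sets:
            for seq, chain, start, end in ps.peptides:
                fh.write(f"{ps.taxon_id}\t{seq}\t{chain}\t{start}\t{end}\n")
    (outdir / "truth.json").write_text(json.dumps(bundle.truth, indent=2, sort_keys=True))


def read_peptide_sets(path: str | Path) -> list[RecoveredPeptideSet]:
    """Read per-taxon recovered peptides from the TSV written above."""
    by_taxon: dict[str, list] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            taxon, seq, chain, start, end = line.rstrip("\n").split("\t")
            by_taxon.setdefault(taxon, []).append((seq, chain, int(start), int(end)))
    return [RecoveredPeptideSet(t, peps) for t, peps in by_taxon.items()]
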