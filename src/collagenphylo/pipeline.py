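"""Pipeline orchestration: screen -> assemble -> ML (+AU) -> date.

A single YAML/dict config drives all stages; every random operation takes an
explicit seed recorded in the run report, artifacts are checksummed, and a
failure on one sample is logged and marked indeterminate rather than
aborting the batch.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import assembly, dating, pmf, search, topotest
from .collagen import read_collagen_fasta
from .likelihood import CompressedAlignment, site_log_likelihoods
from .optimize import optimize
from .peaks import read_peaklist
from .simulate import read_peptide_sets
from .substitution import make_model
from .tree import Tree

log = logging.getLogger("collagenphylo.pipeline")


@dataclass
class RunReport:
    config: dict
    seeds: dict = field(default_factory=dict)
    identifications: list = field(default_factory=list)
    alignment_stats: dict = field(default_factory=dict)
    ml: dict = field(default_factory=dict)
    au: dict = field(default_factory=dict)
    dating: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)  # path -> sha256
    timings: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(report: RunReport, path: Path) -> None:
    report.artifacts[str(path)] = _checksum(path)


def run_screen(config: dict, report: RunReport, outdir: Path) -> None:
    panel = pmf.read_marker_panel(config["panel"])
    peaklist_dir = Path(config["peaklists"])
    tolerance = float(config.get("tolerance", 0.2))
    min_markers = int(config.get("min_markers", 2))
    rows = []
    for path in sorted(peaklist_dir.glob("*")):
        if path.suffix.lower() not in (".tsv", ".txt", ".csv", ".mzml", ".mzxml"):
            continue
        try:
            pl = read_peaklist(path)
            r = pmf.classify_taxon(pl, panel, tolerance=tolerance, min_markers=min_markers)
            rows.append(r)
            log.info("screen %s -> %s (%s)", pl.sample_id, r.assignment, r.preservation_class)
        except Exception as err:
            report.errors.append(f"screen:{path.name}: {err}")
            rows.append(
                pmf.IdentificationResult(
                    sample_id=path.stem,
                    marker_counts={},
                    assignment="indeterminate",
                    preservation_class="poor",
                    deamidation_index=None,
                )
            )
    out = outdir / "screen_report.tsv"
    with open(out, "w") as fh:
        fh.write("sample_id\tassignment\tpreservation\tdeamidation_index\tmarker_counts\n")
        for r in rows:
            di = "NA" if r.deamidation_index is None else f"{r.deamidation_index:.4f}"
            counts = ",".join(f"{t}:{c}" for t, c in sorted(r.marker_counts.items()))
            fh.write(f"{r.sample_id}\t{r.assignment}\t{r.preservation_class}\t{di}\t{counts}\n")
    _register(report, out)
    report.identifications = [
        {
            "sample_id": r.sample_id,
            "assignment": r.assignment,
            "preservation": r.preservation_class,
            "deamidation_index": r.deamidation_index,
        }
        for r in rows
    ]


def run_assemble(config: dict, report: RunReport, outdir: Path) -> assembly.AminoAcidAlignment:
    if "alignment" in config:
        aln = assembly.read_alignment(config["alignment"])
        conflicts: list = []
    else:
        sets = read_peptide_sets(config["peptides"])
        refs = read_collagen_fasta(config["reference_fasta"])
        ref_taxon = config.get("reference_taxon", refs[0].taxon_id)
        reference = next(s for s in refs if s.taxon_id == ref_taxon)
        aln, conflicts = assembly.assemble_alignment(sets, reference)
    stats = assembly.coverage_stats(aln, conflicts)
    out = outdir / "assembled_alignment.fasta"
    assembly.write_alignment(aln, out, "fasta")
    _register(report, out)
    conflict_log = outdir / "conflicts.tsv"
    assembly.write_conflict_log(conflicts, conflict_log)
    _register(report, conflict_log)
    report.alignment_stats = {
        "coverage": stats.coverage,
        "n_variable_columns": stats.n_variable_columns,
        "n_columns": aln.n_columns,
        "n_conflicts": len(conflicts),
    }
    return aln


def run_ml(config: dict, report: RunReport, outdir: Path, aln) -> tuple[Tree, object]:
    seed = int(config.get("seed", 1))
    report.seeds["ml"] = seed
    comp = CompressedAlignment(aln)
    model = make_model(
        config.get("model", "mtMAM"),
        p_inv=float(config.get("p_inv_init", 0.05)),
        r2=(0.5, 0.5) if config.get("free_rates", True) else None,
    )
    if config.get("observed_frequencies", True):
        model.pi = comp.observed_counts() + 0.5
    best, ll = search.nni_search(
        comp, model, restarts=int(config.get("restarts", 2)), seed=seed
    )
    res = optimize(best, comp, model)
    supports = {}
    replicates = int(config.get("bootstrap", 100))
    if replicates > 0:
        supports = search.bootstrap_support(
            comp, model, best, replicates=replicates, seed=seed + 1
        )
    out = outdir / "ml_tree.nwk"
    out.write_text(search.annotate_support(best, supports) + "\n")
    _register(report, out)
    report.ml = {
        "log_likelihood": res.loglik,
        "model": model.describe(),
        "p_inv": model.p_inv,
        "rates": model.rates.tolist(),
        "rate_weights": model.rate_weights.tolist(),
        "tree": best.to_newick(),
        "supports": {"|".join(sorted(k)): v for k, v in supports.items()},
    }
    return best, model


def run_au(config: dict, report: RunReport, outdir: Path, aln, best: Tree, model) -> None:
    seed = int(config.get("seed", 1))
    report.seeds["au"] = seed
    comp = CompressedAlignment(aln)
    trees = [best.copy()]
    names = ["best"]
    alt_path = config.get("topologies")
    if alt_path:
        for i, line in enumerate(Path(alt_path).read_text().splitlines()):
            line = line.strip()
            if line:
                trees.append(Tree.from_newick(line))
                names.append(f"alt{i + 1}")
    else:
        # Default alternatives: the NNI neighbourhood of the best tree.
        from .tree import nni_neighbors

        work = best.copy()
        work.unroot()
        for i, nb in enumerate(nni_neighbors(work)[: int(config.get("max_alternatives", 12))]):
            trees.append(nb)
            names.append(f"nni{i + 1}")
    site_ll = []
    full_ll = []
    for t in trees:
        t.unroot()
        m = model.copy()
        res = optimize(t, comp, m)
        site_ll.append(site_log_likelihoods(t, comp, m))
        full_ll.append(res.loglik)
    result = topotest.au_test(
        np.vstack(site_ll),
        B=int(config.get("au_bootstrap", 10_000)),
        seed=seed,
        full_log_likelihoods=np.array(full_ll),
    )
    out = outdir / "au_test.tsv"
    with open(out, "w") as fh:
        fh.write("topology\tlogL\tdeltaL\tp_AU\tbp\n")
        for name, ll_, dl, p, bp in zip(
            names, result.log_likelihoods, result.delta_l, result.p_au, result.bp
        ):
            fh.write(f"{name}\t{ll_:.4f}\t{dl:.4f}\t{p:.4f}\t{bp:.4f}\n")
    _register(report, out)
    report.au = {
        "topologies": names,
        "delta_l": result.delta_l,
        "p_au": result.p_au,
    }


def run_date(config: dict, report: RunReport, outdir: Path, aln, tree: Tree, model) -> None:
    seed = int(config.get("seed", 1))
    n_chains = int(config.get("chains", 3))
    report.seeds["date"] = seed
    calibrations = dating.read_calibrations(config["calibrations"])
    if "outgroup" in config:
        rooted = tree.root_between(config["outgroup"])
    elif len(tree.root.children) == 2:
        rooted = tree.copy()
    else:
        # No outgroup given: root on the longest pendant edge (deterministic).
        longest = max(tree.leaves(), key=lambda n: (n.length, n.name))
        rooted = tree.root_between(longest.name)
    chains = dating.mcmc_date(
        aln,
        rooted,
        model,
        calibrations,
        chain_length=int(config.get("chain_length", 200_000)),
        sample_every=int(config.get("sample_every", 100)),
        n_chains=n_chains,
        seeds=[seed + i for i in range(n_chains)],
        clock=config.get("clock", "lognormal"),
    )
    post_log = outdir / "posterior.tsv"
    dating.write_posterior_log(chains, post_log)
    _register(report, post_log)
    summary = dating.summarize(chains, burnin_fraction=float(config.get("burnin", 0.10)))
    mcc_out = outdir / "mcc_tree.nwk"
    mcc_out.write_text(summary.newick() + "\n")
    _register(report, mcc_out)
    report.dating = {
        "ess": summary.ess,
        "n_samples": summary.n_samples,
        "nodes": [
            {
                "clade": "|".join(sorted(ns.clade)),
                "mean_age": ns.mean_age,
                "hpd": list(ns.hpd),
                "support": ns.posterior_support,
            }
            for ns in summary.nodes
        ],
    }


def run_pipeline(config: dict, outdir: str | Path) -> RunReport:
    """Run the configured stages in order and write a JSON run report.

    ``config`` keys: ``stages`` (list drawn from screen/assemble/ml/au/date),
    per-stage sub-dicts, and a global ``seed``.  Missing mandatory inputs
    raise before any stage runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", ["screen", "assemble", "ml", "au", "date"])
    # Validate inputs up front.
    requirements = {
        "screen": ["panel", "peaklists"],
        "assemble": [],
        "ml": [],
        "au": [],
        "date": ["calibrations"],
    }
    for stage in stages:
        section = config.get(stage, {})
        for key in requirements.get(stage, []):
            if key not in section:
                raise ValueError(f"stage {stage!r}: missing mandatory config key {key!r}")
            p = Path(section[key])
            if not p.exists():
                raise FileNotFoundError(f"stage {stage!r}: input {p} does not exist")
    if "assemble" in stages:
        sec = config.get("assemble", {})
        if not ("alignment" in sec or ("peptides" in sec and "reference_fasta" in sec)):
            raise ValueError("assemble stage needs 'alignment' or 'peptides'+'reference_fasta'")

    report = RunReport(config=config, seeds={"master": config.get("seed", 1)})
    aln = best = model = None
    for stage in stages:
        t0 = time.time()
        section = {**config.get(stage, {})}
        section.setdefault("seed", config.get("seed", 1))
        if stage == "screen":
            run_screen(section, report, outdir)
        elif stage == "assemble":
            aln = run_assemble(section, report, outdir)
        elif stage == "ml":
            if aln is None:
                raise ValueError("ml stage requires the assemble stage (or an alignment)")
            best, model = run_ml(section, report, outdir, aln)
        elif stage == "au":
            if best is None:
                raise ValueError("au stage requires the ml stage")
            run_au(section, report, outdir, aln, best, model)
        elif stage == "date":
            if best is None:
                raise ValueError("date stage requires the ml stage")
            run_date(section, report, outdir, aln, best, model)
        else:
            raise ValueError(f"unknown stage {stage!r}")
        report.timings[stage] = round(time.time() - t0, 3)
        log.info("stage %s finished in %.1fs", stage, report.timings[stage])
    out = outdir / "run_report.json"
    out.write_text(json.dumps(asdict(report), indent=2, sort_keys=True, default=str))
    return report
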