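"""Config-driven orchestration of the analysis stages.

A run config (YAML or dict) names an output directory, a seed, the stages
to run, and per-stage parameters. Stages execute in dependency order
(simulate -> call -> relate -> fstat / qpadm / graph -> dates -> scan ->
yhap); each writes TSV/YAML artifacts into the run directory and a summary
into the run manifest. Reruns refuse to overwrite existing stage outputs
unless forced. All randomness descends from the single config seed, so a
repeated run is byte-identical.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling import call_pseudohaploid
from .dating import ancestry_covariance, fit_decay
from .fstats import AlleleCounts, BlockPartition, fstat
from .graph import AdmixtureGraph
from .graphfit import fit_graph, observed_f2
from .io import read_eigenstrat, read_pileup, write_eigenstrat, write_pileup
from .matrix import MISSING
from .panel import SNPPanel
from .qpadm import LeftRightConfig, qpadm_weights
from .relatedness import estimate_baseline, pairwise_mismatch, pmr_report
from .scan import (
    WindowSpec,
    blocks_from_tiling,
    call_candidates,
    ldblock_zscores,
    read_bed,
    window_scan,
)
from .simulate import (
    AdmixedSampleSpec,
    CohortSpec,
    simulate_admixed_genotypes,
    simulate_frequencies,
    simulate_genotypes,
    simulate_pileup,
)
from .yhap import MarkerTree, assign_haplogroup, score_branches

__all__ = ["run", "STAGE_ORDER", "load_config"]

STAGE_ORDER = [
    "simulate", "call", "relate", "fstat", "qpadm", "graph", "dates",
    "scan", "yhap",
]


class DependencyError(RuntimeError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a YAML mapping")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise DependencyError(
            f"stage {stage!r} needs missing artifact {name!r}; "
            "run its upstream stage first"
        )
    return p


def _graph_from_config(gcfg) -> AdmixtureGraph:
    if isinstance(gcfg, str):
        return AdmixtureGraph.from_text(Path(gcfg).read_text())
    return AdmixtureGraph(
        [tuple(e) for e in gcfg["edges"]],
        {k: tuple(v) for k, v in gcfg.get("admixtures", {}).items()},
    )


def _stage_simulate(cfg, out: Path, seed: int) -> dict:
    sc = cfg["simulate"]
    graph = _graph_from_config(sc["graph"])
    pc = sc.get("panel", {})
    panel = SNPPanel.uniform(
        pc.get("n_snps", 5000), pc.get("n_chrom", 2),
        pc.get("chrom_length_bp", 50_000_000), pc.get("cM_per_Mb", 1.0),
        seed=seed,
    )
    freqs = simulate_frequencies(graph, panel, seed)
    cohort = CohortSpec(
        groups=dict(sc["cohort"]["groups"]),
        pedigree=[tuple(x) for x in sc["cohort"].get("pedigree", [])],
        mean_depth=sc["cohort"].get("mean_depth", 2.0),
        library_type=sc["cohort"].get("library_type", "double_strand"),
        damage_rate=sc["cohort"].get("damage_rate", 0.0),
    )
    genos = simulate_genotypes(freqs, cohort, seed, panel=panel)
    pileup = simulate_pileup(
        genos, cohort, panel, read_len=sc.get("read_len", 70), seed=seed,
        n_libraries=sc.get("n_libraries", 1),
    )
    write_eigenstrat(out / "truth_genotypes", genos)
    write_pileup(out / "pileup.tsv", pileup)
    truth = {
        "seed": seed,
        "graph": graph.to_text(),
        "groups": dict(sc["cohort"]["groups"]),
        "pedigree": [list(x) for x in cohort.pedigree],
        "root_beta": list(freqs.root_beta),
        "n_clipped": freqs.n_clipped,
    }
    admix = sc.get("admixed")
    if admix:
        spec = AdmixedSampleSpec(
            admix["source1"], admix["source2"], admix["alpha"],
            admix["generations"], admix["n_individuals"],
        )
        agm, _, _ = simulate_admixed_genotypes(spec, freqs, panel, seed)
        write_eigenstrat(out / "admixed_genotypes", agm)
        np.savetxt(out / "source_freqs.tsv",
                   np.column_stack([freqs.freq(spec.source1),
                                    freqs.freq(spec.source2)]),
                   delimiter="\t", header="ref1\tref2", comments="")
        truth["admixed"] = {k: admix[k] for k in admix}
    (out / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
    return {"n_snps": len(panel), "n_individuals": genos.n_individuals,
            "n_reads": int(len(pileup))}


def _stage_call(cfg, out: Path, seed: int) -> dict:
    cc = cfg.get("call", {})
    pile = read_pileup(_require(out, "pileup.tsv", "call"))
    panel, _, _ = read_eigenstrat(_require(out, "truth_genotypes.snp", "call").with_suffix(""))
    calls, counts = call_pseudohaploid(
        pile, panel,
        mode=cc.get("mode"),
        min_base_quality=cc.get("min_base_quality", 30),
        min_map_quality=cc.get("min_map_quality", 30),
        end_trim=cc.get("end_trim", 5),
        seed=seed,
        unit=cc.get("unit", "individual"),
    )
    write_eigenstrat(out / "calls", calls)
    (out / "call_filters.yaml").write_text(yaml.safe_dump(counts))
    return counts


def _stage_relate(cfg, out: Path, seed: int) -> dict:
    rc = cfg.get("relate", {})
    _, calls, _ = read_eigenstrat(_require(out, "calls.geno", "relate").with_suffix(""), ploidy=1)
    results, insufficient = pairwise_mismatch(
        calls, min_overlap=rc.get("min_overlap", 3000)
    )
    if len(results) >= 3:
        baseline = estimate_baseline(results)
    else:
        baseline = rc.get("baseline", 0.24)
    report = pmr_report(results, baseline)
    report.to_csv(out / "relatedness.tsv", sep="\t", index=False)
    return {"n_pairs": len(results), "baseline": float(baseline),
            "insufficient": len(insufficient)}


def _counts_for_analysis(out: Path, stage: str) -> tuple[AlleleCounts, BlockPartition, SNPPanel]:
    prefix = _require(out, "truth_genotypes.geno", stage).with_suffix("")
    panel, genos, _ = read_eigenstrat(prefix)
    counts = AlleleCounts.from_matrix(genos)
    part = BlockPartition.from_panel(panel)
    return counts, part, panel


def _stage_fstat(cfg, out: Path, seed: int) -> dict:
    stats = cfg.get("fstat", {}).get("stats", [])
    counts, part, _ = _counts_for_analysis(out, "fstat")
    rows = []
    for spec_row in stats:
        kind, *pops = spec_row
        r = fstat(kind, counts, tuple(pops), part)
        rows.append(
            {"stat": kind, "pops": ",".join(pops), "estimate": r.estimate,
             "se": r.se, "z": r.z, "n_snps": r.n_snps, "n_blocks": r.n_blocks}
        )
    pd.DataFrame(rows).to_csv(out / "fstats.tsv", sep="\t", index=False)
    return {"n_stats": len(rows)}


def _stage_qpadm(cfg, out: Path, seed: int) -> dict:
    qc = cfg["qpadm"]
    counts, part, _ = _counts_for_analysis(out, "qpadm")
    config = LeftRightConfig(
        list(qc["left"]), list(qc["right"]), qc.get("allsnps", True)
    )
    res = qpadm_weights(counts, config, part, seed=seed)
    df = pd.DataFrame(
        {"source": res.sources, "weight": res.weights, "se": res.se}
    )
    df["p_value"] = res.p_value
    df["feasible"] = res.feasible
    df.to_csv(out / "qpadm.tsv", sep="\t", index=False)
    return {"p_value": float(res.p_value), "feasible": bool(res.feasible)}


def _stage_graph(cfg, out: Path, seed: int) -> dict:
    gc = cfg["graph"]
    topology = _graph_from_config(gc["topology"])
    counts, part, _ = _counts_for_analysis(out, "graph")
    est, se = observed_f2(counts, topology.leaves, part,
                          corrected=gc.get("corrected", True))
    fit = fit_graph(topology, est, se, seed=seed)
    (out / "graph_fitted.dot").write_text(fit.graph.to_dot())
    (out / "graph_fitted.txt").write_text(fit.graph.to_text())
    rows = [
        {"popA": a, "popB": b, "z": z} for (a, b), z in fit.residual_z.items()
    ]
    pd.DataFrame(rows).to_csv(out / "graph_residuals.tsv", sep="\t",
                              index=False)
    return {"score": fit.score, "null_space_dim": fit.null_space_dim}


def _stage_dates(cfg, out: Path, seed: int) -> dict:
    dc = cfg.get("dates", {})
    prefix = _require(out, "admixed_genotypes.geno", "dates").with_suffix("")
    panel, target, _ = read_eigenstrat(prefix)
    fr = np.loadtxt(_require(out, "source_freqs.tsv", "dates"), skiprows=1)
    curve = ancestry_covariance(
        target, fr[:, 0], fr[:, 1], panel,
        binsize_cM=dc.get("binsize_cM", 1.0),
        max_dist_cM=dc.get("max_dist_cM", 100.0),
    )
    pd.DataFrame(
        {"bin_left_cM": curve.bin_left_cM, "covariance": curve.values,
         "n_pairs": curve.n_pairs}
    ).to_csv(out / "dates_curve.tsv", sep="\t", index=False)
    fit = fit_decay(curve, min_dist_cM=dc.get("min_dist_cM", 0.05))
    report = {
        "amplitude": fit.amplitude, "generations": fit.generations,
        "offset": fit.offset, "se": fit.se,
        "fit_window_cM": list(fit.fit_window_cM), "converged": fit.converged,
    }
    (out / "dates_fit.yaml").write_text(yaml.safe_dump(report))
    return {"generations": float(fit.generations), "se": float(fit.se)}


def _stage_scan(cfg, out: Path, seed: int) -> dict:
    sc = cfg["scan"]
    counts, _, panel = _counts_for_analysis(out, "scan")
    spec = WindowSpec(
        size=sc.get("window_bp", 500_000), step=sc.get("step_bp", 10_000),
        min_snps=sc.get("min_snps", 250),
        min_ancient_individuals=sc.get("min_ancient_individuals", 15),
    )
    coverage = np.full(len(panel), sc.get("ancient_coverage",
                                          spec.min_ancient_individuals + 1))
    stats = window_scan(
        counts, coverage, panel, spec,
        target=sc["target"], ancient=sc["ancient"], outgroup=sc["outgroup"],
    )
    blocks = blocks_from_tiling(panel, sc.get("block_bp", 2_000_000))
    stats = ldblock_zscores(stats, blocks, seed=seed)
    stats.to_csv(out / "scan.tsv", sep="\t", index=False)
    genes = read_bed(sc["genes_bed"]) if sc.get("genes_bed") else None
    candidates = call_candidates(
        stats, z_threshold=sc.get("z_threshold", 4.0), genes=genes
    )
    candidates.to_csv(out / "scan_candidates.tsv", sep="\t", index=False)
    return {"n_windows": int(len(stats)),
            "n_scored": int(np.isfinite(stats["z"]).sum()),
            "n_candidates": int(len(candidates))}


def _stage_yhap(cfg, out: Path, seed: int) -> dict:
    yc = cfg["yhap"]
    pile = read_pileup(_require(out, "pileup.tsv", "yhap"))
    tree = MarkerTree.from_table(pd.read_csv(yc["tree_file"], sep="\t"))
    rows = []
    for ind, grp in pile.groupby("individual"):
        support = score_branches(
            grp, tree, transversions_only=yc.get("transversions_only", False)
        )
        call, conflicts = assign_haplogroup(support, tree)
        rows.append(
            {"individual": ind, "haplogroup": call,
             "conflicts": ",".join(conflicts)}
        )
    pd.DataFrame(rows).to_csv(out / "yhap.tsv", sep="\t", index=False)
    return {"n_individuals": len(rows)}


_STAGES = {
    "simulate": _stage_simulate,
    "call": _stage_call,
    "relate": _stage_relate,
    "fstat": _stage_fstat,
    "qpadm": _stage_qpadm,
    "graph": _stage_graph,
    "dates": _stage_dates,
    "scan": _stage_scan,
    "yhap": _stage_yhap,
}

_SENTINELS = {
    "simulate": "truth_genotypes.geno",
    "call": "calls.geno",
    "relate": "relatedness.tsv",
    "fstat": "fstats.tsv",
    "qpadm": "qpadm.tsv",
    "graph": "graph_fitted.dot",
    "dates": "dates_fit.yaml",
    "scan": "scan.tsv",
    "yhap": "yhap.tsv",
}


def run(config: dict | str | Path, force: bool = False) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    out = Path(config.get("out", "adnakit_run"))
    out.mkdir(parents=True, exist_ok=True)
    requested = config.get("stages", ["simulate"])
    unknown = set(requested) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    ordered = [s for s in STAGE_ORDER if s in requested]

    manifest = {"version": __version__, "seed": seed, "stages": {},
                "inputs": {}}
    for key in ("graph_file", "tree_file"):
        for section in config.values():
            if isinstance(section, dict) and key in section:
                p = Path(section[key])
                if p.exists():
                    manifest["inputs"][str(p)] = _digest(p)
    for stage in ordered:
        sentinel = out / _SENTINELS[stage]
        if sentinel.exists() and not force:
            manifest["stages"][stage] = {"skipped": "exists (use force)"}
            continue
        manifest["stages"][stage] = _STAGES[stage](config, out, seed)
    (out / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True)
    )
    return manifest
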