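"""End-to-end pipeline driver: simulate -> calibrate -> call -> deconvolve
-> classify -> enrich -> boundary -> splice -> strand bias -> chromatin.

``run_pipeline`` takes a configuration mapping (or a YAML/JSON file
path), validates it in one pass reporting every violation at once, runs
the stages in dependency order, writes each output table as TSV under
``out_dir`` and records a manifest (parameters, derived seeds, package
version) so a rerun with the same config reproduces every file.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, boundary, calls, chromatin, deconv, elements, io
from . import simulate as sim
from . import splicing, strands

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "out_dir": "hydroxymap_out",
    "simulate": {},  # TruthConfig overrides
    "tab_assay": {},  # AssayErrorModel overrides
    "bs_assay": {"mean_coverage": 10.0},
    "calling": {"fdr": 0.01, "min_cov": 1},
    "deconv": {"min_cov": 1},
    "differential": {"min_cov": 10, "min_diff": 0.3},
    "splicing": {"min_reads": 10, "min_overhang": 8, "as_threshold": 0.8,
                 "psi": 0.6, "n_reads": 400, "read_len": 50},
    "enhancers": {"distal_bp": 2500},
    "boundary": {"flank": 150},
    "strand": {"min_rpkm_sas": 1.0},
    "chromatin": {"flank": 5000, "width": 50, "step": 25,
                  "region_bins": 100, "region_flank": 10000,
                  "region_flank_window": 1000},
}


class ConfigError(ValueError):
    """All configuration problems, reported together."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(problems))


def load_config(source: str | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    problems = []
    for key, value in user.items():
        if key not in cfg:
            problems.append(f"unknown config section or key: {key!r}")
            continue
        if isinstance(cfg[key], dict):
            if not isinstance(value, Mapping):
                problems.append(f"section {key!r} must be a mapping")
                continue
            for sub, sval in value.items():
                cfg[key][sub] = sval
        else:
            cfg[key] = value
    if not isinstance(cfg["seed"], int):
        problems.append("seed must be an integer")
    for field in ("fdr",):
        v = cfg["calling"].get(field)
        if not (isinstance(v, (int, float)) and 0 < v < 1):
            problems.append(f"calling.{field} must lie in (0, 1)")
    if problems:
        raise ConfigError(problems)
    return cfg


def run_pipeline(config: str | Mapping[str, Any]) -> dict[str, Any]:
    """Run every stage on a synthetic dataset; return a result bundle.

    The bundle maps stage names to in-memory tables; everything is also
    written under ``out_dir`` together with ``manifest.json``.
    """
    cfg = load_config(config)
    out_dir = io.ensure_dir(cfg["out_dir"])
    seed = cfg["seed"]
    results: dict[str, Any] = {}

    # --- simulate -----------------------------------------------------
    tcfg = sim.TruthConfig(seed=seed, **cfg["simulate"])
    ref = sim.gen_reference(tcfg)
    truth = sim.gen_truth(ref)
    tab_err = sim.AssayErrorModel(**cfg["tab_assay"])
    bs_err = sim.AssayErrorModel(**cfg["bs_assay"])
    tab = sim.simulate_cytosine_reports(truth, tab_err, "TAB", seed=seed + 1)
    bs = sim.simulate_cytosine_reports(truth, bs_err, "BS", seed=seed + 2)
    io.write_fasta(ref.genome, os.path.join(out_dir, "genome.fa"))
    io.write_refflat(ref.genes, os.path.join(out_dir, "genes.refflat"))
    io.write_cx_report(tab, os.path.join(out_dir, "tab.cx.tsv"))
    io.write_cx_report(bs, os.path.join(out_dir, "bs.cx.tsv"))
    results["reference"] = ref
    results["truth"] = truth

    # --- calibrate + call --------------------------------------------
    spike = calls.spike_in_stats(tab, bs)
    calib = calls.calibration_table(spike)
    calib.to_csv(os.path.join(out_dir, "calibration.tsv"), sep="\t", index=False)
    tab_called = calls.call_sites(
        tab, spike.background_p0(), fdr=cfg["calling"]["fdr"],
        min_cov=cfg["calling"]["min_cov"],
    )
    results["spike_in_stats"] = spike
    results["tab_called"] = tab_called

    # --- deconvolve + classify ---------------------------------------
    rec = deconv.cpg_frequencies(bs, tab, min_cov=cfg["deconv"]["min_cov"])
    called_map = tab_called.set_index(["chrom", "pos", "strand"])["called"]
    keys = pd.MultiIndex.from_frame(rec[["chrom", "pos", "strand"]])
    rec = deconv.classify_records(
        rec, hmc_called=called_map.reindex(keys).fillna(False).to_numpy()
    )
    rec.to_csv(os.path.join(out_dir, "cpg_records.tsv"), sep="\t", index=False)
    census = deconv.summarize_categories(rec)
    census.to_csv(os.path.join(out_dir, "categories.tsv"), sep="\t", index=False)
    results["cpg_records"] = rec
    results["categories"] = census

    # --- elements + enrichment ---------------------------------------
    tss = elements.tss_positions(ref.genes)
    active, poised = elements.derive_enhancers(
        ref.tracks["h3k4me1"], ref.tracks["h3k27ac"], tss,
        distal_bp=cfg["enhancers"]["distal_bp"],
    )
    tracks = elements.genic_tracks(ref.genes)
    tracks["enhancer_active"] = active
    tracks["enhancer_poised"] = poised
    labels = elements.assign_elements(rec, tracks)
    hmc_high = rec["hmc_class"] == "hmC_high"
    enr = elements.fold_enrichment(labels[hmc_high], labels)
    enr.to_csv(os.path.join(out_dir, "enrichment_hmc_high.tsv"), sep="\t",
               index=False)
    lev = elements.element_levels(rec, labels)
    lev.to_csv(os.path.join(out_dir, "element_levels.tsv"), sep="\t", index=False)
    results["enrichment"] = enr
    results["element_levels"] = lev

    # --- boundary + splice site --------------------------------------
    exons = boundary.exon_table(ref.genes)
    prof = boundary.boundary_profile(
        rec, exons, flank=cfg["boundary"]["flank"], genome=ref.genome
    )
    prof.to_csv(os.path.join(out_dir, "boundary_profile.tsv"), sep="\t",
                index=False)
    ss = boundary.detect_ss_cpg(
        ref.genome, exons[exons["kind"] == "internal"]
    )
    ss_classed = boundary.classify_ss_exons(ss, rec)
    ss_classed.to_csv(os.path.join(out_dir, "ss_exons.tsv"), sep="\t",
                      index=False)
    results["boundary_profile"] = prof
    results["ss_exons"] = ss_classed

    # --- splicing -----------------------------------------------------
    scfg = cfg["splicing"]
    gene0 = ref.genes.iloc[0]
    exon_seqs = sim.gene_exon_sequences(ref.genome, gene0)
    focal = len(exon_seqs) // 2
    reads, _ = sim.simulate_junction_reads(
        gene0, ref.genome, {focal: scfg["psi"]},
        n_reads=scfg["n_reads"], read_len=scfg["read_len"], seed=seed + 3,
    )
    lib = splicing.build_eej_library(
        exon_seqs, arm_len=scfg["read_len"] - scfg["min_overhang"]
    )
    region = ref.genome[gene0["chrom"]][gene0["tx_start"]:gene0["tx_end"]]
    if gene0["strand"] == "-":
        region = sim.revcomp(region)
    counts, discards = splicing.count_junction_reads(
        reads, lib, region, min_overhang=scfg["min_overhang"]
    )
    jt = splicing.junction_table(counts, focal)
    incl = splicing.inclusion_rate(jt, min_reads=scfg["min_reads"],
                                   as_threshold=scfg["as_threshold"])
    counts.to_csv(os.path.join(out_dir, "junction_counts.tsv"), sep="\t",
                  index=False)
    results["inclusion"] = incl
    results["junction_discards"] = discards

    # --- strand bias --------------------------------------------------
    expr = strands.rpkm(
        ref.expression.set_index("gene")["rna_count"], ref.genes,
        total_mapped=ref.total_mapped,
    )
    expr.to_csv(os.path.join(out_dir, "expression.tsv"), sep="\t", index=False)
    levels = strands.gene_strand_levels(rec, ref.genes)
    levels.to_csv(os.path.join(out_dir, "gene_strand_levels.tsv"), sep="\t",
                  index=False)
    bias = strands.strand_bias_test(levels, metric="hmc")
    sas = strands.sas_regions(expr, ref.genes,
                              min_rpkm=cfg["strand"]["min_rpkm_sas"])
    io.write_bed(sas, os.path.join(out_dir, "sas_regions.bed"))
    results["expression"] = expr
    results["strand_levels"] = levels
    results["strand_bias"] = bias
    results["sas"] = sas

    # --- chromatin profiles -------------------------------------------
    ccfg = cfg["chromatin"]
    if not poised.empty:
        mp = chromatin.midpoint_profile(
            rec, poised, flank=ccfg["flank"], width=ccfg["width"],
            step=ccfg["step"],
        )
        mp.to_csv(os.path.join(out_dir, "enhancer_profile_poised.tsv"),
                  sep="\t", index=False)
        results["enhancer_profile"] = mp
    rp = chromatin.region_profile(
        rec, ref.tracks["h3k9me3"], bins=ccfg["region_bins"],
        flank=ccfg["region_flank"], flank_window=ccfg["region_flank_window"],
    )
    rp.to_csv(os.path.join(out_dir, "repressive_profile.tsv"), sep="\t",
              index=False)
    results["repressive_profile"] = rp

    # --- manifest + summary -------------------------------------------
    manifest = {
        "version": __version__,
        "config": cfg,
        "derived_seeds": {"truth": seed, "tab": seed + 1, "bs": seed + 2,
                          "junction_reads": seed + 3},
        "outputs": sorted(os.listdir(out_dir)),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    summary = {
        "n_cpg_records": len(rec),
        "spike_in": asdict(spike),
        "hmc_high_fraction": float(
            census.loc[census["category"] == "hmC_high", "fraction"].iloc[0]
        ),
        "strand_bias_hmc": bias,
        "inclusion": None if incl.inclusion is None else float(incl.inclusion),
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    results["summary"] = summary
    results["manifest"] = manifest
    return results
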