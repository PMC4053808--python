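#!/usr/bin/env python
"""Step 06: expression-stratified strand bias and SAS regions.

Computes RPKM expression groups, per-gene sense/antisense pooled hmC and
mC levels over gene bodies, paired-t strand-bias tests stratified by
expression group, scaled sense/antisense metagene profiles, and the
sense-antisense (SAS) paired-region contrast.
"""

import json
import sys

sys.path.insert(0, __file__.rsplit("/", 1)[0])
import common  # noqa: E402

import pandas as pd  # noqa: E402

from hydroxymap import io, strands  # noqa: E402
from hydroxymap import simulate as sim  # noqa: E402


def main() -> None:
    args = common.parse_args(__doc__)
    genes = io.read_refflat(common.results_path(args, "genes.refflat"))
    rec = common.read_tsv(args, "cpg_records.tsv")
    counts = common.read_tsv(args, "expression_counts.tsv")

    with open(common.results_path(args, "simulation_manifest.json")) as fh:
        total_mapped = json.load(fh)["total_mapped"]
    expr = strands.rpkm(
        counts.set_index("gene")["rna_count"], genes,
        total_mapped=int(total_mapped),
    )
    common.write_tsv(expr, args, "expression_rpkm.tsv")

    levels = strands.gene_strand_levels(rec, genes)
    levels = levels.merge(expr[["gene", "group"]], on="gene")
    common.write_tsv(levels, args, "gene_strand_levels.tsv")

    rows = []
    for group, sub in levels.groupby("group"):
        if len(sub) < 3:
            continue
        for metric in ("hmc", "mc"):
            res = strands.strand_bias_test(sub, metric=metric)
            rows.append(dict(group=group, metric=metric, **res))
    common.write_tsv(pd.DataFrame(rows), args, "strand_bias_by_group.tsv")

    profile = strands.gene_body_profile(rec, genes, bins=100,
                                        flank_bp=2000, flank_window=100)
    common.write_tsv(profile, args, "gene_body_profile.tsv")

    # SAS contrast on a dedicated overlapping-gene grid (the simulated
    # genome itself has no overlapping genes)
    sas_genes = sim.make_gene_grid(
        90, groups=["high"], overlap_every=3, overlap_bp=1500
    )
    sas_rec = sim.simulate_strand_records(
        sas_genes, {"high": 0.03}, coverage=40, seed=args.seed + 61
    )
    sas_expr = pd.DataFrame({"gene": sas_genes["gene"], "rpkm": 10.0})
    sas = strands.sas_regions(sas_expr, sas_genes)
    io.write_bed(sas, common.results_path(args, "sas_regions.bed"))
    contrast = strands.sas_bias_contrast(sas_rec, sas_genes, sas)
    common.write_json(contrast, args, "sas_contrast.json")


if __name__ == "__main__":
    main()
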