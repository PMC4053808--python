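#!/usr/bin/env python
"""Step 01: simulate the synthetic brain-methylome dataset.

Generates the toy genome with gene models, chromatin tracks, spike-in
contigs and a truth methylome, then draws paired TAB-Seq and BS-Seq
cytosine reports.  All downstream steps read the text artifacts written
here.
"""

import sys

sys.path.insert(0, __file__.rsplit("/", 1)[0])
import common  # noqa: E402

from hydroxymap import io  # noqa: E402
from hydroxymap import simulate as sim  # noqa: E402


def main() -> None:
    args = common.parse_args(__doc__)
    cfg = sim.TruthConfig(seed=args.seed)
    ref = sim.gen_reference(cfg)
    truth = sim.gen_truth(ref)
    err_tab = sim.AssayErrorModel()
    err_bs = sim.AssayErrorModel(mean_coverage=15.0)
    tab = sim.simulate_cytosine_reports(truth, err_tab, "TAB",
                                        seed=args.seed + 1)
    bs = sim.simulate_cytosine_reports(truth, err_bs, "BS",
                                       seed=args.seed + 2)

    io.write_fasta(ref.genome, common.results_path(args, "genome.fa"))
    io.write_refflat(ref.genes, common.results_path(args, "genes.refflat"))
    for name, track in ref.tracks.items():
        io.write_bed(track, common.results_path(args, f"track_{name}.bed"))
    common.write_tsv(ref.expression, args, "expression_counts.tsv")
    common.write_tsv(truth, args, "truth.tsv")
    io.write_cx_report(tab, common.results_path(args, "tab.cx.tsv"))
    io.write_cx_report(bs, common.results_path(args, "bs.cx.tsv"))
    common.write_json(
        {
            "seed": args.seed,
            "n_chroms": cfg.n_chroms,
            "chrom_len": cfg.chrom_len,
            "n_genes": cfg.n_genes,
            "total_mapped": ref.total_mapped,
            "n_truth_sites": len(truth),
        },
        args,
        "simulation_manifest.json",
    )


if __name__ == "__main__":
    main()
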