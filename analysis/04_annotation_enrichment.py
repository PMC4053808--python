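#!/usr/bin/env python
"""Step 04: genomic-element derivation, enrichment and element levels.

Derives active/poised enhancers from the simulated H3K4me1/H3K27ac
tracks, assigns every CpG to an element, computes fold enrichment of the
hmC_high category per element, pooled element-level modification, and
the in-silico MspI reduced-representation panel.
"""

import sys

sys.path.insert(0, __file__.rsplit("/", 1)[0])
import common  # noqa: E402

from hydroxymap import elements, io  # noqa: E402


def main() -> None:
    args = common.parse_args(__doc__)
    genes = io.read_refflat(common.results_path(args, "genes.refflat"))
    k4 = io.read_bed(common.results_path(args, "track_h3k4me1.bed"))
    k27 = io.read_bed(common.results_path(args, "track_h3k27ac.bed"))
    rec = common.read_tsv(args, "cpg_records.tsv")

    tss = elements.tss_positions(genes)
    active, poised = elements.derive_enhancers(k4, k27, tss)
    io.write_bed(active, common.results_path(args, "enhancers_active.bed"))
    io.write_bed(poised, common.results_path(args, "enhancers_poised.bed"))

    tracks = elements.genic_tracks(genes)
    tracks["enhancer_active"] = active
    tracks["enhancer_poised"] = poised
    labels = elements.assign_elements(rec, tracks)

    for category in ("hmC_high", "hmC_low", "hmC_no"):
        mask = rec["hmc_class"] == category
        if mask.sum() == 0:
            continue
        enr = elements.fold_enrichment(labels[mask], labels)
        common.write_tsv(enr, args, f"enrichment_{category}.tsv")

    common.write_tsv(elements.element_levels(rec, labels), args,
                     "element_levels.tsv")

    genome = io.read_fasta(common.results_path(args, "genome.fa"))
    frags = elements.msp1_fragments(genome)
    io.write_bed(frags, common.results_path(args, "msp1_panel.bed"))
    panel_mask = elements.in_panel(rec, frags)
    common.write_json(
        {
            "n_active_enhancers": len(active),
            "n_poised_enhancers": len(poised),
            "n_msp1_fragments": len(frags),
            "fraction_cpgs_in_msp1_panel": float(panel_mask.mean()),
        },
        args,
        "elements_summary.json",
    )


if __name__ == "__main__":
    main()
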