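#!/usr/bin/env python
"""Step 03: per-CpG hmC/mC deconvolution, categorisation and a
two-sample differential-hmC contrast.

Joins the BS (modC) and TAB (hmC) reports per strand-CpG, subtracts to
get mC, classifies every CpG into the modC/hmC categories, and contrasts
against a second simulated sample with globally reduced hmC (an
"adult-like" comparator) to exercise the differential caller.
"""

import sys

sys.path.insert(0, __file__.rsplit("/", 1)[0])
import common  # noqa: E402

import pandas as pd  # noqa: E402

from hydroxymap import calls, deconv  # noqa: E402
from hydroxymap import simulate as sim  # noqa: E402


def main() -> None:
    args = common.parse_args(__doc__)
    tab = calls.read_cx_report(common.results_path(args, "tab.cx.tsv"))
    bs = calls.read_cx_report(common.results_path(args, "bs.cx.tsv"))
    called = common.read_tsv(args, "tab_called.tsv")

    rec = deconv.cpg_frequencies(bs, tab)
    called_map = called.set_index(["chrom", "pos", "strand"])["called"]
    keys = pd.MultiIndex.from_frame(rec[["chrom", "pos", "strand"]])
    rec = deconv.classify_records(
        rec, hmc_called=called_map.reindex(keys).fillna(False).to_numpy()
    )
    common.write_tsv(rec, args, "cpg_records.tsv")
    census = deconv.summarize_categories(rec)
    common.write_tsv(census, args, "categories.tsv")

    # comparator sample: same genome, hmC scaled down by half
    truth = common.read_tsv(args, "truth.tsv")
    truth_b = truth.copy()
    truth_b["f_hmc"] *= 0.5
    err = sim.AssayErrorModel(mean_coverage=15.0)
    tab_b = sim.simulate_cytosine_reports(truth_b, err, "TAB",
                                          seed=args.seed + 31)
    bs_b = sim.simulate_cytosine_reports(truth_b, err, "BS",
                                         seed=args.seed + 32)
    rec_b = deconv.cpg_frequencies(bs_b, tab_b)
    diff = deconv.differential_hmc(rec, rec_b, label="A > B")
    common.write_tsv(diff, args, "differential_hmc.tsv")
    common.write_json(
        {
            "n_cpg_records": len(rec),
            "n_differential_sites": len(diff),
            "census": census.set_index("category")["fraction"].to_dict(),
        },
        args,
        "deconv_summary.json",
    )


if __name__ == "__main__":
    main()
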