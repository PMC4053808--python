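#!/usr/bin/env python
"""Step 02: spike-in calibration and hmC calling.

Estimates non-conversion rates from the lambda and pUC19 spike-in
contigs, then tests every covered genomic cytosine in the TAB report
with an exact binomial upper tail against the spike-in background and
controls the FDR at 1% separately per (chromosome, context) stratum.
"""

import sys

sys.path.insert(0, __file__.rsplit("/", 1)[0])
import common  # noqa: E402

from hydroxymap import calls  # noqa: E402


def main() -> None:
    args = common.parse_args(__doc__)
    tab = calls.read_cx_report(common.results_path(args, "tab.cx.tsv"))
    bs = calls.read_cx_report(common.results_path(args, "bs.cx.tsv"))

    spike_tab = calls.spike_in_stats(tab, bs)
    spike_bs = calls.spike_in_stats(bs, bs)
    common.write_tsv(
        calls.calibration_table(spike_tab, spike_bs), args, "calibration.tsv"
    )

    called = calls.call_sites(tab, spike_tab.background_p0(), fdr=0.01)
    common.write_tsv(called, args, "tab_called.tsv")
    genomic = called[called["p_value"].notna()]
    common.write_json(
        {
            "background_p0": spike_tab.background_p0(),
            "protection_normalized": spike_tab.protection_normalized,
            "n_tested": int(len(genomic)),
            "n_called": int(genomic["called"].sum()),
            "n_called_cg": int(
                genomic.loc[genomic["context"] == "CG", "called"].sum()
            ),
        },
        args,
        "calling_summary.json",
    )


if __name__ == "__main__":
    main()
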