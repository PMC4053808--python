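#!/usr/bin/env python
"""Step 07: modification profiles anchored on chromatin features.

Sliding-window hmC/mC profiles (with category fractions and the hmC/mC
ratio) around active and poised enhancer midpoints, and scaled region
profiles across the H3K9me3-like repressive domains.
"""

import sys

sys.path.insert(0, __file__.rsplit("/", 1)[0])
import common  # noqa: E402

from hydroxymap import chromatin, io  # noqa: E402


def main() -> None:
    args = common.parse_args(__doc__)
    rec = common.read_tsv(args, "cpg_records.tsv")

    for kind in ("active", "poised"):
        track = io.read_bed(
            common.results_path(args, f"enhancers_{kind}.bed")
        )
        if track.empty:
            print(f"no {kind} enhancers; skipping profile")
            continue
        prof = chromatin.midpoint_profile(
            rec, track, flank=5000, width=50, step=25, with_categories=True
        )
        common.write_tsv(prof, args, f"enhancer_profile_{kind}.tsv")

    repressive = io.read_bed(common.results_path(args, "track_h3k9me3.bed"))
    rp = chromatin.region_profile(
        rec, repressive, bins=100, flank=10_000, flank_window=1_000,
        with_categories=True,
    )
    common.write_tsv(rp, args, "repressive_profile.tsv")

    body = rp[rp["segment"] == "body"]["hmc"].mean()
    flank = rp[rp["segment"] != "body"]["hmc"].mean()
    common.write_json(
        {
            "repressive_body_mean_hmc": float(body),
            "repressive_flank_mean_hmc": float(flank),
        },
        args,
        "chromatin_summary.json",
    )


if __name__ == "__main__":
    main()
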