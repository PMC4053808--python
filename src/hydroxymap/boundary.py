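"""Single-base exon-intron boundary profiles and 5'ss CpG analysis.

Position convention at the 5' splice site (transcript orientation): the
last exonic base is -1, the first intronic base (+1) is the G of the
invariant GT.  A CpG "at position p" has its C at p; the dinucleotide may
cross the boundary (a -1 CpG pairs with the +1 G).  At the 3' splice site
(intron -> exon) negative offsets are intronic (-1 is the G of the
invariant AG) and positive offsets exonic (+1 is the first exonic base).
Minus-strand genes are mapped into transcript coordinates before
averaging, so profiles are sense-strand quantities.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .deconv import MODC_HIGH_MIN, MODC_NO_MAX

SS_CPG_POSITIONS = (-2, -1, 4, 5)


def exon_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Flatten gene models into per-exon records in transcript order.

    ``kind`` is first/internal/last/single by transcript position;
    ``exon_idx`` counts in transcript orientation (0 = first exon).
    """
    rows = []
    for _, g in genes.iterrows():
        starts, ends = g["exon_starts"], g["exon_ends"]
        n = len(starts)
        for k in range(n):
            gk = k if g["strand"] == "+" else n - 1 - k
            if n == 1:
                kind = "single"
            elif k == 0:
                kind = "first"
            elif k == n - 1:
                kind = "last"
            else:
                kind = "internal"
            rows.append(
                {
                    "gene": g["gene"],
                    "transcript": g["transcript"],
                    "exon_id": f"{g['transcript']}:{k}",
                    "exon_idx": k,
                    "chrom": g["chrom"],
                    "strand": g["strand"],
                    "start": starts[gk],
                    "end": ends[gk],
                    "kind": kind,
                }
            )
    return pd.DataFrame(rows)


def _boundary_positions(
    exons: pd.DataFrame, boundary: str, offsets: np.ndarray
) -> pd.DataFrame:
    """Genomic 0-based positions of transcript-oriented offsets.

    Returns long-format (exon_id, chrom, strand, offset, gpos0).
    """
    frames = []
    for _, ex in exons.iterrows():
        if ex["strand"] == "+":
            if boundary == "5ss":
                g = np.where(offsets < 0, ex["end"] + offsets, ex["end"] + offsets - 1)
            else:  # 3ss
                g = np.where(offsets > 0, ex["start"] + offsets - 1, ex["start"] + offsets)
        else:
            if boundary == "5ss":
                g = np.where(offsets < 0, ex["start"] - offsets - 1, ex["start"] - offsets)
            else:
                g = np.where(offsets > 0, ex["end"] - offsets, ex["end"] - offsets - 1)
        frames.append(
            pd.DataFrame(
                {
                    "exon_id": ex["exon_id"],
                    "chrom": ex["chrom"],
                    "strand": ex["strand"],
                    "offset": offsets,
                    "gpos0": g,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def boundary_profile(
    cpg_records: pd.DataFrame,
    exons: pd.DataFrame,
    flank: int = 150,
    genome: Mapping[str, str] | None = None,
    kinds: tuple[str, ...] = ("internal",),
) -> pd.DataFrame:
    """Per-position mean hmC/mC/modC around exon boundaries.

    Averages per-site frequencies over covered sense-strand CpG cytosines
    at each transcript-oriented offset, for the exon->intron (5ss) and
    intron->exon (3ss) boundaries of the selected exon kinds.  When a
    genome is supplied, ``cpg_density`` is the fraction of exons with a
    CpG (its C) at that offset; otherwise it is the fraction with a
    deconvolved CpG record there.
    """
    sel = exons[exons["kind"].isin(kinds)]
    if sel.empty:
        raise ValueError(f"no exons of kind {kinds}")
    offsets = np.concatenate(
        [np.arange(-flank, 0), np.arange(1, flank + 1)]
    )
    rec = cpg_records[["chrom", "pos", "strand", "hmc", "mc", "modc"]]
    out_frames = []
    for boundary in ("5ss", "3ss"):
        grid = _boundary_positions(sel, boundary, offsets)
        grid["pos"] = grid["gpos0"] + 1
        merged = grid.merge(rec, on=["chrom", "pos", "strand"], how="left")
        grouped = merged.groupby("offset")
        prof = grouped.agg(
            n=("hmc", "count"),
            hmc=("hmc", "mean"),
            mc=("mc", "mean"),
            modc=("modc", "mean"),
        ).reset_index()
        n_exons = len(sel)
        if genome is not None:
            is_cpg = _cpg_at(genome, merged)
            density = (
                pd.Series(is_cpg, index=merged.index)
                .groupby(merged["offset"])
                .mean()
            )
        else:
            density = grouped["hmc"].apply(lambda s: s.notna().sum() / n_exons)
        prof["cpg_density"] = prof["offset"].map(density).astype(float)
        prof.insert(0, "boundary", boundary)
        out_frames.append(prof)
    return pd.concat(out_frames, ignore_index=True)


def _cpg_at(genome: Mapping[str, str], grid: pd.DataFrame) -> np.ndarray:
    """Whether the sense-strand base at gpos0 is the C of a CpG."""
    out = np.zeros(len(grid), dtype=bool)
    for chrom, sub in grid.groupby("chrom"):
        seq = genome[chrom]
        n = len(seq)
        g = sub["gpos0"].to_numpy()
        plus = sub["strand"].to_numpy() == "+"
        valid = (g >= 1) & (g < n - 1)
        vals = np.zeros(len(sub), dtype=bool)
        gv = g[valid]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_c_plus = (arr[gv] == ord("C")) & (arr[gv + 1] == ord("G"))
        is_c_minus = (arr[gv] == ord("G")) & (arr[gv - 1] == ord("C"))
        vals[valid] = np.where(plus[valid], is_c_plus, is_c_minus)
        out[sub.index] = vals
    return out


def detect_ss_cpg(
    genome: Mapping[str, str], exons: pd.DataFrame
) -> pd.DataFrame:
    """Find 5'ss CpGs at positions -2/-1/+4/+5 of each exon.

    A CpG at position p means the sense-strand base at p is C and the
    next base in transcript orientation is G; the -1 dinucleotide spans
    into the intron's +1 G.  All matching positions are recorded (long
    format: one row per exon x position, ``gpos0`` is the 0-based genomic
    position of the C).  Exons whose flank runs off the contig are
    skipped at the truncated positions.
    """
    rows = []
    for _, ex in exons.iterrows():
        seq = genome[ex["chrom"]]
        n = len(seq)
        for p in SS_CPG_POSITIONS:
            if ex["strand"] == "+":
                g = ex["end"] + p if p < 0 else ex["end"] + p - 1
                g_next = g + 1
            else:
                g = ex["start"] - p - 1 if p < 0 else ex["start"] - p
                g_next = g - 1
            if not (0 <= g < n and 0 <= g_next < n):
                continue
            if ex["strand"] == "+":
                is_cpg = seq[g] == "C" and seq[g_next] == "G"
            else:
                is_cpg = seq[g] == "G" and seq[g_next] == "C"
            if is_cpg:
                rows.append(
                    {
                        "exon_id": ex["exon_id"],
                        "gene": ex["gene"],
                        "chrom": ex["chrom"],
                        "strand": ex["strand"],
                        "ss_cpg_position": p,
                        "gpos0": g,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "exon_id", "gene", "chrom", "strand", "ss_cpg_position", "gpos0",
        ],
    )


def classify_ss_exons(
    ss_cpgs: pd.DataFrame, cpg_records: pd.DataFrame
) -> pd.DataFrame:
    """Modification-state class of each 5'ss CpG exon.

    The exon inherits the four-way class (mC_high, hmC_high, modC_low,
    modC_no) of its splice-site CpG; sense- and antisense-strand records
    of the dyad are merged coverage-weighted before classing.  Exons whose
    CpG is uncovered in either assay get class NA.
    """
    key = ["chrom", "pos", "strand"]
    rec = cpg_records.set_index(key)[["bs_u", "bs_t", "tab_u", "tab_t"]]
    rows = []
    for _, ss in ss_cpgs.iterrows():
        # the C of the CpG on the sense strand, plus its dyad partner
        if ss["strand"] == "+":
            sites = [(ss["chrom"], ss["gpos0"] + 1, "+"), (ss["chrom"], ss["gpos0"] + 2, "-")]
        else:
            sites = [(ss["chrom"], ss["gpos0"] + 1, "-"), (ss["chrom"], ss["gpos0"], "+")]
        bs_u = bs_t = tab_u = tab_t = 0
        for site in sites:
            if site in rec.index:
                r = rec.loc[site]
                bs_u += int(r["bs_u"])
                bs_t += int(r["bs_t"])
                tab_u += int(r["tab_u"])
                tab_t += int(r["tab_t"])
        if bs_t == 0 or tab_t == 0:
            category = None
        else:
            modc = bs_u / bs_t
            hmc = tab_u / tab_t
            mc = max(0.0, modc - hmc)
            if modc < MODC_NO_MAX:
                category = "modC_no"
            elif modc < MODC_HIGH_MIN:
                category = "modC_low"
            else:
                category = "hmC_high" if hmc > mc else "mC_high"
        row = dict(ss)
        row.update({"modc_cov": bs_t, "hmc_cov": tab_t, "ss_category": category})
        rows.append(row)
    return pd.DataFrame(rows)
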