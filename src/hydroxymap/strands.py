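"""Expression-stratified, strand-resolved gene-body methylation analysis.

The sense strand of a gene is the strand it is transcribed from, so for
minus-strand genes sense levels come from minus-strand cytosines.  Bias
sign conventions: hmC bias = sense - antisense, mC bias = antisense -
sense (both positive in transcribed genes).  Paired two-tailed Student's
t on per-gene strand differences is the default test; a one-tailed mode
is available.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

RPKM_EXPRESSED_MIN = 0.1


def rpkm(
    gene_counts: Mapping[str, int] | pd.Series,
    gene_models: pd.DataFrame,
    total_mapped: int | None = None,
) -> pd.DataFrame:
    """Expression table with RPKM and derived groups.

    RPKM = count / (exonic kb x total mapped reads in millions).  Genes
    with RPKM <= 0.1 are "not expressed"; expressed genes are split into
    equal-size tertiles (low/middle/high) and deciles 1-10 by RPKM rank.
    """
    counts = pd.Series(gene_counts, dtype=float)
    exonic_bp = gene_models.apply(
        lambda g: sum(e - s for s, e in zip(g["exon_starts"], g["exon_ends"])),
        axis=1,
    )
    exonic_bp.index = gene_models["gene"]
    if (exonic_bp <= 0).any():
        bad = exonic_bp.index[exonic_bp <= 0][0]
        raise ValueError(f"gene {bad} has zero-length exon model")
    if total_mapped is None:
        total_mapped = int(counts.sum())
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    genes = gene_models["gene"]
    counts = counts.reindex(genes).fillna(0.0)
    rpkm_vals = counts / (exonic_bp[genes] / 1e3) / (total_mapped / 1e6)
    df = pd.DataFrame(
        {"gene": genes, "count": counts.to_numpy(),
         "rpkm": rpkm_vals.to_numpy()}
    )
    expressed = df["rpkm"] > RPKM_EXPRESSED_MIN
    df["group"] = "not_expressed"
    if expressed.any():
        ranks = df.loc[expressed, "rpkm"].rank(method="first")
        n = int(expressed.sum())
        tertile = np.ceil(ranks / n * 3).astype(int)
        df.loc[expressed, "group"] = np.array(["low", "middle", "high"])[
            tertile - 1
        ]
        df.loc[expressed, "decile"] = np.ceil(ranks / n * 10).astype(int)
    df["decile"] = df.get("decile", pd.Series(index=df.index, dtype=float))
    return df


def gene_strand_levels(
    cpg_records: pd.DataFrame,
    gene_models: pd.DataFrame,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Per-gene pooled hmC/mC/modC levels on the sense and antisense strand.

    Pools CG cytosine counts between TSS and TTS separately per genomic
    strand, then maps strands to sense/antisense by the gene's strand.
    Genes with no covered CpG on a strand get NaN there and drop out of
    paired tests.
    """
    rec = cpg_records.sort_values(["chrom", "strand", "pos"])
    index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key, sub in rec.groupby(["chrom", "strand"], sort=False):
        index[key] = (sub["pos"].to_numpy(), sub.index.to_numpy())
    rows = []
    for _, g in gene_models.iterrows():
        levels = {}
        for genomic_strand in "+-":
            key = (g["chrom"], genomic_strand)
            label = "sense" if genomic_strand == g["strand"] else "antisense"
            if key not in index:
                levels[label] = (np.nan, np.nan, np.nan)
                continue
            pos, idx = index[key]
            lo, hi = np.searchsorted(pos, [g["tx_start"] + 1, g["tx_end"] + 1])
            sub = rec.loc[idx[lo:hi]]
            if mode == "pooled":
                if sub["tab_t"].sum() == 0 or sub["bs_t"].sum() == 0:
                    levels[label] = (np.nan, np.nan, np.nan)
                else:
                    hmc = sub["tab_u"].sum() / sub["tab_t"].sum()
                    modc = sub["bs_u"].sum() / sub["bs_t"].sum()
                    levels[label] = (hmc, max(0.0, modc - hmc), modc)
            elif mode == "per_site":
                if len(sub) == 0:
                    levels[label] = (np.nan, np.nan, np.nan)
                else:
                    levels[label] = (
                        sub["hmc"].mean(), sub["mc"].mean(), sub["modc"].mean()
                    )
            else:
                raise ValueError(f"unknown mode {mode!r}")
        rows.append(
            {
                "gene": g["gene"],
                "sense_hmc": levels["sense"][0],
                "antisense_hmc": levels["antisense"][0],
                "sense_mc": levels["sense"][1],
                "antisense_mc": levels["antisense"][1],
                "sense_modc": levels["sense"][2],
                "antisense_modc": levels["antisense"][2],
            }
        )
    return pd.DataFrame(rows)


def strand_bias_test(
    levels: pd.DataFrame,
    metric: str = "hmc",
    alternative: str = "two-sided",
) -> dict[str, float]:
    """Paired Student's t on per-gene sense/antisense differences.

    For hmC the bias is sense - antisense; for mC (and modC) it is
    antisense - sense.  ``alternative`` 'greater' tests bias > 0
    (one-tailed, as in figure-caption conventions).
    """
    sense = levels[f"sense_{metric}"]
    anti = levels[f"antisense_{metric}"]
    complete = sense.notna() & anti.notna()
    if complete.sum() < 2:
        raise ValueError("need at least two genes with both strands measured")
    diff = (sense - anti) if metric == "hmc" else (anti - sense)
    diff = diff[complete]
    if np.allclose(diff.std(ddof=1), 0.0) and np.allclose(diff.mean(), 0.0):
        t_stat, p = 0.0, 1.0
    else:
        res = stats.ttest_rel(
            diff, np.zeros(len(diff)), alternative=alternative
        )
        t_stat, p = float(res.statistic), float(res.pvalue)
    return {
        "mean_bias": float(diff.mean()),
        "t": t_stat,
        "p_value": p,
        "n": int(complete.sum()),
    }


def gene_body_profile(
    cpg_records: pd.DataFrame,
    gene_models: pd.DataFrame,
    bins: int = 100,
    flank_bp: int = 10_000,
    flank_window: int = 100,
) -> pd.DataFrame:
    """Scaled metagene profile per strand: gene bodies in ``bins`` equal
    bins, flanks in fixed windows.  Genes shorter than ``bins`` bp are
    excluded (count in ``df.attrs['n_excluded']``).

    Output rows: (segment in {upstream, body, downstream}, bin, strand in
    {sense, antisense}, pooled hmc/mc/modc, n sites).
    """
    rec = cpg_records.sort_values(["chrom", "strand", "pos"])
    index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key, sub in rec.groupby(["chrom", "strand"], sort=False):
        index[key] = (sub["pos"].to_numpy(), sub.index.to_numpy())
    n_flank = flank_bp // flank_window
    acc: dict[tuple[str, int, str], np.ndarray] = {}

    def _add(segment, b, label, sub):
        key = (segment, b, label)
        vals = acc.setdefault(key, np.zeros(5))
        vals += np.array(
            [sub["tab_u"].sum(), sub["tab_t"].sum(), sub["bs_u"].sum(),
             sub["bs_t"].sum(), len(sub)]
        )

    n_excluded = 0
    for _, g in gene_models.iterrows():
        length = g["tx_end"] - g["tx_start"]
        if length < bins:
            n_excluded += 1
            continue
        edges = g["tx_start"] + np.round(
            np.linspace(0, length, bins + 1)
        ).astype(int)
        for genomic_strand in "+-":
            key = (g["chrom"], genomic_strand)
            if key not in index:
                continue
            label = "sense" if genomic_strand == g["strand"] else "antisense"
            pos, idx = index[key]
            # body bins (bin order follows transcript orientation)
            for b in range(bins):
                lo, hi = np.searchsorted(
                    pos, [edges[b] + 1, edges[b + 1] + 1]
                )
                sub = rec.loc[idx[lo:hi]]
                tbin = b if g["strand"] == "+" else bins - 1 - b
                _add("body", tbin, label, sub)
            # flanks in transcript orientation
            for w in range(n_flank):
                if g["strand"] == "+":
                    up = (g["tx_start"] - (w + 1) * flank_window,
                          g["tx_start"] - w * flank_window)
                    down = (g["tx_end"] + w * flank_window,
                            g["tx_end"] + (w + 1) * flank_window)
                else:
                    up = (g["tx_end"] + w * flank_window,
                          g["tx_end"] + (w + 1) * flank_window)
                    down = (g["tx_start"] - (w + 1) * flank_window,
                            g["tx_start"] - w * flank_window)
                for segment, (s, e) in (("upstream", up), ("downstream", down)):
                    lo, hi = np.searchsorted(pos, [s + 1, e + 1])
                    sub = rec.loc[idx[lo:hi]]
                    _add(segment, w, label, sub)
    rows = []
    for (segment, b, label), (tab_u, tab_t, bs_u, bs_t, n) in sorted(acc.items()):
        hmc = tab_u / tab_t if tab_t else np.nan
        modc = bs_u / bs_t if bs_t else np.nan
        mc = max(0.0, modc - hmc) if tab_t and bs_t else np.nan
        rows.append(
            {"segment": segment, "bin": b, "strand": label, "n": int(n),
             "hmc": hmc, "mc": mc, "modc": modc}
        )
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    return out


def sas_regions(
    expression: pd.DataFrame,
    gene_models: pd.DataFrame,
    min_rpkm: float = 1.0,
) -> pd.DataFrame:
    """Sense-antisense paired regions: genomic intersection of expressed
    plus-strand gene bodies with expressed minus-strand gene bodies."""
    expr = expression.set_index("gene")["rpkm"]
    bodies = {"+": [], "-": []}
    for _, g in gene_models.iterrows():
        if expr.get(g["gene"], 0.0) >= min_rpkm:
            bodies[g["strand"]].append((g["chrom"], g["tx_start"], g["tx_end"]))
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in bodies["+"]:
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    rows = []
    for chrom, s, e in bodies["-"]:
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.overlap(s, e):
            rows.append((chrom, max(s, iv.begin), min(e, iv.end)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return out.sort_values(["chrom", "start"], ignore_index=True)


def restrict_to_regions(
    cpg_records: pd.DataFrame, regions: pd.DataFrame, invert: bool = False
) -> pd.DataFrame:
    """CpG records inside (or, with invert, outside) a region track."""
    trees: dict[str, IntervalTree] = {}
    for _, iv in regions.iterrows():
        trees.setdefault(iv["chrom"], IntervalTree()).addi(
            int(iv["start"]), int(iv["end"])
        )
    pos0 = cpg_records["pos"].to_numpy() - 1
    chroms = cpg_records["chrom"].to_numpy()
    inside = np.zeros(len(cpg_records), dtype=bool)
    for chrom in np.unique(chroms):
        tree = trees.get(chrom)
        if tree is None:
            continue
        sel = chroms == chrom
        inside[sel] = [bool(tree.overlap(p, p + 1)) for p in pos0[sel]]
    return cpg_records[~inside if invert else inside]


def sas_bias_contrast(
    cpg_records: pd.DataFrame,
    gene_models: pd.DataFrame,
    sas: pd.DataFrame,
    metric: str = "hmc",
) -> dict[str, float]:
    """Mean strand bias inside SAS regions vs in non-SAS gene bodies."""
    in_sas = restrict_to_regions(cpg_records, sas)
    out_sas = restrict_to_regions(cpg_records, sas, invert=True)
    bias = {}
    for name, rec in (("sas", in_sas), ("non_sas", out_sas)):
        levels = gene_strand_levels(rec, gene_models)
        sense = levels[f"sense_{metric}"]
        anti = levels[f"antisense_{metric}"]
        complete = sense.notna() & anti.notna()
        diff = (sense - anti) if metric == "hmc" else (anti - sense)
        bias[f"{name}_bias"] = float(diff[complete].mean()) if complete.any() else np.nan
        bias[f"{name}_n"] = int(complete.sum())
    return bias
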