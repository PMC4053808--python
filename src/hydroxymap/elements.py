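"""Genomic-element derivation, CpG assignment, enrichment and levels.

Enhancers are H3K4me1 peaks distal to every TSS (beyond +/- 2.5 kb),
split into active (overlapping an H3K27ac peak) and poised (H3K4me1
alone).  Fold enrichment of a CpG category at an element is the observed
fraction of category CpGs there divided by the expected fraction of all
captured CpGs.  Element-level modification is pooled (read-weighted) by
default, matching the %hmC definition over a region; a per-site-averaged
mode is provided.  An in-silico MspI digest (cut at C^CGG) with fragment
size selection reproduces the reduced-representation capture panel.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

DEFAULT_PRECEDENCE = [
    "promoter",
    "enhancer_active",
    "enhancer_poised",
    "exon",
    "intron",
]
INTERGENIC = "intergenic"


def build_trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.groupby("chrom"):
        tree = IntervalTree()
        for s, e in zip(sub["start"], sub["end"]):
            if e > s:
                tree.addi(int(s), int(e))
        trees[chrom] = tree
    return trees


def _overlaps(trees: Mapping[str, IntervalTree], chrom: str, start: int, end: int) -> bool:
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlap(start, end))


def genic_tracks(genes: pd.DataFrame, promoter_bp: int = 1000) -> dict[str, pd.DataFrame]:
    """Promoter (TSS +/- promoter_bp), exon and intron tracks from gene models."""
    promoters, exons, introns = [], [], []
    for _, g in genes.iterrows():
        tss = g["tx_start"] if g["strand"] == "+" else g["tx_end"] - 1
        promoters.append((g["chrom"], max(0, tss - promoter_bp), tss + promoter_bp + 1))
        starts, ends = g["exon_starts"], g["exon_ends"]
        for s, e in zip(starts, ends):
            exons.append((g["chrom"], s, e))
        for e_prev, s_next in zip(ends[:-1], starts[1:]):
            introns.append((g["chrom"], e_prev, s_next))
    cols = ["chrom", "start", "end"]
    return {
        "promoter": pd.DataFrame(promoters, columns=cols),
        "exon": pd.DataFrame(exons, columns=cols),
        "intron": pd.DataFrame(introns, columns=cols),
    }


def tss_positions(genes: pd.DataFrame) -> pd.DataFrame:
    tss = np.where(genes["strand"] == "+", genes["tx_start"], genes["tx_end"] - 1)
    return pd.DataFrame({"chrom": genes["chrom"], "pos": tss})


def derive_enhancers(
    h3k4me1: pd.DataFrame,
    h3k27ac: pd.DataFrame | None,
    tss: pd.DataFrame,
    distal_bp: int = 2500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split distal H3K4me1 peaks into active/poised enhancer tracks.

    A peak overlapping any TSS +/- ``distal_bp`` window is discarded.
    The remaining peaks are active when they overlap an H3K27ac peak,
    poised otherwise; the two outputs are disjoint and their union is the
    distal peak set.
    """
    if h3k4me1.empty:
        warnings.warn("empty H3K4me1 track: no enhancers derived")
        empty = h3k4me1.iloc[0:0]
        return empty.copy(), empty.copy()
    tss_iv = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": np.maximum(0, tss["pos"] - distal_bp),
            "end": tss["pos"] + distal_bp + 1,
        }
    )
    tss_trees = build_trees(tss_iv)
    ac_trees = build_trees(h3k27ac) if h3k27ac is not None else {}
    active_rows, poised_rows = [], []
    for _, peak in h3k4me1.iterrows():
        if _overlaps(tss_trees, peak["chrom"], peak["start"], peak["end"]):
            continue
        if _overlaps(ac_trees, peak["chrom"], peak["start"], peak["end"]):
            active_rows.append(peak)
        else:
            poised_rows.append(peak)
    cols = ["chrom", "start", "end"]
    active = pd.DataFrame(active_rows, columns=cols).reset_index(drop=True)
    poised = pd.DataFrame(poised_rows, columns=cols).reset_index(drop=True)
    return active, poised


def assign_elements(
    cpgs: pd.DataFrame,
    tracks: Mapping[str, pd.DataFrame],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    mode: str = "exclusive",
) -> pd.Series | pd.DataFrame:
    """Assign each CpG to genomic element(s).

    In ``exclusive`` mode each CpG gets the first matching element in
    precedence order (unmatched CpGs are labelled intergenic) and a Series
    of labels is returned.  In ``overlay`` mode a boolean DataFrame with
    one column per track is returned (all matches).  CpG positions are
    1-based; tracks are half-open 0-based.
    """
    trees = {name: build_trees(df) for name, df in tracks.items()}
    pos0 = cpgs["pos"].to_numpy() - 1
    chroms = cpgs["chrom"].to_numpy()
    hit = {}
    for name in tracks:
        tr = trees[name]
        hits = np.zeros(len(cpgs), dtype=bool)
        for chrom in np.unique(chroms):
            tree = tr.get(chrom)
            if tree is None:
                continue
            sel = chroms == chrom
            hits[sel] = [bool(tree.overlap(p, p + 1)) for p in pos0[sel]]
        hit[name] = hits
    overlay = pd.DataFrame(hit, index=cpgs.index)
    if mode == "overlay":
        return overlay
    if mode != "exclusive":
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.full(len(cpgs), INTERGENIC, dtype=object)
    for name in reversed([p for p in precedence if p in overlay.columns]):
        labels[overlay[name].to_numpy()] = name
    return pd.Series(labels, index=cpgs.index, name="element")


class EmptyCategoryError(ValueError):
    pass


def fold_enrichment(
    category_labels: pd.Series,
    all_labels: pd.Series,
) -> pd.DataFrame:
    """Observed/expected fold enrichment per element.

    Both inputs are per-CpG element labels (e.g. from
    :func:`assign_elements` exclusive mode) for the category CpGs and for
    all captured CpGs.  Folds are reported only for elements with a
    nonzero expected fraction.
    """
    if len(category_labels) == 0:
        raise EmptyCategoryError("empty CpG category")
    obs = category_labels.value_counts(normalize=True)
    exp = all_labels.value_counts(normalize=True)
    rows = []
    for element, expected in exp.items():
        observed = float(obs.get(element, 0.0))
        rows.append(
            {
                "element": element,
                "n_category": int((category_labels == element).sum()),
                "observed": observed,
                "expected": float(expected),
                "fold": observed / expected,
            }
        )
    return pd.DataFrame(rows)


def element_levels(
    records: pd.DataFrame,
    labels: pd.Series,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Per-element mean hmC/mC/modC levels.

    ``pooled`` divides summed unconverted reads by summed coverage over
    the element's CpGs (read-weighted, the %level definition over a
    region); ``per_site`` averages per-site frequencies.  The element mC
    level is the pooled modC level minus the pooled hmC level, clipped at
    zero.  Elements with no covered CpGs are reported as missing.
    """
    rows = []
    for element in labels.unique():
        sub = records.loc[labels == element]
        if mode == "pooled":
            tab_t, bs_t = sub["tab_t"].sum(), sub["bs_t"].sum()
            if tab_t == 0 or bs_t == 0:
                hmc = mc = modc = np.nan
            else:
                hmc = float(sub["tab_u"].sum() / tab_t)
                modc = float(sub["bs_u"].sum() / bs_t)
                mc = max(0.0, modc - hmc)
        elif mode == "per_site":
            if len(sub) == 0:
                hmc = mc = modc = np.nan
            else:
                hmc = float(sub["hmc"].mean())
                modc = float(sub["modc"].mean())
                mc = float(sub["mc"].mean())
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append(
            {"element": element, "n_cpg": len(sub), "hmc": hmc, "mc": mc,
             "modc": modc}
        )
    return pd.DataFrame(rows)


def msp1_fragments(
    genome: Mapping[str, str],
    min_len: int = 40,
    max_len: int = 220,
) -> pd.DataFrame:
    """In-silico MspI digest with fragment size selection.

    MspI cuts C^CGG: each CCGG occurrence at 0-based offset i yields a cut
    between i and i+1.  Fragments with min_len <= length <= max_len are
    retained (half-open 0-based coordinates).
    """
    rows = []
    for chrom, seq in genome.items():
        cuts = [0]
        start = seq.find("CCGG")
        while start != -1:
            cuts.append(start + 1)
            start = seq.find("CCGG", start + 1)
        cuts.append(len(seq))
        for s, e in zip(cuts[:-1], cuts[1:]):
            if min_len <= e - s <= max_len:
                rows.append((chrom, s, e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def in_panel(cpgs: pd.DataFrame, fragments: pd.DataFrame) -> np.ndarray:
    """Boolean mask of CpGs falling inside retained fragments."""
    trees = build_trees(fragments)
    pos0 = cpgs["pos"].to_numpy() - 1
    chroms = cpgs["chrom"].to_numpy()
    out = np.zeros(len(cpgs), dtype=bool)
    for chrom in np.unique(chroms):
        tree = trees.get(chrom)
        if tree is None:
            continue
        sel = chroms == chrom
        out[sel] = [bool(tree.overlap(p, p + 1)) for p in pos0[sel]]
    return out
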