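"""Profiles of DNA modification anchored on chromatin features.

Two anchorings: sliding windows around interval midpoints (enhancer
peaks; default +/- 5 kb, 50-bp windows in 25-bp steps) and scaled
region profiles (repressive domains; 100 equal bins plus fixed-width
flank windows).  Window levels are pooled (read-weighted); the hmC/mC
ratio is computed from the pooled window levels, not averaged per-site
ratios, and is reported missing when the pooled mC level is zero.
Category fractions (hmC_high, mC_high, modC_low and the mC_all grouping)
are relative to all CpGs in the window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORY_COLUMNS = ("frac_hmc_high", "frac_mc_high", "frac_mc_all", "frac_modc_low")


def _category_masks(records: pd.DataFrame) -> dict[str, np.ndarray]:
    """Boolean masks for the profiled CpG categories.

    mC_high is the hmC_low + hmC_no grouping of highly modified CpGs;
    mC_all additionally requires nothing beyond modC_high without hmC
    dominance, i.e. it aliases mC_high here (the union of hmC_low and
    hmC_no already covers every non-hmC_high modC_high site).
    """
    modc_class = records.get("modc_class")
    hmc_class = records.get("hmc_class")
    if modc_class is None or hmc_class is None:
        raise ValueError("records must carry modc_class/hmc_class columns")
    modc_class = modc_class.to_numpy()
    hmc_class = hmc_class.to_numpy()
    high = modc_class == "modC_high"
    hmc_high = high & (hmc_class == "hmC_high")
    mc_high = high & ~(hmc_class == "hmC_high")
    return {
        "frac_hmc_high": hmc_high,
        "frac_mc_high": mc_high,
        "frac_mc_all": mc_high,
        "frac_modc_low": modc_class == "modC_low",
    }


def _pooled_row(sub: pd.DataFrame, masks: dict[str, np.ndarray] | None,
                rows_mask: np.ndarray | None) -> dict[str, float]:
    out: dict[str, float] = {"n": len(sub)}
    tab_t, bs_t = sub["tab_t"].sum(), sub["bs_t"].sum()
    if tab_t and bs_t:
        hmc = float(sub["tab_u"].sum() / tab_t)
        modc = float(sub["bs_u"].sum() / bs_t)
        mc = max(0.0, modc - hmc)
        out.update(hmc=hmc, mc=mc, modc=modc,
                   ratio=hmc / mc if mc > 0 else np.nan)
    else:
        out.update(hmc=np.nan, mc=np.nan, modc=np.nan, ratio=np.nan)
    if masks is not None:
        for name, mask in masks.items():
            hit = mask[rows_mask]
            out[name] = float(hit.mean()) if len(hit) else np.nan
    return out


def window_grid(flank: int, width: int, step: int) -> np.ndarray:
    """Start offsets of sliding windows covering [-flank, +flank]."""
    return np.arange(-flank, flank - width + step, step)


def midpoint_profile(
    cpg_records: pd.DataFrame,
    intervals: pd.DataFrame,
    flank: int = 5000,
    width: int = 50,
    step: int = 25,
    with_categories: bool = False,
) -> pd.DataFrame:
    """Pooled modification profile around interval midpoints.

    Windows of ``width`` bp slide in ``step`` bp increments across
    +/- ``flank`` around each interval's midpoint; a CpG contributes to
    every window covering it (windows overlap by width - step).
    """
    if intervals.empty:
        raise ValueError("empty interval track")
    rec = cpg_records.sort_values(["chrom", "pos"])
    by_chrom = {
        chrom: (sub["pos"].to_numpy(), sub.index.to_numpy())
        for chrom, sub in rec.groupby("chrom", sort=False)
    }
    masks = _category_masks(rec) if with_categories else None
    starts = window_grid(flank, width, step)
    # offset -> list of row indices
    gathered: dict[int, list[np.ndarray]] = {int(s): [] for s in starts}
    for _, iv in intervals.iterrows():
        if iv["chrom"] not in by_chrom:
            continue
        pos, idx = by_chrom[iv["chrom"]]
        mid = (int(iv["start"]) + int(iv["end"])) // 2
        for s in starts:
            w_lo = mid + int(s)  # 0-based window [w_lo, w_lo + width)
            lo, hi = np.searchsorted(pos, [w_lo + 1, w_lo + width + 1])
            gathered[int(s)].append(idx[lo:hi])
    rows = []
    for s in starts:
        rowset = np.concatenate(gathered[int(s)]) if gathered[int(s)] else np.array([], dtype=int)
        sub = rec.loc[rowset]
        if masks is not None:
            rows_mask = rec.index.get_indexer(rowset)
        else:
            rows_mask = None
        entry = {"offset": int(s)}
        entry.update(_pooled_row(sub, masks, rows_mask))
        rows.append(entry)
    return pd.DataFrame(rows)


def region_profile(
    cpg_records: pd.DataFrame,
    regions: pd.DataFrame,
    bins: int = 100,
    flank: int = 10_000,
    flank_window: int = 1_000,
    with_categories: bool = False,
) -> pd.DataFrame:
    """Scaled profile across regions: ``bins`` equal bins per region plus
    fixed flank windows.  Regions shorter than ``bins`` bp are excluded;
    the count is in ``df.attrs['n_excluded']``."""
    rec = cpg_records.sort_values(["chrom", "pos"])
    by_chrom = {
        chrom: (sub["pos"].to_numpy(), sub.index.to_numpy())
        for chrom, sub in rec.groupby("chrom", sort=False)
    }
    masks = _category_masks(rec) if with_categories else None
    n_flank = flank // flank_window
    gathered: dict[tuple[str, int], list[np.ndarray]] = {}
    n_excluded = 0
    n_used = 0
    for _, rg in regions.iterrows():
        length = int(rg["end"]) - int(rg["start"])
        if length < bins:
            n_excluded += 1
            continue
        if rg["chrom"] not in by_chrom:
            continue
        n_used += 1
        pos, idx = by_chrom[rg["chrom"]]
        edges = int(rg["start"]) + np.round(np.linspace(0, length, bins + 1)).astype(int)
        for b in range(bins):
            lo, hi = np.searchsorted(pos, [edges[b] + 1, edges[b + 1] + 1])
            gathered.setdefault(("body", b), []).append(idx[lo:hi])
        for w in range(n_flank):
            up = (int(rg["start"]) - (w + 1) * flank_window,
                  int(rg["start"]) - w * flank_window)
            down = (int(rg["end"]) + w * flank_window,
                    int(rg["end"]) + (w + 1) * flank_window)
            for segment, (s, e) in (("upstream", up), ("downstream", down)):
                lo, hi = np.searchsorted(pos, [s + 1, e + 1])
                gathered.setdefault((segment, w), []).append(idx[lo:hi])
    if n_used == 0:
        raise ValueError("no usable regions (all shorter than bins or off-genome)")
    rows = []
    for (segment, b), chunks in sorted(gathered.items()):
        rowset = np.concatenate(chunks) if chunks else np.array([], dtype=int)
        sub = rec.loc[rowset]
        rows_mask = rec.index.get_indexer(rowset) if masks is not None else None
        entry = {"segment": segment, "bin": b}
        entry.update(_pooled_row(sub, masks, rows_mask))
        rows.append(entry)
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    return out
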