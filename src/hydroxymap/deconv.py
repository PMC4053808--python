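"""Per-CpG hmC/mC deconvolution and categorisation.

BS-Seq measures total modification (modC = hmC + mC); TAB-Seq measures hmC
alone.  The per-site mC frequency is the difference of the two observed
frequencies, clipped at zero since sampling noise can push it negative.

Categories (thresholds on the modC frequency, hmC-vs-mC dominance within
the highly modified class):

* modC_no   : modC < 0.10
* modC_low  : 0.10 <= modC < 0.50
* modC_high : modC >= 0.50, subdivided into
    - hmC_no   : no significant hmC call (or hmC == 0 in threshold mode)
    - hmC_high : hmC > mC
    - hmC_low  : hmC <= mC
* mC_high   : convenience grouping hmC_low + hmC_no (highly methylated)

Units are strand-resolved CpG cytosines; a dyad-merging mode is available
for analyses that pool the two strands.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MODC_NO_MAX = 0.10
MODC_HIGH_MIN = 0.50

MODC_CLASSES = ("modC_no", "modC_low", "modC_high")
HMC_CLASSES = ("hmC_high", "hmC_low", "hmC_no")


class EmptyInputError(ValueError):
    pass


def cpg_frequencies(
    bs_calls: pd.DataFrame,
    tab_calls: pd.DataFrame,
    min_cov: int = 1,
) -> pd.DataFrame:
    """Join the two assays on (chrom, pos, strand) and deconvolve.

    Only CG-context sites are used; a record is emitted only when both
    assays reach ``min_cov`` reads.  Returned columns keep the raw counts
    (bs_u/bs_t/tab_u/tab_t) so that pooled, read-weighted region levels
    can be recomputed downstream.  Sites present in one assay only are
    dropped; their number is available via ``df.attrs['n_dropped']``.
    """
    key = ["chrom", "pos", "strand"]
    bs = bs_calls.loc[bs_calls["context"] == "CG", key + ["n_unconverted", "n_total"]]
    tab = tab_calls.loc[tab_calls["context"] == "CG", key + ["n_unconverted", "n_total"]]
    merged = bs.merge(tab, on=key, how="outer", suffixes=("_bs", "_tab"),
                      indicator=True)
    n_dropped = int((merged["_merge"] != "both").sum())
    merged = merged[merged["_merge"] == "both"].drop(columns="_merge")
    merged = merged.rename(
        columns={
            "n_unconverted_bs": "bs_u",
            "n_total_bs": "bs_t",
            "n_unconverted_tab": "tab_u",
            "n_total_tab": "tab_t",
        }
    )
    merged = merged[(merged["bs_t"] >= min_cov) & (merged["tab_t"] >= min_cov)]
    merged = merged[(merged["bs_t"] > 0) & (merged["tab_t"] > 0)]
    merged["modc"] = merged["bs_u"] / merged["bs_t"]
    merged["hmc"] = merged["tab_u"] / merged["tab_t"]
    merged["mc"] = np.clip(merged["modc"] - merged["hmc"], 0.0, 1.0)
    merged = merged.sort_values(["chrom", "pos", "strand"], ignore_index=True)
    merged.attrs["n_dropped"] = n_dropped
    return merged


def merge_dyads(records: pd.DataFrame) -> pd.DataFrame:
    """Coverage-weighted merge of the two strands of each CpG dyad.

    The plus-strand C and the minus-strand C of a dyad sit one base apart
    (minus position = plus position + 1); the merged record is keyed by the
    plus-strand position.
    """
    rec = records.copy()
    dyad_pos = np.where(rec["strand"] == "+", rec["pos"], rec["pos"] - 1)
    rec["dyad_pos"] = dyad_pos
    agg = rec.groupby(["chrom", "dyad_pos"], as_index=False)[
        ["bs_u", "bs_t", "tab_u", "tab_t"]
    ].sum()
    agg = agg.rename(columns={"dyad_pos": "pos"})
    agg["strand"] = "."
    agg["modc"] = agg["bs_u"] / agg["bs_t"]
    agg["hmc"] = agg["tab_u"] / agg["tab_t"]
    agg["mc"] = np.clip(agg["modc"] - agg["hmc"], 0.0, 1.0)
    return agg


def classify_cpg(
    modc: float, hmc: float, mc: float, hmc_called: bool | None = None
) -> tuple[str, str | None]:
    """Classify a single CpG record.

    ``hmc_called`` carries the FDR-controlled significance of the TAB
    signal; when None the threshold-only fallback (hmC_no iff hmc == 0)
    is used.  Ties hmC == mC fall to hmC_low (strict hmC > mC rule).
    """
    if modc < MODC_NO_MAX:
        return "modC_no", None
    if modc < MODC_HIGH_MIN:
        return "modC_low", None
    no_hmc = (not hmc_called) if hmc_called is not None else hmc == 0.0
    if no_hmc:
        return "modC_high", "hmC_no"
    return "modC_high", ("hmC_high" if hmc > mc else "hmC_low")


def classify_records(
    records: pd.DataFrame, hmc_called: pd.Series | np.ndarray | None = None
) -> pd.DataFrame:
    """Vectorised classification; adds modc_class and hmc_class columns."""
    rec = records.copy()
    modc = rec["modc"].to_numpy()
    hmc = rec["hmc"].to_numpy()
    mc = rec["mc"].to_numpy()
    modc_class = np.where(
        modc < MODC_NO_MAX,
        "modC_no",
        np.where(modc < MODC_HIGH_MIN, "modC_low", "modC_high"),
    )
    if hmc_called is None:
        no_hmc = hmc == 0.0
    else:
        no_hmc = ~np.asarray(hmc_called, dtype=bool)
    hmc_class = np.where(no_hmc, "hmC_no", np.where(hmc > mc, "hmC_high", "hmC_low"))
    hmc_class = np.where(modc_class == "modC_high", hmc_class, None)
    rec["modc_class"] = modc_class
    rec["hmc_class"] = hmc_class
    return rec


def category_label(rec_row: pd.Series) -> str:
    """Four-way label used in the splice-site analyses.

    hmC_high stays; hmC_low and hmC_no collapse to mC_high; modC_low and
    modC_no stay.
    """
    if rec_row["modc_class"] != "modC_high":
        return rec_row["modc_class"]
    return "hmC_high" if rec_row["hmc_class"] == "hmC_high" else "mC_high"


def summarize_categories(records: pd.DataFrame) -> pd.DataFrame:
    """Category census: fractions of all captured CpGs.

    modC-class fractions sum to 1; hmC subclass fractions are reported
    against all captured CpGs (so the three subclass fractions sum to the
    modC_high fraction).
    """
    if len(records) == 0:
        raise EmptyInputError("no CpG records to summarise")
    n = len(records)
    rows = []
    for cls in MODC_CLASSES:
        cnt = int((records["modc_class"] == cls).sum())
        rows.append({"category": cls, "n": cnt, "fraction": cnt / n})
    for cls in HMC_CLASSES:
        cnt = int((records["hmc_class"] == cls).sum())
        rows.append({"category": cls, "n": cnt, "fraction": cnt / n})
    return pd.DataFrame(rows)


def differential_hmc(
    sample_a: pd.DataFrame,
    sample_b: pd.DataFrame,
    min_cov: int = 10,
    min_diff: float = 0.3,
    label: str = "A > B",
) -> pd.DataFrame:
    """Sites with higher hmC in sample A than B.

    A site qualifies iff both assays' TAB coverage reaches ``min_cov`` in
    both samples and hmc(A) - hmc(B) >= ``min_diff``.
    """
    key = ["chrom", "pos", "strand"]
    joined = sample_a[key + ["tab_t", "hmc"]].merge(
        sample_b[key + ["tab_t", "hmc"]], on=key, suffixes=("_a", "_b")
    )
    if joined.empty:
        raise ValueError("samples share no CpG sites; mismatched genomes?")
    keep = (
        (joined["tab_t_a"] >= min_cov)
        & (joined["tab_t_b"] >= min_cov)
        & (joined["hmc_a"] - joined["hmc_b"] >= min_diff)
    )
    out = joined[keep].copy()
    out["diff"] = out["hmc_a"] - out["hmc_b"]
    out["direction"] = label
    return out.reset_index(drop=True)
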