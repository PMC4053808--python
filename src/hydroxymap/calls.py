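"""Cytosine-report parsing, spike-in calibration and modification calling.

Calling follows the standard base-resolution bisulfite workflow: each
covered cytosine gets an exact upper-tail binomial p-value against the
spike-in-estimated background non-conversion rate, and significance is
assessed with Benjamini-Hochberg FDR control applied separately within
each (chromosome, context) stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CX_COLUMNS, ParseError
from .simulate import LAMBDA_NAME, PUC19_NAME, SPIKE_IN_NAMES


class CalibrationError(ValueError):
    """Spike-in contigs missing or without usable coverage."""


@dataclass
class SpikeInStats:
    """Spike-in-derived non-conversion rates for one assay pair.

    ncr_c:   unmodified-C non-conversion (lambda, non-CpG sites).
    ncr_mc:  mC non-conversion (lambda, CpG sites).
    ncr_hmc: hmC non-conversion, i.e. protection (pUC19, all cytosines).
    bs_ncr_hmc: the BS-Seq pUC19 rate used for normalisation.
    protection_normalized: TAB ncr_hmc / BS ncr_hmc, clipped at 1.
    """

    ncr_c: float
    ncr_mc: float
    ncr_hmc: float
    bs_ncr_hmc: float
    protection_normalized: float

    def background_p0(self) -> float:
        """Conservative TAB-Seq background for hmC calling.

        Residual mC signal is the dominant TAB error mode, so the larger
        of the unmodified-C and mC non-conversion rates is used.
        """
        return max(self.ncr_c, self.ncr_mc)


def read_cx_report(path: str) -> pd.DataFrame:
    """Parse a 7-column CX report into a call table.

    Adds ``n_unconverted``/``n_total`` and a ``zero_coverage`` flag;
    zero-coverage rows are retained.  Malformed rows raise ParseError
    naming the first offending line.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CX_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str,
                   "trinucleotide": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error paths vary
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] != len(CX_COLUMNS):
        raise ParseError(f"{path}: expected {len(CX_COLUMNS)} columns")
    for col in ("pos", "count_unconverted", "count_converted"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.astype("Int64").astype(float))
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(
                f"{path}: non-integer value in column {col!r} at line {line}"
            )
        df[col] = numeric.astype(int)
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(bad_strand.idxmax()) + 1
        raise ParseError(f"{path}: strand not in {{+,-}} at line {line}")
    bad_ctx = ~df["context"].isin(["CG", "CHG", "CHH"])
    if bad_ctx.any():
        line = int(bad_ctx.idxmax()) + 1
        raise ParseError(f"{path}: unknown context at line {line}")
    if (df["count_unconverted"] < 0).any() or (df["count_converted"] < 0).any():
        raise ParseError(f"{path}: negative read count")
    df["n_unconverted"] = df["count_unconverted"]
    df["n_total"] = df["count_unconverted"] + df["count_converted"]
    df["zero_coverage"] = df["n_total"] == 0
    return df.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def _pooled_rate(calls: pd.DataFrame, mask: pd.Series, what: str) -> float:
    sub = calls.loc[mask]
    total = int(sub["n_total"].sum())
    if total == 0:
        raise CalibrationError(f"no covered cytosines for {what}")
    return float(sub["n_unconverted"].sum()) / total


def spike_in_stats(
    tab_calls: pd.DataFrame,
    bs_calls: pd.DataFrame,
    lambda_name: str = LAMBDA_NAME,
    puc19_name: str = PUC19_NAME,
) -> SpikeInStats:
    """Estimate non-conversion rates from the spike-in contigs.

    ncr_c is the pooled unconverted fraction over lambda non-CpG sites,
    ncr_mc over lambda CpG sites, ncr_hmc over all pUC19 cytosines; the
    normalized protection rate divides the TAB pUC19 rate by the BS one
    (clipped at 1).
    """
    for name, calls in (("TAB", tab_calls), ("BS", bs_calls)):
        present = set(calls["chrom"].unique())
        missing = {lambda_name, puc19_name} - present
        if missing:
            raise CalibrationError(
                f"{name} calls lack spike-in contig(s): {sorted(missing)}"
            )
    lam_tab = tab_calls["chrom"] == lambda_name
    ncr_c = _pooled_rate(
        tab_calls, lam_tab & (tab_calls["context"] != "CG"), "lambda non-CG"
    )
    ncr_mc = _pooled_rate(
        tab_calls, lam_tab & (tab_calls["context"] == "CG"), "lambda CG"
    )
    ncr_hmc = _pooled_rate(
        tab_calls, tab_calls["chrom"] == puc19_name, "pUC19 (TAB)"
    )
    bs_ncr_hmc = _pooled_rate(
        bs_calls, bs_calls["chrom"] == puc19_name, "pUC19 (BS)"
    )
    if bs_ncr_hmc == 0:
        raise CalibrationError("BS pUC19 non-conversion rate is zero")
    protection = min(1.0, ncr_hmc / bs_ncr_hmc)
    return SpikeInStats(
        ncr_c=ncr_c,
        ncr_mc=ncr_mc,
        ncr_hmc=ncr_hmc,
        bs_ncr_hmc=bs_ncr_hmc,
        protection_normalized=protection,
    )


def calibration_table(tab: SpikeInStats, bs: SpikeInStats | None = None) -> pd.DataFrame:
    """Calibration summary in the conventional one-row-per-assay layout."""
    rows = [{"assay": "TAB", "ncr_C": tab.ncr_c, "ncr_mC": tab.ncr_mc,
             "ncr_hmC": tab.ncr_hmc,
             "protection_normalized": tab.protection_normalized}]
    if bs is not None:
        rows.append({"assay": "BS", "ncr_C": bs.ncr_c, "ncr_mC": bs.ncr_mc,
                     "ncr_hmC": bs.ncr_hmc,
                     "protection_normalized": np.nan})
    return pd.DataFrame(rows)


def binomial_p(
    n_unconverted: int | np.ndarray,
    n_total: int | np.ndarray,
    p0: float,
) -> float | np.ndarray:
    """Exact upper-tail binomial probability P(X >= k | n, p0).

    Returns 1.0 when k == 0.  Vectorised over arrays.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")
    k = np.asarray(n_unconverted)
    n = np.asarray(n_total)
    if np.any(k > n):
        raise ValueError("n_unconverted exceeds n_total")
    if np.any(k < 0):
        raise ValueError("negative n_unconverted")
    out = stats.binom.sf(k - 1, n, p0)
    if np.ndim(n_unconverted) == 0:
        return float(out)
    return out


def call_sites(
    calls: pd.DataFrame,
    p0: float,
    fdr: float = 0.01,
    min_cov: int = 1,
    exclude_chroms: Sequence[str] = SPIKE_IN_NAMES,
) -> pd.DataFrame:
    """Binomial test + stratified BH FDR over a call table.

    BH is applied independently within each (chromosome, context) stratum.
    Sites with coverage below ``min_cov`` (zero-coverage in particular) and
    sites on excluded contigs (spike-ins by default) are not tested; their
    ``p_value`` is NaN and ``called`` False.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must lie in (0, 1)")
    out = calls.copy()
    out["p_value"] = np.nan
    out["called"] = False
    testable = (out["n_total"] >= max(min_cov, 1)) & ~out["chrom"].isin(
        exclude_chroms
    )
    idx = out.index[testable]
    if len(idx) == 0:
        return out
    pvals = binomial_p(
        out.loc[idx, "n_unconverted"].to_numpy(),
        out.loc[idx, "n_total"].to_numpy(),
        p0,
    )
    out.loc[idx, "p_value"] = pvals
    for _, stratum in out.loc[idx].groupby(["chrom", "context"], sort=False):
        if stratum.empty:
            continue
        rejected, _, _, _ = multipletests(
            stratum["p_value"].to_numpy(), alpha=fdr, method="fdr_bh"
        )
        out.loc[stratum.index, "called"] = rejected
    return out
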