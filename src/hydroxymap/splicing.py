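"""Exon-exon junction counting and exon-inclusion estimation.

A junction library holds, for every ordered exon pair (i < j) of a gene,
the last ``arm_len`` bases of exon i joined to the first ``arm_len``
bases of exon j.  A read supports a junction when it matches the junction
sequence spanning the join point with at least ``min_overhang`` bases on
each side and does not match the unspliced genomic sequence contiguously.

For a focal exon A the junction table aggregates

* CiA:  reads from any upstream donor Ci to A,
* ACj:  reads from A to any downstream acceptor Cj,
* CiC2: reads from any upstream donor to the first downstream acceptor C2,
* C1Cj: reads from the first upstream donor C1 to any downstream acceptor,

and the inclusion rate is (CiA + ACj) / (CiA + ACj + 2*skip) on the 0-1
scale.  Two accounting modes for the C1->C2 junction, which lies in both
skip sums, are provided: ``literal`` keeps the double count (the printed
formula), ``count_once`` dedupes it, which is the unbiased estimator of
the true inclusion fraction and the default.  An exon is alternatively
spliced (AS) when inclusion < 0.8; records need >= 10 supporting reads
and an AG 3' splice site to enter comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Junction:
    donor: int
    acceptor: int
    seq: str
    junction_pos: int  # offset of the join point within seq
    truncated: bool


def build_eej_library(
    exon_seqs: Sequence[str], arm_len: int = 42
) -> dict[tuple[int, int], Junction]:
    """All ordered exon-pair junction sequences for one gene.

    n exons yield n(n-1)/2 junctions.  Arms shorter than ``arm_len`` are
    truncated to the exon length and flagged.
    """
    if arm_len < 8:
        raise ValueError("arm_len must be >= 8")
    lib: dict[tuple[int, int], Junction] = {}
    n = len(exon_seqs)
    for i, j in itertools.combinations(range(n), 2):
        left = exon_seqs[i][-arm_len:]
        right = exon_seqs[j][:arm_len]
        truncated = len(left) < arm_len or len(right) < arm_len
        lib[(i, j)] = Junction(
            donor=i,
            acceptor=j,
            seq=left + right,
            junction_pos=len(left),
            truncated=truncated,
        )
    return lib


def count_junction_reads(
    reads: Sequence[str],
    library: Mapping[tuple[int, int], Junction],
    genomic_seq: str,
    min_overhang: int = 8,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign reads to junctions by exact matching.

    A read counts toward exactly one junction; reads matching the
    unspliced genomic sequence contiguously are discarded as genomic, and
    reads matching several junctions are discarded as ambiguous.  Returns
    (counts DataFrame indexed by donor/acceptor, discard counters).
    """
    counts = {key: 0 for key in library}
    discards = {"genomic": 0, "ambiguous": 0, "unmatched": 0}
    for read in reads:
        if read in genomic_seq:
            discards["genomic"] += 1
            continue
        matches = []
        for key, jn in library.items():
            start = jn.seq.find(read)
            spans = False
            while start != -1:
                left = jn.junction_pos - start
                right = start + len(read) - jn.junction_pos
                if left >= min_overhang and right >= min_overhang:
                    spans = True
                    break
                start = jn.seq.find(read, start + 1)
            if spans:
                matches.append(key)
        if len(matches) == 1:
            counts[matches[0]] += 1
        elif len(matches) > 1:
            discards["ambiguous"] += 1
        else:
            discards["unmatched"] += 1
    df = pd.DataFrame(
        [
            {"donor": d, "acceptor": a, "count": c}
            for (d, a), c in sorted(counts.items())
        ]
    )
    return df, discards


@dataclass
class JunctionTable:
    """Junction counts around one focal exon."""

    focal: int
    ci_a: int
    a_cj: int
    ci_c2: int
    c1_cj: int
    c1_c2: int = 0  # the shared nearest-neighbour skipping junction

    @property
    def n_supporting(self) -> int:
        return self.ci_a + self.a_cj + self.ci_c2 + self.c1_cj


def junction_table(counts: pd.DataFrame, focal: int) -> JunctionTable:
    """Aggregate pairwise junction counts for a focal exon.

    C1 is the nearest upstream exon (focal-1), C2 the nearest downstream
    exon (focal+1); any junction from upstream of A to C2, or from C1 to
    downstream of A, skips A.
    """
    d = counts["donor"].to_numpy()
    a = counts["acceptor"].to_numpy()
    c = counts["count"].to_numpy()
    ci_a = int(c[(a == focal) & (d < focal)].sum())
    a_cj = int(c[(d == focal) & (a > focal)].sum())
    ci_c2 = int(c[(a == focal + 1) & (d < focal)].sum())
    c1_cj = int(c[(d == focal - 1) & (a > focal)].sum())
    c1_c2 = int(c[(d == focal - 1) & (a == focal + 1)].sum())
    return JunctionTable(focal=focal, ci_a=ci_a, a_cj=a_cj, ci_c2=ci_c2,
                         c1_cj=c1_cj, c1_c2=c1_c2)


@dataclass
class InclusionRecord:
    exon: int
    inclusion: float | None
    n_supporting: int
    as_flag: bool | None
    ag_ok: bool
    usable: bool


def inclusion_rate(
    jt: JunctionTable,
    min_reads: int = 10,
    mode: str = "count_once",
    ag_ok: bool = True,
    as_threshold: float = 0.8,
) -> InclusionRecord:
    """Exon inclusion from junction counts, on the 0-1 scale.

    ``count_once`` (default) counts the shared C1->C2 junction once in the
    skip term, giving an unbiased estimate of the inclusion fraction;
    ``literal`` keeps it in both skip sums as the formula is printed.
    A record is unusable when supporting reads fall below ``min_reads``,
    the 3' splice site lacks AG, or the denominator is zero.
    """
    incl = jt.ci_a + jt.a_cj
    if mode == "literal":
        skip = jt.ci_c2 + jt.c1_cj
    elif mode == "count_once":
        skip = jt.ci_c2 + jt.c1_cj - jt.c1_c2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    denom = incl + 2 * skip
    n_supporting = jt.n_supporting
    if denom == 0:
        return InclusionRecord(jt.focal, None, n_supporting, None, ag_ok, False)
    inclusion = incl / denom
    usable = n_supporting >= min_reads and ag_ok
    return InclusionRecord(
        exon=jt.focal,
        inclusion=inclusion,
        n_supporting=n_supporting,
        as_flag=inclusion < as_threshold,
        ag_ok=ag_ok,
        usable=usable,
    )


# ---------------------------------------------------------------------------
# Group comparison


def mww_test(
    x: Sequence[float], y: Sequence[float], exact_max: int = 20
) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test.

    Exact enumeration of the permutation distribution of U when both
    groups have at most ``exact_max`` members (correct with ties, unlike
    the standard exact tables); tie-corrected normal approximation with
    continuity correction otherwise.  Returns (U, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be nonempty")
    u_obs = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    if n1 <= exact_max and n2 <= exact_max:
        combined = np.concatenate([x, y])
        ranks = stats.rankdata(combined)
        mu = n1 * n2 / 2.0
        dev = abs(u_obs - mu)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            r1 = ranks[list(idx)].sum()
            u = r1 - n1 * (n1 + 1) / 2.0
            if abs(u - mu) >= dev - 1e-12:
                count += 1
            total += 1
        return float(u_obs), count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u_obs), float(res.pvalue)


def compare_inclusion(
    records_by_category: Mapping[str, Sequence[InclusionRecord]],
    exact_max: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category AS percentage and median inclusion, plus pairwise MWW.

    Only usable records enter; categories with fewer than two usable
    records are excluded (with a notice row in the summary).
    """
    summary_rows = []
    usable: dict[str, np.ndarray] = {}
    for cat, records in records_by_category.items():
        vals = np.array(
            [r.inclusion for r in records if r.usable and r.inclusion is not None]
        )
        n_as = sum(
            1 for r in records if r.usable and r.as_flag
        )
        summary_rows.append(
            {
                "category": cat,
                "n_usable": len(vals),
                "n_as": n_as,
                "as_percent": 100.0 * n_as / len(vals) if len(vals) else np.nan,
                "median_inclusion": float(np.median(vals)) if len(vals) else np.nan,
                "included": len(vals) >= 2,
            }
        )
        if len(vals) >= 2:
            usable[cat] = vals
    pair_rows = []
    for a, b in itertools.combinations(sorted(usable), 2):
        u, p = mww_test(usable[a], usable[b], exact_max=exact_max)
        pair_rows.append({"category_a": a, "category_b": b, "U": u, "p_value": p})
    return pd.DataFrame(summary_rows), pd.DataFrame(
        pair_rows, columns=["category_a", "category_b", "U", "p_value"]
    )
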