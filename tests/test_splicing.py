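import itertools

import numpy as np
import pytest

from hydroxymap import splicing
from hydroxymap.splicing import JunctionTable


def test_eej_combinatorics():
    exons = ["A" * 60, "C" * 60, "G" * 60, "T" * 60]
    lib = splicing.build_eej_library(exons, arm_len=42)
    assert len(lib) == 6  # 4 exons -> 4*3/2 junctions
    for n in (3, 5, 7):
        lib = splicing.build_eej_library(["ACGT" * 20] * n, arm_len=20)
        assert len(lib) == n * (n - 1) // 2


def test_eej_sequence_is_arm_concatenation():
    exons = ["AAGGTTCCAA", "CCTTGGAACC", "GATTACAGAT"]
    lib = splicing.build_eej_library(exons, arm_len=8)
    jn = lib[(1, 2)]
    assert jn.seq == exons[1][-8:] + exons[2][:8]
    assert jn.junction_pos == 8
    assert not jn.truncated


def test_eej_hand_built_three_exons():
    exons = ["ACGTACGTAC", "GGATCCGGAT", "TTGACATTGA"]
    lib = splicing.build_eej_library(exons, arm_len=8)
    expect = {
        (0, 1): "GTACGTAC" + "GGATCCGG",
        (0, 2): "GTACGTAC" + "TTGACATT",
        (1, 2): "ATCCGGAT" + "TTGACATT",
    }
    for key, seq in expect.items():
        assert lib[key].seq == seq


def test_eej_short_exon_truncated_flag():
    lib = splicing.build_eej_library(["ACGT", "ACGTACGTACGT"], arm_len=8)
    assert lib[(0, 1)].truncated
    assert lib[(0, 1)].junction_pos == 4


def test_genomic_read_discarded():
    exons = ["AACCGGTTAACCGGTT", "TTGGCCAATTGGCCAA"]
    genomic = exons[0] + "GTAAGTTTTTAG" + exons[1]
    lib = splicing.build_eej_library(exons, arm_len=10)
    read = exons[0][:16]  # fully inside exon 0
    counts, discards = splicing.count_junction_reads([read], lib, genomic)
    assert discards["genomic"] == 1
    assert counts["count"].sum() == 0


def test_short_overhang_not_counted():
    exons = ["AACCGGTTAACCGGTT", "TTGGCCAATTGGCCAA"]
    genomic = exons[0] + "GTAAGTTTTTAG" + exons[1]
    lib = splicing.build_eej_library(exons, arm_len=10)
    read = exons[0][-7:] + exons[1][:9]  # 7 nt on the left arm
    counts, discards = splicing.count_junction_reads(
        [read], lib, genomic, min_overhang=8
    )
    assert discards["unmatched"] == 1
    assert counts["count"].sum() == 0
    # with min_overhang=7 the same read counts
    counts, discards = splicing.count_junction_reads(
        [read], lib, genomic, min_overhang=7
    )
    assert counts["count"].sum() == 1


def test_inclusion_trivial_cases():
    full = splicing.inclusion_rate(
        JunctionTable(focal=2, ci_a=5, a_cj=5, ci_c2=0, c1_cj=0, c1_c2=0)
    )
    assert full.inclusion == 1.0
    none = splicing.inclusion_rate(
        JunctionTable(focal=2, ci_a=0, a_cj=0, ci_c2=10, c1_cj=10, c1_c2=10)
    )
    assert none.inclusion == 0.0
    empty = splicing.inclusion_rate(
        JunctionTable(focal=2, ci_a=0, a_cj=0, ci_c2=0, c1_cj=0, c1_c2=0)
    )
    assert empty.inclusion is None and not empty.usable


def test_inclusion_printed_formula_example():
    # CiA=4, ACj=4, the sole skipping junction C1C2=2 enters both skip
    # sums in the literal formula: 8 / (8 + 2*4) = 0.5
    jt = JunctionTable(focal=2, ci_a=4, a_cj=4, ci_c2=2, c1_cj=2, c1_c2=2)
    lit = splicing.inclusion_rate(jt, min_reads=1, mode="literal")
    assert lit.inclusion == pytest.approx(0.5)
    # count-once dedupes the shared junction: 8 / (8 + 2*2) = 2/3,
    # matching the read-level enumeration (8 inclusion vs 2 skip reads)
    once = splicing.inclusion_rate(jt, min_reads=1, mode="count_once")
    assert once.inclusion == pytest.approx(8 / 12)


def _read_level_oracle(jt, mode):
    """Brute-force read enumeration of the inclusion formula.

    Expand the table into individual junction reads; each read lies on
    exactly one junction.  Inclusion reads are those on (Ci,A) or (A,Cj);
    a skip read on the shared (C1,C2) junction contributes to both skip
    sums in literal mode and once in count-once mode.
    """
    reads = (
        ["incl"] * (jt.ci_a + jt.a_cj)
        + ["c1c2"] * jt.c1_c2
        + ["cic2_other"] * (jt.ci_c2 - jt.c1_c2)
        + ["c1cj_other"] * (jt.c1_cj - jt.c1_c2)
    )
    incl = sum(1 for r in reads if r == "incl")
    skip = 0
    for r in reads:
        if r == "c1c2":
            # the shared junction read appears in both printed skip sums
            skip += 2 if mode == "literal" else 1
        elif r in ("cic2_other", "c1cj_other"):
            skip += 1
    denom = incl + 2 * skip
    return incl / denom if denom else None


def test_inclusion_vs_read_level_oracle_random_tables():
    rng = np.random.default_rng(3)
    for _ in range(100):
        ci_a, a_cj = rng.integers(0, 40, 2)
        c1_c2 = int(rng.integers(0, 20))
        ci_c2 = c1_c2 + int(rng.integers(0, 10))
        c1_cj = c1_c2 + int(rng.integers(0, 10))
        jt = JunctionTable(
            focal=2, ci_a=int(ci_a), a_cj=int(a_cj), ci_c2=ci_c2,
            c1_cj=c1_cj, c1_c2=c1_c2,
        )
        for mode in ("literal", "count_once"):
            got = splicing.inclusion_rate(jt, min_reads=1, mode=mode).inclusion
            want = _read_level_oracle(jt, mode)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want)


def test_as_flag_and_gates():
    jt = JunctionTable(focal=2, ci_a=3, a_cj=3, ci_c2=2, c1_cj=2, c1_c2=2)
    rec = splicing.inclusion_rate(jt, min_reads=10)
    assert rec.n_supporting == 10 and rec.usable
    assert rec.inclusion < 0.8 and rec.as_flag
    under = splicing.inclusion_rate(
        JunctionTable(focal=2, ci_a=3, a_cj=3, ci_c2=1, c1_cj=1, c1_c2=1),
        min_reads=10,
    )
    assert not under.usable  # 8 supporting reads < 10
    no_ag = splicing.inclusion_rate(jt, min_reads=10, ag_ok=False)
    assert not no_ag.usable


def _mww_permutation_oracle(x, y):
    """Independent full enumeration of the two-sided MWW p-value."""
    from scipy import stats

    combined = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(combined)
    u_obs = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    mu = n1 * len(y) / 2
    hits = total = 0
    for idx in itertools.combinations(range(len(combined)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def test_mww_identical_groups():
    _, p = splicing.mww_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == 1.0


def test_mww_separated_groups_exact():
    u, p = splicing.mww_test([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments as extreme
    assert p == pytest.approx(_mww_permutation_oracle([1, 2, 3], [4, 5, 6]))


def test_mww_with_ties_matches_oracle():
    rng = np.random.default_rng(5)
    for _ in range(10):
        x = rng.choice([0.9, 0.95, 1.0], size=6)
        y = rng.choice([0.9, 0.95, 1.0], size=5)
        _, p = splicing.mww_test(x, y)
        assert p == pytest.approx(_mww_permutation_oracle(x, y))


def test_compare_inclusion_as_percent_printed_value():
    def rec(val, as_flag):
        return splicing.InclusionRecord(
            exon=2, inclusion=val, n_supporting=50,
            as_flag=as_flag, ag_ok=True, usable=True,
        )

    records = [rec(0.5, True)] * 128 + [rec(0.99, False)] * (2119 - 128)
    summary, _ = splicing.compare_inclusion({"hmC_high": records})
    row = summary.iloc[0]
    assert row["n_usable"] == 2119 and row["n_as"] == 128
    assert round(row["as_percent"], 2) == 6.04
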