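import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from hydroxymap import calls


def _cx_rows(chrom, context, n_sites, u, t):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n_sites + 1),
            "strand": "+",
            "context": context,
            "trinucleotide": "CGA" if context == "CG" else "CAA",
            "n_unconverted": u,
            "n_total": t,
        }
    )


def _spike_tables(lam_noncg=(3, 1000), lam_cg=(12, 1000),
                  puc_tab=(976, 1000), puc_bs=(1000, 1000)):
    tab = pd.concat(
        [
            _cx_rows("lambda_spike", "CHH", 1, [lam_noncg[0]], [lam_noncg[1]]),
            _cx_rows("lambda_spike", "CG", 1, [lam_cg[0]], [lam_cg[1]]),
            _cx_rows("pUC19_spike", "CG", 1, [puc_tab[0]], [puc_tab[1]]),
        ],
        ignore_index=True,
    )
    bs = pd.concat(
        [
            _cx_rows("lambda_spike", "CHH", 1, [1], [1000]),
            _cx_rows("lambda_spike", "CG", 1, [990], [1000]),
            _cx_rows("pUC19_spike", "CG", 1, [puc_bs[0]], [puc_bs[1]]),
        ],
        ignore_index=True,
    )
    return tab, bs


def test_spike_in_ratio_exact():
    tab, bs = _spike_tables()
    stats = calls.spike_in_stats(tab, bs)
    assert stats.ncr_c == 3 / 1000
    assert stats.ncr_mc == 12 / 1000
    # rational-arithmetic check: the float is the correctly rounded ratio
    assert stats.ncr_c == float(Fraction(3, 1000))


def test_protection_normalized_printed_value():
    tab, bs = _spike_tables(puc_tab=(976, 1000), puc_bs=(1000, 1000))
    stats = calls.spike_in_stats(tab, bs)
    assert stats.protection_normalized == 0.976


def test_protection_identity_and_clip():
    tab, bs = _spike_tables(puc_tab=(990, 1000), puc_bs=(990, 1000))
    assert calls.spike_in_stats(tab, bs).protection_normalized == 1.0
    tab, bs = _spike_tables(puc_tab=(999, 1000), puc_bs=(990, 1000))
    assert calls.spike_in_stats(tab, bs).protection_normalized == 1.0


def test_missing_spike_in_contig_raises():
    tab, bs = _spike_tables()
    with pytest.raises(calls.CalibrationError):
        calls.spike_in_stats(tab[tab["chrom"] != "pUC19_spike"], bs)


def test_binomial_trivial_cases():
    assert calls.binomial_p(0, 10, 0.01) == 1.0
    assert calls.binomial_p(10, 10, 0.5) == pytest.approx(
        9.765625e-4, rel=1e-12
    )


def _binom_tail_oracle(k, n, p):
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


def test_binomial_vs_pmf_summation():
    assert calls.binomial_p(3, 20, 0.0036) == pytest.approx(
        _binom_tail_oracle(3, 20, 0.0036), rel=1e-10
    )
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(1, 31))
        k = int(rng.integers(0, n + 1))
        p = float(rng.uniform(0, 1))
        assert calls.binomial_p(k, n, p) == pytest.approx(
            _binom_tail_oracle(k, n, p), rel=1e-9, abs=1e-300
        )


def test_binomial_monotone_in_k():
    for n in (5, 20, 30):
        ps = [calls.binomial_p(k, n, 0.1) for k in range(n + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_binomial_contract_violations():
    with pytest.raises(ValueError):
        calls.binomial_p(5, 3, 0.1)
    with pytest.raises(ValueError):
        calls.binomial_p(1, 3, 1.5)


def _bh_stepup_oracle(pvals, alpha):
    """Independent BH reimplementation (step-up on sorted p-values)."""
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = np.nonzero(np.sort(pvals) <= thresh)[0]
    rejected = np.zeros(m, dtype=bool)
    if len(passed):
        k = passed.max()
        rejected[order[: k + 1]] = True
    return rejected


def _genomic_calls(pvals_to_counts):
    """One-stratum call table with u/t chosen to hit given raw counts."""
    u, t = pvals_to_counts
    return _cx_rows("chr1", "CG", len(u), u, t)


def test_bh_single_site_called():
    # p = P(X >= 5 | 10, 0.1) ~ 0.0016 < 0.01 -> called with m = 1
    tab = _cx_rows("chr1", "CG", 1, [5], [10])
    out = calls.call_sites(tab, p0=0.1, fdr=0.01)
    assert bool(out.iloc[0]["called"])
    assert out.iloc[0]["p_value"] <= 0.01


def test_bh_identical_marginal_pvalues_not_called():
    # 20 sites all with p ~ 0.02: BH cutoff k * 0.01 / 20 is below 0.02
    # for every k, so nothing survives
    u = np.full(20, 2)
    t = np.full(20, 12)
    p_single = calls.binomial_p(2, 12, 0.0136)
    assert 0.01 < p_single < 0.05
    tab = _cx_rows("chr1", "CG", 20, u, t)
    out = calls.call_sites(tab, p0=0.0136, fdr=0.01)
    assert not out["called"].any()


def test_bh_vs_stepup_oracle():
    rng = np.random.default_rng(42)
    t = np.full(200, 30)
    u = rng.binomial(30, rng.choice([0.005, 0.2], size=200, p=[0.7, 0.3]))
    tab = _cx_rows("chr1", "CG", 200, u, t)
    out = calls.call_sites(tab, p0=0.005, fdr=0.05)
    oracle = _bh_stepup_oracle(out["p_value"].to_numpy(), 0.05)
    assert (out["called"].to_numpy() == oracle).all()


def test_call_sites_excludes_spikeins_and_zero_coverage():
    genomic = _cx_rows("chr1", "CG", 2, [10, 0], [10, 0])
    spike = _cx_rows("lambda_spike", "CG", 1, [10], [10])
    tab = pd.concat([genomic, spike], ignore_index=True)
    out = calls.call_sites(tab, p0=0.01, fdr=0.01)
    assert bool(out.iloc[0]["called"])
    assert np.isnan(out.iloc[1]["p_value"]) and not out.iloc[1]["called"]
    assert np.isnan(out.iloc[2]["p_value"]) and not out.iloc[2]["called"]


def test_stratified_fdr_is_per_chrom_and_context():
    # a dense block of significant sites on chr1 must not drag chr2's
    # borderline site across the BH cutoff
    strong = _cx_rows("chr1", "CG", 50, np.full(50, 20), np.full(50, 20))
    weak = _cx_rows("chr2", "CG", 1, [2], [12])
    out = calls.call_sites(
        pd.concat([strong, weak], ignore_index=True), p0=0.0136, fdr=0.01
    )
    assert out[out["chrom"] == "chr1"]["called"].all()
    assert not out[out["chrom"] == "chr2"]["called"].any()
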