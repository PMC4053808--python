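import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hydroxymap import strands
from hydroxymap import simulate as sim


def _gene(name, chrom, strand, start, end):
    return {
        "gene": name,
        "transcript": name,
        "chrom": chrom,
        "strand": strand,
        "tx_start": start,
        "tx_end": end,
        "cds_start": start,
        "cds_end": end,
        "exon_count": 1,
        "exon_starts": [start],
        "exon_ends": [end],
    }


def test_rpkm_unit_definition():
    genes = pd.DataFrame([_gene("g1", "c", "+", 0, 1000)])
    out = strands.rpkm({"g1": 100}, genes, total_mapped=1_000_000)
    assert out.iloc[0]["rpkm"] == pytest.approx(100.0)


def test_rpkm_zero_count_not_expressed():
    genes = pd.DataFrame([_gene("g1", "c", "+", 0, 1000)])
    out = strands.rpkm({"g1": 0}, genes, total_mapped=1_000_000)
    assert out.iloc[0]["rpkm"] == 0.0
    assert out.iloc[0]["group"] == "not_expressed"


def test_rpkm_equal_tertiles():
    genes = pd.DataFrame(
        [_gene(f"g{i}", "c", "+", i * 2000, i * 2000 + 1000) for i in range(9)]
    )
    counts = {f"g{i}": 100 * (i + 1) for i in range(9)}
    out = strands.rpkm(counts, genes, total_mapped=1_000_000)
    sizes = out["group"].value_counts()
    assert sizes["low"] == sizes["middle"] == sizes["high"] == 3
    assert out["decile"].max() == 10


def _records(chrom, pos, strand, tab_u, tab_t, bs_u, bs_t):
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": strand,
            "tab_u": tab_u,
            "tab_t": tab_t,
            "bs_u": bs_u,
            "bs_t": bs_t,
        }
    )
    df["hmc"] = df["tab_u"] / df["tab_t"]
    df["modc"] = df["bs_u"] / df["bs_t"]
    df["mc"] = np.clip(df["modc"] - df["hmc"], 0, 1)
    return df


def test_minus_strand_gene_sense_orientation():
    genes = pd.DataFrame([_gene("g1", "c", "-", 0, 100)])
    rec = _records(
        "c", [10, 11], ["+", "-"], [1, 9], [10, 10], [5, 10], [10, 10]
    )
    levels = strands.gene_strand_levels(rec, genes)
    # sense of a minus-strand gene comes from minus-strand cytosines
    assert levels.iloc[0]["sense_hmc"] == pytest.approx(0.9)
    assert levels.iloc[0]["antisense_hmc"] == pytest.approx(0.1)


def test_strand_bias_all_zero_differences():
    levels = pd.DataFrame(
        {"sense_hmc": [0.2, 0.3, 0.4], "antisense_hmc": [0.2, 0.3, 0.4]}
    )
    out = strands.strand_bias_test(levels, metric="hmc")
    assert out["t"] == 0.0 and out["p_value"] == 1.0


def test_strand_bias_closed_form_t():
    # differences {0.01, 0.02, 0.03}: t = mean / (sd/sqrt(3)) = 3.4641, df=2
    anti = np.array([0.2, 0.2, 0.2])
    levels = pd.DataFrame(
        {"sense_hmc": anti + [0.01, 0.02, 0.03], "antisense_hmc": anti}
    )
    out = strands.strand_bias_test(levels, metric="hmc")
    assert out["t"] == pytest.approx(np.sqrt(12), rel=1e-6)  # 3.4641...
    assert out["p_value"] == pytest.approx(
        2 * sps.t.sf(np.sqrt(12), df=2), rel=1e-6
    )
    assert out["mean_bias"] == pytest.approx(0.02)


def test_mc_bias_sign_convention():
    levels = pd.DataFrame(
        {
            "sense_mc": [0.30, 0.31],
            "antisense_mc": [0.35, 0.37],
        }
    )
    out = strands.strand_bias_test(levels, metric="mc")
    assert out["mean_bias"] == pytest.approx(0.055)  # antisense - sense


def test_gene_body_profile_bin_partition():
    # 1,000-bp gene with 100 bins -> 10-bp bins; a CpG at 1-based 6
    # falls in bin 0, one at 996 in bin 99 (plus strand)
    genes = pd.DataFrame([_gene("g1", "c", "+", 0, 1000)])
    rec = _records("c", [6, 996], ["+", "+"], [1, 2], [10, 10], [5, 5],
                   [10, 10])
    prof = strands.gene_body_profile(rec, genes, bins=100, flank_bp=100)
    body = prof[(prof["segment"] == "body") & (prof["strand"] == "sense")]
    occupied = body[body["n"] > 0]["bin"].tolist()
    assert occupied == [0, 99]
    edges = 0 + np.round(np.linspace(0, 1000, 101)).astype(int)
    assert (np.diff(edges) == 10).all()  # integer-partition oracle


def test_gene_body_profile_minus_strand_bin_orientation():
    genes = pd.DataFrame([_gene("g1", "c", "-", 0, 1000)])
    rec = _records("c", [6], ["-"], [1], [10], [5], [10])
    prof = strands.gene_body_profile(rec, genes, bins=100, flank_bp=100)
    body = prof[(prof["segment"] == "body") & (prof["strand"] == "sense")]
    # genomic bin 0 is the transcript's last bin for a minus-strand gene
    assert body[body["n"] > 0]["bin"].tolist() == [99]


def test_profile_short_gene_excluded():
    genes = pd.DataFrame([_gene("g1", "c", "+", 0, 50)])
    rec = _records("c", [6], ["+"], [1], [10], [5], [10])
    prof = strands.gene_body_profile(rec, genes, bins=100, flank_bp=100)
    assert prof.attrs["n_excluded"] == 1


def test_sas_regions_overlap_and_threshold():
    genes = pd.DataFrame(
        [
            _gene("g1", "c", "+", 0, 1000),
            _gene("g2", "c", "-", 500, 1500),
        ]
    )
    expr = pd.DataFrame({"gene": ["g1", "g2"], "rpkm": [5.0, 5.0]})
    sas = strands.sas_regions(expr, genes, min_rpkm=1.0)
    assert sas.values.tolist() == [["c", 500, 1000]]
    expr.loc[1, "rpkm"] = 0.5
    assert strands.sas_regions(expr, genes, min_rpkm=1.0).empty


def test_strand_bias_recovery_on_gene_grid():
    genes = sim.make_gene_grid(120, groups=["high"])
    rec = sim.simulate_strand_records(
        genes, {"high": 0.02}, coverage=40, seed=8
    )
    levels = strands.gene_strand_levels(rec, genes)
    out = strands.strand_bias_test(levels, metric="hmc")
    assert out["mean_bias"] == pytest.approx(0.02, abs=0.005)
    assert out["p_value"] < 1e-6


def test_sas_bias_contrast_reduced_in_sas():
    genes = sim.make_gene_grid(
        90, groups=["high"], overlap_every=3, overlap_bp=1500
    )
    rec = sim.simulate_strand_records(
        genes, {"high": 0.03}, coverage=40, seed=9
    )
    expr = pd.DataFrame({"gene": genes["gene"], "rpkm": 10.0})
    sas = strands.sas_regions(expr, genes)
    assert not sas.empty
    contrast = strands.sas_bias_contrast(rec, genes, sas, metric="hmc")
    assert contrast["sas_bias"] < contrast["non_sas_bias"]
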