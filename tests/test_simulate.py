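import numpy as np
import pandas as pd
import pytest

from hydroxymap import boundary, splicing
from hydroxymap import simulate as sim


def test_reference_deterministic():
    a = sim.gen_reference(sim.TruthConfig(seed=1))
    b = sim.gen_reference(sim.TruthConfig(seed=1))
    assert a.genome == b.genome
    pd.testing.assert_frame_equal(
        a.genes.drop(columns=["exon_starts", "exon_ends"]),
        b.genes.drop(columns=["exon_starts", "exon_ends"]),
    )


def test_three_exon_genes_have_one_internal_exon():
    ref = sim.gen_reference(sim.TruthConfig(seed=2, exons_per_gene=3))
    exons = boundary.exon_table(ref.genes)
    internal = exons[exons["kind"] == "internal"]
    assert (internal.groupby("gene").size() == 1).all()
    assert len(internal["gene"].unique()) == len(ref.genes)


def test_introns_are_gt_ag(small_ref):
    for _, g in small_ref.genes.iterrows():
        seq = small_ref.genome[g["chrom"]]
        starts, ends = g["exon_starts"], g["exon_ends"]
        for e_prev, s_next in zip(ends[:-1], starts[1:]):
            intron = seq[e_prev:s_next]
            if g["strand"] == "-":
                intron = sim.revcomp(intron)
            assert intron[:2] == "GT"
            assert intron[-2:] == "AG"


def test_truth_at_ss_cpg_is_additive():
    # with the strand-bias deltas switched off, every 5'ss CpG carries
    # exactly base_hmc + ss_peak_delta
    cfg = sim.TruthConfig(
        seed=5,
        strand_bias_delta_by_expression={
            "none": 0.0, "low": 0.0, "middle": 0.0, "high": 0.0
        },
    )
    ref = sim.gen_reference(cfg)
    truth = sim.gen_truth(ref)
    exons = boundary.exon_table(ref.genes)
    ss = boundary.detect_ss_cpg(ref.genome, exons[exons["kind"] == "internal"])
    assert len(ss) > 0
    tr = truth.set_index(["chrom", "pos", "strand"])["f_hmc"]
    vals = [tr.loc[(r["chrom"], r["gpos0"] + 1, r["strand"])] for _, r in ss.iterrows()]
    assert np.allclose(vals, cfg.base_hmc + cfg.ss_peak_delta)


def test_mixture_degenerate_cases():
    err = sim.AssayErrorModel(protection_hmc=1.0, ncr_c=0.0)
    assert sim.mixture_unconverted_prob(1.0, 0.0, err, "TAB") == 1.0
    assert sim.mixture_unconverted_prob(0.0, 0.0, err, "TAB") == 0.0


def test_mixture_mean_recovery():
    # closed form: 0.5 * 0.976 + 0.5 * 0.0036 = 0.4898
    err = sim.AssayErrorModel(protection_hmc=0.976, ncr_c=0.0036,
                              mean_coverage=20.0)
    n_sites = 5000
    truth = pd.DataFrame(
        {
            "chrom": "chrT",
            "pos": np.arange(1, n_sites + 1),
            "strand": "+",
            "context": "CG",
            "trinucleotide": "CGA",
            "f_hmc": 0.5,
            "f_mc": 0.0,
        }
    )
    rep = sim.simulate_cytosine_reports(truth, err, "TAB", seed=11)
    n_reads = rep["n_total"].sum()
    frac = rep["n_unconverted"].sum() / n_reads
    se = np.sqrt(0.4898 * (1 - 0.4898) / n_reads)
    assert abs(frac - 0.4898) <= 3 * se


def test_simulation_deterministic(small_truth):
    err = sim.AssayErrorModel()
    a = sim.simulate_cytosine_reports(small_truth, err, "TAB", seed=9)
    b = sim.simulate_cytosine_reports(small_truth, err, "TAB", seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_spike_in_truth(small_truth):
    lam = small_truth[small_truth["chrom"] == sim.LAMBDA_NAME]
    assert (lam.loc[lam["context"] == "CG", "f_mc"] == 1.0).all()
    assert (lam.loc[lam["context"] != "CG", "f_mc"] == 0.0).all()
    assert (lam["f_hmc"] == 0.0).all()
    puc = small_truth[small_truth["chrom"] == sim.PUC19_NAME]
    assert (puc["f_hmc"] == 1.0).all()


def test_cytosine_table_tiny_genome():
    table = sim.cytosine_table({"t": "ACGTACGG"})
    # the first/last two bases are skipped so trinucleotides are defined:
    # of the plus-strand Cs (0-based 1, 5) only 5 survives; of the
    # minus-strand Cs (under plus Gs 2, 6, 7) only 2 survives
    plus = table[table["strand"] == "+"]
    assert sorted(plus["pos"]) == [6]
    assert set(plus["context"]) == {"CG"}
    minus = table[table["strand"] == "-"]
    assert sorted(minus["pos"]) == [3]
    row = minus.set_index("pos").loc[3]
    assert row["context"] == "CG"
    assert row["trinucleotide"].startswith("CG")


@pytest.mark.parametrize("psi,absent", [(1.0, "skip"), (0.0, "incl")])
def test_junction_reads_degenerate_psi(small_ref, psi, absent):
    gene = small_ref.genes.iloc[0]
    exon_seqs = sim.gene_exon_sequences(small_ref.genome, gene)
    focal = len(exon_seqs) // 2
    reads, _ = sim.simulate_junction_reads(
        gene, small_ref.genome, {focal: psi}, n_reads=400, read_len=50, seed=1
    )
    lib = splicing.build_eej_library(exon_seqs, arm_len=42)
    region = small_ref.genome[gene["chrom"]][gene["tx_start"]:gene["tx_end"]]
    if gene["strand"] == "-":
        region = sim.revcomp(region)
    counts, _ = splicing.count_junction_reads(reads, lib, region)
    jt = splicing.junction_table(counts, focal)
    if absent == "skip":
        assert jt.ci_c2 == jt.c1_cj == 0
        assert jt.ci_a + jt.a_cj > 0
    else:
        assert jt.ci_a == jt.a_cj == 0
        assert jt.ci_c2 + jt.c1_cj > 0


def test_sizing_error():
    with pytest.raises(sim.SizingError):
        sim.gen_reference(sim.TruthConfig(seed=0, chrom_len=20_000, n_genes=200))
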