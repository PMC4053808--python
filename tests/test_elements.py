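import re

import numpy as np
import pandas as pd
import pytest

from hydroxymap import elements


def _iv(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _tss(*rows):
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def test_enhancer_proximal_peak_excluded():
    k4 = _iv(("c", 2400, 2600))  # within 2500 bp of the TSS at 0
    active, poised = elements.derive_enhancers(k4, None, _tss(("c", 0)))
    assert active.empty and poised.empty


def test_enhancer_one_bp_overlap_is_active():
    k4 = _iv(("c", 10_000, 10_500))
    k27 = _iv(("c", 10_499, 11_000))  # overlaps by exactly 1 bp
    active, poised = elements.derive_enhancers(k4, k27, _tss(("c", 0)))
    assert len(active) == 1 and poised.empty


def test_enhancer_no_k27ac_all_poised():
    k4 = _iv(("c", 10_000, 10_500), ("c", 20_000, 20_500))
    active, poised = elements.derive_enhancers(k4, None, _tss(("c", 0)))
    assert active.empty and len(poised) == 2


def test_enhancer_partition_disjoint_and_complete():
    k4 = _iv(*[("c", s, s + 400) for s in range(10_000, 40_000, 3_000)])
    k27 = _iv(("c", 16_000, 16_100), ("c", 25_000, 25_050))
    active, poised = elements.derive_enhancers(k4, k27, _tss(("c", 0)))
    got = set(map(tuple, active.values.tolist() + poised.values.tolist()))
    distal = {("c", s, s + 400) for s in range(10_000, 40_000, 3_000)}
    assert got == distal
    assert not set(map(tuple, active.values.tolist())) & set(
        map(tuple, poised.values.tolist())
    )


def _cpgs(*pos):
    return pd.DataFrame({"chrom": "c", "pos": pos, "strand": "+"})


def test_assign_precedence_and_intergenic():
    tracks = {
        "exon": _iv(("c", 100, 200)),
        "enhancer_poised": _iv(("c", 150, 250)),
    }
    labels = elements.assign_elements(_cpgs(160, 500), tracks)
    assert labels.iloc[0] == "enhancer_poised"  # enhancer precedes exon
    assert labels.iloc[1] == elements.INTERGENIC


def test_assign_overlay_mode():
    tracks = {
        "exon": _iv(("c", 100, 200)),
        "enhancer_poised": _iv(("c", 150, 250)),
    }
    overlay = elements.assign_elements(_cpgs(160), tracks, mode="overlay")
    assert bool(overlay.iloc[0]["exon"]) and bool(
        overlay.iloc[0]["enhancer_poised"]
    )


def test_fold_self_enrichment_identity():
    labels = pd.Series(["exon"] * 10 + ["intron"] * 30)
    out = elements.fold_enrichment(labels, labels).set_index("element")
    assert out["fold"].eq(1.0).all()


def test_fold_observed_over_expected():
    all_labels = pd.Series(["exon"] * 10 + ["intron"] * 90)
    cat_labels = pd.Series(["exon"] * 2 + ["intron"] * 8)
    out = elements.fold_enrichment(cat_labels, all_labels).set_index("element")
    assert out.loc["exon", "fold"] == pytest.approx(2.0)


def test_fold_empty_category_raises():
    with pytest.raises(elements.EmptyCategoryError):
        elements.fold_enrichment(pd.Series(dtype=object), pd.Series(["exon"]))


def _level_records(rows):
    df = pd.DataFrame(
        rows, columns=["tab_u", "tab_t", "bs_u", "bs_t"]
    )
    df["hmc"] = df["tab_u"] / df["tab_t"]
    df["modc"] = df["bs_u"] / df["bs_t"]
    df["mc"] = np.clip(df["modc"] - df["hmc"], 0, 1)
    return df


def test_element_level_equal_coverage():
    rec = _level_records([(3, 10, 5, 10), (3, 10, 5, 10), (3, 10, 5, 10)])
    labels = pd.Series(["e"] * 3)
    out = elements.element_levels(rec, labels).set_index("element")
    assert out.loc["e", "hmc"] == pytest.approx(0.30)


def test_element_level_pooled_vs_per_site_hand_fixture():
    # three sites: (1/10), (5/10), (30/60) hmC
    rec = _level_records([(1, 10, 2, 10), (5, 10, 6, 10), (30, 60, 40, 60)])
    labels = pd.Series(["e"] * 3)
    pooled = elements.element_levels(rec, labels).set_index("element")
    per_site = elements.element_levels(rec, labels, mode="per_site").set_index(
        "element"
    )
    assert pooled.loc["e", "hmc"] == pytest.approx(36 / 80)  # 0.45
    assert per_site.loc["e", "hmc"] == pytest.approx((0.1 + 0.5 + 0.5) / 3)


def test_msp1_no_site_whole_contig():
    frags = elements.msp1_fragments({"c": "A" * 100}, min_len=40, max_len=220)
    assert frags.values.tolist() == [["c", 0, 100]]
    frags = elements.msp1_fragments({"c": "A" * 30}, min_len=40, max_len=220)
    assert frags.empty


def test_msp1_middle_fragment_size_selected_out():
    seq = "A" * 200 + "CCGG" + "A" * 96 + "CCGG" + "A" * 200
    # cuts at C^CGG: fragments of 201, 100, 203 bp
    frags = elements.msp1_fragments({"c": seq}, min_len=180, max_len=600)
    lengths = (frags["end"] - frags["start"]).tolist()
    assert 100 not in lengths
    assert sorted(lengths) == [201, 203]


def test_msp1_vs_regex_oracle():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    frags = elements.msp1_fragments({"c": seq}, min_len=0, max_len=10_000)
    cuts = [0] + [m.start() + 1 for m in re.finditer("(?=CCGG)", seq)] + [
        len(seq)
    ]
    oracle = [["c", s, e] for s, e in zip(cuts[:-1], cuts[1:]) if e > s]
    assert frags.values.tolist() == oracle


def test_in_panel():
    frags = _iv(("c", 10, 20))
    mask = elements.in_panel(_cpgs(11, 20, 25), frags)
    # pos is 1-based: 11 -> 0-based 10 inside, 20 -> 19 inside, 25 -> out
    assert mask.tolist() == [True, True, False]
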