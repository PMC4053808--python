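"""Shared fixtures: one small simulated dataset reused across modules."""

from __future__ import annotations

import pytest

from hydroxymap import deconv
from hydroxymap import simulate as sim


@pytest.fixture(scope="session")
def small_ref():
    cfg = sim.TruthConfig(seed=3)
    return sim.gen_reference(cfg)


@pytest.fixture(scope="session")
def small_truth(small_ref):
    return sim.gen_truth(small_ref)


@pytest.fixture(scope="session")
def small_reports(small_truth):
    tab = sim.simulate_cytosine_reports(
        small_truth, sim.AssayErrorModel(), "TAB", seed=4
    )
    bs = sim.simulate_cytosine_reports(
        small_truth, sim.AssayErrorModel(), "BS", seed=5
    )
    return tab, bs


@pytest.fixture(scope="session")
def small_records(small_reports):
    tab, bs = small_reports
    return deconv.classify_records(deconv.cpg_frequencies(bs, tab))
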