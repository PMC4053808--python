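# hydroxymap

Base-resolution joint analysis of 5-hydroxymethylcytosine (hmC) and
5-methylcytosine (mC) from paired TAB-Seq and BS-Seq cytosine reports,
exercised end to end on simulated data with known ground truth.

BS-Seq reads out total modification (modC = mC + hmC) because both
marks resist bisulfite conversion; TAB-Seq reads out hmC alone. This
repository implements the full analysis chain between those two
measurements and the downstream biology:

* **Simulation** (`hydroxymap.simulate`) — a small genome with gene
  models (GT..AG introns), chromatin tracks, spike-in control contigs,
  and a truth methylome carrying injected signals (splice-site CpG hmC
  peaks, sense-strand hmC excess scaled with expression, enhancer hmC
  enrichment, repressive-domain depletion); read-count simulators for
  cytosine reports and exon–exon junction reads.
* **Calibration and calling** (`hydroxymap.calls`) — CX-report parsing,
  spike-in non-conversion rates (fully methylated lambda, fully
  hydroxymethylated pUC19), exact binomial upper-tail tests, and
  Benjamini–Hochberg FDR control stratified per (chromosome, context).
* **Deconvolution** (`hydroxymap.deconv`) — per-CpG hmC/mC/modC
  frequencies (mC = modC − hmC, clipped at 0), the modC_no / modC_low /
  modC_high census with hmC_high / hmC_low / hmC_no subclasses, and
  two-sample differential hmC.
* **Elements and enrichment** (`hydroxymap.elements`) — active/poised
  enhancer derivation from distal H3K4me1 ± H3K27ac, per-CpG element
  assignment, observed/expected fold enrichment, pooled element levels,
  and an in-silico MspI (C^CGG) reduced-representation panel.
* **Boundaries and splicing** (`hydroxymap.boundary`,
  `hydroxymap.splicing`) — single-base exon-boundary profiles,
  detection of 5′ splice-site CpGs at −2/−1/+4/+5, exon–exon junction
  libraries and read counting, and exon-inclusion estimation with
  Mann–Whitney–Wilcoxon group comparisons (exact under permutation for
  small groups).
* **Strand bias** (`hydroxymap.strands`) — RPKM expression groups,
  per-gene sense/antisense pooled levels, paired-t strand-bias tests,
  scaled metagene profiles, and sense–antisense (SAS) paired regions.
* **Chromatin profiles** (`hydroxymap.chromatin`) — sliding-window
  profiles around feature midpoints and scaled region profiles with
  category fractions and the pooled hmC/mC ratio.

## Usage

The numbered scripts under `analysis/` are the primary interface. They
run in order and share a `results/` directory:

```sh
python analysis/01_simulate_dataset.py   --seed 0
python analysis/02_calibrate_and_call.py --seed 0
python analysis/03_deconvolve_classify.py --seed 0
python analysis/04_annotation_enrichment.py --seed 0
python analysis/05_boundary_splicing.py  --seed 0
python analysis/06_strand_bias.py        --seed 0
python analysis/07_chromatin_profiles.py --seed 0
```

A one-shot driver covering the same stages is available as a library
call and a CLI:

```sh
hydroxymap demo --seed 0 --out-dir demo_out
hydroxymap run --config my_config.yaml
```

`scripts/acceptance.py` reproduces the headline quantities (calibration
rates, deconvolution recovery, realized false-discovery proportion,
boundary-peak elevation, inclusion recovery at ψ = 0.6, strand-bias
recovery) as a single JSON file:

```sh
python scripts/acceptance.py --seed 0 --out acceptance.json
```

## Testing

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the seven acceptance-level tests
(in-print arithmetic identities, parameter-recovery simulations, FDR
calibration and numerical-oracle equivalences); the remaining files are
per-module unit and property tests.

See `docs/methods.md` for definitions, conventions (coordinates, splice
site numbering, inclusion-rate accounting) and modelling decisions.
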