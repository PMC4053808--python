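"""Synthetic reference data with the statistical structure the pipeline assumes.

Generates toy genomes with spliced gene models (introns always GT..AG),
fully methylated lambda and fully hydroxymethylated pUC19 spike-in contigs,
chromatin tracks (H3K4me1/H3K27ac enhancer peaks, repressive domains, CpG
islands, repeats), a per-strand-cytosine truth methylome, and the derived
sequencing observables: TAB-Seq/BS-Seq cytosine reports and exon-exon
junction reads.

The truth methylome encodes the structures the downstream analyses are
meant to recover: hmC peaks at 5' splice-site positions -2/-1/+4/+5, an
expression-correlated sense-strand hmC excess on gene bodies, elevated hmC
at poised enhancers with central depletion at active enhancers, and hmC
depletion in repressive domains.

Sequencing counts follow a binomial read-out of a mixture probability: a
cytosine with true fractions (f_hmc, f_mc) is read as unconverted with
probability ``f_hmc*p_hmc + f_mc*p_mc + (1-f_hmc-f_mc)*ncr_c`` where under
TAB-Seq ``p_hmc`` is the hmC protection rate and ``p_mc`` the mC
non-conversion rate, and under BS-Seq both modifications protect with
probability ``1 - bs_failure``.  Coverage is Poisson per strand-cytosine.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import REFFLAT_COLUMNS

LAMBDA_NAME = "lambda_spike"
PUC19_NAME = "pUC19_spike"
SPIKE_IN_NAMES = (LAMBDA_NAME, PUC19_NAME)

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

EXPRESSION_GROUPS = ("none", "low", "middle", "high")

# structural constants of the toy genome (bp)
_EXON_LEN = (90, 150)
_INTRON_LEN = (250, 400)
_GENE_GAP = (800, 1500)
_ENH_BLOCK = 14_000
_REP_BLOCK = 9_000
_PEAK_WIDTH = 600
_SS_PLANT_PROB = 0.6


class SizingError(ValueError):
    """Requested gene/track layout does not fit the configured chromosomes."""


def revcomp(seq: str) -> str:
    return seq.encode().translate(_COMPLEMENT)[::-1].decode()


@dataclass
class TruthConfig:
    """Parameters of the synthetic genome and truth methylome."""

    n_chroms: int = 2
    chrom_len: int = 150_000
    n_genes: int = 20
    exons_per_gene: int = 6
    base_hmc: float = 0.25
    base_mc: float = 0.35
    ss_peak_delta: float = 0.15
    strand_bias_delta_by_expression: Mapping[str, float] = field(
        default_factory=lambda: {
            "none": 0.0,
            "low": 0.002,
            "middle": 0.004,
            "high": 0.007,
        }
    )
    enhancer_hmc_delta: float = 0.10
    repressive_hmc_delta: float = -0.10
    noncpg_mc: float = 0.0  # >0 gives the "adult-like" non-CpG mode
    seed: int = 0

    def validate(self) -> None:
        if self.chrom_len < 10_000:
            raise SizingError("chrom_len must be at least 10 kb")
        if self.exons_per_gene < 3:
            raise SizingError(
                "exons_per_gene must be >= 3 so internal exons exist"
            )
        for name, value in [
            ("base_hmc", self.base_hmc),
            ("base_mc", self.base_mc),
            ("ss_peak_delta", self.ss_peak_delta),
            ("enhancer_hmc_delta", self.enhancer_hmc_delta),
            ("noncpg_mc", self.noncpg_mc),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not -1.0 <= self.repressive_hmc_delta <= 1.0:
            raise ValueError("repressive_hmc_delta must lie in [-1, 1]")
        for grp, delta in self.strand_bias_delta_by_expression.items():
            if not 0.0 <= delta <= 1.0:
                raise ValueError(f"strand bias delta for {grp!r} not in [0,1]")


@dataclass
class AssayErrorModel:
    """Conversion-error model of one bisulfite-based assay.

    Defaults mirror the adult-brain TAB-Seq calibration: non-conversion of
    unmodified C 0.36%, of mC 1.18%, hmC protection 97.6%.
    """

    ncr_c: float = 0.0036
    ncr_mc: float = 0.0118
    protection_hmc: float = 0.976
    bs_failure: float = 0.005
    mean_coverage: float = 20.0

    def validate(self) -> None:
        for name in ("ncr_c", "ncr_mc", "protection_hmc", "bs_failure"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")


@dataclass
class ReferenceBundle:
    """In-memory reference: genome, gene models, tracks, expression truth."""

    genome: dict[str, str]
    genes: pd.DataFrame
    tracks: dict[str, pd.DataFrame]
    expression: pd.DataFrame
    cfg: TruthConfig
    total_mapped: int
    spike_ins: tuple[str, str] = SPIKE_IN_NAMES


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n)


def _build_gene(
    rng: np.random.Generator, n_exons: int
) -> tuple[np.ndarray, list[tuple[int, int]], list[int]]:
    """Build one gene's sense-strand sequence.

    Returns (sequence array, exon offsets [(start, end)) in sense coords,
    planted 5'ss CpG positions per internal exon or -99 for none).
    """
    exon_lens = rng.integers(_EXON_LEN[0], _EXON_LEN[1] + 1, n_exons)
    intron_lens = rng.integers(_INTRON_LEN[0], _INTRON_LEN[1] + 1, n_exons - 1)
    total = int(exon_lens.sum() + intron_lens.sum())
    seq = _random_seq(rng, total)
    exon_offsets: list[tuple[int, int]] = []
    cursor = 0
    intron_starts: list[int] = []
    for k in range(n_exons):
        exon_offsets.append((cursor, cursor + int(exon_lens[k])))
        cursor += int(exon_lens[k])
        if k < n_exons - 1:
            intron_starts.append(cursor)
            cursor += int(intron_lens[k])
    # canonical splice sites: intron starts GT, ends AG
    for k, istart in enumerate(intron_starts):
        iend = istart + int(intron_lens[k])
        seq[istart] = ord("G")
        seq[istart + 1] = ord("T")
        seq[iend - 2] = ord("A")
        seq[iend - 1] = ord("G")
    # plant 5'ss CpGs on a subset of internal exons
    planted = []
    for k in range(1, n_exons - 1):
        pos = -99
        if rng.random() < _SS_PLANT_PROB:
            pos = int(rng.choice([-2, -1, 4, 5]))
            ss = exon_offsets[k][1]  # first intron base offset (= +1)
            if pos == -2:
                seq[ss - 2] = ord("C")
                seq[ss - 1] = ord("G")
            elif pos == -1:
                seq[ss - 1] = ord("C")  # CpG spans into the intron's G
            elif pos == 4:
                seq[ss + 3] = ord("C")
                seq[ss + 4] = ord("G")
            elif pos == 5:
                seq[ss + 4] = ord("C")
                seq[ss + 5] = ord("G")
        planted.append(pos)
    return seq, exon_offsets, planted


def gen_reference(cfg: TruthConfig, total_mapped: int = 2_000_000) -> ReferenceBundle:
    """Generate the reference bundle: genome, gene models and tracks.

    Chromosomes alternate gene clusters with large intergenic blocks that
    host distal enhancer peaks and repressive domains (so that the distal
    rule TSS +/- 2.5 kb leaves them intact).  Two spike-in contigs with
    reserved names are appended.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome: dict[str, str] = {}
    gene_rows = []
    h3k4me1, h3k27ac = [], []
    active_truth, poised_truth = [], []
    repressive, cgis, repeats = [], [], []

    genes_per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        genes_per_chrom[i] += 1

    gene_id = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = _random_seq(rng, cfg.chrom_len)
        cursor = 1_000
        n_here = genes_per_chrom[ci]
        for gi in range(n_here):
            strand = "+" if (gene_id % 2 == 0) else "-"
            gseq, exon_offsets, _ = _build_gene(rng, cfg.exons_per_gene)
            glen = len(gseq)
            gap = int(rng.integers(*_GENE_GAP))
            start = cursor + gap
            end = start + glen
            if end > cfg.chrom_len - _ENH_BLOCK - 2_000:
                raise SizingError(
                    f"gene {gene_id} does not fit on {chrom}: need {end} bp "
                    f"of {cfg.chrom_len}; increase chrom_len or reduce n_genes"
                )
            if strand == "+":
                seq[start:end] = gseq
                ex_starts = [start + a for a, _ in exon_offsets]
                ex_ends = [start + b for _, b in exon_offsets]
            else:
                rc = np.frombuffer(
                    gseq.tobytes().translate(_COMPLEMENT)[::-1], dtype=np.uint8
                )
                seq[start:end] = rc
                # sense offset [a,b) maps to genomic [start+L-b, start+L-a)
                ex_starts = sorted(start + glen - b for _, b in exon_offsets)
                ex_ends = sorted(start + glen - a for a, _ in exon_offsets)
            name = f"gene_{gene_id:04d}"
            gene_rows.append(
                {
                    "gene": name,
                    "transcript": f"tx_{gene_id:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "tx_start": start,
                    "tx_end": end,
                    "cds_start": start,
                    "cds_end": end,
                    "exon_count": cfg.exons_per_gene,
                    "exon_starts": ex_starts,
                    "exon_ends": ex_ends,
                }
            )
            tss = start if strand == "+" else end - 1
            if gene_id % 2 == 0:
                cgis.append((chrom, max(0, tss - 200), tss + 200))
            # an occasional TSS-proximal H3K4me1 peak (must be filtered out
            # by the distal rule downstream)
            if gene_id % 7 == 0:
                h3k4me1.append((chrom, max(0, tss - 300), tss + 300))
            cursor = end
            gene_id += 1
            # every third gene, insert a large intergenic block with tracks
            if gi % 3 == 2 or gi == n_here - 1:
                block_start = cursor + 2_500
                block_end = block_start + _ENH_BLOCK
                if block_end > cfg.chrom_len - 1_000:
                    raise SizingError(
                        f"intergenic block does not fit on {chrom}"
                    )
                mid = (block_start + block_end) // 2
                peak = (chrom, mid - _PEAK_WIDTH // 2, mid + _PEAK_WIDTH // 2)
                h3k4me1.append(peak)
                if (len(h3k4me1) % 2) == 0:
                    h3k27ac.append(
                        (chrom, peak[1] - 100, peak[2] + 100)
                    )
                    active_truth.append(peak)
                else:
                    poised_truth.append(peak)
                repeats.append(
                    (chrom, block_start + 500, block_start + 900)
                )
                cursor = block_end
        # one repressive domain per chromosome tail
        rep_start = cursor + 3_000
        rep_end = rep_start + _REP_BLOCK
        if rep_end > cfg.chrom_len:
            raise SizingError(f"repressive block does not fit on {chrom}")
        repressive.append((chrom, rep_start + 1_500, rep_end - 1_500))
        genome[chrom] = seq.tobytes().decode()

    # spike-in contigs
    genome[LAMBDA_NAME] = _random_seq(rng, 3_000).tobytes().decode()
    genome[PUC19_NAME] = _random_seq(rng, 1_600).tobytes().decode()

    genes = pd.DataFrame(gene_rows, columns=REFFLAT_COLUMNS)

    def _bed(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    tracks = {
        "h3k4me1": _bed(h3k4me1),
        "h3k27ac": _bed(h3k27ac),
        "enhancer_active_truth": _bed(active_truth),
        "enhancer_poised_truth": _bed(poised_truth),
        "h3k9me3": _bed(repressive),
        "cgi": _bed(cgis),
        "repeat": _bed(repeats),
    }

    # expression truth: groups cycle through genes; RPKM set per group
    groups = [EXPRESSION_GROUPS[i % 4] for i in range(cfg.n_genes)]
    rpkm_centre = {"none": 0.0, "low": 0.5, "middle": 5.0, "high": 50.0}
    exonic_kb = np.array(
        [
            sum(e - s for s, e in zip(r["exon_starts"], r["exon_ends"])) / 1e3
            for r in gene_rows
        ]
    )
    rpkm_truth = np.array(
        [
            0.0 if g == "none" else rpkm_centre[g] * rng.uniform(0.7, 1.3)
            for g in groups
        ]
    )
    counts = rng.poisson(rpkm_truth * exonic_kb * (total_mapped / 1e6))
    expression = pd.DataFrame(
        {
            "gene": genes["gene"],
            "group_truth": groups,
            "rpkm_truth": rpkm_truth,
            "rna_count": counts,
        }
    )
    return ReferenceBundle(
        genome=genome,
        genes=genes,
        tracks=tracks,
        expression=expression,
        cfg=cfg,
        total_mapped=total_mapped,
    )


# ---------------------------------------------------------------------------
# Truth methylome


def cytosine_table(genome: Mapping[str, str]) -> pd.DataFrame:
    """Enumerate every strand-cytosine with its context and trinucleotide.

    Positions are 1-based.  Context is CG/CHG/CHH read in strand
    orientation; the first/last two bases of each contig are skipped so the
    trinucleotide is always defined.
    """
    frames = []
    for chrom, s in genome.items():
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        n = len(arr)
        # plus strand: C at i, context from i+1, i+2
        plus = np.where(arr[: n - 2] == ord("C"))[0]
        plus = plus[plus >= 2]
        nx1, nx2 = arr[plus + 1], arr[plus + 2]
        ctx_p = np.where(
            nx1 == ord("G"), "CG", np.where(nx2 == ord("G"), "CHG", "CHH")
        )
        tri_p = (
            np.stack([arr[plus], nx1, nx2], axis=1)
            .astype(np.uint8)
            .tobytes()
            .decode()
        )
        tri_p = [tri_p[3 * i : 3 * i + 3] for i in range(len(plus))]
        # minus strand: G at i, neighbours at i-1, i-2 (complemented)
        minus = np.where(arr[2:] == ord("G"))[0] + 2
        minus = minus[minus <= n - 3]
        pv1, pv2 = arr[minus - 1], arr[minus - 2]
        ctx_m = np.where(
            pv1 == ord("C"), "CG", np.where(pv2 == ord("C"), "CHG", "CHH")
        )
        tri_m_bytes = (
            np.stack([pv2, pv1, arr[minus]], axis=1)
            .astype(np.uint8)
            .tobytes()
            .translate(_COMPLEMENT)
            .decode()
        )
        tri_m = [
            tri_m_bytes[3 * i : 3 * i + 3][::-1] for i in range(len(minus))
        ]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": plus + 1,
                    "strand": "+",
                    "context": ctx_p,
                    "trinucleotide": tri_p,
                }
            )
        )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": minus + 1,
                    "strand": "-",
                    "context": ctx_m,
                    "trinucleotide": tri_m,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["chrom", "pos", "strand"], ignore_index=True)
    return df


class _SiteIndex:
    """Fast lookup of truth-table rows by (chrom, strand) and position."""

    def __init__(self, truth: pd.DataFrame):
        self._index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        grouped = truth.groupby(["chrom", "strand"], sort=False)
        for key, sub in grouped:
            self._index[key] = (
                sub["pos"].to_numpy(),
                sub.index.to_numpy(),
            )

    def rows_at(self, chrom: str, strand: str, positions: np.ndarray) -> np.ndarray:
        key = (chrom, strand)
        if key not in self._index:
            return np.array([], dtype=int)
        pos, rows = self._index[key]
        loc = np.searchsorted(pos, positions)
        ok = (loc < len(pos)) & (pos[np.minimum(loc, len(pos) - 1)] == positions)
        return rows[loc[ok]]

    def rows_in_range(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Rows with 1-based position in [start, end]."""
        key = (chrom, strand)
        if key not in self._index:
            return np.array([], dtype=int)
        pos, rows = self._index[key]
        lo, hi = np.searchsorted(pos, [start, end + 1])
        return rows[lo:hi]


def internal_exon_ss_positions(gene_row: pd.Series) -> np.ndarray:
    """1-based sense-strand candidate 5'ss CpG positions (-2,-1,+4,+5)
    for every internal exon of a gene, flattened."""
    starts, ends = gene_row["exon_starts"], gene_row["exon_ends"]
    n = len(starts)
    out = []
    internal = range(1, n - 1)
    for k in internal:
        if gene_row["strand"] == "+":
            ss = ends[k]  # genomic 0-based offset of intron base +1
            out.extend([ss - 2, ss - 1, ss + 3, ss + 4])  # -2,-1,+4,+5
        else:
            gk = n - 1 - k  # genomic index of transcript exon k
            ss = starts[gk] - 1  # genomic 0-based offset of intron base +1
            out.extend([ss + 2, ss + 1, ss - 3, ss - 4])
    return np.asarray(out, dtype=int) + 1  # 1-based


def gen_truth(ref: ReferenceBundle, cfg: TruthConfig | None = None) -> pd.DataFrame:
    """Construct the per-strand-cytosine truth methylome.

    Baseline CpG fractions (base_hmc, base_mc) are symmetric across the
    dyad; the configured deltas are then applied additively: 5'ss peak
    positions, sense-strand gene bodies by expression group, poised/active
    enhancers, repressive domains.  Spike-ins: lambda CpGs fully
    methylated (non-CpG unmodified, which is what makes the C
    non-conversion rate estimable), pUC19 cytosines fully
    hydroxymethylated.  All fractions are clipped so f_hmc + f_mc <= 1.
    """
    cfg = cfg or ref.cfg
    truth = cytosine_table(ref.genome)
    is_spike = truth["chrom"].isin(ref.spike_ins)
    is_cg = (truth["context"] == "CG").to_numpy()

    f_hmc = np.zeros(len(truth))
    f_mc = np.zeros(len(truth))
    genome_cg = is_cg & ~is_spike.to_numpy()
    f_hmc[genome_cg] = cfg.base_hmc
    f_mc[genome_cg] = cfg.base_mc
    if cfg.noncpg_mc > 0:  # adult-like non-CpG methylation
        f_mc[~is_cg & ~is_spike.to_numpy()] = cfg.noncpg_mc

    idx = _SiteIndex(truth)

    # CpG islands are lowly modified (promoter-hypomethylation structure)
    for _, iv in ref.tracks["cgi"].iterrows():
        for strand in "+-":
            rows = idx.rows_in_range(
                iv["chrom"], strand, iv["start"] + 1, iv["end"]
            )
            rows = rows[is_cg[rows]]
            f_hmc[rows] *= 0.1
            f_mc[rows] *= 0.1

    # expression-correlated sense-strand hmC excess on gene bodies
    group_of = dict(
        zip(ref.expression["gene"], ref.expression["group_truth"])
    )
    for _, g in ref.genes.iterrows():
        delta = cfg.strand_bias_delta_by_expression.get(group_of[g["gene"]], 0.0)
        if delta == 0.0:
            continue
        rows = idx.rows_in_range(
            g["chrom"], g["strand"], g["tx_start"] + 1, g["tx_end"]
        )
        rows = rows[is_cg[rows]]
        f_hmc[rows] += delta

    # 5'ss peaks at -2/-1/+4/+5 of internal exons (sense strand, CpG only)
    if cfg.ss_peak_delta > 0:
        for _, g in ref.genes.iterrows():
            pos = internal_exon_ss_positions(g)
            rows = idx.rows_at(g["chrom"], g["strand"], np.sort(pos))
            rows = rows[is_cg[rows]]
            f_hmc[rows] += cfg.ss_peak_delta

    def _interval_rows(track: pd.DataFrame) -> list[tuple[np.ndarray, int, int]]:
        out = []
        for _, iv in track.iterrows():
            for strand in "+-":
                rows = idx.rows_in_range(
                    iv["chrom"], strand, iv["start"] + 1, iv["end"]
                )
                out.append((rows[is_cg[rows]], iv["start"], iv["end"]))
        return out

    # poised enhancers: uniformly elevated hmC
    for rows, _, _ in _interval_rows(ref.tracks["enhancer_poised_truth"]):
        f_hmc[rows] += cfg.enhancer_hmc_delta
    # active enhancers: elevated at the edges, depleted at the core
    for rows, start, end in _interval_rows(ref.tracks["enhancer_active_truth"]):
        centre = (start + end) / 2.0
        half_core = (end - start) / 4.0
        pos0 = truth["pos"].to_numpy()[rows] - 1
        core = np.abs(pos0 - centre) <= half_core
        f_hmc[rows[core]] -= cfg.enhancer_hmc_delta
        f_hmc[rows[~core]] += cfg.enhancer_hmc_delta
    # repressive domains: signed delta (negative depletes hmC)
    for rows, _, _ in _interval_rows(ref.tracks["h3k9me3"]):
        f_hmc[rows] += cfg.repressive_hmc_delta

    # spike-ins
    spike_rows = truth.index[is_spike].to_numpy()
    lam = truth["chrom"].to_numpy() == LAMBDA_NAME
    f_mc[lam & is_cg] = 1.0
    f_hmc[lam] = 0.0
    puc = truth["chrom"].to_numpy() == PUC19_NAME
    f_hmc[puc] = 1.0
    f_mc[puc] = 0.0
    del spike_rows

    np.clip(f_hmc, 0.0, 1.0, out=f_hmc)
    np.clip(f_mc, 0.0, 1.0, out=f_mc)
    over = f_hmc + f_mc > 1.0
    f_mc[over] = 1.0 - f_hmc[over]

    truth["f_hmc"] = f_hmc
    truth["f_mc"] = f_mc
    return truth


# ---------------------------------------------------------------------------
# Cytosine report simulation


def mixture_unconverted_prob(
    f_hmc: np.ndarray | float,
    f_mc: np.ndarray | float,
    err: AssayErrorModel,
    assay: str,
) -> np.ndarray | float:
    """Closed-form probability that a read reports this cytosine as C."""
    if assay == "TAB":
        p_hmc, p_mc = err.protection_hmc, err.ncr_mc
    elif assay == "BS":
        p_hmc = p_mc = 1.0 - err.bs_failure
    else:
        raise ValueError(f"assay must be 'TAB' or 'BS', got {assay!r}")
    p = f_hmc * p_hmc + f_mc * p_mc + (1.0 - f_hmc - f_mc) * err.ncr_c
    return np.clip(p, 0.0, 1.0)


def simulate_cytosine_reports(
    truth: pd.DataFrame,
    err: AssayErrorModel,
    assay: str,
    seed: int,
    contexts: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw per-cytosine counts for one assay from the truth methylome.

    Coverage is Poisson(mean_coverage); the unconverted count is binomial
    with the mixture probability.  Zero-coverage sites are retained (with
    0/0 counts) as they are in real cytosine reports.
    """
    err.validate()
    sub = truth if contexts is None else truth[truth["context"].isin(contexts)]
    rng = np.random.default_rng(seed)
    n = len(sub)
    cov = rng.poisson(err.mean_coverage, n)
    p = mixture_unconverted_prob(
        sub["f_hmc"].to_numpy(), sub["f_mc"].to_numpy(), err, assay
    )
    u = rng.binomial(cov, p)
    out = sub[["chrom", "pos", "strand", "context", "trinucleotide"]].copy()
    out["count_unconverted"] = u
    out["count_converted"] = cov - u
    out["n_unconverted"] = u
    out["n_total"] = cov
    out["assay"] = assay
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Junction-read simulation


def make_gene_grid(
    n_genes: int,
    gene_len: int = 4_000,
    gap: int = 2_000,
    groups: Sequence[str] = EXPRESSION_GROUPS,
    overlap_every: int = 0,
    overlap_bp: int = 500,
    chrom: str = "chrS",
) -> pd.DataFrame:
    """Single-exon gene models on a virtual chromosome.

    Strands alternate; ``groups`` are assigned cyclically into a
    ``group_truth`` column.  With ``overlap_every`` = k > 0, every k-th
    gene is shifted to overlap its (opposite-strand) predecessor by
    ``overlap_bp``, creating sense-antisense paired regions.  Intended
    for strand-bias analyses, which only use transcript bounds.
    """
    rows = []
    cursor = 1_000
    for i in range(n_genes):
        start = cursor
        if overlap_every and i % overlap_every == overlap_every - 1 and i > 0:
            start = cursor - gap - overlap_bp
        end = start + gene_len
        rows.append(
            {
                "gene": f"g{i:04d}",
                "transcript": f"t{i:04d}",
                "chrom": chrom,
                "strand": "+" if i % 2 == 0 else "-",
                "tx_start": start,
                "tx_end": end,
                "cds_start": start,
                "cds_end": end,
                "exon_count": 1,
                "exon_starts": [start],
                "exon_ends": [end],
                "group_truth": groups[i % len(groups)],
            }
        )
        cursor = max(cursor, end) + gap
    return pd.DataFrame(rows)


def simulate_strand_records(
    genes: pd.DataFrame,
    delta_by_group: Mapping[str, float],
    base_hmc: float = 0.25,
    base_mc: float = 0.35,
    cpg_spacing: int = 50,
    coverage: int = 30,
    seed: int = 0,
    flank_bp: int = 0,
) -> pd.DataFrame:
    """Deconvolved CpG records over a gene grid, with sense-strand hmC excess.

    Places a CpG dyad every ``cpg_spacing`` bp across the genes' span
    (plus optional flanks); the sense strand of each gene body carries an
    hmC excess given by its expression group (additive where bodies
    overlap).  Counts are binomial at fixed ``coverage`` from an
    error-free read-out, yielding the record table the strand-bias
    analyses consume (bs/tab counts plus modc/hmc/mc frequencies).
    """
    rng = np.random.default_rng(seed)
    lo = int(genes["tx_start"].min()) - flank_bp
    hi = int(genes["tx_end"].max()) + flank_bp
    dyad_pos = np.arange(lo, hi, cpg_spacing)  # 0-based C of the dyad
    frames = []
    for strand, pos0 in (("+", dyad_pos), ("-", dyad_pos + 1)):
        f_hmc = np.full(len(pos0), base_hmc, dtype=float)
        for _, g in genes.iterrows():
            delta = delta_by_group.get(g.get("group_truth", "none"), 0.0)
            if delta == 0.0 or g["strand"] != strand:
                continue
            inside = (pos0 >= g["tx_start"]) & (pos0 < g["tx_end"])
            f_hmc[inside] += delta
        f_hmc = np.clip(f_hmc, 0.0, 1.0)
        f_mc = np.minimum(base_mc, 1.0 - f_hmc)
        tab_u = rng.binomial(coverage, f_hmc)
        bs_u = rng.binomial(coverage, np.clip(f_hmc + f_mc, 0, 1))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": genes["chrom"].iloc[0],
                    "pos": pos0 + 1,
                    "strand": strand,
                    "bs_u": bs_u,
                    "bs_t": coverage,
                    "tab_u": tab_u,
                    "tab_t": coverage,
                }
            )
        )
    rec = pd.concat(frames, ignore_index=True)
    rec["modc"] = rec["bs_u"] / rec["bs_t"]
    rec["hmc"] = rec["tab_u"] / rec["tab_t"]
    rec["mc"] = np.clip(rec["modc"] - rec["hmc"], 0.0, 1.0)
    return rec.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def gene_exon_sequences(
    genome: Mapping[str, str], gene_row: pd.Series
) -> list[str]:
    """Sense-strand exon sequences in transcript order."""
    seq = genome[gene_row["chrom"]]
    exons = [
        seq[s:e] for s, e in zip(gene_row["exon_starts"], gene_row["exon_ends"])
    ]
    if gene_row["strand"] == "-":
        exons = [revcomp(e) for e in reversed(exons)]
    return exons


def simulate_junction_reads(
    gene_row: pd.Series,
    genome: Mapping[str, str],
    psi_per_exon: Mapping[int, float],
    n_reads: int,
    read_len: int,
    seed: int,
) -> tuple[list[str], dict[int, float]]:
    """Sample mRNA-fragment reads from isoforms of one gene.

    Internal exon ``k`` (transcript-order index; first and last exons are
    constitutive) is included in a transcript independently with
    probability ``psi_per_exon[k]``.  Reads are drawn as fragments from
    the resulting mRNA pool: every transcript contributes start positions
    in proportion to its length, so per-position coverage of each
    isoform is proportional to its abundance and junction read counts
    are unbiased estimators of isoform fractions.  Returns the reads and
    the truth psi map.
    """
    if read_len < 16:
        raise ValueError("read_len must be >= 16 so both overhangs can reach 8 nt")
    for k, psi in psi_per_exon.items():
        if not 0.0 <= psi <= 1.0:
            raise ValueError(f"psi for exon {k} outside [0, 1]: {psi}")
    exons = gene_exon_sequences(genome, gene_row)
    n_ex = len(exons)
    variable = sorted(k for k in psi_per_exon if 0 < k < n_ex - 1)
    # Enumerate isoforms over the variable exons; weight each by its
    # abundance times its number of valid read start positions.
    isoforms: list[str] = []
    weights: list[float] = []
    for bits in itertools.product((True, False), repeat=len(variable)):
        keep = [True] * n_ex
        abundance = 1.0
        for k, kp in zip(variable, bits):
            keep[k] = kp
            abundance *= psi_per_exon[k] if kp else 1.0 - psi_per_exon[k]
        mrna = "".join(e for e, kp in zip(exons, keep) if kp)
        n_starts = len(mrna) - read_len + 1
        if abundance > 0 and n_starts > 0:
            isoforms.append(mrna)
            weights.append(abundance * n_starts)
    if not isoforms:
        raise ValueError("no isoform long enough to yield reads")
    w = np.asarray(weights) / sum(weights)
    rng = np.random.default_rng(seed)
    reads = []
    for i in rng.choice(len(isoforms), size=n_reads, p=w):
        mrna = isoforms[i]
        start = int(rng.integers(0, len(mrna) - read_len + 1))
        reads.append(mrna[start : start + read_len])
    return reads, dict(psi_per_exon)
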