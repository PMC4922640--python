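"""Synthetic genomes, annotation tracks, reads and expression counts.

The generator emulates the statistical structure of methylation-enrichment
sequencing of a small exposure cohort with known ground truth:

* a miniature multi-chromosome genome with CpG-island, gene-model and
  repeat tracks (optionally X-like and Y-like chromosomes);
* per-sample read start positions whose window-level counts are exactly
  negative-binomial with a requested mean structure and dispersion — read
  density is elevated inside CpG islands by a configurable enrichment
  factor, spiked truth windows receive a group-dependent 2^log2FC intensity,
  females carry (near-)zero Y-like signal and a 2x X-like dosage;
* gene-level expression counts with a subset of genes coupled to spiked
  methylation regions with the opposite effect sign.

Mechanics of the NB guarantee: each chromosome is divided into step-sized
cells; each cell receives an independent Gamma multiplier with shape
1/(M*phi) (M = cells per window) and Poisson reads given its rate, so the
count in any window-aligned run of M cells is marginally NB(mean, phi).
Randomness is drawn from per-sample PRNG streams keyed by (seed, sample id),
so adding samples never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import AnnotationTrack
from .genome import GenomeSpec, trichotomize_bpa

__all__ = [
    "COMPARISONS",
    "SpikedWindow",
    "DEGene",
    "TruthTable",
    "simulate_genome",
    "simulate_sample_sheet",
    "random_truth",
    "simulate_methylation_reads",
    "simulate_expression_counts",
]

#: comparison label -> (lower-dose group, higher-dose group); the sex
#: comparison keys on the sample sheet's sex column instead of its group
#: column and exists to inject true autosomal sex differences.
COMPARISONS = {
    "nd_vs_low": ("non_detect", "low"),
    "nd_vs_high": ("non_detect", "high"),
    "low_vs_high": ("low", "high"),
    "male_vs_female": ("male", "female"),
}


@dataclass(frozen=True)
class SpikedWindow:
    chrom: str
    start: int
    end: int
    log2fc: float
    comparison: str


@dataclass(frozen=True)
class DEGene:
    gene_id: str
    log2fc: float
    comparison: str


@dataclass
class TruthTable:
    """Ground truth: spiked methylation windows, DE genes, and the coupling
    between spiked regions and inversely-regulated genes."""

    spiked_windows: list = field(default_factory=list)
    de_genes: list = field(default_factory=list)
    #: (chrom, region_start, region_end) -> gene_id
    coupling: dict = field(default_factory=dict)

    def validate(self, genome: GenomeSpec):
        for w in self.spiked_windows:
            if w.chrom not in genome.chrom_names:
                raise ValueError(f"spiked window on unknown chromosome {w.chrom!r}")
            if not 0 <= w.start < w.end <= genome.length(w.chrom):
                raise ValueError(
                    f"spiked window {w.chrom}:{w.start}-{w.end} outside genome bounds"
                )
            if w.comparison not in COMPARISONS:
                raise ValueError(f"unknown comparison {w.comparison!r}")

    def spiked_regions(self) -> list:
        """Merge per-window truth into contiguous (chrom, start, end,
        log2fc, comparison) regions."""
        regions = []
        key = lambda w: (w.comparison, w.chrom, w.log2fc)
        for _, group in pd.DataFrame(
            [(key(w), w) for w in self.spiked_windows], columns=["k", "w"]
        ).groupby("k"):
            ws = sorted(group["w"], key=lambda w: w.start)
            cur = None
            for w in ws:
                if cur is not None and w.start <= cur[2]:
                    cur[2] = max(cur[2], w.end)
                else:
                    if cur is not None:
                        regions.append(tuple(cur))
                    cur = [w.chrom, w.start, w.end, w.log2fc, w.comparison]
            if cur is not None:
                regions.append(tuple(cur))
        return [
            SpikedWindow(c, s, e, f, comp) for c, s, e, f, comp in regions
        ]


def _rng(seed, *extra) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *extra]))


def _sample_rng(seed, sample_id: str) -> np.random.Generator:
    return _rng(seed, 1, zlib.crc32(str(sample_id).encode()))


def _place_nonoverlapping(rng, L, k, lengths, min_gap):
    """Place exactly k non-overlapping intervals of the given lengths
    uniformly on [0, L), separated by at least min_gap bp.  Drops intervals
    from the end if they cannot fit (rare at realistic densities)."""
    lengths = list(lengths)
    while k > 0 and sum(lengths[:k]) + (k + 1) * min_gap > L:
        k -= 1
    if k == 0:
        return np.empty((0, 2), dtype=np.int64)
    lens = np.asarray(lengths[:k], dtype=np.int64)
    slack = L - int(lens.sum()) - (k + 1) * min_gap
    cuts = np.sort(rng.integers(0, slack + 1, size=k))
    gaps = np.diff(np.concatenate(([0], cuts))) + min_gap
    starts = np.cumsum(gaps) + np.cumsum(np.concatenate(([0], lens[:-1])))
    return np.stack([starts, starts + lens], axis=1)


def simulate_genome(
    n_chroms: int = 3,
    mean_length_bp: int = 1_000_000,
    cgi_density: float = 5e-5,
    gene_density: float = 1e-5,
    repeat_fraction: float = 0.3,
    seed: int = 0,
    sex_chroms: bool = False,
    x_length_frac: float = 0.8,
    y_length_frac: float = 0.4,
):
    """Generate a miniature genome with CGI, gene and repeat tracks.

    ``cgi_density`` and ``gene_density`` are expected features per bp;
    feature counts per chromosome are Poisson with that intensity.
    ``repeat_fraction`` is the expected fraction of the genome covered by
    repeats (placed independently; they may overlap genes and CGIs).  With
    ``sex_chroms``, an X-like and a shorter Y-like chromosome are appended.

    Returns ``(GenomeSpec, AnnotationTrack)``; byte-identical per seed.
    """
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if mean_length_bp < 10_000:
        raise ValueError("mean_length_bp must be >= 10000")
    for name, val in [
        ("cgi_density", cgi_density),
        ("gene_density", gene_density),
        ("repeat_fraction", repeat_fraction),
    ]:
        if val < 0:
            raise ValueError(f"{name} must be >= 0, got {val}")

    rng = _rng(seed, 0)
    names, lengths = [], []
    for i in range(n_chroms):
        names.append(f"chr{i + 1}")
        lengths.append(int(mean_length_bp * rng.uniform(0.8, 1.2)))
    if sex_chroms:
        names += ["chrX", "chrY"]
        lengths += [int(x_length_frac * mean_length_bp), int(y_length_frac * mean_length_bp)]
    genome = GenomeSpec(
        chrom_names=tuple(names),
        chrom_lengths=tuple(lengths),
        x_like=frozenset({"chrX"}) if sex_chroms else frozenset(),
        y_like="chrY" if sex_chroms else None,
    )

    cgi, repeats, gene_rows = {}, {}, []
    for name, L in zip(names, lengths):
        k = rng.poisson(cgi_density * L)
        iv = _place_nonoverlapping(rng, L, k, rng.integers(200, 2001, size=k), 10)
        if len(iv):
            cgi[name] = iv

        k = rng.poisson(gene_density * L)
        glens = rng.integers(2000, 10001, size=k)
        giv = _place_nonoverlapping(rng, L, k, glens, 200)
        for gi, (gs, ge) in enumerate(giv):
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 5))
            glen = ge - gs
            if n_ex > 1:
                cuts = np.sort(rng.choice(np.arange(1, glen), 2 * n_ex - 2, replace=False))
            else:
                cuts = np.array([], dtype=np.int64)
            bounds = np.concatenate(([0], cuts, [glen])) + gs
            exon_starts = tuple(int(b) for b in bounds[0:-1:2])
            exon_ends = tuple(int(b) for b in bounds[1::2])
            gene_rows.append(
                {
                    "gene_id": f"{name}_g{gi:04d}",
                    "chrom": name,
                    "strand": strand,
                    "tss": int(gs) if strand == "+" else int(ge) - 1,
                    "start": int(gs),
                    "end": int(ge),
                    "exon_starts": exon_starts,
                    "exon_ends": exon_ends,
                }
            )

        if repeat_fraction > 0:
            mean_rep = 300
            k = rng.poisson(repeat_fraction * L / mean_rep)
            rlens = rng.integers(100, 501, size=k)
            rstarts = rng.integers(0, np.maximum(1, L - rlens))
            if k:
                repeats[name] = np.stack([rstarts, rstarts + rlens], axis=1)

    genes = pd.DataFrame(
        gene_rows,
        columns=[
            "gene_id", "chrom", "strand", "tss", "start", "end",
            "exon_starts", "exon_ends",
        ],
    )
    track = AnnotationTrack(cgi=cgi, repeats=repeats, genes=genes)
    return genome, track


def simulate_sample_sheet(n_per_group: int = 6, seed: int = 0) -> pd.DataFrame:
    """A trichotomized exposure cohort with alternating sexes per group.

    BPA concentrations are drawn uniformly inside each group's defining
    range (non-detect < 0.83, low 3.50-5.79, high 35.44-96.76 ng/g).
    """
    rng = _rng(seed, 2)
    ranges = {"non_detect": (0.0, 0.83), "low": (3.50, 5.79), "high": (35.44, 96.76)}
    rows = []
    i = 0
    for group, (lo, hi) in ranges.items():
        for j in range(n_per_group):
            i += 1
            rows.append(
                {
                    "id": f"s{i:02d}",
                    "sex": "male" if j % 2 == 0 else "female",
                    "bpa_ng_per_g": round(float(rng.uniform(lo, hi)), 3),
                }
            )
    sheet = pd.DataFrame(rows)
    sheet["group"] = [trichotomize_bpa(v) for v in sheet["bpa_ng_per_g"]]
    return sheet


def random_truth(
    genome: GenomeSpec,
    n_spikes: int = 20,
    log2fc: float = 2.0,
    windows_per_spike: int = 4,
    comparison: str = "nd_vs_high",
    seed: int = 0,
    window_size: int = 100,
    step: int = 50,
    signs=(-1, 1),
    annotations: AnnotationTrack = None,
    couple_fraction: float = 0.0,
    expr_log2fc: float = 1.5,
    autosomes_only: bool = True,
    min_separation: int = 2000,
) -> TruthTable:
    """Spike grid-aligned differential regions (and optionally couple them
    to genes with opposite-signed expression effects).

    Each spike is a run of ``windows_per_spike`` consecutive tiling windows
    sharing one true log2 fold change whose sign is drawn from ``signs``.
    With ``couple_fraction`` > 0 and gene models available, that fraction of
    spikes is centred on a gene TSS and the gene added to ``de_genes`` with
    effect ``-sign * expr_log2fc``.
    """
    rng = _rng(seed, 3)
    region_len = window_size + (windows_per_spike - 1) * step
    chroms = [
        (c, L)
        for c, L in zip(genome.chrom_names, genome.chrom_lengths)
        if (not autosomes_only or genome.is_autosome(c)) and L > region_len + 2 * min_separation
    ]
    if not chroms:
        raise ValueError("no chromosome long enough for the requested spikes")

    truth = TruthTable()
    n_coupled = int(round(couple_fraction * n_spikes))
    if n_coupled and (annotations is None or len(annotations.genes) == 0):
        raise ValueError("coupling requested but no gene models given")
    coupled_genes = []
    if n_coupled:
        pool = annotations.genes[
            annotations.genes["chrom"].isin([c for c, _ in chroms])
        ]
        idx = rng.choice(len(pool), size=min(n_coupled, len(pool)), replace=False)
        coupled_genes = [pool.iloc[int(i)] for i in idx]

    placed = {}

    def try_place(chrom, L, start):
        start = max(min_separation, min(start, L - region_len - min_separation))
        start = (start // step) * step
        for s in placed.get(chrom, []):
            if abs(s - start) < region_len + min_separation:
                return None
        placed.setdefault(chrom, []).append(start)
        return start

    spikes = []
    for g in coupled_genes:
        start = try_place(g["chrom"], genome.length(g["chrom"]), g["tss"] - region_len // 2)
        if start is None:
            continue
        spikes.append((g["chrom"], start, g))
    attempts = 0
    while len(spikes) < n_spikes and attempts < 50 * n_spikes:
        attempts += 1
        weights = np.array([L for _, L in chroms], dtype=float)
        ci = rng.choice(len(chroms), p=weights / weights.sum())
        chrom, L = chroms[ci]
        start = try_place(chrom, L, int(rng.integers(0, L - region_len)))
        if start is not None:
            spikes.append((chrom, start, None))

    for chrom, start, gene in spikes:
        sign = int(rng.choice(list(signs)))
        fc = sign * abs(log2fc)
        for j in range(windows_per_spike):
            truth.spiked_windows.append(
                SpikedWindow(chrom, start + j * step, start + j * step + window_size, fc, comparison)
            )
        if gene is not None:
            truth.coupling[(chrom, start, start + region_len)] = gene["gene_id"]
            truth.de_genes.append(
                DEGene(gene["gene_id"], -sign * abs(expr_log2fc), comparison)
            )
    truth.validate(genome)
    return truth


def simulate_methylation_reads(
    genome: GenomeSpec,
    annotations: AnnotationTrack,
    sample_sheet: pd.DataFrame,
    depth_per_sample: float = 100_000,
    cgi_enrichment_factor: float = 5.0,
    truth: TruthTable = None,
    dispersion: float = 0.1,
    seed: int = 0,
    window_size: int = 100,
    step: int = 50,
    female_y_leakage: float = 0.0,
    female_x_dosage: float = 2.0,
) -> dict:
    """Per-sample read start positions as {sample_id: DataFrame(chrom, start)}.

    ``depth_per_sample`` is the expected read total of the baseline (sex- and
    enrichment-adjusted) intensity before spike multipliers are applied, so
    a spike changes local, not global, abundance.
    """
    if depth_per_sample <= 0:
        raise ValueError("depth_per_sample must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if cgi_enrichment_factor <= 0:
        raise ValueError("cgi_enrichment_factor must be positive")
    truth = truth or TruthTable()
    truth.validate(genome)

    cells_per_window = window_size / step
    # base (sample-independent) cell weights: cell length, CGI-boosted
    base = {}
    cell_starts = {}
    for chrom, L in zip(genome.chrom_names, genome.chrom_lengths):
        n_cells = -(-L // step)
        starts = np.arange(n_cells, dtype=np.int64) * step
        lens = np.minimum(starts + step, L) - starts
        w = lens.astype(float)
        for a, b in annotations.cgi.get(chrom, []):
            lo, hi = int(a) // step, (int(b) - 1) // step
            idx = np.arange(lo, hi + 1)
            ov = np.minimum(b, starts[idx] + lens[idx]) - np.maximum(a, starts[idx])
            w[idx] += (cgi_enrichment_factor - 1.0) * ov
        base[chrom] = w
        cell_starts[chrom] = (starts, lens)

    regions = truth.spiked_regions()
    sheet = sample_sheet.set_index("id")
    out = {}
    for sid in sample_sheet["id"]:
        rng = _sample_rng(seed, sid)
        sex = sheet.loc[sid, "sex"]
        group = sheet.loc[sid, "group"]
        weights = {}
        for chrom in genome.chrom_names:
            w = base[chrom].copy()
            if sex == "female":
                if chrom == genome.y_like:
                    w *= female_y_leakage
                elif chrom in genome.x_like:
                    w *= female_x_dosage
            weights[chrom] = w
        total = sum(w.sum() for w in weights.values())
        scale = depth_per_sample / total
        chrom_frames = []
        for chrom in genome.chrom_names:
            rate = weights[chrom] * scale
            for reg in regions:
                if reg.chrom != chrom:
                    continue
                key = sex if reg.comparison == "male_vs_female" else group
                if key == COMPARISONS[reg.comparison][1]:
                    lo, hi = reg.start // step, (reg.end - 1) // step
                    rate[lo : hi + 1] *= 2.0 ** reg.log2fc
            if dispersion > 0:
                shape = 1.0 / (cells_per_window * dispersion)
                g = rng.gamma(shape, 1.0 / shape, size=len(rate))
                lam = rate * g
            else:
                lam = rate
            counts = rng.poisson(lam)
            starts, lens = cell_starts[chrom]
            rep_starts = np.repeat(starts, counts)
            rep_lens = np.repeat(lens, counts)
            if len(rep_starts):
                pos = rep_starts + rng.integers(0, rep_lens)
                chrom_frames.append(
                    pd.DataFrame({"chrom": chrom, "start": np.sort(pos)})
                )
        out[sid] = (
            pd.concat(chrom_frames, ignore_index=True)
            if chrom_frames
            else pd.DataFrame({"chrom": [], "start": []})
        )
    return out


def simulate_expression_counts(
    gene_models: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    truth: TruthTable = None,
    baseline_mean: float = 100.0,
    dispersion: float = 0.1,
    seed: int = 0,
    baseline_log2_sd: float = 0.5,
) -> pd.DataFrame:
    """Gene x sample NB expression counts with truth-driven group effects.

    Per-gene baselines are log-normal around ``baseline_mean`` (spread
    ``baseline_log2_sd`` in log2).  Genes listed in ``truth.de_genes`` have
    their mean multiplied by 2^log2FC in the higher-dose group of their
    comparison.  Columns are drawn from per-sample PRNG streams.
    """
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    truth = truth or TruthTable()
    gene_ids = list(gene_models["gene_id"])
    known = set(gene_ids)
    for dg in truth.de_genes:
        if dg.gene_id not in known:
            raise KeyError(f"truth gene {dg.gene_id!r} not in gene models")

    rng0 = _rng(seed, 4)
    base = baseline_mean * 2.0 ** rng0.normal(0.0, baseline_log2_sd, size=len(gene_ids))
    effects = {}  # gene index -> (high group, multiplier)
    for dg in truth.de_genes:
        gi = gene_ids.index(dg.gene_id)
        effects[gi] = (COMPARISONS[dg.comparison][1], 2.0 ** dg.log2fc)

    sheet = sample_sheet.set_index("id")
    cols = {}
    for sid in sample_sheet["id"]:
        rng = _sample_rng(seed, f"expr:{sid}")
        mu = base.copy()
        group = sheet.loc[sid, "group"]
        for gi, (high, mult) in effects.items():
            if group == high:
                mu[gi] *= mult
        if dispersion > 0:
            lam = rng.gamma(1.0 / dispersion, dispersion * mu)
        else:
            lam = mu
        cols[sid] = rng.poisson(lam)
    return pd.DataFrame(cols, index=gene_ids)
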