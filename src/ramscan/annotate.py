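"""Genomic-context annotation of windows and RAMs.

Context layers:

* CpG-island geography — island (overlap), shore (within 2 kb of an island
  edge), shelf (2-4 kb), open sea (farther); precedence island > shore >
  shelf, measured from island edges.
* Gene features — TSR (+/- 50 bp of the TSS by default), promoter (-500 to
  +100 bp of the TSS, strand-aware), exon, intron, gene locus (full
  transcript extent), intergenic (none of the genic/promoter classes).
* Repeats — an orthogonal flag for any repeat overlap.
* Nearest TSS with signed distance (downstream positive relative to gene
  strand), measured from the window midpoint.

Intervals are 0-based half-open; tracks are merged on construction so
overlap queries reduce to a binary search on sorted non-overlapping
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .genome import GenomeSpec

__all__ = [
    "AnnotationTrack",
    "classify_cgi_context",
    "nearest_tss",
    "classify_features",
    "chrom_distribution",
    "overlap_sets",
]


def merge_intervals(intervals) -> np.ndarray:
    """Sort and merge possibly-overlapping (start, end) pairs."""
    iv = sorted((int(s), int(e)) for s, e in intervals)
    out = []
    for s, e in iv:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def _overlaps(starts: np.ndarray, ends: np.ndarray, s, e) -> np.ndarray:
    """Vectorized: does window [s_i, e_i) overlap any merged interval?"""
    s = np.atleast_1d(np.asarray(s, dtype=np.int64))
    e = np.atleast_1d(np.asarray(e, dtype=np.int64))
    if len(starts) == 0:
        return np.zeros(len(s), dtype=bool)
    i = np.searchsorted(starts, e, side="left")
    hit = np.zeros(len(s), dtype=bool)
    nz = i > 0
    hit[nz] = ends[i[nz] - 1] > s[nz]
    return hit


def _edge_distance(starts: np.ndarray, ends: np.ndarray, s, e) -> np.ndarray:
    """Distance in bp from window [s, e) to the nearest interval; 0 if
    overlapping, inf if the chromosome has no intervals."""
    s = np.atleast_1d(np.asarray(s, dtype=np.int64))
    e = np.atleast_1d(np.asarray(e, dtype=np.int64))
    n = len(s)
    if len(starts) == 0:
        return np.full(n, np.inf)
    i = np.searchsorted(starts, e, side="left")
    left = np.where(i > 0, s - ends[np.clip(i - 1, 0, None)], np.inf)
    right = np.where(i < len(starts), starts[np.clip(i, None, len(starts) - 1)] - e, np.inf)
    d = np.minimum(np.maximum(left, 0), np.maximum(right, 0))
    d[_overlaps(starts, ends, s, e)] = 0
    return d


@dataclass
class AnnotationTrack:
    """CGI and repeat interval sets plus gene models.

    ``cgi`` and ``repeats`` map chromosome -> (k, 2) merged interval arrays.
    ``genes`` is a DataFrame with columns gene_id, chrom, strand, tss,
    start, end, exon_starts, exon_ends (exon columns hold tuples of ints).
    """

    cgi: dict = field(default_factory=dict)
    repeats: dict = field(default_factory=dict)
    genes: pd.DataFrame = None

    def __post_init__(self):
        self.cgi = {c: merge_intervals(iv) for c, iv in self.cgi.items()}
        self.repeats = {c: merge_intervals(iv) for c, iv in self.repeats.items()}
        if self.genes is None:
            self.genes = pd.DataFrame(
                columns=[
                    "gene_id", "chrom", "strand", "tss",
                    "start", "end", "exon_starts", "exon_ends",
                ]
            )
        for _, g in self.genes.iterrows():
            expected_tss = g["start"] if g["strand"] == "+" else g["end"] - 1
            if g["tss"] != expected_tss:
                raise ValueError(
                    f"gene {g['gene_id']}: tss {g['tss']} is not the 5' end "
                    f"({expected_tss}) for strand {g['strand']}"
                )
            for es, ee in zip(g["exon_starts"], g["exon_ends"]):
                if not (g["start"] <= es < ee <= g["end"]):
                    raise ValueError(
                        f"gene {g['gene_id']}: exon ({es},{ee}) outside extent"
                    )


def classify_cgi_context(
    windows: pd.DataFrame,
    track: AnnotationTrack,
    shore_bp: int = 2000,
    shelf_bp: int = 4000,
) -> pd.Series:
    """island / shore / shelf / open_sea per window, from CGI edges."""
    out = np.full(len(windows), "open_sea", dtype=object)
    for chrom, sub in windows.groupby(windows["chrom"].astype(str), observed=True):
        iv = track.cgi.get(chrom, np.empty((0, 2), dtype=np.int64))
        s, e = sub["start"].to_numpy(), sub["end"].to_numpy()
        ov = _overlaps(iv[:, 0], iv[:, 1], s, e)
        d = _edge_distance(iv[:, 0], iv[:, 1], s, e)
        lab = np.where(
            ov, "island",
            np.where(d <= shore_bp, "shore", np.where(d <= shelf_bp, "shelf", "open_sea")),
        )
        out[windows.index.get_indexer(sub.index)] = lab
    return pd.Series(out, index=windows.index, name="cgi_context")


def nearest_tss(
    windows: pd.DataFrame, track: AnnotationTrack, max_distance: int = 5000
) -> pd.DataFrame:
    """Nearest TSS per window midpoint, with strand-signed distance.

    Distance sign: positive when the midpoint lies downstream of the TSS in
    the gene's reading direction.  Ties are broken toward the lower TSS
    coordinate, then the lexicographically smaller gene_id.
    """
    if len(track.genes) == 0:
        raise ValueError("no gene models available")
    genes = track.genes.sort_values(["chrom", "tss", "gene_id"]).reset_index(drop=True)
    by_chrom = {c: g.reset_index(drop=True) for c, g in genes.groupby("chrom")}

    rows = []
    for i in windows.index:
        chrom = str(windows.at[i, "chrom"])
        mid = (windows.at[i, "start"] + windows.at[i, "end"]) / 2
        g = by_chrom.get(chrom)
        if g is None:
            rows.append((None, np.nan, False))
            continue
        tss = g["tss"].to_numpy()
        j = np.searchsorted(tss, mid)
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(tss):
                d = abs(tss[k] - mid)
                if best is None or d < best[0] or (d == best[0] and tss[k] < tss[best[1]]):
                    best = (d, k)
        k = best[1]
        # duplicates of the same tss: take the first (lowest gene_id)
        k = int(np.searchsorted(tss, tss[k], side="left"))
        gene = g.iloc[k]
        signed = mid - gene["tss"] if gene["strand"] == "+" else gene["tss"] - mid
        rows.append((gene["gene_id"], float(signed), abs(signed) <= max_distance))
    return pd.DataFrame(
        rows, columns=["nearest_gene", "tss_distance", "within_5kb"], index=windows.index
    )


def _feature_intervals(track: AnnotationTrack, promoter_up, promoter_down, tsr_halfwidth):
    """Per-chromosome merged interval arrays for each gene-feature class."""
    classes = {k: {} for k in ("tsr", "promoter", "exon", "intron", "gene_locus")}
    raw = {k: {} for k in classes}

    def add(cls, chrom, s, e):
        if e > s:
            raw[cls].setdefault(chrom, []).append((max(0, s), e))

    for _, g in track.genes.iterrows():
        chrom, tss = g["chrom"], g["tss"]
        add("gene_locus", chrom, g["start"], g["end"])
        add("tsr", chrom, tss - tsr_halfwidth, tss + tsr_halfwidth)
        if g["strand"] == "+":
            add("promoter", chrom, tss - promoter_up, tss + promoter_down)
        else:
            add("promoter", chrom, tss - promoter_down, tss + promoter_up)
        exons = sorted(zip(g["exon_starts"], g["exon_ends"]))
        for es, ee in exons:
            add("exon", chrom, es, ee)
        for (_, e1), (s2, _) in zip(exons[:-1], exons[1:]):
            add("intron", chrom, e1, s2)
    for cls in classes:
        classes[cls] = {c: merge_intervals(iv) for c, iv in raw[cls].items()}
    return classes


def classify_features(
    windows: pd.DataFrame,
    track: AnnotationTrack,
    promoter_up: int = 500,
    promoter_down: int = 100,
    tsr_halfwidth: int = 50,
) -> pd.DataFrame:
    """Boolean feature-class flags per window.

    Promoters span -500 to +100 of the TSS in the gene's reading direction;
    intergenic means no genic/promoter/TSR overlap; the repeat flag is
    orthogonal to everything else.
    """
    classes = _feature_intervals(track, promoter_up, promoter_down, tsr_halfwidth)
    flags = {k: np.zeros(len(windows), dtype=bool) for k in classes}
    flags["repeat"] = np.zeros(len(windows), dtype=bool)
    for chrom, sub in windows.groupby(windows["chrom"].astype(str), observed=True):
        pos = windows.index.get_indexer(sub.index)
        s, e = sub["start"].to_numpy(), sub["end"].to_numpy()
        for cls, per_chrom in classes.items():
            iv = per_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))
            flags[cls][pos] = _overlaps(iv[:, 0], iv[:, 1], s, e)
        iv = track.repeats.get(chrom, np.empty((0, 2), dtype=np.int64))
        flags["repeat"][pos] = _overlaps(iv[:, 0], iv[:, 1], s, e)
    out = pd.DataFrame(flags, index=windows.index)
    out["intergenic"] = ~(out["gene_locus"] | out["promoter"] | out["tsr"])
    return out


def chrom_distribution(rams: pd.DataFrame, genome: GenomeSpec) -> pd.DataFrame:
    """Hyper/hypo RAM window counts per chromosome, per Mb of chromosome."""
    rows = []
    counts = {}
    if not rams.empty:
        for chrom, sub in rams.groupby(rams["chrom"].astype(str), observed=True):
            if chrom not in genome.chrom_names:
                raise ValueError(f"RAM on unknown chromosome {chrom!r}")
            counts[chrom] = (
                int((sub["direction"] == "hyper").sum()),
                int((sub["direction"] == "hypo").sum()),
            )
    for name, L in zip(genome.chrom_names, genome.chrom_lengths):
        hyper, hypo = counts.get(name, (0, 0))
        rows.append(
            {
                "chrom": name,
                "n_hyper": hyper,
                "n_hypo": hypo,
                "hyper_per_mb": hyper * 1e6 / L,
                "hypo_per_mb": hypo * 1e6 / L,
            }
        )
    return pd.DataFrame(rows)


def overlap_sets(ram_sets: dict) -> dict:
    """Region-wise set accounting across comparisons (Venn cells and totals).

    ``ram_sets`` maps a comparison label to a collection of window
    identifiers (e.g. (chrom, start) tuples).  Returns per-set sizes, the
    pooled total (sum of set sizes), the union size, every k-way
    intersection size (k >= 2), the exact Venn cell counts keyed by the
    tuple of member labels, and the number of windows in exactly one set.
    """
    sets = {k: set(v) for k, v in ram_sets.items()}
    names = list(sets)
    union = set().union(*sets.values()) if sets else set()
    membership = {}
    for w in union:
        key = tuple(n for n in names if w in sets[n])
        membership[key] = membership.get(key, 0) + 1
    inter = {}
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            inter[combo] = len(set.intersection(*(sets[n] for n in combo)))
    return {
        "sizes": {n: len(sets[n]) for n in names},
        "pooled_total": sum(len(s) for s in sets.values()),
        "union": len(union),
        "exactly_one": sum(c for key, c in membership.items() if len(key) == 1),
        "intersections": inter,
        "cells": membership,
    }
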