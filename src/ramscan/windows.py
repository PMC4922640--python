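"""Genome tiling, per-window read counting and the coverage filter.

The genome is scanned with constant-width windows (default 100 bp) on a
regular start grid (default every 50 bp, i.e. half-overlapping windows).
Reads are represented by their 5' start coordinate only; a read increments
every window whose interval contains that coordinate, so with a 50 bp step
each interior read lands in exactly two windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeSpec

__all__ = [
    "CountMatrix",
    "tile_genome",
    "count_windows",
    "count_reads",
    "coverage_filter",
]

log = logging.getLogger(__name__)


def _n_windows_for_length(L: int, window_size: int, step: int) -> int:
    # partial terminal windows are dropped: starts 0, step, ... while
    # start + window_size <= L
    if L < window_size:
        return 0
    return (L - window_size) // step + 1


def count_windows(genome: GenomeSpec, window_size: int = 100, step: int = 50) -> int:
    """Closed-form total number of tiling windows across the genome."""
    if not 0 < step <= window_size:
        raise ValueError("require 0 < step <= window_size")
    return sum(
        _n_windows_for_length(L, window_size, step) for L in genome.chrom_lengths
    )


def tile_genome(
    genome: GenomeSpec, window_size: int = 100, step: int = 50
) -> pd.DataFrame:
    """Materialize the tiling windows as a (chrom, start, end) frame.

    Chromosomes shorter than ``window_size`` contribute no windows.
    """
    if not 0 < step <= window_size:
        raise ValueError("require 0 < step <= window_size")
    chroms, starts = [], []
    for name, L in zip(genome.chrom_names, genome.chrom_lengths):
        n = _n_windows_for_length(L, window_size, step)
        if n == 0:
            continue
        s = np.arange(n, dtype=np.int64) * step
        starts.append(s)
        chroms.append(np.repeat(name, n))
    if not chroms:
        return pd.DataFrame({"chrom": [], "start": [], "end": []})
    start = np.concatenate(starts)
    return pd.DataFrame(
        {
            "chrom": pd.Categorical(
                np.concatenate(chroms), categories=list(genome.chrom_names)
            ),
            "start": start,
            "end": start + window_size,
        }
    )


@dataclass
class CountMatrix:
    """Integer read counts per (window, sample) with library sizes.

    Attributes
    ----------
    windows : DataFrame with chrom/start/end, one row per window.
    samples : ordered sample ids.
    counts : int array, shape (n_windows, n_samples).
    lib_sizes : total reads counted per sample (before any window filter).
    norm_factors : per-sample normalization factors (1.0 = library size only);
        effective library size = lib_size * norm_factor.
    skipped : reads discarded per sample (unknown chromosome).
    """

    windows: pd.DataFrame
    samples: list
    counts: np.ndarray
    lib_sizes: np.ndarray
    norm_factors: np.ndarray = None
    skipped: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if self.norm_factors is None:
            self.norm_factors = np.ones(len(self.samples))
        self.norm_factors = np.asarray(self.norm_factors, dtype=float)
        if self.counts.shape != (len(self.windows), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.windows)} windows x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def effective_lib_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.norm_factors

    def cpm(self) -> np.ndarray:
        """Counts per million, using effective library sizes."""
        eff = self.effective_lib_sizes
        if (eff <= 0).any():
            bad = [s for s, e in zip(self.samples, eff) if e <= 0]
            raise ValueError(f"non-positive effective library size for {bad}")
        return self.counts * 1e6 / eff[None, :]

    def subset_samples(self, ids) -> "CountMatrix":
        idx = [self.samples.index(s) for s in ids]
        return CountMatrix(
            windows=self.windows,
            samples=list(ids),
            counts=self.counts[:, idx],
            lib_sizes=self.lib_sizes[idx],
            norm_factors=self.norm_factors[idx],
            skipped={s: self.skipped.get(s, 0) for s in ids},
        )

    def subset_windows(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            windows=self.windows.loc[mask].reset_index(drop=True),
            counts=self.counts[mask],
        )


def count_reads(
    genome: GenomeSpec,
    reads_by_sample: dict,
    window_size: int = 100,
    step: int = 50,
) -> CountMatrix:
    """Count read starts per tiling window for each sample.

    Parameters
    ----------
    reads_by_sample : mapping of sample id to a DataFrame with columns
        ``chrom`` and ``start`` (read 5' positions, 0-based).

    A read at position ``p`` increments every window with start <= p < end.
    Reads on chromosomes absent from the genome are skipped (and tallied).
    """
    windows = tile_genome(genome, window_size, step)
    # per-chromosome (row offset, n windows) into the stacked window table
    layout = {}
    offset = 0
    for name, L in zip(genome.chrom_names, genome.chrom_lengths):
        n = _n_windows_for_length(L, window_size, step)
        layout[name] = (offset, n)
        offset += n

    n_win = len(windows)
    samples = list(reads_by_sample)
    counts = np.zeros((n_win, len(samples)), dtype=np.int64)
    lib_sizes = np.zeros(len(samples))
    skipped = {}
    max_span = -(-window_size // step)  # windows possibly covering one position

    for j, sid in enumerate(samples):
        df = reads_by_sample[sid]
        n_skip = 0
        for chrom, sub in df.groupby("chrom", observed=True):
            if chrom not in layout:
                n_skip += len(sub)
                continue
            off, n = layout[chrom]
            lib_sizes[j] += len(sub)
            if n == 0:
                continue
            p = np.asarray(sub["start"], dtype=np.int64)
            j_hi = p // step
            for m in range(max_span):
                widx = j_hi - m
                ok = (widx >= 0) & (widx < n) & (widx * step + window_size > p)
                if ok.any():
                    counts[off : off + n, j] += np.bincount(
                        widx[ok], minlength=n
                    )
        if n_skip:
            log.warning("sample %s: %d reads on unknown chromosomes skipped", sid, n_skip)
        skipped[sid] = n_skip

    return CountMatrix(
        windows=windows,
        samples=samples,
        counts=counts,
        lib_sizes=lib_sizes,
        skipped=skipped,
    )


def coverage_filter(
    cm: CountMatrix, min_samples: int = 3, min_count: int = 20
) -> CountMatrix:
    """Retain windows with a read count strictly above ``min_count`` in at
    least ``min_samples`` samples.

    The default (3 samples with counts > 20) restricts testing to regions
    with appreciable enrichment signal.  Window order is preserved and
    library sizes are untouched, so the filter is idempotent.
    """
    if min_samples > len(cm.samples):
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {len(cm.samples)}"
        )
    keep = (cm.counts > min_count).sum(axis=1) >= min_samples
    return cm.subset_windows(keep)
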