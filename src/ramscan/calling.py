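"""RAM calling: significance thresholding plus two post-processing filters.

A RAM (region of altered methylation) is a tested window that

1. passes the significance threshold (nominal p, or BH q, below alpha),
2. shows a per-sample methylation change consistent with the group-level
   direction in at least half the samples of *both* groups (filter i), and
3. is corroborated by its neighbourhood (filter ii): either an overlapping
   flanking window is itself differential in the same direction, or a second
   candidate window of the same direction lies within a 500 bp stretch.

Both filters only remove windows; each is idempotent.  In every comparison
the second group is the higher-dose group, and "hyper" means elevated
methylation in it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .nbstats import run_differential
from .windows import CountMatrix, coverage_filter

__all__ = [
    "call_candidates",
    "consistency_filter",
    "flanking_filter",
    "call_rams",
    "run_pipeline",
    "merge_ram_windows",
]


def call_candidates(
    results: pd.DataFrame, alpha: float, use_q: bool = False
) -> pd.DataFrame:
    """Windows passing the significance threshold, direction attached."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    col = "q" if use_q else "p"
    return results.loc[results[col] < alpha].copy()


def consistency_filter(
    candidates: pd.DataFrame,
    cm: CountMatrix,
    groups,
    pair: tuple,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Filter (i): require a per-sample change in at least ``min_fraction``
    of the samples of each group.

    A sample "changes" if its CPM-normalized count lies on the group-level
    direction's side of the *other* group's median: higher-group samples must
    sit beyond the lower group's median (above it for hyper, below for hypo)
    and lower-group samples beyond the higher group's median, in the opposite
    sense.  Medians make the rule robust to single-sample outliers, to which
    NB testing is sensitive.
    """
    if candidates.empty:
        return candidates.copy()
    groups = np.asarray(groups)
    label_a, label_b = pair
    idx_a = np.where(groups == label_a)[0]
    idx_b = np.where(groups == label_b)[0]
    cpm = cm.cpm()

    key = pd.MultiIndex.from_frame(cm.windows[["chrom", "start"]].astype({"chrom": str}))
    row_of = pd.Series(np.arange(len(key)), index=key)

    keep = []
    for _, cand in candidates.iterrows():
        k = (str(cand["chrom"]), cand["start"])
        if k not in row_of.index:
            raise KeyError(f"candidate window {k} missing from count matrix")
        row = cpm[row_of[k]]
        m_a = np.median(row[idx_a])
        m_b = np.median(row[idx_b])
        if cand["direction"] == "hyper":
            frac_b = np.mean(row[idx_b] > m_a)
            frac_a = np.mean(row[idx_a] < m_b)
        else:
            frac_b = np.mean(row[idx_b] < m_a)
            frac_a = np.mean(row[idx_a] > m_b)
        keep.append(frac_a >= min_fraction and frac_b >= min_fraction)
    return candidates.loc[np.asarray(keep, dtype=bool)].copy()


def flanking_filter(
    candidates: pd.DataFrame,
    all_results: pd.DataFrame,
    flank_alpha: float = 0.05,
    stretch_bp: int = 500,
    step: int = 50,
) -> pd.DataFrame:
    """Filter (ii): neighbourhood corroboration.

    Retain a candidate iff (a) at least one of its two overlapping flanking
    windows (starts +/- ``step``) has p < ``flank_alpha`` with the same
    direction, or (b) at least one *other* candidate of the same direction
    starts within ``stretch_bp``.  Boolean columns ``flank_neighbor`` and
    ``flank_stretch`` record which branch fired.
    """
    out = candidates.copy()
    if out.empty:
        out["flank_neighbor"] = pd.Series(dtype=bool)
        out["flank_stretch"] = pd.Series(dtype=bool)
        return out

    res_key = pd.MultiIndex.from_frame(
        all_results[["chrom", "start"]].astype({"chrom": str})
    )
    p_of = pd.Series(all_results["p"].to_numpy(), index=res_key)
    dir_of = pd.Series(all_results["direction"].to_numpy(), index=res_key)

    by_chrom_dir = {
        k: np.sort(g["start"].to_numpy())
        for k, g in out.groupby([out["chrom"].astype(str), "direction"], observed=True)
    }

    neigh_flags, stretch_flags = [], []
    for _, cand in out.iterrows():
        chrom, start, direction = str(cand["chrom"]), cand["start"], cand["direction"]
        fired_a = False
        for s in (start - step, start + step):
            k = (chrom, s)
            if k in p_of.index and p_of[k] < flank_alpha and dir_of[k] == direction:
                fired_a = True
                break
        starts = by_chrom_dir.get((chrom, direction), np.array([]))
        near = starts[(np.abs(starts - start) <= stretch_bp) & (starts != start)]
        fired_b = len(near) > 0
        neigh_flags.append(fired_a)
        stretch_flags.append(fired_b)

    out["flank_neighbor"] = neigh_flags
    out["flank_stretch"] = stretch_flags
    return out.loc[out["flank_neighbor"] | out["flank_stretch"]].copy()


def call_rams(
    results: pd.DataFrame,
    cm: CountMatrix,
    groups,
    pair: tuple,
    config: PipelineConfig = None,
    comparison: str = None,
) -> pd.DataFrame:
    """Apply threshold + filters (i) and (ii) to test results."""
    config = config or PipelineConfig()
    cands = call_candidates(results, config.alpha, use_q=config.use_q)
    if config.consistency:
        cands = consistency_filter(cands, cm, groups, pair, config.min_fraction)
    if config.flanking:
        cands = flanking_filter(
            cands, results, config.flank_alpha, config.stretch_bp, config.step
        )
    else:
        cands = cands.copy()
        cands["flank_neighbor"] = False
        cands["flank_stretch"] = False
    cands["comparison"] = comparison if comparison is not None else f"{pair[0]}_vs_{pair[1]}"
    return cands.reset_index(drop=True)


def run_pipeline(
    cm: CountMatrix,
    groups,
    pair: tuple,
    config: PipelineConfig = None,
    comparison: str = None,
):
    """Coverage filter -> NB test -> RAM calling; returns (results, rams).

    ``cm`` is the unfiltered count matrix; ``groups`` aligns with its
    samples.  The identical entry point is used for exposure contrasts and
    for the sex-based empirical-FDR resampling.
    """
    config = config or PipelineConfig()
    groups = np.asarray(groups)
    sel = np.isin(groups, list(pair))
    sub = cm.subset_samples([s for s, ok in zip(cm.samples, sel) if ok])
    sub_groups = groups[sel]
    if config.apply_coverage_filter:
        sub = coverage_filter(sub, config.min_samples, config.min_count)
    results = run_differential(sub, sub_groups, pair, config)
    rams = call_rams(results, sub, sub_groups, pair, config, comparison=comparison)
    return results, rams


def merge_ram_windows(rams: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent RAM windows into regions (reporting only).

    Statistics are always computed per window; merging is a presentation
    convenience for BED export.
    """
    if rams.empty:
        return pd.DataFrame({"chrom": [], "start": [], "end": []})
    rows = []
    for chrom, sub in rams.groupby(rams["chrom"].astype(str), observed=True):
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
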