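"""RNA-seq differential expression and methylation-expression integration.

Expression differences between exposure groups are tested with the same NB
machinery as the methylation windows (TMM normalization, moderated tagwise
dispersion, conditional exact test, BH adjustment), and genes are flagged
differentially expressed under joint FDR (< 0.10) and fold-change (>= 2x)
cutoffs.  Integration then pairs each gene with its strongest nearby RAM
(within 5 kb of the TSS) whose methylation change is opposite in sign to
the gene's expression change — promoter/TSS-proximal hypermethylation with
reduced expression and vice versa.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .nbstats import run_differential
from .windows import CountMatrix

__all__ = ["rnaseq_de", "integrate"]

log = logging.getLogger(__name__)


def rnaseq_de(
    gene_counts: pd.DataFrame,
    groups,
    pair: tuple,
    fdr_cut: float = 0.10,
    fc_cut: float = 2.0,
    config: PipelineConfig = None,
) -> pd.DataFrame:
    """Two-group NB exact-test differential expression per gene.

    Parameters
    ----------
    gene_counts : genes x samples integer DataFrame (index = gene ids).
    groups : per-sample labels aligned with the columns.
    pair : (label_A, label_B), B the higher-dose group.
    fdr_cut, fc_cut : joint thresholds for the ``is_de`` flag
        (q < fdr_cut and fold change >= fc_cut in either direction).

    All-zero genes are dropped (logged), not tested.
    """
    if config is None:
        config = PipelineConfig(normalization="tmm", apply_coverage_filter=False)
    counts = gene_counts.to_numpy()
    nonzero = counts.sum(axis=1) > 0
    if (~nonzero).any():
        log.info("dropping %d all-zero genes", int((~nonzero).sum()))
    kept = gene_counts.loc[nonzero]

    # reuse the window machinery with genes as "windows"
    fake_windows = pd.DataFrame(
        {"chrom": "genes", "start": np.arange(len(kept)), "end": np.arange(len(kept)) + 1}
    )
    cm = CountMatrix(
        windows=fake_windows,
        samples=list(kept.columns),
        counts=kept.to_numpy(),
        lib_sizes=kept.to_numpy().sum(axis=0).astype(float),
    )
    res = run_differential(cm, groups, pair, config)
    out = pd.DataFrame(
        {
            "gene_id": kept.index,
            "log2FC": res["log2FC"].to_numpy(),
            "p": res["p"].to_numpy(),
            "q": res["q"].to_numpy(),
        }
    )
    out["is_de"] = (out["q"] < fdr_cut) & (np.abs(out["log2FC"]) >= np.log2(fc_cut))
    return out


def integrate(
    rams_annotated: pd.DataFrame,
    expr_results: pd.DataFrame,
    expr_alpha: float = 0.05,
    comparison: str = None,
) -> pd.DataFrame:
    """Genes whose expression change opposes a nearby methylation change.

    ``rams_annotated`` must carry ``nearest_gene``, ``within_5kb``,
    ``direction``, ``p`` and ``comparison`` columns (from the annotation
    step); ``expr_results`` comes from :func:`rnaseq_de` for the *same*
    comparison.  A candidate is emitted per gene (strongest RAM by p) when
    the RAM lies within 5 kb of the gene's TSS, the gene's expression is
    nominally significant (p < ``expr_alpha``), and the expression and
    methylation effects have opposite signs.
    """
    if comparison is not None:
        labels = set(rams_annotated["comparison"].unique()) if len(rams_annotated) else set()
        if labels and labels != {comparison}:
            raise ValueError(
                f"RAM comparisons {sorted(labels)} do not match {comparison!r}"
            )
    expr = expr_results.set_index("gene_id")
    rows = []
    near = rams_annotated.loc[rams_annotated["within_5kb"].fillna(False)]
    for gene_id, sub in near.groupby("nearest_gene"):
        if gene_id not in expr.index:
            continue
        e = expr.loc[gene_id]
        if not e["p"] < expr_alpha:
            continue
        best = sub.loc[sub["p"].idxmin()]
        meth_sign = 1 if best["direction"] == "hyper" else -1
        expr_sign = int(np.sign(e["log2FC"]))
        if expr_sign == 0 or expr_sign == meth_sign:
            continue
        rows.append(
            {
                "gene_id": gene_id,
                "comparison": best["comparison"],
                "ram_chrom": best["chrom"],
                "ram_start": best["start"],
                "ram_end": best["end"],
                "methylation_direction": best["direction"],
                "methylation_log2FC": best["log2FC"],
                "ram_p": best["p"],
                "expression_direction": "up" if expr_sign > 0 else "down",
                "expression_log2FC": e["log2FC"],
                "expression_p": e["p"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "comparison", "ram_chrom", "ram_start", "ram_end",
            "methylation_direction", "methylation_log2FC", "ram_p",
            "expression_direction", "expression_log2FC", "expression_p",
        ],
    )
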