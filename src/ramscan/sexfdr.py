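"""Empirical FDR from male-vs-female contrasts.

The X and Y chromosomes carry genuine, large methylation-coverage
differences between the sexes, while autosomal sex differences are
(conservatively) assumed absent.  Running the full calling pipeline on
random male-vs-female sample sets therefore yields a set of "hits" whose
autosomal fraction upper-bounds the pipeline's false-discovery rate: every
autosomal hit is presumed false, every X/Y hit presumed true.  The estimate
is an upper bound to the extent that real autosomal sex differences exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import run_pipeline
from .config import PipelineConfig
from .genome import GenomeSpec
from .windows import CountMatrix

__all__ = ["FdrEstimate", "sex_based_fdr"]

log = logging.getLogger(__name__)


@dataclass
class FdrEstimate:
    """Per-set autosomal hit fractions and their mean.

    ``per_set`` has one row per random subject set: the subjects drawn, the
    number of windows tested (split autosome vs sex chromosome), the number
    of significant RAM windows and how many of those are autosomal, and the
    autosomal fraction (NaN when a set produced no hits).  ``mean_fdr``
    averages the defined fractions only.
    """

    per_set: pd.DataFrame
    mean_fdr: float
    n_sets: int
    seed: int


def sex_based_fdr(
    cm: CountMatrix,
    sample_sheet: pd.DataFrame,
    genome: GenomeSpec,
    n_per_side: int = 6,
    n_sets: int = 8,
    seed: int = 0,
    config: PipelineConfig = None,
) -> FdrEstimate:
    """Estimate the pipeline's empirical FDR from sex contrasts.

    For each of ``n_sets`` independent draws, ``n_per_side`` males and
    ``n_per_side`` females are sampled without replacement, the *identical*
    pipeline (same config as the exposure contrasts) is run on the
    male-vs-female comparison, and the fraction of resulting RAM windows on
    autosomes is recorded.  Sets with zero hits are excluded from the mean
    with a warning.
    """
    config = config or PipelineConfig()
    sheet = sample_sheet.set_index("id")
    males = [s for s in cm.samples if sheet.loc[s, "sex"] == "male"]
    females = [s for s in cm.samples if sheet.loc[s, "sex"] == "female"]
    if len(males) < n_per_side or len(females) < n_per_side:
        raise ValueError(
            f"need {n_per_side} of each sex, have {len(males)} males / "
            f"{len(females)} females"
        )
    if not (genome.x_like or genome.y_like):
        raise ValueError("genome has no flagged sex chromosomes")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for set_id in range(n_sets):
        m = list(rng.choice(males, size=n_per_side, replace=False))
        f = list(rng.choice(females, size=n_per_side, replace=False))
        subjects = m + f
        sub = cm.subset_samples(subjects)
        groups = ["male"] * n_per_side + ["female"] * n_per_side
        results, rams = run_pipeline(
            sub, groups, ("male", "female"), config, comparison="male_vs_female"
        )
        auto_tested = int(
            sum(genome.is_autosome(str(c)) for c in results["chrom"])
        )
        n_sig = len(rams)
        n_auto = int(sum(genome.is_autosome(str(c)) for c in rams["chrom"]))
        frac = n_auto / n_sig if n_sig else np.nan
        rows.append(
            {
                "set_id": set_id,
                "subjects": ",".join(subjects),
                "n_windows_tested": len(results),
                "n_autosomal_windows": auto_tested,
                "n_significant": n_sig,
                "n_autosomal": n_auto,
                "fraction_autosomal": frac,
            }
        )
    per_set = pd.DataFrame(rows)
    defined = per_set["fraction_autosomal"].dropna()
    if len(defined) < n_sets:
        log.warning(
            "%d of %d sets had zero significant windows and were excluded "
            "from the mean FDR",
            n_sets - len(defined),
            n_sets,
        )
    mean_fdr = float(defined.mean()) if len(defined) else np.nan
    return FdrEstimate(per_set=per_set, mean_fdr=mean_fdr, n_sets=n_sets, seed=seed)
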