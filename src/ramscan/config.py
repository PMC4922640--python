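"""Shared pipeline configuration.

A single config object travels through window filtering, testing and RAM
calling so that the empirical-FDR estimator is guaranteed to re-run the
identical pipeline on its sex contrasts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class PipelineConfig:
    """Tunable knobs of the differential-methylation pipeline.

    Attributes
    ----------
    window_size, step : tiling geometry in bp (100 bp windows every 50 bp).
    min_samples, min_count : coverage filter — keep windows with counts
        strictly above ``min_count`` in at least ``min_samples`` samples.
    normalization : "libsize" (methylation default) or "tmm" (RNA-seq).
    prior_df : weight (in windows' worth of likelihood) of the common
        dispersion in the tagwise shrinkage.
    tagwise : use moderated per-window dispersions (else common only).
    two_sided_rule : "doubling" or "smallp" two-sided exact-test rule.
    alpha : significance threshold for candidate windows.
    use_q : threshold BH q-values instead of nominal p-values.
    consistency, min_fraction : per-sample consistency filter (i) and the
        fraction of samples per group that must agree with the change.
    flanking, flank_alpha, stretch_bp : neighbourhood filter (ii) — a
        flanking-window corroboration at ``flank_alpha`` or a second
        candidate within ``stretch_bp``.
    fc_prior : pseudo-count added to group means for log2 fold changes.
    """

    window_size: int = 100
    step: int = 50
    min_samples: int = 3
    min_count: int = 20
    apply_coverage_filter: bool = True
    normalization: str = "libsize"
    prior_df: float = 10.0
    tagwise: bool = True
    two_sided_rule: str = "doubling"
    alpha: float = 0.001
    use_q: bool = False
    consistency: bool = True
    min_fraction: float = 0.5
    flanking: bool = True
    flank_alpha: float = 0.05
    stretch_bp: int = 500
    fc_prior: float = 0.5

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)
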