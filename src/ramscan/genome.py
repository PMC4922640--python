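"""Genome coordinate frames and sample metadata.

Everything downstream (window tiling, read counting, annotation) is expressed
in the coordinate frame of a :class:`GenomeSpec`: an ordered set of named
chromosomes with lengths and sex-chromosome flags.  Coordinates are 0-based,
half-open throughout the package (BED convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "HG19_LENGTHS",
    "hg19_genome",
    "trichotomize_bpa",
    "BPA_GROUPS",
    "validate_sample_sheet",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths plus sex-chromosome flags.

    Parameters
    ----------
    chrom_names : list of str
        Unique chromosome identifiers, in a fixed order.
    chrom_lengths : list of int
        Length in bp of each chromosome; must be positive.
    x_like : frozenset of str
        Chromosomes with X-like dosage (present in both sexes, two copies in
        females).
    y_like : str or None
        The (at most one) Y-like chromosome, absent in females.
    """

    chrom_names: tuple
    chrom_lengths: tuple
    x_like: frozenset = field(default_factory=frozenset)
    y_like: str | None = None

    def __post_init__(self):
        names = tuple(self.chrom_names)
        lengths = tuple(int(x) for x in self.chrom_lengths)
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)
        object.__setattr__(self, "x_like", frozenset(self.x_like))
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if len(names) != len(lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if any(L <= 0 for L in lengths):
            raise ValueError("chromosome lengths must be positive")
        unknown = self.x_like - set(names)
        if unknown:
            raise ValueError(f"x_like chromosomes not in genome: {sorted(unknown)}")
        if self.y_like is not None and self.y_like not in names:
            raise ValueError(f"y_like chromosome {self.y_like!r} not in genome")

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_names.index(chrom)]

    def is_sex_chrom(self, chrom: str) -> bool:
        return chrom in self.x_like or chrom == self.y_like

    def is_autosome(self, chrom: str) -> bool:
        return not self.is_sex_chrom(chrom)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": list(self.chrom_names),
                "length": list(self.chrom_lengths),
                "sex_chrom": [self.is_sex_chrom(c) for c in self.chrom_names],
            }
        )


#: Lengths (bp) of the 25 canonical hg19 chromosomes.
HG19_LENGTHS = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
    "chrX": 155270560,
    "chrY": 59373566,
    "chrM": 16571,
}


def hg19_genome() -> GenomeSpec:
    """The bundled hg19 reference frame (25 canonical chromosomes)."""
    return GenomeSpec(
        chrom_names=tuple(HG19_LENGTHS),
        chrom_lengths=tuple(HG19_LENGTHS.values()),
        x_like=frozenset({"chrX"}),
        y_like="chrY",
    )


# Total-BPA trichotomization bounds (ng/g wet liver tissue).  Concentrations
# falling in the gaps between groups are left unassigned and excluded from
# group comparisons.
BPA_GROUPS = {
    "non_detect": (0.0, 0.83),
    "low": (3.50, 5.79),
    "high": (35.44, 96.76),
}


def trichotomize_bpa(bpa_ng_per_g) -> str:
    """Assign a BPA concentration to an exposure group.

    ``None``/NaN is treated as a non-detect.  Values in the inter-group gaps
    (0.83-3.50 and 5.79-35.44 ng/g) or above the high range return
    ``"unassigned"``.

    Raises
    ------
    ValueError
        If the concentration is negative.
    """
    if bpa_ng_per_g is None or (
        isinstance(bpa_ng_per_g, float) and math.isnan(bpa_ng_per_g)
    ):
        return "non_detect"
    x = float(bpa_ng_per_g)
    if x < 0:
        raise ValueError(f"BPA concentration must be non-negative, got {x}")
    for group, (lo, hi) in BPA_GROUPS.items():
        if lo <= x <= hi:
            return group
    return "unassigned"


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check a sample sheet and (re)derive the exposure group column.

    Expects columns ``id``, ``sex``, ``bpa_ng_per_g``; returns a copy with a
    consistent ``group`` column.
    """
    required = {"id", "sex", "bpa_ng_per_g"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["id"].duplicated().any():
        dup = sheet.loc[sheet["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate sample ids: {dup}")
    bad_sex = set(sheet["sex"]) - {"male", "female"}
    if bad_sex:
        raise ValueError(f"sex must be male/female, got {sorted(bad_sex)}")
    out = sheet.copy()
    out["group"] = [trichotomize_bpa(v) for v in out["bpa_ng_per_g"]]
    return out
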