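"""Copy-neutral LOH versus hemizygous deletion via depth ratios.

A hemizygous deletion halves the expected read depth of the affected sample
over the lost interval; copy-neutral LOH leaves depth unchanged.  The
per-site ratio r = dp_sport / dp_wild is summarized by its median inside the
candidate region and genome-wide (excluding the region), and the verdict is
based on the normalized ratio region_median / genome_median, which cancels
global library-size differences between the two samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Region interval as (scaffold, start, end), 1-based inclusive.
Region = tuple[str, int, int]


@dataclass(frozen=True)
class DepthThresholds:
    """Verdict thresholds on the normalized ratio.

    A deletion is expected near 0.5 and copy-neutral near 1.0; the defaults
    put an ambiguity buffer between the two.
    """

    deletion_max: float = 0.75
    neutral_min: float = 0.85
    min_region_sites: int = 50


@dataclass(frozen=True)
class DepthRatioReport:
    region: Region
    n_region: int
    n_genome: int
    n_zero_depth: int
    region_median: float
    genome_median: float
    normalized_ratio: float
    fraction_in_band: float  # share of region sites with r in [0.5, 1.5]
    fraction_below_1: float
    verdict: str  # copy_neutral | deletion | ambiguous
    ratios_region: np.ndarray = field(repr=False, compare=False, default=None)

    def to_dict(self) -> dict:
        return {
            "region": f"{self.region[0]}:{self.region[1]}-{self.region[2]}",
            "n_region": self.n_region,
            "n_genome": self.n_genome,
            "n_zero_depth": self.n_zero_depth,
            "region_median": round(float(self.region_median), 4),
            "genome_median": round(float(self.genome_median), 4),
            "normalized_ratio": round(float(self.normalized_ratio), 4),
            "fraction_in_band": round(float(self.fraction_in_band), 4),
            "fraction_below_1": round(float(self.fraction_below_1), 4),
            "verdict": self.verdict,
        }


def depth_ratio_report(
    sites: pd.DataFrame,
    region: Region,
    thresholds: DepthThresholds | None = None,
    invert: bool = False,
) -> DepthRatioReport:
    """Compare depth ratios inside a candidate region with the genome-wide
    distribution and call copy_neutral / deletion / ambiguous.

    ``sites`` needs columns scaffold, pos, dp_wild, dp_sport.  Sites with
    zero depth in either sample are excluded and counted.  ``invert``
    flips the ratio orientation to wild/sport; the verdict is unaffected
    because region and genome medians flip together.
    """
    thr = thresholds or DepthThresholds()
    scaffold, start, end = region
    if end < start:
        raise ValueError("region end before start")

    dp_w = sites["dp_wild"].to_numpy(dtype=float)
    dp_s = sites["dp_sport"].to_numpy(dtype=float)
    nonzero = (dp_w > 0) & (dp_s > 0)
    n_zero = int((~nonzero).sum())

    ratio = np.full(len(sites), np.nan)
    if invert:
        ratio[nonzero] = dp_w[nonzero] / dp_s[nonzero]
    else:
        ratio[nonzero] = dp_s[nonzero] / dp_w[nonzero]

    in_region = (
        (sites["scaffold"].to_numpy() == scaffold)
        & (sites["pos"].to_numpy() >= start)
        & (sites["pos"].to_numpy() <= end)
    )
    r_region = ratio[in_region & nonzero]
    r_genome = ratio[~in_region & nonzero]
    if len(r_genome) == 0:
        raise ValueError("no sites outside the region to form the genome baseline")

    region_median = float(np.median(r_region)) if len(r_region) else float("nan")
    genome_median = float(np.median(r_genome))
    normalized = region_median / genome_median if len(r_region) else float("nan")

    if len(r_region) < thr.min_region_sites:
        warnings.warn(
            f"only {len(r_region)} region sites (<{thr.min_region_sites}); "
            "verdict forced to ambiguous",
            stacklevel=2,
        )
        verdict = "ambiguous"
    elif normalized < thr.deletion_max:
        verdict = "deletion"
    elif normalized > thr.neutral_min:
        verdict = "copy_neutral"
    else:
        verdict = "ambiguous"

    frac_band = float(((r_region >= 0.5) & (r_region <= 1.5)).mean()) if len(r_region) else 0.0
    frac_below = float((r_region < 1).mean()) if len(r_region) else 0.0
    return DepthRatioReport(
        region=region,
        n_region=int(len(r_region)),
        n_genome=int(len(r_genome)),
        n_zero_depth=n_zero,
        region_median=region_median,
        genome_median=genome_median,
        normalized_ratio=normalized,
        fraction_in_band=frac_band,
        fraction_below_1=frac_below,
        verdict=verdict,
        ratios_region=r_region,
    )


def ratios_table(sites: pd.DataFrame, invert: bool = False) -> pd.DataFrame:
    """Per-site depth-ratio track (zero-depth sites get NA)."""
    dp_w = sites["dp_wild"].to_numpy(dtype=float)
    dp_s = sites["dp_sport"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = dp_w / dp_s if invert else dp_s / dp_w
    r = np.where((dp_w > 0) & (dp_s > 0), r, np.nan)
    out = sites[["scaffold", "pos"]].copy()
    out["ratio"] = r
    return out
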