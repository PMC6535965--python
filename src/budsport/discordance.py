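"""Numeric genotype coding and per-scaffold discordance/density statistics.

Genotypes at biallelic SNPs are coded 0 (homozygous reference), 1
(heterozygous), 2 (homozygous variant).  Discordance between the paired
samples is summarized per scaffold as a count D over a scaffold of length L
with N called SNPs; the discordance rate D/L and SNP density N/L are reported
in 3-significant-figure scientific notation, and densities additionally as
"1 SNP per X bp" phrases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel code for a missing genotype; never conflated with 0

DiscordanceDef = Literal["any_mismatch", "loh_only"]


def code_genotype(gt: Sequence[int] | None) -> int:
    """Code a biallelic genotype (pair of allele indices) as 0/1/2.

    0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2; a missing call returns the
    ``MISSING`` sentinel.  Allele indices other than 0/1 indicate a
    multiallelic record that leaked past site filtering and raise ValueError.
    """
    if gt is None:
        return MISSING
    a, b = gt
    if a is None or b is None or a < 0 or b < 0:
        return MISSING
    if a > 1 or b > 1:
        raise ValueError(f"allele index >1 in genotype {gt!r}: multiallelic site")
    return a + b


def sci3(x: float) -> str:
    """Format a rate in 3-significant-figure scientific notation (``4.52E-7``).

    Zero formats as ``"0"``; the exponent carries no leading zero.
    """
    if x == 0:
        return "0"
    mantissa_exp = f"{x:.2E}"  # e.g. '4.52E-07'
    mantissa, exp = mantissa_exp.split("E")
    sign = "-" if exp.startswith("-") else "+"
    digits = exp.lstrip("+-").lstrip("0") or "0"
    return f"{mantissa}E{'' if sign == '+' else '-'}{digits}"


def _round_2sf(x: float) -> float:
    if x == 0:
        return 0.0
    ndigits = 1 - int(math.floor(math.log10(abs(x))))
    return round(x, ndigits)


def snp_spacing_phrase(called_snp: int, scaffold_size: int) -> str:
    """Express SNP density as "1 SNP/X bp" with X = L/N rounded to 2 s.f.

    Spacings of 1 kb or more are phrased in kb (``"1 SNP/3.2 kb"``).
    """
    if called_snp <= 0:
        return "NA"
    x = _round_2sf(scaffold_size / called_snp)
    if x >= 1000:
        kb = x / 1000
        num = f"{kb:.0f}" if kb == int(kb) else f"{kb:g}"
        return f"1 SNP/{num} kb"
    num = f"{x:.0f}" if x == int(x) else f"{x:g}"
    return f"1 SNP/{num} bp"


@dataclass(frozen=True)
class ScaffoldStats:
    """One row of the per-scaffold discordance table."""

    scaffold: str
    discordance: int
    called_snp: int
    scaffold_size: int

    def __post_init__(self) -> None:
        if self.scaffold_size <= 0:
            raise ValueError(f"scaffold_size must be positive, got {self.scaffold_size}")
        if self.discordance < 0 or self.called_snp < 0:
            raise ValueError("counts must be non-negative")

    @property
    def discordance_rate(self) -> float:
        return self.discordance / self.scaffold_size

    @property
    def snp_density(self) -> float:
        return self.called_snp / self.scaffold_size

    @property
    def discordance_rate_str(self) -> str:
        return sci3(self.discordance_rate)

    @property
    def snp_density_str(self) -> str:
        return sci3(self.snp_density)


@dataclass(frozen=True)
class ControlStats:
    """Self-comparison control: a sample coded against its own reference.

    ``het_discordance`` counts code-1 calls (false-positive candidates from
    paralogous alignment), ``hom_discordance`` counts code-2 calls (putative
    reference-assembly errors).
    """

    het_discordance: int
    hom_discordance: int
    called_snp: int
    genome_size: int

    @property
    def total(self) -> int:
        return self.het_discordance + self.hom_discordance

    @property
    def het_rate(self) -> float:
        return self.het_discordance / self.genome_size

    @property
    def hom_rate(self) -> float:
        return self.hom_discordance / self.genome_size

    @property
    def total_rate(self) -> float:
        return self.total / self.genome_size


def is_discordant(
    code_wild: np.ndarray, code_sport: np.ndarray, definition: DiscordanceDef = "any_mismatch"
) -> np.ndarray:
    """Boolean mask of discordant sites under the chosen definition.

    ``any_mismatch`` flags every genotype difference; ``loh_only`` flags only
    the het-to-hom direction (wild het, sport homozygous either way).
    """
    cw = np.asarray(code_wild)
    cs = np.asarray(code_sport)
    if definition == "any_mismatch":
        return cw != cs
    if definition == "loh_only":
        return (cw == 1) & ((cs == 0) | (cs == 2))
    raise ValueError(f"unknown discordance definition {definition!r}")


def scaffold_stats(
    sites: pd.DataFrame,
    scaffold_size: int,
    definition: DiscordanceDef = "any_mismatch",
    scaffold: str | None = None,
) -> ScaffoldStats:
    """Discordance statistics for the coded sites of one scaffold.

    ``sites`` needs columns ``code_wild`` and ``code_sport`` (no missing
    codes) and, unless ``scaffold`` is given, a single-valued ``scaffold``
    column.
    """
    if scaffold is None:
        names = sites["scaffold"].unique() if "scaffold" in sites else []
        if len(names) != 1:
            raise ValueError("sites must come from exactly one scaffold")
        scaffold = str(names[0])
    cw = sites["code_wild"].to_numpy()
    cs = sites["code_sport"].to_numpy()
    if np.any(cw == MISSING) or np.any(cs == MISSING):
        raise ValueError("missing genotype codes present; filter first")
    d = int(is_discordant(cw, cs, definition).sum())
    return ScaffoldStats(scaffold, d, len(sites), scaffold_size)


def control_stats(codes: np.ndarray | Sequence[int], genome_size: int) -> ControlStats:
    """Summarize a control sample coded against its own reference genome.

    The reference genotype is 0 everywhere by construction, so every code-1
    call is a het inconsistency and every code-2 call a hom inconsistency.
    """
    arr = np.asarray(codes)
    het = int((arr == 1).sum())
    hom = int((arr == 2).sum())
    return ControlStats(het, hom, called_snp=len(arr), genome_size=genome_size)


def stats_table(stats: Iterable[ScaffoldStats], total_row: bool = True) -> pd.DataFrame:
    """Assemble per-scaffold stats into a report table, optionally with a
    genome-total row (counts summed, rates over the summed size)."""
    stats = list(stats)
    rows = [
        {
            "scaffold": s.scaffold,
            "discordance": s.discordance,
            "called_snp": s.called_snp,
            "scaffold_size": s.scaffold_size,
            "discordance_rate": s.discordance_rate_str,
            "snp_density": s.snp_density_str,
        }
        for s in stats
    ]
    if total_row and stats:
        tot = ScaffoldStats(
            "Total",
            sum(s.discordance for s in stats),
            sum(s.called_snp for s in stats),
            sum(s.scaffold_size for s in stats),
        )
        rows.append(
            {
                "scaffold": tot.scaffold,
                "discordance": tot.discordance,
                "called_snp": tot.called_snp,
                "scaffold_size": tot.scaffold_size,
                "discordance_rate": tot.discordance_rate_str,
                "snp_density": tot.snp_density_str,
            }
        )
    return pd.DataFrame(rows)


def density_report(stats: Iterable[ScaffoldStats]) -> pd.DataFrame:
    """Rank scaffolds by SNP density with "1 SNP per X bp" phrasing.

    Scaffolds with no called SNPs are reported as "NA" and excluded from the
    ranking (rank column left empty for them).
    """
    stats = list(stats)
    rows = []
    for s in stats:
        rows.append(
            {
                "scaffold": s.scaffold,
                "called_snp": s.called_snp,
                "scaffold_size": s.scaffold_size,
                "snp_density": s.snp_density_str if s.called_snp else "NA",
                "spacing": snp_spacing_phrase(s.called_snp, s.scaffold_size),
            }
        )
    df = pd.DataFrame(rows)
    ranked = df[df["called_snp"] > 0].copy()
    ranked["rank"] = (
        (ranked["called_snp"] / ranked["scaffold_size"])
        .rank(ascending=False, method="min")
        .astype(int)
    )
    df = df.merge(ranked[["scaffold", "rank"]], on="scaffold", how="left")
    return df.sort_values("rank", na_position="last").reset_index(drop=True)
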