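"""Haplotype-origin tracing and the marker-SNP dominance rule.

Given four phased haplotypes over a region (two per sample), the identity
matrix measures, for each sport haplotype, the fraction of sites at which it
matches each wild haplotype.  After a copy-neutral LOH both sport haplotypes
descend from a single wild haplotype; call_origin names that haplotype when
both rows agree with sufficient margin.

The dominance-consistency check tests the rule "carrying the dominant T
allele at the fruit-shape marker implies flat fruit" against an observed
genotype-phenotype table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VALID_GENOTYPES = {"A/A", "A/T", "T/A", "T/T"}
VALID_PHENOTYPES = {"flat", "round"}


@dataclass(frozen=True)
class PhasedRegion:
    """Phased haplotypes of the pair over one region.

    Allele vectors are 0 (ref) / 1 (alt) arrays, one entry per site;
    positions are 1-based and strictly increasing.
    """

    positions: np.ndarray
    wild_h1: np.ndarray
    wild_h2: np.ndarray
    sport_h1: np.ndarray
    sport_h2: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.positions)
        for v in (self.wild_h1, self.wild_h2, self.sport_h1, self.sport_h2):
            if len(v) != n:
                raise ValueError("haplotype vectors must all match the number of sites")
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class OriginCall:
    origin: int | None  # wild haplotype index (1 or 2), None if undetermined
    lost: int | None
    duplicated: bool
    matrix: np.ndarray

    def to_dict(self) -> dict:
        return {
            "origin": f"wild_h{self.origin}" if self.origin else "undetermined",
            "lost": f"wild_h{self.lost}" if self.lost else "undetermined",
            "duplicated": self.duplicated,
            "identity_matrix": np.round(self.matrix, 4).tolist(),
        }


def haplotype_identity_matrix(region: PhasedRegion) -> np.ndarray:
    """2x2 matrix: entry (i, j) = fraction of sites where sport haplotype
    i+1 carries the same allele as wild haplotype j+1."""
    if region.n_sites < 1:
        raise ValueError("region must contain at least one site")
    sport = (region.sport_h1, region.sport_h2)
    wild = (region.wild_h1, region.wild_h2)
    return np.array([[float(np.mean(s == w)) for w in wild] for s in sport])


def call_origin(matrix: np.ndarray, min_margin: float = 0.05) -> OriginCall:
    """Decide which wild haplotype both sport haplotypes descend from.

    If each sport haplotype best matches the same wild haplotype with a
    margin of at least ``min_margin`` over the alternative, that haplotype is
    the origin, the other is lost, and duplicated is True.  Otherwise the
    call is undetermined, with duplicated False (normal biparental
    transmission leaves each sport haplotype matching a different parent).
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape != (2, 2):
        raise ValueError("expected a 2x2 identity matrix")
    best = m.argmax(axis=1)
    margins = np.abs(m[:, 0] - m[:, 1])
    if best[0] == best[1] and np.all(margins >= min_margin):
        origin = int(best[0]) + 1
        return OriginCall(origin=origin, lost=3 - origin, duplicated=True, matrix=m)
    return OriginCall(origin=None, lost=None, duplicated=False, matrix=m)


@dataclass(frozen=True)
class DominanceReport:
    n_flat: int
    n_round: int
    flat_with_dominant: int
    flat_with_dominant_fraction: float | None  # None when no flat accessions
    round_all_recessive_hom: bool
    violations: list[str]  # accessions breaking "dominant allele => flat"

    @property
    def flat_with_dominant_pct(self) -> float | str:
        if self.flat_with_dominant_fraction is None:
            return "NA"
        return round(100 * self.flat_with_dominant_fraction, 1)

    def to_dict(self) -> dict:
        return {
            "n_flat": self.n_flat,
            "n_round": self.n_round,
            "flat_with_T": self.flat_with_dominant_pct,
            "round_all_AA": self.round_all_recessive_hom,
            "violations": self.violations,
        }


def dominance_consistency(
    table: pd.DataFrame, dominant_allele: str = "T"
) -> DominanceReport:
    """Test the dominance rule on an (accession, phenotype, genotype) table.

    flat_with_dominant is the share of flat accessions carrying at least one
    dominant allele; round_all_recessive_hom is True iff no round accession
    carries it; violations lists accessions where a dominant allele co-occurs
    with round fruit (the rule "T allele implies flat" broken).
    """
    if len(table) == 0:
        raise ValueError("empty genotype-phenotype table")
    for _, row in table.iterrows():
        if row["genotype"] not in VALID_GENOTYPES:
            raise ValueError(
                f"unknown genotype {row['genotype']!r} for accession {row['accession']!r}"
            )
        if row["phenotype"] not in VALID_PHENOTYPES:
            raise ValueError(
                f"unknown phenotype {row['phenotype']!r} for accession {row['accession']!r}"
            )
    carries = table["genotype"].str.contains(dominant_allele)
    flat = table["phenotype"] == "flat"
    n_flat = int(flat.sum())
    n_round = int((~flat).sum())
    flat_with = int((flat & carries).sum())
    frac = flat_with / n_flat if n_flat else None
    round_carriers = table.loc[~flat & carries, "accession"].tolist()
    # flat accessions without the dominant allele also contradict full
    # dominance-driven determination and are listed alongside
    flat_without = table.loc[flat & ~carries, "accession"].tolist()
    return DominanceReport(
        n_flat=n_flat,
        n_round=n_round,
        flat_with_dominant=flat_with,
        flat_with_dominant_fraction=frac,
        round_all_recessive_hom=len(round_carriers) == 0,
        violations=round_carriers + flat_without,
    )


def read_genotype_phenotype_csv(path: str | Path) -> pd.DataFrame:
    """Read an (accession, phenotype, genotype) CSV."""
    df = pd.read_csv(path)
    missing = {"accession", "phenotype", "genotype"} - set(df.columns)
    if missing:
        raise ValueError(f"genotype-phenotype CSV lacks columns {sorted(missing)}")
    return df


def read_phased_region(
    path: str | Path,
    sample_names: tuple[str, str],
    region: tuple[str, int, int] | None = None,
) -> PhasedRegion:
    """Load a PhasedRegion from a VCF with phased (pipe-separated) genotypes.

    Only biallelic SNPs with phased calls in both samples are used; sites
    with unphased or missing genotypes are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    for s in sample_names:
        if s not in vcf.samples:
            raise ValueError(f"sample {s!r} not in {path}; available: {vcf.samples}")
    iw = vcf.samples.index(sample_names[0])
    isp = vcf.samples.index(sample_names[1])
    pos, w1, w2, s1, s2 = [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        if region is not None:
            scaffold, start, end = region
            if v.CHROM != scaffold or not (start <= v.POS <= end):
                continue
        gw = v.genotypes[iw]  # [a, b, phased]
        gs = v.genotypes[isp]
        if not (gw[2] and gs[2]) or min(gw[0], gw[1], gs[0], gs[1]) < 0:
            continue
        pos.append(v.POS)
        w1.append(gw[0])
        w2.append(gw[1])
        s1.append(gs[0])
        s2.append(gs[1])
    vcf.close()
    return PhasedRegion(
        positions=np.array(pos, dtype=np.int64),
        wild_h1=np.array(w1, dtype=np.int8),
        wild_h2=np.array(w2, dtype=np.int8),
        sport_h1=np.array(s1, dtype=np.int8),
        sport_h2=np.array(s2, dtype=np.int8),
    )
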