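"""Study constants for the flat-peach bud-sport comparison.

The reference system is the peach (*Prunus persica*) genome v2.0 with eight
chromosome-scale scaffolds Pp01-Pp08.  A wild-type flat peach and its
round-fruit bud sport were whole-genome sequenced (~28x / ~26x) and a single
long copy-neutral LOH event was found on the distal end of scaffold Pp06.
These constants parameterize the synthetic generator and serve as printed
inputs to the discordance arithmetic.
"""

from __future__ import annotations

import pandas as pd

#: (scaffold id, length in bp) for the eight main scaffolds.
SCAFFOLDS: list[tuple[str, int]] = [
    ("Pp01", 47_851_208),
    ("Pp02", 30_405_870),
    ("Pp03", 27_368_013),
    ("Pp04", 25_843_236),
    ("Pp05", 18_496_696),
    ("Pp06", 30_767_194),
    ("Pp07", 22_388_614),
    ("Pp08", 22_573_980),
]

GENOME_SIZE: int = 225_694_811
assert sum(length for _, length in SCAFFOLDS) == GENOME_SIZE

#: High-quality called SNPs per scaffold in the wild-type/sport pair.
SNP_COUNTS: dict[str, int] = {
    "Pp01": 35_297,
    "Pp02": 63_329,
    "Pp03": 23_281,
    "Pp04": 21_835,
    "Pp05": 24_476,
    "Pp06": 35_486,
    "Pp07": 26_451,
    "Pp08": 7_101,
}

#: SNPs on unplaced scaffolds (reported without rates).
UNPLACED_SNPS: int = 220

TOTAL_SNPS: int = 237_476
assert sum(SNP_COUNTS.values()) + UNPLACED_SNPS == TOTAL_SNPS

#: Background genotype discordances per scaffold between the pair, i.e. the
#: empirical genotyping-error floor outside the LOH event.
BACKGROUND_DISCORDANCE: dict[str, int] = {
    "Pp01": 7,
    "Pp02": 54,
    "Pp03": 6,
    "Pp04": 10,
    "Pp05": 4,
    "Pp06": 14,
    "Pp07": 7,
    "Pp08": 0,
}

#: Double-haploid self-comparison control (empirical SNP-calling error floor):
#: heterozygous inconsistencies (paralog misalignment candidates) and
#: homozygous inconsistencies (putative reference-assembly errors).
CONTROL_HET_DISCORDANCE: int = 58
CONTROL_HOM_DISCORDANCE: int = 397

# --- the Pp06 LOH event -----------------------------------------------------

EVENT_SCAFFOLD: str = "Pp06"
#: Het->hom transition locus (bp) on Pp06; the event runs from here to the
#: telomere.
BREAKPOINT_BP: int = 22_195_188
#: First discordant SNP of the event; the distal interval spans from here to
#: the scaffold end (8,564,807 bp).
DISTAL_START_BP: int = 22_202_387
DISTAL_SPAN_BP: int = 8_564_807
assert SCAFFOLDS[5][1] - DISTAL_START_BP == DISTAL_SPAN_BP

#: Distal-interval SNP composition in the wild type: only het and hom-variant
#: genotypes occur there.
DISTAL_SNPS: int = 10_515
DISTAL_HET_WILD: int = 8_501
DISTAL_HOM_WILD: int = 2_014
#: Concordant-het sites inside the event (het false negatives of the pipeline).
DISTAL_HET_DROPOUT: int = 36
assert DISTAL_HET_WILD + DISTAL_HOM_WILD == DISTAL_SNPS

PROXIMAL_SNPS: int = SNP_COUNTS["Pp06"] - DISTAL_SNPS  # 24,971

#: Mean sequencing depths of the two samples.
DEPTH_MEAN_WILD: float = 28.0
DEPTH_MEAN_SPORT: float = 26.0

#: Fruit-shape marker SNP (sixth intron of Prupe.6G292200); the T allele is
#: dominant and determines flat fruit.
MARKER_POS_BP: int = 26_924_482
MARKER_DOMINANT_ALLELE: str = "T"


def scaffold_table() -> pd.DataFrame:
    """The eight-scaffold length table as a DataFrame (scaffold, length)."""
    return pd.DataFrame(SCAFFOLDS, columns=["scaffold", "length"])


def gwas_genotype_phenotype() -> pd.DataFrame:
    """Observed marker genotypes vs fruit shape in the 105-accession GWAS panel.

    12 flat accessions (10 A/T, 1 T/T, 1 A/A) and 93 round accessions, all A/A.
    """
    rows = []
    for i in range(10):
        rows.append((f"flat_{i + 1:03d}", "flat", "A/T"))
    rows.append(("flat_011", "flat", "T/T"))
    rows.append(("flat_012", "flat", "A/A"))
    for i in range(93):
        rows.append((f"round_{i + 1:03d}", "round", "A/A"))
    return pd.DataFrame(rows, columns=["accession", "phenotype", "genotype"])


def validation_genotype_phenotype() -> pd.DataFrame:
    """Marker genotypes in the independent 258-accession validation panel.

    22 flat accessions (all A/T) and 236 round accessions (all A/A).
    """
    rows = [(f"vflat_{i + 1:03d}", "flat", "A/T") for i in range(22)]
    rows += [(f"vround_{i + 1:03d}", "round", "A/A") for i in range(236)]
    return pd.DataFrame(rows, columns=["accession", "phenotype", "genotype"])
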