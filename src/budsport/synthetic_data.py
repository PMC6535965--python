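"""Synthetic paired wild-type/bud-sport callsets with planted somatic events.

Emulates the study system: a diploid genome of eight chromosome-scale
scaffolds with the observed per-scaffold SNP counts, the observed
heterozygosity composition of the event interval (8,501 het + 2,014
hom-variant sites distal to the breakpoint), background genotyping errors at
the observed per-scaffold counts, overdispersed sequencing depth around
28x/26x, and a configurable somatic event: copy-neutral LOH from a
breakpoint to the telomere, hemizygous deletion of the same interval, or
none.

Break-induced replication timing is modelled explicitly: repair in G1 yields
a single daughter-cell class (all homozygous distal to the break), repair in
G2 yields two classes (het and hom) so a sampled tissue can be a mosaic; the
``mosaic_fraction`` parameter sets the share of mutant-lineage cells in the
sport sample and mosaic genotypes are re-called from binomially sampled
allele depths.

All output is a deterministic function of the seed.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import peach
from .haplotype_trace import PhasedRegion

EVENTS = ("none", "loh_copy_neutral", "hemizygous_deletion")
MECHANISMS = ("G1", "G2")

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1"}
_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the paired-callset generator.

    Defaults reproduce the study conditions: the eight peach scaffolds with
    their SNP counts, the distal-Pp06 composition, breakpoint 22,195,188 bp,
    36 het dropouts inside the event, per-scaffold background error counts,
    and 28x/26x mean depths.  Depths are negative-binomial; the default
    dispersion of 200 is mildly overdispersed beyond Poisson, putting ~93%
    of per-site depth ratios in the [0.5, 1.5] band at these coverages
    (close to the ~95% share seen in the study system).
    """

    seed: int = 0
    scaffolds: tuple[tuple[str, int], ...] = tuple(peach.SCAFFOLDS)
    snp_counts: dict[str, int] = field(default_factory=lambda: dict(peach.SNP_COUNTS))
    background_errors: dict[str, int] = field(
        default_factory=lambda: dict(peach.BACKGROUND_DISCORDANCE)
    )
    het_fraction_wild: float = peach.DISTAL_HET_WILD / peach.DISTAL_SNPS
    event: str = "loh_copy_neutral"
    event_scaffold: str = peach.EVENT_SCAFFOLD
    breakpoint_bp: int = peach.BREAKPOINT_BP
    mechanism: str = "G1"
    mosaic_fraction: float = 1.0
    genotype_error_rate: float | None = None  # Bernoulli mode when set
    het_dropout_count: int = peach.DISTAL_HET_DROPOUT
    distal_snps: int = peach.DISTAL_SNPS
    distal_het: int = peach.DISTAL_HET_WILD
    depth_mean_wild: float = peach.DEPTH_MEAN_WILD
    depth_mean_sport: float = peach.DEPTH_MEAN_SPORT
    depth_dispersion: float = 200.0

    def __post_init__(self) -> None:
        if self.event not in EVENTS:
            raise ValueError(f"event must be one of {EVENTS}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ValueError("mosaic_fraction must be in [0, 1]")
        if not 0.0 <= self.het_fraction_wild <= 1.0:
            raise ValueError("het_fraction_wild must be in [0, 1]")
        if self.het_dropout_count < 0 or self.distal_snps < 0:
            raise ValueError("counts must be non-negative")
        names = dict(self.scaffolds)
        if self.event != "none":
            if self.event_scaffold not in names:
                raise ValueError(
                    f"event scaffold {self.event_scaffold!r} not in scaffold table"
                )
            if not 1 <= self.breakpoint_bp < names[self.event_scaffold]:
                raise ValueError("breakpoint must lie within the event scaffold")

    @classmethod
    def pp06_preset(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Event scaffold only: fast single-scaffold runs for scan and
        depth-ratio studies (35,486 sites)."""
        cfg = cls(
            seed=seed,
            scaffolds=(peach.SCAFFOLDS[5],),
            snp_counts={"Pp06": peach.SNP_COUNTS["Pp06"]},
            background_errors={"Pp06": peach.BACKGROUND_DISCORDANCE["Pp06"]},
        )
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SimResult:
    """In-memory simulation output: coded site table plus ground truth."""

    config: SimConfig
    sites: pd.DataFrame  # scaffold,pos,ref,alt,code_wild,code_sport,dp_*,gq_*,QD..
    truth: dict
    # planted phase over the distal event interval
    phase_positions: np.ndarray | None = None
    phase_wild_h1: np.ndarray | None = None
    phase_wild_h2: np.ndarray | None = None


def _sample_positions(rng: np.random.Generator, lo: int, hi: int, n: int) -> np.ndarray:
    """n distinct sorted integer positions in [lo, hi]."""
    if hi - lo + 1 < n:
        raise ValueError("interval too small for requested SNP count")
    pos = np.unique(rng.integers(lo, hi + 1, size=int(n * 1.05) + 16))
    while len(pos) < n:
        extra = rng.integers(lo, hi + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    if len(pos) > n:
        pos = np.sort(rng.choice(pos, size=n, replace=False))
    return pos.astype(np.int64)


def _negbin(rng: np.random.Generator, mean: np.ndarray | float, k: float, size: int):
    """Overdispersed depths: NB with mean m and dispersion k (var = m + m^2/k)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    p = k / (k + mean)
    return rng.negative_binomial(k, p).astype(np.int64)


def _call_from_allele_depth(alt: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Hard genotype call from alt-read counts: hom thresholds at 25%/75%
    alt fraction (zero-depth sites call homozygous reference)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(dp > 0, alt / np.maximum(dp, 1), 0.0)
    code = np.ones(len(alt), dtype=np.int64)
    code[frac <= 0.25] = 0
    code[frac >= 0.75] = 2
    return code


def simulate(config: SimConfig) -> SimResult:
    """Generate the paired coded callset and ground-truth record."""
    rng = np.random.default_rng(config.seed)
    scaffold_len = dict(config.scaffolds)
    frames = []
    truth: dict = {
        "event": config.event,
        "mechanism": config.mechanism,
        "event_scaffold": config.event_scaffold,
        "breakpoint_bp": config.breakpoint_bp,
        "mosaic_fraction": config.mosaic_fraction,
        "retained_haplotype": None,
        "dropout_positions": [],
        "error_positions": {},
        "distal_first_snp": None,
        "distal_last_snp": None,
        "hemizygous": config.event == "hemizygous_deletion",
    }
    phase_positions = phase_h1 = phase_h2 = None
    retained = int(rng.integers(2))  # 0-based index of the retained wild haplotype
    truth["retained_haplotype"] = retained + 1

    for scaffold, length in config.scaffolds:
        n = config.snp_counts[scaffold]
        is_event_scaffold = scaffold == config.event_scaffold
        if is_event_scaffold:
            n_distal = config.distal_snps
            n_prox = n - n_distal
            pos_prox = _sample_positions(rng, 1, config.breakpoint_bp, n_prox)
            pos_dist = _sample_positions(rng, config.breakpoint_bp + 1, length, n_distal)
            pos = np.concatenate([pos_prox, pos_dist])
        else:
            pos = _sample_positions(rng, 1, length, n)
        distal = pos > config.breakpoint_bp if is_event_scaffold else np.zeros(n, bool)

        # wild genotypes: the callset contains het and hom-variant sites; the
        # event interval gets its exact observed composition, elsewhere the
        # het share is Bernoulli at the same fraction
        code_wild = np.where(
            rng.random(n) < config.het_fraction_wild, 1, 2
        ).astype(np.int64)
        if is_event_scaffold:
            comp = np.concatenate(
                [
                    np.ones(config.distal_het, dtype=np.int64),
                    np.full(config.distal_snps - config.distal_het, 2, dtype=np.int64),
                ]
            )
            code_wild[distal] = rng.permutation(comp)

        # depths (deletion halves expected sport depth over the lost interval)
        dp_wild = _negbin(rng, config.depth_mean_wild, config.depth_dispersion, n)
        sport_mean = np.full(n, config.depth_mean_sport)
        if config.event == "hemizygous_deletion" and is_event_scaffold:
            sport_mean[distal] /= 2.0
        dp_sport = _negbin(rng, sport_mean, config.depth_dispersion, n)

        # planted phase over the distal interval: at het sites the variant
        # allele rides one haplotype at random; hom-variant sites carry it on
        # both
        code_sport = code_wild.copy()
        if is_event_scaffold:
            h1 = np.where(code_wild[distal] == 2, 1, 0).astype(np.int8)
            h2 = h1.copy()
            het_d = code_wild[distal] == 1
            on_h1 = rng.random(int(het_d.sum())) < 0.5
            h1[np.flatnonzero(het_d)[on_h1]] = 1
            h2[np.flatnonzero(het_d)[~on_h1]] = 1
            phase_positions = pos[distal]
            phase_h1, phase_h2 = h1, h2
            retained_allele = (h1 if retained == 0 else h2).astype(np.int64)

            if config.event != "none":
                het_idx = np.flatnonzero(distal & (code_wild == 1))
                pure = config.mechanism == "G1" or config.mosaic_fraction >= 1.0
                if pure or config.event == "hemizygous_deletion":
                    # every distal het becomes homozygous for the retained
                    # haplotype's allele
                    ra = retained_allele[code_wild[distal] == 1]
                    code_sport[het_idx] = np.where(ra == 1, 2, 0)
                    # het dropouts: calling false negatives left concordant-het
                    # inside the event (interior sites, so the configured count
                    # is realized as in-segment interruptions)
                    k = min(config.het_dropout_count, max(len(het_idx) - 2, 0))
                    if k > 0:
                        interior = het_idx[1:-1]
                        drop = rng.choice(interior, size=k, replace=False)
                        code_sport[drop] = 1
                        truth["dropout_positions"] = sorted(int(p) for p in pos[drop])
                else:
                    # G2 mosaic: the sampled tissue mixes mutant (hom) and
                    # normal (het) lineages; re-call genotypes from binomially
                    # sampled allele depths of the mixture
                    f = config.mosaic_fraction
                    ra = retained_allele[code_wild[distal] == 1]
                    p_alt = f * ra + (1.0 - f) * 0.5
                    dp = dp_sport[het_idx]
                    alt_reads = rng.binomial(dp, p_alt)
                    code_sport[het_idx] = _call_from_allele_depth(alt_reads, dp)
                truth["distal_first_snp"] = int(pos[distal][0])
                truth["distal_last_snp"] = int(pos[distal][-1])

        # background genotyping errors: planted counts (or Bernoulli when a
        # rate is configured); never inside the event interval, whose
        # discordance is purely the event by construction
        eligible = np.flatnonzero(~distal)
        if config.genotype_error_rate is not None:
            k_err = int(rng.binomial(len(eligible), config.genotype_error_rate))
        else:
            k_err = config.background_errors.get(scaffold, 0)
        if k_err > 0 and len(eligible):
            err_idx = rng.choice(eligible, size=min(k_err, len(eligible)), replace=False)
            shift = rng.integers(1, 3, size=len(err_idx))
            code_sport[err_idx] = (code_sport[err_idx] + shift) % 3
            truth["error_positions"][scaffold] = sorted(int(p) for p in pos[err_idx])

        allele_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
        gq_wild = rng.integers(60, 100, size=n)
        gq_sport = rng.integers(60, 100, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaffold,
                    "pos": pos,
                    "ref": [_ALLELE_PAIRS[i][0] for i in allele_idx],
                    "alt": [_ALLELE_PAIRS[i][1] for i in allele_idx],
                    "code_wild": code_wild,
                    "code_sport": code_sport,
                    "dp_wild": dp_wild,
                    "dp_sport": dp_sport,
                    "gq_wild": gq_wild,
                    "gq_sport": gq_sport,
                    "QD": np.round(rng.uniform(15, 35, size=n), 2),
                    "MQ": 60.0,
                    "FS": np.round(rng.uniform(0, 5, size=n), 3),
                    "MQRankSum": np.round(rng.uniform(-0.03, 0.03, size=n), 3),
                    "ReadPosRankSum": np.round(rng.uniform(-1.2, 1.2, size=n), 3),
                    "SOR": np.round(rng.uniform(0.5, 1.5, size=n), 3),
                    "ClippingRankSum": np.round(rng.uniform(-0.25, 0.25, size=n), 3),
                }
            )
        )

    sites = pd.concat(frames, ignore_index=True)
    return SimResult(
        config=config,
        sites=sites,
        truth=truth,
        phase_positions=phase_positions,
        phase_wild_h1=phase_h1,
        phase_wild_h2=phase_h2,
    )


# --- mechanism model --------------------------------------------------------


def simulate_cell_lineage(
    mechanism: str, n_daughters: int, rng: np.random.Generator | int | None = None
) -> Counter:
    """Distribution of daughter-cell genotype classes after break-induced
    replication.

    Repair in G1 precedes replication, so every daughter is homozygous
    distal to the break (one class).  Repair in G2 fixes only one chromatid,
    so the first division yields one het and one hom daughter; later
    daughters descend from either lineage with equal probability (two
    classes at expected frequency 1/2 each).
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"mechanism must be one of {MECHANISMS}")
    if n_daughters < 2:
        raise ValueError("n_daughters must be >= 2")
    if mechanism == "G1":
        return Counter({"hom": n_daughters})
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_het = 1 + int(rng.binomial(n_daughters - 2, 0.5)) if n_daughters > 2 else 1
    return Counter({"het": n_het, "hom": n_daughters - n_het})


# --- phased truth -----------------------------------------------------------


def emit_phased_truth(source: SimConfig | SimResult) -> PhasedRegion:
    """Phased haplotypes over the event interval, from the planted truth.

    Both sport haplotypes equal the retained wild haplotype (copy-neutral
    LOH duplicates it; a hemizygous deletion leaves a single copy of it,
    emitted on both rows and flagged hemizygous in the truth record).
    """
    result = simulate(source) if isinstance(source, SimConfig) else source
    if result.config.event == "none":
        raise ValueError("no event configured: there is no event interval to phase")
    retained = result.truth["retained_haplotype"] - 1
    sport = (result.phase_wild_h1 if retained == 0 else result.phase_wild_h2).copy()
    return PhasedRegion(
        positions=result.phase_positions,
        wild_h1=result.phase_wild_h1,
        wild_h2=result.phase_wild_h2,
        sport_h1=sport,
        sport_h2=sport.copy(),
    )


# --- VCF emission -----------------------------------------------------------

_INFO_HEADERS = [
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand phred p">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQ rank sum">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
    '##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio">',
    '##INFO=<ID=ClippingRankSum,Number=1,Type=Float,Description="Clipping rank sum">',
]
_FORMAT_HEADERS = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
]


def _vcf_header(scaffolds, samples: list[str]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=budsport_synthetic"]
    lines += [f"##contig=<ID={name},length={length}>" for name, length in scaffolds]
    lines += _INFO_HEADERS + _FORMAT_HEADERS
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    return "\n".join(lines) + "\n"


def _info_str(row) -> str:
    return (
        f"QD={row.QD:.2f};MQ={row.MQ:.2f};FS={row.FS:.3f};"
        f"MQRankSum={row.MQRankSum:.3f};ReadPosRankSum={row.ReadPosRankSum:.3f};"
        f"SOR={row.SOR:.3f};ClippingRankSum={row.ClippingRankSum:.3f}"
    )


def write_vcf(
    result: SimResult, path: str | Path, samples: tuple[str, ...] = ("WILD", "SPORT")
) -> None:
    """Write the simulated pair as a two-sample VCF 4.2 (or a single-sample
    VCF when one sample name is given)."""
    sites = result.sites
    cols = {"WILD": ("code_wild", "dp_wild", "gq_wild"), "SPORT": ("code_sport", "dp_sport", "gq_sport")}
    with open(path, "w") as fh:
        fh.write(_vcf_header(result.config.scaffolds, list(samples)))
        for row in sites.itertuples(index=False):
            fields = [
                row.scaffold,
                str(row.pos),
                ".",
                row.ref,
                row.alt,
                "100",
                "PASS",
                _info_str(row),
                "GT:DP:GQ",
            ]
            for s in samples:
                code_col, dp_col, gq_col = cols[s]
                code = getattr(row, code_col)
                fields.append(
                    f"{_GT_STR[code]}:{getattr(row, dp_col)}:{getattr(row, gq_col)}"
                )
            fh.write("\t".join(fields) + "\n")


def write_phased_vcf(
    result: SimResult, path: str | Path, samples: tuple[str, str] = ("WILD", "SPORT")
) -> None:
    """Write the planted phase over the event interval as a phased VCF."""
    region = emit_phased_truth(result)
    cfg = result.config
    sites = result.sites
    ev = sites[
        (sites["scaffold"] == cfg.event_scaffold) & (sites["pos"] > cfg.breakpoint_bp)
    ].reset_index(drop=True)
    assert len(ev) == region.n_sites
    with open(path, "w") as fh:
        fh.write(_vcf_header(cfg.scaffolds, list(samples)))
        for i, row in enumerate(ev.itertuples(index=False)):
            gt_w = f"{region.wild_h1[i]}|{region.wild_h2[i]}"
            gt_s = f"{region.sport_h1[i]}|{region.sport_h2[i]}"
            fh.write(
                f"{row.scaffold}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t100\tPASS\t"
                f"{_info_str(row)}\tGT\t{gt_w}\t{gt_s}\n"
            )


def simulate_pair(
    config: SimConfig,
    out_dir: str | Path,
    split: bool = False,
) -> dict:
    """Run the generator and write VCF(s), the scaffold table, and the truth
    record to ``out_dir``.  Returns the paths plus the truth dict.

    With ``split`` the pair is written as two single-sample VCFs, otherwise
    as one two-sample VCF.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = simulate(config)
    paths: dict = {"truth": out_dir / "truth.json", "scaffolds": out_dir / "scaffolds.tsv"}
    if split:
        paths["wild_vcf"] = out_dir / "wild.vcf"
        paths["sport_vcf"] = out_dir / "sport.vcf"
        write_vcf(result, paths["wild_vcf"], samples=("WILD",))
        write_vcf(result, paths["sport_vcf"], samples=("SPORT",))
    else:
        paths["pair_vcf"] = out_dir / "pair.vcf"
        write_vcf(result, paths["pair_vcf"])
    if config.event != "none":
        paths["phased_vcf"] = out_dir / "phased_truth.vcf"
        write_phased_vcf(result, paths["phased_vcf"])
    with open(paths["scaffolds"], "w") as fh:
        for name, length in config.scaffolds:
            fh.write(f"{name}\t{length}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(result.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"paths": {k: str(v) for k, v in paths.items()}, "truth": result.truth}
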