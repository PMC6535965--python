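"""VCF input, hard filtering, and interval output for the paired comparison.

Reads paired-sample genotype data (one two-sample VCF or two single-sample
VCFs) into SiteRecord rows, applies the GATK-style hard-filter thread plus
per-genotype quality gates, and writes called segments as BED.

All coordinates are 1-based inclusive internally; conversion to BED's
0-based half-open convention happens only in the writer.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

from .discordance import MISSING, code_genotype

logger = logging.getLogger(__name__)

INFO_METRICS = ("QD", "MQ", "FS", "MQRankSum", "ReadPosRankSum", "SOR", "ClippingRankSum")

_BASES = frozenset("ACGT")


@dataclass
class SiteRecord:
    """One biallelic SNP site in the wild-type/sport pair."""

    scaffold: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    gt_wild: tuple[int, int] | None
    gt_sport: tuple[int, int] | None
    dp_wild: int | None = None
    dp_sport: int | None = None
    gq_wild: int | None = None
    gq_sport: int | None = None
    info: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(f"non-SNP alleles {self.ref_allele}>{self.alt_allele}")
        for v in (self.dp_wild, self.dp_sport, self.gq_wild, self.gq_sport):
            if v is not None and v < 0:
                raise ValueError("depth and GQ must be non-negative")


@dataclass(frozen=True)
class HardFilterThresholds:
    """Site- and genotype-level gates of the hard-filter thread.

    A site fails if QD < qd_min, MQ outside (mq_low, mq_high), FS > fs_max,
    |MQRankSum| > mqranksum_abs_max, ReadPosRankSum < readposranksum_min
    (also > -readposranksum_min when two-sided), SOR > sor_max,
    |ClippingRankSum| > clippingranksum_abs_max, any GQ < gq_min, or any
    genotype missing (when require_complete).
    """

    qd_min: float = 10.0
    mq_low: float = 59.9
    mq_high: float = 60.1
    fs_max: float = 15.0
    mqranksum_abs_max: float = 0.04
    readposranksum_min: float = -1.5
    rprs_one_sided: bool = True
    sor_max: float = 2.0
    clippingranksum_abs_max: float = 0.3
    gq_min: int = 20
    require_complete: bool = True

    def __post_init__(self) -> None:
        if not self.mq_low < self.mq_high:
            raise ValueError("mq_low must be < mq_high")


# first-failure attribution order
FILTER_RULES = (
    "QD",
    "MQ_low",
    "MQ_high",
    "FS",
    "MQRankSum",
    "ReadPosRankSum",
    "SOR",
    "ClippingRankSum",
    "GQ",
    "missing_genotype",
)


def _failing_rule(rec: SiteRecord, thr: HardFilterThresholds) -> str | None:
    """First rule a site fails, or None if it passes.

    An absent INFO metric means the corresponding rule cannot fire (GATK
    convention); the leniency is logged at debug level by the caller.
    """
    info = rec.info

    def has(k: str) -> bool:
        v = info.get(k)
        return v is not None and v == v  # NaN-safe

    if has("QD") and info["QD"] < thr.qd_min:
        return "QD"
    if has("MQ"):
        if info["MQ"] < thr.mq_low:
            return "MQ_low"
        if info["MQ"] > thr.mq_high:
            return "MQ_high"
    if has("FS") and info["FS"] > thr.fs_max:
        return "FS"
    if has("MQRankSum") and abs(info["MQRankSum"]) > thr.mqranksum_abs_max:
        return "MQRankSum"
    if has("ReadPosRankSum"):
        v = info["ReadPosRankSum"]
        if v < thr.readposranksum_min:
            return "ReadPosRankSum"
        if not thr.rprs_one_sided and v > -thr.readposranksum_min:
            return "ReadPosRankSum"
    if has("SOR") and info["SOR"] > thr.sor_max:
        return "SOR"
    if has("ClippingRankSum") and abs(info["ClippingRankSum"]) > thr.clippingranksum_abs_max:
        return "ClippingRankSum"
    for gq in (rec.gq_wild, rec.gq_sport):
        if gq is not None and gq < thr.gq_min:
            return "GQ"
    if thr.require_complete:
        for gt in (rec.gt_wild, rec.gt_sport):
            if gt is None or code_genotype(gt) == MISSING:
                return "missing_genotype"
    return None


def apply_hard_filters(
    sites: Iterable[SiteRecord], thr: HardFilterThresholds | None = None
) -> tuple[list[SiteRecord], Counter]:
    """Split sites into those passing the full filter thread and per-rule
    fail counts (first-failure attribution in FILTER_RULES order)."""
    thr = thr or HardFilterThresholds()
    passing: list[SiteRecord] = []
    fails: Counter = Counter()
    n_lenient = 0
    for rec in sites:
        missing_metrics = [m for m in INFO_METRICS if rec.info.get(m) is None]
        if missing_metrics:
            n_lenient += 1
        rule = _failing_rule(rec, thr)
        if rule is None:
            passing.append(rec)
        else:
            fails[rule] += 1
    if n_lenient:
        logger.info("absent INFO metrics at %d sites; those rules did not fire", n_lenient)
    return passing, fails


# --- VCF reading ------------------------------------------------------------


def _gt_tuple(gts: Sequence) -> tuple[int, int] | None:
    a, b = int(gts[0]), int(gts[1])
    if a < 0 or b < 0:
        return None
    return (a, b)


def _fmt_scalar(vcf: VCF, variant, key: str, idx: int) -> int | None:
    try:
        arr = variant.format(key)
    except KeyError:
        return None
    if arr is None:
        return None
    v = arr[idx]
    try:
        v = int(v[0]) if hasattr(v, "__len__") else int(v)
    except (TypeError, ValueError):
        return None
    return v if v >= 0 else None


def _read_one_vcf(path: str | Path, sample: str) -> tuple[dict, Counter]:
    """Read biallelic SNPs from one VCF for one sample.

    Returns a mapping (scaffold, pos, ref, alt) -> (gt, dp, gq, info) in file
    order, plus a skip summary.
    """
    vcf = VCF(str(path))
    if sample not in vcf.samples:
        raise ValueError(
            f"sample {sample!r} not in {path}; available samples: {vcf.samples}"
        )
    idx = vcf.samples.index(sample)
    out: dict = {}
    skips: Counter = Counter()
    last: dict[str, int] = {}
    for v in vcf:
        if len(v.ALT) != 1:
            skips["multiallelic"] += 1
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            skips["indel"] += 1
            continue
        pos = v.POS
        if v.CHROM in last and pos < last[v.CHROM]:
            raise ValueError(
                f"unsorted VCF {path}: {v.CHROM}:{pos} after {v.CHROM}:{last[v.CHROM]}"
            )
        last[v.CHROM] = pos
        info = {}
        for k in INFO_METRICS:
            val = v.INFO.get(k)
            if val is not None:
                info[k] = float(val)
        gt = _gt_tuple(v.genotypes[idx][:2])
        dp = _fmt_scalar(vcf, v, "DP", idx)
        gq = _fmt_scalar(vcf, v, "GQ", idx)
        out[(v.CHROM, pos, ref, alt)] = (gt, dp, gq, info)
    vcf.close()
    return out, skips


def read_pair_vcf(
    path_or_paths: str | Path | Sequence[str | Path],
    sample_names: tuple[str, str],
) -> tuple[list[SiteRecord], Counter]:
    """Read the wild-type/sport pair into SiteRecords plus a skip summary.

    Accepts either a single two-sample VCF or a pair of single-sample VCFs.
    For two files, sites are matched on (scaffold, pos, ref, alt); positions
    present in only one file, or with mismatched alleles, are dropped and
    counted in the skip summary.  Only biallelic SNPs are kept.
    """
    wild_name, sport_name = sample_names
    if isinstance(path_or_paths, (str, Path)):
        paths = [path_or_paths, path_or_paths]
    else:
        paths = list(path_or_paths)
        if len(paths) == 1:
            paths = [paths[0], paths[0]]
        elif len(paths) != 2:
            raise ValueError("expected one or two VCF paths")

    wild_map, skips_w = _read_one_vcf(paths[0], wild_name)
    sport_map, skips_s = _read_one_vcf(paths[1], sport_name)
    skips = skips_w if paths[1] == paths[0] else skips_w + skips_s

    common = [k for k in wild_map if k in sport_map]
    skips["wild_only"] = len(wild_map) - len(common)
    skips["sport_only"] = len(sport_map) - len(common)
    # allele-mismatched positions: same (scaffold,pos) but different alleles
    wild_pos = {k[:2] for k in wild_map}
    sport_pos = {k[:2] for k in sport_map}
    common_full = {k[:2] for k in common}
    skips["allele_mismatch"] = len((wild_pos & sport_pos) - common_full)

    records = []
    for key in sorted(common, key=lambda k: (k[0], k[1])):
        scaffold, pos, ref, alt = key
        gt_w, dp_w, gq_w, info_w = wild_map[key]
        gt_s, dp_s, gq_s, info_s = sport_map[key]
        info = dict(info_w)
        info.update({k: v for k, v in info_s.items() if k not in info})
        records.append(
            SiteRecord(
                scaffold=scaffold,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                gt_wild=gt_w,
                gt_sport=gt_s,
                dp_wild=dp_w,
                dp_sport=dp_s,
                gq_wild=gq_w,
                gq_sport=gq_s,
                info=info,
            )
        )
    return records, skips


def records_to_frame(records: Iterable[SiteRecord]) -> pd.DataFrame:
    """Code SiteRecords into the tabular form the downstream modules use."""
    rows = [
        (
            r.scaffold,
            r.pos,
            code_genotype(r.gt_wild),
            code_genotype(r.gt_sport),
            r.dp_wild if r.dp_wild is not None else 0,
            r.dp_sport if r.dp_sport is not None else 0,
        )
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["scaffold", "pos", "code_wild", "code_sport", "dp_wild", "dp_sport"]
    )


def read_scaffold_table(path: str | Path) -> pd.DataFrame:
    """Read a two-column (scaffold, length) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["scaffold", "length"], comment="#")
    if (df["length"] <= 0).any():
        raise ValueError("scaffold lengths must be positive")
    if df["scaffold"].duplicated().any():
        raise ValueError("duplicate scaffold ids")
    return df


# --- BED output -------------------------------------------------------------


def write_segments_bed(segments: Sequence, out: str | Path) -> None:
    """Write LOH segments as BED (0-based, half-open).

    Input coordinates are 1-based inclusive, so start is shifted by -1 and
    end is kept.  The name column encodes the segment type; ordering is
    deterministic (scaffold, then start).  Overlapping segments on one
    scaffold are an error: merge before writing.
    """
    segs = sorted(segments, key=lambda s: (s.scaffold, s.start))
    for a, b in zip(segs, segs[1:]):
        if a.scaffold == b.scaffold and b.start <= a.end:
            raise ValueError(
                f"overlapping segments on {a.scaffold}: "
                f"{a.start}-{a.end} and {b.start}-{b.end}"
            )
    with open(out, "w") as fh:
        for s in segs:
            name = getattr(s, "segment_type", "loh")
            fh.write(f"{s.scaffold}\t{s.start - 1}\t{s.end}\t{name}\n")


def read_segments_bed(path: str | Path) -> pd.DataFrame:
    """Parse a BED written by write_segments_bed back to 1-based inclusive
    coordinates (round-trip helper)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["scaffold", "bed_start", "bed_end", "name"]
    )
    df["start"] = df["bed_start"] + 1
    df["end"] = df["bed_end"]
    return df[["scaffold", "start", "end", "name"]]
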