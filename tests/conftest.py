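from __future__ import annotations

import pytest

from budsport import synthetic_data as sd


def make_small_config(seed: int = 0, **overrides) -> sd.SimConfig:
    """A miniature single-scaffold study: 400 SNPs on a 1 Mb scaffold with a
    planted event distal to 600 kb (150 sites, 120 het, 5 dropouts)."""
    base = dict(
        seed=seed,
        scaffolds=(("chrA", 1_000_000),),
        snp_counts={"chrA": 400},
        background_errors={"chrA": 2},
        event_scaffold="chrA",
        breakpoint_bp=600_000,
        distal_snps=150,
        distal_het=120,
        het_dropout_count=5,
    )
    base.update(overrides)
    return sd.SimConfig(**base)


@pytest.fixture(scope="session")
def pp06_result() -> sd.SimResult:
    """One realization of the full event-scaffold preset."""
    return sd.simulate(sd.SimConfig.pp06_preset(seed=0))


@pytest.fixture
def small_config():
    return make_small_config


def write_vcf_text(path, body_rows, samples=("WILD", "SPORT"), contigs=(("chrA", 1_000_000),)):
    """Write a minimal hand-crafted VCF for reader tests.

    body_rows: iterable of (chrom, pos, ref, alt, gt_wild, gt_sport) or full
    pre-formatted tab-joined strings.
    """
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in contigs]
    lines += [
        '##INFO=<ID=QD,Number=1,Type=Float,Description="x">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="x">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="x">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for row in body_rows:
        if isinstance(row, str):
            lines.append(row)
        else:
            chrom, pos, ref, alt, *gts = row
            fields = [chrom, str(pos), ".", ref, alt, "50", "PASS", "QD=20.0;MQ=60.0", "GT:DP:GQ"]
            fields += [f"{gt}:30:99" for gt in gts]
            lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path
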